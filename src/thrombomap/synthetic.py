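"""Idealized fusiform-aneurysm test data with closed-form ground truth.

This module emulates the inputs the analysis pipeline expects from image
segmentation and a CFD solve: a luminal surface, a pulsatile per-vertex
WSS vector field, an outer ILT surface and an inflow waveform. The WSS
field is constructed directly on the surface, in each vertex's tangent
frame, as

    tau(t) = (m + a cos(2 pi t / T)) e_ax + b sin(2 pi t / T) e_circ

with per-vertex parameters (m, a, b) >= 0 (Pa). This family has closed
forms for the indices in the regimes used below, which is what makes the
metric suite testable without a flow solver:

    b = 0, m >= a        : TAWSS = m,          OSI = 0,   TransWSS = 0
    m = b = 0, a > 0     : TAWSS = (2/pi) a,   OSI = 0.5, mean = 0
    a = 0, m > 0         : mean = m e_ax,      TransWSS = (2/pi) b

The default scenario mimics a thrombus-laden fusiform aneurysm: the mean
WSS falls inside the sac as the lumen widens (mass conservation makes
near-wall velocity, hence shear, drop roughly with (R0/R)^2), a posterior
sac patch is purely oscillatory (low TAWSS, OSI = 0.5), an anterior patch
carries a transverse component, and the ILT is thickest on the distal
posterior wall — so favorable-hemodynamics maps and the thick-ILT zone
overlap, as observed in thrombus-laden aneurysms.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import SurfaceMesh
from .thickness import DEFAULT_WALL_MASK_MM
from .waveform import Waveform, fit_waveform
from .wss import WSSField

__all__ = [
    "SyntheticSpec",
    "make_aneurysm_mesh",
    "make_wss_field",
    "make_ilt_surfaces",
    "make_inflow_waveform",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Geometry, field and thickness parameters of the synthetic aneurysm.

    Geometry (mm): a tube of radius ``r0`` and length ``length`` with a
    Gaussian fusiform bulge of amplitude ``bulge_amplitude`` centred at
    ``bulge_center`` with axial width ``bulge_sigma``. AAA-typical scale:
    a 2 cm infrarenal aorta dilated to ~4.4 cm maximum diameter.

    Field (Pa): ``m0`` is the baseline mean WSS in the parent vessel;
    ``osc_amplitude`` and ``trans_amplitude`` set the purely oscillatory
    and transverse patch strengths. ``period`` (s) is the cardiac cycle.

    ILT (mm): Gaussian thickness bump of height ``ilt_peak`` on the
    distal posterior sac plus a ``wall_offset`` everywhere.
    """

    seed: int = 0
    r0: float = 10.0
    bulge_amplitude: float = 12.0
    bulge_center: float = 60.0
    bulge_sigma: float = 15.0
    length: float = 120.0
    n_theta: int = 64
    n_z: int = 96
    period: float = 1.0
    m0: float = 1.2
    osc_amplitude: float = 0.5
    trans_amplitude: float = 0.3
    ilt_peak: float = 19.0
    ilt_sigma_z: float = 20.0
    ilt_sigma_theta: float = 1.4
    wall_offset: float = DEFAULT_WALL_MASK_MM

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.bulge_amplitude < 0:
            raise ValueError("need r0 > 0 and bulge_amplitude >= 0")
        if self.n_theta < 8 or self.n_z < 8:
            raise ValueError("resolution must be at least 8 x 8")
        if min(self.m0, self.osc_amplitude, self.trans_amplitude,
               self.ilt_peak) < 0:
            raise ValueError("field and thickness amplitudes must be >= 0")


def _radius_profile(spec: SyntheticSpec, z: np.ndarray) -> np.ndarray:
    return spec.r0 + spec.bulge_amplitude * np.exp(
        -((z - spec.bulge_center) ** 2) / (2.0 * spec.bulge_sigma**2)
    )


def make_aneurysm_mesh(
    spec: SyntheticSpec, closed: bool = False
) -> tuple[SurfaceMesh, np.ndarray]:
    """Surface of revolution R(z) = r0 + dR exp(-(z-z0)^2 / (2 sigma^2)).

    Triangulated on an ``n_theta x n_z`` grid wrapping in theta. Normals
    are the exact analytic outward normals of the surface of revolution.
    Returns the mesh and a boolean "sac" tag for vertices where the local
    radius exceeds r0 by more than 5% of the bulge amplitude. With
    ``closed=True`` the tube ends are capped with triangle fans (apex
    vertices tagged non-sac) so the signed volume is meaningful.
    """
    nt, nz = spec.n_theta, spec.n_z
    z = np.linspace(0.0, spec.length, nz)
    theta = np.linspace(0.0, 2.0 * np.pi, nt, endpoint=False)
    R = _radius_profile(spec, z)
    dRdz = np.gradient(R, z)

    tt, zz = np.meshgrid(theta, z, indexing="ij")  # (nt, nz)
    rr = np.broadcast_to(R, (nt, nz))
    verts = np.column_stack([
        (rr * np.cos(tt)).ravel(),
        (rr * np.sin(tt)).ravel(),
        zz.ravel(),
    ])
    # outward normal of a surface of revolution: (cos t, sin t, -R') / norm
    slope = np.broadcast_to(dRdz, (nt, nz))
    normals = np.column_stack([
        np.cos(tt).ravel(), np.sin(tt).ravel(), (-slope).ravel()
    ])
    normals /= np.linalg.norm(normals, axis=1)[:, None]

    def vid(it: int, iz: int) -> int:
        return (it % nt) * nz + iz

    faces = []
    for it in range(nt):
        for iz in range(nz - 1):
            a, b = vid(it, iz), vid(it + 1, iz)
            c, d = vid(it + 1, iz + 1), vid(it, iz + 1)
            faces.append([a, b, c])  # outward winding (CCW seen from outside)
            faces.append([a, c, d])
    sac = np.broadcast_to(R - spec.r0 > 0.05 * spec.bulge_amplitude, (nt, nz)).ravel()

    if closed:
        verts = np.vstack([verts, [[0, 0, 0]], [[0, 0, spec.length]]])
        normals = np.vstack([normals, [[0, 0, -1.0]], [[0, 0, 1.0]]])
        lo, hi = len(verts) - 2, len(verts) - 1
        for it in range(nt):
            faces.append([lo, vid(it + 1, 0), vid(it, 0)])
            faces.append([hi, vid(it, nz - 1), vid(it + 1, nz - 1)])
        sac = np.concatenate([sac, [False, False]])

    mesh = SurfaceMesh(vertices=verts, faces=np.array(faces), normals=normals)
    return mesh, np.asarray(sac, dtype=bool)


def _plateau_bump(d2: np.ndarray, inner: float, outer: float) -> np.ndarray:
    """Smoothstep weight: 1 inside radius ``inner``, 0 outside ``outer``.

    ``d2`` is a squared normalised distance. An exact plateau (== 1)
    keeps a core of vertices in the pure closed-form regime.
    """
    d = np.sqrt(d2)
    x = np.clip((outer - d) / (outer - inner), 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _patch_weights(spec: SyntheticSpec, mesh: SurfaceMesh):
    """Oscillatory (posterior) and transverse (anterior) patch weights."""
    x, y, z = mesh.vertices.T
    theta = np.arctan2(y, x)
    dz = (z - spec.bulge_center) / spec.bulge_sigma
    # posterior patch around theta = pi
    d_post = np.minimum(np.abs(theta - np.pi), np.abs(theta + np.pi))
    w_osc = _plateau_bump(d_post**2 / 0.8**2 + dz**2 / 0.8**2, 1.0, 2.0)
    # anterior patch around theta = 0
    w_trans = _plateau_bump(theta**2 / 0.8**2 + dz**2 / 0.8**2, 1.0, 2.0)
    return w_osc, w_trans


def wss_parameters(
    spec: SyntheticSpec, mesh: SurfaceMesh
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-vertex (m, a, b) of the synthetic WSS field (Pa)."""
    z = mesh.vertices[:, 2]
    R = _radius_profile(spec, z)
    w_osc, w_trans = _patch_weights(spec, mesh)
    # the oscillatory patch replaces the mean flow only where it exists
    if spec.osc_amplitude == 0:
        w_osc = np.zeros_like(w_osc)
    m = spec.m0 * (spec.r0 / R) ** 2 * (1.0 - w_osc)
    a = spec.osc_amplitude * w_osc
    b = spec.trans_amplitude * w_trans * (1.0 - w_osc)
    return m, a, b


def _tangent_frames(mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """Axial and circumferential unit tangents at each vertex.

    e_ax is +z projected onto the tangent plane; e_circ = n x e_ax.
    Raises where the normal is (anti)parallel to the axis (cap apexes).
    """
    n = mesh.normals
    zhat = np.array([0.0, 0.0, 1.0])
    e_ax = zhat - n * n[:, 2:3]
    norms = np.linalg.norm(e_ax, axis=1)
    if np.any(norms < 1e-8):
        raise ValueError("degenerate tangent frame: normal parallel to the axis")
    e_ax /= norms[:, None]
    e_circ = np.cross(n, e_ax)
    return e_ax, e_circ


def make_wss_field(
    mesh: SurfaceMesh, spec: SyntheticSpec, n_times: int = 360
) -> tuple[WSSField, dict[str, np.ndarray]]:
    """Pulsatile WSS field plus closed-form ground truth.

    Ground-truth arrays (``tawss``, ``osi``, ``transwss``, plus the mean
    vector magnitude ``mean_mag``) hold NaN wherever the (m, a, b)
    combination has no elementary closed form; the masks in the returned
    dict say which regime each vertex is in.
    """
    if n_times < 16:
        raise ValueError("need at least 16 time samples")
    m, a, b = wss_parameters(spec, mesh)
    e_ax, e_circ = _tangent_frames(mesh)
    t = np.linspace(0.0, spec.period, n_times, endpoint=False)
    cos = np.cos(2.0 * np.pi * t / spec.period)
    sin = np.sin(2.0 * np.pi * t / spec.period)
    ax_mag = m[None, :] + a[None, :] * cos[:, None]  # (K, N)
    circ_mag = b[None, :] * sin[:, None]
    vectors = ax_mag[..., None] * e_ax[None] + circ_mag[..., None] * e_circ[None]
    fld = WSSField(mesh=mesh, times=t, period=spec.period, vectors=vectors)

    two_over_pi = 2.0 / np.pi
    nan = np.full(mesh.n_vertices, np.nan)
    uniaxial = (b == 0) & (m >= a)  # steady-dominant, no transverse part
    pure_osc = (m == 0) & (b == 0) & (a > 0)  # zero-mean oscillation
    steady_mean = a == 0  # mean vector is exactly m e_ax

    tawss_gt = nan.copy()
    tawss_gt[uniaxial] = m[uniaxial]
    tawss_gt[pure_osc] = two_over_pi * a[pure_osc]
    pure_trans = steady_mean & (m == 0) & (b > 0)
    tawss_gt[pure_trans] = two_over_pi * b[pure_trans]

    osi_gt = nan.copy()
    osi_gt[uniaxial & (m > 0)] = 0.0
    osi_gt[pure_osc | pure_trans] = 0.5

    transwss_gt = nan.copy()
    transwss_gt[uniaxial & (m > 0)] = 0.0
    has_mean = steady_mean & (m > 0)
    transwss_gt[has_mean] = two_over_pi * b[has_mean]

    mean_mag_gt = nan.copy()
    mean_mag_gt[steady_mean] = m[steady_mean]
    mean_mag_gt[pure_osc] = 0.0

    ground_truth = {
        "m": m, "a": a, "b": b,
        "tawss": tawss_gt, "osi": osi_gt, "transwss": transwss_gt,
        "mean_mag": mean_mag_gt,
        "uniaxial": uniaxial, "pure_oscillatory": pure_osc,
        "steady_mean": steady_mean,
    }
    return fld, ground_truth


def ilt_thickness_profile(spec: SyntheticSpec, mesh: SurfaceMesh) -> np.ndarray:
    """Ground-truth ILT thickness g(v) (mm): distal posterior Gaussian cap.

    The Gaussian is shifted and clamped to compact support (zero beyond
    ~2.45 sigma), so part of the sac stays genuinely ILT-free — the
    partial-coverage configuration seen in many thrombus-laden
    aneurysms. The peak value is preserved.
    """
    x, y, z = mesh.vertices.T
    theta = np.arctan2(y, x)
    d_post = np.minimum(np.abs(theta - np.pi), np.abs(theta + np.pi))
    z_ilt = spec.bulge_center + 0.5 * spec.bulge_sigma  # distal of the apex
    bell = np.exp(
        -(z - z_ilt) ** 2 / (2.0 * spec.ilt_sigma_z**2)
        - d_post**2 / (2.0 * spec.ilt_sigma_theta**2)
    )
    floor = np.exp(-3.0)
    return spec.ilt_peak * np.maximum(bell - floor, 0.0) / (1.0 - floor)


def make_ilt_surfaces(
    mesh: SurfaceMesh,
    spec: SyntheticSpec,
    thickness: np.ndarray | None = None,
) -> tuple[SurfaceMesh, np.ndarray]:
    """Outer ILT surface: lumen displaced outward by g(v) + wall offset.

    Returns the outer mesh and the ground-truth thickness g. A warning is
    issued where the offset exceeds the local radius of curvature enough
    to risk self-intersection (inward offsets only; outward offsets of a
    convex-ish bulge are safe).
    """
    g = ilt_thickness_profile(spec, mesh) if thickness is None else np.asarray(thickness, float)
    if np.any(g < 0):
        raise ValueError("thickness profile must be nonnegative")
    offset = g + spec.wall_offset
    outer_vertices = mesh.vertices + offset[:, None] * mesh.normals
    outer = SurfaceMesh(vertices=outer_vertices, faces=mesh.faces.copy())
    return outer, g


def make_inflow_waveform(
    spec: SyntheticSpec, mean_value: float = 0.25, n_harmonics: int = 10
) -> Waveform:
    """Synthetic triphasic infrarenal-style velocity waveform (m/s).

    Built from three Gaussian lobes — a systolic peak at 15% of the
    cycle, a diastolic reverse lobe and a small late-diastolic forward
    lobe — band-limited to ``n_harmonics`` harmonics and rescaled so the
    cycle mean equals ``mean_value``. Purely synthetic: it emulates the
    triphasic shape of in vivo infrarenal flow, not any measured cohort
    waveform. Deterministic for a given spec.
    """
    T = spec.period

    def lobes(t: np.ndarray) -> np.ndarray:
        ph = (t / T) % 1.0
        return (
            1.0 * np.exp(-((ph - 0.15) ** 2) / (2 * 0.06**2))
            - 0.35 * np.exp(-((ph - 0.42) ** 2) / (2 * 0.07**2))
            + 0.10 * np.exp(-((ph - 0.80) ** 2) / (2 * 0.10**2))
        )

    ts = np.linspace(0.0, T, 256, endpoint=False)
    w = fit_waveform(ts, lobes(ts), n_harmonics, period=T, unit="m/s")
    # rescale so the cycle mean (= a0) matches the requested mean velocity
    scale = mean_value / w.a0
    return Waveform(period=T, a0=w.a0 * scale, a=w.a * scale, b=w.b * scale,
                    unit="m/s")
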