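"""Per-vertex wall-shear-stress derivatives over one cardiac cycle.

Given a per-vertex WSS vector time series tau(t) (Pa) on a surface mesh,
this module computes the standard near-wall hemodynamic indices:

    TAWSS     = (1/T) int_0^T ||tau|| dt
    OSI       = 1/2 (1 - ||(1/T) int tau dt|| / TAWSS)        in [0, 0.5]
    RRT       = 1 / ((1 - 2 OSI) TAWSS) = 1 / ||(1/T) int tau dt||
    ECAP      = OSI / TAWSS
    TransWSS  = (1/T) int |tau . (n x e_mean)| dt
    NTransWSS = TransWSS / max(TransWSS over a region)

where e_mean is the direction of the cycle-mean WSS vector and n the
outward surface normal. Time integration is periodic trapezoidal
quadrature: the cycle is closed by wrapping the first sample to t0 + T,
so non-uniform sample times are handled correctly.

Vertices where TAWSS or the mean-vector magnitude fall below configurable
floors are flagged and capped rather than set to NaN, so downstream
region statistics stay computable.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mesh import SurfaceMesh

__all__ = [
    "WSSField",
    "IndexConfig",
    "HemodynamicIndices",
    "time_average_vector",
    "compute_tawss",
    "compute_osi",
    "compute_rrt",
    "compute_ecap",
    "compute_transwss",
    "normalize_transwss",
    "compute_all_indices",
]


@dataclass
class WSSField:
    """WSS vector samples (Pa) over one cardiac cycle.

    ``times`` are K strictly increasing instants in [0, T); ``vectors`` has
    shape (K, N, 3) for N mesh vertices. The field should be tangent to the
    surface; the normal component is measured (``tangency_residual``) and
    removed before TransWSS.
    """

    mesh: SurfaceMesh
    times: np.ndarray
    period: float
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("need at least two time samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.period <= 0 or self.times[-1] >= self.period:
            raise ValueError("times must lie in [0, period)")
        expected = (len(self.times), self.mesh.n_vertices, 3)
        if self.vectors.shape != expected:
            raise ValueError(
                f"vectors shape {self.vectors.shape} != (K, N, 3) = {expected}"
            )

    @property
    def n_times(self) -> int:
        return len(self.times)

    def tangency_residual(self) -> np.ndarray:
        """Per-vertex max over time of |tau . n| / ||tau|| (0 where tau = 0)."""
        normal_comp = np.abs(np.einsum("knj,nj->kn", self.vectors, self.mesh.normals))
        mag = np.linalg.norm(self.vectors, axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(mag > 0, normal_comp / np.where(mag > 0, mag, 1.0), 0.0)
        return ratio.max(axis=0)


@dataclass(frozen=True)
class IndexConfig:
    """Numerical policy for degenerate vertices and data-quality checks.

    tawss_floor : Pa. Below this the RRT/ECAP denominators are treated as
        zero: the value is capped at ``cap`` and the vertex flagged.
    mean_floor : Pa. Mean-WSS-vector magnitude below which the mean
        direction (hence TransWSS) is undefined; TransWSS is set to 0 and
        the vertex flagged.
    cap : ceiling substituted for RRT/ECAP at degenerate vertices (Pa^-1).
    tangency_tol : max tolerated |tau.n|/||tau|| before a warning.
    """

    tawss_floor: float = 1e-6
    mean_floor: float = 1e-9
    cap: float = 1e6
    tangency_tol: float = 0.05


@dataclass
class HemodynamicIndices:
    """Bundle of per-vertex indices plus degeneracy flags."""

    tawss: np.ndarray
    osi: np.ndarray
    transwss: np.ndarray
    ntranswss: np.ndarray | None
    rrt: np.ndarray
    ecap: np.ndarray
    flags: dict[str, np.ndarray] = field(default_factory=dict)
    config: IndexConfig = field(default_factory=IndexConfig)

    def as_dict(self) -> dict[str, np.ndarray]:
        out = {
            "TAWSS": self.tawss,
            "OSI": self.osi,
            "TransWSS": self.transwss,
            "RRT": self.rrt,
            "ECAP": self.ecap,
        }
        if self.ntranswss is not None:
            out["NTransWSS"] = self.ntranswss
        return out


# -- quadrature ---------------------------------------------------------------


def _periodic_weights(times: np.ndarray, period: float) -> np.ndarray:
    """Trapezoidal weights for a periodic integrand sampled at ``times``.

    The cycle is closed by wrapping: the gap from t_{K-1} back to t_0 + T
    contributes to both end samples. Weights sum to ``period``.
    """
    t = np.concatenate([times, [times[0] + period]])
    dt = np.diff(t)
    w = np.zeros(len(times))
    w += 0.5 * dt  # leading edge of each interval
    w[1:] += 0.5 * dt[:-1]  # trailing edges
    w[0] += 0.5 * dt[-1]  # wrap-around interval ends at t0 + T
    return w


def _cycle_mean(values: np.ndarray, times: np.ndarray, period: float) -> np.ndarray:
    """(1/T) int_0^T f dt for samples ``values`` of shape (K, ...)."""
    w = _periodic_weights(times, period)
    return np.tensordot(w, values, axes=(0, 0)) / period


# -- individual indices -------------------------------------------------------


def time_average_vector(field: WSSField) -> np.ndarray:
    """Cycle-mean WSS vector, (N, 3) Pa."""
    return _cycle_mean(field.vectors, field.times, field.period)


def compute_tawss(field: WSSField) -> np.ndarray:
    """Time-averaged WSS magnitude, (N,) Pa."""
    mag = np.linalg.norm(field.vectors, axis=2)
    return _cycle_mean(mag, field.times, field.period)


def compute_osi(
    field: WSSField,
    config: IndexConfig = IndexConfig(),
    tawss: np.ndarray | None = None,
    mean_vec: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Oscillatory shear index, clipped to [0, 0.5].

    Returns ``(osi, degenerate)`` where ``degenerate`` marks vertices with
    TAWSS below the floor (OSI set to 0 there).
    """
    if tawss is None:
        tawss = compute_tawss(field)
    if mean_vec is None:
        mean_vec = time_average_vector(field)
    mean_mag = np.linalg.norm(mean_vec, axis=1)
    degenerate = tawss < config.tawss_floor
    denom = np.where(degenerate, 1.0, tawss)
    osi = 0.5 * (1.0 - mean_mag / denom)
    osi = np.clip(osi, 0.0, 0.5)
    osi[degenerate] = 0.0
    return osi, degenerate


def compute_rrt(
    tawss: np.ndarray, osi: np.ndarray, config: IndexConfig = IndexConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Relative residence time 1/((1 - 2 OSI) TAWSS), (N,) Pa^-1.

    Degenerate denominators (below ``config.tawss_floor``) are capped at
    ``config.cap`` and flagged.
    """
    denom = (1.0 - 2.0 * osi) * tawss
    capped = denom < config.tawss_floor
    rrt = np.where(capped, config.cap, 1.0 / np.where(capped, 1.0, denom))
    return rrt, capped


def compute_ecap(
    tawss: np.ndarray, osi: np.ndarray, config: IndexConfig = IndexConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Endothelial cell activation potential OSI/TAWSS, (N,) Pa^-1."""
    capped = tawss < config.tawss_floor
    ecap = np.where(capped, config.cap, osi / np.where(capped, 1.0, tawss))
    # OSI = 0 with vanishing TAWSS is 0/0; report 0, not the cap
    ecap = np.where(capped & (osi == 0.0), 0.0, ecap)
    return ecap, capped


def compute_transwss(
    field: WSSField,
    config: IndexConfig = IndexConfig(),
    mean_vec: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Transverse WSS: cycle mean of |tau . (n x e_mean)|, (N,) Pa.

    The WSS vectors are first projected onto the local tangent plane.
    Vertices whose mean-vector magnitude is below ``config.mean_floor``
    have no defined mean direction: TransWSS is 0 there and they are
    flagged undefined.
    """
    normals = field.mesh.normals
    if mean_vec is None:
        mean_vec = time_average_vector(field)
    # project the mean onto the tangent plane before taking its direction
    mean_tan = mean_vec - np.einsum("nj,nj->n", mean_vec, normals)[:, None] * normals
    mean_mag = np.linalg.norm(mean_tan, axis=1)
    undefined = mean_mag < config.mean_floor
    e_mean = mean_tan / np.where(undefined, 1.0, mean_mag)[:, None]
    trans_dir = np.cross(normals, e_mean)  # unit: n and e_mean orthonormal
    # tangent-plane projection of the instantaneous vectors
    normal_comp = np.einsum("knj,nj->kn", field.vectors, normals)
    tangential = field.vectors - normal_comp[..., None] * normals[None]
    comp = np.abs(np.einsum("knj,nj->kn", tangential, trans_dir))
    transwss = _cycle_mean(comp, field.times, field.period)
    transwss[undefined] = 0.0
    return transwss, undefined


def normalize_transwss(transwss: np.ndarray, region: np.ndarray | None = None) -> np.ndarray:
    """TransWSS divided by its maximum over ``region`` (default: all vertices).

    Raises ValueError when the regional maximum is zero.
    """
    if region is None:
        region = np.ones(len(transwss), dtype=bool)
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("normalisation region is empty")
    peak = float(np.max(transwss[region]))
    if peak <= 0:
        raise ValueError("TransWSS is zero over the region; normalisation undefined")
    return transwss / peak


def compute_all_indices(
    field: WSSField,
    config: IndexConfig = IndexConfig(),
    roi: np.ndarray | None = None,
) -> HemodynamicIndices:
    """Compute the full per-vertex index bundle.

    ``roi`` is the region over which NTransWSS is normalised (the
    aneurysm sac); with ``roi=None`` the whole mesh is used. If TransWSS
    vanishes over the region NTransWSS is left as None.
    """
    residual = field.tangency_residual()
    if np.any(residual > config.tangency_tol):
        warnings.warn(
            f"WSS field has tangency residual up to {residual.max():.3g} "
            f"(tolerance {config.tangency_tol}); vectors are projected onto "
            "the tangent plane for TransWSS",
            stacklevel=2,
        )
    mean_vec = time_average_vector(field)
    tawss = compute_tawss(field)
    osi, deg_tawss = compute_osi(field, config, tawss=tawss, mean_vec=mean_vec)
    rrt, rrt_capped = compute_rrt(tawss, osi, config)
    ecap, ecap_capped = compute_ecap(tawss, osi, config)
    transwss, mean_undef = compute_transwss(field, config, mean_vec=mean_vec)
    try:
        ntranswss = normalize_transwss(transwss, roi)
    except ValueError:
        ntranswss = None
    return HemodynamicIndices(
        tawss=tawss,
        osi=osi,
        transwss=transwss,
        ntranswss=ntranswss,
        rrt=rrt,
        ecap=ecap,
        flags={
            "tawss_degenerate": deg_tawss,
            "mean_undefined": mean_undef,
            "rrt_capped": rrt_capped,
            "ecap_capped": ecap_capped,
            "tangency_warning": residual > config.tangency_tol,
        },
        config=config,
    )
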