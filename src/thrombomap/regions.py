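"""Region masks, hemodynamic thresholds and co-localization statistics.

The aneurysmatic sac is the region of interest (ROI); the parent vessel
and iliac arteries are masked out. Within the ROI the surface is split
into ILT-covered and ILT-free vertices, and the ILT further into its
thickest (>= 1.7 cm by default) and thinnest (<= 0.15 cm) zones. Each
hemodynamic index carries a literature threshold marking conditions
favorable for thrombus deposition: TAWSS < 0.4 Pa, OSI > 0.2 (or 0.3),
ECAP > 1.4 Pa^-1, RRT > 10 Pa^-1. Co-localization of indices with ILT
thickness is quantified by the Spearman rank correlation.

Thickness is held in mm internally; the thick/thin thresholds are given
in cm and converted explicitly (factor 10), so the two unit conventions
never mix silently.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mesh import SurfaceMesh
from .thickness import ThicknessField
from .wss import HemodynamicIndices

__all__ = [
    "ThresholdConfig",
    "RegionMask",
    "RegionSummary",
    "CorrelationResult",
    "make_roi",
    "split_ilt",
    "extreme_ilt_regions",
    "threshold_maps",
    "classify_flow_nature",
    "FLOW_CLASS_NAMES",
    "region_summary",
    "spearman",
    "growth_potential_report",
]

MM_PER_CM = 10.0


@dataclass(frozen=True)
class ThresholdConfig:
    """Literature cut-offs for ILT-favorable hemodynamics and ILT zoning.

    tawss_low : Pa; TAWSS below this is favorable for deposition (0.4).
    osi_high : OSI above this is favorable (0.2; 0.3 is the common
        alternative).
    ecap_high : Pa^-1 (1.4).  rrt_high : Pa^-1 (10).
    thick_min : cm; ILT at least this thick is "thickest" (1.7; alt 1.5).
    thin_max : cm; ILT no thicker than this is "thinnest" (0.15; alt 0.3).
    ilt_presence_min : mm; thickness above this counts as ILT-covered.
    ntranswss_split : high/low split for normalized TransWSS.
    """

    tawss_low: float = 0.4
    osi_high: float = 0.2
    ecap_high: float = 1.4
    rrt_high: float = 10.0
    thick_min: float = 1.7
    thin_max: float = 0.15
    ilt_presence_min: float = 0.1
    ntranswss_split: float = 0.5

    def __post_init__(self) -> None:
        vals = asdict(self)
        if any(v <= 0 for v in vals.values()):
            raise ValueError("all thresholds must be positive")
        if self.thin_max >= self.thick_min:
            raise ValueError("thin_max must be below thick_min")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class RegionMask:
    """Named boolean vertex selection on a surface mesh."""

    name: str
    mesh: SurfaceMesh
    selected: np.ndarray

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=bool)
        if len(self.selected) != self.mesh.n_vertices:
            raise ValueError("mask length does not match mesh vertex count")

    @property
    def vertex_count(self) -> int:
        return int(self.selected.sum())

    @property
    def area_mm2(self) -> float:
        return float(self.mesh.vertex_areas()[self.selected].sum())

    def __and__(self, other: "RegionMask") -> "RegionMask":
        return RegionMask(f"{self.name}&{other.name}", self.mesh,
                          self.selected & other.selected)


@dataclass
class RegionSummary:
    """Order statistics of one scalar field over one region."""

    median: float
    q1: float
    q3: float
    iqr: float
    p10: float
    p90: float
    min: float
    max: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class CorrelationResult:
    """Spearman rank correlation of an index against ILT thickness."""

    index_name: str
    region_name: str
    rho: float
    p_value: float
    n: int
    degenerate: bool = False  # constant input: rho undefined


# -- region construction ------------------------------------------------------


def make_roi(
    mesh: SurfaceMesh,
    z_bounds: tuple[float, float] | None = None,
    labels: np.ndarray | None = None,
    axis: int = 2,
) -> RegionMask:
    """Select the aneurysmatic region, by axial bounds or an explicit label set.

    Exactly one of ``z_bounds`` (inclusive coordinate interval along
    ``axis``) or ``labels`` (boolean per-vertex array) must be given.
    """
    if (z_bounds is None) == (labels is None):
        raise ValueError("give exactly one of z_bounds or labels")
    if labels is not None:
        selected = np.asarray(labels, dtype=bool)
        if len(selected) != mesh.n_vertices:
            raise ValueError("label array does not match vertex count")
    else:
        z = mesh.vertices[:, axis]
        lo, hi = z_bounds
        selected = (z >= lo) & (z <= hi)
    if not selected.any():
        raise ValueError("ROI selection is empty")
    return RegionMask("ROI", mesh, selected)


def split_ilt(
    thickness: ThicknessField, cfg: ThresholdConfig, roi: RegionMask
) -> dict[str, RegionMask]:
    """Partition the ROI into ILT-covered and ILT-free vertex sets."""
    _check_same_mesh(thickness.mesh, roi.mesh)
    ilt = roi.selected & (thickness.thickness > cfg.ilt_presence_min)
    return {
        "ILT": RegionMask("ILT", roi.mesh, ilt),
        "ILT-free": RegionMask("ILT-free", roi.mesh, roi.selected & ~ilt),
    }


def extreme_ilt_regions(
    thickness: ThicknessField, cfg: ThresholdConfig, roi: RegionMask
) -> dict[str, RegionMask]:
    """Thickest (>= thick_min cm) and thinnest (0 < t <= thin_max cm) ILT zones."""
    masks = split_ilt(thickness, cfg, roi)
    t_mm = thickness.thickness
    ilt = masks["ILT"].selected
    thickest = ilt & (t_mm >= cfg.thick_min * MM_PER_CM)
    thinnest = ilt & (t_mm > 0) & (t_mm <= cfg.thin_max * MM_PER_CM)
    return {
        "thickest": RegionMask("thickest", roi.mesh, thickest),
        "thinnest": RegionMask("thinnest", roi.mesh, thinnest),
    }


def threshold_maps(
    indices: HemodynamicIndices, cfg: ThresholdConfig, roi: RegionMask
) -> dict[str, RegionMask]:
    """Per-index masks of ILT-favorable hemodynamic conditions within the ROI.

    ``combined`` is the conjunction of the four single-index maps.
    """
    sel = roi.selected
    fav = {
        "favorable_TAWSS": sel & (indices.tawss < cfg.tawss_low),
        "favorable_OSI": sel & (indices.osi > cfg.osi_high),
        "favorable_ECAP": sel & (indices.ecap > cfg.ecap_high),
        "favorable_RRT": sel & (indices.rrt > cfg.rrt_high),
    }
    fav["favorable_combined"] = np.logical_and.reduce(list(fav.values()))
    return {k: RegionMask(k, roi.mesh, v) for k, v in fav.items()}


FLOW_CLASS_NAMES = [
    f"{t}TAWSS/{o}OSI/{n}NTransWSS"
    for t in ("low", "high")
    for o in ("low", "high")
    for n in ("low", "high")
]


def classify_flow_nature(
    indices: HemodynamicIndices, cfg: ThresholdConfig, roi: RegionMask
) -> tuple[np.ndarray, pd.DataFrame]:
    """Classify near-wall flow into 8 compartments within the ROI.

    Octants of {low, high} TAWSS x {low, high} OSI x {low, high}
    NTransWSS using ``tawss_low``, ``osi_high`` and ``ntranswss_split``.
    Returns per-vertex labels (-1 outside the ROI) and a table of vertex
    counts and area fractions per class.
    """
    if indices.ntranswss is None:
        raise ValueError("NTransWSS is required for flow-nature classification")
    high_t = (indices.tawss >= cfg.tawss_low).astype(int)
    high_o = (indices.osi > cfg.osi_high).astype(int)
    high_n = (indices.ntranswss > cfg.ntranswss_split).astype(int)
    labels = high_t * 4 + high_o * 2 + high_n
    labels = np.where(roi.selected, labels, -1)
    areas = roi.mesh.vertex_areas()
    roi_area = areas[roi.selected].sum()
    rows = []
    for c, name in enumerate(FLOW_CLASS_NAMES):
        in_class = labels == c
        rows.append({
            "class": name,
            "vertex_count": int(in_class.sum()),
            "area_fraction": float(areas[in_class].sum() / roi_area) if roi_area else 0.0,
        })
    return labels, pd.DataFrame(rows)


# -- statistics ---------------------------------------------------------------


def region_summary(values: np.ndarray, mask: RegionMask) -> RegionSummary:
    """Median, quartiles (linear interpolation), IQR, P10/P90, extrema, n."""
    v = np.asarray(values, dtype=float)[mask.selected]
    if v.size == 0:
        raise ValueError(f"region {mask.name!r} is empty")
    q1, med, q3, p10, p90 = np.percentile(v, [25, 50, 75, 10, 90])
    return RegionSummary(
        median=float(med), q1=float(q1), q3=float(q3), iqr=float(q3 - q1),
        p10=float(p10), p90=float(p90), min=float(v.min()), max=float(v.max()),
        n=int(v.size),
    )


def spearman(
    thickness_mm: np.ndarray,
    index_values: np.ndarray,
    mask: RegionMask,
    index_name: str = "",
) -> CorrelationResult:
    """Spearman rank correlation between ILT thickness and an index.

    Average ranks for ties; two-sided p-value from the large-sample t
    approximation. With a constant input the coefficient is undefined and
    flagged (rho = NaN). Spatial autocorrelation between neighbouring
    vertices is ignored, so p-values are optimistic.
    """
    sel = mask.selected
    x = np.asarray(thickness_mm, dtype=float)[sel]
    y = np.asarray(index_values, dtype=float)[sel]
    if x.size < 3:
        raise ValueError("need at least 3 vertices for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(index_name, mask.name, float("nan"),
                                 float("nan"), int(x.size), degenerate=True)
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(index_name, mask.name, float(rho), float(p), int(x.size))


def growth_potential_report(
    indices: HemodynamicIndices,
    thickness: ThicknessField,
    cfg: ThresholdConfig,
    roi: RegionMask,
) -> pd.DataFrame:
    """One row per (region, index): summary statistics, favorable fraction,
    and Spearman rho/p of the index against thickness over the ILT region.

    Regions: AAA (whole ROI), ILT, ILT-free, thickest, thinnest. The
    correlation is always computed over the ILT vertex set, so it is
    repeated across the region rows of a given index. Deterministic:
    identical inputs give identical tables.
    """
    _check_same_mesh(thickness.mesh, roi.mesh)
    parts = split_ilt(thickness, cfg, roi)
    extremes = extreme_ilt_regions(thickness, cfg, roi)
    regions = {
        "AAA": roi,
        "ILT": parts["ILT"],
        "ILT-free": parts["ILT-free"],
        "thickest": extremes["thickest"],
        "thinnest": extremes["thinnest"],
    }
    favorable = {
        "TAWSS": lambda v: v < cfg.tawss_low,
        "OSI": lambda v: v > cfg.osi_high,
        "ECAP": lambda v: v > cfg.ecap_high,
        "RRT": lambda v: v > cfg.rrt_high,
        "TransWSS": None,  # no literature threshold
        "NTransWSS": None,
    }
    ilt_mask = parts["ILT"]
    rows = []
    for index_name, values in indices.as_dict().items():
        if ilt_mask.vertex_count >= 3:
            corr = spearman(thickness.thickness, values, ilt_mask, index_name)
            rho, pval = corr.rho, corr.p_value
        else:
            rho, pval = float("nan"), float("nan")
        for region_name, mask in regions.items():
            row = {"region": region_name, "index": index_name,
                   "n": mask.vertex_count}
            if mask.vertex_count:
                row.update(region_summary(values, mask).as_dict())
                fav = favorable.get(index_name)
                row["favorable_fraction"] = (
                    float(fav(values[mask.selected]).mean()) if fav else float("nan")
                )
            else:
                row.update({k: float("nan") for k in
                            ("median", "q1", "q3", "iqr", "p10", "p90",
                             "min", "max", "favorable_fraction")})
                row["n"] = 0
            row["spearman_rho_vs_thickness"] = rho
            row["spearman_p"] = pval
            rows.append(row)
    return pd.DataFrame(rows)


def _check_same_mesh(a: SurfaceMesh, b: SurfaceMesh) -> None:
    if a.n_vertices != b.n_vertices:
        raise ValueError("fields are defined on different meshes")
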