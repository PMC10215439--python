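"""Grid Convergence Index (GCI) for three-mesh refinement studies.

Richardson-extrapolation-based estimate of discretisation uncertainty
from a coarse/medium/fine grid triplet with constant refinement ratio r:

    p        = ln|(f_coarse - f_medium) / (f_medium - f_fine)| / ln r
    GCI_fine = Fs |(f_medium - f_fine) / f_fine| / (r^p - 1) * 100%

with safety factor Fs = 1.25 for a three-grid study. The asymptotic
ratio GCI_coarse / (r^p GCI_fine) should approach 1 when the grids are
in the asymptotic convergence range.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["GridTriplet", "GCIResult", "observed_order", "gci"]


@dataclass(frozen=True)
class GridTriplet:
    """Scalar quantity on coarse/medium/fine grids, refinement ratio r > 1."""

    f_coarse: float
    f_medium: float
    f_fine: float
    r: float = 2.0
    fs: float = 1.25

    def __post_init__(self) -> None:
        if self.r <= 1:
            raise ValueError("refinement ratio must exceed 1")
        for v in (self.f_coarse, self.f_medium, self.f_fine):
            if not math.isfinite(v):
                raise ValueError("grid values must be finite")


@dataclass
class GCIResult:
    gci_fine_pct: float
    gci_coarse_pct: float
    asymptotic_ratio: float
    p: float
    relative: bool  # False when f_fine = 0 and the absolute form was used


def observed_order(t: GridTriplet) -> float:
    """Observed order of convergence p.

    Requires monotone convergence: the two consecutive differences must
    be nonzero and share a sign; oscillatory or stalled sequences raise.
    """
    e_cm = t.f_coarse - t.f_medium
    e_mf = t.f_medium - t.f_fine
    if e_cm == 0 or e_mf == 0:
        raise ValueError("consecutive grid values are equal; order undefined")
    if e_cm * e_mf < 0:
        raise ValueError("oscillatory convergence; observed order not reported")
    p = math.log(abs(e_cm / e_mf)) / math.log(t.r)
    if p <= 0:
        raise ValueError("non-convergent sequence (observed order <= 0)")
    return p


def gci(t: GridTriplet, p: float | None = None) -> GCIResult:
    """GCI on the fine and coarse grids plus the asymptotic-range ratio.

    ``p`` defaults to the observed order of the triplet. When the
    medium and fine values coincide the GCI is zero by definition.
    """
    if p is None:
        if t.f_medium == t.f_fine:
            p_val = float("nan")
            return GCIResult(0.0, 0.0, float("nan"), p_val, relative=True)
        p = observed_order(t)
    if p <= 0:
        raise ValueError("order p must be positive")
    rp = t.r**p
    relative = t.f_fine != 0
    def err(num: float, den: float) -> float:
        return abs(num / den) if relative else abs(num)
    gci_fine = t.fs * err(t.f_medium - t.f_fine, t.f_fine) / (rp - 1.0) * 100.0
    gci_coarse = t.fs * err(t.f_coarse - t.f_medium, t.f_medium) / (rp - 1.0) * 100.0
    # asymptotic-range check on absolute errors, so an exact power-law
    # sequence gives 1 identically (the relative form differs by f_f/f_m)
    e_mf = abs(t.f_medium - t.f_fine)
    ratio = abs(t.f_coarse - t.f_medium) / (rp * e_mf) if e_mf > 0 else float("nan")
    return GCIResult(gci_fine, gci_coarse, ratio, p, relative)
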