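"""Linear growth dynamics of crown roots and shoots.

Both crown-root length and the shoot canopy pixel proxy are modelled as a
straight line in time, ``L(t) = a + b t``, with ``t = 0`` anchored at the
start of the split-nitrogen application.  The slope ``b`` is the elongation
rate (cm/day for roots, pixels/day for the shoot, traits ER_Cr / ER_S) and
the intercept ``a`` is the size at treatment start (IC_Cr / IC_S).

Fits are plain ordinary least squares, one per root or plant; residual QC
flags grossly outlying points (studentised residual > 4) but never removes
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import InsufficientDataError, SingularFitError
from .experiment import TraitTable

#: Studentised-residual magnitude beyond which a point is flagged (not removed).
OUTLIER_FLAG_THRESHOLD = 4.0


@dataclass
class GrowthFit:
    """OLS line fit of a growth series."""

    a: float  # intercept at t = 0 (solution change)
    b: float  # slope per day
    n_points: int
    r2: float
    residual_sd: float
    flagged_points: List[int] = field(default_factory=list)

    def se_slope(self, t: np.ndarray) -> float:
        """Analytic standard error of the slope for the design ``t``."""
        sxx = float(np.sum((t - t.mean()) ** 2))
        return self.residual_sd / np.sqrt(sxx)


def fit_linear(t: Sequence[float], y: Sequence[float]) -> GrowthFit:
    """Ordinary least-squares line through ``(t, y)``.

    Raises
    ------
    InsufficientDataError
        Fewer than two observations.
    SingularFitError
        All time values identical.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be 1-d arrays of equal length")
    n = t.size
    if n < 2:
        raise InsufficientDataError(f"need >= 2 observations, got {n}")
    if np.ptp(t) == 0:
        raise SingularFitError("all time values identical; slope not estimable")

    X = np.column_stack([np.ones(n), t])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    resid = y - (a + b * t)
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    # tss == 0 (constant response) forces rss == 0: a perfect flat fit
    r2 = 1.0 if (tss <= 1e-30 or rss <= 1e-30) else 1.0 - rss / tss
    dof = n - 2
    residual_sd = float(np.sqrt(rss / dof)) if dof > 0 else float("nan")

    flagged: List[int] = []
    if dof > 0 and residual_sd > 0:
        # leverage of each design point
        h = 1.0 / n + (t - t.mean()) ** 2 / np.sum((t - t.mean()) ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            student = resid / (residual_sd * np.sqrt(1.0 - h))
        flagged = [int(i) for i in np.flatnonzero(np.abs(student) > OUTLIER_FLAG_THRESHOLD)]
    return GrowthFit(a=a, b=b, n_points=n, r2=r2, residual_sd=residual_sd,
                     flagged_points=flagged)


@dataclass
class GrowthSeries:
    """A time series tagged with its experimental unit.

    ``kind`` is ``"crown_root"`` (yields ER_Cr / IC_Cr, per compartment) or
    ``"shoot"`` (yields ER_S / IC_S, whole plant).  ``t`` is in days since
    solution change.
    """

    unit_id: str
    kind: str
    t: np.ndarray
    y: np.ndarray
    genotype: int
    replicate: int
    n_level: str = "none"  # high/low for roots, none for shoot
    side: str = "none"  # front/back for roots, none for shoot

    def __post_init__(self):
        if self.kind not in ("crown_root", "shoot"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)


_TRAITS = {
    "crown_root": ("ER_Cr", "IC_Cr", "cm/d", "cm"),
    "shoot": ("ER_S", "IC_S", "pixel/d", "pixel"),
}


def fit_all(
    series: Sequence[GrowthSeries],
    include_pretreatment: bool = False,
    shoot_overflow_day: Optional[float] = None,
) -> tuple[TraitTable, List[Dict]]:
    """Fit every growth series and collect slope/intercept trait records.

    Root fits drop pre-treatment observations (``t < 0``) unless
    *include_pretreatment* is set.  Shoot fits drop observations after
    *shoot_overflow_day* (days since solution change) — once leaves exceed
    the imaging frame the pixel proxy saturates and the dynamics can only
    be assessed up to that point.  Roots first observed after the solution
    change get a slope record only; their intercept is not extrapolated.
    Inestimable fits yield no records plus a QC entry.
    """
    records: List[dict] = []
    qc: List[Dict] = []
    for s in series:
        t, y = s.t, s.y
        first_obs = float(t.min()) if t.size else float("nan")
        if s.kind == "crown_root" and not include_pretreatment:
            keep = t >= 0
            t, y = t[keep], y[keep]
        if s.kind == "shoot" and shoot_overflow_day is not None:
            keep = t <= shoot_overflow_day
            t, y = t[keep], y[keep]
        try:
            fit = fit_linear(t, y)
        except (InsufficientDataError, SingularFitError) as exc:
            qc.append({"unit_id": s.unit_id, "kind": s.kind, "reason": str(exc)})
            continue
        slope_name, icpt_name, slope_unit, icpt_unit = _TRAITS[s.kind]
        base = {
            "genotype": s.genotype,
            "n_level": s.n_level,
            "replicate": s.replicate,
            "side": s.side,
        }
        records.append({**base, "trait": slope_name, "value": fit.b, "units": slope_unit})
        if s.kind == "crown_root" and first_obs > 0:
            qc.append({
                "unit_id": s.unit_id, "kind": s.kind,
                "reason": "first observation after solution change; intercept not extrapolated",
            })
        else:
            records.append({**base, "trait": icpt_name, "value": fit.a, "units": icpt_unit})
        if fit.flagged_points:
            qc.append({
                "unit_id": s.unit_id, "kind": s.kind,
                "reason": f"studentised residual > {OUTLIER_FLAG_THRESHOLD} at "
                          f"indices {fit.flagged_points} (kept)",
            })
    import pandas as pd

    if records:
        table = TraitTable(pd.DataFrame(records))
    else:
        from .experiment import TRAIT_COLUMNS

        table = TraitTable(pd.DataFrame(columns=TRAIT_COLUMNS))
    return table, qc
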