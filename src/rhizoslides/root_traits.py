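"""Traced root systems: eligibility filters, length series and
branching-zone lateral traits.

Root tracing itself happens in external software; the pipeline consumes its
RSML export (one file per slide side and timepoint, see :mod:`.rsml`).
Coordinates are kept in cm from the paper's top-left corner, x rightward,
y downward.

Crown roots are only used for growth analysis if they could grow
unconstrained: a root is excluded if it ever crosses the wax barrier or if
its tip ends up within a safety margin of the paper's side or bottom edges
at the final timepoint, so that zero measured growth is never an artefact
of the root simply running out of paper.

The branching zone of a crown root is the interval between the most distal
lateral already present at solution change (proximal end) and the most
distal lateral at harvest (distal end).  It is split into two equal-length
segments in which lateral number, median and maximum lateral length, and
branching density are scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    InsufficientDataError,
    RootLookupError,
    ZoneEmptyError,
    ZoneUndefinedError,
)
from .experiment import SlideGeometry

ROOT_CLASSES = ("primary", "seminal", "crown_whorl1", "crown_whorl2")
CROWN_CLASSES = ("crown_whorl1", "crown_whorl2")

#: Default distance (cm) a final root tip must keep from the paper's side
#: and bottom edges to count as unconstrained.
DEFAULT_EDGE_MARGIN_CM = 0.5


def polyline_length(points: np.ndarray) -> float:
    """Arc length of an ``(N, 2)`` polyline."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("polyline must be an (N>=2, 2) array")
    return float(np.hypot(*np.diff(pts, axis=0).T).sum())


@dataclass
class LateralRoot:
    """First-order branch of an axile root."""

    id: str
    insertion_position: float  # cm along the parent from its base
    length: float  # cm
    emergence_timepoint: Optional[int] = None  # day index, if known
    polyline: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.insertion_position < 0:
            raise ValueError(f"lateral {self.id}: negative insertion position")
        if self.length < 0:
            raise ValueError(f"lateral {self.id}: negative length")


@dataclass
class AxileRoot:
    """Main root axis (primary, seminal or crown) with its laterals."""

    id: str
    root_class: str
    polyline: np.ndarray  # (N, 2) cm from paper origin
    laterals: List[LateralRoot] = field(default_factory=list)

    def __post_init__(self):
        if self.root_class not in ROOT_CLASSES:
            raise ValueError(
                f"root {self.id}: class {self.root_class!r} not in {ROOT_CLASSES}"
            )
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.polyline.ndim != 2 or self.polyline.shape[1] != 2 or len(self.polyline) < 2:
            raise ValueError(f"root {self.id}: polyline must have >= 2 (x, y) points")

    @property
    def length(self) -> float:
        return polyline_length(self.polyline)

    @property
    def base(self) -> np.ndarray:
        return self.polyline[0]

    @property
    def tip(self) -> np.ndarray:
        return self.polyline[-1]

    @property
    def is_crown(self) -> bool:
        return self.root_class in CROWN_CLASSES


@dataclass
class RootSystem:
    """All traced roots of one slide side at one timepoint."""

    timepoint: int  # day index since sowing
    axile_roots: List[AxileRoot]
    slide_id: str = ""
    side: str = "front"
    scale_mm_per_px: Optional[float] = None

    def find(self, root_id: str) -> Optional[AxileRoot]:
        for r in self.axile_roots:
            if r.id == root_id:
                return r
        return None

    @property
    def crown_roots(self) -> List[AxileRoot]:
        return [r for r in self.axile_roots if r.is_crown]


def _system_at(systems: Sequence[RootSystem], day: int) -> RootSystem:
    """Latest system observed at or before *day*."""
    eligible = [s for s in systems if s.timepoint <= day]
    if not eligible:
        raise InsufficientDataError(f"no root system observed at or before day {day}")
    return max(eligible, key=lambda s: s.timepoint)


def compartment_of(root: AxileRoot, geometry: SlideGeometry) -> str:
    """Compartment (``"left"``/``"right"``) of a root, by its base x."""
    return "left" if root.base[0] < geometry.barrier_x_cm else "right"


def crosses_barrier(root: AxileRoot, geometry: SlideGeometry) -> bool:
    x = root.polyline[:, 0]
    return bool((x < geometry.barrier_x_cm).any() and (x > geometry.barrier_x_cm).any())


def tip_near_edge(root: AxileRoot, geometry: SlideGeometry, margin: float) -> bool:
    x, y = root.tip
    return bool(
        x < margin
        or x > geometry.width_cm - margin
        or y > geometry.height_cm - margin
    )


def filter_traceable(
    systems: Sequence[RootSystem],
    geometry: SlideGeometry,
    n_level_by_compartment: Dict[str, str],
    baseline_day: Optional[int] = None,
    margin_cm: float = DEFAULT_EDGE_MARGIN_CM,
) -> Dict[str, List[str]]:
    """Crown roots eligible for growth analysis, per N level.

    A crown root is eligible if it (i) is already present at *baseline_day*
    (default: the earliest supplied timepoint), (ii) never crosses the wax
    barrier at any timepoint, and (iii) keeps its final tip at least
    *margin_cm* from the paper's side and bottom edges.  The result maps
    each N level to the (possibly empty) list of eligible root ids; an
    empty list on a side is valid and simply reported.
    """
    if len(systems) < 2:
        raise InsufficientDataError("need root systems from >= 2 timepoints")
    ordered = sorted(systems, key=lambda s: s.timepoint)
    if baseline_day is None:
        baseline_day = ordered[0].timepoint
    baseline = _system_at(ordered, baseline_day)
    final = ordered[-1]

    out: Dict[str, List[str]] = {lvl: [] for lvl in set(n_level_by_compartment.values())}
    for root in final.crown_roots:
        if baseline.find(root.id) is None:
            continue
        if any(
            crosses_barrier(s.find(root.id), geometry)
            for s in ordered
            if s.find(root.id) is not None
        ):
            continue
        if tip_near_edge(root, geometry, margin_cm):
            continue
        level = n_level_by_compartment[compartment_of(root, geometry)]
        out[level].append(root.id)
    for lvl in out:
        out[lvl].sort()
    return out


#: Drop in traced length between consecutive timepoints (cm) beyond which a
#: QC warning is emitted (tracing noise tolerance).
SHRINKAGE_QC_CM = 0.5


def crown_length_series(
    systems: Sequence[RootSystem],
    root_id: str,
    solution_change_day: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Length time series of one crown root, re-origined to solution change.

    Returns ``(t, length)`` arrays with ``t`` in days since the solution
    change (negative for pre-treatment observations).  A drop of more than
    0.5 cm between consecutive timepoints is kept but triggers a QC warning;
    fewer than two observations is an error.
    """
    obs = []
    for s in sorted(systems, key=lambda s: s.timepoint):
        root = s.find(root_id)
        if root is not None:
            obs.append((s.timepoint - solution_change_day, root.length))
    if not obs:
        raise RootLookupError(f"root {root_id!r} absent from all timepoints")
    if len(obs) < 2:
        raise InsufficientDataError(
            f"root {root_id!r} observed at a single timepoint; excluded from fitting"
        )
    t, length = map(np.asarray, zip(*obs))
    drops = np.diff(length)
    if (drops < -SHRINKAGE_QC_CM).any():
        warnings.warn(
            f"root {root_id!r}: traced length decreases by more than "
            f"{SHRINKAGE_QC_CM} cm between timepoints (tracing QC)",
            stacklevel=2,
        )
    return t.astype(float), length.astype(float)


# ---------------------------------------------------------------------------
# Branching zone

@dataclass(frozen=True)
class BranchingZone:
    """Interval of the parent axis colonised by new laterals during the
    split-N treatment, split into two equal segments."""

    proximal_pos: float
    distal_pos: float

    def __post_init__(self):
        if not self.proximal_pos < self.distal_pos:
            raise ZoneEmptyError(
                f"branching zone empty: [{self.proximal_pos}, {self.distal_pos}]"
            )

    @property
    def midpoint(self) -> float:
        return (self.proximal_pos + self.distal_pos) / 2.0

    @property
    def segment1(self) -> Tuple[float, float]:
        return (self.proximal_pos, self.midpoint)

    @property
    def segment2(self) -> Tuple[float, float]:
        return (self.midpoint, self.distal_pos)

    @property
    def length(self) -> float:
        return self.distal_pos - self.proximal_pos


def _most_distal_insertion(root: AxileRoot) -> Optional[float]:
    if not root.laterals:
        return None
    return max(l.insertion_position for l in root.laterals)


def branching_zone(
    root_id: str,
    systems: Sequence[RootSystem],
    t_change: int,
    t_harvest: int,
) -> BranchingZone:
    """Branching zone of a crown root between solution change and harvest.

    Proximal end: insertion position of the most distal lateral already
    present at *t_change*.  Distal end: insertion position of the most
    distal lateral at *t_harvest*.  Positions are arc distances along the
    parent root.
    """
    at_change = _system_at(systems, t_change).find(root_id)
    at_harvest = _system_at(systems, t_harvest).find(root_id)
    if at_change is None or at_harvest is None:
        raise RootLookupError(f"root {root_id!r} missing at change or harvest")
    proximal = _most_distal_insertion(at_change)
    if proximal is None:
        raise ZoneUndefinedError(
            f"root {root_id!r} has no lateral at solution change; "
            "branching zone undefined (trait recorded missing)"
        )
    distal = _most_distal_insertion(at_harvest)
    if distal is None or distal <= proximal:
        raise ZoneEmptyError(
            f"root {root_id!r}: no new lateral distal to {proximal:.2f} cm at harvest"
        )
    return BranchingZone(proximal_pos=proximal, distal_pos=distal)


def lateral_metrics(root: AxileRoot, zone: BranchingZone) -> Dict[str, float]:
    """Lateral-root traits of the two branching-zone segments.

    Per segment: ``No_Lat`` (count), ``Max_Lat`` (longest lateral, cm),
    ``Med_Lat`` (median lateral length; lower median for even counts) and
    ``density`` (count per cm of parent axis).  A lateral inserted exactly
    at the segment midpoint belongs to the distal segment.  Empty segments
    report count 0 and missing (NaN) lengths.
    """
    seg1, seg2 = [], []
    for lat in root.laterals:
        p = lat.insertion_position
        if zone.proximal_pos <= p < zone.midpoint:
            seg1.append(lat.length)
        elif zone.midpoint <= p <= zone.distal_pos:
            seg2.append(lat.length)

    def _summary(lengths: List[float], seg_len: float, tag: str) -> Dict[str, float]:
        if not lengths:
            return {
                f"No_Lat_{tag}": 0.0,
                f"Max_Lat_{tag}": float("nan"),
                f"Med_Lat_{tag}": float("nan"),
                f"density_{tag}": 0.0,
            }
        ordered = sorted(lengths)
        lower_median = ordered[(len(ordered) - 1) // 2]
        return {
            f"No_Lat_{tag}": float(len(ordered)),
            f"Max_Lat_{tag}": float(ordered[-1]),
            f"Med_Lat_{tag}": float(lower_median),
            f"density_{tag}": len(ordered) / seg_len,
        }

    half = zone.length / 2.0
    out = _summary(seg1, half, "1st")
    out.update(_summary(seg2, half, "2nd"))
    return out


def laterals_in_pre_change_zone(
    root_id: str,
    systems: Sequence[RootSystem],
    t_change: int,
    t_harvest: int,
) -> Tuple[int, int]:
    """Lateral counts in the pre-treatment zone ``[0, proximal)`` at
    solution change and at harvest.

    Used to check the stasis hypothesis that only tissue formed after the
    solution change responds to the local N supply.  The zone includes its
    anchor lateral (closed at ``proximal``); if there is no lateral at
    change the zone is empty and both counts are 0.
    """
    at_change = _system_at(systems, t_change).find(root_id)
    at_harvest = _system_at(systems, t_harvest).find(root_id)
    if at_change is None or at_harvest is None:
        raise RootLookupError(f"root {root_id!r} missing at change or harvest")
    proximal = _most_distal_insertion(at_change)
    if proximal is None:
        return (0, 0)
    count = lambda root: sum(
        1 for l in root.laterals if l.insertion_position <= proximal
    )
    return (count(at_change), count(at_harvest))
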