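"""Experiment design model, trait-table I/O and SPAD reduction.

A trial consists of slides hanging in the platform rack; each slide carries
one plant whose root system develops on both paper sides (front/back), and
each paper side is split by a wax barrier into a high-N and a low-N
compartment.  Genotypes are identified by their panel EU_ID integers;
display names are metadata.

Day indexing convention: day 0 = sowing into the slides, nutrient-solution
change (start of the split-N treatment) at day 14, harvest at day 26,
imaging every second day.  Downstream growth models re-origin their time
axes to the solution change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError

N_LEVELS = ("high", "low")
SIDES = ("front", "back")

#: Germination-paper geometry of the platform, cm.
DEFAULT_PAPER_WIDTH_CM = 49.0
DEFAULT_PAPER_HEIGHT_CM = 61.0


@dataclass(frozen=True)
class SlideGeometry:
    """Physical geometry of one germination paper."""

    width_cm: float = DEFAULT_PAPER_WIDTH_CM
    height_cm: float = DEFAULT_PAPER_HEIGHT_CM
    barrier_x_cm: float = DEFAULT_PAPER_WIDTH_CM / 2

    def __post_init__(self):
        if not (0 < self.barrier_x_cm < self.width_cm):
            raise IntegrityError("wax barrier must lie strictly inside the paper")


@dataclass
class PaperSide:
    """One paper side of a slide: two compartments with distinct N levels.

    ``compartments`` maps ``"left"``/``"right"`` (relative to the paper
    origin at the top-left corner, x rightward) to an N level.
    """

    side: str
    compartments: Dict[str, str]

    def __post_init__(self):
        if self.side not in SIDES:
            raise SchemaError(f"side must be one of {SIDES}, got {self.side!r}")
        if set(self.compartments) != {"left", "right"}:
            raise IntegrityError("each paper side needs a left and a right compartment")
        levels = set(self.compartments.values())
        if levels != set(N_LEVELS):
            raise IntegrityError(
                f"compartments of one side must carry distinct N levels "
                f"{{high, low}}, got {sorted(self.compartments.values())}"
            )

    def n_level_at(self, compartment: str) -> str:
        return self.compartments[compartment]


@dataclass
class SlideRecord:
    slide_id: str
    genotype_id: int
    replicate: int
    sides: Dict[str, PaperSide]
    geometry: SlideGeometry = field(default_factory=SlideGeometry)


@dataclass
class ExperimentDesign:
    """Validated design of one split-nitrogen rhizoslide trial."""

    slides: List[SlideRecord]
    solution_change_day: int = 14
    harvest_day: int = 26
    imaging_interval_days: int = 2

    def __post_init__(self):
        ids = [s.slide_id for s in self.slides]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate slide ids: {dupes}")
        if not self.solution_change_day < self.harvest_day:
            raise IntegrityError("solution change must precede harvest")

    @property
    def genotypes(self) -> List[int]:
        return sorted({s.genotype_id for s in self.slides})

    @property
    def n_replicates(self) -> int:
        return len({s.replicate for s in self.slides})


_DESIGN_COLUMNS = ["slide_id", "genotype", "replicate", "side", "compartment", "n_level"]


def load_design(path) -> ExperimentDesign:
    """Read a design CSV (one row per slide, side and compartment).

    Required columns: ``slide_id, genotype, replicate, side, compartment,
    n_level``.  Optional geometry columns ``paper_width_cm, paper_height_cm,
    barrier_x_cm`` default to the platform paper (49 x 61 cm, central
    barrier).  Replicates outside 1-4 are kept with a warning; duplicate
    (slide, side, compartment) keys and sides whose two compartments do not
    carry distinct high/low N levels are integrity errors.
    """
    df = pd.read_csv(path)
    missing = [c for c in _DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"design file missing required columns: {missing}")

    bad_levels = sorted(set(df["n_level"].astype(str)) - set(N_LEVELS))
    if bad_levels:
        raise SchemaError(f"n_level must be one of {N_LEVELS}, found {bad_levels}")

    dup = df.duplicated(subset=["slide_id", "side", "compartment"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["slide_id", "side", "compartment"]].drop_duplicates()
        raise IntegrityError(
            "duplicate (slide, side, compartment) rows: "
            + "; ".join("/".join(map(str, r)) for r in keys.itertuples(index=False))
        )

    odd_reps = sorted(set(df["replicate"].astype(int)) - {1, 2, 3, 4})
    if odd_reps:
        warnings.warn(
            f"replicate values outside the declared 1-4 design kept as-is: {odd_reps}",
            stacklevel=2,
        )

    slides: List[SlideRecord] = []
    for slide_id, grp in df.groupby("slide_id", sort=True):
        genotypes = grp["genotype"].unique()
        if len(genotypes) != 1:
            raise IntegrityError(f"slide {slide_id!r} maps to several genotypes")
        reps = grp["replicate"].unique()
        if len(reps) != 1:
            raise IntegrityError(f"slide {slide_id!r} maps to several replicates")
        sides: Dict[str, PaperSide] = {}
        for side, sgrp in grp.groupby("side"):
            comps = dict(zip(sgrp["compartment"].astype(str), sgrp["n_level"].astype(str)))
            sides[str(side)] = PaperSide(side=str(side), compartments=comps)
        geometry = SlideGeometry(
            width_cm=float(grp["paper_width_cm"].iloc[0]) if "paper_width_cm" in grp else DEFAULT_PAPER_WIDTH_CM,
            height_cm=float(grp["paper_height_cm"].iloc[0]) if "paper_height_cm" in grp else DEFAULT_PAPER_HEIGHT_CM,
            barrier_x_cm=float(grp["barrier_x_cm"].iloc[0]) if "barrier_x_cm" in grp else DEFAULT_PAPER_WIDTH_CM / 2,
        )
        slides.append(
            SlideRecord(
                slide_id=str(slide_id),
                genotype_id=int(genotypes[0]),
                replicate=int(reps[0]),
                sides=sides,
                geometry=geometry,
            )
        )
    return ExperimentDesign(slides=slides)


def write_design(design: ExperimentDesign, path) -> None:
    """Write a design back to its canonical CSV form (round-trips with
    :func:`load_design`)."""
    rows = []
    for s in design.slides:
        for side_name in sorted(s.sides):
            ps = s.sides[side_name]
            for comp in ("left", "right"):
                rows.append(
                    {
                        "slide_id": s.slide_id,
                        "genotype": s.genotype_id,
                        "replicate": s.replicate,
                        "side": side_name,
                        "compartment": comp,
                        "n_level": ps.compartments[comp],
                        "paper_width_cm": s.geometry.width_cm,
                        "paper_height_cm": s.geometry.height_cm,
                        "barrier_x_cm": s.geometry.barrier_x_cm,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SPAD

@dataclass(frozen=True)
class SpadTriple:
    """Chlorophyll-meter readings at leaf base, middle and tip."""

    base: float
    middle: float
    tip: float

    def __post_init__(self):
        for name in ("base", "middle", "tip"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ValueError(f"SPAD reading {name!r} is missing")
            if v < 0:
                raise ValueError(f"SPAD reading {name!r} is negative: {v}")


def average_spad(s: SpadTriple) -> float:
    """Arithmetic mean of the three per-leaf SPAD readings."""
    return (s.base + s.middle + s.tip) / 3.0


# ---------------------------------------------------------------------------
# Trait table

TRAIT_KEY = ["genotype", "n_level", "replicate", "side", "trait"]
TRAIT_COLUMNS = TRAIT_KEY + ["value", "units"]


@dataclass
class TraitTable:
    """Long-format trait records: one measurement per (genotype, N level,
    replicate, side, trait).

    ``n_level`` and ``side`` take the value ``"none"`` for whole-plant shoot
    traits that are not tied to a compartment or paper side.
    """

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in TRAIT_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"trait table missing columns: {missing}")
        df = self.df.loc[:, TRAIT_COLUMNS].copy()
        df["genotype"] = df["genotype"].astype(int)
        df["replicate"] = df["replicate"].astype(int)
        for c in ("n_level", "side", "trait", "units"):
            df[c] = df[c].astype(str)
        df["value"] = df["value"].astype(float)
        dup = df.duplicated(subset=TRAIT_KEY, keep=False)
        if dup.any():
            offenders = df.loc[dup, TRAIT_KEY].drop_duplicates()
            raise IntegrityError(
                f"duplicate trait keys:\n{offenders.to_string(index=False)}"
            )
        self.df = df.sort_values(["trait", "genotype", "replicate", "n_level", "side"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "TraitTable":
        return cls(pd.DataFrame(list(records)))

    @classmethod
    def read_csv(cls, path) -> "TraitTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, float_format="%.12g")

    def subset(self, trait: str) -> pd.DataFrame:
        return self.df[self.df["trait"] == str(trait)].copy()

    @property
    def traits(self) -> List[str]:
        return sorted(self.df["trait"].unique())


def merge_trait_tables(tables: Sequence[TraitTable]) -> TraitTable:
    """Concatenate trait tables, deduplicating identical records.

    Records sharing a key with *identical* values collapse to one; records
    sharing a key with conflicting values raise :class:`IntegrityError`
    listing the offenders.  The result is sorted by (trait, genotype,
    replicate), so merging is associative and order-insensitive.
    """
    if not tables:
        return TraitTable(pd.DataFrame(columns=TRAIT_COLUMNS))
    df = pd.concat([t.df for t in tables], ignore_index=True)
    df = df.drop_duplicates(subset=TRAIT_KEY + ["value"])
    dup = df.duplicated(subset=TRAIT_KEY, keep=False)
    if dup.any():
        offenders = df.loc[dup].sort_values(TRAIT_KEY)
        raise IntegrityError(
            "conflicting values for trait keys:\n"
            + offenders.to_string(index=False)
        )
    return TraitTable(df)
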