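import numpy as np
import pandas as pd
import pytest

from rhizoslides.experiment import TraitTable
from rhizoslides.root_traits import AxileRoot, LateralRoot, RootSystem


@pytest.fixture
def rng():
    return np.random.default_rng(20160905)


def make_axile(root_id="cr1", length=20.0, laterals=(), x=10.0, root_class="crown_whorl1"):
    """Vertical axile root of the given length with (position, length[, day])
    laterals."""
    lats = []
    for i, spec in enumerate(laterals):
        pos, ln, *rest = spec
        lats.append(LateralRoot(
            id=f"{root_id}.l{i + 1}",
            insertion_position=float(pos),
            length=float(ln),
            emergence_timepoint=rest[0] if rest else None,
            polyline=np.array([[x, pos], [x + ln, pos]]),
        ))
    return AxileRoot(
        id=root_id,
        root_class=root_class,
        polyline=np.array([[x, 0.0], [x, float(length)]]),
        laterals=lats,
    )


def make_system(timepoint, axile_roots, **kw):
    return RootSystem(timepoint=timepoint, axile_roots=list(axile_roots), **kw)


def trait_records(values, trait="ER_Cr", units="cm/d"):
    """Long-format records from a {(genotype, n_level, rep, side): value} map."""
    rows = []
    for (g, lvl, rep, side), v in values.items():
        rows.append({"genotype": g, "n_level": lvl, "replicate": rep,
                     "side": side, "trait": trait, "value": v, "units": units})
    return TraitTable(pd.DataFrame(rows))
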