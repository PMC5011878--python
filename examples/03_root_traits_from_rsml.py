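"""Extract branching-zone lateral-root traits from RSML traces.

Builds RSML files for one crown root at solution change (day 14) and at
harvest (day 26), reads them back and computes the branching zone and the
per-segment lateral traits.
"""

import tempfile
from pathlib import Path

import numpy as np

from rhizoslides import (
    AxileRoot,
    LateralRoot,
    RootSystem,
    branching_zone,
    lateral_metrics,
    laterals_in_pre_change_zone,
    read_rsml,
    write_rsml,
)


def crown_root(laterals):
    lats = [
        LateralRoot(id=f"l{i}", insertion_position=pos, length=ln,
                    polyline=np.array([[10.0, pos], [10.0 + ln, pos]]))
        for i, (pos, ln) in enumerate(laterals)
    ]
    return AxileRoot(id="cr1", root_class="crown_whorl1",
                     polyline=np.array([[10.0, 0.0], [10.0, 20.0]]),
                     laterals=lats)


with tempfile.TemporaryDirectory() as d:
    p14, p26 = Path(d) / "day14.rsml", Path(d) / "day26.rsml"
    write_rsml(RootSystem(14, [crown_root([(3.0, 1.0), (6.0, 0.8)])]), p14)
    write_rsml(RootSystem(26, [crown_root(
        [(3.0, 1.0), (6.0, 0.9), (8.5, 1.4), (11.0, 2.1), (14.0, 0.6)])]), p26)
    systems = [read_rsml(p14), read_rsml(p26)]

zone = branching_zone("cr1", systems, t_change=14, t_harvest=26)
print(f"branching zone: [{zone.proximal_pos:.1f}, {zone.distal_pos:.1f}] cm "
      f"(segments {zone.segment1} / {zone.segment2})")
for key, val in lateral_metrics(systems[1].axile_roots[0], zone).items():
    print(f"  {key:12s} = {val:.3g}")
before, after = laterals_in_pre_change_zone("cr1", systems, 14, 26)
print(f"laterals in the pre-change zone: {before} at change, {after} at harvest")
print("The zone spans the most distal lateral at solution change to the most")
print("distal at harvest; only tissue formed after the change responds to N.")
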