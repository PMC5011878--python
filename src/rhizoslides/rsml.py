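"""Root System Markup Language (RSML) input/output.

RSML is the XML interchange format exported by root-tracing software; one
file describes the traced architecture of one slide side at one timepoint.
The reader converts coordinates to cm using the file's unit/resolution
metadata:

* ``unit = "cm"`` — coordinates used as-is;
* ``unit = "mm"`` — divided by 10;
* ``unit = "pixel"`` — multiplied by ``resolution`` (interpreted as mm per
  pixel) and divided by 10.  If the resolution element is absent, the
  platform default of 0.13 mm per pixel is assumed with a warning.

Axile roots are top-level ``<root>`` elements; their first-order children
are lateral roots.  Root classes and per-root annotations (emergence day,
insertion position) travel in the ``label`` attribute and ``<properties>``
block; when a lateral's insertion position is not annotated it is recovered
by projecting the lateral's first point onto the parent polyline.
"""

from __future__ import annotations

import warnings
from typing import List, Optional

import numpy as np
from lxml import etree

from .errors import IntegrityError
from .raster import DEFAULT_SCALE_MM_PER_PX
from .root_traits import AxileRoot, LateralRoot, RootSystem, polyline_length


def _arc_position(parent: np.ndarray, point: np.ndarray) -> float:
    """Arc distance along *parent* of the point on it nearest to *point*."""
    seg_starts = parent[:-1]
    seg_vecs = np.diff(parent, axis=0)
    seg_lens = np.hypot(*seg_vecs.T)
    cum = np.concatenate([[0.0], np.cumsum(seg_lens)])
    best_d2, best_arc = np.inf, 0.0
    for i, (s, v, L) in enumerate(zip(seg_starts, seg_vecs, seg_lens)):
        if L == 0:
            continue
        t = float(np.clip(np.dot(point - s, v) / (L * L), 0.0, 1.0))
        proj = s + t * v
        d2 = float(np.sum((point - proj) ** 2))
        if d2 < best_d2:
            best_d2, best_arc = d2, cum[i] + t * L
    return best_arc


def _parse_polyline(root_el, to_cm: float) -> np.ndarray:
    pts = root_el.findall("./geometry/polyline/point")
    if len(pts) < 2:
        raise IntegrityError(
            f"root {root_el.get('id') or root_el.get('ID')!r}: polyline needs >= 2 points"
        )
    xy = np.array([[float(p.get("x")), float(p.get("y"))] for p in pts], dtype=float)
    return xy * to_cm


def _properties(root_el) -> dict:
    props = {}
    for p in root_el.findall("./properties/property"):
        props[p.get("name")] = p.get("value")
    return props


def read_rsml(path, default_scale_mm_per_px: float = DEFAULT_SCALE_MM_PER_PX) -> RootSystem:
    """Parse an RSML file into a :class:`~rhizoslides.root_traits.RootSystem`."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise IntegrityError(f"malformed RSML: {exc}") from exc
    root = tree.getroot()

    unit_el = root.find("./metadata/unit")
    res_el = root.find("./metadata/resolution")
    unit = unit_el.text.strip().lower() if unit_el is not None and unit_el.text else "pixel"
    if unit == "cm":
        to_cm = 1.0
    elif unit == "mm":
        to_cm = 0.1
    else:  # pixel coordinates
        if res_el is not None and res_el.text:
            mm_per_px = float(res_el.text)
        else:
            warnings.warn(
                "RSML has pixel coordinates but no resolution metadata; "
                f"assuming {default_scale_mm_per_px} mm per pixel",
                stacklevel=2,
            )
            mm_per_px = default_scale_mm_per_px
        to_cm = mm_per_px / 10.0

    timepoint = 0
    tp_meta = root.find("./metadata/timepoint")
    if tp_meta is not None and tp_meta.text:
        timepoint = int(float(tp_meta.text))

    scene = root.find("./scene")
    if scene is None:
        raise IntegrityError("RSML has no <scene> element")

    axile_roots: List[AxileRoot] = []
    seen_ids = set()
    for plant in scene.findall("./plant"):
        for root_el in plant.findall("./root"):
            rid = root_el.get("id") or root_el.get("ID")
            if rid is None:
                raise IntegrityError("axile root without id attribute")
            if rid in seen_ids:
                raise IntegrityError(f"duplicate root id {rid!r}")
            seen_ids.add(rid)
            label = (root_el.get("label") or "crown_whorl1").strip()
            props = _properties(root_el)
            poly = _parse_polyline(root_el, to_cm)
            laterals = []
            for lat_el in root_el.findall("./root"):
                lid = lat_el.get("id") or lat_el.get("ID")
                if lid is None:
                    raise IntegrityError(f"lateral of root {rid!r} without id")
                lprops = _properties(lat_el)
                parent_ref = lat_el.get("parent") or lprops.get("parent")
                if parent_ref is not None and parent_ref != rid:
                    raise IntegrityError(
                        f"lateral {lid!r} references parent {parent_ref!r}, "
                        f"which is not its enclosing root {rid!r}"
                    )
                lpoly = _parse_polyline(lat_el, to_cm)
                if "insertion_position" in lprops:
                    # annotated insertion positions are always stored in cm
                    ins = float(lprops["insertion_position"])
                else:
                    ins = _arc_position(poly, lpoly[0])
                emergence = (
                    int(float(lprops["emergence_day"]))
                    if "emergence_day" in lprops
                    else None
                )
                laterals.append(
                    LateralRoot(
                        id=lid,
                        insertion_position=ins,
                        length=polyline_length(lpoly),
                        emergence_timepoint=emergence,
                        polyline=lpoly,
                    )
                )
            axile_roots.append(
                AxileRoot(id=rid, root_class=label, polyline=poly, laterals=laterals)
            )

    return RootSystem(
        timepoint=timepoint,
        axile_roots=axile_roots,
        slide_id=root.get("slide_id", "") or "",
        side=root.get("side", "front") or "front",
        scale_mm_per_px=None if unit == "cm" else to_cm * 10.0,
    )


def write_rsml(
    system: RootSystem,
    path,
    unit: str = "cm",
    resolution_mm_per_px: Optional[float] = None,
) -> None:
    """Serialise a :class:`RootSystem` to RSML.

    With ``unit="cm"`` coordinates are written as-is; with ``unit="pixel"``
    they are converted using *resolution_mm_per_px* (cm -> px), and the
    resolution is recorded in the metadata so the reader can invert it.
    """
    if unit == "cm":
        from_cm = 1.0
    elif unit == "pixel":
        if not resolution_mm_per_px:
            raise ValueError("pixel output needs resolution_mm_per_px")
        from_cm = 10.0 / resolution_mm_per_px
    else:
        raise ValueError("unit must be 'cm' or 'pixel'")

    rsml = etree.Element("rsml", slide_id=system.slide_id, side=system.side)
    meta = etree.SubElement(rsml, "metadata")
    etree.SubElement(meta, "version").text = "1"
    etree.SubElement(meta, "unit").text = unit
    if unit == "pixel":
        etree.SubElement(meta, "resolution").text = f"{resolution_mm_per_px:.10g}"
    etree.SubElement(meta, "software").text = "rhizoslides"
    etree.SubElement(meta, "timepoint").text = str(system.timepoint)

    scene = etree.SubElement(rsml, "scene")
    plant = etree.SubElement(scene, "plant", id="plant_1")

    def _write_poly(el, poly):
        geom = etree.SubElement(el, "geometry")
        pl = etree.SubElement(geom, "polyline")
        for x, y in np.asarray(poly, dtype=float) * from_cm:
            etree.SubElement(pl, "point", x=f"{x:.10g}", y=f"{y:.10g}")

    for root in system.axile_roots:
        rel = etree.SubElement(plant, "root", id=root.id, label=root.root_class)
        _write_poly(rel, root.polyline)
        for lat in root.laterals:
            lel = etree.SubElement(rel, "root", id=lat.id, label="lateral", parent=root.id)
            props = etree.SubElement(lel, "properties")
            etree.SubElement(
                props, "property",
                name="insertion_position", value=f"{lat.insertion_position:.10g}",
            )
            if lat.emergence_timepoint is not None:
                etree.SubElement(
                    props, "property",
                    name="emergence_day", value=str(lat.emergence_timepoint),
                )
            if lat.polyline is not None:
                _write_poly(lel, lat.polyline)
            else:
                # synthesise a straight lateral of the recorded length,
                # perpendicular placement is irrelevant to trait extraction
                x0, y0 = np.asarray(root.polyline[0], dtype=float)
                _write_poly(lel, [[x0, y0], [x0 + lat.length, y0]])
    etree.ElementTree(rsml).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
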