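"""Predefined 2D template: perimeter, anchors and the 24-region partition.

The unfolded atrium is a disk whose perimeter is the mitral annulus.  The
template tiles that disk into 24 labeled regions: one disk and one ostial
ring per pulmonary vein (8), one appendage region, and 15 body sectors
(roof x3 in the center, a middle annulus of posterior x3 / anterior x3 /
lateral x2 / septal x2, and floor x2 next to the mitral rim).  The exact
region outlines used in clinical unfolding tools are not standardized; this
template is an explicit, versioned, anchor-driven stand-in that users can
replace by loading their own JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Point, Polygon

TEMPLATE_VERSION = "1.0"

#: region ids are 1..24 in this order
PV_ORDER = ("LSPV", "LIPV", "RSPV", "RIPV")
_SECTOR_PLAN = [
    ("roof", 3),
    ("posterior", 3),
    ("anterior", 3),
    ("lateral", 2),
    ("septal", 2),
    ("floor", 2),
]


class TemplateError(ValueError):
    pass


@dataclass
class Template2D:
    perimeter: Polygon
    anchors: dict  # name -> (x, y)
    regions: list  # of (region_id, name, shapely geometry)
    version: str = TEMPLATE_VERSION
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.regions) != 24:
            raise TemplateError(f"template must have 24 regions, got {len(self.regions)}")

    def region_ids(self):
        return [r[0] for r in self.regions]

    def region_names(self):
        return {r[0]: r[1] for r in self.regions}

    # ------------------------------------------------------------------
    def to_json(self) -> str:
        def poly_coords(geom):
            if geom.geom_type == "Polygon":
                return [list(map(list, geom.exterior.coords))] + [
                    list(map(list, i.coords)) for i in geom.interiors
                ]
            return [poly_coords(g) for g in geom.geoms]

        payload = {
            "version": self.version,
            "perimeter": list(map(list, self.perimeter.exterior.coords)),
            "anchors": {k: list(v) for k, v in self.anchors.items()},
            "regions": [
                {
                    "id": rid,
                    "name": name,
                    "type": geom.geom_type,
                    "wkt": geom.wkt,
                }
                for rid, name, geom in self.regions
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Template2D":
        payload = json.loads(text)
        regions = [
            (r["id"], r["name"], shapely.from_wkt(r["wkt"])) for r in payload["regions"]
        ]
        return cls(
            perimeter=Polygon(payload["perimeter"]),
            anchors={k: tuple(v) for k, v in payload["anchors"].items()},
            regions=regions,
            version=payload.get("version", TEMPLATE_VERSION),
        )


def _circle(center, r, n=128) -> Polygon:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Polygon(np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)]))


def _wedge(r_in, r_out, a0, a1, n=64) -> Polygon:
    """Annulus sector between radii and angles (radians)."""
    th = np.linspace(a0, a1, n)
    outer = np.column_stack([r_out * np.cos(th), r_out * np.sin(th)])
    if r_in > 0:
        inner = np.column_stack([r_in * np.cos(th[::-1]), r_in * np.sin(th[::-1])])
        pts = np.vstack([outer, inner])
    else:
        pts = np.vstack([outer, [[0.0, 0.0]]])
    return Polygon(pts)


_DEFAULT_ANCHORS = {
    "LSPV": (-0.42, 0.38),
    "LIPV": (-0.52, -0.18),
    "RSPV": (0.42, 0.38),
    "RIPV": (0.52, -0.18),
    "appendage": (-0.12, 0.55),
}


def _assemble_template(
    perimeter: Polygon,
    anchors: dict,
    disks: dict,
    rings: dict,
    meta: dict | None = None,
) -> Template2D:
    """Assemble the 24-region list from per-feature disk/ring geometries.

    Disjointness is enforced by sequential difference in region order (PV
    disks, then ostial rings, then the appendage, then body sectors), so
    earlier regions shadow later ones where raw geometries overlap.
    """
    regions = []
    claimed = None
    rid = 1

    def push(name, geom):
        nonlocal claimed, rid
        geom = geom if claimed is None else geom.difference(claimed)
        if geom.is_empty:
            raise TemplateError(f"region {name} is empty after overlap resolution")
        claimed = geom if claimed is None else shapely.unary_union([claimed, geom])
        regions.append((rid, name, geom))
        rid += 1

    for n in PV_ORDER:
        push(n, disks[n])
    for n in PV_ORDER:
        push(f"{n}_ostium", rings[n])
    push("appendage", disks["appendage"])

    body = perimeter.difference(claimed)
    # radial bands as fractions of the perimeter radius
    r_max = float(np.linalg.norm(np.asarray(perimeter.exterior.coords), axis=1).max())
    r1, r2 = 0.38 * r_max, 0.72 * r_max
    bands = {"roof": (0.0, r1), "mid": (r1, r2), "floor": (r2, 1.02 * r_max)}
    mid_order = ["posterior"] * 3 + ["anterior"] * 3 + ["lateral"] * 2 + ["septal"] * 2
    layout = (
        [("roof", bands["roof"], k, 3) for k in range(3)]
        + [(mid_order[k], bands["mid"], k, 10) for k in range(10)]
        + [("floor", bands["floor"], k, 2) for k in range(2)]
    )
    counters: dict[str, int] = {}
    for name, (ri, ro), k, total in layout:
        a0 = 2 * np.pi * k / total
        a1 = 2 * np.pi * (k + 1) / total
        geom = _wedge(ri, ro, a0, a1).intersection(body)
        if geom.is_empty:
            raise TemplateError(f"body sector {name}[{k}] is empty; anchors too large")
        counters[name] = counters.get(name, 0) + 1
        regions.append((rid, f"{name}_{counters[name]}", geom))
        rid += 1

    return Template2D(
        perimeter=perimeter,
        anchors={k: tuple(v) for k, v in anchors.items()},
        regions=regions,
        meta=meta or {},
    )


def build_template(
    anchors: dict | None = None,
    pv_radius: float = 0.10,
    appendage_radius: float = 0.12,
    radius: float = 1.0,
) -> Template2D:
    """Default circular template: PV disks with ostial rings of twice the
    disk radius around fixed anchors, appendage disk, 15 body sectors.

    ``radius`` scales the whole template (perimeter, anchors, disk radii);
    matching it to mitral-rim-length / 2 pi reduces area distortion of the
    unfolding.
    """
    anchors = dict(_DEFAULT_ANCHORS if anchors is None else anchors)
    missing = {*PV_ORDER, "appendage"} - set(anchors)
    if missing:
        raise TemplateError(f"anchors missing: {sorted(missing)}")
    pos = {n: radius * np.asarray(anchors[n], float) for n in anchors}
    disks = {n: _circle(pos[n], radius * pv_radius) for n in PV_ORDER}
    disks["appendage"] = _circle(pos["appendage"], radius * appendage_radius)
    rings = {
        n: _circle(pos[n], 2 * radius * pv_radius).difference(disks[n]) for n in PV_ORDER
    }
    return _assemble_template(
        _circle((0, 0), radius),
        {k: tuple(v) for k, v in pos.items()},
        disks,
        rings,
        meta={"pv_radius": pv_radius, "appendage_radius": appendage_radius, "radius": radius},
    )


def template_from_unfolded(
    uv: np.ndarray, vertex_labels: np.ndarray, label_codes: dict
) -> Template2D:
    """Anchor-driven template fitted to an unfolded map.

    Each PV/appendage region is the convex hull of the unfolded positions of
    its rim vertices with a small margin (harmonic maps make the holes small
    and eccentric, so circles of one radius do not fit them); the ostial
    rings grow adaptively until they capture a few peri-ostial vertices.
    """
    uv = np.asarray(uv, dtype=float)
    anchors = {}
    disks = {}
    rings = {}
    hulls = {}
    for name in list(PV_ORDER) + ["appendage"]:
        sel = vertex_labels == label_codes[name]
        if not sel.any():
            raise TemplateError(f"label class {name} missing from the unfolded map")
        pts = uv[sel]
        c = pts.mean(axis=0)
        anchors[name] = tuple(c)
        spread = float(np.linalg.norm(pts - c, axis=1).max())
        hull = shapely.MultiPoint(pts).convex_hull.buffer(max(0.15 * spread, 5e-3))
        hulls[name] = (hull, spread, sel)
        disks[name] = hull
    others = lambda n: shapely.unary_union([hulls[m][0] for m in hulls if m != n])
    for name in PV_ORDER:
        hull, spread, sel = hulls[name]
        width = 0.4 * spread
        ring = None
        for _ in range(5):
            cand = hull.buffer(width).difference(hull).difference(others(name))
            covered = shapely.covers(cand, shapely.points(uv[~sel]))
            if covered.sum() >= 3:
                ring = cand
                break
            width *= 1.8
        if ring is None:
            raise TemplateError(f"could not grow a populated ostial ring for {name}")
        rings[name] = ring
    return _assemble_template(
        _circle((0, 0), 1.0), anchors, disks, rings, meta={"fitted": True}
    )


def point_region_ids(template: Template2D, xy: np.ndarray):
    """Region id per point (0 where no region covers the point).

    Regions are tested in template order, so PV disks shadow their rings and
    rings shadow the body sectors on shared boundaries.
    """
    xy = np.asarray(xy, dtype=float)
    out = np.zeros(len(xy), dtype=np.int64)
    todo = np.ones(len(xy), dtype=bool)
    for rid, _, geom in template.regions:
        if not todo.any():
            break
        hit = shapely.covers(geom, shapely.points(xy[todo]))
        idx = np.where(todo)[0][hit]
        out[idx] = rid
        todo[idx] = False
    return out


def snap_to_regions(template: Template2D, xy: np.ndarray, ids: np.ndarray):
    """Assign each uncovered point (id 0) to its nearest region; returns the
    completed ids and the snap count."""
    miss = np.where(ids == 0)[0]
    for i in miss:
        p = Point(xy[i])
        dists = [(geom.distance(p), rid) for rid, _, geom in template.regions]
        ids[i] = min(dists)[1]
    return ids, len(miss)
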