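"""Core annotations (GeoJSON) and the CoreSample container.

Annotations arrive as a GeoJSON FeatureCollection in μm image coordinates
(origin top-left, y increasing downward). Each feature carries properties
``core_id`` and ``role`` in {``tissue``, ``exclusion``, ``cd21_meshwork``}.
Exactly one tissue polygon per core; exclusions mark artefact areas removed
from both the cell set and the tissue area; cd21_meshwork polygons outline
follicular dendritic meshwork regions.

Cells on a polygon boundary count as inside (closed polygons), so filtering
is deterministic; a cell on an exclusion boundary is therefore excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import shapely
from shapely.geometry import mapping as shp_mapping, shape as shp_shape
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .errors import FormatError, GeometryError, ValidationError

ROLES = ("tissue", "exclusion", "cd21_meshwork")

UM2_PER_MM2 = 1e6


@dataclass
class CoreAnnotations:
    """Polygons for one TMA core, in μm."""

    core_id: str
    tissue: Polygon
    exclusions: list[Polygon] = field(default_factory=list)
    cd21_meshwork: list[Polygon] = field(default_factory=list)

    def validate(self) -> None:
        for name, polys in (
            ("tissue", [self.tissue]),
            ("exclusion", self.exclusions),
            ("cd21_meshwork", self.cd21_meshwork),
        ):
            for p in polys:
                if not p.is_valid:
                    raise GeometryError(
                        f"core {self.core_id}: invalid {name} polygon "
                        f"({shapely.is_valid_reason(p)})"
                    )

    @property
    def tissue_area_mm2(self) -> float:
        """Tissue polygon area minus artefact exclusions, in mm²."""
        area = self.tissue.area
        if self.exclusions:
            area -= unary_union(self.exclusions).intersection(self.tissue).area
        return area / UM2_PER_MM2


@dataclass
class CoreSample:
    """One TMA core: its retained cells plus annotation geometry.

    ``cells`` holds only cells inside the tissue polygon and outside every
    exclusion polygon (boundary-inclusive on both).
    """

    core_id: str
    patient_id: str
    cells: pd.DataFrame
    annotations: CoreAnnotations

    @property
    def tissue_area_mm2(self) -> float:
        return self.annotations.tissue_area_mm2


def read_annotations(path: str | Path) -> dict[str, CoreAnnotations]:
    """Read a GeoJSON FeatureCollection into per-core annotation sets."""
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    tissue: dict[str, Polygon] = {}
    extras: dict[str, dict[str, list[Polygon]]] = {}
    for feat in data.get("features", []):
        props = feat.get("properties") or {}
        core_id = props.get("core_id")
        role = props.get("role")
        if core_id is None or role not in ROLES:
            raise FormatError(
                f"{path}: every feature needs properties core_id and "
                f"role in {ROLES} (got {props})"
            )
        geom = shp_shape(feat["geometry"])
        core_id = str(core_id)
        if role == "tissue":
            if core_id in tissue:
                raise FormatError(f"{path}: duplicate tissue polygon for core {core_id}")
            tissue[core_id] = geom
        else:
            extras.setdefault(core_id, {"exclusion": [], "cd21_meshwork": []})[
                role
            ].append(geom)
    out: dict[str, CoreAnnotations] = {}
    for core_id, tis in tissue.items():
        ex = extras.get(core_id, {})
        ann = CoreAnnotations(
            core_id=core_id,
            tissue=tis,
            exclusions=ex.get("exclusion", []),
            cd21_meshwork=ex.get("cd21_meshwork", []),
        )
        ann.validate()
        out[core_id] = ann
    return out


def write_annotations(annotations: dict[str, CoreAnnotations], path: str | Path) -> None:
    features = []
    for core_id, ann in annotations.items():
        features.append(_feature(ann.tissue, core_id, "tissue"))
        features.extend(_feature(p, core_id, "exclusion") for p in ann.exclusions)
        features.extend(
            _feature(p, core_id, "cd21_meshwork") for p in ann.cd21_meshwork
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def _feature(poly: Polygon, core_id: str, role: str) -> dict:
    return {
        "type": "Feature",
        "properties": {"core_id": core_id, "role": role},
        "geometry": shp_mapping(poly),
    }


def build_cores(
    cells: pd.DataFrame, annotations: dict[str, CoreAnnotations]
) -> list[CoreSample]:
    """Group a cell table by core and apply the tissue/exclusion filters."""
    cores: list[CoreSample] = []
    for core_id, group in cells.groupby("core_id", sort=True):
        core_id = str(core_id)
        if core_id not in annotations:
            raise ValidationError(f"no annotations for core {core_id!r}")
        ann = annotations[core_id]
        if ann.tissue_area_mm2 <= 0:
            raise ValidationError(f"core {core_id}: non-positive tissue area")
        pts = shapely.points(group["x_um"].to_numpy(float), group["y_um"].to_numpy(float))
        keep = shapely.covers(ann.tissue, pts)
        for ex in ann.exclusions:
            keep &= ~shapely.covers(ex, pts)
        patient = (
            str(group["patient_id"].iloc[0]) if "patient_id" in group.columns else ""
        )
        cores.append(
            CoreSample(
                core_id=core_id,
                patient_id=patient,
                cells=group.loc[keep].reset_index(drop=True),
                annotations=ann,
            )
        )
    return cores
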