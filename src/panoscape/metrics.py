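"""Landscape-pattern metrics on categorical scene rasters.

The visual pattern of a street scene is measured by analogy with landscape
ecology: connected same-category pixel regions are *patches*, categories are
*classes*, and the whole scene is the *landscape*.  Three metrics are
computed, all area-ratio quantities, so pixel counts on an equal-area
(Hammer) raster stand in for physical areas:

* PLAND — percentage of the scene occupied by one category,
  ``100 * sum_j a_ij / A``.
* DIVISION — landscape division index ``1 - sum_ij (a_ij / A)**2``, the
  probability that two random points fall in different patches; higher
  means a more fragmented scene.
* SHDI — Shannon's diversity index ``-sum_i P_i ln P_i`` over category
  proportions; higher means richer / more even composition.

Patch connectivity defaults to 8-connected (the FRAGSTATS convention);
4-connected is available everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .color import COLOR_CLASSES, ColorRules, classify_raster
from .projection import equirect_to_hammer
from .rasters import SphericalRaster

OTHER = "other"

STREET_SCALES = ("small", "medium", "large")

#: layer tags
ELEMENTS = "constituent_elements"
COLORS = "colors"

#: the ten model covariates (five per layer)
ELEMENT_COVARIATES = ["pland_plant", "pland_sky", "pland_road", "division_ce", "shdi_ce"]
COLOR_COVARIATES = ["pland_green", "pland_blue", "pland_red", "division_co", "shdi_co"]


@dataclass
class ClassScheme:
    """Ordered scene categories plus the raw-id -> category mapping.

    ``mapping`` sends raw label ids (e.g. ADE20K's 0-149, or color-class
    indices) to a category name or :data:`OTHER`.  ``OTHER`` is always a
    real category for landscape-level metrics (it occupies visual field)
    but is not emitted as a model covariate.
    """

    categories: list[str]
    mapping: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("categories must be distinct")
        if OTHER in self.categories:
            raise ValueError(f"{OTHER!r} is implicit; do not list it")
        bad = {v for v in self.mapping.values() if v != OTHER and v not in self.categories}
        if bad:
            raise ValueError(f"mapping targets not in categories: {sorted(bad)}")

    @property
    def all_categories(self) -> list[str]:
        return list(self.categories) + [OTHER]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassScheme":
        raw = yaml.safe_load(Path(path).read_text())
        categories = [c for c in raw if c != OTHER]
        mapping = {}
        for cat, ids in raw.items():
            for i in ids or []:
                mapping[int(i)] = cat
        return cls(categories, mapping)

    def to_yaml(self, path: str | Path) -> None:
        out: dict[str, list[int]] = {c: [] for c in self.all_categories}
        for i, cat in sorted(self.mapping.items()):
            out[cat].append(int(i))
        Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


@dataclass(frozen=True)
class Patch:
    """A maximal connected same-category pixel region."""

    category: int
    area: int


def group_labels(src: SphericalRaster, scheme: ClassScheme) -> SphericalRaster:
    """Map a raw-id raster to category indices (into ``scheme.all_categories``).

    Every id present under the mask must be mapped; unmapped ids raise with
    the offending list.
    """
    if src.is_rgb:
        raise ValueError("group_labels expects a categorical raster")
    mask = src.valid_mask()
    present = np.unique(src.values[mask])
    unmapped = [int(i) for i in present if int(i) not in scheme.mapping]
    if unmapped:
        raise KeyError(f"unmapped raw label ids: {unmapped}")
    names = scheme.all_categories
    lut = np.zeros(int(present.max()) + 1 if present.size else 1, dtype=np.int64)
    for i in present:
        lut[int(i)] = names.index(scheme.mapping[int(i)])
    out = np.zeros_like(src.values, dtype=np.int64)
    out[mask] = lut[src.values[mask]]
    return SphericalRaster(out, src.geometry, src.mask)


def _masked_counts(src: SphericalRaster):
    mask = src.valid_mask()
    total = int(mask.sum())
    if total == 0:
        raise ValueError("empty mask: no valid pixels")
    vals = src.values[mask]
    labels, counts = np.unique(vals, return_counts=True)
    return labels, counts, total


def pland(src: SphericalRaster, names: list[str] | None = None) -> dict:
    """Percent of the valid area occupied by each present category.

    Returns a dict keyed by category value (or by name if ``names`` is
    given); absent categories are simply absent from the dict.  Values sum
    to 100.
    """
    labels, counts, total = _masked_counts(src)
    out = {}
    for lab, c in zip(labels, counts):
        key = names[int(lab)] if names is not None else int(lab)
        out[key] = 100.0 * float(c) / total
    return out


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError("connectivity must be 4 or 8")


def label_patches(src: SphericalRaster, connectivity: int = 8) -> list[Patch]:
    """Partition the valid pixels into maximal connected same-category patches."""
    if src.is_rgb:
        raise ValueError("label_patches expects a categorical raster")
    structure = _structure(connectivity)
    mask = src.valid_mask()
    if not mask.any():
        raise ValueError("empty mask: no valid pixels")
    patches: list[Patch] = []
    for cat in np.unique(src.values[mask]):
        comp, n = ndimage.label((src.values == cat) & mask, structure=structure)
        if n:
            areas = np.bincount(comp.ravel())[1:]
            patches.extend(Patch(int(cat), int(a)) for a in areas)
    return patches


def division(src: SphericalRaster, connectivity: int = 8) -> float:
    """Landscape division index ``1 - sum (a_ij / A)**2`` in ``[0, 1)``."""
    patches = label_patches(src, connectivity)
    total = sum(p.area for p in patches)
    return 1.0 - sum((p.area / total) ** 2 for p in patches)


def shdi(src: SphericalRaster) -> float:
    """Shannon's diversity index ``-sum P_i ln P_i`` over present categories."""
    _, counts, total = _masked_counts(src)
    p = counts / total
    return float(-(p * np.log(p)).sum())


@dataclass
class SceneAudit:
    """Per-scene visual-pattern indicator vector for one layer."""

    scene_id: str
    layer: str
    street_scale: str
    pland: dict[str, float]
    division: float
    shdi: float

    def __post_init__(self) -> None:
        if self.street_scale not in STREET_SCALES:
            raise ValueError(f"street_scale must be one of {STREET_SCALES}")
        if not (0.0 <= self.division < 1.0):
            raise ValueError("DIVISION out of [0, 1)")
        if self.shdi < 0.0:
            raise ValueError("SHDI must be nonnegative")

    def row(self) -> dict:
        out = {
            "scene_id": self.scene_id,
            "layer": self.layer,
            "street_scale": self.street_scale,
        }
        for cat, val in self.pland.items():
            out[f"pland_{cat}"] = val
        out["division"] = self.division
        out["shdi"] = self.shdi
        return out


def audit_scene(
    element_raster: SphericalRaster,
    color_source: SphericalRaster,
    scheme: ClassScheme,
    rules: ColorRules | None = None,
    street_scale: str = "medium",
    scene_id: str = "scene",
    out_width: int | None = None,
    connectivity: int = 8,
) -> tuple[SceneAudit, SceneAudit]:
    """Audit one scene on both layers (constituent elements and colors).

    ``element_raster`` holds raw segmentation ids; ``color_source`` is either
    the RGB panorama (classified here on the equirectangular grid, before
    reprojection, so interpolated colors are never classified) or an already
    categorical color raster.  Both are resampled to the Hammer ellipse with
    nearest-neighbor sampling and measured there, where pixel counts are
    solid-angle proportions.
    """
    if element_raster.values.shape[:2] != color_source.values.shape[:2]:
        raise ValueError("element and color rasters must share pixel geometry")
    grouped = group_labels(element_raster, scheme)
    elem_hammer = equirect_to_hammer(grouped, out_width, "nearest")
    if color_source.is_rgb:
        color_codes = classify_raster(color_source, rules)
    else:
        color_codes = color_source
    color_hammer = equirect_to_hammer(color_codes, out_width, "nearest")

    elem_audit = SceneAudit(
        scene_id=scene_id,
        layer=ELEMENTS,
        street_scale=street_scale,
        pland=pland(elem_hammer, names=scheme.all_categories),
        division=division(elem_hammer, connectivity),
        shdi=shdi(elem_hammer),
    )
    color_audit = SceneAudit(
        scene_id=scene_id,
        layer=COLORS,
        street_scale=street_scale,
        pland=pland(color_hammer, names=list(COLOR_CLASSES)),
        division=division(color_hammer, connectivity),
        shdi=shdi(color_hammer),
    )
    return elem_audit, color_audit


def audits_to_frame(audits: list[SceneAudit]):
    """Long-format audit table (one row per scene x layer)."""
    import pandas as pd

    rows = [a.row() for a in audits]
    df = pd.DataFrame(rows)
    front = ["scene_id", "layer", "street_scale"]
    metric_cols = [c for c in df.columns if c not in front]
    return df[front + metric_cols]


def covariate_table(audit_frame):
    """Pivot the long audit table into one row per scene carrying the ten
    model covariates (five per layer) plus the street-scale label."""
    import pandas as pd

    rename_elem = {
        "pland_plant": "pland_plant",
        "pland_sky": "pland_sky",
        "pland_road": "pland_road",
        "division": "division_ce",
        "shdi": "shdi_ce",
    }
    rename_col = {
        "pland_green": "pland_green",
        "pland_blue": "pland_blue",
        "pland_red": "pland_red",
        "division": "division_co",
        "shdi": "shdi_co",
    }
    elems = audit_frame[audit_frame["layer"] == ELEMENTS].set_index("scene_id")
    cols = audit_frame[audit_frame["layer"] == COLORS].set_index("scene_id")
    out = pd.DataFrame(index=elems.index)
    out["street_scale"] = elems["street_scale"]
    for src_col, dst in rename_elem.items():
        out[dst] = elems[src_col] if src_col in elems else 0.0
    for src_col, dst in rename_col.items():
        out[dst] = cols[src_col] if src_col in cols else 0.0
    out = out.fillna(0.0)
    return out.reset_index()
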