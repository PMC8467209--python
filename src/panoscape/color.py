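"""Six-class HSV color classification of street panoramas.

Each RGB pixel is converted to hue/saturation/value and assigned to one of
six color classes — red, green, blue, gray, white, black — by an ordered,
first-match rule table over (H, S, V) intervals.  The rule table is a
config (YAML-serializable): the shipped default uses a darkness gate
(``v < 0.15`` -> black), a low-saturation split (``s < 0.15`` with
``v >= 0.80`` -> white, else gray), and 120-degree hue sectors for the
chromatic classes (red ``[300, 60)`` wrapping through 0, green
``[60, 180)``, blue ``[180, 300)``).  Interval convention: closed-open
``[lo, hi)``, with the top of each scale (360 for hue, 1 for s and v)
included in its containing interval so the partition is exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from matplotlib.colors import rgb_to_hsv as _mpl_rgb_to_hsv

from .rasters import SphericalRaster

#: Fixed class order; categorical color rasters store indices into this.
COLOR_CLASSES = ("red", "green", "blue", "gray", "white", "black")


@dataclass(frozen=True)
class ColorRule:
    """One first-match rule: intervals over (h, s, v) and a target class.

    ``h`` is in degrees ``[0, 360)`` and may wrap (``lo > hi`` means the
    interval passes through 360/0); ``s`` and ``v`` are fractions in
    ``[0, 1]``.  A ``None`` interval matches everything.
    """

    cls: str
    h: tuple[float, float] | None = None
    s: tuple[float, float] | None = None
    v: tuple[float, float] | None = None

    def matches(self, h: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
        out = np.ones(np.broadcast(h, s, v).shape, dtype=bool)
        if self.h is not None:
            lo, hi = self.h
            if lo <= hi:
                m = (h >= lo) & ((h < hi) | (hi >= 360.0))
            else:  # wrap through 360 -> 0
                m = (h >= lo) | (h < hi)
            out &= m
        for interval, chan in ((self.s, s), (self.v, v)):
            if interval is not None:
                lo, hi = interval
                out &= (chan >= lo) & ((chan < hi) | (hi >= 1.0))
        return out


class ColorRules:
    """Ordered, exhaustive first-match rule table over six color classes."""

    def __init__(self, rules: list[ColorRule]):
        self.rules = list(rules)
        classes = {r.cls for r in self.rules}
        unknown = classes - set(COLOR_CLASSES)
        if unknown:
            raise ValueError(f"unknown color classes: {sorted(unknown)}")
        if classes != set(COLOR_CLASSES):
            missing = set(COLOR_CLASSES) - classes
            raise ValueError(f"rule set must cover all six classes; missing {sorted(missing)}")
        self._check_exhaustive()

    def _check_exhaustive(self) -> None:
        """Reject rule tables with uncovered (h, s, v) cells.

        The rules partition each axis at their interval endpoints; testing
        one probe point per cell of the induced grid decides exhaustiveness
        exactly for interval-based rules.
        """
        eps = 1e-9

        def probes(breaks, top):
            pts = sorted(set([0.0, top] + list(breaks)))
            mids = [(a + b) / 2.0 for a, b in zip(pts[:-1], pts[1:])]
            edges = [p for p in pts if 0.0 <= p < top] + [top - eps]
            return np.array(sorted(set(mids + edges)))

        hb, sb, vb = [], [], []
        for r in self.rules:
            if r.h is not None:
                hb += list(r.h)
            if r.s is not None:
                sb += list(r.s)
            if r.v is not None:
                vb += list(r.v)
        hh = probes(hb, 360.0)
        ss = probes(sb, 1.0)
        vv = probes(vb, 1.0)
        H, S, V = np.meshgrid(hh, ss, vv, indexing="ij")
        assigned = np.zeros(H.shape, dtype=bool)
        for r in self.rules:
            assigned |= r.matches(H, S, V)
        if not assigned.all():
            i = np.argwhere(~assigned)[0]
            raise ValueError(
                "color rules are not exhaustive, e.g. no rule matches "
                f"h={hh[i[0]]:.3f}, s={ss[i[1]]:.3f}, v={vv[i[2]]:.3f}"
            )

    # -- serialization ----------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColorRules":
        raw = yaml.safe_load(Path(path).read_text())
        rules = []
        for item in raw:
            rules.append(
                ColorRule(
                    cls=item["class"],
                    h=tuple(item["h"]) if "h" in item else None,
                    s=tuple(item["s"]) if "s" in item else None,
                    v=tuple(item["v"]) if "v" in item else None,
                )
            )
        return cls(rules)

    def to_yaml(self, path: str | Path) -> None:
        out = []
        for r in self.rules:
            item: dict = {"class": r.cls}
            for name, interval in (("h", r.h), ("s", r.s), ("v", r.v)):
                if interval is not None:
                    item[name] = [float(interval[0]), float(interval[1])]
            out.append(item)
        Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


def default_rules() -> ColorRules:
    """The shipped default six-class threshold table (editable config)."""
    return ColorRules(
        [
            ColorRule("black", v=(0.0, 0.15)),
            ColorRule("white", s=(0.0, 0.15), v=(0.80, 1.0)),
            ColorRule("gray", s=(0.0, 0.15)),
            ColorRule("red", h=(300.0, 60.0)),
            ColorRule("green", h=(60.0, 180.0)),
            ColorRule("blue", h=(180.0, 300.0)),
        ]
    )


def rgb_to_hsv(r, g=None, b=None):
    """Convert 0-255 RGB channels to (h degrees, s, v) fractions.

    Standard hexcone conversion: ``v = max/255``, ``s = (max - min)/max``
    (0 when ``max == 0``, in which case h is stored as 0).  Accepts either
    three scalars or an ``(..., 3)`` array.
    """
    if g is None:
        arr = np.asarray(r, dtype=float)
        if arr.shape[-1] != 3:
            raise ValueError("expected an (..., 3) RGB array")
    else:
        arr = np.asarray([r, g, b], dtype=float)
        arr = np.moveaxis(arr, 0, -1)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("RGB channels must lie in [0, 255]")
    hsv = _mpl_rgb_to_hsv(arr / 255.0)
    h = hsv[..., 0] * 360.0
    s = hsv[..., 1]
    v = hsv[..., 2]
    if h.ndim == 0:
        return float(h), float(s), float(v)
    return h, s, v


def classify_hsv(h, s, v, rules: ColorRules | None = None):
    """Assign color-class indices (into :data:`COLOR_CLASSES`) to HSV values."""
    if rules is None:
        rules = default_rules()
    h = np.asarray(h, dtype=float)
    s = np.asarray(s, dtype=float)
    v = np.asarray(v, dtype=float)
    out = np.full(np.broadcast(h, s, v).shape, -1, dtype=np.int64)
    for rule in rules.rules:
        unassigned = out < 0
        if not unassigned.any():
            break
        hit = unassigned & rule.matches(h, s, v)
        out[hit] = COLOR_CLASSES.index(rule.cls)
    if (out < 0).any():  # pragma: no cover - exhaustiveness enforced at load
        raise RuntimeError("unclassified pixel despite exhaustive rules")
    return out


def classify_pixel(h: float, s: float, v: float, rules: ColorRules | None = None) -> str:
    """Classify a single HSV triple, returning the class name."""
    idx = classify_hsv(np.asarray(h), np.asarray(s), np.asarray(v), rules)
    return COLOR_CLASSES[int(idx)]


def classify_raster(src: SphericalRaster, rules: ColorRules | None = None) -> SphericalRaster:
    """Classify every pixel of an RGB raster into the six color classes.

    Geometry and mask are preserved; output values are indices into
    :data:`COLOR_CLASSES`.
    """
    if not src.is_rgb:
        raise ValueError("classify_raster expects an RGB raster")
    h, s, v = rgb_to_hsv(src.values)
    codes = classify_hsv(h, s, v, rules)
    return SphericalRaster(codes, src.geometry, src.mask)
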