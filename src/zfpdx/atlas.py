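"""Anatomical region atlas for the embryo coordinate frame.

Foci coordinates are expressed in micrometres relative to the injection
site in the pericardial space (PCS): x runs along the anteroposterior
axis (positive toward the tail), y along the dorsoventral axis (positive
toward dorsal).  Ten regions, chosen by larval hemodynamics, partition
the embryo: pericardial space (PCS), yolk, caudal hematopoietic tissue
(CHT), caudal fin (CF), intersegmental vessels (ISV), primordial
hindbrain channel (PHBC), posterior cardinal vein (PCV), primordial
midbrain channel (PMBC), dorsal longitudinal anastomotic vessel (DLAV),
and mandibular arch (AA1).

Each region is an axis-aligned rectangle; containment is half-open
([x0, x1) x [y0, y1)) so every point inside the bounding box belongs to
exactly one region.  Points outside every rectangle are attached to the
nearest rectangle by Euclidean distance (ties broken by region order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

#: Canonical region order used for tropism vectors everywhere in the package.
REGION_NAMES = ("PCS", "Yolk", "CHT", "CF", "ISV", "PHBC", "PCV", "PMBC", "DLAV", "AA1")


@dataclass(frozen=True)
class RegionAtlas:
    """Ten named axis-aligned rectangles tiling the embryo frame."""

    rects: dict[str, tuple[float, float, float, float]]  # name -> (x0, x1, y0, y1)
    names: tuple[str, ...] = field(default=REGION_NAMES)

    def __post_init__(self) -> None:
        if set(self.rects) != set(REGION_NAMES):
            missing = set(REGION_NAMES) - set(self.rects)
            extra = set(self.rects) - set(REGION_NAMES)
            raise ValueError(
                f"atlas must define exactly the 10 canonical regions; "
                f"missing={sorted(missing)} unexpected={sorted(extra)}"
            )
        for name, (x0, x1, y0, y1) in self.rects.items():
            if not (x0 < x1 and y0 < y1):
                raise ValueError(f"region {name!r} has an empty rectangle {self.rects[name]}")

    @property
    def bounding_box(self) -> tuple[float, float, float, float]:
        r = np.array([self.rects[n] for n in self.names])
        return float(r[:, 0].min()), float(r[:, 1].max()), float(r[:, 2].min()), float(r[:, 3].max())

    def contains(self, x: float, y: float, name: str) -> bool:
        x0, x1, y0, y1 = self.rects[name]
        return (x0 <= x < x1) and (y0 <= y < y1)

    def assign(self, x, y) -> np.ndarray:
        """Region label per point (vectorized).

        Half-open containment first; points outside the tiling fall back
        to the nearest rectangle (closed distance, first match wins).
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("focus coordinates must be finite")
        r = np.array([self.rects[n] for n in self.names])  # (10, 4)
        inside = (
            (r[:, 0][:, None] <= x) & (x < r[:, 1][:, None])
            & (r[:, 2][:, None] <= y) & (y < r[:, 3][:, None])
        )  # (10, n)
        # distance from each point to each rectangle (0 when inside-or-on-edge)
        dx = np.maximum(np.maximum(r[:, 0][:, None] - x, x - r[:, 1][:, None]), 0.0)
        dy = np.maximum(np.maximum(r[:, 2][:, None] - y, y - r[:, 3][:, None]), 0.0)
        dist = np.hypot(dx, dy)
        # points inside some rectangle take the first containing region;
        # the rest take the nearest rectangle
        idx = np.where(inside.any(axis=0), inside.argmax(axis=0), dist.argmin(axis=0))
        names = np.array(self.names)
        return names[idx]

    def sample_point(self, name: str, rng: np.random.Generator) -> tuple[float, float]:
        """Uniform draw inside a region's rectangle."""
        x0, x1, y0, y1 = self.rects[name]
        return float(rng.uniform(x0, x1)), float(rng.uniform(y0, y1))


def _from_mapping(mapping: dict) -> RegionAtlas:
    rects = {
        str(name): (float(r["x0"]), float(r["x1"]), float(r["y0"]), float(r["y1"]))
        for name, r in mapping["regions"].items()
    }
    return RegionAtlas(rects=rects)


def load_atlas(path: str | Path) -> RegionAtlas:
    """Load an atlas from a YAML (or JSON, a YAML subset) region file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"atlas file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        return _from_mapping(yaml.safe_load(fh))


def default_atlas() -> RegionAtlas:
    """The schematic atlas shipped with the package (editable YAML)."""
    text = resources.files("zfpdx").joinpath("data/atlas_default.yaml").read_text("utf-8")
    return _from_mapping(yaml.safe_load(text))
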