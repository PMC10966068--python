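"""Brain parcellation fixture: 65 homologous left/right region pairs.

The analysis operates on gray-matter volumes summarised in 65 paired
parcels — 48 cortical (Harvard-Oxford cortical atlas naming), 7
subcortical (Harvard-Oxford subcortical gray structures) and 10
cerebellar (Diedrichsen lobules) — i.e. 130 volumes per subject.  The
parcel *names* are the published atlas labels; the parcel *centroids*
shipped here are synthetic unit-sphere coordinates (a Fibonacci lattice
per tissue class, mirrored across the x = 0 plane for the right
hemisphere) because spin-permutation nulls only need a spherical
geometry, not the true anatomy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CORTICAL = "cortical"
SUBCORTICAL = "subcortical"
CEREBELLAR = "cerebellar"

#: Harvard-Oxford cortical parcels (48).
_CORTICAL_NAMES = [
    "Frontal Pole",
    "Insular Cortex",
    "Superior Frontal Gyrus",
    "Middle Frontal Gyrus",
    "Inferior Frontal Gyrus pars triangularis",
    "Inferior Frontal Gyrus pars opercularis",
    "Precentral Gyrus",
    "Temporal Pole",
    "Superior Temporal Gyrus anterior",
    "Superior Temporal Gyrus posterior",
    "Middle Temporal Gyrus anterior",
    "Middle Temporal Gyrus posterior",
    "Middle Temporal Gyrus temporooccipital",
    "Inferior Temporal Gyrus anterior",
    "Inferior Temporal Gyrus posterior",
    "Inferior Temporal Gyrus temporooccipital",
    "Postcentral Gyrus",
    "Superior Parietal Lobule",
    "Supramarginal Gyrus anterior",
    "Supramarginal Gyrus posterior",
    "Angular Gyrus",
    "Lateral Occipital Cortex superior",
    "Lateral Occipital Cortex inferior",
    "Intracalcarine Cortex",
    "Frontal Medial Cortex",
    "Juxtapositional Lobule Cortex",
    "Subcallosal Cortex",
    "Paracingulate Gyrus",
    "Cingulate Gyrus anterior",
    "Cingulate Gyrus posterior",
    "Precuneous Cortex",
    "Cuneal Cortex",
    "Frontal Orbital Cortex",
    "Parahippocampal Gyrus anterior",
    "Parahippocampal Gyrus posterior",
    "Lingual Gyrus",
    "Temporal Fusiform Cortex anterior",
    "Temporal Fusiform Cortex posterior",
    "Temporal Occipital Fusiform Cortex",
    "Occipital Fusiform Gyrus",
    "Frontal Operculum Cortex",
    "Central Opercular Cortex",
    "Parietal Operculum Cortex",
    "Planum Polare",
    "Heschl's Gyrus",
    "Planum Temporale",
    "Supracalcarine Cortex",
    "Occipital Pole",
]

#: Harvard-Oxford subcortical gray structures with a left/right homolog (7).
_SUBCORTICAL_NAMES = [
    "Thalamus",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens",
]

#: Diedrichsen cerebellar lobules (10 paired).
_CEREBELLAR_NAMES = [
    "Cerebellum I-IV",
    "Cerebellum V",
    "Cerebellum VI",
    "Cerebellum Crus I",
    "Cerebellum Crus II",
    "Cerebellum VIIb",
    "Cerebellum VIIIa",
    "Cerebellum VIIIb",
    "Cerebellum IX",
    "Cerebellum X",
]


def fibonacci_sphere(n: int, offset: float = 0.0) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-angle lattice).

    ``offset`` rotates the lattice in longitude so that disjoint parcel
    sets (tissue classes) do not share coordinates.
    """
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi + offset
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    # renormalise against rounding
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


@dataclass(frozen=True)
class AtlasSpec:
    """Ordered set of homologous region pairs with per-hemisphere centroids.

    Attributes
    ----------
    names : list of str
        Unique region names, one per homologous pair.
    tissue_class : list of str
        One of ``cortical`` / ``subcortical`` / ``cerebellar`` per region.
    centroid_left, centroid_right : (n, 3) arrays
        Unit-norm centroid coordinates per hemisphere.  The right
        hemisphere mirrors the left across the x = 0 plane.
    """

    names: tuple
    tissue_class: tuple
    centroid_left: np.ndarray = field(repr=False)
    centroid_right: np.ndarray = field(repr=False)

    def __post_init__(self):
        n = len(self.names)
        if len(set(self.names)) != n:
            raise ValueError("region names must be unique")
        if len(self.tissue_class) != n:
            raise ValueError("tissue_class length mismatch")
        for arr in (self.centroid_left, self.centroid_right):
            if arr.shape != (n, 3):
                raise ValueError("centroid arrays must be (n_regions, 3)")
            norms = np.linalg.norm(arr, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("centroids must have unit norm")

    @property
    def n_regions(self) -> int:
        return len(self.names)

    def indices_of(self, tissue: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.tissue_class) == tissue)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def tissue_counts(self) -> dict:
        classes, counts = np.unique(np.asarray(self.tissue_class), return_counts=True)
        return dict(zip(classes.tolist(), counts.tolist()))

    # ---- serialisation -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "regions": [
                {
                    "name": nm,
                    "tissue_class": tc,
                    "centroid_left": self.centroid_left[i].tolist(),
                    "centroid_right": self.centroid_right[i].tolist(),
                }
                for i, (nm, tc) in enumerate(zip(self.names, self.tissue_class))
            ]
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "AtlasSpec":
        payload = json.loads(Path(path).read_text())
        regs = payload["regions"]
        return cls(
            names=tuple(r["name"] for r in regs),
            tissue_class=tuple(r["tissue_class"] for r in regs),
            centroid_left=np.array([r["centroid_left"] for r in regs], float),
            centroid_right=np.array([r["centroid_right"] for r in regs], float),
        )


def default_atlas() -> AtlasSpec:
    """The packaged 65-pair fixture (48 cortical, 7 subcortical, 10 cerebellar).

    Cortical, subcortical and cerebellar centroids are laid out on
    separate Fibonacci lattices of the unit sphere; right-hemisphere
    centroids are exact x-mirrors of the left.
    """
    names = _CORTICAL_NAMES + _SUBCORTICAL_NAMES + _CEREBELLAR_NAMES
    tissue = (
        [CORTICAL] * len(_CORTICAL_NAMES)
        + [SUBCORTICAL] * len(_SUBCORTICAL_NAMES)
        + [CEREBELLAR] * len(_CEREBELLAR_NAMES)
    )
    left = np.vstack(
        [
            fibonacci_sphere(len(_CORTICAL_NAMES)),
            fibonacci_sphere(len(_SUBCORTICAL_NAMES), offset=1.0),
            fibonacci_sphere(len(_CEREBELLAR_NAMES), offset=2.0),
        ]
    )
    # ensure every left centroid sits strictly in the x<0 half-space is NOT
    # required: the spin machinery treats hemispheres via the x-flip, and
    # only relative geometry matters for nearest-centroid reassignment.
    right = left * np.array([-1.0, 1.0, 1.0])
    return AtlasSpec(
        names=tuple(names),
        tissue_class=tuple(tissue),
        centroid_left=left,
        centroid_right=right,
    )
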