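"""From paired regional volumes to analysis-ready asymmetry indices.

A cohort table is a pandas DataFrame with one row per subject and
columns ``subject_id, group, age, sex, site`` followed by paired volume
columns ``<region>_L`` and ``<region>_R`` for each atlas region.  The
asymmetry index (AI) for a homologous pair is

    AI = (L - R) / ((L + R) / 2)

so a positive AI signifies leftward asymmetry.  Two z-scoring
conventions are provided: ``control_z`` standardises every column by
the control group's mean and SD (used for descriptive group tests) and
``pooled_z`` standardises across all subjects entering a model fit
(used before discriminant learning).  Sample SD (n-1) is used
throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasSpec

GROUP_LABELS = (
    "control",
    "1q21.1del",
    "1q21.1dup",
    "15q11.2del",
    "15q11.2dup",
    "16p11.2del",
    "16p11.2dup",
    "22q11.2del",
    "22q11.2dup",
)

META_COLUMNS = ("subject_id", "group", "age", "sex", "site")

RAW = "raw"
CONTROL_Z = "control_z"
POOLED_Z = "pooled_z"


def volume_columns(atlas: AtlasSpec) -> list[str]:
    """The 2*n paired volume column names, region-major, L before R."""
    cols = []
    for name in atlas.names:
        cols.append(f"{name}_L")
        cols.append(f"{name}_R")
    return cols


def asymmetry_index(left, right):
    """AI = (L - R) / ((L + R) / 2) for strictly positive volumes."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if np.any(left <= 0) or np.any(right <= 0):
        raise ValueError("volumes must be strictly positive")
    return (left - right) / ((left + right) / 2.0)


def adjust_site(table: pd.DataFrame, atlas: AtlasSpec) -> pd.DataFrame:
    """Remove additive per-site offsets from every volume column.

    Per (region, hemisphere) column the least-squares fit on site
    indicator variables is the per-site mean; the adjustment subtracts
    each site's mean and restores the grand mean, fitted jointly on all
    subjects.  Sites with a single subject are passed through unchanged
    (with a warning): a one-subject site mean would collapse that
    subject onto the grand mean.
    """
    cols = volume_columns(atlas)
    out = table.copy()
    site_sizes = table["site"].value_counts()
    singletons = site_sizes[site_sizes < 2].index.tolist()
    if singletons:
        warnings.warn(
            f"sites with <2 subjects passed through unadjusted: {singletons}"
        )
    adjustable = ~table["site"].isin(singletons)
    if site_sizes.size - len(singletons) <= 1:
        return out  # nothing to contrast against
    vols = table.loc[adjustable, cols]
    grand = vols.mean(axis=0)
    site_means = vols.groupby(table.loc[adjustable, "site"]).transform("mean")
    out.loc[adjustable, cols] = vols - site_means + grand
    return out


@dataclass
class AsymmetryMatrix:
    """Subjects x regions asymmetry indices with scaling provenance.

    ``values`` is indexed by subject_id with one column per atlas
    region; ``groups`` carries each subject's group label.  When scaled,
    ``ref_mean``/``ref_sd`` record the per-region statistics used, so
    the transform is reproducible and invertible.
    """

    values: pd.DataFrame
    groups: pd.Series
    scaling: str = RAW
    ref_mean: pd.Series | None = field(default=None, repr=False)
    ref_sd: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.scaling not in (RAW, CONTROL_Z, POOLED_Z):
            raise ValueError(f"unknown scaling {self.scaling!r}")
        if not self.values.index.equals(self.groups.index):
            raise ValueError("values and groups must share an index")

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def subset(self, labels) -> "AsymmetryMatrix":
        mask = self.groups.isin(labels)
        return AsymmetryMatrix(
            values=self.values.loc[mask],
            groups=self.groups.loc[mask],
            scaling=self.scaling,
            ref_mean=self.ref_mean,
            ref_sd=self.ref_sd,
        )

    def group_values(self, label: str) -> np.ndarray:
        return self.values.loc[self.groups == label].to_numpy()

    # ---- I/O -----------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "group", self.groups)
        out.to_csv(path, sep="\t", float_format="%.10g")
        sidecar = {
            "scaling": self.scaling,
            "ref_mean": None if self.ref_mean is None else self.ref_mean.tolist(),
            "ref_sd": None if self.ref_sd is None else self.ref_sd.tolist(),
            "regions": list(self.values.columns),
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AsymmetryMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        groups = df.pop("group")
        ref_mean = sidecar["ref_mean"]
        ref_sd = sidecar["ref_sd"]
        cols = pd.Index(sidecar["regions"])
        return cls(
            values=df[cols],
            groups=groups,
            scaling=sidecar["scaling"],
            ref_mean=None if ref_mean is None else pd.Series(ref_mean, index=cols),
            ref_sd=None if ref_sd is None else pd.Series(ref_sd, index=cols),
        )


def compute_ai(table: pd.DataFrame, atlas: AtlasSpec) -> AsymmetryMatrix:
    """Compute the raw AI matrix from a cohort table."""
    left = table[[f"{n}_L" for n in atlas.names]].to_numpy(float)
    right = table[[f"{n}_R" for n in atlas.names]].to_numpy(float)
    ai = asymmetry_index(left, right)
    idx = pd.Index(table["subject_id"], name="subject_id")
    values = pd.DataFrame(ai, index=idx, columns=list(atlas.names))
    groups = pd.Series(table["group"].to_numpy(), index=idx, name="group")
    return AsymmetryMatrix(values=values, groups=groups, scaling=RAW)


def zscore(
    ai: AsymmetryMatrix, mode: str, reference_group: str = "control"
) -> AsymmetryMatrix:
    """Standardise AI columns by a reference population's mean and SD.

    ``control_z`` uses the control rows of the matrix as reference;
    ``pooled_z`` uses every row present (so subset to the two classes
    entering a model fit first).  Sample SD (ddof=1).  Applying the
    transform again with the same reference is idempotent because the
    reference statistics of an already-scaled matrix are 0/1.
    """
    if mode == CONTROL_Z:
        ref = ai.values.loc[ai.groups == reference_group]
        if ref.empty:
            raise ValueError(f"reference group {reference_group!r} is empty")
    elif mode == POOLED_Z:
        ref = ai.values
    else:
        raise ValueError(f"unknown z-scoring mode {mode!r}")
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    # a constant column's std comes back as rounding dust, not exactly 0
    tol = 1e-12 * np.maximum(1.0, mean.abs())
    bad = sd[~(sd > tol)]
    if len(bad):
        raise ValueError(f"zero reference SD for region(s): {list(bad.index)}")
    return AsymmetryMatrix(
        values=(ai.values - mean) / sd,
        groups=ai.groups,
        scaling=mode,
        ref_mean=mean,
        ref_sd=sd,
    )


def read_cohort(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table.to_csv(path, sep=sep, index=False, float_format="%.10g")
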