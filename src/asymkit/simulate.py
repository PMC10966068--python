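"""Synthetic cohorts with planted asymmetry effects.

The generator emulates the statistical structure the downstream
analysis assumes: a control group plus eight carrier groups of recurrent
copy-number variants (deletions/duplications at 1q21.1, 15q11.2,
16p11.2 and 22q11.2), each subject carrying 130 paired gray-matter
volumes, covariates (age, sex) and a scanning site.

Volumes are lognormal (positivity of the AI denominator) with
within-pair L/R correlation ``corr_lr`` in log space, so the asymmetry
index AI = (L-R)/((L+R)/2) ~ log(L/R) has realistic spread.  Group
effects are planted as shifts of the expected AI expressed in units of
the control group's per-region AI standard deviation, applied by
scaling the left volume (the configurable ``effect_side``) by a factor
1+f with f = 2*delta/(2-delta) — exact for a symmetric pair, first-order
exact otherwise.  Site effects are additive per-(region, hemisphere)
constants drawn once per site, which is precisely the model the
site-adjustment step removes.

Everything is deterministic given the spec's integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import AtlasSpec, default_atlas
from .preprocess import GROUP_LABELS, asymmetry_index

#: Carrier counts of the reference cohort (multi-site clinical + biobank).
DEFAULT_N_PER_CNV = {
    "1q21.1del": 32,
    "1q21.1dup": 27,
    "15q11.2del": 110,
    "15q11.2dup": 144,
    "16p11.2del": 82,
    "16p11.2dup": 69,
    "22q11.2del": 66,
    "22q11.2dup": 22,
}

#: Planted per-region AI shifts (control-SD units).  Regions and signs
#: follow the qualitative pattern of reported carrier effects: planum
#: temporale asymmetry increased by 16p11.2/22q11.2 deletions and the
#: 15q11.2 duplication, decreased by the 1q21.1 deletion; temporal
#: fusiform and parahippocampal effects for the two focal deletions;
#: plus parietal-operculum, cuneal, supracalcarine, putamen and
#: cerebellar lobule VIIIb effects for the 16p11.2 deletion.
DEFAULT_EFFECT_MAP = {
    ("16p11.2del", "Planum Temporale"): 1.0,
    ("16p11.2del", "Temporal Fusiform Cortex posterior"): -0.6,
    ("16p11.2del", "Parahippocampal Gyrus anterior"): 0.5,
    ("16p11.2del", "Parietal Operculum Cortex"): 0.5,
    ("16p11.2del", "Cuneal Cortex"): 0.4,
    ("16p11.2del", "Supracalcarine Cortex"): -0.4,
    ("16p11.2del", "Putamen"): -0.4,
    ("16p11.2del", "Cerebellum VIIIb"): -0.5,
    ("22q11.2del", "Planum Temporale"): 0.8,
    ("22q11.2del", "Temporal Fusiform Cortex posterior"): -0.4,
    ("22q11.2del", "Parahippocampal Gyrus anterior"): 0.4,
    ("15q11.2dup", "Planum Temporale"): 0.4,
    ("1q21.1del", "Planum Temporale"): -0.5,
    ("16p11.2dup", "Planum Temporale"): -0.4,
    ("16p11.2dup", "Temporal Fusiform Cortex posterior"): 0.3,
    ("22q11.2dup", "Temporal Fusiform Cortex posterior"): 0.3,
    ("15q11.2del", "Cerebellum VIIIb"): 0.3,
    ("1q21.1dup", "Middle Frontal Gyrus"): 0.4,
}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic cohort.

    effect_map maps (group label, region name) -> planted AI shift in
    control-SD units.  ``baseline_mean`` may be a scalar (same expected
    volume everywhere) or a mapping region -> volume.
    """

    n_control: int = 290
    n_per_cnv: dict = field(default_factory=lambda: dict(DEFAULT_N_PER_CNV))
    effect_map: dict = field(default_factory=dict)
    baseline_mean: float | dict = 5000.0
    baseline_cv: float = 0.12
    corr_lr: float = 0.9
    site_labels: tuple = ("siteA", "siteB", "siteC")
    site_offset_sd: float = 150.0
    age_range: tuple = (6.0, 64.0)
    male_fraction: float = 0.56
    effect_side: str = "left"  # left | right | both
    seed: int = 0

    def validate(self, atlas: AtlasSpec) -> None:
        if self.n_control < 2 or any(n < 2 for n in self.n_per_cnv.values()):
            raise ValueError("every generated group needs at least 2 subjects")
        if not (0.0 <= self.corr_lr < 1.0):
            raise ValueError("corr_lr must lie in [0, 1)")
        if not self.baseline_cv > 0:
            raise ValueError("baseline_cv must be positive")
        if self.effect_side not in ("left", "right", "both"):
            raise ValueError("effect_side must be left, right or both")
        known = set(atlas.names)
        for (group, region) in self.effect_map:
            if group not in GROUP_LABELS or group == "control":
                raise ValueError(f"unknown CNV group label {group!r}")
            if group not in self.n_per_cnv:
                raise ValueError(f"effect_map group {group!r} not generated")
            if region not in known:
                raise ValueError(f"effect_map region {region!r} not in atlas")

    # ---- YAML ----------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "n_control": self.n_control,
            "n_per_cnv": dict(self.n_per_cnv),
            "effect_map": [
                {"group": g, "region": r, "shift": float(s)}
                for (g, r), s in self.effect_map.items()
            ],
            "baseline_mean": self.baseline_mean,
            "baseline_cv": self.baseline_cv,
            "corr_lr": self.corr_lr,
            "site_labels": list(self.site_labels),
            "site_offset_sd": self.site_offset_sd,
            "age_range": list(self.age_range),
            "male_fraction": self.male_fraction,
            "effect_side": self.effect_side,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        payload = yaml.safe_load(Path(path).read_text())
        effect_map = {
            (e["group"], e["region"]): float(e["shift"])
            for e in payload.pop("effect_map", [])
        }
        payload["site_labels"] = tuple(payload.get("site_labels", ()))
        payload["age_range"] = tuple(payload.get("age_range", (6.0, 64.0)))
        return cls(effect_map=effect_map, **payload)


def default_spec(seed: int = 0) -> SyntheticSpec:
    """The packaged demo cohort: reference sample sizes + planted effects."""
    return SyntheticSpec(effect_map=dict(DEFAULT_EFFECT_MAP), seed=seed)


def _baseline_means(spec: SyntheticSpec, atlas: AtlasSpec) -> np.ndarray:
    if isinstance(spec.baseline_mean, dict):
        return np.array([spec.baseline_mean[n] for n in atlas.names], float)
    return np.full(atlas.n_regions, float(spec.baseline_mean))


def _draw_log_pairs(rng, n, p, sigma, rho):
    """n x p correlated (left, right) log deviations, unit-variance sigma."""
    common = rng.standard_normal((n, p))
    eps_l = rng.standard_normal((n, p))
    eps_r = rng.standard_normal((n, p))
    a = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * eps_l
    b = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * eps_r
    return sigma * a, sigma * b


def generate_cohort(spec: SyntheticSpec, atlas: AtlasSpec | None = None) -> pd.DataFrame:
    """Generate a cohort table honouring the spec's planted effects.

    The control group is drawn first; its empirical per-region AI SD
    (offset-free) converts each planted shift from control-SD units to
    an AI displacement, which is then realised as a multiplicative
    left-volume factor.  Site offsets are added last.
    """
    if atlas is None:
        atlas = default_atlas()
    spec.validate(atlas)
    rng = np.random.default_rng(spec.seed)
    p = atlas.n_regions
    sigma = np.sqrt(np.log1p(spec.baseline_cv**2))
    means = _baseline_means(spec, atlas)

    # site offsets: one constant per (site, region, hemisphere)
    offsets = {
        site: rng.normal(0.0, spec.site_offset_sd, size=(p, 2))
        for site in spec.site_labels
    }

    groups = ["control"] + sorted(spec.n_per_cnv)
    frames = []
    control_ai_sd = None
    subject_counter = 0
    for g in groups:
        n = spec.n_control if g == "control" else spec.n_per_cnv[g]
        a, b = _draw_log_pairs(rng, n, p, sigma, spec.corr_lr)
        left = means * np.exp(a)
        right = means * np.exp(b)
        if g == "control":
            control_ai_sd = asymmetry_index(left, right).std(axis=0, ddof=1)
        else:
            for r_idx, name in enumerate(atlas.names):
                s = spec.effect_map.get((g, name))
                if not s:
                    continue
                delta = s * control_ai_sd[r_idx]
                f = 2.0 * delta / (2.0 - delta)
                if spec.effect_side == "left":
                    left[:, r_idx] *= 1.0 + f
                elif spec.effect_side == "right":
                    right[:, r_idx] /= 1.0 + f
                else:  # both, split symmetrically
                    half = 2.0 * (delta / 2.0) / (2.0 - delta / 2.0)
                    left[:, r_idx] *= 1.0 + half
                    right[:, r_idx] /= 1.0 + half

        sites = rng.choice(list(spec.site_labels), size=n)
        for i, site in enumerate(sites):
            left[i] += offsets[site][:, 0]
            right[i] += offsets[site][:, 1]
        if np.any(left <= 0) or np.any(right <= 0):
            raise RuntimeError("site offsets produced non-positive volumes")

        age = rng.uniform(*spec.age_range, size=n)
        sex = np.where(rng.random(n) < spec.male_fraction, "M", "F")
        data = {
            "subject_id": [f"S{subject_counter + i:05d}" for i in range(n)],
            "group": g,
            "age": np.round(age, 2),
            "sex": sex,
            "site": sites,
        }
        subject_counter += n
        for r_idx, name in enumerate(atlas.names):
            data[f"{name}_L"] = left[:, r_idx]
            data[f"{name}_R"] = right[:, r_idx]
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# term-activation map fixtures for functional decoding


@dataclass
class TermMapTable:
    """terms x (region, hemisphere) activation intensities.

    ``values`` has one row per term and 2*n_regions columns keyed
    ``<region>_L`` / ``<region>_R`` in atlas order (L before R).
    """

    values: pd.DataFrame

    @property
    def terms(self) -> list[str]:
        return list(self.values.index)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TermMapTable":
        return cls(values=pd.read_csv(path, sep="\t", index_col=0))


def generate_term_maps(
    atlas: AtlasSpec,
    n_terms: int = 50,
    signal_terms: dict | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> TermMapTable:
    """Noise term maps plus optional planted-signal terms.

    ``signal_terms`` maps a term name to a spatial loading: either a
    dict {column -> weight} over ``<region>_L/_R`` columns or a full
    130-vector in column order.  Signal terms receive their loading plus
    Gaussian noise of ``noise_sd``; the remaining terms are pure noise.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    signal_terms = signal_terms or {}
    cols = []
    for name in atlas.names:
        cols.append(f"{name}_L")
        cols.append(f"{name}_R")
    rng = np.random.default_rng(seed)
    rows = {}
    for term, loading in sorted(signal_terms.items()):
        base = np.zeros(len(cols))
        if isinstance(loading, dict):
            for col, w in loading.items():
                base[cols.index(col)] = w
        else:
            base = np.asarray(loading, float)
            if base.shape != (len(cols),):
                raise ValueError("signal loading length must be 2*n_regions")
        rows[term] = base + rng.normal(0.0, noise_sd, len(cols)) if noise_sd else base
    n_noise = n_terms - len(rows)
    for k in range(max(0, n_noise)):
        rows[f"term{k:04d}"] = rng.normal(0.0, max(noise_sd, 1e-12), len(cols))
    values = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    values.index.name = "term"
    return TermMapTable(values=values)
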