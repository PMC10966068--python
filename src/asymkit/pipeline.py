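"""End-to-end orchestration: simulate/ingest -> AI -> patterns -> reports.

A run is driven by a :class:`RunConfig` (YAML-serialisable).  Stages:

1. generate (or load) the cohort and atlas, validate the table;
2. site-adjust volumes, compute raw / control-z asymmetry matrices;
3. per carrier group: pooled-z scaling over that group + controls,
   two-class LDA, bootstrap significance;
4. univariate effects: control-z group tests with FDR, per-hemisphere
   Cohen's d with bootstrap CIs for the focus groups,
   coefficient-vs-control-asymmetry correlations;
5. pattern comparison: pairwise correlations with spin-permutation
   p-values and FDR, Ward clustering; multiclass LDA across carriers;
6. functional decoding of the focus groups against term maps.

Every output is a TSV/JSON file under ``out_dir``; the manifest records
seeds, parameters and a sha256 per file, and an identical config
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import AtlasSpec, default_atlas
from .decoding import DecodingResult, bilateral_map, binned_weighted_decode, correlation_decode
from .discriminant import bootstrap_significance, fit_lda, fit_multiclass_lda
from .effects import (
    ai_group_tests,
    coef_vs_control_asymmetry,
    hemispheric_effect_table,
)
from .preprocess import (
    CONTROL_Z,
    GROUP_LABELS,
    POOLED_Z,
    adjust_site,
    compute_ai,
    read_cohort,
    volume_columns,
    write_cohort,
    zscore,
)
from .simulate import SyntheticSpec, default_spec, generate_cohort, generate_term_maps

logger = logging.getLogger("asymkit")

CNV_GROUPS = tuple(g for g in GROUP_LABELS if g != "control")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run (no wall-clock seeding)."""

    out_dir: str
    seed: int = 0
    cohort_path: str | None = None  # None -> synthetic
    atlas_path: str | None = None
    synthetic: SyntheticSpec | None = None
    groups: tuple = CNV_GROUPS
    focus_groups: tuple = ("16p11.2del", "22q11.2del")
    bootstrap_B: int = 1000
    n_spin: int = 1000
    alpha: float = 0.05
    n_terms: int = 50
    term_maps_path: str | None = None

    def validate(self) -> None:
        unknown = [g for g in self.groups if g not in CNV_GROUPS]
        if unknown:
            raise ValueError(f"unknown group label(s): {unknown}")
        if any(g not in self.groups for g in self.focus_groups):
            raise ValueError("focus_groups must be a subset of groups")
        for p in (self.cohort_path, self.atlas_path, self.term_maps_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.bootstrap_B < 1 or self.n_spin < 1:
            raise ValueError("bootstrap_B and n_spin must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        syn = payload.pop("synthetic", None)
        cfg = cls(**{k: tuple(v) if k in ("groups", "focus_groups") else v
                     for k, v in payload.items()})
        if syn is not None:
            effect_map = {
                (e["group"], e["region"]): float(e["shift"])
                for e in syn.pop("effect_map", [])
            }
            if "site_labels" in syn:
                syn["site_labels"] = tuple(syn["site_labels"])
            if "age_range" in syn:
                syn["age_range"] = tuple(syn["age_range"])
            cfg.synthetic = SyntheticSpec(effect_map=effect_map, **syn)
        return cfg


def validate_cohort(table: pd.DataFrame, atlas: AtlasSpec) -> dict:
    """Structural checks on a cohort table; returns a machine-readable report.

    Violation classes: missing_column, unpaired_region, nonpositive_volume,
    missing_cell, unknown_group, duplicate_subject.
    """
    violations = []
    for col in ("subject_id", "group", "age", "sex", "site"):
        if col not in table.columns:
            violations.append({"class": "missing_column", "detail": col})
    for name in atlas.names:
        for hemi in ("L", "R"):
            if f"{name}_{hemi}" not in table.columns:
                violations.append(
                    {"class": "unpaired_region", "detail": f"{name}_{hemi}"}
                )
    present = [c for c in volume_columns(atlas) if c in table.columns]
    if present:
        vols = table[present]
        n_missing = int(vols.isna().sum().sum())
        if n_missing:
            violations.append({"class": "missing_cell", "detail": n_missing})
        bad = (vols <= 0).sum()
        for col, cnt in bad[bad > 0].items():
            violations.append(
                {"class": "nonpositive_volume", "detail": col, "count": int(cnt)}
            )
    if "group" in table.columns:
        unknown = sorted(set(table["group"]) - set(GROUP_LABELS))
        for g in unknown:
            violations.append({"class": "unknown_group", "detail": g})
    if "subject_id" in table.columns and table["subject_id"].duplicated().any():
        violations.append(
            {
                "class": "duplicate_subject",
                "detail": sorted(table.loc[table["subject_id"].duplicated(), "subject_id"]),
            }
        )
    return {"n_subjects": int(len(table)), "violations": violations,
            "valid": not violations}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "groups": list(config.groups),
            "focus_groups": list(config.focus_groups),
            "bootstrap_B": config.bootstrap_B,
            "n_spin": config.n_spin,
            "alpha": config.alpha,
            "n_terms": config.n_terms,
        },
        "inputs": {},
        "outputs": {},
        "warnings": [],
        "completed_stages": [],
    }
    files: dict[str, Path] = {}

    def record(key: str, path: Path):
        files[key] = path

    try:
        # ---- stage 1: data -------------------------------------------
        ss = np.random.SeedSequence(config.seed)
        seeds = {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(
                ["cohort", "terms", "bootstrap", "spin", "effects"], ss.spawn(5)
            )
        }
        if config.atlas_path:
            atlas = AtlasSpec.from_json(config.atlas_path)
            manifest["inputs"]["atlas"] = _sha256(Path(config.atlas_path))
        else:
            atlas = default_atlas()
        if config.cohort_path:
            table = read_cohort(config.cohort_path)
            manifest["inputs"]["cohort"] = _sha256(Path(config.cohort_path))
        else:
            spec = config.synthetic or default_spec()
            spec.seed = seeds["cohort"]
            table = generate_cohort(spec, atlas)
        report = validate_cohort(table, atlas)
        if not report["valid"]:
            raise ValueError(f"cohort validation failed: {report['violations']}")
        atlas.to_json(out / "atlas.json")
        record("atlas", out / "atlas.json")
        write_cohort(table, out / "cohort.csv")
        record("cohort", out / "cohort.csv")
        (out / "validation.json").write_text(json.dumps(report, indent=1))
        record("validation", out / "validation.json")
        manifest["completed_stages"].append("data")

        # ---- stage 2: preprocess -------------------------------------
        adjusted = adjust_site(table, atlas)
        ai_raw = compute_ai(adjusted, atlas)
        ai_raw.to_tsv(out / "ai_raw.tsv")
        record("ai_raw", out / "ai_raw.tsv")
        ai_cz = zscore(ai_raw, CONTROL_Z)
        manifest["completed_stages"].append("preprocess")

        # ---- stage 3: per-group patterns -----------------------------
        pat_dir = out / "patterns"
        pat_dir.mkdir(exist_ok=True)
        patterns = {}
        boots = {}
        for i, g in enumerate(config.groups):
            sub = ai_raw.subset([g, "control"])
            pz = zscore(sub, POOLED_Z)
            pattern = fit_lda(pz, g)
            boot = bootstrap_significance(
                pz, g, B=config.bootstrap_B, seed=seeds["bootstrap"] + i
            )
            patterns[g] = pattern
            boots[g] = boot
            path = pat_dir / f"{g}_pattern.tsv"
            pattern.to_tsv(path, bootstrap=boot)
            record(f"pattern_{g}", path)
            logger.info("fitted %s: auc=%.3f, %d significant regions",
                        g, pattern.auc, int(boot.significant.sum()))
        manifest["completed_stages"].append("patterns")

        # ---- stage 4: univariate effects -----------------------------
        eff_dir = out / "effects"
        eff_dir.mkdir(exist_ok=True)
        for g in config.groups:
            tests = ai_group_tests(ai_cz, g, alpha=config.alpha)
            path = eff_dir / f"group_tests_{g}.tsv"
            _write_tsv(tests, path)
            record(f"group_tests_{g}", path)
        for i, g in enumerate(config.focus_groups):
            hemi = hemispheric_effect_table(
                adjusted, atlas, g, B=config.bootstrap_B,
                seed=seeds["effects"] + i,
            )
            path = eff_dir / f"hemispheric_d_{g}.tsv"
            _write_tsv(hemi, path)
            record(f"hemispheric_d_{g}", path)
        rows = []
        for g in config.groups:
            r, p = coef_vs_control_asymmetry(patterns[g], ai_raw)
            rows.append({"group": g, "r": r, "p": p})
        path = eff_dir / "coef_vs_control_asymmetry.tsv"
        _write_tsv(pd.DataFrame(rows), path)
        record("coef_vs_control_asymmetry", path)
        manifest["completed_stages"].append("effects")

        # ---- stage 5: similarity + multiclass ------------------------
        from .similarity import pairwise_spin_tests, spin_null, ward_cluster

        sim_dir = out / "similarity"
        sim_dir.mkdir(exist_ok=True)
        coef_maps = {g: patterns[g].coefficients for g in config.groups}
        null_table = spin_null(atlas, n_spin=config.n_spin, seed=seeds["spin"])
        r_df, p_df, p_fdr_df = pairwise_spin_tests(
            coef_maps, null_table, q=config.alpha
        )
        for key, name, df in (
            ("similarity_correlations", "pattern_correlations", r_df),
            ("similarity_spin_p", "spin_p", p_df),
            ("similarity_spin_p_fdr", "spin_p_fdr", p_fdr_df),
        ):
            path = sim_dir / f"{name}.tsv"
            _write_tsv(df, path, index=True)
            record(key, path)
        clusters = ward_cluster(coef_maps)
        clusters.to_json(sim_dir / "ward_linkage.json")
        record("ward_linkage", sim_dir / "ward_linkage.json")

        carriers = ai_raw.subset(list(config.groups))
        pz_all = zscore(carriers, POOLED_Z)
        mc = fit_multiclass_lda(pz_all)
        mc_df = pd.DataFrame(
            mc.axes.T, index=list(mc.regions),
            columns=[f"axis{i+1}" for i in range(mc.axes.shape[0])],
        )
        path = sim_dir / "multiclass_axes.tsv"
        _write_tsv(mc_df, path, index=True)
        record("multiclass_axes", path)
        _write_tsv(mc.class_means, sim_dir / "multiclass_class_means.tsv", index=True)
        record("multiclass_class_means", sim_dir / "multiclass_class_means.tsv")
        manifest["completed_stages"].append("similarity")

        # ---- stage 6: decoding ---------------------------------------
        dec_dir = out / "decoding"
        dec_dir.mkdir(exist_ok=True)
        if config.term_maps_path:
            from .simulate import TermMapTable

            terms = TermMapTable.from_tsv(config.term_maps_path)
            manifest["inputs"]["term_maps"] = _sha256(Path(config.term_maps_path))
        else:
            terms = generate_term_maps(
                atlas, n_terms=config.n_terms, seed=seeds["terms"]
            )
        terms.to_tsv(out / "term_maps.tsv")
        record("term_maps", out / "term_maps.tsv")
        for g in config.focus_groups:
            abs_map = bilateral_map(patterns[g], "absolute")
            corr = correlation_decode(abs_map, terms)
            path = dec_dir / f"{g}_correlation_decode.tsv"
            _write_tsv(corr, path)
            record(f"decode_corr_{g}", path)
            signed = bilateral_map(patterns[g], "signed")
            binned: DecodingResult = binned_weighted_decode(signed, terms)
            df = binned.scores.copy()
            df["location"] = binned.locations
            df["flagged"] = binned.flagged
            path = dec_dir / f"{g}_binned_decode.tsv"
            _write_tsv(df, path, index=True)
            record(f"decode_binned_{g}", path)
        manifest["completed_stages"].append("decoding")

        manifest["patterns_summary"] = {
            g: {
                "auc": patterns[g].auc,
                "n_significant": int(boots[g].significant.sum()),
                "shrinkage": patterns[g].shrinkage,
            }
            for g in config.groups
        }
    except Exception as exc:  # record partial completion before re-raising
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest["outputs"] = {k: _sha256(p) for k, p in files.items() if p.exists()}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    manifest["outputs"] = {
        k: {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
        for k, p in sorted(files.items())
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
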