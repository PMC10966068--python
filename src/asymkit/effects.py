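"""Univariate effect characterisation around the discriminant patterns.

Cohen's d here is the standardised mean difference with the average-
variance denominator,

    d = (x1_bar - x2_bar) / sqrt((s1^2 + s2^2) / 2),

with sample SDs (n-1).  Per-hemisphere volume effects use a stratified
percentile bootstrap (B draws, 2.5/97.5%) for the confidence interval.
Group tests on control-z asymmetry indices are Welch two-sided t-tests
with Benjamini-Hochberg FDR across the 65 regions of one contrast.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import AtlasSpec
from .discriminant import LdaPattern
from .preprocess import CONTROL_Z, RAW, AsymmetryMatrix, volume_columns


def cohens_d(x1, x2) -> float:
    """(x1_bar - x2_bar) / sqrt((s1^2 + s2^2) / 2), sample SDs."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("need n >= 2 per sample")
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
        raise ValueError("samples must be finite")
    s1 = x1.std(ddof=1)
    s2 = x2.std(ddof=1)
    denom = np.sqrt((s1**2 + s2**2) / 2.0)
    if denom == 0:
        raise ValueError("zero pooled SD")
    return float((x1.mean() - x2.mean()) / denom)


def cohens_d_bootstrap_ci(x1, x2, B: int = 1000, seed: int = 0):
    """Percentile 2.5/97.5% CI of Cohen's d over B stratified resamples.

    Degenerate draws (zero variance in both resamples) are redrawn and
    counted with a warning.
    """
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    cohens_d(x1, x2)  # validate inputs
    rng = np.random.default_rng(seed)
    ds = np.empty(B)
    n_redrawn = 0
    for b in range(B):
        while True:
            r1 = x1[rng.integers(0, len(x1), len(x1))]
            r2 = x2[rng.integers(0, len(x2), len(x2))]
            s1 = r1.std(ddof=1)
            s2 = r2.std(ddof=1)
            denom = np.sqrt((s1**2 + s2**2) / 2.0)
            if denom == 0:
                n_redrawn += 1
                continue
            ds[b] = (r1.mean() - r2.mean()) / denom
            break
    if n_redrawn:
        warnings.warn(f"{n_redrawn} degenerate bootstrap draw(s) redrawn")
    return float(np.percentile(ds, 2.5)), float(np.percentile(ds, 97.5))


def hemispheric_effect_table(
    table: pd.DataFrame,
    atlas: AtlasSpec,
    case_label: str,
    control_label: str = "control",
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohen's d with bootstrap CIs per (region, hemisphere) raw volume.

    Vectorised over the 130 volume columns: one set of B stratified
    index draws serves every column, which keeps the B x 130 resampling
    affordable and the draws consistent across columns.
    """
    cols = volume_columns(atlas)
    case = table.loc[table["group"] == case_label, cols].to_numpy(float)
    ctrl = table.loc[table["group"] == control_label, cols].to_numpy(float)
    if case.shape[0] < 2 or ctrl.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    d = _d_columns(case, ctrl)
    rng = np.random.default_rng(seed)
    boot = np.empty((B, len(cols)))
    for b in range(B):
        rc = case[rng.integers(0, case.shape[0], case.shape[0])]
        rk = ctrl[rng.integers(0, ctrl.shape[0], ctrl.shape[0])]
        boot[b] = _d_columns(rc, rk)
    lo = np.percentile(boot, 2.5, axis=0)
    hi = np.percentile(boot, 97.5, axis=0)
    region = [c.rsplit("_", 1)[0] for c in cols]
    hemi = [c.rsplit("_", 1)[1] for c in cols]
    return pd.DataFrame(
        {
            "region": region,
            "hemisphere": hemi,
            "d": d,
            "ci_low": lo,
            "ci_high": hi,
            "n_case": case.shape[0],
            "n_control": ctrl.shape[0],
            "B": B,
            "seed": seed,
        }
    )


def _d_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    s1 = a.std(axis=0, ddof=1)
    s2 = b.std(axis=0, ddof=1)
    denom = np.sqrt((s1**2 + s2**2) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (a.mean(axis=0) - b.mean(axis=0)) / denom


def covariate_adjust_volumes(
    table: pd.DataFrame, atlas: AtlasSpec, icv_column: str | None = "icv"
) -> pd.DataFrame:
    """Residualise raw volumes on [ICV, age, age^2, sex, site] + grand mean.

    Used only on the raw-volume effect path, never before AI
    computation.  Age is centred before squaring (pure reparametrisation
    of the design; identical residuals).  ICV is optional and skipped
    with a warning when the column is absent.  Collinear columns are
    handled by least squares via SVD (minimum-norm solution).
    """
    cols = volume_columns(atlas)
    design = [np.ones(len(table))]
    if icv_column is not None and icv_column in table.columns:
        design.append(table[icv_column].to_numpy(float))
    elif icv_column is not None:
        warnings.warn("no intracranial-volume column; adjusting without ICV")
    age_c = table["age"].to_numpy(float)
    age_c = age_c - age_c.mean()
    design.append(age_c)
    design.append(age_c**2)
    sex = pd.get_dummies(table["sex"], drop_first=True)
    for c in sex.columns:
        design.append(sex[c].to_numpy(float))
    site = pd.get_dummies(table["site"], drop_first=True)
    for c in site.columns:
        design.append(site[c].to_numpy(float))
    D = np.column_stack(design)
    Y = table[cols].to_numpy(float)
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ beta
    out = table.copy()
    out[cols] = resid + Y.mean(axis=0)
    return out


def benjamini_hochberg(p, q: float = 0.05):
    """BH step-up FDR: (adjusted p, reject flags)."""
    p = np.asarray(p, float)
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def ai_group_tests(
    ai: AsymmetryMatrix,
    case_label: str,
    control_label: str = "control",
    alpha: float = 0.05,
    welch: bool = True,
) -> pd.DataFrame:
    """Two-sided t-test per region on control-z AI, BH-FDR across regions.

    Direction is the sign of (case mean - control mean); "none" when the
    adjusted p fails alpha.
    """
    if ai.scaling != CONTROL_Z:
        raise ValueError("ai_group_tests expects a control_z AsymmetryMatrix")
    case = ai.group_values(case_label)
    ctrl = ai.group_values(control_label)
    if case.shape[0] < 2 or ctrl.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    t, p = stats.ttest_ind(case, ctrl, axis=0, equal_var=not welch)
    p_adj, reject = benjamini_hochberg(p, q=alpha)
    delta = case.mean(axis=0) - ctrl.mean(axis=0)
    direction = np.where(~reject, "none", np.where(delta > 0, "increase", "decrease"))
    return pd.DataFrame(
        {
            "region": list(ai.values.columns),
            "t": t,
            "p": p,
            "p_fdr": p_adj,
            "direction": direction,
        }
    )


def coef_vs_control_asymmetry(
    pattern: LdaPattern, ai: AsymmetryMatrix, control_label: str = "control"
):
    """Pearson r (and two-sided p) between pattern coefficients and the
    control group's mean raw AI per region."""
    if ai.scaling != RAW:
        raise ValueError("expects the raw AI matrix (control asymmetry in AI units)")
    ctrl = ai.group_values(control_label)
    if ctrl.shape[0] == 0:
        raise ValueError("control group is empty")
    means = ctrl.mean(axis=0)
    coef = np.asarray(pattern.coefficients, float)
    if means.std() == 0 or coef.std() == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(coef, means)
    return float(r), float(p)
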