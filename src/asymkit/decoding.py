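"""Functional annotation of asymmetry patterns against term maps.

Two decoding modes mirror how meta-analytic term-activation maps are
used to annotate a brain map:

* correlation mode — the pattern's 65 coefficients are mapped onto both
  hemispheres as absolute values (same value for homologous regions)
  and Pearson-correlated with every term's activation map; terms are
  ranked by r.
* binned mode — a signed bilateral map (original coefficients on the
  right hemisphere, opposite sign on the left) ranks the 130 spatial
  units into 20 five-percentile bins; per term, the mean activation per
  bin is z-scored, bins with z < 0.5 are zeroed, and a weighted score
  per bin is the product of the thresholded activation and the bin's
  mean coefficient.  A term's location on the coefficient spectrum is
  the score-weighted mean bin index (1..20).

The same machinery accepts denser unit tables (e.g. vertex values): the
operations only assume a signed map and a matching term matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discriminant import LdaPattern
from .simulate import TermMapTable

N_BINS = 20
Z_THRESHOLD = 0.5


def bilateral_map(pattern: LdaPattern, mode: str) -> pd.Series:
    """Project 65 pair coefficients onto 130 (region, hemisphere) units.

    ``absolute``: |c| on both hemispheres (whole-brain similarity mask);
    ``signed``: +c on the right hemisphere, -c on the left, so the map
    encodes which hemisphere a positive coefficient favours.
    """
    coef = np.asarray(pattern.coefficients, float)
    index = []
    values = []
    for name, c in zip(pattern.regions, coef):
        if mode == "absolute":
            l_val = r_val = abs(c)
        elif mode == "signed":
            l_val, r_val = -c, c
        else:
            raise ValueError("mode must be 'absolute' or 'signed'")
        index += [f"{name}_L", f"{name}_R"]
        values += [l_val, r_val]
    return pd.Series(values, index=index, name=pattern.group)


def correlation_decode(map_values: pd.Series, terms: TermMapTable) -> pd.DataFrame:
    """Pearson r between the map and every term map, sorted descending.

    Terms whose map is constant are skipped with a warning.
    """
    cols = list(map_values.index)
    if set(cols) != set(terms.values.columns):
        raise ValueError("term-map columns do not match the input map")
    T = terms.values[cols].to_numpy(float)
    x = map_values.to_numpy(float)
    if x.std() == 0:
        raise ValueError("constant input map")
    xc = x - x.mean()
    Tc = T - T.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(xc) * np.linalg.norm(Tc, axis=1)
    ok = denom > 0
    if not ok.all():
        skipped = [t for t, o in zip(terms.terms, ok) if not o]
        warnings.warn(f"constant term map(s) skipped: {skipped}")
    r = (Tc[ok] @ xc) / denom[ok]
    out = pd.DataFrame({"term": np.asarray(terms.terms)[ok], "r": r})
    return out.sort_values("r", ascending=False, ignore_index=True)


def _symmetric_chunks(order: np.ndarray, n_bins: int) -> list:
    """Split ranked indices into n_bins contiguous chunks, sizes differing
    by at most one, with the larger chunks placed symmetrically from both
    ends so that reversing the ranking mirrors the binning exactly."""
    base, extra = divmod(len(order), n_bins)
    sizes = np.full(n_bins, base)
    for k in range(extra):
        pos = k // 2 if k % 2 == 0 else n_bins - 1 - k // 2
        sizes[pos] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    return [order[bounds[k] : bounds[k + 1]] for k in range(n_bins)]


@dataclass
class DecodingResult:
    """Binned weighted-score decoding of one signed map."""

    scores: pd.DataFrame  # term x 20 bin scores
    locations: pd.Series  # weighted-mean bin per term (NaN when all zeroed)
    flagged: pd.Series  # True when every bin was zeroed
    bin_assignment: np.ndarray = field(repr=False)  # bin index (1..20) per unit
    bin_coefficients: np.ndarray = field(repr=False)  # mean coefficient per bin
    n_bins: int = N_BINS
    z_threshold: float = Z_THRESHOLD


def binned_weighted_decode(
    map_values: pd.Series, terms: TermMapTable, n_bins: int = N_BINS,
    z_threshold: float = Z_THRESHOLD,
) -> DecodingResult:
    """Weighted-score decoding along the ranked coefficient spectrum.

    Units are ranked by signed coefficient (ties broken by position for
    determinism) and split into ``n_bins`` contiguous rank bins whose
    sizes differ by at most one unit; bin 1 holds the most negative
    coefficients, bin ``n_bins`` the most positive.
    """
    cols = list(map_values.index)
    if set(cols) != set(terms.values.columns):
        raise ValueError("term-map columns do not match the input map")
    x = map_values.to_numpy(float)
    n = len(x)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} spatial units")
    order = np.argsort(x, kind="stable")  # ties by position
    chunks = _symmetric_chunks(order, n_bins)
    assignment = np.empty(n, dtype=int)
    for k, chunk in enumerate(chunks):
        assignment[chunk] = k + 1
    bin_coef = np.array([x[chunk].mean() for chunk in chunks])

    T = terms.values[cols].to_numpy(float)
    binned_act = np.column_stack([T[:, chunk].mean(axis=1) for chunk in chunks])
    sd = binned_act.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (binned_act - binned_act.mean(axis=1, keepdims=True)) / sd
    z = np.where(sd > 0, z, 0.0)  # uniform activation: nothing survives
    # after z-scoring, the z-scores ARE the binned activation values;
    # retained entries are therefore >= z_threshold >= 0
    act_thr = np.where(z >= z_threshold, z, 0.0)
    scores = act_thr * bin_coef[None, :]
    total = scores.sum(axis=1)
    flagged = ~np.any(act_thr != 0.0, axis=1)
    bins = np.arange(1, n_bins + 1, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        loc = (scores @ bins) / total
    loc = np.where(flagged | (total == 0), np.nan, loc)
    idx = pd.Index(terms.terms, name="term")
    return DecodingResult(
        scores=pd.DataFrame(scores, index=idx, columns=[f"bin{k}" for k in range(1, n_bins + 1)]),
        locations=pd.Series(loc, index=idx, name="location"),
        flagged=pd.Series(flagged, index=idx, name="flagged"),
        bin_assignment=assignment,
        bin_coefficients=bin_coef,
        n_bins=n_bins,
        z_threshold=z_threshold,
    )
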