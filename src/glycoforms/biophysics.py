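"""Glycoform biophysics: detergent-based solubility differentials and
thermal-profile ΔAUC.

Solubility: the log2 ratio of a feature's intensity in a mild detergent
(NP40) over a strongly denaturing one (SDS) measures how soluble the species
is; a glycoform whose ratio deviates from its parent protein's ratio has
glycoform-specific solubility.

Thermal profiling: lysates are heated across a nine-temperature gradient
(40.4-66.3 °C) and the soluble fraction quantified.  Replicate TMT sets are
aligned with an internal-reference factor computed from first-temperature
protein intensities, curves are anchored by subtracting each condition's
mean of the first two temperatures, and ΔAUC is the difference of summed
anchored intensities between conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .quant import benjamini_hochberg, squeeze_variances

from scipy import stats

__all__ = [
    "TPP_TEMPERATURES",
    "solubility_ratio",
    "differential_solubility",
    "tpp_align",
    "delta_auc",
]

#: The nine-point thermal gradient (°C).
TPP_TEMPERATURES = (40.4, 44.0, 46.9, 49.8, 52.9, 55.5, 58.6, 62.0, 66.3)


def solubility_ratio(np40: pd.DataFrame, sds: pd.DataFrame) -> pd.DataFrame:
    """Per-feature, per-replicate log2(NP40/SDS) solubility ratios.

    Inputs are replicate-matched raw intensity frames (features x replicate
    columns, identical layout).  Cells where either side is missing or the
    SDS denominator is zero become missing; the number of such cells is in
    ``df.attrs['n_undefined']``.
    """
    if list(np40.columns) != list(sds.columns):
        raise ValueError("NP40 and SDS frames must share replicate columns")
    common = np40.index.intersection(sds.index)
    a = np40.loc[common].to_numpy(dtype=float)
    b = sds.loc[common].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(a / b)
    bad = ~np.isfinite(ratio)
    ratio[bad] = np.nan
    out = pd.DataFrame(ratio, index=common, columns=np40.columns)
    out.attrs["n_undefined"] = int(bad.sum())
    return out


def differential_solubility(
    glyco_ratios: pd.DataFrame,
    protein_ratios: pd.DataFrame,
    mapping: pd.Series,
    lfc_threshold: float = np.log2(1.5),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Moderated glycoform-vs-protein solubility comparison.

    Glycopeptides without a matched measured protein are excluded (count in
    ``df.attrs['n_unmatched']``).  Both ratio sets are median-normalized
    (per-replicate medians equalized), then per glycoform the paired
    replicate differences (glycoform ratio - protein ratio) are tested with
    a moderated one-sample t (empirical-Bayes squeezed variances, BH across
    glycoforms).  Significance: |log2_fc| > log2(1.5) and adjusted p < 0.05.

    Returns per-glycoform ``log2_fc`` (glycoform - protein solubility),
    ``p_raw``, ``p_adj`` and ``significant``.
    """
    matched = [f for f in glyco_ratios.index if mapping.get(f) in set(protein_ratios.index)]
    n_unmatched = len(glyco_ratios.index) - len(matched)
    if not matched:
        raise ValueError("no glycoform has a matched protein solubility ratio")
    g = glyco_ratios.loc[matched].copy()
    p = protein_ratios.copy()
    # median normalization: equalize per-replicate medians within each set
    for frame in (g, p):
        med = frame.median(axis=0)
        frame.loc[:, :] = frame.to_numpy() - med.to_numpy()[None, :] + float(med.mean())
    prot = p.loc[[mapping[f] for f in matched]].to_numpy(dtype=float)
    diff = g.to_numpy(dtype=float) - prot
    ok = np.isfinite(diff)
    n_rep = ok.sum(axis=1)
    keep = n_rep >= 2
    diff = diff[keep]
    feats = [f for f, k in zip(matched, keep) if k]
    mean = np.nanmean(diff, axis=1)
    n = np.isfinite(diff).sum(axis=1)
    s2 = np.nanvar(diff, axis=1, ddof=1)
    df_resid = float(np.median(n - 1))
    s2_post, df_prior, _ = squeeze_variances(s2, df_resid)
    se = np.sqrt(s2_post / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / se, np.where(mean == 0, 0.0, np.inf))
    df_total = df_resid + (df_prior if np.isfinite(df_prior) else 1e6)
    p_raw = 2 * stats.t.sf(np.abs(t), df_total)
    p_adj = benjamini_hochberg(p_raw)
    out = pd.DataFrame(
        {
            "protein": [mapping[f] for f in feats],
            "log2_fc": mean,
            "t": t,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": (np.abs(mean) > lfc_threshold) & (p_adj < alpha),
        },
        index=pd.Index(feats, name="feature"),
    )
    out.attrs["n_unmatched"] = n_unmatched
    return out


def tpp_align(sets: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Align replicate TMT sets of melting series by an internal reference.

    Each value of ``sets`` is a protein x temperature frame for one
    multiplex set (first column = lowest temperature).  The per-set scaling
    factor is the across-set mean of first-temperature protein intensities
    divided by the set's own mean (proteins missing at the first temperature
    are excluded from the factor).  After scaling, samples (columns across
    all sets) are quantile normalized jointly and the matrix is divided by
    its global mean, fixing the overall scale so that downstream ΔAUC values
    are exactly invariant to per-set global intensity scaling.
    """
    if len(sets) < 2:
        raise ValueError("need at least two multiplex sets to align")
    first = {name: frame.iloc[:, 0] for name, frame in sets.items()}
    shared = None
    for s in first.values():
        idx = s.index[np.isfinite(s)]
        shared = idx if shared is None else shared.intersection(idx)
    if shared is None or len(shared) == 0:
        raise ValueError("no shared proteins quantified at the first temperature")
    grand_mean = float(np.mean([first[name].loc[shared].mean() for name in sets]))
    scaled = {}
    for name, frame in sets.items():
        factor = grand_mean / float(first[name].loc[shared].mean())
        scaled[name] = frame * factor
    # joint quantile normalization across all columns of all sets
    stacked = pd.concat(
        {name: frame for name, frame in scaled.items()}, axis=1
    )
    v = stacked.to_numpy(dtype=float)
    order = np.argsort(v, axis=0)
    ranked = np.take_along_axis(v, order, axis=0)
    means = np.nanmean(ranked, axis=1)
    out = np.empty_like(v)
    for j in range(v.shape[1]):
        out[order[:, j], j] = means
    out /= np.nanmean(out)
    stacked.loc[:, :] = out
    return {name: stacked[name] for name in sets}


def delta_auc(series_a: pd.DataFrame, series_b: pd.DataFrame) -> pd.Series:
    """ΔAUC between two conditions' melting series (A - B).

    Inputs are protein x temperature frames on identical temperature grids.
    Each condition is anchored by subtracting its own mean of the first two
    temperatures from every temperature, then ΔAUC is the plain sum over
    temperatures of (anchored A - anchored B).  Zero for identical series
    and antisymmetric under swapping conditions.
    """
    if list(series_a.columns) != list(series_b.columns):
        raise ValueError("conditions must share the temperature grid")
    if series_a.shape[1] < 3:
        raise ValueError("need at least three temperatures")
    common = series_a.index.intersection(series_b.index)
    a = series_a.loc[common].to_numpy(dtype=float)
    b = series_b.loc[common].to_numpy(dtype=float)
    a_anch = a - a[:, :2].mean(axis=1, keepdims=True)
    b_anch = b - b[:, :2].mean(axis=1, keepdims=True)
    return pd.Series((a_anch - b_anch).sum(axis=1), index=common, name="delta_auc")
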