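"""Normalization, protein-abundance correction and moderated differential
abundance analysis of glycopeptide intensity matrices.

Differential testing uses a per-feature linear model with empirical-Bayes
variance moderation: residual variances are squeezed toward a pooled prior
whose scale and degrees of freedom are estimated by method of moments from
the distribution of log residual variances (the standard squeezed-variance
construction for moderated t statistics).  Significance combines an adjusted
p-value cutoff with an absolute log2 fold-change threshold, defaulting to
adjusted p < 0.05 and |log2 FC| > log2(1.5); the tissue-comparison preset
tightens the fold-change threshold to log2(2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .matrix import IntensityMatrix, SampleDesign

__all__ = [
    "normalize",
    "correct_by_regression",
    "correct_by_ratio",
    "differential",
    "benjamini_hochberg",
    "DifferentialResult",
    "squeeze_variances",
]


# ---------------------------------------------------------------------------
# normalization

def _quantile_normalize(v: np.ndarray) -> np.ndarray:
    """Columns get identical value distributions (mean of per-rank values)."""
    order = np.argsort(v, axis=0)
    ranked = np.take_along_axis(v, order, axis=0)
    means = ranked.mean(axis=1)
    out = np.empty_like(v)
    inv = np.empty_like(order)
    rows = np.arange(v.shape[0])[:, None]
    np.put_along_axis(inv, order, rows + np.zeros_like(order), axis=0)
    for j in range(v.shape[1]):
        out[:, j] = means[inv[:, j]]
    return out


def normalize(matrix: IntensityMatrix, method: str = "vsn_like") -> IntensityMatrix:
    """Per-sample calibration of an intensity matrix.

    ``median``
        On the raw scale, scale each column so per-sample medians agree (on a
        log scale, shift).  Monotone per sample.
    ``quantile``
        Classical quantile normalization: after the transform all columns
        share the same sorted value distribution.
    ``vsn_like``
        Variance-stabilizing-style transform: arsinh of raw intensities
        scaled to log2-like units (arsinh(x)/ln 2 approaches log2(x) + 1 for
        large x), followed by a per-sample affine calibration matching every
        sample's median and median absolute deviation to their across-sample
        references.  Output scale tag is ``normalized``; differences on this
        scale read as log2 fold changes.
    """
    v = matrix.values.to_numpy(dtype=float, copy=True)
    if method == "median":
        med = np.nanmedian(v, axis=0)
        if matrix.scale == "raw":
            if np.any(med <= 0):
                raise ValueError("median normalization on raw scale needs positive medians")
            target = np.exp(np.mean(np.log(med)))
            out = v * (target / med)[None, :]
            scale = "raw"
        else:
            out = v - med[None, :] + med.mean()
            scale = matrix.scale
    elif method == "quantile":
        if np.isnan(v).any():
            raise ValueError("quantile normalization requires complete values")
        out = _quantile_normalize(v)
        scale = "normalized" if matrix.scale != "raw" else "raw"
    elif method == "vsn_like":
        if matrix.scale != "raw":
            raise ValueError("vsn_like expects raw-scale intensities")
        if np.nanmin(v) <= 0:
            raise ValueError("vsn_like requires strictly positive intensities")
        h = np.arcsinh(v) / np.log(2)
        med = np.nanmedian(h, axis=0)
        mad = np.nanmedian(np.abs(h - med[None, :]), axis=0)
        mad[mad == 0] = 1.0
        ref_med, ref_mad = med.mean(), np.exp(np.mean(np.log(mad)))
        out = (h - med[None, :]) / mad[None, :] * ref_mad + ref_med
        scale = "normalized"
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return matrix.with_values(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        scale=scale,
    )


# ---------------------------------------------------------------------------
# protein-abundance correction

def correct_by_regression(
    glyco: IntensityMatrix,
    protein: IntensityMatrix,
    mapping: pd.Series,
):
    """Remove protein-abundance-derived signal from glycopeptide profiles.

    For each glycopeptide with a matched protein profile (``mapping`` maps
    glycopeptide feature id -> protein id), fit ordinary least squares of the
    glycopeptide log-intensity on the protein log-intensity across samples
    and keep residuals plus the glycopeptide's own mean (location preserved).
    Unmatched glycopeptides pass through unchanged; a zero-variance protein
    profile yields slope 0 (pass-through).  Returns ``(corrected, flags)``
    where ``flags`` marks pass-through features.
    """
    if glyco.scale == "raw" or protein.scale == "raw":
        raise ValueError("regression correction expects log-scale matrices")
    if glyco.values.shape[1] < 3:
        raise ValueError("need at least 3 samples for regression correction")
    g = glyco.values
    p = protein.values
    out = g.copy()
    flags = pd.Series("corrected", index=g.index, dtype=object)
    for fid in g.index:
        prot = mapping.get(fid)
        if prot is None or prot not in p.index:
            flags[fid] = "unmatched"
            continue
        y = g.loc[fid].to_numpy(dtype=float)
        x = p.loc[prot].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(x)
        if ok.sum() < 3 or np.var(x[ok]) == 0:
            flags[fid] = "zero_variance_protein" if ok.sum() >= 3 else "insufficient"
            continue
        slope = np.cov(x[ok], y[ok], ddof=0)[0, 1] / np.var(x[ok])
        resid = y - (y[ok].mean() + slope * (x - x[ok].mean()))
        out.loc[fid] = resid + y[ok].mean()
    return glyco.with_values(out), flags


def correct_by_ratio(
    glyco: IntensityMatrix,
    protein: IntensityMatrix,
    mapping: pd.Series,
    global_medians: bool = False,
):
    """Protein-abundance correction by the median-anchored ratio formula.

    Per sample: ``corrected = ((g / p) / (median_g / median_p)) * median_g``
    where the medians are per-sample medians over glycopeptides with a
    matched protein (or dataset-global medians with ``global_medians``).
    Invariant to global rescaling of the protein matrix.  Cells where the
    protein intensity is zero or missing become missing.
    """
    if glyco.scale != "raw" or protein.scale != "raw":
        raise ValueError("ratio correction operates on raw-scale intensities")
    g = glyco.values
    matched = [f for f in g.index if mapping.get(f) in set(protein.values.index)]
    if not matched:
        raise ValueError("no glycopeptide has a matched protein profile")
    prot_rows = protein.values.loc[[mapping[f] for f in matched]].to_numpy(dtype=float)
    g_rows = g.loc[matched].to_numpy(dtype=float)
    if global_medians:
        med_g = np.full(g_rows.shape[1], np.nanmedian(g_rows))
        med_p = np.full(g_rows.shape[1], np.nanmedian(prot_rows))
    else:
        med_g = np.nanmedian(g_rows, axis=0)
        med_p = np.nanmedian(prot_rows, axis=0)
    if np.any(~(med_g > 0)) or np.any(~(med_p > 0)):
        raise ValueError("per-sample medians must be strictly positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = (g_rows / prot_rows) / (med_g / med_p)[None, :] * med_g[None, :]
    corrected[~np.isfinite(corrected)] = np.nan
    corrected[prot_rows <= 0] = np.nan
    out = pd.DataFrame(corrected, index=matched, columns=g.columns)
    return glyco.with_values(out)


# ---------------------------------------------------------------------------
# moderated differential analysis

def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of residual variances.

    Fits a scaled inverse-chi-square prior (scale ``s2_prior``, degrees of
    freedom ``df_prior``) to the observed residual variances by method of
    moments on ``log(s2)``, then returns the posterior (squeezed) variances
    ``(df_prior * s2_prior + df * s2) / (df_prior + df)``.

    Returns ``(s2_post, df_prior, s2_prior)``; ``df_prior`` may be ``inf``
    when the observed variances show no excess spread over chi-square
    sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return s2.copy(), 0.0, float(np.mean(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = e.mean()
    e_var = e.var(ddof=1) * (1 - 1 / ok.sum())  # moment estimator, finite-n bias tweak
    excess = e_var - special.polygamma(1, df / 2)
    if excess <= 0:
        df_prior = np.inf
        s2_prior = float(np.exp(e_mean))
    else:
        # invert trigamma(d0/2) = excess by Newton iteration
        y = excess
        x = 0.5 + 1 / y
        for _ in range(50):
            tri = special.polygamma(1, x)
            delta = tri * (1 - tri / y) / special.polygamma(2, x)
            x += delta
            if abs(delta) < 1e-10 * x:
                break
        df_prior = float(2 * x)
        s2_prior = float(np.exp(e_mean + special.digamma(x) - np.log(x)))
    if np.isinf(df_prior):
        s2_post = np.full_like(s2, s2_prior)
        s2_post[~ok] = s2_prior
    else:
        s2_post = (df_prior * s2_prior + df * s2) / (df_prior + df)
    return s2_post, df_prior, s2_prior


@dataclass
class DifferentialResult:
    """Per-feature, per-contrast moderated test results.

    ``table`` columns: ``feature``, ``contrast``, ``log2_fc``, ``t``,
    ``p_raw``, ``p_adj``, ``significant``.
    """

    table: pd.DataFrame
    lfc_threshold: float
    alpha: float
    df_prior: float
    s2_prior: float

    def for_contrast(self, contrast: str) -> pd.DataFrame:
        sub = self.table[self.table["contrast"] == contrast]
        if sub.empty:
            raise KeyError(f"no such contrast {contrast!r}")
        return sub.set_index("feature")

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _design_matrix(design: SampleDesign, covariates: tuple[str, ...]):
    """Cell-means coding for condition plus additive covariate effects."""
    tab = design.table
    levels = list(dict.fromkeys(tab["condition"]))
    cols = {f"condition[{lv}]": (tab["condition"] == lv).to_numpy(float) for lv in levels}
    for cov in covariates:
        if cov in tab.columns:
            cov_levels = list(dict.fromkeys(tab[cov]))
            for lv in cov_levels[1:]:  # first level absorbed in condition means
                cols[f"{cov}[{lv}]"] = (tab[cov] == lv).to_numpy(float)
    X = np.column_stack(list(cols.values()))
    return X, list(cols.keys()), levels


def differential(
    matrix: IntensityMatrix,
    contrasts: list[tuple[str, str]],
    lfc_threshold: float = np.log2(1.5),
    alpha: float = 0.05,
    covariates: tuple[str, ...] = ("replicate",),
    assume_log2: bool = True,
) -> DifferentialResult:
    """Moderated differential abundance between condition groups.

    Fits one linear model per feature over the sample design (condition cell
    means plus additive covariates such as replicate when declared), computes
    the contrast ``log2_fc = mean(a) - mean(b)`` for each ``(a, b)`` pair,
    moderates residual variances with :func:`squeeze_variances`, and adjusts
    p-values per contrast with Benjamini-Hochberg.  A feature is significant
    iff ``|log2_fc| > lfc_threshold`` and ``p_adj < alpha``.

    The matrix must be on a log2-like scale (``assume_log2=False`` only skips
    the scale-tag check) and complete-case features are required.
    """
    if matrix.scale == "raw" and assume_log2:
        raise ValueError("differential analysis expects a log/normalized-scale matrix")
    work = matrix.complete_cases()
    Y = work.values.to_numpy(dtype=float)
    if Y.shape[0] == 0:
        raise ValueError("no complete-case features to test")
    X, coef_names, levels = _design_matrix(work.design, covariates)
    for a, b in contrasts:
        for lv in (a, b):
            if lv not in levels:
                raise ValueError(f"contrast level {lv!r} absent from design conditions {levels}")
        if (work.design.table["condition"] == a).sum() < 2 or (
            work.design.table["condition"] == b
        ).sum() < 2:
            raise ValueError(f"contrast ({a}, {b}) needs >=2 samples per group")
    rank = np.linalg.matrix_rank(X)
    n = X.shape[0]
    df_resid = n - rank
    if df_resid < 1:
        raise ValueError("design leaves no residual degrees of freedom")
    pinv = np.linalg.pinv(X)
    beta = Y @ pinv.T  # features x coefficients
    resid = Y - beta @ X.T
    s2 = (resid**2).sum(axis=1) / df_resid
    s2_post, df_prior, s2_prior = squeeze_variances(s2, df_resid)
    df_total = df_resid + (df_prior if np.isfinite(df_prior) else 0)
    if np.isinf(df_prior):
        df_total = 1e6  # effectively normal reference
    xtx_inv = pinv @ pinv.T
    rows = []
    for a, b in contrasts:
        c = np.zeros(X.shape[1])
        c[coef_names.index(f"condition[{a}]")] = 1.0
        c[coef_names.index(f"condition[{b}]")] = -1.0
        var_factor = float(c @ xtx_inv @ c)
        lfc = beta @ c
        se = np.sqrt(s2_post * var_factor)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = lfc / se
        p = 2 * stats.t.sf(np.abs(t), df_total)
        p_adj = benjamini_hochberg(p)
        sig = (np.abs(lfc) > lfc_threshold) & (p_adj < alpha)
        contrast_label = f"{a}_vs_{b}"
        for i, fid in enumerate(work.values.index):
            rows.append(
                {
                    "feature": fid,
                    "contrast": contrast_label,
                    "log2_fc": lfc[i],
                    "t": t[i],
                    "p_raw": p[i],
                    "p_adj": p_adj[i],
                    "significant": bool(sig[i]),
                }
            )
    return DifferentialResult(
        table=pd.DataFrame(rows),
        lfc_threshold=lfc_threshold,
        alpha=alpha,
        df_prior=df_prior,
        s2_prior=s2_prior,
    )
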