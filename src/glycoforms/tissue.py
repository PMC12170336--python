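"""Tissue specificity of glycosylation patterns.

A glycosite's glycosylation pattern in one tissue is the vector of relative
intensities of its glycopeptides (replicate-averaged, normalized to sum 1
within the site and tissue).  Sites whose patterns correlate poorly across
tissues are tissue-specific; the specificity cutoff is the dataset mean of
per-site mean correlations, always recomputed from the data at hand.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .glycans import classify_n, parse_composition, glycan_mass
from .matrix import IntensityMatrix

__all__ = [
    "site_tissue_correlation",
    "class_abundance_by_tissue",
    "top_fraction_compositions",
]


def _tissue_profiles(matrix: IntensityMatrix, site_map: pd.Series):
    """Per (site, tissue): replicate-averaged, site-normalized glycopeptide
    intensity vectors.  Returns dict site -> {tissue: Series over features}."""
    design = matrix.design.table
    if "tissue" not in design.columns:
        raise ValueError("design requires a 'tissue' column")
    tissues = list(dict.fromkeys(design["tissue"]))
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues")
    # mean across replicate channels per tissue
    per_tissue = {}
    for t in tissues:
        cols = design.index[design["tissue"] == t]
        per_tissue[t] = matrix.values[cols].mean(axis=1)
    profiles: dict[str, dict[str, pd.Series]] = {}
    for site, feats in site_map.groupby(site_map).groups.items():
        profiles[site] = {}
        for t in tissues:
            v = per_tissue[t].loc[feats]
            total = v.sum()
            profiles[site][t] = v / total if total > 0 else v * np.nan
    return profiles, tissues


def site_tissue_correlation(
    matrix: IntensityMatrix,
    site_map: pd.Series,
    min_glycopeptides: int = 6,
) -> pd.DataFrame:
    """Cross-tissue Pearson correlation of per-site glycosylation patterns.

    ``site_map`` maps feature id -> site id.  Only sites with at least
    ``min_glycopeptides`` quantified glycopeptides are scored (default 6,
    i.e. strictly more than five).  For each site, the relative-intensity
    vectors of every tissue pair are correlated; the per-site mean over
    available pairs is compared to the dataset mean of those means:
    ``specific`` below the cutoff, ``conserved`` at or above it.

    Returns one row per scored site, with per-pair correlations in
    ``corr_<t1>_<t2>`` columns, ``mean_correlation``, ``specificity`` and a
    flag for sites missing a tissue pair; the cutoff is stored in
    ``df.attrs['cutoff']``.
    """
    profiles, tissues = _tissue_profiles(matrix, site_map)
    pairs = list(combinations(tissues, 2))
    rows = []
    for site, per_t in profiles.items():
        n_gp = len(next(iter(per_t.values())))
        if n_gp < min_glycopeptides:
            continue
        cors = {}
        for t1, t2 in pairs:
            a, b = per_t[t1], per_t[t2]
            ok = a.notna() & b.notna()
            if ok.sum() < 2 or a[ok].std() == 0 or b[ok].std() == 0:
                cors[(t1, t2)] = np.nan
                continue
            cors[(t1, t2)] = float(np.corrcoef(a[ok], b[ok])[0, 1])
        vals = [c for c in cors.values() if np.isfinite(c)]
        if not vals:
            continue
        row = {
            "site": site,
            "n_glycopeptides": n_gp,
            "mean_correlation": float(np.mean(vals)),
            "incomplete_pairs": len(vals) < len(pairs),
        }
        for (t1, t2), c in cors.items():
            row[f"corr_{t1}_{t2}"] = c
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        df.attrs["cutoff"] = np.nan
        return df
    cutoff = float(df["mean_correlation"].mean())
    df["specificity"] = np.where(df["mean_correlation"] < cutoff, "specific", "conserved")
    df.attrs["cutoff"] = cutoff
    return df


def class_abundance_by_tissue(matrix: IntensityMatrix, classes: pd.Series) -> pd.DataFrame:
    """Summed intensity per glycan class per tissue (absolute and relative).

    ``classes`` maps feature id -> glycan class.  Summed TMT intensities act
    as a proxy for class abundance; relative values are per-tissue fractions
    summing to 1.
    """
    design = matrix.design.table
    rows = []
    for t in dict.fromkeys(design["tissue"]):
        cols = design.index[design["tissue"] == t]
        summed = matrix.values[cols].sum(axis=1)
        by_class = summed.groupby(classes).sum()
        total = by_class.sum()
        for cls, v in by_class.items():
            rows.append(
                {
                    "tissue": t,
                    "glycan_class": cls,
                    "summed_intensity": float(v),
                    "fraction": float(v / total) if total > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def top_fraction_compositions(
    matrix: IntensityMatrix,
    compositions: pd.Series,
    top_percent: float = 1.0,
) -> pd.DataFrame:
    """The most fractionally abundant glycopeptides per tissue.

    Per tissue, fractional abundance = glycopeptide intensity / total tissue
    intensity; the top ``top_percent`` percent of glycopeptides (at least 1;
    ties broken deterministically by feature id) are reported with their
    composition, monoisotopic mass and N-glycan class, plus per-tissue
    summary statistics (median mass, fucosylated fraction) in
    ``df.attrs['summary']``.
    """
    design = matrix.design.table
    n_features = matrix.values.shape[0]
    k = max(1, round(n_features * top_percent / 100.0))
    if n_features < 100:
        import warnings

        warnings.warn(f"fewer than 100 glycopeptides; top set size {k}")
    rows, summaries = [], []
    for t in dict.fromkeys(design["tissue"]):
        cols = design.index[design["tissue"] == t]
        summed = matrix.values[cols].sum(axis=1)
        frac = summed / summed.sum()
        # deterministic tie-break: descending fraction, then feature id
        ordered = pd.DataFrame({"fid": frac.index, "frac": frac.to_numpy()}).sort_values(
            ["frac", "fid"], ascending=[False, True], kind="mergesort"
        )
        top = ordered.iloc[:k]
        masses, fuc_flags = [], []
        for fid, f in zip(top["fid"], top["frac"]):
            comp = parse_composition(compositions[fid])
            mass = glycan_mass(comp)
            cls = classify_n(comp)
            masses.append(mass)
            fuc_flags.append(comp.fuc > 0)
            rows.append(
                {
                    "tissue": t,
                    "feature_id": fid,
                    "fractional_abundance": float(f),
                    "composition": compositions[fid],
                    "mass": mass,
                    "glycan_class": cls,
                }
            )
        summaries.append(
            {
                "tissue": t,
                "median_mass": float(np.median(masses)),
                "fucosylated_fraction": float(np.mean(fuc_flags)),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["summary"] = pd.DataFrame(summaries)
    return df
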