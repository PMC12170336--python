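"""Site microheterogeneity statistics.

Microheterogeneity is the set of distinct glycan compositions observed at one
glycosite.  This module summarizes it per site (glycoform counts, class
tallies, low/medium/high bins), computes fractional intensities, compares
within-protein glycosylation profiles against a shuffled null, flags
glycosite-phosphosite proximity, and runs contingency (Fisher) enrichment of
categorical annotations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glycans import classify_n, classify_o
from .ingest import GlycopeptideRecord

__all__ = [
    "site_microheterogeneity",
    "fractional_intensity",
    "label_low_high",
    "site_profile_correlation",
    "shuffle_null",
    "ShuffleNullResult",
    "phospho_proximity",
    "contingency_enrichment",
]


def _bin_label(n: int) -> str:
    # low = 1-2, medium = 3-10, high = >=11 distinct glycoforms
    if n <= 2:
        return "low"
    if n <= 10:
        return "medium"
    return "high"


def site_microheterogeneity(records: list[GlycopeptideRecord], mode: str = "N") -> pd.DataFrame:
    """Per-site distinct-glycoform counts, glycan-class tallies and bins.

    Returns one row per glycosite with ``protein``, ``site_position``,
    ``n_glycoforms`` (distinct compositions), ``heterogeneity_bin`` and one
    ``class_<label>`` column per glycan class observed in the data.
    """
    classify = classify_n if mode == "N" else classify_o
    per_site: dict[tuple[str, int], set] = {}
    for r in records:
        per_site.setdefault((r.protein, r.site_position), set()).add(r.composition)
    rows = []
    for (protein, site), comps in sorted(per_site.items()):
        counts: dict[str, int] = {}
        for c in comps:
            counts[classify(c)] = counts.get(classify(c), 0) + 1
        row = {
            "protein": protein,
            "site_position": site,
            "n_glycoforms": len(comps),
            "heterogeneity_bin": _bin_label(len(comps)),
        }
        for cls, n in counts.items():
            row[f"class_{cls}"] = n
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        class_cols = [c for c in df.columns if c.startswith("class_")]
        df[class_cols] = df[class_cols].fillna(0).astype(int)
    return df


def fractional_intensity(records: list[GlycopeptideRecord], min_glycoforms_top: int = 10):
    """MS1 fractional intensities per (site, glycoform) and per-site maxima.

    The fractional intensity of a glycoform is its MS1 intensity divided by
    the summed MS1 intensity of all glycoforms at its site.  Returns
    ``(fractions, top)``: ``fractions`` has one row per glycoform with its
    fraction (NaN rows flagged where a site's total intensity is zero or
    missing), and ``top`` reports the highest fraction per site restricted
    to sites with at least ``min_glycoforms_top`` glycoforms.
    """
    rows = [
        {
            "protein": r.protein,
            "site_position": r.site_position,
            "feature_id": r.feature_id,
            "composition": str(r.composition),
            "ms1_intensity": r.ms1_intensity,
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(fraction=[]), pd.DataFrame(columns=["protein", "site_position", "top_fraction"])
    grp = df.groupby(["protein", "site_position"])["ms1_intensity"]
    total = grp.transform(lambda x: np.nansum(x))
    with np.errstate(invalid="ignore", divide="ignore"):
        df["fraction"] = np.where(total > 0, df["ms1_intensity"] / total, np.nan)
    df["flagged_zero_site"] = ~(total > 0)
    sizes = df.groupby(["protein", "site_position"])["feature_id"].transform("size")
    eligible = df[(sizes >= min_glycoforms_top) & df["fraction"].notna()]
    top = (
        eligible.groupby(["protein", "site_position"])["fraction"]
        .max()
        .rename("top_fraction")
        .reset_index()
    )
    return df, top


def label_low_high(summaries: pd.DataFrame, percentile: float = 90.0):
    """Label sites as lowly/highly glycosylated for downstream modeling.

    ``low`` = exactly one glycoform; ``high`` = glycoform count strictly above
    the dataset's ``percentile`` (default 90th) of the per-site glycoform
    count distribution; everything else ``unlabeled``.  Returns
    ``(labeled_summaries, threshold)``.
    """
    if len(summaries) < 10:
        raise ValueError("need at least 10 sites to set a percentile threshold")
    counts = summaries["n_glycoforms"].to_numpy()
    threshold = float(np.percentile(counts, percentile))
    labels = np.where(
        counts == 1, "low", np.where(counts > threshold, "high", "unlabeled")
    )
    out = summaries.copy()
    out["ml_label"] = labels
    if not (labels == "high").any():
        import warnings

        warnings.warn("degenerate glycoform-count distribution: no sites exceed the threshold")
    return out, threshold


def _presence_matrix(records: list[GlycopeptideRecord]):
    """Binary site x composition presence matrix over the dataset universe."""
    universe = sorted({str(r.composition) for r in records})
    comp_idx = {c: j for j, c in enumerate(universe)}
    sites: dict[tuple[str, int], set[int]] = {}
    for r in records:
        sites.setdefault((r.protein, r.site_position), set()).add(comp_idx[str(r.composition)])
    site_ids = sorted(sites)
    mat = np.zeros((len(site_ids), len(universe)), dtype=np.int8)
    for i, sid in enumerate(site_ids):
        mat[i, list(sites[sid])] = 1
    return site_ids, universe, mat


def _pairwise_tau(site_ids, mat) -> pd.DataFrame:
    by_protein: dict[str, list[int]] = {}
    for i, (protein, _site) in enumerate(site_ids):
        by_protein.setdefault(protein, []).append(i)
    rows, skipped = [], 0
    for protein, idxs in by_protein.items():
        if len(idxs) < 2:
            continue
        for a_pos in range(len(idxs)):
            for b_pos in range(a_pos + 1, len(idxs)):
                ia, ib = idxs[a_pos], idxs[b_pos]
                va, vb = mat[ia], mat[ib]
                if va.min() == va.max() or vb.min() == vb.max():
                    skipped += 1
                    continue
                tau = stats.kendalltau(va, vb, variant="b").statistic
                rows.append(
                    {
                        "protein": protein,
                        "site_a": site_ids[ia][1],
                        "site_b": site_ids[ib][1],
                        "kendall_tau": tau,
                    }
                )
    df = pd.DataFrame(rows, columns=["protein", "site_a", "site_b", "kendall_tau"])
    df.attrs["n_skipped_constant"] = skipped
    return df


def site_profile_correlation(records: list[GlycopeptideRecord]) -> pd.DataFrame:
    """Kendall tau-b between within-protein glycosylation profiles.

    Each site's profile is a binary vector over the union of all compositions
    observed in the dataset (1 = composition observed at the site).  tau-b is
    computed for every pair of sites on the same protein; constant-vector
    pairs are skipped (count in ``df.attrs['n_skipped_constant']``).
    """
    site_ids, _universe, mat = _presence_matrix(records)
    df = _pairwise_tau(site_ids, mat)
    df["source"] = "observed"
    return df


@dataclass
class ShuffleNullResult:
    observed: pd.DataFrame
    shuffled: pd.DataFrame
    statistic: float
    p_value: float
    test: str


def shuffle_null(
    records: list[GlycopeptideRecord],
    n_perm: int = 20,
    seed: int = 0,
    test: str = "ranksum",
) -> ShuffleNullResult:
    """Compare observed within-protein profile similarity to a shuffled null.

    Each permutation redistributes the global multiset of (site, composition)
    assignments across sites, preserving every site's glycoform-slot count,
    then recomputes the pairwise tau-b distribution.  The observed and pooled
    shuffled tau distributions are compared with a two-sided Wilcoxon
    rank-sum test (``test='signedrank'`` pairs permutation medians instead).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    site_ids, universe, mat = _presence_matrix(records)
    observed = _pairwise_tau(site_ids, mat)
    observed["source"] = "observed"
    slot_counts = mat.sum(axis=1)
    # global multiset of composition assignments (slot-level, with multiplicity)
    all_slots = np.concatenate([np.flatnonzero(row) for row in mat])
    shuffled_frames = []
    for _ in range(n_perm):
        perm = rng.permutation(all_slots)
        newmat = np.zeros_like(mat)
        start = 0
        for i, k in enumerate(slot_counts):
            newmat[i, perm[start : start + k]] = 1
            start += k
        assert (newmat.sum(axis=1) <= slot_counts).all()
        sh = _pairwise_tau(site_ids, newmat)
        shuffled_frames.append(sh)
    shuffled = pd.concat(shuffled_frames, ignore_index=True)
    shuffled["source"] = "shuffled"
    obs_tau = observed["kendall_tau"].to_numpy()
    sh_tau = shuffled["kendall_tau"].to_numpy()
    if test == "ranksum":
        stat, p = stats.mannwhitneyu(obs_tau, sh_tau, alternative="two-sided")
    elif test == "signedrank":
        keys = ["protein", "site_a", "site_b"]
        paired = observed.merge(
            shuffled.groupby(keys)["kendall_tau"].mean().rename("tau_null").reset_index(),
            on=keys,
        )
        diff = paired["kendall_tau"] - paired["tau_null"]
        stat, p = stats.wilcoxon(diff)
    else:
        raise ValueError(f"unknown test {test!r}")
    return ShuffleNullResult(
        observed=observed, shuffled=shuffled, statistic=float(stat), p_value=float(p), test=test
    )


def phospho_proximity(
    records: list[GlycopeptideRecord],
    phosphosites: pd.DataFrame,
    mode: str = "N",
    window: int = 5,
    peptide_start: pd.Series | None = None,
) -> pd.DataFrame:
    """Flag glycopeptides with a known phosphosite nearby.

    N mode: a phosphosite within +/- ``window`` residues of the glycosite.
    O mode: within +/- ``window`` residues of the peptide start position
    (HCD data cannot localize O-sites), supplied via ``peptide_start``
    (feature_id -> 1-based start) or falling back to the record's site
    position.  ``phosphosites`` needs columns ``protein`` and ``position``.
    """
    by_protein: dict[str, np.ndarray] = {
        prot: grp["position"].to_numpy(dtype=int)
        for prot, grp in phosphosites.groupby("protein")
    }
    rows = []
    for r in records:
        if mode == "N":
            anchor = r.site_position
        else:
            anchor = (
                int(peptide_start[r.feature_id])
                if peptide_start is not None and r.feature_id in peptide_start
                else r.site_position
            )
        positions = by_protein.get(r.protein)
        near = bool(positions is not None and (np.abs(positions - anchor) <= window).any())
        rows.append(
            {
                "feature_id": r.feature_id,
                "protein": r.protein,
                "anchor_position": anchor,
                "phospho_nearby": near,
            }
        )
    return pd.DataFrame(rows)


def contingency_enrichment(
    counts: pd.DataFrame, alpha: float = 1e-3
) -> pd.DataFrame:
    """Per-category 2x2 Fisher enrichment with BH adjustment.

    ``counts`` is indexed by category with columns
    ``in_group, out_group, in_background, out_background`` (the 2x2 table per
    category).  Returns per category the two-sided Fisher exact p, the log2
    odds ratio (0.5 Haldane correction when any cell is zero), the BH
    adjusted p across categories and a significance flag at adjusted
    p < ``alpha`` (default 1e-3).
    """
    required = ["in_group", "out_group", "in_background", "out_background"]
    for col in required:
        if col not in counts.columns:
            raise ValueError(f"missing column {col!r}")
    if (counts[required] < 0).any().any():
        raise ValueError("contingency counts must be non-negative")
    ps, log2_ors = [], []
    for _, row in counts.iterrows():
        table = [[row["in_group"], row["out_group"]], [row["in_background"], row["out_background"]]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        a, b, c, d = (float(x) for x in (row[c] for c in required))
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        log2_ors.append(np.log2((a * d) / (b * c)))
        ps.append(p)
    from .quant import benjamini_hochberg

    p_adj = benjamini_hochberg(ps)
    return pd.DataFrame(
        {
            "log2_odds_ratio": log2_ors,
            "p_raw": ps,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        },
        index=counts.index,
    )
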