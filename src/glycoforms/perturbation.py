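"""Perturbation analyses: surface-exposure classification from enzymatic
treatments of intact cells, cross-treatment agreement, and neural-gas
clustering of kinetic fold-change profiles.

Surface exposure: treating intact cells with a deglycosidase (PNGase F) or a
broad protease (proteinase K) only affects surface-exposed glycoforms, so a
glycosite where at least two glycoforms change significantly in abundance is
classified as affected (surface-exposed).

Neural gas is a rank-based vector quantizer: each presented profile ranks all
prototypes by distance and every prototype moves toward it with a step that
decays exponentially in both rank and time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .quant import DifferentialResult

__all__ = [
    "classify_site_exposure",
    "composition_exposure_counts",
    "NeuralGasConfig",
    "NeuralGasResult",
    "neural_gas",
    "cluster_kinetics",
]


def classify_site_exposure(
    diff: pd.DataFrame,
    site_map: pd.Series,
    min_glycoforms: int = 2,
) -> pd.DataFrame:
    """Classify glycosites as affected by an enzymatic surface treatment.

    ``diff`` is a per-feature differential table (one contrast) with columns
    ``log2_fc`` and ``significant`` indexed by feature id; ``site_map`` maps
    feature id -> site id.  A site is ``affected`` iff at least
    ``min_glycoforms`` of its glycoforms are significant; sites with exactly
    one significant glycoform are reported but flagged unaffected.
    """
    feats = diff.index.intersection(site_map.index)
    d = diff.loc[feats]
    sites = site_map.loc[feats]
    n_sig = d["significant"].groupby(sites).sum()
    n_tot = d["significant"].groupby(sites).size()
    out = pd.DataFrame(
        {
            "n_glycoforms": n_tot,
            "n_significant_glycoforms": n_sig.astype(int),
            "affected": n_sig >= min_glycoforms,
        }
    )
    out.index.name = "site"
    return out


def composition_exposure_counts(
    diff_a: pd.DataFrame,
    diff_b: pd.DataFrame,
    composition_map: pd.Series,
    site_map: pd.Series,
) -> dict:
    """Composition-level and fold-change agreement between two treatments.

    Per glycan composition, counts how many significantly changing
    glycopeptides carry it in each treatment and correlates the two count
    vectors (Pearson).  Additionally correlates per-glycopeptide log2 fold
    changes across treatments, restricted to glycopeptides shared by both
    experiments on sites affected (>= 2 significant glycoforms) in both.

    Returns a dict with ``counts`` (composition x treatment counts),
    ``count_correlation``, ``fold_change_correlation`` and ``n_shared``;
    correlations are NaN when undefined (no shared support).
    """
    counts = {}
    for label, diff in (("a", diff_a), ("b", diff_b)):
        sig = diff[diff["significant"]]
        comp = composition_map.loc[sig.index.intersection(composition_map.index)]
        counts[label] = comp.value_counts()
    table = pd.DataFrame(counts).fillna(0).astype(int)
    table.columns = ["treatment_a", "treatment_b"]
    if len(table) >= 2 and table["treatment_a"].std() > 0 and table["treatment_b"].std() > 0:
        count_corr = float(stats.pearsonr(table["treatment_a"], table["treatment_b"]).statistic)
    else:
        count_corr = np.nan
    exp_a = classify_site_exposure(diff_a, site_map)
    exp_b = classify_site_exposure(diff_b, site_map)
    both = set(exp_a.index[exp_a["affected"]]) & set(exp_b.index[exp_b["affected"]])
    shared = diff_a.index.intersection(diff_b.index)
    shared = [f for f in shared if site_map.get(f) in both]
    if len(shared) >= 3:
        fc_corr = float(
            stats.pearsonr(diff_a.loc[shared, "log2_fc"], diff_b.loc[shared, "log2_fc"]).statistic
        )
    else:
        fc_corr = np.nan
    return {
        "counts": table,
        "count_correlation": count_corr,
        "fold_change_correlation": fc_corr,
        "n_shared": len(shared),
    }


@dataclass
class NeuralGasConfig:
    """Hyperparameters of the neural-gas quantizer.

    Defaults follow the classical published schedule: learning rate decaying
    from 0.5 to 0.005 and neighborhood range from k/2 to 0.01, with
    ``t_max = 100 * n_samples`` adaptation steps when left unset.
    """

    k: int = 4
    epsilon_initial: float = 0.5
    epsilon_final: float = 0.005
    lambda_initial: float | None = None  # defaults to k / 2
    lambda_final: float = 0.01
    t_max: int | None = None  # defaults to 100 * n_samples
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.epsilon_final <= self.epsilon_initial < 1):
            raise ValueError("need 0 < epsilon_final <= epsilon_initial < 1")
        if self.lambda_initial is not None and self.lambda_initial <= 0:
            raise ValueError("lambda_initial must be > 0")
        if self.lambda_final <= 0:
            raise ValueError("lambda_final must be > 0")
        if self.t_max is not None and self.t_max < 1:
            raise ValueError("t_max must be >= 1")


@dataclass
class NeuralGasResult:
    prototypes: np.ndarray  # k x d
    assignments: np.ndarray  # n
    quantization_error: float
    config: NeuralGasConfig = field(repr=False)


def neural_gas(profiles: np.ndarray, config: NeuralGasConfig) -> NeuralGasResult:
    """Rank-based vector quantization of profile vectors.

    Prototypes initialize as ``k`` distinct input vectors sampled with the
    configured seed.  For step ``t = 1..t_max`` one input ``x`` is presented
    (seeded shuffled cyclic order); all prototypes are ranked by Euclidean
    distance to ``x`` (0-based rank ``r``) and updated as
    ``w += eps(t) * exp(-r / lam(t)) * (x - w)`` with exponential schedules
    ``eps(t) = eps_i * (eps_f / eps_i)**(t / t_max)`` (same for ``lam``).
    The final assignment is the nearest prototype; quantization error is the
    mean squared distance to the assigned prototype.  Deterministic given the
    seed.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2:
        raise ValueError("profiles must be a 2-D array (n x d)")
    if not np.isfinite(X).all():
        raise ValueError("profiles must not contain missing values")
    n, _d = X.shape
    distinct = np.unique(X, axis=0)
    if config.k > len(distinct):
        raise ValueError(f"k={config.k} exceeds the {len(distinct)} distinct profiles")
    rng = np.random.default_rng(config.seed)
    init_idx = rng.choice(len(distinct), size=config.k, replace=False)
    W = distinct[init_idx].copy()
    t_max = config.t_max if config.t_max is not None else 100 * n
    lam_i = config.lambda_initial if config.lambda_initial is not None else config.k / 2
    eps_i, eps_f, lam_f = config.epsilon_initial, config.epsilon_final, config.lambda_final
    order = rng.permutation(n)
    pos = 0
    for t in range(1, t_max + 1):
        if pos == n:
            order = rng.permutation(n)
            pos = 0
        x = X[order[pos]]
        pos += 1
        frac = t / t_max
        eps = eps_i * (eps_f / eps_i) ** frac
        lam = lam_i * (lam_f / lam_i) ** frac
        dist = np.linalg.norm(W - x[None, :], axis=1)
        ranks = np.argsort(np.argsort(dist, kind="stable"), kind="stable")
        W += eps * np.exp(-ranks / lam)[:, None] * (x - W)
    d2 = ((X[:, None, :] - W[None, :, :]) ** 2).sum(axis=2)
    assignments = d2.argmin(axis=1)
    qe = float(d2[np.arange(n), assignments].mean())
    return NeuralGasResult(prototypes=W, assignments=assignments, quantization_error=qe, config=config)


def cluster_kinetics(
    diff: DifferentialResult,
    k: int = 4,
    subset: pd.Index | None = None,
    direction: str = "any",
    config: NeuralGasConfig | None = None,
) -> pd.DataFrame:
    """Cluster per-time-point log2 fold-change profiles with neural gas.

    Uses every feature significant at >= 1 time point (contrasts of ``diff``
    are interpreted as time points in table order).  ``subset`` restricts the
    candidate features (e.g. the fucosylated class); ``direction='down'``
    additionally requires a significant negative fold change at >= 1 time
    point, which with ``k=3`` reproduces the downregulated-fucosylation
    grouping (``k=4`` on all regulated features is the full-kinetics preset).

    Returns a feature x time table of profiles with a ``cluster`` column;
    cluster mean profiles are in ``df.attrs['prototypes']`` and the
    quantization error in ``df.attrs['quantization_error']``.
    """
    wide_fc = diff.table.pivot(index="feature", columns="contrast", values="log2_fc")
    wide_sig = diff.table.pivot(index="feature", columns="contrast", values="significant")
    order = list(dict.fromkeys(diff.table["contrast"]))
    wide_fc, wide_sig = wide_fc[order], wide_sig[order]
    if subset is not None:
        keep = wide_fc.index.intersection(subset)
        wide_fc, wide_sig = wide_fc.loc[keep], wide_sig.loc[keep]
    if direction == "any":
        regulated = wide_sig.any(axis=1)
    elif direction == "down":
        regulated = (wide_sig & (wide_fc < 0)).any(axis=1)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    X = wide_fc.loc[regulated].dropna()
    if len(X) < k:
        raise ValueError(f"only {len(X)} regulated features for k={k}")
    cfg = config or NeuralGasConfig(k=k)
    if cfg.k != k:
        raise ValueError("config.k disagrees with k")
    result = neural_gas(X.to_numpy(), cfg)
    out = X.copy()
    out["cluster"] = result.assignments
    out.attrs["prototypes"] = pd.DataFrame(
        result.prototypes, columns=order, index=[f"cluster_{i}" for i in range(k)]
    )
    out.attrs["quantization_error"] = result.quantization_error
    return out
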