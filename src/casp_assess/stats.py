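"""Bootstrap significance and difficulty-matched cross-experiment comparison.

Head-to-head comparisons resample common evaluation units with replacement
(1000 replicates by default) and count how often one group's EU-weighted
summed z exceeds the other's; significance at confidence level alpha means a
win fraction of at least 1 − alpha.

Cross-experiment progress comparisons control for target difficulty (proxied
by a baseline predictor's first-model GDT_HA) either by Hungarian one-to-one
matching, or by weighted bootstrap with weights from the ratio of Gaussian
kernel density estimates of the two difficulty distributions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import linear_sum_assignment

__all__ = [
    "HeadToHeadMatrix",
    "DifficultyRecord",
    "MatchResult",
    "head_to_head",
    "head_to_head_matrix",
    "significance_matrix",
    "hungarian_match",
    "kde_weighted_resample",
    "progress_test",
    "metric_correlation",
]


@dataclass
class DifficultyRecord:
    """One EU of one experiment: difficulty proxy and the best achieved score."""

    eu: str
    difficulty: float          # baseline first-model GDT_HA
    best_score: float          # best group GDT_HA
    experiment: str = ""
    gdt_ts95: float = float("nan")


@dataclass
class MatchResult:
    pairs: list                      # (source eu, reference eu)
    total_cost: float
    mean_difficulty: tuple           # (source-side, reference-side)
    mean_best: tuple                 # (source-side, reference-side)
    p_value: float = float("nan")
    best_pairs: list = field(default_factory=list)  # (source best, reference best)


@dataclass
class HeadToHeadMatrix:
    groups: list
    win_fraction: np.ndarray
    n_boot: int
    alpha: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        return significance_matrix(self, self.alpha)

    def row_sum_order(self) -> list:
        order = np.argsort(-self.win_fraction.sum(axis=1), kind="stable")
        return [self.groups[i] for i in order]


# ---------------------------------------------------------------------------
# Bootstrap head-to-head


def head_to_head(
    zA: pd.Series,
    zB: pd.Series,
    weights: pd.Series | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> float:
    """Fraction of bootstrap replicates where group A outperforms group B.

    ``zA``/``zB`` are per-EU composite z-scores indexed by EU id; only EUs
    present in both are used.  Each replicate resamples the common EUs with
    replacement and compares the EU-weight-weighted sums; ties count 0.5.
    """
    common = zA.index.intersection(zB.index)
    if len(common) == 0:
        raise ValueError("no common EUs between the two groups")
    if n_boot < 1:
        raise ValueError("n_boot must be ≥ 1")
    a = zA.loc[common].to_numpy(dtype=float)
    b = zB.loc[common].to_numpy(dtype=float)
    w = (
        weights.reindex(common).to_numpy(dtype=float)
        if weights is not None
        else np.ones(len(common))
    )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(common), size=(n_boot, len(common)))
    sa = (a[idx] * w[idx]).sum(axis=1)
    sb = (b[idx] * w[idx]).sum(axis=1)
    wins = (sa > sb).sum() + 0.5 * (sa == sb).sum()
    return float(wins / n_boot)


def head_to_head_matrix(
    z_by_group: dict,
    weights: pd.Series | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> HeadToHeadMatrix:
    """Pairwise bootstrap win fractions for a set of groups.

    ``z_by_group`` maps group → per-EU composite z (Series indexed by EU).
    The same replicate seed is derived per unordered pair so that
    win[a][b] + win[b][a] = 1 under tie-splitting.
    """
    groups = list(z_by_group)
    n = len(groups)
    frac = np.full((n, n), 0.5)
    pair_seed = {
        (i, j): seed + k  # deterministic per unordered pair
        for k, (i, j) in enumerate(itertools.combinations(range(n), 2))
    }
    for (i, j), s in pair_seed.items():
        f = head_to_head(z_by_group[groups[i]], z_by_group[groups[j]], weights, n_boot, s)
        frac[i, j] = f
        frac[j, i] = 1.0 - f
    return HeadToHeadMatrix(groups=groups, win_fraction=frac, n_boot=n_boot, alpha=alpha)


def significance_matrix(m: HeadToHeadMatrix, alpha: float = 0.05) -> np.ndarray:
    """significant[a][b] iff A beats B in at least 1 − alpha of replicates."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    sig = m.win_fraction >= 1.0 - alpha
    np.fill_diagonal(sig, False)
    return sig


# ---------------------------------------------------------------------------
# Difficulty matching


def hungarian_match(d_source, d_reference) -> MatchResult:
    """Optimal one-to-one difficulty matching of reference items to source items.

    Minimizes Σ |d_source − d_reference| over assignments; every reference
    item is matched, surplus source items stay unmatched.  Accepts lists of
    :class:`DifficultyRecord` or plain difficulty values.
    """
    src = [d if isinstance(d, DifficultyRecord) else DifficultyRecord(str(i), float(d), np.nan)
           for i, d in enumerate(d_source)]
    ref = [d if isinstance(d, DifficultyRecord) else DifficultyRecord(str(i), float(d), np.nan)
           for i, d in enumerate(d_reference)]
    if not src or not ref:
        raise ValueError("both difficulty lists must be non-empty")
    if len(ref) > len(src):
        raise ValueError("reference set larger than source set")
    cost = np.abs(
        np.array([r.difficulty for r in ref])[:, None]
        - np.array([s.difficulty for s in src])[None, :]
    )
    rows, cols = linear_sum_assignment(cost)
    pairs = [(src[c].eu, ref[r].eu) for r, c in zip(rows, cols)]
    best_pairs = [(src[c].best_score, ref[r].best_score) for r, c in zip(rows, cols)]
    total = float(cost[rows, cols].sum())
    sd = [src[c].difficulty for c in cols]
    rd = [ref[r].difficulty for r in rows]
    sb = [src[c].best_score for c in cols]
    rb = [ref[r].best_score for r in rows]
    return MatchResult(
        pairs=pairs,
        total_cost=total,
        mean_difficulty=(float(np.mean(sd)), float(np.mean(rd))),
        mean_best=(float(np.nanmean(sb)), float(np.nanmean(rb))),
        best_pairs=best_pairs,
    )


def kde_weighted_resample(
    source,
    reference,
    n: int | None = None,
    n_samples: int = 1000,
    seed: int = 0,
    bandwidth="scott",
    weight_floor: float = 1e-12,
):
    """Bootstrap the source set with weights matching the reference difficulty profile.

    Gaussian KDEs are fitted to the source and reference difficulty values;
    each source record is weighted ∝ f_ref(d) / f_src(d) (normalized, densities
    floored at ``weight_floor``), and ``n_samples`` bootstrap samples of size
    ``n`` (default: reference set size) are drawn with replacement.

    Returns ``(samples, frac_source_above_reference, weights, draws)``:
    a DataFrame with per-sample ``mean_difficulty`` and ``mean_best``, the
    fraction of samples whose mean best score exceeds the reference's mean
    best, the normalized weights, and the (n_samples, n) array of drawn
    source indices.
    """
    src = [d if isinstance(d, DifficultyRecord) else DifficultyRecord(str(i), float(d), np.nan)
           for i, d in enumerate(source)]
    ref = [d if isinstance(d, DifficultyRecord) else DifficultyRecord(str(i), float(d), np.nan)
           for i, d in enumerate(reference)]
    if len(src) < 2 or len(ref) < 2:
        raise ValueError("source and reference need at least 2 records each")
    if n is None:
        n = len(ref)
    if n < 1:
        raise ValueError("sample size must be ≥ 1")
    sd = np.array([r.difficulty for r in src])
    rd = np.array([r.difficulty for r in ref])
    kde_src = sps.gaussian_kde(sd, bw_method=bandwidth)
    kde_ref = sps.gaussian_kde(rd, bw_method=bandwidth)
    f_src = kde_src(sd)
    f_ref = kde_ref(sd)
    if np.any(~np.isfinite(f_src)) or np.any(~np.isfinite(f_ref)) or np.any(f_src <= 0):
        warnings.warn("non-positive or non-finite KDE density; weights floored")
    w = np.clip(f_ref, weight_floor, None) / np.clip(f_src, weight_floor, None)
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    sb = np.array([r.best_score for r in src])
    rb_mean = float(np.nanmean([r.best_score for r in ref]))
    draws = rng.choice(len(src), size=(n_samples, n), replace=True, p=w)
    mean_diff = sd[draws].mean(axis=1)
    mean_best = sb[draws].mean(axis=1)
    samples = pd.DataFrame({"mean_difficulty": mean_diff, "mean_best": mean_best})
    frac_above = float(np.mean(mean_best > rb_mean)) if np.isfinite(rb_mean) else float("nan")
    return samples, frac_above, w, draws


def progress_test(matched: MatchResult, method: str = "t") -> tuple[float, float]:
    """Paired test on best scores of difficulty-matched EU pairs.

    Differences are reference − source.  ``method='t'`` uses the paired
    t-statistic with an epsilon guard on a zero-variance difference vector
    (all-zero differences give p = 1, a constant nonzero shift p ≈ 0);
    ``method='wilcoxon'`` uses the signed-rank test.  Returns
    ``(mean_difference, two_sided_p)``.
    """
    if len(matched.best_pairs) < 2:
        raise ValueError("progress test needs at least 2 matched pairs")
    diffs = np.array([r - s for s, r in matched.best_pairs], dtype=float)
    mean_diff = float(diffs.mean())
    n = len(diffs)
    if method == "t":
        sd = float(diffs.std(ddof=1))
        if sd == 0 and mean_diff == 0:
            return mean_diff, 1.0
        sd = max(sd, 1e-12)
        t = mean_diff / (sd / np.sqrt(n))
        p = float(2 * sps.t.sf(abs(t), df=n - 1))
    elif method == "wilcoxon":
        if np.all(diffs == 0):
            return mean_diff, 1.0
        p = float(sps.wilcoxon(diffs).pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return mean_diff, p


# ---------------------------------------------------------------------------
# Metric correlations


def metric_correlation(df: pd.DataFrame, metrics) -> pd.DataFrame:
    """Pearson correlation matrix of raw scores across metrics.

    Rows are (group, eu, model) observations complete for all requested
    metrics; constant metrics get NaN correlations.
    """
    metrics = list(metrics)
    if len(metrics) < 2:
        raise ValueError("need at least 2 metrics")
    wide = df[df["metric"].isin(metrics)].pivot_table(
        index=["group", "eu", "model"], columns="metric", values="value", aggfunc="first"
    )
    wide = wide.reindex(columns=metrics).dropna()
    if len(wide) < 3:
        raise ValueError("need at least 3 complete observations")
    return wide.corr(method="pearson")
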