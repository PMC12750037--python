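"""Composite z-score ranking of prediction groups.

The ranking follows the CASP convention: for every evaluation unit (EU) and
every component metric, group scores are converted to z-scores in two rounds
(outliers below −2 excluded from the second round's mean/sd, final z floored
at −2, missing submissions scored −2), combined as a weighted sum over the
nine component metrics, and summed over EUs with weight 1/N per EU of an
N-EU target so that every target counts equally:

    Z_total = Σ_target Σ_EU w_EU · Σ_metric w_m · z_m

Default weights: 1/6 for GDT_HA, QSE, reLLG_const; 1/8 for SphGr, CAD_AA;
1/16 for GDC_SC, AL0_P, lDDT, MolProbity (lower-is-better, negated before
the z-computation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structio import EUDefinition

__all__ = [
    "RANKING_METRICS",
    "WeightScheme",
    "ZScoreResult",
    "read_score_table",
    "write_score_table",
    "validate_score_table",
    "impute_unscored",
    "two_round_z",
    "composite_z",
    "select_models",
    "aggregate_ranking",
    "first_model_best_frequency",
]

#: The nine component metrics of the composite ranking score.
RANKING_METRICS = (
    "GDT_HA", "QSE", "reLLG_const", "SphGr", "CAD_AA",
    "GDC_SC", "AL0_P", "lDDT", "MolProbity",
)

SCORE_COLUMNS = ["group", "target", "eu", "phase", "model", "metric", "value"]


@dataclass
class WeightScheme:
    """Metric → weight and orientation (``higher_better`` / ``lower_better``)."""

    weights: dict
    orientation: dict = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1 (got {total!r})")
        for m in self.weights:
            self.orientation.setdefault(m, "higher_better")
            if self.orientation[m] not in ("higher_better", "lower_better"):
                raise ValueError(f"bad orientation for {m}")

    @classmethod
    def default(cls) -> "WeightScheme":
        w = {
            "GDT_HA": 1 / 6, "QSE": 1 / 6, "reLLG_const": 1 / 6,
            "SphGr": 1 / 8, "CAD_AA": 1 / 8,
            "GDC_SC": 1 / 16, "AL0_P": 1 / 16, "lDDT": 1 / 16, "MolProbity": 1 / 16,
        }
        return cls(weights=w, orientation={"MolProbity": "lower_better"})

    @classmethod
    def single(cls, metric: str, orientation: str = "higher_better") -> "WeightScheme":
        """Degenerate scheme with full weight on one metric (e.g. QSE-only ranking)."""
        return cls(weights={metric: 1.0}, orientation={metric: orientation})

    def restrict(self, metrics) -> "WeightScheme":
        """Drop absent metrics and renormalize the remaining weights to sum 1."""
        kept = {m: w for m, w in self.weights.items() if m in set(metrics)}
        if not kept:
            raise ValueError("no scheme metrics present")
        total = sum(kept.values())
        return WeightScheme(
            weights={m: w / total for m, w in kept.items()},
            orientation={m: self.orientation[m] for m in kept},
        )

    @property
    def metrics(self):
        return tuple(self.weights)


@dataclass
class ZScoreResult:
    z: pd.Series                      # index: observation key, final z (≥ floor)
    excluded_round1: frozenset = frozenset()
    imputed_missing: frozenset = frozenset()
    floored: frozenset = frozenset()


def read_score_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"score table missing columns {missing}")
    return df


def write_score_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def validate_score_table(df: pd.DataFrame) -> None:
    if df.empty:
        raise ValueError("empty score table")
    dup = df.duplicated(subset=["group", "eu", "model", "metric"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicate (group, eu, model, metric) records")


# ---------------------------------------------------------------------------
# Imputation of partially scored submissions


def impute_unscored(df: pd.DataFrame, scheme: WeightScheme | None = None) -> pd.DataFrame:
    """Fill metrics a submitted model could not be scored on.

    A submitted model (present in the table for the EU) that lacks a value
    for some metric receives the worst observed value for that EU/metric:
    the minimum for higher-better metrics, the maximum for lower-better ones.
    Entirely missing submissions are not imputed here — they are scored −2 at
    the z level.  Metrics absent for every model of an EU are dropped for
    that EU with a warning.
    """
    scheme = scheme or WeightScheme.default()
    validate_score_table(df)
    out = []
    for eu, sub in df.groupby("eu", sort=False):
        wide = sub.pivot_table(
            index=["group", "model"], columns="metric", values="value", aggfunc="first"
        )
        # pivot_table drops all-NaN metrics silently; keep them so the drop warns
        wide = wide.reindex(columns=pd.unique(sub["metric"]))
        meta = sub.drop_duplicates(["group", "model"]).set_index(["group", "model"])[
            [c for c in ("target", "phase") if c in sub.columns]
        ]
        for metric in list(wide.columns):
            col = wide[metric]
            if col.isna().all():
                warnings.warn(f"EU {eu}: metric {metric} unscored for all models; dropped")
                wide = wide.drop(columns=metric)
                continue
            if col.isna().any():
                orient = scheme.orientation.get(metric, "higher_better")
                worst = col.max() if orient == "lower_better" else col.min()
                wide[metric] = col.fillna(worst)
        long = (
            wide.reset_index()
            .melt(id_vars=["group", "model"], var_name="metric", value_name="value")
            .dropna(subset=["value"])
        )
        long["eu"] = eu
        long = long.join(meta, on=["group", "model"])
        out.append(long)
    res = pd.concat(out, ignore_index=True)
    return res[[c for c in SCORE_COLUMNS if c in res.columns]]


# ---------------------------------------------------------------------------
# Two-round z-scores


def two_round_z(
    values: pd.Series,
    orientation: str = "higher_better",
    all_keys=None,
    floor: float = -2.0,
    exclusion_threshold: float = -2.0,
) -> ZScoreResult:
    """Two-round z-scores for one EU/metric.

    Round 1: z from the population mean/sd of all values; members below the
    exclusion threshold are dropped.  Round 2: mean/sd recomputed from the
    remainder and applied to *all* members; final z floored at ``floor``.
    Keys in ``all_keys`` with no value are scored ``floor`` (missing
    submission).  A zero sd yields z = 0 for members at the mean.
    """
    values = pd.Series(values, dtype=float).dropna()
    all_keys = list(all_keys) if all_keys is not None else list(values.index)
    x = -values if orientation == "lower_better" else values

    def zscore(v, mu, sd):
        if sd == 0:
            d = v - mu
            return pd.Series(
                np.where(d == 0, 0.0, np.where(d < 0, -np.inf, np.inf)), index=v.index
            )
        return (v - mu) / sd

    if len(x) < 2:
        warnings.warn("fewer than 2 values; z set to 0")
        z = pd.Series(0.0, index=x.index)
        excluded = frozenset()
    else:
        mu1, sd1 = float(x.mean()), float(x.std(ddof=0))
        z1 = zscore(x, mu1, sd1)
        kept = x[z1 >= exclusion_threshold]
        excluded = frozenset(x.index[z1 < exclusion_threshold])
        if len(kept) == 0:
            kept = x
            excluded = frozenset()
        mu2, sd2 = float(kept.mean()), float(kept.std(ddof=0))
        z = zscore(x, mu2, sd2)

    final = z.clip(lower=floor)
    floored = frozenset(z.index[z < floor])
    missing = [k for k in all_keys if k not in final.index]
    if missing:
        final = pd.concat([final, pd.Series(floor, index=missing)])
    final = final.reindex(all_keys) if all_keys else final
    return ZScoreResult(
        z=final,
        excluded_round1=excluded,
        imputed_missing=frozenset(missing),
        floored=floored,
    )


def composite_z(z: dict, scheme: WeightScheme | None = None) -> float:
    """Weighted sum of per-metric z-scores for one group/EU."""
    scheme = scheme or WeightScheme.default()
    missing = [m for m in scheme.metrics if m not in z]
    if missing:
        raise ValueError(f"metrics missing from z: {missing}")
    return float(sum(scheme.weights[m] * z[m] for m in scheme.metrics))


# ---------------------------------------------------------------------------
# Model selection


def _composite_per_model(sub: pd.DataFrame, scheme: WeightScheme, floor: float) -> pd.Series:
    """Composite z per (group, model) within one EU, z over the model pool."""
    wide = sub.pivot_table(
        index=["group", "model"], columns="metric", values="value", aggfunc="first"
    )
    local = scheme.restrict([m for m in scheme.metrics if m in wide.columns])
    zcols = {}
    for metric in local.metrics:
        zcols[metric] = two_round_z(
            wide[metric], local.orientation[metric], floor=floor
        ).z
    zdf = pd.DataFrame(zcols).reindex(wide.index)
    return zdf.fillna(floor).mul(pd.Series(local.weights)).sum(axis=1)


def select_models(
    df: pd.DataFrame,
    mode: str = "first",
    selector_metric: str | None = None,
    scheme: WeightScheme | None = None,
    floor: float = -2.0,
) -> pd.DataFrame:
    """Reduce the score table to one model per (group, EU).

    ``first``: model index 1, else the lowest index present.  ``best``: the
    model maximizing the composite weighted z within the EU's model pool (or
    the raw ``selector_metric`` when given); ties go to the lowest model
    index.  ``model6``: keep model 6 only; groups without one contribute no
    record (scored as missing downstream).
    """
    validate_score_table(df)
    scheme = scheme or WeightScheme.default()
    if mode not in ("first", "best", "model6"):
        raise ValueError(f"unknown selection mode {mode!r}")
    picks = []
    for (eu, group), sub in df.groupby(["eu", "group"], sort=False):
        models = sorted(sub["model"].unique())
        if mode == "first":
            picks.append((eu, group, models[0]))
        elif mode == "model6":
            if 6 in models:
                picks.append((eu, group, 6))
        else:
            if selector_metric is not None:
                vals = (
                    sub[sub["metric"] == selector_metric]
                    .set_index("model")["value"]
                    .dropna()
                )
                if vals.empty:
                    picks.append((eu, group, models[0]))
                    continue
                best_val = vals.max()
                picks.append((eu, group, min(m for m, v in vals.items() if v == best_val)))
            else:
                picks.append((eu, group, None))  # resolved per-EU below
    if mode == "best" and selector_metric is None:
        picks = []
        for eu, sub in df.groupby("eu", sort=False):
            comp = _composite_per_model(sub, scheme, floor)
            for group, gz in comp.groupby(level="group"):
                best_val = gz.max()
                model = min(m for (_, m), v in gz.items() if v == best_val)
                picks.append((eu, group, model))
    key = pd.DataFrame(picks, columns=["eu", "group", "model"])
    return df.merge(key, on=["eu", "group", "model"])


# ---------------------------------------------------------------------------
# Aggregation


def aggregate_ranking(
    df: pd.DataFrame,
    eus: list[EUDefinition],
    scheme: WeightScheme | None = None,
    mode: str = "best",
    floor: float = -2.0,
) -> pd.DataFrame:
    """Full group ranking: imputation, model selection, two-round z, weighted sum.

    Returns a DataFrame indexed by group, sorted by descending ``total_z``,
    with per-metric contribution columns and ``n_submitted`` (EUs with any
    submission).  Groups with no submission for an EU receive z = floor on
    every metric there.
    """
    scheme = scheme or WeightScheme.default()
    eu_weight = {eu.eu_id: eu.weight for eu in eus}
    unknown = set(df["eu"]) - set(eu_weight)
    if unknown:
        raise ValueError(f"EUs in table without definitions: {sorted(unknown)}")
    df = impute_unscored(df, scheme)
    sel = select_models(df, mode=mode, scheme=scheme, floor=floor)
    groups = sorted(df["group"].unique())
    total = pd.Series(0.0, index=groups)
    contrib = pd.DataFrame(0.0, index=groups, columns=list(scheme.metrics))
    n_submitted = pd.Series(0, index=groups)
    for eu, sub in sel.groupby("eu", sort=False):
        w_eu = eu_weight[eu]
        wide = sub.pivot_table(index="group", columns="metric", values="value", aggfunc="first")
        local = scheme.restrict([m for m in scheme.metrics if m in wide.columns])
        for metric in local.metrics:
            zres = two_round_z(
                wide[metric].dropna(), local.orientation[metric],
                all_keys=groups, floor=floor,
            )
            contrib[metric] += w_eu * local.weights[metric] * zres.z
            total += w_eu * local.weights[metric] * zres.z
        n_submitted[wide.index] += 1
    out = pd.DataFrame({"total_z": total, "n_submitted": n_submitted})
    out = pd.concat([out, contrib], axis=1)
    return out.sort_values("total_z", ascending=False)


# ---------------------------------------------------------------------------
# First-model statistics


def first_model_best_frequency(df: pd.DataFrame, metric: str) -> pd.DataFrame:
    """How often each group's first model is also its best.

    Over EUs where the group submitted ≥ 2 models scored on ``metric``,
    counts those where the first (lowest-index) model attains the maximum
    (ties credited).  A random ordering of distinct scores gives an expected
    ratio of 1/n_models (20% for five models).
    """
    sub = df[df["metric"] == metric].dropna(subset=["value"])
    if sub.empty:
        raise ValueError(f"no values for metric {metric!r}")
    multi = sub[sub.groupby(["group", "eu"])["value"].transform("size") >= 2]
    if multi.empty:
        raise ValueError("no EUs with ≥ 2 scored models")
    firsts = (
        multi.sort_values("model")
        .drop_duplicates(["group", "eu"], keep="first")
        .set_index(["group", "eu"])["value"]
    )
    maxima = multi.groupby(["group", "eu"])["value"].max()
    wins = (firsts.reindex(maxima.index) >= maxima).groupby(level="group").agg(["sum", "size"])
    out = pd.DataFrame(
        {
            "count_best_first": wins["sum"].astype(int),
            "n_targets": wins["size"].astype(int),
        }
    )
    out["ratio"] = out["count_best_first"] / out["n_targets"]
    return out
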