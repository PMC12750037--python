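"""Secondary assessment analyses.

Evaluation-unit difficulty classification from the 95% quantile of GDT_TS,
interface vs non-interface accuracy, the Grishin-plot merge check for
deciding whether two EUs of one target should be scored together, model-6
ratio statistics, cross-phase score deltas, and comparison of submitted
models against a large sampled model pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structio import Structure

__all__ = [
    "DifficultyClassification",
    "InterfaceSplit",
    "eu_difficulty",
    "interface_residues",
    "interface_split",
    "grishin_merge_check",
    "model6_ratio",
    "cross_phase_delta",
    "best_of_pool",
]


@dataclass
class DifficultyClassification:
    table: pd.DataFrame  # index eu; columns gdt_ts95, size, label

    def labels(self) -> dict:
        return self.table["label"].to_dict()


@dataclass
class InterfaceSplit:
    interface: set
    interface_mean: float
    non_interface_mean: float
    models_used: int


def eu_difficulty(
    df: pd.DataFrame,
    sizes: dict,
    line: tuple[float, float],
    metric: str = "GDT_TS",
) -> DifficultyClassification:
    """Classify EUs as easy/difficult from the 95% quantile of GDT_TS.

    GDT_TS95 is the 95th percentile (linear interpolation) of the metric over
    all models of the EU; an EU is ``difficult`` iff GDT_TS95 falls below the
    partition line ``slope × size + intercept``.
    """
    slope, intercept = line
    sub = df[df["metric"] == metric].dropna(subset=["value"])
    rows = []
    for eu, esub in sub.groupby("eu", sort=False):
        if eu not in sizes:
            raise ValueError(f"no residue count for EU {eu}")
        vals = esub["value"].to_numpy(dtype=float)
        if len(vals) < 5:
            warnings.warn(f"EU {eu}: fewer than 5 models for the 95% quantile")
        q95 = float(np.percentile(vals, 95))  # linear interpolation convention
        size = sizes[eu]
        label = "difficult" if q95 < slope * size + intercept else "easy"
        rows.append((eu, q95, size, label))
    if not rows:
        raise ValueError(f"no values for metric {metric!r}")
    table = pd.DataFrame(rows, columns=["eu", "gdt_ts95", "size", "label"]).set_index("eu")
    return DifficultyClassification(table)


def interface_residues(assembly: Structure, partition: dict, cutoff: float = 5.0) -> set:
    """Residues with any heavy atom within ``cutoff`` Å of a different unit.

    ``partition`` maps residue key → unit id (chain or EU); at least two
    units are required.  Symmetric in units by construction.
    """
    units = set(partition.values())
    if len(units) < 2:
        raise ValueError("interface detection needs at least 2 units")
    keys, xyz, unit_of = [], [], []
    for r in assembly.residues:
        u = partition.get(r.key)
        if u is None:
            continue
        for a in r.atoms:
            keys.append(r.key)
            xyz.append(a.coord)
            unit_of.append(u)
    xyz = np.array(xyz)
    unit_of = np.array(unit_of, dtype=object)
    d2 = ((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(-1)
    cross = unit_of[:, None] != unit_of[None, :]
    close = (d2 <= cutoff**2) & cross
    iface = {keys[i] for i in np.flatnonzero(close.any(axis=1))}
    return iface


def interface_split(
    per_model_scores: list[tuple[float, dict]],
    iface: set,
    gate: float = 80.0,
) -> InterfaceSplit:
    """Mean per-residue score over interface vs non-interface residues.

    ``per_model_scores`` holds ``(model GDT_TS, per-residue scores)`` tuples;
    only models with GDT_TS strictly above ``gate`` are pooled.
    """
    pooled_iface, pooled_other = [], []
    used = 0
    for gdt_ts, per_res in per_model_scores:
        if gdt_ts <= gate:
            continue
        used += 1
        for key, score in per_res.items():
            (pooled_iface if key in iface else pooled_other).append(score)
    if used == 0:
        raise ValueError(f"no models with GDT_TS above {gate}")
    imean = float(np.mean(pooled_iface)) if pooled_iface else float("nan")
    omean = float(np.mean(pooled_other)) if pooled_other else float("nan")
    return InterfaceSplit(iface, imean, omean, used)


def grishin_merge_check(
    scores_d1: dict,
    scores_d2: dict,
    scores_merged: dict,
    tolerance: float = 5.0,
):
    """Decide whether two EUs should be scored merged or split.

    For each model the per-part accuracy is min(GDT_TS on part 1, part 2);
    the degradation statistic is the median over models of that minimum minus
    the merged-unit GDT_TS.  Merge iff degradation ≤ tolerance (boundary
    merges).  Returns ``(decision, summary)`` where summary carries the
    Grishin-plot data: per-model (min of parts, merged).
    """
    if set(scores_d1) != set(scores_d2) or set(scores_d1) != set(scores_merged):
        raise ValueError("model sets differ between the three score lists")
    if not scores_d1:
        raise ValueError("empty score lists")
    points = [
        (min(scores_d1[m], scores_d2[m]), scores_merged[m]) for m in sorted(scores_d1)
    ]
    degradation = float(np.median([p - m for p, m in points]))
    decision = "merge" if degradation <= tolerance else "keep_split"
    return decision, {"degradation": degradation, "points": points}


def model6_ratio(
    df: pd.DataFrame,
    baseline: str = "own_model1",
    metric: str = "GDT_HA",
    baseline_group: str | None = None,
) -> pd.DataFrame:
    """Mean per-target ratio of model-6 score to a model-1 baseline score.

    ``own_model1`` compares each group's model 6 with its own model 1;
    ``external_model1`` with model 1 of ``baseline_group``.  Targets with a
    zero baseline are skipped with a warning.
    """
    if baseline not in ("own_model1", "external_model1"):
        raise ValueError(f"unknown baseline {baseline!r}")
    if baseline == "external_model1" and baseline_group is None:
        raise ValueError("external baseline requires baseline_group")
    sub = df[df["metric"] == metric].dropna(subset=["value"])
    rows = []
    for group, gsub in sub.groupby("group", sort=False):
        if group == baseline_group:
            continue
        m6 = gsub[gsub["model"] == 6].set_index("eu")["value"]
        if baseline == "own_model1":
            m1 = gsub[gsub["model"] == 1].set_index("eu")["value"]
        else:
            bsub = sub[(sub["group"] == baseline_group) & (sub["model"] == 1)]
            m1 = bsub.set_index("eu")["value"]
        common = m6.index.intersection(m1.index)
        ratios = []
        for eu in common:
            if m1.loc[eu] == 0:
                warnings.warn(f"group {group}, EU {eu}: zero baseline; skipped")
                continue
            ratios.append(m6.loc[eu] / m1.loc[eu])
        if ratios:
            rows.append((group, float(np.mean(ratios)), len(ratios)))
    if not rows:
        raise ValueError("no group has targets with both members of the pair")
    return pd.DataFrame(rows, columns=["group", "mean_ratio", "n"]).set_index("group")


def cross_phase_delta(
    t_prev: pd.DataFrame,
    t_next: pd.DataFrame,
    model_mode: str = "first",
    metric: str = "GDT_HA",
) -> pd.DataFrame:
    """Per-group mean score change between two phases on shared targets.

    The model of each phase is chosen by ``model_mode`` (``first`` = lowest
    model index, ``best`` = highest metric value); delta = next − previous,
    averaged over targets the group has in both phases.
    """
    def pick(df):
        sub = df[df["metric"] == metric].dropna(subset=["value"])
        out = {}
        for (group, eu), esub in sub.groupby(["group", "eu"], sort=False):
            vals = esub.set_index("model")["value"]
            if model_mode == "first":
                out[(group, eu)] = vals.loc[min(vals.index)]
            elif model_mode == "best":
                out[(group, eu)] = vals.max()
            else:
                raise ValueError(f"unknown model mode {model_mode!r}")
        return out

    prev, nxt = pick(t_prev), pick(t_next)
    rows = []
    for group in sorted({g for g, _ in nxt}):
        deltas = [
            nxt[(group, eu)] - prev[(group, eu)]
            for g, eu in nxt
            if g == group and (group, eu) in prev
        ]
        if not deltas:
            warnings.warn(f"group {group}: no shared targets; omitted")
            continue
        rows.append((group, float(np.mean(deltas)), len(deltas)))
    if not rows:
        raise ValueError("no shared targets between the two phases")
    return pd.DataFrame(rows, columns=["group", "mean_delta", "n"]).set_index("group")


def best_of_pool(pool_scores: dict, submitted: dict) -> pd.DataFrame:
    """Compare the best of a large model pool against submitted-model scores.

    ``pool_scores`` maps target → list of pool scores; ``submitted`` maps
    target → {set name → best value} (e.g. best model, first model, named
    baselines).  Targets with an empty pool are excluded with a warning.
    Output rows are ordered by descending best submitted value.
    """
    rows = []
    for tgt, pool in pool_scores.items():
        if not pool:
            warnings.warn(f"target {tgt}: empty pool; excluded")
            continue
        sub = submitted.get(tgt, {})
        row = {"target": tgt, "pool_max": float(max(pool))}
        row.update({k: float(v) for k, v in sub.items()})
        row["_order"] = max(sub.values()) if sub else float("-inf")
        rows.append(row)
    if not rows:
        raise ValueError("no targets with a non-empty pool")
    out = pd.DataFrame(rows).sort_values("_order", ascending=False).drop(columns="_order")
    return out.set_index("target")
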