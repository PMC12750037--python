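"""End-to-end assessment: score model/target pairs, rank, run statistics.

File conventions: targets live as ``<targets_dir>/<structure_id>.pdb`` (one
file per conformational version; the EU definition's ``versions`` list names
them), models as ``<models_dir>/<target_id>/<group>_<model>.pdb``.  EU
definitions are a JSON list of objects with ``target_id``, ``eu_id``,
``ranges`` ([chain, start, end] inclusive), ``weight`` and optional
``versions``.  Externally computed metrics (MolProbity, CAD_AA, SphGr,
reLLG_const) are merged from a score TSV keyed by (group, eu, model); when
no external table is supplied the weight scheme renormalizes over the
internally computed metrics so the pipeline runs on purely synthetic data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import compute_metrics
from .ranking import (
    RANKING_METRICS,
    SCORE_COLUMNS,
    WeightScheme,
    aggregate_ranking,
    impute_unscored,
    select_models,
    two_round_z,
    write_score_table,
)
from .stats import head_to_head_matrix
from .structio import EUDefinition, extract_eu, map_residues, parse_structure

log = logging.getLogger("casp_assess")

EXTERNAL_METRICS = ("MolProbity", "CAD_AA", "SphGr", "reLLG_const")

__all__ = ["RunConfig", "run_assessment", "score_models", "load_eu_definitions", "composite_z_by_eu"]


@dataclass
class RunConfig:
    targets_dir: Path
    models_dir: Path
    eu_file: Path
    out_dir: Path
    external_table: Path | None = None
    weights_file: Path | None = None
    floor: float = -2.0
    n_boot: int = 1000
    seed: int = 0
    mode: str = "best"
    h2h_top_fraction: float = 0.25
    strict_metrics: bool = False  # require the full nine-metric scheme

    def __post_init__(self):
        for name in ("targets_dir", "models_dir", "eu_file"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p}")
        self.out_dir = Path(self.out_dir)
        if self.external_table is not None:
            self.external_table = Path(self.external_table)


def load_eu_definitions(path) -> list[EUDefinition]:
    data = json.loads(Path(path).read_text())
    out = []
    for rec in data:
        out.append(
            EUDefinition(
                target_id=rec["target_id"],
                eu_id=rec["eu_id"],
                ranges=[tuple(r) for r in rec["ranges"]],
                weight=rec.get("weight", 1.0),
                versions=rec.get("versions", [rec["target_id"]]),
            )
        )
    return out


def load_weight_scheme(path) -> WeightScheme:
    """Weight scheme config: one ``metric<TAB>weight<TAB>orientation`` line per metric."""
    weights, orientation = {}, {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        metric, w, orient = line.split("\t")
        weights[metric] = float(w)
        orientation[metric] = orient
    return WeightScheme(weights=weights, orientation=orientation)


def score_models(
    targets: dict,
    models: dict,
    eus: list[EUDefinition],
    phase: int = 1,
) -> pd.DataFrame:
    """Score every model against every EU, maximizing over target versions.

    ``targets`` maps structure id → Structure (all conformational versions);
    ``models`` maps (target_id, group, model_index) → Structure.  Metrics of
    multi-version EUs are evaluated against every version and the highest
    score from any version is used.
    """
    records = []
    for eu in eus:
        versions = eu.versions or [eu.target_id]
        version_eus = []
        for vid in versions:
            if vid not in targets:
                raise ValueError(f"EU {eu.eu_id}: version structure {vid!r} not loaded")
            version_eus.append(extract_eu(targets[vid], eu))
        for (target_id, group, model_idx), model in models.items():
            if target_id != eu.target_id:
                continue
            best: dict = {}
            for veu in version_eus:
                try:
                    meu = extract_eu(model, eu)
                    corr = map_residues(veu, meu)
                except ValueError as exc:
                    log.warning("skipping %s/%s model %s on %s: %s",
                                group, target_id, model_idx, eu.eu_id, exc)
                    continue
                vals = compute_metrics(veu, meu, corr)
                for metric, value in vals.items():
                    if metric.startswith("_") or not np.isfinite(value):
                        continue
                    if metric not in best or value > best[metric]:
                        best[metric] = value
            for metric, value in best.items():
                records.append(
                    (group, eu.target_id, eu.eu_id, phase, model_idx, metric, value)
                )
    if not records:
        raise ValueError("no models scored")
    return pd.DataFrame(records, columns=SCORE_COLUMNS)


def composite_z_by_eu(
    df: pd.DataFrame,
    eus: list[EUDefinition],
    scheme: WeightScheme,
    mode: str = "best",
    floor: float = -2.0,
) -> dict:
    """Per-group Series of composite z per EU (input to head-to-head bootstrap)."""
    df = impute_unscored(df, scheme)
    sel = select_models(df, mode=mode, scheme=scheme, floor=floor)
    groups = sorted(df["group"].unique())
    comp: dict = {g: {} for g in groups}
    for eu_id, sub in sel.groupby("eu", sort=False):
        wide = sub.pivot_table(index="group", columns="metric", values="value", aggfunc="first")
        local = scheme.restrict([m for m in scheme.metrics if m in wide.columns])
        ztotal = pd.Series(0.0, index=groups)
        for metric in local.metrics:
            zres = two_round_z(
                wide[metric].dropna(), local.orientation[metric],
                all_keys=groups, floor=floor,
            )
            ztotal += local.weights[metric] * zres.z
        submitted = set(wide.index)
        for g in groups:
            if g in submitted:
                comp[g][eu_id] = float(ztotal[g])
    return {g: pd.Series(v) for g, v in comp.items() if v}


def _load_structures(cfg: RunConfig):
    targets = {}
    for path in sorted(Path(cfg.targets_dir).glob("*.pdb")):
        targets[path.stem] = parse_structure(path.read_text(), "pdb", structure_id=path.stem)
    if not targets:
        raise ValueError(f"no target PDB files in {cfg.targets_dir}")
    models = {}
    for tdir in sorted(Path(cfg.models_dir).iterdir()):
        if not tdir.is_dir():
            continue
        for path in sorted(tdir.glob("*.pdb")):
            group, model_idx = path.stem.rsplit("_", 1)
            models[(tdir.name, group, int(model_idx))] = parse_structure(
                path.read_text(), "pdb", structure_id=path.stem
            )
    if not models:
        raise ValueError(f"no model PDB files in {cfg.models_dir}")
    return targets, models


def run_assessment(cfg: RunConfig) -> dict:
    """Run the full assessment and write the output bundle.

    Produces ``scores.tsv``, ``ranking_best.tsv``, ``ranking_first.tsv``,
    ``h2h.tsv`` and ``manifest.json`` in ``cfg.out_dir``.  Deterministic
    under a fixed seed and inputs.
    """
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    eus = load_eu_definitions(cfg.eu_file)
    targets, models = _load_structures(cfg)
    df = score_models(targets, models, eus)

    if cfg.external_table is not None:
        ext = pd.read_csv(cfg.external_table, sep="\t")
        known = set(zip(df["group"], df["eu"], df["model"]))
        bad = [
            k for k in set(zip(ext["group"], ext["eu"], ext["model"]))
            if k not in known
        ]
        if bad:
            warnings.warn(f"{len(bad)} external records match no scored model")
        df = pd.concat([df, ext], ignore_index=True)

    scheme = (
        load_weight_scheme(cfg.weights_file)
        if cfg.weights_file is not None
        else WeightScheme.default()
    )
    present = set(df["metric"].unique())
    missing = [m for m in scheme.metrics if m not in present]
    if missing:
        if cfg.strict_metrics:
            raise ValueError(f"strict mode: metrics missing from the table: {missing}")
        warnings.warn(
            f"metrics {missing} unavailable; weight scheme renormalized over the rest"
        )
        scheme = scheme.restrict(present)

    write_score_table(df, cfg.out_dir / "scores.tsv")
    rankings = {}
    for mode in ("best", "first"):
        r = aggregate_ranking(df, eus, scheme, mode=mode, floor=cfg.floor)
        r.to_csv(cfg.out_dir / f"ranking_{mode}.tsv", sep="\t")
        rankings[mode] = r

    main = rankings[cfg.mode]
    n_top = max(2, int(np.ceil(len(main) * cfg.h2h_top_fraction)))
    top_groups = list(main.index[:n_top])
    zmap = composite_z_by_eu(df, eus, scheme, mode=cfg.mode, floor=cfg.floor)
    weights = pd.Series({eu.eu_id: eu.weight for eu in eus})
    h2h = head_to_head_matrix(
        {g: zmap[g] for g in top_groups if g in zmap},
        weights=weights, n_boot=cfg.n_boot, seed=cfg.seed,
    )
    pd.DataFrame(h2h.win_fraction, index=h2h.groups, columns=h2h.groups).to_csv(
        cfg.out_dir / "h2h.tsv", sep="\t"
    )

    cfg_text = json.dumps(
        {k: str(v) for k, v in vars(cfg).items()}, sort_keys=True
    )
    manifest = {
        "seed": cfg.seed,
        "n_eus": len(eus),
        "n_models": len(models),
        "groups": sorted(df["group"].unique()),
        "metrics": sorted(present),
        "weights": scheme.weights,
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest(),
    }
    (cfg.out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"scores": df, "rankings": rankings, "h2h": h2h, "manifest": manifest}
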