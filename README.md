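# casp-assess

Assessment machinery for blind protein structure prediction experiments, in
the style of the CASP monomer evaluation: given experimental target
structures, predicted models (with per-residue confidence in the B-factor
column), and evaluation-unit (EU) definitions, the package scores every
model, ranks predictor groups with a composite weighted z-score, quantifies
the significance of ranking differences by bootstrap, and compares
experiments of different years on difficulty-matched target sets.

It is written for structure-prediction assessors and method developers who
need a transparent, reproducible, fully tested reimplementation of the
assessment pipeline that runs end-to-end on synthetic data — no archive
downloads required.

## What it computes

**Structure-comparison metrics** (`casp_assess.metrics`), all on a 0–100
scale:

- **GDT_TS / GDT_HA** — percentage of Cα atoms fittable under one rigid
  superposition within cutoffs {1, 2, 4, 8} / {0.5, 1, 2, 4} Å, averaged.
  The superposition search is exact (subset enumeration) for ≤ 12 residues
  and a windowed seed-and-extend heuristic beyond that.
- **GDC (sc / mc / all)** — threshold-weighted distance score
  `100 · Σ_{k=1..10} (11−k) P_k / 55` over characteristic sidechain atoms,
  backbone atoms, or all heavy atoms, under the GDT_TS-optimal frame.
- **AL0_P** — percentage of residues whose model Cα is both within 3.8 Å of
  and nearest to its target counterpart under that frame.
- **lDDT** — superposition-free fraction of preserved local interatomic
  distances (15 Å inclusion radius, thresholds {0.5, 1, 2, 4} Å).
- **ASE/QSE** — self-assessment agreement, `100 − mean |pLDDT − lDDT|`.
- **AAA** — sidechain accuracy: fraction of χ-angles within 40° of the
  target (terminal 2-fold symmetric groups compared modulo 180°).

**Ranking** (`casp_assess.ranking`) — the composite score

```
Z_total = Σ_target Σ_EU w_EU [ 1/6 (z_GDT_HA + z_QSE + z_reLLG) +
                               1/8 (z_SphGr + z_CAD_AA) +
                               1/16 (z_GDC_SC + z_AL0_P + z_lDDT + z_MolProbity) ]
```

with `w_EU = 1/N` for a target split into N EUs.  z-scores are computed per
EU and metric in two rounds: outliers below −2 are excluded from the second
round's mean/sd, final values are floored at −2, and missing submissions
score −2.  MolProbity (lower is better) is negated before standardization.
MolProbity, CAD_AA, SphGr and reLLG_const are consumed from external score
tables; when absent, weights renormalize over the internally computed
metrics.

**Statistics** (`casp_assess.stats`) — bootstrap head-to-head win-fraction
matrices with tie-splitting, Hungarian difficulty matching, Gaussian-KDE
weighted resampling, and paired progress tests.

**Synthetic data** (`casp_assess.synthetic`) — toy targets built from ideal
internal coordinates, decoys with graded coordinate/χ/pLDDT noise, and score
tables drawn from a latent group-skill × target-difficulty model.

## Worked example

Simulate a small experiment (8 groups, 12 single-EU targets, 10% missing
submissions) and rank the groups on best models:

```python
import casp_assess as ca

df = ca.simulate_experiment(ca.LatentExperiment(n_groups=8, n_targets=12), seed=42)
eus = [ca.EUDefinition(target_id=t, eu_id=f"{t}-D1", ranges=[("A", 1, 30)], weight=1.0)
       for t in sorted(df["target"].unique())]
ranking = ca.aggregate_ranking(df, eus, mode="best")
print(ranking[["total_z", "n_submitted"]].round(3))
```

```
     total_z  n_submitted
g04    9.366           11
g03    9.079           11
g07    1.036           10
g01    0.573           10
g08   -2.813           11
g02  -11.253           10
g06  -12.467           10
g05  -16.854           12
```

`total_z` is the EU-weighted sum of composite z-scores; `n_submitted` counts
EUs with any submission (missing ones score −2 on every metric, which is why
g05, despite submitting everywhere, ranks below groups that skipped an EU
but predicted well elsewhere).  The recovered order matches the simulation's
latent skill order (groups 4 and 3 on top).

The same pipeline runs from the shell on PDB inputs:

```
casp-assess synth target --seed 1 --out demo/T1.pdb
casp-assess score --target demo/T1.pdb --model demo/model.pdb --out scores.tsv
casp-assess rank --scores scores.tsv --eus eus.json --mode best
```

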