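# Methods

This note documents the models, conventions and numerical choices behind
`casp-assess`, and what the synthetic-data experiments do and do not show.

## Scope and data model

The package evaluates monomeric protein models against experimental targets
at the level of *evaluation units* (EUs): one domain or a group of domains
scored as a unit.  Each EU carries weight `1/N` among the N EUs of its
target so every target counts equally in aggregate scores.  Targets with
several deposited conformations list them as *versions*; every metric is
evaluated against each version and the highest score is kept, so a model is
never penalized for matching a legitimate alternative conformation.

Structures are parsed from PDB or mmCIF (via gemmi) into light containers
holding author numbering, named heavy atoms, coordinates in Å, occupancy and
the B-factor column, which carries the predictor's per-residue confidence
(pLDDT, 0–100) in submitted models.  Alternate locations resolve to the
highest-occupancy copy (ties to first in file); hydrogens are dropped;
non-water HETATM groups are kept as ligands; nonstandard residues (MSE, SEP,
…) map to their parent standard residue for metric purposes.  Model/target
residue correspondence uses author-numbering equality — the submission
convention for blind prediction experiments — with residue-name mismatches
reported rather than silently accepted; no sequence-alignment fallback is
attempted for renumbered models.

## Superposition metrics

All rigid fits use the Kabsch SVD solution with reflections forbidden
(determinant of the rotation forced to +1).  Collinear point sets are
rejected.

**GDT search.**  The global distance test asks, per cutoff, for the largest
set of paired Cα atoms simultaneously fittable under one rigid
superposition.  Finding the true optimum is combinatorial, so the search is
organized in two regimes:

- *n ≤ 12*: exact subset enumeration — every residue subset of size ≥ 3 is
  least-squares fitted and the atoms within each cutoff under that fit are
  counted.  This is the same computation as the validation oracle, so the
  search is provably optimal (within the subset-fit family) exactly where
  optimality can be checked.
- *n > 12*: windowed seed-and-extend — every contiguous window of length 3,
  5, 7 and the full chain seeds a fit; each fit is iteratively recomputed on
  the residues currently within the cutoff (also with a +1 Å refit margin,
  which rescues borderline sets), capped at 10 iterations.

The windowed path is validated statistically rather than by exact equality:
it never exceeds the oracle (every candidate fit is a subset fit) and on
noisy 8-residue instances trails it by < 5 GDT points on average.  Exact
equality of a genuinely windowed search with an all-subsets oracle is not
achievable: the oracle's optimum is frequently witnessed by a fit on a
scattered subset that is not the refit-closure of any contiguous seed.  The
two-regime design acknowledges this instead of pretending the windowed
search is exact.

The superposition reported (and reused as the fixed frame for GDC and
AL0_P) is the candidate with the largest within-cutoff count summed over
cutoffs, ties to lower RMSD.

**GDC.**  `100 · Σ_{k=1..10} (11−k) · P_k / 55`, where `P_k` is the
fraction of selected target atoms whose model counterpart lies within
`0.5·k` Å under the fixed frame.  Selector `sc` uses one characteristic
distal atom per residue type (Ser OG, Leu CD1, Phe CZ, … — shipped as a
table in `metrics.py`; Gly has none), `mc` uses N/CA/C/O, `all` every heavy
atom.  Atoms missing from the model count as failures at every threshold —
the denominator is always the target's atoms, so incomplete models are
penalized consistently.

**AL0_P.**  A residue is correctly aligned iff its superposed model Cα lies
within 3.8 Å of the target Cα *and* that target Cα is the nearest target Cα
to the model atom.  The 3.8 Å radius (one Cα–Cα step) and the
nearest-neighbor condition are conventions fixed here and pinned by tests.

## lDDT and self-assessment

lDDT uses the standard published parameters: reference set = all heavy-atom
pairs from *different* target residues closer than 15 Å; thresholds
{0.5, 1, 2, 4} Å; no stereochemistry checks.  Per-residue lDDT is the mean
over thresholds of the preserved fraction among pairs involving the residue
(scaled to 0–100); the global score is the mean of per-residue values, so
both scales match the pLDDT convention.  Pairs with either atom absent from
the model are scored unpreserved.

ASE (the self-assessment agreement, reported as QSE in score tables) is
`100 − mean_i |pLDDT_i − lDDT_i|`, clamped to [0, 100], with pLDDT read
from the Cα B-factor.  The linear absolute-difference form is a
documented design choice; models carrying no self-estimate (all-zero
B-factors) are an error rather than a silent 100.

## Sidechain accuracy (AAA)

Per residue: `100 × (# χ within 40° of target) / (# χ defined in target)`,
averaged without weighting over residues having at least one target χ.
Differences are circular; dihedrals of 2-fold symmetric terminal groups are
compared modulo 180°.  The symmetric set used is the chemically correct
one — Asp χ2, Glu χ3, Phe χ2, Tyr χ2, Arg χ5 — i.e. the dihedral that flips
the terminal O/N pair, not a fixed χ index.  Missing model sidechain atoms
truncate the model's χ list and the missing angles count as failures.

## Ranking

Per EU and metric, group scores become z-scores in two rounds: round 1 uses
the population mean/sd of all values; members with z < −2 are excluded;
round 2 recomputes mean/sd from the remainder and assigns z to *all*
members from those parameters; final z is floored at −2, and groups with no
submission score −2.  Conventions fixed here (the protocol's edge cases are
otherwise underdetermined): population (not sample) sd; sd = 0 gives z = 0
for members at the mean; round-2 parameters are applied to round-1 outliers
before flooring.  The alternative floor-at-0 strategy is available as a
configuration (`floor=0.0`).

The composite score weights z_GDT_HA, z_QSE, z_reLLG_const at 1/6,
z_SphGr, z_CAD_AA at 1/8, and z_GDC_SC, z_AL0_P, z_lDDT, z_MolProbity at
1/16 (weights sum to 1).  MolProbity is negated before standardization so
lower raw scores yield higher z.  Models lacking individual metric values
are first imputed with the worst observed value for that EU/metric
(orientation-aware); wholly missing submissions are handled at the z level,
not imputed.

Model selection: *first* = model index 1, else the lowest index present;
*best* = the model maximizing the composite z within the EU's model pool
(z computed across all submitted models of the EU), ties to the lowest
index; *model6* = the optional sixth model only.  For the best-model
ranking, per-group z-scores are then recomputed across the selected models.

## Bootstrap and progress statistics

Head-to-head comparison of two groups resamples their common EUs with
replacement (default 1000 replicates), sums EU-weighted composite z per
replicate, and counts wins; ties add 0.5, which makes self-comparison
exactly 0.5 and the matrix antisymmetric.  Significance at level α means a
win fraction ≥ 1 − α; groups are displayed in row-sum order.

Cross-experiment comparison controls for target difficulty, proxied by a
baseline predictor's first-model GDT_HA.  Two mechanisms:

- *Hungarian matching*: minimum-cost one-to-one assignment of the reference
  EU set into the source set under |Δdifficulty| cost
  (`scipy.optimize.linear_sum_assignment`); validated against brute-force
  permutation enumeration at small sizes.
- *KDE-weighted bootstrap*: Gaussian KDEs (Scott's bandwidth by default) of
  the two difficulty distributions give per-record weights
  ∝ f_ref(d)/f_src(d) (densities floored at 1e-12), under which source
  records are resampled; sample size defaults to the reference set size.

The paired progress test on matched best scores defaults to the paired
t-statistic with an epsilon guard on zero-variance differences (all-zero
differences give p = 1; a constant nonzero shift gives p ≈ 0); a Wilcoxon
signed-rank option is provided since the appropriate test is a matter of
taste.

## Synthetic data

`build_target` constructs toy proteins by natural-extension internal
coordinates: ideal bond lengths/angles, ω = 180°, segment-typed φ/ψ
(helix −57/−47, strand −120/+120, coil sampled uniformly in allowed
ranges), and sidechains from template rotamers for a curated palette
(Ser, Leu, Phe, Arg, Ala, Gly — enough to exercise every χ count, both
symmetry classes, and the Gly/Ala edge cases; full rotamer libraries would
add realism the metrics do not need).  `make_decoy` degrades a target by
rotating sidechains about their χ bonds (Gaussian, sd `sigma_chi`), adding
i.i.d. Gaussian coordinate noise (`sigma_xyz`), optionally rigidly rotating
a residue segment (domain-orientation error), and writing
pLDDT = clamp(realized per-residue lDDT + N(0, `plddt_tau`), 0, 100) into
the B-factors — so `plddt_tau = 0` yields a perfectly calibrated
self-estimate (ASE = 100) by construction.

`simulate_experiment` draws score tables from a latent model:
`value = clip(base + skill_g − difficulty_t + model noise + metric noise)`,
with MolProbity emitted on its inverted scale and whole (group, EU)
submissions dropped with probability `p_missing`.  Defaults (20 groups, 30
EUs, skill sd 10 = twice the noise sd, 10% missingness, base 70) define the
study conditions under which the ranking provably recovers latent skill
(Spearman ≥ 0.9).

What the synthetic data does *not* emulate: physically realistic error
correlations along the chain, rotamer-library sidechain distributions,
alignment/register errors beyond the rigid segment swap, and any
sequence-dependent difficulty structure.  Passing tests therefore
demonstrate the correctness and calibration of the assessment machinery,
not predictor behavior on real proteomes.

## Validation harness choices

- **Problem sizes.**  Synthetic targets are 30 residues (8 for GDT oracle
  instances, where exhaustive enumeration is the comparison); identity and
  monotonicity suites use 50 targets and 20 replicates per noise level.
  These sizes give stable statistics while keeping the whole suite fast.
- **Noise grid.**  The graded grid {0, 0.5, 1, 2, 4, 8} drives `sigma_xyz`
  (Å) for GDT_TS and lDDT.  For AAA the same grid drives the χ-noise axis
  (30° per grid unit, backbone fixed): under heavy *coordinate* noise the
  χ measurement saturates at its random-agreement floor (~22%), so no
  Å-driven grid can show strict decrease at the top end, while the χ axis
  keeps expected signal at both ends of the 16× range.
- **Degenerate inputs.**  sd = 0 in z-scores → z = 0 at the mean; empty
  metric columns are dropped with a warning rather than imputed;
  assignment ties break to the lower index; zero model-6 baselines skip the
  target with a warning.  All are pinned by tests.

## Known limitations

- The GDT heuristic above 12 residues is a bounded-effort search; like all
  practical implementations of this metric it can underestimate the true
  optimum on adversarial inputs (quantified above).
- reLLG_const, SphGr, CAD_AA and MolProbity are consumed, not computed;
  without an external table the composite scheme renormalizes, which
  changes the absolute scale of total z (rankings on synthetic data are
  unaffected in the dominance cases tested).
- AL0_P's exact historical convention varies between assessments; the
  3.8 Å/nearest-neighbor rule here is fixed and documented rather than
  claimed canonical.
- The per-pair bootstrap seeds in the head-to-head matrix are derived from
  the base seed by enumeration; comparing matrices across group subsets
  therefore requires the same group ordering.
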