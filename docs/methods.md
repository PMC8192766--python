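# Methods

## Model and assumptions

The pipeline rests on one biological premise: in a homomultimer, the
monomer's multiple sequence alignment carries co-evolutionary signal for
intrachain and interchain residue pairs alike, so a monomeric contact
predictor emits a single upper-triangle map in which both signals are
superimposed. Given the monomer's tertiary structure, the intrachain
component is known exactly and can be subtracted; the remainder is treated
as interchain signal. The approach assumes (i) the monomer structure is
available and essentially rigid across the assembly, and (ii) interchain
contacts are not systematically hidden under intrachain ones — pairs that
are both intrachain contacts and interface contacts are unavoidably lost in
the subtraction, as are near-diagonal interface pairs (sequence separation
< 6), which the short-range filter removes before any other step.

## Definitions and parameters

| parameter | default | meaning |
|---|---|---|
| intra cutoff | 8.0 Å | Cβ–Cβ (Cα fallback) distance for intrachain contacts |
| inter cutoff | 6.0 Å | minimum heavy-atom distance for interchain contacts |
| min separation | 6 | short-range filter: keep pairs with j − i ≥ 6 |
| n_removal | 0–2 | half-width of the subtraction window |
| n_eval | 0–2 | half-width of the evaluation (matching) window |
| Top-k grid | 5, 10, L/10, L/5, L/2, L, 2L | ⌊·⌋, clamped to ≥ 1 |
| chain similarity | 0.95 | homogenization gate (identity = matches / aligned columns) |
| dedup identity | 0.30 | greedy redundancy threshold |

All distance boundaries are inclusive (≤). The Cα fallback applies to any
residue missing a Cβ, not only glycine. Interchain maps are stored
asymmetrically: (i, j) means residue i of chain A contacts residue j of the
partner; evaluation consults both (i, j) and (j, i). The windows are
(2n+1)×(2n+1) — the half-width definition [i−n, i+n] × [j−n, j+n] is taken
as authoritative — and indices are clipped to 1..L. Subtraction also wipes
the mirror window around (j, i); for canonical upper-triangle predictions
this is provably subsumed by the direct window (a test asserts the
near-diagonal case), so it acts purely as a guard for non-canonical input.
Precision uses the resolved k as denominator even when fewer predictions
survive, the fixed-k convention of contact assessment; a single true
contact may validate several predictions (no consumption of truth entries).
Whether the filter runs before or after subtraction is immaterial to the
surviving set, but filter-first is implemented and documented as the
pipeline order.

Homogenization aligns the two sequences globally (match 1, mismatch 0,
linear gap −1 — a deliberately plain, reproducible scheme), computes
identity over aligned columns, rejects pairs below 95 %, and deletes
mismatched or gapped columns from *both* chains so the retained sequences
are identical. Identity over columns (not over the shorter sequence) was an
open choice; columns penalize terminal overhangs, which is the conservative
direction for calling two chains "the same protein". Non-standard residues
become 'X' and never count as matches. Validity of a chain means "parses
with ≥ 1 atom per residue"; no secondary-structure gate is applied.
Redundancy removal is a greedy scan in input order dropping any record
above 30 % identity to a kept one.

## Random baseline

The baseline draws pairs uniformly without replacement from the same
support the predictor emits (upper triangle, separation ≥ 6) with uniform
scores, and runs through the identical downstream pipeline. The analytic
single-draw expectation — the fraction of eligible pairs that relax-match
the truth — follows from exchangeability of a uniform sample and anchors a
calibration test (empirical mean over 10 000 seeded draws within 3 standard
errors).

## Reconstruction

The monomer is rigid; only the second copy's rotation and translation are
searched (6 DOF). Energy: Σ max(0, d_ij − d_c)² over restraints, where d_ij
is the pair's minimum heavy-atom distance and each pair contributes the
lighter of its (i, j)/(j, i) orientations (an upper-triangle prediction
does not say which copy holds i), plus clash_weight · Σ max(0, 2.5 Å − d)²
over atom pairs. The search is Metropolis annealing with a geometric
schedule (T: 60 → 0.05, cooling 0.82, 50 steps per temperature, move sizes
proportional to T/T₀, floored at 5 %), 6 randomized restarts (uniform
random orientation, centroid placed 1.2–2.2 monomer radii away in a random
direction), followed by a Powell polish of the best pose. Defaults were
chosen so that recovery of a synthetic dimer from its complete true
interchain restraints runs in a few seconds per seed. The energy is zero on
a *set* of poses (flat bottoms), so recovered models scatter within ~2 Å
RMSD of the native even when every restraint is satisfied; with sparse
restraints the placement is legitimately underdetermined. RMSD is computed
over all Cα of the complex after least-squares (Kabsch) superposition,
taking the minimum over the two chain pairings, since copies are
interchangeable.

## Synthetic data: what it emulates, and what it does not

The generator produces an L=48 (default) monomer — an ideal α-helix Cα
trace (rise 1.5 Å, turn 100°, radius 2.3 Å) or a 3.8 Å-step self-avoiding
walk — decorated with a pseudo-Cβ 1.5 Å along the outward local normal and
1–3 pseudo side-chain heavy atoms; glycines carry only Cα, exercising the
fallback. The default dimer flips the copy end-over-end and slides it along
x until the closest heavy-atom approach first reaches 3.0 Å, giving an
antiparallel, coiled-coil-like interface whose contacts pair residue i with
residues near L+1−i: sequence-distant pairs that survive the short-range
filter, as real interface contacts typically do (a pure-translation
parallel packing of a helix would put all interface pairs at small |i−j|
and the filter would erase them — that geometry is exercised in tests, not
used as the default). Typical fixtures have ~18 interchain contacts,
density ≈ 0.3–0.4 contacts/residue, matching the sparse regime real
homodimers mostly occupy. Higher-order assemblies apply powers of the
transform (an alternating fibril-like row); the max-contact partner rule
then selects chain B.

The fabricated "prediction" keeps each true intrachain entry with
probability 0.85 and each folded interchain entry with probability 0.70,
injects false positives on 10 % of the non-contact upper-triangle pairs,
and scores true/false entries at base 0.8/0.4 with Gaussian noise (σ = 0.1)
clipped to [0, 1]. These rates are a deliberate stand-in for an imperfect
but informative deep-learning predictor; they are fixed defaults, not
fitted to anything. What the fixture does **not** emulate: realistic fold
geometry and side-chain packing, the spatial clustering and error
correlations of a real predictor's mistakes, score calibration, or
heteromeric interfaces. Passing tests therefore demonstrate the
correctness of the subtraction/evaluation/reconstruction machinery, not the
accuracy a trained predictor would achieve on real homodimers — on the
clean synthetic fixture the pipeline's Top-L/10 precision is far higher
than any real-data figure.

## Numerical choices and degenerate inputs

Contact maps use exact distance comparisons on float64 coordinates; PDB
output rounds to the format's 3 decimals (round-trip tests compare at that
precision; writer→reader→writer is byte-stable). Ties in ranking break by
(i, j) ascending so ranking is total and deterministic. Residues lacking
both Cβ and Cα are excluded from intrachain maps with a warning; an empty
ranked list yields zero precision with a warning; k < 1 clamps to 1 with a
warning; zero restraints, empty chains, single-chain pair selection, and
oversampling the eligible-pair pool are errors. All stochastic interfaces
(generator, baseline, annealer) take explicit seeds; per-purpose child
streams are derived as `default_rng([tag, seed])` so fixtures and scores
are independently reproducible.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen for exhaustive
cross-checking against brute-force oracles: random instances at L ≤ 40
(100 trials per windowed operation), a 24-target synthetic panel for the
precision summary, 10 000 draws for baseline calibration, and 10 (tests) /
3 (script) seeded annealing runs at L = 48.

## Known limitations

- The subtraction is blind to interface contacts that coincide with
  intrachain contacts or sit within the removal window of one; relax
  removal trades recall for precision by design.
- Reconstruction assumes a rigid monomer and a single dimeric interface;
  no symmetry constraints, flexible refinement, or >2-copy assembly.
- The homogenization aligner is intentionally simple; highly divergent or
  heavily gapped chain pairs may align differently than a
  substitution-matrix aligner would.
- Interchain truth counts (i, j) and (j, i) separately; density values are
  therefore up to 2× those of a folded-map convention.
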