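# Methods

## Problem and model

`cssr` assigns canonical RNA secondary structure — Watson–Crick (A:U,
C:G) and wobble (G:U) base pairs — to 3D structures in which each
nucleotide may be represented by anything from a full backbone down to a
single atom. It considers ten atom types per nucleotide: the phosphate
P, the sugar/backbone heavy atoms C5', C4', C3', C2', C1', O5', O4',
O3', and the glycosidic nitrogen N (N9 in purines, N1 in pyrimidines).

The central quantity is a per-pair score. For a candidate pair (i, j)
whose bases are canonically compatible, and for each atom type *a*
present in both nucleotides, up to seven geometry sub-terms are
evaluated from the coordinates of i, j and their sequence neighbors
i±1, j±1:

| sub-term | definition |
|---|---|
| dis0      | \|a_i − a_j\| |
| dis_up    | \|a_{i+1} − a_{j−1}\| |
| dis_down  | \|a_{i−1} − a_{j+1}\| |
| ang_i     | angle(a_{i+1}, a_i, a_j) |
| ang_j     | angle(a_{j−1}, a_j, a_i) |
| dih_i     | dihedral(a_{i+1}, a_i, a_j, a_{j−1}) |
| dih_j     | dihedral(a_{j+1}, a_j, a_i, a_{i−1}) |

The three distances cover the pair itself and the two stacked neighbor
pairs of an antiparallel helix (i+1 with j−1, i−1 with j+1); the angles
and dihedrals capture the relative orientation of the two strands.
Each evaluable sub-term contributes an unnormalized Gaussian agreement
kernel

    c = exp(−Δ² / 2σ²),

where Δ is the deviation of the observed value from the calibrated mean
μ (on the circle, for angles and dihedrals) and σ the calibrated
spread. The score is the equal-weight arithmetic mean of all evaluable
contributions. Sub-terms that cannot be computed — missing atom,
missing neighbor (chain end, chain break), or a bucket never populated
during calibration — are skipped, and the mean renormalizes over what
remains. This renormalization is what makes a single-atom trace
scoreable at all: a P-only structure contributes at most 7 sub-terms
instead of 70, but its score still lives on the same [0, 1] scale with
1 = perfect helix geometry.

A flag (`nested_mean`) averages per atom type first and then across
atom types instead; on fixtures with complete atom sets the two
coincide, and the flat mean is the default.

Pairs are canonicalized to i < j (global position over the concatenated
chains) before both calibration bucketing and scoring. This makes the
score exactly symmetric under i↔j by construction. (The sub-term set
itself is *not* closed under the swap — the two angle terms use i+1 and
j−1 respectively — so without canonicalization the score would be
almost, but not exactly, symmetric.)

## Candidate enumeration and conflict resolution

Candidates are all position pairs whose bases form a legal pair class,
with an intra-chain separation of at least `min_separation` (default 4,
the standard minimal hairpin-loop constraint; the value is tunable).
Inter-chain pairs are scored only with `--inter-chain`, since the
default protocol evaluates intra-chain structure.

Assignment keeps every candidate with score ≥ cutoff (default 0.5,
closed bound), sorts descending, and accepts a pair iff neither
nucleotide is already used by a higher-ranked pair. Ties are broken by
(smaller i, then smaller j) for determinism. There is no dynamic
programming and no planarity constraint, so crossing pairs survive and
pseudoknots are representable. The dot-bracket writer assigns each pair
to the lowest bracket level — () [] {} <> then Aa…Zz — at which it
crosses nothing already placed.

## Calibration

`calibrate` takes structures with annotated canonical pairs, evaluates
every sub-term of every annotated pair, buckets values by (pair class ×
atom type × sub-term), and stores mean, spread and count per bucket
(at most 2 × 10 × 7 = 140 cells). Distances use plain sample moments
(SD with ddof = 1); angles and dihedrals use the circular mean and the
circular standard deviation √(−2 ln R), which handles distributions
straddling ±180° and converges to the linear SD for tight clusters.
Buckets with fewer than two observations are dropped. Spreads are
clamped from below by `sigma_floor` (default 0.01 Å or degrees) so that
degenerate, noise-free calibration sets cannot produce σ = 0 and
undefined kernels. No outlier trimming is applied (plain moments).

The packaged default table (`src/cssr/data/default_params.tsv`,
regenerable with `scripts/make_default_params.py`) is calibrated on the
synthetic helix ensemble described below — 40 duplexes × 20 bp with
0.5 Å coordinate noise and 10% wobble steps, fixed seed — so the tool
works out of the box with no external data. These defaults describe the
synthetic geometry, not experimental RNA: for real structures, calibrate
on annotated experimental coordinates (`cssr calibrate`) and pass the
resulting file via `--params`. The parameter file is versioned,
human-readable TSV and round-trips exactly.

## Synthetic fixtures

The generator builds coordinates with known ground truth from
cylindrical per-atom templates on an exactly periodic helix (rise
2.81 Å, twist 32.7°, pairing phase 154°; per-atom radius/phase/z
constants are plain data on `HelixSpec`). The constants are A-form-like
but idealized: the pipeline needs calibration and test geometry to be
internally consistent, not to reproduce literature coordinates, and the
templates are configuration, not hidden state.

* **Duplexes** place the two antiparallel strands with mirrored
  templates, so every helix step is congruent (sub-term values of
  interior pairs agree to 10⁻⁶ across the helix).
* **Hairpins** reuse the duplex for the stem. The first and last loop
  residues are pinned to the exact helix-continuation positions of the
  two strands, which keeps the loop-closing pair's neighbor-dependent
  sub-terms ideal; interior loop residues are arched between the
  anchors. Loops default to all-A, which cannot form canonical pairs
  with itself, avoiding phantom geometric matches at the anchors.
* **H-type pseudoknots** combine two duplex blocks, the second rigidly
  rotated and translated well away from the first; linker residues
  adjacent to stem ends are pinned to helix continuations the same way
  (hence linkers must be ≥ 2 nt), and the ground-truth pair sets cross.
* **Wobble geometry.** The U of a G:U pair is displaced by +4° phase
  and +0.3 Å rise, giving the WOBBLE class statistics genuinely distinct
  from WC, as in real helices.
* **Noise** is i.i.d. isotropic Gaussian per atom coordinate, seeded —
  a deliberately simple stand-in for the coordinate uncertainty of
  low-resolution structures. It does not emulate correlated backbone
  motion, missing-residue patterns, or modeling bias.

What passing tests on these fixtures shows: internal consistency of the
whole pipeline (calibrate → score → filter → serialize), correct
handling of missing atoms/neighbors, pseudoknot capability, and the
expected qualitative behavior (accuracy ordered by atom-subset
informativeness, degradation with noise). What it does not show:
accuracy numbers transferable to experimental RNA, which depend on
calibrating against real annotated structures.

## Numerical and design choices

* Degenerate geometry (zero-length arms, collinear dihedral frames,
  tolerance 10⁻⁶ Å) raises an error in the geometry kernels; during
  scoring, `term_value` treats such configurations as "not evaluable"
  (like a missing atom) rather than aborting the pair, since absence
  tolerance is the operation's contract and exact degeneracy cannot
  arise from measured coordinates.
* Circular mean is undefined for resultant length ≈ 0 (near-uniform
  samples) and raises.
* Modified residues map to parent bases through gemmi's chemical
  component table plus a small bundled supplement (e.g. 5MC→C);
  unmapped residues get base UNKNOWN and can never enter a candidate
  pair. Alternate locations keep the highest-occupancy conformer (ties:
  first in file). Residues with none of the ten atom types are dropped
  and break sequence adjacency, so neighbor-dependent sub-terms are not
  computed across the gap.
* Multi-model files use one model (default: the first), selected with
  `--model-index`.
* Evaluation counts a predicted pair as correct only on exact index
  identity (a slippage-tolerant mode exists, default off). The MCC
  negative universe is all L(L−1)/2 unordered pairs. Conventions: both
  structures empty → precision = recall = F1 = MCC = 1; exactly one
  side empty → F1 = 0. Aggregation over targets is the unweighted mean
  with SEM = sample SD (ddof 1)/√n.

## Problem sizes used in tests and the reproduction script

The simulated benchmark uses 50 targets (alternating hairpins with
stems of 4–10 bp and pseudoknots with 3–5 bp stems, 10% wobble steps)
at 0.5 Å noise for the atom-subset ladder, and 30 targets per noise
level for the degradation sweep; calibration ensembles are 40 duplexes
× 20 bp (2,000 annotated pairs per calibration at the defaults). These
sizes give SEMs of ~0.02 on mean F1, small enough to resolve the
orderings the package asserts.

## Known limitations

* Only canonical WC and wobble pairs are assigned; Hoogsteen and
  sugar-edge pairs are out of scope, as are base-pair edge/orientation
  (cis/trans) classifications.
* The score is calibrated per pair class only; it does not distinguish
  which partner is the purine, pooling both orientations.
* On noise-free fixtures scored against floor-clamped sigmas, WC pairs
  stacked directly against a wobble pair inherit a deterministic
  geometric offset in their stacking sub-terms and can fall below the
  0.5 cutoff; with realistic (noisy) calibration spreads the effect is
  negligible. Exact-recovery guarantees are therefore stated for
  WC-only noise-free fixtures.
* No energy model, no structure prediction, no gradients: the tool
  annotates coordinates it is given.
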