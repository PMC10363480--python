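# Methods

This note documents the models, conventions and numerical choices behind
`peptarget`, and what the synthetic-data tests do and do not establish.

## Peptide model and construct grammar

Peptides are uppercase strings over the 20 standard residues. A targeting
peptide (TP) carries a 1-based `cleavage_index` pointing at the **last
presequence residue**; cleavage occurs between that residue and the next.
All internal slicing is half-open; reported indices are inclusive.

Chimeric constructs concatenate, without linkers:

    [cTP-N] + core (after K/R substitution) + [cTP-C | mTP-C]

where cTP-N is the first 15 residues of the chloroplast preprotein
(upstream of its helix), and the C-elements span 10 residues upstream to 23
residues downstream of the donor's cleavage site, so each construct with a
C-element carries a functional peptidase recognition region and its own
cleavage index 23 residues before its end. "Mostly K" / "mostly R" variants
are implemented as **total** substitution of the other basic residue;
peptides natively lacking the source residue are unchanged but keep the
variant label. Special cores: `CH`/`MH` are the TP helical fragments left
after removing the N-terminal stretch and C-element, `AA` a poly-alanine of
`CH`'s length, `-` no core. The code grammar `[^c] CORE [_K|_R] [^c|^m]`
and the row letters A–L (the twelve variant × element combinations) round-
trip exactly through `parse_construct_code`/`format_construct_code`.

The packaged peptide panel is a **synthetic stand-in**: the real peptide
panel is not redistributable here, so the package ships generated sequences
with the right cast (13 antimicrobial cores, two TP preproteins with
declared cleavage sites at residues 45 and 36, two random controls) and
realistic composition. Everything that depends only on structure — element
arithmetic, grammar, assembly invariants such as
`^cCH_R^c == preprotein[1..cleavage+23]` — is exercised on it; nothing in
the package claims sequence fidelity.

## Amphipathic-helix detection

Residues sit on an ideal helical wheel at δ = 100°/residue (3.6
residues/turn; config-exposed). The hydrophobic moment of a window is the
per-residue-normalized magnitude of the vector sum of Fauchère–Pliska
hydrophobicities; prefix sums over absolute positions give any window's
moment in O(1), since an index offset only rotates the vector.

A stretch qualifies as an amphipathic helix when

1. length ≥ 9 (two and a half turns);
2. μH ≥ 0.35;
3. **local amphipathicity**: every 9-residue sub-window keeps at least 85%
   of the μH threshold. Without this, the longest-stretch search happily
   bridges a non-amphipathic spacer between two strong helices (the global
   moment of the union stays above threshold) and over-extends into
   unstructured flanks;
4. identifiable faces: among residues whose wheel angle lies within ±90° of
   the moment direction, ≥ 60% are from {L,I,V,F,M,W,Y,A}, and the opposite
   face has ≥ 2 residues from {R,K,D,E,S,T,N,Q,H,G,P}.

The longest qualifying stretch is recorded (ties: higher μH, then leftmost),
masked, and the search recurses on both flanks, yielding non-overlapping
annotations. All five constants are config keys. The thresholds were
calibrated once against the package's own qualitative contracts (designed
amphipathic peptides are recovered essentially exactly; a poly-serine
spacer splits two designed helices; poly-S and random peptides are mostly
helix-free) — they are declared defaults, not values recovered from any
published tool.

Per-peptide metrics: `helix_fraction` counts annotated residues within the
evaluation limit (the cleavage site for TPs, otherwise the full length)
divided by that limit; `upstream_length` is the number of residues before
the longest helix. Helix-free peptides report `upstream_length` equal to
the evaluated length — placing them at the "maximally unstructured" end of
the axis — and carry a `helix_free` flag. Externally determined helices
(e.g. from NMR) can be injected from a sidecar TSV and take precedence over
prediction.

A note on a tempting invariant: raising the μH threshold does **not**
always reduce the total number of annotated residues. The qualifying-window
set shrinks monotonically, but the greedy longest-first selection over a
smaller set can cover more residues (a long borderline stretch that blocked
its flanks disappears, freeing two shorter helices). The tests assert
monotonicity at the window level, where it is true.

## Physico-chemical features

ACC terms use the classical three Z-scales (hydrophobic, steric, electronic
principal properties), shipped as a versioned TSV. Terms are **uncentered**
products normalized by (N−d), ordered (j,k,d) lexicographically as
`acc_j_k_d`; a centered variant (per-sequence mean subtraction) sits behind
a flag because the convention is not universal. Similarity to a reference
class is the Euclidean distance to the coordinate-wise mean (barycenter) of
the reference ACC vectors.

The Boman index is the per-residue mean of inverted water→cyclohexane
transfer free energies (high = protein-interactive); proline has no
experimental value in that series and is set to 0. Charge profiles use
K = R = +1, D = E = −1, H configurable (default 0), summed over 10-residue
windows with C-terminally truncated windows dropped. Database-baseline
amino-acid frequencies are configuration data, never recomputed.

## Motif rules

FGLK windows are 8 residues; a window qualifies when it contains F, [P/G],
[K/R], [A/L/V] and neither D nor E — presence tests, not counts. FGLK-1
relaxes to any 3 of the 4 positive determinant classes. Overlapping
qualifying windows merge into maximal "sites" for counting; per-window
detail is retained, so both merged and unmerged counts are available. Hsp70
sites are sliding 7-residue affinity sums (the chaperone's binding-core
length) over a per-residue scale; **the shipped scale is synthetic** — it
preserves only the qualitative orientation of the experimental data
(aliphatic/aromatic favored, acidic strongly disfavored) and must be
replaced by transcribed experimental values for quantitative use. The
multi-R rule reports maximal runs of ≥ 2 consecutive arginines within the
N-terminal 15 residues.

## Classification protocol

Features: 36 ACC terms of each peptide's first 15 residues (peptides
shorter than 15 are dropped with a warning). Model: binomial logistic
regression with elastic-net penalty, saga solver, l1-ratio 0 and C = 0.1 by
default, tolerance 1e-6; convergence failures raise, never pass silently.
Features are standardized **on the training folds only** (the protocol's
regularization is scale-sensitive, so this is fixed, not optional).

Per run: draw the same number of sequences per class without replacement,
split into 5 stratified folds, record held-out accuracy; 100 runs by
default, all seeded from one integer, so the same seed yields a
byte-identical report. Accuracy aggregates fold-mean then run-mean; per-run
values are retained. The final coefficient vector comes from one fit on all
data. Hyperparameter search evaluates an (l1-ratio, C) grid by 10-fold CV
and reports the full table with exact ties marked, not silently broken.

The TP-similarity model (l1-ratio 0.15) featurizes **whole peptides** —
antimicrobial peptides have no cleavage sites, so no N-terminal truncation
is meaningful — and scores candidates by the fitted TP-class probability.

## Targeting-outcome grid

The grid stores one call per organelle per construct: NONE < PARTIAL <
FULL. Dual targeting (both ≥ PARTIAL) is always derived. The K→R
comparison classifies each of the 6 row pairs × 13 cores as GAIN
(NONE→≥PARTIAL), IMPROVE (PARTIAL→FULL), LOSS, DECREASE or UNCHANGED; these
partition the evaluated cells and are antisymmetric under swapping the K
and R rows. A dual-gain flag marks pairs whose R variant targets both
organelles where the K variant did not. Control columns (random peptides,
TP fragments, poly-alanine and no-core constructs) are stored but excluded
from all tallies.

The packaged grid is a transcription of reported outcomes; every cell
carries a provenance note (`text` = explicitly enumerated, `implied` =
forced by the enumerated change/tally coordinates, `default` = never
reported as targeting, `lowconf` = ambiguous wording). The transcription
reproduces all enumerated counts exactly (8 mitochondrial and 15
chloroplast K→R gains+improvements with 3 dual gains and 3
losses/decreases; 22 of 26 cTP-N+cTP-C constructs with chloroplast
targeting; 10 chloroplast-only and 6 dual cTP-N+mTP-C constructs) and the
core-attribution shares to the printed precision (cp-set share 57.4% of
chloroplast targeting, 65.6% excluding the double-cTP-element rows). The
mt-set mitochondrial share computes to 69.2% on this transcription.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
the study-condition defaults: mTP-like peptides are N(37, 8) residues long,
helical from residue 1 for ~80% of their length, arginine-rich; cTP-like
peptides are N(49, 8) long with an unstructured N(15, 5) prefix of
{S,T,P,G,A,R} before a central helix and a short tail; HA-RAMP-like
peptides are fully helical and lysine-rich (N(28, 8)); random peptides are
i.i.d. draws from database-like background frequencies. Helices place
hydrophobic-arc positions (180° by default) in {L,I,V,F,A} and the rest in
a polar pool with the class's basic residue at weight 0.5. Acidic residues
appear only in unstructured segments, at rate 0.01 by default. Every
dataset is a pure function of its spec (seed included) and ships with a
ground-truth table of designed helix spans.

What passing tests show — and what they do not: the generator reproduces
the *contrasts* the analysis relies on (length, helix position, K/R usage,
acidic depletion), so recovering them demonstrates that the pipeline
measures what it claims. It does not demonstrate performance on real
peptides, whose composition, helix imperfections and length distributions
are richer; in particular the classifier's high accuracy on the synthetic
contrast is not a claim about real mTP/cTP discrimination accuracy.

## Statistics

Two-group property comparisons use Welch's unequal-variance t-test (pooled
variance behind a flag); one-sided tests state the alternative direction
a priori. Amino-acid frequency comparisons across ≥ 3 groups use
Kruskal–Wallis followed by Dunn's pairwise z-tests on rank sums with tie
correction; the multiplicity correction defaults to Holm (Bonferroni and
none are available). All-tied inputs report an undefined omnibus rather
than erroring. All statistics are deterministic.

## Problem sizes and tolerances

The verification suite uses sizes chosen to make the checks sharp yet
quick: ACC oracle equivalence to 1e-12 on 1000 random peptides of length
5–60; helix invariants on 1000 fuzzed peptides and designed-span recovery
(mean Jaccard ≥ 0.8) on 200 seeded 14–35-mers; the cross-validation
protocol at its full 100 runs on 40/40 separable classes and 34/85
same-distribution null classes with 33 drawn per class per run; property-
contrast recovery on 100 replicate 40/40 datasets at the defaults above.
Logistic fits use tolerance 1e-6 with a generous iteration cap; moment and
ACC computations are exact to floating-point rounding.

## Known limitations

- The helix detector is a wheel-projection heuristic: no solvation, no
  helix-capping, no kinked or split helices (two helices at an angle are
  reported as separate annotations or one, depending on thresholds).
- The qualification thresholds are declared package defaults; published
  annotations made with other tools will differ at the margins.
- The Hsp70 scale is synthetic (orientation only), and the bundled peptide
  panel is a stand-in; analyses of the real peptides require supplying the
  real sequences and affinity values as drop-in data files.
- The targeting grid inherits the precision of the reported outcomes;
  cells marked `implied`/`lowconf` are constrained but not individually
  stated.
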