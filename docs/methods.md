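# Methods

This note documents the models and procedures implemented in `fungpcr`,
the parameters that matter, the numerical choices, and the limits of what
the synthetic benchmarks demonstrate.

## The identification cascade

A candidate receptor must clear a conjunction of per-sequence predicates;
because each gate is a pure predicate on one sequence's evidence, the
cascade is order-independent and each stage can be re-run in isolation.

| Gate | Rule | Default |
|---|---|---|
| BLAST | E-value and dual coverage, strict inequalities | E < 1e-5, coverage > 0.75 of both query and subject |
| HMM | per-class profile E-value, strict | E < 1e-5 |
| Helix count | class-specific allowed set | 6–7 (most fungal classes); 7–9 (classes 9 and 11); exactly 7 (classes 15–17 and the novel-candidate pool) |
| Orientation | first topology segment `outside`, last `inside` | required |
| Pfam | class-diagnostic domain present | confirmation, not a filter |

Notes on the choices:

* Coverage is `(qend − qstart + 1)/qlen` (and the subject analogue), on
  1-based inclusive coordinates; requiring both sides suppresses
  domain-only matches to large multi-domain proteins. Both length fields
  are therefore mandatory: the BLAST parser accepts the 12-column tabular
  dialect only together with a sequence-length map, or the 14-column
  dialect with `qlen slen` appended.
* The 7–9 helix window is applied to class 9 *and* class 11: members of
  both classes are described with up to nine helices, and the union is
  the safer screen. The 6–7 window elsewhere tolerates the one-helix
  under-call that topology predictors commonly make.
* When one sequence hits several class profiles, the smallest E-value
  wins; ties break on larger bit score, then smaller class index. This
  tie-break is a package choice — hit tables rarely make it observable —
  and is fixed so results are deterministic.
* Pfam-domain consistency requires at least one class-matching domain;
  extra unrelated domains do not penalize a sequence. Percentages are
  reported to one decimal with round-half-even at the last digit
  (banker's rounding via Python's `round`); e.g. shares of 984/918/187
  out of 2089 print as 47.1/43.9/9.0.
* The mammalian-homolog screen (classes 15–17) starts from family Pfam
  domains (7tm_1, 7tm_3, Frizzled/Fz) rather than HMM profiles, and
  applies the exactly-7 and orientation gates. Taste2 and Adhesion
  domains are screened and recorded but never assigned: those families
  appear absent in fungi, and the screen preserves the evidence trail for
  any future counter-example.

## Topology representation and the fallback predictor

Topology is an ordered tiling of `1..seq_len` into
`inside`/`TMhelix`/`outside` segments (two helices never adjacent), as
produced by TMHMM-style predictors; both the long per-segment report and
the one-line summary dialect are parsed, and declared helix counts are
cross-checked against the segments.

For testing without an external predictor, a deliberately simple
hydropathy predictor is included: Kyte–Doolittle means over a sliding
window (window 19, threshold 1.6), maximal super-threshold runs of at
least 15 window positions (runs separated by fewer than 5 positions are
merged) becoming helices, flanks alternating from a declared N-terminal
side. These constants are fixed in the package and are not meant to be
tuned per dataset. The predictor knows nothing about insertion
energetics, signal peptides, or re-entrant loops, and cannot infer
sidedness from sequence — orientation checks in the pipeline always use
the (parsed or generated) topology labels, never re-inference.

## Markov clustering

`MarkovClustering` iterates the textbook recipe on a column-stochastic
matrix: expansion (matrix power, default 2), inflation (elementwise
power, default 2.0 — the conventional default; larger values give finer
partitions), pruning of entries below 1e-5 with column renormalization,
until the matrix changes by less than 1e-8 or 200 iterations (a
non-convergence warning interprets the current matrix). Self-loops equal
to each node's maximum incident weight are added before iteration, the
standard damping of the algorithm's parity oscillation. Clusters are read
from the limit matrix by merging attractor rows (positive diagonal) with
their support; stray nodes become singletons, so the result is always a
partition, and node order is sorted first, so relabeling the input cannot
change the partition. Similarity graphs built from BLAST hits use
−log10(E-value) capped at 200 (or bit score), symmetrized by taking the
larger direction, with self-hits dropped.

The implementation is dense `numpy`; it is intended for desk-scale
graphs (thousands of nodes), not for out-of-core clustering of entire
proteome collections.

## The 1D-CNN classifier

Sequences are one-hot encoded over the 20 standard residues in the fixed
order `ACDEFGHIKLMNPQRSTVWY`; padding rows and non-standard residues are
all-zero, and sequences longer than the padding length are
right-truncated with a warning. The padding length defaults to the 95th
percentile of training lengths, capped at 2000. The network is
conv1d(32 filters, kernel 3, ReLU) → max-pool(2) → flatten → dense(64,
ReLU) → dense(1, sigmoid), trained with Adam (rate 1e-3, β₁ 0.9, β₂
0.999) on binary cross-entropy for exactly 10 epochs at batch size 32
(no early stopping), on a stratified 80/20 split. Layer parameter counts
follow the closed forms `kernel·20·filters + filters` (conv; 1952 for
the defaults) and `dense_units + 1` (output; 65).

Forward and backward passes are written directly on `numpy` (im2col
windows via stride tricks, argmax routing through the pool with
first-max tie-breaking, Glorot-uniform initialization). Every stochastic
step — initialization, split, epoch shuffling — derives from the single
`seed` parameter, so training is bit-reproducible; prediction is
batch-size independent.

## Consensus calls

A candidate is consensus-positive when all three model scores strictly
exceed their thresholds: ProteInfer > 0.8, DeepFRI > 0.2, CNN > 0.9.
Conjunction (rather than a cutoff on the sum) is the package's reading of
the combination rule: it explains the observed floor of the score
distribution, since any positive necessarily sums above 1.9. The
consensus score is the plain sum, binned over
[1.9, 2.0), [2.0, 2.25), [2.25, 2.5), [2.5, 3.0] for reporting, and
sequences missing any model's score are excluded and logged rather than
imputed.

## Interaction triage

The canonical metrics input is a JSON payload `{ptm, iptm, plddt[],
pae[][], chain_ranges}` — predictor-agnostic on purpose, since pinning to
one predictor's pickle format is brittle. Coordinates come from PDB.

* Ranking confidence is `0.8·ipTM + 0.2·pTM`; tiers: > 0.5 good,
  > 0.75 very high, > 0.8 top.
* Interface contacts are residue pairs across chains with any heavy atom
  within 8 Å, the convention of the pDockQ score lineage.
* Per-chain pDockQ2 uses the published sigmoid
  `L/(1 + e^{−k(x − x0)}) + b` with (L, x0, k, b) =
  (1.31, 84.733, 0.075, 0.005) and PAE normalization distance d0 = 10 Å,
  transcribed into a versioned constants table and never re-fit. The
  argument `x` multiplies the mean interface pLDDT of the chain by the
  mean PAE term over its inter-chain contact pairs; PAE rows are
  direction-specific, which is why the two chains of a pair can score
  differently. A chain with no contacts scores 0 and is flagged (no
  interaction surface) rather than treated as evidence.
* A pair is a high-confidence interaction when min-over-chains
  pDockQ2 > 0.23; a receptor + Gα/Gβ/Gγ heterotrimer model applies the
  same rule over all four chains, which makes the four-chain verdict
  strictly harder.
* Mean pLDDT is computed over all residues (not interface-only — the
  reporting convention here is a package choice) and flagged
  high-confidence above 80. Across repeated models of one pair, the
  assessment with the highest ranking confidence is kept.

## Enrichment and co-location

Term enrichment uses Fisher's exact two-sided test per term (the
standard choice for count-based domain/GO enrichment) on
foreground-vs-background 2×2 tables, with Benjamini–Hochberg adjustment
across all tested terms. A receptor is co-located with a biosynthetic
gene cluster when their intervals share at least one base on the same
scaffold; distance to the nearest PKS/NRPS core gene is reported up to a
configurable horizon (default 10 kb). "Within a cluster" as ≥ 1 bp
overlap, and the 10 kb proximity horizon, are interpretations, exposed
as parameters rather than hard-coded. BED input (0-based half-open) is
converted to the package-wide 1-based inclusive convention at parse
time.

## The synthetic generator, and what passing tests show

The generator emulates the *signal structure* of the pipeline's inputs,
not fungal biology. Membrane proteins are alternating segments: helices
of 18–25 residues drawn from I/V/L (weights 0.60/0.25/0.15), loops of
10–40 residues from P/Y/S (0.60/0.30/0.10). These low-variance,
high-contrast alphabets are chosen so the hydropathy predictor separates
helix from loop with a wide margin on both sides of its threshold — the
inter-helix dip at the shortest (10-residue) loops and the run length at
the shortest (18-residue) helices are the two binding constraints — and
designed helix counts are recovered exactly. Decoys come in three kinds:
wrong helix count, inverted orientation (intracellular N-terminus), and
soluble (all-loop, with lengths drawn to overlap the positive length
distribution so composition rather than length carries the signal for
that decoy class). The CNN benchmark pairs seven-helix positives with an
even mixture of soluble, 3-helix and 12-helix decoys.

Structure fixtures are straight CA traces with a designed contact patch
per partner chain; a single quality dial q ∈ [0, 1] sets interface PAE
to `31(1−q) + 1` Å, pLDDT to `40 + 60q`, pTM to `0.2 + 0.6q` and ipTM
to `0.1 + 0.8q`, spanning the verdict boundary so both triage outcomes
are exercised.

Consequences for interpretation: the classifier's perfect held-out
metrics on this benchmark demonstrate that the implementation — encoding,
architecture, optimization, evaluation — works end-to-end on a task with
the right shape, at a separation far cleaner than real proteomes, where
positives and negatives share composition statistics and hard negatives
(transporters, other 7-TM non-GPCRs) abound. They are an implementation
check, not an estimate of real-data generalization. The same applies to
the topology gates: 100% separation of generated positives from decoys
reflects the generator's margins, not TMHMM's error profile.

## Problem sizes and determinism

The standard benchmark runs at 4000 sequences per class (padding length
≈ 600, ≈ 510k trainable parameters, about a minute of CPU training);
clustering and triage tests run on graphs of tens of nodes and complexes
of 2 × 60 to 4 × 60 residues. All randomness in the package flows
through explicit integer seeds (`numpy` Generators; scikit-learn
`random_state` for splits), so every reported number is reproducible
bit-for-bit at a fixed seed.

## Known limitations

* The cascade consumes evidence files; it cannot detect upstream search
  errors (wrong BLAST database, truncated TMHMM runs) beyond format
  validation.
* The dense MCL does not scale past desk-size graphs.
* The CNN's right-truncation silently caps very long sequences at the
  padding length; for proteomes with unusual length distributions, set
  `max_len` explicitly.
* pDockQ2 constants were fit (elsewhere) for AlphaFold-Multimer outputs;
  applying them to other predictors' PAE/pLDDT payloads shifts the score
  scale in unvalidated ways.
* Orientation checking trusts the topology labels; inverted predictions
  by the upstream tool propagate.
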