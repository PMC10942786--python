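# Methods

## The screen

The unit of evidence is the per-group expressing-cell fraction
`p_i = num_expr_i / ncells_i`, where a cell counts as expressing a
gene if it has at least one read. Working on binarized counts makes
the screen insensitive to sequencing depth and to the choice of
normalization; normalization is used only for marker-based cell
gating, never for scoring.

For an ordered bipartition (S1, S2) of the G group labels the score is

    score = mean_{i in S1} log2(eps_pos - 1 + p_i)
          - mean_{j in S2} log2(eps_nega + p_j)

Averaging log terms (equivalently: scoring the geometric mean of the
shifted proportions) weights each group equally irrespective of its
cell count and penalizes outlier groups hard — one silent group in S1,
or one broadly expressing group in S2, dominates its side's mean.

Parameters:

* `eps_pos` (default 0.9) sets the hard floor: any S1 group with
  `p <= 1 - eps_pos` (10% at the default) makes the log argument
  non-positive and the gene takes the minimal possible score, −∞, for
  that split. The −∞ is represented as IEEE negative infinity
  internally and serialized as the string `"-inf"`; this preserves a
  total ordering without a magic sentinel.
* `eps_nega` (default 0.02) floors the S2 penalty term so that fully
  silent S2 groups contribute `−log2(0.02) ≈ +5.64` rather than +∞.
  It must be strictly positive; the only legitimate route to −∞ is the
  S1 floor.

All `2^G − 2` ordered splits are enumerated (subset_1 encoded as an
ascending bitmask over the input group order) and both orientations of
every split are scored — for 8 groups, 254 comparisons. Ranking is
descending by score over all (gene, split) pairs irrespective of which
split produced them; with deduplication (default) each gene keeps only
its best-scoring split. Ties are broken by the larger proportion
margin `min(S1 p) − max(S2 p)`, then by the split's bitmask, then by
gene identifier — the choice is arbitrary but fixed, so rankings are
reproducible. Entries that are −∞ on every split (e.g. genes silent
everywhere) are never ranked above finite scores and are excluded from
the truncated top list.

**Numerical boundary.** The penalty condition `p <= 1 − eps_pos` is a
statement about exact rationals, but `eps_pos − 1 + p` evaluated in
floating point can round to ~1e−17 instead of 0 (e.g. p = 0.1 at the
default). Arguments within 1e−12 of zero are therefore treated as
zero (score −∞). Proportion gaps of interest are ≥ 1/ncells ≫ 1e−12,
so the tolerance cannot misclassify a genuinely positive argument.

## Pattern taxonomy

A split's label depends only on which roles (sympathetic,
parasympathetic, pelvic cluster) sit in subset_1:

| label | subset_1 | category |
|---|---|---|
| I | all sympathetic + pelvic clusters, no parasympathetic | sympathetic-and-pelvic |
| II | parasympathetic only | parasympathetic-not-pelvic |
| III | all sympathetic only | sympathetic-not-pelvic |
| IV | parasympathetic + pelvic subset ≠ cholinergic set | parasympathetic-and-some-pelvic |
| V | parasympathetic + exactly the cholinergic pelvic set | cholinergic |
| VI | all sympathetic + exactly the noradrenergic pelvic set | noradrenergic |
| VII | a pelvic-only subset on either side of the split | pelvic-specific |
| other | anything else (e.g. splits cutting across sympathetic ganglia) | other |

Two readings of pattern I are defensible: requiring *all* pelvic
clusters alongside the sympathetic ganglia, or any nonempty pelvic
subset. The default is the permissive reading, switchable via
`require_all_pelvic=True`. Under the permissive reading the I and VI
definitions overlap (all-sympathetic + {P3} satisfies both), so
classification tests the exact-set patterns (VII, V, VI, II, III)
before the subset patterns (I, IV); this makes the labels a true
partition — each of the 254 default splits gets exactly one label
(I: 14, II: 1, III: 1, IV: 14, V: 1, VI: 1, VII: 30, other: 192).
Pattern VII deliberately covers both orientations: pelvic-only
expression (subset_1 ⊆ pelvic) and pelvic-only absence (subset_2 ⊆
pelvic).

Heatmap ordering groups genes contiguously by pattern in the fixed
order I…VII, other, score-descending within each block.

## QC gating

* **Droplet filter.** Retain droplets with detected genes strictly
  above `min_genes_exclusive` (1500), strictly below
  `max_genes_exclusive` (11000), and mitochondrial fraction strictly
  below `max_mito_fraction` (0.15). "Detected" means count ≥ 1; the
  mito fraction is mito counts over total counts per cell, with mito
  genes identified by a `var["mito"]` flag or a configurable name
  prefix (default `mt-`). If no mito gene is flagged the predicate
  passes vacuously and the report records a warning. All three
  predicates are pure per-cell functions, so joint and sequential
  application agree in any order.
* **Normalization.** Default `median_log1p`: scale each cell to the
  median library size, then log1p. This is a deliberately simple
  variance-dampening depth correction — a GLM-based method is out of
  scope here, and normalization affects only the marker gating, not
  the binarized screen. Consequence: the conventional fixed neuron
  threshold of 3 belongs to a variance-stabilized scale and is kept
  only as a user-overridable default; on this package's scale (and on
  simulated data) the `"auto"` rule is the appropriate choice.
* **Neuron selection.** Per-cell score = mean normalized expression
  over the available neuron markers; a cell is kept iff its score
  strictly exceeds the threshold. `"auto"` picks the threshold that
  minimizes intra-class variance of the score distribution (Otsu's
  criterion on a 256-bin histogram), a concrete instantiation of
  "best separates the bimodal distribution"; the chosen value is
  recorded in the report. The rule is invariant to cell order and to
  duplicating all cells.
* **Glial-doublet exclusion.** Same scoring over the glial markers;
  cells strictly above the threshold are removed. No fixed default
  threshold is published for this gate, so `"auto"` is the default.

Every stage returns a report with exact per-cell pass/fail flags;
`n_input = n_retained + n_removed` holds by construction and the flags
reproduce the counts.

## Synthetic data generator

The generator emulates the screen's input conditions: 8 labeled groups
(1 parasympathetic ganglion, 3 sympathetic ganglia, 4 pelvic clusters)
across two batches. Default group sizes follow realistic per-ganglion
neuron counts scaled down 4× to keep tests fast while
preserving the ~10-fold group-size imbalance (sphenopalatine 464,
stellate 672, coeliac 59, lumbar 231); the pooled pelvic neurons are
split evenly across the four clusters (~76 each) since no per-cluster
counts are published.

Counts follow a gated count model: each (cell, gene) is expressing
with probability p (Bernoulli), and expressing cells draw
`1 + NegativeBinomial(mean − 1, dispersion)` reads. The `1 +` shift
makes the expressing-cell fraction *exactly* Bernoulli(p), which is
the quantity the screen consumes — so planted effect sizes translate
directly into proportion-table values with pure binomial noise.
Defaults: planted genes p_on = 0.8 / p_off = 0.02 with mean 4 reads
and dispersion 2; background genes p = 0.1, mean 2. Planted splits
are drawn uniformly over the 254 bipartitions.

Artifacts: non-neuronal contaminant cells (glial profile, no neuronal
markers — these make the marker-score distribution bimodal, as in real
dissociated ganglia, and are what the neuron gate exists to remove);
low-quality droplets, half with ~2% of a normal library (fail the
min-genes bound) and half with mitochondrial fraction ~Beta(20, 20)
(mean 50%, fail the mito bound); glial doublets with a full neuron
profile plus strong glial markers. Healthy cells draw mito fractions
from Beta(5, 95) (mean 5%, sd ≈ 2%), so they essentially never hit
the 15% bound. An optional per-batch multiplicative depth factor is
the only batch effect: the screen is binarized, so depth is the
relevant nuisance; batch integration methods are out of scope.

What the generator does **not** emulate: ambient RNA, UMI collisions,
read-level error, gene–gene correlation structure, or continuous
cell-state gradients within groups. Passing recovery tests therefore
demonstrates correctness of the scoring/gating machinery under the
stated generative model, not robustness to every artifact of real
droplet data.

`recommended_qc_params` maps QC bounds onto the simulation's scale by
placing the min-genes bound at 40% of the expected detected-gene count
of a healthy simulated cell — the analogue of the 1500-gene bound for
a real library.

## Problem sizes and determinism

Test and demo runs use the scaled-down group sizes (or 200 cells per
group for recovery checks) with 50 planted + 500 background genes;
at this size the full 254-split screen over ~570 genes takes about a
second. All randomness flows from one `numpy` Generator seeded from
the config, and pipeline outputs are content-digested in
`manifest.json`; identical config + seed reproduces identical bytes.

## Known limitations

* The screen performs no multiple-testing correction or null
  calibration, matching its original design as a ranking device.
* Score ties are resolved by a fixed but arbitrary rule; alternative
  rules permute tied neighbors only.
* The fixed neuron threshold of 3 is meaningful only on a
  variance-stabilized normalization scale (see above).
* `classify_split` with a role map lacking parasympathetic groups
  treats patterns II/IV/V as unreachable rather than erroring.
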