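# dichoscreen

Marker screening for single-cell RNA-seq by **dichotomized expression
patterns**: given a cell × gene count matrix whose cells carry group
labels (here: four autonomic ganglia and four pelvic neuron clusters),
the package scores every gene against every ordered bipartition of the
groups and ranks the genes that most cleanly separate one subset of
groups from its complement. It was built for the question of whether
pelvic ganglion neurons are transcriptionally sympathetic,
parasympathetic, or something else — but the screen itself applies to
any labeled cluster set.

## The score

For a gene with expressing-cell fraction $p_i$ in group $i$ (a cell
"expresses" a gene if it has ≥ 1 read), and an ordered split of the
$G$ groups into $S_1$ and $S_2$:

$$
\mathrm{score} \;=\; \frac{1}{|S_1|}\sum_{i \in S_1} \log_2\!\big(\varepsilon_{pos} - 1 + p_i\big)
\;-\; \frac{1}{|S_2|}\sum_{j \in S_2} \log_2\!\big(\varepsilon_{neg} + p_j\big)
$$

with defaults $\varepsilon_{pos} = 0.9$, $\varepsilon_{neg} = 0.02$.
Each group contributes with equal weight regardless of its cell count.
Whenever some $S_1$ group has $p_i \le 1 - \varepsilon_{pos}$ (≤ 10% at
the default), the first log argument is non-positive and the gene
receives the minimal possible score ($-\infty$) for that split: a gene
must be expressed in more than 10% of cells of *every* $S_1$ group to
be a candidate. With 8 groups there are $2^8 - 2 = 254$ ordered
splits; the screen evaluates all of them for every gene and keeps the
top-K genes (default 100), each with its best-scoring split.

Each top gene's best split is then classified into one of seven
patterns (I–VII, else "other"): sympathetic-and-pelvic (I),
parasympathetic-not-pelvic (II), sympathetic-not-pelvic (III),
parasympathetic-and-some-pelvic (IV), cholinergic (V, tracks the
cholinergic pelvic clusters), noradrenergic (VI), and pelvic-specific
(VII, expression or absence exclusive to pelvic clusters).

The package also implements the upstream gating that produces the
neuron-only matrix: droplet QC (more than 1500 detected genes, fewer
than 11000, mitochondrial fraction below 15% — all strict), neuron
selection by mean normalized expression of Stmn2/Stmn3/Gap43/Tubb3
over a threshold, and glial-doublet exclusion by
Plp1/Ttyh1/Fabp7/Cryab/Mal. A seeded synthetic-data generator plants
genes with known dichotomous patterns plus QC artifacts, so the whole
pipeline is testable without any download.

## Worked example

```python
import dichoscreen as d
from dichoscreen import synth

cfg = d.default_sim_config(n_planted=5, n_background_genes=300, seed=1, scale=0.1)
adata = d.generate_counts(cfg)                 # labeled counts, 8 groups
table = d.binarize_and_tabulate(adata)         # expressing fractions per group
ranked = d.top_genes(d.screen_all(table), d.ScreenConfig(top_k=5),
                     group_order=table.groups)
roles = synth.role_map(cfg)
for s in ranked:
    label = d.classify_split(s.split, roles)
    print(f"{s.gene:12s} {s.score:7.3f}  {label:5s}  S1={','.join(s.split.subset_1)}")
```

prints

```
planted002     4.391  VII    S1=P3,P4
planted001     4.035  other  S1=sphenopalatine,stellate,P4
planted003     3.828  other  S1=stellate,P1,P2,P3,P4
planted000     3.771  other  S1=sphenopalatine,lumbar,P1,P2,P3
planted004     3.688  other  S1=sphenopalatine,lumbar
```

All five planted genes are recovered with their true split as the
top-scoring one. `planted002` sits on a pelvic-only split, hence
pattern VII; the other planted splits cut across sympathetic ganglia,
hence "other". Scores around 4 reflect a clean 0.8-vs-0.02
expressing-fraction dichotomy blurred only by sampling noise.

The same pipeline runs from the shell:

```sh
dichoscreen demo --out demo_run --seed 3        # simulate → qc → screen → patterns
dichoscreen screen --counts DIR --eps-pos 0.9 --eps-nega 0.02 --top 100 --out scores.tsv
dichoscreen run --config cfg.yaml --out out_dir # full pipeline from a YAML config
```

A `demo_run` directory contains `scores.tsv` (ranked genes with their
best split), `patterns.tsv` and `tally.json` (pattern classification
and counts), `qc_report.json` (exact per-stage retention bookkeeping),
and `manifest.json` (content digests; identical seeds reproduce
identical digests).

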