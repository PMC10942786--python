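"""Synthetic labeled count matrices with planted dichotomous patterns.

Emulates the input to the autonomic-ganglion screen: eight labeled cell
groups (three sympathetic ganglia, one parasympathetic ganglion, four
pelvic clusters) across two batches, with

* background genes expressed at a baseline fraction in every group,
* planted genes whose expressing-cell fraction is high in every group
  of a chosen bipartition's subset_1 and low in subset_2,
* neuronal and glial marker genes,
* mitochondrial genes driven by a per-cell Beta-distributed mito
  fraction, and
* QC artifacts: low-quality droplets (tiny libraries or high mito
  load) and glial-containing doublets (neuron + glial markers).

Counts follow a gated negative binomial: a Bernoulli gate decides
whether a cell expresses the gene at all, and expressing cells draw
``1 + NB`` so the expressing fraction equals the gate probability
exactly.  Everything is driven by one seeded generator, so a fixed
seed yields byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from . import io as dio
from .patterns import GroupRoleMap, classify_split
from .screen import Bipartition

__all__ = [
    "GroupSpec",
    "PlantedGene",
    "SimConfig",
    "default_groups",
    "default_sim_config",
    "role_map",
    "generate_counts",
    "planted_truth",
    "recommended_qc_params",
    "write_simulation",
]


@dataclass(frozen=True)
class GroupSpec:
    name: str
    role: str  # sympathetic | parasympathetic | pelvic_cluster
    n_cells: int
    batch: str = "batch1"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"group {self.name!r}: n_cells must be >= 1")


@dataclass(frozen=True)
class PlantedGene:
    """A gene expressed in a high fraction (p_on) of cells in every
    subset_1 group of its split and a low fraction (p_off) elsewhere."""

    gene_id: str
    split: Bipartition
    p_on: float = 0.8
    p_off: float = 0.02
    mean_on: float = 4.0
    dispersion: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_on <= 1.0) or not (0.0 <= self.p_off < 1.0):
            raise ValueError(f"{self.gene_id}: need 0 < p_on <= 1 and 0 <= p_off < 1")
        if self.p_on <= self.p_off:
            raise ValueError(f"{self.gene_id}: p_on must exceed p_off")
        if self.mean_on <= 0:
            raise ValueError(f"{self.gene_id}: mean_on must be > 0")


@dataclass(frozen=True)
class SimConfig:
    groups: tuple[GroupSpec, ...]
    planted: tuple[PlantedGene, ...] = ()
    n_background_genes: int = 500
    background_p: float = 0.1
    background_mean: float = 2.0
    dispersion: float = 2.0
    mito_gene_count: int = 10
    # Beta(a, b) per-cell mito fraction: healthy cells centre on 5%
    # with sd ~2%, so they essentially never hit the 15% QC bound
    mito_fraction_params: tuple[float, float] = (5.0, 95.0)
    lowquality_mito_params: tuple[float, float] = (20.0, 20.0)
    neuron_marker_ids: tuple[str, ...] = ("Stmn2", "Stmn3", "Gap43", "Tubb3")
    glial_marker_ids: tuple[str, ...] = ("Plp1", "Ttyh1", "Fabp7", "Cryab", "Mal")
    marker_mean: float = 8.0
    n_nonneuron_cells: int = 0
    n_lowquality_droplets: int = 0
    n_glial_doublets: int = 0
    batch_depth_factors: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        ids: list[str] = [p.gene_id for p in self.planted]
        ids += list(self.neuron_marker_ids) + list(self.glial_marker_ids)
        ids += [f"mt-{i}" for i in range(self.mito_gene_count)]
        ids += [f"bg{i:04d}" for i in range(self.n_background_genes)]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"gene identifier lists overlap: {dup}")
        for p in self.planted:
            unknown = set(p.split.groups) - set(names)
            if unknown:
                raise ValueError(
                    f"planted gene {p.gene_id} references unknown groups {sorted(unknown)}"
                )


# Default sizes follow realistic per-ganglion neuron counts scaled
# down 4x for speed, preserving the strong group-size imbalance; the
# pooled pelvic neurons are split evenly across the four clusters.
def default_groups(scale: float = 0.25) -> tuple[GroupSpec, ...]:
    base = [
        ("sphenopalatine", "parasympathetic", 1857, "batch1"),
        ("stellate", "sympathetic", 2689, "batch1"),
        ("coeliac", "sympathetic", 236, "batch2"),
        ("lumbar", "sympathetic", 925, "batch2"),
        ("P1", "pelvic_cluster", 306, "batch1"),
        ("P2", "pelvic_cluster", 306, "batch1"),
        ("P3", "pelvic_cluster", 306, "batch2"),
        ("P4", "pelvic_cluster", 305, "batch2"),
    ]
    return tuple(
        GroupSpec(n, r, max(1, round(c * scale)), b) for n, r, c, b in base
    )


def role_map(config: SimConfig) -> GroupRoleMap:
    """Role map implied by the config's group specs; the neurotransmitter
    partition of pelvic clusters uses the conventional P1/P2/P4
    (cholinergic) vs P3 (noradrenergic) assignment where those names
    exist."""
    roles = {g.name: g.role for g in config.groups}
    pelvic = {g.name for g in config.groups if g.role == "pelvic_cluster"}
    return GroupRoleMap(
        roles=roles,
        cholinergic_pelvic=frozenset(pelvic & {"P1", "P2", "P4"}),
        noradrenergic_pelvic=frozenset(pelvic & {"P3"}),
    )


def default_sim_config(
    n_planted: int = 50,
    n_background_genes: int = 500,
    n_nonneuron_cells: int = 0,
    n_lowquality_droplets: int = 0,
    n_glial_doublets: int = 0,
    seed: int = 0,
    scale: float = 0.25,
    p_on: float = 0.8,
    p_off: float = 0.02,
) -> SimConfig:
    """Standard simulation: default groups plus ``n_planted`` genes on
    splits drawn uniformly from the 254 bipartitions."""
    groups = default_groups(scale)
    names = [g.name for g in groups]
    rng = np.random.default_rng(seed)
    n_splits = (1 << len(names)) - 2
    planted = []
    for k in range(n_planted):
        mask = int(rng.integers(1, n_splits + 1))
        s1 = tuple(g for i, g in enumerate(names) if mask >> i & 1)
        s2 = tuple(g for i, g in enumerate(names) if not mask >> i & 1)
        planted.append(
            PlantedGene(f"planted{k:03d}", Bipartition(s1, s2), p_on=p_on, p_off=p_off)
        )
    return SimConfig(
        groups=groups,
        planted=tuple(planted),
        n_background_genes=n_background_genes,
        n_nonneuron_cells=n_nonneuron_cells,
        n_lowquality_droplets=n_lowquality_droplets,
        n_glial_doublets=n_glial_doublets,
        seed=seed,
    )


def _gene_ids(config: SimConfig) -> tuple[list[str], dict[str, slice]]:
    planted = [p.gene_id for p in config.planted]
    bg = [f"bg{i:04d}" for i in range(config.n_background_genes)]
    mito = [f"mt-{i}" for i in range(config.mito_gene_count)]
    neuron = list(config.neuron_marker_ids)
    glial = list(config.glial_marker_ids)
    ids = planted + bg + neuron + glial + mito
    bounds = {}
    start = 0
    for name, block in (
        ("planted", planted),
        ("background", bg),
        ("neuron", neuron),
        ("glial", glial),
        ("mito", mito),
    ):
        bounds[name] = slice(start, start + len(block))
        start += len(block)
    return ids, bounds


def _gated_nb(rng, n: int, p_expr: float, mean: float, dispersion: float) -> np.ndarray:
    """Counts with expressing fraction exactly Bernoulli(p_expr): a cell
    either has zero reads or 1 + NB(mean - 1, dispersion) reads."""
    gate = rng.random(n) < p_expr
    counts = np.zeros(n, dtype=np.int64)
    k = int(gate.sum())
    if k:
        m = max(mean - 1.0, 1e-9)
        nb = rng.negative_binomial(dispersion, dispersion / (dispersion + m), size=k)
        counts[gate] = 1 + nb
    return counts


def generate_counts(config: SimConfig) -> AnnData:
    """Simulate the full labeled matrix, artifacts included.

    Cell order: the real neurons group by group, then non-neuronal
    contaminants, then low-quality droplets, then glial doublets.
    Ground-truth artifact flags live in ``obs["is_nonneuron"]``,
    ``obs["is_lowquality"]`` and ``obs["is_glial_doublet"]``.
    """
    rng = np.random.default_rng(config.seed)
    ids, bounds = _gene_ids(config)
    n_genes = len(ids)

    real_cells = sum(g.n_cells for g in config.groups)
    n_total = (
        real_cells
        + config.n_nonneuron_cells
        + config.n_lowquality_droplets
        + config.n_glial_doublets
    )

    X = np.zeros((n_total, n_genes), dtype=np.int64)
    group_lab = np.empty(n_total, dtype=object)
    batch_lab = np.empty(n_total, dtype=object)
    is_nonneuron = np.zeros(n_total, dtype=bool)
    is_lowq = np.zeros(n_total, dtype=bool)
    is_doublet = np.zeros(n_total, dtype=bool)

    group_of = {g.name: g for g in config.groups}

    def fill_cells(
        rows: np.ndarray,
        group: GroupSpec,
        library_scale: float = 1.0,
        neuron_p: float = 0.995,
        glial_p: float = 0.0,
        planted_off: bool = False,
    ):
        n = len(rows)
        depth = config.batch_depth_factors.get(group.batch, 1.0) * library_scale
        detect = min(1.0, library_scale * 2)  # shallow libraries detect less
        for j, p in enumerate(config.planted):
            in_s1 = (not planted_off) and group.name in p.split.subset_1
            prob = p.p_on if in_s1 else p.p_off
            X[rows, j] = _gated_nb(
                rng, n, min(1.0, prob * detect), p.mean_on * depth, p.dispersion
            )
        b = bounds["background"]
        for j in range(b.start, b.stop):
            X[rows, j] = _gated_nb(
                rng, n, config.background_p * detect,
                config.background_mean * depth, config.dispersion,
            )
        for j in range(bounds["neuron"].start, bounds["neuron"].stop):
            X[rows, j] = _gated_nb(
                rng, n, min(1.0, neuron_p * detect),
                config.marker_mean * depth, config.dispersion,
            )
        if glial_p > 0:
            for j in range(bounds["glial"].start, bounds["glial"].stop):
                X[rows, j] = _gated_nb(
                    rng, n, min(1.0, glial_p * detect),
                    config.marker_mean * depth, config.dispersion,
                )
        group_lab[rows] = group.name
        batch_lab[rows] = group.batch

    row = 0
    for g in config.groups:
        rows = np.arange(row, row + g.n_cells)
        fill_cells(rows, g)
        row += g.n_cells

    group_names = [g.name for g in config.groups]

    def random_group() -> GroupSpec:
        return group_of[group_names[int(rng.integers(len(group_names)))]]

    # non-neuronal contaminants (glia etc.): pass droplet QC but show
    # no neuronal markers; they make the marker-score distribution
    # bimodal, as in real dissociated ganglia
    for _ in range(config.n_nonneuron_cells):
        rows = np.array([row])
        fill_cells(rows, random_group(), neuron_p=0.01, glial_p=0.995, planted_off=True)
        is_nonneuron[row] = True
        row += 1

    # low-quality droplets: half near-empty (fail the min-genes
    # predicate), half with a high mitochondrial load (fail mito)
    for k in range(config.n_lowquality_droplets):
        rows = np.array([row])
        fill_cells(rows, random_group(), library_scale=0.02 if k % 2 == 0 else 1.0)
        is_lowq[row] = True
        row += 1

    # glial doublets: a normal neuron profile plus strong glial markers
    for _ in range(config.n_glial_doublets):
        rows = np.array([row])
        fill_cells(rows, random_group(), glial_p=0.995)
        is_doublet[row] = True
        row += 1

    # mitochondrial counts: per-cell fraction f (Beta) converted to a
    # mito total matching f relative to the cell's final library size
    a, b_ = config.mito_fraction_params
    frac = rng.beta(a, b_, size=n_total)
    la, lb = config.lowquality_mito_params
    # odd-indexed low-quality droplets carry the high-mito fraction
    lowq_rows = np.flatnonzero(is_lowq)
    high_mito = lowq_rows[1::2]
    frac[high_mito] = rng.beta(la, lb, size=len(high_mito))
    if config.mito_gene_count > 0:
        nonmito_tot = X.sum(axis=1)
        mito_tot = np.round(frac / (1.0 - frac) * nonmito_tot).astype(np.int64)
        msl = bounds["mito"]
        for i in range(n_total):
            if mito_tot[i] > 0:
                X[i, msl] = rng.multinomial(
                    mito_tot[i], np.full(config.mito_gene_count, 1.0 / config.mito_gene_count)
                )

    obs = pd.DataFrame(
        {
            "group": group_lab.astype(str),
            "batch": batch_lab.astype(str),
            "is_nonneuron": is_nonneuron,
            "is_lowquality": is_lowq,
            "is_glial_doublet": is_doublet,
        },
        index=pd.Index([f"cell-{i:06d}" for i in range(n_total)], name="barcode"),
    )
    var = pd.DataFrame(index=pd.Index(ids, name="gene"))
    var["gene_id"] = ids
    var["mito"] = [i.startswith("mt-") for i in ids]
    var["marker_class"] = "none"
    var.iloc[bounds["planted"], var.columns.get_loc("marker_class")] = "planted"
    var.iloc[bounds["neuron"], var.columns.get_loc("marker_class")] = "neuron"
    var.iloc[bounds["glial"], var.columns.get_loc("marker_class")] = "glial"

    return AnnData(X=sp.csr_matrix(X), obs=obs, var=var)


def planted_truth(config: SimConfig) -> dict[str, tuple[Bipartition, str]]:
    """Ground truth for recovery checks: each planted gene's split and
    the pattern label that split classifies to."""
    roles = role_map(config)
    return {
        p.gene_id: (p.split, classify_split(p.split, roles)) for p in config.planted
    }


def recommended_qc_params(config: SimConfig, **overrides):
    """QC thresholds matched to the simulation's scale.

    The droplet gene-count bounds are placed relative to the expected
    number of detected genes in a healthy simulated cell (roughly
    background_p x n_background_genes plus markers and planted genes),
    so that the near-empty planted droplets fail the lower bound the
    same way real empty droplets fail the standard 1500-gene bound.
    """
    from .qc import QCParams

    expected = (
        config.background_p * config.n_background_genes
        + sum(
            (p.p_on * len(p.split.subset_1) + p.p_off * len(p.split.subset_2))
            / max(1, len(p.split.groups))
            for p in config.planted
        )
        + len(config.neuron_marker_ids)
        + config.mito_gene_count
    )
    defaults = dict(
        min_genes_exclusive=max(3, int(0.4 * expected)),
        max_genes_exclusive=int(20 * expected + 100),
        max_mito_fraction=0.15,
        neuron_markers=config.neuron_marker_ids,
        glial_markers=config.glial_marker_ids,
        # the conventional fixed marker threshold refers to the SCT scale;
        # on this generator's log1p scale the bimodal rule is the
        # appropriate default
        neuron_threshold="auto",
        glial_threshold="auto",
    )
    defaults.update(overrides)
    return QCParams(**defaults)


def write_simulation(config: SimConfig, out_dir, compress: bool = False) -> Path:
    """Generate and write the triplet + labels.tsv + truth.json."""
    adata = generate_counts(config)
    out = dio.write_cellranger_mtx(adata, out_dir, compress=compress)
    truth = {
        gene: {"subset_1": list(split.subset_1), "subset_2": list(split.subset_2), "pattern": label}
        for gene, (split, label) in planted_truth(config).items()
    }
    with open(Path(out) / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
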