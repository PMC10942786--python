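"""Dichotomized expression screen.

Binarizes a labeled count matrix into per-group expressing-cell
proportions, enumerates every ordered bipartition of the cell groups,
scores each (gene, split) pair, and ranks the top discriminating genes.

The score for a gene on an ordered split (S1, S2) is

    score = (1/|S1|) * sum_{i in S1} log2(eps_pos - 1 + p_i)
          - (1/|S2|) * sum_{j in S2} log2(eps_nega + p_j)

where p_i is the fraction of cells in group i with at least one read of
the gene.  With the default eps_pos = 0.9, any S1 group whose expressing
fraction is 0.1 or lower drives the log argument to zero or below: the
gene then receives the minimal possible score (-inf) for that split.
eps_nega > 0 keeps the S2 terms finite; small values penalize any
expression on the S2 side harshly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData

__all__ = [
    "Bipartition",
    "ScoreParams",
    "ScreenConfig",
    "GeneSplitScore",
    "ProportionTable",
    "binarize_and_tabulate",
    "enumerate_bipartitions",
    "score_gene_split",
    "screen_all",
    "top_genes",
    "write_scores_tsv",
]


# The penalty boundary (expressing fraction == 1 - eps_pos) is an exact
# rational statement; eps_pos - 1 + p can round to ~1e-17 instead of 0,
# so arguments this close to zero are treated as zero (-> -inf score).
_BOUNDARY_TOL = 1e-12


@dataclass(frozen=True, order=True)
class Bipartition:
    """Ordered split of the group set into (subset_1, subset_2).

    subset_1 is the side where expression is rewarded, subset_2 the side
    where it is penalized; a split and its complement are distinct.
    """

    subset_1: tuple[str, ...]
    subset_2: tuple[str, ...]

    def __post_init__(self) -> None:
        s1, s2 = set(self.subset_1), set(self.subset_2)
        if not s1 or not s2:
            raise ValueError("both sides of a bipartition must be nonempty")
        if s1 & s2:
            raise ValueError(f"subsets overlap: {sorted(s1 & s2)}")

    @property
    def n_s1(self) -> int:
        return len(self.subset_1)

    @property
    def n_s2(self) -> int:
        return len(self.subset_2)

    @property
    def groups(self) -> tuple[str, ...]:
        return self.subset_1 + self.subset_2

    def mask(self, group_order: Sequence[str]) -> int:
        """Bitmask encoding of subset_1 over ``group_order`` (bit i = group i)."""
        s1 = set(self.subset_1)
        return sum(1 << i for i, g in enumerate(group_order) if g in s1)


@dataclass(frozen=True)
class ScoreParams:
    """Score offsets.  eps_pos sets the hard floor on subset_1 expressing
    fractions (fractions <= 1 - eps_pos force -inf); eps_nega floors the
    subset_2 penalty term."""

    eps_pos: float = 0.9
    eps_nega: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 < self.eps_pos <= 1.0):
            raise ValueError(f"eps_pos must be in (0, 1], got {self.eps_pos}")
        if self.eps_nega <= 0.0:
            raise ValueError(f"eps_nega must be > 0, got {self.eps_nega}")


@dataclass(frozen=True)
class ScreenConfig:
    top_k: int = 100
    dedup: bool = True

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass(frozen=True)
class GeneSplitScore:
    """One scored (gene, split) pair.  ``margin`` is the separation
    min(subset_1 proportions) - max(subset_2 proportions), kept for
    tie-breaking in :func:`top_genes`."""

    gene: str
    split: Bipartition
    score: float
    margin: float = float("nan")


class ProportionTable:
    """Per-(gene, group) expressing-cell tallies.

    Holds, for each gene and group, the number of cells with >= 1 read
    (``num_expr``), the per-group cell counts (``ncells``) and their
    ratio (``prop``).
    """

    def __init__(self, num_expr: pd.DataFrame, ncells: pd.Series):
        if list(num_expr.columns) != list(ncells.index):
            raise ValueError("num_expr columns must match ncells index")
        if (ncells < 1).any():
            raise ValueError("every group needs at least one cell")
        self.num_expr = num_expr
        self.ncells = ncells.astype(int)
        self.prop = num_expr / self.ncells

    @property
    def groups(self) -> list[str]:
        return list(self.num_expr.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.num_expr.index)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ProportionTable({len(self.genes)} genes x "
            f"{len(self.groups)} groups)"
        )


def binarize_and_tabulate(adata: AnnData, group_key: str = "group") -> ProportionTable:
    """Count expressing cells (count >= 1) per gene and group.

    Parameters
    ----------
    adata
        Cell x gene count matrix with a categorical group label in
        ``adata.obs[group_key]``.
    group_key
        Column of ``adata.obs`` holding the group label.
    """
    if group_key not in adata.obs:
        raise ValueError(f"missing obs column {group_key!r}")
    labels = adata.obs[group_key]
    if labels.isna().any():
        bad = adata.obs_names[labels.isna()].tolist()
        raise ValueError(f"unlabeled cells: {bad}")

    X = adata.X
    expressed = (X > 0).astype(np.int64)
    groups = pd.unique(labels.astype(str))
    cols: dict[str, np.ndarray] = {}
    ncells: dict[str, int] = {}
    lab = labels.astype(str).to_numpy()
    for g in groups:
        sel = lab == g
        sub = expressed[sel]
        counts = np.asarray(sub.sum(axis=0)).ravel()
        cols[g] = counts
        ncells[g] = int(sel.sum())
    num_expr = pd.DataFrame(cols, index=adata.var_names)
    return ProportionTable(num_expr, pd.Series(ncells))


def enumerate_bipartitions(groups: Sequence[str]) -> list[Bipartition]:
    """All 2^G - 2 ordered splits of ``groups``, in ascending-bitmask
    order of subset_1 (bit i of the mask selects ``groups[i]``)."""
    groups = list(groups)
    if len(set(groups)) != len(groups):
        raise ValueError("group names must be unique")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n = len(groups)
    out = []
    for mask in range(1, (1 << n) - 1):
        s1 = tuple(g for i, g in enumerate(groups) if mask >> i & 1)
        s2 = tuple(g for i, g in enumerate(groups) if not mask >> i & 1)
        out.append(Bipartition(s1, s2))
    return out


def score_gene_split(
    props: "pd.Series | dict[str, float]",
    split: Bipartition,
    params: ScoreParams = ScoreParams(),
) -> float:
    """Score one gene on one ordered split from its per-group expressing
    fractions.  Returns -inf when any subset_1 fraction is at or below
    1 - eps_pos."""
    if isinstance(props, dict):
        props = pd.Series(props)
    missing = [g for g in split.groups if g not in props.index]
    if missing:
        raise ValueError(f"groups missing from proportions: {missing}")

    pos_args = params.eps_pos - 1.0 + props[list(split.subset_1)].to_numpy(float)
    if np.any(pos_args <= _BOUNDARY_TOL):
        return float("-inf")
    neg_args = params.eps_nega + props[list(split.subset_2)].to_numpy(float)
    return float(np.mean(np.log2(pos_args)) - np.mean(np.log2(neg_args)))


def screen_all(
    table: ProportionTable,
    params: ScoreParams = ScoreParams(),
) -> list[GeneSplitScore]:
    """Score every gene on every ordered bipartition of the table's groups.

    Vectorized over genes: per-group log terms are precomputed once and
    combined per split.  Equivalent to calling :func:`score_gene_split`
    for each (gene, split) pair.
    """
    groups = table.groups
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    P = table.prop.to_numpy(float)  # genes x groups
    genes = table.genes
    splits = enumerate_bipartitions(groups)

    with np.errstate(divide="ignore", invalid="ignore"):
        Lpos = np.log2(params.eps_pos - 1.0 + P)
    # arguments <= 0 force the minimal score for any split putting that
    # group in subset_1
    Lpos[(params.eps_pos - 1.0 + P) <= _BOUNDARY_TOL] = -np.inf
    Lneg = np.log2(params.eps_nega + P)

    idx = {g: i for i, g in enumerate(groups)}
    out: list[GeneSplitScore] = []
    for split in splits:
        i1 = [idx[g] for g in split.subset_1]
        i2 = [idx[g] for g in split.subset_2]
        scores = Lpos[:, i1].mean(axis=1) - Lneg[:, i2].mean(axis=1)
        # -inf - (-inf) etc. cannot occur: Lneg is finite (eps_nega > 0)
        margins = P[:, i1].min(axis=1) - P[:, i2].max(axis=1)
        for k, gene in enumerate(genes):
            out.append(GeneSplitScore(gene, split, float(scores[k]), float(margins[k])))
    return out


def top_genes(
    scores: Iterable[GeneSplitScore],
    config: ScreenConfig = ScreenConfig(),
    group_order: Sequence[str] | None = None,
) -> list[GeneSplitScore]:
    """Rank scored pairs descending and truncate to ``config.top_k``.

    With ``config.dedup`` each gene keeps only its best-scoring split.
    Ties are broken by larger proportion margin, then by the split's
    bitmask encoding, then by gene identifier.  Entries with score -inf
    never outrank finite ones and are dropped from the ranking.
    """
    scores = list(scores)
    if not scores:
        return []
    if group_order is None:
        seen: list[str] = []
        for s in scores:
            for g in s.split.groups:
                if g not in seen:
                    seen.append(g)
        group_order = sorted(seen)

    def sort_key(s: GeneSplitScore):
        margin = s.margin if np.isfinite(s.margin) else -np.inf
        return (-s.score, -margin, s.split.mask(group_order), s.gene)

    ranked = sorted(scores, key=sort_key)
    if config.dedup:
        best: dict[str, GeneSplitScore] = {}
        for s in ranked:
            if s.gene not in best:
                best[s.gene] = s
        ranked = sorted(best.values(), key=sort_key)
    ranked = [s for s in ranked if np.isfinite(s.score)]
    return ranked[: config.top_k]


def write_scores_tsv(ranked: Sequence[GeneSplitScore], path) -> pd.DataFrame:
    """Write a ranked score list as a TSV (gene, subset_1, subset_2,
    score, rank); returns the frame written."""
    rows = [
        {
            "gene": s.gene,
            "subset_1": ";".join(s.split.subset_1),
            "subset_2": ";".join(s.split.subset_2),
            "score": "-inf" if s.score == float("-inf") else s.score,
            "rank": i + 1,
        }
        for i, s in enumerate(ranked)
    ]
    df = pd.DataFrame(rows, columns=["gene", "subset_1", "subset_2", "score", "rank"])
    df.to_csv(path, sep="\t", index=False)
    return df
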