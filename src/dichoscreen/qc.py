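"""Droplet QC, neuron selection, and glial-doublet exclusion.

The screen operates on neurons only.  Three sequential gates produce
them from a raw droplet matrix:

1. :func:`filter_droplets` — keep droplets with more than
   ``min_genes_exclusive`` detected genes (count >= 1), fewer than
   ``max_genes_exclusive``, and a mitochondrial read fraction below
   ``max_mito_fraction``.  All three inequalities are strict.
2. :func:`select_neurons` — keep cells whose mean normalized expression
   over the neuronal markers (Stmn2, Stmn3, Gap43, Tubb3 by default)
   exceeds a threshold; ``"auto"`` picks the threshold that best
   separates the bimodal marker-score distribution (Otsu).
3. :func:`exclude_glial_doublets` — drop cells whose mean normalized
   glial-marker expression (Plp1, Ttyh1, Fabp7, Cryab, Mal) exceeds a
   threshold, removing droplets that contain glial material alongside
   a neuron.

Normalization here is depth-scaling to the median library size followed
by log1p; the neuron threshold default of 3 refers to a
variance-stabilized scale, so when using this normalization prefer
``"auto"`` or a value calibrated to your data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from skimage.filters import threshold_otsu

from .io import FormatError, read_cellranger_mtx  # re-exported entry point

__all__ = [
    "QCParams",
    "QCReport",
    "read_cellranger_mtx",
    "FormatError",
    "filter_droplets",
    "normalize",
    "select_neurons",
    "exclude_glial_doublets",
    "run_qc",
]

DEFAULT_NEURON_MARKERS = ("Stmn2", "Stmn3", "Gap43", "Tubb3")
DEFAULT_GLIAL_MARKERS = ("Plp1", "Ttyh1", "Fabp7", "Cryab", "Mal")


@dataclass(frozen=True)
class QCParams:
    min_genes_exclusive: int = 1500
    max_genes_exclusive: int = 11000
    max_mito_fraction: float = 0.15
    neuron_markers: tuple[str, ...] = DEFAULT_NEURON_MARKERS
    neuron_threshold: "float | str" = 3.0
    glial_markers: tuple[str, ...] = DEFAULT_GLIAL_MARKERS
    glial_threshold: "float | str" = "auto"
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if not (0 < self.min_genes_exclusive < self.max_genes_exclusive):
            raise ValueError("need 0 < min_genes_exclusive < max_genes_exclusive")
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValueError("max_mito_fraction must be in [0, 1]")
        for name in ("neuron_threshold", "glial_threshold"):
            v = getattr(self, name)
            if isinstance(v, str) and v != "auto":
                raise ValueError(f"{name} must be a number or 'auto'")
        object.__setattr__(self, "neuron_markers", tuple(self.neuron_markers))
        object.__setattr__(self, "glial_markers", tuple(self.glial_markers))


@dataclass
class QCReport:
    """Bookkeeping for one filtering stage: exact per-cell flags plus
    retained/removed tallies (n_input = n_retained + n_removed)."""

    stage: str
    n_input: int
    n_retained: int
    flags: pd.DataFrame  # per-cell booleans, one column per predicate + "pass"
    removed_per_predicate: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_removed": self.n_removed,
            "removed_per_predicate": self.removed_per_predicate,
            "thresholds": self.thresholds,
            "warnings": self.warnings,
        }


def _detected_genes(X) -> np.ndarray:
    return np.asarray((X > 0).sum(axis=1)).ravel()


def _mito_mask(adata: AnnData, prefix: str) -> np.ndarray:
    if "mito" in adata.var:
        return adata.var["mito"].to_numpy(bool)
    return adata.var_names.str.startswith(prefix).to_numpy()


def filter_droplets(
    adata: AnnData, params: QCParams = QCParams()
) -> tuple[AnnData, QCReport]:
    """Apply the three droplet-quality predicates (strict inequalities)."""
    X = adata.X
    n_genes = _detected_genes(X)
    total = np.asarray(X.sum(axis=1)).ravel().astype(float)
    mito = _mito_mask(adata, params.mito_prefix)
    warnings = []
    if mito.any():
        mito_counts = np.asarray(X[:, mito].sum(axis=1)).ravel().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.divide(
                mito_counts, total, out=np.zeros_like(mito_counts), where=total > 0
            )
        mito_ok = mito_frac < params.max_mito_fraction
    else:
        warnings.append("no mitochondrial genes flagged; mito predicate passes vacuously")
        mito_frac = np.zeros(adata.n_obs)
        mito_ok = np.ones(adata.n_obs, dtype=bool)

    flags = pd.DataFrame(
        {
            "min_genes": n_genes > params.min_genes_exclusive,
            "max_genes": n_genes < params.max_genes_exclusive,
            "mito_fraction": mito_ok,
        },
        index=adata.obs_names,
    )
    flags["pass"] = flags.all(axis=1)
    keep = flags["pass"].to_numpy()
    report = QCReport(
        stage="filter_droplets",
        n_input=adata.n_obs,
        n_retained=int(keep.sum()),
        flags=flags,
        removed_per_predicate={c: int((~flags[c]).sum()) for c in ("min_genes", "max_genes", "mito_fraction")},
        thresholds={
            "min_genes_exclusive": params.min_genes_exclusive,
            "max_genes_exclusive": params.max_genes_exclusive,
            "max_mito_fraction": params.max_mito_fraction,
        },
        warnings=warnings,
    )
    out = adata[keep].copy()
    out.obs["mito_fraction"] = mito_frac[keep]
    return out, report


def normalize(adata: AnnData, method: str = "median_log1p") -> AnnData:
    """Depth-normalize counts; the result keeps raw counts in
    ``layers["counts"]`` and the normalized values in ``X``.

    ``median_log1p`` scales each cell to the median library size and
    applies log1p, which removes a pure depth factor between otherwise
    identical cells.
    """
    if method != "median_log1p":
        raise ValueError(f"unknown normalization method {method!r}")
    X = adata.X
    counts = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr().copy()
    total = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    target = float(np.median(total[total > 0])) if (total > 0).any() else 1.0
    scale = np.divide(target, total, out=np.zeros_like(total), where=total > 0)
    norm = sp.diags(scale) @ counts.astype(float)
    norm.data = np.log1p(norm.data)
    out = AnnData(X=norm.tocsr(), obs=adata.obs.copy(), var=adata.var.copy())
    out.layers["counts"] = counts.astype(np.int64)
    return out


def _marker_score(adata: AnnData, markers: Sequence[str]) -> np.ndarray:
    present = [m for m in markers if m in adata.var_names]
    if not present:
        raise ValueError(f"none of the markers {list(markers)} present in the matrix")
    sub = adata[:, present].X
    return np.asarray(sub.mean(axis=1)).ravel()


def _auto_threshold(scores: np.ndarray) -> float:
    """Threshold minimizing within-class variance of the score histogram
    (Otsu); degenerates to max(scores) when the scores are constant, so
    that nothing is selected above it."""
    if scores.size == 0:
        return float("inf")
    if np.ptp(scores) == 0:
        return float(scores.max())
    return float(threshold_otsu(scores, nbins=256))


def select_neurons(
    adata: AnnData, params: QCParams = QCParams()
) -> tuple[AnnData, QCReport]:
    """Keep cells whose mean normalized neuronal-marker expression
    strictly exceeds the threshold.  Expects a normalized matrix (see
    :func:`normalize`)."""
    scores = _marker_score(adata, params.neuron_markers)
    thr = (
        _auto_threshold(scores)
        if params.neuron_threshold == "auto"
        else float(params.neuron_threshold)
    )
    flags = pd.DataFrame({"neuron_score": scores > thr}, index=adata.obs_names)
    flags["pass"] = flags["neuron_score"]
    keep = flags["pass"].to_numpy()
    report = QCReport(
        stage="select_neurons",
        n_input=adata.n_obs,
        n_retained=int(keep.sum()),
        flags=flags,
        removed_per_predicate={"neuron_score": int((~keep).sum())},
        thresholds={"neuron_threshold": thr, "auto": params.neuron_threshold == "auto"},
    )
    out = adata[keep].copy()
    out.obs["neuron_score"] = scores[keep]
    return out, report


def exclude_glial_doublets(
    adata: AnnData, params: QCParams = QCParams()
) -> tuple[AnnData, QCReport]:
    """Remove cells whose mean normalized glial-marker expression
    strictly exceeds the threshold."""
    scores = _marker_score(adata, params.glial_markers)
    thr = (
        _auto_threshold(scores)
        if params.glial_threshold == "auto"
        else float(params.glial_threshold)
    )
    flags = pd.DataFrame({"glial_score": scores <= thr}, index=adata.obs_names)
    flags["pass"] = flags["glial_score"]
    keep = flags["pass"].to_numpy()
    report = QCReport(
        stage="exclude_glial_doublets",
        n_input=adata.n_obs,
        n_retained=int(keep.sum()),
        flags=flags,
        removed_per_predicate={"glial_score": int((~keep).sum())},
        thresholds={"glial_threshold": thr, "auto": params.glial_threshold == "auto"},
    )
    out = adata[keep].copy()
    out.obs["glial_score"] = scores[keep]
    return out, report


def counts_view(adata: AnnData) -> AnnData:
    """Labeled count matrix from a normalized object (raw counts back
    into X), for downstream binarized screening."""
    if "counts" not in adata.layers:
        return adata
    out = AnnData(X=adata.layers["counts"].copy(), obs=adata.obs.copy(), var=adata.var.copy())
    return out


def run_qc(
    adata: AnnData, params: QCParams = QCParams()
) -> tuple[AnnData, list[QCReport]]:
    """Full gate sequence: droplet filter -> normalize -> neuron
    selection -> glial-doublet exclusion.  Returns the neuron-only
    count matrix and the per-stage reports."""
    filtered, rep1 = filter_droplets(adata, params)
    norm = normalize(filtered)
    neurons, rep2 = select_neurons(norm, params)
    clean, rep3 = exclude_glial_doublets(neurons, params)
    return counts_view(clean), [rep1, rep2, rep3]
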