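"""Reading and writing CellRanger-style Matrix Market triplets.

The on-disk layout mirrors a CellRanger ``filtered_feature_bc_matrix``
directory: ``matrix.mtx`` (features x barcodes, integer counts),
``features.tsv`` (id, name, feature type) and ``barcodes.tsv``, each
optionally gzip-compressed, plus an optional ``labels.tsv`` sidecar
(barcode, group, batch; tab-separated with header) carrying the
per-cell group assignment.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData


class FormatError(ValueError):
    """Raised when a triplet file is missing or inconsistent."""


def _find(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FormatError(f"missing {stem}[.gz] in {directory}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_cellranger_mtx(
    path,
    labels: "str | Path | None" = None,
    sample_label: str | None = None,
    mito_prefix: str = "mt-",
) -> AnnData:
    """Load a triplet directory into a cells x genes AnnData.

    Group/batch labels come from ``labels`` (or ``<path>/labels.tsv`` if
    present); otherwise every cell gets the constant ``sample_label``.
    Genes whose name starts with ``mito_prefix`` are flagged in
    ``var["mito"]``.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise FormatError(f"not a directory: {directory}")
    mtx_path = _find(directory, "matrix.mtx")
    feat_path = _find(directory, "features.tsv")
    bc_path = _find(directory, "barcodes.tsv")

    with _open_text(mtx_path) as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csr_matrix(mat)
    if not np.issubdtype(mat.dtype, np.integer):
        if np.any(mat.data != np.round(mat.data)):
            raise FormatError(f"non-integer values in {mtx_path.name}")
        mat = mat.astype(np.int64)

    features = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)
    if features.shape[0] != mat.shape[0]:
        raise FormatError(
            f"{feat_path.name} has {features.shape[0]} rows but "
            f"{mtx_path.name} has {mat.shape[0]} feature rows"
        )
    if barcodes.shape[0] != mat.shape[1]:
        raise FormatError(
            f"{bc_path.name} has {barcodes.shape[0]} rows but "
            f"{mtx_path.name} has {mat.shape[1]} barcode columns"
        )

    gene_names = features.iloc[:, 1] if features.shape[1] > 1 else features.iloc[:, 0]
    var = pd.DataFrame(index=pd.Index(gene_names.to_numpy(), name="gene"))
    var["gene_id"] = features.iloc[:, 0].to_numpy()
    var["mito"] = var.index.str.startswith(mito_prefix)
    obs = pd.DataFrame(index=pd.Index(barcodes.iloc[:, 0].to_numpy(), name="barcode"))

    adata = AnnData(X=sp.csr_matrix(mat.T), obs=obs, var=var)

    labels_path = Path(labels) if labels is not None else directory / "labels.tsv"
    if labels_path.exists():
        lab = pd.read_csv(labels_path, sep="\t", dtype=str)
        required = {"barcode", "group"}
        if not required <= set(lab.columns):
            raise FormatError(f"{labels_path.name} must have columns barcode, group")
        lab = lab.set_index("barcode")
        missing = adata.obs_names.difference(lab.index)
        if len(missing):
            raise FormatError(
                f"{labels_path.name} lacks labels for {len(missing)} barcodes "
                f"(e.g. {list(missing[:3])})"
            )
        adata.obs["group"] = lab.loc[adata.obs_names, "group"].to_numpy()
        if "batch" in lab.columns:
            adata.obs["batch"] = lab.loc[adata.obs_names, "batch"].to_numpy()
    elif labels is not None:
        raise FormatError(f"labels file not found: {labels_path}")
    elif sample_label is not None:
        adata.obs["group"] = sample_label
    return adata


def write_cellranger_mtx(adata: AnnData, path, compress: bool = False) -> Path:
    """Write an AnnData as a triplet directory (plus labels.tsv when the
    cells carry group labels).  Returns the directory path."""
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if compress else ""

    mat = sp.coo_matrix(adata.X.T)

    def _writer(name: str):
        p = directory / (name + suffix)
        return (gzip.open(p, "wb") if compress else open(p, "wb")), p

    fh, _ = _writer("matrix.mtx")
    with fh:
        scipy.io.mmwrite(fh, mat, field="integer")

    feat = pd.DataFrame(
        {
            "id": adata.var.get("gene_id", pd.Series(adata.var_names, index=adata.var_names)),
            "name": adata.var_names,
            "type": "Gene Expression",
        }
    )
    fh, _ = _writer("features.tsv")
    with fh:
        feat.to_csv(fh, sep="\t", header=False, index=False)
    fh, _ = _writer("barcodes.tsv")
    with fh:
        pd.Series(adata.obs_names).to_csv(fh, sep="\t", header=False, index=False)

    if "group" in adata.obs:
        lab = pd.DataFrame(
            {
                "barcode": adata.obs_names,
                "group": adata.obs["group"].astype(str).to_numpy(),
                "batch": adata.obs.get(
                    "batch", pd.Series("batch1", index=adata.obs_names)
                ).astype(str).to_numpy(),
            }
        )
        lab.to_csv(directory / "labels.tsv", sep="\t", index=False)
    return directory
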