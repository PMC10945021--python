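"""Reading count matrices and cell annotations, assembling labeled datasets.

Convention throughout the package: rows are cells, columns are genes.  The
on-disk 10x triplet (MatrixMarket matrix + features/genes TSV + barcodes
TSV) is usually stored genes x cells; orientation is detected from the TSV
lengths and the matrix transposed as needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "CellAnnotation",
    "LabeledDataset",
    "CONTROL_SENTINEL",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_counts_table",
    "read_annotations",
    "write_annotations",
    "assemble_dataset",
    "write_signature_table",
    "SIGNATURE_COLUMNS",
]

#: target_gene value marking a negative-control cell
CONTROL_SENTINEL = "none"

SIGNATURE_COLUMNS = ["gene", "attribution", "mean_rank", "sd_rank",
                     "log2fc", "direction", "stable"]


@dataclass
class CountMatrix:
    """Cells x genes matrix of raw UMI counts with identifiers."""

    values: np.ndarray          # (n_cells, n_genes) nonnegative integers
    gene_ids: list[str]
    barcodes: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.gene_ids = list(self.gene_ids)
        self.barcodes = list(self.barcodes)
        n, d = self.values.shape
        if len(self.barcodes) != n or len(self.gene_ids) != d:
            raise ValueError(
                f"matrix is {n}x{d} but got {len(self.barcodes)} barcodes "
                f"and {len(self.gene_ids)} gene ids"
            )
        if len(set(self.gene_ids)) != d:
            raise ValueError("gene_ids are not unique")
        if len(set(self.barcodes)) != n:
            raise ValueError("barcodes are not unique")
        if np.any(self.values < 0):
            raise ValueError("counts contain negative entries")
        if not np.all(np.isfinite(self.values.astype(float))):
            raise ValueError("counts contain non-finite entries")
        if not np.allclose(self.values, np.round(self.values.astype(float))):
            raise ValueError("counts contain non-integer entries")
        self.values = self.values.astype(np.int64)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CellAnnotation:
    """Per-cell metadata: assigned gRNA, its target, and the culture condition."""

    barcode: str
    grna_id: str
    target_gene: str
    condition: str

    @property
    def is_control(self) -> bool:
        return self.target_gene == CONTROL_SENTINEL


@dataclass
class LabeledDataset:
    """Controls + targeted cells of one (target gene, condition) pair.

    ``X`` holds raw counts (float for the model), ``Y`` is 0 for control
    cells and 1 for gRNA-targeted cells; controls come first.
    """

    X: np.ndarray
    Y: np.ndarray
    gene_ids: list[str]
    target_gene: str
    condition: str
    barcodes: list[str]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=int)
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y length mismatch")
        if self.X.shape[1] != len(self.gene_ids):
            raise ValueError("X columns do not match gene_ids")
        if not (np.any(self.Y == 0) and np.any(self.Y == 1)):
            raise ValueError("both classes must be non-empty")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def control_indices(self) -> np.ndarray:
        return np.flatnonzero(self.Y == 0)

    @property
    def targeted_indices(self) -> np.ndarray:
        return np.flatnonzero(self.Y == 1)


def _read_single_column(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].tolist()


def _find(directory: Path, names: tuple[str, ...], what: str) -> Path:
    for name in names:
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"no {what} file in {directory} (tried {names})")


def read_counts_mtx(directory) -> CountMatrix:
    """Read a 10x-style triplet directory into a cells x genes CountMatrix.

    Expects ``matrix.mtx``, a features/genes TSV and a barcodes TSV.
    Orientation on disk (genes x cells vs cells x genes) is resolved by
    matching matrix dimensions against the TSV lengths; square ambiguous
    matrices default to the 10x convention (genes x cells).
    """
    directory = Path(directory)
    mtx_path = _find(directory, ("matrix.mtx", "matrix.mtx.gz"), "matrix")
    feat_path = _find(directory, ("features.tsv", "features.tsv.gz",
                                  "genes.tsv", "genes.tsv.gz"), "features")
    bc_path = _find(directory, ("barcodes.tsv", "barcodes.tsv.gz"), "barcodes")

    mat = scipy.io.mmread(mtx_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    genes = _read_single_column(feat_path)
    barcodes = _read_single_column(bc_path)

    n_genes, n_cells = len(genes), len(barcodes)
    if mat.shape == (n_genes, n_cells):
        mat = mat.T
    elif mat.shape != (n_cells, n_genes):
        raise ValueError(
            f"matrix shape {mat.shape} matches neither "
            f"(cells={n_cells}, genes={n_genes}) nor its transpose"
        )
    return CountMatrix(values=mat, gene_ids=genes, barcodes=barcodes)


def write_counts_mtx(counts: CountMatrix, directory) -> None:
    """Write the 10x triplet (genes x cells on disk, per convention)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(directory / "matrix.mtx",
                     scipy.sparse.coo_matrix(counts.values.T))
    pd.Series(counts.gene_ids).to_csv(directory / "features.tsv",
                                      sep="\t", index=False, header=False)
    pd.Series(counts.barcodes).to_csv(directory / "barcodes.tsv",
                                      sep="\t", index=False, header=False)


def read_counts_table(path) -> CountMatrix:
    """Dense CSV/TSV alternative: rows = cells (index column), columns = genes."""
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return CountMatrix(values=df.to_numpy(),
                       gene_ids=[str(c) for c in df.columns],
                       barcodes=[str(i) for i in df.index])


REQUIRED_ANNOTATION_COLUMNS = ("barcode", "grna_id", "target_gene", "condition")


def read_annotations(path) -> list[CellAnnotation]:
    """Read the per-cell annotation TSV.

    Required columns: barcode, grna_id, target_gene, condition.  Cells with
    ``target_gene == "none"`` are negative controls.  Duplicate barcodes are
    rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table is missing columns: {missing}")
    dupes = df["barcode"][df["barcode"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate barcodes in annotations: {list(dupes)[:5]}")
    return [
        CellAnnotation(barcode=row.barcode, grna_id=row.grna_id,
                       target_gene=row.target_gene, condition=row.condition)
        for row in df.itertuples(index=False)
    ]


def write_annotations(annotations: list[CellAnnotation], path) -> None:
    pd.DataFrame(
        [(a.barcode, a.grna_id, a.target_gene, a.condition) for a in annotations],
        columns=list(REQUIRED_ANNOTATION_COLUMNS),
    ).to_csv(path, sep="\t", index=False)


def assemble_dataset(counts: CountMatrix, annotations: list[CellAnnotation],
                     target_gene: str, condition: str,
                     normalize: bool = False) -> LabeledDataset:
    """Build the labeled dataset for one (target gene, condition) pair.

    Controls are cells carrying a negative-control gRNA in the requested
    condition; targeted cells carry a gRNA against ``target_gene`` in the
    same condition.  Cells targeted for other genes are never reused as
    controls.  ``X`` holds raw counts by default; ``normalize=True`` applies
    per-cell library-size scaling (to the median library size) followed by
    log1p, for robustness experiments.
    """
    by_barcode = {a.barcode: a for a in annotations}
    ctrl_idx, tgt_idx = [], []
    for i, bc in enumerate(counts.barcodes):
        a = by_barcode.get(bc)
        if a is None or a.condition != condition:
            continue
        if a.is_control:
            ctrl_idx.append(i)
        elif a.target_gene == target_gene:
            tgt_idx.append(i)
    if not ctrl_idx:
        raise ValueError(
            f"no control cells for condition {condition!r}")
    if not tgt_idx:
        raise ValueError(
            f"no cells targeted for {target_gene!r} in condition {condition!r}")
    order = ctrl_idx + tgt_idx
    X = counts.values[order].astype(float)
    if normalize:
        lib = X.sum(axis=1)
        lib[lib == 0] = 1.0
        X = np.log1p(X / lib[:, None] * np.median(lib))
    Y = np.concatenate([np.zeros(len(ctrl_idx), dtype=int),
                        np.ones(len(tgt_idx), dtype=int)])
    return LabeledDataset(
        X=X, Y=Y, gene_ids=list(counts.gene_ids), target_gene=target_gene,
        condition=condition, barcodes=[counts.barcodes[i] for i in order],
    )


def write_signature_table(signature: pd.DataFrame, path) -> None:
    """Write a signature table as TSV, sorted by mean rank ascending."""
    if signature is None or len(signature) == 0:
        raise ValueError("signature is empty")
    missing = [c for c in SIGNATURE_COLUMNS if c not in signature.columns]
    if missing:
        raise ValueError(f"signature table is missing columns: {missing}")
    out = signature[SIGNATURE_COLUMNS].sort_values(
        "mean_rank", kind="mergesort").reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False)
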