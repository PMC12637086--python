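"""Core in-memory containers for the pipeline.

Two matrices travel through the single-cell branch of the pipeline:

``CountMatrix``
    Raw UMI counts, genes x cells, with per-cell metadata (sample,
    timepoint).  Counts are kept sparse (CSR) because UMI matrices are
    >90% zeros at realistic depth.

``LTQMatrix``
    Log transcription quotients: a denoised natural-log estimate of each
    gene's fraction of a cell's transcriptome, plus one mean sampling
    error per gene.  Dense, because denoised values are nonzero
    everywhere.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite


class EmptyResultError(RuntimeError):
    """Raised when a filter removes every cell (or gene)."""


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        raise ValueError(f"{what} ids are not unique")


@dataclass
class CountMatrix:
    """Integer UMI counts, genes x cells, with cell metadata.

    ``cell_meta`` is indexed by ``cell_ids`` and carries at least
    ``sample`` and ``timepoint`` columns when produced by the simulator.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.cell_meta is None or len(self.cell_meta) == 0:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids))
        else:
            self.cell_meta = self.cell_meta.loc[self.cell_ids]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_detected_per_cell(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def cells_detected_per_gene(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        m = self.counts
        genes, cells, meta = self.gene_ids, self.cell_ids, self.cell_meta
        if gene_mask is not None:
            m = m[gene_mask, :]
            genes = genes[gene_mask]
        if cell_mask is not None:
            m = m[:, cell_mask]
            cells = cells[cell_mask]
            meta = meta.iloc[np.where(cell_mask)[0]] if np.asarray(cell_mask).dtype == bool else meta.iloc[cell_mask]
        return CountMatrix(sp.csr_matrix(m), genes, cells, meta.copy())

    # ------------------------------------------------------------------ io
    def write_mtx(self, outdir: str | Path) -> None:
        """Write the MTX triplet (matrix.mtx, features.tsv, barcodes.tsv)
        plus metadata.csv, mirroring the CellRanger directory layout."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mmwrite(outdir / "matrix.mtx", self.counts.tocoo())
        pd.Series(self.gene_ids).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
        pd.Series(self.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
        meta = self.cell_meta.copy()
        meta.insert(0, "cell_id", self.cell_ids)
        meta.to_csv(outdir / "metadata.csv", index=False)

    @classmethod
    def read_mtx(cls, indir: str | Path) -> "CountMatrix":
        indir = Path(indir)
        counts = sp.csr_matrix(mmread(indir / "matrix.mtx"))
        genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].to_numpy(dtype=object)
        cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].to_numpy(dtype=object)
        meta_path = indir / "metadata.csv"
        meta = pd.DataFrame(index=pd.Index(cells))
        if meta_path.exists():
            meta = pd.read_csv(meta_path).set_index("cell_id")
            meta.index = meta.index.astype(object)
        return cls(counts, genes, cells, meta)

    @classmethod
    def read_csv(cls, path: str | Path, meta: pd.DataFrame | None = None) -> "CountMatrix":
        """Dense CSV, genes as rows (index), cells as columns."""
        df = pd.read_csv(path, index_col=0)
        return cls(
            sp.csr_matrix(df.to_numpy()),
            df.index.to_numpy(dtype=object),
            df.columns.to_numpy(dtype=object),
            meta if meta is not None else pd.DataFrame(index=df.columns),
        )


@dataclass
class LTQMatrix:
    """Log transcription quotients (natural log) with per-gene mean
    sampling error."""

    ltq: np.ndarray  # genes x cells, dense
    gene_error: np.ndarray  # per gene, >= 0
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.ltq = np.asarray(self.ltq, dtype=float)
        self.gene_error = np.asarray(self.gene_error, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if not np.all(np.isfinite(self.ltq)):
            raise ValueError("LTQ values must be finite")
        if np.any(self.gene_error < 0):
            raise ValueError("gene_error must be >= 0")
        if self.ltq.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("ltq shape does not match id lengths")
        if self.cell_meta is None or len(self.cell_meta) == 0:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids))

    @property
    def n_genes(self) -> int:
        return self.ltq.shape[0]

    @property
    def n_cells(self) -> int:
        return self.ltq.shape[1]

    def subset(self, gene_mask=None, cell_mask=None) -> "LTQMatrix":
        ltq, err = self.ltq, self.gene_error
        genes, cells, meta = self.gene_ids, self.cell_ids, self.cell_meta
        if gene_mask is not None:
            ltq, err, genes = ltq[gene_mask, :], err[gene_mask], genes[gene_mask]
        if cell_mask is not None:
            idx = np.where(cell_mask)[0] if np.asarray(cell_mask).dtype == bool else np.asarray(cell_mask)
            ltq, cells = ltq[:, idx], cells[idx]
            meta = meta.iloc[idx]
        return LTQMatrix(ltq.copy(), err.copy(), genes, cells, meta.copy())

    def write_csv(self, path: str | Path, error_path: str | Path | None = None) -> None:
        df = pd.DataFrame(self.ltq, index=self.gene_ids, columns=self.cell_ids)
        if str(path).endswith(".gz"):
            import gzip

            # fixed mtime so identical runs give identical bytes
            with open(path, "wb") as raw, gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as fh:
                df.to_csv(fh)
        else:
            df.to_csv(path)
        if error_path is not None:
            pd.DataFrame({"gene": self.gene_ids, "gene_error": self.gene_error}).to_csv(
                error_path, index=False
            )

    @classmethod
    def read_csv(cls, path: str | Path, error_path: str | Path) -> "LTQMatrix":
        df = pd.read_csv(path, index_col=0)
        err = pd.read_csv(error_path).set_index("gene")["gene_error"]
        return cls(
            df.to_numpy(),
            err.loc[df.index].to_numpy(),
            df.index.to_numpy(dtype=object),
            df.columns.to_numpy(dtype=object),
        )
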