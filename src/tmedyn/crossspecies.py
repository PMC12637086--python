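"""Cross-species comparison of tumor cellular composition.

Mouse and human tumors differ systematically in immune composition
(e.g. more neutrophils in human, more lymphocytes in mouse), so
log-transformed compositions are centered within each species before a
joint PCA; samples are weighted by the inverse of their species' sample
count so both species contribute equally to the principal components
regardless of cohort size.  A pseudo-bulk per-sample TPM utility
supports gene-level dynamics comparisons against bulk profiling
studies (TPM here is the UMI fraction x 1e6; no gene-length term, as
appropriate for 3'-counted UMI data).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .hierarchy import PCAProjection


def validate_composition(comp: pd.DataFrame) -> None:
    vals = comp.to_numpy(dtype=float)
    if np.any(vals < -1e-12):
        raise ValueError("fractions must be >= 0")
    if np.any(np.abs(vals.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("composition rows must sum to 1")


def log_center_by_species(
    comp: pd.DataFrame,
    species: pd.Series,
    zero_floor: float | None = None,
    return_floored: bool = False,
):
    """log(fraction + floor), then per-species column centering.

    ``comp``: samples x cell types (rows sum to 1); ``species``: per
    sample.  The zero floor defaults to half the smallest nonzero
    fraction in the table; floored entries are flagged."""
    validate_composition(comp)
    vals = comp.to_numpy(dtype=float)
    nonzero = vals[vals > 0]
    if zero_floor is None:
        zero_floor = float(nonzero.min()) / 2.0 if nonzero.size else 1e-6
    floored = int((vals < zero_floor).sum())
    logged = np.log(np.clip(vals, zero_floor, None))
    out = pd.DataFrame(logged, index=comp.index, columns=comp.columns)
    sp = pd.Series(species).reindex(comp.index)
    for s in sp.unique():
        m = (sp == s).to_numpy()
        out.iloc[m] = out.iloc[m] - out.iloc[m].mean(axis=0)
    return (out, {"floor": zero_floor, "n_floored": floored}) if return_floored else out


def species_weights(species: pd.Series) -> pd.Series:
    """Per-sample weight 1 / (number of samples of that species)."""
    sp = pd.Series(species)
    counts = sp.value_counts()
    return sp.map(lambda s: 1.0 / counts[s]).astype(float)


def weighted_pca(centered: pd.DataFrame, weights: pd.Series | np.ndarray) -> PCAProjection:
    """PCA of the weighted covariance sum_s w_s x_s x_s^T / sum_s w_s.

    Input is assumed centered (see :func:`log_center_by_species`).
    Scores are the projections of all samples on the eigenvectors; the
    eigenvalues are the variance explained.  Duplicating a sample while
    halving its weight leaves the PCs unchanged."""
    X = centered.to_numpy(dtype=float) if isinstance(centered, pd.DataFrame) else np.asarray(centered, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    C = (X.T * w) @ X / w.sum()
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    flip = np.sign(evecs[np.abs(evecs).argmax(axis=0), np.arange(evecs.shape[1])])
    flip[flip == 0] = 1.0
    evecs = evecs * flip[None, :]
    return PCAProjection(scores=X @ evecs, loadings=evecs, variance_explained=evals)


def pseudobulk_tpm(counts: CountMatrix, group: str = "sample") -> pd.DataFrame:
    """Gene x sample TPM: per group of cells, summed UMIs per gene
    scaled to a library size of one million."""
    if group not in counts.cell_meta.columns:
        raise ValueError(f"cell metadata lacks column {group!r}")
    groups = counts.cell_meta[group]
    out = {}
    for g in pd.unique(groups):
        m = (groups == g).to_numpy()
        if m.sum() == 0:
            continue
        s = np.asarray(counts.counts[:, m].sum(axis=1)).ravel().astype(float)
        total = s.sum()
        if total == 0:
            raise ValueError(f"group {g!r} has zero total UMIs")
        out[g] = s / total * 1e6
    if not out:
        raise ValueError("no non-empty groups")
    return pd.DataFrame(out, index=counts.gene_ids)
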