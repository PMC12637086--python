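"""Per-cell fitness scores from CRISPR-screen gene effects.

A genome-wide CRISPR screen under cytotoxic-T-cell selection assigns
each gene a NormZ score: the z-scale selective advantage of knocking
the gene out.  Weighting each gene's NormZ by its expression in a
single cell (its LTQ) gives a transcriptome-based fitness score per
cell: ``score_c = sum_g ltq_gc * normz_g`` over the shared gene
universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .containers import LTQMatrix


def load_normz(table: pd.DataFrame | str) -> pd.Series:
    """Validate a (gene, normz) table: finite, one value per gene."""
    df = pd.read_csv(table) if isinstance(table, (str,)) else pd.DataFrame(table)
    if df["gene"].duplicated().any():
        raise ValueError("duplicate gene ids in NormZ table")
    s = df.set_index("gene")["normz"].astype(float)
    if not np.all(np.isfinite(s.to_numpy())):
        raise ValueError("NormZ values must be finite")
    return s


def fitness_scores(
    ltq: LTQMatrix,
    normz: pd.DataFrame | pd.Series,
    center_genes: bool = False,
    return_n_shared: bool = False,
):
    """Dot product of per-cell LTQs with per-gene NormZ over the id
    intersection of the two gene universes.

    LTQs enter as-is on the natural-log scale by default;
    ``center_genes=True`` subtracts each gene's mean first (the variant
    where only expression deviations contribute)."""
    nz = normz if isinstance(normz, pd.Series) else load_normz(normz)
    gene_index = pd.Index(ltq.gene_ids)
    shared = gene_index.intersection(nz.index)
    if len(shared) == 0:
        raise ValueError("empty gene intersection between LTQ matrix and NormZ table")
    gidx = gene_index.get_indexer(shared)
    L = ltq.ltq[gidx, :]
    if center_genes:
        L = L - L.mean(axis=1, keepdims=True)
    scores = pd.Series(nz.loc[shared].to_numpy() @ L, index=ltq.cell_ids, name="fitness")
    return (scores, len(shared)) if return_n_shared else scores


def archetype_fitness_test(
    scores: np.ndarray | pd.Series,
    distances: np.ndarray,
    frac: float = 0.05,
) -> dict:
    """Rank-sum comparison of fitness in the ``frac`` closest cells to a
    target archetype vs all other cells (two-sided; the direction of
    the difference is reported alongside)."""
    s = np.asarray(scores, dtype=float)
    d = np.asarray(distances, dtype=float)
    n = len(s)
    k = int(frac * n)
    if k < 3:
        raise ValueError(f"frac*n = {k} < 3 cells; increase n or frac")
    member = np.zeros(n, dtype=bool)
    member[np.argpartition(d, k - 1)[:k]] = True
    stat, p = mannwhitneyu(s[member], s[~member], alternative="two-sided")
    direction = "closest_higher" if np.median(s[member]) > np.median(s[~member]) else "closest_lower"
    return {"statistic": float(stat), "p": float(p), "direction": direction,
            "n_closest": int(k), "n_other": int(n - k)}
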