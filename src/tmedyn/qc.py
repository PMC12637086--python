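"""Quality filters and log-transcription-quotient (LTQ) estimation.

The LTQ estimator is a deliberately simple empirical-Bayes stand-in for
a full Bayesian Poisson-noise deconvolution: per gene, a Gaussian prior
on the log transcription quotient (the log fraction of the cell's
transcriptome) is combined with a Laplace (Gaussian) approximation to
the Poisson likelihood.  It honours the same contract — denoised
log-scale values plus one mean sampling-error bar per gene — without
claiming exactness of any particular external tool.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .containers import CountMatrix, EmptyResultError, LTQMatrix

MITO_PREFIX = "mt-"


def qc_filter(
    counts: CountMatrix,
    min_cells_per_gene: int = 5,
    min_genes_per_cell: int = 100,
    mito_frac_max: float = 0.125,
    mito_prefix: str = MITO_PREFIX,
    per_sample: bool = False,
    return_report: bool = False,
):
    """Remove low-quality genes and cells.

    Order of operations is fixed for reproducibility: (1) genes detected
    in fewer than ``min_cells_per_gene`` cells, (2) cells with fewer
    than ``min_genes_per_cell`` detected genes, (3) cells with a
    mitochondrial transcript fraction above ``mito_frac_max``
    (mitochondrial genes identified by id prefix).  The mito cutoff is
    applied globally by default; ``per_sample=True`` applies it within
    each sample (same threshold, useful when depth varies by sample).
    """
    report = {"n_genes_in": counts.n_genes, "n_cells_in": counts.n_cells}

    gene_keep = counts.cells_detected_per_gene() >= min_cells_per_gene
    report["genes_removed_min_cells"] = int((~gene_keep).sum())
    out = counts.subset(gene_mask=gene_keep)

    cell_keep = out.genes_detected_per_cell() >= min_genes_per_cell
    report["cells_removed_min_genes"] = int((~cell_keep).sum())
    out = out.subset(cell_mask=cell_keep)

    is_mito = np.array([str(g).startswith(mito_prefix) for g in out.gene_ids])
    totals = out.cell_totals().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            totals > 0,
            np.asarray(out.counts[is_mito, :].sum(axis=0)).ravel() / np.maximum(totals, 1.0),
            0.0,
        )
    # threshold is a constant, so the global and per-sample rules only
    # differ if a caller overrides it per sample later; both paths kept
    # for the documented switch
    mito_keep = mito_frac <= mito_frac_max
    if per_sample and "sample" in out.cell_meta.columns:
        mito_keep = np.ones(out.n_cells, dtype=bool)
        for s in out.cell_meta["sample"].unique():
            m = (out.cell_meta["sample"] == s).to_numpy()
            mito_keep[m] = mito_frac[m] <= mito_frac_max
    report["cells_removed_mito"] = int((~mito_keep).sum())
    out = out.subset(cell_mask=mito_keep)

    report["n_genes_out"] = out.n_genes
    report["n_cells_out"] = out.n_cells
    if out.n_cells == 0:
        raise EmptyResultError("QC filter removed every cell")
    return (out, report) if return_report else out


def estimate_ltq(
    counts: CountMatrix,
    pseudocount_prior: float = 0.5,
    min_prior_var: float = 1e-2,
) -> LTQMatrix:
    """Empirical-Bayes LTQ estimate with per-gene mean sampling error.

    Model: count ``n_gc ~ Poisson(N_c * q_gc)`` with ``x = log q``.  The
    likelihood is approximated as Gaussian in ``x`` with center
    ``log((n + pseudocount)/N)`` and precision ``n + pseudocount``
    (the Poisson Fisher information), and combined with a gene-wise
    prior ``N(mu_g, tau_g^2)`` fitted by moments: ``mu_g`` is the
    precision-weighted mean of the plug-in values and ``tau_g^2`` the
    across-cell variance in excess of the mean sampling variance,
    floored at ``min_prior_var``.  The posterior mean is the LTQ; the
    per-gene mean posterior sd is the error bar.
    """
    totals = counts.cell_totals().astype(float)
    if np.any(totals <= 0):
        raise EmptyResultError("zero-total cell present; run qc_filter first")

    n = np.asarray(counts.counts.todense(), dtype=float)  # genes x cells
    prec = n + pseudocount_prior  # likelihood precision per entry
    x_hat = np.log(prec) - np.log(totals)[None, :]

    w = prec / prec.sum(axis=1, keepdims=True)
    mu = (w * x_hat).sum(axis=1)
    resid_var = ((x_hat - mu[:, None]) ** 2 * w).sum(axis=1)
    mean_noise_var = (1.0 / prec).mean(axis=1)
    tau2 = np.maximum(resid_var - mean_noise_var, min_prior_var)

    post_prec = prec + (1.0 / tau2)[:, None]
    ltq = (mu[:, None] / tau2[:, None] + x_hat * prec) / post_prec
    # the error bar is the mean per-cell SAMPLING error (likelihood sd
    # ~ 1/sqrt(count)), the quantity the SNR gene filter divides by;
    # unlike the posterior sd it is independent of the prior strength
    # and shrinks with sequencing depth
    gene_error = np.sqrt(1.0 / prec).mean(axis=1)
    return LTQMatrix(ltq, gene_error, counts.gene_ids, counts.cell_ids, counts.cell_meta.copy())


def plugin_log_frequency(counts: CountMatrix, pseudocount: float = 0.5) -> np.ndarray:
    """Plain ``log((n + pseudocount) / N)`` — the un-shrunk comparator."""
    totals = counts.cell_totals().astype(float)
    n = np.asarray(counts.counts.todense(), dtype=float)
    return np.log(n + pseudocount) - np.log(totals)[None, :]


def snr_genes(ltq: LTQMatrix, threshold: float = 0.25) -> np.ndarray:
    """Indices of genes whose across-cell LTQ standard deviation exceeds
    ``threshold`` times their mean sampling error (SNR filter).  Genes
    with zero error but positive signal are kept (infinite SNR)."""
    sd = ltq.ltq.std(axis=1, ddof=1) if ltq.n_cells > 1 else np.zeros(ltq.n_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(ltq.gene_error > 0, sd / np.where(ltq.gene_error > 0, ltq.gene_error, 1.0), np.where(sd > 0, np.inf, 0.0))
    return np.where(snr > threshold)[0]


def low_rna_mask(totals: np.ndarray, mad_k: float = 3.0) -> np.ndarray:
    """Keep-mask over a vector of per-cell total UMI counts: flags the
    lower tail, ``log total < median - mad_k * MAD``.  MAD = 0 (all
    cells at equal depth) keeps every cell."""
    totals = np.asarray(totals, dtype=float)
    log_tot = np.log(np.maximum(totals, 1.0))
    med = np.median(log_tot)
    mad = np.median(np.abs(log_tot - med)) * 1.4826  # normal-consistent
    if mad == 0:
        return np.ones(len(totals), dtype=bool)
    return log_tot >= med - mad_k * mad


def low_rna_filter(counts: CountMatrix, mad_k: float = 3.0) -> np.ndarray:
    """Keep-mask over cells of ``counts`` (see :func:`low_rna_mask`).
    Run within the cell group under analysis — low RNA content is
    relative to the group, not global."""
    return low_rna_mask(counts.cell_totals(), mad_k=mad_k)
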