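"""Phenotype discretization, temporal prevalence/density summaries, and
small measurement utilities.

Discretization rules mirror the study design: sign of a time-associated
PC for 1D-continuum cell types, the positive-positive quadrant of the
first two PCs for cytotoxic T cells, a fixed LTQ threshold for the
bimodal IFN-response marker gene in cancer cells, and archetype
proximity for the macrophage simplex (see ``archetypes``).

Prevalences are normalized to the total number of cells sequenced at
each timepoint (not to the cell type), so phenotype dynamics and
cell-type abundance dynamics compose correctly; 1D phenotype densities
are scaled so the area under each curve equals the cell type's
prevalence at that timepoint.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde


# --------------------------------------------------------------------------
# discretization
# --------------------------------------------------------------------------
def discretize_pc_sign(scores: np.ndarray, pc_index: int = 0) -> np.ndarray:
    """{positive, negative} by the sign of one PC; an exact 0 counts as
    positive (documented tie rule)."""
    s = np.atleast_2d(np.asarray(scores, dtype=float))[:, pc_index]
    return np.where(s >= 0, "positive", "negative").astype(object)


def discretize_tc(scores: np.ndarray) -> np.ndarray:
    """Cytotoxic T cells: 'cytotoxic_proliferative' iff PC1 > 0 and
    PC2 > 0 (strict), else 'other'."""
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    lab = (X[:, 0] > 0) & (X[:, 1] > 0)
    return np.where(lab, "cytotoxic_proliferative", "other").astype(object)


def discretize_threshold(ltq_gene: np.ndarray, threshold: float = -7.7) -> np.ndarray:
    """{high, low} around a fixed LTQ threshold (default -7.7, the
    bimodal split of the IFN-response marker in cancer cells); ties go
    to 'high'."""
    v = np.asarray(ltq_gene, dtype=float)
    return np.where(v >= threshold, "high", "low").astype(object)


# --------------------------------------------------------------------------
# prevalence and density over time
# --------------------------------------------------------------------------
def prevalence_over_time(
    phenotypes: pd.DataFrame,
    totals_per_timepoint: pd.Series | dict,
) -> pd.DataFrame:
    """Tidy (timepoint, phenotype, n, fraction) table.

    ``phenotypes`` needs columns 'phenotype' and 'timepoint'.  Fractions
    divide by ALL cells sequenced at the timepoint, so phenotypes of a
    single cell type remain comparable across timepoints with different
    type abundance.  Absent phenotype/timepoint combinations appear
    with fraction 0; an 'unlabeled' row absorbs the remainder so
    fractions sum to 1 per timepoint."""
    totals = pd.Series(totals_per_timepoint, dtype=float)
    df = phenotypes.copy()
    labels = sorted(df["phenotype"].unique())
    rows = []
    for tp, total in totals.items():
        sub = df[df["timepoint"] == tp]
        counted = 0
        for lab in labels:
            n = int((sub["phenotype"] == lab).sum())
            counted += n
            rows.append({"timepoint": tp, "phenotype": lab, "n": n,
                         "fraction": n / total if total else 0.0})
        rows.append({"timepoint": tp, "phenotype": "unlabeled",
                     "n": int(total - counted),
                     "fraction": (total - counted) / total if total else 0.0})
    return pd.DataFrame(rows)


def phenotype_density(
    scores_1d: np.ndarray,
    timepoints: np.ndarray,
    totals_per_timepoint: pd.Series | dict,
    bandwidth: float | str = "scott",
    grid: np.ndarray | None = None,
    grid_size: int = 200,
) -> pd.DataFrame:
    """Per-timepoint KDE curves over a 1D phenotype axis, scaled so each
    curve integrates to (cells of this type at t) / (all cells at t).
    Returns a tidy (timepoint, x, density) grid; timepoints with no
    cells get a flat zero curve."""
    s = np.asarray(scores_1d, dtype=float)
    tp = np.asarray(timepoints)
    totals = pd.Series(totals_per_timepoint, dtype=float)
    if grid is None:
        if len(s):
            lo, hi = s.min(), s.max()
            pad = 0.15 * (hi - lo + 1e-12)
            grid = np.linspace(lo - pad, hi + pad, grid_size)
        else:
            grid = np.linspace(-1, 1, grid_size)
    out = []
    for t, total in totals.items():
        vals = s[tp == t]
        frac = len(vals) / total if total else 0.0
        if len(vals) >= 2 and np.std(vals) > 0:
            dens = gaussian_kde(vals, bw_method=bandwidth)(grid) * frac
        else:
            dens = np.zeros_like(grid)
        for x, d in zip(grid, dens):
            out.append({"timepoint": t, "x": float(x), "density": float(d)})
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# measurement utilities
# --------------------------------------------------------------------------
def caliper_volume(L: float, l: float) -> float:
    """Tumor volume from caliper length L and width l:
    V = (1/6) * pi * L * l^2 (ellipsoid approximation)."""
    return np.pi / 6.0 * L * l**2


# --------------------------------------------------------------------------
# temporal pattern classification
# --------------------------------------------------------------------------
def classify_temporal_pattern(
    series,
    rise_factor: float = 2.0,
    peak_factor: float = 1.5,
    stable_cv_max: float = 0.25,
) -> str:
    """Classify a prevalence time series into one of the three study
    patterns (or 'other').

    Rules, checked in order and invariant to uniform rescaling:

    * stable_colonization — rise from the first timepoint (second value
      >= rise_factor * first, or first is 0 and second > 0) followed by
      a coefficient of variation over the later points <= stable_cv_max;
    * wave_like — an interior maximum >= peak_factor * both endpoints;
    * progressive_increase — monotone non-decreasing with last >=
      rise_factor * first (or first 0 and last > 0).
    """
    v = np.asarray(series, dtype=float)
    if len(v) < 3 or np.all(v == 0):
        return "other"

    rest = v[1:]
    rose = v[1] > 0 if v[0] == 0 else v[1] >= rise_factor * v[0]
    if rose and rest.mean() > 0 and rest.std(ddof=0) / rest.mean() <= stable_cv_max:
        return "stable_colonization"

    k = int(np.argmax(v))
    if 0 < k < len(v) - 1:
        ends = max(v[0], v[-1])
        if (ends == 0 and v[k] > 0) or (ends > 0 and v[k] >= peak_factor * ends):
            return "wave_like"

    monotone = np.all(np.diff(v) >= -1e-12 * max(v.max(), 1.0))
    total_rise = v[-1] > 0 if v[0] == 0 else v[-1] >= rise_factor * v[0]
    if monotone and total_rise:
        return "progressive_increase"
    return "other"
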