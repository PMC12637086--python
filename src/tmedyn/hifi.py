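"""Cell typing from multiplexed immunofluorescence intensity tables.

Log-transformed fluorescence intensities are bimodal — a negative and a
positive cell population per marker — with very different
positive-fractions across markers.  Plain centering/scaling would
center rare markers on their negative population and amplify noise, so
each channel is instead divided by the location of its *highest*
(rightmost) intensity mode, putting the positive population at ~1 and
negatives near 0.  For rare, nested markers the mode is searched only
within the parent-positive gate (e.g. T-cell markers within pan-immune
positive cells), mirroring how a cytometrist gates.

Typed clusters come from Leiden clustering on the first two PCs of the
scaled channels, with k = max(round(n_cells * 1e-3), 10) neighbors and
resolution 1, annotated by necessary/possible marker rules.
"""

from __future__ import annotations

import warnings
from graphlib import TopologicalSorter

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde, pearsonr

from .hierarchy import cluster_graph, run_pca

POSITIVITY_CUTOFF = 0.5  # scaled value separating the ~0 and ~1 populations


def find_high_mode(
    values: np.ndarray,
    bandwidth: float | str = "scott",
    min_prominence: float = 0.05,
    grid_size: int = 512,
) -> float:
    """Location of the rightmost (highest-intensity) KDE mode whose
    prominence exceeds ``min_prominence`` (relative to the maximum
    density); falls back to the global maximum when no prominent local
    maximum exists."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty input to find_high_mode")
    if v.size < 3 or np.std(v) == 0:
        return float(np.median(v))
    kde = gaussian_kde(v, bw_method=bandwidth)
    pad = 0.1 * (v.max() - v.min() + 1e-12)
    grid = np.linspace(v.min() - pad, v.max() + pad, grid_size)
    dens = kde(grid)
    peaks, _ = find_peaks(dens, prominence=min_prominence * dens.max())
    if len(peaks) == 0:
        return float(grid[np.argmax(dens)])
    return float(grid[peaks[-1]])


def _gating_order(gating: dict) -> list:
    """Topological order of markers: parents before children."""
    ts = TopologicalSorter()
    for child, parent in gating.items():
        if parent is not None:
            ts.add(child, parent)
    return list(ts.static_order())


def scale_markers(
    table: pd.DataFrame,
    gating: dict | None = None,
    bandwidth: float | str = "scott",
    min_prominence: float = 0.05,
    positivity_cutoff: float = POSITIVITY_CUTOFF,
    return_modes: bool = False,
):
    """Scale each channel by its gated high mode on the log1p scale.

    ``scaled = log1p(raw) / high_mode(log1p(raw) within gate)``.  The
    gate of a marker is the parent-positive cell set (scaled parent >
    ``positivity_cutoff``); parents are scaled before children.  A
    channel whose gate collapses to the global population (no gating or
    empty gate) is flagged in the returned mode table."""
    gating = gating or {}
    log_table = np.log1p(table.astype(float))
    order = _gating_order(gating)
    markers = [m for m in order if m in table.columns]
    markers += [m for m in table.columns if m not in markers]
    scaled = pd.DataFrame(index=table.index, columns=table.columns, dtype=float)
    modes = {}
    for m in markers:
        parent = gating.get(m)
        vals = log_table[m]
        gate_note = "global"
        if parent is not None and parent in scaled.columns and scaled[parent].notna().any():
            gate_mask = scaled[parent] > positivity_cutoff
            if gate_mask.sum() >= 10:
                vals = log_table.loc[gate_mask, m]
                gate_note = f"within {parent}+"
        mode = find_high_mode(vals.to_numpy(), bandwidth=bandwidth, min_prominence=min_prominence)
        if mode <= 0:
            warnings.warn(f"marker {m}: non-positive mode, channel left on log1p scale", stacklevel=2)
            mode = 1.0
            gate_note += " (fallback)"
        scaled[m] = log_table[m] / mode
        modes[m] = {"mode": mode, "gate": gate_note}
    mode_df = pd.DataFrame(modes).T
    return (scaled, mode_df) if return_modes else scaled


def hifi_k_neighbors(n_cells: int) -> int:
    """k = max(round(n_cells * 1e-3), 10)."""
    return max(int(round(n_cells * 1e-3)), 10)


def cluster_hifi(
    scaled: pd.DataFrame,
    n_pcs: int = 2,
    resolution: float = 1.0,
    seed: int = 0,
    positivity_cutoff: float = POSITIVITY_CUTOFF,
) -> pd.Series:
    """Leiden clustering of cells expressing at least one marker, on the
    first ``n_pcs`` PCs of the scaled channels.  Cells expressing no
    marker get label -1."""
    expressing = (scaled > positivity_cutoff).any(axis=1)
    X = scaled.loc[expressing].to_numpy()
    labels = pd.Series(-1, index=scaled.index, dtype=int, name="cluster")
    if expressing.sum() == 0:
        return labels
    pca = run_pca(X.T, n_pcs_max=n_pcs)
    k = hifi_k_neighbors(int(expressing.sum()))
    memb = cluster_graph(pca.scores[:, :n_pcs], k_neighbors=k, resolution=resolution, seed=seed)
    labels.loc[expressing] = memb
    return labels


def annotate_hifi(
    labels: pd.Series,
    scaled: pd.DataFrame,
    rules: dict,
    positivity_cutoff: float = POSITIVITY_CUTOFF,
) -> dict:
    """Annotate clusters by necessary/possible marker rules.

    A cluster matches a type iff its median scaled value exceeds the
    positivity cutoff for every necessary marker, and no marker outside
    the type's possible set is positive.  No match, or more than one
    match, yields "undetermined" (ambiguity warns, never guesses).

    ``rules``: type -> {"necessary": [...], "possible": [...]}; the
    possible set is in addition to the necessary one."""
    out = {}
    for c in sorted(set(labels) - {-1}):
        med = scaled.loc[labels == c].median(axis=0)
        positive = set(med.index[med > positivity_cutoff])
        matches = []
        for t, rule in rules.items():
            necessary = set(rule["necessary"])
            allowed = necessary | set(rule.get("possible", []))
            if necessary <= positive and positive <= allowed:
                matches.append(t)
        if len(matches) == 1:
            out[int(c)] = matches[0]
        else:
            if len(matches) > 1:
                warnings.warn(f"cluster {c} matches several types {matches}; undetermined", stacklevel=2)
            out[int(c)] = "undetermined"
    return out


def compare_compositions(
    hifi_fractions: pd.Series | dict,
    scrna_fractions: pd.Series | dict,
    floor: float | None = None,
) -> dict:
    """Compare log-transformed cell-type proportions between the imaging
    and scRNA-seq modalities (Pearson r on logs over the union of
    types; zero fractions floored at half the smallest nonzero fraction
    and flagged)."""
    h = pd.Series(hifi_fractions, dtype=float)
    s = pd.Series(scrna_fractions, dtype=float)
    types = h.index.union(s.index)
    h = h.reindex(types, fill_value=0.0)
    s = s.reindex(types, fill_value=0.0)
    nonzero = np.concatenate([h[h > 0].to_numpy(), s[s > 0].to_numpy()])
    if floor is None:
        floor = nonzero.min() / 2.0 if nonzero.size else 1e-6
    floored = sorted(set(types[h == 0]) | set(types[s == 0]))
    lh, ls = np.log(h.clip(lower=floor)), np.log(s.clip(lower=floor))
    if len(types) >= 2 and lh.std() > 0 and ls.std() > 0:
        r = float(pearsonr(lh, ls)[0])
    else:
        r = np.nan
    return {
        "pairs": pd.DataFrame({"log_hifi": lh, "log_scrna": ls}),
        "pearson_r": r,
        "floored_types": floored,
        "floor": float(floor),
    }
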