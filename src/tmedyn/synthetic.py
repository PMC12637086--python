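"""Synthetic single-cell tumor-microenvironment data with planted ground truth.

The generator emulates the data modalities of a longitudinal tumor
time-course study so every downstream stage (QC, normalization,
hierarchical typing, archetype analysis, fitness scoring, dynamics,
multiplexed-imaging typing) can be exercised against a known truth:

* multi-cell-type UMI counts with Poisson sampling noise around
  cell-specific log rates, log-normal cell size factors, and a reserved
  ``mt-`` mitochondrial gene subset;
* a simplex-shaped phenotypic continuum inside one designated cell type
  (cells are convex combinations of archetype expression profiles);
* a 1D phenotypic trajectory inside another cell type;
* per-timepoint cell-type compositions following one of three temporal
  patterns: stable colonization, wave-like, or progressive increase;
* bimodal log-intensity marker channels with gated (nested) marker
  subpopulations, standing in for segmented multiplexed-imaging data;
* per-gene CRISPR-screen NormZ scores enriched in a designated gene
  signature.

All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawning, so identical configs give
bitwise-identical outputs and the per-stage streams are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix

TEMPORAL_PATTERNS = ("stable_colonization", "wave_like", "progressive_increase", "other")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------
@dataclass
class CellTypeSpec:
    """One cell type: its per-timepoint fractional abundance, its marker
    genes, and its mean log-rate profile (natural log, later
    log-softmax-normalized per cell)."""

    name: str
    frac_per_timepoint: np.ndarray
    marker_genes: np.ndarray  # indices into the gene universe
    lograte: np.ndarray  # length n_genes
    pattern: str = "other"

    def __post_init__(self) -> None:
        self.frac_per_timepoint = np.asarray(self.frac_per_timepoint, dtype=float)
        self.marker_genes = np.asarray(self.marker_genes, dtype=int)
        self.lograte = np.asarray(self.lograte, dtype=float)
        if self.pattern not in TEMPORAL_PATTERNS:
            raise ValueError(f"unknown temporal pattern {self.pattern!r}")


@dataclass
class SimplexSpec:
    """A phenotypic continuum inside ``cell_type``: each cell's log-rate
    profile is a barycentric mixture of ``archetype_logrates`` rows,
    with Dirichlet(concentration) weights."""

    cell_type: str
    archetype_logrates: np.ndarray  # n_archetypes x n_genes
    concentration: float = 0.8

    def __post_init__(self) -> None:
        self.archetype_logrates = np.asarray(self.archetype_logrates, dtype=float)
        a = self.archetype_logrates
        if a.shape[0] < 2:
            raise ValueError("need at least 2 archetypes")
        rank = np.linalg.matrix_rank(a[1:] - a[0])
        if rank < a.shape[0] - 1:
            raise ValueError("archetype log-rate profiles are affinely dependent (degenerate simplex)")


@dataclass
class TrajectorySpec:
    """A 1D phenotypic continuum inside ``cell_type``: log rate =
    type profile + position * loading, position ~ N(mean(timepoint), sd)."""

    cell_type: str
    loading: np.ndarray  # length n_genes
    position_mean_per_timepoint: np.ndarray
    position_sd: float = 0.5

    def __post_init__(self) -> None:
        self.loading = np.asarray(self.loading, dtype=float)
        self.position_mean_per_timepoint = np.asarray(self.position_mean_per_timepoint, dtype=float)


@dataclass
class SimConfig:
    n_genes: int
    timepoints: list
    cells_per_timepoint: np.ndarray  # total cells sequenced per timepoint
    cell_type_specs: list
    simplex_spec: SimplexSpec | None = None
    trajectory_spec: TrajectorySpec | None = None
    depth: float = 5000.0
    size_factor_sigma: float = 0.3
    mito_frac: float = 0.02
    damaged_frac: float = 0.01  # cells with inflated mitochondrial content
    overdispersion: float | None = None  # NB inverse dispersion; None = pure Poisson
    n_samples_per_timepoint: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.cells_per_timepoint = np.asarray(self.cells_per_timepoint, dtype=int)
        self.validate()

    def validate(self) -> None:
        T = len(self.timepoints)
        if len(self.cells_per_timepoint) != T:
            raise ValueError("cells_per_timepoint length mismatch")
        fr = np.stack([s.frac_per_timepoint for s in self.cell_type_specs])
        if fr.shape[1] != T:
            raise ValueError("frac_per_timepoint length mismatch")
        sums = fr.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError(f"type fractions must sum to 1 per timepoint, got {sums}")
        for s in self.cell_type_specs:
            if len(s.lograte) != self.n_genes:
                raise ValueError(f"lograte length mismatch for type {s.name}")
            _check_pattern(s.pattern, s.frac_per_timepoint)
        if self.simplex_spec is not None:
            if self.simplex_spec.archetype_logrates.shape[1] != self.n_genes:
                raise ValueError("archetype profile length mismatch")

    @property
    def gene_ids(self) -> np.ndarray:
        n_mito = int(round(self.mito_frac * self.n_genes))
        ids = [f"mt-gene{i:04d}" if i < n_mito else f"gene{i:04d}" for i in range(self.n_genes)]
        return np.asarray(ids, dtype=object)

    def marker_table(self) -> pd.DataFrame:
        """Tidy (cell_type, gene) marker table for cluster annotation."""
        ids = self.gene_ids
        rows = [
            {"cell_type": s.name, "gene": ids[g]}
            for s in self.cell_type_specs
            for g in s.marker_genes
        ]
        return pd.DataFrame(rows)


def _check_pattern(pattern: str, frac: np.ndarray) -> None:
    if pattern == "progressive_increase":
        if np.any(np.diff(frac) < -1e-12):
            raise ValueError("progressive_increase fractions must be non-decreasing")
    elif pattern == "wave_like":
        k = int(np.argmax(frac))
        if k in (0, len(frac) - 1):
            raise ValueError("wave_like fractions must peak at an interior timepoint")


@dataclass
class GroundTruth:
    """Planted truth for every simulated cell."""

    cells: pd.DataFrame  # index cell_id: cell_type, timepoint, sample, damaged
    archetype_weights: pd.DataFrame | None = None  # simplex cells x archetypes
    trajectory_positions: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.archetype_weights is not None:
            w = self.archetype_weights.to_numpy()
            if np.any(w < -1e-12) or np.any(np.abs(w.sum(axis=1) - 1) > 1e-9):
                raise ValueError("archetype weights must be barycentric (>=0, row sums 1)")


# --------------------------------------------------------------------------
# counts
# --------------------------------------------------------------------------
def _largest_remainder(fracs: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of `total` cells proportional to `fracs`."""
    raw = fracs * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw a UMI count matrix from the configured cell-type mixture.

    Counts are Poisson around ``s_c * softmax(lograte_gc)`` with
    log-normal size factors ``s_c`` centered on ``config.depth``; an
    optional negative-binomial switch adds gamma overdispersion.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss)

    gene_ids = config.gene_ids
    n_mito = int(round(config.mito_frac * config.n_genes))
    blocks: list[sp.csr_matrix] = []
    meta_rows = []
    arch_w: list[np.ndarray] = []
    arch_ids: list[str] = []
    traj_pos: list[float] = []
    traj_ids: list[str] = []
    cell_counter = 0

    for t_idx, tp in enumerate(config.timepoints):
        fr = np.array([s.frac_per_timepoint[t_idx] for s in config.cell_type_specs])
        n_per_type = _largest_remainder(fr, int(config.cells_per_timepoint[t_idx]))
        for spec, n_ct in zip(config.cell_type_specs, n_per_type):
            if n_ct == 0:
                continue
            ids = np.array([f"cell{cell_counter + i:06d}" for i in range(n_ct)], dtype=object)
            cell_counter += n_ct
            # per-cell log-rate profiles
            if config.simplex_spec is not None and spec.name == config.simplex_spec.cell_type:
                p = config.simplex_spec.archetype_logrates.shape[0]
                w = rng.dirichlet([config.simplex_spec.concentration] * p, size=n_ct)
                lograte = w @ config.simplex_spec.archetype_logrates
                arch_w.append(w)
                arch_ids.extend(ids)
            elif config.trajectory_spec is not None and spec.name == config.trajectory_spec.cell_type:
                mu = config.trajectory_spec.position_mean_per_timepoint[t_idx]
                pos = rng.normal(mu, config.trajectory_spec.position_sd, size=n_ct)
                lograte = spec.lograte[None, :] + pos[:, None] * config.trajectory_spec.loading[None, :]
                traj_pos.extend(pos)
                traj_ids.extend(ids)
            else:
                lograte = np.repeat(spec.lograte[None, :], n_ct, axis=0)

            damaged = rng.random(n_ct) < config.damaged_frac
            if n_mito and damaged.any():
                lograte = lograte.copy()
                lograte[np.ix_(damaged, np.arange(n_mito))] += 2.5

            # normalize to per-cell transcriptome fractions
            lograte = lograte - lograte.max(axis=1, keepdims=True)
            q = np.exp(lograte)
            q /= q.sum(axis=1, keepdims=True)
            s_c = config.depth * np.exp(rng.normal(0.0, config.size_factor_sigma, size=n_ct))
            rate = q * s_c[:, None]
            if config.overdispersion is not None:
                rate = rate * rng.gamma(config.overdispersion, 1.0 / config.overdispersion, size=rate.shape)
            counts = rng.poisson(rate)  # cells x genes
            blocks.append(sp.csr_matrix(counts.T))
            sample_idx = rng.integers(0, config.n_samples_per_timepoint, size=n_ct)
            for cid, dmg, si in zip(ids, damaged, sample_idx):
                meta_rows.append(
                    {"cell_id": cid, "true_type": spec.name, "timepoint": tp,
                     "sample": f"{tp}_rep{si + 1}", "damaged": bool(dmg)}
                )

    meta = pd.DataFrame(meta_rows).set_index("cell_id")
    if len(meta) == 0:
        counts = sp.csr_matrix((config.n_genes, 0), dtype=np.int64)
        cm = CountMatrix(counts, gene_ids, np.array([], dtype=object), meta)
        return cm, GroundTruth(meta)
    counts = sp.hstack(blocks, format="csr")
    cm = CountMatrix(counts, gene_ids, meta.index.to_numpy(dtype=object),
                     meta[["sample", "timepoint", "true_type"]])
    gt = GroundTruth(
        cells=meta,
        archetype_weights=(
            pd.DataFrame(np.vstack(arch_w), index=arch_ids,
                         columns=[f"archetype{i + 1}" for i in range(np.vstack(arch_w).shape[1])])
            if arch_w else None
        ),
        trajectory_positions=pd.Series(traj_pos, index=traj_ids) if traj_ids else None,
    )
    return cm, gt


# --------------------------------------------------------------------------
# simplex population (PC-space scale)
# --------------------------------------------------------------------------
def simulate_simplex_population(
    n_cells: int,
    archetype_profiles: np.ndarray,
    noise_sd: float,
    seed: int,
    concentration: float = 0.8,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cells = Dirichlet(concentration) mixtures of archetype rows plus
    isotropic Gaussian noise.  Returns (cells x dims matrix, weights)."""
    A = np.asarray(archetype_profiles, dtype=float)
    if A.shape[0] < 2:
        raise ValueError("need at least 2 archetypes")
    rng = np.random.default_rng(seed)
    if weights is None:
        weights = rng.dirichlet([concentration] * A.shape[0], size=n_cells)
    else:
        weights = np.asarray(weights, dtype=float)
    X = weights @ A
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    return X, weights


# --------------------------------------------------------------------------
# CRISPR NormZ table
# --------------------------------------------------------------------------
def simulate_normz(
    n_genes: int,
    signature_genes,
    effect: float,
    seed: int,
    gene_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene knockout fitness effects on a z-scale: signature genes
    ~ N(effect, 1), background ~ N(0, 1)."""
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = np.asarray([f"gene{i:04d}" for i in range(n_genes)], dtype=object)
    gene_ids = np.asarray(gene_ids, dtype=object)
    normz = rng.normal(0.0, 1.0, size=n_genes)
    sig = np.asarray(list(signature_genes), dtype=int)
    if sig.size:
        normz[sig] += effect
    return pd.DataFrame({"gene": gene_ids, "normz": normz})


# --------------------------------------------------------------------------
# multiplexed-imaging intensities
# --------------------------------------------------------------------------
def simulate_hifi_intensities(
    composition: dict,
    panel: dict,
    mode_locations: dict,
    n_cells: int,
    seed: int,
    sd: float = 0.1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-cell raw marker intensities with bimodal log1p-intensity
    channels.

    Parameters
    ----------
    composition : cell type -> fraction (must sum to 1)
    panel : cell type -> iterable of markers that type expresses.
        Nested (gated) markers are encoded here: a T cell's set contains
        both the pan-immune and the T markers, so child markers are
        positive only within parent-positive cells.
    mode_locations : marker -> (negative mode, positive mode) on the
        log1p scale.
    """
    fr = np.array(list(composition.values()), dtype=float)
    if n_cells and abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("composition fractions must sum to 1")
    types = list(composition.keys())
    markers = list(mode_locations.keys())
    rng = np.random.default_rng(seed)
    if n_cells == 0:
        return (
            pd.DataFrame(columns=markers, dtype=float),
            pd.Series([], dtype=object, name="true_type"),
        )
    n_per = _largest_remainder(fr, n_cells)
    true_types = np.repeat(types, n_per)
    perm = rng.permutation(n_cells)
    true_types = np.asarray(true_types, dtype=object)[perm]
    log_int = np.empty((n_cells, len(markers)))
    for j, m in enumerate(markers):
        neg, pos = mode_locations[m]
        positive = np.array([m in panel[t] for t in true_types])
        loc = np.where(positive, pos, neg)
        log_int[:, j] = rng.normal(loc, sd)
    raw = np.expm1(np.clip(log_int, 0.0, None))
    idx = pd.Index([f"hifi{i:06d}" for i in range(n_cells)])
    table = pd.DataFrame(raw, columns=markers, index=idx)
    return table, pd.Series(true_types, index=idx, name="true_type")


def default_hifi_panel() -> tuple[dict, dict, dict]:
    """A 6-type, 7-marker panel mirroring a breast-tumor staining design
    (cancer, myeloid and lymphoid compartments with nested T-cell
    markers).  Returns (composition, panel, gating parent map)."""
    composition = {
        "cancer": 0.42,
        "macrophage": 0.22,
        "phagocytic_macrophage": 0.10,
        "tc": 0.08,
        "th": 0.10,
        "other_immune": 0.08,
    }
    panel = {
        "cancer": {"SOX9"},
        "macrophage": {"CD45", "IBA1", "F480"},
        "phagocytic_macrophage": {"CD45", "IBA1", "F480", "CD68"},
        "tc": {"CD45", "CD3", "CD8A"},
        "th": {"CD45", "CD3"},
        "other_immune": {"CD45"},
    }
    gating = {"CD3": "CD45", "CD8A": "CD3", "IBA1": "CD45", "F480": "IBA1", "CD68": "F480"}
    return composition, panel, gating


def default_mode_locations(markers=("SOX9", "CD45", "IBA1", "F480", "CD68", "CD3", "CD8A")) -> dict:
    return {m: (0.1, 1.5) for m in markers}


# --------------------------------------------------------------------------
# the default tumor time-course configuration
# --------------------------------------------------------------------------
#: per-type fractional abundance over the four sampling days and the
#: temporal pattern each follows.  Columns: day11, day14, day18, day24.
DEFAULT_COMPOSITION = {
    "cancer": ([0.56, 0.40, 0.37, 0.50], "other"),
    "stroma": ([0.25, 0.10, 0.03, 0.01], "other"),
    "macrophage": ([0.10, 0.20, 0.20, 0.20], "stable_colonization"),
    "dc": ([0.015, 0.04, 0.04, 0.04], "stable_colonization"),
    "b_cell": ([0.015, 0.04, 0.04, 0.04], "stable_colonization"),
    "tc": ([0.03, 0.05, 0.08, 0.12], "progressive_increase"),
    "th": ([0.01, 0.08, 0.10, 0.04], "wave_like"),
    "treg": ([0.01, 0.05, 0.08, 0.03], "wave_like"),
    "ilc": ([0.01, 0.04, 0.06, 0.02], "wave_like"),
}

#: lineage structure used to give the expression space a hierarchy:
#: lineage marker blocks are shared by all member types, so top-level
#: clustering separates compartments before subtypes.
LINEAGES = {
    "myeloid": ["macrophage", "dc"],
    "lymphoid": ["b_cell", "tc", "th", "treg", "ilc"],
    "t_lineage": ["tc", "th", "treg"],
}


def tumor_timecourse_config(
    n_genes: int = 600,
    cells_per_timepoint=(700, 750, 800, 750),
    depth: float = 5000.0,
    marker_boost: float = 2.5,
    archetype_boost: float = 2.0,
    block_size: int = 20,
    seed: int = 0,
) -> SimConfig:
    """Build the default desk-scale 9-type tumor time-course: four
    sampling days, hierarchical marker structure, a 4-archetype simplex
    inside macrophages and a 1D trajectory inside Tregs."""
    ss = np.random.SeedSequence([seed, 0xC0FFEE])
    rng = np.random.default_rng(ss)
    timepoints = ["day11", "day14", "day18", "day24"]
    names = list(DEFAULT_COMPOSITION.keys())
    n_mito = int(round(0.02 * n_genes))

    baseline = rng.normal(0.0, 0.4, size=n_genes)
    baseline[:n_mito] += 1.3  # mitochondrial genes are well expressed

    cursor = n_mito
    def take(k):
        nonlocal cursor
        idx = np.arange(cursor, cursor + k)
        cursor += k
        return idx

    type_blocks = {name: take(block_size) for name in names}
    lineage_blocks = {lin: take(block_size) for lin in LINEAGES}
    arch_blocks = [take(max(block_size // 2, 8)) for _ in range(4)]
    traj_block = take(max(block_size // 2, 8))
    if cursor > n_genes:
        raise ValueError(f"n_genes={n_genes} too small for marker layout (need {cursor})")

    specs = []
    for name in names:
        lr = baseline.copy()
        lr[type_blocks[name]] += marker_boost
        for lin, members in LINEAGES.items():
            if name in members:
                lr[lineage_blocks[lin]] += marker_boost
        specs.append(
            CellTypeSpec(
                name=name,
                frac_per_timepoint=DEFAULT_COMPOSITION[name][0],
                marker_genes=type_blocks[name],
                lograte=lr,
                pattern=DEFAULT_COMPOSITION[name][1],
            )
        )

    mac_lr = [s for s in specs if s.name == "macrophage"][0].lograte
    arch_profiles = np.stack([mac_lr.copy() for _ in range(4)])
    for a, blk in enumerate(arch_blocks):
        arch_profiles[a, blk] += archetype_boost
    simplex = SimplexSpec("macrophage", arch_profiles, concentration=0.8)

    loading = np.zeros(n_genes)
    loading[traj_block] = 0.8
    trajectory = TrajectorySpec(
        "treg", loading, position_mean_per_timepoint=[-1.0, -0.3, 0.3, 1.0], position_sd=0.5
    )

    return SimConfig(
        n_genes=n_genes,
        timepoints=timepoints,
        cells_per_timepoint=np.asarray(cells_per_timepoint),
        cell_type_specs=specs,
        simplex_spec=simplex,
        trajectory_spec=trajectory,
        depth=depth,
        seed=seed,
    )
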