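"""Simplex / archetype analysis of phenotypic continua in PC space.

Cells are modeled as convex (barycentric) combinations of a small number
of extreme expression profiles — archetypes.  A p-archetype model lives
in the first p-1 PCs, so four archetypes span a tetrahedron in 3D.

Fitting is alternating least squares archetypal analysis: given
archetypes, each cell's weights solve an exact simplex-constrained
regression (active-set by support enumeration, exact for the small p
used here); given weights, the archetypes solve an unconstrained least
squares, which lets them sit slightly outside the data hull (the
relaxation needed to fit noisy corner cells).

Goodness of fit is the t-ratio: the volume of the minimal enclosing
version of the fitted simplex divided by the volume of the convex hull
of the data.  A t-ratio near 1 means the data fill a simplex; data
without simplex structure force a much larger enclosing simplex.
Significance comes from refitting on shuffled datasets in which every
PC column is permuted independently — marginals are preserved,
correlations destroyed — with a one-sided p-value on the t-ratio
(smaller = tighter simplex).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.stats import gaussian_kde, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .containers import LTQMatrix

MAX_HULL_DIM = 8


class DegenerateSimplexWarning(UserWarning):
    pass


# --------------------------------------------------------------------------
# exact simplex-constrained regression
# --------------------------------------------------------------------------
def simplex_regression(X: np.ndarray, A: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Per-row exact solution of min ||x - A^T w|| s.t. w >= 0, sum w = 1.

    ``X``: n x d data, ``A``: p x d archetypes.  Solved by enumerating
    all non-empty supports (exact for the optimal active set); feasible
    candidates compete on residual.  Intended for small p (<= ~8).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    A = np.asarray(A, dtype=float)
    n, d = X.shape
    p = A.shape[0]
    if p > 12:
        raise ValueError("support enumeration not intended for p > 12 archetypes")
    best_res = np.full(n, np.inf)
    W = np.zeros((n, p))
    xsq = (X**2).sum(axis=1)
    for k in range(1, p + 1):
        for S in itertools.combinations(range(p), k):
            M = A[list(S)]  # k x d
            G = M @ M.T
            G = G + np.eye(k) * (tol * max(np.trace(G), 1.0))
            Gi = np.linalg.inv(G)
            u = Gi.sum(axis=1)  # G^-1 1
            w0 = X @ M.T @ Gi.T  # n x k, unconstrained-lambda part
            lam = (w0.sum(axis=1) - 1.0) / u.sum()
            Wc = w0 - np.outer(lam, u)
            feas = Wc.min(axis=1) >= -1e-8
            if not feas.any():
                continue
            R = X - Wc @ M
            res = (R**2).sum(axis=1)
            upd = feas & (res < best_res - 1e-12)
            if upd.any():
                best_res[upd] = res[upd]
                W[upd] = 0.0
                W[np.ix_(upd, list(S))] = Wc[upd]
    np.clip(W, 0.0, None, out=W)
    W /= W.sum(axis=1, keepdims=True)
    return W


def _furthest_sum_init_indices(X: np.ndarray, p: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of p mutually distant data points (furthest-sum start)."""
    n = X.shape[0]
    first = int(rng.integers(n))
    chosen = [first]
    dist_sum = np.linalg.norm(X - X[first], axis=1)
    for _ in range(p - 1):
        cand = int(np.argmax(dist_sum))
        if cand in chosen:  # duplicate points; fall back to random
            cand = int(rng.integers(n))
        chosen.append(cand)
        dist_sum = dist_sum + np.linalg.norm(X - X[cand], axis=1)
    return np.asarray(chosen)


@dataclass
class SimplexFit:
    """Fitted archetypes, per-cell barycentric weights and the t-ratio
    goodness of fit (with permutation p-value once tested)."""

    archetypes: np.ndarray  # p x d
    weights: np.ndarray  # n x p, rows on the simplex
    t_ratio: float
    rss: float
    p_value: float | None = None
    n_shuffles: int | None = None
    seed: int | None = None
    expansion_factor: float = 1.0
    objective_history: np.ndarray = field(default_factory=lambda: np.zeros(0))
    null_t_ratios: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = self.weights
        if w.size and (w.min() < -1e-9 or np.abs(w.sum(axis=1) - 1).max() > 1e-6):
            raise ValueError("weights must be barycentric")
        if np.isfinite(self.t_ratio) and self.t_ratio < 1 - 1e-9:
            raise ValueError(f"t_ratio must be >= 1, got {self.t_ratio}")

    def to_dict(self) -> dict:
        return {
            "archetypes": self.archetypes.tolist(),
            "t_ratio": float(self.t_ratio),
            "p_value": self.p_value,
            "n_shuffles": self.n_shuffles,
            "seed": self.seed,
            "rss": float(self.rss),
            "expansion_factor": float(self.expansion_factor),
        }


def _project_rows_to_simplex(B: np.ndarray, total: float = 1.0) -> np.ndarray:
    """Euclidean projection of each row onto {b >= 0, sum b = total}."""
    p, n = B.shape
    U = np.sort(B, axis=1)[:, ::-1]
    css = np.cumsum(U, axis=1) - total
    ind = np.arange(1, n + 1)
    cond = U - css / ind > 0
    rho = n - 1 - np.argmax(cond[:, ::-1], axis=1)
    theta = css[np.arange(p), rho] / (rho + 1)
    return np.clip(B - theta[:, None], 0.0, None)


def _project_rows_relaxed(B: np.ndarray, delta: float) -> np.ndarray:
    """Projection onto {b >= 0, 1 - delta <= sum b <= 1 + delta}."""
    if delta <= 0:
        return _project_rows_to_simplex(B)
    out = np.clip(B, 0.0, None)
    sums = out.sum(axis=1)
    hi = sums > 1 + delta
    lo = sums < 1 - delta
    if hi.any():
        out[hi] = _project_rows_to_simplex(B[hi], total=1 + delta)
    if lo.any():
        out[lo] = _project_rows_to_simplex(B[lo], total=1 - delta)
    return out


def _als_fit(X: np.ndarray, p: int, rng: np.random.Generator, max_iter: int,
             tol: float, delta: float = 0.0, n_inner: int = 8):
    """Principal-convex-hull alternating minimization.

    Archetypes are convex combinations of data points, A = B X with
    row-stochastic B (relaxation ``delta`` lets row sums roam in
    [1-delta, 1+delta], letting archetypes sit slightly outside the
    hull).  Weights W are exact simplex regressions; B moves by
    projected gradient with a backtracking step, so the objective is
    monotone non-increasing.
    """
    n, d = X.shape
    first = _furthest_sum_init_indices(X, p, rng)
    B = np.zeros((p, n))
    B[np.arange(p), first] = 1.0
    A = B @ X
    obj_hist = []
    step = 1.0 / (2.0 * max(np.linalg.eigvalsh(X.T @ X).max(), 1e-12))
    prev = np.inf
    W = simplex_regression(X, A)
    for _ in range(max_iter):
        W = simplex_regression(X, A)
        cur = float(((X - W @ A) ** 2).sum())
        WtW = W.T @ W
        for _ in range(n_inner):
            grad_B = 2.0 * (WtW @ (B @ X) - W.T @ X) @ X.T
            for _ in range(12):  # backtracking
                B_new = _project_rows_relaxed(B - step * grad_B, delta)
                new = float(((X - W @ (B_new @ X)) ** 2).sum())
                if new <= cur + 1e-12:
                    break
                step *= 0.5
            if new > cur + 1e-12:
                break
            B, cur = B_new, new
            step *= 1.2
        A = B @ X
        obj_hist.append(cur)
        if prev - cur < tol * max(prev, 1.0):
            break
        prev = cur
    W = simplex_regression(X, A)
    obj_hist.append(float(((X - W @ A) ** 2).sum()))
    return A, W, np.asarray(obj_hist)


def barycentric_coordinates(scores: np.ndarray, archetypes: np.ndarray) -> np.ndarray:
    """Exact affine barycentric coordinates (may be negative outside the
    simplex).  Requires p = d + 1 vertices in d dimensions."""
    A = np.asarray(archetypes, dtype=float)
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    p, d = A.shape
    if p != d + 1:
        raise ValueError(f"need d+1 vertices in d dims, got {p} in {d}")
    M = np.vstack([A.T, np.ones(p)])  # (d+1) x p
    rhs = np.hstack([X, np.ones((X.shape[0], 1))]).T
    return np.linalg.solve(M, rhs).T


def simplex_volume(vertices: np.ndarray) -> float:
    V = np.asarray(vertices, dtype=float)
    p, d = V.shape
    if p != d + 1:
        raise ValueError("volume needs d+1 vertices in d dims")
    from math import factorial

    return abs(np.linalg.det(V[1:] - V[0])) / factorial(d)


def _hull_volume(scores: np.ndarray) -> float:
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    d = X.shape[1]
    if d > MAX_HULL_DIM:
        raise ValueError(f"convex hull volume refused for d > {MAX_HULL_DIM}")
    if d == 1:
        return float(X.max() - X.min())
    return float(ConvexHull(X).volume)


def minimal_enclosing_expansion(scores: np.ndarray, archetypes: np.ndarray) -> tuple[np.ndarray, float]:
    """Smallest face-shift of the simplex that brings every cell inside.

    Each face is pushed outward exactly by its worst violation: with
    m_j = min(0, min_cell b_j) the map b -> (b - m) / (1 - sum m) keeps
    barycentric coordinates non-negative, which in vertex space is a
    homothety with ratio (1 - sum m) about the point with barycentric
    coordinates m / sum m.  Returns (new vertices, linear scale factor).
    """
    A = np.asarray(archetypes, dtype=float)
    b = barycentric_coordinates(scores, A)
    m = np.minimum(b.min(axis=0), 0.0)  # per-face worst violation
    s = float(1.0 - m.sum())
    V = (1.0 - m.sum()) * A + (m @ A)[None, :]
    return V, s


def _hull_vertices(scores: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.shape[1] == 1:
        return np.array([[X.min()], [X.max()]])
    return X[ConvexHull(X).vertices]


def minimum_volume_enclosing_simplex(
    scores: np.ndarray,
    init_vertices: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Approximate minimum-volume simplex (d+1 vertices in d dims)
    enclosing all points.

    Only the data's hull vertices matter, so the search runs on them: a
    principal-convex-hull fit on the hull vertices (or the supplied
    initial vertices), expanded to enclose, then local volume
    minimization (SLSQP on the vertex coordinates) under the
    containment constraints.  Falls back to the feasible start if the
    optimization fails."""
    from scipy.optimize import minimize

    P = _hull_vertices(scores)
    d = P.shape[1]
    p = d + 1
    if init_vertices is None:
        rng = np.random.default_rng(seed)
        A0, _, _ = _als_fit(P, p, rng, max_iter=80, tol=1e-9)
    else:
        A0 = np.asarray(init_vertices, dtype=float)
    V0, _ = minimal_enclosing_expansion(P, A0)
    vol0 = simplex_volume(V0)
    scale = max(float(np.abs(P).max()), 1e-12)

    def volume(v):
        V = v.reshape(p, d)
        return abs(np.linalg.det((V[1:] - V[0]) / scale))

    def containment(v):
        V = v.reshape(p, d)
        M = np.vstack([V.T, np.ones(p)])
        try:
            b = np.linalg.solve(M, np.vstack([P.T, np.ones(len(P))]))
        except np.linalg.LinAlgError:
            return -np.ones(p * len(P))
        return b.ravel()

    try:
        res = minimize(volume, V0.ravel(), method="SLSQP",
                       constraints=[{"type": "ineq", "fun": containment}],
                       options={"maxiter": 200, "ftol": 1e-10})
        V = res.x.reshape(p, d)
        ok = containment(res.x).min() > -1e-6 and simplex_volume(V) <= vol0 * (1 + 1e-9)
    except Exception:  # noqa: BLE001
        ok = False
    return V if ok else V0


def t_ratio(scores: np.ndarray, archetypes: np.ndarray | None = None, seed: int = 0) -> float:
    """Volume of the minimum-volume enclosing simplex over the volume
    of the convex hull of the data, both in the fit dimension.  The
    fitted archetypes, when given, seed the enclosing-simplex search."""
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    vol_h = _hull_volume(X)
    if vol_h <= 0 or not np.isfinite(vol_h):
        warnings.warn("degenerate data hull (zero volume)", DegenerateSimplexWarning, stacklevel=2)
        return np.inf
    V = minimum_volume_enclosing_simplex(X, init_vertices=archetypes, seed=seed)
    return simplex_volume(V) / vol_h


def fit_simplex(
    scores: np.ndarray,
    n_archetypes: int | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-8,
    delta: float = 0.0,
) -> SimplexFit:
    """Fit ``n_archetypes`` (default d+1) by principal-convex-hull
    alternating least squares; the best of ``n_restarts`` furthest-sum
    starts is kept.  ``delta`` > 0 relaxes the hull constraint, letting
    archetypes sit slightly outside the data."""
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    n, d = X.shape
    p = d + 1 if n_archetypes is None else int(n_archetypes)
    if n < p:
        raise ValueError(f"fewer cells ({n}) than archetypes ({p})")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        A, W, hist = _als_fit(X, p, rng, max_iter, tol, delta=delta)
        rss = hist[-1] if len(hist) else float(((X - W @ A) ** 2).sum())
        if best is None or rss < best[3]:
            best = (A, W, hist, rss)
    A, W, hist, rss = best

    expansion = 1.0
    if p == d + 1:
        vol = simplex_volume(A)
        scale = float(np.abs(X).max()) or 1.0
        if vol < 1e-10 * scale**d:
            warnings.warn("fitted simplex has (near-)zero volume",
                          DegenerateSimplexWarning, stacklevel=2)
            tr = np.inf
        else:
            tr = t_ratio(X, A, seed=seed)
            _, expansion = minimal_enclosing_expansion(X, A)
    else:
        tr = np.nan  # volume ratio undefined when p != d+1
    return SimplexFit(
        archetypes=A, weights=W, t_ratio=float(tr), rss=float(rss),
        seed=seed, expansion_factor=expansion, objective_history=hist,
    )


def t_ratio_test(
    scores: np.ndarray,
    n_archetypes: int | None = None,
    n_shuffles: int = 1000,
    seed: int = 0,
    n_restarts: int = 3,
    max_iter: int = 60,
) -> SimplexFit:
    """Permutation test of simplex structure.

    Every shuffle permutes each PC column independently across cells,
    preserving marginal distributions while destroying their
    correlation; the minimum-volume enclosing simplex is refit on the
    shuffled data and the t-ratio recomputed.  The one-sided
    add-one-smoothed p-value counts shuffles with a t-ratio at most the
    observed one (small t-ratio = tight simplex).
    """
    if n_shuffles < 19:
        warnings.warn("n_shuffles < 19: p-value floor coarser than 0.05", stacklevel=2)
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    fit = fit_simplex(X, n_archetypes, n_restarts=n_restarts, seed=seed, max_iter=max_iter)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A7]))
    # the observed statistic is recomputed through exactly the same
    # procedure as the shuffles (hull-seeded enclosing-simplex search),
    # so the permutation p-value is exact under the null
    t_obs = t_ratio(X, seed=int(rng.integers(2**31 - 1)))
    fit.t_ratio = min(fit.t_ratio, t_obs) if np.isfinite(fit.t_ratio) else t_obs
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        Xs = np.column_stack([rng.permutation(X[:, j]) for j in range(X.shape[1])])
        null[i] = t_ratio(Xs, seed=int(rng.integers(2**31 - 1)))
    fit.p_value = float((1 + (null <= t_obs).sum()) / (1 + n_shuffles))
    fit.n_shuffles = n_shuffles
    fit.null_t_ratios = null
    return fit


# --------------------------------------------------------------------------
# archetype-based phenotyping
# --------------------------------------------------------------------------
def distance_to_archetype(scores: np.ndarray, archetypes: np.ndarray, which: int | None = None) -> np.ndarray:
    """Euclidean distance in the fitted PC space; all archetypes
    (n x p) or a single one (n,)."""
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    A = np.asarray(archetypes, dtype=float)
    if which is not None:
        return np.linalg.norm(X - A[which], axis=1)
    return np.linalg.norm(X[:, None, :] - A[None, :, :], axis=2)


def discretize_archetypes(
    scores: np.ndarray,
    archetypes: np.ndarray,
    frac_closest: float = 0.25,
    frac_generalist: float = 0.20,
    archetype_names: list | None = None,
    origin: np.ndarray | None = None,
) -> np.ndarray:
    """Discrete phenotype per cell from archetype proximity.

    The ``frac_closest`` fraction of cells nearest each archetype forms
    that archetype's candidate set; the ``frac_generalist`` fraction
    nearest the origin (PC-space mean) is labeled "generalist".
    Conflicts: a cell in several archetype sets goes to the nearer
    archetype; the generalist label wins over archetype labels.
    Everything else is "unassigned"."""
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    A = np.asarray(archetypes, dtype=float)
    n, p = X.shape[0], A.shape[0]
    names = archetype_names or [f"archetype{i + 1}" for i in range(p)]
    D = distance_to_archetype(X, A)
    labels = np.full(n, "unassigned", dtype=object)

    k = int(frac_closest * n)
    member = np.zeros((n, p), dtype=bool)
    for a in range(p):
        if k > 0:
            member[np.argpartition(D[:, a], k - 1)[:k], a] = True
    any_member = member.any(axis=1)
    masked = np.where(member, D, np.inf)
    nearest = masked.argmin(axis=1)
    labels[any_member] = np.asarray(names, dtype=object)[nearest[any_member]]

    o = np.zeros(X.shape[1]) if origin is None else np.asarray(origin, dtype=float)
    kg = int(frac_generalist * n)
    if kg > 0:
        d0 = np.linalg.norm(X - o, axis=1)
        labels[np.argpartition(d0, kg - 1)[:kg]] = "generalist"
    return labels


def archetype_enrichment(
    features,
    distances: np.ndarray,
    frac_closest: float = 0.25,
    feature_sets: dict | None = None,
    archetype_names: list | None = None,
) -> pd.DataFrame:
    """Rank-sum enrichment of features in each archetype's closest cells.

    ``features``: LTQMatrix or DataFrame (features x cells).  For each
    archetype, the ``frac_closest`` nearest cells are compared with all
    other cells per feature (one-sided: expression peaks toward the
    archetype), with Benjamini-Hochberg q-values within each archetype.
    ``feature_sets`` adds pathway-level features (mean over member
    genes) on top of single genes."""
    if isinstance(features, LTQMatrix):
        fdf = pd.DataFrame(features.ltq, index=features.gene_ids)
    else:
        fdf = pd.DataFrame(features)
    if feature_sets:
        extra = {}
        for name, genes in feature_sets.items():
            present = fdf.index.intersection(pd.Index(list(genes)))
            if len(present):
                extra[name] = fdf.loc[present].mean(axis=0)
        if extra:
            fdf = pd.concat([fdf, pd.DataFrame(extra).T.set_axis(fdf.columns, axis=1)])
    D = np.atleast_2d(np.asarray(distances, dtype=float))
    n, p = D.shape
    names = archetype_names or [f"archetype{i + 1}" for i in range(p)]
    k = max(int(frac_closest * n), 1)
    rows = []
    vals = fdf.to_numpy()
    if vals.shape[0] == 0:
        return pd.DataFrame(columns=["feature", "archetype", "statistic", "p", "q"])
    for a in range(p):
        member = np.zeros(n, dtype=bool)
        member[np.argpartition(D[:, a], k - 1)[:k]] = True
        stat, pval = mannwhitneyu(vals[:, member], vals[:, ~member],
                                  alternative="greater", axis=1)
        q = multipletests(pval, method="fdr_bh")[1]
        for f, s, pv, qv in zip(fdf.index, stat, pval, q):
            rows.append({"feature": f, "archetype": names[a],
                         "statistic": float(s), "p": float(pv), "q": float(qv)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# continuum vs cluster diagnostic
# --------------------------------------------------------------------------
def propagated_error_radius(gene_error: np.ndarray, loadings: np.ndarray, n_pcs: int) -> float:
    """Mean measurement-error radius in PC space: per PC, the sd of the
    score under independent per-gene errors is sqrt(sum (loading *
    err)^2); averaged over the first ``n_pcs``."""
    L = np.asarray(loadings, dtype=float)[:, :n_pcs]
    e = np.asarray(gene_error, dtype=float)
    per_pc = np.sqrt(((L * e[:, None]) ** 2).sum(axis=0))
    return float(per_pc.mean())


def continuum_diagnostic(
    scores: np.ndarray,
    error_radius: float,
    bandwidth: float | str = "scott",
    grid_size: int = 80,
    min_rel_height: float = 0.10,
) -> dict:
    """Decide whether a 2D score cloud looks like discrete clusters
    blurred by measurement error or a genuine continuum.

    A KDE over the first two score dimensions is scanned for local
    maxima; each peak's width (mean axis-wise FWHM) is compared with
    the measurement-error radius.  If every peak is no wider than the
    error radius the verdict is "cluster_like", otherwise
    "continuum_like"."""
    X = np.atleast_2d(np.asarray(scores, dtype=float))[:, :2]
    kde = gaussian_kde(X.T, bw_method=bandwidth)
    lo, hi = X.min(axis=0), X.max(axis=0)
    pad = 0.1 * (hi - lo + 1e-12)
    gx = np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid_size)
    gy = np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid_size)
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    Z = kde(np.vstack([GX.ravel(), GY.ravel()])).reshape(grid_size, grid_size)

    peaks = []
    zmax = Z.max()
    for i in range(1, grid_size - 1):
        for j in range(1, grid_size - 1):
            z = Z[i, j]
            if z < min_rel_height * zmax:
                continue
            neigh = Z[i - 1 : i + 2, j - 1 : j + 2]
            if z >= neigh.max() and (neigh < z).sum() >= 7:
                peaks.append((i, j, z))

    def axis_fwhm(i, j, z):
        half = z / 2.0
        widths = []
        for axis in (0, 1):
            lo_k = hi_k = 0
            kk = 1
            line = Z[:, j] if axis == 0 else Z[i, :]
            pos = i if axis == 0 else j
            while pos - kk >= 0 and line[pos - kk] > half:
                kk += 1
            lo_k = kk
            kk = 1
            while pos + kk < grid_size and line[pos + kk] > half:
                kk += 1
            hi_k = kk
            step = gx[1] - gx[0] if axis == 0 else gy[1] - gy[0]
            widths.append((lo_k + hi_k) * step)
        return float(np.mean(widths))

    # the KDE convolves the true density with its kernel; subtract the
    # kernel's own FWHM in quadrature so tight clusters are not read as
    # broad peaks
    kernel_sd = kde.factor * np.sqrt(np.diag(np.cov(X.T))).mean()
    kernel_fwhm = 2.3548 * kernel_sd
    peak_report = []
    for i, j, z in peaks:
        raw = axis_fwhm(i, j, z)
        corrected = float(np.sqrt(max(raw**2 - kernel_fwhm**2, 0.0)))
        peak_report.append({
            "location": [float(gx[i]), float(gy[j])], "height": float(z),
            "fwhm_raw": raw, "fwhm": corrected,
        })
    cluster_like = bool(peak_report) and all(p["fwhm"] <= error_radius for p in peak_report)
    return {
        "peaks": peak_report,
        "n_peaks": len(peak_report),
        "error_radius": float(error_radius),
        "verdict": "cluster_like" if cluster_like else "continuum_like",
    }
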