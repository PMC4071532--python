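"""Spatial weights, SAR error-model estimation, Moran's I and correlograms.

The regression response (per-region extinction severity) is spatially
autocorrelated, so the headline model is a simultaneous autoregressive model
of the error type: y = X beta + u, u = lambda W u + eps, eps ~ N(0, sigma^2 I),
estimated by maximum likelihood with the likelihood concentrated in lambda.
Residual autocorrelation before and after the SAR fit is summarized with
Moran's I correlograms over fixed-width distance classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree
from scipy.stats import norm

from .errors import (
    DegenerateInputError,
    DesignError,
    EstimationError,
    InvalidConfigError,
)

EARTH_RADIUS_KM = 6371.0


@dataclass
class SpatialWeights:
    """Row-standardized k-nearest-neighbour spatial weights.

    Each row of ``matrix`` has exactly ``k`` entries of 1/k and a zero
    diagonal.  The underlying adjacency may be asymmetric (A being among B's
    four closest neighbours does not imply the reverse).
    """

    matrix: sp.csr_matrix
    k: int
    style: str = "row-standardized"

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def __post_init__(self) -> None:
        rows = np.asarray(self.matrix.sum(axis=1)).ravel()
        if not np.allclose(rows, 1.0):
            raise InvalidConfigError("weight rows must sum to 1")

    @property
    def is_symmetric(self) -> bool:
        d = self.matrix - self.matrix.T
        return np.abs(d.data).max() < 1e-12 if d.nnz else True


def great_circle_km(coords_deg: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) for lon/lat columns in degrees."""
    lon = np.radians(coords_deg[:, 0])
    lat = np.radians(coords_deg[:, 1])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(
        dlon / 2
    ) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def knn_weights(centroids: np.ndarray, k: int = 4, spherical: bool = False) -> SpatialWeights:
    """Connect each point to its ``k`` closest neighbours; weights 1/k.

    ``centroids`` is (n, 2): planar km coordinates, or lon/lat degrees when
    ``spherical``.  Distance ties are broken by smallest index, making the
    neighbour sets deterministic.
    """
    pts = np.asarray(centroids, dtype=float)
    n = pts.shape[0]
    if n <= k:
        raise InvalidConfigError(f"need more than k={k} points, got {n}")
    if np.unique(pts, axis=0).shape[0] != n:
        raise DegenerateInputError("duplicate centroids")
    if spherical:
        dist = great_circle_km(pts)
        np.fill_diagonal(dist, np.inf)
        # lexsort on (index, distance): stable tie-break by smallest id
        order = np.lexsort((np.tile(np.arange(n), (n, 1)), dist), axis=1)
        nbrs = order[:, :k]
    else:
        tree = cKDTree(pts)
        _, idx = tree.query(pts, k=k + 1)
        nbrs = np.empty((n, k), dtype=int)
        for i in range(n):
            row = [j for j in idx[i] if j != i][:k]
            nbrs[i] = row
    rows = np.repeat(np.arange(n), k)
    data = np.full(n * k, 1.0 / k)
    w = sp.csr_matrix((data, (rows, nbrs.ravel())), shape=(n, n))
    return SpatialWeights(w, k=k)


# ---------------------------------------------------------------------------
# SAR error model
# ---------------------------------------------------------------------------


@dataclass
class SarFit:
    """Maximum-likelihood fit of the SAR error model."""

    params: np.ndarray
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    lam: float
    lam_se: float
    sigma2: float
    loglik: float
    aic: float
    pseudo_r2: float
    names: list[str]
    trend: np.ndarray
    residuals: np.ndarray  # y - X beta (spatially correlated errors u-hat)
    innovations: np.ndarray  # (I - lam W)(y - X beta) (whitened eps-hat)
    X: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def _logdet(lam: float, W: sp.csr_matrix) -> float:
    """log |det(I - lam W)| via sparse LU factorization."""
    n = W.shape[0]
    A = (sp.identity(n, format="csc") - lam * W.tocsc()).tocsc()
    lu = splu(A)
    diag = lu.U.diagonal()
    if np.any(diag == 0):
        raise EstimationError(f"I - lambda W singular at lambda={lam}")
    return float(np.sum(np.log(np.abs(diag))))


def concentrated_loglik(
    lam: float, X: np.ndarray, y: np.ndarray, W: sp.csr_matrix
) -> float:
    """Profile log-likelihood of the SAR error model at a given lambda.

    beta and sigma^2 are maximized analytically: transform both sides by
    (I - lam W), solve least squares, and plug sigma^2 = RSS/n back in.
    """
    n = len(y)
    A = sp.identity(n, format="csr") - lam * W
    ys = A @ y
    Xs = A @ X
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    rss = float(np.sum((ys - Xs @ beta) ** 2))
    if rss <= 0:
        return np.inf
    sigma2 = rss / n
    return -(n / 2.0) * (np.log(2 * np.pi * sigma2) + 1.0) + _logdet(lam, W)


def _full_loglik(
    beta: np.ndarray, lam: float, sigma2: float, X, y, W
) -> float:
    n = len(y)
    A = sp.identity(n, format="csr") - lam * W
    e = A @ (y - X @ beta)
    return (
        -(n / 2.0) * np.log(2 * np.pi * sigma2)
        - float(e @ e) / (2 * sigma2)
        + _logdet(lam, W)
    )


def _golden_max(f, lo, hi, tol=1e-7):
    """Golden-section maximization on [lo, hi]."""
    invphi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while abs(b - a) > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2


def sar_error_fit(
    X: np.ndarray,
    y: np.ndarray,
    W: SpatialWeights | sp.spmatrix,
    names: list[str] | None = None,
    lam_bounds: tuple[float, float] = (-0.999, 0.999),
    n_grid: int = 41,
    fix_lam: float | None = None,
) -> SarFit:
    """Fit y = X beta + u, u = lambda W u + eps by maximum likelihood.

    The likelihood is concentrated over lambda (grid scan bracketing a
    golden-section refinement); log-determinants come from sparse LU.
    Standard errors are from the inverse numerical Hessian of the full
    log-likelihood at the optimum.  ``fix_lam`` constrains lambda (e.g. 0
    reduces the fit to ordinary least squares).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    Wm = W.matrix if isinstance(W, SpatialWeights) else sp.csr_matrix(W)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise DesignError("design matrix is rank deficient")
    if names is None:
        names = [f"x{j}" for j in range(p)]

    if fix_lam is not None:
        lam = float(fix_lam)
    else:
        grid = np.linspace(lam_bounds[0], lam_bounds[1], n_grid)
        lls = []
        for g in grid:
            try:
                lls.append(concentrated_loglik(g, X, y, Wm))
            except EstimationError:
                lls.append(-np.inf)
        lls = np.asarray(lls)
        if not np.any(np.isfinite(lls)):
            raise EstimationError("likelihood undefined over the whole lambda grid")
        i = int(np.argmax(lls))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, n_grid - 1)]
        lam = _golden_max(lambda g: concentrated_loglik(g, X, y, Wm), lo, hi)

    A = sp.identity(n, format="csr") - lam * Wm
    ys, Xs = A @ y, A @ X
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    eps = ys - Xs @ beta
    rss = float(eps @ eps)
    sigma2 = rss / n
    ll = _full_loglik(beta, lam, sigma2, X, y, Wm)
    k_params = p + 2  # beta, lambda, sigma^2
    aic = -2 * ll + 2 * k_params

    # numerical Hessian of the full log-likelihood in (beta, lambda)
    theta = np.append(beta, lam)

    def ll_theta(t: np.ndarray) -> float:
        b, l = t[:p], t[p]
        Al = sp.identity(n, format="csr") - l * Wm
        e = Al @ (y - X @ b)
        r = float(e @ e)
        s2 = max(r / n, 1e-300)
        try:
            ld = _logdet(l, Wm)
        except EstimationError:
            return -np.inf
        return -(n / 2.0) * (np.log(2 * np.pi * s2) + 1.0) + ld

    m = p + 1
    h = 1e-4 * np.maximum(np.abs(theta), 1.0)
    H = np.empty((m, m))
    f0 = ll_theta(theta)
    for a_ in range(m):
        for b_ in range(a_, m):
            ea = np.zeros(m)
            eb = np.zeros(m)
            ea[a_] = h[a_]
            eb[b_] = h[b_]
            if a_ == b_:
                val = (ll_theta(theta + ea) - 2 * f0 + ll_theta(theta - ea)) / h[a_] ** 2
            else:
                val = (
                    ll_theta(theta + ea + eb)
                    - ll_theta(theta + ea - eb)
                    - ll_theta(theta - ea + eb)
                    + ll_theta(theta - ea - eb)
                ) / (4 * h[a_] * h[b_])
            H[a_, b_] = H[b_, a_] = val
    try:
        cov = np.linalg.inv(-H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(m, np.nan)
    bse = se_all[:p]
    lam_se = float(se_all[p]) if fix_lam is None else 0.0

    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / bse
    pv = 2 * norm.sf(np.abs(z))
    trend = X @ beta
    resid = y - trend
    innov = A @ resid
    pr2 = pseudo_r2_values(y, trend)
    return SarFit(
        params=beta,
        bse=bse,
        zvalues=z,
        pvalues=pv,
        lam=float(lam),
        lam_se=lam_se,
        sigma2=sigma2,
        loglik=float(ll),
        aic=float(aic),
        pseudo_r2=pr2,
        names=list(names),
        trend=trend,
        residuals=resid,
        innovations=innov,
        X=X,
    )


def predict_sar_trend(
    fit: SarFit, X_new: np.ndarray, back_transform: bool = False
) -> np.ndarray:
    """Trend component X beta-hat (no spatial smoothing).

    With ``back_transform`` the arcsine-scale trend is mapped back to a
    proportion via sin^2 after clamping to [0, pi/2].
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != len(fit.params):
        raise DesignError(
            f"X_new has {X_new.shape[1]} columns, fit has {len(fit.params)}"
        )
    eta = X_new @ fit.params
    if back_transform:
        return np.sin(np.clip(eta, 0.0, np.pi / 2)) ** 2
    return eta


def pseudo_r2_values(y: np.ndarray, trend: np.ndarray) -> float:
    """Squared Pearson correlation between observed y and the fitted trend."""
    if np.std(trend) == 0 or np.std(y) == 0:
        import warnings

        warnings.warn("constant trend or response; pseudo-R2 reported as 0")
        return 0.0
    return float(np.corrcoef(y, trend)[0, 1] ** 2)


def pseudo_r2(fit: SarFit, y: np.ndarray) -> float:
    return pseudo_r2_values(np.asarray(y, dtype=float), fit.trend)


# ---------------------------------------------------------------------------
# Moran's I and correlograms
# ---------------------------------------------------------------------------


def morans_i(z: np.ndarray, weights: SpatialWeights | sp.spmatrix | np.ndarray) -> float:
    """Moran's I: (n/S0) * sum_ij w_ij (z_i - zbar)(z_j - zbar) / sum_i (z_i - zbar)^2."""
    z = np.asarray(z, dtype=float).ravel()
    W = weights.matrix if isinstance(weights, SpatialWeights) else sp.csr_matrix(weights)
    n = len(z)
    d = z - z.mean()
    ss = float(d @ d)
    if ss == 0:
        raise DegenerateInputError("zero-variance vector")
    s0 = float(W.sum())
    if s0 == 0:
        raise DegenerateInputError("no weighted pairs")
    return (n / s0) * float(d @ (W @ d)) / ss


@dataclass
class Correlogram:
    """Moran's I by distance class with permutation p-values."""

    class_lo_km: np.ndarray
    class_hi_km: np.ndarray
    n_pairs: np.ndarray
    moran_i: np.ndarray  # NaN for empty classes (undefined, not zero)
    p_perm: np.ndarray

    def first_class(self) -> tuple[float, float]:
        """(I, p) of the first non-empty distance class."""
        for i in range(len(self.moran_i)):
            if self.n_pairs[i] > 0:
                return float(self.moran_i[i]), float(self.p_perm[i])
        raise DegenerateInputError("correlogram has no non-empty class")


def correlogram(
    residuals: np.ndarray,
    coords: np.ndarray,
    class_width_km: float = 500.0,
    n_perm: int = 999,
    seed: int = 0,
    spherical: bool = False,
    max_classes: int | None = None,
) -> Correlogram:
    """Moran's I per contiguous distance class, with two-sided permutation p.

    Distance classes are [0, w), [w, 2w), ... covering the largest pairwise
    distance.  Each class uses binary symmetric pair weights.  Empty classes
    get NaN I and p.  Permutation p-values are two-sided:
    2 * min(P(I* >= I), P(I* <= I)) capped at 1, including the observed value
    in the reference set.  ``max_classes`` limits the I/p computation to the
    first classes (pair counts are still reported for all classes).
    """
    z = np.asarray(residuals, dtype=float).ravel()
    pts = np.asarray(coords, dtype=float)
    n = len(z)
    if pts.shape[0] != n:
        raise DesignError("coords and residuals length mismatch")
    if np.unique(pts, axis=0).shape[0] != n:
        raise DegenerateInputError("duplicate coordinates")
    if class_width_km <= 0:
        raise InvalidConfigError("class width must be positive")
    if spherical:
        dist = great_circle_km(pts)
    else:
        diff = pts[:, None, :] - pts[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(n, 1)
    dmax = dist[iu].max()
    n_classes = int(np.floor(dmax / class_width_km)) + 1
    edges = np.arange(n_classes + 1) * class_width_km

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    d = z - z.mean()
    ss = float(d @ d)
    if ss == 0:
        raise DegenerateInputError("zero-variance residuals")

    lo, hi = edges[:-1], edges[1:]
    n_pairs = np.zeros(n_classes, dtype=int)
    moran = np.full(n_classes, np.nan)
    pvals = np.full(n_classes, np.nan)
    cls = np.floor(dist / class_width_km).astype(int)
    for c in range(n_classes):
        mask = (cls == c) & ~np.eye(n, dtype=bool)
        pair_count = int(mask.sum()) // 2
        n_pairs[c] = pair_count
        if pair_count == 0:
            continue
        if max_classes is not None and c >= max_classes:
            continue
        Wc = sp.csr_matrix(mask.astype(float))
        s0 = float(Wc.sum())
        obs = (n / s0) * float(d @ (Wc @ d)) / ss
        moran[c] = obs
        dp = d[perms]  # (n_perm, n)
        quad = np.einsum("ij,ij->i", dp, (Wc @ dp.T).T)
        istar = (n / s0) * quad / ss
        ge = int(np.sum(istar >= obs)) + 1
        le = int(np.sum(istar <= obs)) + 1
        pvals[c] = min(1.0, 2.0 * min(ge, le) / (n_perm + 1))
    return Correlogram(lo, hi, n_pairs, moran, pvals)
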