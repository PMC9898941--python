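"""Correlated Bernoulli model of read-level CpG methylation patterns.

A CpG segment of ``n`` sites carries a binary methylation pattern
``X = [X_1, ..., X_n]`` with marginals ``X_i ~ Bern(p_i)`` and between-site
(spatial) correlations ``r_ij = cor(X_i, X_j)``.  This module represents the
model parameters, evaluates the joint distribution of the ``2**n`` patterns,
and samples read matrices from it.

For correlated sites the joint distribution is obtained by latent-Gaussian
thresholding: ``X_i = 1`` iff ``Z_i <= z_i`` where ``Z ~ MVN(0, Sigma)`` is a
standard multivariate normal, ``z_i`` is the normal quantile of ``p_i``, and
each latent correlation ``Sigma_ij`` solves the tetrachoric-type equation

    Phi2(z_i, z_j; Sigma_ij) = r_ij * sqrt(p_i q_i p_j q_j) + p_i p_j,

with ``Phi2`` the bivariate standard-normal CDF and ``q_i = 1 - p_i``.

Bit-order convention (used everywhere in this package): pattern index ``i``
written in binary has the LAST CpG site as its least-significant bit, so
``q_1`` is the probability of pattern ``[0, ..., 0, 1]``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import reduce

import numpy as np
from scipy import optimize
from scipy.special import ndtr, ndtri, owens_t
from statsmodels.stats.correlation_tools import corr_nearest

__all__ = [
    "BernoulliParams",
    "LatentGaussianModel",
    "PatternDistribution",
    "ReadMatrix",
    "bivariate_normal_cdf",
    "pairwise_correlation_bounds",
    "solve_latent_correlation",
    "build_latent_model",
    "pattern_distribution",
    "sample_reads",
]

# Numerical policy for the whole package.
ROOT_RESIDUAL_TOL = 1e-8     # |Phi2 - target| after the latent-correlation solve
FEASIBILITY_SLACK = 1e-9     # tolerance when checking r_ij against its bounds
NORMALIZATION_TOL = 1e-6     # allowed |sum(q) - 1| before renormalization
MAX_REPAIR_PERTURBATION = 0.01  # refuse nearest-correlation repairs beyond this
_QUAD_NODES = 64             # Gauss-Legendre order for recursive conditioning


# ---------------------------------------------------------------------------
# Bivariate normal CDF (Owen's T), exact and fast
# ---------------------------------------------------------------------------

def bivariate_normal_cdf(h: float, k: float, rho: float) -> float:
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal with correlation rho.

    Evaluated through Owen's T function, accurate to ~1e-15.  Handles
    infinite arguments and the degenerate correlations rho = +-1.
    """
    if rho >= 1.0 - 1e-15:
        return ndtr(min(h, k))
    if rho <= -1.0 + 1e-15:
        return max(0.0, ndtr(h) + ndtr(k) - 1.0)
    if math.isinf(h) or math.isinf(k):
        if h == -math.inf or k == -math.inf:
            return 0.0
        return float(ndtr(k)) if math.isinf(h) else float(ndtr(h))
    if h == 0.0 and k == 0.0:
        return 0.25 + math.asin(rho) / (2.0 * math.pi)
    s = math.sqrt(1.0 - rho * rho)
    ah = math.copysign(math.inf, k) if h == 0.0 else (k - rho * h) / (h * s)
    ak = math.copysign(math.inf, h) if k == 0.0 else (h - rho * k) / (k * s)

    def _T(x: float, a: float) -> float:
        if math.isinf(a):
            return math.copysign(0.5 * ndtr(-abs(x)), a)
        return float(owens_t(x, a))

    delta = 0.5 if (h * k < 0.0 or (h * k == 0.0 and h + k < 0.0)) else 0.0
    val = 0.5 * (ndtr(h) + ndtr(k)) - _T(h, ah) - _T(k, ak) - delta
    return min(1.0, max(0.0, val))


# ---------------------------------------------------------------------------
# Model parameters
# ---------------------------------------------------------------------------

def pairwise_correlation_bounds(p_i: float, p_j: float) -> tuple[float, float]:
    """Attainable correlation interval for a bivariate Bernoulli.

    The joint success cell is Frechet-bounded,
    ``P11 in [max(0, p_i + p_j - 1), min(p_i, p_j)]``; mapping the interval
    endpoints to the correlation scale gives the feasible range of ``r_ij``.

    Raises ``ValueError`` for degenerate marginals (p in {0, 1}), where the
    correlation is undefined.
    """
    for p in (p_i, p_j):
        if not 0.0 < p < 1.0:
            raise ValueError(
                f"correlation undefined for degenerate marginal p={p!r}"
            )
    sd = math.sqrt(p_i * (1.0 - p_i) * p_j * (1.0 - p_j))
    lo = (max(0.0, p_i + p_j - 1.0) - p_i * p_j) / sd
    hi = (min(p_i, p_j) - p_i * p_j) / sd
    return lo, hi


def _as_prob_vector(p, n: int | None) -> np.ndarray:
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if p.size == 1 and n is not None:
        p = np.full(n, p[0])
    if n is not None and p.size != n:
        raise ValueError(f"expected {n} methylation probabilities, got {p.size}")
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("methylation probabilities must lie in [0, 1]")
    return p


@dataclass(frozen=True)
class BernoulliParams:
    """Parameters (p, R) of a correlated Bernoulli methylation-pattern model.

    ``p`` is the vector of per-site methylation probabilities and ``R`` the
    between-site (spatial) correlation matrix.  ``R`` must be symmetric with
    unit diagonal, every off-diagonal entry must respect the pairwise
    Frechet feasibility bounds for its marginals, and correlations to a
    degenerate site (p in {0, 1}) must vanish.
    """

    p: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        p = _as_prob_vector(self.p, None)
        R = np.asarray(self.R, dtype=float)
        n = p.size
        if R.shape != (n, n):
            raise ValueError(f"R must be {n}x{n}, got {R.shape}")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ValueError("R must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise ValueError("R must have a unit diagonal")
        if np.any(np.abs(R) > 1.0 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        for i, j in itertools.combinations(range(n), 2):
            r = R[i, j]
            if 0.0 < p[i] < 1.0 and 0.0 < p[j] < 1.0:
                lo, hi = pairwise_correlation_bounds(p[i], p[j])
                if r < lo - FEASIBILITY_SLACK or r > hi + FEASIBILITY_SLACK:
                    raise ValueError(
                        f"r[{i},{j}]={r:.6g} outside the feasible range "
                        f"[{lo:.6g}, {hi:.6g}] for marginals "
                        f"({p[i]:.6g}, {p[j]:.6g})"
                    )
            elif abs(r) > 1e-12:
                raise ValueError(
                    f"site {i if p[i] in (0.0, 1.0) else j} is degenerate; "
                    f"its correlations must be 0 (got r[{i},{j}]={r:.6g})"
                )
        p.setflags(write=False)
        R.setflags(write=False)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "R", R)

    @property
    def n(self) -> int:
        return self.p.size

    # -- convenience constructors ------------------------------------------
    @classmethod
    def independent(cls, p, n: int | None = None) -> "BernoulliParams":
        """Independent sites: R is the identity; scalar p means homogeneous."""
        p = _as_prob_vector(p, n)
        return cls(p, np.eye(p.size))

    @classmethod
    def exchangeable(cls, p, r: float, n: int | None = None) -> "BernoulliParams":
        """Exchangeable (compound-symmetric) correlation r_ij = r."""
        p = _as_prob_vector(p, n)
        R = np.full((p.size, p.size), float(r))
        np.fill_diagonal(R, 1.0)
        return cls(p, R)

    @classmethod
    def ar1(cls, p, r: float, n: int | None = None) -> "BernoulliParams":
        """First-order autoregressive correlation r_ij = r ** |i - j|."""
        p = _as_prob_vector(p, n)
        idx = np.arange(p.size)
        R = float(r) ** np.abs(idx[:, None] - idx[None, :])
        np.fill_diagonal(R, 1.0)
        return cls(p, R)


# ---------------------------------------------------------------------------
# Latent-Gaussian thresholding model
# ---------------------------------------------------------------------------

def solve_latent_correlation(p_i: float, p_j: float, r_ij: float) -> float:
    """Latent normal correlation reproducing a Bernoulli correlation.

    Solves ``Phi2(z_i, z_j; rho) = r_ij * sd + p_i * p_j`` for ``rho`` on
    [-1, 1] by bracketed root finding (the left side is monotone increasing
    in rho); the residual is below 1e-8.  Raises for infeasible ``r_ij`` or
    degenerate marginals.
    """
    lo, hi = pairwise_correlation_bounds(p_i, p_j)  # raises on degenerate p
    if r_ij < lo - FEASIBILITY_SLACK or r_ij > hi + FEASIBILITY_SLACK:
        bound = f"lower bound {lo:.6g}" if r_ij < lo else f"upper bound {hi:.6g}"
        raise ValueError(
            f"no latent correlation in [-1, 1]: r={r_ij:.6g} violates the "
            f"{bound} for marginals ({p_i:.6g}, {p_j:.6g})"
        )
    r_ij = min(max(r_ij, lo), hi)
    if r_ij == 0.0:
        return 0.0
    sd = math.sqrt(p_i * (1.0 - p_i) * p_j * (1.0 - p_j))
    target = r_ij * sd + p_i * p_j
    z_i, z_j = float(ndtri(p_i)), float(ndtri(p_j))

    def f(rho: float) -> float:
        return bivariate_normal_cdf(z_i, z_j, rho) - target

    if f(1.0) <= 0.0:    # r_ij at the comonotone bound
        return 1.0
    if f(-1.0) >= 0.0:   # r_ij at the antithetic bound
        return -1.0
    rho = optimize.brentq(f, -1.0, 1.0, xtol=1e-13, rtol=8.9e-16)
    if abs(f(rho)) > ROOT_RESIDUAL_TOL:
        raise RuntimeError(
            f"latent correlation solve residual {f(rho):.3g} exceeds tolerance"
        )
    return float(rho)


@dataclass(frozen=True)
class LatentGaussianModel:
    """Thresholds and latent-normal correlation of the dichotomized MVN.

    ``z`` holds the per-site dichotomization thresholds (normal quantiles of
    the methylation probabilities; +-inf for degenerate sites) and ``Sigma``
    the latent correlation matrix.  ``repaired`` flags a projection to the
    nearest correlation matrix, with ``max_perturbation`` the largest entry
    change the repair introduced.
    """

    z: np.ndarray
    Sigma: np.ndarray
    repaired: bool = False
    max_perturbation: float = 0.0

    @property
    def n(self) -> int:
        return self.z.size


def build_latent_model(params: BernoulliParams) -> LatentGaussianModel:
    """Assemble the latent MVN model from pairwise tetrachoric-type solves.

    A non-positive-semi-definite pairwise assembly is projected to the
    nearest correlation matrix (warning issued, perturbation recorded);
    perturbations beyond 0.01 are refused.
    """
    p, R, n = params.p, params.R, params.n
    with np.errstate(divide="ignore"):
        z = ndtri(p)  # -inf at p=0, +inf at p=1
    Sigma = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        if not (0.0 < p[i] < 1.0 and 0.0 < p[j] < 1.0):
            continue  # degenerate site: correlation constrained to 0
        try:
            rho = solve_latent_correlation(p[i], p[j], R[i, j])
        except (ValueError, RuntimeError) as exc:
            raise type(exc)(f"latent solve failed for sites ({i}, {j}): {exc}")
        Sigma[i, j] = Sigma[j, i] = rho
    eigmin = float(np.linalg.eigvalsh(Sigma).min())
    repaired = False
    max_pert = 0.0
    if eigmin < -1e-10:
        fixed = np.asarray(corr_nearest(Sigma, threshold=1e-12, n_fact=200))
        max_pert = float(np.abs(fixed - Sigma).max())
        if max_pert > MAX_REPAIR_PERTURBATION:
            raise ValueError(
                f"latent correlation repair perturbs entries by {max_pert:.4g} "
                f"(> {MAX_REPAIR_PERTURBATION}); parameters too incoherent"
            )
        warnings.warn(
            f"latent correlation matrix repaired (max entry change {max_pert:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
        Sigma = fixed
        repaired = True
    return LatentGaussianModel(z=z, Sigma=Sigma, repaired=repaired,
                               max_perturbation=max_pert)


# ---------------------------------------------------------------------------
# Pattern distribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternDistribution:
    """Probabilities q_0 .. q_{2**n - 1} over the methylation patterns.

    Index convention: the last CpG site is the least-significant bit, so
    index 1 is the pattern [0, ..., 0, 1].
    """

    n: int
    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.shape != (2 ** self.n,):
            raise ValueError(f"need {2 ** self.n} probabilities, got {q.shape}")
        if np.any(q < -1e-12):
            raise ValueError("pattern probabilities must be non-negative")
        if abs(q.sum() - 1.0) > NORMALIZATION_TOL:
            raise ValueError(f"pattern probabilities sum to {q.sum():.8g}, not 1")
        q = np.clip(q, 0.0, None)
        q = q / q.sum()
        q.setflags(write=False)
        object.__setattr__(self, "q", q)

    def marginals(self) -> np.ndarray:
        """Per-site methylation probabilities implied by the q's."""
        idx = np.arange(2 ** self.n)
        out = np.empty(self.n)
        for site in range(self.n):
            bit = (idx >> (self.n - 1 - site)) & 1
            out[site] = self.q[bit == 1].sum()
        return out

    def implied_correlation(self) -> np.ndarray:
        """Pairwise Bernoulli correlation matrix implied by the q's."""
        idx = np.arange(2 ** self.n)
        bits = np.array(
            [(idx >> (self.n - 1 - s)) & 1 for s in range(self.n)], dtype=float
        )
        mean = bits @ self.q
        cov = (bits * self.q) @ bits.T - np.outer(mean, mean)
        sd = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
        R = cov / np.outer(sd, sd)
        np.fill_diagonal(R, 1.0)
        return R


def _product_form(p: np.ndarray) -> np.ndarray:
    """Joint distribution under independent sites: tensor product of
    per-site (1-p, p) factors, first site most significant."""
    return reduce(np.kron, [np.array([1.0 - pi, pi]) for pi in p])


def _pair_closed_form(p1: float, p2: float, r: float) -> np.ndarray:
    """Exact 2-site joint distribution; for homogeneous p this is the
    closed form q0 = r p(1-p) + (1-p)^2, q1 = q2 = p(1-p)(1-r),
    q3 = r p(1-p) + p^2."""
    q11 = p1 * p2 + r * math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    q10 = p1 - q11
    q01 = p2 - q11
    q00 = 1.0 - p1 - p2 + q11
    return np.array([q00, q01, q10, q11])


def _exchangeable_pattern_probs(z: np.ndarray, rho: float) -> np.ndarray:
    """All 2**n pattern probabilities under a 1-factor latent model.

    With equicorrelated latent normals, Z_i = sqrt(rho) W + sqrt(1-rho) e_i,
    sites are conditionally independent given the shared factor W, so one
    quadrature over W yields every pattern probability at once.  The
    integration uses composite Gauss-Legendre panels whose edges bracket
    the conditional-probability transition regions, which keeps the result
    accurate (~1e-10) even as rho approaches 1 and the transitions sharpen.
    """
    if rho < 1e-10:  # factor carries no weight: sites independent
        return _product_form(ndtr(z))
    a, b = math.sqrt(rho), math.sqrt(1.0 - rho)
    centers = z / a
    halfwidth = 9.0 * b / a
    edges = {-9.0, 9.0}
    for c in centers:
        for e in (c - halfwidth, c + halfwidth):
            if -9.0 < e < 9.0:
                edges.add(float(e))
    edges = sorted(edges)
    xs, ws = _gauss_legendre(48)
    nodes, weights = [], []
    for lo, hi in zip(edges, edges[1:]):
        mid, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
        nodes.append(mid + half * xs)
        weights.append(half * ws)
    x = np.concatenate(nodes)
    w = np.concatenate(weights) * np.exp(-0.5 * x * x) / math.sqrt(2 * math.pi)
    cond = ndtr((z[None, :] - a * x[:, None]) / b)  # P(X_i=1 | W) per node
    probs = np.ones((x.size, 1))
    for site in range(z.size):
        site_f = np.stack([1.0 - cond[:, site], cond[:, site]], axis=1)
        probs = (probs[:, :, None] * site_f[:, None, :]).reshape(x.size, -1)
    return w @ probs


def _bvn_many(h: np.ndarray, k: np.ndarray, rho: float) -> np.ndarray:
    """Vectorized Owen's-T bivariate normal CDF for arrays h, k and a
    scalar correlation with |rho| < 1; handles infinite limits."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    out = np.empty(np.broadcast(h, k).shape)
    h, k = np.broadcast_arrays(h, k)
    neg = (h == -np.inf) | (k == -np.inf)
    h_inf = np.isposinf(h) & ~neg
    k_inf = np.isposinf(k) & ~neg
    fin = ~(neg | h_inf | k_inf)
    out[neg] = 0.0
    out[h_inf] = ndtr(k[h_inf])
    out[k_inf] = ndtr(h[k_inf])
    hf, kf = h[fin], k[fin]
    s = math.sqrt(1.0 - rho * rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        ah = (kf - rho * hf) / (hf * s)
        ak = (hf - rho * kf) / (kf * s)
    ah = np.where(hf == 0.0, np.copysign(np.inf, kf), ah)
    ak = np.where(kf == 0.0, np.copysign(np.inf, hf), ak)
    t_h = np.where(
        np.isinf(ah), np.copysign(0.5 * ndtr(-np.abs(hf)), ah), owens_t(hf, np.where(np.isinf(ah), 0.0, ah))
    )
    t_k = np.where(
        np.isinf(ak), np.copysign(0.5 * ndtr(-np.abs(kf)), ak), owens_t(kf, np.where(np.isinf(ak), 0.0, ak))
    )
    hk = hf * kf
    delta = np.where((hk < 0.0) | ((hk == 0.0) & (hf + kf < 0.0)), 0.5, 0.0)
    val = 0.5 * (ndtr(hf) + ndtr(kf)) - t_h - t_k - delta
    both_zero = (hf == 0.0) & (kf == 0.0)
    if both_zero.any():
        val = np.where(both_zero, 0.25 + math.asin(rho) / (2.0 * math.pi), val)
    out[fin] = np.clip(val, 0.0, 1.0)
    return out


def _rect2_many(l1, u1, l2, u2, rho: float) -> np.ndarray:
    """Vectorized bivariate rectangle probabilities."""
    if rho >= 1.0 - 1e-15 or rho <= -1.0 + 1e-15:
        # degenerate conditional correlation: fall back to scalar handling
        return np.array([
            bivariate_normal_cdf(a, b, rho) - bivariate_normal_cdf(c, b, rho)
            - bivariate_normal_cdf(a, d, rho) + bivariate_normal_cdf(c, d, rho)
            for a, b, c, d in zip(np.atleast_1d(u1), np.atleast_1d(u2),
                                  np.atleast_1d(l1), np.atleast_1d(l2))
        ])
    return np.clip(
        _bvn_many(u1, u2, rho) - _bvn_many(l1, u2, rho)
        - _bvn_many(u1, l2, rho) + _bvn_many(l1, l2, rho),
        0.0, 1.0,
    )


_leg_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gauss_legendre(order: int) -> tuple[np.ndarray, np.ndarray]:
    if order not in _leg_cache:
        _leg_cache[order] = np.polynomial.legendre.leggauss(order)
    return _leg_cache[order]


def _mvn_rectangle(lower: np.ndarray, upper: np.ndarray,
                   Sigma: np.ndarray) -> float:
    """P(lower < Z <= upper) for Z ~ MVN(0, Sigma), by recursive 1-D
    conditioning down to the exact bivariate CDF (accuracy ~1e-9)."""
    k = lower.size
    if k == 1:
        return float(ndtr(upper[0]) - ndtr(lower[0]))
    if k == 2:
        return float(_rect2_many(lower[0:1], upper[0:1],
                                 lower[1:2], upper[1:2], Sigma[0, 1])[0])
    lo0 = max(lower[0], -8.5)
    up0 = min(upper[0], 8.5)
    if lo0 >= up0:
        return 0.0
    xs, ws = _gauss_legendre(_QUAD_NODES)
    mid, half = 0.5 * (up0 + lo0), 0.5 * (up0 - lo0)
    nodes = mid + half * xs
    beta = Sigma[1:, 0]
    cond_cov = Sigma[1:, 1:] - np.outer(beta, beta)
    sd = np.sqrt(np.clip(np.diag(cond_cov), 1e-14, None))
    cond_corr = cond_cov / np.outer(sd, sd)
    np.fill_diagonal(cond_corr, 1.0)
    dens = ws * np.exp(-0.5 * nodes * nodes)
    if k == 3:
        mean1 = np.outer(nodes, beta)  # conditional means per node
        l = (lower[1:] - mean1) / sd
        u = (upper[1:] - mean1) / sd
        vals = _rect2_many(l[:, 0], u[:, 0], l[:, 1], u[:, 1], cond_corr[0, 1])
        return float(dens @ vals * half / math.sqrt(2.0 * math.pi))
    total = 0.0
    for xv, dv in zip(nodes, dens):
        mean = beta * xv
        total += dv * _mvn_rectangle(
            (lower[1:] - mean) / sd, (upper[1:] - mean) / sd, cond_corr
        )
    return total * half / math.sqrt(2.0 * math.pi)


def _latent_pattern_probs(model: LatentGaussianModel) -> np.ndarray:
    """Pattern probabilities from the latent model (no degenerate sites)."""
    z, Sigma, n = model.z, model.Sigma, model.n
    off = Sigma[~np.eye(n, dtype=bool)]
    if n >= 2 and off.size and np.all(np.abs(off - off[0]) < 1e-12):
        rho = float(off[0])
        if rho >= 1.0 - 1e-12:
            # comonotone latent: one variable Z drives every site, so the
            # methylated set is {i: z_i >= Z} and patterns are nested
            q = np.zeros(2 ** n)
            order = np.argsort(z)  # ascending thresholds
            edges = np.concatenate(([0.0], ndtr(z[order]), [1.0]))
            for k in range(n + 1):
                pattern = np.zeros(n, dtype=int)
                pattern[order[k:]] = 1  # sites whose threshold exceeds Z
                idx = int("".join(map(str, pattern)), 2)
                q[idx] += max(0.0, edges[k + 1] - edges[k])
            return q
        if rho >= 0.0:
            return _exchangeable_pattern_probs(z, rho)
    q = np.empty(2 ** n)
    for idx in range(2 ** n):
        bits = [(idx >> (n - 1 - s)) & 1 for s in range(n)]
        upper = np.where(bits, z, np.inf)
        lower = np.where(bits, -np.inf, z)
        q[idx] = _mvn_rectangle(lower, upper, Sigma)
    return q


def pattern_distribution(params: BernoulliParams) -> PatternDistribution:
    """Joint distribution of the 2**n methylation patterns.

    Independent sites use the exact product form; two sites use the exact
    closed form; larger segments go through the latent-Gaussian thresholding
    model.  Degenerate sites (p in {0, 1}) are held constant and the
    distribution computed on the remaining sites.  The result is
    renormalized after checking |sum(q) - 1| <= 1e-6.
    """
    p, R, n = params.p, params.R, params.n
    free = np.flatnonzero((p > 0.0) & (p < 1.0))
    if free.size < n:
        fixed_bits = (p > 0.5).astype(int)  # 1 where p == 1, 0 where p == 0
        if free.size == 0:
            sub_q = np.ones(1)
        else:
            sub = BernoulliParams(p[free], R[np.ix_(free, free)])
            sub_q = pattern_distribution(sub).q
        q = np.zeros(2 ** n)
        for sub_idx in range(sub_q.size):
            bits = fixed_bits.copy()
            for pos, site in enumerate(free):
                bits[site] = (sub_idx >> (free.size - 1 - pos)) & 1
            full_idx = int("".join(map(str, bits)), 2)
            q[full_idx] = sub_q[sub_idx]
        return PatternDistribution(n=n, q=q)
    if np.allclose(R, np.eye(n), atol=1e-14):
        return PatternDistribution(n=n, q=_product_form(p))
    if n == 2:
        return PatternDistribution(n=2, q=_pair_closed_form(p[0], p[1], R[0, 1]))
    model = build_latent_model(params)
    q = _latent_pattern_probs(model)
    if abs(q.sum() - 1.0) > NORMALIZATION_TOL:
        raise RuntimeError(
            f"pattern probabilities sum to {q.sum():.8g}; numerical failure"
        )
    return PatternDistribution(n=n, q=q)


# ---------------------------------------------------------------------------
# Read matrices and sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadMatrix:
    """m x n binary matrix of methylation states on reads fully covering a
    segment; optionally annotated with chromosome and 0-based site
    coordinates."""

    x: np.ndarray
    sites: tuple[int, ...] | None = None
    chrom: str | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x)
        if x.ndim != 2 or x.shape[0] < 1 or x.shape[1] < 1:
            raise ValueError("read matrix must be 2-D with m >= 1, n >= 1")
        if not np.isin(x, (0, 1)).all():
            raise ValueError("read matrix entries must be 0/1")
        x = x.astype(np.int8)
        if self.sites is not None and len(self.sites) != x.shape[1]:
            raise ValueError("site coordinates must match the column count")
        x.setflags(write=False)
        object.__setattr__(self, "x", x)

    @property
    def m(self) -> int:
        return self.x.shape[0]

    @property
    def n(self) -> int:
        return self.x.shape[1]

    def pattern_counts(self) -> np.ndarray:
        """Counts O_0 .. O_{2**n - 1} of observed patterns (last site =
        least-significant bit)."""
        weights = 1 << np.arange(self.n - 1, -1, -1)
        return np.bincount(self.x @ weights, minlength=2 ** self.n)


def sample_reads(params: BernoulliParams, m: int,
                 seed: int | np.random.Generator | None = None) -> ReadMatrix:
    """Sample m reads by thresholding latent multivariate-normal draws.

    Deterministic given the seed; accepts an integer seed or a
    ``numpy.random.Generator`` threaded in by the caller.
    """
    if m < 1:
        raise ValueError("need at least one read")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    model = build_latent_model(params)
    w, V = np.linalg.eigh(model.Sigma)
    A = V * np.sqrt(np.clip(w, 0.0, None))
    latent = rng.standard_normal((m, params.n)) @ A.T
    with np.errstate(invalid="ignore"):
        x = (latent <= model.z).astype(np.int8)
    return ReadMatrix(x=x)
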