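"""Two-component normal mixture for combining per-gene p-values.

Per-gene p-values from K = 1 or 2 association tests are transformed to
z-values, x_gk = Phi^{-1}(1 - p_gk), so smaller p-values map to larger
z-values. The G z-vectors are modelled as a two-component normal mixture

    f(x) = pi0 f0(x) + pi1 f1(x),

with f0 the null (non-associated) and f1 the associated component. In the
bivariate case the component densities factorize across the two test
dimensions (conditional independence given association status), i.e. each
component has a diagonal covariance. Parameters are fitted by EM; the
posterior probability of association,

    P(assoc | x_g) = pi1 f1(x_g) / (pi0 f0(x_g) + pi1 f1(x_g)),

ranks genes (ties share the top rank), and averaging (1 - posterior) over
a declared set estimates that set's FDR in the local-fdr sense. Under
model misfit the posteriors remain usable for ranking but the FDR
estimate should be treated with caution; results carry a caveat flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm, rankdata

VARIANCE_FLOOR = 1e-6

FDR_CAVEAT = (
    "FDR estimates assume the mixture fits the z-values; under misfit, "
    "use posteriors only to rank genes."
)


@dataclass
class MixtureParams:
    """Fitted mixture parameters.

    ``means``/``variances`` are (2, K) arrays; row 0 is the null component,
    row 1 the associated component (identified as the one with the larger
    mean in dimension 1, breaking ties on dimension 2).
    """

    pi0: float
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float = float("nan")
    n_iter: int = 0
    converged: bool = True
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def pi1(self) -> float:
        return 1.0 - self.pi0

    @property
    def n_dims(self) -> int:
        return self.means.shape[1]


@dataclass
class PosteriorResult:
    """Per-gene posterior probabilities of association with ranks.

    Ranks are by descending posterior; tied genes share the smallest
    (best) rank of their group.
    """

    gene_ids: list[str]
    posterior: np.ndarray
    rank: np.ndarray
    params: MixtureParams
    fdr_caveat: str = FDR_CAVEAT

    def fdr(self, cutoff: float) -> float:
        return estimate_fdr(self.posterior, cutoff)


def p_to_z(p, clamp: float | None = None) -> np.ndarray | float:
    """z-transformation x = Phi^{-1}(1 - p); strictly decreasing in p.

    ``clamp`` (e.g. 1/(2B) for B permutations) restricts p to
    [clamp, 1 - clamp] first so the transform stays finite.
    """
    arr = np.asarray(p, dtype=float)
    if clamp is not None:
        arr = np.clip(arr, clamp, 1.0 - clamp)
    if np.any((arr <= 0) | (arr >= 1)):
        raise ValueError("p-values must lie in (0, 1) after clamping")
    out = norm.ppf(1.0 - arr)
    return float(out) if np.isscalar(p) else out


def _log_component_density(z: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """(G, 2) log density of each observation under each diagonal component."""
    z = z[:, None, :]  # (G, 1, K)
    mu = means[None, :, :]
    var = variances[None, :, :]
    ll = -0.5 * (np.log(2 * np.pi * var) + (z - mu) ** 2 / var)
    return ll.sum(axis=2)


def _em_once(
    z: np.ndarray, resp1: np.ndarray, tol: float, max_iter: int
) -> MixtureParams:
    """EM from an initial responsibility vector for component 1."""
    G, K = z.shape
    resp = np.column_stack([1.0 - resp1, resp1])
    loglik_prev = -np.inf
    trace = []
    pi = resp.mean(axis=0)
    means = np.zeros((2, K))
    variances = np.ones((2, K))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # M step
        nk = resp.sum(axis=0) + 1e-12
        pi = nk / G
        means = (resp.T @ z) / nk[:, None]
        for l in range(2):
            dev = z - means[l]
            variances[l] = (resp[:, l] @ dev**2) / nk[l]
        variances = np.maximum(variances, VARIANCE_FLOOR)
        # E step
        log_dens = _log_component_density(z, means, variances)
        log_weighted = log_dens + np.log(np.maximum(pi, 1e-300))
        log_norm = logsumexp(log_weighted, axis=1)
        resp = np.exp(log_weighted - log_norm[:, None])
        loglik = float(log_norm.sum())
        trace.append(loglik)
        if loglik - loglik_prev < tol * (abs(loglik_prev) + 1.0) and it > 1:
            converged = True
            break
        loglik_prev = loglik
    # relabel: associated component has the larger mean in dim 1 (tie: dim 2)
    assoc = 1 if tuple(means[1]) >= tuple(means[0]) else 0
    null = 1 - assoc
    return MixtureParams(
        pi0=float(pi[null]),
        means=means[[null, assoc]].copy(),
        variances=variances[[null, assoc]].copy(),
        log_likelihood=trace[-1],
        n_iter=it,
        converged=converged,
        loglik_trace=np.array(trace),
    )


def fit_mixture(
    z: np.ndarray,
    n_restarts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | None = 0,
) -> MixtureParams:
    """Fit the two-component diagonal-covariance mixture by EM.

    The first start assigns component 1 to observations above the 90th
    percentile of the first dimension; further restarts use random split
    quantiles in [0.75, 0.95]. The best fit by final log-likelihood wins.
    Variances are floored at 1e-6 to prevent collapse; non-convergence
    within ``max_iter`` yields a warning and the best iterate.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[0] == 1 and z.shape[1] > 2:
        z = z.T
    G, K = z.shape
    if G < 10:
        raise ValueError("need at least 10 genes to fit the mixture")
    if K not in (1, 2):
        raise ValueError("K must be 1 or 2")
    if not np.isfinite(z).all():
        raise ValueError("z-matrix must be finite (clamp p-values before transforming)")
    rng = np.random.default_rng(seed)
    best: MixtureParams | None = None
    for r in range(n_restarts):
        q = 0.90 if r == 0 else float(rng.uniform(0.75, 0.95))
        cut = np.quantile(z[:, 0], q)
        resp1 = (z[:, 0] > cut).astype(float)
        if resp1.sum() == 0:  # everything below the cut; soften
            resp1 = np.full(G, 0.1)
        fit = _em_once(z, resp1, tol, max_iter)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    if not best.converged:
        warnings.warn("EM did not converge within max_iter; returning best iterate")
    return best


def posterior(
    z: np.ndarray, params: MixtureParams, gene_ids: list[str] | None = None
) -> PosteriorResult:
    """Posterior probability of association per gene, with shared-tie ranks.

    Computed in log space, so simultaneous density underflow cannot
    produce NaN.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] != params.n_dims:
        z = z.T
    G = z.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(G)]
    log_dens = _log_component_density(z, params.means, params.variances)
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.array([params.pi0, params.pi1]))
    log_weighted = log_dens + log_pi
    post = np.exp(log_weighted[:, 1] - logsumexp(log_weighted, axis=1))
    post = np.where(np.isfinite(post), post, 0.0)
    ranks = rankdata(-post, method="min").astype(int)
    return PosteriorResult(list(gene_ids), post, ranks, params)


def estimate_fdr(posteriors: np.ndarray, cutoff: float) -> float:
    """FDR of the set {posterior >= cutoff}: mean local fdr (1 - posterior).

    An empty declared set returns 0.0 with a warning.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must lie in (0, 1]")
    posteriors = np.asarray(posteriors, dtype=float)
    declared = posteriors >= cutoff
    if not declared.any():
        warnings.warn("no genes declared at this cutoff; FDR defined as 0")
        return 0.0
    return float(np.mean(1.0 - posteriors[declared]))


def combine(
    p1: np.ndarray,
    p2: np.ndarray | None = None,
    gene_ids: list[str] | None = None,
    *,
    clamp: float | None = None,
    n_restarts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | None = 0,
) -> PosteriorResult:
    """Full pipeline: z-transform -> EM fit -> posteriors and ranks.

    With two p-value vectors (e.g. SIFT-based and PolyPhen-2-based VT
    tests) the bivariate conditional-independence mixture is fitted; with
    one, the univariate variant. ``clamp`` defaults to half the smallest
    attainable permutation p-value inferred from the data (half of min p),
    which keeps the transform finite for add-one permutation p-values.
    """
    p1 = np.asarray(p1, dtype=float)
    if p2 is not None:
        p2 = np.asarray(p2, dtype=float)
        if p1.shape != p2.shape:
            raise ValueError("p-value vectors have mismatched lengths")
    if gene_ids is not None and len(gene_ids) != len(p1):
        raise ValueError("gene_ids length does not match p-values")
    if clamp is None:
        pmin = np.nanmin(p1 if p2 is None else np.minimum(p1, p2))
        clamp = min(pmin / 2.0, 1e-4)
    cols = [p_to_z(p1, clamp=clamp)]
    if p2 is not None:
        cols.append(p_to_z(p2, clamp=clamp))
    z = np.column_stack(cols)
    params = fit_mixture(z, n_restarts=n_restarts, tol=tol, max_iter=max_iter, seed=seed)
    return posterior(z, params, gene_ids)
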