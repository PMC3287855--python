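"""Variable-threshold (VT) burden test with functional weights.

For a gene with m variants, phenotype pi_j in {0,1} and weights S_i, the
z-score at a MAF threshold T is

    z(T) = sum_i d_i(T) S_i sum_j C_ij (pi_j - pibar)
           / sqrt( sum_i d_i(T) S_i^2 sum_j C_ij^2 )

where d_i(T) = 1 if MAF_i < T else 0 and C_ij is the minor-allele count.
z_max maximizes z(T) over a grid of candidate thresholds derived from the
gene's observed MAFs; significance comes from permuting phenotype labels
and re-running the same maximization in every permutation.

The test is one-sided: large z means an excess of (weighted) rare minor
alleles in cases.

Because the denominator and the per-threshold weighted burden do not
depend on the phenotype, permutations reduce to a single matrix product
per gene, which is what :func:`vt_permutation_test` exploits.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_io import GeneIndex, GenotypeMatrix, PhenotypeVector
from .errors import DegenerateGeneWarning, DegeneratePhenotypeError
from .weighting import SCHEMES, make_weights

NEG_INF = float("-inf")

# Permutations are processed in blocks to bound peak memory.
_PERM_BLOCK = 2000


@dataclass
class GeneTestResult:
    """Result of one weighted VT test on one gene.

    ``p_value`` is NaN for degenerate genes (no threshold configuration
    with positive denominator, e.g. all weights zero or all counts zero).
    """

    gene: str
    scheme: str
    z_max: float
    best_threshold: float
    p_value: float
    n_permutations: int
    n_snps: int
    n_nonsyn: int
    # mid-p assigns half weight to permutations tying the observed z_max;
    # with few carriers z_max is heavily discrete, and the plain estimator
    # is conservative while mid-p is close to uniform under the null
    mid_p: float = float("nan")


def candidate_thresholds(mafs: Sequence[float]) -> np.ndarray:
    """Candidate MAF thresholds for a gene.

    The inclusion rule is strict (MAF_i < T), so the grid consists of the
    midpoints between consecutive distinct observed MAFs plus one value
    above the maximum: one threshold per distinct MAF, each realizing one
    nested variant configuration, the last including every variant.
    """
    mafs = np.asarray(mafs, dtype=float)
    if mafs.size == 0:
        raise ValueError("empty MAF list")
    if ((mafs < 0) | (mafs > 0.5)).any():
        raise ValueError("MAF values must lie in [0, 0.5]")
    distinct = np.unique(mafs)
    if distinct.size == 1:
        # single configuration: anything above the one observed MAF
        return np.array([distinct[0] + 0.01])
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    top = distinct[-1] + (distinct[-1] - distinct[-2]) / 2.0
    return np.append(mids, top)


def z_score(
    counts: np.ndarray,
    phenotype: PhenotypeVector | np.ndarray,
    weights: np.ndarray,
    mafs: np.ndarray,
    T: float,
) -> float:
    """z(T) by direct evaluation of the defining formula.

    Returns -inf when no variant contributes (empty configuration or all
    included weights zero) so that the maximization can never select it.
    """
    pi = phenotype.values if isinstance(phenotype, PhenotypeVector) else np.asarray(phenotype)
    if pi.min() == pi.max():
        raise DegeneratePhenotypeError("phenotype is constant")
    counts = np.asarray(counts, dtype=float)
    weights = np.asarray(weights, dtype=float)
    mafs = np.asarray(mafs, dtype=float)
    include = mafs < T
    s = np.where(include, weights, 0.0)
    denom_sq = float(np.sum(s**2 * np.sum(counts**2, axis=0)))
    if denom_sq <= 0.0:
        return NEG_INF
    pibar = pi.mean()
    num = float(np.sum(s * (counts.T @ (pi - pibar))))
    return num / np.sqrt(denom_sq)


def _sweep_matrices(
    counts: np.ndarray, weights: np.ndarray, mafs: np.ndarray, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-threshold weighted burden B (k x n_subjects) and denominators.

    B[t, j] = sum_i d_i(T_t) S_i C_ij; denom[t] = sqrt(sum_i d_i S_i^2 sum_j C_ij^2).
    Degenerate thresholds get denom 0.
    """
    counts = np.asarray(counts, dtype=float)
    include = mafs[None, :] < grid[:, None]  # (k, m)
    sw = include * weights[None, :]
    B = sw @ counts.T
    css = np.sum(counts**2, axis=0)
    denom = np.sqrt((include * weights[None, :] ** 2) @ css)
    return B, denom


def z_max(
    counts: np.ndarray,
    phenotype: PhenotypeVector | np.ndarray,
    weights: np.ndarray,
    mafs: np.ndarray,
    grid: np.ndarray | None = None,
) -> tuple[float, float]:
    """Maximum z over the threshold grid; ties go to the smallest threshold.

    Returns ``(-inf, nan)`` when every threshold is degenerate.
    """
    pi = phenotype.values if isinstance(phenotype, PhenotypeVector) else np.asarray(phenotype)
    if pi.min() == pi.max():
        raise DegeneratePhenotypeError("phenotype is constant")
    if grid is None:
        grid = candidate_thresholds(mafs)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    B, denom = _sweep_matrices(counts, weights, np.asarray(mafs, float), grid)
    ok = denom > 0
    if not ok.any():
        return NEG_INF, float("nan")
    pibar = pi.mean()
    num = B @ (pi - pibar)
    z = np.full(grid.shape, NEG_INF)
    z[ok] = num[ok] / denom[ok]
    best = int(np.argmax(z))  # argmax takes the first (smallest threshold) on ties
    return float(z[best]), float(grid[best])


def vt_permutation_test(
    counts: np.ndarray,
    phenotype: PhenotypeVector | np.ndarray,
    weights: np.ndarray,
    mafs: np.ndarray,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    gene: str = "",
    scheme: str = "",
    n_nonsyn: int | None = None,
) -> GeneTestResult:
    """Permutation VT test for one gene.

    The MAF grid is fixed from the full observed sample; phenotype labels
    are permuted and the full threshold maximization re-runs in each
    permutation. The p-value uses the add-one estimator
    p = (1 + #{z_max_perm >= z_max_obs}) / (1 + n_perm), so p >= 1/(n_perm+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pi = phenotype.values if isinstance(phenotype, PhenotypeVector) else np.asarray(phenotype)
    if pi.min() == pi.max():
        raise DegeneratePhenotypeError("phenotype is constant")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.asarray(counts, dtype=float)
    weights = np.asarray(weights, dtype=float)
    mafs = np.asarray(mafs, dtype=float)
    n_snps = counts.shape[1]
    if n_nonsyn is None:
        n_nonsyn = n_snps
    grid = candidate_thresholds(mafs)
    B, denom = _sweep_matrices(counts, weights, mafs, grid)
    ok = denom > 0
    if not ok.any():
        warnings.warn(f"gene {gene!r}: degenerate (no testable threshold)", DegenerateGeneWarning)
        return GeneTestResult(
            gene, scheme, NEG_INF, float("nan"), float("nan"), n_perm, n_snps, n_nonsyn
        )
    pi = pi.astype(float)
    pibar = pi.mean()
    num_obs = B[ok] @ (pi - pibar)
    z = num_obs / denom[ok]
    best_local = int(np.argmax(z))
    z_obs = float(z[best_local])
    best_threshold = float(grid[np.flatnonzero(ok)[best_local]])

    Bok = B[ok]
    dok = denom[ok]
    offset = pibar * Bok.sum(axis=1)  # sum_j B[t,j] * pibar, permutation-invariant
    greater = 0
    tied = 0
    done = 0
    # small tolerance so fp noise cannot turn an exact tie into a miss
    tol = 1e-12 * max(1.0, abs(z_obs))
    while done < n_perm:
        block = min(_PERM_BLOCK, n_perm - done)
        perms = rng.permuted(np.broadcast_to(pi, (block, pi.size)), axis=1)
        numer = Bok @ perms.T - offset[:, None]
        z_perm = (numer / dok[:, None]).max(axis=0)
        greater += int(np.sum(z_perm > z_obs + tol))
        tied += int(np.sum(np.abs(z_perm - z_obs) <= tol))
        done += block
    p = (1 + greater + tied) / (1 + n_perm)
    mid_p = (0.5 + greater + 0.5 * tied) / (1 + n_perm)
    return GeneTestResult(
        gene, scheme, z_obs, best_threshold, p, n_perm, n_snps, n_nonsyn, mid_p
    )


def _gene_seed(master_seed: int, gene: str, scheme: str) -> np.random.Generator:
    """Per-(gene, scheme) RNG substream, invariant to processing order."""
    key = zlib.crc32(f"{gene}\x00{scheme}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), key]))


def run_all_schemes(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeVector,
    annotation: pd.DataFrame,
    gene_index: GeneIndex,
    schemes: Iterable[str] | str = "all",
    n_perm: int = 10_000,
    seed: int = 0,
    *,
    sift_impute: float = 0.1,
    polyphen_impute: float = 0.2,
) -> list[GeneTestResult]:
    """Run the VT test for every gene in the (filtered) index under each scheme.

    Permutation streams are derived from ``(seed, gene, scheme)`` so results
    do not depend on gene processing order.
    """
    if schemes == "all":
        scheme_list = list(SCHEMES)
    elif isinstance(schemes, str):
        scheme_list = [schemes]
    else:
        scheme_list = list(schemes)
    ann_by_vid = annotation.set_index("variant_id")
    results: list[GeneTestResult] = []
    for gene, cols in gene_index.items():
        cols = np.asarray(cols)
        counts = genotypes.counts[:, cols]
        mafs = genotypes.maf[cols]
        vids = [genotypes.variant_ids[c] for c in cols]
        ann = ann_by_vid.loc[vids].reset_index()
        n_nonsyn = int(ann["is_nonsynonymous"].sum())
        for scheme in scheme_list:
            w = make_weights(
                scheme, ann, sift_impute=sift_impute, polyphen_impute=polyphen_impute
            )
            rng = _gene_seed(seed, gene, scheme)
            results.append(
                vt_permutation_test(
                    counts, phenotype, w, mafs, n_perm, rng,
                    gene=gene, scheme=scheme, n_nonsyn=n_nonsyn,
                )
            )
    return results
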