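import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vtcombine import (
    SimConfig,
    candidate_thresholds,
    filter_genes,
    run_all_schemes,
    simulate_dataset,
    vt_permutation_test,
    z_max,
    z_score,
)
from vtcombine.errors import DegenerateGeneWarning, DegeneratePhenotypeError


def brute_force_z(counts, pi, weights, include):
    """Literal evaluation of the weighted burden z-score on an inclusion set."""
    pibar = np.mean(pi)
    num = 0.0
    den = 0.0
    for i in range(counts.shape[1]):
        if include[i]:
            num += weights[i] * sum(counts[j, i] * (pi[j] - pibar) for j in range(len(pi)))
            den += weights[i] ** 2 * sum(counts[j, i] ** 2 for j in range(len(pi)))
    if den <= 0:
        return -math.inf
    return num / math.sqrt(den)


def brute_force_zmax(counts, pi, weights, mafs):
    """Exhaustive maximization over every MAF-threshold inclusion set."""
    best = -math.inf
    for t in sorted(set(mafs)):
        include = [m <= t for m in mafs]
        best = max(best, brute_force_z(counts, pi, weights, include))
    return best


def random_gene(rng, n_subjects=30, max_variants=12):
    m = rng.integers(2, max_variants + 1)
    mafs_true = rng.uniform(0.01, 0.4, size=m)
    counts = rng.binomial(2, mafs_true, size=(n_subjects, m))
    # fold so the counted allele is minor, as the loader guarantees
    f = counts.sum(axis=0) / (2 * n_subjects)
    counts[:, f > 0.5] = 2 - counts[:, f > 0.5]
    mafs = counts.sum(axis=0) / (2 * n_subjects)
    pi = np.zeros(n_subjects, dtype=int)
    pi[rng.choice(n_subjects, size=n_subjects // 2, replace=False)] = 1
    weights = rng.uniform(0, 1, size=m)
    return counts, pi, weights, mafs


class TestCandidateThresholds:
    def test_one_configuration_per_distinct_maf(self):
        grid = candidate_thresholds([0.01, 0.01, 0.10])
        assert len(grid) == 2
        # first threshold captures only the rare pair, last captures all
        assert 0.01 < grid[0] <= 0.10 < grid[-1]

    def test_single_distinct_maf_single_configuration(self):
        grid = candidate_thresholds([0.05, 0.05])
        assert len(grid) == 1 and grid[0] > 0.05

    def test_three_nested_configurations(self):
        mafs = np.array([0.01, 0.02, 0.03])
        grid = candidate_thresholds(mafs)
        sets = [tuple(mafs < t) for t in grid]
        assert sets == [
            (True, False, False),
            (True, True, False),
            (True, True, True),
        ]

    def test_grid_strictly_increasing_and_covers_all(self):
        mafs = np.array([0.3, 0.001, 0.05, 0.05])
        grid = candidate_thresholds(mafs)
        assert (np.diff(grid) > 0).all()
        assert (mafs < grid[-1]).all()

    def test_rejects_invalid_maf(self):
        with pytest.raises(ValueError):
            candidate_thresholds([0.6])


class TestZScore:
    def test_hand_computed_example(self):
        # 4 subjects, phenotypes (1,1,0,0), one carrier among cases:
        # pibar=0.5, numerator 1*(0.5)=0.5, denominator sqrt(1*1)=1
        counts = np.array([[1], [0], [0], [0]])
        z = z_score(counts, np.array([1, 1, 0, 0]), np.array([1.0]), np.array([0.1]), 0.5)
        assert z == pytest.approx(0.5)

    def test_all_zero_weights_give_sentinel(self):
        counts = np.array([[1], [0], [0], [0]])
        z = z_score(counts, np.array([1, 1, 0, 0]), np.array([0.0]), np.array([0.1]), 0.5)
        assert z == -math.inf

    def test_weight_scale_cancels_for_single_variant(self):
        counts = np.array([[2], [1], [0], [0]])
        args = (counts, np.array([1, 0, 1, 0]), np.array([0.1]))
        z1 = z_score(args[0], args[1], np.array([0.4]), np.array([0.1]), 0.5)
        z2 = z_score(args[0], args[1], np.array([0.8]), np.array([0.1]), 0.5)
        assert z1 == pytest.approx(z2)

    def test_constant_phenotype_rejected(self):
        with pytest.raises(DegeneratePhenotypeError):
            z_score(np.ones((3, 1)), np.array([1, 1, 1]), np.ones(1), np.array([0.1]), 0.5)


class TestZMax:
    def test_single_configuration_equals_z(self):
        counts, pi, w, mafs = random_gene(np.random.default_rng(0))
        grid = np.array([1.0])  # include everything
        zm, thr = z_max(counts, pi, w, mafs, grid)
        assert zm == pytest.approx(z_score(counts, pi, w, mafs, 1.0))
        assert thr == 1.0

    def test_matches_brute_force_on_random_genes(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            counts, pi, w, mafs = random_gene(rng)
            zm, _ = z_max(counts, pi, w, mafs)
            assert zm == pytest.approx(brute_force_zmax(counts, pi, w, mafs), abs=1e-10)

    def test_zmax_dominates_every_threshold(self):
        rng = np.random.default_rng(1)
        counts, pi, w, mafs = random_gene(rng)
        grid = candidate_thresholds(mafs)
        zm, _ = z_max(counts, pi, w, mafs, grid)
        for t in grid:
            assert zm >= z_score(counts, pi, w, mafs, t) - 1e-12

    def test_best_threshold_is_grid_member(self):
        counts, pi, w, mafs = random_gene(np.random.default_rng(2))
        grid = candidate_thresholds(mafs)
        _, thr = z_max(counts, pi, w, mafs, grid)
        assert thr in grid

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_joint_subject_permutation(self, seed):
        rng = np.random.default_rng(seed)
        counts, pi, w, mafs = random_gene(rng, n_subjects=15, max_variants=6)
        perm = rng.permutation(len(pi))
        z1, t1 = z_max(counts, pi, w, mafs)
        z2, t2 = z_max(counts[perm], pi[perm], w, mafs)
        assert z1 == pytest.approx(z2) and t1 == t2


class TestPermutationTest:
    def test_p_bounded_below_by_add_one(self):
        counts, pi, w, mafs = random_gene(np.random.default_rng(3))
        res = vt_permutation_test(counts, pi, w, mafs, n_perm=50, seed=0)
        assert res.p_value >= 1 / 51

    def test_fixed_seed_reproducible(self):
        counts, pi, w, mafs = random_gene(np.random.default_rng(4))
        r1 = vt_permutation_test(counts, pi, w, mafs, n_perm=300, seed=9)
        r2 = vt_permutation_test(counts, pi, w, mafs, n_perm=300, seed=9)
        assert r1.p_value == r2.p_value and r1.z_max == r2.z_max

    def test_matches_exhaustive_permutation_small_n(self):
        # n=6 subjects, 3 cases: only C(6,3)=20 distinct label placements
        rng = np.random.default_rng(7)
        counts = rng.binomial(2, 0.3, size=(6, 3))
        mafs = counts.sum(axis=0) / 12.0
        mafs = np.minimum(mafs, 1 - mafs)
        w = np.array([1.0, 0.6, 0.3])
        pi = np.array([1, 1, 1, 0, 0, 0])
        z_obs = brute_force_zmax(counts, pi, w, mafs)
        exhaustive = []
        for cases in itertools.combinations(range(6), 3):
            perm_pi = np.zeros(6, dtype=int)
            perm_pi[list(cases)] = 1
            exhaustive.append(brute_force_zmax(counts, perm_pi, w, mafs))
        p_exact = np.mean([z >= z_obs - 1e-12 for z in exhaustive])
        n_perm = 10_000
        res = vt_permutation_test(counts, pi, w, mafs, n_perm=n_perm, seed=1)
        se = math.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(res.p_value - p_exact) <= 3 * se + 1 / (n_perm + 1)

    def test_degenerate_gene_reports_nan_with_warning(self):
        counts = np.zeros((6, 2), dtype=int)
        pi = np.array([1, 1, 1, 0, 0, 0])
        with pytest.warns(DegenerateGeneWarning):
            res = vt_permutation_test(counts, pi, np.ones(2), np.zeros(2), n_perm=10, seed=0)
        assert math.isnan(res.p_value)


class TestRunAllSchemes:
    def test_one_result_per_gene_scheme(self, small_bundle):
        b = small_bundle
        idx = filter_genes(b.annotation, 2, variant_ids=b.genotypes.variant_ids)
        genes = dict(itertools.islice(idx.items(), 3))
        res = run_all_schemes(
            b.genotypes, b.phenotype, b.annotation, genes, n_perm=50, seed=0
        )
        assert len(res) == 12
        assert {(r.gene, r.scheme) for r in res} == {
            (g, s) for g in genes for s in ("unweighted", "binary", "sift", "polyphen")
        }

    def test_results_invariant_to_gene_order(self, small_bundle):
        b = small_bundle
        idx = filter_genes(b.annotation, 2, variant_ids=b.genotypes.variant_ids)
        genes = dict(itertools.islice(idx.items(), 4))
        fwd = run_all_schemes(
            b.genotypes, b.phenotype, b.annotation, genes, "unweighted", n_perm=100, seed=3
        )
        rev = run_all_schemes(
            b.genotypes, b.phenotype, b.annotation, dict(reversed(genes.items())),
            "unweighted", n_perm=100, seed=3,
        )
        assert {r.gene: r.p_value for r in fwd} == {r.gene: r.p_value for r in rev}

    def test_unweighted_equals_binary_when_all_nonsynonymous(self):
        rng = np.random.default_rng(10)
        counts = rng.binomial(2, 0.1, size=(40, 4))
        ann = pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(4)],
                "gene": "G",
                "is_nonsynonymous": True,
                "sift_score": 0.0,  # SIFT weight 1 - 0 = 1: coincides too
                "polyphen_score": np.nan,
            }
        )
        from vtcombine.data_io import GenotypeMatrix, PhenotypeVector

        g = GenotypeMatrix.from_counts([f"s{i}" for i in range(40)], ann.variant_id, counts)
        pi = PhenotypeVector(g.subject_ids, rng.permutation([1] * 12 + [0] * 28))
        res = run_all_schemes(g, pi, ann, {"G": np.arange(4)}, n_perm=200, seed=5)
        by_scheme = {r.scheme: r for r in res}
        assert by_scheme["unweighted"].z_max == pytest.approx(by_scheme["binary"].z_max)
        assert by_scheme["binary"].z_max == pytest.approx(by_scheme["sift"].z_max)


class TestNullCalibration:
    def test_type_one_error_near_nominal(self, null_vt_pvalues):
        """Rejection rate at alpha=0.05 on null genes stays within 3 binomial SDs."""
        p = null_vt_pvalues
        n = len(p)
        rate = float(np.mean(p <= 0.05))
        sd = math.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) <= 3 * sd

    def test_null_pvalues_look_uniform(self, null_vt_results):
        """KS vs uniform on mid-p values (midpoint correction for ties)."""
        from scipy.stats import kstest

        mid = np.array([r.mid_p for r in null_vt_results])
        mid = mid[np.isfinite(mid)]
        assert kstest(mid, "uniform").pvalue > 0.01
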