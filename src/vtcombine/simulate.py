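"""Synthetic mini-exome generator with known ground truth.

Emulates the structure of a small case-control exome study: ~700 unrelated
subjects with a ~30% case fraction, genes carrying 2-231 variants (median
6), a rare-skewed MAF spectrum, ~55% nonsynonymous variants, SIFT and
PolyPhen-2 scores whose dichotomized calls agree with a configurable odds
ratio (default 5), score missingness at the observed rates, and causal
genes whose risk variants are rare, nonsynonymous and latently damaging,
so that deleteriousness-weighted tests are favored by construction.

Genotypes are Hardy-Weinberg draws, Binomial(2, MAF) per subject, with no
linkage disequilibrium. The binary phenotype comes from a liability
threshold model: liability = sum of per-allele effects over causal
variants plus standard normal noise, with case status assigned to the top
liability quantile so the case count is exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data_io import (
    GenotypeMatrix,
    PhenotypeVector,
    write_annotation,
    write_genotypes,
    write_phenotypes,
)

# Observed marginal rates of damaging calls among jointly scored variants
# (4945/11840 SIFT-damaging, 6003/11840 PolyPhen-damaging).
SIFT_DAMAGING_MARGINAL = 0.418
POLYPHEN_DAMAGING_MARGINAL = 0.507


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic mini-exome.

    Defaults mirror the emulated study: 697 subjects with 209 cases, gene
    sizes log-normal-ish with min 2 / median ~6 / max 231, Beta(0.25, 5)
    MAFs (mostly below 5%), 55% nonsynonymous, score-concordance odds
    ratio 5, and missing-score fractions 939/13572 and 1241/13572.
    """

    n_subjects: int = 697
    case_fraction: float = 209 / 697
    n_genes: int = 100
    gene_size_min: int = 2
    gene_size_max: int = 231
    gene_size_log_mu: float = math.log(4.0)
    gene_size_log_sigma: float = 1.1
    maf_beta_a: float = 0.25
    maf_beta_b: float = 5.0
    nonsyn_fraction: float = 0.55
    score_or_target: float = 5.0
    latent_damaging_fraction: float = 0.5
    sift_damaging_marginal: float = SIFT_DAMAGING_MARGINAL
    polyphen_damaging_marginal: float = POLYPHEN_DAMAGING_MARGINAL
    sift_missing_fraction: float = 939 / 13572
    polyphen_missing_fraction: float = 1241 / 13572
    causal_gene_fraction: float = 0.1
    effect_size: float = 0.8
    causal_maf_max: float = 0.05
    seed: int = 0

    def validate(self) -> "SimConfig":
        fracs = (
            self.case_fraction, self.nonsyn_fraction, self.latent_damaging_fraction,
            self.sift_missing_fraction, self.polyphen_missing_fraction,
            self.causal_gene_fraction,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if not math.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")
        return self


@dataclass
class SimTruth:
    """Ground truth: the causal genes and their causal variants/effects."""

    causal_genes: list[str]
    causal_variants: list[str]
    effects: dict[str, float] = field(default_factory=dict)


@dataclass
class Bundle:
    """A complete in-memory synthetic dataset."""

    genotypes: GenotypeMatrix
    annotation: pd.DataFrame
    phenotype: PhenotypeVector
    truth: SimTruth
    config: SimConfig


def _draw_gene_sizes(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    raw = config.gene_size_min + rng.lognormal(
        config.gene_size_log_mu, config.gene_size_log_sigma, size=config.n_genes
    ) - 2.0
    return np.clip(np.round(raw), config.gene_size_min, config.gene_size_max).astype(int)


def simulate_gene_structure(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Gene/variant scaffold: ids, gene sizes, nonsynonymous flags."""
    sizes = _draw_gene_sizes(config, rng)
    genes = [f"GENE{g:04d}" for g in range(config.n_genes)]
    rows = []
    v = 0
    for gene, size in zip(genes, sizes):
        for _ in range(size):
            rows.append((f"SNP{v:06d}", gene, bool(rng.random() < config.nonsyn_fraction)))
            v += 1
    return pd.DataFrame(rows, columns=["variant_id", "gene", "is_nonsynonymous"]).assign(
        sift_score=np.nan, polyphen_score=np.nan
    )


def simulate_genotypes(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    variant_ids: list[str] | None = None,
) -> GenotypeMatrix:
    """HWE genotypes with per-variant MAFs drawn Beta(a, b) (rare-skewed)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if variant_ids is None:
        sizes = _draw_gene_sizes(config, rng)
        variant_ids = [f"SNP{v:06d}" for v in range(int(sizes.sum()))]
    m = len(variant_ids)
    mafs = np.minimum(rng.beta(config.maf_beta_a, config.maf_beta_b, size=m), 0.5)
    counts = rng.binomial(2, mafs[None, :], size=(config.n_subjects, m)).astype(np.int16)
    subjects = [f"S{j:04d}" for j in range(config.n_subjects)]
    return GenotypeMatrix.from_counts(subjects, variant_ids, counts)


def _concordance_probs(lam: float, config: SimConfig) -> tuple[float, float, float, float]:
    """Classifier sensitivities/false-positive rates at separation lam.

    Given the latent damaging fraction q and a marginal damaging-call rate
    m, the damaging-conditional call rate interpolates from m (lam=0, no
    signal) to min(1, m/q) (lam=1, maximal), with the benign-conditional
    rate solved from the marginal constraint.
    """
    q = config.latent_damaging_fraction
    ms, mp = config.sift_damaging_marginal, config.polyphen_damaging_marginal
    s1 = ms + lam * (min(1.0, ms / q) - ms)
    p1 = mp + lam * (min(1.0, mp / q) - mp)
    s0 = (ms - q * s1) / (1.0 - q)
    p0 = (mp - q * p1) / (1.0 - q)
    return s1, s0, p1, p0


def _dichotomized_or(lam: float, config: SimConfig) -> float:
    q = config.latent_damaging_fraction
    s1, s0, p1, p0 = _concordance_probs(lam, config)
    pp = q * s1 * p1 + (1 - q) * s0 * p0
    pm = q * s1 * (1 - p1) + (1 - q) * s0 * (1 - p0)
    mp_ = q * (1 - s1) * p1 + (1 - q) * (1 - s0) * p0
    mm = q * (1 - s1) * (1 - p1) + (1 - q) * (1 - s0) * (1 - p0)
    if pm * mp_ == 0:
        return 1e12  # effectively infinite; keeps the root find finite
    return (pp * mm) / (pm * mp_)


def calibrate_score_separation(config: SimConfig) -> float:
    """Find the latent separation hitting the target dichotomized OR.

    One-dimensional root find; OR is 1 at zero separation and increases
    monotonically, so targets <= 1 are infeasible for this concordant
    construction and raise.
    """
    if config.score_or_target <= 1.0:
        raise ValueError("concordant construction requires an OR target > 1")
    hi = 0.999
    while _dichotomized_or(hi, config) < config.score_or_target:
        hi = 1 - (1 - hi) / 10
        if 1 - hi < 1e-12:
            raise ValueError("OR target unattainable under the marginal constraints")
    return float(
        brentq(lambda l: _dichotomized_or(l, config) - config.score_or_target, 1e-9, hi)
    )


def simulate_scores(
    annotation: pd.DataFrame, config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Attach SIFT/PolyPhen scores (and latent damaging flags) to nonsyn variants.

    Each nonsynonymous variant gets a latent damaging status; the two
    algorithms' dichotomous calls are drawn conditionally independently
    given that status, with rates calibrated so the realized dichotomized
    OR matches the configured target. Continuous scores are then drawn
    uniformly within the call's interval (SIFT damaging: [0, 0.05);
    PolyPhen damaging: (0.2, 1]). The configured fractions are set to
    missing completely at random.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ann = annotation.copy()
    lam = calibrate_score_separation(config)
    s1, s0, p1, p0 = _concordance_probs(lam, config)
    nonsyn = ann["is_nonsynonymous"].to_numpy(dtype=bool)
    n_ns = int(nonsyn.sum())
    damaging = rng.random(n_ns) < config.latent_damaging_fraction
    s_plus = rng.random(n_ns) < np.where(damaging, s1, s0)
    p_plus = rng.random(n_ns) < np.where(damaging, p1, p0)
    sift = np.where(s_plus, rng.uniform(0.0, 0.05, n_ns), rng.uniform(0.05, 1.0, n_ns))
    poly = np.where(p_plus, rng.uniform(0.2, 1.0, n_ns), rng.uniform(0.0, 0.2, n_ns))
    sift[rng.random(n_ns) < config.sift_missing_fraction] = np.nan
    poly[rng.random(n_ns) < config.polyphen_missing_fraction] = np.nan
    ann["sift_score"] = np.nan
    ann["polyphen_score"] = np.nan
    ann.loc[nonsyn, "sift_score"] = sift
    ann.loc[nonsyn, "polyphen_score"] = poly
    ann["latent_damaging"] = False
    ann.loc[nonsyn, "latent_damaging"] = damaging
    return ann


def choose_causal(
    annotation: pd.DataFrame,
    genotypes: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SimTruth:
    """Pick causal genes and their causal variants.

    Eligible genes have at least one rare (MAF < causal_maf_max),
    nonsynonymous, latently damaging variant; those variants become causal
    with a common per-allele liability effect.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    maf_by_vid = dict(zip(genotypes.variant_ids, genotypes.maf))
    ann = annotation.assign(maf=[maf_by_vid[v] for v in annotation["variant_id"]])
    eligible_mask = (
        ann["is_nonsynonymous"]
        & ann.get("latent_damaging", pd.Series(True, index=ann.index))
        & (ann["maf"] < config.causal_maf_max)
        & (ann["maf"] > 0)
    )
    eligible_genes = sorted(ann.loc[eligible_mask, "gene"].unique())
    n_causal = int(round(config.causal_gene_fraction * config.n_genes))
    if n_causal == 0:
        return SimTruth([], [], {})
    if not eligible_genes:
        raise ValueError("causal fraction > 0 but no gene has eligible causal variants")
    n_causal = min(n_causal, len(eligible_genes))
    causal_genes = sorted(rng.choice(eligible_genes, size=n_causal, replace=False).tolist())
    mask = eligible_mask & ann["gene"].isin(causal_genes)
    causal_variants = ann.loc[mask, "variant_id"].tolist()
    effects = {v: config.effect_size for v in causal_variants}
    return SimTruth(causal_genes, causal_variants, effects)


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> PhenotypeVector:
    """Liability-threshold phenotype with an exact case count.

    liability_j = sum over causal variants i of effect_i * C_ij + N(0,1);
    the ceil(n * case_fraction) subjects with the highest liability are
    cases, so the case count is deterministic given the config.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = genotypes.n_subjects
    liability = rng.standard_normal(n)
    if truth.causal_variants:
        pos = {v: i for i, v in enumerate(genotypes.variant_ids)}
        idx = np.array([pos[v] for v in truth.causal_variants])
        eff = np.array([truth.effects[v] for v in truth.causal_variants])
        liability = liability + genotypes.counts[:, idx] @ eff
    n_cases = int(round(config.case_fraction * n))
    order = np.argsort(-liability, kind="stable")
    values = np.zeros(n, dtype=np.int8)
    values[order[:n_cases]] = 1
    return PhenotypeVector(genotypes.subject_ids, values)


def simulate_dataset(config: SimConfig, seed: int | None = None) -> Bundle:
    """Generate a complete synthetic dataset (single seeded RNG stream)."""
    config.validate()
    if seed is not None:
        config = SimConfig(**{**asdict(config), "seed": seed})
    rng = np.random.default_rng(config.seed)
    ann = simulate_gene_structure(config, rng)
    genotypes = simulate_genotypes(config, rng, variant_ids=ann["variant_id"].tolist())
    ann = simulate_scores(ann, config, rng)
    truth = choose_causal(ann, genotypes, config, rng)
    phenotype = simulate_phenotype(genotypes, truth, config, rng)
    return Bundle(genotypes, ann, phenotype, truth, config)


def make_benchmark(config: SimConfig, outdir: str | Path) -> Bundle:
    """Write a self-contained benchmark directory in the package's formats.

    Emits genotypes.tsv, annotation.tsv, phenotype.tsv, truth.json and a
    MANIFEST.json with the seed and realized summary statistics.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_dataset(config)
    write_genotypes(bundle.genotypes, outdir / "genotypes.tsv")
    write_annotation(bundle.annotation, outdir / "annotation.tsv")
    write_phenotypes(bundle.phenotype, outdir / "phenotype.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "causal_genes": bundle.truth.causal_genes,
                "causal_variants": bundle.truth.causal_variants,
                "effects": bundle.truth.effects,
            },
            fh,
            indent=2,
        )
    ns = bundle.annotation["is_nonsynonymous"]
    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "n_subjects": bundle.genotypes.n_subjects,
        "n_cases": bundle.phenotype.n_cases,
        "n_variants": bundle.genotypes.n_variants,
        "n_genes": int(bundle.annotation["gene"].nunique()),
        "nonsyn_fraction": float(ns.mean()),
        "n_causal_genes": len(bundle.truth.causal_genes),
    }
    with open(outdir / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return bundle
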