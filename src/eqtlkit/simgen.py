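"""Synthetic multi-study eQTL data with known causal architecture.

Generates genotype panels with block-wise linkage disequilibrium (LD),
negative-binomial expression counts driven by planted cis effects, latent
covariates and technical factors, and GWAS summary statistics simulated
directly in z-score space on the same LD structure.  Three studies drawn
from one population share the variant panel, so colocalization and
cross-study classification can be scored against ground truth.

The model deliberately avoids coalescent machinery: haplotypes are
thresholded latent Gaussians with correlation exp(-ld_decay * distance)
inside each LD block, which is adequate (and fast) for LD-aware testing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PopulationModel",
    "GeneEffect",
    "GwasSignal",
    "CausalArchitecture",
    "GenotypeMatrix",
    "ExpressionCounts",
    "SummaryStatTrack",
    "ScenarioBundle",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_gwas_summary",
    "make_scenario",
    "SCENARIOS",
]

#: Ridge mixed into the LD correlation matrix before Cholesky.
LD_RIDGE = 1e-3

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PopulationModel:
    """LD and allele-frequency model for one genotype region.

    Parameters
    ----------
    n_variants : number of variants in the region.
    maf_range : (low, high) minor allele frequencies, sampled uniformly.
    ld_decay : latent correlation decay rate per base pair (>= 0).
    block_size : variants per LD block; blocks are independent.
    region_span : base pairs covered by the region.
    """

    n_variants: int = 60
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 5e-5
    block_size: int = 20
    region_span: int = 120_000

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.ld_decay < 0:
            raise ValueError("ld_decay must be >= 0")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")


@dataclass(frozen=True)
class GeneEffect:
    """One planted cis-eQTL: variant index, per-allele effect, active studies."""

    gene: str
    causal_index: int
    effect_size: float  # phenotype SD units per alt allele in active studies
    studies: frozenset = frozenset()
    amplification: dict = field(default_factory=dict)  # study -> multiplier > 0

    def __post_init__(self) -> None:
        for study, amp in self.amplification.items():
            if amp <= 0:
                raise ValueError(f"amplification for {study} must be > 0, got {amp}")

    def beta_in(self, study: str) -> float:
        if study not in self.studies:
            return 0.0
        return self.effect_size * self.amplification.get(study, 1.0)


@dataclass(frozen=True)
class GwasSignal:
    """GWAS causal variant for one locus: index, non-centrality, eQTL match flag."""

    causal_index: int
    lam: float  # non-centrality of the causal z-score
    matches_eqtl: bool


@dataclass
class CausalArchitecture:
    """Planted truth for a scenario: per-gene eQTL effects plus GWAS signals."""

    effects: list  # list[GeneEffect]
    gwas: list  # list[GwasSignal]

    def effects_for(self, gene: str) -> list:
        return [e for e in self.effects if e.gene == gene]


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with per-variant metadata.

    ``variants`` columns: variant_id, chrom, pos (1-based), ref, alt, maf
    (realized minor allele frequency computed from the dosages).
    """

    dosages: np.ndarray  # (n_samples, n_variants), values in [0, 2]
    variants: pd.DataFrame
    samples: list

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in panel")
        return self.dosages[:, idx[0]]

    def concat(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        if self.samples != other.samples:
            raise ValueError("sample lists differ")
        variants = pd.concat([self.variants, other.variants], ignore_index=True)
        return GenotypeMatrix(
            dosages=np.hstack([self.dosages, other.dosages]),
            variants=variants,
            samples=self.samples,
        )


@dataclass
class ExpressionCounts:
    """Genes x samples raw counts plus annotations and simulation truth."""

    counts: np.ndarray  # (n_genes, n_samples), non-negative integers
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand
    samples: list
    library_sizes: np.ndarray = None
    known_covariates: pd.DataFrame = None  # per-sample sex (0/1), batch (int)
    latent_factors: np.ndarray = None  # (n_samples, q) truth, testing only
    latent_values: np.ndarray = None  # (n_genes, n_samples) pre-count truth

    def __post_init__(self) -> None:
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]


@dataclass
class SummaryStatTrack:
    """Per-variant summary statistics for one trait over one region."""

    trait_id: str
    trait_type: str  # "quantitative" | "case-control"
    table: pd.DataFrame  # variant_id, chrom, pos, ref, alt, beta, se, z, p, maf
    n: int
    case_fraction: float = None
    sd_y: float = 1.0

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "case-control"):
            raise ValueError(f"unknown trait type {self.trait_type!r}")
        if (self.table["se"] <= 0).any():
            raise ValueError("standard errors must be positive")

    def subset(self, variant_ids) -> "SummaryStatTrack":
        mask = self.table["variant_id"].isin(set(variant_ids))
        return dataclasses.replace(self, table=self.table[mask].reset_index(drop=True))


@dataclass
class ScenarioBundle:
    """Three-study fixture plus ground truth for downstream scoring."""

    name: str
    studies: dict  # study name -> (GenotypeMatrix, ExpressionCounts)
    gwas: SummaryStatTrack
    truth: CausalArchitecture
    labels: dict  # gene_id -> expected sharing/novelty label
    disease_study: str = "disease"


# ---------------------------------------------------------------------------
# genotypes


def _block_chol(positions: np.ndarray, ld_decay: float) -> np.ndarray:
    dist = np.abs(positions[:, None] - positions[None, :])
    corr = np.exp(-ld_decay * dist)
    corr = (1.0 - LD_RIDGE) * corr + LD_RIDGE * np.eye(len(positions))
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - ridge prevents this
        raise ArithmeticError("LD matrix not positive definite after ridge") from exc


def define_variant_panel(
    pop: PopulationModel, seed: int, chrom: str = "1", start: int = 1
) -> pd.DataFrame:
    """Positions, alleles and target allele frequencies for one region.

    The panel definition is what studies drawn from the same population
    share; genotype sampling happens per study in :func:`simulate_genotypes`.
    """
    rng = np.random.default_rng(seed)
    positions = np.sort(
        rng.choice(pop.region_span, size=pop.n_variants, replace=False)
    ) + start
    target_maf = rng.uniform(*pop.maf_range, size=pop.n_variants)
    ref = _BASES[rng.integers(0, 4, size=pop.n_variants)]
    alt = np.array(
        [_BASES[(list(_BASES).index(r) + rng.integers(1, 4)) % 4] for r in ref]
    )
    return pd.DataFrame(
        {
            "variant_id": [
                f"{chrom}_{p}_{r}_{a}" for p, r, a in zip(positions, ref, alt)
            ],
            "chrom": chrom,
            "pos": positions.astype(int),
            "ref": ref,
            "alt": alt,
            "target_maf": target_maf,
        }
    )


def simulate_genotypes(
    pop: PopulationModel,
    n_samples: int,
    seed: int,
    chrom: str = "1",
    start: int = 1,
    panel: pd.DataFrame = None,
) -> GenotypeMatrix:
    """Draw a dosage matrix from a latent Gaussian copula with block LD.

    Two latent haplotype draws per individual are thresholded at each
    variant's allele frequency and summed, so dosages are hard calls in
    {0, 1, 2} and within-block correlation decays as exp(-ld_decay * d).
    Deterministic given ``seed``.  Passing the same ``panel`` (from
    :func:`define_variant_panel`) to several calls yields studies sampled
    from one population sharing positions, alleles and frequencies.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if pop.n_variants < 1:
        raise ValueError("empty variant panel")
    if panel is None:
        panel = define_variant_panel(pop, seed, chrom, start)
    rng = np.random.default_rng(seed)

    positions = panel["pos"].to_numpy()
    thresholds = stats.norm.ppf(panel["target_maf"].to_numpy())

    dosage = np.zeros((n_samples, pop.n_variants), dtype=np.float64)
    for lo in range(0, pop.n_variants, pop.block_size):
        hi = min(lo + pop.block_size, pop.n_variants)
        chol = _block_chol(positions[lo:hi].astype(float), pop.ld_decay)
        for _hap in range(2):
            z = rng.standard_normal((n_samples, hi - lo)) @ chol.T
            dosage[:, lo:hi] += (z < thresholds[lo:hi]).astype(np.float64)

    freq = dosage.mean(axis=0) / 2.0
    variants = panel.drop(columns=["target_maf"]).copy()
    variants["maf"] = np.minimum(freq, 1.0 - freq)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    return GenotypeMatrix(dosages=dosage, variants=variants, samples=samples)


# ---------------------------------------------------------------------------
# expression


def effect_for_variance(variance_explained: float, dosage: np.ndarray) -> float:
    """Per-allele effect so the genetic term explains the requested fraction.

    The non-genetic latent variance is standardized to 1, so an effect
    beta = sqrt(v / (1 - v)) / sd(dosage) yields genetic fraction v.
    """
    if not (0.0 <= variance_explained < 1.0):
        raise ValueError("variance fraction must be in [0, 1)")
    sd = dosage.std()
    if sd == 0:
        raise ValueError("monomorphic causal variant")
    return np.sqrt(variance_explained / (1.0 - variance_explained)) / sd


def simulate_expression(
    geno: GenotypeMatrix,
    arch: CausalArchitecture,
    genes: pd.DataFrame,
    study: str,
    seed: int,
    overdispersion: float = 0.05,
    n_latent_factors: int = 0,
    factor_loading_sd: float = 1.0,
    covariate_loading_sd: float = 0.25,
    baseline_log_mean: tuple[float, float] = (3.5, 6.0),
    library_size_sd: float = 0.25,
    n_batches: int = 2,
) -> ExpressionCounts:
    """Negative-binomial counts with planted cis effects and latent structure.

    Per gene, the latent value is the amplified genetic term plus sex/batch
    loadings, latent factor loadings and unit-variance Gaussian noise; counts
    are gamma-Poisson with mean ``libsize_factor * exp(baseline + 0.5*latent)``.
    """
    if overdispersion < 0:
        raise ValueError("overdispersion must be >= 0")
    rng = np.random.default_rng(seed)
    n = geno.n_samples
    n_genes = len(genes)

    sex = rng.integers(0, 2, size=n)
    batch = rng.integers(0, n_batches, size=n)
    factors = rng.standard_normal((n, n_latent_factors))

    sex_load = rng.normal(0.0, covariate_loading_sd, size=n_genes)
    batch_load = rng.normal(0.0, covariate_loading_sd, size=(n_genes, n_batches))
    fac_load = rng.normal(0.0, factor_loading_sd, size=(n_genes, n_latent_factors))
    baseline = rng.uniform(*baseline_log_mean, size=n_genes)
    lib_factor = np.exp(rng.normal(0.0, library_size_sd, size=n))

    effects_by_gene: dict[str, list] = {}
    for eff in arch.effects:
        effects_by_gene.setdefault(eff.gene, []).append(eff)

    latent = np.empty((n_genes, n), dtype=np.float64)
    for gi, gene_id in enumerate(genes["gene_id"]):
        genetic = np.zeros(n)
        for eff in effects_by_gene.get(gene_id, []):
            if eff.causal_index >= geno.n_variants or eff.causal_index < 0:
                raise ValueError(
                    f"causal index {eff.causal_index} out of range for panel"
                )
            genetic += eff.beta_in(study) * geno.dosages[:, eff.causal_index]
        nongenetic = (
            sex_load[gi] * sex
            + batch_load[gi, batch]
            + fac_load[gi] @ factors.T
            + rng.standard_normal(n)
        )
        # standardize so the requested variance fraction is met regardless of
        # how much covariate/factor structure this gene happens to carry
        sd = nongenetic.std()
        latent[gi] = genetic + (nongenetic - nongenetic.mean()) / (sd if sd > 0 else 1.0)

    mu = lib_factor[None, :] * np.exp(baseline[:, None] + latent)
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        lam = rng.gamma(shape, mu * overdispersion)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)

    covs = pd.DataFrame({"sex": sex, "batch": batch}, index=geno.samples)
    return ExpressionCounts(
        counts=counts,
        genes=genes.reset_index(drop=True),
        samples=list(geno.samples),
        # sequencing depth is a known technical quantity, recorded rather
        # than re-derived from the (small) simulated gene set
        library_sizes=lib_factor * 1e6,
        known_covariates=covs,
        latent_factors=factors,
        latent_values=latent,
    )


# ---------------------------------------------------------------------------
# GWAS summary statistics


def regularized_ld(dosages: np.ndarray, ridge: float = LD_RIDGE) -> np.ndarray:
    """Dosage correlation matrix shrunk to positive definiteness."""
    sd = dosages.std(axis=0)
    if (sd == 0).any():
        # monomorphic columns get unit diagonal / zero correlation
        safe = dosages + 1e-9 * np.random.default_rng(0).standard_normal(dosages.shape)
        corr = np.corrcoef(safe, rowvar=False)
    else:
        corr = np.corrcoef(dosages, rowvar=False)
    m = corr.shape[0]
    return (1.0 - ridge) * corr + ridge * np.eye(m)


def simulate_gwas_summary(
    geno_ref: GenotypeMatrix,
    causal_index: int,
    lam: float,
    n_gwas: int,
    seed: int,
    trait_id: str = "trait",
    trait_type: str = "case-control",
    case_fraction: float = 0.5,
) -> SummaryStatTrack:
    """Draw one GWAS z-vector from N(R e_c * lam, R) on the panel's LD.

    beta = z / sqrt(n) and se = 1 / sqrt(n), so z = beta / se exactly.
    No individual-level cohort is materialized.
    """
    if not np.isfinite(lam):
        raise ValueError("lambda must be finite")
    if n_gwas < 1:
        raise ValueError("n_gwas must be >= 1")
    if causal_index < 0 or causal_index >= geno_ref.n_variants:
        raise ValueError("causal_index out of range")
    rng = np.random.default_rng(seed)
    R = regularized_ld(geno_ref.dosages)
    try:
        chol = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ArithmeticError("LD matrix not invertible after regularization") from exc
    mean = R[:, causal_index] * lam
    z = mean + chol @ rng.standard_normal(geno_ref.n_variants)
    se = np.full_like(z, 1.0 / np.sqrt(n_gwas))
    beta = z * se
    table = geno_ref.variants[["variant_id", "chrom", "pos", "ref", "alt", "maf"]].copy()
    table["beta"] = beta
    table["se"] = se
    table["z"] = z
    table["p"] = 2.0 * stats.norm.sf(np.abs(z))
    return SummaryStatTrack(
        trait_id=trait_id,
        trait_type=trait_type,
        table=table,
        n=n_gwas,
        case_fraction=case_fraction if trait_type == "case-control" else None,
    )


# ---------------------------------------------------------------------------
# scenarios

#: Default study sample sizes mirror a smaller disease cohort against two
#: larger reference cohorts.
DEFAULT_SAMPLE_SIZES = {"disease": 250, "ref1": 350, "ref2": 450}

#: Spacing between gene regions; larger than the cis window so each gene's
#: window contains only its own variants.
GENE_SPACING = 3_000_000

#: Default GWAS non-centrality for a genome-wide-significant index variant.
GWAS_LAMBDA = 12.0

GWAS_N = 40_000


#: background genes per scenario: no cis variants (they sit on their own
#: chromosome) but full covariate/factor structure, so normalization and
#: control-gene selection see a realistic expression matrix
N_BACKGROUND_GENES = 150


def _gene_table(n_genes: int, pop: PopulationModel,
                n_background: int = N_BACKGROUND_GENES) -> pd.DataFrame:
    """Genes on alternating strands, one region per gene, TSS mid-region."""
    rows = []
    for gi in range(n_genes):
        region_start = 1 + gi * GENE_SPACING
        strand = "+" if gi % 2 == 0 else "-"
        gstart = region_start + pop.region_span // 2
        gend = gstart + 20_000
        rows.append(
            {
                "gene_id": f"gene_{gi:03d}",
                "chrom": "1",
                "start": gstart,
                "end": gend,
                "strand": strand,
            }
        )
    for bi in range(n_background):
        gstart = 1 + bi * 200_000
        rows.append(
            {
                "gene_id": f"bg_{bi:03d}",
                "chrom": "2",
                "start": gstart,
                "end": gstart + 20_000,
                "strand": "+" if bi % 2 == 0 else "-",
            }
        )
    return pd.DataFrame(rows)


def _panel(
    pop: PopulationModel,
    n_genes: int,
    n_samples: int,
    panel_seed: int,
    sample_seed: int,
) -> GenotypeMatrix:
    """One genotype matrix covering all gene regions.

    The variant panel (positions, alleles, frequencies) depends only on
    ``panel_seed`` so every study drawn from the population shares it; the
    individuals depend on ``sample_seed``.
    """
    out = None
    for gi in range(n_genes):
        defn = define_variant_panel(
            pop, seed=panel_seed + 7919 * gi, chrom="1", start=1 + gi * GENE_SPACING
        )
        g = simulate_genotypes(
            pop, n_samples, seed=sample_seed + 7919 * gi, panel=defn
        )
        out = g if out is None else out.concat(g)
    return out


@dataclass(frozen=True)
class _ScenarioSpec:
    n_genes: int
    build: callable


def _distinct_block_index(pop: PopulationModel, causal: int) -> int:
    """A variant index in a different LD block from ``causal``."""
    block = causal // pop.block_size
    other = (block + 2) % max(1, (pop.n_variants + pop.block_size - 1) // pop.block_size)
    if other == block:
        other = (block + 1) % 2
    return other * pop.block_size + pop.block_size // 2


#: Planted variance fraction per scenario when the caller does not choose
#: one.  The distinct-causal scenario plants a strong eQTL: separating H3
#: from H2 requires the eQTL signal to be independently detectable against
#: the 1e-4 per-variant prior, i.e. a lead |z| of roughly 5 or more.
SCENARIO_VARIANCE = {
    "null": 0.0,
    "shared-coloc": 0.10,
    "distinct-causal": 0.15,
    "disease-unique": 0.15,
    "rescue": 0.10,
    "three-study": 0.10,
}


def make_scenario(
    name: str,
    seed: int,
    sample_sizes: dict = None,
    pop: PopulationModel = None,
    eqtl_variance: float = None,
    overdispersion: float = 0.05,
    n_latent_factors: int = 3,
) -> ScenarioBundle:
    """Build a packaged three-study scenario with ground-truth labels.

    Catalogue
    ---------
    null            no causal effects anywhere.
    shared-coloc    one gene with an eQTL in all studies; GWAS causal variant
                    coincides with the eQTL causal variant (label: shared).
    distinct-causal eQTL and GWAS causal variants in different LD blocks
                    (label: not-colocalized).
    disease-unique  the eQTL is active only in the disease study and matches
                    the GWAS causal variant (label: novel).
    rescue          strong eQTL in ref1 colocalizing with GWAS; the disease
                    study carries a weaker sub-threshold copy of the same
                    signal (label: rescued).
    three-study     multi-gene mix of all of the above plus null genes,
                    exercised by the end-to-end pipeline.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; options: {sorted(SCENARIOS)}")
    sizes = dict(DEFAULT_SAMPLE_SIZES if sample_sizes is None else sample_sizes)
    pop = pop or PopulationModel()
    if eqtl_variance is None:
        eqtl_variance = SCENARIO_VARIANCE[name]
    return SCENARIOS[name](
        name=name,
        seed=seed,
        sizes=sizes,
        pop=pop,
        eqtl_variance=eqtl_variance,
        overdispersion=overdispersion,
        n_latent_factors=n_latent_factors,
    )


def _assemble(
    name,
    seed,
    sizes,
    pop,
    n_genes,
    effects_fn,
    gwas_fn,
    labels_fn,
    eqtl_variance,
    overdispersion,
    n_latent_factors,
):
    genes = _gene_table(n_genes, pop)
    studies = {}
    panels = {}
    for si, (study, n_s) in enumerate(sorted(sizes.items())):
        panels[study] = _panel(
            pop, n_genes, n_s, panel_seed=seed,
            sample_seed=seed + 104729 * (si + 1),
        )

    # effects are sized on the disease panel's realized dosage spread
    ref_panel = panels.get("disease", next(iter(panels.values())))
    effects = effects_fn(ref_panel, genes, eqtl_variance)
    gwas_signals = gwas_fn(effects, genes)
    arch = CausalArchitecture(effects=effects, gwas=gwas_signals)

    for si, (study, n_s) in enumerate(sorted(sizes.items())):
        expr = simulate_expression(
            panels[study],
            arch,
            genes,
            study=study,
            seed=seed + 15485863 * (si + 1),
            overdispersion=overdispersion,
            n_latent_factors=n_latent_factors,
        )
        studies[study] = (panels[study], expr)

    # GWAS z-draws are taken region by region on the largest panel's LD
    gwas_panel = max(panels.values(), key=lambda g: g.n_samples)
    per_gene = pop.n_variants
    tracks = []
    for gi, sig in enumerate(gwas_signals):
        lo, hi = gi * per_gene, (gi + 1) * per_gene
        sub = GenotypeMatrix(
            dosages=gwas_panel.dosages[:, lo:hi],
            variants=gwas_panel.variants.iloc[lo:hi].reset_index(drop=True),
            samples=gwas_panel.samples,
        )
        trk = simulate_gwas_summary(
            sub,
            causal_index=sig.causal_index - lo if sig.lam != 0 else 0,
            lam=sig.lam,
            n_gwas=GWAS_N,
            seed=seed + 32452843 * (gi + 1),
            trait_id="gwas",
        )
        tracks.append(trk.table)
    gwas = SummaryStatTrack(
        trait_id="gwas",
        trait_type="case-control",
        table=pd.concat(tracks, ignore_index=True),
        n=GWAS_N,
        case_fraction=0.5,
    )
    labels = labels_fn(effects)
    return ScenarioBundle(
        name=name, studies=studies, gwas=gwas, truth=arch, labels=labels
    )


def _scn_null(name, seed, sizes, pop, eqtl_variance, overdispersion, n_latent_factors):
    def effects_fn(panel, genes, v):
        return []

    def gwas_fn(effects, genes):
        return [GwasSignal(causal_index=gi * pop.n_variants, lam=0.0, matches_eqtl=False)
                for gi in range(2)]

    def labels_fn(effects):
        return {"gene_000": "none", "gene_001": "none"}

    return _assemble(name, seed, sizes, pop, 2, effects_fn, gwas_fn, labels_fn,
                     eqtl_variance, overdispersion, n_latent_factors)


def _single_gene_scenario(label, active_studies, gwas_matches):
    # gene_000 carries the planted signal; two null background genes keep
    # library sizes and TMM normalization meaningful
    n_genes = 3

    def builder(name, seed, sizes, pop, eqtl_variance, overdispersion, n_latent_factors):
        causal = pop.n_variants // 4

        def effects_fn(panel, genes, v):
            beta = effect_for_variance(v, panel.dosages[:, causal])
            studies = frozenset(sizes) if active_studies is None else frozenset(active_studies)
            return [GeneEffect(gene="gene_000", causal_index=causal,
                               effect_size=beta, studies=studies)]

        def gwas_fn(effects, genes):
            if gwas_matches:
                idx = causal
            else:
                idx = _distinct_block_index(pop, causal)
            sigs = [GwasSignal(causal_index=idx, lam=GWAS_LAMBDA,
                               matches_eqtl=gwas_matches)]
            for gi in range(1, n_genes):
                sigs.append(GwasSignal(causal_index=gi * pop.n_variants, lam=0.0,
                                       matches_eqtl=False))
            return sigs

        def labels_fn(effects):
            out = {"gene_000": label}
            out.update({f"gene_{gi:03d}": "none" for gi in range(1, n_genes)})
            return out

        return _assemble(name, seed, sizes, pop, n_genes, effects_fn, gwas_fn,
                         labels_fn, eqtl_variance, overdispersion, n_latent_factors)

    return builder


def _scn_rescue(name, seed, sizes, pop, eqtl_variance, overdispersion, n_latent_factors):
    causal = pop.n_variants // 4
    # sized so the covariate-adjusted nominal p lands in the suggestive
    # range (roughly 1e-7..1e-3) at n = 250 without reaching genome-scale
    # significance strength
    disease_variance = 0.04
    n_genes = 3

    def effects_fn(panel, genes, v):
        strong = effect_for_variance(v, panel.dosages[:, causal])
        weak = effect_for_variance(disease_variance, panel.dosages[:, causal])
        return [
            GeneEffect(gene="gene_000", causal_index=causal, effect_size=strong,
                       studies=frozenset({"ref1"})),
            GeneEffect(gene="gene_000", causal_index=causal, effect_size=weak,
                       studies=frozenset({"disease"})),
        ]

    def gwas_fn(effects, genes):
        sigs = [GwasSignal(causal_index=causal, lam=GWAS_LAMBDA, matches_eqtl=True)]
        for gi in range(1, n_genes):
            sigs.append(GwasSignal(causal_index=gi * pop.n_variants, lam=0.0,
                                   matches_eqtl=False))
        return sigs

    def labels_fn(effects):
        return {"gene_000": "rescued", "gene_001": "none", "gene_002": "none"}

    return _assemble(name, seed, sizes, pop, n_genes, effects_fn, gwas_fn, labels_fn,
                     eqtl_variance, overdispersion, n_latent_factors)


def _scn_three_study(name, seed, sizes, pop, eqtl_variance, overdispersion,
                     n_latent_factors):
    n_genes = 8
    causal = pop.n_variants // 4

    def effects_fn(panel, genes, v):
        def beta(gi, variance):
            col = gi * pop.n_variants + causal
            return effect_for_variance(variance, panel.dosages[:, col])

        all_studies = frozenset(sizes)
        return [
            # 0: shared eQTL, colocalizes with GWAS everywhere
            GeneEffect("gene_000", 0 * pop.n_variants + causal, beta(0, v),
                       all_studies),
            # 1: disease-unique novel GWAS colocalization
            GeneEffect("gene_001", 1 * pop.n_variants + causal, beta(1, 0.15),
                       frozenset({"disease"})),
            # 2: shared eQTL, GWAS causal in a different LD block
            GeneEffect("gene_002", 2 * pop.n_variants + causal, beta(2, v),
                       all_studies),
            # 3: shared eQTL, amplified in disease, no GWAS signal
            GeneEffect("gene_003", 3 * pop.n_variants + causal, beta(3, v),
                       all_studies, amplification={"disease": 1.5}),
            # 4: eQTL only in the reference studies, no GWAS signal
            GeneEffect("gene_004", 4 * pop.n_variants + causal, beta(4, v),
                       frozenset({"ref1", "ref2"})),
            # 5-7: null genes
        ]

    def gwas_fn(effects, genes):
        sigs = []
        for gi in range(n_genes):
            base = gi * pop.n_variants
            if gi in (0, 1):
                sigs.append(GwasSignal(base + causal, GWAS_LAMBDA, True))
            elif gi == 2:
                sigs.append(
                    GwasSignal(base + _distinct_block_index(pop, causal),
                               GWAS_LAMBDA, False))
            else:
                sigs.append(GwasSignal(base, 0.0, False))
        return sigs

    def labels_fn(effects):
        return {
            "gene_000": "shared",
            "gene_001": "novel",
            "gene_002": "not-colocalized",
            "gene_003": "no-gwas",
            "gene_004": "no-gwas",
            "gene_005": "none",
            "gene_006": "none",
            "gene_007": "none",
        }

    return _assemble(name, seed, sizes, pop, n_genes, effects_fn, gwas_fn, labels_fn,
                     eqtl_variance, overdispersion, n_latent_factors)


SCENARIOS = {
    "null": _scn_null,
    "shared-coloc": _single_gene_scenario("shared", None, True),
    "distinct-causal": _single_gene_scenario("not-colocalized", None, False),
    "disease-unique": _single_gene_scenario("novel", ("disease",), True),
    "rescue": _scn_rescue,
    "three-study": _scn_three_study,
}
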