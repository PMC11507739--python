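"""cis-eQTL mapping with permutation-calibrated gene-level significance.

For each gene, variants within a transcription-start-site-anchored window
are tested by linear regression of the covariate-residualized phenotype on
the covariate-residualized dosage.  Gene-level significance comes from a
beta-distribution approximation to the null distribution of the minimum
nominal p-value, fitted by maximum likelihood to seeded phenotype
permutations.  Genome-wide control uses the Storey-Tibshirani q-value
procedure, and independent signals per gene are discovered by a
forward-backward conditional scan.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "AssociationRecord",
    "BetaNull",
    "PermutationResult",
    "SignalSet",
    "tss_of",
    "nominal_scan",
    "fit_beta_null",
    "permutation_pass",
    "storey_pi0",
    "storey_qvalues",
    "conditional_scan",
    "pi1_replication",
]

#: numeric floor for p-values (avoids log(0) downstream)
P_FLOOR = 1e-300


@dataclass(frozen=True)
class AssociationRecord:
    gene_id: str
    variant_id: str
    slope: float  # phenotype SD per alt allele
    se: float
    tstat: float
    nominal_p: float
    maf: float
    distance_to_tss: int  # signed; negative = upstream on the gene's strand


@dataclass(frozen=True)
class BetaNull:
    """Beta(a, b) approximation to the permutation minimum-p distribution."""

    a: float
    b: float
    n_perm: int

    def cdf(self, p: float) -> float:
        return float(special.betainc(self.a, self.b, min(max(p, 0.0), 1.0)))


@dataclass
class PermutationResult:
    gene_id: str
    lead: AssociationRecord
    beta_null: BetaNull
    adjusted_p: float  # beta-CDF of the lead nominal p
    empirical_p: float  # rank-based permutation p, (1 + #{min <= obs}) / (1 + P)
    n_variants: int
    qvalue: float = None


@dataclass
class SignalSet:
    gene_id: str
    leads: list  # rank 0 = primary; list[AssociationRecord]


# ---------------------------------------------------------------------------


def tss_of(start: int, end: int, strand: str) -> int:
    """Transcription start site: ``start`` on '+', ``end`` on '-'."""
    if strand == "+":
        return int(start)
    if strand == "-":
        return int(end)
    raise ValueError(f"bad strand {strand!r}")


def _signed_distance(pos: np.ndarray, tss: int, strand: str) -> np.ndarray:
    d = pos - tss
    return d if strand == "+" else -d


def _residualize(mat: np.ndarray, covariates: np.ndarray = None) -> np.ndarray:
    """Project out covariates plus an intercept; ``mat`` columns are variables."""
    n = mat.shape[0]
    cols = [np.ones(n)]
    if covariates is not None and covariates.size:
        cols.append(np.asarray(covariates, dtype=float).reshape(n, -1))
    design = np.column_stack(cols)
    q, _ = np.linalg.qr(design)
    return mat - q @ (q.T @ mat)


def _window_mask(variants: pd.DataFrame, tss: int, window: int, maf_min: float,
                 chrom: str = None):
    dist = np.abs(variants["pos"].to_numpy() - tss)
    mask = (dist <= window) & (variants["maf"].to_numpy() >= maf_min)
    if chrom is not None:
        mask &= variants["chrom"].astype(str).to_numpy() == str(chrom)
    return mask


def _pvals_from_r(r: np.ndarray, dof: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    denom = np.maximum(1.0 - r * r, 1e-16)
    t = r * np.sqrt(dof / denom)
    return np.maximum(2.0 * stats.t.sf(np.abs(t), dof), P_FLOOR)


def nominal_scan(
    pheno: np.ndarray,
    geno,
    covariates: np.ndarray = None,
    gene_id: str = "gene",
    tss: int = None,
    strand: str = "+",
    window: int = 1_000_000,
    maf_min: float = 0.02,
    chrom: str = None,
) -> list:
    """All per-variant association records for one gene's cis window.

    Phenotype and dosages are residualized against the covariates (with
    intercept); slope/se/t/p come from the simple regression of residuals
    with n - c - 2 degrees of freedom.
    """
    y = np.asarray(pheno, dtype=float)
    n = y.size
    if tss is None:
        tss = int(geno.variants["pos"].median())
    mask = _window_mask(geno.variants, tss, window, maf_min, chrom)
    if not mask.any():
        return []
    sub = geno.variants[mask]
    g = geno.dosages[:, mask.to_numpy() if hasattr(mask, "to_numpy") else mask]

    c = 0 if covariates is None else np.atleast_2d(np.asarray(covariates).T).shape[0]
    dof = n - c - 2
    if dof < 1:
        raise ValueError("not enough residual degrees of freedom")
    yr = _residualize(y[:, None], covariates)[:, 0]
    gr = _residualize(g, covariates)

    gvar = gr.var(axis=0)
    ok = gvar > 1e-12
    if not ok.all():
        log.info("%s: skipped %d zero-variance dosage columns", gene_id, (~ok).sum())
    sub = sub[ok]
    gr = gr[:, ok]
    gvar = gvar[ok]
    if gr.shape[1] == 0:
        return []

    yvar = yr.var()
    cov = (gr * yr[:, None]).mean(axis=0)
    slope = cov / gvar
    if yvar <= 0:
        r = np.zeros(gr.shape[1])
    else:
        r = cov / np.sqrt(gvar * yvar)
    p = _pvals_from_r(r, dof)
    resid_var = np.maximum(yvar - slope * cov, 0.0) * n / dof
    se = np.sqrt(resid_var / (gvar * n))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, slope / se, np.sign(slope) * np.inf)

    dists = _signed_distance(sub["pos"].to_numpy(), tss, strand)
    return [
        AssociationRecord(
            gene_id=gene_id,
            variant_id=v,
            slope=float(b),
            se=float(s),
            tstat=float(t),
            nominal_p=float(pv),
            maf=float(m),
            distance_to_tss=int(d),
        )
        for v, b, s, t, pv, m, d in zip(
            sub["variant_id"], slope, se, tstat, p, sub["maf"], dists
        )
    ]


# ---------------------------------------------------------------------------
# beta null


def _beta_nll(params: np.ndarray, logp: np.ndarray, log1mp: np.ndarray) -> float:
    a, b = np.exp(params)
    return -(
        logp.size * (special.gammaln(a + b) - special.gammaln(a) - special.gammaln(b))
        + (a - 1.0) * logp.sum()
        + (b - 1.0) * log1mp.sum()
    )


def beta_moment_estimate(p: np.ndarray) -> tuple[float, float]:
    m, v = p.mean(), p.var()
    if v <= 0:
        raise ValueError("degenerate permutation vector (zero variance)")
    common = m * (1.0 - m) / v - 1.0
    return max(m * common, 1e-6), max((1.0 - m) * common, 1e-6)


def fit_beta_null(perm_min_p: np.ndarray) -> BetaNull:
    """Maximum-likelihood Beta fit to permutation minimum p-values.

    Initialized at the method-of-moments estimate; optimized on the log
    scale so the shapes stay positive.
    """
    p = np.asarray(perm_min_p, dtype=float)
    if p.size < 100:
        raise ValueError("need >= 100 permutation values")
    if ((p <= 0) | (p >= 1)).any():
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
    a0, b0 = beta_moment_estimate(p)
    logp, log1mp = np.log(p), np.log1p(-p)
    res = optimize.minimize(
        _beta_nll,
        x0=np.log([a0, b0]),
        args=(logp, log1mp),
        method="L-BFGS-B",
        options={"ftol": 1e-12, "gtol": 1e-10},
    )
    if not res.success and not np.isfinite(res.fun):
        raise ArithmeticError("beta null fit failed")
    a, b = np.exp(res.x)
    return BetaNull(a=float(a), b=float(b), n_perm=p.size)


def _lead_index(records: list) -> int:
    """argmin nominal p; ties -> smaller |TSS distance| -> smaller position."""
    key = [
        (r.nominal_p, abs(r.distance_to_tss), r.variant_id) for r in records
    ]
    return int(min(range(len(records)), key=key.__getitem__))


def permutation_pass(
    pheno: np.ndarray,
    geno,
    covariates: np.ndarray = None,
    gene_id: str = "gene",
    tss: int = None,
    strand: str = "+",
    window: int = 1_000_000,
    maf_min: float = 0.02,
    n_perm: int = 1000,
    seed: int = 0,
    chrom: str = None,
) -> PermutationResult:
    """Gene-level adjusted p from a beta fit to seeded phenotype permutations.

    The covariate-residualized phenotype is permuted against the fixed
    residualized dosages; the minimum nominal p over the cis window is
    recorded per permutation, a Beta(a, b) is fitted to the minima, and the
    adjusted p is its CDF at the observed lead p.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    records = nominal_scan(pheno, geno, covariates, gene_id, tss, strand, window,
                           maf_min, chrom)
    if not records:
        log.info("%s: no variants in the cis window; gene skipped", gene_id)
        return None
    lead = records[_lead_index(records)]

    if tss is None:
        tss = int(geno.variants["pos"].median())
    mask = _window_mask(geno.variants, tss, window, maf_min, chrom)
    g = geno.dosages[:, np.asarray(mask)]
    y = np.asarray(pheno, dtype=float)
    n = y.size
    c = 0 if covariates is None else np.atleast_2d(np.asarray(covariates).T).shape[0]
    dof = n - c - 2
    yr = _residualize(y[:, None], covariates)[:, 0]
    gr = _residualize(g, covariates)
    keep = gr.var(axis=0) > 1e-12
    gr = gr[:, keep]

    gn = gr - gr.mean(axis=0)
    gn /= np.linalg.norm(gn, axis=0)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(yr) for _ in range(n_perm)]).T  # n x P
    perms = perms - perms.mean(axis=0)
    norms = np.linalg.norm(perms, axis=0)
    norms[norms == 0] = 1.0
    perms /= norms
    rmat = gn.T @ perms  # variants x perms
    max_abs_r = np.abs(rmat).max(axis=0)
    perm_min_p = _pvals_from_r(max_abs_r, dof)

    beta_null = fit_beta_null(perm_min_p)
    adjusted = beta_null.cdf(lead.nominal_p)
    empirical = (1.0 + (perm_min_p <= lead.nominal_p).sum()) / (1.0 + n_perm)
    return PermutationResult(
        gene_id=gene_id,
        lead=lead,
        beta_null=beta_null,
        adjusted_p=float(adjusted),
        empirical_p=float(empirical),
        n_variants=int(gr.shape[1]),
    )


# ---------------------------------------------------------------------------
# Storey FDR


def storey_pi0(p: np.ndarray, lambdas: np.ndarray = None) -> float:
    """Storey pi0: smoothed pi0(lambda) evaluated at the largest lambda.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over a lambda grid,
    smoothed with a cubic least-squares fit (a stand-in for the reference
    implementation's df=3 smoothing spline) and clipped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    pi0s = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    coef = np.polynomial.polynomial.polyfit(lambdas, pi0s, deg=3)
    pi0 = float(np.polynomial.polynomial.polyval(lambdas[-1], coef))
    return float(np.clip(pi0, 1.0 / p.size, 1.0))


def storey_qvalues(pvec: np.ndarray, lambdas: np.ndarray = None):
    """(pi0, q-values) by the Storey-Tibshirani procedure.

    Falls back to Benjamini-Hochberg (pi0 = 1) with a warning when fewer
    than 100 p-values are supplied.
    """
    p = np.asarray(pvec, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must be in (0, 1]")
    if p.size < 100:
        warnings.warn("fewer than 100 p-values: falling back to Benjamini-Hochberg",
                      stacklevel=2)
        return 1.0, multipletests(p, method="fdr_bh")[1]
    pi0 = storey_pi0(p, lambdas)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]  # min over tail
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return pi0, out


def pi1_replication(replication_nominal_p: np.ndarray) -> float:
    """Storey's pi1 = 1 - pi0 on replication-study nominal p-values."""
    p = np.asarray(replication_nominal_p, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ValueError("need >= 100 matched replication p-values")
    return 1.0 - storey_pi0(np.clip(p, P_FLOOR, 1.0))


# ---------------------------------------------------------------------------
# conditional mapping


def conditional_scan(
    pheno: np.ndarray,
    geno,
    covariates: np.ndarray = None,
    gene_id: str = "gene",
    tss: int = None,
    strand: str = "+",
    threshold: float = 0.01,
    window: int = 1_000_000,
    maf_min: float = 0.02,
    n_perm: int = 1000,
    seed: int = 0,
    max_signals: int = 10,
    collinearity_r2: float = 0.95,
) -> SignalSet:
    """Forward-backward discovery of independent cis signals for one gene.

    Forward: repeatedly add the current lead's dosage to the covariates and
    re-run the permutation pass until the adjusted p exceeds the gene-level
    ``threshold``.  Backward: re-test each retained lead conditional on all
    the others, dropping those no longer significant; ranks follow the
    backward-stage adjusted p ascending.
    """

    def with_leads(leads):
        if not leads:
            return covariates
        cols = [geno.column(v) for v in leads]
        if covariates is None:
            return np.column_stack(cols)
        return np.column_stack([np.asarray(covariates).reshape(len(pheno), -1)] + cols)

    primary = permutation_pass(
        pheno, geno, covariates, gene_id, tss, strand, window, maf_min, n_perm, seed
    )
    if primary is None or primary.adjusted_p >= threshold:
        raise ValueError("gene not significant in the primary pass")

    forward = [primary.lead.variant_id]
    records = {primary.lead.variant_id: primary.lead}
    for step in range(1, max_signals):
        res = permutation_pass(
            pheno, geno, with_leads(forward), gene_id, tss, strand, window, maf_min,
            n_perm, seed + step,
        )
        if res is None or res.adjusted_p >= threshold:
            break
        vid = res.lead.variant_id
        if vid in records:
            break
        cand = geno.column(vid)
        collinear = False
        for prev in forward:
            r = np.corrcoef(cand, geno.column(prev))[0, 1]
            if r * r > collinearity_r2:
                log.info("%s: lead %s collinear with %s; dropped", gene_id, vid, prev)
                collinear = True
                break
        if collinear:
            break
        forward.append(vid)
        records[vid] = res.lead

    if len(forward) == 1:
        return SignalSet(gene_id=gene_id, leads=[primary.lead])

    kept = []
    for i, vid in enumerate(forward):
        others = [v for v in forward if v != vid]
        res = permutation_pass(
            pheno, geno, with_leads(others), gene_id, tss, strand, window, maf_min,
            n_perm, seed + 1000 + i,
        )
        if res is not None and res.adjusted_p < threshold:
            kept.append((res.adjusted_p, res.lead))
    if not kept:
        kept = [(primary.adjusted_p, primary.lead)]
    kept.sort(key=lambda t: t[0])
    return SignalSet(gene_id=gene_id, leads=[lead for _, lead in kept])
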