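"""Expression preparation for eQTL mapping.

Raw counts are filtered for low expression, normalized between samples by
the trimmed mean of M-values (TMM), and rank inverse normal transformed
(RINT) per gene to give the mapping phenotype.  Hidden structure is
estimated in the remove-unwanted-variation (RUV) style: negative-control
genes (stably expressed across samples) are selected on a covariate-
corrected log matrix, factors come from an SVD of the control submatrix,
and the number of factors carried into the eQTL model is chosen with the
kneedle knee-point rule on the eGene-discovery-versus-k curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simgen import ExpressionCounts

__all__ = [
    "PhenotypeMatrix",
    "RuvModel",
    "filter_low_expression",
    "tmm_factors",
    "rank_inverse_normal",
    "log_cpm",
    "regress_out",
    "select_control_genes",
    "ruv_factors",
    "choose_k_kneedle",
    "prepare_phenotypes",
    "ruv_prep_matrix",
]


@dataclass
class PhenotypeMatrix:
    """Genes x samples matrix on a normalized scale, with provenance."""

    values: pd.DataFrame  # index gene_id, columns sample ids
    provenance: list = field(default_factory=list)

    @property
    def genes(self):
        return list(self.values.index)

    @property
    def samples(self):
        return list(self.values.columns)


@dataclass
class RuvModel:
    """Estimated unwanted-variation factors and the curve used to pick k."""

    control_genes: list
    factors: np.ndarray  # (n_samples, k)
    k: int
    egene_curve: list = field(default_factory=list)  # [(k, n_egenes), ...]


# ---------------------------------------------------------------------------


def filter_low_expression(
    counts: ExpressionCounts, min_count: int = 5, min_fraction: float = 0.25
) -> ExpressionCounts:
    """Keep genes with >= ``min_count`` raw reads in >= ``min_fraction`` of samples."""
    if counts.n_genes == 0:
        raise ValueError("empty count matrix")
    n = counts.n_samples
    ok = (counts.counts >= min_count).sum(axis=1) >= min_fraction * n
    return ExpressionCounts(
        counts=counts.counts[ok],
        genes=counts.genes[ok].reset_index(drop=True),
        samples=counts.samples,
        library_sizes=counts.library_sizes,
        known_covariates=counts.known_covariates,
        latent_factors=counts.latent_factors,
        latent_values=None if counts.latent_values is None else counts.latent_values[ok],
    )


def tmm_factors(
    counts: np.ndarray,
    lib_sizes: np.ndarray = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors (Robinson-Oshlack style).

    The reference sample is the one whose upper-quartile (of counts/libsize)
    is closest to the mean upper-quartile.  Each factor is the exponent of a
    precision-weighted mean of M-values after two-sided trimming (``trim_m``
    per tail on M, ``trim_a`` per tail on A); the returned vector is rescaled
    to geometric mean 1.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM requires >= 2 samples")
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if (lib_sizes <= 0).any():
        raise ValueError("sample with zero total count")

    rel = counts / lib_sizes[None, :]
    uq = np.array([np.quantile(rel[:, j][rel[:, j] > 0], 0.75) if (rel[:, j] > 0).any()
                   else 0.0 for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        obs, refc = counts[:, j], counts[:, ref]
        keep = (obs > 0) & (refc > 0)
        if keep.sum() < 2:
            continue
        o, r = obs[keep], refc[keep]
        no, nr = lib_sizes[j], lib_sizes[ref]
        m = np.log2((o / no) / (r / nr))
        a = 0.5 * np.log2((o / no) * (r / nr))
        # asymptotic binomial variance of M (delta method)
        w = (no - o) / (no * o) + (nr - r) / (nr * r)

        m_lo, m_hi = np.quantile(m, [trim_m, 1.0 - trim_m])
        a_lo, a_hi = np.quantile(a, [trim_a, 1.0 - trim_a])
        sel = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if sel.sum() == 0 or w[sel].sum() == 0:
            continue
        log_factors[j] = np.log2(2.0 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])))

    factors = 2.0 ** log_factors
    return factors / np.exp(np.mean(np.log(factors)))


def rank_inverse_normal(values: np.ndarray, offset: float = 0.5) -> np.ndarray:
    """Phi^-1((rank - offset) / n) with average ranks for ties.

    Strictly rank-preserving for distinct inputs; a constant vector is a
    degenerate input (such genes should have been filtered) and raises.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need >= 3 values")
    if not np.isfinite(v).all():
        raise ValueError("non-finite values")
    if np.ptp(v) == 0:
        raise ValueError("constant vector: rank transform undefined")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - offset) / v.size)


def log_cpm(counts: np.ndarray, lib_sizes: np.ndarray, tmm: np.ndarray = None) -> np.ndarray:
    """log2(CPM + 1) with TMM-effective library sizes."""
    eff = lib_sizes * (tmm if tmm is not None else 1.0)
    return np.log2(1e6 * counts / eff[None, :] + 1.0)


def regress_out(matrix: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Remove covariates (plus intercept) from each row by least squares."""
    n = matrix.shape[1]
    design = np.column_stack([np.ones(n)] + ([covariates] if covariates is not None else []))
    q, _ = np.linalg.qr(design)
    return matrix - (matrix @ q) @ q.T


def select_control_genes(
    corrected: PhenotypeMatrix,
    n_top_expressed: int = 5000,
    n_controls: int = 1000,
) -> list:
    """Stably expressed genes: smallest coefficient of variation among the
    most highly expressed.

    Genes are ranked by mean expression on the normalized non-log scale, the
    top ``n_top_expressed`` retained, and within them the ``n_controls`` with
    the smallest CV = sd/mean are returned.  CV ties break toward higher mean
    expression, then lexicographic gene id.
    """
    if n_controls > n_top_expressed:
        raise ValueError("n_controls must be <= n_top_expressed")
    lin = np.power(2.0, corrected.values.to_numpy())
    mean = lin.mean(axis=1)
    if len(mean) < n_top_expressed:
        warnings.warn(
            f"only {len(mean)} genes available; truncating n_top_expressed",
            stacklevel=2,
        )
        n_top_expressed = len(mean)
        n_controls = min(n_controls, n_top_expressed)
    order = np.argsort(-mean, kind="stable")[:n_top_expressed]
    sd = lin[order].std(axis=1)
    cv = np.where(mean[order] > 0, sd / mean[order], np.inf)
    ids = np.array(corrected.genes, dtype=object)[order]
    tbl = pd.DataFrame({"gene_id": ids, "cv": cv, "mean": mean[order]})
    tbl = tbl.sort_values(["cv", "mean", "gene_id"], ascending=[True, False, True])
    return list(tbl["gene_id"].head(n_controls))


def ruv_factors(log_counts: PhenotypeMatrix, controls, k: int) -> np.ndarray:
    """First k sample-side singular vectors of the centered control submatrix,
    scaled by their singular values."""
    if k < 0:
        raise ValueError("k must be >= 0")
    controls = [g for g in controls if g in log_counts.values.index]
    if not controls:
        raise ValueError("no control genes present in the matrix")
    x = log_counts.values.loc[controls].to_numpy().T  # samples x controls
    if k > min(x.shape):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(x.shape)}")
    if k == 0:
        return np.empty((x.shape[0], 0))
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    return u[:, :k] * s[:k]


def choose_k_kneedle(egene_curve, sensitivity: float = 1.0):
    """Knee of an increasing-concave curve via the kneedle difference rule.

    Both axes are normalized to [0, 1]; the difference d = y_n - x_n is
    scanned for local maxima, and a maximum qualifies as the knee when the
    curve later drops below d_max - S * mean(dx) before a higher maximum is
    reached (the curve is discrete and left unsmoothed).  Returns the knee's
    k, or ``None`` when no knee exists.
    """
    pts = [(float(k), float(v)) for k, v in egene_curve]
    if len(pts) < 5:
        raise ValueError("need >= 5 curve points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if (np.diff(x) <= 0).any():
        raise ValueError("k grid must be strictly increasing")
    if np.ptp(y) == 0:
        return None
    xn = (x - x[0]) / np.ptp(x)
    yn = (y - y.min()) / np.ptp(y)
    d = yn - xn

    maxima = [
        i
        for i in range(1, len(d) - 1)
        if d[i] > 0 and d[i] >= d[i - 1] and d[i] >= d[i + 1]
    ]
    if not maxima:
        return None
    threshold_drop = sensitivity * np.mean(np.diff(xn))
    for mi, i in enumerate(maxima):
        thresh = d[i] - threshold_drop
        nxt = maxima[mi + 1] if mi + 1 < len(maxima) else len(d)
        tail = d[i + 1:] if mi + 1 == len(maxima) else d[i + 1: nxt + 1]
        if (tail < thresh).any():
            return int(x[i]) if float(x[i]).is_integer() else x[i]
    return None


# ---------------------------------------------------------------------------
# composed pipeline


def prepare_phenotypes(counts: ExpressionCounts) -> PhenotypeMatrix:
    """filter -> TMM -> per-gene rank inverse normal transform."""
    filtered = filter_low_expression(counts)
    tmm = tmm_factors(filtered.counts, filtered.library_sizes)
    cpm = 1e6 * filtered.counts / (filtered.library_sizes * tmm)[None, :]
    rint = np.vstack([rank_inverse_normal(row) for row in cpm])
    values = pd.DataFrame(rint, index=list(filtered.genes["gene_id"]),
                          columns=filtered.samples)
    return PhenotypeMatrix(values=values, provenance=["filter", "tmm", "rint"])


def ruv_prep_matrix(
    counts: ExpressionCounts, known_covariates: np.ndarray = None
) -> PhenotypeMatrix:
    """Covariate-corrected log2(CPM+1) on TMM-normalized counts.

    Stands in for a variance-stabilizing transform as the RUV input scale;
    known covariates are removed by least-squares projection before control
    selection so they do not masquerade as hidden factors.
    """
    filtered = filter_low_expression(counts)
    tmm = tmm_factors(filtered.counts, filtered.library_sizes)
    mat = log_cpm(filtered.counts, filtered.library_sizes, tmm)
    prov = ["filter", "tmm", "log_cpm"]
    if known_covariates is not None:
        mat = regress_out(mat, np.asarray(known_covariates, dtype=float))
        prov.append("covariate_regression")
    values = pd.DataFrame(mat, index=list(filtered.genes["gene_id"]),
                          columns=filtered.samples)
    return PhenotypeMatrix(values=values, provenance=prov)


def estimate_ruv(
    counts: ExpressionCounts,
    known_covariates: np.ndarray = None,
    k: int = None,
    n_top_expressed: int = 5000,
    n_controls: int = 1000,
) -> RuvModel:
    """Select control genes and estimate up to k factors (default 0.25 * n)."""
    prep = ruv_prep_matrix(counts, known_covariates)
    n = len(prep.samples)
    k_max = max(1, int(0.25 * n))
    if k is None:
        k = k_max
    if k > k_max:
        raise ValueError(f"k={k} exceeds the 0.25*n candidate ceiling {k_max}")
    n_top = min(n_top_expressed, len(prep.genes))
    n_ctl = min(n_controls, n_top)
    controls = select_control_genes(prep, n_top, n_ctl)
    factors = ruv_factors(prep, controls, k)
    return RuvModel(control_genes=controls, factors=factors, k=k)
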