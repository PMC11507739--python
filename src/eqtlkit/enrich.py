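"""Comparative statistics downstream of mapping and colocalization.

Covers eVariant enrichment among GWAS-significant variants, Pearson
chi-square contingency tests across studies, per-gene Mann-Whitney
comparisons of posterior effect magnitudes with Benjamini-Hochberg
correction, and TSS-distance summaries by sharing/novelty group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "enrichment_fold",
    "contingency_chisq",
    "mann_whitney",
    "compare_effect_distributions",
    "distance_summary",
    "pearson_r",
]

GWAS_SIG_P = 5e-8  # genome-wide significance threshold for "GWAS variants"


@dataclass(frozen=True)
class EnrichmentResult:
    study: str
    trait: str
    n_tested: int
    n_evar: int
    n_gwas_sig: int
    n_overlap: int
    fold: float


def enrichment_fold(
    evariants: set,
    gwas_sig: set,
    tested: set,
    study: str = "study",
    trait: str = "trait",
) -> EnrichmentResult:
    """Fold enrichment of eVariants among GWAS-significant variants.

    fold = (|eVar ∩ GWAS| / |GWAS ∩ tested|) / (|eVar| / |tested|), with the
    GWAS set restricted to eQTL-tested variants.
    """
    evariants, gwas_sig, tested = set(evariants), set(gwas_sig), set(tested)
    if not evariants <= tested:
        raise ValueError("evariants must be a subset of tested")
    gwas_tested = gwas_sig & tested
    if not gwas_tested:
        raise ValueError("no GWAS-significant variants among tested: enrichment undefined")
    n_overlap = len(evariants & gwas_tested)
    base = len(evariants) / len(tested)
    fold = 0.0 if base == 0 else (n_overlap / len(gwas_tested)) / base
    return EnrichmentResult(
        study=study,
        trait=trait,
        n_tested=len(tested),
        n_evar=len(evariants),
        n_gwas_sig=len(gwas_tested),
        n_overlap=n_overlap,
        fold=fold,
    )


def contingency_chisq(table) -> tuple[float, int, float]:
    """Pearson chi-square for an r x c count table: (statistic, df, p)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows <= 0).any() or (cols <= 0).any():
        raise ValueError("zero marginal in contingency table")
    expected = np.outer(rows, cols) / obs.sum()
    if (expected <= 0).any():
        raise ValueError("expected count of zero")
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return statistic, df, float(stats.chi2.sf(statistic, df))


def mann_whitney(x, y, exact_max_n: int = 20) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small tie-free samples, else the
    normal approximation with continuity and tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(x.size * y.size / 2.0), 1.0
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (max(x.size, y.size) <= exact_max_n and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_effect_distributions(groups: dict) -> pd.DataFrame:
    """Per-gene Mann-Whitney comparison of paired |effect| sets, BH-corrected.

    ``groups`` maps gene id -> (values_a, values_b); every group needs at
    least 3 values per side.
    """
    rows = []
    for gene, (a, b) in groups.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size < 3 or b.size < 3:
            raise ValueError(f"gene {gene}: each group needs >= 3 values")
        u, p = mann_whitney(a, b)
        rows.append({"gene_id": gene, "U": u, "p": p})
    out = pd.DataFrame(rows)
    out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def distance_summary(leads_by_group: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median |TSS distance| per sharing/novelty group plus pairwise tests.

    ``leads_by_group`` maps group label -> iterable of signed TSS distances
    (or AssociationRecords).  Returns (medians, pairwise Mann-Whitney table).
    """
    dists = {}
    for label, leads in leads_by_group.items():
        vals = [
            abs(getattr(rec, "distance_to_tss", rec)) for rec in leads
        ]
        if not vals:
            raise ValueError(f"group {label!r} is empty")
        dists[label] = np.asarray(vals, dtype=float)
    medians = pd.DataFrame(
        [{"group": g, "n": v.size, "median_abs_distance": float(np.median(v))}
         for g, v in dists.items()]
    )
    labels = sorted(dists)
    pairs = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if dists[a].size and dists[b].size:
                u, p = mann_whitney(dists[a], dists[b])
                pairs.append({"group_a": a, "group_b": b, "U": u, "p": p})
    return medians, pd.DataFrame(pairs)


def pearson_r(x, y) -> float:
    """Pearson correlation; symmetric, r = 1 for identical vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of size >= 3")
    return float(np.corrcoef(x, y)[0, 1])
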