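"""Bayesian colocalization of two association tracks over a shared region.

Per-variant evidence is summarized by Wakefield's log approximate Bayes
factor (lABF) computed from the effect estimate, its standard error and a
prior effect variance W.  Posteriors over the five hypotheses (H0 neither
trait associated, H1/H2 one trait only, H3 both with distinct causal
variants, H4 both sharing one causal variant) follow from the standard
single-causal-variant enumeration, accumulated in log space so large lABFs
cannot overflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .simgen import GenotypeMatrix, SummaryStatTrack

log = logging.getLogger(__name__)

__all__ = [
    "ColocPriors",
    "ColocResult",
    "wakefield_labf",
    "labf_for_track",
    "coloc_abf",
    "posteriors_from_labf",
    "ld_r2",
    "prioritize_pairs",
    "DEFAULT_PRIORS",
]

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")

#: default prior effect standard deviations of the cited framework
SD_PRIOR_QUANTITATIVE = 0.15  # times sd(Y)
SD_PRIOR_BINARY = 0.2  # log-odds scale


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant priors: trait-1 only (p1), trait-2 only (p2), both (p12)."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("require 0 < p12 <= min(p1, p2)")


DEFAULT_PRIORS = ColocPriors()


@dataclass
class ColocResult:
    pair_id: str
    n_snps: int
    pp: dict  # hypothesis -> posterior probability
    priors: ColocPriors = field(default_factory=lambda: DEFAULT_PRIORS)
    labf1: np.ndarray = None
    labf2: np.ndarray = None
    variant_ids: list = None

    @property
    def max_hypothesis(self) -> str:
        return max(self.pp, key=self.pp.get)

    def __getitem__(self, h: str) -> float:
        return self.pp[h]

    def to_row(self) -> dict:
        row = {"pair_id": self.pair_id, "n_snps": self.n_snps}
        row.update({f"PP{h[-1]}": self.pp[h] for h in HYPOTHESES})
        row["max_hypothesis"] = self.max_hypothesis
        return row


# ---------------------------------------------------------------------------


def wakefield_labf(beta, se, w: float):
    """Wakefield log approximate Bayes factor for a single variant.

    lABF = 0.5 * [log(1 - r) + r z^2] with r = W / (V + W), V = se^2,
    z = beta / se.  W = 0 gives lABF = 0 for any z.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if not (np.isfinite(beta).all() and np.isfinite(se).all() and np.isfinite(w)):
        raise ValueError("non-finite inputs")
    if (se <= 0).any():
        raise ValueError("se must be > 0")
    if w < 0:
        raise ValueError("prior variance W must be >= 0")
    v = se**2
    r = w / (v + w)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z * z)
    return float(out) if out.ndim == 0 else out


def prior_effect_variance(track: SummaryStatTrack) -> float:
    if track.trait_type == "quantitative":
        return (SD_PRIOR_QUANTITATIVE * track.sd_y) ** 2
    return SD_PRIOR_BINARY**2


def labf_for_track(track: SummaryStatTrack, w: float = None) -> np.ndarray:
    if w is None:
        w = prior_effect_variance(track)
    return wakefield_labf(track.table["beta"].to_numpy(),
                          track.table["se"].to_numpy(), w)


def harmonize_tracks(track1: SummaryStatTrack, track2: SummaryStatTrack):
    """Intersect two tracks on (chrom, pos, unordered allele pair).

    The second track's beta (and z) sign is flipped where its ref/alt are
    swapped relative to the first.  Unmatched allele pairs at a shared
    position are dropped with a logged count.
    """
    t1 = track1.table.copy()
    t2 = track2.table.copy()
    t1["_key"] = list(zip(t1["chrom"].astype(str), t1["pos"].astype(int)))
    t2["_key"] = list(zip(t2["chrom"].astype(str), t2["pos"].astype(int)))
    merged = t1.merge(t2, on="_key", suffixes=("_1", "_2"))
    same = (merged["ref_1"] == merged["ref_2"]) & (merged["alt_1"] == merged["alt_2"])
    flipped = (merged["ref_1"] == merged["alt_2"]) & (merged["alt_1"] == merged["ref_2"])
    dropped = (~(same | flipped)).sum()
    if dropped:
        log.info("dropped %d shared positions with unmatched alleles", dropped)
    merged = merged[same | flipped].copy()
    flip = np.where(merged["ref_1"] == merged["alt_2"], -1.0, 1.0)
    merged["beta_2"] = merged["beta_2"] * flip
    merged["z_2"] = merged["z_2"] * flip
    return merged


def coloc_abf(
    track1: SummaryStatTrack,
    track2: SummaryStatTrack,
    priors: ColocPriors = DEFAULT_PRIORS,
    pair_id: str = None,
) -> ColocResult:
    """Posterior probabilities PP0-PP4 under the single-causal-variant model.

    With S1 = sum exp(lABF1), S2 = sum exp(lABF2) and S12 = sum
    exp(lABF1 + lABF2), the unnormalized posteriors are proportional to
    {1, p1 S1, p2 S2, p1 p2 (S1 S2 - S12), p12 S12}; the sums are
    accumulated in log space.
    """
    merged = harmonize_tracks(track1, track2)
    if len(merged) == 0:
        raise ValueError("no shared variants between tracks")
    w1 = prior_effect_variance(track1)
    w2 = prior_effect_variance(track2)
    l1 = np.atleast_1d(
        wakefield_labf(merged["beta_1"].to_numpy(), merged["se_1"].to_numpy(), w1)
    )
    l2 = np.atleast_1d(
        wakefield_labf(merged["beta_2"].to_numpy(), merged["se_2"].to_numpy(), w2)
    )
    pp = posteriors_from_labf(l1, l2, priors)
    return ColocResult(
        pair_id=pair_id or f"{track1.trait_id}|{track2.trait_id}",
        n_snps=len(merged),
        pp=pp,
        priors=priors,
        labf1=l1,
        labf2=l2,
        variant_ids=list(merged["variant_id_1"]),
    )


def posteriors_from_labf(
    labf1: np.ndarray, labf2: np.ndarray, priors: ColocPriors = DEFAULT_PRIORS
) -> dict:
    """PP0-PP4 from two aligned per-variant lABF vectors (log-space sums)."""
    l1 = np.asarray(labf1, dtype=float)
    l2 = np.asarray(labf2, dtype=float)
    if l1.shape != l2.shape or l1.ndim != 1 or l1.size == 0:
        raise ValueError("need two aligned non-empty lABF vectors")
    log_s1 = logsumexp(l1)
    log_s2 = logsumexp(l2)
    log_s12 = logsumexp(l1 + l2)

    # log(S1*S2 - S12), stable; exact zero when a single variant is shared
    diff = log_s12 - (log_s1 + log_s2)
    if diff >= 0.0:
        log_h3_sum = -np.inf
    else:
        log_h3_sum = log_s1 + log_s2 + np.log1p(-np.exp(diff))

    logs = np.array(
        [
            0.0,
            np.log(priors.p1) + log_s1,
            np.log(priors.p2) + log_s2,
            np.log(priors.p1) + np.log(priors.p2) + log_h3_sum,
            np.log(priors.p12) + log_s12,
        ]
    )
    denom = logsumexp(logs)
    pp = np.exp(logs - denom)
    return dict(zip(HYPOTHESES, pp.tolist()))


# ---------------------------------------------------------------------------
# LD utilities


def ld_r2(geno: GenotypeMatrix, v1: str, v2: str) -> float:
    """Squared Pearson correlation between two variants' dosage vectors."""
    a = geno.column(v1)
    b = geno.column(v2)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("monomorphic variant: LD undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def prioritize_pairs(
    gwas_index_variants,
    eqtl_leads,
    panels,
    r2_min: float = 0.2,
):
    """LD-prioritized (GWAS locus, gene) test pairs.

    A pair is retained iff the index and lead variants are identical or
    their LD r^2 strictly exceeds ``r2_min`` in at least one reference
    panel.  Pairs whose variants are absent from every panel are flagged
    "untestable-LD" and excluded.
    """
    if isinstance(panels, GenotypeMatrix):
        panels = [panels]
    retained, untestable = [], []
    for index_v in gwas_index_variants:
        for gene, lead_v in eqtl_leads:
            if index_v == lead_v:
                retained.append((index_v, gene))
                continue
            tested = False
            keep = False
            for panel in panels:
                try:
                    r2 = ld_r2(panel, index_v, lead_v)
                except KeyError:
                    continue
                except ValueError:
                    tested = True
                    continue
                tested = True
                if r2 > r2_min:
                    keep = True
                    break
            if keep:
                retained.append((index_v, gene))
            elif not tested:
                untestable.append((index_v, gene))
                log.info("pair (%s, %s) untestable-LD", index_v, gene)
    return retained
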