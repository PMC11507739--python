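"""File-based pipeline stages over a run directory.

Each stage reads what the previous one wrote, so the steps can be driven
from the command line (simulate -> prep -> map-eqtl -> coloc -> cross-coloc
-> mash -> report) or called directly.  All stages are deterministic given
the seed recorded at simulation time.

Run-directory layout::

    run/
      manifest.json               scenario name, seed, studies, truth labels
      <study>.vcf                 genotypes (GT + DS)
      <study>.counts.bed          raw counts with gene annotations
      <study>.covariates.tsv      known covariates (sex, batch)
      gwas.tsv                    GWAS summary track
      <study>.phenotypes.bed      prepared phenotypes        (prep)
      <study>.model_covariates.tsv  known covs + RUV factors (prep)
      <study>.eqtl.tsv            gene-level permutation results (map-eqtl)
      <study>.nominal.tsv         per-variant associations   (map-eqtl)
      coloc_studies.tsv           cross-study colocalizations (coloc)
      coloc_gwas.tsv              GWAS colocalizations        (coloc)
      sharing.tsv / novelty.tsv / rescue.tsv                  (cross-coloc)
      mash_posterior.tsv          shrunken effects with lfsr  (mash)
      report.md + report tables                               (report)
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc as coloc_mod
from . import crosscoloc, enrich, io, mash, qtlmap, simgen, xprep

log = logging.getLogger(__name__)

__all__ = [
    "stage_simulate",
    "stage_prep",
    "stage_map",
    "stage_coloc",
    "stage_crosscoloc",
    "stage_mash",
    "stage_report",
    "run_all",
]

EGENE_Q = 0.05  # gene-level FDR threshold for calling eGenes


# ---------------------------------------------------------------------------
# simulate


def stage_simulate(scenario: str, seed: int, out_dir, **scenario_kwargs) -> Path:
    """Generate a scenario and write its fixture files to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = simgen.make_scenario(scenario, seed, **scenario_kwargs)
    for study, (geno, expr) in bundle.studies.items():
        io.write_vcf(geno, out / f"{study}.vcf")
        io.write_counts_bed(expr, out / f"{study}.counts.bed")
        covs = expr.known_covariates.copy()
        covs["library_size"] = expr.library_sizes
        io.write_covariates_tsv(covs, out / f"{study}.covariates.tsv")
    io.write_gwas_tsv(bundle.gwas, out / "gwas.tsv")
    manifest = {
        "scenario": scenario,
        "seed": seed,
        "studies": sorted(bundle.studies),
        "disease_study": bundle.disease_study,
        "labels": bundle.labels,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _load_manifest(run_dir) -> dict:
    return json.loads((Path(run_dir) / "manifest.json").read_text())


def _load_study(run_dir, study):
    run_dir = Path(run_dir)
    geno = io.read_vcf(run_dir / f"{study}.vcf")
    counts = io.read_counts_bed(run_dir / f"{study}.counts.bed")
    covs = io.read_covariates_tsv(run_dir / f"{study}.covariates.tsv")
    if "library_size" in covs.columns:
        counts.library_sizes = covs.pop("library_size").to_numpy(float)
    counts.known_covariates = covs
    return geno, counts


def _known_covariate_matrix(covs: pd.DataFrame) -> np.ndarray:
    """Sex plus batch indicator columns (first batch as reference)."""
    cols = [covs["sex"].to_numpy(float)]
    batches = sorted(covs["batch"].unique())
    for b in batches[1:]:
        cols.append((covs["batch"] == b).to_numpy(float))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# prep


def _count_egenes(pheno, genes, geno, covariates, n_perm, seed):
    """Number of FDR-significant genes under the given covariate model.

    The k-selection scan uses Benjamini-Hochberg rather than the Storey
    q-value: under an unadjusted (confounded) model the gene-level p-values
    are positively dependent through the shared hidden factors, and the
    pi0 estimate can collapse, cascading into inflated eGene counts.  The
    final mapping pass (with the chosen covariates) keeps Storey.
    """
    from statsmodels.stats.multitest import multipletests

    adj = []
    for gi, row in genes.iterrows():
        res = qtlmap.permutation_pass(
            pheno.values.loc[row.gene_id].to_numpy(),
            geno,
            covariates,
            gene_id=row.gene_id,
            tss=qtlmap.tss_of(row.start, row.end, row.strand),
            strand=row.strand,
            n_perm=n_perm,
            seed=seed + gi,
            chrom=row.chrom,
        )
        if res is not None:
            adj.append(res.adjusted_p)
    if not adj:
        return 0
    q = multipletests(np.clip(adj, qtlmap.P_FLOOR, 1.0), method="fdr_bh")[1]
    return int((q < EGENE_Q).sum())


def choose_ruv_k(
    counts,
    geno,
    known,
    k_grid=None,
    n_perm: int = 100,
    seed: int = 0,
):
    """eGene-discovery curve over candidate k, knee via kneedle.

    Returns (chosen_k, curve, RuvModel at the ceiling).  When kneedle finds
    no knee the curve's argmax is used (a flat curve keeps k = 0).
    """
    n = counts.n_samples
    k_max = max(1, int(0.25 * n))
    if k_grid is None:
        k_grid = list(range(0, min(10, k_max) + 1))
    ruv = xprep.estimate_ruv(counts, known, k=min(max(k_grid), k_max))
    pheno = xprep.prepare_phenotypes(counts)
    genes = xprep.filter_low_expression(counts).genes
    curve = []
    for k in k_grid:
        cov = known if k == 0 else np.column_stack([known, ruv.factors[:, :k]])
        curve.append((k, _count_egenes(pheno, genes, geno, cov, n_perm, seed)))
    chosen = xprep.choose_k_kneedle(curve)
    if chosen is None:
        counts_arr = np.array([c for _, c in curve])
        chosen = int(curve[int(np.argmax(counts_arr))][0]) if np.ptp(counts_arr) else 0
    ruv.k = int(chosen)
    ruv.egene_curve = curve
    return int(chosen), curve, ruv


def stage_prep(run_dir, k="auto", seed: int = 0, scan_perm: int = 100,
               k_grid=None) -> dict:
    """Phenotype preparation and RUV covariate estimation for every study."""
    run_dir = Path(run_dir)
    manifest = _load_manifest(run_dir)
    info = {}
    for si, study in enumerate(manifest["studies"]):
        geno, counts = _load_study(run_dir, study)
        known = _known_covariate_matrix(counts.known_covariates)
        pheno = xprep.prepare_phenotypes(counts)
        genes = xprep.filter_low_expression(counts).genes
        if k == "auto":
            chosen, curve, ruv = choose_ruv_k(
                counts, geno, known, k_grid=k_grid, n_perm=scan_perm,
                seed=seed + 1000 * (si + 1),
            )
        else:
            chosen = int(k)
            ruv = xprep.estimate_ruv(counts, known, k=max(chosen, 1))
            curve = []
        model_cov = known if chosen == 0 else np.column_stack(
            [known, ruv.factors[:, :chosen]]
        )
        cov_df = pd.DataFrame(
            model_cov,
            index=counts.samples,
            columns=[f"cov_{i}" for i in range(model_cov.shape[1])],
        )
        io.write_phenotype_bed(pheno.values, genes, run_dir / f"{study}.phenotypes.bed")
        io.write_covariates_tsv(cov_df, run_dir / f"{study}.model_covariates.tsv")
        info[study] = {"k": int(chosen), "egene_curve": [list(map(float, c)) for c in curve],
                       "n_controls": len(ruv.control_genes)}
    (run_dir / "prep.json").write_text(json.dumps(info, indent=2))
    return info


# ---------------------------------------------------------------------------
# map


def stage_map(run_dir, n_perm: int = 1000, seed: int = 0,
              conditional: bool = False, window: int = 1_000_000,
              maf_min: float = 0.02) -> dict:
    """Permutation pass (and optional conditional scan) for every study."""
    run_dir = Path(run_dir)
    manifest = _load_manifest(run_dir)
    out = {}
    for study in manifest["studies"]:
        geno, _ = _load_study(run_dir, study)
        values, genes = io.read_phenotype_bed(run_dir / f"{study}.phenotypes.bed")
        covs = io.read_covariates_tsv(run_dir / f"{study}.model_covariates.tsv")
        cov_mat = covs.to_numpy(float) if covs.shape[1] else None

        results, nominal_rows = [], []
        for gi, row in genes.iterrows():
            tss = qtlmap.tss_of(row.start, row.end, row.strand)
            y = values.loc[row.gene_id].to_numpy()
            records = qtlmap.nominal_scan(
                y, geno, cov_mat, gene_id=row.gene_id, tss=tss, strand=row.strand,
                window=window, maf_min=maf_min, chrom=row.chrom,
            )
            nominal_rows.extend(vars(r) for r in records)
            res = qtlmap.permutation_pass(
                y, geno, cov_mat, gene_id=row.gene_id, tss=tss, strand=row.strand,
                window=window, maf_min=maf_min, n_perm=n_perm, seed=seed + gi,
                chrom=row.chrom,
            )
            if res is not None:
                results.append(res)

        adj = np.array([r.adjusted_p for r in results])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pi0, q = qtlmap.storey_qvalues(np.clip(adj, qtlmap.P_FLOOR, 1.0))
        rows = []
        for r, qv in zip(results, q):
            r.qvalue = float(qv)
            rows.append(
                {
                    "gene_id": r.gene_id,
                    "n_variants": r.n_variants,
                    "beta_shape1": r.beta_null.a,
                    "beta_shape2": r.beta_null.b,
                    "variant_id": r.lead.variant_id,
                    "distance": r.lead.distance_to_tss,
                    "nominal_p": r.lead.nominal_p,
                    "slope": r.lead.slope,
                    "se": r.lead.se,
                    "adjusted_p": r.adjusted_p,
                    "qvalue": r.qvalue,
                }
            )
        eqtl = pd.DataFrame(rows)
        eqtl.to_csv(run_dir / f"{study}.eqtl.tsv", sep="\t", index=False,
                    float_format="%.8g")
        pd.DataFrame(nominal_rows).to_csv(
            run_dir / f"{study}.nominal.tsv", sep="\t", index=False,
            float_format="%.8g",
        )
        out[study] = {"pi0": float(pi0), "n_egenes": int((q < EGENE_Q).sum())}

        if conditional:
            sig = eqtl[eqtl["qvalue"] < EGENE_Q]
            threshold = float(sig["adjusted_p"].max()) if len(sig) else 0.0
            cond_rows = []
            for gi, row in genes.iterrows():
                if row.gene_id not in set(sig["gene_id"]):
                    continue
                signals = qtlmap.conditional_scan(
                    values.loc[row.gene_id].to_numpy(), geno, cov_mat,
                    gene_id=row.gene_id,
                    tss=qtlmap.tss_of(row.start, row.end, row.strand),
                    strand=row.strand, threshold=max(threshold, 1e-12),
                    window=window, maf_min=maf_min, n_perm=n_perm, seed=seed + gi,
                    chrom=row.chrom,
                )
                for rank, lead in enumerate(signals.leads):
                    cond_rows.append({"gene_id": row.gene_id, "rank": rank,
                                      **vars(lead)})
            pd.DataFrame(cond_rows).to_csv(
                run_dir / f"{study}.conditional.tsv", sep="\t", index=False,
                float_format="%.8g",
            )
    (run_dir / "map.json").write_text(json.dumps(out, indent=2))
    return out


# ---------------------------------------------------------------------------
# in-memory helpers (used by tests and the acceptance script as well)


def scenario_known_covariates(expr) -> np.ndarray:
    return _known_covariate_matrix(expr.known_covariates)


def scenario_gene_track(
    bundle,
    study: str,
    gene_id: str = "gene_000",
    k_ruv: int = 3,
    maf_min: float = 0.02,
):
    """Covariate-adjusted eQTL summary track for one gene of a scenario.

    Runs the standard preparation (filter, TMM, RINT) and nominal scan with
    sex/batch plus ``k_ruv`` RUV factors as covariates, without touching the
    filesystem.  Returns a quantitative SummaryStatTrack.
    """
    geno, expr = bundle.studies[study]
    pheno = xprep.prepare_phenotypes(expr)
    known = _known_covariate_matrix(expr.known_covariates)
    if k_ruv > 0:
        ruv = xprep.estimate_ruv(expr, known, k=k_ruv,
                                 n_top_expressed=min(5000, pheno.values.shape[0]),
                                 n_controls=min(1000, pheno.values.shape[0] // 2))
        cov = np.column_stack([known, ruv.factors])
    else:
        cov = known
    grow = expr.genes[expr.genes["gene_id"] == gene_id].iloc[0]
    tss = qtlmap.tss_of(grow.start, grow.end, grow.strand)
    records = qtlmap.nominal_scan(
        pheno.values.loc[gene_id].to_numpy(), geno, cov, gene_id=gene_id,
        tss=tss, strand=grow.strand, maf_min=maf_min, chrom=grow.chrom,
    )
    tab = pd.DataFrame([vars(r) for r in records]).merge(
        geno.variants[["variant_id", "chrom", "pos", "ref", "alt"]], on="variant_id"
    )
    table = pd.DataFrame(
        {
            "variant_id": tab["variant_id"].values,
            "chrom": tab["chrom"].astype(str).values,
            "pos": tab["pos"].values,
            "ref": tab["ref"].values,
            "alt": tab["alt"].values,
            "beta": tab["slope"].values,
            "se": tab["se"].values,
            "z": (tab["slope"] / tab["se"]).values,
            "p": tab["nominal_p"].values,
            "maf": tab["maf"].values,
        }
    )
    return simgen.SummaryStatTrack(
        trait_id=f"{study}:{gene_id}", trait_type="quantitative",
        table=table, n=geno.n_samples,
    )


def scenario_gwas_locus(bundle, gene_index: int = 0,
                        n_variants_per_gene: int = None):
    """The GWAS sub-track covering one gene's region of a scenario bundle."""
    geno = next(iter(bundle.studies.values()))[0]
    genes = next(iter(bundle.studies.values()))[1].genes
    n_cis = len(genes[genes["chrom"] == "1"])
    per_gene = (n_variants_per_gene
                or geno.n_variants // max(n_cis, 1))
    ids = geno.variants["variant_id"].iloc[
        gene_index * per_gene: (gene_index + 1) * per_gene
    ]
    return bundle.gwas.subset(ids)


# ---------------------------------------------------------------------------
# coloc helpers


def _study_tracks(run_dir, study, n_samples: int) -> dict:
    """Per-gene quantitative summary tracks from the nominal scan output."""
    run_dir = Path(run_dir)
    nominal = pd.read_csv(run_dir / f"{study}.nominal.tsv", sep="\t")
    geno_meta = io.read_vcf(run_dir / f"{study}.vcf").variants
    merged = nominal.merge(geno_meta, on="variant_id", suffixes=("", "_v"))
    tracks = {}
    for gene_id, sub in merged.groupby("gene_id"):
        table = pd.DataFrame(
            {
                "variant_id": sub["variant_id"].values,
                "chrom": sub["chrom"].astype(str).values,
                "pos": sub["pos"].values,
                "ref": sub["ref"].values,
                "alt": sub["alt"].values,
                "beta": sub["slope"].values,
                "se": sub["se"].values,
                "z": (sub["slope"] / sub["se"]).values,
                "p": sub["nominal_p"].values,
                "maf": sub["maf"].values,
            }
        )
        tracks[gene_id] = simgen.SummaryStatTrack(
            trait_id=f"{study}:{gene_id}",
            trait_type="quantitative",
            table=table,
            n=n_samples,
        )
    return tracks


def _gwas_loci(gwas: simgen.SummaryStatTrack, spacing: int = simgen.GENE_SPACING):
    """Split the GWAS track into per-region loci keyed by region index."""
    table = gwas.table
    region = ((table["pos"] - 1) // spacing).astype(int)
    loci = {}
    for ridx, sub in table.groupby(region):
        track = simgen.SummaryStatTrack(
            trait_id=f"{gwas.trait_id}:locus_{ridx:03d}",
            trait_type=gwas.trait_type,
            table=sub.reset_index(drop=True),
            n=gwas.n,
            case_fraction=gwas.case_fraction,
        )
        idx = sub["p"].idxmin()
        loci[f"locus_{ridx:03d}"] = {
            "track": track,
            "index_variant": str(sub.loc[idx, "variant_id"]),
            "index_p": float(sub.loc[idx, "p"]),
            "region": int(ridx),
        }
    return loci


def _gene_region(genes: pd.DataFrame, spacing: int = simgen.GENE_SPACING) -> dict:
    return {
        row.gene_id: int((row.start - 1) // spacing) for _, row in genes.iterrows()
    }


def stage_coloc(run_dir, gwas_sig_p: float = enrich.GWAS_SIG_P,
                r2_min: float = 0.2) -> dict:
    """Cross-study eQTL colocalization plus LD-prioritized GWAS colocalization."""
    run_dir = Path(run_dir)
    manifest = _load_manifest(run_dir)
    studies = manifest["studies"]
    genos = {s: io.read_vcf(run_dir / f"{s}.vcf") for s in studies}
    eqtl = {s: pd.read_csv(run_dir / f"{s}.eqtl.tsv", sep="\t") for s in studies}
    tracks = {s: _study_tracks(run_dir, s, genos[s].n_samples) for s in studies}
    gwas = io.read_gwas_tsv(run_dir / "gwas.tsv")
    loci = _gwas_loci(gwas)
    _, genes = io.read_phenotype_bed(
        run_dir / f"{manifest['disease_study']}.phenotypes.bed"
    )
    gene_region = _gene_region(genes)

    # --- eQTL-eQTL colocalization for genes significant in >= 1 study
    sig_genes = set()
    for s in studies:
        sig = eqtl[s][eqtl[s]["qvalue"] < EGENE_Q]
        sig_genes.update(sig["gene_id"])
    rows = []
    for gene in sorted(sig_genes):
        for i, s1 in enumerate(studies):
            for s2 in studies[i + 1:]:
                if gene not in tracks[s1] or gene not in tracks[s2]:
                    continue
                res = coloc_mod.coloc_abf(
                    tracks[s1][gene], tracks[s2][gene],
                    pair_id=f"{s1}|{s2}|{gene}",
                )
                rows.append({"gene_id": gene, "study_1": s1, "study_2": s2,
                             **res.to_row()})
    pd.DataFrame(rows).to_csv(run_dir / "coloc_studies.tsv", sep="\t", index=False,
                              float_format="%.8g")

    # --- GWAS colocalization with two-stage LD prioritization
    panels = list(genos.values())
    gwas_rows = []
    for locus_id, locus in sorted(loci.items()):
        if locus["index_p"] >= gwas_sig_p:
            continue
        for s in studies:
            sig = eqtl[s][eqtl[s]["qvalue"] < EGENE_Q]
            leads = [
                (row.gene_id, row.variant_id)
                for row in sig.itertuples()
                if gene_region.get(row.gene_id) == locus["region"]
            ]
            pairs = coloc_mod.prioritize_pairs(
                [locus["index_variant"]], leads, panels, r2_min=r2_min
            )
            for _, gene in pairs:
                res = coloc_mod.coloc_abf(
                    tracks[s][gene], locus["track"],
                    pair_id=f"{s}|gwas|{locus_id}|{gene}",
                )
                gwas_rows.append(
                    {"locus_id": locus_id, "gene_id": gene, "study": s,
                     "index_variant": locus["index_variant"], **res.to_row()}
                )
    pd.DataFrame(gwas_rows).to_csv(run_dir / "coloc_gwas.tsv", sep="\t", index=False,
                                   float_format="%.8g")
    return {"n_study_pairs": len(rows), "n_gwas_pairs": len(gwas_rows)}


# ---------------------------------------------------------------------------
# cross-coloc


def _pp_dict(row) -> dict:
    return {f"H{i}": float(row[f"PP{i}"]) for i in range(5)}


def _result_from_row(row) -> coloc_mod.ColocResult:
    return coloc_mod.ColocResult(
        pair_id=str(row["pair_id"]), n_snps=int(row["n_snps"]), pp=_pp_dict(row)
    )


def stage_crosscoloc(run_dir) -> dict:
    """Sharing labels, GWAS novelty labels, and the rescue scan."""
    run_dir = Path(run_dir)
    manifest = _load_manifest(run_dir)
    studies = manifest["studies"]
    home = manifest["disease_study"]
    others = [s for s in studies if s != home]
    genos = {s: io.read_vcf(run_dir / f"{s}.vcf") for s in studies}
    eqtl = {s: pd.read_csv(run_dir / f"{s}.eqtl.tsv", sep="\t") for s in studies}
    tracks = {s: _study_tracks(run_dir, s, genos[s].n_samples) for s in studies}
    gwas = io.read_gwas_tsv(run_dir / "gwas.tsv")
    loci = _gwas_loci(gwas)
    study_coloc = pd.read_csv(run_dir / "coloc_studies.tsv", sep="\t")
    gwas_coloc = pd.read_csv(run_dir / "coloc_gwas.tsv", sep="\t")

    # sharing of home-study eGenes
    home_sig = eqtl[home][eqtl[home]["qvalue"] < EGENE_Q]["gene_id"]
    sharing_rows = []
    for gene in home_sig:
        per_other = {}
        for other in others:
            sub = study_coloc[
                (study_coloc["gene_id"] == gene)
                & (
                    ((study_coloc["study_1"] == home) & (study_coloc["study_2"] == other))
                    | ((study_coloc["study_1"] == other) & (study_coloc["study_2"] == home))
                )
            ]
            per_other[other] = _result_from_row(sub.iloc[0]) if len(sub) else None
        label = crosscoloc.eqtl_sharing_class(gene, per_other)
        sharing_rows.append({"gene_id": gene, "label": label.label,
                             "supporting": ";".join(label.supporting)})
    pd.DataFrame(sharing_rows, columns=["gene_id", "label", "supporting"]).to_csv(
        run_dir / "sharing.tsv", sep="\t", index=False
    )

    # novelty of home-study GWAS colocalizations (cross-coloc run regardless
    # of other-study significance or LD prioritization)
    novelty_rows = []
    if len(gwas_coloc):
        home_hits = gwas_coloc[
            (gwas_coloc["study"] == home)
            & (gwas_coloc["PP4"] > crosscoloc.PP_THRESHOLD)
        ]
        for row in home_hits.itertuples():
            cross = {}
            for other in others:
                if row.gene_id in tracks[other]:
                    cross[other] = coloc_mod.coloc_abf(
                        tracks[other][row.gene_id], loci[row.locus_id]["track"],
                        pair_id=f"cross:{other}|{row.locus_id}|{row.gene_id}",
                    )
                else:
                    cross[other] = None
            label = crosscoloc.gwas_coloc_novelty(
                row.locus_id, row.gene_id, _result_from_row(row._asdict()), cross
            )
            novelty_rows.append(
                {"locus_id": row.locus_id, "gene_id": row.gene_id,
                 "label": label.label,
                 "cross": ";".join(f"{s}={h}" for s, h in
                                   sorted(label.cross_max_hypotheses.items()))}
            )
    pd.DataFrame(
        novelty_rows, columns=["locus_id", "gene_id", "label", "cross"]
    ).to_csv(run_dir / "novelty.tsv", sep="\t", index=False)

    # rescue: genes colocalized with GWAS only in another study
    rescue_rows = []
    if len(gwas_coloc):
        other_hits = gwas_coloc[
            (gwas_coloc["study"] != home)
            & (gwas_coloc["PP4"] > crosscoloc.PP_THRESHOLD)
        ]
        home_tested = set(
            gwas_coloc[gwas_coloc["study"] == home]["gene_id"]
        )
        candidates = {}
        for row in other_hits.itertuples():
            if row.gene_id not in home_tested:
                candidates[row.gene_id] = row.locus_id
        gwas_by_gene = {g: loci[lid]["track"] for g, lid in candidates.items()}
        rescued, max_h4, untestable = crosscoloc.rescue_scan(
            sorted(candidates), tracks[home], gwas_by_gene
        )
        rescued_ids = {g for g, _ in rescued}
        for gene, res in max_h4:
            rescue_rows.append(
                {"gene_id": gene, "locus_id": candidates[gene],
                 "PP4": res["H4"], "rescued": gene in rescued_ids}
            )
        for gene, res in rescued:
            if res.max_hypothesis != "H4":  # PP4 > 0.5 implies max-H4; safety
                rescue_rows.append({"gene_id": gene, "locus_id": candidates[gene],
                                    "PP4": res["H4"], "rescued": True})
    pd.DataFrame(
        rescue_rows, columns=["gene_id", "locus_id", "PP4", "rescued"]
    ).to_csv(run_dir / "rescue.tsv", sep="\t", index=False, float_format="%.8g")
    return {
        "n_sharing": len(sharing_rows),
        "n_novelty": len(novelty_rows),
        "n_rescue": len(rescue_rows),
    }


# ---------------------------------------------------------------------------
# mash


def stage_mash(run_dir, seed: int = 0, max_random: int = 50_000) -> dict:
    """Multivariate shrinkage across studies on the shared variant-gene pairs."""
    run_dir = Path(run_dir)
    manifest = _load_manifest(run_dir)
    studies = manifest["studies"]
    nominal = {
        s: pd.read_csv(run_dir / f"{s}.nominal.tsv", sep="\t") for s in studies
    }
    merged = None
    for s in studies:
        sub = nominal[s][["gene_id", "variant_id", "slope", "se"]].rename(
            columns={"slope": f"beta_{s}", "se": f"se_{s}"}
        )
        merged = sub if merged is None else merged.merge(
            sub, on=["gene_id", "variant_id"]
        )
    if merged is None or len(merged) == 0:
        raise ValueError("no variant-gene pairs shared across studies")
    beta = merged[[f"beta_{s}" for s in studies]].to_numpy()
    se = merged[[f"se_{s}" for s in studies]].to_numpy()
    z = np.abs(beta / se)

    rng = np.random.default_rng(seed)
    n_rows = len(merged)
    take = min(max_random, n_rows)
    rand_idx = rng.choice(n_rows, size=take, replace=False)
    random_panel = mash.EffectPanel(beta[rand_idx], se[rand_idx], role="random",
                                    conditions=studies)
    # strong set: per gene, the row with the largest |z| in any study
    strongest = merged.assign(maxz=z.max(axis=1)).groupby("gene_id")["maxz"].idxmax()
    strong_idx = strongest.to_numpy()
    strong_panel = mash.EffectPanel(beta[strong_idx], se[strong_idx], role="strong",
                                    conditions=studies,
                                    row_ids=list(strongest.index))

    if n_rows >= 1000:
        v = mash.estimate_null_correlation(random_panel)
    else:
        log.info("only %d shared rows; identity null correlation used", n_rows)
        v = np.eye(len(studies))
    model = mash.fit_mixture_em(random_panel, null_correlation=v, seed=seed)
    post = mash.posterior_lfsr(strong_panel, model)

    rows = []
    for i, (gene, ridx) in enumerate(strongest.items()):
        for si, s in enumerate(studies):
            rows.append(
                {
                    "gene_id": gene,
                    "variant_id": merged.loc[ridx, "variant_id"],
                    "study": s,
                    "beta_hat": beta[ridx, si],
                    "se": se[ridx, si],
                    "post_mean": post.post_mean[i, si],
                    "post_sd": post.post_sd[i, si],
                    "lfsr": post.lfsr[i, si],
                }
            )
    pd.DataFrame(rows).to_csv(run_dir / "mash_posterior.tsv", sep="\t", index=False,
                              float_format="%.8g")
    agg = mash.aggregate_weights(model)
    (run_dir / "mash.json").write_text(json.dumps(
        {"aggregate_weights": agg,
         "null_correlation": v.tolist(),
         "n_random": int(take), "n_strong": int(len(strong_idx))}, indent=2))
    return agg


# ---------------------------------------------------------------------------
# report


def stage_report(run_dir) -> Path:
    """Aggregate run outputs into summary tables and a markdown report."""
    run_dir = Path(run_dir)
    manifest = _load_manifest(run_dir)
    studies = manifest["studies"]
    home = manifest["disease_study"]
    eqtl = {s: pd.read_csv(run_dir / f"{s}.eqtl.tsv", sep="\t") for s in studies}
    nominal = {s: pd.read_csv(run_dir / f"{s}.nominal.tsv", sep="\t") for s in studies}
    gwas = io.read_gwas_tsv(run_dir / "gwas.tsv")
    sharing = pd.read_csv(run_dir / "sharing.tsv", sep="\t")
    novelty = pd.read_csv(run_dir / "novelty.tsv", sep="\t")
    rescue = pd.read_csv(run_dir / "rescue.tsv", sep="\t")

    # eVariant enrichment among GWAS-significant variants, per study
    gwas_sig = set(gwas.table.loc[gwas.table["p"] < enrich.GWAS_SIG_P, "variant_id"])
    enrich_rows = []
    for s in studies:
        tested = set(nominal[s]["variant_id"])
        sig_genes = set(eqtl[s].loc[eqtl[s]["qvalue"] < EGENE_Q, "gene_id"])
        evar = set()
        for gene in sig_genes:
            g = eqtl[s][eqtl[s]["gene_id"] == gene].iloc[0]
            thresh = _nominal_threshold(g)
            sub = nominal[s][nominal[s]["gene_id"] == gene]
            evar.update(sub.loc[sub["nominal_p"] <= thresh, "variant_id"])
        try:
            res = enrich.enrichment_fold(evar, gwas_sig, tested, study=s, trait="gwas")
            enrich_rows.append(vars(res))
        except ValueError:
            enrich_rows.append({"study": s, "trait": "gwas", "n_tested": len(tested),
                                "n_evar": len(evar), "n_gwas_sig": 0, "n_overlap": 0,
                                "fold": float("nan")})
    enrich_df = pd.DataFrame(enrich_rows)
    enrich_df.to_csv(run_dir / "enrichment.tsv", sep="\t", index=False,
                     float_format="%.6g")

    # lead-distance summary by sharing label
    groups = {}
    lead_dist = dict(zip(eqtl[home]["gene_id"], eqtl[home]["distance"]))
    for row in sharing.itertuples():
        if row.gene_id in lead_dist:
            groups.setdefault(row.label, []).append(int(lead_dist[row.gene_id]))
    if groups:
        medians, _ = enrich.distance_summary(groups)
    else:
        medians = pd.DataFrame(columns=["group", "n", "median_abs_distance"])
    medians.to_csv(run_dir / "distance_summary.tsv", sep="\t", index=False,
                   float_format="%.6g")

    # effect-size correlations between studies on shared lead pairs
    corr_rows = []
    for i, s1 in enumerate(studies):
        for s2 in studies[i + 1:]:
            pairs = eqtl[s1][["gene_id", "variant_id", "slope"]].merge(
                eqtl[s2][["gene_id", "variant_id", "slope"]],
                on=["gene_id", "variant_id"], suffixes=("_1", "_2"),
            )
            r = (enrich.pearson_r(pairs["slope_1"], pairs["slope_2"])
                 if len(pairs) >= 3 else float("nan"))
            corr_rows.append({"study_1": s1, "study_2": s2,
                              "n_shared_leads": len(pairs), "pearson_r": r})
    corr_df = pd.DataFrame(corr_rows)
    corr_df.to_csv(run_dir / "effect_correlation.tsv", sep="\t", index=False,
                   float_format="%.6g")

    novel = novelty[novelty["label"] == "novel"] if len(novelty) else novelty
    lines = [
        f"# eQTL pipeline report — scenario `{manifest['scenario']}`, "
        f"seed {manifest['seed']}",
        "",
        "## eGenes per study",
        "",
    ]
    for s in studies:
        n_eg = int((eqtl[s]["qvalue"] < EGENE_Q).sum())
        lines.append(f"- {s}: {n_eg} eGenes (q < {EGENE_Q}) of {len(eqtl[s])} tested")
    lines += ["", "## GWAS colocalization novelty", ""]
    if len(novel):
        for row in novel.itertuples():
            lines.append(
                f"- **novel target gene {row.gene_id}** at {row.locus_id} "
                f"(disease-study colocalization absent elsewhere: {row.cross})"
            )
    else:
        lines.append("- no novel disease-study colocalizations")
    if len(rescue):
        lines += ["", "## Rescued colocalizations", ""]
        for row in rescue.itertuples():
            mark = "rescued" if row.rescued else "max-H4 only"
            lines.append(f"- {row.gene_id} at {row.locus_id}: PP4 = {row.PP4:.3f} ({mark})")
    lines += ["", "## eVariant enrichment among GWAS variants", "",
              enrich_df.to_string(index=False), ""]
    if len(medians):
        lines += ["## Lead-variant TSS distance by sharing label", "",
                  medians.to_string(index=False), ""]
    lines += ["## Cross-study lead effect-size correlation", "",
              corr_df.to_string(index=False), ""]
    report = run_dir / "report.md"
    report.write_text("\n".join(lines))
    return report


def _nominal_threshold(gene_row) -> float:
    """Per-gene nominal p threshold at the gene's significance boundary.

    Inverts the fitted beta null at the gene-level adjusted-p threshold
    (EGENE_Q on the adjusted scale), mirroring the usual per-gene eVariant
    calling rule.
    """
    from scipy import stats as _stats

    return float(_stats.beta.ppf(EGENE_Q, gene_row["beta_shape1"],
                                 gene_row["beta_shape2"]))


def run_all(scenario: str, seed: int, out_dir, n_perm: int = 1000,
            k: str = "auto", conditional: bool = False) -> Path:
    """simulate -> prep -> map -> coloc -> cross-coloc -> mash -> report."""
    out = stage_simulate(scenario, seed, out_dir)
    stage_prep(out, k=k, seed=seed)
    stage_map(out, n_perm=n_perm, seed=seed, conditional=conditional)
    stage_coloc(out)
    stage_crosscoloc(out)
    stage_mash(out, seed=seed)
    return stage_report(out)
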