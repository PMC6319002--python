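"""End-to-end orchestration: simulate -> preprocess -> h2 -> eQTL -> classify
-> pQTL -> co-localization, with tab-separated artifacts and summary tables."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import io as _io
from .coloc import conditional_coloc, find_overlaps, map_pqtl
from .gwa import (backsolve_snp_effects, call_eqtl, conditional_peak_scan,
                  detect_hotspots, enrichment_test, gene_fdr, snp_test)
from .mixedmodel import GBLUPRunner, bh_fdr, compute_grm, lrt_heritability, standardize_genotypes
from .preprocess import GenotypeData, filter_markers, normalize_expression
from .simdata import SimConfig, simulate_dataset

logger = logging.getLogger("eqtlcross")

__all__ = ["PipelineConfig", "StudyResult", "run_study", "summarize"]


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    maf_min: float = 0.01
    ld_r_max: float = 0.95
    min_total: int | None = None        # count filter; default = n samples
    alpha_eqtl: float = 0.01
    alpha_pqtl: float = 0.05
    alpha_h2: float = 0.01
    hotspot_min_genes: int = 10
    conditional_scan: bool = True
    method: str = "reml"
    out: str | None = None

    def __post_init__(self):
        for name, v in (("maf_min", self.maf_min), ("ld_r_max", self.ld_r_max),
                        ("alpha_eqtl", self.alpha_eqtl),
                        ("alpha_pqtl", self.alpha_pqtl), ("alpha_h2", self.alpha_h2)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class StudyResult:
    geno: GenotypeData
    h2_table: pd.DataFrame
    eqtl_records: list
    eqtl_table: pd.DataFrame
    hotspots: pd.DataFrame
    pqtl_records: list
    pqtl_table: pd.DataFrame
    coloc_records: list
    coloc_table: pd.DataFrame
    class_summary: pd.DataFrame
    confusion: pd.DataFrame | None
    enrichment_p: float | None
    truth: object | None


def _expression_design(phen: pd.DataFrame) -> np.ndarray:
    cols = [np.ones(len(phen))]
    for c in ("sex", "scheme"):
        if c in phen.columns:
            cols.append(phen[c].to_numpy(float))
    return np.column_stack(cols)


def _records_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "response": r.response, "chrom": r.chrom,
            "start": r.start, "end": r.end,
            "interval_mb": (r.end - r.start) / 1e6,
            "peak_marker": r.peak_marker, "peak_pos": r.peak_pos,
            "n_snps": r.n_snps, "peak_q": r.peak_q,
            "h2": r.h2, "class": r.reg_class,
            "distance_mb": r.distance_mb, "parent": r.parent,
        })
    return pd.DataFrame(rows)


def summarize(records) -> pd.DataFrame:
    """Per-regulator-class N / min / max / mean / sd of interval length (Mb),
    gene distance (Mb), SNPs per QTL and heritability.  Distances of
    cross-chromosome (distant) records are undefined and reported as NaN."""
    rows = []
    df = _records_frame(records)
    if df.empty:
        return pd.DataFrame()
    df["class"] = df["class"].fillna("all")
    groups = [("all_regulators", df)] + [(c, g) for c, g in df.groupby("class")]
    for name, g in groups:
        for metric, col in (("interval_mb", "interval_mb"),
                            ("distance_mb", "distance_mb"),
                            ("n_snps", "n_snps"), ("h2", "h2")):
            v = g[col].astype(float)
            v = v[np.isfinite(v)]
            if len(v) == 0:
                rows.append((name, metric, len(g), np.nan, np.nan, np.nan, np.nan))
            else:
                sd = float(v.std(ddof=0)) if len(v) == 1 else float(v.std(ddof=1))
                rows.append((name, metric, len(g), float(v.min()), float(v.max()),
                             float(v.mean()), sd))
    return pd.DataFrame(rows, columns=["class", "metric", "n", "min", "max",
                                       "mean", "sd"])


def map_eqtl(norm, geno: GenotypeData, X, runner: GBLUPRunner,
             cfg: PipelineConfig):
    """Per-gene heritability, LRT, backsolve GWAS, eQTL calling and the
    conditional secondary-peak scan."""
    km = geno.kept_map
    h2_rows, records, sig_pairs = [], [], []
    for gi, gene in enumerate(norm.genes["gene"]):
        y = norm.y[gi]
        w = float(norm.w_std[gi])
        fit = runner.fit(y, X, weight=w, method=cfg.method)
        p_lrt = lrt_heritability(fit)
        h2_rows.append((gene, fit.sigma2_a, fit.sigma2_e, fit.h2, p_lrt))
        ghat, var_ghat = backsolve_snp_effects(fit)
        _, p = snp_test(ghat, var_ghat)
        q = gene_fdr([p], alpha=cfg.alpha_eqtl)[0]
        annot = norm.genes.iloc[gi]
        recs = call_eqtl(gene, q, p, km, gene_annot=annot, alpha=cfg.alpha_eqtl)
        for r in recs:
            r.h2 = fit.h2
            sig_pairs.extend((m, gene) for m in r.sig_markers)
        if cfg.conditional_scan:
            extra = []
            for r in recs:
                if r.n_snps >= 2:
                    extra.extend(conditional_peak_scan(
                        y, X, runner, w, km, r, gene_annot=annot,
                        alpha=cfg.alpha_eqtl, method=cfg.method))
            for r in extra:
                r.h2 = fit.h2
            recs.extend(extra)
        records.extend(recs)
    h2 = pd.DataFrame(h2_rows, columns=["gene", "sigma2_a", "sigma2_e", "h2", "lrt_p"])
    h2["q"], h2["significant"] = bh_fdr(h2["lrt_p"].to_numpy(), alpha=cfg.alpha_h2)
    return h2, records, sig_pairs


def _classify_all(records, full_map):
    for r in records:
        r.reg_class = _classify.classify_regulator(r, full_map)
        r.distance_mb = _classify.eqtl_gene_distance(r)
    return records


def _confusion(truth_genes: pd.DataFrame, records) -> pd.DataFrame:
    by_gene = {}
    for r in records:
        by_gene.setdefault(r.response, []).append(r)
    rows = []
    for _, t in truth_genes.iterrows():
        if t["class"] == "null" or t["causal_marker"] is None:
            continue
        recs = by_gene.get(t["gene"], [])
        called = sorted({r.reg_class for r in recs}) if recs else []
        rows.append((t["gene"], t["class"], bool(recs), ";".join(c or "" for c in called)))
    df = pd.DataFrame(rows, columns=["gene", "truth_class", "detected", "called_classes"])
    return df


def run_study(cfg: PipelineConfig, outdir: str | None = None) -> StudyResult:
    """Execute the full study on a simulated dataset and (optionally) write
    every stage artifact under ``outdir``."""
    t0 = time.time()
    outdir = outdir or cfg.out
    geno_raw, counts, phen, truth = simulate_dataset(cfg.sim)
    logger.info("simulate: %d animals, %d markers, %d genes (%.1fs)",
                geno_raw.M.shape[0], geno_raw.M.shape[1], counts.counts.shape[0],
                time.time() - t0)

    geno = filter_markers(geno_raw.M.astype(int), geno_raw.map,
                          maf_min=cfg.maf_min, ld_r_max=cfg.ld_r_max)
    geno.animal_ids = geno_raw.animal_ids
    X = _expression_design(phen)
    norm = normalize_expression(counts, X, min_total=cfg.min_total)
    logger.info("preprocess: %d kept markers, %d genes after count filter",
                geno.M.shape[1], norm.y.shape[0])

    Z = standardize_genotypes(geno.M, geno.p)
    G = compute_grm(Z)
    runner = GBLUPRunner(G)
    runner.set_markers(Z)

    h2_table, eqtl_records, sig_pairs = map_eqtl(norm, geno, X, runner, cfg)
    _classify_all(eqtl_records, geno.map)
    hotspots = detect_hotspots(sig_pairs, min_genes=cfg.hotspot_min_genes)
    logger.info("eQTL: %d records, %d hotspots", len(eqtl_records), len(hotspots))

    traits = [c for c in phen.columns if c not in ("animal", "sex", "scheme")]
    pqtl_records, pfits = map_pqtl(phen, traits, geno, runner,
                                   covariates=[c for c in ("sex", "scheme")
                                               if c in phen.columns],
                                   alpha=cfg.alpha_pqtl, method=cfg.method)

    pairs = find_overlaps(eqtl_records, pqtl_records)
    gene_idx = {g: i for i, g in enumerate(norm.genes["gene"])}
    coloc_records = []
    for e, p in pairs:
        gi = gene_idx[e.response]
        coloc_records.append(conditional_coloc(
            norm.y[gi], X, runner, float(norm.w_std[gi]), (e, p), geno,
            n_tests=len(pairs), phen_value=phen[p.response].to_numpy(float),
            alpha_eqtl=cfg.alpha_eqtl, method=cfg.method))
    logger.info("coloc: %d candidate pairs, %d significant",
                len(pairs), sum(c.significant_coloc for c in coloc_records))

    eqtl_table = _records_frame(eqtl_records)
    pqtl_table = _records_frame(pqtl_records)
    coloc_table = pd.DataFrame([{
        "gene": c.gene, "phenotype": c.phenotype,
        "eqtl_chrom": c.eqtl.chrom, "eqtl_start": c.eqtl.start,
        "eqtl_end": c.eqtl.end, "class": c.eqtl.reg_class,
        "pqtl_peak": c.pqtl.peak_marker, "b_snp": c.b_snp, "p_snp": c.p_snp,
        "bonferroni": c.bonferroni, "eliminated": c.eliminated,
        "significant": c.significant_coloc,
        "prop_expr_var": c.prop_expr_var, "prop_phen_var": c.prop_phen_var,
        "ld_r": c.ld_r,
    } for c in coloc_records])

    class_summary = summarize(eqtl_records)
    confusion = _confusion(truth.genes, eqtl_records) if truth is not None else None

    enrich_p = None
    if truth is not None and not h2_table.empty:
        has_eqtl = h2_table["gene"].isin({r.response for r in eqtl_records})
        sig = h2_table["significant"].astype(bool)
        table = [[int((has_eqtl & sig).sum()), int((has_eqtl & ~sig).sum())],
                 [int((~has_eqtl & sig).sum()), int((~has_eqtl & ~sig).sum())]]
        enrich_p = enrichment_test(table)

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_dataset(out, geno_raw, counts, phen, truth)
        _io.write_marker_map(out / "marker_map.tsv", geno.map)
        h2_table.to_csv(out / "h2_genes.tsv", sep="\t", index=False)
        eqtl_table.to_csv(out / "eqtl.tsv", sep="\t", index=False)
        hotspots.assign(genes=[";".join(g) for g in hotspots["genes"]] if len(hotspots) else []) \
            .to_csv(out / "hotspots.tsv", sep="\t", index=False)
        pqtl_table.to_csv(out / "pqtl.tsv", sep="\t", index=False)
        coloc_table.to_csv(out / "coloc.tsv", sep="\t", index=False)
        class_summary.to_csv(out / "class_summary.tsv", sep="\t", index=False)
        if confusion is not None:
            confusion.to_csv(out / "confusion.tsv", sep="\t", index=False)
    logger.info("run_study done in %.1fs", time.time() - t0)

    return StudyResult(geno=geno, h2_table=h2_table, eqtl_records=eqtl_records,
                       eqtl_table=eqtl_table, hotspots=hotspots,
                       pqtl_records=pqtl_records, pqtl_table=pqtl_table,
                       coloc_records=coloc_records, coloc_table=coloc_table,
                       class_summary=class_summary, confusion=confusion,
                       enrichment_p=enrich_p, truth=truth)
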