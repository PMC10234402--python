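"""End-to-end orchestration of the analysis stages on one input bundle.

Stages run in a fixed order — simulate (optional) → assembly QC → gene-age
strata → chromosomal landscape → poly(A) — each consuming only its
declared files and writing its outputs plus a section of a combined JSON
report. A fixed seed makes the whole run deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from chronotopo import __version__, asmqc, chromscape, io, phylostrat, polya, synthetic

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    outdir: str = "chronotopo_run"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    run_asmqc: bool = True
    run_strata: bool = True
    run_chromscape: bool = True
    run_polya: bool = True
    # inputs (filled from the synthetic bundle when simulate=True)
    genome: Optional[str] = None
    genes: Optional[str] = None
    ages: Optional[str] = None
    hits: Optional[str] = None
    taxon_map: Optional[str] = None
    lineages: Optional[str] = None
    tree: Optional[str] = None
    srna_loci: Optional[str] = None
    coverage: Optional[str] = None
    methylation: Optional[str] = None
    reads: Optional[str] = None
    # parameters (defaults follow the study conventions)
    focal_taxon_id: int = synthetic.FOCAL_TAXON_ID
    evalue_max: float = 1e-5
    rep_threshold_pct: float = 30.0
    bin_size: int = 200
    n_perm: int = 1000
    polya_window: int = 50
    min_tail: int = 10
    min_gap_run: int = 10
    telomere_window_bp: int = 1000
    telomere_min_tandem: int = 8
    synthetic_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _gene_srna_rpkm(genes: pd.DataFrame, srna: pd.DataFrame) -> pd.Series:
    """Summed weight of small-RNA loci overlapping each gene."""
    vals = []
    by_chrom = {c: g.sort_values("start") for c, g in srna.groupby("chrom")}
    for g in genes.itertuples():
        loci = by_chrom.get(g.chrom)
        if loci is None:
            vals.append(0.0)
            continue
        hit = loci[(loci.end > g.start) & (loci.start < g.end)]
        vals.append(float(hit.rpkm.sum()) if len(hit) else 0.0)
    return pd.Series(vals, index=genes.index)


def _bin_weighted_track(
    intervals: pd.DataFrame, chrom_sizes: dict, bin_size: int, value_col: str
) -> pd.DataFrame:
    """Per-bin sum of interval weights (weight spread over covered bins)."""
    out_rows = []
    arrays = {c: np.zeros(-(-s // bin_size)) for c, s in chrom_sizes.items()}
    for r in intervals.itertuples():
        w = getattr(r, value_col)
        b0 = r.start // bin_size
        b1 = (r.end - 1) // bin_size
        length = r.end - r.start
        for b in range(b0, min(b1 + 1, len(arrays[r.chrom]))):
            lo = max(r.start, b * bin_size)
            hi = min(r.end, (b + 1) * bin_size)
            arrays[r.chrom][b] += w * (hi - lo) / length
    for chrom in sorted(chrom_sizes):
        for b, v in enumerate(arrays[chrom]):
            out_rows.append({"chrom": chrom, "pos": b * bin_size, "value": float(v)})
    return pd.DataFrame(out_rows)


def run_asmqc_stage(cfg: RunConfig, outdir: Path) -> dict:
    scaffolds = asmqc.read_fasta(cfg.genome)
    stats = asmqc.assembly_stats(scaffolds, min_gap_run=cfg.min_gap_run)
    states = [
        asmqc.classify_telomere_ends(
            name, seq, window_bp=cfg.telomere_window_bp,
            min_tandem=cfg.telomere_min_tandem,
        )
        for name, seq in sorted(scaffolds.items())
    ]
    summary = asmqc.telomere_summary(states)
    tel_df = pd.DataFrame(
        [
            {
                "scaffold_id": s.scaffold_id,
                "end_5prime": s.end_5prime,
                "end_3prime": s.end_3prime,
                "t2t": s.t2t,
            }
            for s in states
        ]
    )
    tel_df.to_csv(outdir / "telomere_states.tsv", sep="\t", index=False)
    section = {**dataclasses.asdict(stats), **{f"n_{k}": v for k, v in summary.items()}}
    pd.DataFrame([section]).to_csv(outdir / "assembly_stats.tsv", sep="\t", index=False)
    return section


def run_strata_stage(cfg: RunConfig, outdir: Path) -> dict:
    hits = phylostrat.read_hits_table(cfg.hits, cfg.taxon_map)
    lineages = phylostrat.load_lineages(cfg.lineages, cfg.focal_taxon_id)
    distances = phylostrat.TreeDistances.from_newick(cfg.tree) if cfg.tree else None
    gene_ids = None
    if cfg.genes:
        gene_ids = io.read_gff3_genes(cfg.genes).gene_id.tolist()
    assignments = phylostrat.assign_all(
        hits, lineages, cfg.focal_taxon_id, gene_ids=gene_ids, distances=distances,
        evalue_max=cfg.evalue_max, rep_threshold_pct=cfg.rep_threshold_pct,
    )
    n_ranks = len(lineages[cfg.focal_taxon_id].ranks)
    profile = phylostrat.stratum_profile(assignments, n_ranks)
    assignments.to_csv(outdir / "phylorank_assignments.tsv", sep="\t", index=False)
    profile.to_csv(outdir / "stratum_profile.tsv", sep="\t", index=False)
    n_ok = int((~assignments.flag_contaminant_or_hgt).sum())
    return {
        "n_genes": int(len(assignments)),
        "n_flagged": int(assignments.flag_contaminant_or_hgt.sum()),
        "n_high_confidence": int(assignments.high_confidence.fillna(False).sum()),
        "rank1_share_pct": phylostrat.stratum_share_percent(
            int(profile.n_genes.iloc[0]), max(n_ok, 1)
        ),
        "profile": profile.to_dict(orient="records"),
    }


def run_chromscape_stage(cfg: RunConfig, outdir: Path) -> dict:
    genes = io.read_gff3_genes(cfg.genes)
    ages = io.read_true_ages(cfg.ages)
    age_col = "phylorank" if "phylorank" in ages.columns else "true_rank"
    genes = genes.merge(
        ages.rename(columns={age_col: "phylorank"})[["gene_id", "phylorank"]], on="gene_id"
    )
    chrom_sizes = io.chrom_sizes_from_fasta(cfg.genome)
    srna = io.read_bed(cfg.srna_loci)
    genes["srna_rpkm"] = _gene_srna_rpkm(genes, srna)

    results, frame = chromscape.permute_ages_test(
        genes, n_perm=cfg.n_perm, seed=cfg.seed
    )
    frame.to_csv(outdir / "gene_age_fits.tsv", sep="\t", index=False)
    perm_df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    perm_df.to_csv(outdir / "permutation_tests.tsv", sep="\t", index=False)

    srna_bins = _bin_weighted_track(srna, chrom_sizes, cfg.bin_size, "rpkm")
    track_rows = []
    for chrom, sub in frame.groupby("chrom"):
        sb = srna_bins[srna_bins.chrom == chrom]
        sm = np.interp(sb.pos, sub.start, sub.observed_fit)
        # the raw binned sRNA signal is sparse; smooth it like the plotted
        # expression profiles so quantile thresholds are meaningful
        srna_smooth = chromscape.smooth_track(
            sb.pos.to_numpy(dtype=float), sb.value.to_numpy(dtype=float)
        )
        for pos, rank_v, srna_v in zip(sb.pos, sm, srna_smooth):
            track_rows.append(
                {"chrom": chrom, "pos": int(pos), "smoothed_rank": float(rank_v),
                 "srna_rpkm": float(srna_v)}
            )
    track = pd.DataFrame(track_rows)
    regions = chromscape.detect_young_regions(track, bin_size=cfg.bin_size)
    pd.DataFrame([dataclasses.asdict(r) for r in regions]).to_csv(
        outdir / "young_regions.bed", sep="\t", index=False, header=False
    )
    corr, corr_p = chromscape.per_gene_age_expression_corr(genes)
    meth = chromscape.filter_high_methylation(io.read_methylation(cfg.methylation))
    meth.to_csv(outdir / "high_methylation.tsv", sep="\t", index=False)
    return {
        "permutation_tests": perm_df.to_dict(orient="records"),
        "n_young_regions": len(regions),
        "young_regions": [dataclasses.asdict(r) for r in regions],
        "per_gene_age_srna_spearman": corr,
        "per_gene_age_srna_p": corr_p,
        "n_high_meth_sites": int(len(meth)),
    }


def run_polya_stage(cfg: RunConfig, outdir: Path) -> dict:
    calls = polya.call_tails_from_fastq(cfg.reads, min_tail=cfg.min_tail)
    reads = asmqc.read_fastq_ids_seqs(cfg.reads)
    sites = polya.sites_from_reads(
        reads, {c.read_id: c for c in calls}, window=cfg.polya_window
    )
    tally = polya.tally_hexamers([s.upstream_window for s in sites])
    stats = polya.tail_stats(calls)
    pd.DataFrame(
        [
            {"read_id": c.read_id, "tail_length_nt": c.tail_length_nt, "purity": c.purity}
            for c in calls
        ]
    ).to_csv(outdir / "tail_calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"Sequence": v, "Number": tally.counts[v], "Percent": tally.percents[v]}
            for v in list(polya.HEXAMER_PANEL) + [polya.NO_SIGNAL]
        ]
    ).to_csv(outdir / "polya_signal_tally.tsv", sep="\t", index=False)
    return {
        "n_tail_calls": stats["n"],
        "tail_mean_nt": stats["mean"],
        "tail_min_nt": stats["min"],
        "tail_max_nt": stats["max"],
        "n_sites": tally.total_sites,
        "canonical_pct": tally.percents["AAUAAA"],
    }


def run_all(cfg: RunConfig) -> Path:
    """Execute the enabled stages; returns the report directory.

    Any stage failure aborts with the stage name; outputs written so far
    are kept alongside a FAILED marker naming the stage.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}
    cfg.to_yaml(outdir / "run_config.yaml")

    stage = "simulate"
    try:
        if cfg.simulate:
            syn_cfg = synthetic.SyntheticConfig(seed=cfg.seed, **cfg.synthetic_overrides)
            bundle = synthetic.generate_bundle(syn_cfg, outdir / "synthetic")
            cfg.genome = str(bundle.genome)
            cfg.genes = str(bundle.genes)
            cfg.ages = str(bundle.true_ages)
            cfg.hits = str(bundle.hits)
            cfg.taxon_map = str(bundle.taxon_map)
            cfg.lineages = str(bundle.lineages)
            cfg.tree = str(bundle.tree)
            cfg.srna_loci = str(bundle.srna_loci)
            cfg.coverage = str(bundle.coverage)
            cfg.methylation = str(bundle.methylation)
            cfg.reads = str(bundle.reads)
            report["stages"]["simulate"] = {"outdir": str(bundle.outdir)}
        if cfg.run_asmqc:
            stage = "asmqc"
            report["stages"]["asmqc"] = run_asmqc_stage(cfg, outdir)
        if cfg.run_strata:
            stage = "strata"
            report["stages"]["strata"] = run_strata_stage(cfg, outdir)
        if cfg.run_chromscape:
            stage = "chromscape"
            report["stages"]["chromscape"] = run_chromscape_stage(cfg, outdir)
        if cfg.run_polya:
            stage = "polya"
            report["stages"]["polya"] = run_polya_stage(cfg, outdir)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return outdir
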