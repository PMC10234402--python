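"""Synthetic genome bundles with planted, recoverable ground truth.

Emulates the input data of a chromosome-scale fungal genome project so
that every downstream analysis is testable without external downloads:

* chromosomes carrying telomeric (TTAGGG) arrays at both ends and literal
  N-gap runs at stated coordinates;
* genes on a jittered grid whose evolutionary ages are spatially
  autocorrelated — planted "young blocks" mimic the ~2 Mb young loci seen
  in real assemblies, the background is dominated by ancient genes;
* long-RNA coverage elevated in old regions and small-RNA weight elevated
  in young regions (the two-speed expression contrast), plus CG
  methylation elevated in young blocks;
* homology-hit tables whose bitscores decay exponentially with patristic
  tree distance, so gene-age assignment and the homology-detection-failure
  test can be exercised against known true ranks;
* long cDNA reads with poly(A) tails whose upstream 50 nt windows carry a
  chosen polyadenylation-signal variant at configurable proportions.

All randomness flows from a single integer seed; identical configs give
byte-identical output files. Planted truths are recorded in a manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from chronotopo import phylostrat
from chronotopo.polya import HEXAMER_PANEL, NO_SIGNAL

logger = logging.getLogger(__name__)

FOCAL_TAXON_ID = 1432141

#: Default focal lineage for a 9-level ladder (root to species), modelled
#: on an arbuscular mycorrhizal fungus.
DEFAULT_LADDER_9 = (
    "cellular_organisms",
    "Eukaryota",
    "Opisthokonta",
    "Fungi",
    "Mucoromycota",
    "Glomeromycotina",
    "Glomerales",
    "Rhizophagus",
    "Rhizophagus_irregularis",
)

#: Polyadenylation-signal mix used by default: the observed fungal panel
#: shares (fractions of sites), remainder = no recognizable signal.
DEFAULT_HEXAMER_PROPORTIONS = {
    "AAUAAA": 0.567,
    "CAUAAA": 0.001,
    "GAUAAA": 0.001,
    "UAUAAA": 0.019,
    "ACUAAA": 0.001,
    "AGUAAA": 0.002,
    "AUUAAA": 0.116,
    "AACAAA": 0.002,
    "AAGAAA": 0.002,
    "AAUACA": 0.002,
    "AAUAGA": 0.001,
    "AAUAUA": 0.047,
    "AAUAAC": 0.001,
    "AAUAAG": 0.0005,
    "AAUAAU": 0.008,
    "CAUGAA": 0.0001,
    "GAUGAA": 0.0004,
    "UAUGAA": 0.001,
}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic bundle.

    Defaults are a scaled-down genome with realistic density: four ~1.5 Mb
    chromosomes at one gene per ~5 kb, one planted young block, telomere
    arrays of 25 repeat units, bitscore decay gentle enough that in-clade
    homologs stay detectable.
    """

    seed: int = 0
    n_chrom: int = 4
    chrom_length_bp: int = 1_500_000
    telomere_copies_per_end: int = 25
    gap_runs: list[tuple[int, int, int]] = field(
        default_factory=lambda: [(1, 700_000, 100)]
    )
    n_genes_per_chrom: int = 300
    young_blocks: list[tuple[int, int, int, float]] = field(
        default_factory=lambda: [(0, 400_000, 900_000, 8.0)]
    )
    n_phyloranks: int = 9
    background_mean_rank: float = 1.5
    rank_dispersion: float = 0.8
    taxa_per_rank: int = 3
    decay_a: float = 400.0
    decay_b: float = 0.4
    bitscore_noise_sd: float = 5.0
    search_space: float = phylostrat.DEFAULT_SEARCH_SPACE
    evalue_max: float = phylostrat.DEFAULT_EVALUE_MAX
    hexamer_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HEXAMER_PROPORTIONS)
    )
    tail_length_mean: float = 42.0
    min_tail: int = 10
    n_polya_reads: int = 2000
    sRNA_effect: float = 8.0
    longRNA_effect: float = 4.0
    srna_loci_per_chrom: int = 150
    gene_length_bp: int = 1500

    def validate(self) -> None:
        if self.n_chrom < 1 or self.chrom_length_bp < 1:
            raise ValueError("need at least one chromosome of positive length")
        if self.telomere_copies_per_end < 0:
            raise ValueError("telomere_copies_per_end must be >= 0")
        if self.sRNA_effect <= 0 or self.longRNA_effect <= 0:
            raise ValueError("effect sizes must be positive")
        if self.decay_a <= 0 or self.decay_b < 0 or self.bitscore_noise_sd < 0:
            raise ValueError("decay parameters must be non-negative (a positive)")
        if sum(self.hexamer_proportions.values()) > 1.0 + 1e-9:
            raise ValueError("hexamer proportions must sum to <= 1")
        unknown = set(self.hexamer_proportions) - set(HEXAMER_PANEL) - {NO_SIGNAL}
        if unknown:
            raise ValueError(f"hexamer proportions name unknown variants: {unknown}")
        if not self.tail_length_mean > self.min_tail:
            raise ValueError("tail_length_mean must exceed the minimum tail length")
        tel = 6 * self.telomere_copies_per_end
        spans: dict[int, list[tuple[int, int]]] = {}
        for ci, start, length in self.gap_runs:
            if not 0 <= ci < self.n_chrom:
                raise ValueError(f"gap run on nonexistent chromosome index {ci}")
            end = start + length
            if start < tel or end > self.chrom_length_bp - tel:
                raise ValueError(
                    f"gap run {ci}:{start}+{length} extends past chromosome body"
                )
            for s0, e0 in spans.get(ci, []):
                if start < e0 and s0 < end:
                    raise ValueError(f"overlapping gap runs on chromosome {ci}")
            spans.setdefault(ci, []).append((start, end))
        for ci, start, end, mean_rank in self.young_blocks:
            if not 0 <= ci < self.n_chrom:
                raise ValueError(f"young block on nonexistent chromosome index {ci}")
            if not 0 <= start < end <= self.chrom_length_bp:
                raise ValueError(f"young block out of bounds: {ci}:{start}-{end}")
            if not 1 <= mean_rank <= self.n_phyloranks:
                raise ValueError("young-block mean rank outside the ladder")
        min_len = 2 * tel + sum(l for _, _, l in self.gap_runs)
        if self.chrom_length_bp < min_len:
            raise ValueError("chromosome too short for telomeres plus gaps")
        if self.n_genes_per_chrom * self.gene_length_bp > self.chrom_length_bp:
            raise ValueError("n_genes_per_chrom too large for chromosome length")


@dataclass
class SyntheticBundle:
    """File layout of one generated bundle."""

    outdir: Path
    genome: Path
    genes: Path
    true_ages: Path
    hits: Path
    taxon_map: Path
    lineages: Path
    tree: Path
    srna_loci: Path
    coverage: Path
    methylation: Path
    reads: Path
    manifest: Path


def _stage_rng(cfg: SyntheticConfig, stage: int) -> np.random.Generator:
    # per-stage streams so editing one stage leaves the others' output intact
    return np.random.default_rng([cfg.seed, stage])


def chrom_name(i: int) -> str:
    return f"chr{i + 1}"


# ---------------------------------------------------------------------------
# genome

def make_genome(cfg: SyntheticConfig) -> tuple[dict[str, str], list[dict]]:
    """Chromosome sequences with planted telomere arrays and N gaps.

    Returns ({chrom: seq}, manifest rows). Background sequence is uniform
    ACGT from the seeded generator.
    """
    cfg.validate()
    rng = _stage_rng(cfg, 0)
    k = cfg.telomere_copies_per_end
    tel5 = "CCCTAA" * k
    tel3 = "TTAGGG" * k
    bases = np.frombuffer(b"ACGT", dtype="S1")
    chroms: dict[str, str] = {}
    manifest: list[dict] = []
    for ci in range(cfg.n_chrom):
        body_len = cfg.chrom_length_bp - len(tel5) - len(tel3)
        body = rng.choice(bases, size=body_len)
        seq = np.frombuffer((tel5.encode() + body.tobytes() + tel3.encode()), dtype="S1").copy()
        for gi, (gci, start, length) in enumerate(cfg.gap_runs):
            if gci != ci:
                continue
            seq[start : start + length] = b"N"
            manifest.append(
                {"category": "gap", "key": f"{chrom_name(ci)}:{start}", "value": str(length)}
            )
        chroms[chrom_name(ci)] = seq.tobytes().decode()
        manifest.append(
            {"category": "telomere", "key": chrom_name(ci), "value": f"both_ends,k={k}"}
        )
    return chroms, manifest


# ---------------------------------------------------------------------------
# genes and ages

def make_gene_ages(cfg: SyntheticConfig) -> pd.DataFrame:
    """Genes on a jittered grid with spatially autocorrelated ages.

    Genes inside a planted young block draw their phylorank from a Normal
    centred on the block mean; background genes from a Normal centred on
    ``background_mean_rank``. Ranks are rounded and clipped to the ladder.
    Returns a frame: gene_id, chrom, start, end, strand, true_rank.
    """
    cfg.validate()
    rng = _stage_rng(cfg, 1)
    spacing = cfg.chrom_length_bp / cfg.n_genes_per_chrom
    rows = []
    gid = 0
    for ci in range(cfg.n_chrom):
        blocks = [(s, e, m) for (bci, s, e, m) in cfg.young_blocks if bci == ci]
        for gi in range(cfg.n_genes_per_chrom):
            jitter = rng.uniform(0, max(spacing - cfg.gene_length_bp, 1))
            start = int(gi * spacing + jitter)
            end = min(start + cfg.gene_length_bp, cfg.chrom_length_bp)
            mean = cfg.background_mean_rank
            for bs, be, bm in blocks:
                if bs <= start < be:
                    mean = bm
                    break
            rank = int(round(rng.normal(mean, cfg.rank_dispersion)))
            rank = min(max(rank, 1), cfg.n_phyloranks)
            gid += 1
            rows.append(
                {
                    "gene_id": f"g{gid}",
                    "chrom": chrom_name(ci),
                    "start": start,
                    "end": end,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "true_rank": rank,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression / methylation tracks

def make_tracks(
    cfg: SyntheticConfig, genes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """sRNA loci (BED-like), long-RNA coverage (bedGraph-like, 200 bp bins)
    and a CG-methylation table.

    Small-RNA locus weight is sRNA_effect-fold higher inside young blocks;
    long-RNA coverage is longRNA_effect-fold higher outside them (old
    regions transcribe more poly(A)+ RNA); methylation is elevated inside
    young blocks.
    """
    cfg.validate()
    rng = _stage_rng(cfg, 2)
    blocks_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for bci, s, e, _m in cfg.young_blocks:
        blocks_by_chrom.setdefault(chrom_name(bci), []).append((s, e))

    def in_block(chrom: str, pos: int) -> bool:
        return any(s <= pos < e for s, e in blocks_by_chrom.get(chrom, []))

    srna_rows = []
    for ci in range(cfg.n_chrom):
        chrom = chrom_name(ci)
        starts = np.sort(
            rng.integers(0, cfg.chrom_length_bp - 200, size=cfg.srna_loci_per_chrom)
        )
        for j, s in enumerate(starts):
            width = int(rng.integers(100, 400))
            base = rng.gamma(shape=4.0, scale=2.5)
            weight = base * (cfg.sRNA_effect if in_block(chrom, int(s)) else 1.0)
            srna_rows.append(
                {
                    "chrom": chrom,
                    "start": int(s),
                    "end": min(int(s) + width, cfg.chrom_length_bp),
                    "name": f"srna_{chrom}_{j}",
                    "rpkm": float(weight),
                }
            )
    srna = pd.DataFrame(srna_rows)

    cov_rows = []
    bin_size = 200
    for ci in range(cfg.n_chrom):
        chrom = chrom_name(ci)
        n_bins = -(-cfg.chrom_length_bp // bin_size)
        starts = np.arange(n_bins) * bin_size
        base = rng.gamma(shape=4.0, scale=2.5, size=n_bins)
        mult = np.array(
            [1.0 if in_block(chrom, int(s)) else cfg.longRNA_effect for s in starts]
        )
        vals = base * mult
        for s, v in zip(starts, vals):
            cov_rows.append(
                {
                    "chrom": chrom,
                    "start": int(s),
                    "end": int(min(s + bin_size, cfg.chrom_length_bp)),
                    "value": float(v),
                }
            )
    coverage = pd.DataFrame(cov_rows)

    meth_rows = []
    n_cg_per_chrom = max(cfg.chrom_length_bp // 2000, 10)
    for ci in range(cfg.n_chrom):
        chrom = chrom_name(ci)
        pos = np.sort(rng.integers(0, cfg.chrom_length_bp, size=n_cg_per_chrom))
        for p in pos:
            if in_block(chrom, int(p)):
                v = rng.beta(8, 2) * 100.0
            else:
                v = rng.beta(2, 8) * 100.0
            meth_rows.append({"chrom": chrom, "pos": int(p), "meth_pct": float(v)})
    methylation = pd.DataFrame(meth_rows)
    return srna, coverage, methylation


# ---------------------------------------------------------------------------
# taxonomy, tree and homology hits

def make_taxonomy(cfg: SyntheticConfig) -> tuple[pd.DataFrame, str, dict[int, int]]:
    """Database taxa, their lineages and an additive tree.

    One focal taxon plus ``taxa_per_rank`` taxa at every divergence rank
    from 1 to n_phyloranks - 1. The tree is a ladder mirroring the
    lineage: a taxon of divergence rank r sits at patristic distance
    2 * unit * (n_phyloranks - r) from the focal tip (unit = 0.25).

    Returns (lineage frame [taxon_id, lineage], newick string,
    {taxon_id: divergence rank}).
    """
    n = cfg.n_phyloranks
    if n == len(DEFAULT_LADDER_9):
        focal_ranks = list(DEFAULT_LADDER_9)
    else:
        focal_ranks = [f"clade_level_{i}" for i in range(1, n)] + ["focal_species"]
        focal_ranks[0] = "cellular_organisms"
    unit = 0.25

    lineage_rows = [
        {"taxon_id": FOCAL_TAXON_ID, "lineage": ";".join(focal_ranks)}
    ]
    dranks = {FOCAL_TAXON_ID: n}
    tips_at_rank: dict[int, list[int]] = {}
    for r in range(1, n):
        tips_at_rank[r] = []
        for j in range(cfg.taxa_per_rank):
            tid = 1000 * r + j + 1
            lineage = focal_ranks[:r] + [f"outclade_r{r}", f"species_r{r}_{j}"]
            lineage_rows.append({"taxon_id": tid, "lineage": ";".join(lineage)})
            dranks[tid] = r
            tips_at_rank[r].append(tid)

    def subtree(r: int) -> str:
        if r == n:
            return f"{FOCAL_TAXON_ID}:{unit}"
        # focal-to-node_r path is unit*(n-r); the tip edge mirrors it so the
        # focal-to-tip patristic distance is 2*unit*(n-r)
        tip_len = unit * (n - r)
        tips = ",".join(f"{tid}:{tip_len}" for tid in tips_at_rank[r])
        return f"({subtree(r + 1)},{tips}):{unit}"

    newick = f"({subtree(1)});"
    return pd.DataFrame(lineage_rows), newick, dranks


def make_homology_hits(
    cfg: SyntheticConfig, true_ages: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, str]:
    """Simulated tabular homology-search results consistent with true ages.

    A gene of true rank r has homologs only in taxa whose divergence rank
    is >= r. Each homolog's bitscore is decay_a * exp(-decay_b * d) plus
    Normal noise; hits whose bitscore falls below the detection threshold
    (in bits, from the E-value cutoff and search-space size) are not
    emitted — that is exactly the homology-detection-failure mechanism.
    E-values derive deterministically from bitscores.

    Returns (hits frame in 12-column outfmt-6 layout, subject→taxon map,
    lineage frame, newick string).
    """
    cfg.validate()
    if not {"gene_id", "true_rank"}.issubset(true_ages.columns):
        raise ValueError("true_ages must have columns gene_id, true_rank")
    rng = _stage_rng(cfg, 3)
    lineages_df, newick, dranks = make_taxonomy(cfg)
    tree = phylostrat.TreeDistances.from_newick_string(newick)
    thr = phylostrat.detection_threshold_bits(cfg.evalue_max, cfg.search_space)

    taxa = sorted(t for t in dranks if t != FOCAL_TAXON_ID)
    dist = {t: tree.distance(FOCAL_TAXON_ID, t) for t in taxa}
    hit_rows = []
    subj_rows = {}
    for g in true_ages.itertuples():
        # self-hit in the focal species
        self_subj = f"prot_{FOCAL_TAXON_ID}_{g.gene_id}"
        subj_rows[self_subj] = FOCAL_TAXON_ID
        hit_rows.append(_hit_row(g.gene_id, self_subj, cfg.decay_a, cfg))
        for t in taxa:
            if dranks[t] < g.true_rank:
                continue
            score = cfg.decay_a * np.exp(-cfg.decay_b * dist[t])
            if cfg.bitscore_noise_sd > 0:
                score += rng.normal(0.0, cfg.bitscore_noise_sd)
            if score < thr:
                continue  # homology detection failure: the search misses it
            subj = f"prot_{t}_{g.gene_id}"
            subj_rows[subj] = t
            hit_rows.append(_hit_row(g.gene_id, subj, float(score), cfg))
    hits = pd.DataFrame(hit_rows)
    taxon_map = pd.DataFrame(
        [{"subject_id": s, "taxon_id": t} for s, t in sorted(subj_rows.items())]
    )
    return hits, taxon_map, lineages_df, newick


def _hit_row(gene_id: str, subject_id: str, bitscore: float, cfg: SyntheticConfig) -> dict:
    evalue = phylostrat.bitscore_to_evalue(bitscore, cfg.search_space)
    return {
        "qseqid": gene_id,
        "sseqid": subject_id,
        "pident": 50.0,
        "length": 200,
        "mismatch": 100,
        "gapopen": 5,
        "qstart": 1,
        "qend": 200,
        "sstart": 1,
        "send": 200,
        "evalue": evalue,
        "bitscore": round(float(bitscore), 1),
    }


# ---------------------------------------------------------------------------
# poly(A) reads

def make_polya_reads(cfg: SyntheticConfig) -> tuple[list[tuple[str, str]], list[dict]]:
    """Long cDNA reads with planted poly(A) tails and signal variants.

    Each read is a transcript body whose final 50 nt window carries the
    chosen hexamer variant (DNA alphabet) starting 10-30 nt before the
    cleavage point — or no panel variant at all for NONE — followed by a
    poly(A) tail of geometric-around-mean length floored at ``min_tail``.
    Windows are rejection-sampled so the downstream signal caller
    recovers exactly the planted variant; the last 3 window bases are
    non-A so tail detection recovers the exact cleavage point.

    Returns ([(read_id, seq)], manifest rows recording variant and tail
    length per read).
    """
    cfg.validate()
    rng = _stage_rng(cfg, 4)
    variants = list(cfg.hexamer_proportions)
    probs = np.array([cfg.hexamer_proportions[v] for v in variants], dtype=float)
    rest = 1.0 - probs.sum()
    if rest > 1e-12:
        variants.append(NO_SIGNAL)
        probs = np.append(probs, rest)
    probs = probs / probs.sum()

    from chronotopo.polya import call_signal

    bases = np.array(list("ACGT"))
    non_a = np.array(list("CGT"))
    reads: list[tuple[str, str]] = []
    manifest: list[dict] = []
    for i in range(cfg.n_polya_reads):
        variant = variants[rng.choice(len(variants), p=probs)]
        window = _sample_window(rng, variant, bases, non_a, call_signal)
        body_prefix_len = int(rng.integers(150, 400))
        prefix = "".join(rng.choice(bases, size=body_prefix_len))
        p_geo = 1.0 / (cfg.tail_length_mean - cfg.min_tail + 1)
        tail_len = cfg.min_tail + int(rng.geometric(p_geo)) - 1
        read_id = f"read_{i}"
        reads.append((read_id, prefix + window + "A" * tail_len))
        manifest.append(
            {
                "category": "polya_read",
                "key": read_id,
                "value": f"{variant},{tail_len}",
            }
        )
    return reads, manifest


def _sample_window(rng, variant, bases, non_a, call_signal, window_len=50, max_tries=200):
    for _ in range(max_tries):
        win = rng.choice(bases, size=window_len)
        win[-3:] = rng.choice(non_a, size=3)
        if variant != NO_SIGNAL:
            gap = int(rng.integers(10, 31))  # hexamer start, nt before cleavage
            dna = variant.replace("U", "T")
            win[window_len - gap : window_len - gap + 6] = list(dna)
        s = "".join(win)
        if call_signal(s) == variant:
            return s
    raise RuntimeError(f"could not sample a clean window for variant {variant}")


# ---------------------------------------------------------------------------
# file writing

def _write_fasta(path: Path, seqs: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_gff3(path: Path, genes: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            fh.write(
                f"{g.chrom}\tchronotopo\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def _write_fastq(path: Path, reads: Sequence[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def generate_bundle(cfg: SyntheticConfig, outdir) -> SyntheticBundle:
    """Generate every input file of the pipeline under ``outdir``."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    chroms, manifest = make_genome(cfg)
    genes = make_gene_ages(cfg)
    srna, coverage, methylation = make_tracks(cfg, genes)
    true_ages = genes[["gene_id", "true_rank"]]
    hits, taxon_map, lineages_df, newick = make_homology_hits(cfg, true_ages)
    reads, read_manifest = make_polya_reads(cfg)
    manifest = manifest + read_manifest
    for bci, s, e, m in cfg.young_blocks:
        manifest.append(
            {"category": "young_block", "key": f"{chrom_name(bci)}:{s}-{e}", "value": str(m)}
        )

    b = SyntheticBundle(
        outdir=outdir,
        genome=outdir / "genome.fa",
        genes=outdir / "genes.gff3",
        true_ages=outdir / "true_ages.tsv",
        hits=outdir / "hits.tsv",
        taxon_map=outdir / "taxon_map.tsv",
        lineages=outdir / "lineages.tsv",
        tree=outdir / "tree.nwk",
        srna_loci=outdir / "srna_loci.bed",
        coverage=outdir / "coverage.bedgraph",
        methylation=outdir / "methylation.tsv",
        reads=outdir / "reads.fastq",
        manifest=outdir / "manifest.tsv",
    )
    _write_fasta(b.genome, chroms)
    _write_gff3(b.genes, genes)
    true_ages.to_csv(b.true_ages, sep="\t", index=False)
    hits.to_csv(b.hits, sep="\t", index=False, header=False)
    taxon_map.to_csv(b.taxon_map, sep="\t", index=False)
    lineages_df.to_csv(b.lineages, sep="\t", index=False)
    b.tree.write_text(newick + "\n")
    srna[["chrom", "start", "end", "name", "rpkm"]].to_csv(
        b.srna_loci, sep="\t", index=False, header=False
    )
    coverage[["chrom", "start", "end", "value"]].to_csv(
        b.coverage, sep="\t", index=False, header=False
    )
    methylation.to_csv(b.methylation, sep="\t", index=False)
    _write_fastq(b.reads, reads)
    pd.DataFrame(manifest).to_csv(b.manifest, sep="\t", index=False)
    return b
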