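"""Phylostratigraphic gene-age assignment with a homology-detection-failure test.

A gene's phylorank (phylostratum) is the most inclusive taxonomic level at
which it still has a detectable homolog: rank 1 is the root of the ladder
("cellular organisms", the oldest genes), the highest rank is the focal
species (genes with no homologs outside it, the youngest). Ages are
assigned from a tabular homology search (BLAST/DIAMOND outfmt-6-like)
against a taxon-labelled database:

* each subject taxon has a *divergence rank* — the depth at which its
  lineage splits from the focal species' lineage;
* a gene's phylorank is the minimum divergence rank over its hits passing
  the E-value filter (default 1e-5);
* *taxonomic representativeness* — the fraction of taxa at the
  age-defining level that actually contain a homolog — flags likely
  contamination or horizontal transfer when below 30%;
* the *homology-detection-failure* (HDF) test asks whether the apparent
  youth of a gene could instead be explained by alignment scores decaying
  below the detection threshold with evolutionary distance. Per gene, the
  bitscores of its hits are regressed as ln(bitscore) = ln(a) - b*d
  against patristic tree distance d; the fitted model predicts the
  probability of detecting a homolog at the nearest outgroup beyond the
  assigned clade. If detection there was near-certain yet no homolog was
  found, the young age is high-confidence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_REP_THRESHOLD_PCT = 30.0
#: Karlin-Altschul-style effective search-space size m*n used to map
#: bitscores to E-values (E = m*n * 2**-S); only relative consistency
#: between the two filters matters.
DEFAULT_SEARCH_SPACE = 1e18


def bitscore_to_evalue(bitscore: float, search_space: float = DEFAULT_SEARCH_SPACE) -> float:
    return search_space * 2.0 ** (-bitscore)


def detection_threshold_bits(
    evalue_max: float = DEFAULT_EVALUE_MAX, search_space: float = DEFAULT_SEARCH_SPACE
) -> float:
    """Bitscore below which a hit's E-value exceeds evalue_max."""
    return math.log2(search_space / evalue_max)


@dataclass
class TaxonLineage:
    """An ordered root-to-tip lineage for one taxon.

    ranks[0] is the most inclusive clade shared by all taxa (rank 1,
    "cellular organisms"); the focal species' lineage is the longest and
    defines the phylorank ladder.
    """

    taxon_id: int
    ranks: list[str]


@dataclass
class RankCorrectionRules:
    """Lineage clean-up rules applied before rank computation.

    strain_to_species renames a strain-level name to its species name
    (duplicates created by the rename are merged); reassignments move a
    named clade to a different 1-based level; collapsed_ranks removes rank
    names entirely (their taxa merge into the parent level). Applying the
    rules twice equals applying them once.
    """

    strain_to_species: list[tuple[str, str]] = field(default_factory=list)
    reassignments: list[tuple[str, int]] = field(default_factory=list)
    collapsed_ranks: list[str] = field(default_factory=list)


@dataclass
class HomologyHit:
    query_gene_id: str
    subject_taxon_id: int
    evalue: float
    bitscore: float


@dataclass
class PhylorankAssignment:
    gene_id: str
    phylorank: int
    representativeness_pct: Optional[float]
    flag_contaminant_or_hgt: bool
    high_confidence: Optional[bool] = None


@dataclass
class HDFModel:
    """Per-gene exponential bitscore-decay model S(d) = a*exp(-b*d)."""

    gene_id: str
    a: float
    b: float
    sigma: float
    detect_threshold_bits: float
    n_points: int


class TreeDistances:
    """Patristic (branch-length) distances between taxa of a newick tree.

    Leaf labels are taxon ids (integers as strings are accepted).
    """

    def __init__(self, tree: dendropy.Tree):
        pdm = tree.phylogenetic_distance_matrix()
        self._dist: dict[tuple[str, str], float] = {}
        taxa = list(tree.taxon_namespace)
        for i, t1 in enumerate(taxa):
            for t2 in taxa[i:]:
                d = pdm.patristic_distance(t1, t2) if t1 is not t2 else 0.0
                self._dist[(t1.label, t2.label)] = d
                self._dist[(t2.label, t1.label)] = d
        self.labels = [t.label for t in taxa]

    @classmethod
    def from_newick(cls, path) -> "TreeDistances":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        return cls(tree)

    @classmethod
    def from_newick_string(cls, newick: str) -> "TreeDistances":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    def distance(self, taxon_a: int | str, taxon_b: int | str) -> float:
        key = (str(taxon_a), str(taxon_b))
        if key not in self._dist:
            raise KeyError(f"taxon pair {key} not in tree")
        return self._dist[key]


# ---------------------------------------------------------------------------
# lineages and divergence ranks

def load_lineages(path, focal_taxon_id: int) -> dict[int, TaxonLineage]:
    """Load a lineage table (taxon_id TAB semicolon-joined root-to-tip names).

    The focal taxon must be present; its lineage defines the ladder.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: int, 1: str})
    df.columns = ["taxon_id", "lineage"]
    lineages = {
        int(r.taxon_id): TaxonLineage(int(r.taxon_id), [x.strip() for x in r.lineage.split(";")])
        for r in df.itertuples()
    }
    if focal_taxon_id not in lineages:
        raise ValueError(f"focal taxon {focal_taxon_id} absent from lineage table")
    return lineages


def divergence_rank(
    lineage: TaxonLineage, focal: TaxonLineage, n_phyloranks: Optional[int] = None
) -> int:
    """Depth at which a taxon's lineage splits from the focal lineage.

    Counted as the length of the shared root-to-tip prefix (the shared root
    itself is level 1), capped at the ladder height. The focal taxon maps
    to the top rank; a taxon sharing only the root maps to rank 1.
    """
    if n_phyloranks is None:
        n_phyloranks = len(focal.ranks)
    lcp = 0
    for a, b in zip(lineage.ranks, focal.ranks):
        if a != b:
            break
        lcp += 1
    if lcp == 0:
        raise ValueError(
            f"taxon {lineage.taxon_id} shares no root with the focal lineage"
        )
    return min(lcp, n_phyloranks)


def divergence_ranks(
    lineages: Mapping[int, TaxonLineage], focal_taxon_id: int, n_phyloranks: Optional[int] = None
) -> dict[int, int]:
    focal = lineages[focal_taxon_id]
    if n_phyloranks is None:
        n_phyloranks = len(focal.ranks)
    return {
        tid: divergence_rank(lin, focal, n_phyloranks) for tid, lin in lineages.items()
    }


def apply_rank_corrections(
    lineages: Mapping[int, TaxonLineage], rules: RankCorrectionRules
) -> dict[int, TaxonLineage]:
    """Apply lineage corrections; unknown names are skipped with a warning.

    Idempotent: renames to an already-present parent merge, reassignments
    target absolute levels, collapses remove names outright.
    """
    all_names = {n for lin in lineages.values() for n in lin.ranks}
    for frm, _ in rules.strain_to_species:
        if frm not in all_names:
            logger.warning("rank-correction rule names unknown clade %r; skipped", frm)
    for name in rules.collapsed_ranks:
        if name not in all_names:
            logger.warning("collapse rule names unknown clade %r; skipped", name)
    rename = dict(rules.strain_to_species)
    out: dict[int, TaxonLineage] = {}
    for tid, lin in lineages.items():
        ranks = [rename.get(n, n) for n in lin.ranks]
        # merge duplicates created by renaming (keep first occurrence)
        seen: set[str] = set()
        ranks = [n for n in ranks if not (n in seen or seen.add(n))]
        ranks = [n for n in ranks if n not in rules.collapsed_ranks]
        for name, new_level in rules.reassignments:
            if name in ranks:
                ranks.remove(name)
                idx = min(max(new_level - 1, 0), len(ranks))
                ranks.insert(idx, name)
        out[tid] = TaxonLineage(tid, ranks)
    return out


# ---------------------------------------------------------------------------
# phylorank assignment

def assign_phylorank(
    gene_hits: Sequence[HomologyHit],
    div_ranks: Mapping[int, int],
    focal_taxon_id: int,
    n_phyloranks: int,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> int:
    """Minimum divergence rank over qualifying non-focal hits.

    Genes with no qualifying hit outside the focal taxon are
    species-restricted (the youngest rank).
    """
    if not gene_hits:
        logger.info("gene with no hits at all: assigned youngest rank")
        return n_phyloranks
    best = n_phyloranks
    for h in gene_hits:
        if h.evalue > evalue_max or h.subject_taxon_id == focal_taxon_id:
            continue
        r = div_ranks[h.subject_taxon_id]
        if r < best:
            best = r
    return best


def taxonomic_representativeness(
    gene_hits: Sequence[HomologyHit],
    assigned_rank: int,
    div_ranks: Mapping[int, int],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    threshold_pct: float = DEFAULT_REP_THRESHOLD_PCT,
) -> tuple[Optional[float], bool]:
    """Share of age-diagnostic taxa carrying a qualifying hit.

    Diagnostic taxa are the database taxa whose divergence rank equals the
    assigned rank (the level whose presence set the age). Returns
    (percent, flagged); percent is None (and flagged False) when the
    database has no diagnostic taxa, in which case the caller should
    exclude the gene.
    """
    diagnostic = {tid for tid, r in div_ranks.items() if r == assigned_rank}
    if not diagnostic:
        logger.warning("no diagnostic taxa at rank %d; representativeness undefined", assigned_rank)
        return None, False
    hit_taxa = {
        h.subject_taxon_id
        for h in gene_hits
        if h.evalue <= evalue_max and h.subject_taxon_id in diagnostic
    }
    pct = 100.0 * len(hit_taxa) / len(diagnostic)
    return pct, pct < threshold_pct


# ---------------------------------------------------------------------------
# homology detection failure

def fit_bitscore_decay(
    gene_id: str,
    gene_hits: Sequence[HomologyHit],
    distances: TreeDistances,
    focal_taxon_id: int,
    detect_threshold: Optional[float] = None,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> Optional[HDFModel]:
    """Least-squares fit of ln(bitscore) = ln(a) - b*d over a gene's hits.

    d is the patristic distance from the focal taxon to the hit's taxon.
    Requires >= 3 hits in distinct taxa at positive distances; otherwise
    the gene is HDF-untestable (None). The decay rate b is floored at 0.
    """
    if detect_threshold is None:
        detect_threshold = detection_threshold_bits(evalue_max)
    best_by_taxon: dict[int, float] = {}
    for h in gene_hits:
        if h.subject_taxon_id == focal_taxon_id or h.bitscore <= 0:
            continue
        d = distances.distance(focal_taxon_id, h.subject_taxon_id)
        if d <= 0:
            continue
        if h.bitscore > best_by_taxon.get(h.subject_taxon_id, 0.0):
            best_by_taxon[h.subject_taxon_id] = h.bitscore
    if len(best_by_taxon) < 3:
        logger.info("gene %s: <3 usable hit taxa; HDF untestable", gene_id)
        return None
    d = np.array([distances.distance(focal_taxon_id, t) for t in best_by_taxon])
    if np.unique(d).size < 2:
        logger.info("gene %s: hits at a single distance; HDF untestable", gene_id)
        return None
    y = np.log([best_by_taxon[t] for t in best_by_taxon])
    slope, intercept = np.polyfit(d, y, 1)
    b = max(-slope, 0.0)
    if b < 1e-12:  # numerically flat
        b = 0.0
    ln_a = intercept if slope <= 0 else float(np.mean(y))
    resid = y - (ln_a - b * d)
    dof = max(len(d) - 2, 1)
    sigma = float(np.sqrt(np.sum(resid**2) / dof))
    return HDFModel(
        gene_id=gene_id,
        a=float(np.exp(ln_a)),
        b=float(b),
        sigma=sigma,
        detect_threshold_bits=float(detect_threshold),
        n_points=len(d),
    )


def hdf_classify(
    model: Optional[HDFModel], outgroup_distance: float, alpha: float = 0.05
) -> bool:
    """True when a gene's young age cannot be explained by detection failure.

    Under the fitted decay model the ln-bitscore of a homolog at the
    nearest outgroup beyond the assigned clade is Normal(ln a - b*d,
    sigma). If detection there was near-certain (P >= 1 - alpha) yet no
    homolog was observed, absence is informative and the age is
    high-confidence. Untestable genes are conservatively non-confident.
    """
    if model is None:
        logger.info("HDF-untestable gene: classified non-confident")
        return False
    mu = math.log(model.a) - model.b * outgroup_distance
    thr = math.log(model.detect_threshold_bits)
    if model.sigma == 0:
        p_detect = 1.0 if mu > thr else 0.0
    else:
        p_detect = 1.0 - stats.norm.cdf(thr, loc=mu, scale=model.sigma)
    return bool(p_detect >= 1.0 - alpha)


def nearest_outgroup_distance(
    assigned_rank: int,
    div_ranks: Mapping[int, int],
    distances: TreeDistances,
    focal_taxon_id: int,
) -> Optional[float]:
    """Distance from the focal taxon to the nearest database taxon just
    beyond the assigned clade (divergence rank < assigned rank)."""
    cands = [
        distances.distance(focal_taxon_id, t)
        for t, r in div_ranks.items()
        if r < assigned_rank
    ]
    return min(cands) if cands else None


# ---------------------------------------------------------------------------
# whole-table driver and profile

def read_hits_table(
    path,
    taxon_map_path,
    qseqid_col: int = 1,
    sseqid_col: int = 2,
    evalue_col: int = 11,
    bitscore_col: int = 12,
) -> pd.DataFrame:
    """Read an outfmt-6-like hits TSV plus a subject->taxon map.

    Column indices are 1-based positions in the tab-separated file
    (BLAST/DIAMOND defaults: query 1, subject 2, E-value 11, bitscore 12).
    Returns a frame with columns gene_id, subject_taxon_id, evalue, bitscore.
    """
    raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    tmap = pd.read_csv(taxon_map_path, sep="\t", dtype={0: str, 1: int})
    tmap.columns = ["subject_id", "taxon_id"]
    lookup = dict(zip(tmap.subject_id, tmap.taxon_id))
    out = pd.DataFrame(
        {
            "gene_id": raw[qseqid_col - 1].astype(str),
            "subject_id": raw[sseqid_col - 1].astype(str),
            "evalue": raw[evalue_col - 1].astype(float),
            "bitscore": raw[bitscore_col - 1].astype(float),
        }
    )
    missing = set(out.subject_id) - set(lookup)
    if missing:
        raise ValueError(f"subjects with no taxon mapping: {sorted(missing)[:5]} ...")
    out["subject_taxon_id"] = out.subject_id.map(lookup).astype(int)
    return out[["gene_id", "subject_taxon_id", "evalue", "bitscore"]]


def assign_all(
    hits: pd.DataFrame,
    lineages: Mapping[int, TaxonLineage],
    focal_taxon_id: int,
    gene_ids: Optional[Iterable[str]] = None,
    distances: Optional[TreeDistances] = None,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    rep_threshold_pct: float = DEFAULT_REP_THRESHOLD_PCT,
    hdf_min_rank: int = 4,
    hdf_max_rank: Optional[int] = None,
    alpha: float = 0.05,
    rules: Optional[RankCorrectionRules] = None,
) -> pd.DataFrame:
    """Assign phyloranks, representativeness flags and (optionally) HDF
    confidence for every gene of a hits table.

    gene_ids may add genes with zero hits (assigned the youngest rank).
    When a TreeDistances is given, genes assigned within
    [hdf_min_rank, hdf_max_rank] are HDF-tested; older genes are
    high-confidence by definition (their age needs no detection at longer
    distances than observed).
    """
    if rules is not None:
        lineages = apply_rank_corrections(lineages, rules)
    n_phyloranks = len(lineages[focal_taxon_id].ranks)
    if hdf_max_rank is None:
        hdf_max_rank = n_phyloranks - 1
    dranks = divergence_ranks(lineages, focal_taxon_id, n_phyloranks)

    per_gene: dict[str, list[HomologyHit]] = {}
    for r in hits.itertuples():
        per_gene.setdefault(r.gene_id, []).append(
            HomologyHit(r.gene_id, int(r.subject_taxon_id), float(r.evalue), float(r.bitscore))
        )
    all_genes = list(per_gene)
    if gene_ids is not None:
        extra = [g for g in gene_ids if g not in per_gene]
        all_genes.extend(extra)

    rows = []
    for gid in sorted(all_genes):
        ghits = per_gene.get(gid, [])
        rank = assign_phylorank(ghits, dranks, focal_taxon_id, n_phyloranks, evalue_max)
        rep, flagged = taxonomic_representativeness(
            ghits, rank, dranks, evalue_max, rep_threshold_pct
        )
        high_conf: Optional[bool] = None
        if distances is not None:
            if rank < hdf_min_rank:
                high_conf = True  # old enough that HDF cannot explain it
            elif rank > hdf_max_rank:
                high_conf = False  # beyond the testable range: conservative
            else:
                model = fit_bitscore_decay(gid, ghits, distances, focal_taxon_id, evalue_max=evalue_max)
                ogd = nearest_outgroup_distance(rank, dranks, distances, focal_taxon_id)
                if ogd is None:
                    high_conf = False
                else:
                    high_conf = hdf_classify(model, ogd, alpha)
        rows.append(
            {
                "gene_id": gid,
                "phylorank": rank,
                "representativeness_pct": rep,
                "flag_contaminant_or_hgt": flagged,
                "high_confidence": high_conf,
            }
        )
    return pd.DataFrame(rows)


def stratum_profile(assignments: pd.DataFrame, n_phyloranks: int) -> pd.DataFrame:
    """Gene counts per phylorank before and after the HDF filter.

    Flagged contaminant/HGT genes are excluded from both profiles. The
    post-HDF profile counts only high-confidence genes.
    """
    ok = assignments[~assignments.flag_contaminant_or_hgt.astype(bool)]
    rows = []
    for rank in range(1, n_phyloranks + 1):
        at = ok[ok.phylorank == rank]
        n_all = len(at)
        if "high_confidence" in ok.columns and ok.high_confidence.notna().any():
            n_hc = int(at.high_confidence.fillna(False).astype(bool).sum())
        else:
            n_hc = n_all
        rows.append({"phylorank": rank, "n_genes": n_all, "n_high_confidence": n_hc})
    return pd.DataFrame(rows)


def stratum_share_percent(count_at_rank: int, total_genes: int, decimals: int = 0) -> float:
    """Percentage of genes at one phylorank, rounded as printed in summaries."""
    from chronotopo.asmqc import completeness_percent

    return completeness_percent(count_at_rank, total_genes, decimals=decimals)
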