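"""Assembly quality statistics: N50/L50, gap splitting, telomere detection.

Works on scaffold-level FASTA assemblies. Contigs are derived from
scaffolds by splitting at runs of N of at least ``min_gap_run`` bases
(NCBI convention: 10). Telomere arrays are exact tandem repeats of the
fungal/vertebrate unit TTAGGG: the forward unit is expected at scaffold 3'
ends and its reverse complement (CCCTAA) at 5' ends. A scaffold carrying
arrays at both ends is telomere-to-telomere (T2T).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

from Bio import SeqIO
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

TELOMERE_UNIT = "TTAGGG"


@dataclass
class AssemblyStats:
    """Scaffold- and contig-level summary of an assembly."""

    n_scaffolds: int
    n_contigs: int
    scaffold_n50_bp: int
    scaffold_l50: int
    contig_n50_bp: int
    contig_l50: int
    n_gaps: int
    total_bp: int


@dataclass
class TelomereEndState:
    """Presence of telomeric arrays at the two ends of one scaffold."""

    scaffold_id: str
    end_5prime: bool
    end_3prime: bool
    copies_5prime: int = 0
    copies_3prime: int = 0

    @property
    def t2t(self) -> bool:
        return self.end_5prime and self.end_3prime

    @property
    def n_telomeres(self) -> int:
        return int(self.end_5prime) + int(self.end_3prime)


def nX_stats(lengths: Sequence[int], x: int = 50) -> tuple[int, int]:
    """NX and LX of a set of piece lengths.

    NX is the length of the piece at which, going through pieces from
    longest to shortest, the cumulative length first reaches x% of the
    total; LX is how many pieces that takes.
    """
    if len(lengths) == 0:
        raise ValueError("nX_stats requires at least one length")
    if any(l <= 0 for l in lengths):
        raise ValueError("piece lengths must be positive")
    srt = sorted(lengths, reverse=True)
    target = sum(srt) * x / 100.0
    cum = 0
    for i, l in enumerate(srt, start=1):
        cum += l
        if cum >= target:
            return l, i
    raise AssertionError("unreachable: cumulative sum must reach target")


_GAP_RE_CACHE: dict[int, re.Pattern] = {}


def split_at_gaps(scaffold_seq: str, min_gap_run: int = 10) -> tuple[list[str], list[tuple[int, int]]]:
    """Split a scaffold into contigs at N-runs of >= min_gap_run.

    Returns (contigs, gaps) where gaps is a list of (start, length) of each
    gap run, 0-based. Shorter N runs stay inside contigs. Leading/trailing
    gap runs produce no empty contigs.
    """
    seq = scaffold_seq.upper()
    if not seq:
        return [], []
    if min_gap_run not in _GAP_RE_CACHE:
        _GAP_RE_CACHE[min_gap_run] = re.compile("N{%d,}" % min_gap_run)
    pat = _GAP_RE_CACHE[min_gap_run]
    gaps = [(m.start(), m.end() - m.start()) for m in pat.finditer(seq)]
    contigs = [c for c in pat.split(seq) if c]
    return contigs, gaps


def join_contigs(contigs: Sequence[str], gaps: Sequence[tuple[int, int]]) -> str:
    """Inverse of :func:`split_at_gaps`: rebuild the scaffold sequence."""
    pieces: list[str] = []
    pos = 0
    ci = 0
    for gstart, glen in gaps:
        if gstart > pos:
            pieces.append(contigs[ci])
            pos += len(contigs[ci])
            ci += 1
        pieces.append("N" * glen)
        pos += glen
    pieces.extend(contigs[ci:])
    return "".join(pieces)


def _max_tandem_copies(seq: str, unit: str) -> int:
    """Longest run of exact tandem copies of unit (forward orientation only)."""
    best = 0
    n, u = len(seq), len(unit)
    i = seq.find(unit)
    while i != -1 and i < n:
        j = i
        while seq.startswith(unit, j):
            j += u
        best = max(best, (j - i) // u)
        i = seq.find(unit, j)
    return best


def find_telomere_reads(
    reads: Iterable[tuple[str, str]], unit: str = TELOMERE_UNIT, min_tandem: int = 8
) -> list[str]:
    """Ids of reads containing >= min_tandem exact tandem copies of the
    telomeric unit or of its reverse complement, anywhere in the read."""
    rc = reverse_complement(unit)
    out = []
    for read_id, seq in reads:
        s = seq.upper()
        if _max_tandem_copies(s, unit) >= min_tandem or _max_tandem_copies(s, rc) >= min_tandem:
            out.append(read_id)
    return out


def classify_telomere_ends(
    scaffold_id: str,
    scaffold_seq: str,
    window_bp: int = 1000,
    unit: str = TELOMERE_UNIT,
    min_tandem: int = 8,
) -> TelomereEndState:
    """Classify both scaffold ends for telomeric arrays.

    The 5' terminal window is scanned for tandem copies of the
    reverse-complement unit (CCCTAA for TTAGGG), the 3' terminal window for
    the forward unit. Scaffolds shorter than two windows are scanned whole.
    """
    seq = scaffold_seq.upper()
    rc = reverse_complement(unit)
    if len(seq) < 2 * window_bp:
        logger.warning(
            "scaffold %s shorter than 2x window (%d bp); scanning whole sequence",
            scaffold_id, len(seq),
        )
        w5 = w3 = seq
    else:
        w5 = seq[:window_bp]
        w3 = seq[-window_bp:]
    c5 = _max_tandem_copies(w5, rc)
    c3 = _max_tandem_copies(w3, unit)
    return TelomereEndState(
        scaffold_id=scaffold_id,
        end_5prime=c5 >= min_tandem,
        end_3prime=c3 >= min_tandem,
        copies_5prime=c5,
        copies_3prime=c3,
    )


def telomere_summary(states: Iterable[TelomereEndState]) -> dict[str, int]:
    """Aggregate end states into T2T / one-telomere / no-telomere counts."""
    counts = {"t2t": 0, "one_telomere": 0, "no_telomere": 0}
    for st in states:
        if st.t2t:
            counts["t2t"] += 1
        elif st.n_telomeres == 1:
            counts["one_telomere"] += 1
        else:
            counts["no_telomere"] += 1
    return counts


def coverage_uniformity(depth_by_contig: Mapping[str, Sequence[float]]) -> dict:
    """Per-contig mean depth plus min/max of the means and their CV.

    Contigs with no depth rows are excluded (logged)."""
    means: dict[str, float] = {}
    for contig, depths in depth_by_contig.items():
        arr = np.asarray(depths, dtype=float)
        if arr.size == 0:
            logger.warning("contig %s has no depth rows; excluded", contig)
            continue
        if (arr < 0).any():
            raise ValueError(f"negative depth values for contig {contig}")
        means[contig] = float(arr.mean())
    if not means:
        return {"per_contig_mean": {}, "min_mean": None, "max_mean": None, "cv": None}
    vals = np.array(list(means.values()))
    cv = float(vals.std(ddof=0) / vals.mean()) if vals.mean() > 0 else 0.0
    return {
        "per_contig_mean": means,
        "min_mean": float(vals.min()),
        "max_mean": float(vals.max()),
        "cv": cv,
    }


def completeness_percent(found: int, total: int, decimals: int = 1) -> float:
    """100*found/total, rounded half-up to `decimals` (as printed in QC
    reports, e.g. BUSCO completeness or read-retention percentages)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= found <= total:
        raise ValueError("found must be between 0 and total")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(found) / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    )


def assembly_stats(scaffolds: Mapping[str, str], min_gap_run: int = 10) -> AssemblyStats:
    """Scaffold/contig N50, L50, counts, total size and gap count for an
    assembly given as {scaffold_id: sequence}."""
    if not scaffolds:
        raise ValueError("empty assembly")
    scaf_lengths = [len(s) for s in scaffolds.values()]
    contig_lengths: list[int] = []
    n_gaps = 0
    for seq in scaffolds.values():
        contigs, gaps = split_at_gaps(seq, min_gap_run=min_gap_run)
        contig_lengths.extend(len(c) for c in contigs)
        n_gaps += len(gaps)
    s_n50, s_l50 = nX_stats(scaf_lengths)
    c_n50, c_l50 = nX_stats(contig_lengths)
    return AssemblyStats(
        n_scaffolds=len(scaf_lengths),
        n_contigs=len(contig_lengths),
        scaffold_n50_bp=s_n50,
        scaffold_l50=s_l50,
        contig_n50_bp=c_n50,
        contig_l50=c_l50,
        n_gaps=n_gaps,
        total_bp=sum(scaf_lengths),
    )


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file as {id: sequence} (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_fastq_ids_seqs(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]
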