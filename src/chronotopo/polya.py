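"""Poly(A) tails, cleavage-site collapsing and polyadenylation-signal tallies.

The polyadenylation signal of most eukaryotes is a hexanucleotide
(canonically AAUAAA) located a short distance upstream of the mRNA
cleavage/poly(A) site. Given long cDNA reads, this module calls 3'-terminal
poly(A) tails, collapses per-read cleavage positions into unique sites,
extracts the 50 nt immediately upstream of each site, and tallies a fixed
panel of 18 single-substitution hexamer variants of AAUAAA (plus the
AAUGAA-type derivatives seen in fungi). Reports use the RNA alphabet.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

#: Hexamer panel tallied in upstream windows (RNA alphabet). The canonical
#: signal first, then single-base variants, then AAUGAA-type derivatives.
HEXAMER_PANEL: tuple[str, ...] = (
    "AAUAAA",
    "CAUAAA",
    "GAUAAA",
    "UAUAAA",
    "ACUAAA",
    "AGUAAA",
    "AUUAAA",
    "AACAAA",
    "AAGAAA",
    "AAUACA",
    "AAUAGA",
    "AAUAUA",
    "AAUAAC",
    "AAUAAG",
    "AAUAAU",
    "CAUGAA",
    "GAUGAA",
    "UAUGAA",
)

NO_SIGNAL = "NONE"


@dataclass
class TailCall:
    """A poly(A) tail called at the 3' end of one read."""

    read_id: str
    tail_start_offset_from_3prime: int
    tail_length_nt: int
    purity: float


@dataclass
class PolyASite:
    """A collapsed cleavage/polyadenylation site."""

    reference_id: str
    cleavage_pos: int
    strand: str
    n_supporting_reads: int
    upstream_window: str


@dataclass
class HexamerTally:
    counts: dict[str, int]
    total_sites: int
    percents: dict[str, float]


def detect_tail(
    read_id: str,
    read_seq: str,
    min_tail: int = 10,
    min_purity: float = 0.9,
    max_interrupt: int = 2,
) -> Optional[TailCall]:
    """Call the poly(A) tail of one read, or None.

    The tail is the longest 3'-terminal segment with A content >=
    ``min_purity`` and no internal run of more than ``max_interrupt``
    consecutive non-A bases, of length >= ``min_tail``. Up to
    ``max_interrupt`` trailing non-A bases are clipped before the scan (the
    clip is reported as the offset from the 3' end).
    """
    seq = read_seq.upper()
    if not seq:
        return None
    # clip a short non-A overhang at the very 3' end
    offset = 0
    while offset < len(seq) and offset < max_interrupt and seq[-1 - offset] != "A":
        offset += 1
    if offset == max_interrupt and (len(seq) == offset or seq[-1 - offset] != "A"):
        offset = 0  # no A follows the clip: not an overhang, scan from the end
    core = seq[: len(seq) - offset] if offset else seq
    if not core or core[-1] != "A":
        return None

    best_len = 0
    best_purity = 0.0
    n_a = 0
    non_a_run = 0
    for k in range(1, len(core) + 1):
        base = core[-k]
        if base == "A":
            n_a += 1
            non_a_run = 0
        else:
            non_a_run += 1
            if non_a_run > max_interrupt:
                break
        purity = n_a / k
        # a tail segment must begin on an A at its 5' boundary
        if base == "A" and purity >= min_purity and k >= min_tail:
            best_len = k
            best_purity = purity
    if best_len >= min_tail:
        return TailCall(
            read_id=read_id,
            tail_start_offset_from_3prime=offset,
            tail_length_nt=best_len,
            purity=best_purity,
        )
    return None


def collapse_sites(
    positions: Sequence[tuple[str, int, str]],
    cluster_radius_nt: int = 5,
) -> list[tuple[str, int, str, int]]:
    """Collapse per-read cleavage positions into unique sites.

    positions: (reference_id, cleavage_pos, strand) per supporting read.
    Single-linkage clustering joins positions on the same reference and
    strand that are within ``cluster_radius_nt`` of the next one. Each
    cluster is reported at its modal position (ties -> smallest), with its
    read support. Returns (reference_id, site_pos, strand, n_supporting)
    sorted by reference, strand, position.
    """
    by_key: dict[tuple[str, str], list[int]] = {}
    for ref, pos, strand in positions:
        by_key.setdefault((ref, strand), []).append(pos)
    sites = []
    for (ref, strand), pos_list in sorted(by_key.items()):
        pos_list.sort()
        cluster: list[int] = [pos_list[0]]
        for p in pos_list[1:]:
            if p - cluster[-1] <= cluster_radius_nt:
                cluster.append(p)
            else:
                sites.append(_emit_cluster(ref, strand, cluster))
                cluster = [p]
        sites.append(_emit_cluster(ref, strand, cluster))
    sites.sort(key=lambda s: (s[0], s[2], s[1]))
    return sites


def _emit_cluster(ref: str, strand: str, cluster: list[int]) -> tuple[str, int, str, int]:
    counts = Counter(cluster)
    top = max(counts.values())
    modal = min(p for p, c in counts.items() if c == top)
    return (ref, modal, strand, len(cluster))


def upstream_window(reference_seq: str, cleavage_pos: int, window: int = 50) -> str:
    """The `window` bases immediately 5' of a cleavage position (plus
    strand); shorter only when the site is within `window` of the
    reference 5' edge."""
    start = max(0, cleavage_pos - window)
    win = reference_seq[start:cleavage_pos]
    if len(win) < window:
        logger.info("upstream window truncated to %d nt at reference 5' edge", len(win))
    return win


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def call_signal(window_seq: str, panel: Sequence[str] = HEXAMER_PANEL) -> str:
    """Call the polyadenylation signal of one upstream window.

    The window is converted to RNA. If the canonical AAUAAA occurs anywhere
    it is called; otherwise the panel variant whose occurrence lies nearest
    the cleavage end (rightmost start) is called; windows with no panel
    match (or shorter than 6 nt) are NONE. One call per site, so tallies
    sum to the number of sites.
    """
    rna = to_rna(window_seq)
    if len(rna) < 6:
        logger.info("window shorter than 6 nt; no signal call")
        return NO_SIGNAL
    if panel[0] in rna:
        return panel[0]
    best_var = NO_SIGNAL
    best_pos = -1
    for var in panel[1:]:
        p = rna.rfind(var)
        if p > best_pos:
            best_pos = p
            best_var = var
    return best_var if best_pos >= 0 else NO_SIGNAL


def tally_hexamers(
    windows: Iterable[str], panel: Sequence[str] = HEXAMER_PANEL
) -> HexamerTally:
    """Tally signal calls over upstream windows, with percents to 1 decimal."""
    counts = {v: 0 for v in panel}
    counts[NO_SIGNAL] = 0
    total = 0
    for w in windows:
        counts[call_signal(w, panel)] += 1
        total += 1
    percents = {
        v: round(100.0 * c / total, 1) if total else 0.0 for v, c in counts.items()
    }
    return HexamerTally(counts=counts, total_sites=total, percents=percents)


def tail_stats(tail_calls: Sequence[TailCall]) -> dict:
    """Arithmetic mean (1 decimal), min, max and count of tail lengths."""
    if not tail_calls:
        return {"n": 0, "mean": None, "min": None, "max": None}
    lengths = [t.tail_length_nt for t in tail_calls]
    return {
        "n": len(lengths),
        "mean": round(sum(lengths) / len(lengths), 1),
        "min": min(lengths),
        "max": max(lengths),
    }


def call_tails_from_fastq(
    path, min_tail: int = 10, min_purity: float = 0.9, max_interrupt: int = 2
) -> list[TailCall]:
    """Run tail detection over every read of a FASTQ file."""
    from Bio import SeqIO

    calls = []
    for rec in SeqIO.parse(str(path), "fastq"):
        tc = detect_tail(rec.id, str(rec.seq), min_tail, min_purity, max_interrupt)
        if tc is not None:
            calls.append(tc)
    return calls


def sites_from_reads(
    reads: Iterable[tuple[str, str]],
    tail_calls: dict[str, TailCall],
    window: int = 50,
    cluster_radius_nt: int = 5,
) -> list[PolyASite]:
    """Build poly(A) sites directly from reads and their tail calls.

    Without a genome alignment each read defines its own cleavage point:
    the boundary between transcript body and tail. Reads are collapsed by
    their upstream window sequence (identical windows = one site), an
    approximation of reference-space clustering adequate for tallying.
    """
    window_counts: Counter[str] = Counter()
    for read_id, seq in reads:
        tc = tail_calls.get(read_id)
        if tc is None:
            continue
        body_end = len(seq) - tc.tail_start_offset_from_3prime - tc.tail_length_nt
        window_counts[upstream_window(seq, body_end, window)] += 1
    return [
        PolyASite(
            reference_id=f"site_{i}",
            cleavage_pos=len(w),
            strand="+",
            n_supporting_reads=n,
            upstream_window=w,
        )
        for i, (w, n) in enumerate(sorted(window_counts.items()))
    ]
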