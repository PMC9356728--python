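"""Assembly-hygiene computations.

Chloroplast read selection (aligned span, mapping quality, GC window),
organelle scaffold scrubbing (merged-hit coverage and length-weighted
identity against the organelle reference), telomere end scanning, N50-class
statistics, and per-sub-genome soft-mask accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import (
    ParameterError,
    count_overlapping,
    gc_content,
    log,
    merge_intervals,
    revcomp,
)
from .config import ReadFilterParams, ScrubParams, TelomereParams
from .records import PafRecord, SequenceRecord, TabularHit


# ------------------------------------------------- chloroplast read filter

@dataclass(slots=True)
class ReadFilterReport:
    n_input: int
    n_pass: int
    n_fail_mlen: int
    n_fail_qval: int
    n_fail_gc: int


def filter_chloroplast_reads(
    records: list[PafRecord],
    params: ReadFilterParams | None = None,
    read_gc: dict[str, float] | None = None,
    read_sequences: dict[str, str] | None = None,
) -> tuple[list[str], ReadFilterReport]:
    """Select organelle-derived reads.

    A read passes iff its aligned query span (query_end - query_start) is
    strictly greater than min_mlen AND its mapping quality is strictly
    greater than min_qval AND its GC fraction lies in the closed
    [gc_low, gc_high] window. GC comes from ``read_gc`` or is computed from
    ``read_sequences``. A read may fail several predicates; the report
    counts each.
    """
    params = params or ReadFilterParams()
    if read_gc is None:
        if read_sequences is None:
            raise ParameterError(
                "need per-read GC values or read sequences to compute them")
        read_gc = {rid: gc_content(seq)
                   for rid, seq in read_sequences.items()}
    passing = []
    f_mlen = f_qval = f_gc = 0
    for rec in records:
        ok_mlen = rec.aligned_query_span > params.min_mlen
        ok_qval = rec.mapping_quality > params.min_qval
        gc = read_gc[rec.query_id]
        ok_gc = params.gc_low <= gc <= params.gc_high
        f_mlen += not ok_mlen
        f_qval += not ok_qval
        f_gc += not ok_gc
        if ok_mlen and ok_qval and ok_gc:
            passing.append(rec.query_id)
    report = ReadFilterReport(
        n_input=len(records), n_pass=len(passing), n_fail_mlen=f_mlen,
        n_fail_qval=f_qval, n_fail_gc=f_gc)
    log.info("filter_chloroplast_reads: %d/%d pass", report.n_pass,
             report.n_input)
    return passing, report


# ------------------------------------------------------- organelle scrub

@dataclass(slots=True)
class ScaffoldScrubReport:
    scaffold_id: str
    identity: float     # alignment-length-weighted mean percent identity
    coverage: float     # merged hit span / scaffold length
    removed: bool


def scrub_organelle_scaffolds(
    hits: list[TabularHit],
    scaffold_lengths: dict[str, int],
    params: ScrubParams | None = None,
) -> tuple[list[str], list[ScaffoldScrubReport]]:
    """Flag scaffolds that are effectively the organelle sequence.

    Per scaffold, hit query intervals are merged (union coverage) and the
    identity is the alignment-length-weighted mean of contributing hits; a
    scaffold is removed iff identity >= min_identity and coverage >=
    min_coverage.
    """
    params = params or ScrubParams()
    by_scaffold: dict[str, list[TabularHit]] = {}
    for hit in hits:
        if hit.query_id not in scaffold_lengths:
            raise ParameterError(f"hit on unknown scaffold {hit.query_id!r}")
        lo, hi = sorted((hit.query_start, hit.query_end))
        if hi > scaffold_lengths[hit.query_id]:
            raise ParameterError(
                f"hit interval exceeds scaffold length for {hit.query_id!r}")
        by_scaffold.setdefault(hit.query_id, []).append(hit)

    removed: list[str] = []
    reports: list[ScaffoldScrubReport] = []
    for sid in sorted(by_scaffold):
        shits = by_scaffold[sid]
        spans = []
        for h in shits:
            lo, hi = sorted((h.query_start, h.query_end))
            spans.append((lo - 1, hi))  # to 0-based half-open
        cov = sum(e - s for s, e in merge_intervals(spans)) \
            / scaffold_lengths[sid]
        total_len = sum(h.alignment_length for h in shits)
        ident = sum(h.percent_identity * h.alignment_length
                    for h in shits) / total_len
        is_removed = ident >= params.min_identity \
            and cov >= params.min_coverage
        if is_removed:
            removed.append(sid)
        reports.append(ScaffoldScrubReport(sid, ident, cov, is_removed))
    log.info("scrub_organelle_scaffolds: removing %d/%d scaffolds",
             len(removed), len(by_scaffold))
    return removed, reports


# --------------------------------------------------------- telomere scan

@dataclass(slots=True)
class TelomereScan:
    chromosome: str
    left_copies: int
    right_copies: int
    classification: str  # both / left / right / none


@dataclass(slots=True)
class TelomereSummary:
    scans: list[TelomereScan]
    n_both: int
    n_one_end: int
    n_none: int


def scan_telomeres(
    assembly: list[SequenceRecord],
    params: TelomereParams | None = None,
) -> TelomereSummary:
    """Classify chromosome ends by telomere-motif abundance.

    The left end counts the reverse-complement motif in the first terminal
    window, the right end counts the motif in the last window (overlapping
    occurrences included); an end is positive at >= min_copies exact
    copies. Sequences shorter than the window are scanned whole.
    """
    params = params or TelomereParams()
    motif = params.motif.upper()
    rc_motif = revcomp(motif)
    scans = []
    for rec in assembly:
        seq = rec.residues.upper()
        w = min(params.terminal_window, len(seq))
        left = count_overlapping(seq[:w], rc_motif)
        right = count_overlapping(seq[-w:], motif)
        ok_left = left >= params.min_copies
        ok_right = right >= params.min_copies
        cls = ("both" if ok_left and ok_right else
               "left" if ok_left else
               "right" if ok_right else "none")
        scans.append(TelomereScan(rec.id, left, right, cls))
    return TelomereSummary(
        scans=scans,
        n_both=sum(s.classification == "both" for s in scans),
        n_one_end=sum(s.classification in ("left", "right") for s in scans),
        n_none=sum(s.classification == "none" for s in scans),
    )


# ------------------------------------------------------------- N50 stats

@dataclass(slots=True)
class AssemblyStats:
    total_bp: int
    n_sequences: int
    n50: int
    l50: int
    sorted_lengths: list[int] = field(default_factory=list, repr=False)

    def top_n_fraction(self, n: int) -> float:
        return sum(self.sorted_lengths[:n]) / self.total_bp


def nx_stats(lengths: list[int]) -> AssemblyStats:
    """N50/L50 by descending cumulative scan.

    N50 is the length of the first sequence at which the cumulative sorted
    sum reaches half the total; L50 is its 1-based rank.
    """
    if not lengths:
        raise ParameterError("empty length list")
    if any(x <= 0 for x in lengths):
        raise ParameterError("all lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    running = 0
    for rank, length in enumerate(ordered, 1):
        running += length
        if 2 * running >= total:
            return AssemblyStats(
                total_bp=total, n_sequences=len(ordered), n50=length,
                l50=rank, sorted_lengths=ordered)
    raise AssertionError("unreachable")


# ------------------------------------------------------- mask accounting

def masked_fraction(
    records: list[SequenceRecord],
    label_of: dict[str, str],
) -> dict[str, tuple[float, int]]:
    """Per-label (masked_fraction, nonrepetitive_bp) from soft-masked input.

    masked_fraction = lowercase bp over non-N bp; nonrepetitive_bp counts
    uppercase A/C/G/T. Ambiguity characters are excluded throughout.
    """
    lower = {}
    upper = {}
    for rec in records:
        if rec.id not in label_of:
            raise ParameterError(f"unlabelled chromosome {rec.id!r}")
        label = label_of[rec.id]
        n_lower = sum(rec.residues.count(b) for b in "acgt")
        n_upper = sum(rec.residues.count(b) for b in "ACGT")
        lower[label] = lower.get(label, 0) + n_lower
        upper[label] = upper.get(label, 0) + n_upper
    out = {}
    for label in sorted(set(lower) | set(upper)):
        denom = lower.get(label, 0) + upper.get(label, 0)
        frac = lower.get(label, 0) / denom if denom else 0.0
        out[label] = (frac, upper.get(label, 0))
    return out
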