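"""Sub-genome assignment of homoeologous chromosome triads.

For a BCD allohexaploid, each homoeologous set of three chromosomes gets
one B, one C, and one D label: B goes to the chromosome with the highest
density of the B-diagnostic repeat, D to the remaining chromosome with the
higher density of mapped diploid-ancestor reads, and C to the one left
over. Densities come from 500-kb windowed tracks (the same granularity
used for circular genome plots). "Clear" overrepresentation is quantified
as a clarity ratio (top/second density within the triad); calls below the
clarity floor are flagged ambiguous but still made.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

from ._util import ParameterError, log
from .records import GenomicInterval, PafRecord


@dataclass(slots=True)
class WindowDensityTrack:
    signal: str
    windows: list[tuple[GenomicInterval, int]] = field(default_factory=list)

    def chromosome_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for iv, count in self.windows:
            totals[iv.seq_id] = totals.get(iv.seq_id, 0) + count
        return totals

    def chromosome_lengths(self) -> dict[str, int]:
        lengths: dict[str, int] = {}
        for iv, _ in self.windows:
            lengths[iv.seq_id] = max(lengths.get(iv.seq_id, 0), iv.end)
        return lengths


@dataclass(slots=True)
class ChromosomeScore:
    chromosome: str
    signal: str
    density: float            # counts per Mb
    enrichment: float         # density / median density across chromosomes
    median_undefined: bool = False


@dataclass(slots=True)
class TriadAssignment:
    triad_id: str
    labels: dict[str, str]    # chromosome -> B/C/D
    b_clarity: float
    d_clarity: float
    ambiguous: bool


def make_windows(chromosome_lengths: dict[str, int],
                 window: int = 500_000) -> list[GenomicInterval]:
    """Half-open tiling of each chromosome; the last window may be short."""
    if window < 1:
        raise ParameterError("window must be >= 1")
    out = []
    for chrom, length in chromosome_lengths.items():
        if length <= 0:
            raise ParameterError(f"zero-length chromosome {chrom!r}")
        for start in range(0, length, window):
            out.append(GenomicInterval(chrom, start,
                                       min(start + window, length)))
    return out


def density_track(
    windows: list[GenomicInterval],
    features: list[GenomicInterval] | list[PafRecord],
    signal: str,
    mapq_min: int = 20,
) -> WindowDensityTrack:
    """Count features per window by start position.

    Interval features count in the window containing their start; PAF
    records count only when primary with mapping quality >= mapq_min, at
    their target start. Eligible feature totals are conserved across
    windows.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in windows:
        by_chrom.setdefault(iv.seq_id, []).append(iv)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda iv: iv.start)
    counts = {id(iv): 0 for chrom in by_chrom for iv in by_chrom[chrom]}

    unknown = []
    for feat in features:
        if isinstance(feat, PafRecord):
            if not feat.is_primary or feat.mapping_quality < mapq_min:
                continue
            chrom, pos = feat.target_id, feat.target_start
        else:
            chrom, pos = feat.seq_id, feat.start
        if chrom not in by_chrom:
            unknown.append(chrom)
            continue
        for iv in by_chrom[chrom]:
            if iv.start <= pos < iv.end:
                counts[id(iv)] += 1
                break
    if unknown:
        raise ParameterError(
            f"features on unknown chromosomes: {sorted(set(unknown))}")
    track = WindowDensityTrack(
        signal=signal,
        windows=[(iv, counts[id(iv)]) for chrom in sorted(by_chrom)
                 for iv in by_chrom[chrom]],
    )
    return track


def chromosome_signal_score(
    track: WindowDensityTrack,
    chromosome_lengths: dict[str, int] | None = None,
) -> list[ChromosomeScore]:
    """Per-chromosome density (per Mb) and enrichment over the run median."""
    if not track.windows:
        raise ParameterError("empty track")
    lengths = chromosome_lengths or track.chromosome_lengths()
    totals = track.chromosome_totals()
    densities = {
        chrom: totals.get(chrom, 0) / (lengths[chrom] / 1e6)
        for chrom in lengths
    }
    med = median(densities.values())
    scores = []
    for chrom in sorted(lengths):
        d = densities[chrom]
        scores.append(ChromosomeScore(
            chromosome=chrom, signal=track.signal, density=d,
            enrichment=(d / med) if med > 0 else float("nan"),
            median_undefined=med == 0,
        ))
    return scores


# pseudo-density floor (counts per Mb) protecting clarity ratios from /0
_PSEUDO = 1.0


def assign_triads(
    triads: list[tuple[str, str, str]],
    diag_scores: list[ChromosomeScore],
    read_scores: list[ChromosomeScore],
    clarity_min: float = 2.0,
) -> list[TriadAssignment]:
    """Label each triad with one B, one C, and one D.

    B = highest diagnostic-repeat density in the triad; D = higher
    diploid-read density among the two remaining chromosomes; C = the rest.
    Clarity ratios (top/second, second floored at one pseudo-count per Mb)
    below ``clarity_min`` set the ambiguous flag without refusing the call.
    """
    seen: set[str] = set()
    for triad in triads:
        for chrom in triad:
            if chrom in seen:
                raise ParameterError(f"chromosome {chrom!r} in two triads")
            seen.add(chrom)
    diag = {s.chromosome: s.density for s in diag_scores}
    reads = {s.chromosome: s.density for s in read_scores}
    missing = seen - set(diag) | seen - set(reads)
    if missing:
        raise ParameterError(f"missing scores for {sorted(missing)}")

    out = []
    for t_index, triad in enumerate(triads, 1):
        chroms = sorted(triad)
        by_diag = sorted(chroms, key=lambda c: (-diag[c], c))
        b = by_diag[0]
        b_clarity = max(
            1.0, diag[b] / max(diag[by_diag[1]], _PSEUDO))
        rest = [c for c in chroms if c != b]
        by_reads = sorted(rest, key=lambda c: (-reads[c], c))
        d = by_reads[0]
        c_label = by_reads[1]
        d_clarity = max(
            1.0, reads[d] / max(reads[by_reads[1]], _PSEUDO))
        out.append(TriadAssignment(
            triad_id=f"triad{t_index}",
            labels={b: "B", c_label: "C", d: "D"},
            b_clarity=b_clarity,
            d_clarity=d_clarity,
            ambiguous=b_clarity < clarity_min or d_clarity < clarity_min,
        ))
    log.info("assign_triads: %d triads, %d ambiguous", len(out),
             sum(a.ambiguous for a in out))
    return out


def assignment_summary(
    assignments: list[TriadAssignment],
    chromosome_lengths: dict[str, int],
) -> dict[str, dict]:
    """Per-label chromosome sets, total length, and assembly fraction."""
    total = sum(chromosome_lengths[c] for a in assignments
                for c in a.labels)
    summary: dict[str, dict] = {}
    for label in "BCD":
        chroms = sorted(c for a in assignments
                        for c, lab in a.labels.items() if lab == label)
        bp = sum(chromosome_lengths[c] for c in chroms)
        summary[label] = {
            "chromosomes": chroms,
            "total_bp": bp,
            "fraction": bp / total if total else 0.0,
        }
    return summary
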