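"""Satellite-DNA discovery and curation.

The stage mirrors the classical tandem-repeat workflow — detect arrays,
keep abundant non-microsatellite candidates (total copy number strictly
greater than 50, monomer strictly longer than 12 bp), merge homologous
monomer consensi into families up to cyclic rotation and strand, and
re-annotate the assembly at 90/80/75% similarity — but as one deterministic
algorithm rather than a chain of interactive tools:

* arrays are seeded by per-position autocorrelation (the best period p is
  the lag at which a 2p window self-matches above the identity floor) and
  extended monomer-by-monomer against a running majority-vote consensus;
* monomers are canonicalized to the lexicographically smallest rotation of
  either strand, so pooling and merging are rotation/strand invariant;
* cross-candidate and genome-mapping identities are cyclic: a monomer is
  aligned against the doubled other sequence on both strands (edlib).

A Tandem Repeats Finder ``.dat`` file read with
:func:`repeatscape.io.read_trf_dat` can be substituted for the built-in
detector anywhere a list of TandemArray records is expected.
"""

from __future__ import annotations

import numpy as np
import edlib

from ._util import ParameterError, encode_seq, log, merge_intervals, revcomp
from .config import CurationParams, DetectorParams
from .records import (
    GenomicInterval,
    SatFamily,
    SatFamilyCandidate,
    SequenceRecord,
    TandemArray,
)

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


# ----------------------------------------------------------- canonical form

def canonical_rotation(monomer: str) -> str:
    """Lexicographically smallest string over all rotations of the monomer
    and of its reverse complement. Idempotent; a monomer and its reverse
    complement share one canonical form."""
    if not monomer:
        raise ParameterError("empty monomer")
    if set(monomer) - set("ACGT"):
        raise ParameterError(f"non-ACGT character in monomer {monomer!r}")
    best = monomer
    for s in (monomer, revcomp(monomer)):
        doubled = s + s
        for k in range(len(s)):
            rot = doubled[k:k + len(s)]
            if rot < best:
                best = rot
    return best


def cyclic_identity(a: str, b: str) -> float:
    """Best cyclic-alignment identity between two monomers, both strands.

    The shorter monomer is aligned (edlib infix mode) against the doubled
    longer one; identity is 1 - edit_distance / len(shorter).
    """
    q, t = (a, b) if len(a) <= len(b) else (b, a)
    doubled = t + t
    best = 0.0
    for query in (q, revcomp(q)):
        ed = edlib.align(query, doubled, mode="HW")["editDistance"]
        best = max(best, 1.0 - ed / len(query))
    return best


# ------------------------------------------------------------- detection

def _grow_array(a: np.ndarray, seed: int, period: int, min_identity: float):
    """Extend a tandem array from a seed position in whole-monomer steps,
    comparing each candidate monomer to the running majority-vote consensus."""
    n = len(a)
    if seed + period > n:
        return None
    first = a[seed:seed + period]
    if (first > 3).any():
        return None
    counts = np.zeros((4, period), dtype=np.int32)
    cols = np.arange(period)
    counts[first, cols] += 1
    start, end = seed, seed + period
    while end + period <= n:
        cand = a[end:end + period]
        if (cand > 3).any():
            break
        if (cand == counts.argmax(axis=0)).mean() < min_identity:
            break
        counts[cand, cols] += 1
        end += period
    while start - period >= 0:
        cand = a[start - period:start]
        if (cand > 3).any():
            break
        if (cand == counts.argmax(axis=0)).mean() < min_identity:
            break
        counts[cand, cols] += 1
        start -= period
    consensus = counts.argmax(axis=0).astype(np.uint8)
    k = (end - start) // period
    monomers = a[start:end].reshape(k, period)
    idents = (monomers == consensus).mean(axis=1)
    return start, end, consensus, idents


def detect_tandem_arrays(
    record: SequenceRecord,
    min_period: int = 5,
    max_period: int = 1000,
    min_copies: float = 3.0,
    min_identity: float = 0.70,
) -> list[TandemArray]:
    """Detect tandem-repeat arrays on one sequence.

    Candidate periods are scored per position by autocorrelation (fraction
    of matching offsets over a 2p window at lag p); positions whose best
    score reaches ``min_identity`` seed arrays, with near-tied harmonics
    resolved in favour of the smallest period. Soft-masked (lowercase)
    positions never seed arrays. Returns arrays sorted by location.
    """
    if not 1 <= min_period <= max_period <= 2000:
        raise ParameterError("need 1 <= min_period <= max_period <= 2000")
    s = record.residues
    n = len(s)
    if n < 2 * min_period:
        return []
    raw = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    is_masked = (raw >= 97) & (raw <= 122)
    a = encode_seq(s.upper())

    best_score = np.zeros(n, dtype=np.float32)
    best_p = np.zeros(n, dtype=np.int32)
    margin = 0.02  # a longer period must beat the incumbent clearly
    for p in range(min_period, min(max_period, n // 2) + 1):
        valid = (a[:-p] == a[p:]) & (a[:-p] <= 3)
        w = 2 * p
        if len(valid) < w:
            break
        c = np.concatenate(([0], np.cumsum(valid, dtype=np.int64)))
        scores = ((c[w:] - c[:-w]) / w).astype(np.float32)
        view_s = best_score[:len(scores)]
        view_p = best_p[:len(scores)]
        upd = scores > view_s + margin
        view_s[upd] = scores[upd]
        view_p[upd] = p

    seeds = np.nonzero((best_score >= min_identity) & ~is_masked)[0]
    # best-scoring seeds first: a true-period in-array seed outranks a
    # harmonic seed whose long window merely reaches into the array
    seeds = seeds[np.argsort(-best_score[seeds], kind="stable")]
    covered = np.zeros(n, dtype=bool)
    arrays: list[TandemArray] = []
    for i in seeds:
        if covered[i]:
            continue
        grown = _grow_array(a, int(i), int(best_p[i]), min_identity)
        if grown is None:
            continue
        start, end, consensus, idents = grown
        k = (end - start) // int(best_p[i])
        if k < min_copies:
            continue
        if covered[start:end].mean() > 0.3:
            continue  # harmonic / re-detection of an accepted call
        covered[start:end] = True
        arrays.append(TandemArray(
            location=GenomicInterval(record.id, start, end),
            period=int(best_p[i]),
            copy_number=float(k),
            monomer_consensus=_DECODE[consensus].tobytes().decode("ascii"),
            mean_monomer_identity=float(idents.mean()),
        ))
    arrays.sort(key=lambda t: (t.location.start, t.location.end))
    log.info("detect_tandem_arrays: %d arrays on %s", len(arrays), record.id)
    return arrays


def detect_all(assembly: list[SequenceRecord],
               params: DetectorParams) -> list[TandemArray]:
    out: list[TandemArray] = []
    for rec in assembly:
        out.extend(detect_tandem_arrays(
            rec, params.min_period, params.max_period, params.min_copies,
            params.min_identity))
    return out


# -------------------------------------------------------------- curation

def is_microsatellite(consensus: str, max_subperiod: int = 6,
                      min_cover: float = 0.90) -> bool:
    """True when an internal sub-period <= max_subperiod explains at least
    ``min_cover`` of the consensus positions (cyclic comparison)."""
    L = len(consensus)
    for q in range(1, min(max_subperiod, L - 1) + 1):
        matches = sum(
            consensus[i] == consensus[(i + q) % L] for i in range(L))
        if matches / L >= min_cover:
            return True
    return False


def curate_candidates(
    arrays: list[TandemArray], params: CurationParams,
) -> tuple[list[SatFamilyCandidate], list[tuple[SatFamilyCandidate, str]]]:
    """Pool arrays by identical canonical monomer and apply the curation
    rules. Returns (kept, rejected-with-reason)."""
    pools: dict[str, list[TandemArray]] = {}
    for arr in arrays:
        key = canonical_rotation(arr.monomer_consensus.upper())
        pools.setdefault(key, []).append(arr)
    kept: list[SatFamilyCandidate] = []
    rejected: list[tuple[SatFamilyCandidate, str]] = []
    for cons in sorted(pools):
        members = pools[cons]
        cand = SatFamilyCandidate(
            consensus=cons,
            monomer_length=len(cons),
            total_copy_number=sum(m.copy_number for m in members),
            total_bp=sum(len(m.location) for m in members),
            member_arrays=members,
        )
        reasons = []
        if not cand.total_copy_number > params.min_copy_number:
            reasons.append(
                f"copy_number {cand.total_copy_number:g} not > "
                f"{params.min_copy_number:g}")
        if not cand.monomer_length > params.min_monomer_length:
            reasons.append(
                f"monomer {cand.monomer_length} bp not > "
                f"{params.min_monomer_length} bp")
        if is_microsatellite(cons, params.microsatellite_max_subperiod,
                             params.microsatellite_min_cover):
            reasons.append("microsatellite")
        if reasons:
            rejected.append((cand, "; ".join(reasons)))
            log.info("candidate rejected (%s): %s", reasons, cons[:40])
        else:
            kept.append(cand)
    return kept, rejected


def filter_candidates(arrays: list[TandemArray],
                      params: CurationParams) -> list[SatFamilyCandidate]:
    """Curated candidates only (see :func:`curate_candidates`)."""
    return curate_candidates(arrays, params)[0]


# --------------------------------------------------------------- merging

def _best_rotation_codes(seq: str, ref: str) -> np.ndarray:
    """2-bit codes of the rotation/strand of ``seq`` closest to ``ref``
    (equal lengths, Hamming distance over exhaustive rotations)."""
    best, best_d = None, len(ref) + 1
    for cand in (seq, revcomp(seq)):
        doubled = cand + cand
        for k in range(len(cand)):
            rot = doubled[k:k + len(cand)]
            d = sum(x != y for x, y in zip(rot, ref))
            if d < best_d:
                best, best_d = rot, d
    return encode_seq(best)


def merge_families(
    candidates: list[SatFamilyCandidate],
    params: CurationParams,
    known_library: list[SequenceRecord] | None = None,
) -> list[SatFamily]:
    """Merge homologous candidates into satellite families.

    Candidates whose monomer lengths lie within the size tolerance are
    compared by cyclic identity and linked transitively at
    ``params.merge_identity``. The family consensus is rebuilt by majority
    vote over phase-aligned equal-length member monomers (the most abundant
    member anchors the phase); the result is canonicalized. Families are
    flagged novel when no known-library monomer matches by the same rule.
    """
    n = len(candidates)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tol = params.size_group_tolerance
    for i in range(n):
        for j in range(i + 1, n):
            li = candidates[i].monomer_length
            lj = candidates[j].monomer_length
            if max(li, lj) > (1 + tol) * min(li, lj):
                continue  # outside the size group
            if cyclic_identity(candidates[i].consensus,
                               candidates[j].consensus) \
                    >= params.merge_identity:
                parent[find(i)] = find(j)

    groups: dict[int, list[SatFamilyCandidate]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(candidates[i])

    families: list[SatFamily] = []
    for members in groups.values():
        members = sorted(members, key=lambda c: (-c.total_bp, c.consensus))
        rep = members[0].consensus
        stack = [encode_seq(rep)]
        weights = [max(1, len(members[0].member_arrays))]
        for m in members[1:]:
            if m.monomer_length == len(rep):
                stack.append(_best_rotation_codes(m.consensus, rep))
                weights.append(max(1, len(m.member_arrays)))
        mat = np.stack(stack)
        wts = np.asarray(weights)[:, None]
        counts = np.zeros((4, len(rep)), dtype=np.int64)
        for b in range(4):
            counts[b] = ((mat == b) * wts).sum(axis=0)
        consensus = canonical_rotation(
            _DECODE[counts.argmax(axis=0).astype(np.uint8)]
            .tobytes().decode("ascii"))
        families.append(SatFamily(id="", consensus=consensus,
                                  members=members))

    families.sort(key=lambda f: (-f.total_bp, f.consensus))
    for k, fam in enumerate(families, 1):
        fam.id = f"fam{k:02d}"
        if known_library:
            fam.novel = not any(
                max(len(fam.consensus), len(rec.residues))
                <= (1 + tol) * min(len(fam.consensus), len(rec.residues))
                and cyclic_identity(fam.consensus, rec.residues.upper())
                >= params.merge_identity
                for rec in known_library
            )
    log.info("merge_families: %d candidates -> %d families", n,
             len(families))
    return families


# --------------------------------------------------------------- mapping

def _kmer_codes(a: np.ndarray, k: int) -> np.ndarray:
    """Rolling 2-bit k-mer codes; positions containing any non-ACGT get -1."""
    n = len(a)
    if n < k:
        return np.empty(0, dtype=np.int64)
    valid = a <= 3
    codes = np.zeros(n - k + 1, dtype=np.int64)
    ok = np.ones(n - k + 1, dtype=bool)
    for off in range(k):
        codes = codes * 4 + a[off:n - k + 1 + off]
        ok &= valid[off:n - k + 1 + off]
    codes[~ok] = -1
    return codes


def _window_identity(window: str, doubled: str, rc_doubled: str,
                     L: int) -> float:
    best = 0.0
    for target in (doubled, rc_doubled):
        ed = edlib.align(window, target, mode="HW")["editDistance"]
        best = max(best, 1.0 - ed / L)
    return best


def map_families(
    assembly: list[SequenceRecord],
    families: list[SatFamily],
    thresholds: set[float] | tuple[float, ...] = (0.90, 0.80, 0.75),
) -> dict[float, list[GenomicInterval]]:
    """Annotate the assembly with family hits at each similarity threshold.

    Each monomer-length genomic window is scored once (best cyclic identity
    to the family consensus, both strands); thresholds are then applied to
    the same scores, so hit covers are nested across thresholds by
    construction. An exact k-mer prefilter keeps the scan near-linear.
    """
    thresholds = tuple(sorted(set(thresholds)))
    if not all(0.5 < t <= 1.0 for t in thresholds):
        raise ParameterError("thresholds must lie in (0.5, 1.0]")
    results: dict[float, list[GenomicInterval]] = {t: [] for t in thresholds}
    for rec in assembly:
        seq_up = rec.residues.upper()
        a = encode_seq(seq_up)
        n = len(a)
        kmer_cache: dict[int, np.ndarray] = {}
        for fam in families:
            L = len(fam.consensus)
            if L > n:
                continue
            k = min(8, L)
            if k not in kmer_cache:
                kmer_cache[k] = _kmer_codes(a, k)
            doubled = fam.consensus + fam.consensus
            rc_doubled = revcomp(fam.consensus) * 2
            fam_codes = np.unique(np.concatenate([
                _kmer_codes(encode_seq(doubled), k),
                _kmer_codes(encode_seq(rc_doubled), k),
            ]))
            hits = np.nonzero(np.isin(kmer_cache[k], fam_codes))[0]
            if len(hits) == 0:
                continue
            regions = merge_intervals(
                [(max(0, int(h) - L), min(n - L, int(h) + L)) for h in hits])
            stride = max(1, L // 2)
            scored: list[tuple[int, float]] = []
            for rs, re_ in regions:
                for ws in range(rs, re_ + 1, stride):
                    ident = _window_identity(
                        seq_up[ws:ws + L], doubled, rc_doubled, L)
                    scored.append((ws, ident))
            for t in thresholds:
                ivs = merge_intervals(
                    [(ws, ws + L) for ws, ident in scored if ident >= t])
                for s0, e0 in ivs:
                    idents = [ident for ws, ident in scored
                              if ident >= t and s0 <= ws < e0]
                    results[t].append(GenomicInterval(
                        rec.id, s0, e0, name=fam.id,
                        score=round(float(np.mean(idents)), 4)))
    for t in thresholds:
        results[t].sort(key=lambda iv: (iv.seq_id, iv.start, iv.end))
    return results


def mask_known(
    assembly: list[SequenceRecord],
    known_library: list[SequenceRecord],
    threshold: float = 0.80,
) -> list[SequenceRecord]:
    """Soft-mask (lowercase) regions matching any known satellite monomer.

    Idempotent; with an empty library the assembly is returned unchanged
    (with a logged warning). Masked regions are skipped by the detector's
    seeding stage.
    """
    if not 0.5 < threshold <= 1.0:
        raise ParameterError("threshold must lie in (0.5, 1.0]")
    if not known_library:
        log.warning("mask_known: empty known library, nothing to mask")
        return [SequenceRecord(r.id, r.residues) for r in assembly]
    families = [
        SatFamily(id=rec.id,
                  consensus=canonical_rotation(rec.residues.upper()))
        for rec in known_library
    ]
    cover = map_families(assembly, families, {threshold})[threshold]
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in cover:
        by_chrom.setdefault(iv.seq_id, []).append((iv.start, iv.end))
    out = []
    for rec in assembly:
        if rec.id not in by_chrom:
            out.append(SequenceRecord(rec.id, rec.residues))
            continue
        residues = list(rec.residues)
        for s0, e0 in merge_intervals(by_chrom[rec.id]):
            residues[s0:e0] = rec.residues[s0:e0].lower()
        out.append(SequenceRecord(rec.id, "".join(residues)))
    return out
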