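"""Shared helpers: sequence primitives, interval arithmetic, errors, logging."""

from __future__ import annotations

import logging
import sys

import numpy as np

log = logging.getLogger("repeatscape")

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

# 2-bit base codes used by the k-mer machinery; N and lowercase are upcased first
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ParameterError(ValueError):
    """An argument is outside its documented domain."""


class CapacityError(RuntimeError):
    """Planted features do not fit on a simulated chromosome."""


class ResourceError(RuntimeError):
    """An operation would exceed its documented size cap."""


class UndefinedEstimateError(ValueError):
    """A divergence estimate has no aligned sites to be computed from."""


def setup_logging(verbose: int = 0) -> None:
    """Route package logs to stderr. verbose: 0 = warnings, 1 = info, 2 = debug."""
    level = [logging.WARNING, logging.INFO, logging.DEBUG][min(verbose, 2)]
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """GC fraction over A/C/G/T bases (case-insensitive); N's ignored."""
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        raise ParameterError("sequence has no unambiguous bases")
    return (s.count("G") + s.count("C")) / acgt


def encode_seq(seq: str) -> np.ndarray:
    """2-bit encode (A,C,G,T)->(0..3); anything else -> 255."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, returned sorted and disjoint."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def count_overlapping(haystack: str, needle: str) -> int:
    """Occurrences of needle in haystack, overlaps allowed."""
    n = 0
    i = haystack.find(needle)
    while i != -1:
        n += 1
        i = haystack.find(needle, i + 1)
    return n
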