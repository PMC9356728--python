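"""Declarative configuration: every tunable threshold in one place.

Defaults reproduce the published workflow's stated values (satellite curation
cut-offs, the 90/80/75% mapping thresholds, the chloroplast read filter, the
>=99%/>=99% organelle scrub rule, the plant telomere motif, the 500-kb window,
and the rice LTR substitution rate used for the divergence-to-time axis).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from ._util import ParameterError


@dataclass(slots=True)
class CurationParams:
    """Satellite-DNA candidate curation thresholds."""

    min_copy_number: float = 50.0      # strict >
    min_monomer_length: int = 12       # bp, strict >
    microsatellite_max_subperiod: int = 6
    microsatellite_min_cover: float = 0.90
    size_group_tolerance: float = 0.20  # +/- fraction of monomer length
    merge_identity: float = 0.80
    map_thresholds: tuple[float, ...] = (0.90, 0.80, 0.75)

    def __post_init__(self) -> None:
        if not all(0.5 < t <= 1.0 for t in self.map_thresholds):
            raise ParameterError("map thresholds must lie in (0.5, 1.0]")
        if not 0.0 < self.merge_identity <= 1.0:
            raise ParameterError("merge_identity must lie in (0, 1]")


@dataclass(slots=True)
class DetectorParams:
    """Tandem-array detector settings (autocorrelation seeding)."""

    min_period: int = 5
    max_period: int = 1000
    min_copies: float = 3.0
    min_identity: float = 0.70

    def __post_init__(self) -> None:
        if not 1 <= self.min_period <= self.max_period <= 2000:
            raise ParameterError("need 1 <= min_period <= max_period <= 2000")


@dataclass(slots=True)
class AlignScoring:
    """Affine-gap global alignment scores."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ParameterError("gap penalties must be negative")
        if self.match <= self.mismatch:
            raise ParameterError("match score must exceed mismatch score")


@dataclass(slots=True)
class ClockParams:
    """Divergence-to-time calibration (substitutions/site/year)."""

    rate: float = 1.3e-8

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ParameterError("substitution rate must be positive")


@dataclass(slots=True)
class ReadFilterParams:
    """Organelle read selection: span, mapping quality, GC window."""

    min_mlen: int = 8000        # strict >
    min_qval: int = 40          # strict >
    gc_low: float = 0.32        # inclusive
    gc_high: float = 0.40       # inclusive

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_low <= self.gc_high <= 1.0:
            raise ParameterError("GC bounds must satisfy 0 <= low <= high <= 1")


@dataclass(slots=True)
class ScrubParams:
    """Organelle scaffold removal rule."""

    min_identity: float = 99.0   # percent, >=
    min_coverage: float = 0.99   # fraction of scaffold length, >=

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity <= 100.0:
            raise ParameterError("min_identity must lie in [0, 100]")
        if not 0.0 <= self.min_coverage <= 1.0:
            raise ParameterError("min_coverage must lie in [0, 1]")


@dataclass(slots=True)
class TelomereParams:
    """Telomere end-scan settings (plant motif by default)."""

    motif: str = "TTTAGGG"
    terminal_window: int = 10_000
    min_copies: int = 25
    max_mismatch_per_copy: int = 0

    def __post_init__(self) -> None:
        if len(self.motif) < 5:
            raise ParameterError("telomere motif must be >= 5 bp")
        if self.terminal_window < len(self.motif) * self.min_copies:
            raise ParameterError("terminal window too small for min_copies")


@dataclass(slots=True)
class AssignParams:
    """Windowed density tracks and triad labelling."""

    window: int = 500_000
    mapq_min: int = 20
    clarity_min: float = 2.0


@dataclass(slots=True)
class PipelineConfig:
    """Top-level configuration bundle with the published defaults."""

    curation: CurationParams = field(default_factory=CurationParams)
    detector: DetectorParams = field(default_factory=DetectorParams)
    scoring: AlignScoring = field(default_factory=AlignScoring)
    clock: ClockParams = field(default_factory=ClockParams)
    read_filter: ReadFilterParams = field(default_factory=ReadFilterParams)
    scrub: ScrubParams = field(default_factory=ScrubParams)
    telomere: TelomereParams = field(default_factory=TelomereParams)
    assign: AssignParams = field(default_factory=AssignParams)
    cpg_adjust: bool = True

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            sub = raw[f.name]
            if dataclasses.is_dataclass(f.type) or f.name != "cpg_adjust":
                factory = {
                    "curation": CurationParams, "detector": DetectorParams,
                    "scoring": AlignScoring, "clock": ClockParams,
                    "read_filter": ReadFilterParams, "scrub": ScrubParams,
                    "telomere": TelomereParams, "assign": AssignParams,
                }.get(f.name)
                if factory is not None:
                    if "map_thresholds" in (sub or {}):
                        sub["map_thresholds"] = tuple(sub["map_thresholds"])
                    kwargs[f.name] = factory(**sub)
                    continue
            kwargs[f.name] = sub
        return cls(**kwargs)
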