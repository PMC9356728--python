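"""Synthetic allopolyploid genome generator with complete truth tables.

Emulates, at desk scale, a three-sub-genome (B/C/D) assembly: planted LTR
retrotransposon copies at controlled divergence from a family consensus
(including a B-sub-genome expansion peaking at 7% divergence), tandem
satellite-DNA arrays, a B-diagnostic motif at contrasting densities,
telomeric arrays per an end plan, gene intervals, and long reads drawn from
one sub-genome's chromosomes (standing in for reads of the corresponding
diploid ancestor). Every planted feature is recorded in a TruthSet so each
downstream stage has a known-answer oracle.

All outputs are pure functions of (config, seed): two runs with the same
configuration produce byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from ._util import CapacityError, ParameterError, log, revcomp
from .io import write_bed, write_fasta, write_paf
from .records import GenomicInterval, PafRecord, SequenceRecord, TabularHit

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i

#: default B-diagnostic motif (an arbitrary fixed 24-mer; the real-world
#: analogue is a short repeat known to be overrepresented on B chromosomes)
DIAGNOSTIC_MOTIF = "CATTCGGTTAGAGCCTATCAAGTT"


# ------------------------------------------------------------- config types

@dataclass(slots=True)
class SubgenomeSpec:
    label: str
    n_chromosomes: int
    chromosome_length: int


@dataclass(slots=True)
class LtrFamilySpec:
    """One LTR retrotransposon family planted as diverged consensus clones."""

    name: str
    superfamily: str
    consensus_length: int
    copies_per_chromosome: dict[str, int]
    divergence_mean: dict[str, float]
    divergence_sd: dict[str, float]
    tstv_ratio: float = 2.0


@dataclass(slots=True)
class SatFamilySpec:
    """One satellite family planted as tandem arrays of a monomer."""

    name: str
    monomer_length: int
    arrays_per_chromosome: dict[str, int]
    copies_per_array: int
    within_array_identity: float = 0.95
    monomer: str | None = None  # fixed sequence; random when None


@dataclass(slots=True)
class DiagnosticMotifSpec:
    sequence: str = DIAGNOSTIC_MOTIF
    enriched_subgenome: str = "B"
    density_enriched_per_mb: float = 120.0
    density_background_per_mb: float = 5.0


@dataclass(slots=True)
class TelomereSpec:
    motif: str = "TTTAGGG"
    copies: int = 40
    #: end classes applied to chromosomes in generation order (cycled)
    end_plan: tuple[str, ...] = (
        "both", "both", "right", "left", "both", "none", "right", "both",
        "left",
    )


@dataclass(slots=True)
class ReadSimSpec:
    source_subgenome: str = "D"
    read_length: int = 8000
    n_reads: int = 600
    error_rate: float = 0.01


@dataclass(slots=True)
class SimConfig:
    seed: int
    subgenomes: list[SubgenomeSpec]
    ltr_families: list[LtrFamilySpec]
    sat_families: list[SatFamilySpec]
    diagnostic_motif: DiagnosticMotifSpec
    telomere: TelomereSpec
    gene_density_per_mb: float = 10.0
    gene_length: int = 2000
    read_sim: ReadSimSpec = field(default_factory=ReadSimSpec)


def default_sim_config(seed: int = 0) -> SimConfig:
    """The package's standard desk-scale study conditions.

    Three chromosomes per sub-genome with B > C > D chromosome lengths
    (600/500/400 kb); one Gypsy family expanded in B (30 copies/chromosome,
    divergence mean 0.07, sd 0.01) against 8 older copies in C and D; one
    Copia family at uniform moderate divergence; five satellite families
    with monomers 20-300 bp plus one AT microsatellite that the curation
    rules must reject; the diagnostic motif at 120/Mb on B vs 5/Mb
    elsewhere; telomeres on a mixed end plan; reads drawn from sub-genome D.
    """
    return SimConfig(
        seed=seed,
        subgenomes=[
            SubgenomeSpec("B", 3, 600_000),
            SubgenomeSpec("C", 3, 500_000),
            SubgenomeSpec("D", 3, 400_000),
        ],
        ltr_families=[
            LtrFamilySpec(
                name="gypsy1", superfamily="Gypsy", consensus_length=5000,
                copies_per_chromosome={"B": 30, "C": 8, "D": 8},
                divergence_mean={"B": 0.07, "C": 0.18, "D": 0.22},
                divergence_sd={"B": 0.01, "C": 0.04, "D": 0.04},
            ),
            LtrFamilySpec(
                name="copia1", superfamily="Copia", consensus_length=4500,
                copies_per_chromosome={"B": 5, "C": 5, "D": 5},
                divergence_mean={"B": 0.12, "C": 0.12, "D": 0.12},
                divergence_sd={"B": 0.03, "C": 0.03, "D": 0.03},
            ),
        ],
        sat_families=[
            SatFamilySpec("satA", 20, {"B": 1, "C": 1, "D": 1}, 60),
            SatFamilySpec("satB", 57, {"B": 1, "C": 1, "D": 1}, 40),
            SatFamilySpec("satC", 118, {"B": 1, "C": 1, "D": 1}, 30),
            SatFamilySpec("satD", 170, {"B": 2, "C": 1, "D": 0}, 30),
            SatFamilySpec("satE", 300, {"B": 1, "C": 0, "D": 1}, 20),
            SatFamilySpec("msatAT", 2, {"B": 1, "C": 1, "D": 1}, 300,
                          within_array_identity=1.0, monomer="AT"),
        ],
        diagnostic_motif=DiagnosticMotifSpec(),
        telomere=TelomereSpec(),
        gene_density_per_mb=10.0,
        read_sim=ReadSimSpec(),
    )


# --------------------------------------------------------------- truth set

@dataclass(slots=True)
class PlantedInsertion:
    location: GenomicInterval
    family: str
    superfamily: str
    applied_divergence: float
    realized_transitions: int
    realized_transversions: int


@dataclass(slots=True)
class PlantedArray:
    location: GenomicInterval
    family: str
    copy_count: int


@dataclass(slots=True)
class TruthSet:
    """Complete ledger of planted features; the downstream acceptance oracle."""

    insertions: list[PlantedInsertion] = field(default_factory=list)
    sat_arrays: list[PlantedArray] = field(default_factory=list)
    diagnostic_hits: list[GenomicInterval] = field(default_factory=list)
    telomere_ends: dict[str, str] = field(default_factory=dict)
    subgenome_of: dict[str, str] = field(default_factory=dict)
    triads: list[tuple[str, str, str]] = field(default_factory=list)
    genes: list[GenomicInterval] = field(default_factory=list)
    read_truth: list[PafRecord] = field(default_factory=list)
    consensi: dict[str, str] = field(default_factory=dict)
    superfamily_of: dict[str, str] = field(default_factory=dict)
    chromosome_lengths: dict[str, int] = field(default_factory=dict)

    def subgenome_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for chrom, label in self.subgenome_of.items():
            sizes[label] = sizes.get(label, 0) + self.chromosome_lengths[chrom]
        return sizes

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        write_bed(
            [
                GenomicInterval(
                    i.location.seq_id, i.location.start, i.location.end,
                    name=f"{i.family};{i.superfamily};"
                         f"{i.applied_divergence:.4f}",
                )
                for i in self.insertions
            ],
            os.path.join(outdir, "truth_insertions.bed"),
        )
        write_bed(
            [
                GenomicInterval(a.location.seq_id, a.location.start,
                                a.location.end,
                                name=f"{a.family};copies={a.copy_count}")
                for a in self.sat_arrays
            ],
            os.path.join(outdir, "truth_sat_arrays.bed"),
        )
        write_bed(self.diagnostic_hits,
                  os.path.join(outdir, "truth_diagnostic.bed"))
        with open(os.path.join(outdir, "truth_telomeres.tsv"), "w") as fh:
            fh.write("chromosome\tend_class\n")
            for chrom in sorted(self.telomere_ends):
                fh.write(f"{chrom}\t{self.telomere_ends[chrom]}\n")
        with open(os.path.join(outdir, "truth_subgenomes.tsv"), "w") as fh:
            fh.write("chromosome\tsubgenome\n")
            for chrom in sorted(self.subgenome_of):
                fh.write(f"{chrom}\t{self.subgenome_of[chrom]}\n")
        with open(os.path.join(outdir, "triads.tsv"), "w") as fh:
            fh.write("triad_id\tchrom1\tchrom2\tchrom3\n")
            for i, triad in enumerate(self.triads, 1):
                fh.write(f"triad{i}\t" + "\t".join(sorted(triad)) + "\n")
        with open(os.path.join(outdir, "truth_genes.gff3"), "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                fh.write(
                    f"{g.seq_id}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t+\t."
                    f"\tID={g.name}\n"
                )
        write_fasta(
            [SequenceRecord(name, seq) for name, seq in self.consensi.items()],
            os.path.join(outdir, "truth_consensi.fasta"),
        )
        if self.read_truth:
            write_paf(self.read_truth, os.path.join(outdir, "reads_truth.paf"))


# -------------------------------------------------------------- primitives

def _random_seq(n: int, rng: np.random.Generator) -> str:
    return _DECODE[rng.integers(0, 4, n)].tobytes().decode("ascii")


def _mutate_array(arr: np.ndarray, divergence: float, tstv_ratio: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, int, int]:
    """Per-site independent substitution of a 2-bit-coded sequence.

    Each site mutates with probability ``divergence``; a mutating site takes
    its transition partner with probability tstv/(tstv+1), otherwise one of
    its two transversion partners uniformly. Base coding: A=0, C=1, G=2, T=3,
    so the transition partner is ``base ^ 2`` and the transversion partners
    share the opposite purine/pyrimidine parity bit.
    """
    n = len(arr)
    hit = np.nonzero(rng.random(n) < divergence)[0]
    if len(hit) == 0:
        return arr.copy(), 0, 0
    is_ts = rng.random(len(hit)) < tstv_ratio / (tstv_ratio + 1.0)
    ts_new = arr[hit] ^ 2
    tv_new = ((arr[hit] & 1) ^ 1) + 2 * rng.integers(0, 2, len(hit)).astype(
        np.uint8)
    out = arr.copy()
    out[hit] = np.where(is_ts, ts_new, tv_new.astype(arr.dtype))
    n_ts = int(is_ts.sum())
    return out, n_ts, len(hit) - n_ts


def mutate_sequence(seq: str, target_divergence: float, tstv_ratio: float,
                    seed: int) -> tuple[str, int, int]:
    """Mutate an uppercase ACGT sequence under the per-site model.

    Returns (mutated sequence, realized transitions, realized transversions).
    Deterministic for a fixed seed.
    """
    if not 0.0 <= target_divergence < 0.6:
        raise ParameterError("target_divergence must lie in [0, 0.6)")
    if not seq:
        raise ParameterError("sequence must be non-empty")
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr > 3).any():
        raise ParameterError("sequence must be uppercase ACGT")
    rng = np.random.default_rng(seed)
    out, n_ts, n_tv = _mutate_array(arr, target_divergence, tstv_ratio, rng)
    return _DECODE[out].tobytes().decode("ascii"), n_ts, n_tv


# ------------------------------------------------------------ build_genome

def _chromosome_plan(config: SimConfig,
                     rng: np.random.Generator) -> list[tuple[str, str, int]]:
    """Name chromosomes neutrally and assign sub-genome labels per triad.

    Returns (name, label, length) in generation order. When all sub-genomes
    have the same chromosome count, chromosomes chr{t}a/b/c form triad t with
    labels shuffled across the suffixes so names never encode the answer.
    """
    counts = {s.n_chromosomes for s in config.subgenomes}
    if len(counts) != 1:
        raise ParameterError(
            "triads require equal chromosome counts across sub-genomes")
    n_triads = counts.pop()
    by_label = {s.label: s for s in config.subgenomes}
    plan = []
    for t in range(1, n_triads + 1):
        labels = [s.label for s in config.subgenomes]
        order = rng.permutation(len(labels))
        for suffix, k in zip("abc", order):
            label = labels[k]
            plan.append(
                (f"chr{t}{suffix}", label, by_label[label].chromosome_length))
    return plan


def build_genome(config: SimConfig) -> tuple[list[SequenceRecord], TruthSet]:
    """Build the synthetic assembly and its truth ledger.

    Planted features never overlap; the generator raises CapacityError
    before emitting anything if a chromosome cannot host its plan.
    """
    rng = np.random.default_rng(config.seed)
    truth = TruthSet()

    for fam in config.ltr_families:
        truth.consensi[fam.name] = _random_seq(fam.consensus_length, rng)
        truth.superfamily_of[fam.name] = fam.superfamily
    monomers: dict[str, str] = {}
    for sat in config.sat_families:
        monomers[sat.name] = (
            sat.monomer if sat.monomer is not None
            else _random_seq(sat.monomer_length, rng)
        )
        truth.consensi[sat.name] = monomers[sat.name]
        truth.superfamily_of[sat.name] = "Satellite"

    plan = _chromosome_plan(config, rng)
    motif = config.diagnostic_motif
    tel = config.telomere

    records: list[SequenceRecord] = []
    for chrom_index, (name, label, length) in enumerate(plan):
        truth.subgenome_of[name] = label
        truth.chromosome_lengths[name] = length
        mb = length / 1e6

        # ---- collect feature sequences with their truth metadata
        features: list[tuple[str, str, str, object]] = []
        for fam in config.ltr_families:
            n_copies = fam.copies_per_chromosome.get(label, 0)
            mean = fam.divergence_mean.get(label, 0.0)
            sd = fam.divergence_sd.get(label, 0.0)
            cons = _ENCODE[np.frombuffer(
                truth.consensi[fam.name].encode(), dtype=np.uint8)]
            for _ in range(n_copies):
                d = float(np.clip(rng.normal(mean, sd), 0.0, 0.59))
                arr, n_ts, n_tv = _mutate_array(cons, d, fam.tstv_ratio, rng)
                features.append(
                    (_DECODE[arr].tobytes().decode(), "ltr", fam.name,
                     (fam.superfamily, d, n_ts, n_tv))
                )
        for sat in config.sat_families:
            n_arrays = sat.arrays_per_chromosome.get(label, 0)
            mono = _ENCODE[np.frombuffer(monomers[sat.name].encode(),
                                         dtype=np.uint8)]
            per_copy_div = 1.0 - sat.within_array_identity
            for _ in range(n_arrays):
                parts = []
                for _c in range(sat.copies_per_array):
                    arr, _, _ = _mutate_array(mono, per_copy_div, 2.0, rng)
                    parts.append(_DECODE[arr].tobytes().decode())
                features.append(("".join(parts), "sat", sat.name,
                                 sat.copies_per_array))
        density = (motif.density_enriched_per_mb
                   if label == motif.enriched_subgenome
                   else motif.density_background_per_mb)
        for _ in range(int(round(density * mb))):
            features.append((motif.sequence, "diag", "diagnostic", None))
        for g in range(int(round(config.gene_density_per_mb * mb))):
            features.append((_random_seq(config.gene_length, rng), "gene",
                             f"{name}_g{g + 1}", None))

        # ---- telomeres per end plan
        end_class = tel.end_plan[chrom_index % len(tel.end_plan)]
        truth.telomere_ends[name] = end_class
        left_tel = (revcomp(tel.motif) * tel.copies
                    if end_class in ("both", "left") else "")
        right_tel = (tel.motif * tel.copies
                     if end_class in ("both", "right") else "")

        planted_bp = (len(left_tel) + len(right_tel)
                      + sum(len(f[0]) for f in features))
        if planted_bp > length:
            raise CapacityError(
                f"{name}: planted features span {planted_bp} bp but the "
                f"chromosome is only {length} bp"
            )

        # ---- lay out: [left telomere] gap f1 gap f2 ... gap [right telomere]
        order = rng.permutation(len(features))
        features = [features[k] for k in order]
        background = length - planted_bp
        gaps = rng.multinomial(
            background, np.full(len(features) + 1, 1.0 / (len(features) + 1)))
        chunks = [left_tel]
        pos = len(left_tel)
        for gap_len, feat in zip(gaps, features + [None]):
            chunks.append(_random_seq(int(gap_len), rng))
            pos += int(gap_len)
            if feat is None:
                break
            seq_text, kind, fam_name, meta = feat
            iv = GenomicInterval(name, pos, pos + len(seq_text),
                                 name=fam_name)
            if kind == "ltr":
                superfamily, d, n_ts, n_tv = meta
                truth.insertions.append(
                    PlantedInsertion(iv, fam_name, superfamily, d, n_ts,
                                     n_tv))
            elif kind == "sat":
                truth.sat_arrays.append(PlantedArray(iv, fam_name, meta))
            elif kind == "diag":
                truth.diagnostic_hits.append(iv)
            elif kind == "gene":
                truth.genes.append(iv)
            chunks.append(seq_text)
            pos += len(seq_text)
        chunks.append(right_tel)
        seq = "".join(chunks)
        assert len(seq) == length
        records.append(SequenceRecord(name, seq))

    n_triads = len(plan) // len(config.subgenomes)
    for t in range(1, n_triads + 1):
        triad = tuple(f"chr{t}{s}" for s in "abc")
        truth.triads.append(triad)
    log.info("build_genome: %d chromosomes, %d insertions, %d sat arrays",
             len(records), len(truth.insertions), len(truth.sat_arrays))
    return records, truth


# --------------------------------------------------------------- read sim

def simulate_diploid_reads(
    assembly: list[SequenceRecord], truth: TruthSet, config: SimConfig,
) -> tuple[list[SequenceRecord], list[PafRecord]]:
    """Draw error-bearing reads from one sub-genome's chromosomes.

    The generator itself emits the PAF an aligner would produce (mapping
    quality 60, primary), with each read's true placement — error reads keep
    their truth coordinates, so no external mapper is involved.
    """
    sim = config.read_sim
    sources = [r for r in assembly
               if truth.subgenome_of.get(r.id) == sim.source_subgenome]
    if not sources:
        raise ParameterError(
            f"no chromosomes labelled {sim.source_subgenome!r} to read from")
    if any(len(r) < sim.read_length for r in sources):
        raise ParameterError("read_length exceeds a source chromosome length")
    rng = np.random.default_rng([config.seed, 7])
    reads: list[SequenceRecord] = []
    paf: list[PafRecord] = []
    for i in range(sim.n_reads):
        src = sources[int(rng.integers(0, len(sources)))]
        start = int(rng.integers(0, len(src) - sim.read_length + 1))
        raw = src.residues[start:start + sim.read_length].upper()
        arr = _ENCODE[np.frombuffer(raw.encode(), dtype=np.uint8)]
        mutated, n_ts, n_tv = _mutate_array(arr, sim.error_rate, 1.0, rng)
        read_id = f"read{i:05d}"
        reads.append(SequenceRecord(
            read_id, _DECODE[mutated].tobytes().decode()))
        paf.append(PafRecord(
            query_id=read_id, query_length=sim.read_length, query_start=0,
            query_end=sim.read_length, strand="+", target_id=src.id,
            target_length=len(src), target_start=start,
            target_end=start + sim.read_length,
            residue_matches=sim.read_length - n_ts - n_tv,
            block_length=sim.read_length, mapping_quality=60,
            is_primary=True,
        ))
    truth.read_truth = paf
    return reads, paf


# -------------------------------------------------------- organelle fixture

@dataclass(slots=True)
class OrganelleFixture:
    """Boundary-straddling fixture for the organelle read/scaffold filters."""

    chloroplast: SequenceRecord
    reads_paf: list[PafRecord]
    read_gc: dict[str, float]
    hits: list[TabularHit]
    scaffold_lengths: dict[str, int]
    expected_pass_reads: int
    expected_pass_ids: set[str]
    expected_removed_scaffolds: int
    expected_removed_ids: set[str]


def make_organelle_fixture(seed: int = 0) -> OrganelleFixture:
    """Emit reads and scaffold hits that straddle every filter boundary.

    Read grid: aligned query span (mlen) 7999/8000/8001/9000 x mapping
    quality 40/41/60 x GC 31.9/32.0/35.0/40.0/40.1%. Scaffold cases bracket
    the >=99% identity and >=99% coverage rules, including a merged-interval
    case. Expected pass/removal sets are computed here by direct predicate
    evaluation, independently of the QC module.
    """
    rng = np.random.default_rng(seed)
    chloro_len = 150_000
    chloroplast = SequenceRecord("chloroplast_synthetic",
                                 _random_seq(20_000, rng))

    reads_paf: list[PafRecord] = []
    read_gc: dict[str, float] = {}
    expected_pass_ids: set[str] = set()
    i = 0
    for mlen in (7999, 8000, 8001, 9000):
        for qval in (40, 41, 60):
            for gc in (0.319, 0.320, 0.350, 0.400, 0.401):
                rid = f"cpread{i:03d}"
                i += 1
                reads_paf.append(PafRecord(
                    query_id=rid, query_length=mlen + 100, query_start=50,
                    query_end=50 + mlen, strand="+",
                    target_id=chloroplast.id, target_length=len(chloroplast),
                    target_start=0, target_end=min(mlen, len(chloroplast)),
                    residue_matches=mlen - 20, block_length=mlen,
                    mapping_quality=qval, is_primary=True,
                ))
                read_gc[rid] = gc
                # brute-force predicate (the oracle): strict spans, closed GC
                if mlen > 8000 and qval > 40 and 0.32 <= gc <= 0.40:
                    expected_pass_ids.add(rid)

    # scaffold cases: (id, [(start0, end0, identity_pct), ...])
    cases = {
        "scf_cov_pass": [(0, 149_000, 99.5)],
        "scf_cov_fail": [(0, 148_000, 99.5)],
        "scf_merged": [(0, 100_000, 99.2), (50_000, 149_500, 99.2)],
        "scf_ident_fail": [(0, 150_000, 98.9)],
        "scf_boundary": [(0, 148_500, 99.0)],
        "scf_cov_edge_fail": [(0, 148_499, 99.0)],
    }
    scaffold_lengths = {sid: chloro_len for sid in cases}
    hits: list[TabularHit] = []
    expected_removed_ids: set[str] = set()
    for sid, spans in cases.items():
        for s0, e0, ident in spans:
            span = e0 - s0
            hits.append(TabularHit(
                query_id=sid, subject_id=chloroplast.id,
                percent_identity=ident, alignment_length=span,
                mismatches=int(span * (100 - ident) / 100), gap_opens=0,
                query_start=s0 + 1, query_end=e0, subject_start=1,
                subject_end=span, evalue=0.0, bitscore=2.0 * span / 1000,
            ))
        # brute-force merged-interval coverage + weighted identity (oracle)
        spans_sorted = sorted((s, e) for s, e, _ in spans)
        merged = []
        for s, e in spans_sorted:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        cov = sum(e - s for s, e in merged) / chloro_len
        wsum = sum((e - s) * ident for s, e, ident in spans)
        wident = wsum / sum(e - s for s, e, _ in spans)
        if wident >= 99.0 and cov >= 0.99:
            expected_removed_ids.add(sid)

    return OrganelleFixture(
        chloroplast=chloroplast, reads_paf=reads_paf, read_gc=read_gc,
        hits=hits, scaffold_lengths=scaffold_lengths,
        expected_pass_reads=len(expected_pass_ids),
        expected_pass_ids=expected_pass_ids,
        expected_removed_scaffolds=len(expected_removed_ids),
        expected_removed_ids=expected_removed_ids,
    )
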