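"""End-to-end pipeline on a synthetic study: simulate, discover satellites,
build divergence landscapes, assign sub-genomes, and run assembly QC.

Every stage writes deterministic TSV/BED/FASTA outputs under the chosen
directory; two runs with the same configuration and seed produce
byte-identical text files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from . import assign as assign_mod
from . import landscape as landscape_mod
from . import qc as qc_mod
from . import satdna as satdna_mod
from ._util import log
from .config import PipelineConfig
from .io import write_bed, write_fasta, write_paf
from .records import GenomicInterval, SatFamily, SequenceRecord
from .simulate import (
    OrganelleFixture,
    SimConfig,
    TruthSet,
    build_genome,
    default_sim_config,
    make_organelle_fixture,
    simulate_diploid_reads,
)


@dataclass(slots=True)
class PipelineResult:
    assembly: list[SequenceRecord]
    truth: TruthSet
    families: list[SatFamily]
    family_maps: dict[float, list[GenomicInterval]]
    landscape: landscape_mod.LandscapeTable
    assignments: list[assign_mod.TriadAssignment]
    assignment_accuracy: float
    telomeres: qc_mod.TelomereSummary
    stats: qc_mod.AssemblyStats
    masked: dict[str, tuple[float, int]]
    organelle: OrganelleFixture
    organelle_pass: list[str]
    organelle_removed: list[str]
    pairs: list = field(default_factory=list)
    diag_scores: list[assign_mod.ChromosomeScore] = field(default_factory=list)
    read_scores: list[assign_mod.ChromosomeScore] = field(default_factory=list)


def scan_motif(assembly: list[SequenceRecord],
               motif: str) -> list[GenomicInterval]:
    """Exact occurrences of a motif (either strand) across the assembly."""
    from ._util import revcomp

    out = []
    for rec in assembly:
        seq = rec.residues.upper()
        for needle, strand in ((motif.upper(), "+"),
                               (revcomp(motif.upper()), "-")):
            i = seq.find(needle)
            while i != -1:
                out.append(GenomicInterval(rec.id, i, i + len(needle),
                                           name="diagnostic", strand=strand))
                i = seq.find(needle, i + 1)
    out.sort(key=lambda iv: (iv.seq_id, iv.start, iv.strand))
    return out


def _mask_by_annotation(assembly: list[SequenceRecord],
                        intervals: list[tuple[str, int, int]],
                        ) -> list[SequenceRecord]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    out = []
    for rec in assembly:
        if rec.id not in by_chrom:
            out.append(SequenceRecord(rec.id, rec.residues))
            continue
        residues = list(rec.residues.upper())
        from ._util import merge_intervals

        for s, e in merge_intervals(by_chrom[rec.id]):
            residues[s:e] = "".join(residues[s:e]).lower()
        out.append(SequenceRecord(rec.id, "".join(residues)))
    return out


def run_pipeline(
    sim_config: SimConfig | None = None,
    config: PipelineConfig | None = None,
    outdir: str | os.PathLike | None = None,
    seed: int | None = None,
    plot: bool = False,
) -> PipelineResult:
    """Run every stage on a synthetic genome and (optionally) write outputs."""
    config = config or PipelineConfig()
    if sim_config is None:
        sim_config = default_sim_config(seed if seed is not None else 0)

    # ---- simulate
    assembly, truth = build_genome(sim_config)
    reads, reads_paf = simulate_diploid_reads(assembly, truth, sim_config)
    organelle = make_organelle_fixture(sim_config.seed)

    # ---- satellite discovery
    arrays = satdna_mod.detect_all(assembly, config.detector)
    candidates, rejected = satdna_mod.curate_candidates(
        arrays, config.curation)
    known = [SequenceRecord(name, truth.consensi[name])
             for name in truth.consensi
             if truth.superfamily_of.get(name) == "Satellite"]
    families = satdna_mod.merge_families(candidates, config.curation,
                                         known_library=known)
    family_maps = satdna_mod.map_families(
        assembly, families, config.curation.map_thresholds)

    # ---- divergence landscape (copies from the repeat-annotation track)
    annotations = [
        (ins.location, ins.family, ins.superfamily)
        for ins in truth.insertions
    ]
    assembly_by_id = {r.id: r.residues for r in assembly}
    pairs = landscape_mod.pairs_from_annotations(
        assembly_by_id, annotations, truth.consensi, truth.subgenome_of,
        scoring=config.scoring)
    # The simulator's substitution model is CpG-neutral, so the matched
    # estimator here is plain K2P; the CpG adjustment (the default on real
    # annotations, config.cpg_adjust) corrects a hypermutability bias the
    # generator does not model and would deflate divergence by ~7%.
    land = landscape_mod.build_landscape(
        pairs, truth.subgenome_sizes(), cpg_adjust=False)

    # ---- sub-genome assignment
    windows = assign_mod.make_windows(truth.chromosome_lengths,
                                      config.assign.window)
    diag_hits = scan_motif(assembly, sim_config.diagnostic_motif.sequence)
    diag_track = assign_mod.density_track(windows, diag_hits,
                                          "diagnostic_repeat")
    read_track = assign_mod.density_track(windows, reads_paf, "diploid_reads",
                                          mapq_min=config.assign.mapq_min)
    diag_scores = assign_mod.chromosome_signal_score(
        diag_track, truth.chromosome_lengths)
    read_scores = assign_mod.chromosome_signal_score(
        read_track, truth.chromosome_lengths)
    assignments = assign_mod.assign_triads(
        truth.triads, diag_scores, read_scores, config.assign.clarity_min)
    n_correct = sum(
        lab == truth.subgenome_of[chrom]
        for a in assignments for chrom, lab in a.labels.items())
    accuracy = n_correct / (3 * len(assignments)) if assignments else 0.0

    # ---- assembly QC
    telomeres = qc_mod.scan_telomeres(assembly, config.telomere)
    stats = qc_mod.nx_stats([len(r) for r in assembly])
    repeat_intervals = (
        [(i.location.seq_id, i.location.start, i.location.end)
         for i in truth.insertions]
        + [(a.location.seq_id, a.location.start, a.location.end)
           for a in truth.sat_arrays]
        + [(iv.seq_id, iv.start, iv.end) for iv in truth.diagnostic_hits]
    )
    tel_len = len(sim_config.telomere.motif) * sim_config.telomere.copies
    for chrom, cls in truth.telomere_ends.items():
        L = truth.chromosome_lengths[chrom]
        if cls in ("both", "left"):
            repeat_intervals.append((chrom, 0, tel_len))
        if cls in ("both", "right"):
            repeat_intervals.append((chrom, L - tel_len, L))
    masked_assembly = _mask_by_annotation(assembly, repeat_intervals)
    masked = qc_mod.masked_fraction(masked_assembly, truth.subgenome_of)
    organelle_pass, _ = qc_mod.filter_chloroplast_reads(
        organelle.reads_paf, config.read_filter, read_gc=organelle.read_gc)
    organelle_removed, scrub_reports = qc_mod.scrub_organelle_scaffolds(
        organelle.hits, organelle.scaffold_lengths, config.scrub)

    result = PipelineResult(
        assembly=assembly, truth=truth, families=families,
        family_maps=family_maps, landscape=land, assignments=assignments,
        assignment_accuracy=accuracy, telomeres=telomeres, stats=stats,
        masked=masked, organelle=organelle, organelle_pass=organelle_pass,
        organelle_removed=organelle_removed, diag_scores=diag_scores,
        read_scores=read_scores, pairs=pairs,
    )
    if outdir is not None:
        _write_outputs(result, reads, reads_paf, diag_hits, scrub_reports,
                       outdir, config, plot)
    return result


def _write_outputs(res: PipelineResult, reads, reads_paf, diag_hits,
                   scrub_reports, outdir, config: PipelineConfig,
                   plot: bool) -> None:
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    write_fasta(res.assembly, os.path.join(outdir, "assembly.fasta"))
    write_fasta(reads, os.path.join(outdir, "reads.fasta"))
    write_paf(reads_paf, os.path.join(outdir, "reads.paf"))
    res.truth.write(os.path.join(outdir, "truth"))

    satdir = os.path.join(outdir, "satdna")
    os.makedirs(satdir, exist_ok=True)
    write_fasta(
        [SequenceRecord(f.id, f.consensus) for f in res.families],
        os.path.join(satdir, "families.fasta"))
    with open(os.path.join(satdir, "summary.tsv"), "w") as fh:
        fh.write("family\tmonomer_length\ttotal_copy_number\ttotal_bp"
                 "\tnovel\n")
        for f in res.families:
            fh.write(f"{f.id}\t{f.monomer_length}\t{f.total_copy_number:g}"
                     f"\t{f.total_bp}\t{f.novel}\n")
    for t, intervals in sorted(res.family_maps.items()):
        write_bed(intervals,
                  os.path.join(satdir, f"map_{int(round(t * 100))}.bed"))

    landdir = os.path.join(outdir, "landscape")
    os.makedirs(landdir, exist_ok=True)
    res.landscape.table.to_csv(
        os.path.join(landdir, "landscape.tsv"), sep="\t", index=False)
    if plot and not res.landscape.table.empty:
        landscape_mod.plot_landscape(
            res.landscape, os.path.join(landdir, "landscape.png"),
            config.clock)

    adir = os.path.join(outdir, "assign")
    os.makedirs(adir, exist_ok=True)
    write_bed(diag_hits, os.path.join(adir, "diagnostic_hits.bed"))
    with open(os.path.join(adir, "scores.tsv"), "w") as fh:
        fh.write("chromosome\tsignal\tdensity_per_mb\tenrichment\n")
        for s in res.diag_scores + res.read_scores:
            fh.write(f"{s.chromosome}\t{s.signal}\t{s.density:.6g}"
                     f"\t{s.enrichment:.6g}\n")
    with open(os.path.join(adir, "assignments.tsv"), "w") as fh:
        fh.write("triad_id\tchromosome\tlabel\tb_clarity\td_clarity"
                 "\tambiguous\n")
        for a in res.assignments:
            for chrom in sorted(a.labels):
                fh.write(f"{a.triad_id}\t{chrom}\t{a.labels[chrom]}"
                         f"\t{a.b_clarity:.4g}\t{a.d_clarity:.4g}"
                         f"\t{a.ambiguous}\n")
    summary = assign_mod.assignment_summary(
        res.assignments, res.truth.chromosome_lengths)
    with open(os.path.join(adir, "summary.tsv"), "w") as fh:
        fh.write("label\tn_chromosomes\ttotal_bp\tfraction\n")
        for label, row in summary.items():
            fh.write(f"{label}\t{len(row['chromosomes'])}\t{row['total_bp']}"
                     f"\t{row['fraction']:.6f}\n")

    qdir = os.path.join(outdir, "qc")
    os.makedirs(qdir, exist_ok=True)
    with open(os.path.join(qdir, "telomeres.tsv"), "w") as fh:
        fh.write("chromosome\tleft_copies\tright_copies\tclass\n")
        for s in res.telomeres.scans:
            fh.write(f"{s.chromosome}\t{s.left_copies}\t{s.right_copies}"
                     f"\t{s.classification}\n")
    with open(os.path.join(qdir, "stats.tsv"), "w") as fh:
        fh.write("total_bp\tn_sequences\tN50\tL50\n")
        fh.write(f"{res.stats.total_bp}\t{res.stats.n_sequences}"
                 f"\t{res.stats.n50}\t{res.stats.l50}\n")
    with open(os.path.join(qdir, "masked.tsv"), "w") as fh:
        fh.write("subgenome\tmasked_fraction\tnonrepetitive_bp\n")
        for label, (frac, bp) in sorted(res.masked.items()):
            fh.write(f"{label}\t{frac:.6f}\t{bp}\n")
    with open(os.path.join(qdir, "organelle.tsv"), "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"reads_pass\t{len(res.organelle_pass)}\n")
        fh.write(f"reads_expected_pass\t{res.organelle.expected_pass_reads}\n")
        fh.write(f"scaffolds_removed\t{len(res.organelle_removed)}\n")
        fh.write("scaffolds_expected_removed"
                 f"\t{res.organelle.expected_removed_scaffolds}\n")
    with open(os.path.join(qdir, "scrub_report.tsv"), "w") as fh:
        fh.write("scaffold\tidentity\tcoverage\tremoved\n")
        for r in scrub_reports:
            fh.write(f"{r.scaffold_id}\t{r.identity:.4f}\t{r.coverage:.6f}"
                     f"\t{r.removed}\n")
    log.info("pipeline outputs written to %s", outdir)
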