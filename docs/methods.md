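# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations behind `repeatscape`.

## Coordinate and masking conventions

All in-memory coordinates are 0-based half-open (BED semantics). Formats
that are 1-based inclusive on disk — TRF `.dat` arrays and 12-column
tabular hits — are converted at parse time and nowhere else. Soft-masking
(lowercase) is the sole repeat-mask representation; hard-masked `N` input
is accepted but `N` bases count as neither repeat nor non-repeat in any
fraction.

## Synthetic study design

The generator emulates the repeat architecture of a BCD allohexaploid at
desk scale. Defaults (`default_sim_config`):

| feature | default | rationale |
|---|---|---|
| chromosomes | 3 per sub-genome; 600/500/400 kb for B/C/D | preserves the B > C > D sub-genome size ordering driven by repeat expansion, at minutes-scale runtime |
| Gypsy family | 5-kb consensus; 30 copies/chromosome in B at divergence mean 0.07 (sd 0.01); 8 copies in C (0.18 ± 0.04) and D (0.22 ± 0.04) | a scaled analogue of a recent B-specific expansion against older C/D complements |
| Copia family | 4.5-kb consensus, 5 copies everywhere at 0.12 ± 0.03 | background LTR fraction |
| satellites | five families, monomers 20/57/118/170/300 bp, 20–60 copies per array, within-array identity 0.95 | spans the short-to-long monomer range with totals safely above the copy-number filter |
| microsatellite | (AT)n arrays, 300 copies | must be rejected by curation, not recovered |
| diagnostic motif | fixed 24-mer at 120/Mb on B vs 5/Mb elsewhere | makes "clear overrepresentation" a measurable ~20x density contrast; shrinking it exercises the ambiguity flag |
| telomeres | (TTTAGGG)x40 per planted end; mixed end plan (both/left/right/none) | exercises all four end classes |
| reads | 600 x 8 kb from sub-genome D chromosomes, 1% error | the diploid-ancestor read signal for D assignment |

The substitution model is per-site independent substitution with a fixed
transition bias (default transition:transversion = 2): a site mutates with
probability equal to the target divergence; a mutating site takes its
transition partner with probability tstv/(tstv+1). There are no indels in
planted copies by default, which keeps parameter recovery exact: the
divergence realized in a copy equals its Hamming distance to the
consensus, and the truth ledger stores the realized transition and
transversion counts per copy. The generator also emits the read-placement
PAF itself (error reads keep truth coordinates), so no external aligner
participates in the study.

What the generator does not model: long-read error profiles, indels,
nested or truncated insertions, structural variation, higher-order repeat
structure, CpG hypermutability (see below), and sequence divergence
between a diploid ancestor and the derived sub-genome (reads are drawn
from the assembly itself). Passing tests therefore demonstrate correctness
of the computations under a clean substitution-only model, not robustness
to every artefact of real long-read assemblies.

## Satellite discovery

Detection scores each position/period pair by autocorrelation: for lag
`p`, the score is the fraction of matching offsets over a `2p` window.
Positions reaching the identity floor (default 0.70) seed arrays;
near-tied harmonics resolve to the smallest period (a longer period must
beat the incumbent by > 0.02), and seeds are processed best-score-first so
that an in-array seed at the true period outranks a flanking seed whose
long window merely overlaps the array. Arrays grow in whole-monomer steps
against a running majority-vote consensus and must reach 3 copies.
Detection never seeds in soft-masked sequence, so pre-masking known
satellites (`mask_known`) excludes them from rediscovery.

Curation follows the classical thresholds read strictly: total copy
number > 50 (summed genome-wide per pooled canonical monomer — the
per-array alternative is one config switch away), monomer length > 12 bp,
and a microsatellite exclusion operationalized as an internal sub-period
≤ 6 bp (mono- through hexanucleotide) explaining ≥ 90% of consensus
positions under cyclic comparison. "Similar sizes" for merging means
monomer lengths within ±20%; within a size group, candidates merge
transitively at ≥ 80% cyclic identity (the midpoint of the mapping
thresholds; configurable). Cyclic identity aligns the shorter monomer
against the doubled longer one on both strands (edlib infix alignment),
so rotation and strand never split a family. Genome mapping scores each
monomer-length window once and applies the 90/80/75% thresholds to the
same scores, which makes the hit covers nested by construction; an exact
8-mer prefilter keeps the scan near-linear.

## Divergence landscapes

Copies are globally aligned to consensi with affine gap scoring
(match +2, mismatch −3, gap open −5, gap extend −2; a gap of length L
costs open + L·extend). Ties in the dynamic program are broken
deterministically. Columns with a gap or an ambiguity character in either
row are excluded from the site count; a pair with no usable columns is an
error, and estimates with 1−2P−Q ≤ 0 or 1−2Q ≤ 0 are flagged saturated and
excluded from landscapes (not clamped, which would pile artefacts into the
last bin).

The CpG adjustment mirrors the conventional behaviour of repeat-annotation
divergence tooling: at consensus CpG dinucleotides (C followed by G among
consecutive consensus positions; copy-row gaps do not break adjacency), a
single transition counts 1/10 and a double transition counts 1 in total;
transversions are never reweighted. The rule is a documented convention
for reproducibility, not a mechanistic mutation model.

Landscape bins are [i, i+1) percent of K, weighted by aligned copy bp
(unambiguous copy bases in columns whose consensus is not N) and divided
by the sub-genome assembly size — consistent with expressing abundance as
"aligned nucleotides over assembly nucleotides". The time axis is
t = K/(2r), r = 1.3 × 10⁻⁸ substitutions/site/year by default.

**Estimator/model matching.** The synthetic pipeline computes its
landscape with the CpG adjustment off: the generator's substitution model
is CpG-neutral, so plain K2P is the matched estimator, and applying the
adjustment to CpG-neutral data would deflate divergence by ~7% (shifting
a planted 7% peak into bin 6). On real annotations the adjustment is the
default, because real plant CpG sites are hypermutable. The adjustment
itself is validated against hand-derived cases and a brute-force recount.

## Sub-genome assignment

Windowed density tracks count features by start position in 500-kb tiles
(no fractional overlap weighting — simple, conserving, and sufficient at
this granularity). PAF features require a primary alignment with mapping
quality ≥ 20, which suppresses multi-mapper inflation on repeats. The
triad rule is argmax-based and deterministic; "clear" overrepresentation
becomes a clarity ratio (top/second density within the triad, the second
floored at one pseudo-count per Mb to avoid division by zero) with
default floor 2.0. Calls below the floor are flagged ambiguous but still
made, so a weak study degrades visibly rather than crashing. Triads
themselves are an input: homoeolog detection via synteny is out of scope.

## Assembly QC

The chloroplast read filter reads its thresholds strictly ("> 8000",
"> 40") and the GC window as a closed interval [0.32, 0.40]. "Query
length" is the aligned query span (query_end − query_start) and "query
value" the PAF mapping-quality column — the only per-record fields
matching those names' plain reading; both are documented choices.
Scaffold scrubbing merges hit intervals per scaffold (union coverage) and
weights identity by alignment length, the conservative reading when hits
are fragmented; removal requires identity ≥ 99% and coverage ≥ 99%.
Telomere "abundance" is ≥ 25 exact motif copies within a 10-kb terminal
window (reverse complement on the left end, overlapping occurrences
counted); the threshold is exposed in config since published end
classifications rarely state one. N50 is the length at which the
descending cumulative sum reaches half the total, L50 its 1-based rank.

## Determinism and problem sizes

Every stage is a pure function of (configuration, seed); the pipeline
writes byte-identical text outputs across runs. Default problem sizes —
nine chromosomes totalling ~4.5 Mb, ~180 LTR copies, ~50 satellite
arrays, 600 reads, 1,000-case estimator oracles — were chosen so a full
study runs in minutes on one core while keeping every planted signal
comfortably above its detection threshold.

## Known limitations

* The tandem detector targets satellite-scale arrays; it does not
  implement wraparound dynamic programming and will fragment arrays whose
  monomers diverge far beyond the identity floor.
* Family consensus rebuilding majority-votes only equal-length members;
  length-variant members inform membership but not the consensus.
* `map_families` reports window-resolution covers (stride = half a
  monomer), not base-precise array boundaries.
* The K2P estimator treats all aligned columns as independent; no rate
  heterogeneity or maximum-likelihood refinement.
* Organelle scrubbing is chloroplast-generic: any organelle reference
  works, but mitochondrial-specific curation is not modelled.
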