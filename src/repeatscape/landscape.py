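"""CpG-adjusted Kimura 2-parameter repeat landscapes with a time axis.

Each annotated repeat copy is globally aligned to its family consensus; the
alignment yields transition (P) and transversion (Q) fractions over aligned
ungapped sites and the K2P distance

    K = -1/2 ln((1 - 2P - Q) * sqrt(1 - 2Q))

Methylated CpG sites deaminate rapidly in plant genomes, so raw divergence
at consensus CpG dinucleotides overstates age. With the CpG adjustment, a
transition at either position of a consensus CpG counts as 1/10 of a
transition, and when both positions of one CpG carry transitions the pair
counts as a single full transition; transversions are never reweighted.

Landscapes histogram aligned copy bp into integer percent-divergence bins
per (sub-genome, superfamily), expressed as genome proportion, and the bin
axis converts to absolute time via time = K / (2r) with r the substitution
rate (default 1.3e-8 substitutions/site/year, an LTR rate estimated in
rice).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

from ._util import ParameterError, ResourceError, UndefinedEstimateError, log
from .config import AlignScoring, ClockParams
from .records import AlignedPair, GenomicInterval

_GAP = "-"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = set("ACGT")

MAX_BINS = 60  # bins [i, i+1) percent for i in 0..59


@dataclass(slots=True)
class DivergenceEstimate:
    """P/Q fractions and the K2P distance for one copy-consensus alignment."""

    P: float
    Q: float
    K: float
    n_sites: int
    cpg_adjusted: bool
    saturated: bool


@dataclass(slots=True)
class LandscapeTable:
    """Long-format landscape with per-sub-genome assembly sizes attached."""

    table: pd.DataFrame  # subgenome, superfamily, divergence_bin,
    #                      aligned_bp, genome_proportion
    subgenome_sizes: dict[str, int]
    n_excluded: int = 0

    def modal_bin(self, subgenome: str, superfamily: str) -> int | None:
        sub = self.table[
            (self.table.subgenome == subgenome)
            & (self.table.superfamily == superfamily)
        ]
        if sub.empty:
            return None
        return int(sub.loc[sub.aligned_bp.idxmax(), "divergence_bin"])


# ------------------------------------------------------------- alignment

def global_align(copy: str, consensus: str,
                 scoring: AlignScoring | None = None,
                 family: str = "", superfamily: str = "",
                 location: GenomicInterval | None = None,
                 subgenome: str = "") -> AlignedPair:
    """Optimal global alignment of a repeat copy against its consensus.

    Affine gap scoring (a gap of length L costs gap_open + L*gap_extend);
    deterministic. Sequence-length product is capped at 1e8 — chunk longer
    inputs upstream.
    """
    scoring = scoring or AlignScoring()
    if not copy or not consensus:
        raise ParameterError("sequences must be non-empty")
    if len(copy) * len(consensus) > 10**8:
        raise ResourceError(
            "alignment problem exceeds the 1e8 cell cap; align in chunks")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    aln = aligner.align(copy.upper(), consensus.upper())[0]
    return AlignedPair(
        copy_row=str(aln[0]),
        consensus_row=str(aln[1]),
        family=family,
        superfamily=superfamily,
        location=location or GenomicInterval("unplaced", 0, len(copy)),
        subgenome=subgenome,
    )


def alignment_score(pair: AlignedPair,
                    scoring: AlignScoring | None = None) -> float:
    """Score of an existing gapped pair under the affine model (for tests
    and audits; gap of length L costs gap_open + L*gap_extend per row run)."""
    scoring = scoring or AlignScoring()
    score = 0.0
    for row in (pair.copy_row, pair.consensus_row):
        in_gap = False
        for ch in row:
            if ch == _GAP:
                if not in_gap:
                    score += scoring.gap_open
                    in_gap = True
                score += scoring.gap_extend
            else:
                in_gap = False
    for a, b in zip(pair.copy_row.upper(), pair.consensus_row.upper()):
        if a == _GAP or b == _GAP:
            continue
        score += scoring.match if a == b else scoring.mismatch
    return score


# ------------------------------------------------------------------ K2P

def kimura2p(pair: AlignedPair, cpg_adjust: bool = True) -> DivergenceEstimate:
    """K2P divergence of one aligned pair, optionally CpG-adjusted.

    Gap columns and columns with an ambiguity character in either row are
    excluded from the site count. Transitions are A<->G and C<->T; all other
    mismatches are transversions. Saturated estimates (1-2P-Q <= 0 or
    1-2Q <= 0) carry K = nan and are flagged.
    """
    copy_row = pair.copy_row.upper()
    cons_row = pair.consensus_row.upper()
    n_cols = len(copy_row)

    # valid aligned sites: both rows unambiguous bases
    valid = [
        copy_row[i] in _BASES and cons_row[i] in _BASES
        for i in range(n_cols)
    ]
    n_sites = sum(valid)
    if n_sites == 0:
        raise UndefinedEstimateError("no aligned ungapped sites")

    is_transition = [
        valid[i] and copy_row[i] != cons_row[i]
        and (cons_row[i], copy_row[i]) in _TRANSITIONS
        for i in range(n_cols)
    ]
    n_transversions = sum(
        1 for i in range(n_cols)
        if valid[i] and copy_row[i] != cons_row[i] and not is_transition[i]
    )

    if cpg_adjust:
        # consensus CpG = C followed by G among consecutive consensus
        # non-gap positions (copy-row gaps do not break adjacency)
        cons_positions = [i for i in range(n_cols) if cons_row[i] != _GAP]
        in_cpg = [False] * n_cols
        cpg_pairs: list[tuple[int, int]] = []
        for a, b in zip(cons_positions, cons_positions[1:]):
            if cons_row[a] == "C" and cons_row[b] == "G":
                cpg_pairs.append((a, b))
                in_cpg[a] = in_cpg[b] = True
        weighted = float(sum(
            1 for i in range(n_cols) if is_transition[i] and not in_cpg[i]))
        for a, b in cpg_pairs:
            ta, tb = is_transition[a], is_transition[b]
            if ta and tb:
                weighted += 1.0
            elif ta or tb:
                weighted += 0.1
    else:
        weighted = float(sum(is_transition))

    P = weighted / n_sites
    Q = n_transversions / n_sites
    saturated = (1.0 - 2.0 * P - Q) <= 0.0 or (1.0 - 2.0 * Q) <= 0.0
    K = (
        float("nan") if saturated
        else -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
    )
    return DivergenceEstimate(P=P, Q=Q, K=K, n_sites=n_sites,
                              cpg_adjusted=cpg_adjust, saturated=saturated)


def aligned_copy_bp(pair: AlignedPair) -> int:
    """Copy-row bases contributing landscape weight: unambiguous copy bases
    in columns where the consensus is not an ambiguity character."""
    return sum(
        1 for a, b in zip(pair.copy_row.upper(), pair.consensus_row.upper())
        if a in _BASES and b != "N"
    )


# ------------------------------------------------------------- landscape

def build_landscape(
    pairs: list[AlignedPair],
    subgenome_sizes: dict[str, int],
    bin_width: int = 1,
    cpg_adjust: bool = True,
) -> LandscapeTable:
    """Aggregate per-copy divergences into a genome-proportion landscape.

    Each non-saturated pair contributes its aligned copy bp to the
    [i, i+1)-percent bin of floor(100*K) for its (subgenome, superfamily);
    proportions divide by the sub-genome assembly size. Saturated pairs and
    pairs beyond the last bin are excluded and counted.
    """
    if bin_width != 1:
        raise ParameterError("only 1-percent bins are supported")
    unknown = sorted({p.subgenome for p in pairs} - set(subgenome_sizes))
    if unknown:
        raise ParameterError(
            f"pairs carry unknown sub-genome labels: {unknown}")
    rows = []
    n_excluded = 0
    for pair in pairs:
        est = kimura2p(pair, cpg_adjust=cpg_adjust)
        if est.saturated:
            n_excluded += 1
            log.info("excluded saturated pair at %s:%d",
                     pair.location.seq_id, pair.location.start)
            continue
        bin_i = int(math.floor(100.0 * est.K))
        if bin_i >= MAX_BINS:
            n_excluded += 1
            continue
        rows.append((pair.subgenome, pair.superfamily, bin_i,
                     aligned_copy_bp(pair)))
    if rows:
        df = pd.DataFrame(
            rows, columns=["subgenome", "superfamily", "divergence_bin",
                           "aligned_bp"])
        df = (df.groupby(["subgenome", "superfamily", "divergence_bin"],
                         as_index=False)["aligned_bp"].sum())
    else:
        df = pd.DataFrame(columns=["subgenome", "superfamily",
                                   "divergence_bin", "aligned_bp"])
    df["genome_proportion"] = [
        bp / subgenome_sizes[sg]
        for sg, bp in zip(df.get("subgenome", []), df.get("aligned_bp", []))
    ]
    df = df.sort_values(
        ["subgenome", "superfamily", "divergence_bin"]).reset_index(drop=True)
    return LandscapeTable(table=df, subgenome_sizes=dict(subgenome_sizes),
                          n_excluded=n_excluded)


def time_axis(K: float, clock: ClockParams | None = None) -> float:
    """Convert a K2P divergence to million years: time = K / (2r) / 1e6."""
    clock = clock or ClockParams()
    if K < 0:
        raise ParameterError("divergence must be non-negative")
    return K / (2.0 * clock.rate) / 1e6


def plot_landscape(table: LandscapeTable, path,
                   clock: ClockParams | None = None) -> None:
    """Stacked per-superfamily divergence histograms, one panel per
    sub-genome, with percent-divergence and million-year x axes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    clock = clock or ClockParams()
    if table.table.empty:
        raise ParameterError("cannot plot an empty landscape table")
    subgenomes = sorted(table.table.subgenome.unique())
    superfamilies = sorted(table.table.superfamily.unique())
    fig, axes = plt.subplots(
        1, len(subgenomes), figsize=(4 * len(subgenomes), 3.2),
        sharey=True, squeeze=False)
    bins = np.arange(MAX_BINS)
    cmap = plt.get_cmap("tab10")
    for ax, sg in zip(axes[0], subgenomes):
        bottom = np.zeros(MAX_BINS)
        for k, sf in enumerate(superfamilies):
            sub = table.table[(table.table.subgenome == sg)
                              & (table.table.superfamily == sf)]
            heights = np.zeros(MAX_BINS)
            heights[sub.divergence_bin.to_numpy()] = (
                100.0 * sub.genome_proportion.to_numpy())
            ax.bar(bins, heights, bottom=bottom, width=1.0, color=cmap(k),
                   label=sf)
            bottom += heights
        ax.set_title(f"sub-genome {sg}")
        ax.set_xlabel("divergence from consensus (%)")
        ticks = [0, 10, 20, 30, 40, 50]
        # array-safe variant of time_axis for the axis transform
        sec = ax.secondary_xaxis(
            -0.25,
            functions=(lambda K: K / 100.0 / (2.0 * clock.rate) / 1e6,
                       lambda t: 100.0 * t * 2.0 * clock.rate * 1e6))
        sec.set_xticks([time_axis(t / 100.0, clock) for t in ticks])
        sec.set_xlabel("time (My)")
    axes[0][0].set_ylabel("genome proportion (%)")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ------------------------------------------------------ pairs from truth

def pairs_from_annotations(
    assembly_by_id: dict[str, str],
    annotations: list[tuple[GenomicInterval, str, str]],
    consensi: dict[str, str],
    subgenome_of: dict[str, str],
    scoring: AlignScoring | None = None,
) -> list[AlignedPair]:
    """Align each annotated repeat copy to its family consensus.

    ``annotations`` is (interval, family, superfamily) per copy; the copy
    sequence is sliced from the assembly and globally aligned. This is the
    standard bridge from an annotation track to landscape input.
    """
    pairs = []
    for iv, family, superfamily in annotations:
        copy = assembly_by_id[iv.seq_id][iv.start:iv.end]
        pairs.append(global_align(
            copy, consensi[family], scoring=scoring, family=family,
            superfamily=superfamily, location=iv,
            subgenome=subgenome_of.get(iv.seq_id, ""),
        ))
    return pairs
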