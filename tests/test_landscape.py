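import math
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from repeatscape._util import ParameterError, UndefinedEstimateError
from repeatscape.config import AlignScoring, ClockParams
from repeatscape.landscape import (
    LandscapeTable,
    aligned_copy_bp,
    alignment_score,
    build_landscape,
    global_align,
    kimura2p,
    plot_landscape,
    time_axis,
)
from repeatscape.records import AlignedPair, GenomicInterval


# --------------------------------------------------------------- oracles

def brute_force_align_score(a: str, b: str, sc: AlignScoring) -> float:
    """Exhaustive enumeration of all global alignments (affine gaps; a gap
    run of length L costs gap_open + L*gap_extend). Independent of the DP
    path under test; feasible for len <= 7."""
    best = [-math.inf]

    def rec(i, j, last, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = sc.match if a[i] == b[j] else sc.mismatch
            rec(i + 1, j + 1, "M", score + s)
        if i < len(a):
            open_cost = sc.gap_open if last != "I" else 0.0
            rec(i + 1, j, "I", score + open_cost + sc.gap_extend)
        if j < len(b):
            open_cost = sc.gap_open if last != "D" else 0.0
            rec(i, j + 1, "D", score + open_cost + sc.gap_extend)

    rec(0, 0, None, 0.0)
    return best[0]


def naive_k2p(copy_row: str, cons_row: str):
    """Independent mismatch classifier + closed form (no CpG handling)."""
    purines = {"A", "G"}
    sites = ts = tv = 0
    for x, y in zip(copy_row.upper(), cons_row.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        sites += 1
        if x == y:
            continue
        if (x in purines) == (y in purines):
            ts += 1
        else:
            tv += 1
    P, Q = ts / sites, tv / sites
    if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
        return P, Q, None
    return P, Q, -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))


def random_gapped_pair(rng: random.Random, n_cols: int) -> AlignedPair:
    copy_chars, cons_chars = [], []
    for _ in range(n_cols):
        kind = rng.random()
        if kind < 0.08:
            copy_chars.append("-")
            cons_chars.append(rng.choice("ACGT"))
        elif kind < 0.16:
            copy_chars.append(rng.choice("ACGT"))
            cons_chars.append("-")
        else:
            copy_chars.append(rng.choice("ACGTN"))
            cons_chars.append(rng.choice("ACGT"))
    # guarantee at least one aligned site
    copy_chars[0], cons_chars[0] = "A", "A"
    return AlignedPair("".join(copy_chars), "".join(cons_chars), "f", "s",
                       GenomicInterval("c", 0, n_cols))


# ---------------------------------------------------------- global_align

class TestGlobalAlign:
    def test_identity_alignment(self):
        pair = global_align("ACGT", "ACGT")
        assert pair.copy_row == "ACGT" and pair.consensus_row == "ACGT"
        assert alignment_score(pair) == 8.0

    def test_single_deletion(self):
        pair = global_align("ACT", "ACGT")
        assert pair.copy_row.count("-") == 1
        assert pair.consensus_row == "ACGT"

    def test_matches_exhaustive_enumeration(self):
        rng = random.Random(0)
        sc = AlignScoring()
        for _ in range(40):
            a = "".join(rng.choice("ACGT")
                        for _ in range(rng.randint(1, 7)))
            b = "".join(rng.choice("ACGT")
                        for _ in range(rng.randint(1, 7)))
            pair = global_align(a, b, sc)
            assert alignment_score(pair, sc) == pytest.approx(
                brute_force_align_score(a, b, sc))

    def test_size_cap(self):
        from repeatscape._util import ResourceError
        with pytest.raises(ResourceError):
            global_align("A" * 20_000, "A" * 20_000)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ParameterError):
            global_align("", "ACGT")


# ----------------------------------------------------------------- K2P

def _pair(copy_row, cons_row):
    return AlignedPair(copy_row, cons_row, "f", "s",
                       GenomicInterval("c", 0, max(1, len(copy_row))))


class TestKimura2P:
    def test_identical_rows(self):
        est = kimura2p(_pair("ACGT", "ACGT"), cpg_adjust=False)
        assert est.P == 0 and est.Q == 0 and est.K == 0
        assert not est.saturated

    def test_closed_form_example(self):
        # 100 ungapped columns: 10 transitions, 5 transversions, no CpG
        cons = ("AT" * 50)
        copy = list(cons)
        for i in range(10):          # A->G transitions at even positions
            copy[2 * i] = "G"
        for i in range(5):           # T->G transversions at odd positions
            copy[2 * i + 41] = "G"
        est = kimura2p(_pair("".join(copy), cons), cpg_adjust=True)
        assert est.P == pytest.approx(0.10)
        assert est.Q == pytest.approx(0.05)
        expected = -0.5 * math.log(0.75 * math.sqrt(0.90))
        assert est.K == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.1702, abs=5e-4)

    def test_cpg_single_transition_weighted_tenth(self):
        est = kimura2p(_pair("TGCG", "CGCG"), cpg_adjust=True)
        assert est.P == pytest.approx(0.1 / 4)
        raw = kimura2p(_pair("TGCG", "CGCG"), cpg_adjust=False)
        assert raw.P == pytest.approx(0.25)

    def test_cpg_double_transition_counts_once(self):
        # both positions of the single CpG carry transitions: T<-C, A<-G
        est = kimura2p(_pair("TACG", "CGCG"), cpg_adjust=True)
        assert est.P == pytest.approx(1.0 / 4)

    def test_cpg_detection_spans_copy_gap(self):
        # consensus C and G adjacent among consensus positions despite the
        # copy-row gap between them
        pair = _pair("T-GG", "CG-G")
        est = kimura2p(pair, cpg_adjust=True)
        assert est.P == pytest.approx(0.1 / 2)  # 2 aligned sites

    def test_transversions_never_reweighted(self):
        est = kimura2p(_pair("AGCG", "CGCG"), cpg_adjust=True)
        assert est.Q == pytest.approx(0.25) and est.P == 0

    def test_gap_and_n_columns_excluded(self):
        est = kimura2p(_pair("AC-TN", "ACGTA"), cpg_adjust=False)
        assert est.n_sites == 3

    def test_saturation_flagged(self):
        est = kimura2p(_pair("GGGG", "AAAA"), cpg_adjust=False)
        assert est.saturated and math.isnan(est.K)

    def test_all_gap_pair_rejected(self):
        with pytest.raises(UndefinedEstimateError):
            kimura2p(_pair("--A", "GG-"), cpg_adjust=False)

    def test_matches_naive_recount_on_random_pairs(self):
        rng = random.Random(1)
        for _ in range(300):
            pair = random_gapped_pair(rng, rng.randint(10, 120))
            P, Q, K = naive_k2p(pair.copy_row, pair.consensus_row)
            est = kimura2p(pair, cpg_adjust=False)
            assert est.P == pytest.approx(P, abs=1e-12)
            assert est.Q == pytest.approx(Q, abs=1e-12)
            if K is None:
                assert est.saturated
            else:
                assert est.K == pytest.approx(K, abs=1e-12)

    def test_monotone_in_P_and_Q(self):
        def k_of(p, q):
            return -0.5 * math.log((1 - 2 * p - q) * math.sqrt(1 - 2 * q))

        for q in (0.0, 0.05, 0.1):
            ks = [k_of(p, q) for p in (0.0, 0.05, 0.1, 0.2)]
            assert ks == sorted(ks)
        for p in (0.0, 0.05, 0.1):
            ks = [k_of(p, q) for q in (0.0, 0.05, 0.1, 0.2)]
            assert ks == sorted(ks)


# ------------------------------------------------------------- landscape

class TestBuildLandscape:
    def test_single_pair_arithmetic(self):
        # 1000 ungapped columns, 60 transitions, 10 transversions:
        # P=.06 Q=.01 -> K = -.5 ln(.87 sqrt(.98)) ~ 0.0747 -> bin 7
        cons = "AT" * 500
        copy = list(cons)
        for i in range(60):
            copy[2 * i] = "G"          # A->G ts
        for i in range(10):
            copy[2 * i + 121] = "G"    # T->G tv
        pair = AlignedPair("".join(copy), cons, "fam", "Gypsy",
                           GenomicInterval("c", 0, 1000), "B")
        table = build_landscape([pair], {"B": 100_000}, cpg_adjust=False)
        row = table.table.iloc[0]
        assert row.divergence_bin == 7
        assert row.aligned_bp == 1000
        assert row.genome_proportion == pytest.approx(0.01)

    def test_empty_input(self):
        table = build_landscape([], {"B": 1000})
        assert table.table.empty

    def test_unknown_subgenome_rejected(self):
        pair = AlignedPair("ACGT", "ACGT", "f", "s",
                           GenomicInterval("c", 0, 4), "Z")
        with pytest.raises(ParameterError, match="Z"):
            build_landscape([pair], {"B": 1000})

    def test_aligned_bp_conserved(self):
        rng = random.Random(2)
        pairs = []
        for i in range(50):
            p = random_gapped_pair(rng, rng.randint(20, 200))
            pairs.append(AlignedPair(p.copy_row, p.consensus_row, "f", "s",
                                     p.location, "B"))
        table = build_landscape(pairs, {"B": 10**6}, cpg_adjust=False)
        kept_bp = table.table.aligned_bp.sum() if not table.table.empty \
            else 0
        expected = sum(
            aligned_copy_bp(p) for p in pairs
            if not kimura2p(p, cpg_adjust=False).saturated
            and math.floor(100 * kimura2p(p, cpg_adjust=False).K) < 60)
        assert kept_bp == expected


class TestTimeAxis:
    def test_stated_calibration_points(self):
        assert time_axis(0.0) == 0.0
        assert time_axis(0.07) == pytest.approx(2.6923, abs=1e-4)
        assert time_axis(0.26) == pytest.approx(10.0, abs=1e-9)

    @given(st.floats(min_value=0, max_value=0.6),
           st.floats(min_value=0, max_value=4))
    def test_linearity(self, k, a):
        assert time_axis(a * k) == pytest.approx(a * time_axis(k),
                                                 rel=1e-12, abs=1e-12)

    def test_negative_divergence_rejected(self):
        with pytest.raises(ParameterError):
            time_axis(-0.01)

    def test_custom_rate(self):
        assert time_axis(0.26, ClockParams(rate=2.6e-8)) == \
            pytest.approx(5.0)


class TestPlot:
    def test_plot_written(self, tmp_path):
        import pandas as pd
        df = pd.DataFrame({
            "subgenome": ["B", "B"], "superfamily": ["Gypsy", "Copia"],
            "divergence_bin": [7, 12], "aligned_bp": [1000, 500],
            "genome_proportion": [0.01, 0.005]})
        table = LandscapeTable(df, {"B": 100_000})
        out = tmp_path / "l.png"
        plot_landscape(table, out)
        assert out.exists() and out.stat().st_size > 0

    def test_empty_table_rejected(self, tmp_path):
        import pandas as pd
        table = LandscapeTable(pd.DataFrame(
            columns=["subgenome", "superfamily", "divergence_bin",
                     "aligned_bp", "genome_proportion"]), {})
        with pytest.raises(ParameterError):
            plot_landscape(table, tmp_path / "x.png")
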