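import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from repeatscape._util import ParameterError, revcomp
from repeatscape.config import CurationParams
from repeatscape.records import GenomicInterval, SequenceRecord, TandemArray
from repeatscape.satdna import (
    canonical_rotation,
    curate_candidates,
    cyclic_identity,
    detect_tandem_arrays,
    filter_candidates,
    is_microsatellite,
    map_families,
    mask_known,
    merge_families,
)
from repeatscape.simulate import mutate_sequence

dna = st.text(alphabet="ACGT", min_size=1, max_size=30)


def _candidate(consensus, copies=60.0):
    from repeatscape.records import SatFamilyCandidate
    arr = _array(consensus, copies=copies)
    return SatFamilyCandidate(
        consensus=consensus, monomer_length=len(consensus),
        total_copy_number=copies, total_bp=len(arr.location),
        member_arrays=[arr])


def _array(consensus, seq_id="c", start=0, copies=100.0):
    length = int(len(consensus) * copies)
    return TandemArray(
        location=GenomicInterval(seq_id, start, start + length),
        period=len(consensus), copy_number=copies,
        monomer_consensus=consensus, mean_monomer_identity=0.95)


class TestCanonicalRotation:
    def test_hand_enumerated_example(self):
        # rotations of GTAC: GTAC, TACG, ACGT, CGTA; RC(GTAC)=GTAC
        assert canonical_rotation("GTAC") == "ACGT"

    @given(dna)
    def test_idempotent(self, s):
        assert canonical_rotation(canonical_rotation(s)) == \
            canonical_rotation(s)

    @given(dna)
    def test_strand_and_rotation_invariant(self, s):
        assert canonical_rotation(revcomp(s)) == canonical_rotation(s)
        k = len(s) // 2
        assert canonical_rotation(s[k:] + s[:k]) == canonical_rotation(s)

    def test_non_acgt_rejected(self):
        with pytest.raises(ParameterError):
            canonical_rotation("ACGN")


class TestDetect:
    def test_exact_tandem(self):
        rec = SequenceRecord("s", "ACGTT" * 20)
        arrays = detect_tandem_arrays(rec, min_period=5, max_period=50)
        assert len(arrays) == 1
        a = arrays[0]
        assert a.period == 5
        assert abs(a.copy_number - 20) <= 1
        assert canonical_rotation(a.monomer_consensus) == \
            canonical_rotation("ACGTT")

    def test_noisy_planted_array_covered(self):
        rng = np.random.default_rng(0)
        decode = np.array(list("ACGT"))
        bg = "".join(decode[rng.integers(0, 4, 20_000)])
        monomer = "".join(decode[rng.integers(0, 4, 57)])
        copies = [mutate_sequence(monomer, 0.10, 2.0, seed=i)[0]
                  for i in range(40)]
        start = 9_000
        seq = bg[:start] + "".join(copies) + bg[start:]
        planted = (start, start + 57 * 40)
        arrays = detect_tandem_arrays(SequenceRecord("s", seq),
                                      min_period=5, max_period=200)
        best = 0
        for a in arrays:
            ov = max(0, min(planted[1], a.location.end)
                     - max(planted[0], a.location.start))
            best = max(best, ov)
        assert best >= 0.90 * (planted[1] - planted[0])

    def test_random_background_null(self):
        rng = np.random.default_rng(42)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 50_000)])
        arrays = detect_tandem_arrays(SequenceRecord("s", seq),
                                      min_period=5, max_period=200)
        assert not any(a.copy_number >= 5 and a.period >= 10 for a in arrays)

    def test_too_short_sequence_gives_empty(self):
        assert detect_tandem_arrays(SequenceRecord("s", "ACGTACG"),
                                    min_period=5) == []

    def test_masked_regions_never_seed(self):
        seq = ("acgtt" * 20) + "ACGT" * 100  # masked tandem + plain bg
        arrays = detect_tandem_arrays(SequenceRecord("s", seq),
                                      min_period=5, max_period=8)
        assert all(a.location.start >= 100 for a in arrays)


class TestCuration:
    def test_abundant_long_monomer_kept(self):
        params = CurationParams()
        cons = canonical_rotation(
            "".join(np.array(list("ACGT"))[
                np.random.default_rng(1).integers(0, 4, 170)]))
        kept = filter_candidates([_array(cons, copies=60.0)], params)
        assert len(kept) == 1
        assert kept[0].total_copy_number == 60.0

    def test_copy_number_threshold_is_strict(self):
        params = CurationParams()
        cons = canonical_rotation(
            "".join(np.array(list("ACGT"))[
                np.random.default_rng(2).integers(0, 4, 170)]))
        assert filter_candidates([_array(cons, copies=50.0)], params) == []

    def test_short_and_microsatellite_monomers_rejected(self):
        params = CurationParams()
        cons12 = canonical_rotation(
            "".join(np.array(list("ACGT"))[
                np.random.default_rng(3).integers(0, 4, 12)]))
        assert filter_candidates([_array(cons12, copies=1000.0)],
                                 params) == []
        at20 = "AT" * 10
        kept, rejected = curate_candidates([_array(at20, copies=1000.0)],
                                           params)
        assert kept == []
        assert any("microsatellite" in reason for _, reason in rejected)

    def test_copy_number_pooled_across_arrays(self):
        params = CurationParams()
        cons = canonical_rotation(
            "".join(np.array(list("ACGT"))[
                np.random.default_rng(4).integers(0, 4, 100)]))
        arrays = [_array(cons, start=0, copies=30.0),
                  _array(cons, start=10_000, copies=30.0)]
        kept = filter_candidates(arrays, params)
        assert len(kept) == 1 and kept[0].total_copy_number == 60.0

    def test_microsatellite_subperiod_detection(self):
        assert is_microsatellite("ATATATATATATATATATAT")
        assert is_microsatellite("ACGACGACGACGACGACG")  # sub-period 3
        rng = np.random.default_rng(5)
        random_monomer = "".join(np.array(list("ACGT"))[
            rng.integers(0, 4, 50)])
        assert not is_microsatellite(random_monomer)


class TestMerge:
    def test_rotated_candidates_form_one_family(self):
        params = CurationParams()
        rng = np.random.default_rng(6)
        mono = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 80)])
        rot = mono[30:] + mono[:30]
        kept = filter_candidates(
            [_array(canonical_rotation(mono), copies=60.0),
             _array(canonical_rotation(rot), start=10**5, copies=60.0)],
            params)
        families = merge_families(kept, params)
        assert len(families) == 1

    def test_size_gate_prevents_comparison(self):
        params = CurationParams()
        rng = np.random.default_rng(7)
        m100 = canonical_rotation(
            "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)]))
        m300 = canonical_rotation(m100 * 3)  # would merge if compared
        fams = merge_families(
            [_candidate(m100), _candidate(m300)], params)
        assert len(fams) == 2

    def test_known_library_sets_novel_flag(self):
        params = CurationParams()
        rng = np.random.default_rng(8)
        m1 = canonical_rotation(
            "".join(np.array(list("ACGT"))[rng.integers(0, 4, 90)]))
        m2 = canonical_rotation(
            "".join(np.array(list("ACGT"))[rng.integers(0, 4, 90)]))
        fams = merge_families(
            [_candidate(m1), _candidate(m2)],
            params, known_library=[SequenceRecord("known1", m1)])
        by_cons = {f.consensus: f.novel for f in fams}
        assert by_cons[m1] is False and by_cons[m2] is True


class TestMapFamilies:
    def _family(self, consensus):
        from repeatscape.records import SatFamily
        return SatFamily(id="famX", consensus=canonical_rotation(consensus))

    def test_exact_array_hit_at_all_thresholds(self):
        rng = np.random.default_rng(9)
        decode = np.array(list("ACGT"))
        mono = "".join(decode[rng.integers(0, 4, 40)])
        bg = "".join(decode[rng.integers(0, 4, 5000)])
        seq = bg + mono * 25 + bg
        maps = map_families([SequenceRecord("s", seq)], [self._family(mono)])
        for t in (0.90, 0.80, 0.75):
            hits = [iv for iv in maps[t]
                    if iv.start < 5000 + 40 * 25 and iv.end > 5000]
            assert hits, f"no hit at threshold {t}"

    def test_mutated_array_drops_out_at_high_threshold(self):
        rng = np.random.default_rng(10)
        decode = np.array(list("ACGT"))
        mono = "".join(decode[rng.integers(0, 4, 100)])
        # substitute exactly 15 positions per copy -> 85% monomer identity
        def diverged_copy(i):
            rng_i = np.random.default_rng(100 + i)
            positions = rng_i.choice(100, size=15, replace=False)
            chars = list(mono)
            for p in positions:
                chars[p] = "ACGT"[("ACGT".index(chars[p]) + 1) % 4]
            return "".join(chars)

        copies = [diverged_copy(i) for i in range(30)]
        assert all(sum(a != b for a, b in zip(c, mono)) == 15
                   for c in copies)
        bg = "".join(decode[rng.integers(0, 4, 3000)])
        seq = bg + "".join(copies) + bg
        maps = map_families([SequenceRecord("s", seq)], [self._family(mono)])

        def planted_bp(t):
            lo, hi = 3000, 3000 + 100 * 30
            return sum(max(0, min(hi, iv.end) - max(lo, iv.start))
                       for iv in maps[t])

        assert planted_bp(0.75) >= 0.5 * 3000
        assert planted_bp(0.90) <= 0.1 * planted_bp(0.75)

    def test_threshold_monotone_cover(self):
        rng = np.random.default_rng(11)
        decode = np.array(list("ACGT"))
        mono = "".join(decode[rng.integers(0, 4, 60)])
        seq = "".join(decode[rng.integers(0, 4, 2000)]) + mono * 20
        maps = map_families([SequenceRecord("s", seq)], [self._family(mono)])
        bp = {t: sum(len(iv) for iv in maps[t]) for t in maps}
        assert bp[0.75] >= bp[0.80] >= bp[0.90]


class TestMaskKnown:
    def test_empty_library_is_noop(self, small_genome):
        _, assembly, _ = small_genome
        out = mask_known(assembly[:1], [], 0.8)
        assert out[0].residues == assembly[0].residues

    def test_planted_known_array_masked_and_idempotent(self, small_genome):
        _, assembly, truth = small_genome
        known = [SequenceRecord("satA", truth.consensi["satA"])]
        masked = mask_known(assembly, known, 0.9)
        for arr in truth.sat_arrays:
            if arr.family != "satA":
                continue
            seg = masked[
                [r.id for r in masked].index(arr.location.seq_id)
            ].residues[arr.location.start:arr.location.end]
            assert sum(c.islower() for c in seg) / len(seg) >= 0.90
        again = mask_known(masked, known, 0.9)
        assert [r.residues for r in again] == [r.residues for r in masked]


class TestStrandInvariance:
    def test_detection_invariant_under_reverse_complement(self):
        rng = np.random.default_rng(12)
        decode = np.array(list("ACGT"))
        mono = "".join(decode[rng.integers(0, 4, 30)])
        bg1 = "".join(decode[rng.integers(0, 4, 4000)])
        bg2 = "".join(decode[rng.integers(0, 4, 4000)])
        seq = bg1 + mono * 60 + bg2
        fwd = detect_tandem_arrays(SequenceRecord("s", seq), 5, 100)
        rev = detect_tandem_arrays(SequenceRecord("s", revcomp(seq)), 5, 100)
        fwd_cons = sorted(canonical_rotation(a.monomer_consensus)
                          for a in fwd if a.copy_number >= 50)
        rev_cons = sorted(canonical_rotation(a.monomer_consensus)
                          for a in rev if a.copy_number >= 50)
        assert fwd_cons == rev_cons


def test_cyclic_identity_of_related_monomers():
    rng = np.random.default_rng(13)
    mono = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 120)])
    rotated = mono[50:] + mono[:50]
    assert cyclic_identity(mono, rotated) == 1.0
    assert cyclic_identity(mono, revcomp(rotated)) == 1.0
    mutated, ts, tv = mutate_sequence(mono, 0.1, 2.0, seed=14)
    assert cyclic_identity(mono, mutated) >= 1.0 - (ts + tv + 2) / 120
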