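"""Fragmenting, six-frame translation, metal profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metbind import (
    MetalProfile,
    PredictionResult,
    aggregate_fragment_scores,
    fragment_sequence,
    metal_profile,
    profile_distance,
    six_frame_translate,
)
from metbind.structure_labeling import ION_ORDER

# Independent codon table (bacterial/standard codon assignments), written
# out by hand so the translation path is checked against a second source.
_T = {}
_BASES = "TCAG"
_AA = ("FFLLSSSSYY**CC*W" "LLLLPPPPHHQQRRRR"
       "IIIMTTTTNNKKSSRR" "VVVVAAAADDEEGGGG")
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _T[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def oracle_translate(read: str, min_len: int = 16) -> set[tuple[int, str]]:
    """Frame-by-frame codon walk with stop splitting and length filter."""
    read = read.upper()
    rc = "".join(_COMP[b] for b in reversed(read))
    out = set()
    for frame in (1, 2, 3, -1, -2, -3):
        strand = read if frame > 0 else rc
        sub = strand[abs(frame) - 1 :]
        if len(sub) % 3:
            sub += "N" * (3 - len(sub) % 3)
        peptide = []
        for i in range(0, len(sub), 3):
            codon = sub[i : i + 3]
            peptide.append("X" if "N" in codon else _T[codon])
        for segment in "".join(peptide).split("*"):
            if len(segment) >= min_len:
                out.add((frame, segment))
    return out


class TestFragments:
    @pytest.mark.parametrize("length,count", [(49, 0), (50, 1), (52, 3), (120, 71)])
    def test_fragment_count_formula(self, length, count):
        frags = fragment_sequence("A" * length, "p", window=50, step=1)
        assert len(frags) == count
        if count:
            assert [f.start for f in frags] == list(range(count))
            assert all(len(f.sequence) == 50 for f in frags)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(length=st.integers(min_value=50, max_value=400))
    def test_count_property(self, length):
        assert len(fragment_sequence("G" * length, "p")) == length - 49

    def test_step_spacing(self):
        frags = fragment_sequence("A" * 60, "p", window=50, step=5)
        assert [f.start for f in frags] == [0, 5, 10]

    def test_aggregation_rules(self):
        assert aggregate_fragment_scores([0.1, 0.9, 0.2], "max") == 0.9
        assert aggregate_fragment_scores([0.4], "max") == 0.4
        assert aggregate_fragment_scores([0.2, 0.4], "mean") == pytest.approx(0.3)
        assert aggregate_fragment_scores(
            [0.2, 0.8, 0.9], "fraction_positive", cutoff=0.5
        ) == pytest.approx(2 / 3)
        with pytest.raises(ValueError):
            aggregate_fragment_scores([], "max")

    def test_max_dominates_mean(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            scores = rng.random(rng.integers(1, 20))
            assert aggregate_fragment_scores(scores, "max") >= (
                aggregate_fragment_scores(scores, "mean")
            )


class TestSixFrameTranslation:
    def test_48nt_stop_free_read_gives_six_16mers(self):
        # codons chosen with no stop in any frame of either strand
        read = "GCTGCCGCAGCGCTGGCCGCAGCGGCTGCCGCAGCGGCTGCCGCAGCT"
        assert len(read) == 48
        peptides = six_frame_translate(read)
        assert len(peptides) == 6
        assert {p.frame for p in peptides} == {1, 2, 3, -1, -2, -3}
        # every frame yields exactly 16 residues (48/3); shifted frames
        # end in an unknown residue for the partial trailing codon
        by_frame = {p.frame: p.sequence for p in peptides}
        assert all(len(s) == 16 for s in by_frame.values())
        assert "X" not in by_frame[1] and by_frame[2].endswith("X")

    def test_45nt_read_discarded_by_length_filter(self):
        read = "GCTGCCGCAGCGCTGGCCGCAGCGGCTGCCGCAGCGGCTGCCGCA"
        assert len(read) == 45
        assert six_frame_translate(read) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_codon_walk_oracle(self, seed):
        rng = np.random.default_rng(seed)
        read = "".join(rng.choice(list("ACGT"), size=300))
        got = {(p.frame, p.sequence) for p in six_frame_translate(read)}
        assert got == oracle_translate(read)

    def test_n_codons_translate_to_x(self):
        read = "ATGNNT" + "GCT" * 20
        peptides = six_frame_translate(read, min_len=1)
        plus1 = next(p for p in peptides if p.frame == 1)
        assert plus1.sequence[1] == "X"

    def test_reverse_complement_swaps_frames(self):
        rng = np.random.default_rng(77)
        read = "".join(rng.choice(list("ACGT"), size=120))
        rc = "".join(_COMP[b] for b in reversed(read))
        fwd = {(p.frame, p.sequence) for p in six_frame_translate(read, min_len=4)}
        rev = {(-p.frame, p.sequence) for p in six_frame_translate(rc, min_len=4)}
        assert fwd == rev

    def test_empty_and_invalid_input(self):
        assert six_frame_translate("") == []
        with pytest.raises(ValueError):
            six_frame_translate("ACGTQ")


def _pred(ion_calls: dict) -> PredictionResult:
    return PredictionResult(
        sequence_id="p",
        tier1_score=0.5,
        tier1_call=True,
        ion_scores={ion: 1.0 for ion in ion_calls},
        ion_calls=ion_calls,
    )


class TestMetalProfile:
    def test_no_positive_calls_zero_vector(self):
        profile = metal_profile([_pred({}), _pred({})])
        assert np.all(profile.vector() == 0)

    def test_relative_frequency(self):
        preds = [_pred({"Fe": True}), _pred({"Fe": True}), _pred({}), _pred({})]
        profile = metal_profile(preds)
        assert profile.frequencies["Fe"] == 0.5
        assert profile.total_peptides == 4

    def test_duplication_invariance(self):
        preds = [_pred({"Zn": True}), _pred({})]
        one = metal_profile(preds)
        two = metal_profile(preds * 3)
        np.testing.assert_allclose(one.vector(), two.vector())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            metal_profile([])

    def test_ion_order_is_fixed(self):
        profile = metal_profile([_pred({"Zn": True})])
        assert profile.ion_order == ION_ORDER
        assert profile.vector()[ION_ORDER.index("Zn")] == 1.0


class TestProfileDistance:
    def _profile(self, values):
        return MetalProfile(
            frequencies=dict(zip(ION_ORDER, values)), total_peptides=10
        )

    def test_identical_profiles_distance_zero(self):
        p = self._profile(np.linspace(0, 0.9, 10))
        assert profile_distance(p, p) == 0.0

    def test_three_four_five(self):
        p = self._profile([0.3, 0.4] + [0.0] * 8)
        q = self._profile([0.0] * 10)
        assert profile_distance(p, q) == pytest.approx(0.5)

    def test_matches_componentwise_oracle(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(10), rng.random(10)
        expected = float(np.sqrt(((a - b) ** 2).sum()))
        assert profile_distance(self._profile(a), self._profile(b)) == (
            pytest.approx(expected)
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.floats(0, 1), min_size=10, max_size=10),
        b=st.lists(st.floats(0, 1), min_size=10, max_size=10),
        c=st.lists(st.floats(0, 1), min_size=10, max_size=10),
    )
    def test_metric_axioms(self, a, b, c):
        pa, pb, pc = self._profile(a), self._profile(b), self._profile(c)
        dab = profile_distance(pa, pb)
        assert dab >= 0
        assert dab == profile_distance(pb, pa)
        assert dab <= profile_distance(pa, pc) + profile_distance(pc, pb) + 1e-9
        if a == b:
            assert dab == 0

    def test_mismatched_ion_order_rejected(self):
        p = self._profile(np.zeros(10))
        q = MetalProfile(
            frequencies={ion: 0.0 for ion in ION_ORDER},
            total_peptides=1,
            ion_order=tuple(reversed(ION_ORDER)),
        )
        with pytest.raises(ValueError):
            profile_distance(p, q)
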