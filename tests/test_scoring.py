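"""Scoring: confusion counts, Q scores, MCC, segment overlap, pooling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcrnssp import (
    ConfusionMatrix3,
    confusion,
    mcc_class,
    q3,
    q_class,
    q_he_error,
    score_chains,
    sov,
)

STATES = "HEC"

# confusion matrices transcribed from the published benchmark tables
CB513_55 = [[16333, 62, 1962], [87, 9001, 2763], [2288, 2279, 16859]]
CB513_CV = [[16469, 48, 1840], [92, 8804, 2955], [2313, 2032, 17081]]
GSW_55 = [[680, 0, 42], [25, 384, 137], [51, 20, 61]]
GSW_CV = [[682, 1, 39], [58, 352, 136], [53, 40, 39]]


def random_ss(rng, n):
    return "".join(rng.choice(list(STATES), size=n))


# ---------------------------------------------------------------- oracles


def confusion_oracle(obs, pred):
    counts = np.zeros((3, 3), dtype=int)
    for o, p in zip(obs, pred):
        counts[STATES.index(o), STATES.index(p)] += 1
    return counts


def mcc_oracle(counts, j):
    """One-vs-rest tally by explicit per-position enumeration."""
    i = STATES.index(j)
    tp = counts[i, i]
    fn = sum(counts[i, c] for c in range(3) if c != i)
    fp = sum(counts[r, i] for r in range(3) if r != i)
    tn = counts.sum() - tp - fn - fp
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom**0.5


def segments_oracle(s, state):
    return [
        (min(g), max(g))
        for key, grp in itertools.groupby(range(len(s)), key=lambda i: s[i])
        if key == state
        for g in [list(grp)]
    ]


def sov_oracle(obs, pred, states):
    """Independent segment-pair enumeration of the 1999 overlap score."""
    num = norm = 0.0
    for state in states:
        s1_list = segments_oracle(obs, state)
        s2_list = segments_oracle(pred, state)
        for s1 in s1_list:
            pairs = [
                s2
                for s2 in s2_list
                if not (s2[1] < s1[0] or s1[1] < s2[0])
            ]
            len1 = s1[1] - s1[0] + 1
            if not pairs:
                norm += len1
                continue
            for s2 in pairs:
                len2 = s2[1] - s2[0] + 1
                minov = min(s1[1], s2[1]) - max(s1[0], s2[0]) + 1
                maxov = max(s1[1], s2[1]) - min(s1[0], s2[0]) + 1
                delta = min(maxov - minov, minov, len1 // 2, len2 // 2)
                num += len1 * (minov + delta) / maxov
                norm += len1
    return None if norm == 0 else 100.0 * num / norm


# ------------------------------------------------------------------ tests


class TestConfusion:
    def test_hand_counted_example(self):
        cm = confusion("HHEE", "HEEC")
        assert cm["H", "H"] == 1 and cm["H", "E"] == 1
        assert cm["E", "E"] == 1 and cm["E", "C"] == 1
        assert cm.total == 4

    def test_identity_prediction_is_diagonal(self, rng):
        s = random_ss(rng, 500)
        cm = confusion(s, s)
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))

    def test_matches_pair_counting_oracle(self, rng):
        obs, pred = random_ss(rng, 10_000), random_ss(rng, 10_000)
        np.testing.assert_array_equal(
            confusion(obs, pred).counts, confusion_oracle(obs, pred)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion("HH", "H")

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ConfusionMatrix3(np.array([[1, -1, 0], [0, 0, 0], [0, 0, 0]]))


class TestResidueScores:
    def test_q3_published_benchmark_values(self):
        # printed values round inconsistently in the last digit, so the
        # comparison allows the documented +-0.01
        assert q3(CB513_55) == pytest.approx(81.72, abs=0.011)
        assert q3(CB513_CV) == pytest.approx(82.03, abs=0.011)
        assert q3(GSW_55) == pytest.approx(80.36, abs=0.011)
        assert q3(GSW_CV) == pytest.approx(76.65, abs=0.011)  # 1073/1400

    def test_q3_perfect_prediction(self):
        assert q3(np.diag([5, 3, 2])) == 100.0

    def test_per_class_published_values(self):
        assert q_class(CB513_CV, "H") == pytest.approx(89.72, abs=0.005)
        assert q_class(GSW_55, "E") == pytest.approx(70.33, abs=0.005)
        assert q_class(GSW_55, "C") == pytest.approx(46.22, abs=0.01)

    def test_empty_class_is_absent_not_zero(self):
        cm = [[5, 0, 0], [0, 0, 0], [0, 0, 5]]
        assert q_class(cm, "E") is None
        assert q_class(cm, "H") == 100.0

    def test_mcc_published_value(self):
        assert mcc_class(CB513_55, "H") == pytest.approx(0.815, abs=5e-4)
        assert round(mcc_class(GSW_55, "E"), 2) == 0.73

    def test_mcc_perfect_and_degenerate(self):
        assert mcc_class(np.diag([4, 4, 4]), "H") == pytest.approx(1.0)
        assert mcc_class(np.zeros((3, 3)), "E") == 0.0
        # all predicted H: TN+FN factor... a zero factor gives 0
        assert mcc_class([[3, 0, 0], [2, 0, 0], [1, 0, 0]], "E") == 0.0

    def test_mcc_matches_one_vs_rest_oracle(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 40, size=(3, 3))
            for j in STATES:
                assert mcc_class(counts, j) == pytest.approx(
                    mcc_oracle(counts, j), abs=1e-12
                )

    def test_mcc_invariant_under_other_class_swap(self, rng):
        counts = rng.integers(0, 50, size=(3, 3))
        swapped = counts[np.ix_([0, 2, 1], [0, 2, 1])]  # swap E and C
        assert mcc_class(counts, "H") == pytest.approx(mcc_class(swapped, "H"))

    def test_q_he_error_published_values(self):
        assert q_he_error(GSW_55) == pytest.approx(1.786, abs=5e-4)
        assert q_he_error(GSW_CV) == pytest.approx(4.214, abs=5e-4)
        assert q_he_error(np.diag([9, 9, 9])) == 0.0

    @given(
        st.lists(
            st.integers(min_value=0, max_value=500), min_size=9, max_size=9
        )
    )
    @settings(deadline=None, max_examples=60)
    def test_q3_is_row_weighted_mean_of_class_scores(self, cells):
        counts = np.array(cells).reshape(3, 3)
        if counts.sum() == 0:
            return
        cm = ConfusionMatrix3(counts)
        acc = 0.0
        for j, row in zip(STATES, counts):
            qj = q_class(cm, j)
            if qj is not None:
                acc += qj * row.sum()
        assert q3(cm) == pytest.approx(acc / counts.sum())


class TestSov:
    def test_perfect_prediction_scores_100(self, rng):
        s = random_ss(rng, 200)
        assert sov(s, s) == pytest.approx(100.0)
        for j in STATES:
            if j in s:
                assert sov(s, s, states=[j]) == pytest.approx(100.0)

    def test_no_overlap_scores_zero(self):
        assert sov("CHHHHC", "CCCCCC", states=["H"]) == 0.0

    def test_worked_segment_example(self):
        obs, pred = "CCHHHHHCC", "CHHHCCCCC"
        assert sov(obs, pred, states=["H"]) == pytest.approx(
            sov_oracle(obs, pred, "H")
        )
        # hand evaluation: s1=(2,6) len 5, s2=(1,3) len 3,
        # minov=2, maxov=6, delta=min(4,2,2,1)=1 -> 5*(3)/6 / 5
        assert sov(obs, pred, states=["H"]) == pytest.approx(100.0 * 0.5)

    def test_matches_enumeration_oracle_on_random_pairs(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 50))
            obs, pred = random_ss(rng, n), random_ss(rng, n)
            for states in (["H"], ["E"], ["C"], list(STATES)):
                expected = sov_oracle(obs, pred, states)
                got = sov(obs, pred, states=states)
                if expected is None:
                    assert got is None
                else:
                    assert got == pytest.approx(expected, abs=1e-9)

    @given(st.text(alphabet=STATES, min_size=1, max_size=60),
           st.text(alphabet=STATES, min_size=1, max_size=60))
    @settings(deadline=None, max_examples=100)
    def test_bounded_above_by_100(self, obs, pred):
        n = min(len(obs), len(pred))
        val = sov(obs[:n], pred[:n])
        if val is not None:
            assert val <= 100.0 + 1e-9

    def test_chains_never_merge_segments(self):
        # one helix split across two chains is two segments, not one
        two_chains = sov(["HH", "HH"], ["HH", "CC"], states=["H"])
        one_chain = sov("HHHH", "HHCC", states=["H"])
        assert two_chains != one_chain
        assert two_chains == pytest.approx(50.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            sov("HH", "H")


class TestScoreChains:
    def test_perfect_chain_all_scores_maximal(self):
        report = score_chains([("HHHEEECCC", "HHHEEECCC")])
        assert report.q3 == 100.0
        assert report.sov == pytest.approx(100.0)
        assert report.mcc_H == report.mcc_E == report.mcc_C == pytest.approx(1.0)
        assert report.q_he_error == 0.0

    def test_trypsin_inhibitor_coil_accuracy(self):
        obs = "CCCCECCCHHHCCCCCCEEC"
        pred = "EEEEECCCCCCCCCEEEECE"
        report = score_chains([(obs, pred)])
        assert report.q_C == pytest.approx(100 * 6 / 14, abs=1e-9)  # 42.86%

    def test_kinase_inhibitor_coil_accuracy(self):
        report = score_chains([("HHHCCCCCCCCC", "HHCCCCCCCCCC")])
        assert report.q_C == pytest.approx(100.0)

    def test_pooling_matches_summed_confusions(self, rng):
        pairs = [
            (random_ss(rng, int(rng.integers(5, 40))),) * 2 for _ in range(4)
        ]
        pairs = [(o, random_ss(rng, len(o))) for o, _ in pairs]
        report = score_chains(pairs)
        total = sum(confusion(o, p).counts for o, p in pairs)
        np.testing.assert_array_equal(report.confusion.counts, total)

    def test_mismatched_pair_names_chain(self):
        with pytest.raises(ValueError, match="bad_chain"):
            score_chains({"bad_chain": ("HH", "H")})

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no chain pairs"):
            score_chains([])
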