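import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fgrscreen import (
    DegenerateCutoffError,
    FgrScreenError,
    PRESET_O,
    PRESET_W,
    augment_with_sentinels,
    candidate_cutoffs,
    combine_cutoffs,
    paper_ow_preset,
    train_cutoff_set,
    youden_scan,
)
from fgrscreen.cutoffs import CutoffSet, DualCutoffs, LabeledQuotients


def brute_force_best_j(values, labels):
    """Independent oracle: maximal Youden J over every threshold that
    separates the data differently, by direct classification."""
    thresholds = sorted(set(values))
    candidates = [thresholds[0] - 1.0]
    candidates += [(a + b) / 2 for a, b in zip(thresholds, thresholds[1:])]
    candidates += [thresholds[-1] + 1.0]
    n_pos = sum(1 for l in labels if l == "FGR")
    n_neg = len(labels) - n_pos
    best = -2.0
    for c in candidates:
        tp = sum(1 for v, l in zip(values, labels) if l == "FGR" and v > c)
        fp = sum(1 for v, l in zip(values, labels) if l == "CTRL" and v > c)
        best = max(best, tp / n_pos + (n_neg - fp) / n_neg - 1.0)
    return best


def _labeled(values, labels, quotient="A"):
    return [
        LabeledQuotients(str(i), quotient, float(v), l)
        for i, (v, l) in enumerate(zip(values, labels))
    ]


class TestSentinels:
    def test_rule_applied_literally(self):
        assert augment_with_sentinels([2.0, 5.0, 3.0]) == [1.0, 2.0, 3.0, 5.0, 6.0]

    def test_single_value(self):
        assert augment_with_sentinels([4.2]) == [3.2, 4.2, 5.2]

    def test_duplicates_preserved(self):
        assert augment_with_sentinels([2, 2]) == [1, 2, 2, 3]

    def test_empty_rejected(self):
        with pytest.raises(FgrScreenError):
            augment_with_sentinels([])

    @given(st.lists(st.floats(0.1, 100.0), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True)
    def test_sentinels_bracket_data(self, values):
        out = augment_with_sentinels(values)
        assert len(out) == len(values) + 2
        assert out == sorted(out)
        assert out[0] == min(values) - 1 and out[-1] == max(values) + 1


class TestCandidates:
    def test_midpoints(self):
        assert candidate_cutoffs([1, 2, 3, 5, 6]) == [1.5, 2.5, 4.0, 5.5]

    def test_two_values(self):
        assert candidate_cutoffs([0, 10]) == [5.0]

    def test_equal_neighbors_degenerate_midpoint(self):
        assert candidate_cutoffs([1, 2, 2, 3]) == [1.5, 2.0, 2.5]

    def test_unsorted_rejected(self):
        with pytest.raises(FgrScreenError, match="sorted"):
            candidate_cutoffs([3, 1, 2])


class TestYoudenScan:
    def test_perfect_separation(self):
        data = _labeled([1, 2, 3, 10, 11, 12],
                        ["CTRL"] * 3 + ["FGR"] * 3)
        cutoff, jmax, sens, spec, scan = youden_scan(data)
        assert jmax == 1.0
        assert cutoff == 6.5  # midpoint of 3 and 10
        assert sens == 1.0 and spec == 1.0
        assert len(scan) == len(data) + 1

    def test_no_separation(self):
        data = _labeled([5, 5, 5, 5, 5, 5], ["CTRL"] * 3 + ["FGR"] * 3)
        _, jmax, _, _, _ = youden_scan(data)
        assert jmax == 0.0

    def test_overlapping_case_matches_brute_force(self):
        values = [1, 2, 3, 4.5, 4, 6, 7, 8]
        labels = ["CTRL"] * 4 + ["FGR"] * 4
        cutoff, jmax, *_ = youden_scan(_labeled(values, labels))
        assert jmax == pytest.approx(brute_force_best_j(values, labels))
        assert jmax == 0.75
        # two candidates tie at J = 0.75 (between 3 and 4, and between 4.5
        # and 6); the tie-break picks the smaller one
        assert cutoff == 3.5

    def test_single_label_rejected(self):
        with pytest.raises(FgrScreenError, match="sensitivity"):
            youden_scan(_labeled([1, 2], ["FGR", "FGR"]))

    def test_tie_broken_to_smallest_candidate(self):
        # two candidates achieve J=1; the smaller must win
        data = _labeled([1.0, 10.0], ["CTRL", "FGR"])
        cutoff, jmax, *_ = youden_scan(data)
        candidates = candidate_cutoffs(augment_with_sentinels([1.0, 10.0]))
        winners = [c for c in candidates if 1.0 <= c < 10.0]
        assert cutoff == min(winners)

    def test_jmax_bounds_and_random_oracle(self):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            n = int(rng.integers(2, 50))
            values = rng.uniform(0.1, 20.0, size=n).round(2)
            labels = list(rng.choice(["FGR", "CTRL"], size=n))
            if len(set(labels)) < 2:
                labels[0], labels[1] = "FGR", "CTRL"
            _, jmax, _, _, scan = youden_scan(_labeled(values, labels))
            assert jmax == pytest.approx(brute_force_best_j(list(values), labels))
            assert all(-1.0 <= row.youden_j <= 1.0 for row in scan)
            assert jmax >= 0.0

    def test_monotone_transform_preserves_classification(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(1.0, 9.0, size=20)
        labels = ["CTRL"] * 10 + ["FGR"] * 10
        cutoff, jmax, *_ = youden_scan(_labeled(values, labels))
        transformed = np.exp(values / 3.0)  # strictly increasing
        cutoff_t, jmax_t, *_ = youden_scan(_labeled(transformed, labels))
        assert jmax_t == pytest.approx(jmax)
        assert np.array_equal(values > cutoff, transformed > cutoff_t)


class TestTrainCutoffSet:
    def _table(self, rng=None, separated=True):
        rng = rng or np.random.default_rng(0)
        n = 14
        ctrl = pd.DataFrame({
            "A": rng.normal(2.5, 0.3, n), "B": rng.normal(3.0, 0.3, n),
            "C": rng.normal(2.5, 0.3, n), "label": "CTRL",
        })
        shift = 4.0 if separated else 0.0
        fgr = pd.DataFrame({
            "A": rng.normal(2.5 + shift, 0.3, n), "B": rng.normal(3.0 + shift, 0.3, n),
            "C": rng.normal(2.5 + shift, 0.3, n), "label": "FGR",
        })
        return pd.concat([ctrl, fgr], ignore_index=True)

    def test_separable_training_is_perfect(self):
        cs = train_cutoff_set(self._table())
        for q in "ABC":
            assert getattr(cs, q).jmax == 1.0
            assert getattr(cs, q).sensitivity == 1.0
            assert getattr(cs, q).specificity == 1.0

    def test_permuted_labels_give_near_zero_jmax(self):
        # after label permutation Jmax collapses from 1.0 to chance level
        # (the maximum over candidates keeps it somewhat above 0 at n=14+14)
        table = self._table()
        rng = np.random.default_rng(99)
        jmaxes = []
        for _ in range(10):
            permuted = table.assign(label=rng.permutation(table["label"].values))
            cs = train_cutoff_set(permuted)
            jmaxes.extend(getattr(cs, q).jmax for q in "ABC")
        assert max(jmaxes) <= 0.6
        assert float(np.median(jmaxes)) <= 0.4
        assert sum(j <= 0.45 for j in jmaxes) / len(jmaxes) >= 0.9

    def test_deterministic(self):
        t = self._table()
        c1, c2 = train_cutoff_set(t), train_cutoff_set(t)
        assert c1.cutoffs() == c2.cutoffs()

    def test_missing_column_rejected(self):
        with pytest.raises(FgrScreenError, match="'C'"):
            train_cutoff_set(self._table().drop(columns=["C"]))


class TestCombineCutoffs:
    def test_published_sets_combine_to_dual(self):
        dual = combine_cutoffs(PRESET_O, PRESET_W)
        assert dual.bounds("A") == (3.4, 4.2)
        assert dual.bounds("B") == (5.0, 7.0)
        assert dual.bounds("C") == (4.0, 5.1)
        assert paper_ow_preset() == dual

    def test_symmetric(self):
        assert combine_cutoffs(PRESET_W, PRESET_O) == combine_cutoffs(PRESET_O, PRESET_W)

    def test_equal_cutoff_degenerate(self):
        with pytest.raises(DegenerateCutoffError, match="A"):
            combine_cutoffs(PRESET_O, PRESET_O)

    def test_json_round_trip(self, tmp_path):
        dual = paper_ow_preset()
        p = tmp_path / "dual.json"
        dual.to_json(p)
        assert DualCutoffs.from_json(p) == dual
        p2 = tmp_path / "single.json"
        PRESET_O.to_json(p2)
        assert CutoffSet.from_json(p2).cutoffs() == PRESET_O.cutoffs()
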