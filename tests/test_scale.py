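import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from padcare import (
    EmotionBenchmark,
    PADScore,
    aggregate_items,
    classify_emotion,
    compute_pad,
    evaluate_all,
    proximity,
    validate_responses,
)
from padcare.scale import ITEM_CODES

from conftest import INCONSISTENT_CELLS


def _responses(rows):
    return pd.DataFrame(
        rows, columns=["respondent_id", "indicator_code", "item_code", "score"]
    )


class TestValidation:
    def test_boundary_scores_accepted_and_out_of_range_rejected(self, codebook):
        df = _responses(
            [
                ("r1", "S_1", "C1", 4),
                ("r1", "S_1", "C2", -4),
                ("r1", "S_1", "C3", 5),
                ("r1", "S_1", "C4", 3.5),
            ]
        )
        v = validate_responses(df, codebook)
        assert len(v.accepted) == 2
        assert list(v.rejected["reason"]) == ["out_of_range", "out_of_range"]

    def test_duplicate_unknown_indicator_and_item(self, codebook):
        df = _responses(
            [
                ("r1", "S_1", "C1", 2),
                ("r1", "S_1", "C1", 2),   # duplicate triple, first kept
                ("r1", "S_99", "C1", 1),
                ("r1", "S_1", "C13", 1),
            ]
        )
        v = validate_responses(df, codebook)
        assert len(v.accepted) == 1
        assert sorted(v.rejected["reason"]) == [
            "duplicate", "unknown_indicator", "unknown_item",
        ]

    def test_empty_input_raises(self, codebook):
        with pytest.raises(ValueError, match="no responses"):
            validate_responses(_responses([]), codebook)


class TestAggregation:
    def test_single_respondent_mean(self, codebook):
        df = _responses([("r1", "S_1", c, 1) for c in ITEM_CODES])
        means = aggregate_items(df, "S_1")
        assert (means == 1.0).all()

    def test_two_respondent_mean(self):
        rows = [("r1", "S_1", c, 2) for c in ITEM_CODES]
        rows += [("r2", "S_1", c, 3) for c in ITEM_CODES]
        means = aggregate_items(_responses(rows), "S_1")
        assert means["C1"] == 2.5

    def test_incomplete_respondent_dropped_or_error(self):
        rows = [("r1", "S_1", c, 2) for c in ITEM_CODES]
        rows += [("r2", "S_1", c, 4) for c in ITEM_CODES[:-1]]  # r2 misses C12
        df = _responses(rows)
        assert (aggregate_items(df, "S_1", missing="drop") == 2).all()
        with pytest.raises(ValueError, match="r2"):
            aggregate_items(df, "S_1", missing="error")

    def test_no_complete_respondent_raises(self):
        df = _responses([("r1", "S_1", "C1", 2)])
        with pytest.raises(ValueError, match="insufficient data"):
            aggregate_items(df, "S_1")


class TestComputePad:
    @pytest.mark.parametrize(
        "code, dim, expected",
        [("S_1", "P", 2.7050), ("S_1", "A", 1.6000), ("S_1", "D", 1.3600),
         ("S_4", "A", -0.7525), ("S_11", "D", 1.2375)],
    )
    def test_published_rows(self, item_means, code, dim, expected):
        row = item_means.set_index("indicator_code").loc[code]
        pad = compute_pad(row[list(ITEM_CODES)])
        assert getattr(pad, dim) == pytest.approx(expected, abs=1e-12)

    def test_zero_items_give_origin(self):
        pad = compute_pad({c: 0.0 for c in ITEM_CODES})
        assert (pad.P, pad.A, pad.D) == (0.0, 0.0, 0.0)

    def test_missing_item_raises(self):
        with pytest.raises(ValueError, match="C12"):
            compute_pad({c: 0.0 for c in ITEM_CODES[:-1]})

    @given(
        st.lists(
            st.lists(st.integers(-4, 4), min_size=12, max_size=12),
            min_size=1, max_size=8,
        )
    )
    def test_linearity_of_scoring(self, cohort):
        """Scoring per respondent then averaging equals averaging then scoring."""
        arr = np.array(cohort, dtype=float)
        mean_items = dict(zip(ITEM_CODES, arr.mean(axis=0)))
        pad_of_means = compute_pad(mean_items)
        per_resp = [compute_pad(dict(zip(ITEM_CODES, row))) for row in arr]
        for dim in ("P", "A", "D"):
            avg = np.mean([getattr(p, dim) for p in per_resp])
            assert abs(avg - getattr(pad_of_means, dim)) <= 1e-12

    @given(st.lists(st.floats(-4, 4), min_size=12, max_size=12))
    def test_range_invariant(self, items):
        """In-range items always yield P, A, D within the ±4 scale."""
        pad = compute_pad(dict(zip(ITEM_CODES, items)))
        for dim in ("P", "A", "D"):
            assert -4.0 <= getattr(pad, dim) <= 4.0


def _bench(name, p, a, d, no="01", polarity="positive"):
    return EmotionBenchmark(no=no, name=name, P=p, A=a, D=d, polarity=polarity)


class TestProximity:
    def test_hand_computed_distance_to_joy(self, benchmarks):
        joy = next(b for b in benchmarks if b.name == "Joy")
        got = proximity(PADScore(1, 1, 1), joy)
        assert got == pytest.approx(math.sqrt(1.77**2 + 0.21**2 + 0.42**2), abs=1e-12)
        assert round(got, 4) == 1.8312

    def test_identity_and_symmetry(self, benchmarks):
        for b in benchmarks:
            assert proximity(PADScore(b.P, b.A, b.D), b) == 0.0
        # symmetric in its two points
        x, y = PADScore(1.0, -2.0, 0.5), _bench("tmp", -0.5, 3.0, 1.5)
        assert proximity(x, y) == proximity(PADScore(y.P, y.A, y.D), _bench("tmp", x.P, x.A, x.D))

    @given(
        st.lists(st.floats(-4, 4, allow_nan=False), min_size=9, max_size=9)
    )
    def test_metric_properties_on_random_triples(self, coords):
        x = PADScore(*coords[0:3])
        y = _bench("y", *coords[3:6])
        z = _bench("z", *coords[6:9])
        dxy = proximity(x, y)
        dxz = proximity(x, z)
        dyz = proximity(PADScore(y.P, y.A, y.D), z)
        assert dxy >= 0
        assert dxy <= dxz + dyz + 1e-9
        if coords[0:3] == coords[3:6]:
            assert dxy == 0.0


class TestClassification:
    def test_benchmark_fixed_points(self, benchmarks):
        for b in benchmarks:
            res = classify_emotion(PADScore(b.P, b.A, b.D), benchmarks)
            assert res.tendency == b.name
            assert res.distances[b.name] == 0.0
            assert res.polarity == b.polarity

    @pytest.mark.parametrize(
        "pad, emotion, dist",
        [(PADScore(-2.0850, 1.1600, 0.7750), "Anger", 0.2127),
         (PADScore(-0.9600, 1.2500, -0.5750), "Fear", 0.0873)],
    )
    def test_published_argmin_examples(self, benchmarks, pad, emotion, dist):
        res = classify_emotion(pad, benchmarks)
        assert res.tendency == emotion
        assert res.distances[emotion] == pytest.approx(dist, abs=5e-4)

    def test_tie_broken_toward_lowest_code_and_flagged(self):
        names = ["E1", "E2", "E3", "E4", "E5", "E6", "E7", "E8"]
        pts = [(1, 0, 0), (-1, 0, 0), (0, 3, 0), (0, -3, 0),
               (3, 3, 0), (3, -3, 0), (-3, 3, 0), (-3, -3, 0)]
        pols = ["positive"] * 4 + ["negative"] * 4
        bench = [
            _bench(n, *p, no=f"{i+1:02d}", polarity=pol)
            for i, (n, p, pol) in enumerate(zip(names, pts, pols))
        ]
        res = classify_emotion(PADScore(0, 0, 0), bench)
        assert res.tendency == "E1" and res.tie and res.tied_with == ("E2",)

    def test_incomplete_benchmark_set_rejected(self, benchmarks):
        with pytest.raises(ValueError, match="8"):
            classify_emotion(PADScore(0, 0, 0), benchmarks[:7])

    def test_agrees_with_bruteforce_oracle_on_random_points(self, benchmarks):
        rng = np.random.default_rng(20240917)
        pts = rng.uniform(-4, 4, size=(1000, 3))
        coords = np.array([[b.P, b.A, b.D] for b in sorted(benchmarks, key=lambda b: b.no)])
        names = [b.name for b in sorted(benchmarks, key=lambda b: b.no)]
        for p in pts:
            res = classify_emotion(PADScore(*p), benchmarks)
            dists = np.sqrt(((p[None, :] - coords) ** 2).sum(axis=1))
            assert res.tendency == names[int(np.argmin(dists))]
            assert res.distances[res.tendency] == pytest.approx(dists.min(), abs=1e-12)


class TestEvaluateAll:
    def test_reproduces_published_pad_tendencies_and_distances(
        self, evaluated, published
    ):
        got = evaluated.set_index("indicator_code")
        for _, row in published.iterrows():
            g = got.loc[row.code]
            for dim in ("P", "A", "D"):
                assert round(g[dim], 4) == pytest.approx(row[dim], abs=1e-12)
            assert g["tendency"] == row["tendency"]
            for col in published.columns:
                if not col.startswith("dist_"):
                    continue
                cell = (row.code, col.removeprefix("dist_"))
                if cell in INCONSISTENT_CELLS:
                    # printed cell contradicts the printed PAD row; our value
                    # is the true distance from the printed PAD coordinates
                    assert abs(g[col] - row[col]) > 0.05
                else:
                    assert g[col] == pytest.approx(row[col], abs=5e-4)
        assert (evaluated["polarity"] == "positive").sum() == 10
        assert not evaluated["tie"].any()

    def test_permutation_invariance(self, item_means, codebook, benchmarks, evaluated):
        shuffled = item_means.sample(frac=1.0, random_state=3).reset_index(drop=True)
        again = evaluate_all(shuffled, codebook, benchmarks)
        pd.testing.assert_frame_equal(again, evaluated)

    def test_single_indicator_subset(self, item_means, codebook, benchmarks):
        sub = item_means[item_means["indicator_code"] == "S_13"]
        res = evaluate_all(sub, codebook, benchmarks)
        assert len(res) == 1
        assert res.loc[0, "tendency"] == "Reliance"
        assert res.loc[0, "dist_Reliance"] == pytest.approx(0.0798, abs=5e-4)

    def test_unknown_indicator_and_missing_rows_raise(
        self, item_means, codebook, benchmarks
    ):
        bad = item_means.copy()
        bad.loc[0, "indicator_code"] = "S_99"
        with pytest.raises(ValueError, match="S_99"):
            evaluate_all(bad, codebook, benchmarks)
        with pytest.raises(ValueError, match="S_1"):
            evaluate_all(
                item_means.iloc[1:], codebook, benchmarks, require_complete=True
            )

    def test_responses_and_item_means_paths_agree(
        self, item_means, codebook, benchmarks
    ):
        # integer-score cohort: one respondent per indicator
        rows = []
        ints = item_means.copy()
        for c in ITEM_CODES:
            ints[c] = np.sign(ints[c]) * np.ceil(np.abs(ints[c]) - 0.5)
        for _, r in ints.iterrows():
            rows += [("r1", r["indicator_code"], c, int(r[c])) for c in ITEM_CODES]
        long = _responses(rows)
        via_responses = evaluate_all(long, codebook, benchmarks)
        via_means = evaluate_all(
            ints[["indicator_code", *ITEM_CODES]], codebook, benchmarks
        )
        pd.testing.assert_frame_equal(via_responses, via_means)

    def test_rejects_unrecognized_table_shape(self, codebook, benchmarks):
        with pytest.raises(ValueError, match="item-means"):
            evaluate_all(pd.DataFrame({"x": [1]}), codebook, benchmarks)
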