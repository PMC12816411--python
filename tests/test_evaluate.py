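"""Correlation harness: Pearson r, the report join, and the window sweep."""

import numpy as np
import pandas as pd
import pytest

from mssc import (
    DataError,
    DimensionError,
    ScaleWindow,
    compute_mssc,
    correlation_report,
    load_ratings,
    pearson_r,
    window_sweep,
)
from mssc.benchmark import run_replicate
from mssc.synthetic import FixtureSpec, generate

from .conftest import mono


def ratings_frame(rows):
    return pd.DataFrame(rows, columns=["image_id", "category", "score"])


class TestPearsonR:
    def test_perfect_self_correlation(self):
        assert pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_perfect_reversal(self):
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_definitional_oracle(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        xc, yc = x - x.mean(), y - y.mean()
        expected = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_yields_none(self):
        assert pearson_r([1.0, 1.0, 1.0], [1, 2, 3]) is None

    def test_affine_invariance_and_sign_flip(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r = pearson_r(x, y)
        assert pearson_r(3.0 * x + 7.0, y) == pytest.approx(r, abs=1e-12)
        assert pearson_r(-2.0 * x, y) == pytest.approx(-r, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            pearson_r([1, 2, 3], [1, 2])


class TestRatingsIO:
    def test_load_valid_csv(self, tmp_path):
        p = tmp_path / "ratings.csv"
        p.write_text("image_id,category,score\na,cat,1.5\nb,cat,2.0\nc,cat,0.5\n")
        df = load_ratings(p)
        assert len(df) == 3
        assert df["score"].tolist() == [1.5, 2.0, 0.5]

    def test_bad_score_names_line(self, tmp_path):
        p = tmp_path / "ratings.csv"
        p.write_text("image_id,category,score\na,cat,1.5\nb,cat,oops\n")
        with pytest.raises(DataError, match="line 3"):
            load_ratings(p)

    def test_missing_column(self, tmp_path):
        p = tmp_path / "ratings.csv"
        p.write_text("image_id,score\na,1.5\n")
        with pytest.raises(DataError, match="category"):
            load_ratings(p)

    def test_duplicate_id_within_category(self, tmp_path):
        p = tmp_path / "ratings.csv"
        p.write_text("image_id,category,score\na,cat,1\na,cat,2\n")
        with pytest.raises(DataError, match="duplicate"):
            load_ratings(p)


def _scores_for(specs):
    return {fid: compute_mssc(generate(spec)) for fid, spec in specs}


@pytest.fixture(scope="module")
def mixed_scores():
    specs = [
        (f"img{i}", FixtureSpec("band_limited", 64, {"lo": 2.0, "hi": 6.0 + 3 * i}, seed=i))
        for i in range(6)
    ]
    return _scores_for(specs)


class TestCorrelationReport:
    def test_ratings_equal_totals_give_r_one(self, mixed_scores):
        ratings = ratings_frame(
            [{"image_id": i, "category": "only", "score": r.total} for i, r in mixed_scores.items()]
        )
        report = correlation_report(mixed_scores, ratings)
        r, n = report.totals["only"]
        assert r == pytest.approx(1.0)
        assert n == 6
        assert report.unmatched_ids == ()

    def test_constant_scores_yield_undefined_marker(self):
        scores = {f"c{i}": compute_mssc(mono(np.full((64, 64), 0.5))) for i in range(4)}
        ratings = ratings_frame(
            [{"image_id": f"c{i}", "category": "flat", "score": float(i)} for i in range(4)]
        )
        report = correlation_report(scores, ratings)
        r, n = report.totals["flat"]
        assert r is None and n == 4

    def test_unmatched_ids_surfaced_not_dropped(self, mixed_scores):
        rows = [
            {"image_id": i, "category": "only", "score": r.total} for i, r in mixed_scores.items()
        ]
        rows.append({"image_id": "ghost", "category": "only", "score": 1.0})
        report = correlation_report(mixed_scores, ratings_frame(rows))
        assert "ghost" in report.unmatched_ids
        assert report.totals["only"][1] == 6

    def test_row_order_irrelevant(self, mixed_scores):
        rows = [
            {"image_id": i, "category": "only", "score": 2.0 * r.total + 0.3}
            for i, r in mixed_scores.items()
        ]
        a = correlation_report(mixed_scores, ratings_frame(rows))
        b = correlation_report(mixed_scores, ratings_frame(rows[::-1]).reset_index(drop=True))
        assert a.totals == b.totals
        assert a.steps == b.steps

    def test_no_overlap_is_data_error(self, mixed_scores):
        ratings = ratings_frame([{"image_id": "zz", "category": "x", "score": 1.0}])
        with pytest.raises(DataError):
            correlation_report(mixed_scores, ratings)

    def test_long_frame_shape(self, mixed_scores):
        ratings = ratings_frame(
            [{"image_id": i, "category": "only", "score": r.total} for i, r in mixed_scores.items()]
        )
        frame = correlation_report(mixed_scores, ratings).to_frame()
        assert list(frame.columns) == ["category", "step_or_total", "r", "n"]
        assert len(frame) == 1 + 10  # one total row + one per step


class TestWindowSweep:
    def test_planted_single_step_recovered(self, rng):
        profiles = {f"i{j}": rng.uniform(0.1, 1.0, size=6) for j in range(20)}
        ratings = ratings_frame(
            [
                {"image_id": k, "category": "c", "score": float(p[3])}
                for k, p in profiles.items()
            ]
        )
        sweep = window_sweep(profiles, ratings)
        assert sweep.best == ScaleWindow(3, 3)
        best_row = sweep.table[(sweep.table.lo == 3) & (sweep.table.hi == 3)]
        assert best_row["mean_r"].iloc[0] == pytest.approx(1.0)

    def test_identical_profiles_all_undefined(self):
        profiles = {f"i{j}": np.ones(4) for j in range(5)}
        ratings = ratings_frame(
            [{"image_id": f"i{j}", "category": "c", "score": float(j)} for j in range(5)]
        )
        with pytest.raises(DataError, match="undefined"):
            window_sweep(profiles, ratings)

    def test_full_window_matches_total_correlation(self, mixed_scores):
        ratings = ratings_frame(
            [
                {"image_id": i, "category": "only", "score": float(np.sum(r.aggregate_profile()))}
                for i, r in mixed_scores.items()
            ]
        )
        profiles = {i: r.aggregate_profile() for i, r in mixed_scores.items()}
        sweep = window_sweep(profiles, ratings)
        full = sweep.per_category[
            (sweep.per_category.lo == 0) & (sweep.per_category.hi == 9)
        ]["r"].iloc[0]
        totals = [float(np.sum(p)) for p in profiles.values()]
        scores = ratings["score"].tolist()
        assert full == pytest.approx(pearson_r(totals, scores), abs=1e-12)
        assert full == pytest.approx(1.0)

    def test_two_category_planted_window_replicate(self):
        rep = run_replicate(seed=909, n_per_category=60)
        assert rep.recovered == ScaleWindow(2, 7)
        for meas, exp in zip(rep.r_measured, rep.r_expected):
            assert meas == pytest.approx(exp, abs=0.12)
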