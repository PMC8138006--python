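"""Minimum-attainable-error scoring, selection, and the Fisher projection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specell.discriminant import (
    SelectionPolicy,
    fit_canonical_projection,
    min_attainable_error,
    project,
    rank_features,
    select_features,
)


def brute_force_min_error(values, labels):
    """Independent oracle: try every midpoint threshold and both polarities."""
    v = np.asarray(values, float)
    y = np.asarray(labels)
    uniq = np.unique(v)
    thresholds = [-np.inf, np.inf] + [
        0.5 * (a + b) for a, b in zip(uniq[:-1], uniq[1:])
    ]
    best = 1.0
    for t in thresholds:
        for pred in ((v > t).astype(int), (v < t).astype(int)):
            best = min(best, float((pred != y).mean()))
    return best


class TestMinAttainableError:
    def test_perfect_separation(self):
        assert min_attainable_error([0, 1, 2, 3], [0, 0, 1, 1]).min_error == 0.0

    def test_indistinguishable_equal_priors(self):
        s = min_attainable_error([1] * 6, [0, 0, 0, 1, 1, 1])
        assert s.min_error == 0.5

    def test_overlapping_triples(self):
        s = min_attainable_error([1, 2, 3, 2, 3, 4], [0, 0, 0, 1, 1, 1])
        assert s.min_error == pytest.approx(1 / 3)

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 31))
            # integer grid values force ties and duplicates
            v = rng.integers(0, 8, size=n).astype(float)
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            assert min_attainable_error(v, y).min_error == pytest.approx(
                brute_force_min_error(v, y)
            )

    def test_threshold_achieves_reported_error(self, rng):
        for _ in range(50):
            v = rng.normal(size=20)
            y = rng.integers(0, 2, size=20)
            if len(np.unique(y)) < 2:
                continue
            s = min_attainable_error(v, y)
            pred = (v > s.threshold) if s.polarity == 1 else (v < s.threshold)
            assert (pred.astype(int) != y).mean() == pytest.approx(s.min_error)

    def test_single_class_is_fatal(self):
        with pytest.raises(ValueError, match="class"):
            min_attainable_error([1.0, 2.0], [1, 1])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=15)
        y = rng.integers(0, 2, size=15)
        if len(np.unique(y)) < 2:
            return
        base = min_attainable_error(v, y).min_error
        for f in (np.exp, lambda x: x**3, lambda x: np.arctan(2 * x)):
            assert min_attainable_error(f(v), y).min_error == pytest.approx(base)


def _table(columns: dict, labels):
    df = pd.DataFrame(columns)
    df.insert(0, "group_label", labels)
    df.insert(0, "cell_id", range(1, len(df) + 1))
    df.insert(0, "field_id", "F")
    df.insert(0, "patient_id", "P")
    return df


class TestRankAndSelect:
    def test_label_copy_ranks_first(self, rng):
        y = rng.integers(0, 2, size=30)
        df = _table({"a": rng.normal(size=30), "b": y.astype(float)}, y)
        scores = rank_features(df)
        assert scores[0].name == "b"
        assert scores[0].min_error == 0.0

    def test_identical_columns_tie_break_by_column_order(self, rng):
        y = np.array([0] * 10 + [1] * 10)
        v = rng.normal(size=20) + y
        df = _table({"z_first": v, "a_second": v.copy()}, y)
        scores = rank_features(df)
        assert [s.name for s in scores] == ["z_first", "a_second"]

    def test_redundant_duplicate_skipped(self, rng):
        y = np.array([0] * 10 + [1] * 10)
        v = rng.normal(size=20) + 2 * y
        df = _table({"a": v, "b": v * 2.0, "c": rng.normal(size=20)}, y)
        kept = select_features(rank_features(df), SelectionPolicy(n=2), df)
        assert kept == ["a", "c"]

    def test_overfitting_guard_boundary(self, rng):
        y = np.array([0] * 41 + [1] * 84)
        df = _table({f"f{i}": rng.normal(size=125) for i in range(45)}, y)
        scores = rank_features(df)
        assert len(select_features(scores, SelectionPolicy(n=6), df)) == 6
        with pytest.raises(ValueError, match="overfitting"):
            select_features(scores, SelectionPolicy(n=41), df)


def fisher_criterion(X, y, w):
    w = w / np.linalg.norm(w)
    z = X @ w
    z0, z1 = z[y == 0], z[y == 1]
    n0, n1 = len(z0), len(z1)
    sw = ((n0 - 1) * z0.var(ddof=1) + (n1 - 1) * z1.var(ddof=1)) / (n0 + n1 - 2)
    return (z1.mean() - z0.mean()) ** 2 / sw if sw > 0 else np.inf


class TestCanonicalProjection:
    def test_axis_aligned_separation_recovers_e1(self, rng):
        y = np.array([0] * 60 + [1] * 60)
        X = rng.normal(size=(120, 3))
        X[:, 0] += 6 * y
        df = _table({f"f{i}": X[:, i] for i in range(3)}, y)
        proj = fit_canonical_projection(df, ["f0", "f1", "f2"])
        assert abs(abs(proj.w1[0]) - 1) < 1e-2
        assert np.linalg.norm(proj.w1[1:]) < 0.15

    def test_unit_norm_and_orthogonality(self, rng):
        y = rng.integers(0, 2, size=40)
        y[:2], y[-2:] = 0, 1
        df = _table({f"f{i}": rng.normal(size=40) + 0.5 * y * i for i in range(5)}, y)
        proj = fit_canonical_projection(df, [f"f{i}" for i in range(5)])
        assert np.linalg.norm(proj.w1) == pytest.approx(1.0)
        assert np.linalg.norm(proj.w2) == pytest.approx(1.0)
        assert abs(proj.w1 @ proj.w2) < 1e-8

    def test_equal_class_means_warns_and_returns_variance_axis(self, rng, caplog):
        y = np.array([0, 1] * 20)
        base = rng.normal(size=40)
        df = _table({"a": base, "b": rng.normal(size=40) * 0.1}, y)
        # force exactly equal class means in both features
        for col in ("a", "b"):
            v = df[col].to_numpy()
            v[y == 1] = v[y == 0]
            df[col] = v
        import logging

        with caplog.at_level(logging.WARNING, logger="specell.discriminant"):
            proj = fit_canonical_projection(df, ["a", "b"])
        assert proj.fisher_criterion == 0.0
        # leading within-class variance axis is the (standardized) first feature
        assert abs(abs(proj.w1[0]) - 1) < 0.2 or np.linalg.norm(proj.w1) == pytest.approx(1.0)

    def test_w1_beats_1000_random_directions(self, rng):
        y = np.array([0] * 30 + [1] * 30)
        X = rng.normal(size=(60, 6))
        X += np.outer(y, rng.normal(size=6))
        df = _table({f"f{i}": X[:, i] for i in range(6)}, y)
        proj = fit_canonical_projection(df, [f"f{i}" for i in range(6)], gamma_grid=(0.0,))
        Z = (X - proj.means) / proj.sds
        c_star = fisher_criterion(Z, y, proj.w1)
        dirs = rng.normal(size=(1000, 6))
        crit = np.array([fisher_criterion(Z, y, d) for d in dirs])
        assert c_star >= crit.max() - 1e-9

    def test_w1_invariant_to_feature_rescaling(self, rng):
        y = np.array([0] * 25 + [1] * 25)
        X = rng.normal(size=(50, 4)) + np.outer(y, [1.0, -0.5, 0.3, 0.0])
        df1 = _table({f"f{i}": X[:, i] for i in range(4)}, y)
        scales = np.array([3.0, 0.1, 40.0, 1.0])
        df2 = _table({f"f{i}": X[:, i] * scales[i] for i in range(4)}, y)
        p1 = fit_canonical_projection(df1, [f"f{i}" for i in range(4)])
        p2 = fit_canonical_projection(df2, [f"f{i}" for i in range(4)])
        # standardization absorbs the rescaling entirely
        assert np.allclose(p1.w1, p2.w1, atol=1e-8)

    def test_projection_at_least_as_good_as_best_single_feature(self, rng):
        y = np.array([0] * 40 + [1] * 40)
        X = rng.normal(size=(80, 5)) + np.outer(y, [0.8, 0.6, 0.0, 0.2, -0.4])
        feats = [f"f{i}" for i in range(5)]
        df = _table(dict(zip(feats, X.T)), y)
        proj = fit_canonical_projection(df, feats)
        z = project(df, proj, dims=1)
        err_proj = min_attainable_error(z, y).min_error
        err_single = min(min_attainable_error(X[:, i], y).min_error for i in range(5))
        assert err_proj <= err_single + 1e-12

    def test_2d_first_axis_equals_1d_projection(self, rng):
        y = np.array([0] * 20 + [1] * 20)
        df = _table({f"f{i}": rng.normal(size=40) + y * (i + 1) / 4 for i in range(3)}, y)
        proj = fit_canonical_projection(df, [f"f{i}" for i in range(3)])
        xy = project(df, proj, dims=2)
        z = project(df, proj, dims=1)
        assert np.allclose(xy[:, 0], z)

    def test_zero_vector_cell_projects_to_negative_standardized_mean(self, rng):
        y = np.array([0] * 20 + [1] * 20)
        feats = [f"f{i}" for i in range(3)]
        df = _table({f: rng.normal(size=40) + y for f in feats}, y)
        proj = fit_canonical_projection(df, feats)
        zero = df.iloc[[0]].copy()
        zero[feats] = 0.0
        z = project(zero, proj, dims=1)
        assert z[0] == pytest.approx((-proj.means / proj.sds) @ proj.w1)

    def test_missing_feature_column_fatal(self, rng):
        y = np.array([0] * 10 + [1] * 10)
        feats = ["a", "b"]
        df = _table({f: rng.normal(size=20) + y for f in feats}, y)
        proj = fit_canonical_projection(df, feats)
        with pytest.raises(KeyError, match="b"):
            project(df.drop(columns=["b"]), proj)

    def test_group_one_projects_higher(self, rng):
        y = np.array([0] * 30 + [1] * 30)
        df = _table({"a": rng.normal(size=60) - 2 * y}, y)
        proj = fit_canonical_projection(df, ["a"])
        z = project(df, proj, dims=1)
        assert z[y == 1].mean() > z[y == 0].mean()
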