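"""Feature scoring, selection, and the canonical discriminant projection.

Features are scored by their *minimum attainable classification error*: the
smallest misclassification fraction achievable by a single threshold on that
feature, over both polarities, with cells weighted equally (so the error is
a pooled fraction under empirical class priors).  The best n features, with
n kept below the smaller group's cell count N to limit overfitting, feed a
Fisher discriminant: the first canonical axis maximizes between-group
scatter over within-group scatter; a second axis repeats the construction in
the orthogonal complement, giving the 2-D discriminative scatter space.  The
1-D projection used for histograms and the classifier score is the first
axis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import feature_columns

logger = logging.getLogger(__name__)

#: shrinkage grid for the pooled within-class covariance
GAMMA_GRID = (0.0, 0.05, 0.2, 0.5)


@dataclass(frozen=True)
class FeatureScore:
    """Score of one feature: its minimum attainable error and the achieving rule."""

    name: str
    min_error: float
    threshold: float
    polarity: int  # +1: predict class 1 when value > threshold; -1: when value < threshold

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_error <= 0.5 + 1e-12:
            raise ValueError(f"min_error {self.min_error} outside [0, 0.5]")


@dataclass(frozen=True)
class SelectionPolicy:
    """How many features to keep, guarded against overfitting.

    ``n`` must stay below ``n_min_group`` (N, the smaller group's cell
    count).  ``redundancy_rho`` caps the absolute correlation between kept
    features; near-duplicates (e.g. a channel's mean and its top-decile
    mean) would otherwise fill the whole subset.
    """

    n: int = 6
    n_min_group: int | None = None
    redundancy_rho: float = 0.95


def min_attainable_error(values, labels, name: str = "") -> FeatureScore:
    """Smallest threshold-rule misclassification fraction for one feature.

    Evaluates every threshold at midpoints between consecutive sorted unique
    values (plus +/- infinity) and both polarities; ties in error are broken
    toward the threshold at the midpoint of the widest achieving gap.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be 1-D and aligned")
    n = v.size
    n1 = int((y == 1).sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be non-empty")

    order = np.argsort(v, kind="mergesort")
    vs, ys = v[order], y[order]
    uniq, start_idx = np.unique(vs, return_index=True)
    # counts of class-1 / class-0 per unique value block
    ones = np.add.reduceat((ys == 1).astype(int), start_idx)
    zeros = np.add.reduceat((ys == 0).astype(int), start_idx)
    c1_le = np.concatenate([[0], np.cumsum(ones)])  # class-1 count with value <= boundary i
    c0_le = np.concatenate([[0], np.cumsum(zeros)])
    # boundary i sits between uniq[i-1] and uniq[i]; i = 0 is -inf, i = len is +inf
    m = uniq.size
    thresholds = np.empty(m + 1)
    widths = np.empty(m + 1)
    thresholds[0], widths[0] = -np.inf, np.inf
    thresholds[-1], widths[-1] = np.inf, np.inf
    if m > 1:
        thresholds[1:m] = 0.5 * (uniq[:-1] + uniq[1:])
        widths[1:m] = np.diff(uniq)
    # polarity +1: predict 1 when v > t  -> errors = (#1 <= t) + (#0 > t)
    err_pos = c1_le + (n0 - c0_le)
    # polarity -1: predict 1 when v < t  -> errors = (#1 >= t) + (#0 < t)
    err_neg = (n1 - c1_le) + c0_le

    best = None
    for polarity, err in ((1, err_pos), (-1, err_neg)):
        e_min = err.min()
        idx = np.flatnonzero(err == e_min)
        j = idx[np.argmax(widths[idx])]
        cand = (e_min / n, -widths[j], polarity, thresholds[j])
        if best is None or cand[:2] < best[:2]:
            best = cand
    e, _, pol, thr = best
    return FeatureScore(name=name, min_error=float(e), threshold=float(thr), polarity=pol)


def rank_features(table: pd.DataFrame, columns=None) -> list:
    """Score every feature column and return FeatureScores ascending by error.

    Ties are broken by canonical column order (the table's feature-column
    order), which is stable and documented.
    """
    cols = list(columns) if columns is not None else feature_columns(table)
    y = table["group_label"].to_numpy()
    scores = [min_attainable_error(table[c].to_numpy(), y, name=c) for c in cols]
    order = {c: i for i, c in enumerate(cols)}
    return sorted(scores, key=lambda s: (s.min_error, order[s.name]))


def select_features(
    scores, policy: SelectionPolicy, table: pd.DataFrame
) -> list:
    """Walk the ranking, skipping redundant features, keeping ``policy.n``.

    ``policy.n_min_group`` (N) defaults to the smaller group's cell count in
    ``table``; selecting n >= N is refused as an overfitting hazard.
    """
    y = table["group_label"].to_numpy()
    n_min_group = policy.n_min_group
    if n_min_group is None:
        n_min_group = int(min((y == 0).sum(), (y == 1).sum()))
    if policy.n >= n_min_group:
        raise ValueError(
            f"n = {policy.n} features must stay below the smaller group's cell "
            f"count N = {n_min_group} to limit overfitting"
        )
    kept: list = []
    kept_values = []
    for s in scores:
        if len(kept) == policy.n:
            break
        v = table[s.name].to_numpy(dtype=float)
        redundant = False
        for kv in kept_values:
            sd_v, sd_k = v.std(), kv.std()
            if sd_v == 0 or sd_k == 0:
                rho = 1.0 if sd_v == sd_k else 0.0
            else:
                rho = abs(np.corrcoef(v, kv)[0, 1])
            if rho > policy.redundancy_rho:
                redundant = True
                break
        if not redundant:
            kept.append(s.name)
            kept_values.append(v)
    if len(kept) < policy.n:
        logger.warning(
            "only %d of %d requested features survive the redundancy cap",
            len(kept),
            policy.n,
        )
    return kept


@dataclass
class CanonicalProjection:
    """Selected features, standardization constants, and discriminant axes.

    ``w1`` is the Fisher direction; ``w2`` the Fisher direction restricted to
    the orthogonal complement of ``w1`` (the classical two-class analysis
    yields only one canonical variable, so the second scatter axis is this
    greedy orthogonal construction).  ``w1d = w1`` is the optimal 1-D
    projection.  All unit length, signed so group 1 projects higher than
    group 0 on ``w1``.
    """

    features: list
    w1: np.ndarray
    w2: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    gamma: float
    fisher_criterion: float

    @property
    def w1d(self) -> np.ndarray:
        return self.w1

    def to_json(self, path) -> None:
        payload = {
            "features": list(self.features),
            "w1": self.w1.tolist(),
            "w2": self.w2.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "gamma": self.gamma,
            "fisher_criterion": self.fisher_criterion,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, path) -> "CanonicalProjection":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            features=p["features"],
            w1=np.array(p["w1"]),
            w2=np.array(p["w2"]),
            means=np.array(p["means"]),
            sds=np.array(p["sds"]),
            gamma=p["gamma"],
            fisher_criterion=p["fisher_criterion"],
        )


def _fisher_direction(X0, X1, gamma):
    """Fisher direction w ~ Sw^-1 (m1 - m0) with diagonal shrinkage gamma."""
    m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
    delta = m1 - m0
    S0 = np.cov(X0, rowvar=False, ddof=1) if X0.shape[0] > 1 else np.zeros((X0.shape[1],) * 2)
    S1 = np.cov(X1, rowvar=False, ddof=1) if X1.shape[0] > 1 else np.zeros((X1.shape[1],) * 2)
    n0, n1 = X0.shape[0], X1.shape[0]
    Sw = ((n0 - 1) * np.atleast_2d(S0) + (n1 - 1) * np.atleast_2d(S1)) / max(n0 + n1 - 2, 1)
    Sw = (1 - gamma) * Sw + gamma * np.diag(np.diag(Sw))
    # ridge floor keeps the solve well-posed even for constant features
    Sw = Sw + 1e-10 * np.eye(Sw.shape[0]) * max(np.trace(Sw), 1.0)
    try:
        w = np.linalg.solve(Sw, delta)
    except np.linalg.LinAlgError:
        w = np.linalg.lstsq(Sw, delta, rcond=None)[0]
    return w, delta, Sw


def _criterion(w, delta, Sw):
    denom = w @ Sw @ w
    return float((w @ delta) ** 2 / denom) if denom > 0 else 0.0


def fit_canonical_projection(
    table: pd.DataFrame, features, gamma_grid=GAMMA_GRID
) -> CanonicalProjection:
    """Fit the standardized two-axis Fisher projection on selected features.

    Features are standardized by training mean/SD.  The shrinkage intensity
    gamma (toward the diagonal of the pooled within-class covariance) is
    chosen from a small fixed grid by the training minimum attainable error
    of the 1-D projection, preferring heavier shrinkage on ties for
    stability with few cells.
    """
    features = list(features)
    X = table[features].to_numpy(dtype=float)
    y = table["group_label"].to_numpy()
    if (y == 0).sum() < 2 or (y == 1).sum() < 2:
        raise ValueError("need at least 2 cells per class")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    sds = np.where(sds == 0, 1.0, sds)
    Z = (X - means) / sds
    Z0, Z1 = Z[y == 0], Z[y == 1]

    degenerate = (
        np.linalg.norm(Z1.mean(axis=0) - Z0.mean(axis=0)) < 1e-12
    )
    if degenerate:
        logger.warning("equal class means: Fisher criterion 0; returning variance axes")
        gamma = gamma_grid[0]
        _, delta, Sw = _fisher_direction(Z0, Z1, gamma)
        evals, evecs = np.linalg.eigh(Sw)
        w1 = evecs[:, -1]
    else:
        best = None
        for gamma in gamma_grid:
            w, delta, Sw = _fisher_direction(Z0, Z1, gamma)
            norm = np.linalg.norm(w)
            if norm == 0 or not np.all(np.isfinite(w)):
                continue
            w = w / norm
            err = min_attainable_error(Z @ w, y).min_error
            if best is None or err <= best[0] - 1e-12 or (abs(err - best[0]) < 1e-12):
                best = (err, gamma, w, delta, Sw)
        if best is None:
            raise ValueError("within-class scatter singular for every shrinkage level")
        _, gamma, w1, delta, Sw = best

    # second axis: Fisher direction restricted to the orthogonal complement of w1
    k = w1.size
    if k > 1:
        basis = np.linalg.svd(np.eye(k) - np.outer(w1, w1))[0][:, : k - 1]
        Z0c, Z1c = Z0 @ basis, Z1 @ basis
        wc, delta_c, Sw_c = _fisher_direction(Z0c, Z1c, gamma)
        if np.linalg.norm(delta_c) < 1e-12 or np.linalg.norm(wc) == 0:
            evals, evecs = np.linalg.eigh(Sw_c)
            wc = evecs[:, -1]
        w2 = basis @ (wc / np.linalg.norm(wc))
    else:
        w2 = np.zeros(1)

    # sign convention: group 1 mean projects higher than group 0
    for w in (w1, w2):
        if (Z1.mean(axis=0) - Z0.mean(axis=0)) @ w < 0:
            w *= -1.0
    crit = _criterion(w1, delta, Sw) if not degenerate else 0.0
    return CanonicalProjection(
        features=features,
        w1=w1,
        w2=w2,
        means=means,
        sds=sds,
        gamma=float(gamma),
        fisher_criterion=crit,
    )


def project(table: pd.DataFrame, projection: CanonicalProjection, dims: int = 1) -> np.ndarray:
    """Project cells onto the canonical axes; (n_cells,) for 1-D, (n_cells, 2) for 2-D."""
    missing = [f for f in projection.features if f not in table.columns]
    if missing:
        raise KeyError(f"table lacks projection features {missing}")
    Z = (table[projection.features].to_numpy(dtype=float) - projection.means) / projection.sds
    if dims == 1:
        return Z @ projection.w1d
    if dims == 2:
        return np.column_stack([Z @ projection.w1, Z @ projection.w2])
    raise ValueError("dims must be 1 or 2")
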