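"""Survival-based evaluation of BiNet gene sets as prognostic biomarkers.

For each BiNet, the union of its tumor- and stroma-side genes is taken as a
feature set over a patient cohort; patients are split into two groups with
a K=2 city-block K-means (median centroid update, best of 100 restarts),
and the two groups' survival curves are compared with the standard
two-group log-rank test.  A BiNet is called prognostic in a cohort when the
log-rank p-value is below 0.05 (raw, uncorrected; a Benjamini-Hochberg
option is available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import chi2
from sklearn.base import BaseEstimator, ClusterMixin

from .mining import BiNet

__all__ = [
    "SurvivalCohort",
    "SplitResult",
    "LogRankResult",
    "CityBlockKMeans",
    "binet_feature_matrix",
    "two_group_split",
    "logrank",
    "evaluate_binets",
    "summarize_evaluation",
]

logger = logging.getLogger(__name__)


@dataclass
class SurvivalCohort:
    """Follow-up times, event indicators and per-sample gene features."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    features: pd.DataFrame  # samples x genes

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length must match sample_ids")
        if np.any(self.time < 0):
            raise ValueError("negative follow-up time")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        if self.features.shape[0] != n:
            raise ValueError("feature rows must match sample_ids")
        if self.features.columns.has_duplicates:
            raise ValueError("duplicate feature column ids")


@dataclass
class SplitResult:
    labels: np.ndarray
    inertia: float
    n_restarts_used: int
    seed: int | None
    degenerate: bool = False


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    group_sizes: tuple[int, int]
    observed_events: tuple[float, float]
    expected_events: tuple[float, float]


class CityBlockKMeans(BaseEstimator, ClusterMixin):
    """K-means under city-block (L1) distance with median centroid update.

    The component-wise median minimizes total L1 distance, so each
    Lloyd-style iteration cannot increase the within-cluster cost.  The
    best of ``n_init`` random restarts (lowest total L1 cost, ties to the
    first found) is kept.

    Attributes
    ----------
    labels_ : int ndarray of shape (n_samples,)
    inertia_ : float
        Total within-cluster L1 cost of the best restart.
    cluster_centers_ : ndarray of shape (n_clusters, n_features)
    degenerate_ : bool
        True when all rows are identical, in which case no meaningful
        split exists and all labels are 0.
    """

    def __init__(self, n_clusters: int = 2, n_init: int = 100, max_iter: int = 100,
                 random_state: int | None = None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None) -> "CityBlockKMeans":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < self.n_clusters:
            raise ValueError("need a 2-D matrix with at least n_clusters rows")
        rng = np.random.default_rng(self.random_state)
        unique_rows = np.unique(X, axis=0)
        if unique_rows.shape[0] < self.n_clusters:
            self.labels_ = np.zeros(X.shape[0], dtype=int)
            self.inertia_ = 0.0
            self.cluster_centers_ = np.repeat(X[:1], self.n_clusters, axis=0)
            self.degenerate_ = True
            return self
        best_cost = np.inf
        best: tuple[np.ndarray, np.ndarray] | None = None
        for _ in range(self.n_init):
            centers = X[rng.choice(X.shape[0], self.n_clusters, replace=False)]
            labels = None
            for _it in range(self.max_iter):
                d = cdist(X, centers, metric="cityblock")
                new_labels = d.argmin(axis=1)
                for k in range(self.n_clusters):
                    if (new_labels == k).any():
                        centers[k] = np.median(X[new_labels == k], axis=0)
                    else:  # re-seed an emptied cluster at the worst-fit row
                        centers[k] = X[d.min(axis=1).argmax()]
                        new_labels[d.min(axis=1).argmax()] = k
                if labels is not None and np.array_equal(labels, new_labels):
                    break
                labels = new_labels
            cost = cdist(X, centers, metric="cityblock")[
                np.arange(X.shape[0]), labels
            ].sum()
            if cost < best_cost - 1e-12:
                best_cost = cost
                best = (labels.copy(), centers.copy())
        self.labels_, self.cluster_centers_ = best
        self.inertia_ = float(best_cost)
        self.degenerate_ = False
        return self


def two_group_split(
    features, n_restarts: int = 100, seed: int | None = None
) -> SplitResult:
    """Split samples into two groups by L1 K-means on their feature rows."""
    X = np.asarray(features, dtype=float)
    if X.shape[0] < 2 or X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("need >= 2 samples and >= 1 feature")
    km = CityBlockKMeans(n_clusters=2, n_init=n_restarts, random_state=seed).fit(X)
    return SplitResult(
        labels=km.labels_,
        inertia=km.inertia_,
        n_restarts_used=n_restarts,
        seed=seed,
        degenerate=km.degenerate_,
    )


def logrank(time, event, labels) -> LogRankResult:
    """Two-group log-rank test.

    At every distinct event time the observed events in group 1 are
    compared with their hypergeometric expectation given the risk sets;
    the statistic (sum(O1 - E1))**2 / sum(V) is chi-square with 1 df under
    the null of equal hazards.  Censored samples leave the risk set at
    their censoring time.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = np.asarray(labels, dtype=int)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("exactly two non-empty groups required")
    g1 = labels == groups[1]
    n1_tot, n2_tot = int(g1.sum()), int((~g1).sum())

    o1 = o2 = e1 = v = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        o1 += d1
        o2 += d - d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v == 0:
        stat, p = 0.0, 1.0
    else:
        stat = (o1 - e1) ** 2 / v
        p = float(chi2.sf(stat, df=1))
    e2 = (o1 + o2) - e1
    return LogRankResult(
        statistic=float(stat),
        p_value=p,
        group_sizes=(n2_tot, n1_tot),
        observed_events=(float(o2), float(o1)),
        expected_events=(float(e2), float(e1)),
    )


def binet_feature_matrix(binet: BiNet, cohort: SurvivalCohort) -> pd.DataFrame:
    """Restrict the cohort's feature columns to the BiNet's union gene set.

    Genes absent from the cohort are dropped with a logged count; zero
    overlap raises, and evaluate_binets records the skip.
    """
    genes = sorted(binet.genes)
    present = [g for g in genes if g in cohort.features.columns]
    missing = len(genes) - len(present)
    if not present:
        raise ValueError("no BiNet gene present among cohort features")
    if missing:
        logger.warning("%d of %d BiNet genes absent from cohort", missing, len(genes))
    return cohort.features[present]


def evaluate_binets(
    binets: list[BiNet],
    cohorts: dict[str, SurvivalCohort],
    n_restarts: int = 100,
    seed: int = 0,
    standardize: bool = False,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Log-rank evaluation of every BiNet on every cohort.

    Returns one row per (BiNet, cohort) with columns binet_id, cohort, n1,
    n2, statistic, p_value, poor_group, status.  By default raw p-values
    are reported (no multiple-testing correction); ``bh_correct`` adds a
    Benjamini-Hochberg ``q_value`` column.
    """
    rows = []
    for bi, binet in enumerate(binets):
        for name, cohort in cohorts.items():
            row = {
                "binet_id": bi,
                "cohort": name,
                "n1": 0,
                "n2": 0,
                "statistic": np.nan,
                "p_value": np.nan,
                "poor_group": -1,
                "status": "ok",
            }
            try:
                feats = binet_feature_matrix(binet, cohort)
            except ValueError:
                row["status"] = "no_overlap"
                rows.append(row)
                continue
            X = feats.to_numpy()
            if standardize:
                sd = X.std(axis=0, ddof=1)
                X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
            split = two_group_split(X, n_restarts=n_restarts, seed=seed)
            if split.degenerate or len(np.unique(split.labels)) < 2:
                row["status"] = "degenerate"
                rows.append(row)
                continue
            lr = logrank(cohort.time, cohort.event, split.labels)
            rate0 = lr.observed_events[0] / max(lr.group_sizes[0], 1)
            rate1 = lr.observed_events[1] / max(lr.group_sizes[1], 1)
            row.update(
                n1=lr.group_sizes[0],
                n2=lr.group_sizes[1],
                statistic=lr.statistic,
                p_value=lr.p_value,
                poor_group=int(rate1 > rate0),
            )
            rows.append(row)
    table = pd.DataFrame(rows)
    if bh_correct and len(table):
        from statsmodels.stats.multitest import multipletests

        ok = table["status"] == "ok"
        q = np.full(len(table), np.nan)
        if ok.any():
            q[ok.to_numpy()] = multipletests(
                table.loc[ok, "p_value"], method="fdr_bh"
            )[1]
        table["q_value"] = q
    table.attrs["alpha"] = alpha
    table.attrs["multiple_testing"] = "bh" if bh_correct else "none (raw p-values)"
    return table


def summarize_evaluation(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Counts of significant BiNets per cohort and in >= 1 cohort."""
    ok = table[table["status"] == "ok"]
    per_cohort = {
        name: int((grp["p_value"] < alpha).sum())
        for name, grp in ok.groupby("cohort")
    }
    sig_any = ok[ok["p_value"] < alpha]["binet_id"].nunique()
    return {
        "per_cohort": per_cohort,
        "significant_in_any": int(sig_any),
        "n_binets": int(table["binet_id"].nunique()) if len(table) else 0,
    }
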