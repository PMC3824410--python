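"""Age-trend profiles, silhouette-gated k-means, and acceleration calling.

A gene's *trend profile* is its mean expression over equal-count age bins,
z-standardized across bins: it captures the shape of the age trajectory,
not its level, so Euclidean k-means groups genes by how they change with
age.  Alongside the profile a per-gene least-squares slope (log2 units per
year) is computed on the raw age/expression pairs; slopes drive the
accelerated/decelerated calls.

The clustering is gated on the per-cluster average silhouette width S_avg:
starting from k = 2, partitions are re-run with fresh seeds and k is
incremented until every cluster reaches S_avg >= 0.6 (default), capped at
k = 20; if no partition qualifies the best-scoring one is returned flagged
as not accepted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

logger = logging.getLogger(__name__)

TREND_LABELS = ("accelerated", "decelerated", "concordant", "discordant", "flat")


@dataclass
class TrendProfiles:
    """Standardized bin-mean profiles and OLS slopes for one cohort."""

    cohort: str
    profiles: pd.DataFrame  # genes x bins, z-scored per gene
    slopes: pd.Series  # log2 units per year
    bin_ages: np.ndarray  # mean age per bin
    constant_genes: list = field(default_factory=list)


@dataclass
class ClusterSet:
    k: int
    assignment: pd.Series  # gene -> cluster index
    centroids: np.ndarray  # k x n_features
    s_avg: dict[int, float]  # per-cluster average silhouette
    accepted: bool
    mean_silhouette: float
    inertia: float


def build_trend_profiles(
    expr: pd.DataFrame, meta: pd.DataFrame, cohort: str, n_bins: int = 5
) -> TrendProfiles:
    """Bin one cohort's samples into equal-count age bins and standardize the
    per-gene bin means.

    Bins are quantile bins over age; duplicated ages that exhaust a bin cause
    bins to be merged with a warning.  Constant genes get an all-zero profile
    and are flagged.
    """
    if n_bins < 3:
        raise ValueError("need n_bins >= 3")
    sub_meta = meta[meta["cohort"] == cohort]
    if len(sub_meta) < n_bins:
        raise ValueError(f"cohort {cohort!r} has fewer samples than bins")
    samples = sub_meta["sample_id"].to_numpy()
    ages = sub_meta["age_years"].to_numpy(dtype=float)

    bins = pd.qcut(ages, q=n_bins, labels=False, duplicates="drop")
    if bins.max() + 1 < n_bins:
        warnings.warn(
            f"duplicated ages collapsed {n_bins} bins to {bins.max() + 1}", stacklevel=2
        )

    values = expr[samples].to_numpy(dtype=float)
    n_used = int(bins.max()) + 1
    bin_means = np.column_stack(
        [values[:, bins == b].mean(axis=1) for b in range(n_used)]
    )
    bin_ages = np.array([ages[bins == b].mean() for b in range(n_used)])

    mu = bin_means.mean(axis=1, keepdims=True)
    sd = bin_means.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    profiles = (bin_means - mu) / sd
    profiles[constant] = 0.0

    # per-gene OLS slope over all cohort samples
    age_c = ages - ages.mean()
    denom = float(np.sum(age_c**2))
    slopes = (values - values.mean(axis=1, keepdims=True)) @ age_c / denom

    constant_genes = list(expr.index[constant])
    if constant_genes:
        logger.info("build_trend_profiles: %d constant genes flagged", len(constant_genes))
    return TrendProfiles(
        cohort=cohort,
        profiles=pd.DataFrame(profiles, index=expr.index),
        slopes=pd.Series(slopes, index=expr.index, name="slope"),
        bin_ages=bin_ages,
        constant_genes=constant_genes,
    )


def silhouette_values(points: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    """Per-point silhouette widths s(i) = (b - a) / max(a, b).

    a(i) is the mean distance to the other members of i's cluster, b(i) the
    smallest mean distance to any other cluster.  Singleton-cluster members
    get s = 0, as do points where max(a, b) = 0 (all distances degenerate).
    """
    points = np.asarray(points, dtype=float)
    assignment = np.asarray(assignment)
    labels = np.unique(assignment)
    if len(labels) < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    dist = cdist(points, points)
    n = len(points)
    s = np.zeros(n)
    sizes = {lab: int(np.sum(assignment == lab)) for lab in labels}
    for i in range(n):
        own = assignment[i]
        if sizes[own] == 1:
            continue  # singleton convention: s = 0
        mask_own = assignment == own
        a = dist[i, mask_own].sum() / (sizes[own] - 1)
        b = min(
            dist[i, assignment == lab].mean() for lab in labels if lab != own
        )
        denom = max(a, b)
        s[i] = (b - a) / denom if denom > 0 else 0.0
    return s


def average_silhouette(points: np.ndarray, assignment: np.ndarray) -> dict[int, float]:
    """Per-cluster mean silhouette width S_avg."""
    s = silhouette_values(points, assignment)
    assignment = np.asarray(assignment)
    return {int(lab): float(s[assignment == lab].mean()) for lab in np.unique(assignment)}


def _lloyd(
    x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """One k-means run (k-means++ init, Lloyd iterations).

    Returns (labels, centers, inertia, objective trace); the trace of the
    within-cluster sum of squares is non-increasing by construction.
    """
    centers, _ = kmeans_plusplus(
        x, n_clusters=k, random_state=int(rng.integers(2**31 - 1))
    )
    trace: list[float] = []
    labels = np.zeros(len(x), dtype=int)
    for _ in range(max_iter):
        dist2 = cdist(x, centers, metric="sqeuclidean")
        new_labels = dist2.argmin(axis=1)
        inertia = float(dist2[np.arange(len(x)), new_labels].sum())
        trace.append(inertia)
        if trace[:-1] and trace[-1] >= trace[-2] - 1e-12 and np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
        for j in range(k):
            members = x[labels == j]
            if len(members):
                centers[j] = members.mean(axis=0)
            else:  # re-seed empty cluster at the farthest point
                centers[j] = x[dist2.min(axis=1).argmax()]
    inertia = float(
        cdist(x, centers, metric="sqeuclidean")[np.arange(len(x)), labels].sum()
    )
    return labels, centers, inertia, trace


def silhouette_gated_kmeans(
    profiles: pd.DataFrame,
    k_max: int = 20,
    s_min: float = 0.6,
    max_restarts: int = 5,
    seed: int = 0,
) -> ClusterSet:
    """Smallest k whose every cluster clears the silhouette gate.

    For each k = 2..k_max the k-means run is restarted ``max_restarts`` times
    with fresh seeds; the first partition in which every cluster has
    S_avg >= s_min is returned.  If no partition qualifies, the one with the
    highest overall mean silhouette is returned with ``accepted=False``.
    """
    x = profiles.to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    rng = np.random.default_rng(seed)
    best: ClusterSet | None = None
    for k in range(2, min(k_max, len(x) - 1) + 1):
        for _ in range(max_restarts):
            labels, centers, inertia, _ = _lloyd(x, k, rng)
            if len(np.unique(labels)) < 2:
                continue
            s_avg = average_silhouette(x, labels)
            mean_s = float(silhouette_values(x, labels).mean())
            candidate = ClusterSet(
                k=k,
                assignment=pd.Series(labels, index=profiles.index, name="cluster"),
                centroids=centers,
                s_avg=s_avg,
                accepted=all(v >= s_min for v in s_avg.values()),
                mean_silhouette=mean_s,
                inertia=inertia,
            )
            if candidate.accepted:
                return candidate
            if best is None or candidate.mean_silhouette > best.mean_silhouette:
                best = candidate
    assert best is not None
    logger.info(
        "silhouette_gated_kmeans: no partition reached S_avg >= %.2f up to k=%d; "
        "returning best (k=%d, mean silhouette %.3f)",
        s_min, k_max, best.k, best.mean_silhouette,
    )
    return best


def classify_acceleration(
    control: TrendProfiles,
    carrier: TrendProfiles,
    ratio_threshold: float = 1.5,
    flat_threshold: float = 0.005,
) -> pd.DataFrame:
    """Label each gene by how its carrier age-slope compares to its control
    age-slope.

    With r = carrier_slope / control_slope (same-sign slopes give r > 0):
    ``accelerated`` if r >= ratio_threshold, ``decelerated`` if
    r <= 1/ratio_threshold, ``concordant`` otherwise; opposite signs give
    ``discordant``; genes with both slopes below ``flat_threshold`` in
    magnitude are ``flat``.  A trend present only in carriers (flat control,
    non-flat carrier) counts as accelerated.
    """
    genes = control.slopes.index.intersection(carrier.slopes.index)
    skipped = len(control.slopes.index.symmetric_difference(carrier.slopes.index))
    if skipped:
        logger.info("classify_acceleration: skipped %d genes missing from one cohort", skipped)
    if len(genes) == 0:
        raise ValueError("no gene is present in both cohorts")

    ctl = control.slopes.loc[genes].to_numpy()
    car = carrier.slopes.loc[genes].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ctl != 0, car / ctl, np.nan)

    labels = np.empty(len(genes), dtype=object)
    flat_ctl = np.abs(ctl) < flat_threshold
    flat_car = np.abs(car) < flat_threshold
    labels[:] = "concordant"
    labels[ratio >= ratio_threshold] = "accelerated"
    labels[ratio <= 1.0 / ratio_threshold] = "decelerated"
    labels[np.sign(ctl) * np.sign(car) < 0] = "discordant"
    labels[flat_ctl & ~flat_car] = "accelerated"  # carrier-only trend
    labels[flat_ctl & flat_car] = "flat"

    return pd.DataFrame(
        {
            "label": labels,
            "control_slope": ctl,
            "carrier_slope": car,
            "slope_ratio": ratio,
        },
        index=genes,
    )


def summarize_clusters(labels: pd.DataFrame, clusters: ClusterSet) -> pd.DataFrame:
    """Majority trend label and size per cluster."""
    joined = labels.join(clusters.assignment, how="inner")
    rows = []
    for cluster, sub in joined.groupby("cluster"):
        rows.append(
            {
                "cluster": cluster,
                "n_genes": len(sub),
                "majority_label": sub["label"].mode().iloc[0],
                "s_avg": clusters.s_avg.get(int(cluster), np.nan),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
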