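"""Clustering social event types by their thermal signatures.

Each event type gets a profile vector of per-subject mean residual log
temperatures (residual = log temperature minus the estimated ambient and
movement confound effects), plus the type's overall mean and SD.
Profiles are standardized and clustered agglomeratively with Ward's
minimum-variance criterion; the number of clusters is chosen by mean
silhouette width.  Cophenetic correlations for Ward and single linkage
are reported as a linkage-adequacy check.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_samples

from .simulate import CLUSTER_A_TYPES, CLUSTER_B_TYPES, CLUSTER_C_TYPES

logger = logging.getLogger(__name__)


def build_profiles(events: pd.DataFrame,
                   ambient_slope: float,
                   movement_effects: dict[str, float],
                   response: str = "log_temp",
                   ambient_column: str = "ambient_centered",
                   exclude_types: tuple[str, ...] = ("baseline",)
                   ) -> pd.DataFrame:
    """Per-event-type feature vectors of confound-adjusted temperatures.

    ``residual = log_temp - ambient_slope * ambient_centered - movement
    offset``; the profile of a type is its per-subject mean residual
    (subjects with no events of that type filled with the subject's
    grand-mean residual), plus the type's overall mean and SD appended.
    Event types in ``exclude_types`` (the resting baseline by default)
    are left out; so are types with zero events, with a log message.
    """
    ev = events.loc[~events["event_type"].isin(exclude_types)].copy()
    if ev.empty:
        raise ValueError("no events left after excluding baseline")
    offsets = ev["movement"].map(movement_effects)
    if offsets.isna().any():
        missing = sorted(set(ev.loc[offsets.isna(), "movement"]))
        raise ValueError(f"movement levels without an estimated offset: {missing}")
    ev["residual"] = (ev[response]
                      - ambient_slope * ev[ambient_column]
                      - offsets)

    subjects = sorted(events["subject_id"].unique())
    grand = ev.groupby("subject_id")["residual"].mean()
    cell = (ev.groupby(["event_type", "subject_id"])["residual"].mean()
            .unstack("subject_id").reindex(columns=subjects))
    n_filled = int(cell.isna().sum().sum())
    if n_filled:
        logger.info("%d subject-by-type cells had no events; filled with the "
                    "subject's grand-mean residual", n_filled)
    cell = cell.fillna(grand)
    cell["overall_mean"] = ev.groupby("event_type")["residual"].mean()
    cell["overall_sd"] = ev.groupby("event_type")["residual"].std(ddof=1).fillna(0.0)
    return cell.sort_index()


@dataclass
class ClusterResult:
    """Ward linkage over event types with the silhouette-chosen cut."""

    labels: list[str]  # event types, in profile order
    linkage_matrix: np.ndarray  # scipy linkage format
    chosen_k: int
    assignment: dict[str, int]  # event type -> cluster id (1..k)
    silhouette_by_k: dict[int, float]
    silhouette_widths: dict[str, float]  # per event type, at chosen k
    cophenetic: dict[str, float]  # linkage method -> cophenetic correlation

    def cut(self, k: int) -> dict[str, int]:
        flat = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))


def ward_cluster(profiles: pd.DataFrame, standardize: bool = True) -> ClusterResult:
    """Ward minimum-variance agglomeration of event-type profiles.

    Features are z-scored column-wise by default (constant columns left
    as zeros) and distances are Euclidean, as Ward's criterion requires.
    The full merge tree is kept; ``chosen_k`` is filled in by
    :func:`choose_k_silhouette` (initialized to 1 here).
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 event-type profiles to cluster")
    X = profiles.to_numpy(float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    Z = linkage(X, method="ward")
    d = pdist(X)
    coph = {}
    for method in ("ward", "single"):
        Zm = Z if method == "ward" else linkage(X, method=method)
        c, _ = cophenet(Zm, d)
        coph[method] = float(c)
    labels = list(profiles.index)
    return ClusterResult(labels=labels, linkage_matrix=Z, chosen_k=1,
                         assignment={t: 1 for t in labels},
                         silhouette_by_k={}, silhouette_widths={},
                         cophenetic=coph, )


def choose_k_silhouette(result: ClusterResult, profiles: pd.DataFrame,
                        k_range=range(2, 8), standardize: bool = True
                        ) -> ClusterResult:
    """Pick the cut maximizing mean silhouette width; ties go to smaller k.

    Silhouette widths use the same (standardized) feature space as the
    clustering; singleton clusters get silhouette 0 by convention.
    Updates and returns ``result`` with the chosen k, the assignment and
    the per-type widths at that k.
    """
    n = len(result.labels)
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError(f"no valid k in {list(k_range)} for {n} profiles")
    X = profiles.loc[result.labels].to_numpy(float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    by_k: dict[int, float] = {}
    widths_at: dict[int, np.ndarray] = {}
    for k in ks:
        flat = fcluster(result.linkage_matrix, t=k, criterion="maxclust")
        if len(np.unique(flat)) < 2:
            continue
        s = silhouette_samples(X, flat)
        by_k[k] = float(s.mean())
        widths_at[k] = s
    best = min(by_k, key=lambda k: (-by_k[k], k))
    flat = fcluster(result.linkage_matrix, t=best, criterion="maxclust")
    result.chosen_k = int(best)
    result.assignment = dict(zip(result.labels, (int(c) for c in flat)))
    result.silhouette_by_k = by_k
    result.silhouette_widths = dict(zip(result.labels, widths_at[best].tolist()))
    return result


def reference_partition() -> dict[str, int]:
    """The three-group partition of the 15 social event types reported on
    the field data: cooperative (A), competitive (B) and coerced-
    cooperation (C) event types.  Used as a named comparison for runs on
    the deposited data; never enforced in tests of synthetic runs.
    """
    out = {}
    for i, group in enumerate((CLUSTER_A_TYPES, CLUSTER_B_TYPES, CLUSTER_C_TYPES), 1):
        for t in group:
            out[t] = i
    return out


def adjusted_rand(a: dict[str, int], b: dict[str, int]) -> float:
    """Adjusted Rand index between two partitions of the same label set."""
    keys = sorted(a)
    if sorted(b) != keys:
        raise ValueError("partitions cover different label sets")
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score([a[k] for k in keys], [b[k] for k in keys]))


def greedy_ward_oracle(X: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Brute-force greedy Ward agglomeration for tiny instances.

    At each step merges the pair of clusters whose fusion least
    increases the total within-cluster sum of squares; the recorded
    height is ``sqrt(2 * delta_ESS)``, the scale scipy's Ward linkage
    reports.  Independent of scipy's nearest-neighbor chain algorithm;
    used as a test oracle only.
    """
    clusters: list[frozenset] = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            ca = X[list(a)].mean(axis=0)
            cb = X[list(b)].mean(axis=0)
            delta = (len(a) * len(b)) / (len(a) + len(b)) * float(((ca - cb) ** 2).sum())
            key = (delta, sorted(a | b))
            if best is None or key < best[0]:
                best = (key, a, b)
        (delta, _), a, b = best
        merges.append((a, b, float(np.sqrt(2.0 * delta))))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return merges
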