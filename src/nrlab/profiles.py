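"""Noise-tolerance profiling: weighted ratings and k-means subgrouping.

The subjective task yields, per participant and sentence, absolute ratings
(1–10) of three noise-tolerance domains — noise annoyance, speech
interference, listening effort — plus three paired comparisons asking which
domain was more responsible for the noise being intolerable. The weighted
rating of a domain is

``w_d = mean(absolute rating of d) * (wins of d / appearances of d)``

with each domain appearing in 2 of the 3 pairs per sentence, so ``w_d`` lies
in [0, 10]. Participants are then clustered on the raw (unstandardized)
3-vector of weighted ratings — all domains share the same 0–10 scale — with
k-means, and the cluster count is adjusted by the study's decision rule:
start from the elbow suggestion (capped at 3), require every pairwise group
comparison in every domain to be significant (one-way ANOVA + Tukey HSD),
and drop to a smaller k when it is not, recomputing the silhouette at each
step; a two-cluster solution is finally validated with per-domain Welch
t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .exceptions import (
    DegenerateInputError,
    IncompleteParticipantError,
    InvalidArgumentError,
)
from .simulate import DOMAINS, RatingDataset

__all__ = [
    "ClusterSolution",
    "ElbowResult",
    "weighted_ratings",
    "kmeans_profile",
    "elbow_select",
    "distinctness_check",
    "profile_pipeline",
]


@dataclass(frozen=True)
class ClusterSolution:
    k: int
    labels: np.ndarray
    centroids: np.ndarray
    silhouette: float
    inertia: float
    domains: tuple[str, ...]


@dataclass(frozen=True)
class ElbowResult:
    k_values: np.ndarray
    wcss: np.ndarray
    suggested_k: int
    clear: bool


def weighted_ratings(data: RatingDataset | tuple[pd.DataFrame, pd.DataFrame]) -> pd.DataFrame:
    """Per-participant weighted ratings, one column per domain, in [0, 10]."""
    if isinstance(data, RatingDataset):
        ratings, comparisons = data.ratings, data.comparisons
    else:
        ratings, comparisons = data

    participants = sorted(ratings["participant"].unique())
    incomplete = []
    rows = []
    for pid in participants:
        r = ratings[ratings["participant"] == pid]
        c = comparisons[comparisons["participant"] == pid]
        if set(r["domain"]) != set(DOMAINS) or len(c) == 0:
            incomplete.append(pid)
            continue
        row = {}
        for domain in DOMAINS:
            mean_rating = r.loc[r["domain"] == domain, "rating"].mean()
            appearances = ((c["domain_a"] == domain) | (c["domain_b"] == domain)).sum()
            if appearances == 0:
                incomplete.append(pid)
                break
            wins = (c["choice"] == domain).sum()
            row[domain] = mean_rating * wins / appearances
        else:
            rows.append((pid, *[row[d] for d in DOMAINS]))
    if incomplete:
        raise IncompleteParticipantError(sorted(set(incomplete)))
    out = pd.DataFrame(rows, columns=["participant", *DOMAINS]).set_index("participant")
    return out


def _features(w: pd.DataFrame, domains) -> np.ndarray:
    return w[list(domains)].to_numpy(float)


def kmeans_profile(
    w: pd.DataFrame,
    k: int,
    restarts: int = 50,
    seed: int = 0,
    domains: tuple[str, ...] = DOMAINS,
) -> ClusterSolution:
    """Best-of-restarts k-means on raw weighted ratings.

    Cluster labels are reordered by descending noise-annoyance centroid (or
    first listed domain when clustering a domain subset), so cluster 1 is the
    annoyance-weighted group.
    """
    x = _features(w, domains)
    n = len(x)
    if not (2 <= k <= n - 1):
        raise InvalidArgumentError("need 2 <= k <= n - 1 (silhouette degenerate otherwise)")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(x)
    order = np.argsort(-km.cluster_centers_[:, 0], kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[labels]
    centroids = km.cluster_centers_[order]
    sil = float(silhouette_score(x, labels)) if len(np.unique(labels)) > 1 else np.nan
    return ClusterSolution(
        k=k,
        labels=labels,
        centroids=centroids,
        silhouette=sil,
        inertia=float(km.inertia_),
        domains=tuple(domains),
    )


def elbow_select(
    w: pd.DataFrame,
    k_range=range(2, 7),
    seed: int = 0,
    restarts: int = 20,
    domains: tuple[str, ...] = DOMAINS,
) -> ElbowResult:
    """Within-cluster sum-of-squares curve and a largest-second-difference elbow.

    Advisory only. The elbow is called *clear* when the suggested k removes
    most of the improvable inertia, i.e. its residual WCSS is under a quarter
    of the k-min WCSS; a single Gaussian blob fails this and is flagged.
    """
    x = _features(w, domains)
    ks = np.array(sorted(k_range))
    if ks.size == 0 or ks[0] < 2 or ks[-1] > len(x) - 1:
        raise InvalidArgumentError("k_range must lie within [2, n-1]")
    wcss = np.array(
        [KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(x).inertia_ for k in ks]
    )
    if ks.size < 3:
        suggested, clear = int(ks[np.argmin(wcss)]), False
    else:
        d2 = wcss[:-2] - 2 * wcss[1:-1] + wcss[2:]  # curvature at interior ks
        i = int(np.argmax(d2))
        suggested = int(ks[1:-1][i])
        resid = wcss[1:-1][i]
        clear = bool(d2[i] > 0 and resid < 0.25 * wcss[0])
    return ElbowResult(k_values=ks, wcss=wcss, suggested_k=suggested, clear=clear)


def distinctness_check(
    w: pd.DataFrame, labels, alpha: float = 0.05, domains: tuple[str, ...] = DOMAINS
) -> dict:
    """Per-domain one-way ANOVA plus Tukey HSD over all group pairs.

    Returns a dict with per-domain F/p, the pairwise adjusted p-values, and
    ``verdict``: True only when every pairwise comparison in every domain is
    significant at ``alpha``.
    """
    labels = np.asarray(labels)
    groups_ids = np.unique(labels)
    if len(groups_ids) < 2:
        raise InvalidArgumentError("need at least two groups")
    if any((labels == g).sum() < 2 for g in groups_ids):
        raise DegenerateInputError("every group needs at least two members")
    report, verdict = {}, True
    for domain in domains:
        vals = w[domain].to_numpy(float)
        groups = [vals[labels == g] for g in groups_ids]
        f_stat, p = sps.f_oneway(*groups)
        pairwise = {}
        if len(groups) > 2:
            tukey = sps.tukey_hsd(*groups)
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    pairwise[(int(groups_ids[i]), int(groups_ids[j]))] = float(
                        tukey.pvalue[i, j]
                    )
        else:
            pairwise[(int(groups_ids[0]), int(groups_ids[1]))] = float(p)
        all_sig = all(pv < alpha for pv in pairwise.values())
        verdict &= all_sig
        report[domain] = {
            "F": float(f_stat),
            "p": float(p),
            "pairwise_p": pairwise,
            "all_significant": all_sig,
        }
    return {"domains": report, "alpha": alpha, "verdict": bool(verdict)}


def profile_pipeline(
    w: pd.DataFrame,
    seed: int = 0,
    *,
    alpha: float = 0.05,
    restarts: int = 50,
    max_k: int = 3,
    start_k: int | None = None,
    domains: tuple[str, ...] = DOMAINS,
) -> dict:
    """The full cluster-count adjustment procedure with an audit trail.

    Start at ``start_k`` when given (e.g. a literature-motivated initial
    cluster count), else at the elbow suggestion capped at ``max_k``; while any pairwise
    group comparison fails significance and k > 2, reduce k by one and
    recompute the silhouette. At k = 2 the final validation is a per-domain
    Welch two-sample t-test. Returns the final :class:`ClusterSolution`, the
    silhouettes seen along the way, and every decision taken.
    """
    if len(w) < 4:
        raise InvalidArgumentError("need at least four participants")
    audit = []
    elbow = elbow_select(w, seed=seed, domains=domains)
    k = int(start_k) if start_k is not None else int(np.clip(elbow.suggested_k, 2, max_k))
    if not (2 <= k <= len(w) - 1):
        raise InvalidArgumentError("start_k outside [2, n-1]")
    audit.append(
        {
            "step": "elbow",
            "suggested_k": elbow.suggested_k,
            "clear": elbow.clear,
            "start_k": k,
        }
    )
    silhouettes = {}
    while True:
        sol = kmeans_profile(w, k, restarts=restarts, seed=seed, domains=domains)
        silhouettes[k] = sol.silhouette
        check = distinctness_check(w, sol.labels, alpha=alpha, domains=domains)
        audit.append(
            {
                "step": "distinctness",
                "k": k,
                "silhouette": sol.silhouette,
                "verdict": check["verdict"],
                "detail": check,
            }
        )
        if check["verdict"] or k <= 2:
            break
        k -= 1
        audit.append({"step": "reduce_k", "new_k": k})

    final_tests = None
    if sol.k == 2:
        final_tests = {}
        for domain in domains:
            vals = w[domain].to_numpy(float)
            a, b = vals[sol.labels == 0], vals[sol.labels == 1]
            res = sps.ttest_ind(a, b, equal_var=False)
            final_tests[domain] = {
                "t": float(res.statistic),
                "df": float(res.df),
                "p": float(res.pvalue),
                "significant": bool(res.pvalue < alpha),
            }
        audit.append({"step": "two_cluster_validation", "tests": final_tests})
    return {
        "solution": sol,
        "silhouettes": silhouettes,
        "final_tests": final_tests,
        "audit": audit,
    }
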