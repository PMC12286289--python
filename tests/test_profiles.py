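"""Weighted ratings, k-means profiling, and the cluster-count adjustment."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from nrlab.exceptions import IncompleteParticipantError, InvalidArgumentError
from nrlab.profiles import (
    distinctness_check,
    elbow_select,
    kmeans_profile,
    profile_pipeline,
    weighted_ratings,
)
from nrlab.simulate import DOMAINS, ClusterSpec, RatingDataset, gen_rating_dataset


def _tiny_dataset(rating, wins_per_pair):
    """One participant, two sentences, hand-built ratings and comparisons."""
    ratings = pd.DataFrame(
        [(0, s, d, rating) for s in range(2) for d in DOMAINS],
        columns=["participant", "sentence", "domain", "rating"],
    )
    rows = []
    for s in range(2):
        for (a, b), w in wins_per_pair.items():
            rows.append((0, s, a, b, a if s < w else b))
    comparisons = pd.DataFrame(
        rows, columns=["participant", "sentence", "domain_a", "domain_b", "choice"]
    )
    return ratings, comparisons


def test_weighted_ratings_hand_computed_cases():
    # always rated 10 and chosen in every comparison -> the 0-10 maximum
    pairs = {(DOMAINS[0], DOMAINS[1]): 2, (DOMAINS[0], DOMAINS[2]): 2, (DOMAINS[1], DOMAINS[2]): 2}
    w = weighted_ratings(_tiny_dataset(10, pairs))
    assert w.loc[0, DOMAINS[0]] == 10.0
    # rated 6, chosen in half its appearances -> 6 * 0.5 = 3.0
    pairs = {(DOMAINS[0], DOMAINS[1]): 1, (DOMAINS[0], DOMAINS[2]): 1, (DOMAINS[1], DOMAINS[2]): 1}
    w = weighted_ratings(_tiny_dataset(6, pairs))
    assert w.loc[0, DOMAINS[0]] == pytest.approx(3.0)


def test_weighted_ratings_match_explicit_tally_oracle():
    spec = ClusterSpec([[7.0, 4.0, 2.0], [2.0, 5.0, 7.0]], spread=1.5)
    data = gen_rating_dataset(spec, 12, 10, seed=21, rating_sd=1.0)
    w = weighted_ratings(data)
    for pid in range(12):
        r = data.ratings[data.ratings["participant"] == pid]
        c = data.comparisons[data.comparisons["participant"] == pid]
        for domain in DOMAINS:
            total, count = 0.0, 0
            for _, row in r.iterrows():
                if row["domain"] == domain:
                    total += row["rating"]
                    count += 1
            wins = appearances = 0
            for _, row in c.iterrows():
                if domain in (row["domain_a"], row["domain_b"]):
                    appearances += 1
                    wins += row["choice"] == domain
            expected = (total / count) * (wins / appearances)
            assert w.loc[pid, domain] == pytest.approx(expected, abs=1e-12)


def test_weighted_ratings_report_incomplete_participants():
    spec = ClusterSpec([[5.0, 5.0, 5.0]])
    data = gen_rating_dataset(spec, 3, 4, seed=0)
    broken = data.ratings[
        ~((data.ratings["participant"] == 1) & (data.ratings["domain"] == DOMAINS[2]))
    ]
    with pytest.raises(IncompleteParticipantError) as err:
        weighted_ratings(RatingDataset(broken, data.comparisons, data.true_labels, data.latent))
    assert err.value.participant_ids == [1]


def _planted(centroids, n, spread, seed=0, rating_sd=0.5):
    data = gen_rating_dataset(ClusterSpec(centroids, spread=spread), n, 10, seed=seed,
                              rating_sd=rating_sd)
    return weighted_ratings(data), data.true_labels


def test_kmeans_recovers_well_separated_clusters():
    w, truth = _planted([[8.0, 2.0, 2.0], [2.0, 3.0, 8.0]], 30, spread=0.3)
    sol = kmeans_profile(w, k=2, seed=0)
    assert adjusted_rand_score(truth, sol.labels) == 1.0
    # labels ordered by descending noise-annoyance centroid
    assert sol.centroids[0, 0] > sol.centroids[1, 0]


def test_kmeans_rejects_degenerate_k():
    w, _ = _planted([[8.0, 2.0, 2.0], [2.0, 3.0, 8.0]], 10, spread=0.3)
    for k in (1, len(w)):  # k = n leaves the silhouette undefined
        with pytest.raises(InvalidArgumentError):
            kmeans_profile(w, k=k)


def _silhouette_oracle(x, labels):
    n = len(x)
    dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    vals = []
    for i in range(n):
        same = labels == labels[i]
        a = dist[i, same & (np.arange(n) != i)].mean()
        b = min(dist[i, labels == g].mean() for g in np.unique(labels) if g != labels[i])
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def test_silhouette_matches_brute_force_oracle():
    w, _ = _planted([[8.0, 2.0, 2.0], [5.0, 5.0, 5.0], [2.0, 3.0, 8.0]], 24, spread=0.8)
    sol = kmeans_profile(w, k=3, seed=1)
    oracle = _silhouette_oracle(w[list(DOMAINS)].to_numpy(), sol.labels)
    assert sol.silhouette == pytest.approx(oracle, abs=1e-9)


def test_elbow_on_point_masses_and_single_blob(rng):
    w, _ = _planted([[8.0, 1.0, 1.0], [1.0, 8.0, 1.0], [1.0, 1.0, 8.0]], 30, spread=0.0,
                    rating_sd=0.0)
    jitter = pd.DataFrame(
        w[list(DOMAINS)].to_numpy() + 0.01 * rng.standard_normal(w[list(DOMAINS)].shape),
        columns=list(DOMAINS), index=w.index,
    )
    res = elbow_select(jitter)
    assert res.suggested_k == 3 and res.clear
    assert np.all(np.diff(res.wcss) <= 1e-9)  # WCSS non-increasing in k

    blob = pd.DataFrame(
        5.0 + 0.8 * rng.standard_normal((60, 3)), columns=list(DOMAINS)
    )
    res = elbow_select(blob)
    assert not res.clear
    assert np.all(np.diff(res.wcss) <= 1e-9)


def test_distinctness_check_verdicts_and_anova_oracle(rng):
    w, truth = _planted([[8.0, 2.0, 2.0], [2.0, 3.0, 8.0]], 24, spread=0.4)
    res = distinctness_check(w, truth)
    assert res["verdict"]

    # make one domain identical across groups: that domain must fail
    w2 = w.copy()
    w2[DOMAINS[1]] = 5.0 + 0.01 * rng.standard_normal(len(w2))
    res = distinctness_check(w2, truth)
    assert not res["verdict"]
    assert not res["domains"][DOMAINS[1]]["all_significant"]

    # F statistic against a from-scratch partitioned sums-of-squares oracle
    vals = w[DOMAINS[0]].to_numpy()
    groups = [vals[truth == g] for g in np.unique(truth)]
    grand = vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = len(groups) - 1, len(vals) - len(groups)
    f_oracle = (ss_between / df_b) / (ss_within / df_w)
    assert res["domains"][DOMAINS[0]]["F"] == pytest.approx(f_oracle, abs=1e-9)


def test_pipeline_reduces_three_to_two_on_two_planted_clusters():
    # two true clusters, pipeline forced to start at k=3 (the literature prior)
    w, truth = _planted([[8.0, 3.0, 2.0], [3.0, 6.0, 6.0]], 42, spread=0.9, seed=4)
    res = profile_pipeline(w, seed=0, start_k=3)
    assert res["solution"].k == 2
    assert set(res["silhouettes"]) == {2, 3}
    assert all(t["significant"] for t in res["final_tests"].values())
    assert adjusted_rand_score(truth, res["solution"].labels) == 1.0
    steps = [a["step"] for a in res["audit"]]
    assert "reduce_k" in steps and "two_cluster_validation" in steps


def test_pipeline_keeps_three_clean_clusters():
    # three clusters separated in every domain: the all-pairwise rule holds
    w, truth = _planted(
        [[9.0, 1.0, 4.0], [5.0, 8.0, 1.0], [1.0, 4.5, 8.0]], 30, spread=0.4, seed=2
    )
    res = profile_pipeline(w, seed=0, start_k=3)
    assert res["solution"].k == 3
    assert adjusted_rand_score(truth, res["solution"].labels) == 1.0


def test_domain_subset_profiling():
    # exploratory variant on speech interference + listening effort only
    w, truth = _planted([[5.0, 8.0, 2.0], [5.0, 2.0, 8.0]], 30, spread=0.5, seed=6)
    sub = (DOMAINS[1], DOMAINS[2])
    sol = kmeans_profile(w, k=2, seed=0, domains=sub)
    assert sol.domains == sub
    assert adjusted_rand_score(truth, sol.labels) == 1.0
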