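"""Clustering-quality assessment.

Three complementary checks of a proposed sample stratification:

* average silhouette width (ASW) — per-sample cohesion vs. separation;
* prediction strength (PS) — cross-validated co-assignment stability at a
  given cluster count (values > 0.8 indicate a reproducible clustering);
* a simulation test — the observed Calinski-Harabasz index at the chosen k
  is compared against tables simulated from a single-component Dirichlet-
  multinomial null fitted to the data (p < 0.05 rejects "no structure").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import AbundanceTable
from .stratify import (
    DistanceMatrix,
    calinski_harabasz,
    dmm_fit,
    jsd_distance,
    pam,
)

__all__ = [
    "ValidationReport",
    "silhouette",
    "prediction_strength",
    "simulation_test",
    "validate_clustering",
]


@dataclass
class ValidationReport:
    """Bundle of quality metrics for one clustering decision."""

    asw: float
    per_k_asw: dict[int, float] = field(default_factory=dict)
    ps: float = float("nan")
    ps_sd: float = float("nan")
    per_k_ps: dict[int, float] = field(default_factory=dict)
    simulation_p: float = float("nan")
    null_ch: np.ndarray | None = None
    ps_threshold: float = 0.8
    p_threshold: float = 0.05
    supported: bool | None = None


def silhouette(dist: DistanceMatrix, labels) -> tuple[np.ndarray, float]:
    """Per-sample silhouette values s(i) and their mean (ASW).

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean distance to
    the sample's own cluster (self excluded) and b(i) the smallest mean
    distance to another cluster.  Samples in singleton clusters score 0.
    """
    labels = np.asarray(labels, dtype=int)
    D = dist.values
    n = dist.n
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    s = np.zeros(n)
    members = {c: np.flatnonzero(labels == c) for c in clusters}
    for i in range(n):
        own = members[labels[i]]
        if len(own) == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (len(own) - 1)
        b = min(D[i, members[c]].mean() for c in clusters if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


def prediction_strength(
    dist: DistanceMatrix,
    k: int,
    repeats: int = 50,
    seed: int = 0,
) -> tuple[float, float]:
    """Prediction strength of a k-cluster solution on a distance matrix.

    Each repeat splits the samples into random halves, clusters both with
    PAM, classifies test samples to the nearest training medoid, and
    scores each test-side cluster (size >= 2) by the fraction of its
    member pairs that the training classifier co-assigns; the repeat's
    statistic is the minimum over clusters (clusters of size < 2
    contribute 1).  Returns the mean and sd over repeats.  k = 1 is a
    degenerate case with PS = 1 by convention.
    """
    if k == 1:
        return 1.0, 0.0
    n = dist.n
    if n < 2 * k + 2:
        raise ValueError(f"prediction strength needs n >= 2k+2 = {2 * k + 2}")
    rng = np.random.default_rng(seed)
    D = dist.values
    stats = []
    for _ in range(repeats):
        perm = rng.permutation(n)
        half = n // 2
        train, test = np.sort(perm[:half]), np.sort(perm[half:])
        sub = lambda idx: DistanceMatrix(
            ids=[dist.ids[i] for i in idx], values=D[np.ix_(idx, idx)],
            metric=dist.metric)
        train_sub = sub(train)
        train_res = pam(train_sub, k)
        test_res = pam(sub(test), k)
        train_medoids = np.array(
            [train[train_sub.ids.index(m)] for m in train_res.medoids])
        # classify test points to the nearest training medoid
        assigned = np.argmin(D[np.ix_(train_medoids, test)], axis=0)
        per_cluster = []
        for c in range(k):
            mem = np.flatnonzero(test_res.labels == c)
            m = len(mem)
            if m < 2:
                per_cluster.append(1.0)
                continue
            lab = assigned[mem]
            same = sum(
                1 for x in range(m) for y in range(x + 1, m)
                if lab[x] == lab[y]
            )
            per_cluster.append(same / (m * (m - 1) / 2))
        stats.append(min(per_cluster))
    return float(np.mean(stats)), float(np.std(stats))


def simulation_test(
    table: AbundanceTable,
    chosen_k: int,
    B: int = 199,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Significance of the chosen clustering against a no-structure null.

    A single-component Dirichlet-multinomial is fitted to all samples and
    ``B`` tables are simulated from it (same n, same per-sample totals).
    For the observed and each simulated table, PAM at ``chosen_k`` on
    sqrt-JSD distances yields a CH index; the add-one p-value is
    (1 + #{CH_sim >= CH_obs}) / (B + 1), so p is never 0 and never below
    1/(B+1).
    """
    if B < 19:
        raise ValueError("B < 19 gives insufficient p-value resolution")
    rng = np.random.default_rng(seed)
    null = dmm_fit(table, K=1, n_restarts=1, seed=seed)
    alpha = null.alpha[0]
    totals = table.library_sizes().to_numpy().astype(int)
    n = table.n_samples

    def _ch_of(counts: np.ndarray) -> float:
        df = pd.DataFrame(counts, columns=[f"s{i}" for i in range(n)])
        rel = df / df.sum(axis=0)
        d = jsd_distance(rel)
        labels = pam(d, chosen_k).labels
        return calinski_harabasz(d, labels)

    ch_obs = _ch_of(table.counts.to_numpy())
    null_ch = np.empty(B)
    for b in range(B):
        sim = np.empty((len(alpha), n), dtype=np.int64)
        for i in range(n):
            p = rng.dirichlet(alpha)
            sim[:, i] = rng.multinomial(totals[i], p)
        null_ch[b] = _ch_of(sim)
    p = (1 + int((null_ch >= ch_obs).sum())) / (B + 1)
    return float(p), null_ch


def validate_clustering(
    table: AbundanceTable,
    dist: DistanceMatrix,
    labels,
    chosen_k: int,
    k_range=range(2, 7),
    ps_repeats: int = 50,
    B: int = 199,
    seed: int = 0,
    ps_threshold: float = 0.8,
    p_threshold: float = 0.05,
) -> ValidationReport:
    """Full quality report: ASW at the chosen k (and over ``k_range``),
    prediction strength over ``k_range``, and the simulation p-value.
    The verdict is "supported" iff PS(chosen k) > 0.8 and p < 0.05
    (thresholds overridable)."""
    _, asw = silhouette(dist, labels)
    per_k_asw, per_k_ps = {}, {}
    for k in k_range:
        if not 2 <= k < dist.n:
            continue
        res = pam(dist, k)
        _, per_k_asw[k] = silhouette(dist, res.labels)
        if dist.n >= 2 * k + 2:
            per_k_ps[k], _ = prediction_strength(dist, k, repeats=ps_repeats,
                                                 seed=seed)
    ps, ps_sd = prediction_strength(dist, chosen_k, repeats=ps_repeats,
                                    seed=seed)
    p, null_ch = simulation_test(table, chosen_k, B=B, seed=seed)
    return ValidationReport(
        asw=asw, per_k_asw=per_k_asw, ps=ps, ps_sd=ps_sd, per_k_ps=per_k_ps,
        simulation_p=p, null_ch=null_ch, ps_threshold=ps_threshold,
        p_threshold=p_threshold,
        supported=bool(ps > ps_threshold and p < p_threshold),
    )
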