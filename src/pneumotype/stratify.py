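"""Subgroup (pneumotype) discovery.

Two complementary routes stratify samples from their taxon composition:

* distance-based — square-root Jensen-Shannon divergence between sample
  compositions, partitioning-around-medoids (PAM) clustering, and the
  Calinski-Harabasz (CH) pseudo-F index to pick the number of clusters
  (the standard enterotyping recipe);
* model-based — a Dirichlet multinomial mixture (DMM) fitted by EM on the
  raw counts, with the component count picked by BIC.

Agreement between the two labelings is summarised by Hungarian-matched
mismatch counts and the adjusted Rand index.  Per-subgroup dominant
("core") taxa and their correlation structure are also reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import digamma, gammaln, logsumexp
from sklearn.metrics import adjusted_rand_score

from .abundance import AbundanceTable, RelativeAbundance

__all__ = [
    "DistanceMatrix",
    "ClusteringResult",
    "DMMModel",
    "jsd_distance",
    "pam",
    "calinski_harabasz",
    "select_k_pam",
    "dmm_fit",
    "dmm_select_K",
    "method_agreement",
    "core_microbes",
    "pcoa_coordinates",
]

_ALPHA_FLOOR = 1e-10  # keeps Dirichlet parameters positive in the fixed point

MAX_JSD = float(np.sqrt(np.log(2.0)))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample distances with zero diagonal."""

    ids: list[str]
    values: np.ndarray
    metric: str = "sqrt-jsd"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(v < -1e-15):
            raise ValueError("negative distances")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class ClusteringResult:
    """Labels plus provenance for one clustering run or a k/K sweep."""

    method: str                      # "pam" or "dmm"
    ids: list[str]
    labels: np.ndarray               # values in [0, k)
    k: int
    medoids: list[str] | None = None           # pam only
    index_table: pd.DataFrame | None = None    # per-k CH or per-K BIC sweep
    model: "DMMModel | None" = None            # dmm only

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.ids):
            raise ValueError("labels length does not match sample ids")
        present = np.unique(self.labels)
        if self.k > 1 and (present.min() < 0 or present.max() >= self.k):
            raise ValueError("labels outside [0, k)")


def _entropy_cols(p: np.ndarray) -> np.ndarray:
    """Natural-log entropy of each column, with 0*ln(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return -plogp.sum(axis=0)


def jsd_distance(rel: RelativeAbundance | pd.DataFrame) -> DistanceMatrix:
    """Square-root Jensen-Shannon divergence between sample columns.

    d(i, j) = sqrt( H(m) - (H(p_i) + H(p_j)) / 2 ),  m = (p_i + p_j) / 2,
    with natural-log entropy H; a metric bounded by sqrt(ln 2) ~ 0.8326.
    Columns must each sum to 1.
    """
    df = rel.values if isinstance(rel, RelativeAbundance) else rel
    P = df.to_numpy(dtype=float)
    if not np.allclose(P.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("jsd_distance requires columns normalised to sum 1")
    n = P.shape[1]
    H = _entropy_cols(P)
    D = np.zeros((n, n))
    for i in range(n):
        M = (P[:, i][:, None] + P[:, i:]) / 2.0
        Hm = _entropy_cols(M)
        jsd = Hm - (H[i] + H[i:]) / 2.0
        D[i, i:] = np.sqrt(np.clip(jsd, 0.0, None))
    D = D + D.T
    np.fill_diagonal(D, 0.0)  # exact zeros despite entropy round-off
    return DistanceMatrix(ids=list(df.columns), values=D, metric="sqrt-jsd")


# --------------------------------------------------------------------------
# PAM (k-medoids): exact enumeration over medoid subsets when that space is
# tiny, deterministic BUILD + SWAP beyond; ties to the lowest index.

_EXACT_PAM_MAX_SUBSETS = 2000


def _pam_indices(D: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, float]:
    import itertools
    from math import comb

    n = D.shape[0]
    if comb(n, k) <= _EXACT_PAM_MAX_SUBSETS:
        combos = np.array(list(itertools.combinations(range(n), k)))
        costs = D[combos].min(axis=1).sum(axis=1)
        med = combos[int(np.argmin(costs))]   # first = lexicographically lowest
        labels = np.argmin(D[med], axis=0)
        return med, labels, float(costs.min())
    # BUILD: first medoid minimises total distance; each next medoid
    # maximises the total reduction in nearest-medoid distance.
    medoids = [int(np.argmin(D.sum(axis=1)))]
    d_near = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(d_near[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
        d_near = np.minimum(d_near, D[medoids[-1]])

    # SWAP: steepest-descent over all (medoid, non-medoid) exchanges.
    medoids = sorted(medoids)
    while True:
        med = np.array(medoids)
        dm = D[med]                       # k x n
        order = np.argsort(dm, axis=0, kind="stable")
        nearest = order[0]                # index into med
        d1 = dm[nearest, np.arange(n)]
        d2 = dm[order[1], np.arange(n)] if k > 1 else np.full(n, np.inf)
        cost = d1.sum()
        best_delta, best_swap = -1e-12, None
        non_med = [h for h in range(n) if h not in set(medoids)]
        for mi in range(k):
            is_m = nearest == mi
            for h in non_med:
                newd = np.where(is_m, np.minimum(d2, D[h]),
                                np.minimum(d1, D[h]))
                delta = newd.sum() - cost
                if delta < best_delta:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        medoids = sorted(medoids)

    med = np.array(medoids)
    labels = np.argmin(D[med], axis=0)    # argmin breaks ties low
    cost = D[med, :][labels, np.arange(n)].sum()
    return med, labels, float(cost)


def pam(dist: DistanceMatrix, k: int) -> ClusteringResult:
    """Partitioning around medoids minimising the summed distance of each
    sample to its medoid.

    Deterministic, with ties broken by the lowest sample index.  When the
    number of candidate medoid subsets C(n, k) is small (<= 2000) the
    optimum is found by direct enumeration — BUILD + SWAP is a local
    search and can stall in a 1-swap-stable configuration on instances
    this small, where exactness is cheap; larger instances use the classic
    BUILD then steepest-descent SWAP heuristic."""
    n = dist.n
    if not 2 <= k <= n:
        raise ValueError(f"k must satisfy 2 <= k <= n={n}, got {k}")
    med, labels, cost = _pam_indices(dist.values, k)
    return ClusteringResult(
        method="pam", ids=dist.ids, labels=labels, k=k,
        medoids=[dist.ids[m] for m in med],
    )


def _cluster_medoid(D: np.ndarray, members: np.ndarray) -> int:
    sub = D[np.ix_(members, members)].sum(axis=1)
    return int(members[np.argmin(sub)])


def calinski_harabasz(dist: DistanceMatrix, labels) -> float:
    """Medoid-based Calinski-Harabasz pseudo-F on a distance matrix.

    CH = [sum_c n_c d(m_c, m)^2 / (k-1)] / [sum_i d(i, m_c(i))^2 / (n-k)]
    with m_c the cluster medoid and m the global medoid.  Returns NaN for
    k = 1 or k = n (undefined) and the maximum float when the within term
    is exactly zero.
    """
    labels = np.asarray(labels, dtype=int)
    D = dist.values
    n = dist.n
    ks = np.unique(labels)
    k = len(ks)
    if k < 2 or k >= n:
        return float("nan")
    global_medoid = int(np.argmin(D.sum(axis=1)))
    between = 0.0
    within = 0.0
    for c in ks:
        members = np.flatnonzero(labels == c)
        m_c = _cluster_medoid(D, members)
        between += len(members) * D[m_c, global_medoid] ** 2
        within += (D[m_c, members] ** 2).sum()
    if within == 0.0:
        return float(np.finfo(float).max)
    return float((between / (k - 1)) / (within / (n - k)))


def select_k_pam(dist: DistanceMatrix, k_range=range(2, 7)) -> ClusteringResult:
    """Run PAM over ``k_range`` and keep the k with the highest CH index.

    The returned result carries the full per-k CH table; ties go to the
    smallest k.
    """
    ks = [k for k in k_range]
    if not ks:
        raise ValueError("empty k range")
    rows, results = {}, {}
    for k in ks:
        res = pam(dist, k)
        rows[k] = {"ch": calinski_harabasz(dist, res.labels)}
        results[k] = res
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "k"
    best_k = int(table["ch"].idxmax())
    best = results[best_k]
    best.index_table = table
    return best


# --------------------------------------------------------------------------
# Dirichlet multinomial mixture via EM.

@dataclass
class DMMModel:
    """Fitted Dirichlet multinomial mixture.

    ``alpha`` is K x T (components x taxa, all > 0), ``pi`` the mixing
    weights, ``resp`` the n x K posterior responsibilities.  The
    log-likelihood omits the multinomial coefficient consistently (it is
    constant in the parameters).
    """

    K: int
    pi: np.ndarray
    alpha: np.ndarray
    resp: np.ndarray
    loglik: float
    n_iter: int
    seed: int
    converged: bool = True
    loglik_trace: list[float] = field(default_factory=list)

    def labels(self) -> np.ndarray:
        return np.argmax(self.resp, axis=1)


def dm_logpmf(X: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-row Dirichlet-multinomial log density (multinomial coefficient
    omitted):

    ln P(x | alpha) = lnG(A) - lnG(N + A) + sum_t [lnG(x_t + a_t) - lnG(a_t)]
    """
    X = np.asarray(X, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    A = alpha.sum()
    N = X.sum(axis=1)
    return (gammaln(A) - gammaln(N + A)
            + (gammaln(X + alpha) - gammaln(alpha)).sum(axis=1))


def _init_alpha(X: np.ndarray, resp: np.ndarray) -> np.ndarray:
    """Moment-style start: component mean composition scaled to total T."""
    T = X.shape[1]
    rel = X / np.maximum(X.sum(axis=1, keepdims=True), 1.0)
    w = resp / np.maximum(resp.sum(axis=0, keepdims=True), 1e-12)
    comp = w.T @ rel                     # K x T
    return np.maximum(comp * T, _ALPHA_FLOOR)


def _em(X: np.ndarray, K: int, resp: np.ndarray, tol: float,
        max_iter: int, seed: int) -> DMMModel:
    n, T = X.shape
    N = X.sum(axis=1)
    alpha = _init_alpha(X, resp)
    pi = np.maximum(resp.mean(axis=0), 1e-12)
    pi /= pi.sum()
    prev_ll = -np.inf
    trace: list[float] = []
    converged = False
    for it in range(1, max_iter + 1):
        # E-step
        logp = np.stack([dm_logpmf(X, alpha[k]) for k in range(K)], axis=1)
        logw = np.log(pi)[None, :] + logp
        norm = logsumexp(logw, axis=1)
        ll = float(norm.sum())
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite DMM log-likelihood")
        resp = np.exp(logw - norm[:, None])
        trace.append(ll)
        if ll < prev_ll - 1e-8:
            warnings.warn("DMM EM log-likelihood decreased beyond slack")
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
        # M-step: mixing weights + one MM fixed-point step on each alpha_k.
        pi = np.maximum(resp.mean(axis=0), 1e-12)
        pi /= pi.sum()
        for k in range(K):
            w = resp[:, k]
            a = alpha[k]
            A = a.sum()
            num = (w[:, None] * (digamma(X + a) - digamma(a))).sum(axis=0)
            den = (w * (digamma(N + A) - digamma(A))).sum()
            if den <= 0:
                continue
            alpha[k] = np.maximum(a * num / den, _ALPHA_FLOOR)
    return DMMModel(K=K, pi=pi, alpha=alpha, resp=resp, loglik=trace[-1],
                    n_iter=len(trace), seed=seed, converged=converged,
                    loglik_trace=trace)


def dmm_fit(
    table: AbundanceTable,
    K: int,
    n_restarts: int = 3,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> DMMModel:
    """Fit a K-component Dirichlet multinomial mixture to the count table
    (samples = columns) by EM, keeping the best of ``n_restarts`` runs.

    Restart 0 initialises responsibilities from PAM labels on sqrt-JSD
    distances (K >= 2); further restarts use random soft assignments.
    E-step responsibilities are computed with log-sum-exp; the M-step pairs
    the closed-form mixing-weight update with the digamma fixed-point
    update of each Dirichlet parameter vector (an MM step, so the observed
    log-likelihood is non-decreasing).
    """
    X = table.counts.to_numpy(dtype=float).T     # samples x taxa
    n, T = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of samples n={n}")
    inits: list[np.ndarray] = []
    if K == 1:
        inits.append(np.ones((n, 1)))
        n_restarts = 1
    else:
        rel = X / np.maximum(X.sum(axis=1, keepdims=True), 1.0)
        d = jsd_distance(pd.DataFrame(rel.T, columns=table.samples))
        labels = pam(d, K).labels
        hard = np.full((n, K), 0.05 / max(K - 1, 1))
        hard[np.arange(n), labels] = 0.95
        inits.append(hard)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   ss.spawn(max(n_restarts - 1, 0))]
    for cs in child_seeds:
        rng = np.random.default_rng(cs)
        inits.append(rng.dirichlet(np.ones(K), size=n))
    best: DMMModel | None = None
    errors = []
    extra_seed = int(ss.generate_state(1)[0] % (2**31))
    for r, resp0 in enumerate(inits):
        try:
            model = _em(X, K, resp0.copy(), tol, max_iter, seed)
        except FloatingPointError as exc:
            # retry once with a fresh random initialisation
            rng = np.random.default_rng(extra_seed + r)
            try:
                model = _em(X, K, rng.dirichlet(np.ones(K), size=n),
                            tol, max_iter, seed)
            except FloatingPointError as exc2:
                errors.append(exc2)
                continue
        if best is None or model.loglik > best.loglik:
            best = model
    if best is None:
        raise RuntimeError(f"all DMM restarts failed: {errors}")
    return best


def dmm_select_K(
    table: AbundanceTable,
    K_range=range(1, 7),
    n_restarts: int = 3,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ClusteringResult:
    """Fit DMMs over ``K_range`` and choose K by BIC.

    BIC = -2 loglik + p ln(n) with p = K*T + (K - 1) free parameters.
    (The reference DMM approach scores models by a Laplace approximation to
    the evidence; BIC is used here and flagged in reports.)  Ties go to
    the smallest K.
    """
    Ks = [K for K in K_range]
    if not Ks:
        raise ValueError("empty K range")
    n = table.n_samples
    T = len(table.taxa)
    rows, models = {}, {}
    for K in Ks:
        m = dmm_fit(table, K, n_restarts=n_restarts, seed=seed,
                    tol=tol, max_iter=max_iter)
        p = K * T + (K - 1)
        rows[K] = {"loglik": m.loglik, "n_params": p,
                   "bic": -2.0 * m.loglik + p * np.log(n)}
        models[K] = m
    tbl = pd.DataFrame.from_dict(rows, orient="index")
    tbl.index.name = "K"
    best_K = int(tbl["bic"].idxmin())
    model = models[best_K]
    return ClusteringResult(
        method="dmm", ids=table.samples, labels=model.labels(), k=best_K,
        index_table=tbl, model=model,
    )


# --------------------------------------------------------------------------
# Agreement, core microbes, ordination.

def method_agreement(result_a: ClusteringResult, result_b: ClusteringResult
                     ) -> dict:
    """Compare two labelings of the same samples.

    Labels are matched by Hungarian assignment on the confusion matrix
    (maximising agreement); reports the mismatch count and the adjusted
    Rand index.
    """
    if result_a.ids != result_b.ids:
        raise ValueError("clusterings cover different sample sets")
    a, b = result_a.labels, result_b.labels
    ka, kb = a.max() + 1, b.max() + 1
    conf = np.zeros((ka, kb), dtype=int)
    for i, j in zip(a, b):
        conf[i, j] += 1
    rows, cols = linear_sum_assignment(-conf)
    matched = conf[rows, cols].sum()
    return {
        "n_mismatched": int(len(a) - matched),
        "ari": float(adjusted_rand_score(a, b)),
        "confusion": conf,
    }


def core_microbes(
    rel: RelativeAbundance,
    labels,
    top_m: int = 2,
    min_mean: float = 0.05,
) -> dict:
    """Per-subgroup dominant ("core") taxa and their correlation structure.

    A subgroup's core set holds up to ``top_m`` taxa that (a) have within-
    subgroup mean read abundance >= ``min_mean`` and (b) achieve their
    across-subgroup maximum mean in that subgroup.  Spearman rho and p are
    reported over all samples for every within-core and between-core taxon
    pair.  Subgroups with no qualifying taxon get an empty set (warning).
    """
    from scipy import stats as _st
    labels = np.asarray(labels, dtype=int)
    df = rel.values
    groups = np.unique(labels)
    means = pd.DataFrame(
        {c: df.loc[:, np.asarray(labels) == c].mean(axis=1) for c in groups})
    argmax_group = means.idxmax(axis=1)
    cores: dict[int, list[str]] = {}
    for c in groups:
        ok = means.index[(means[c] >= min_mean) & (argmax_group == c)]
        ranked = means.loc[ok, c].sort_values(ascending=False)
        cores[int(c)] = list(ranked.index[:top_m])
        if not cores[int(c)]:
            warnings.warn(f"subgroup {c} has no qualifying core taxon")
    pairs = []
    core_list = [(c, t) for c, ts in cores.items() for t in ts]
    for i in range(len(core_list)):
        for j in range(i + 1, len(core_list)):
            (ci, ti), (cj, tj) = core_list[i], core_list[j]
            rho, p = _st.spearmanr(df.loc[ti].to_numpy(), df.loc[tj].to_numpy())
            pairs.append({
                "taxon_a": ti, "taxon_b": tj,
                "group_a": ci, "group_b": cj,
                "kind": "within" if ci == cj else "between",
                "rho": float(rho), "p": float(p),
            })
    report = pd.DataFrame(pairs) if pairs else pd.DataFrame(
        columns=["taxon_a", "taxon_b", "group_a", "group_b", "kind", "rho", "p"])
    if len(groups) < 2:
        report.attrs["between_note"] = (
            "single subgroup: between-core comparison not applicable")
    return {"cores": cores, "pairs": report}


def pcoa_coordinates(dist: DistanceMatrix, n_axes: int = 2) -> pd.DataFrame:
    """Classical MDS (principal coordinates) of the distance matrix; a plain
    coordinate dump for plotting, not an inference step."""
    D2 = dist.values ** 2
    n = dist.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    coords = v[:, :n_axes] * np.sqrt(np.clip(w[:n_axes], 0, None))
    return pd.DataFrame(coords, index=dist.ids,
                        columns=[f"PCo{i+1}" for i in range(n_axes)])
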