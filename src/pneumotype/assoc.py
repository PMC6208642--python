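"""Association testing between subgroups and clinical features.

Implements the statistical machinery used for the Table-1-style screen:
an exact Fisher r x c test (full enumeration over margin-fixed tables,
Monte-Carlo fallback for large totals), a goodness-of-fit chi-square for
event counts against exposure, Kruskal-Wallis and Mann-Whitney rank tests,
Spearman correlation, and multiple-testing control (Benjamini-Hochberg and
a single-lambda Storey q-value).  Features are dispatched to tests by
their declared type (categorical / continuous / event-count).

These tests are implemented from first principles so that exactness
conventions (two-sided "sum of tables no more probable than observed" for
Fisher, enumeration for small rank tests) are explicit and testable; the
scipy equivalents serve as independent cross-checks in the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm as norm_dist
from scipy.stats import rankdata
from scipy.stats import random_table
from scipy.stats import t as t_dist

__all__ = [
    "ClinicalTable",
    "TestResult",
    "AssociationReport",
    "fisher_exact_rxc",
    "chisq_events",
    "kruskal_wallis",
    "mann_whitney",
    "spearman",
    "adjust_p",
    "run_feature_screen",
    "codetection_test",
    "read_clinical_tsv",
    "write_clinical_tsv",
]

FEATURE_TYPES = ("categorical", "continuous", "event-count")


@dataclass
class TestResult:
    """Outcome of a single hypothesis test."""

    test: str
    statistic: float
    p: float
    df: float | None = None
    n: int = 0
    effect: dict = field(default_factory=dict)
    note: str = ""


@dataclass
class ClinicalTable:
    """Per-sample clinical features with declared types.

    ``data`` is indexed by sample id; ``types`` maps each feature column to
    ``categorical``, ``continuous`` or ``event-count``.  Missing values are
    tolerated and dropped per-test (the n actually used is reported).
    """

    data: pd.DataFrame
    types: dict[str, str]

    def __post_init__(self) -> None:
        for feat, t in self.types.items():
            if t not in FEATURE_TYPES:
                raise ValueError(f"unknown feature type {t!r} for {feat!r}")
            if feat not in self.data.columns:
                raise ValueError(f"typed feature {feat!r} missing from table")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)


@dataclass
class AssociationReport:
    """Per-feature test results with BH-adjusted p and Storey q values."""

    results: pd.DataFrame
    q_threshold: float = 0.1
    padj_threshold: float = 0.05

    def significant(self, by: str = "q") -> pd.DataFrame:
        thr = self.q_threshold if by == "q" else self.padj_threshold
        return self.results[self.results[by] < thr]


# --------------------------------------------------------------------------
# Fisher exact test for r x c tables.

def _table_logp(cells: np.ndarray, const: float) -> float:
    return const - gammaln(cells + 1.0).sum()


def _enumerate_two_sided(row: np.ndarray, col: np.ndarray,
                         obs_logp: float, const: float) -> float:
    """Sum hypergeometric probabilities of all margin-fixed tables whose
    probability does not exceed the observed table's (two-sided p)."""
    r, c = len(row), len(col)
    total_p = 0.0
    tol = 1e-7

    def fill_row(ri: int, col_rem: np.ndarray, acc: float) -> None:
        nonlocal total_p
        if ri == r - 1:
            # last row forced by the remaining column margins
            logp = acc + const - gammaln(col_rem + 1.0).sum()
            if logp <= obs_logp + tol:
                total_p += math.exp(logp)
            return
        target = row[ri]

        def fill_cell(ci: int, rem: int, col_rem2: np.ndarray,
                      acc2: float) -> None:
            if ci == c - 1:
                if rem <= col_rem2[ci]:
                    new_col = col_rem2.copy()
                    new_col[ci] -= rem
                    fill_row(ri + 1, new_col, acc2 - gammaln(rem + 1.0))
                return
            for v in range(min(rem, col_rem2[ci]) + 1):
                new_col = col_rem2.copy()
                new_col[ci] -= v
                fill_cell(ci + 1, rem - v, new_col,
                          acc2 - gammaln(v + 1.0))

        fill_cell(0, target, col_rem, acc)

    fill_row(0, col.copy(), 0.0)
    return min(total_p, 1.0)


def fisher_exact_rxc(
    table,
    max_enumeration_total: int = 300,
    mc_draws: int = 100_000,
    seed: int = 0,
) -> TestResult:
    """Two-sided Fisher exact test for an r x c contingency table.

    p is the total hypergeometric probability of all tables with the same
    margins whose probability is <= the observed table's.  Exact
    enumeration is used when the grand total is <= ``max_enumeration_total``;
    larger tables fall back to seeded Patefield Monte-Carlo sampling with
    an add-one estimator.  A zero row or column margin gives p = 1 with a
    note (the table carries no information about association).
    """
    T = np.asarray(table, dtype=np.int64)
    if T.ndim != 2 or T.shape[0] < 2 or T.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if np.any(T < 0):
        raise ValueError("contingency table cells must be non-negative")
    row, col = T.sum(axis=1), T.sum(axis=0)
    N = int(T.sum())
    if np.any(row == 0) or np.any(col == 0):
        return TestResult(test="fisher_exact", statistic=float("nan"), p=1.0,
                          n=N, note="zero margin: no information, p set to 1")
    const = float(gammaln(row + 1.0).sum() + gammaln(col + 1.0).sum()
                  - gammaln(N + 1.0))
    obs_logp = _table_logp(T.astype(float), const)
    if N <= max_enumeration_total:
        p = _enumerate_two_sided(row, col, obs_logp, const)
        note = "exact enumeration"
    else:
        rng = np.random.default_rng(seed)
        draws = random_table(row, col).rvs(mc_draws, random_state=rng)
        logps = const - gammaln(draws + 1.0).sum(axis=(1, 2))
        p = (1 + int((logps <= obs_logp + 1e-7).sum())) / (mc_draws + 1)
        note = f"monte carlo ({mc_draws} draws)"
    return TestResult(test="fisher_exact", statistic=float(math.exp(obs_logp)),
                      p=float(min(p, 1.0)), n=N, note=note,
                      effect={"table": T.tolist()})


def chisq_events(events, exposure) -> TestResult:
    """Goodness-of-fit chi-square for event counts against group exposure.

    Under the null that events fall on groups proportionally to exposure,
    E_g = total * exposure_g / sum(exposure); X^2 = sum (O-E)^2 / E with
    df = groups - 1.  Flags validity when any expected count is < 1.
    """
    O = np.asarray(events, dtype=float)
    w = np.asarray(exposure, dtype=float)
    if O.sum() <= 0:
        raise ValueError("total event count must be positive")
    if np.any(w <= 0):
        raise ValueError("exposures must be positive")
    E = O.sum() * w / w.sum()
    x2 = float(((O - E) ** 2 / E).sum())
    df = len(O) - 1
    p = float(chi2_dist.sf(x2, df))
    note = "warning: expected count < 1" if np.any(E < 1) else ""
    return TestResult(test="chisq_events", statistic=x2, p=p, df=df,
                      n=int(O.sum()),
                      effect={"rates": (O / w).tolist(),
                              "expected": E.tolist()},
                      note=note)


def _tie_correction(all_values: np.ndarray) -> float:
    _, counts = np.unique(all_values, return_counts=True)
    n = len(all_values)
    if n < 2:
        return 1.0
    return 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis rank-sum test across >= 2 groups with average-rank
    ties and tie correction; p from the chi-square approximation with
    df = groups - 1.  All values identical gives H = 0, p = 1."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 1 for g in gs):
        raise ValueError("kruskal_wallis needs >= 2 non-empty groups")
    pooled = np.concatenate(gs)
    n = len(pooled)
    if n < 3:
        raise ValueError("kruskal_wallis needs >= 3 observations in total")
    if np.all(pooled == pooled[0]):
        return TestResult(test="kruskal_wallis", statistic=0.0, p=1.0,
                          df=len(gs) - 1, n=n, note="all values identical")
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    medians = []
    for g in gs:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        medians.append(float(np.median(g)))
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    corr = _tie_correction(pooled)
    if corr > 0:
        h /= corr
    df = len(gs) - 1
    return TestResult(test="kruskal_wallis", statistic=float(h),
                      p=float(chi2_dist.sf(h, df)), df=df, n=n,
                      effect={"group_medians": medians,
                              "group_sizes": [len(g) for g in gs]})


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    With n_x + n_y <= 12 and no ties the null distribution of U is fully
    enumerated (two-sided p doubles the smaller tail, capped at 1); larger
    or tied samples use the normal approximation with continuity and tie
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 1 or ny < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_x = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    n = nx + ny
    medians = {"median_x": float(np.median(x)), "median_y": float(np.median(y))}
    if n <= 12 and not has_ties:
        # enumerate all C(n, nx) placements of x's ranks
        all_ranks = np.arange(1, n + 1)
        us = np.array([sum(c) - nx * (nx + 1) / 2.0
                       for c in itertools.combinations(all_ranks, nx)])
        m = len(us)
        lo = (us <= u_x + 1e-9).sum() / m
        hi = (us >= u_x - 1e-9).sum() / m
        p = min(1.0, 2.0 * min(lo, hi))
        return TestResult(test="mann_whitney_exact", statistic=float(u_x),
                          p=float(p), n=n, effect=medians)
    mu = nx * ny / 2.0
    tie_term = 0.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return TestResult(test="mann_whitney_normal", statistic=float(u_x),
                          p=1.0, n=n, note="zero variance (all ties)",
                          effect=medians)
    z = (abs(u_x - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = float(min(1.0, 2.0 * norm_dist.sf(z)))
    return TestResult(test="mann_whitney_normal", statistic=float(u_x),
                      p=p, n=n, effect=medians)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with average ranks.

    p is exact (full permutation enumeration) for n <= 9, else from the
    t approximation t = rho sqrt((n-2)/(1-rho^2)) with df = n - 2.
    Zero variance in either vector is flagged as undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("spearman needs two equal-length vectors, n >= 3")
    rx, ry = rankdata(x), rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return TestResult(test="spearman", statistic=float("nan"), p=float("nan"),
                          n=n, note="zero variance: correlation undefined")
    rxs = (rx - rx.mean()) / rx.std()
    rys = (ry - ry.mean()) / ry.std()
    rho = float((rxs * rys).mean())
    if n <= 9:
        perms = np.array(list(itertools.permutations(range(n))))
        rho_perm = (rys[perms] @ rxs) / n
        p = float((np.abs(rho_perm) >= abs(rho) - 1e-12).mean())
        return TestResult(test="spearman_exact", statistic=rho, p=p, n=n)
    if abs(rho) >= 1.0:
        return TestResult(test="spearman_t", statistic=rho, p=0.0, n=n,
                          note="|rho| = 1: p below floating resolution")
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = float(min(1.0, 2.0 * t_dist.sf(abs(t), n - 2)))
    return TestResult(test="spearman_t", statistic=rho, p=p, n=n)


def adjust_p(pvalues, method: str = "bh", lam: float = 0.5) -> np.ndarray:
    """Multiple-testing adjustment.

    ``bh``: Benjamini-Hochberg step-up adjusted p-values with enforced
    monotonicity.  ``qvalue``: single-lambda Storey estimate,
    pi0 = min(1, #{p > lambda} / ((1 - lambda) m)), q_i = pi0 * BH_i.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    bh = np.empty(m)
    bh[order] = np.minimum(ranked, 1.0)
    if method == "bh":
        return bh
    if method == "qvalue":
        pi0 = min(1.0, float((p > lam).sum()) / ((1.0 - lam) * m))
        return np.minimum(pi0 * bh, 1.0)
    raise ValueError(f"unknown adjustment method: {method!r}")


# --------------------------------------------------------------------------
# Table-1-style screen and co-detection permutation test.

def run_feature_screen(clinical: ClinicalTable, labels) -> AssociationReport:
    """Test every declared clinical feature against the subgroup labels.

    Dispatch by type: categorical -> Fisher exact on the feature x subgroup
    contingency table; continuous -> Kruskal-Wallis across subgroups;
    event-count -> goodness-of-fit chi-square with subgroup patient counts
    as exposure.  BH-adjusted p and Storey q values are attached across
    the whole screen.
    """
    labels = np.asarray(labels)
    if len(labels) != len(clinical.samples):
        raise ValueError("labels length does not match clinical table")
    lab = pd.Series(labels, index=clinical.data.index)
    groups = np.unique(labels)
    rows = []
    for feat, ftype in clinical.types.items():
        col = clinical.data[feat]
        ok = col.notna()
        if ftype == "categorical":
            sub = pd.crosstab(col[ok], lab[ok])
            res = fisher_exact_rxc(sub.to_numpy()) if sub.shape[0] >= 2 \
                else TestResult(test="fisher_exact", statistic=float("nan"),
                                p=1.0, n=int(ok.sum()),
                                note="single category observed")
        elif ftype == "continuous":
            vals = [col[ok & (lab == g)].astype(float).to_numpy()
                    for g in groups]
            vals = [v for v in vals if len(v) > 0]
            res = kruskal_wallis(vals)
        elif ftype == "event-count":
            events = [float(col[ok & (lab == g)].sum()) for g in groups]
            exposure = [int((ok & (lab == g)).sum()) for g in groups]
            res = chisq_events(events, exposure)
        else:  # pragma: no cover - guarded by ClinicalTable
            raise ValueError(f"unknown feature type for column {feat!r}")
        rows.append({"feature": feat, "type": ftype, "test": res.test,
                     "statistic": res.statistic, "p": res.p,
                     "n": res.n, "note": res.note})
    df = pd.DataFrame(rows).set_index("feature")
    pclip = df["p"].clip(lower=np.nextafter(0, 1)).to_numpy()
    df["padj"] = adjust_p(pclip, "bh")
    df["q"] = adjust_p(pclip, "qvalue")
    return AssociationReport(results=df)


def codetection_test(
    presence: pd.DataFrame,
    uo_taxa,
    group,
    B: int = 9999,
    seed: int = 0,
) -> TestResult:
    """Permutation test for co-detection of a taxon set within a sample
    group.

    The statistic is the number of group samples in which >= 2 of the
    given taxa are present; the null permutes group membership over all
    samples ``B`` times (add-one p-value).
    """
    uo_taxa = [t for t in uo_taxa]
    group = [s for s in group]
    if not uo_taxa or not group:
        raise ValueError("taxon set and sample group must be non-empty")
    if len(group) > presence.shape[1]:
        raise ValueError("group is larger than the number of samples")
    P = presence.loc[uo_taxa].to_numpy().astype(bool)
    n_codetected = P.sum(axis=0)  # per sample: how many uo taxa present
    is_group = np.array([s in set(group) for s in presence.columns])
    obs = int((n_codetected[is_group] >= 2).sum())
    if obs == 0:
        return TestResult(test="codetection_perm", statistic=0.0, p=1.0,
                          n=len(group), note="no co-detection observed")
    rng = np.random.default_rng(seed)
    g = int(is_group.sum())
    count = 0
    hits = (n_codetected >= 2).astype(int)
    n = presence.shape[1]
    for _ in range(B):
        perm = rng.choice(n, size=g, replace=False)
        if hits[perm].sum() >= obs:
            count += 1
    p = (1 + count) / (B + 1)
    return TestResult(test="codetection_perm", statistic=float(obs), p=float(p),
                      n=len(group))


def read_clinical_tsv(data_path, types_path) -> ClinicalTable:
    """Read a clinical table (rows = samples, first column sample id) and a
    type sidecar TSV with columns ``feature`` and ``type``."""
    data = pd.read_csv(data_path, sep="\t", index_col=0)
    tdf = pd.read_csv(types_path, sep="\t")
    types = dict(zip(tdf["feature"], tdf["type"]))
    return ClinicalTable(data=data, types=types)


def write_clinical_tsv(clinical: ClinicalTable, data_path, types_path) -> None:
    clinical.data.to_csv(data_path, sep="\t", index_label="sample")
    pd.DataFrame(
        {"feature": list(clinical.types), "type": list(clinical.types.values())}
    ).to_csv(types_path, sep="\t", index=False)
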