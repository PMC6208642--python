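"""Host-microbe interaction screens.

Links the microbial community to the host transcriptome and cytokine
profile: a taxon-by-gene Spearman correlation screen with FDR control, a
per-gene nonparametric differential-expression screen across subgroups, a
focused gene-set comparison between two subgroups (e.g. the Th17
differentiation pathway), and a per-analyte cytokine comparison.

Expression values are TPM; the working scale is log2(TPM + 1e-5), which
keeps zeros finite while preserving per-gene sample ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm as norm_dist
from scipy.stats import rankdata
from scipy.stats import t as t_dist

from .abundance import RelativeAbundance
from .assoc import adjust_p, kruskal_wallis, mann_whitney

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "TH17_KEY_GENES",
    "TH_PATHWAY_GENES",
    "log_transform",
    "taxa_gene_screen",
    "subgroup_de_screen",
    "geneset_compare",
    "cytokine_compare",
    "read_expression_tsv",
]

LOG_PSEUDO = 1e-5  # log2(TPM + 1e-5)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a transform tag."""

    values: pd.DataFrame
    transform: str = "tpm"  # "tpm" (raw) or "log2"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if self.transform == "tpm" and (self.values.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneSet:
    """Named list of gene ids (e.g. Th17 differentiation markers)."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene set must be non-empty")

    def resolve(self, expr: ExpressionMatrix) -> tuple[list[str], list[str]]:
        """(present, missing) against the matrix; missing ids are reported,
        not fatal."""
        idx = set(expr.genes)
        present = [g for g in self.genes if g in idx]
        missing = [g for g in self.genes if g not in idx]
        return present, missing


# The 13 key genes of the Th17 differentiation pathway tracked in the
# focused comparison (IL-6/TGF-beta signalling through STAT3/RORC to the
# IL-17 effector cytokines); overridable by any user GeneSet.
TH17_KEY_GENES = GeneSet(
    name="th17_key",
    genes=["IL6", "TGFB1", "STAT3", "RORC", "RORA", "IL17A", "IL17F",
           "IL21", "IL22", "IL23A", "IL23R", "IL1B", "IRF4"],
)

# Broader T-helper differentiation panel (36 genes) used for the pathway-
# wide subgroup comparison.
TH_PATHWAY_GENES = GeneSet(
    name="th_differentiation",
    genes=TH17_KEY_GENES.genes + [
        "IL2", "IL4", "IL5", "IL10", "IL12A", "IL12B", "IL13", "IFNG",
        "TBX21", "GATA3", "STAT1", "STAT4", "STAT5A", "STAT6", "FOXP3",
        "SMAD2", "SMAD3", "SMAD4", "NFATC1", "NFKB1", "RELA", "JAK1",
        "JAK2",
    ],
)


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1e-5); refuses to transform twice."""
    if expr.transform == "log2":
        raise ValueError("expression matrix is already log2-transformed")
    return ExpressionMatrix(values=np.log2(expr.values + LOG_PSEUDO),
                            transform="log2")


def _spearman_matrix(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and two-sided t-approximation p between the
    rows of A and the rows of B (columns = shared samples)."""
    n = A.shape[1]
    ra = np.apply_along_axis(rankdata, 1, A)
    rb = np.apply_along_axis(rankdata, 1, B)
    ra = (ra - ra.mean(axis=1, keepdims=True))
    rb = (rb - rb.mean(axis=1, keepdims=True))
    sa = ra.std(axis=1)
    sb = rb.std(axis=1)
    rho = (ra @ rb.T) / n / np.outer(np.maximum(sa, 1e-300),
                                     np.maximum(sb, 1e-300))
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho ** 2, 1e-300))
    p = np.minimum(2.0 * t_dist.sf(np.abs(t), n - 2), 1.0)
    return rho, p


def taxa_gene_screen(
    rel: RelativeAbundance,
    expr: ExpressionMatrix,
    p_thresh: float = 0.01,
    q_thresh: float = 0.01,
) -> pd.DataFrame:
    """Spearman screen of every (taxon, gene) pair over shared samples.

    Returns pairs with p < ``p_thresh`` and q < ``q_thresh`` (Storey q
    over all tested pairs).  Constant taxa or genes are skipped with a
    warning.  Expects the relative-abundance table to already hold only
    the taxa in the analysis universe (detection-filtered).
    """
    shared = [s for s in rel.samples if s in set(expr.samples)]
    if len(shared) < 6:
        raise ValueError(f"need >= 6 shared samples, got {len(shared)}")
    A = rel.values[shared].to_numpy(dtype=float)
    B = expr.values[shared].to_numpy(dtype=float)
    taxa = np.array(rel.taxa)
    genes = np.array(expr.genes)
    keep_t = A.std(axis=1) > 0
    keep_g = B.std(axis=1) > 0
    if not keep_t.all() or not keep_g.all():
        warnings.warn(
            f"skipped {int((~keep_t).sum())} constant taxa and "
            f"{int((~keep_g).sum())} constant genes")
    A, taxa = A[keep_t], taxa[keep_t]
    B, genes = B[keep_g], genes[keep_g]
    rho, p = _spearman_matrix(A, B)
    p_flat = np.clip(p.ravel(), np.nextafter(0, 1), 1.0)
    q = adjust_p(p_flat, "qvalue").reshape(p.shape)
    ti, gi = np.where((p < p_thresh) & (q < q_thresh))
    out = pd.DataFrame({
        "taxon": taxa[ti], "gene": genes[gi],
        "rho": rho[ti, gi], "p": p[ti, gi], "q": q[ti, gi],
    }).sort_values(["q", "p"], kind="stable").reset_index(drop=True)
    out.attrs["n_pairs_tested"] = int(rho.size)
    out.attrs["n_shared_samples"] = len(shared)
    return out


def _vectorised_kw(B: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-row Kruskal-Wallis p over the given column-index groups."""
    n = sum(len(g) for g in groups)
    ranks = np.apply_along_axis(rankdata, 1, B)
    h = np.zeros(B.shape[0])
    for g in groups:
        r = ranks[:, g].sum(axis=1)
        h += r ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # per-row tie correction
    corr = np.array([_row_tie_correction(row) for row in B])
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(corr > 0, h / corr, 0.0)
    return chi2_dist.sf(h, len(groups) - 1)


def _row_tie_correction(row: np.ndarray) -> float:
    _, counts = np.unique(row, return_counts=True)
    n = len(row)
    return 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)


def _vectorised_mwu(B: np.ndarray, gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Per-row two-sided Mann-Whitney normal-approximation p."""
    nx, ny = len(gx), len(gy)
    n = nx + ny
    sub = B[:, np.concatenate([gx, gy])]
    ranks = np.apply_along_axis(rankdata, 1, sub)
    u = ranks[:, :nx].sum(axis=1) - nx * (nx + 1) / 2.0
    mu = nx * ny / 2.0
    tie = np.array([(np.unique(row, return_counts=True)[1] ** 3
                     - np.unique(row, return_counts=True)[1]).sum()
                    for row in sub]) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie)
    z = np.where(sigma2 > 0,
                 np.maximum(np.abs(u - mu) - 0.5, 0.0) / np.sqrt(
                     np.maximum(sigma2, 1e-300)),
                 0.0)
    p = np.minimum(2.0 * norm_dist.sf(z), 1.0)
    return np.where(sigma2 > 0, p, 1.0)


def subgroup_de_screen(
    expr: ExpressionMatrix,
    labels,
    padj_thresh: float = 0.01,
) -> pd.DataFrame:
    """Per-gene nonparametric differential-expression screen across
    subgroups.

    Kruskal-Wallis for >= 3 subgroups, Mann-Whitney for 2, BH adjustment
    across genes.  Subgroups with fewer than 3 samples are excluded with a
    warning; constant genes are never reported.  Returns the per-gene
    table (p, padj, per-subgroup medians) with the significant subset
    flagged.  Method note: the DE test is a rank test chosen for small
    per-group sample sizes; it is recorded in the output attrs.
    """
    labels = np.asarray(labels)
    if len(labels) != len(expr.samples):
        raise ValueError("labels length does not match expression samples")
    groups, counts = np.unique(labels, return_counts=True)
    keep_groups = [g for g, c in zip(groups, counts) if c >= 3]
    dropped = [g for g, c in zip(groups, counts) if c < 3]
    if dropped:
        warnings.warn(f"subgroups with < 3 samples excluded from DE: {dropped}")
    if len(keep_groups) < 2:
        raise ValueError("need >= 2 subgroups with >= 3 samples each")
    B = expr.values.to_numpy(dtype=float)
    col_groups = [np.flatnonzero(labels == g) for g in keep_groups]
    variable = B[:, np.concatenate(col_groups)].std(axis=1) > 0
    if len(keep_groups) == 2:
        p = _vectorised_mwu(B, col_groups[0], col_groups[1])
        test = "mann_whitney"
    else:
        p = _vectorised_kw(B[:, np.concatenate(col_groups)],
                           _regroup(col_groups))
        test = "kruskal_wallis"
    p = np.where(variable, p, 1.0)
    out = pd.DataFrame({"gene": expr.genes, "p": p}).set_index("gene")
    for g, cols in zip(keep_groups, col_groups):
        out[f"median_{g}"] = np.median(B[:, cols], axis=1)
    out["padj"] = adjust_p(out["p"].clip(lower=np.nextafter(0, 1)).to_numpy(),
                           "bh")
    out["significant"] = (out["padj"] < padj_thresh) & variable
    out.attrs["test"] = test
    out.attrs["note"] = ("nonparametric rank test per gene with BH control; "
                         "chosen for small per-subgroup sample sizes")
    return out


def _regroup(col_groups: list[np.ndarray]) -> list[np.ndarray]:
    """Column groups re-indexed into the concatenated submatrix."""
    out, start = [], 0
    for g in col_groups:
        out.append(np.arange(start, start + len(g)))
        start += len(g)
    return out


def geneset_compare(
    expr: ExpressionMatrix,
    labels,
    geneset: GeneSet,
    pair: tuple = (0, 1),
) -> dict:
    """Compare a gene set's expression between two subgroups, gene by gene.

    Each present gene gets a Mann-Whitney test between the two subgroups
    (the exact small-sample path applies automatically, so p-values for
    tiny subgroups carry their honest enumeration floor).  The summary
    counts genes with p < 0.05 and reports the fraction whose median
    difference points the same way as the majority.
    """
    labels = np.asarray(labels)
    a, b = pair
    idx_a = np.flatnonzero(labels == a)
    idx_b = np.flatnonzero(labels == b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError(f"both subgroups {pair} must be present")
    present, missing = geneset.resolve(expr)
    B = expr.values
    rows = []
    for g in present:
        x = B.loc[g].to_numpy()[idx_a]
        y = B.loc[g].to_numpy()[idx_b]
        res = mann_whitney(x, y)
        rows.append({"gene": g, "test": res.test, "statistic": res.statistic,
                     "p": res.p,
                     "median_a": res.effect["median_x"],
                     "median_b": res.effect["median_y"],
                     "direction": float(np.sign(res.effect["median_x"]
                                                - res.effect["median_y"]))})
    table = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame()
    n_sig = int((table["p"] < 0.05).sum()) if rows else 0
    directions = table["direction"].to_numpy() if rows else np.array([])
    nonzero = directions[directions != 0]
    consistency = (float(max((nonzero > 0).mean(), (nonzero < 0).mean()))
                   if len(nonzero) else float("nan"))
    return {
        "geneset": geneset.name,
        "pair": (a, b),
        "per_gene": table,
        "n_significant": n_sig,
        "direction_consistency": consistency,
        "missing_genes": missing,
    }


def cytokine_compare(cytokines: pd.DataFrame, labels) -> pd.DataFrame:
    """Kruskal-Wallis per analyte (rows) across subgroups.

    Returns every analyte with its p-value and per-subgroup medians and a
    ``significant`` flag at p < 0.05.  Non-numeric cells raise with their
    location.
    """
    labels = np.asarray(labels)
    if len(labels) != cytokines.shape[1]:
        raise ValueError("labels length does not match cytokine samples")
    for analyte in cytokines.index:
        for sample in cytokines.columns:
            v = cytokines.loc[analyte, sample]
            if not isinstance(v, (int, float, np.integer, np.floating)) \
                    or pd.isna(v):
                raise ValueError(
                    f"non-numeric cytokine value at ({analyte!r}, {sample!r})")
    groups = np.unique(labels)
    rows = []
    for analyte in cytokines.index:
        vals = cytokines.loc[analyte].to_numpy(dtype=float)
        per_group = [vals[labels == g] for g in groups]
        res = kruskal_wallis(per_group)
        row = {"analyte": analyte, "statistic": res.statistic, "p": res.p}
        for g, v in zip(groups, per_group):
            row[f"median_{g}"] = float(np.median(v))
        rows.append(row)
    out = pd.DataFrame(rows).set_index("analyte")
    out["significant"] = out["p"] < 0.05
    return out


def read_expression_tsv(path, transform: str = "tpm") -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df, transform=transform)


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")
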