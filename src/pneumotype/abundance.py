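"""Abundance tables, relative ("read") abundance, detection filtering,
alpha diversity, rarefaction, and cross-assay concordance.

The central object is :class:`AbundanceTable`, a taxa-by-samples matrix of
non-negative integer read counts at a single taxonomic rank.  "Read
abundance" is a taxon's fraction of the microbial (archaea/bacteria/fungi/
virus) reads in a sample, used throughout as a proxy for transcriptional
activity.  Taxa are retained for analysis when their read abundance reaches
a threshold (default 1%) in at least one sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AbundanceTable",
    "RelativeAbundance",
    "ComparisonReport",
    "to_relative",
    "detection_filter",
    "alpha_diversity",
    "rarefaction",
    "compare_tables",
    "read_counts_tsv",
    "write_counts_tsv",
]

RANKS = ("phylum", "genus", "species")


@dataclass
class AbundanceTable:
    """Taxa x samples integer read counts at one taxonomic rank.

    Parameters
    ----------
    counts
        DataFrame with taxon ids as the index and sample ids as columns.
    rank
        Taxonomic rank label of the rows (e.g. ``"genus"``).
    sample_meta
        Optional per-sample metadata (index = sample ids).
    """

    counts: pd.DataFrame
    rank: str = "genus"
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate taxon ids in abundance table")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in abundance table")
        vals = self.counts.to_numpy()
        if vals.size == 0:
            raise ValueError("empty abundance table")
        if np.any(vals < 0):
            raise ValueError("negative counts in abundance table")
        if vals.sum() == 0:
            raise ValueError("abundance table has no nonzero column")

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_taxa(self, taxa: list[str]) -> "AbundanceTable":
        return AbundanceTable(self.counts.loc[taxa], rank=self.rank,
                              sample_meta=self.sample_meta)


@dataclass
class RelativeAbundance:
    """Taxa x samples proportions; columns sum to 1 (or 0 if the sample
    was empty).  Produced by :func:`to_relative`."""

    values: pd.DataFrame
    rank: str = "genus"

    def __post_init__(self) -> None:
        sums = self.values.sum(axis=0).to_numpy()
        ok = np.isclose(sums, 1.0, atol=1e-9) | (sums == 0)
        if not np.all(ok):
            raise ValueError("relative-abundance columns must sum to 1 (or 0)")

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset_taxa(self, taxa: list[str]) -> pd.DataFrame:
        """Raw (non-renormalised) proportions of the given taxa."""
        return self.values.loc[taxa]


def to_relative(table: AbundanceTable) -> RelativeAbundance:
    """Convert counts to per-sample read abundance (column proportions).

    Empty samples (zero total) become all-zero columns, with a warning.
    """
    totals = table.counts.sum(axis=0)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            f"samples with zero total reads set to all-zero columns: "
            f"{list(totals.index[empty])}"
        )
    safe = totals.replace(0, 1)
    rel = table.counts.div(safe, axis=1)
    return RelativeAbundance(rel, rank=table.rank)


def detection_filter(
    rel: RelativeAbundance, threshold: float = 0.01
) -> tuple[RelativeAbundance, list[str]]:
    """Keep taxa whose read abundance reaches ``threshold`` (inclusive) in
    at least one sample; row order is preserved.

    Returns the filtered table (proportions are *not* renormalised) and the
    kept-taxa list.  An empty result is returned as an empty table, not an
    error.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    keep = rel.values.max(axis=1) >= threshold
    kept = list(rel.values.index[keep])
    filtered = RelativeAbundance.__new__(RelativeAbundance)
    filtered.values = rel.values.loc[kept]
    filtered.rank = rel.rank
    return filtered, kept


def _sample_diversity(p: np.ndarray, index: str) -> float:
    p = p[p > 0]
    if index == "shannon":
        return float(-(p * np.log(p)).sum())
    if index == "simpson":
        return float(1.0 - (p ** 2).sum())
    if index == "richness":
        return float(len(p))
    raise ValueError(f"unknown diversity index: {index!r}")


def alpha_diversity(rel: RelativeAbundance, index: str = "shannon") -> pd.Series:
    """Per-sample alpha diversity.

    ``shannon`` is -sum(p ln p) with 0*ln(0) = 0 (natural log), ``simpson``
    is 1 - sum(p^2), ``richness`` counts taxa with p > 0.
    """
    if index not in ("shannon", "simpson", "richness"):
        raise ValueError(f"unknown diversity index: {index!r}")
    vals = {
        s: _sample_diversity(rel.values[s].to_numpy(), index)
        for s in rel.samples
    }
    return pd.Series(vals, name=index)


def rarefaction(
    table: AbundanceTable,
    depths: list[int],
    threshold: float = 0.0,
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean number of detected taxa after subsampling each sample to the
    given depths.

    Reads are drawn without replacement (multivariate hypergeometric); a
    taxon is "detected" when its subsampled relative abundance is >=
    ``threshold`` (with ``threshold`` 0, any taxon with >= 1 read counts).
    The result is averaged over ``reps`` draws.  Depths exceeding a
    sample's total are skipped for that sample (NaN) with a warning.
    """
    rng = np.random.default_rng(seed)
    totals = table.library_sizes()
    out = pd.DataFrame(index=pd.Index(depths, name="depth"),
                       columns=table.samples, dtype=float)
    counts = table.counts.to_numpy().astype(np.int64)
    for j, s in enumerate(table.samples):
        col = counts[:, j]
        total = int(totals[s])
        for depth in depths:
            if depth > total:
                warnings.warn(
                    f"depth {depth} exceeds total {total} for sample {s}; skipped"
                )
                continue
            detected = 0.0
            for _ in range(reps):
                sub = rng.multivariate_hypergeometric(col, depth)
                if threshold <= 0:
                    detected += int((sub > 0).sum())
                else:
                    detected += int((sub / depth >= threshold).sum())
            out.loc[depth, s] = detected / reps
    return out


@dataclass
class ComparisonReport:
    """Concordance between two relative-abundance tables (e.g. the
    metatranscriptome- and 16S-derived genus profiles)."""

    pooled_rho: float
    pooled_p: float
    per_sample: pd.DataFrame  # index = shared samples; columns rho, p
    shared_taxa: list[str] = field(default_factory=list)
    only_a: list[str] = field(default_factory=list)
    only_b: list[str] = field(default_factory=list)


def compare_tables(rel_a: RelativeAbundance, rel_b: RelativeAbundance) -> ComparisonReport:
    """Spearman concordance of two assays over shared samples.

    Correlations are computed on the union of the two taxon sets with
    absent taxa entered as abundance 0 (the zero -> 1e-6 convention is a
    display device for log axes only and is never applied here).  The
    pooled correlation treats every (sample, taxon) pair as one
    observation; per-sample correlations use each sample's union-taxon
    profile.  Requires >= 3 shared taxa and >= 1 shared sample.
    """
    taxa_a, taxa_b = set(rel_a.taxa), set(rel_b.taxa)
    shared_taxa = sorted(taxa_a & taxa_b)
    if len(shared_taxa) < 3:
        raise ValueError(
            f"need >= 3 shared taxa to compare tables, got {len(shared_taxa)}"
        )
    shared_samples = [s for s in rel_a.samples if s in set(rel_b.samples)]
    if not shared_samples:
        raise ValueError("no shared samples between tables")
    union = sorted(taxa_a | taxa_b)
    a = rel_a.values.reindex(index=union, columns=shared_samples).fillna(0.0)
    b = rel_b.values.reindex(index=union, columns=shared_samples).fillna(0.0)

    rho, p = stats.spearmanr(a.to_numpy().ravel(), b.to_numpy().ravel())
    rows = {}
    for s in shared_samples:
        r_s, p_s = stats.spearmanr(a[s].to_numpy(), b[s].to_numpy())
        rows[s] = {"rho": r_s, "p": p_s}
    return ComparisonReport(
        pooled_rho=float(rho),
        pooled_p=float(p),
        per_sample=pd.DataFrame.from_dict(rows, orient="index"),
        shared_taxa=shared_taxa,
        only_a=sorted(taxa_a - taxa_b),
        only_b=sorted(taxa_b - taxa_a),
    )


def read_counts_tsv(path, rank: str = "genus") -> AbundanceTable:
    """Read a counts TSV: taxa as rows, first column taxon id, header =
    sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AbundanceTable(df.astype(np.int64), rank=rank)


def write_counts_tsv(table: AbundanceTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="taxon")
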