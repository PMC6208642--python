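"""Synthetic data with the statistical structure the analysis assumes.

Three generators produce the full input bundle for an end-to-end run:

* community counts — samples drawn from K planted Dirichlet-multinomial
  components with lognormal library sizes (the generative twin of the
  mixture model the clustering route fits);
* clinical covariates — smear status, leukocyte percentages and Poisson
  exacerbation counts coupled to the planted component labels;
* expression — log-normal baseline TPM with subgroup-shifted gene blocks
  and genes tied monotonically to a taxon's relative abundance.

Defaults emulate the study conditions: 3 components over 30 taxa, each
dominated by a disjoint pair of taxa, library sizes with median ~8.1k
microbial reads, exacerbation rates {0.4, 2, 3.5} events per patient over
follow-up, and a smear-negative low-biomass middle component.

:func:`paper_fixtures` returns the small printed inputs used by the
fixture-level checks (exacerbation bookkeeping, biomass medians, subgroup
sizes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import AbundanceTable
from .assoc import ClinicalTable
from .hostlink import ExpressionMatrix

__all__ = [
    "ConfigError",
    "CommunityConfig",
    "ClinicalConfig",
    "ExpressionConfig",
    "PaperFixtures",
    "generate_community",
    "generate_clinical",
    "generate_expression",
    "paper_fixtures",
]


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


def default_alphas(K: int, n_taxa: int, dominant: float = 100.0,
                   base: float = 5.0) -> np.ndarray:
    """Default Dirichlet parameters: component k is dominated by taxa
    2k and 2k+1 (disjoint pairs) on a common low-abundance background.

    With base 5 and two dominants at 100 over 30 taxa, each dominant
    taxon has expected relative abundance ~0.31 in its component —
    co-dominant pairs like the Streptococcus/Rothia-style subgroup.  The
    total concentration (~340) keeps within-component composition spread
    small relative to the between-component separation, so the planted K
    is identifiable from a few dozen samples: these defaults deliberately
    describe the "well-separated planted components" regime the recovery
    checks assume, not the messier dispersion of real communities."""
    if n_taxa < 2 * K:
        raise ConfigError("n_taxa: need at least 2 taxa per component")
    alpha = np.full((K, n_taxa), base)
    for k in range(K):
        alpha[k, 2 * k] = dominant
        alpha[k, 2 * k + 1] = dominant
    return alpha


@dataclass
class CommunityConfig:
    """Planted Dirichlet-multinomial community mixture."""

    n_samples: int = 40
    n_taxa: int = 30
    K: int = 3
    mixing: np.ndarray | None = None          # defaults to uniform
    alpha: np.ndarray | None = None           # K x n_taxa, > 0
    depth_log_mean: float = 9.0               # lognormal library sizes,
    depth_log_sd: float = 0.5                 # median exp(9) ~ 8.1e3 reads
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples: must be a positive integer")
        if self.n_taxa < 1:
            raise ConfigError("n_taxa: must be a positive integer")
        if self.K < 1:
            raise ConfigError("K: must be a positive integer")
        if self.n_samples < self.K:
            raise ConfigError("n_samples: must be >= K")
        if self.mixing is None:
            self.mixing = np.full(self.K, 1.0 / self.K)
        self.mixing = np.asarray(self.mixing, dtype=float)
        if len(self.mixing) != self.K:
            raise ConfigError("mixing: length must equal K")
        if abs(self.mixing.sum() - 1.0) > 1e-12:
            raise ConfigError("mixing: proportions must sum to 1")
        if np.any(self.mixing < 0):
            raise ConfigError("mixing: proportions must be non-negative")
        if self.alpha is None:
            self.alpha = default_alphas(self.K, self.n_taxa)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (self.K, self.n_taxa):
            raise ConfigError("alpha: shape must be (K, n_taxa)")
        if np.any(self.alpha <= 0):
            raise ConfigError("alpha: all entries must be > 0")
        if self.depth_log_sd < 0:
            raise ConfigError("depth_log_sd: must be >= 0")


def generate_community(config: CommunityConfig, labels=None
                       ) -> tuple[AbundanceTable, np.ndarray]:
    """Draw a taxa x samples count table from the planted mixture.

    Sample i: label ~ Categorical(mixing); p ~ Dirichlet(alpha[label]);
    counts ~ Multinomial(N_i, p) with N_i ~ round(lognormal), floored at 1.
    Deterministic under a fixed seed (bitwise-identical tables).

    ``labels`` may fix the component memberships (length n_samples, values
    in [0, K)), e.g. to plant exact group sizes; by default they are drawn
    from ``mixing``.
    """
    rng = np.random.default_rng(config.seed)
    n, T, K = config.n_samples, config.n_taxa, config.K
    if labels is not None:
        labels = np.asarray(labels, dtype=int)
        if len(labels) != n:
            raise ConfigError("labels: length must equal n_samples")
        if labels.min() < 0 or labels.max() >= K:
            raise ConfigError("labels: values must lie in [0, K)")
    else:
        labels = rng.choice(K, size=n, p=config.mixing)
    counts = np.empty((T, n), dtype=np.int64)
    for i in range(n):
        p = rng.dirichlet(config.alpha[labels[i]])
        depth = max(int(round(rng.lognormal(config.depth_log_mean,
                                            config.depth_log_sd))), 1)
        counts[:, i] = rng.multinomial(depth, p)
    df = pd.DataFrame(counts,
                      index=[f"taxon_{t:02d}" for t in range(T)],
                      columns=[f"sample_{i:02d}" for i in range(n)])
    return AbundanceTable(df, rank="genus"), labels


@dataclass
class ClinicalConfig:
    """Per-component clinical distributions coupled to community labels.

    Defaults emulate the study's feature classes: a smear-negative
    low-biomass middle component, raised lymphocyte (and lowered
    macrophage) percentages in the small third component, and exacerbation
    rates {0.4, 2, 3.5} events per patient over the follow-up window.
    """

    smear_pos_prob: tuple = (0.8, 0.0, 0.75)
    lymphocyte_mean: tuple = (18.0, 15.0, 45.0)   # percent
    lymphocyte_sd: tuple = (8.0, 8.0, 10.0)
    macrophage_mean: tuple = (62.0, 65.0, 35.0)
    macrophage_sd: tuple = (10.0, 10.0, 10.0)
    exacerbation_rate: tuple = (0.4, 2.0, 3.5)    # events/patient over follow-up
    follow_up_years: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 <= p <= 1 for p in self.smear_pos_prob):
            raise ConfigError("smear_pos_prob: probabilities must lie in [0, 1]")
        if any(r < 0 for r in self.exacerbation_rate):
            raise ConfigError("exacerbation_rate: rates must be >= 0")
        if self.follow_up_years <= 0:
            raise ConfigError("follow_up_years: must be positive")
        lens = {len(self.smear_pos_prob), len(self.lymphocyte_mean),
                len(self.lymphocyte_sd), len(self.macrophage_mean),
                len(self.macrophage_sd), len(self.exacerbation_rate)}
        if len(lens) != 1:
            raise ConfigError("per-component fields must have equal length")
        self.n_components = lens.pop()


def generate_clinical(labels, config: ClinicalConfig) -> ClinicalTable:
    """Per-sample clinical features conditional on component labels.

    smear ~ Bernoulli(p_component) coded Positive/negative; leukocyte
    percentages ~ Normal truncated (clipped) to [0, 100]; exacerbations ~
    Poisson(rate_component).  Deterministic under a fixed seed.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.max() >= config.n_components:
        raise ConfigError(
            f"labels reference component {labels.max()} but config has "
            f"{config.n_components} components")
    rng = np.random.default_rng(config.seed)
    n = len(labels)
    p = np.asarray(config.smear_pos_prob)[labels]
    smear = np.where(rng.random(n) < p, "Positive", "negative")
    lym = np.clip(rng.normal(np.asarray(config.lymphocyte_mean)[labels],
                             np.asarray(config.lymphocyte_sd)[labels]),
                  0.0, 100.0)
    mac = np.clip(rng.normal(np.asarray(config.macrophage_mean)[labels],
                             np.asarray(config.macrophage_sd)[labels]),
                  0.0, 100.0)
    exa = rng.poisson(np.asarray(config.exacerbation_rate)[labels])
    data = pd.DataFrame({
        "smear": smear,
        "lymphocyte_pct": lym,
        "macrophage_pct": mac,
        "exacerbations": exa,
    }, index=[f"sample_{i:02d}" for i in range(n)])
    return ClinicalTable(data=data, types={
        "smear": "categorical",
        "lymphocyte_pct": "continuous",
        "macrophage_pct": "continuous",
        "exacerbations": "event-count",
    })


@dataclass
class ExpressionConfig:
    """Host expression with planted subgroup shifts and taxon links.

    ``subgroup_shift_genes``: (gene index, component, log2 effect) — the
    gene's log2-TPM is raised by the effect in that component's samples.
    ``taxon_linked_genes``: (gene index, taxon index, slope, noise sd) —
    the gene's log2-TPM follows slope * standardised log relative
    abundance of the taxon plus Gaussian noise.
    """

    n_genes: int = 200
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    subgroup_shift_genes: list = field(default_factory=list)
    taxon_linked_genes: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes: must be a positive integer")
        if self.baseline_log2_sd < 0:
            raise ConfigError("baseline_log2_sd: must be >= 0")
        for g, _c, _e in self.subgroup_shift_genes:
            if not 0 <= g < self.n_genes:
                raise ConfigError(f"subgroup_shift_genes: gene index {g} out of range")
        for g, _t, _s, sd in self.taxon_linked_genes:
            if not 0 <= g < self.n_genes:
                raise ConfigError(f"taxon_linked_genes: gene index {g} out of range")
            if sd < 0:
                raise ConfigError("taxon_linked_genes: noise sd must be >= 0")


def default_expression_config(n_genes: int = 200, seed: int = 0,
                              shift_component: int = 0,
                              n_shift_genes: int = 50,
                              log2_effect: float = 2.0) -> ExpressionConfig:
    """Planted structure for the end-to-end demo: a block of genes
    up-shifted in one component plus two taxon-linked genes."""
    shifts = [(g, shift_component, log2_effect) for g in range(n_shift_genes)]
    links = [(n_shift_genes, 0, 1.0, 0.5), (n_shift_genes + 1, 4, 1.0, 0.5)]
    return ExpressionConfig(n_genes=n_genes, subgroup_shift_genes=shifts,
                            taxon_linked_genes=links, seed=seed)


def generate_expression(
    abundance: AbundanceTable,
    labels,
    config: ExpressionConfig,
) -> ExpressionMatrix:
    """Genes x samples TPM matrix with the configured planted structure.

    Taxon-linked genes depend monotonically on the taxon's relative
    abundance (noise sd 0 gives a noiseless monotone map, Spearman rho 1);
    shift genes differ between components by the configured log2 effect in
    expectation.  Deterministic under a fixed seed.
    """
    labels = np.asarray(labels, dtype=int)
    if abundance.n_samples != len(labels):
        raise ConfigError("labels: length must match abundance sample count")
    for _g, t, _s, _sd in config.taxon_linked_genes:
        if not 0 <= t < len(abundance.taxa):
            raise ConfigError(f"taxon_linked_genes: taxon index {t} out of range")
    rng = np.random.default_rng(config.seed)
    n = len(labels)
    G = config.n_genes
    base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                      size=G)
    log2 = base[:, None] + rng.normal(0.0, 1.0, size=(G, n))
    for g, comp, effect in config.subgroup_shift_genes:
        log2[g, labels == comp] += effect
    rel = abundance.counts.to_numpy(dtype=float)
    rel = rel / np.maximum(rel.sum(axis=0), 1.0)
    for g, t, slope, sd in config.taxon_linked_genes:
        x = np.log(rel[t] + 1e-6)
        x = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
        log2[g] = (config.baseline_log2_mean + slope * x
                   + rng.normal(0.0, sd, size=n))
    tpm = np.power(2.0, log2)
    df = pd.DataFrame(tpm,
                      index=[f"gene_{g:03d}" for g in range(G)],
                      columns=abundance.samples)
    return ExpressionMatrix(values=df, transform="tpm")


@dataclass(frozen=True)
class PaperFixtures:
    """Printed study inputs for the fixture-level checks.

    ``exacerbation_events`` per subgroup (I, II, III) sum to the 29
    recorded events across the 21 followed COPD patients.
    ``biomass_median_pg_ml`` is ordered as printed — (subgroup I,
    subgroup III, subgroup II) — so its last entry is the low-biomass
    subgroup II.  The patient
    counts are DERIVED, not printed: the published per-subgroup
    frequencies {0.4, 2, 3.5} with 21 patients in total give
    (5/0.4, 10/2, 14/3.5) -> (12.5, 5, 4); 12 + 5 + 4 is the only integer
    split matching the total, and 5/12 = 0.417 rounds to the printed 0.4.
    """

    exacerbation_events: tuple = (5, 10, 14)
    exacerbation_patients: tuple = (12, 5, 4)
    biomass_median_pg_ml: tuple = (77.2, 25.6, 2.7)
    subgroup_sizes: tuple = (20, 10, 4)

    def frequencies(self) -> tuple:
        return tuple(e / p for e, p in zip(self.exacerbation_events,
                                           self.exacerbation_patients))

    def biomass_folds_vs_low(self) -> tuple[int, int]:
        """Fold changes of subgroup I and III biomass medians over the
        low-biomass subgroup II, truncated to integers as printed."""
        hi, mid, lo = self.biomass_median_pg_ml
        return int(hi / lo), int(mid / lo)


def paper_fixtures() -> PaperFixtures:
    """The printed worked-example inputs (see :class:`PaperFixtures`)."""
    return PaperFixtures()
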