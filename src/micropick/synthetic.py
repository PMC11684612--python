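"""Synthetic paired ASV/OTU cohorts with planted phenotype structure.

The generator emulates the inputs of a two-phase amplicon study: a
compositional count table over fine-grained features (ASV-like), a
coarser table formed by many-to-one merging of those features (OTU-like),
and a dichotomous phenotype.  The noise model is Dirichlet-multinomial:
a base mean composition on the simplex, per-class tilting of a chosen
set of affected features by exp(+/- effect_log_fold), per-sample
compositions drawn from a Dirichlet centred on the class mean, and
multinomial counts at a negative-binomial sequencing depth.

Defaults mirror a realistic infant-gut 16S cohort: 199 samples, 326
taxonomically collapsed features, ~20k reads per sample, and a minority
phenotype class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .feature_table import FeatureTable, PhenotypeMetadata

__all__ = ["SyntheticConfig", "SyntheticTruth", "simulate_cohort", "plant_diversity_gradient"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    concentration is the mean per-feature Dirichlet weight: per-sample
    compositions are drawn from Dirichlet(concentration * n_features *
    class_mean), so larger values give less between-sample variation.
    depth_dispersion is the negative-binomial size parameter (smaller =
    more depth variation).
    """

    n_samples: int = 199
    n_asv_features: int = 326
    n_otu_groups: int = 110
    class_fraction: float = 0.35
    n_affected_features: int = 20
    effect_log_fold: float = 1.0
    depth_mean: float = 20000.0
    depth_dispersion: float = 3.0
    concentration: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_asv_features < 2:
            raise ValueError("need at least 2 samples and 2 features")
        if not (0 < self.n_otu_groups <= self.n_asv_features):
            raise ValueError("n_otu_groups must be in [1, n_asv_features]")
        if not (0.0 < self.class_fraction < 1.0):
            raise ValueError("class_fraction must lie in (0, 1)")
        if not (0 <= self.n_affected_features <= self.n_asv_features):
            raise ValueError("n_affected_features out of range")
        if self.effect_log_fold < 0:
            raise ValueError("effect_log_fold must be >= 0")
        if min(self.depth_mean, self.depth_dispersion, self.concentration) <= 0:
            raise ValueError("depth_mean, depth_dispersion, concentration must be positive")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated cohort."""

    affected_features: dict[str, str]  # feature -> "over"/"under" in case class
    asv_to_otu: dict[str, str]
    class_labels: dict[str, str]
    base_composition: np.ndarray = field(repr=False, default=None)


def _nb_depths(rng, n: int, mean: float, dispersion: float) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return np.maximum(1, rng.negative_binomial(dispersion, p, size=n))


def _sample_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def simulate_cohort(config: SyntheticConfig):
    """Generate (asv_table, otu_table, phenotype, truth).

    The ASV table holds multinomial counts per sample; the OTU table sums
    ASV counts within randomly drawn many-to-one groups (all groups
    non-empty), so per-sample totals are conserved exactly.  Affected
    features are drawn from the more-abundant half of the base
    composition (a fold change on an effectively unobserved taxon would
    be undetectable by design) and split evenly between over- and
    under-represented in the case class.  Fixed seed => bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_asv_features
    n = config.n_samples

    # Base mean composition: uniform Dirichlet draw => realistic skew
    base = rng.dirichlet(np.ones(m))

    feature_ids = [f"ASV{j + 1:04d}" for j in range(m)]
    sample_ids = _sample_ids(n)

    # plant effects among the more-abundant half of features
    eligible = np.argsort(-base, kind="stable")[: max(config.n_affected_features, m // 2)]
    affected = rng.choice(eligible, size=config.n_affected_features, replace=False)
    signs = np.ones(len(affected))
    signs[1::2] = -1.0  # alternate over/under

    case_mean = base.copy()
    case_mean[affected] *= np.exp(signs * config.effect_log_fold)
    case_mean /= case_mean.sum()

    n_case = max(1, int(round(config.class_fraction * n)))
    labels = np.array(["case"] * n_case + ["control"] * (n - n_case))
    rng.shuffle(labels)

    alpha0 = config.concentration * m
    depths = _nb_depths(rng, n, config.depth_mean, config.depth_dispersion)
    counts = np.zeros((n, m), dtype=np.int64)
    for i in range(n):
        mean = case_mean if labels[i] == "case" else base
        comp = rng.dirichlet(alpha0 * mean)
        counts[i] = rng.multinomial(depths[i], comp)

    # many-to-one ASV -> OTU map with every group non-empty
    perm = rng.permutation(m)
    group = np.empty(m, dtype=np.int64)
    group[perm[: config.n_otu_groups]] = np.arange(config.n_otu_groups)
    group[perm[config.n_otu_groups:]] = rng.integers(
        0, config.n_otu_groups, size=m - config.n_otu_groups
    )
    otu_ids = [f"OTU{g + 1:04d}" for g in range(config.n_otu_groups)]
    otu_counts = np.zeros((n, config.n_otu_groups), dtype=np.int64)
    np.add.at(otu_counts.T, group, counts.T)

    asv = FeatureTable(tuple(sample_ids), tuple(feature_ids), counts.astype(float),
                       mode="counts")
    otu = FeatureTable(tuple(sample_ids), tuple(otu_ids), otu_counts.astype(float),
                       mode="counts")
    phenotype = PhenotypeMetadata(labels=dict(zip(sample_ids, labels)))
    truth = SyntheticTruth(
        affected_features={
            feature_ids[j]: ("over" if s > 0 else "under")
            for j, s in zip(affected, signs)
        },
        asv_to_otu={feature_ids[j]: otu_ids[group[j]] for j in range(m)},
        class_labels=dict(zip(sample_ids, labels)),
        base_composition=base,
    )
    return asv, otu, phenotype, truth


def plant_diversity_gradient(config: SyntheticConfig, low: float, high: float) -> FeatureTable:
    """Count table whose samples span a planted evenness gradient.

    Sample i's composition is drawn from a symmetric Dirichlet whose
    concentration is linearly interpolated between ``low`` and ``high``
    with sample index, so true evenness (and hence inverse Simpson
    diversity) increases stochastically with index.  Used to verify that
    diverse selection recovers the most even communities.
    """
    if not (0 < low <= high):
        raise ValueError("need 0 < low <= high (low = high gives a flat gradient)")
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_asv_features
    concentrations = np.linspace(low, high, n)
    depths = _nb_depths(rng, n, config.depth_mean, config.depth_dispersion)
    counts = np.zeros((n, m), dtype=np.int64)
    for i in range(n):
        comp = rng.dirichlet(np.full(m, concentrations[i]))
        counts[i] = rng.multinomial(depths[i], comp)
    return FeatureTable(tuple(_sample_ids(n)), tuple(f"F{j + 1:04d}" for j in range(m)),
                        counts.astype(float), mode="counts")
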