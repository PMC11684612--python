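"""Agreement between selections and differential-representation screening.

Agreement between two or more subsample selections (e.g. the same method
run on an ASV table and on an OTU table) is summarized as pairwise
overlap fractions and UpSet-style exclusive intersection counts.

Differential representation follows the two-class core of the LEfSe
procedure: a per-feature Kruskal-Wallis rank-sum screen at alpha = 0.05
(no multiple-testing correction, the LEfSe convention), then an LDA-based
effect size on a log10 scale for the screened features, averaged over
bootstrap rounds; features pass at effect >= 2.0 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import kruskal
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .feature_table import FeatureTable

__all__ = [
    "AgreementReport",
    "EffectSizeRecord",
    "pairwise_overlap",
    "upset_counts",
    "kruskal_wallis_screen",
    "lda_effect_size",
    "lefse",
    "records_frame",
    "write_effect_report",
]

#: LEfSe rescales relative abundances to parts-per-million before LDA so
#: that log10 effect sizes land on its conventional 0-6 scale.
LEFSE_SCALE = 1e6


@dataclass(frozen=True)
class AgreementReport:
    """Set sizes and exclusive intersections among named selections."""

    set_sizes: dict[str, int]
    intersections: dict[frozenset, int]
    overlap_fraction: float | None = None
    asymmetric: bool = False

    def union_size(self) -> int:
        return sum(self.intersections.values())

    def to_json_dict(self) -> dict:
        return {
            "set_sizes": dict(self.set_sizes),
            "intersections": {
                "&".join(sorted(labels)): count
                for labels, count in sorted(
                    self.intersections.items(), key=lambda kv: sorted(kv[0])
                )
            },
            "overlap_fraction": self.overlap_fraction,
            "asymmetric": self.asymmetric,
        }

    def upset_matrix(self) -> pd.DataFrame:
        """Membership-pattern table (one row per exclusive intersection)
        for external UpSet plotting."""
        labels = sorted(self.set_sizes)
        rows = []
        for subset, count in self.intersections.items():
            row = {lab: lab in subset for lab in labels}
            row["count"] = count
            rows.append(row)
        return pd.DataFrame(rows).sort_values("count", ascending=False, ignore_index=True)


@dataclass(frozen=True)
class EffectSizeRecord:
    """Per-feature Kruskal-Wallis p-value and LDA effect size."""

    feature_id: str
    kw_p: float
    direction: str  # over/under in the group of interest
    lda_effect: float | None = None
    significant: bool = False


def _exclusive_intersections(named_sets: dict[str, frozenset]) -> dict[frozenset, int]:
    membership: dict[str, frozenset] = {}
    pattern: dict[frozenset, int] = {}
    universe = set().union(*named_sets.values())
    for item in universe:
        key = frozenset(lab for lab, s in named_sets.items() if item in s)
        pattern[key] = pattern.get(key, 0) + 1
    return pattern


def pairwise_overlap(a, b, label_a: str = "a", label_b: str = "b") -> AgreementReport:
    """Agreement between two selections over one sample universe.

    overlap_fraction = |A ∩ B| / k when both have size k; with unequal
    sizes the denominator is max(kA, kB) and the report is flagged
    asymmetric.
    """
    sa, sb = frozenset(a.selected), frozenset(b.selected)
    named = {label_a: sa, label_b: sb}
    asymmetric = len(sa) != len(sb)
    denom = max(len(sa), len(sb))
    return AgreementReport(
        set_sizes={label_a: len(sa), label_b: len(sb)},
        intersections=_exclusive_intersections(named),
        overlap_fraction=len(sa & sb) / denom if denom else 0.0,
        asymmetric=asymmetric,
    )


def upset_counts(selections: dict) -> AgreementReport:
    """Exclusive (UpSet-style) intersection counts among >= 2 labelled
    selections; counts over all non-empty membership patterns partition
    the union."""
    if len(selections) < 2:
        raise ValueError("need at least 2 selections")
    named = {str(lab): frozenset(sel.selected) for lab, sel in selections.items()}
    report = AgreementReport(
        set_sizes={lab: len(s) for lab, s in named.items()},
        intersections=_exclusive_intersections(named),
    )
    return report


def _two_group_arrays(table: FeatureTable, groups: dict[str, str]):
    labels = np.array([groups[s] for s in table.sample_ids])
    names = sorted(set(labels))
    if len(names) != 2:
        raise ValueError(f"need exactly two groups, got {names}")
    masks = {g: labels == g for g in names}
    for g, m in masks.items():
        if m.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    return names, masks


def kruskal_wallis_screen(table: FeatureTable, groups: dict[str, str],
                          alpha: float = 0.05, group_of_interest: str | None = None,
                          correct: bool = False) -> list[EffectSizeRecord]:
    """Per-feature Kruskal-Wallis rank-sum test between two groups.

    Uses the tie-corrected chi-square approximation (1 df).  Features
    constant across all samples get p = 1.  ``direction`` is "over" when
    the group of interest (default: the lexicographically first group
    name) has the larger mean.  No multiple-testing correction by
    default (the LEfSe convention); ``correct=True`` applies
    Benjamini-Hochberg.
    """
    if table.mode != "relative":
        raise ValueError("screen expects a relative-frequency table")
    names, masks = _two_group_arrays(table, groups)
    goi = group_of_interest if group_of_interest is not None else names[0]
    if goi not in names:
        raise ValueError(f"group_of_interest {goi!r} not among {names}")
    other = names[1] if goi == names[0] else names[0]
    pvals = np.empty(table.n_features)
    directions = []
    for j in range(table.n_features):
        col = table.values[:, j]
        x, y = col[masks[goi]], col[masks[other]]
        if np.ptp(col) == 0:
            pvals[j] = 1.0
        else:
            pvals[j] = kruskal(x, y).pvalue
        directions.append("over" if x.mean() >= y.mean() else "under")
    padj = pvals
    if correct:
        from statsmodels.stats.multitest import multipletests

        padj = multipletests(pvals, method="fdr_bh")[1]
    return [
        EffectSizeRecord(
            feature_id=table.feature_ids[j],
            kw_p=float(padj[j]),
            direction=directions[j],
            significant=bool(padj[j] < alpha),
        )
        for j in range(table.n_features)
    ]


def _lda_round(x: np.ndarray, y01: np.ndarray) -> np.ndarray:
    """One LEfSe-style LDA effect estimate per feature (pre-log scale).

    Fits a one-dimensional LDA; the feature effect combines the raw class
    mean difference with the feature's share of the class separation
    along the discriminant axis:
        effect_f = (|mu1_f - mu0_f| + |w_f| * |m1 - m0|) / 2
    where w is the unit discriminant vector and m_c the projected class
    means.
    """
    lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=None, tol=1e-10)
    try:
        lda.fit(x, y01)
        w = lda.scalings_[:, 0]
    except np.linalg.LinAlgError:
        w = np.zeros(x.shape[1])
    nw = np.linalg.norm(w)
    w = w / nw if nw > 0 else w
    mu0 = x[y01 == 0].mean(axis=0)
    mu1 = x[y01 == 1].mean(axis=0)
    sep = abs(float((mu1 - mu0) @ w))
    return (np.abs(mu1 - mu0) + np.abs(w) * sep) / 2.0


def lda_effect_size(table: FeatureTable, groups: dict[str, str], screened,
                    n_boot: int = 30, seed: int = 0, threshold: float = 2.0,
                    subsample_fraction: float = 2 / 3,
                    group_of_interest: str | None = None) -> list[EffectSizeRecord]:
    """LDA effect size (log10 scale) for screened features.

    For each bootstrap round a fraction of samples is drawn (redrawn, up
    to 100 retries, if a class drops below 2 samples), abundances are
    rescaled to parts-per-million, a one-dimensional LDA is fitted, and a
    per-feature effect is computed; the log10(1 + effect) values are
    averaged over rounds.  A feature is significant at
    ``lda_effect >= threshold`` (default 2.0).
    """
    screened = list(screened)
    if not screened:
        raise ValueError("no screened features supplied")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    names, masks = _two_group_arrays(table, groups)
    goi = group_of_interest if group_of_interest is not None else names[0]
    other = names[1] if goi == names[0] else names[0]
    cols = [table.feature_ids.index(f) for f in screened]
    x_all = table.values[:, cols] * LEFSE_SCALE
    y01 = masks[goi].astype(int)  # 1 = group of interest
    rng = np.random.default_rng(seed)
    n = table.n_samples
    m = max(4, int(round(subsample_fraction * n)))
    effects = np.zeros((n_boot, len(cols)))
    for b in range(n_boot):
        for _try in range(100):
            idx = rng.choice(n, size=min(m, n), replace=False)
            if y01[idx].sum() >= 2 and (1 - y01[idx]).sum() >= 2:
                break
        else:
            raise RuntimeError("could not draw a bootstrap round containing both classes")
        effects[b] = _lda_round(x_all[idx], y01[idx])
    scores = np.log10(1.0 + effects).mean(axis=0)
    mu_goi = x_all[y01 == 1].mean(axis=0)
    mu_oth = x_all[y01 == 0].mean(axis=0)
    return [
        EffectSizeRecord(
            feature_id=screened[j],
            kw_p=float("nan"),
            direction="over" if mu_goi[j] >= mu_oth[j] else "under",
            lda_effect=float(scores[j]),
            significant=bool(scores[j] >= threshold),
        )
        for j in range(len(cols))
    ]


def lefse(table: FeatureTable, groups: dict[str, str], alpha: float = 0.05,
          threshold: float = 2.0, n_boot: int = 30, seed: int = 0,
          group_of_interest: str | None = None) -> list[EffectSizeRecord]:
    """Full two-class screen: Kruskal-Wallis at ``alpha`` then LDA effect
    size for the surviving features.  Features failing the screen are
    reported with their p-value and no effect size."""
    kw = kruskal_wallis_screen(table, groups, alpha=alpha,
                               group_of_interest=group_of_interest)
    survivors = [r.feature_id for r in kw if r.significant]
    if not survivors:
        return [
            EffectSizeRecord(r.feature_id, r.kw_p, r.direction, None, False)
            for r in kw
        ]
    lda = {
        r.feature_id: r
        for r in lda_effect_size(table, groups, survivors, n_boot=n_boot,
                                 seed=seed, threshold=threshold,
                                 group_of_interest=group_of_interest)
    }
    out = []
    for r in kw:
        if r.feature_id in lda:
            lr = lda[r.feature_id]
            out.append(EffectSizeRecord(r.feature_id, r.kw_p, lr.direction,
                                        lr.lda_effect, lr.significant))
        else:
            out.append(EffectSizeRecord(r.feature_id, r.kw_p, r.direction, None, False))
    return out


def records_frame(records) -> pd.DataFrame:
    """EffectSizeRecords as a DataFrame (column order mirrors LEfSe's
    res-file layout)."""
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "direction": r.direction,
                "kw_p": r.kw_p,
                "lda_effect": r.lda_effect,
                "significant": r.significant,
            }
            for r in records
        ]
    )


def write_effect_report(records, path) -> None:
    records_frame(records).to_csv(path, sep="\t", index=False)
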