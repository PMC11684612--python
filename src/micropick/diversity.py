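"""Alpha- and beta-diversity metrics.

Beta diversity between samples i and j is the Bray-Curtis dissimilarity

    BC_ij = 1 - 2 C_ij / (S_i + S_j)

where C_ij = sum_f min(x_if, x_jf) is the shared abundance and S_i, S_j are
the sample totals.  Alpha diversity uses the Simpson family: the
concentration lambda = sum_f p_f^2, its Gini-Simpson complement
D = 1 - lambda (finite-sample form D = 1 - sum k(k-1) / (K(K-1)) on
counts), the inverse form 1/lambda, and the Shannon entropy
H = -sum p ln p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_table import FeatureTable

__all__ = [
    "DistanceMatrix",
    "DiversityProfile",
    "bray_curtis",
    "dissimilarity_matrix",
    "simpson_profile",
    "shannon",
    "diversity_frame",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities over named samples."""

    sample_ids: tuple[str, ...]
    d: np.ndarray
    metric: str = "braycurtis"

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} does not match {n} samples")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")

    def __getitem__(self, pair) -> float:
        i, j = pair
        if isinstance(i, str):
            i = self.sample_ids.index(i)
        if isinstance(j, str):
            j = self.sample_ids.index(j)
        return float(self.d[i, j])

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def write_tsv(self, path) -> None:
        """Square TSV with sample IDs as header row and column (lsmat style)."""
        pd.DataFrame(
            self.d, index=list(self.sample_ids), columns=list(self.sample_ids)
        ).to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, metric: str = "braycurtis") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("row and column sample IDs differ")
        return cls(sample_ids=tuple(str(s) for s in df.index),
                   d=df.to_numpy(dtype=float), metric=metric)


@dataclass(frozen=True)
class DiversityProfile:
    """Simpson-family alpha diversity of one sample.

    ``simpson_lambda`` is the probability two organisms drawn from the
    sample are the same species (Sigma p^2, or its unbiased finite-sample
    analogue on counts); ``gini_simpson`` its complement D; shannon uses
    natural log.
    """

    sample_id: str
    simpson_lambda: float
    gini_simpson: float
    inverse_simpson: float
    shannon: float


def _check_vector(x, name: str = "vector") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.any(x < 0):
        raise ValueError(f"{name} has negative entries")
    if x.sum() <= 0:
        raise ValueError(f"{name} is all zeros")
    return x


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity between two abundance vectors, in [0, 1]."""
    x = _check_vector(x, "x")
    y = _check_vector(y, "y")
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    c = np.minimum(x, y).sum()
    return float(1.0 - 2.0 * c / (x.sum() + y.sum()))


def dissimilarity_matrix(table: FeatureTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis over all samples of a table."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    v = table.values
    totals = v.sum(axis=1)
    zero = np.argwhere(totals <= 0)
    if zero.size:
        raise ValueError(f"sample {table.sample_ids[int(zero[0, 0])]!r} is all zeros")
    n = table.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        # vectorized over j > i: C_ij = sum min(x_i, x_j)
        c = np.minimum(v[i + 1:], v[i]).sum(axis=1)
        d[i, i + 1:] = 1.0 - 2.0 * c / (totals[i + 1:] + totals[i])
    d = d + d.T
    return DistanceMatrix(sample_ids=table.sample_ids, d=d, metric="braycurtis")


def simpson_profile(x, mode: str = "relative", sample_id: str = "") -> DiversityProfile:
    """Simpson-family diversity of one abundance vector.

    counts mode uses the finite-sample Gini-Simpson
    D = 1 - Sigma k(k-1) / (K(K-1)) (requires integer counts, K >= 2);
    relative mode uses lambda = Sigma p^2, D = 1 - lambda.  The reported
    ``simpson_lambda`` is 1 - D in either mode, so the profile fields are
    mutually consistent.
    """
    x = _check_vector(x)
    if mode == "counts":
        if np.any(np.abs(x - np.round(x)) > 1e-9):
            raise ValueError("counts mode requires integer-valued abundances")
        k = np.round(x)
        K = k.sum()
        if K < 2:
            raise ValueError("counts mode needs at least 2 organisms (K >= 2)")
        lam = float((k * (k - 1)).sum() / (K * (K - 1)))
        p = k / K
    elif mode == "relative":
        p = x / x.sum()
        lam = float((p**2).sum())
    else:
        raise ValueError(f"mode must be 'counts' or 'relative', got {mode!r}")
    lam = max(lam, 0.0)
    h = shannon(p)
    return DiversityProfile(
        sample_id=sample_id,
        simpson_lambda=lam,
        gini_simpson=1.0 - lam,
        inverse_simpson=float("inf") if lam == 0.0 else 1.0 / lam,
        shannon=h,
    )


def shannon(x, base: float | None = None) -> float:
    """Shannon entropy -Sigma p ln p of the vector's proportions.

    Natural log by default; 0 ln 0 := 0.
    """
    x = _check_vector(x)
    p = x / x.sum()
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def diversity_frame(table: FeatureTable, mode: str | None = None) -> pd.DataFrame:
    """Per-sample alpha-diversity summary as a DataFrame.

    Columns: simpson_lambda, gini_simpson, inverse_simpson, shannon.
    ``mode`` defaults to the table's own mode.
    """
    mode = mode or table.mode
    rows = []
    for i, s in enumerate(table.sample_ids):
        prof = simpson_profile(table.values[i], mode=mode, sample_id=s)
        rows.append(
            {
                "sample_id": s,
                "simpson_lambda": prof.simpson_lambda,
                "gini_simpson": prof.gini_simpson,
                "inverse_simpson": prof.inverse_simpson,
                "shannon": prof.shannon,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
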