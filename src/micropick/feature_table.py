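"""Abundance feature tables and phenotype metadata.

The entry point of a two-phase study is a samples x features abundance
table (ASV or OTU counts, or relative frequencies) plus a dichotomous
per-sample phenotype.  This module holds the table container, readers and
writers for the common on-disk dialects, relative-frequency normalization,
and taxonomic collapse.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "PhenotypeMetadata",
    "load_table",
    "write_table",
    "load_metadata",
    "to_relative_frequency",
    "collapse_taxonomy",
    "impute_phenotype",
]

#: row sums within this tolerance of 1 are treated as relative frequencies
RELATIVE_SUM_TOL = 1e-6

_RANK_PREFIX = re.compile(r"^[a-zA-Z]__")


@dataclass(frozen=True)
class FeatureTable:
    """Samples x features abundance matrix.

    Parameters
    ----------
    sample_ids, feature_ids
        Unique, ordered identifiers for rows and columns of ``values``.
    values
        Non-negative float matrix of shape ``(n_samples, n_features)``.
    mode
        ``"counts"`` or ``"relative"``; in relative mode every row sums
        to 1 (within 1e-9).
    taxonomy
        Optional mapping feature_id -> semicolon-delimited taxonomy string.
    """

    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    values: np.ndarray
    mode: str = "counts"
    taxonomy: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        n, m = values.shape
        if n == 0 or m == 0:
            raise ValueError("empty table: need at least one sample and one feature")
        if n != len(self.sample_ids) or m != len(self.feature_ids):
            raise ValueError(
                f"shape {values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        for name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {name} ID: {dup!r}")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value {values[i, j]} at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"mode must be 'counts' or 'relative', got {self.mode!r}")
        if self.mode == "relative":
            sums = values.sum(axis=1)
            bad = np.argwhere(np.abs(sums - 1.0) > 1e-9)
            if bad.size:
                i = int(bad[0, 0])
                raise ValueError(
                    f"relative-mode row for sample {self.sample_ids[i]!r} "
                    f"sums to {sums[i]!r}, not 1"
                )
        if self.taxonomy is not None:
            object.__setattr__(self, "taxonomy", dict(self.taxonomy))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample ID {sample_id!r}") from None

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_index(sample_id)]

    def to_dataframe(self) -> pd.DataFrame:
        """Samples-as-rows DataFrame view (copy)."""
        return pd.DataFrame(
            self.values.copy(), index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    def select_samples(self, sample_ids: list[str]) -> "FeatureTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return replace(self, sample_ids=tuple(sample_ids), values=self.values[idx])


@dataclass(frozen=True)
class PhenotypeMetadata:
    """Dichotomous sample -> class labels with an imputation record."""

    labels: dict[str, str]
    imputed: frozenset[str] = frozenset()
    classes: tuple[str, str] = ("case", "control")

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", dict(self.labels))
        object.__setattr__(self, "imputed", frozenset(self.imputed))
        bad = {s: c for s, c in self.labels.items() if c not in self.classes}
        if bad:
            s, c = next(iter(bad.items()))
            raise ValueError(
                f"label {c!r} for sample {s!r} is outside the class alphabet {self.classes}"
            )

    def members(self, cls: str) -> list[str]:
        return [s for s, c in self.labels.items() if c == cls]

    def label_array(self, sample_ids) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.labels]
        if missing:
            raise KeyError(f"samples without phenotype label: {missing}")
        return np.array([self.labels[s] for s in sample_ids])


def _first_duplicate(ids):
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def _infer_mode(values: np.ndarray) -> str:
    sums = values.sum(axis=1)
    return "relative" if np.all(np.abs(sums - 1.0) <= RELATIVE_SUM_TOL) else "counts"


def load_table(path, format: str = "tsv", orientation: str = "features-as-rows") -> FeatureTable:
    """Read a feature table from disk.

    Parameters
    ----------
    path
        TSV or BIOM 1.0 JSON file.
    format
        ``"tsv"`` or ``"biom-json"``.
    orientation
        For TSV only: ``"features-as-rows"`` (the QIIME/BIOM convention,
        default) or ``"samples-as-rows"``.  BIOM files carry their own
        orientation.

    Mode is inferred: relative iff every sample row sums to 1 within
    ``RELATIVE_SUM_TOL``, else counts.
    """
    if format == "tsv":
        return _load_tsv(path, orientation)
    if format == "biom-json":
        return _load_biom_json(path)
    raise ValueError(f"unknown format {format!r}")


def _load_tsv(path, orientation: str) -> FeatureTable:
    # pandas silently renames duplicate header cells; check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup = _first_duplicate(header)
    if dup is not None:
        kind = "sample" if orientation == "features-as-rows" else "feature"
        raise ValueError(f"duplicate {kind} ID in header: {dup!r}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, comment=None, dtype=str)
    if df.empty:
        raise ValueError(f"empty table in {path}")
    taxonomy = None
    if orientation == "features-as-rows":
        if "Taxonomy" in df.columns:
            taxonomy = {str(f): str(t) for f, t in df["Taxonomy"].items()}
            df = df.drop(columns=["Taxonomy"])
        values = df.to_numpy(dtype=float).T
        sample_ids, feature_ids = list(df.columns), list(df.index)
    elif orientation == "samples-as-rows":
        values = df.to_numpy(dtype=float)
        sample_ids, feature_ids = list(df.index), list(df.columns)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return FeatureTable(
        sample_ids=tuple(sample_ids),
        feature_ids=tuple(feature_ids),
        values=values,
        mode=_infer_mode(values),
        taxonomy=taxonomy,
    )


def _load_biom_json(path) -> FeatureTable:
    # BIOM format 1.0: JSON with rows = observations (features), columns = samples.
    with open(path) as fh:
        doc = json.load(fh)
    feature_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    n_feat, n_samp = doc["shape"]
    if n_feat != len(feature_ids) or n_samp != len(sample_ids):
        raise ValueError("BIOM shape field disagrees with rows/columns")
    dense = np.zeros((n_samp, n_feat), dtype=float)
    if doc.get("matrix_type") == "dense":
        dense[:] = np.asarray(doc["data"], dtype=float).T
    else:  # sparse: [row, col, value] triplets
        for r, c, v in doc["data"]:
            dense[int(c), int(r)] = float(v)
    taxonomy = None
    if doc["rows"] and isinstance(doc["rows"][0].get("metadata"), dict):
        tax = {}
        for r in doc["rows"]:
            t = (r.get("metadata") or {}).get("taxonomy")
            if t is not None:
                tax[r["id"]] = ";".join(t) if isinstance(t, list) else str(t)
        taxonomy = tax or None
    return FeatureTable(
        sample_ids=tuple(sample_ids),
        feature_ids=tuple(feature_ids),
        values=dense,
        mode=_infer_mode(dense),
        taxonomy=taxonomy,
    )


def write_table(table: FeatureTable, path, precision: int = 6) -> None:
    """Write a features-as-rows TSV (first cell ``#FeatureID``, optional
    final ``Taxonomy`` column)."""
    df = pd.DataFrame(
        table.values.T, index=list(table.feature_ids), columns=list(table.sample_ids)
    )
    df.index.name = "#FeatureID"
    out = df.map(lambda v: format(v, f".{precision}g"))
    if table.taxonomy is not None:
        out["Taxonomy"] = [table.taxonomy.get(f, "") for f in table.feature_ids]
    out.to_csv(path, sep="\t")


def load_metadata(path) -> dict[str, str | None]:
    """Read a two-column metadata TSV (sample_id, phenotype); empty or NA
    cells become ``None`` (missing)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols or "phenotype" not in cols:
        raise ValueError("metadata TSV needs columns 'sample_id' and 'phenotype'")
    out: dict[str, str | None] = {}
    for _, row in df.iterrows():
        v = row[cols["phenotype"]]
        missing = pd.isna(v) or str(v).strip() in ("", "NA", "na", "NaN")
        out[str(row[cols["sample_id"]])] = None if missing else str(v).strip()
    return out


def to_relative_frequency(table: FeatureTable) -> FeatureTable:
    """Divide each count by its sample's total so rows sum to 1.

    Idempotent: a relative-mode table is returned unchanged.
    """
    if table.mode == "relative":
        return table
    totals = table.values.sum(axis=1)
    zero = np.argwhere(totals <= 0)
    if zero.size:
        raise ValueError(
            f"sample {table.sample_ids[int(zero[0, 0])]!r} has zero total count"
        )
    return replace(table, values=table.values / totals[:, None], mode="relative")


def _taxonomy_prefix(taxonomy: str, rank: int) -> str:
    parts = [p.strip() for p in taxonomy.split(";")]
    parts = [_RANK_PREFIX.sub("", p) for p in parts]
    return ";".join(parts[:rank])


def collapse_taxonomy(table: FeatureTable, rank: int) -> FeatureTable:
    """Sum features sharing an identical taxonomy prefix truncated at
    ``rank`` levels into one feature named by that prefix.

    Per-sample totals are conserved exactly.  Rank prefixes like ``g__``
    are stripped before comparison so Silva and Greengenes strings
    collapse identically.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if table.taxonomy is None:
        raise ValueError("table has no taxonomy")
    missing = [f for f in table.feature_ids if f not in table.taxonomy]
    if missing:
        raise ValueError(f"features without taxonomy: {missing}")
    groups: dict[str, list[int]] = {}
    for j, f in enumerate(table.feature_ids):
        groups.setdefault(_taxonomy_prefix(table.taxonomy[f], rank), []).append(j)
    names = list(groups)  # dict preserves first-appearance order
    collapsed = np.column_stack(
        [table.values[:, groups[name]].sum(axis=1) for name in names]
    )
    return FeatureTable(
        sample_ids=table.sample_ids,
        feature_ids=tuple(names),
        values=collapsed,
        mode=table.mode,
        taxonomy={name: name for name in names},
    )


def impute_phenotype(
    raw_labels: dict[str, str | None],
    reference_class: str = "control",
    classes: tuple[str, str] = ("case", "control"),
) -> PhenotypeMetadata:
    """Fill missing labels with ``reference_class``.

    The study convention: subjects with no phenotype record are assumed to
    belong to the reference class (e.g. "no known allergy").  The
    ``imputed`` set records which samples were filled.
    """
    if reference_class not in classes:
        raise ValueError(f"reference class {reference_class!r} not in {classes}")
    labels: dict[str, str] = {}
    imputed = set()
    for s, c in raw_labels.items():
        if c is None:
            labels[s] = reference_class
            imputed.add(s)
        elif c in classes:
            labels[s] = c
        else:
            raise ValueError(f"label {c!r} for sample {s!r} not in class alphabet {classes}")
    return PhenotypeMetadata(labels=labels, imputed=frozenset(imputed), classes=classes)
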