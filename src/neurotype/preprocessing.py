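"""Feature-table pipeline: load -> merge lines -> drop incomplete -> split -> normalize.

The table convention is a pandas DataFrame with the meta columns
``sample_id``, ``organism``, ``broad_label``, ``line_tag``,
``subclass_label`` and one numeric column per electrophysiological feature.
Normalization is a per-feature z-score whose statistics are fit on the
training partition only and reused for validation and test, so no
information leaks across the split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import META_COLUMNS, broad_label_of

logger = logging.getLogger(__name__)

EXCLUDE = "exclude"


class SchemaError(ValueError):
    pass


class PipelineError(RuntimeError):
    pass


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


@dataclass
class DataSplit:
    """Disjoint, exhaustive train/validation/test partitions of one table.

    After :func:`normalize`, ``mean`` and ``sd`` hold the per-feature
    statistics computed from the training partition.
    """

    train: pd.DataFrame
    validation: pd.DataFrame
    test: pd.DataFrame
    mean: pd.Series | None = None
    sd: pd.Series | None = None
    seed: int | None = None
    source_domain: str = "mouse"

    @property
    def n_source(self) -> int:
        """Number of source-domain rows across all partitions (n)."""
        return int(
            sum((p["organism"] == self.source_domain).sum() for p in self.partitions())
        )

    @property
    def n_total(self) -> int:
        """Total rows across partitions (N)."""
        return sum(len(p) for p in self.partitions())

    def partitions(self):
        return (self.train, self.validation, self.test)

    @property
    def is_normalized(self) -> bool:
        return self.mean is not None


def load_feature_table(
    path, schema: list[str] | None = None, infer_schema: bool = True
) -> pd.DataFrame:
    """Read a CSV feature table; empty or unparseable cells become NaN.

    ``schema`` lists the required feature columns; with ``infer_schema`` every
    non-meta column is treated as a feature.  Missing required columns raise
    :class:`SchemaError` listing them.
    """
    table = pd.read_csv(path)
    if table.empty:
        raise SchemaError(f"{path}: empty feature table")
    if schema is not None:
        missing = [c for c in schema if c not in table.columns]
        if missing:
            raise SchemaError(f"{path}: missing required columns {missing}")
        feats = list(schema)
    elif infer_schema:
        feats = feature_columns(table)
        if not feats:
            raise SchemaError(f"{path}: no feature columns found")
    else:
        raise SchemaError("either a schema or infer_schema=True is required")
    for c in feats:
        table[c] = pd.to_numeric(table[c], errors="coerce")
    n_missing = int(table[feats].isna().sum().sum())
    logger.info("loaded %s: %d rows, %d features, %d missing cells",
                path, len(table), len(feats), n_missing)
    return table


def merge_lines(table: pd.DataFrame, line_map: dict) -> pd.DataFrame:
    """Assign each row's subclass from its transgenic-line tag.

    ``line_map`` maps line tag -> subclass name or ``"exclude"``.  Any tag
    present in the table but absent from the map is an error (no silent
    drops); excluded rows are removed and their count logged.
    """
    tags = table["line_tag"].astype(str)
    unmapped = sorted(set(tags) - set(line_map))
    if unmapped:
        raise SchemaError(f"line tags with no merge-map entry: {unmapped}")
    mapped = tags.map(line_map)
    keep = mapped != EXCLUDE
    n_excluded = int((~keep).sum())
    out = table.loc[keep].copy()
    out["subclass_label"] = mapped[keep].to_numpy()
    out["broad_label"] = [broad_label_of(c) for c in out["subclass_label"]]
    logger.info("merge_lines: %d rows excluded, %d retained", n_excluded, len(out))
    return out


def drop_incomplete(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove rows with any missing feature value; returns (table, n_dropped)."""
    feats = feature_columns(table)
    keep = ~table[feats].isna().any(axis=1)
    n_dropped = int((~keep).sum())
    out = table.loc[keep].copy()
    if out.empty:
        raise PipelineError("all rows contained missing values; nothing to process")
    logger.info("drop_incomplete: dropped %d of %d rows", n_dropped, len(table))
    return out, n_dropped


def _largest_remainder(n: int, fractions) -> list[int]:
    raw = [n * f for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    short = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])  # largest remainder first
    for k in order[:short]:
        base[k] += 1
    return base


def split(
    table: pd.DataFrame,
    fractions=(0.6797, 0.1201, 0.2002),
    stratify_on=("organism", "broad_label"),
    seed: int = 0,
) -> DataSplit:
    """Stratified train/validation/test split with largest-remainder rounding.

    Within every stratum (the cross of ``stratify_on`` columns) rows are
    shuffled with the seed and allotted so per-stratum proportions are
    preserved to within one row.  Strata smaller than the number of
    partitions are assigned best-effort with a warning.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f < 0 for f in fractions) or not np.isclose(sum(fractions), 1.0, atol=1e-6):
        raise ValueError(f"fractions must be non-negative and sum to 1, got {fractions}")
    allowed = {"organism", "broad_label", "subclass_label"}
    if not set(stratify_on) <= allowed:
        raise ValueError(f"stratify_on must be a subset of {sorted(allowed)}")

    rng = np.random.default_rng(seed)
    parts = {0: [], 1: [], 2: []}
    if stratify_on:
        codes = table[list(stratify_on)].astype(str).agg("|".join, axis=1).to_numpy()
        group_positions = [np.flatnonzero(codes == s) for s in sorted(set(codes))]
    else:
        group_positions = [np.arange(len(table))]
    n_parts = sum(1 for f in fractions if f > 0)
    for pos in group_positions:
        if len(pos) < n_parts:
            warnings.warn(
                f"stratum with {len(pos)} rows is smaller than the number of "
                "partitions; best-effort assignment", stacklevel=2,
            )
        shuffled = rng.permutation(pos)
        sizes = _largest_remainder(len(pos), fractions)
        a, b = sizes[0], sizes[0] + sizes[1]
        parts[0].append(shuffled[:a])
        parts[1].append(shuffled[a:b])
        parts[2].append(shuffled[b:])
    out = []
    for k in range(3):
        idx = np.sort(np.concatenate(parts[k])) if parts[k] else np.array([], dtype=int)
        out.append(table.iloc[idx].copy())
    logger.info("split sizes: train=%d validation=%d test=%d",
                len(out[0]), len(out[1]), len(out[2]))
    return DataSplit(train=out[0], validation=out[1], test=out[2], seed=seed)


def normalize(data: DataSplit, per_domain: bool = False) -> DataSplit:
    """z-score all partitions with statistics fit on the training partition.

    Zero-variance features pass through unscaled with a warning.  With
    ``per_domain`` the statistics are fit separately per organism (the
    default pools both organisms, since the joint classifier consumes both
    domains through one input layer).
    """
    if data.train.empty:
        raise PipelineError("cannot normalize a split with an empty train partition")
    feats = feature_columns(data.train)
    if data.train[feats].isna().any().any():
        raise PipelineError("normalize requires complete rows; run drop_incomplete first")

    def _fit(df):
        mean = df[feats].mean()
        sd = df[feats].std(ddof=0)
        zero = sd == 0
        if zero.any():
            warnings.warn(
                f"zero-variance features pass through unscaled: {list(sd.index[zero])}",
                stacklevel=2,
            )
            sd = sd.mask(zero, 1.0)
            mean = mean.mask(zero, 0.0)
        return mean, sd

    if not per_domain:
        mean, sd = _fit(data.train)
        def _apply(df):
            out = df.copy()
            out[feats] = (df[feats] - mean) / sd
            return out
        train, val, test = (_apply(p) for p in data.partitions())
        return DataSplit(train, val, test, mean=mean, sd=sd, seed=data.seed,
                         source_domain=data.source_domain)

    stats = {
        dom: _fit(data.train[data.train["organism"] == dom])
        for dom in data.train["organism"].unique()
    }
    def _apply_dom(df):
        out = df.copy()
        for dom, (mean, sd) in stats.items():
            sel = out["organism"] == dom
            out.loc[sel, feats] = ((df.loc[sel, feats] - mean) / sd).to_numpy()
        return out
    train, val, test = (_apply_dom(p) for p in data.partitions())
    mean, sd = _fit(data.train)  # pooled stats kept for reference
    return DataSplit(train, val, test, mean=mean, sd=sd, seed=data.seed,
                     source_domain=data.source_domain)


def run_preprocessing(
    table: pd.DataFrame,
    line_map: dict | None = None,
    fractions=(0.6797, 0.1201, 0.2002),
    stratify_on=("organism", "broad_label"),
    seed: int = 0,
    per_domain_normalize: bool = False,
) -> tuple[DataSplit, dict]:
    """The full pipeline in its fixed order; returns (split, accounting).

    The accounting dict satisfies
    ``rows_in == rows_out + excluded_by_merge + n_dropped``.
    """
    rows_in = len(table)
    if line_map is not None:
        merged = merge_lines(table, line_map)
    else:
        merged = table
    excluded = rows_in - len(merged)
    complete, n_dropped = drop_incomplete(merged)
    parts = split(complete, fractions=fractions, stratify_on=stratify_on, seed=seed)
    data = normalize(parts, per_domain=per_domain_normalize)
    accounting = {
        "rows_in": rows_in,
        "excluded_by_merge": excluded,
        "n_dropped": n_dropped,
        "rows_out": data.n_total,
    }
    assert accounting["rows_in"] == (
        accounting["rows_out"] + accounting["excluded_by_merge"] + accounting["n_dropped"]
    )
    return data, accounting
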