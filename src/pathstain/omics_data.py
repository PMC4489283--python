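"""Typed omics matrices and sample-group summarization.

Input matrices are plain tab-delimited text: a header row (``GENE`` followed
by sample ids) and one row per gene, first column the HUGO symbol.  Each
declared biological data type maps onto one of four internal representations
which determine both the visualizations that apply and the rule used to
collapse a sample group to one value per gene:

==========================  ==================
data type                   internal repr
==========================  ==================
mrna_expression             continuous
microrna_expression         continuous
protein_expression          continuous
copynumber_discrete         discrete_ordered
copynumber_continuous       continuous
mutation                    discrete_unordered
gene_list                   set
==========================  ==================

Group summarization: continuous values are averaged by default (median, min
and max are selectable); mutation data uses "at least one member of the group
is mutated"; discrete ordered data takes the mode with ties broken toward the
value of largest magnitude; set data takes the union.  A gene whose members
are all missing stays missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .map_model import canonical_symbol

__all__ = [
    "DATA_TYPES",
    "INTERNAL_REPRS",
    "DataTable",
    "SampleAnnotation",
    "SampleGroup",
    "DataParseError",
    "internal_repr_of",
    "parse_data_table",
    "parse_annotation",
    "build_groups",
    "summarize_group",
    "summarize_table",
    "is_missing_token",
    "is_mutated_label",
]

#: Biological data type -> internal representation.
DATA_TYPES: dict[str, str] = {
    "mrna_expression": "continuous",
    "microrna_expression": "continuous",
    "protein_expression": "continuous",
    "copynumber_discrete": "discrete_ordered",
    "copynumber_continuous": "continuous",
    "mutation": "discrete_unordered",
    "gene_list": "set",
}

INTERNAL_REPRS = ("continuous", "discrete_ordered", "discrete_unordered", "set")

#: Cell contents treated as missing (matched case-insensitively).
MISSING_TOKENS = frozenset({"", "na", "nan", "n/a"})

#: Mutation cell contents treated as "not mutated" (besides missing).
WILDTYPE_TOKENS = frozenset({"wt", "0"})

#: Sentinel stored in non-continuous tables for a missing cell.
MISSING = None


class DataParseError(ValueError):
    pass


def is_missing_token(cell: str) -> bool:
    return cell.strip().lower() in MISSING_TOKENS


def is_mutated_label(cell: str) -> bool:
    """Any non-missing, non-wild-type label counts as a mutation call."""
    c = cell.strip().lower()
    return c not in MISSING_TOKENS and c not in WILDTYPE_TOKENS


def internal_repr_of(data_type: str) -> str:
    try:
        return DATA_TYPES[data_type]
    except KeyError:
        raise DataParseError(
            f"unknown data type {data_type!r}; accepted types: {sorted(DATA_TYPES)}"
        ) from None


@dataclass
class DataTable:
    """A typed genes x samples matrix.

    ``values`` is a pandas DataFrame indexed by canonical gene symbol with one
    column per sample.  Continuous and discrete-ordered tables hold floats
    with NaN marking missing; discrete-unordered tables hold the original
    label strings with ``None`` marking missing; set tables hold booleans
    (membership) in a single implicit column.
    """

    name: str
    data_type: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.internal_repr = internal_repr_of(self.data_type)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SampleAnnotation:
    """Per-sample factor labels (first column sample id, rest factors)."""

    samples: list[str]
    factors: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, col in self.factors.items():
            if len(col) != len(self.samples):
                raise DataParseError(
                    f"factor {name!r} has {len(col)} values for {len(self.samples)} samples"
                )


@dataclass(frozen=True)
class SampleGroup:
    group_id: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise DataParseError(f"group {self.group_id!r} has no members")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _split_lines(text: str) -> list[list[str]]:
    rows = []
    for line in text.split("\n"):
        if line.endswith("\r"):
            line = line[:-1]
        if line == "":
            continue
        rows.append(line.split("\t"))
    return rows


def parse_data_table(
    text: str,
    data_type: str,
    name: str = "table",
    aggregate_duplicates: str | None = None,
) -> DataTable:
    """Parse a tab-delimited matrix (or gene-list file) into a DataTable.

    Duplicate gene rows are a hard error unless ``aggregate_duplicates="mean"``
    is passed (continuous tables only): silently averaging duplicates hides
    upstream mistakes.  Ragged rows and non-numeric cells in numeric tables
    are errors naming the line / (gene, sample).
    """
    repr_ = internal_repr_of(data_type)
    rows = _split_lines(text)
    if not rows:
        raise DataParseError("empty input")

    if repr_ == "set":
        return _parse_gene_list(rows, data_type, name)

    header = rows[0]
    samples = header[1:]
    if not samples:
        raise DataParseError("header row has no sample columns")
    ncol = len(header)

    genes: list[str] = []
    data: list[list] = []
    numeric = repr_ in ("continuous", "discrete_ordered")
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise DataParseError(
                f"line {lineno}: expected {ncol} tab-separated fields, got {len(row)}"
            )
        gene = canonical_symbol(row[0])
        if not gene:
            raise DataParseError(f"line {lineno}: empty gene symbol")
        parsed: list = []
        for sample, cell in zip(samples, row[1:]):
            if is_missing_token(cell):
                parsed.append(math.nan if numeric else MISSING)
                continue
            if numeric:
                try:
                    v = float(cell)
                except ValueError:
                    raise DataParseError(
                        f"non-numeric value {cell!r} at gene {gene!r}, sample {sample!r}"
                    ) from None
                if repr_ == "discrete_ordered" and not float(v).is_integer():
                    raise DataParseError(
                        f"non-integer value {cell!r} at gene {gene!r}, sample {sample!r} "
                        f"in a discrete ordered table"
                    )
                parsed.append(v)
            else:
                parsed.append(cell.strip())
        genes.append(gene)
        data.append(parsed)

    dup = pd.Index(genes)[pd.Index(genes).duplicated()]
    if len(dup):
        if aggregate_duplicates == "mean" and repr_ == "continuous":
            frame = pd.DataFrame(data, index=genes, columns=samples, dtype=float)
            frame = frame.groupby(level=0, sort=False).mean()
            return DataTable(name=name, data_type=data_type, values=frame)
        raise DataParseError(f"duplicate gene row {dup[0]!r}")

    if numeric:
        frame = pd.DataFrame(data, index=genes, columns=samples, dtype=float)
    else:
        frame = pd.DataFrame(data, index=genes, columns=samples, dtype=object)
    return DataTable(name=name, data_type=data_type, values=frame)


def _parse_gene_list(rows: list[list[str]], data_type: str, name: str) -> DataTable:
    # gene-list files: one symbol per line, optional "GENE" header
    genes: list[str] = []
    start = 1 if rows and canonical_symbol(rows[0][0]) == "GENE" else 0
    for lineno, row in enumerate(rows[start:], start=start + 1):
        sym = canonical_symbol(row[0])
        if not sym:
            continue
        if sym in genes:
            raise DataParseError(f"duplicate gene row {sym!r}")
        genes.append(sym)
    frame = pd.DataFrame({"member": [True] * len(genes)}, index=genes)
    return DataTable(name=name, data_type=data_type, values=frame)


def parse_annotation(text: str) -> SampleAnnotation:
    rows = _split_lines(text)
    if not rows:
        raise DataParseError("empty annotation")
    header = rows[0]
    factor_names = header[1:]
    samples: list[str] = []
    cols: dict[str, list[str]] = {f: [] for f in factor_names}
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise DataParseError(
                f"line {lineno}: expected {len(header)} fields, got {len(row)}"
            )
        samples.append(row[0].strip())
        for f, cell in zip(factor_names, row[1:]):
            cols[f].append("NA" if is_missing_token(cell) else cell.strip())
    return SampleAnnotation(samples=samples, factors=cols)


# ---------------------------------------------------------------------------
# Groups and summaries
# ---------------------------------------------------------------------------


def build_groups(annotation: SampleAnnotation, factor: str) -> list[SampleGroup]:
    """One group per distinct non-NA level of a factor, in first-seen order."""
    if factor not in annotation.factors:
        raise DataParseError(
            f"unknown factor {factor!r}; available: {sorted(annotation.factors)}"
        )
    levels: dict[str, list[str]] = {}
    for sample, level in zip(annotation.samples, annotation.factors[factor]):
        if level == "NA":
            continue
        levels.setdefault(level, []).append(sample)
    return [
        SampleGroup(group_id=f"{factor}={level}", members=tuple(members))
        for level, members in levels.items()
    ]


def _mode_largest_magnitude(values: np.ndarray) -> float:
    # mode; ties broken toward the value of largest magnitude
    uniq, counts = np.unique(values, return_counts=True)
    best = counts.max()
    tied = uniq[counts == best]
    return float(tied[np.argmax(np.abs(tied))])


def summarize_group(
    table: DataTable, group: SampleGroup, method: str | None = None
) -> pd.Series:
    """Collapse a sample group to one value per gene, by representation.

    Returns a Series indexed by gene.  Continuous: mean over non-missing
    members (``method`` may override with ``median``/``min``/``max``).
    Discrete unordered (mutation): True iff at least one member is mutated,
    missing if all members are missing.  Discrete ordered: mode with
    largest-magnitude tie-break.  Set: the membership flags themselves
    (union over the single implicit column).
    """
    cols = [s for s in group.members if s in table.values.columns]
    if table.internal_repr == "set":
        return table.values["member"].copy()
    if not cols:
        raise DataParseError(
            f"group {group.group_id!r} shares no samples with table {table.name!r}"
        )
    sub = table.values[cols]

    if table.internal_repr == "continuous":
        method = method or "mean"
        if method not in ("mean", "median", "min", "max"):
            raise DataParseError(f"unknown continuous summary method {method!r}")
        return getattr(sub, method)(axis=1, skipna=True)

    if table.internal_repr == "discrete_unordered":
        out: list[bool | None] = []
        for _, row in sub.iterrows():
            labels = [v for v in row if v is not MISSING]
            out.append(
                MISSING if not labels else bool(any(is_mutated_label(v) for v in labels))
            )
        return pd.Series(out, index=sub.index, dtype=object)

    # discrete_ordered
    def mode_row(row: pd.Series) -> float:
        vals = row.to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            return math.nan
        return _mode_largest_magnitude(vals)

    return sub.apply(mode_row, axis=1)


def summarize_table(
    table: DataTable, groups: list[SampleGroup], method: str | None = None
) -> pd.DataFrame:
    """Group summaries side by side: one column per group, indexed by gene."""
    return pd.DataFrame(
        {g.group_id: summarize_group(table, g, method=method) for g in groups}
    )
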