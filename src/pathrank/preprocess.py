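"""Expression preprocessing: log2 transformation, quantile normalization,
and probe-to-gene summarization.

The pipeline starts from a numeric intensity table (probes or genes in rows,
samples in columns) with a two-group design label per sample.  Scanner-level
feature extraction and background correction are upstream of this package.
The fixed stage order is log2 -> quantile normalization -> probe averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("pathrank.preprocess")

TREATED = "treated"
CONTROL = "control"
VALID_GROUPS = (TREATED, CONTROL)


class PathrankError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(PathrankError):
    """A numeric value outside the mathematically valid domain."""


class DesignError(PathrankError):
    """An experimental design the method cannot handle."""


class AnnotationError(PathrankError):
    """Probe/gene annotation inconsistent with the expression table."""


class InputError(PathrankError):
    """Malformed or inconsistent user input."""


@dataclass
class ExpressionMatrix:
    """Intensity table with sample group labels.

    ``values`` holds rows = probes or genes, columns = samples; after
    :func:`log2_transform` the units are log2 intensity.  ``group_of`` maps
    every sample id to ``"treated"`` or ``"control"``.
    """

    values: pd.DataFrame
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate row ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise InputError("duplicate sample ids")
        missing = [s for s in self.values.columns if s not in self.group_of]
        if missing:
            raise DesignError(f"samples without group label: {missing}")
        bad = {s: g for s, g in self.group_of.items() if g not in VALID_GROUPS}
        if bad:
            raise DesignError(f"invalid group labels (expect treated/control): {bad}")
        for g in VALID_GROUPS:
            if not any(self.group_of.get(s) == g for s in self.values.columns):
                raise DesignError(f"group {g!r} has no samples")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of[s] == group]

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, group_of=dict(self.group_of))


@dataclass
class ProbeAnnotation:
    """Many-to-one map from probe id to gene id."""

    probe_to_gene: dict[str, str]

    def genes(self) -> set[str]:
        return set(self.probe_to_gene.values())


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every intensity by its base-2 logarithm.

    Raises :class:`DomainError` naming the first offending cell if any value
    is non-positive.
    """
    vals = m.values
    bad = vals.to_numpy() <= 0
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DomainError(
            f"non-positive intensity at row {vals.index[i]!r}, "
            f"column {vals.columns[j]!r}: {vals.iat[i, j]}"
        )
    return m.with_values(np.log2(vals))


def quantile_normalize(m: ExpressionMatrix | pd.DataFrame):
    """Force every column onto the common per-rank mean distribution.

    The reference distribution is the mean across columns of the
    column-sorted values.  Each value is replaced by the reference value at
    its within-column rank; ties within a column receive the mean of the
    reference values over the rank span they occupy, so the result is
    invariant to the order of tied entries.  Accepts a labelled matrix or a
    bare DataFrame (returned in kind).
    """
    vals = m if isinstance(m, pd.DataFrame) else m.values
    if vals.shape[0] < 2:
        raise InputError("quantile normalization requires at least 2 rows")
    arr = vals.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)

    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average the reference over each tie group
        sorted_col = col[order]
        k = 0
        while k < len(sorted_col):
            k2 = k
            while k2 + 1 < len(sorted_col) and sorted_col[k2 + 1] == sorted_col[k]:
                k2 += 1
            if k2 > k:
                assigned[order[k : k2 + 1]] = reference[k : k2 + 1].mean()
            k = k2 + 1
        out[:, j] = assigned
    frame = pd.DataFrame(out, index=vals.index, columns=vals.columns)
    return frame if isinstance(m, pd.DataFrame) else m.with_values(frame)


def aggregate_probes(m: ExpressionMatrix, ann: ProbeAnnotation) -> ExpressionMatrix:
    """Summarize probe-level rows to one row per gene by arithmetic mean.

    Every probe must be annotated; output genes are in lexicographic order.
    """
    unmapped = [p for p in m.values.index if p not in ann.probe_to_gene]
    if unmapped:
        raise AnnotationError(f"probes without gene annotation: {unmapped[:10]}")
    gene_ids = pd.Index([ann.probe_to_gene[p] for p in m.values.index], name="gene")
    aggregated = m.values.groupby(gene_ids, sort=True).mean()
    return m.with_values(aggregated)


def preprocess_pipeline(
    m: ExpressionMatrix, ann: ProbeAnnotation | None = None
) -> ExpressionMatrix:
    """Run log2 -> quantile normalization -> probe averaging (if annotated)."""
    out = quantile_normalize(log2_transform(m))
    if ann is not None:
        out = aggregate_probes(out, ann)
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression(
    expression_path: str | Path, groups_path: str | Path
) -> ExpressionMatrix:
    """Read an expression TSV (first column = row id) and a two-column
    sample->group TSV."""
    vals = pd.read_csv(expression_path, sep="\t", index_col=0)
    vals.index = vals.index.astype(str)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    group_of = {str(k): str(v) for k, v in groups.items()}
    return ExpressionMatrix(values=vals, group_of=group_of)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="id", float_format="%.10g")


def write_groups(m: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s in m.sample_ids:
            fh.write(f"{s}\t{m.group_of[s]}\n")


def read_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"annotation file {path} needs two columns")
    return ProbeAnnotation(probe_to_gene=dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tgene_id\n")
        for p, g in ann.probe_to_gene.items():
            fh.write(f"{p}\t{g}\n")
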