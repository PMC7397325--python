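"""Reading, writing and assembling expression matrices and gene sets.

An expression matrix is represented as a :class:`pandas.DataFrame` with gene
identifiers as the index and sample identifiers as the columns; all values
are finite floats.  Gene sets (pathways or prognostic signatures) are
:class:`GeneSet` instances and travel on disk in the standard GMT format.

The cohort-assembly helpers implement the conventions of multi-dataset
microarray meta-analyses: duplicate probes for the same gene are collapsed
to the probe with the highest mean expression, genes are median-centred
across samples, and samples are quantile-normalised to a shared reference
distribution before cohorts are merged on their common genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DegenerateInputError, FormatError, MergeError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "collapse_duplicates",
    "median_center",
    "quantile_normalize",
    "merge_cohorts",
]


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty collection of unique gene identifiers."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("gene set name must be non-empty")
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def restrict(self, universe: Iterable[str]) -> frozenset[str]:
        """Members of this set present in ``universe``."""
        return self.genes & frozenset(universe)


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dups = sorted(seen[seen.duplicated()].unique())
        raise FormatError(f"duplicate {what} IDs: {', '.join(map(str, dups))}")


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check uniqueness of IDs and finiteness of values; return the matrix."""
    _check_unique(list(matrix.index), "gene")
    _check_unique(list(matrix.columns), "sample")
    values = matrix.to_numpy()
    if values.size and not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[0]
        raise FormatError(
            f"non-finite value at gene {matrix.index[bad[0]]!r}, "
            f"sample {matrix.columns[bad[1]]!r}"
        )
    return matrix


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV (header = sample IDs, first column = gene IDs)."""
    try:
        matrix = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty expression file: {path}") from exc
    if matrix.shape[1] == 0:
        raise FormatError(f"no sample columns in expression file: {path}")
    non_numeric = matrix.columns[[not pd.api.types.is_numeric_dtype(d) for d in matrix.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        coerced = pd.to_numeric(matrix[col], errors="coerce")
        row = matrix.index[coerced.isna().to_numpy().argmax()]
        raise FormatError(f"non-numeric value at gene {row!r}, sample {col!r}")
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    return validate_expression(matrix.astype(float))


def write_expression(matrix: pd.DataFrame, path) -> None:
    """Write a genes x samples TSV round-trippable by :func:`read_expression`."""
    validate_expression(matrix)
    matrix.to_csv(path, sep="\t", float_format="%.10g", index_label="gene_id")


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file (per line: name, description, tab-separated genes).

    Duplicate genes within one line are removed with a logged warning.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "expected name, description and at least one gene"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if len(set(genes)) < len(genes):
                logger.warning(
                    "GMT set %r (line %d) contains duplicate genes; deduplicated",
                    name,
                    lineno,
                )
            sets.append(GeneSet(name=name, genes=frozenset(genes)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path, descriptions: Mapping[str, str] | None = None) -> None:
    """Write gene sets as GMT; genes are written in sorted order."""
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as handle:
        for gs in sets:
            desc = descriptions.get(gs.name, "na")
            handle.write("\t".join([gs.name, desc, *sorted(gs.genes)]) + "\n")


def collapse_duplicates(matrix: pd.DataFrame, probe_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Collapse probe-level rows to one row per gene.

    For each gene the retained row is the mapped probe with the highest mean
    expression across samples; mean ties keep the probe occurring first in
    the input.  Probes absent from ``probe_to_gene`` are dropped.
    """
    if not probe_to_gene:
        raise DegenerateInputError("probe_to_gene mapping is empty")
    mapped = matrix.loc[[p for p in matrix.index if p in probe_to_gene]]
    if mapped.empty:
        raise DegenerateInputError("no probe in the matrix maps to a gene")
    genes = pd.Series([probe_to_gene[p] for p in mapped.index], index=mapped.index)
    means = mapped.mean(axis=1)
    keep: list[str] = []
    for _gene, probes in genes.groupby(genes, sort=False):
        # idxmax keeps the first occurrence on ties, matching input order
        keep.append(means.loc[probes.index].idxmax())
    collapsed = mapped.loc[keep]
    collapsed.index = pd.Index([probe_to_gene[p] for p in keep], name=matrix.index.name)
    return validate_expression(collapsed)


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract from every gene its median across samples."""
    if matrix.shape[1] < 1:
        raise DegenerateInputError("median centering requires at least one sample")
    return matrix.sub(matrix.median(axis=1), axis=0)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the mean-of-order-statistics reference.

    Ranks within a column are preserved; ties receive the mean of their tied
    reference quantiles.  After normalisation the sorted values of every
    column are identical.
    """
    if matrix.shape[1] < 2:
        raise DegenerateInputError("quantile normalization requires >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, len(reference) + 1), reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def merge_cohorts(matrices: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate cohorts on the intersection of their gene IDs.

    Sample IDs must be globally unique.  Logs the number of genes dropped
    from each input.
    """
    if len(matrices) < 2:
        raise MergeError("merging requires at least two cohorts")
    common = matrices[0].index
    for m in matrices[1:]:
        common = common.intersection(m.index)
    if len(common) == 0:
        raise MergeError("gene intersection across cohorts is empty")
    common = common.sort_values()
    for i, m in enumerate(matrices):
        dropped = m.shape[0] - len(common)
        logger.info("cohort %d: dropped %d gene(s) outside the intersection", i, dropped)
    merged = pd.concat([m.loc[common] for m in matrices], axis=1)
    return validate_expression(merged)
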