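"""Per-sample pathway activation z-scores.

For a gene set S and a sample t the activation score is

    Z(t, S) = (mean_S(x_t) - mean(x_t)) / (sd(x_t) / sqrt(|S|))

where the mean and standard deviation in the denominator run over *all*
genes measured in sample t, and |S| counts only the set's genes actually
present in the matrix (genes lost in cross-platform merging are dropped).
The score is the one-sample z-statistic of the set mean against the
sample-wide expression distribution: positive values mean the pathway's
genes sit above the sample average.

The standard deviation uses the n-1 (sample) divisor by default; this is
configurable via ``ddof``.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateSampleError, MissingGeneError
from .expression_io import GeneSet

logger = logging.getLogger(__name__)

__all__ = ["score_pathway", "score_pathways"]


def _sample_stats(matrix: pd.DataFrame, ddof: int) -> tuple[pd.Series, pd.Series]:
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=ddof)
    return mean, sd


def score_pathway(matrix: pd.DataFrame, gene_set: GeneSet, sample: str, ddof: int = 1) -> float:
    """Activation z-score of one gene set in one sample."""
    if sample not in matrix.columns:
        raise KeyError(f"sample {sample!r} not in matrix")
    if matrix.shape[0] < 2:
        raise DegenerateSampleError("need at least two genes to define a sample SD")
    present = sorted(gene_set.restrict(matrix.index))
    if not present:
        raise MissingGeneError(
            f"no gene of set {gene_set.name!r} is present in the matrix"
        )
    x = matrix[sample]
    sd = float(x.std(ddof=ddof))
    if sd == 0.0:
        raise DegenerateSampleError(f"sample {sample!r} has zero expression variance")
    set_mean = float(x.loc[present].mean())
    return (set_mean - float(x.mean())) / (sd / np.sqrt(len(present)))


def score_pathways(matrix: pd.DataFrame, gene_sets: Sequence[GeneSet], ddof: int = 1) -> pd.DataFrame:
    """Activation z-scores for every (gene set, sample) pair.

    Returns a pathways x samples DataFrame.  Per-set counts of genes absent
    from the matrix are logged.  Errors from individual scores are re-raised
    with the pathway and sample named.
    """
    if matrix.shape[0] < 2:
        raise DegenerateSampleError("need at least two genes to define a sample SD")
    mean, sd = _sample_stats(matrix, ddof)
    degenerate = sd.index[sd.to_numpy() == 0.0]
    if len(degenerate):
        raise DegenerateSampleError(
            f"sample(s) with zero expression variance: {', '.join(map(str, degenerate[:5]))}"
        )
    values = np.empty((len(gene_sets), matrix.shape[1]))
    for i, gs in enumerate(gene_sets):
        present = sorted(gs.restrict(matrix.index))
        absent = len(gs) - len(present)
        if absent:
            logger.info("set %r: %d gene(s) absent from the matrix", gs.name, absent)
        if not present:
            raise MissingGeneError(f"no gene of set {gs.name!r} is present in the matrix")
        set_mean = matrix.loc[present].mean(axis=0)
        values[i] = ((set_mean - mean) / (sd / np.sqrt(len(present)))).to_numpy()
    return pd.DataFrame(values, index=[gs.name for gs in gene_sets], columns=matrix.columns)
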