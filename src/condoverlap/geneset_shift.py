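"""Collective p-value shift test for a named gene set.

Asks whether the members of a gene set (e.g. transcription factors, or
genes known to cause IgA deficiency when knocked out) are collectively
shifted toward small differential-analysis p-values, without requiring
any individual member to pass a significance threshold.  The observed
statistic is the Wilcoxon rank-sum (midranks for ties) of the set's
p-values against the rest of the universe; the null is built by drawing
same-size gene sets uniformly at random from the universe and
recomputing.  The empirical p-value is one-sided in the small-p
direction (smaller rank-sum = stronger collective shift).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ValidationError
from .overlap import DifferentialTable, _sample_index_matrix

__all__ = ["GeneSetShiftResult", "geneset_shift_test", "rank_sum_statistic"]


@dataclass(frozen=True)
class GeneSetShiftResult:
    """Observed rank-sum statistic, its resampling null, and the
    one-sided (small-p) empirical p-value."""

    observed_statistic: float
    null_statistics: np.ndarray = field(repr=False)
    empirical_p: float
    set_size: int
    n_resamples: int
    n_dropped: int = 0


def rank_sum_statistic(p_values: np.ndarray, in_set: np.ndarray) -> float:
    """Sum of the midranks of the set members' p-values within the full
    universe."""
    ranks = rankdata(p_values, method="average")
    return float(ranks[in_set].sum())


def geneset_shift_test(
    table: DifferentialTable,
    gene_set: Sequence,
    n_resamples: int = 10_000,
    seed: Optional[int] = None,
) -> GeneSetShiftResult:
    """Test a gene set for a collective shift toward small p-values.

    ``gene_set`` must be a non-empty proper subset of the table's
    universe; ids absent from the universe are dropped with a warning.
    Null sets are drawn uniformly without replacement from the whole
    universe (the true set's members included).  The empirical p uses
    the (1 + #{null <= observed}) / (R + 1) pseudocount convention.
    """
    ids = pd.Index(gene_set)
    if len(ids) == 0:
        raise ValidationError("gene_set is empty")
    present = ids.intersection(table.feature_ids)
    n_dropped = len(ids) - len(present)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} gene-set ids absent from the universe were dropped",
            UserWarning,
            stacklevel=2,
        )
    if len(present) == 0:
        raise ValidationError("no gene-set ids found in the universe")
    m = len(table)
    k = len(present)
    if k == m:
        raise ValidationError("gene_set equals the whole universe; the "
                              "complement comparison is undefined")
    if n_resamples < 1:
        raise ValidationError("n_resamples must be >= 1")

    p = table.p_values.to_numpy()
    ranks = rankdata(p, method="average")
    in_set = table.feature_ids.isin(present)
    observed = float(ranks[in_set].sum())

    rng = np.random.default_rng(seed)
    idx = _sample_index_matrix(rng, m, k, n_resamples)
    null = ranks[idx].sum(axis=1)

    empirical_p = (1.0 + np.sum(null <= observed)) / (n_resamples + 1.0)
    return GeneSetShiftResult(
        observed_statistic=observed,
        null_statistics=null,
        empirical_p=float(empirical_p),
        set_size=k,
        n_resamples=n_resamples,
        n_dropped=n_dropped,
    )
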