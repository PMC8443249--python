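"""Sliding rank-threshold conditional-proportion scans.

Links one experiment's top-ranked features (e.g. the most differentially
accessible promoter peaks) to differential signal in a mapped second
experiment (e.g. expression of the downstream genes): for each rank
threshold K, take the top-K source features by p-value, map them to
target features, and estimate the proportion of targets that are truly
differential (pi1) from the response p-values.  Plotting the proportion
against K shows how the association dilutes as the source calls become
less stringent.  Also provides median fold-change collapsing of
many-to-one maps, the "uniquely top-ranked" selection rule, and the
quartile cross-tabulation of a gene set between two rankings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .overlap import DifferentialTable
from .pvalue_stats import estimate_pi0

__all__ = [
    "DEFAULT_THRESHOLDS",
    "FeatureMap",
    "RankScanCurve",
    "rank_conditional_proportion",
    "collapse_effects",
    "select_unique_top",
    "quartile_cross_table",
]

#: Rank thresholds 1000, 1250, ..., 5000.
DEFAULT_THRESHOLDS = tuple(range(1000, 5001, 250))


@dataclass(frozen=True)
class FeatureMap:
    """Many-to-many map from source features to target features
    (e.g. promoter peak -> downstream gene)."""

    pairs: pd.DataFrame  # columns: source, target

    def __post_init__(self) -> None:
        df = self.pairs
        if list(df.columns) != ["source", "target"]:
            raise ValidationError("FeatureMap requires columns ['source', 'target']")
        if df.duplicated().any():
            raise ValidationError("FeatureMap contains duplicate pairs")
        if (df["source"].astype(str) == "").any() or (df["target"].astype(str) == "").any():
            raise ValidationError("FeatureMap ids must be non-empty")

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple]) -> "FeatureMap":
        return cls(pd.DataFrame(pairs, columns=["source", "target"]))

    def targets_of(self, source_ids: Sequence) -> pd.Index:
        mask = self.pairs["source"].isin(set(source_ids))
        return pd.Index(self.pairs.loc[mask, "target"].unique())


@dataclass(frozen=True)
class RankScanCurve:
    """Estimated differential proportion of mapped targets per rank
    threshold; ``proportions`` entries are NaN where no targets mapped."""

    thresholds: np.ndarray
    proportions: np.ndarray
    n_mapped: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "proportion_differential": self.proportions,
                "n_mapped": self.n_mapped,
            }
        )


def _ranked_ids(table: DifferentialTable) -> pd.Index:
    """Feature ids by ascending p-value, ties broken stably by id."""
    order = np.lexsort(
        (table.feature_ids.to_numpy(), table.p_values.to_numpy())
    )
    return table.feature_ids[order]


def rank_conditional_proportion(
    ranking: DifferentialTable,
    response: DifferentialTable,
    feature_map: FeatureMap,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    pi0_method: str = "bootstrap",
    fixed_lambda: Optional[float] = None,
    seed: Optional[int] = None,
) -> RankScanCurve:
    """For each threshold K: top-K ranking features, mapped to targets
    (deduplicated), then pi1 of the response p-values on that target set.

    K counts source features (peaks), not targets; a fixed lambda, when
    given, overrides the automatic lambda rule at every threshold.
    """
    thresholds = np.asarray(thresholds, dtype=int)
    if np.any(np.diff(thresholds) <= 0):
        raise ValidationError("thresholds must be strictly increasing")
    if thresholds[-1] > len(ranking):
        raise ValidationError(
            f"largest threshold {thresholds[-1]} exceeds the {len(ranking)} "
            "ranked features"
        )
    unknown = feature_map.pairs["target"][
        ~feature_map.pairs["target"].isin(response.feature_ids)
    ]
    if len(unknown) > 0:
        raise ValidationError(
            f"{len(unknown)} map targets absent from the response universe"
        )
    method = "fixed" if fixed_lambda is not None else pi0_method
    ranked = _ranked_ids(ranking)
    props = np.full(len(thresholds), np.nan)
    n_mapped = np.zeros(len(thresholds), dtype=int)
    for i, k in enumerate(thresholds):
        targets = feature_map.targets_of(ranked[:k])
        n_mapped[i] = len(targets)
        if len(targets) == 0:
            warnings.warn(
                f"threshold {k}: no mapped targets; proportion recorded as "
                "missing",
                UserWarning,
                stacklevel=2,
            )
            continue
        p = response.p_values.loc[targets].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            try:
                est = estimate_pi0(p, method=method, fixed_lambda=fixed_lambda,
                                   seed=seed)
            except ValidationError:
                est = estimate_pi0(p, method="fixed", fixed_lambda=0.5)
        props[i] = est.pi1
    return RankScanCurve(thresholds, props, n_mapped)


def collapse_effects(
    feature_map: FeatureMap, source: DifferentialTable
) -> pd.Series:
    """Per-target median log2 fold change across its mapped source
    features (midpoint convention for even counts)."""
    pairs = feature_map.pairs
    missing = pairs["source"][~pairs["source"].isin(source.feature_ids)]
    if len(missing) > 0:
        raise ValidationError(
            f"{len(missing)} mapped source features absent from the source table"
        )
    lfc = source.lfc.loc[pairs["source"]].to_numpy()
    out = (
        pd.DataFrame({"target": pairs["target"].to_numpy(), "lfc": lfc})
        .groupby("target", sort=True)["lfc"]
        .median()
    )
    out.name = "median_lfc"
    return out


def select_unique_top(
    experiments: Mapping[str, DifferentialTable],
    focal: str,
    top_k: int = 1000,
    exclusion_k: int = 5000,
    shared_ids: Sequence = (),
) -> pd.Index:
    """Features uniquely top-ranked in the focal experiment: within its
    top ``top_k`` by p-value, not in ``shared_ids``, and not within any
    other experiment's top ``exclusion_k``."""
    if focal not in experiments:
        raise ValidationError(f"focal experiment {focal!r} not among "
                              f"{sorted(experiments)}")
    if not (top_k <= exclusion_k):
        raise ValidationError("top_k must not exceed exclusion_k")
    top = pd.Index(_ranked_ids(experiments[focal])[:top_k])
    keep = top.difference(pd.Index(shared_ids))
    for name, table in experiments.items():
        if name == focal:
            continue
        keep = keep.difference(pd.Index(_ranked_ids(table)[:exclusion_k]))
    return keep.sort_values()


def quartile_cross_table(
    ranking_a: DifferentialTable,
    ranking_b: DifferentialTable,
    gene_set: Sequence,
) -> pd.Series:
    """Cross-ranking quartile stratification of a gene set.

    Genes are binned by their p-value quartile in ``ranking_b``
    (quartiles computed within the gene set; boundary ties fall to the
    lower quartile).  Each bin reports the fraction of its genes that
    belong to the top 25% of the gene set by ``ranking_a`` p-value.
    Under independent rankings every fraction is ~0.25.
    """
    ids = pd.Index(gene_set)
    if len(ids) < 8:
        raise ValidationError(
            f"gene set of size {len(ids)} is too small for quartile "
            "stratification (need >= 8)"
        )
    for t in (ranking_a, ranking_b):
        missing = ids.difference(t.feature_ids)
        if len(missing) > 0:
            raise ValidationError(
                f"{len(missing)} gene-set members absent from table {t.name!r}"
            )
    p_a = ranking_a.p_values.loc[ids].to_numpy()
    p_b = ranking_b.p_values.loc[ids].to_numpy()
    n = len(ids)

    n_top = n // 4
    order_a = np.lexsort((ids.to_numpy(), p_a))
    in_top = np.zeros(n, dtype=bool)
    in_top[order_a[:n_top]] = True

    edges = np.quantile(p_b, [0.25, 0.5, 0.75])
    bins = np.searchsorted(edges, p_b, side="left")  # ties -> lower quartile
    frac = pd.Series(
        [in_top[bins == q].mean() if (bins == q).any() else np.nan
         for q in range(4)],
        index=pd.Index(["Q1", "Q2", "Q3", "Q4"], name="quartile_in_b"),
        name="fraction_top25_in_a",
    )
    return frac
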