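"""Conditional overlap between lists of differential features.

Given two differential analyses over the same feature universe, the
question is whether significance in experiment 1 is informative about
the null/differential state of the same features in experiment 2, and if
so, which features are differential in both.  Writing ``X_i`` for the
significance indicator from experiment 1 and ``pi_{1|1}`` (``pi_{1|0}``)
for the proportion of truly differential experiment-2 features among
those with ``X_i = 1`` (``X_i = 0``), the null of no information is

    H0 : pi_{1|0} = pi_{1|1}.

Under H0 an estimate of ``pi_{1|1}`` on the conditioning set has the
same distribution as ``pi1_hat(n)``, the estimated differential
proportion in a random sample of n features from experiment 2 — so the
test resamples n-feature subsets to build the null.  Identification of
the common hits then computes q-values on experiment 2 restricted to the
conditioning set only, decoupling "how big is the overlap" from "which
features are in it" and spending the multiple-testing budget only on
features already in play.

The naive baseline — threshold each experiment separately and intersect
— double-thresholds and systematically underestimates the overlap; it is
provided here for comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InfeasibleError, ValidationError
from .pvalue_stats import Pi0Estimate, compute_qvalues, estimate_pi0

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialTable",
    "ConditionalOverlapResult",
    "SharedFeatureSet",
    "ChainResult",
    "conditional_overlap_test",
    "identify_shared_features",
    "filter_concordant",
    "chain_overlap",
    "naive_intersection",
]


@dataclass(frozen=True)
class DifferentialTable:
    """One experiment's differential-analysis results.

    ``data`` is indexed by unique feature id, with a ``p_value`` column
    in [0, 1], an optional signed ``lfc`` column (log2 fold change) and
    an optional ``stat`` column.
    """

    data: pd.DataFrame
    name: str = ""

    def __post_init__(self) -> None:
        df = self.data
        if "p_value" not in df.columns:
            raise ValidationError("DifferentialTable requires a 'p_value' column")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()[:5]
            raise ValidationError(f"duplicate feature_ids: {dups}")
        p = df["p_value"].to_numpy(dtype=float)
        if p.size == 0:
            raise ValidationError("DifferentialTable is empty")
        if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
            raise ValidationError("p_value column must lie in [0, 1]")

    @classmethod
    def from_arrays(
        cls,
        feature_ids: Sequence,
        p_values: Sequence[float],
        lfc: Optional[Sequence[float]] = None,
        stat: Optional[Sequence[float]] = None,
        name: str = "",
    ) -> "DifferentialTable":
        cols = {"p_value": np.asarray(p_values, dtype=float)}
        if lfc is not None:
            cols["lfc"] = np.asarray(lfc, dtype=float)
        if stat is not None:
            cols["stat"] = np.asarray(stat, dtype=float)
        df = pd.DataFrame(cols, index=pd.Index(feature_ids, name="feature_id"))
        return cls(df, name=name)

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def p_values(self) -> pd.Series:
        return self.data["p_value"]

    @property
    def lfc(self) -> pd.Series:
        if "lfc" not in self.data.columns:
            raise ValidationError(
                f"table {self.name!r} has no log2 fold change ('lfc') column"
            )
        return self.data["lfc"]

    def restrict(self, ids: Sequence) -> "DifferentialTable":
        idx = pd.Index(ids)
        missing = idx.difference(self.data.index)
        if len(missing) > 0:
            raise ValidationError(
                f"{len(missing)} requested features absent from table "
                f"{self.name!r}, e.g. {missing[:3].tolist()}"
            )
        return DifferentialTable(self.data.loc[idx], name=self.name)

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class ConditionalOverlapResult:
    """Outcome of the conditional overlap test of one experiment pair."""

    n_conditioning: int
    pi1_given_1: float
    pi1_given_0: float
    null_pi1_samples: np.ndarray = field(repr=False)
    empirical_p: float
    normal_approx_p: float
    estimated_shared_count: int
    pi0_detail: Optional[Pi0Estimate] = field(default=None, repr=False)


@dataclass(frozen=True)
class SharedFeatureSet:
    """Features identified as differential in both experiments."""

    feature_ids: np.ndarray
    qvalues: np.ndarray
    direction_concordant: np.ndarray
    source_experiments: tuple

    def __len__(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "qvalue": self.qvalues,
                "direction_concordant": self.direction_concordant,
            },
            index=pd.Index(self.feature_ids, name="feature_id"),
        )


@dataclass(frozen=True)
class ChainResult:
    """Per-stage results of a multi-experiment conditional chain."""

    stages: list
    status: str  # "complete" or "stopped:<stage>"


def harmonize_universe(*tables: DifferentialTable) -> list[DifferentialTable]:
    """Inner-join all tables on their feature ids, warning about drops."""
    common = tables[0].feature_ids
    for t in tables[1:]:
        common = common.intersection(t.feature_ids)
    if len(common) == 0:
        raise ValidationError("tables share no features")
    common = common.sort_values()
    out = []
    for t in tables:
        dropped = len(t) - len(common)
        if dropped:
            warnings.warn(
                f"table {t.name!r}: {dropped} features outside the common "
                "universe dropped",
                UserWarning,
                stacklevel=2,
            )
        out.append(DifferentialTable(t.data.loc[common], name=t.name))
    return out


def _pi1(
    pvals: np.ndarray,
    pi0_method: str,
    fixed_lambda: Optional[float],
    seed: Optional[int],
    n_boot: int = 100,
) -> float:
    """pi1 = 1 - pi0 with the small-set warning silenced and a fixed
    lambda = 0.5 fallback when the bootstrap/smoother rules are
    undefined (e.g. all p-values identical in a resample)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        try:
            est = estimate_pi0(
                pvals, method=pi0_method, fixed_lambda=fixed_lambda,
                n_boot=n_boot, seed=seed,
            )
        except ValidationError:
            logger.info(
                "pi0 %s rule undefined on a %d-value set; falling back to "
                "fixed lambda = 0.5", pi0_method, len(pvals),
            )
            est = estimate_pi0(pvals, method="fixed", fixed_lambda=0.5)
    return est.pi1


def _sample_index_matrix(
    rng: np.random.Generator, m: int, n: int, n_draws: int
) -> np.ndarray:
    """n_draws independent uniform samples of n indices from range(m),
    each without replacement; chunked to bound memory."""
    out = np.empty((n_draws, n), dtype=np.int64)
    chunk = max(1, int(2e7) // m)
    for start in range(0, n_draws, chunk):
        stop = min(start + chunk, n_draws)
        keys = rng.random((stop - start, m))
        out[start:stop] = np.argpartition(keys, n - 1, axis=1)[:, :n]
    return out


def significant_ids(
    table: DifferentialTable,
    fdr_level: float,
    pi0_method: str = "bootstrap",
    fixed_lambda: Optional[float] = None,
    seed: Optional[int] = None,
) -> pd.Index:
    """Feature ids significant at ``fdr_level`` by Storey q-values."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        try:
            est = estimate_pi0(
                table.p_values.to_numpy(), method=pi0_method,
                fixed_lambda=fixed_lambda, seed=seed,
            )
        except ValidationError:
            est = estimate_pi0(table.p_values.to_numpy(), method="fixed",
                               fixed_lambda=0.5)
    qt = compute_qvalues(
        table.p_values.to_numpy(), est.pi0, alpha=fdr_level,
        feature_ids=table.feature_ids.to_numpy(),
    )
    return pd.Index(qt.significant_ids)


def overlap_test_with_conditioning(
    conditioning_ids: Sequence,
    exp2: DifferentialTable,
    n_resamples: int = 1000,
    pi0_method: str = "bootstrap",
    fixed_lambda: Optional[float] = None,
    seed: Optional[int] = None,
) -> ConditionalOverlapResult:
    """Core of the overlap test, for an externally supplied conditioning
    set (used directly by multi-stage chains).

    With ``n_resamples = 0`` the resampling null is skipped: the point
    estimates and the estimated shared count are still returned, but the
    p-values are NaN and ``null_pi1_samples`` is empty.
    """
    cond = pd.Index(conditioning_ids)
    if len(cond) == 0:
        raise InfeasibleError("conditioning set is empty")
    missing = cond.difference(exp2.feature_ids)
    if len(missing) > 0:
        raise ValidationError(
            f"{len(missing)} conditioning features absent from experiment 2"
        )
    rng = np.random.default_rng(seed)
    p2 = exp2.p_values
    n = len(cond)
    m = len(exp2)

    def pi1_of(vals: np.ndarray) -> float:
        return _pi1(vals, pi0_method, fixed_lambda,
                    seed=int(rng.integers(2**31)))

    pi1_11 = pi1_of(p2.loc[cond].to_numpy())
    complement = exp2.feature_ids.difference(cond)
    pi1_10 = pi1_of(p2.loc[complement].to_numpy()) if len(complement) else float("nan")

    if n_resamples > 0:
        pvec = p2.to_numpy()
        idx = _sample_index_matrix(rng, m, n, n_resamples)
        null = np.array([pi1_of(pvec[row]) for row in idx])
        empirical_p = (1.0 + np.sum(null >= pi1_11)) / (n_resamples + 1.0)
        sd = null.std(ddof=1) if n_resamples > 1 else np.nan
        if np.isfinite(sd) and sd > 0:
            normal_p = float(stats.norm.sf((pi1_11 - null.mean()) / sd))
        else:
            normal_p = float(pi1_11 <= null.mean()) if n_resamples > 1 else np.nan
    else:
        null = np.empty(0)
        empirical_p = np.nan
        normal_p = np.nan

    return ConditionalOverlapResult(
        n_conditioning=n,
        pi1_given_1=pi1_11,
        pi1_given_0=pi1_10,
        null_pi1_samples=null,
        empirical_p=float(empirical_p),
        normal_approx_p=normal_p,
        estimated_shared_count=int(round(pi1_11 * n)),
    )


def conditional_overlap_test(
    exp1: DifferentialTable,
    exp2: DifferentialTable,
    fdr_level: float = 0.1,
    n_resamples: int = 1000,
    pi0_method: str = "bootstrap",
    fixed_lambda: Optional[float] = None,
    seed: Optional[int] = None,
) -> ConditionalOverlapResult:
    """Test whether experiment 1's differential calls are informative
    about experiment 2, and estimate the overlap size.

    Steps: (1) call experiment-1 features at ``fdr_level`` (group 1,
    size n); (2) estimate ``pi1_hat_{1|1}`` on experiment 2 restricted
    to group 1; (3) build the null by repeatedly drawing n features
    uniformly without replacement from experiment 2 and estimating
    ``pi1_hat(n)`` on each draw with the same machinery.  The empirical
    p-value uses the (1 + exceedances) / (B + 1) pseudocount convention;
    a Gaussian upper-tail approximation from the null's moments is also
    reported because the resampling resolution cannot go below
    1 / (B + 1).
    """
    exp1, exp2 = harmonize_universe(exp1, exp2)
    rng = np.random.default_rng(seed)
    group1 = significant_ids(
        exp1, fdr_level, pi0_method, fixed_lambda, seed=int(rng.integers(2**31))
    )
    if len(group1) == 0:
        raise InfeasibleError(
            f"no experiment-1 features significant at FDR level {fdr_level}"
        )
    return overlap_test_with_conditioning(
        group1, exp2, n_resamples=n_resamples, pi0_method=pi0_method,
        fixed_lambda=fixed_lambda, seed=int(rng.integers(2**31)),
    )


def identify_shared_features(
    exp1_significant_ids: Sequence,
    exp2: DifferentialTable,
    fdr_level: float = 0.1,
    pi0_method: str = "bootstrap",
    fixed_lambda: Optional[float] = None,
    seed: Optional[int] = None,
    source_experiments: tuple = (),
) -> SharedFeatureSet:
    """Identify which conditioning-set features are differential in
    experiment 2: q-values are computed on experiment 2 restricted to
    the conditioning set only, so the multiple-testing burden applies
    just to that subset."""
    cond = pd.Index(exp1_significant_ids)
    if len(cond) < 2:
        raise InfeasibleError(
            f"conditioning set of size {len(cond)} is too small to identify "
            "shared features"
        )
    sub = exp2.restrict(cond)
    p = sub.p_values.to_numpy()
    if len(cond) < 200:
        warnings.warn(
            f"conditioning set has only {len(cond)} features; pi0 (hence "
            "q-values) may be unstable — inspect the p-value histogram",
            UserWarning,
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        try:
            est = estimate_pi0(p, method=pi0_method, fixed_lambda=fixed_lambda,
                               seed=seed)
        except ValidationError:
            est = estimate_pi0(p, method="fixed", fixed_lambda=0.5)
    qt = compute_qvalues(p, est.pi0, alpha=fdr_level,
                         feature_ids=cond.to_numpy())
    keep = qt.significant
    return SharedFeatureSet(
        feature_ids=qt.feature_ids[keep],
        qvalues=qt.qvalues[keep],
        direction_concordant=np.ones(int(keep.sum()), dtype=bool),
        source_experiments=tuple(source_experiments),
    )


def filter_concordant(
    shared: SharedFeatureSet,
    exp_a: DifferentialTable,
    exp_b: DifferentialTable,
) -> SharedFeatureSet:
    """Retain shared features whose log2 fold changes agree in sign
    between the two experiments; zero fold changes match no sign and are
    dropped (counted in a warning)."""
    ids = pd.Index(shared.feature_ids)
    lfc_a = exp_a.lfc.loc[ids].to_numpy()
    lfc_b = exp_b.lfc.loc[ids].to_numpy()
    sign_a, sign_b = np.sign(lfc_a), np.sign(lfc_b)
    zero = (sign_a == 0) | (sign_b == 0)
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} shared features with a zero log2 fold change "
            "dropped (no direction to concord)",
            UserWarning,
            stacklevel=2,
        )
    keep = (sign_a == sign_b) & ~zero
    return SharedFeatureSet(
        feature_ids=shared.feature_ids[keep],
        qvalues=shared.qvalues[keep],
        direction_concordant=np.ones(int(keep.sum()), dtype=bool),
        source_experiments=shared.source_experiments,
    )


def _mean_lfc_table(tables: Sequence[DifferentialTable]) -> DifferentialTable:
    """Synthetic table carrying the mean log2 fold change across prior
    experiments (p_value column is a placeholder, never consulted)."""
    lfcs = pd.concat([t.lfc for t in tables], axis=1).mean(axis=1)
    df = pd.DataFrame({"p_value": np.ones(len(lfcs)), "lfc": lfcs.to_numpy()},
                      index=lfcs.index)
    return DifferentialTable(df, name="mean(" + ",".join(t.name for t in tables) + ")")


def chain_overlap(
    tables: Sequence[DifferentialTable],
    fdr_level: float = 0.1,
    n_resamples: int = 1000,
    pi0_method: str = "bootstrap",
    fixed_lambda: Optional[float] = None,
    seed: Optional[int] = None,
    concordance: bool = True,
) -> ChainResult:
    """Chain the conditional overlap across >= 2 experiments.

    Stage 1 conditions experiment 2 on experiment 1's significant set;
    each later stage conditions experiment k+1 on the previous stage's
    (optionally concordance-filtered) shared set.  Multi-way concordance
    compares experiment k+1's fold-change sign against the sign of the
    mean fold change of all prior experiments.  An empty conditioning
    set stops the chain; partial results carry a status flag.
    """
    if len(tables) < 2:
        raise ValidationError("chain_overlap needs at least two tables")
    tables = harmonize_universe(*tables)
    rng = np.random.default_rng(seed)

    stages: list[tuple[ConditionalOverlapResult, SharedFeatureSet]] = []
    names = [t.name or f"exp{i + 1}" for i, t in enumerate(tables)]

    cond = significant_ids(
        tables[0], fdr_level, pi0_method, fixed_lambda,
        seed=int(rng.integers(2**31)),
    )
    for k in range(1, len(tables)):
        if len(cond) < 2:
            return ChainResult(stages, status=f"stopped:stage{k}")
        nxt = tables[k]
        result = overlap_test_with_conditioning(
            cond, nxt, n_resamples=n_resamples, pi0_method=pi0_method,
            fixed_lambda=fixed_lambda, seed=int(rng.integers(2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            shared = identify_shared_features(
                cond, nxt, fdr_level=fdr_level, pi0_method=pi0_method,
                fixed_lambda=fixed_lambda, seed=int(rng.integers(2**31)),
                source_experiments=tuple(names[: k + 1]),
            )
            if concordance and len(shared):
                prior = tables[0] if k == 1 else _mean_lfc_table(tables[:k])
                shared = filter_concordant(shared, prior, nxt)
        stages.append((result, shared))
        cond = pd.Index(shared.feature_ids)
    return ChainResult(stages, status="complete")


def naive_intersection(
    tables: Sequence[DifferentialTable],
    fdr_level: float = 0.1,
    pi0_method: str = "bootstrap",
    fixed_lambda: Optional[float] = None,
    seed: Optional[int] = None,
) -> tuple[int, pd.Index]:
    """Baseline: per-table significance at ``fdr_level`` independently,
    then the plain set intersection of the significant ids."""
    tables = harmonize_universe(*tables)
    rng = np.random.default_rng(seed)
    ids: Optional[pd.Index] = None
    for t in tables:
        sig = significant_ids(t, fdr_level, pi0_method, fixed_lambda,
                              seed=int(rng.integers(2**31)))
        ids = sig if ids is None else ids.intersection(sig)
    ids = ids.sort_values()
    return len(ids), ids
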