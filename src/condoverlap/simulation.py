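"""Ground-truth simulation study for the conditional overlap method.

Three experiments are simulated over the same feature universe with a
known sharing structure.  By default (matching the study conditions the
method was validated under): m = 10,000 features per experiment, 2,000
truly differential and 8,000 truly null per experiment, 1,400 shared
true differentials between experiments 1 and 2, and 1,000 shared across
all three.  Null features are N(0, 1) in both groups; differential
features are N(0, 1) in one group and N(effect, 1) in the other, with
effect = 0.5 and 75 samples per group; every feature gets a Welch
two-sample t-test.  Each repetition then runs the conditional chain
(experiment 1 -> 2 -> 3) and the naive per-experiment
threshold-and-intersect baseline at the same FDR level, and measures the
realized false-discovery proportion (FDP) of the three-way identified
set against the truth labels.

Truth placement uses disjoint feature blocks: the three-way shared
block, the extra 1-and-2 shared block, then per-experiment unique
blocks, so pairwise overlaps beyond the stated counts are zero.  The
RNG is stream-split per (repetition, experiment), so reducing the
number of repetitions leaves earlier repetitions unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .overlap import (
    DifferentialTable,
    chain_overlap,
    naive_intersection,
)

__all__ = [
    "SimulationConfig",
    "TruthLabels",
    "SimulationSummary",
    "WelchResult",
    "assign_truth",
    "simulate_trio",
    "welch_t_pvalue",
    "run_simulation_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings of the three-experiment simulation.

    Defaults are the study conditions under which the method's FDR
    behaviour was established; change them only to explore other
    regimes.
    """

    m: int = 10_000
    n_diff: int = 2_000
    n_shared_12: int = 1_400
    n_shared_123: int = 1_000
    effect: float = 0.5
    variance: float = 1.0
    n_per_group: int = 75
    fdr_level: float = 0.1
    n_reps: int = 1_000
    seed: int = 0
    #: resamples for the overlap-test null within each repetition;
    #: 0 skips the null (the summary needs only the point estimates).
    n_resamples: int = 0
    #: apply direction-concordance filtering between chain stages.
    use_concordance: bool = False
    pi0_method: str = "bootstrap"

    def __post_init__(self) -> None:
        if not (0 < self.n_shared_123 <= self.n_shared_12 <= self.n_diff <= self.m):
            raise ValidationError(
                "need 0 < n_shared_123 <= n_shared_12 <= n_diff <= m; got "
                f"n_shared_123={self.n_shared_123}, n_shared_12="
                f"{self.n_shared_12}, n_diff={self.n_diff}, m={self.m}"
            )
        # disjoint-block layout must fit in the universe
        needed = (self.n_shared_12
                  + 2 * (self.n_diff - self.n_shared_12)
                  + (self.n_diff - self.n_shared_123))
        if needed > self.m:
            raise ValidationError(
                f"block layout needs {needed} features but m={self.m}"
            )
        if self.variance <= 0:
            raise ValidationError("variance must be positive")
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if not (0 < self.fdr_level < 1):
            raise ValidationError("fdr_level must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TruthLabels:
    """Per-feature differential status for the three experiments."""

    differential: np.ndarray  # (m, 3) bool
    feature_ids: np.ndarray

    def ids_differential_in(self, *experiments: int) -> np.ndarray:
        mask = np.all(self.differential[:, list(experiments)], axis=1)
        return self.feature_ids[mask]


@dataclass(frozen=True)
class SimulationSummary:
    """Means over repetitions of the overlap estimates, the naive
    intersection counts, and the three-way FDP."""

    mean_estimated_overlap_12: float
    mean_estimated_overlap_123: float
    mean_naive_intersection_12: float
    mean_naive_intersection_123: float
    mean_fdp_shared_123: float
    n_reps_run: int
    n_reps_excluded: int = 0
    per_rep: pd.DataFrame = field(default=None, repr=False)


def assign_truth(config: SimulationConfig) -> TruthLabels:
    """Deterministic block layout of the true differential sets.

    Features [0, s123) are differential in all three experiments;
    [s123, s12) in experiments 1 and 2 only; the remaining per-
    experiment slots come from disjoint blocks, so pairwise overlaps
    beyond the stated counts are exactly zero.
    """
    m, d = config.m, config.n_diff
    s12, s123 = config.n_shared_12, config.n_shared_123
    diff = np.zeros((m, 3), dtype=bool)
    diff[:s123, :] = True
    diff[s123:s12, [0, 1]] = True
    u = d - s12        # unique slots for experiments 1 and 2
    u3 = d - s123      # unique slots for experiment 3
    diff[s12:s12 + u, 0] = True
    diff[s12 + u:s12 + 2 * u, 1] = True
    diff[s12 + 2 * u:s12 + 2 * u + u3, 2] = True
    ids = np.array([f"f{i:05d}" for i in range(m)])
    labels = TruthLabels(diff, ids)
    assert (diff.sum(axis=0) == d).all()
    assert (diff[:, 0] & diff[:, 1]).sum() == s12
    assert diff.all(axis=1).sum() == s123
    return labels


class WelchResult(NamedTuple):
    statistic: float
    p_value: float
    df: float


def welch_t_pvalue(group_a, group_b) -> WelchResult:
    """Welch two-sample t-test: t = (mean_b - mean_a) / sqrt(s_a^2/n_a +
    s_b^2/n_b), Welch-Satterthwaite degrees of freedom, two-sided p."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValidationError("zero variance in both groups")
    sa, sb = va / a.size, vb / b.size
    t = (b.mean() - a.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(p), float(df))


def _rep_rng(config: SimulationConfig, rep_index: int, experiment: int):
    ss = np.random.SeedSequence(config.seed, spawn_key=(rep_index, experiment))
    return np.random.default_rng(ss)


def simulate_trio(
    config: SimulationConfig, rep_index: int = 0
) -> tuple[list[DifferentialTable], TruthLabels]:
    """One repetition: draw the three experiments' data and test every
    feature with a Welch t-test (vectorized).

    The fold-change column is the group-2 minus group-1 mean difference
    (the shift is always applied to group 2), kept as a diagnostic and
    for concordance filtering.
    """
    if rep_index < 0:
        raise ValidationError("rep_index must be >= 0")
    truth = assign_truth(config)
    sd = np.sqrt(config.variance)
    n = config.n_per_group
    tables = []
    for e in range(3):
        rng = _rep_rng(config, rep_index, e)
        g1 = rng.normal(0.0, sd, size=(config.m, n))
        g2 = rng.normal(0.0, sd, size=(config.m, n))
        g2 += config.effect * truth.differential[:, e][:, None]

        m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
        v1, v2 = g1.var(axis=1, ddof=1), g2.var(axis=1, ddof=1)
        s1, s2 = v1 / n, v2 / n
        t = (m2 - m1) / np.sqrt(s1 + s2)
        df = (s1 + s2) ** 2 / (s1**2 / (n - 1) + s2**2 / (n - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        tables.append(
            DifferentialTable.from_arrays(
                truth.feature_ids, p, lfc=m2 - m1, stat=t, name=f"exp{e + 1}"
            )
        )
    return tables, truth


def _fdp(identified_ids, truly_shared_ids) -> float:
    """Realized false-discovery proportion; 0 when nothing is called."""
    n = len(identified_ids)
    if n == 0:
        return 0.0
    false = len(pd.Index(identified_ids).difference(pd.Index(truly_shared_ids)))
    return false / n


def run_simulation_study(
    config: SimulationConfig, n_reps: Optional[int] = None
) -> SimulationSummary:
    """Run the full simulation study and evaluate the conditional method
    against the naive intersection.

    Per repetition: simulate the trio; run the conditional chain
    (1 -> 2 -> 3) at ``config.fdr_level``; record the estimated overlap
    sizes (round(pi1_hat * n) at each stage), the naive intersection
    counts, and the FDP of the three-way identified set against the
    features truly differential in all three experiments.  Repetitions
    whose chain stops on an empty conditioning set are excluded from the
    means and counted.
    """
    reps = config.n_reps if n_reps is None else n_reps
    truth = assign_truth(config)
    true_123 = truth.ids_differential_in(0, 1, 2)

    rows = []
    excluded = 0
    for r in range(reps):
        tables, _ = simulate_trio(config, r)
        chain_seed = int(
            np.random.SeedSequence(config.seed, spawn_key=(r, 3)).generate_state(1)[0]
            % (2**31)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            chain = chain_overlap(
                tables,
                fdr_level=config.fdr_level,
                n_resamples=config.n_resamples,
                pi0_method=config.pi0_method,
                seed=chain_seed,
                concordance=config.use_concordance,
            )
            if chain.status != "complete":
                excluded += 1
                continue
            (res12, shared12), (res123, shared123) = chain.stages
            _, naive12 = naive_intersection(
                tables[:2], fdr_level=config.fdr_level,
                pi0_method=config.pi0_method, seed=chain_seed,
            )
            _, naive123 = naive_intersection(
                tables, fdr_level=config.fdr_level,
                pi0_method=config.pi0_method, seed=chain_seed,
            )
        rows.append(
            {
                "rep": r,
                "estimated_overlap_12": res12.estimated_shared_count,
                "estimated_overlap_123": res123.estimated_shared_count,
                "identified_12": len(shared12),
                "identified_123": len(shared123),
                "naive_12": len(naive12),
                "naive_123": len(naive123),
                "fdp_123": _fdp(shared123.feature_ids, true_123),
            }
        )
    if not rows:
        raise ValidationError("every repetition was excluded (empty chains)")
    per_rep = pd.DataFrame(rows).set_index("rep")
    return SimulationSummary(
        mean_estimated_overlap_12=float(per_rep["estimated_overlap_12"].mean()),
        mean_estimated_overlap_123=float(per_rep["estimated_overlap_123"].mean()),
        mean_naive_intersection_12=float(per_rep["naive_12"].mean()),
        mean_naive_intersection_123=float(per_rep["naive_123"].mean()),
        mean_fdp_shared_123=float(per_rep["fdp_123"].mean()),
        n_reps_run=len(per_rep),
        n_reps_excluded=excluded,
        per_rep=per_rep,
    )
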