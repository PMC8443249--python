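"""Tests for the conditional overlap test, identification, concordance
filtering, chaining, and the naive-intersection baseline."""

import numpy as np
import pandas as pd
import pytest

from condoverlap import (
    DifferentialTable,
    InfeasibleError,
    ValidationError,
    chain_overlap,
    compute_qvalues,
    conditional_overlap_test,
    estimate_pi0,
    filter_concordant,
    identify_shared_features,
    naive_intersection,
)
from condoverlap.overlap import (
    SharedFeatureSet,
    harmonize_universe,
    overlap_test_with_conditioning,
    significant_ids,
)
from conftest import make_table


def enriched_pair(rng, m=1000, n_sig=100):
    """Experiment 1 with n_sig clear hits whose experiment-2 p-values
    are all 1e-6; the remaining experiment-2 p-values are uniform."""
    ids = np.array([f"f{i:05d}" for i in range(m)])
    # exp1 nulls floored at 0.05 so group 1 is exactly the planted block
    p1 = rng.uniform(0.05, 1.0, size=m)
    p1[:n_sig] = rng.uniform(0, 1e-8, size=n_sig)
    p2 = rng.uniform(size=m)
    p2[:n_sig] = 1e-6
    lfc1 = rng.normal(0, 0.5, m)
    lfc2 = rng.normal(0, 0.5, m)
    exp1 = DifferentialTable.from_arrays(ids, p1, lfc=lfc1, name="exp1")
    exp2 = DifferentialTable.from_arrays(ids, p2, lfc=lfc2, name="exp2")
    return exp1, exp2, ids


class TestConditionalOverlapTest:
    def test_constructed_enrichment(self, rng):
        exp1, exp2, ids = enriched_pair(rng)
        res = conditional_overlap_test(exp1, exp2, fdr_level=0.1,
                                       n_resamples=199, seed=3,
                                       pi0_method="fixed", fixed_lambda=0.5)
        assert res.n_conditioning >= 100
        assert res.pi1_given_1 >= 0.95
        # every null draw is far below the observed pi1
        assert res.empirical_p == pytest.approx(1 / 200)
        assert res.estimated_shared_count == round(
            res.pi1_given_1 * res.n_conditioning
        )
        assert len(res.null_pi1_samples) == 199
        assert res.pi1_given_0 < 0.3
        assert res.normal_approx_p < 0.01

    def test_pi1_matches_fixed_lambda_counting_formula(self, rng):
        # verify pi1|1 against the literal counting formula at lambda=0.5
        exp1, exp2, ids = enriched_pair(rng)
        res = conditional_overlap_test(
            exp1, exp2, fdr_level=0.1, n_resamples=0,
            pi0_method="fixed", fixed_lambda=0.5, seed=0,
        )
        cond = significant_ids(exp1, 0.1, "fixed", 0.5)
        p = exp2.p_values.loc[cond].to_numpy()
        pi0_hand = min(1.0, (p > 0.5).sum() / (p.size * 0.5))
        assert res.pi1_given_1 == pytest.approx(1 - pi0_hand)

    def test_no_signal_gives_unremarkable_p(self, rng):
        ids = [f"f{i:04d}" for i in range(800)]
        p1 = rng.uniform(size=800)
        p1[:60] = rng.uniform(0, 1e-8, 60)  # exp1 hits, exp2 exchangeable
        exp1 = DifferentialTable.from_arrays(ids, p1, name="exp1")
        exp2 = DifferentialTable.from_arrays(ids, rng.uniform(size=800),
                                             name="exp2")
        res = conditional_overlap_test(exp1, exp2, n_resamples=199, seed=1,
                                       pi0_method="fixed", fixed_lambda=0.5)
        assert res.empirical_p > 0.05
        assert res.pi1_given_1 < 0.35

    def test_empty_conditioning_set_errors(self, rng):
        exp1 = make_table(rng.uniform(0.3, 1.0, size=500), name="exp1")
        exp2 = make_table(rng.uniform(size=500), name="exp2")
        with pytest.raises(InfeasibleError, match="0.1"):
            conditional_overlap_test(exp1, exp2, fdr_level=0.1, seed=0)

    def test_universe_harmonized_with_warning(self, rng):
        exp1, exp2, ids = enriched_pair(rng)
        wider = DifferentialTable(
            pd.concat([
                exp2.data,
                pd.DataFrame({"p_value": [0.5]},
                             index=pd.Index(["extra"], name="feature_id")),
            ]),
            name="exp2",
        )
        with pytest.warns(UserWarning, match="dropped"):
            res = conditional_overlap_test(exp1, wider, n_resamples=19, seed=0)
        assert res.n_conditioning >= 100

    def test_skip_null_mode(self, rng):
        exp1, exp2, _ = enriched_pair(rng)
        res = conditional_overlap_test(exp1, exp2, n_resamples=0, seed=0)
        assert len(res.null_pi1_samples) == 0
        assert np.isnan(res.empirical_p)
        assert res.pi1_given_1 >= 0.95

    def test_seed_reproducibility(self, rng):
        exp1, exp2, _ = enriched_pair(rng)
        a = conditional_overlap_test(exp1, exp2, n_resamples=50, seed=9)
        b = conditional_overlap_test(exp1, exp2, n_resamples=50, seed=9)
        assert np.array_equal(a.null_pi1_samples, b.null_pi1_samples)
        assert a.empirical_p == b.empirical_p

    def test_shared_count_monotone_in_signal(self, rng):
        # shrinking conditioning-set p-values toward 0 never decreases
        # the estimated shared count (fixed-lambda estimator)
        ids = [f"f{i:04d}" for i in range(600)]
        p1 = rng.uniform(size=600)
        p1[:80] = rng.uniform(0, 1e-8, 80)
        exp1 = DifferentialTable.from_arrays(ids, p1, name="exp1")
        base_p2 = rng.uniform(size=600)
        counts = []
        for shrink in (1.0, 0.5, 0.1, 0.01):
            p2 = base_p2.copy()
            p2[:80] = base_p2[:80] * shrink
            exp2 = DifferentialTable.from_arrays(ids, p2, name="exp2")
            res = conditional_overlap_test(
                exp1, exp2, n_resamples=0, pi0_method="fixed",
                fixed_lambda=0.5, seed=0,
            )
            counts.append(res.estimated_shared_count)
        assert np.all(np.diff(counts) >= 0)


class TestIdentifySharedFeatures:
    def test_hand_computed_qvalues(self):
        ids = ["a", "b", "c", "d"]
        exp2 = make_table([0.001, 0.002, 0.9, 0.95], ids=ids, name="exp2")
        with pytest.warns(UserWarning, match="unstable"):
            shared = identify_shared_features(
                ids, exp2, fdr_level=0.1, pi0_method="fixed", fixed_lambda=0.5
            )
        # pi0 = #{p > 0.5} / (4 * 0.5) = 1.0; q = (0.004, 0.004, 0.95, 0.95)
        assert list(shared.feature_ids) == ["a", "b"]
        assert shared.qvalues == pytest.approx([0.004, 0.004])

    def test_all_large_pvalues_empty(self):
        ids = [f"g{i}" for i in range(10)]
        exp2 = make_table([0.99] * 9 + [0.98], ids=ids)
        with pytest.warns(UserWarning):
            shared = identify_shared_features(
                ids, exp2, fdr_level=0.1, pi0_method="fixed", fixed_lambda=0.5
            )
        assert len(shared) == 0

    def test_conditioning_on_everything_is_no_conditioning(self, rng):
        p = rng.uniform(size=500) ** 3
        ids = np.array([f"g{i:03d}" for i in range(500)])
        exp2 = DifferentialTable.from_arrays(ids, p, name="exp2")
        shared = identify_shared_features(ids, exp2, fdr_level=0.1,
                                          pi0_method="bootstrap", seed=4)
        est = estimate_pi0(p, method="bootstrap", seed=4)
        qt = compute_qvalues(p, est.pi0, alpha=0.1, feature_ids=ids)
        assert sorted(shared.feature_ids) == sorted(qt.significant_ids)

    def test_too_small_conditioning_set(self, uniform_table):
        with pytest.raises(InfeasibleError, match="too small"):
            identify_shared_features(["f00000"], uniform_table)

    def test_qvalues_below_fdr_level(self, rng):
        exp1, exp2, ids = enriched_pair(rng)
        shared = identify_shared_features(ids[:300], exp2, fdr_level=0.1,
                                          seed=0)
        assert np.all(shared.qvalues < 0.1)
        assert set(shared.feature_ids) <= set(ids[:300])


class TestFilterConcordant:
    def make_shared(self, ids):
        return SharedFeatureSet(
            feature_ids=np.asarray(ids),
            qvalues=np.full(len(ids), 0.01),
            direction_concordant=np.ones(len(ids), dtype=bool),
            source_experiments=("exp1", "exp2"),
        )

    def test_sign_rule(self):
        ids = ["a", "b"]
        ta = make_table([0.01, 0.01], lfc=[1.2, 1.2], ids=ids)
        tb = make_table([0.01, 0.01], lfc=[0.3, -0.3], ids=ids)
        out = filter_concordant(self.make_shared(ids), ta, tb)
        assert list(out.feature_ids) == ["a"]

    def test_zero_lfc_dropped_with_warning(self):
        ids = ["a"]
        ta = make_table([0.01], lfc=[0.0], ids=ids)
        tb = make_table([0.01], lfc=[0.5], ids=ids)
        with pytest.warns(UserWarning, match="zero log2 fold change"):
            out = filter_concordant(self.make_shared(ids), ta, tb)
        assert len(out) == 0

    def test_concordant_fraction(self, rng):
        ids = [f"x{i}" for i in range(10)]
        lfc_a = np.array([1, 1, 1, 1, 1, 1, 1, -1, -1, -1.0])
        lfc_b = np.array([1, 1, 1, 1, 1, -1, -1, -1, -1, 1.0])
        ta = make_table(np.full(10, 0.01), lfc=lfc_a, ids=ids)
        tb = make_table(np.full(10, 0.01), lfc=lfc_b, ids=ids)
        out = filter_concordant(self.make_shared(ids), ta, tb)
        assert len(out) == 7

    def test_missing_lfc_column_errors(self):
        ids = ["a"]
        ta = make_table([0.01], ids=ids)
        tb = make_table([0.01], lfc=[0.5], ids=ids)
        with pytest.raises(ValidationError, match="lfc"):
            filter_concordant(self.make_shared(ids), ta, tb)


class TestChainOverlap:
    def test_two_table_chain_equals_composition(self, rng):
        exp1, exp2, _ = enriched_pair(rng)
        seed = 42
        chain = chain_overlap([exp1, exp2], fdr_level=0.1, n_resamples=29,
                              seed=seed, concordance=True)
        assert chain.status == "complete"
        result, shared = chain.stages[0]

        # compose the three single-step operations on the same seed stream
        stream = np.random.default_rng(seed)
        h1, h2 = harmonize_universe(exp1, exp2)
        cond = significant_ids(h1, 0.1, "bootstrap",
                               seed=int(stream.integers(2**31)))
        res2 = overlap_test_with_conditioning(
            cond, h2, n_resamples=29, seed=int(stream.integers(2**31))
        )
        shared2 = identify_shared_features(
            cond, h2, fdr_level=0.1, seed=int(stream.integers(2**31)),
            source_experiments=("exp1", "exp2"),
        )
        shared2 = filter_concordant(shared2, h1, h2)
        assert result.pi1_given_1 == res2.pi1_given_1
        assert np.array_equal(result.null_pi1_samples, res2.null_pi1_samples)
        assert result.empirical_p == res2.empirical_p
        assert np.array_equal(shared.feature_ids, shared2.feature_ids)
        assert shared.qvalues == pytest.approx(shared2.qvalues)

    def test_chain_stops_on_empty_stage(self, rng):
        ids = [f"f{i:04d}" for i in range(600)]
        p1 = rng.uniform(size=600)
        p1[:40] = rng.uniform(0, 1e-9, 40)
        t1 = DifferentialTable.from_arrays(ids, p1,
                                           lfc=rng.normal(size=600), name="a")
        # experiment 2 carries no signal on the conditioning set
        t2 = DifferentialTable.from_arrays(
            ids, rng.uniform(0.3, 1.0, size=600),
            lfc=rng.normal(size=600), name="b")
        t3 = DifferentialTable.from_arrays(
            ids, rng.uniform(size=600), lfc=rng.normal(size=600), name="c")
        chain = chain_overlap([t1, t2, t3], n_resamples=0, seed=0,
                              pi0_method="fixed", fixed_lambda=0.5)
        assert chain.status == "stopped:stage2"
        assert len(chain.stages) == 1

    def test_three_way_chain_on_planted_signal(self, rng):
        m = 1200
        ids = np.array([f"f{i:05d}" for i in range(m)])
        shared_block = 150
        tables = []
        for name in ("a", "b", "c"):
            p = rng.uniform(size=m)
            p[:shared_block] = rng.uniform(0, 1e-7, shared_block)
            lfc = rng.normal(0, 0.3, m)
            lfc[:shared_block] = 1.0  # same direction everywhere
            tables.append(DifferentialTable.from_arrays(ids, p, lfc=lfc,
                                                        name=name))
        chain = chain_overlap(tables, n_resamples=19, seed=5)
        assert chain.status == "complete"
        assert len(chain.stages) == 2
        final = chain.stages[-1][1]
        recovered = set(final.feature_ids) & set(ids[:shared_block])
        assert len(recovered) >= 0.9 * shared_block
        assert chain.stages[-1][0].pi1_given_1 > 0.8

    def test_needs_two_tables(self, uniform_table):
        with pytest.raises(ValidationError, match="two tables"):
            chain_overlap([uniform_table])


class TestNaiveIntersection:
    def _table(self, rng, tiny_ids, m=400):
        ids = [f"f{i:04d}" for i in range(m)]
        p = rng.uniform(0.3, 1.0, size=m)
        for fid in tiny_ids:
            p[ids.index(fid)] = rng.uniform(0, 1e-9)
        return DifferentialTable.from_arrays(ids, p, name="t")

    def test_set_intersection(self, rng):
        t1 = self._table(rng, ["f0000", "f0001", "f0002"])  # {A,B,C}
        t2 = self._table(rng, ["f0001", "f0002", "f0003"])  # {B,C,D}
        count, ids = naive_intersection([t1, t2], fdr_level=0.1,
                                        pi0_method="fixed", fixed_lambda=0.5)
        assert count == 2
        assert set(ids) == {"f0001", "f0002"}

    def test_disjoint_sets(self, rng):
        t1 = self._table(rng, ["f0000", "f0001"])
        t2 = self._table(rng, ["f0005", "f0006"])
        count, ids = naive_intersection([t1, t2], fdr_level=0.1,
                                        pi0_method="fixed", fixed_lambda=0.5)
        assert count == 0 and len(ids) == 0
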