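"""Fixed/random pooling, Cochran's Q and the model-selection rule."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from genemeta import (
    ContrastModel,
    DegenerateDataError,
    EffectEstimate,
    FourfoldTable,
    PoolingMethod,
    SyntheticMetaConfig,
    ValidationError,
    apply_continuity,
    collapse,
    estimate_effect,
    heterogeneity,
    pool_auto,
    pool_fixed,
    pool_mh,
    pool_random,
    simulate_corpus,
)

MODEL = ContrastModel.RECESSIVE


def make_effect(log_or, variance, study_id="s", model=MODEL):
    z = 1.959964
    se = math.sqrt(variance)
    return EffectEstimate(
        study_id=study_id,
        model=model,
        log_or=log_or,
        variance=variance,
        or_value=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
    )


effects_st = st.lists(
    st.builds(
        make_effect,
        st.floats(-2, 2),
        st.floats(0.01, 2),
        study_id=st.uuids().map(str),
    ),
    min_size=2,
    max_size=10,
)


@pytest.fixture()
def recessive_effects(rs2808630):
    tables = [apply_continuity(collapse(s, MODEL)) for s in rs2808630]
    return [estimate_effect(t) for t in tables], tables


class TestPoolFixed:
    def test_five_study_oracle(self, recessive_effects):
        """Inverse-variance pooling, hand-computed on the corrected tables."""
        effects, _ = recessive_effects
        pooled = pool_fixed(effects)
        assert pooled.or_value == pytest.approx(0.865407, abs=1e-5)
        assert pooled.ci_low == pytest.approx(0.627346, abs=1e-5)
        assert pooled.ci_high == pytest.approx(1.193806, abs=1e-5)
        assert pooled.k == 5

    def test_single_effect_identity(self):
        e = make_effect(0.3, 0.04)
        pooled = pool_fixed([e])
        assert pooled.pooled_log_or == pytest.approx(e.log_or)
        assert pooled.se == pytest.approx(e.se)
        assert pooled.heterogeneity.p_value is None

    def test_replication_divides_variance(self):
        e = make_effect(0.3, 0.04)
        pooled = pool_fixed([dataclasses.replace(e, study_id=f"s{i}") for i in range(4)])
        assert pooled.pooled_log_or == pytest.approx(e.log_or)
        assert pooled.se**2 == pytest.approx(e.variance / 4)

    def test_empty_and_mixed_models_rejected(self):
        with pytest.raises(ValidationError):
            pool_fixed([])
        with pytest.raises(ValueError, match="contrast"):
            pool_fixed([make_effect(0, 0.1), make_effect(0, 0.1, model=ContrastModel.DOMINANT)])

    def test_matches_statsmodels(self, recessive_effects):
        from statsmodels.stats.meta_analysis import combine_effects

        effects, _ = recessive_effects
        res = combine_effects(
            np.array([e.log_or for e in effects]),
            np.array([e.variance for e in effects]),
            method_re="dl",
        )
        pooled = pool_fixed(effects)
        assert pooled.pooled_log_or == pytest.approx(float(res.mean_effect_fe))
        assert pooled.se == pytest.approx(float(res.sd_eff_w_fe))
        assert pooled.heterogeneity.q_statistic == pytest.approx(float(res.q))


class TestHeterogeneity:
    def test_five_study_oracle(self, recessive_effects):
        effects, _ = recessive_effects
        het = heterogeneity(effects)
        assert het.q_statistic == pytest.approx(1.587642, abs=1e-5)
        assert het.p_value == pytest.approx(0.811011, abs=1e-5)
        assert het.df == 4
        assert het.tau_squared == 0.0  # Q < df
        assert het.i_squared == 0.0

    def test_two_lung_studies_oracle(self, rs1417938):
        """Chi-square(1) survival at the hand-computed Q of the two lung arms."""
        lung = [s for s in rs1417938 if s.cancer_type == "Lung"]
        effects = [estimate_effect(apply_continuity(collapse(s, MODEL))) for s in lung]
        het = heterogeneity(effects)
        assert het.q_statistic == pytest.approx(0.371317, abs=1e-5)
        assert het.p_value == pytest.approx(0.542287, abs=1e-5)

    def test_identical_effects_have_no_dispersion(self):
        effects = [make_effect(0.2, 0.05, f"s{i}") for i in range(4)]
        het = heterogeneity(effects)
        assert het.q_statistic == pytest.approx(0.0, abs=1e-12)
        assert het.tau_squared == 0.0
        assert het.i_squared == 0.0

    @given(effects_st)
    def test_q_nonnegative_and_order_invariant(self, effects):
        effects = [
            dataclasses.replace(e, study_id=f"s{i}") for i, e in enumerate(effects)
        ]
        het = heterogeneity(effects)
        assert het.q_statistic >= 0
        assert 0 <= het.i_squared < 1
        reversed_het = heterogeneity(effects[::-1])
        assert reversed_het.q_statistic == pytest.approx(het.q_statistic)


class TestPoolRandom:
    def test_collapses_to_fixed_when_tau_zero(self, recessive_effects):
        effects, _ = recessive_effects
        fixed, random = pool_fixed(effects), pool_random(effects)
        assert random.heterogeneity.tau_squared == 0.0
        assert random.pooled_log_or == pytest.approx(fixed.pooled_log_or)
        assert random.se == pytest.approx(fixed.se)
        assert random.method is PoolingMethod.RANDOM_DL

    def test_symmetric_effects_pool_to_null(self):
        effects = [make_effect(1.0, 0.05, "s1"), make_effect(-1.0, 0.05, "s2")]
        assert pool_random(effects).pooled_log_or == pytest.approx(0.0)

    def test_wider_ci_under_heterogeneity(self):
        corpus = simulate_corpus(
            SyntheticMetaConfig(
                k=12, n_cases=1500, n_controls=1500, p=0.3,
                psi_hom=1.5, tau=0.5, seed=7,
            )
        )
        effects = [estimate_effect(apply_continuity(collapse(s, MODEL))) for s in corpus]
        fixed, random = pool_fixed(effects), pool_random(effects)
        assert random.heterogeneity.tau_squared > 0
        assert random.se > fixed.se
        assert (random.ci_high - random.ci_low) > (fixed.ci_high - fixed.ci_low)

    def test_matches_statsmodels_dl(self):
        from statsmodels.stats.meta_analysis import combine_effects

        effects = [
            make_effect(lo, v, f"s{i}")
            for i, (lo, v) in enumerate([(0.8, 0.03), (-0.4, 0.06), (0.1, 0.02), (0.9, 0.1)])
        ]
        res = combine_effects(
            np.array([e.log_or for e in effects]),
            np.array([e.variance for e in effects]),
            method_re="dl",
        )
        assert float(res.tau2) > 0  # heterogeneous by construction
        pooled = pool_random(effects)
        assert pooled.heterogeneity.tau_squared == pytest.approx(float(res.tau2))
        assert pooled.pooled_log_or == pytest.approx(float(res.mean_effect_re))
        assert pooled.se == pytest.approx(float(res.sd_eff_w_re))


class TestPoolMH:
    def test_single_table_identity(self):
        t = FourfoldTable(19, 180, 34, 328, MODEL, "s")
        pooled = pool_mh([t])
        assert pooled.or_value == pytest.approx(19 * 328 / (180 * 34))

    def test_five_study_oracle_uncorrected(self, rs2808630):
        """MH needs no zero-cell correction; hand-computed cross-product sums."""
        tables = [collapse(s, MODEL) for s in rs2808630]
        pooled = pool_mh(tables)
        assert pooled.or_value == pytest.approx(0.849810, abs=1e-5)
        assert pooled.method is PoolingMethod.FIXED_MH

    def test_five_study_oracle_corrected(self, rs2808630):
        tables = [collapse(s, MODEL) for s in rs2808630]
        pooled = pool_mh(tables, continuity_increment=0.5)
        assert pooled.or_value == pytest.approx(0.858825, abs=1e-5)
        assert pooled.ci_low == pytest.approx(0.622339, abs=1e-5)
        assert pooled.ci_high == pytest.approx(1.185176, abs=1e-5)

    def test_homogeneous_null_tables(self):
        tables = [FourfoldTable(10, 10, 10, 10, MODEL, f"s{i}") for i in range(3)]
        assert pool_mh(tables).or_value == pytest.approx(1.0)

    def test_degenerate_cross_products(self):
        tables = [FourfoldTable(0, 5, 0, 5, MODEL, "s")]
        with pytest.raises(DegenerateDataError):
            pool_mh(tables)

    def test_matches_statsmodels_stratified(self, rs2808630):
        from statsmodels.stats.contingency_tables import StratifiedTable

        tables = [collapse(s, MODEL) for s in rs2808630]
        sm = StratifiedTable(
            [np.array([[t.a, t.b], [t.c, t.d]]) for t in tables]
        )
        pooled = pool_mh(tables)
        assert pooled.or_value == pytest.approx(float(sm.oddsratio_pooled))
        assert pooled.se == pytest.approx(float(sm.logodds_pooled_se))


class TestPoolAuto:
    def test_homogeneous_fixture_selects_fixed(self, recessive_effects):
        effects, tables = recessive_effects
        assert pool_auto(effects).method is PoolingMethod.FIXED_IV
        assert pool_auto(effects, tables=tables).method is PoolingMethod.FIXED_MH

    def test_heterogeneous_selects_random(self):
        effects = [make_effect(1.5, 0.01, "s1"), make_effect(-1.5, 0.01, "s2")]
        pooled = pool_auto(effects)
        assert pooled.heterogeneity.p_value < 0.05
        assert pooled.method is PoolingMethod.RANDOM_DL

    def test_single_study_is_fixed(self):
        assert pool_auto([make_effect(0.2, 0.1)]).method is PoolingMethod.FIXED_IV


@given(effects_st)
def test_pooled_estimate_in_convex_hull(effects):
    effects = [dataclasses.replace(e, study_id=f"s{i}") for i, e in enumerate(effects)]
    lo = min(e.log_or for e in effects)
    hi = max(e.log_or for e in effects)
    for pooled in (pool_fixed(effects), pool_random(effects)):
        assert lo - 1e-9 <= pooled.pooled_log_or <= hi + 1e-9
    assert pool_random(effects).se >= pool_fixed(effects).se - 1e-12


def test_mh_and_iv_agree_on_large_balanced_tables():
    rng = np.random.default_rng(11)
    tables = []
    for i in range(6):
        n = 100_000
        p_exp = rng.uniform(0.2, 0.4)
        a = rng.binomial(n, p_exp * 1.2 / (1 + p_exp * 0.2))
        c = rng.binomial(n, p_exp)
        tables.append(FourfoldTable(a, n - a, c, n - c, MODEL, f"s{i}"))
    effects = [estimate_effect(t) for t in tables]
    delta = abs(pool_mh(tables).pooled_log_or - pool_fixed(effects).pooled_log_or)
    assert delta < 0.01
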