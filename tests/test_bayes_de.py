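import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mirualb as m
from mirualb.bayes_de import MCMCSpec, PriorSpec, records_to_frame
from mirualb.qpcr_io import CqMatrix

from .conftest import sample_frame


def _matrix_with_detection(fracs, n_samples=27, seed=0):
    """One species per requested detection fraction."""
    rng = np.random.default_rng(seed)
    species = [f"s{i}" for i in range(len(fracs))]
    det = np.zeros((len(fracs), n_samples), dtype=bool)
    for i, f in enumerate(fracs):
        k = int(round(f * n_samples))
        det[i, :k] = True
    cq = np.where(det, 25 + rng.random(det.shape), 40.0)
    return CqMatrix(species, [f"c{j}" for j in range(n_samples)], cq, det)


class TestRouting:
    def test_above_threshold_is_continuous(self):
        cq = _matrix_with_detection([19 / 27])  # 70.4% > 65%
        assert m.route_species(cq)["continuous"] == ["s0"]

    def test_below_threshold_is_detection(self):
        cq = _matrix_with_detection([17 / 27])  # 63.0%
        assert m.route_species(cq)["detection"] == ["s0"]

    def test_exact_threshold_goes_to_detection(self):
        cq = _matrix_with_detection([13 / 20], n_samples=20)  # exactly 65%
        assert m.route_species(cq)["detection"] == ["s0"]

    def test_threshold_domain(self):
        cq = _matrix_with_detection([0.5])
        with pytest.raises(ValueError):
            m.route_species(cq, threshold=1.0)


def _balanced_labels(n_per_arm):
    groups = ["MA"] * n_per_arm + ["N"] * n_per_arm
    sex = (["F", "M"] * n_per_arm)[: 2 * n_per_arm]
    return np.array(groups), np.array(sex)


class TestContinuousBranch:
    def test_recovers_planted_two_cycle_effect(self):
        rng = np.random.default_rng(42)
        groups, sex = _balanced_labels(30)
        y = rng.normal(28.0, 0.5, 60) - 2.0 * (groups == "MA")
        draws = m.fit_continuous(y, groups, sex, rng=np.random.default_rng(1))
        assert np.median(draws["effect"]) == pytest.approx(-2.0, abs=0.3)

    def test_null_data_gives_por_near_one(self):
        groups, sex = _balanced_labels(10)
        y = np.tile([28.0, 28.5, 29.0, 28.2], 5)
        draws = m.fit_continuous(y, groups, sex, rng=np.random.default_rng(2))
        por, _, _ = m.posterior_odds(draws["effect"])
        assert abs(np.median(draws["effect"])) < 0.5
        assert por < 3

    def test_location_shift_moves_intercept_not_effect(self):
        rng = np.random.default_rng(3)
        groups, sex = _balanced_labels(15)
        y = rng.normal(28, 0.5, 30) - 1.5 * (groups == "MA")
        d1 = m.fit_continuous(y, groups, sex, rng=np.random.default_rng(4))
        d2 = m.fit_continuous(y + 10, groups, sex, rng=np.random.default_rng(4))
        assert np.median(d2["intercept"]) - np.median(d1["intercept"]) == \
            pytest.approx(10.0, abs=0.3)
        assert np.median(d2["effect"]) == pytest.approx(np.median(d1["effect"]),
                                                        abs=0.1)

    def test_confounded_design_rejected(self):
        groups = np.array(["MA"] * 5 + ["N"] * 5)
        sex = np.where(groups == "MA", "F", "M")  # sex == group
        y = np.arange(10.0)
        with pytest.raises(ValueError, match="confounded"):
            m.fit_continuous(y, groups, sex)

    def test_posterior_matches_ols_oracle(self):
        # flat-prior posterior median must agree with the frequentist
        # sex-adjusted point estimate within Monte-Carlo error
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        groups, sex = _balanced_labels(20)
        y = rng.normal(30, 1.0, 40) - 1.0 * (groups == "MA") + 0.5 * (sex == "F")
        X = sm.add_constant(
            np.column_stack([(groups == "MA").astype(float),
                             (sex == "F").astype(float)])
        )
        ols = sm.OLS(y, X).fit()
        draws = m.fit_continuous(y, groups, sex, rng=np.random.default_rng(10))
        assert np.median(draws["effect"]) == pytest.approx(ols.params[1], abs=0.1)


class TestDetectionBranch:
    def test_strong_detection_difference_gives_large_or(self):
        detected = [True] * 9 + [False] + [True] + [False] * 9
        groups = np.array(["MA"] * 10 + ["N"] * 10)
        sex = np.array(["F", "M"] * 10)
        res = m.fit_detection(detected, groups, sex,
                              rng=np.random.default_rng(0))
        med = float(np.exp(np.median(res["log_or"])))
        assert med > 10
        # conjugate beta oracle on the unadjusted 2x2 (uniform priors)
        rng = np.random.default_rng(1)
        p_ma = rng.beta(10, 2, 20000)
        p_n = rng.beta(2, 10, 20000)
        oracle = np.median(p_ma / (1 - p_ma) * (1 - p_n) / p_n)
        assert med == pytest.approx(oracle, rel=0.8)

    def test_equal_rates_give_or_near_one(self):
        detected = ([True] * 5 + [False] * 5) * 2
        groups = np.array(["MA"] * 10 + ["N"] * 10)
        sex = np.array(["F", "M"] * 10)
        res = m.fit_detection(detected, groups, sex,
                              rng=np.random.default_rng(2))
        assert float(np.exp(np.median(res["log_or"]))) == pytest.approx(1.0, rel=0.6)

    def test_fully_detected_species_rejected(self):
        groups = np.array(["MA"] * 5 + ["N"] * 5)
        sex = np.array(["F", "M"] * 5)
        with pytest.raises(ValueError, match="continuous"):
            m.fit_detection([True] * 10, groups, sex)

    def test_complete_separation_flagged_not_fatal(self):
        detected = [True] * 10 + [False] * 10
        groups = np.array(["MA"] * 10 + ["N"] * 10)
        sex = np.array(["F", "M"] * 10)
        res = m.fit_detection(detected, groups, sex,
                              rng=np.random.default_rng(3))
        assert any(f.startswith("separation") for f in res["flags"])
        assert np.isfinite(res["log_or"]).all()


class TestPosteriorOdds:
    def test_symmetric_draws_por_near_one(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal(10000)
        por, _, degen = m.posterior_odds(draws)
        assert por < 1.3 and not degen

    def test_127_of_128_mass(self):
        # uncorrected one-sided mass 127/128 -> odds about 127
        draws = np.concatenate([np.ones(127000), -np.ones(1000)])
        por, direction, _ = m.posterior_odds(draws)
        assert direction == "up"
        assert por == pytest.approx(127000.5 / 1000.5, rel=1e-12)
        assert por == pytest.approx(127, rel=0.01)

    def test_all_draws_one_sided_gives_corrected_cap(self):
        draws = -np.abs(np.random.default_rng(1).standard_normal(4000)) - 0.1
        por, direction, _ = m.posterior_odds(draws)
        assert direction == "down"
        assert por == pytest.approx(4000.5 / 0.5, rel=1e-12)  # 8001
        assert m.classify_evidence(por) == "very_strong"

    def test_degenerate_all_zero(self):
        por, direction, degen = m.posterior_odds(np.zeros(2000))
        assert (por, direction, degen) == (1.0, "up", True)

    def test_needs_1000_draws(self):
        with pytest.raises(ValueError):
            m.posterior_odds(np.ones(999))

    @settings(max_examples=30, derandomize=True)
    @given(st.floats(0.001, 1000), st.integers(0, 2**31 - 1))
    def test_invariant_to_positive_rescaling(self, scale, seed):
        draws = np.random.default_rng(seed).standard_normal(2000) + 0.3
        p1 = m.posterior_odds(draws)
        p2 = m.posterior_odds(draws * scale)
        assert p1 == p2


class TestClassifyEvidence:
    @pytest.mark.parametrize(
        "por, cat",
        [
            (1.0, "bare_mention"),
            (2.999, "bare_mention"),
            (3.0, "positive"),
            (13.6, "positive"),  # printed example: positive evidence
            (20.0, "strong"),
            (126.0, "strong"),  # printed example: strong evidence
            (150.0, "strong"),  # boundary closed on the strong side
            (150.0001, "very_strong"),
            (8001.0, "very_strong"),
        ],
    )
    def test_cutpoints(self, por, cat):
        assert m.classify_evidence(por) == cat

    def test_sub_unit_por_rejected(self):
        with pytest.raises(ValueError):
            m.classify_evidence(0.5)

    @settings(max_examples=60, derandomize=True)
    @given(st.floats(1, 1e5), st.floats(1, 1e5))
    def test_monotone_in_por(self, a, b):
        from mirualb.bayes_de import CATEGORY_ORDER

        lo, hi = sorted([a, b])
        assert CATEGORY_ORDER.index(m.classify_evidence(lo)) <= \
            CATEGORY_ORDER.index(m.classify_evidence(hi))


@pytest.fixture(scope="module")
def planted_panel():
    cfg = m.SynthConfig(seed=0, n_species=100)
    planted = [cfg.species_name(i) for i in range(0, 100, 10)]
    shifts = [-2.0 if k % 2 == 0 else 2.0 for k in range(10)]
    cfg = m.plant_signature(cfg, planted, shifts)
    cq, samples, _ = m.generate(cfg)
    records = m.run_de(cq, samples, cfg.reference_panel(), seed=0)
    return planted, records


class TestRunDE:
    def test_planted_effects_reach_strong_evidence(self, planted_panel):
        planted, records = planted_panel
        by = {r.species: r for r in records}
        strong = [s for s in planted if by[s].category in ("strong", "very_strong")]
        assert len(strong) >= 8

    def test_null_species_rarely_reach_strong(self, planted_panel):
        # null |t| calibration: ~7.6% of nulls land at POR >= 20 by chance
        # (df=24), i.e. about 7 of 90; assert a generous binomial bound
        planted, records = planted_panel
        nulls = [r for r in records if r.species not in planted]
        n_strong = sum(r.category in ("strong", "very_strong") for r in nulls)
        assert n_strong <= 15

    def test_planted_direction_matches_shift_sign(self, planted_panel):
        planted, records = planted_panel
        by = {r.species: r for r in records}
        # negative Cq shift = higher concentration in MA = direction up
        for k, sp in enumerate(planted):
            if by[sp].category in ("strong", "very_strong"):
                assert by[sp].direction == ("up" if k % 2 == 0 else "down")

    def test_sex_contrast_null_calibration(self):
        # directional posterior odds cross 150 on null data with chance
        # ~2*(1 - F_t24(2.675)) = 1.3%; assert the empirical rate over
        # three generator seeds stays within 4x of that calibration
        hits = total = 0
        for seed in (0, 1, 2):
            cfg = m.SynthConfig(seed=seed, n_species=40)
            cq, samples, _ = m.generate(cfg)
            records = m.run_de(cq, samples, cfg.reference_panel(),
                               contrast="F_vs_M", seed=seed)
            hits += sum(r.category == "very_strong" for r in records)
            total += len(records)
        assert hits / total <= 0.05

    def test_same_seed_reproduces_records(self):
        # high baseline forces both branches to run, including the MCMC one
        cfg = m.SynthConfig(seed=8, n_species=12, baseline_mean=38.0,
                            baseline_sd=2.0)
        cq, samples, _ = m.generate(cfg)
        panel = cfg.reference_panel()
        r1 = m.run_de(cq, samples, panel, seed=99)
        r2 = m.run_de(cq, samples, panel, seed=99)
        assert records_to_frame(r1).equals(records_to_frame(r2))
        branches = {r.branch for r in r1}
        assert branches == {"continuous", "detection"}

    def test_per_species_failures_flagged_not_fatal(self):
        cfg = m.SynthConfig(seed=2, n_species=6)
        cq, samples, _ = m.generate(cfg)
        # blank out one species entirely: no detected samples at all
        i = cq.species_index(cfg.species_name(0))
        cq.detected[i, :] = False
        cq.impute_nondetects()
        records = m.run_de(cq, samples, cfg.reference_panel(), seed=2)
        rec = {r.species: r for r in records}[cfg.species_name(0)]
        assert any(f.startswith("error:") for f in rec.flags)
        assert len(records) == 6


def test_prior_spec_validation():
    with pytest.raises(ValueError):
        PriorSpec(delta_cq_bound=-1.0)
    with pytest.raises(ValueError):
        MCMCSpec(draws=500)


def test_model_results_interface(small_cohort):
    cfg, cq, samples, _ = small_cohort
    res = m.DifferentialExpression(cq, samples, cfg.reference_panel()).fit(seed=3)
    df = res.summary()
    assert list(df["por"]) == sorted(df["por"], reverse=True)
    assert set(res.category_counts().index) == set(
        ("bare_mention", "positive", "strong", "very_strong")
    )
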