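import math
from itertools import product

import numpy as np
import pytest
from scipy.stats import hypergeom, norm

import linesag as ls
from conftest import score_map_from_values


GRID = ls.full_grid()


def flat_maps(values_per_subject):
    return [
        score_map_from_values(f"s{i}", {loc: v for loc, v in zip(GRID, vals)})
        for i, vals in enumerate(values_per_subject)
    ]


# ------------------------------------------------------------- oracles
def mcnemar_exact_enumeration(b, c):
    """Two-sided exact McNemar p by enumerating all 2^(b+c) discordance
    assignments: total probability of outcomes no more likely than (b, c)."""
    n = b + c
    p_obs = math.comb(n, b) / 2**n
    return sum(
        math.comb(n, k) / 2**n for k in range(n + 1) if math.comb(n, k) <= math.comb(n, b)
    )


def fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration over all tables
    with the observed margins."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = hypergeom.pmf(k, n, col1, row1)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


# ------------------------------------------------------------ normative
class TestNormative:
    def test_two_point_sample_mean_and_sd(self):
        maps = flat_maps([[0.0] * 24, [2.0] * 24])
        model = ls.fit_normative(maps)
        loc = GRID[0]
        assert model.mean_arcmin[loc] == pytest.approx(1.0)
        assert model.sd_arcmin[loc] == pytest.approx(math.sqrt(2.0))

    def test_identical_cohorts_give_identical_models(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 3, size=(5, 24))
        m1 = ls.fit_normative(flat_maps(vals))
        m2 = ls.fit_normative(flat_maps(vals))
        assert m1 == m2

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ls.fit_normative(flat_maps([[1.0] * 24]))
        with pytest.raises(ValueError):
            ls.fit_normative(flat_maps([[1.0] * 24, [1.0] * 24]))  # zero variance

    def test_simulated_normal_cohort_means_near_zero(self):
        # 12 observers at sigma=4, lapse=0.02: per-location normative means
        # within 1 arcmin of zero
        spec = ls.CohortSpec(n_subjects=12, kind="normal", seed=1)
        observers, manifest = ls.generate_cohort(spec)
        maps = [
            ls.run_session(
                obs,
                ls.ProtocolConfig(master_seed=seed),
                subject_id=sid,
                keep_traces=False,
            )
            for obs, seed, sid in zip(
                observers, manifest["subject_seeds"], manifest["subject_ids"]
            )
        ]
        model = ls.fit_normative(maps)
        for loc in GRID:
            assert abs(model.mean_arcmin[loc]) < 2.0


class TestCoverage:
    def test_detection_band_covers_9979_percent(self):
        assert round(100 * ls.coverage_of_z(3.08), 2) == 99.79

    def test_trivial_and_tabled_values(self):
        assert ls.coverage_of_z(0.0) == 0.0
        assert ls.coverage_of_z(1.959964) == pytest.approx(0.95, abs=1e-6)


class TestFlagging:
    def test_scores_at_normative_mean_are_negative(self):
        maps = flat_maps(np.random.default_rng(0).normal(0, 2, size=(6, 24)))
        model = ls.fit_normative(maps)
        at_mean = score_map_from_values("probe", dict(model.mean_arcmin))
        result = ls.flag_subject(at_mean, model)
        assert not result.positive
        assert result.flagged_locations == ()
        assert all(z == pytest.approx(0.0) for z in result.z_scores.values())

    def test_single_crossing_flags_exactly_that_location(self):
        maps = flat_maps(np.random.default_rng(1).normal(0, 2, size=(6, 24)))
        model = ls.fit_normative(maps)
        values = dict(model.mean_arcmin)
        target = GRID[5]
        values[target] = model.mean_arcmin[target] + 3.5 * model.sd_arcmin[target]
        result = ls.flag_subject(score_map_from_values("probe", values), model)
        assert result.positive
        assert result.flagged_locations == (target,)
        assert target in result.display_flagged_locations

    def test_per_location_false_flag_rate_matches_z_band(self):
        # scores drawn from the normative model itself: flag probability
        # 2*(1 - Phi(3.08)) within 3 binomial SE over 1e5 draws
        maps = flat_maps(np.random.default_rng(2).normal(1, 3, size=(8, 24)))
        model = ls.fit_normative(maps)
        loc = GRID[0]
        rng = np.random.default_rng(42)
        draws = rng.normal(model.mean_arcmin[loc], model.sd_arcmin[loc], size=100_000)
        z = model.z_score(loc, draws)
        rate = np.mean(np.abs(z) > model.z_detect)
        p = 2 * (1 - norm.cdf(3.08))
        assert abs(rate - p) < 3 * np.sqrt(p * (1 - p) / draws.size)

    def test_leave_one_out_subject_false_positive_rate(self):
        # 500 subjects with iid normal scores, each flagged against the
        # other 499: subject-level positive rate near 1 - 0.9979**24
        rng = np.random.default_rng(7)
        scores = rng.normal(0.0, 3.0, size=(500, 24))
        maps = flat_maps(scores)
        positives = 0
        for i in range(500):
            others = maps[:i] + maps[i + 1 :]
            model = ls.fit_normative(others)
            positives += ls.flag_subject(maps[i], model).positive
        expected = 1 - ls.coverage_of_z(3.08) ** 24
        rate = positives / 500
        se = np.sqrt(expected * (1 - expected) / 500)
        assert abs(rate - expected) < 3 * se


class TestHitRate:
    @pytest.mark.parametrize("k,n,percent", [(14, 21, 67), (3, 21, 14), (0, 5, 0)])
    def test_whole_number_percentages(self, k, n, percent):
        hr = ls.hit_rate([True] * k + [False] * (n - k))
        assert hr.fraction == pytest.approx(k / n)
        assert hr.percent == percent

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            ls.hit_rate([])


class TestMcNemar:
    def test_table3_corrected_rounds_to_0003(self):
        chi2, p = ls.mcnemar_test(ls.Agreement2x2(3, 11, 0, 7))
        assert chi2 == pytest.approx(100 / 11)
        assert round(p, 3) == 0.003

    def test_table3_exact_binomial(self):
        _, p = ls.mcnemar_test(ls.Agreement2x2(3, 11, 0, 7), method="exact")
        assert p == pytest.approx(2 * 0.5**11)

    def test_symmetric_discordance(self):
        _, p = ls.mcnemar_test(ls.Agreement2x2(0, 5, 5, 0), method="exact")
        assert p == pytest.approx(1.0)
        chi2, _ = ls.mcnemar_test(ls.Agreement2x2(0, 5, 5, 0))
        assert chi2 <= 1 / 10

    def test_no_discordance_degenerate(self):
        with pytest.warns(UserWarning):
            stat, p = ls.mcnemar_test(ls.Agreement2x2(4, 0, 0, 6))
        assert (stat, p) == (0.0, 1.0)

    def test_exact_matches_enumeration_for_all_small_tables(self):
        for n in range(1, 13):
            for b in range(n + 1):
                c = n - b
                _, p = ls.mcnemar_test(ls.Agreement2x2(0, b, c, 0), method="exact")
                assert p == pytest.approx(mcnemar_exact_enumeration(b, c)), (b, c)


class TestFisher:
    def test_known_tables(self):
        assert ls.fisher_exact_test([[0, 4], [0, 6]]) == pytest.approx(1.0)
        assert ls.fisher_exact_test([[5, 0], [0, 5]]) == pytest.approx(
            2 / math.comb(10, 5)
        )
        assert ls.fisher_exact_test([[2, 1], [1, 2]]) == pytest.approx(1.0)

    def test_accepts_agreement_table(self):
        t = ls.Agreement2x2(5, 0, 0, 5)
        assert ls.fisher_exact_test(t) == ls.fisher_exact_test([[5, 0], [0, 5]])

    def test_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(0)
        tables = [tuple(rng.integers(0, 11, size=4)) for _ in range(150)]
        tables += [(3, 11, 0, 7), (14, 7, 3, 18), (0, 20, 20, 0)]
        for a, b, c, d in tables:
            if a + b + c + d == 0 or a + b + c + d > 40:
                continue
            got = ls.fisher_exact_test([[a, b], [c, d]])
            want = fisher_enumeration(a, b, c, d)
            assert got == pytest.approx(want, abs=1e-10), (a, b, c, d)


class TestRepeatability:
    def test_identical_runs_have_zero_rc(self):
        r = ls.bland_altman_repeatability([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.s_w_arcmin == 0.0
        assert r.rc_deg == 0.0

    def test_printed_run_difference_sds_reproduce_rc(self):
        # S_w of 5.016 / 5.226 arcmin -> RC 0.23 / 0.24 degrees
        for s_w, rc in [(5.016, 0.23), (5.226, 0.24)]:
            r = ls.RepeatabilityResult(n_pairs=100, mean_diff_arcmin=0.2, s_w_arcmin=s_w)
            assert round(r.rc_deg, 2) == rc
            assert r.rc_deg / r.s_w_deg == pytest.approx(2.77)

    def test_pair_order_flips_mean_but_not_rc(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=50), rng.normal(size=50)
        fwd = ls.bland_altman_repeatability(a, b)
        rev = ls.bland_altman_repeatability(b, a)
        assert fwd.mean_diff_arcmin == pytest.approx(-rev.mean_diff_arcmin)
        assert fwd.rc_deg == pytest.approx(rev.rc_deg)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            ls.bland_altman_repeatability([1.0], [2.0])
        with pytest.raises(ValueError):
            ls.bland_altman_repeatability([1.0, 2.0], [1.0])


class TestHedgesG:
    def test_identical_groups_zero(self):
        assert ls.hedges_g([1, 2, 3], [1, 2, 3]) == 0.0

    def test_small_sample_correction(self):
        # m1-m2 = -1, pooled SD = sqrt(1/2), J = 1 - 3/7
        d = -1.0 / math.sqrt(0.5)
        assert ls.hedges_g([0, 1], [1, 2]) == pytest.approx(d * (1 - 3 / 7))

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 15), rng.normal(0.8, 1.2, 11)
        assert ls.hedges_g(a, b) == pytest.approx(
            float(pg.compute_effsize(a, b, eftype="hedges"))
        )

    def test_correction_shrinks_towards_zero(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        g = ls.hedges_g(a, b)
        d = (a.mean() - b.mean()) / math.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
            / (len(a) + len(b) - 2)
        )
        assert abs(g) < abs(d)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            ls.hedges_g([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            ls.hedges_g([1.0, 1.0], [1.0, 1.0])


class TestRankSum:
    def test_exact_small_sample_by_enumeration(self):
        # complete separation of 3 vs 3: two-sided p = 2/C(6,3) * 1 = 0.1
        assert ls.compare_cohort_scores([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_identical_constant_groups(self):
        assert ls.compare_cohort_scores([5, 5, 5], [5, 5]) == 1.0

    def test_shift_invariance(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 10)
        assert ls.compare_cohort_scores(a, b) == pytest.approx(
            ls.compare_cohort_scores(a + 100, b + 100)
        )
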