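import math
import subprocess

import numpy as np
import pytest
from scipy import stats

from tshmeta.effect_measures import Estimate, log_rom
from tshmeta.pooling import (
    compare_two_pooled,
    i_squared,
    leave_one_out,
    pool_dl,
    pool_fixed,
    subgroup_pool,
)
from tshmeta.study_io import StudyRecord

from ._oracles import dl_oracle
from .conftest import make_estimates


class TestISquared:
    def test_direct_formula(self):
        assert i_squared(10, 5) == pytest.approx(0.5)
        assert i_squared(200, 55) == pytest.approx(0.725)

    def test_truncation_at_zero(self):
        assert i_squared(3, 5) == 0.0
        assert i_squared(0, 5) == 0.0

    def test_monotone_in_q(self):
        vals = [i_squared(q, 5) for q in (6, 10, 50, 500)]
        assert vals == sorted(vals)
        assert all(0 <= v < 1 for v in vals)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            i_squared(-1, 5)
        with pytest.raises(ValueError):
            i_squared(10, 0)


class TestPoolFixed:
    def test_single_study(self):
        (e,) = make_estimates([0.3], [0.04])
        res = pool_fixed([e])
        assert res.y_pooled == e.y
        assert res.se_pooled == pytest.approx(0.2)
        assert res.Q == 0.0

    def test_two_equal_weight_studies(self):
        res = pool_fixed(make_estimates([0.0, 1.0], [1.0, 1.0]))
        assert res.y_pooled == pytest.approx(0.5)
        assert res.Q == pytest.approx(0.5)

    def test_identical_studies_no_heterogeneity(self):
        res = pool_fixed(make_estimates([0.4] * 5, [0.02] * 5))
        assert res.y_pooled == pytest.approx(0.4)
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.i_squared == 0.0

    def test_pooled_within_range_and_weights_proportional(self, toy_estimates):
        res = pool_fixed(toy_estimates)
        ys = [e.y for e in toy_estimates]
        assert min(ys) <= res.y_pooled <= max(ys)
        w = np.array([1 / e.v for e in toy_estimates])
        expected = w / w.sum()
        got = np.array([res.weights[e.study_id] for e in toy_estimates])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_fixed([])


class TestPoolDL:
    def test_two_studies_truncated_tau(self):
        """Q = 0.5 <= df = 1 so tau2 truncates to 0 and DL equals fixed."""
        ests = make_estimates([0.0, 1.0], [1.0, 1.0])
        res = pool_dl(ests)
        fixed = pool_fixed(ests)
        assert res.tau_squared == 0.0
        assert res.y_pooled == pytest.approx(fixed.y_pooled)
        assert res.se_pooled == pytest.approx(fixed.se_pooled)

    def test_oracle_equivalence_on_toy_set(self, toy_estimates):
        res = pool_dl(toy_estimates)
        o = dl_oracle([e.y for e in toy_estimates], [e.v for e in toy_estimates])
        assert res.Q == pytest.approx(o["Q"], abs=1e-10)
        assert res.tau_squared == pytest.approx(o["tau2"], abs=1e-10)
        assert res.y_pooled == pytest.approx(o["y_random"], abs=1e-10)
        assert res.se_pooled == pytest.approx(o["se_random"], abs=1e-10)
        got_w = [res.weights[e.study_id] for e in toy_estimates]
        assert got_w == pytest.approx(o["weights_random"], abs=1e-10)

    def test_oracle_equivalence_on_random_sets(self, rng):
        for _ in range(25):
            k = int(rng.integers(2, 7))
            y = rng.normal(0.3, 0.6, size=k)
            v = rng.uniform(0.005, 0.3, size=k)
            res = pool_dl(make_estimates(y, v))
            o = dl_oracle(list(y), list(v))
            assert res.y_pooled == pytest.approx(o["y_random"], abs=1e-10)
            assert res.tau_squared == pytest.approx(o["tau2"], abs=1e-10)
            assert res.se_pooled == pytest.approx(o["se_random"], abs=1e-10)

    def test_ci_is_symmetric_on_log_scale_and_back_transformed(self, toy_estimates):
        res = pool_dl(toy_estimates)
        z = stats.norm.ppf(0.975)
        assert res.ci_low == pytest.approx(math.exp(res.y_pooled - z * res.se_pooled))
        assert res.ci_high == pytest.approx(math.exp(res.y_pooled + z * res.se_pooled))
        assert res.ci_low < res.effect < res.ci_high

    def test_random_se_at_least_fixed_se(self, toy_estimates):
        assert pool_dl(toy_estimates).se_pooled >= pool_fixed(toy_estimates).se_pooled

    def test_weights_sum_to_one(self, toy_estimates):
        assert sum(pool_dl(toy_estimates).weights.values()) == pytest.approx(1.0, abs=1e-12)

    def test_huge_heterogeneity_approaches_equal_weights(self):
        """When tau2 dwarfs every v_i the random weights flatten to 1/k."""
        res = pool_dl(make_estimates([0.0, 5.0, 10.0, 15.0], [1e-6, 2e-6, 1e-6, 3e-6]))
        assert res.tau_squared > 1.0
        for w in res.weights.values():
            assert w == pytest.approx(0.25, rel=1e-4)

    def test_single_study_contract(self):
        res = pool_dl(make_estimates([0.7], [0.09]))
        assert res.tau_squared == 0.0
        assert res.y_pooled == 0.7
        assert res.k == 1

    def test_p_q_from_chi_square(self, toy_estimates):
        res = pool_dl(toy_estimates)
        assert res.p_q == pytest.approx(stats.chi2.sf(res.Q, res.df), rel=1e-12)

    def test_mixed_measures_rejected(self):
        a = Estimate("a", 0.2, 0.1, "log_rom")
        b = Estimate("b", 0.2, 0.1, "log_or")
        with pytest.raises(ValueError, match="mixed"):
            pool_dl([a, b])


def _records_for_subgroups():
    recs = []
    spec = [
        ("a", "asian", 2.0), ("b", "asian", 2.2), ("c", "asian", 1.8),
        ("d", "caucasian", 2.6), ("e", "caucasian", 2.4),
        ("f", None, 2.1),
    ]
    for sid, eth, mc in spec:
        recs.append(StudyRecord(sid, sid, 120, 240, mc, 1.0, 1.5, 0.8,
                                ethnicity=eth or "missing"))
    return recs


class TestSubgroupPool:
    def test_levels_match_manual_subsets(self):
        recs = _records_for_subgroups()
        result = subgroup_pool(recs, "ethnicity")
        assert set(result) == {"asian", "caucasian", "unknown"}
        manual = pool_dl([log_rom(r) for r in recs if r.ethnicity == "asian"])
        assert result["asian"].y_pooled == pytest.approx(manual.y_pooled, abs=1e-14)
        assert result["asian"].tau_squared == pytest.approx(manual.tau_squared, abs=1e-14)

    def test_union_of_levels_covers_input(self):
        recs = _records_for_subgroups()
        result = subgroup_pool(recs, "ethnicity")
        assert sum(r.k for r in result.values()) == len(recs)

    def test_single_level_equals_overall(self):
        recs = [r for r in _records_for_subgroups() if r.ethnicity == "asian"]
        result = subgroup_pool(recs, "ethnicity")
        overall = pool_dl([log_rom(r) for r in recs])
        assert list(result) == ["asian"]
        assert result["asian"].y_pooled == pytest.approx(overall.y_pooled)

    def test_singleton_level_uses_k1_contract(self):
        recs = _records_for_subgroups()[:4]  # one caucasian study
        result = subgroup_pool(recs, "ethnicity")
        assert result["caucasian"].k == 1
        assert result["caucasian"].tau_squared == 0.0

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError, match="factor"):
            subgroup_pool(_records_for_subgroups(), "nonexistent")


class TestCompareTwoPooled:
    def test_identical_results_give_z_zero(self, toy_estimates):
        res = pool_dl(toy_estimates)
        z, p = compare_two_pooled(res, res)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_normal_quantile_boundary(self, toy_estimates):
        a = pool_dl(toy_estimates)
        b = pool_dl(make_estimates(
            [e.y - 1.959963984540054 * math.sqrt(2) * a.se_pooled for e in toy_estimates],
            [e.v for e in toy_estimates]))
        # shift every study so the pooled gap is exactly z_crit * sqrt(2 se^2)
        assert b.se_pooled == pytest.approx(a.se_pooled, rel=1e-9)
        z, p = compare_two_pooled(a, b)
        assert p == pytest.approx(0.05, rel=1e-6)

    def test_antisymmetry_and_closed_form(self, toy_estimates):
        a = pool_dl(toy_estimates[:3])
        b = pool_dl(toy_estimates[3:])
        z_ab, p_ab = compare_two_pooled(a, b)
        z_ba, p_ba = compare_two_pooled(b, a)
        assert z_ab == pytest.approx(-z_ba)
        assert p_ab == pytest.approx(p_ba)
        expected_z = (a.y_pooled - b.y_pooled) / math.sqrt(a.se_pooled**2 + b.se_pooled**2)
        assert z_ab == pytest.approx(expected_z, rel=1e-12)
        assert p_ab == pytest.approx(2 * stats.norm.sf(abs(expected_z)), rel=1e-12)


class TestLeaveOneOut:
    def test_each_entry_matches_manual_subset(self, toy_estimates):
        for sid, res in leave_one_out(toy_estimates):
            rest = [e for e in toy_estimates if e.study_id != sid]
            manual = pool_dl(rest)
            assert res.y_pooled == pytest.approx(manual.y_pooled, abs=1e-14)
            assert res.tau_squared == pytest.approx(manual.tau_squared, abs=1e-14)

    def test_identical_studies_invariant(self):
        ests = make_estimates([0.4] * 4, [0.02] * 4)
        results = leave_one_out(ests)
        assert len(results) == 4
        assert all(r.y_pooled == pytest.approx(0.4) for _, r in results)

    def test_omitting_the_outlier_minimizes_tau2(self, toy_estimates):
        outlier = Estimate("OUT", 5.0, 0.01, "log_rom")
        ests = toy_estimates + [outlier]
        results = leave_one_out(ests)
        best = min(results, key=lambda t: t[1].tau_squared)
        assert best[0] == "OUT"

    def test_too_few_studies_rejected(self):
        with pytest.raises(ValueError, match="3"):
            leave_one_out(make_estimates([0.1, 0.2], [0.01, 0.01]))


@pytest.mark.parametrize("method", ["DL"])
def test_dl_agrees_with_metafor(toy_estimates, method, tmp_path):
    """Independent cross-check of the full DL pipeline against R metafor."""
    y = ",".join(repr(e.y) for e in toy_estimates)
    v = ",".join(repr(e.v) for e in toy_estimates)
    script = (
        "suppressMessages(library(metafor));"
        f"f <- rma(yi=c({y}), vi=c({v}), method='{method}');"
        "cat(f$beta[1], f$se, f$tau2, f$QE, f$I2, sep='\\n')"
    )
    try:
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=120, check=True)
    except (FileNotFoundError, subprocess.CalledProcessError) as exc:
        pytest.fail(f"metafor oracle unavailable: {exc}")
    beta, se, tau2, Q, i2 = (float(x) for x in out.stdout.strip().splitlines())
    res = pool_dl(toy_estimates)
    assert res.y_pooled == pytest.approx(beta, rel=1e-6)
    assert res.se_pooled == pytest.approx(se, rel=1e-6)
    assert res.tau_squared == pytest.approx(tau2, rel=1e-6)
    assert res.Q == pytest.approx(Q, rel=1e-6)
    assert 100 * res.i_squared == pytest.approx(i2, rel=1e-3)
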