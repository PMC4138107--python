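"""Efficiency-corrected ΔΔCt quantification and the desk-scale statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aedes_ptp.errors import ContractError, ValidationError
from aedes_ptp.expression import (
    normalize_egg_counts,
    one_way_anova,
    relative_expression,
    two_sample_t,
)
from aedes_ptp.synth import make_cage_table, make_ct_table


def _ct_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "condition", "gene",
                                       "replicate", "ct", "efficiency"])


def _flat_table(ct_target, ct_ref, eff_t=2.0, eff_r=2.0):
    rows = []
    for cond, (t, r) in {"cal": (ct_target[0], ct_ref[0]),
                         "trt": (ct_target[1], ct_ref[1])}.items():
        for rep in (1, 2):
            rows.append([f"{cond}{rep}", cond, "tgt", rep, t, eff_t])
            rows.append([f"{cond}{rep}", cond, "rp49", rep, r, eff_r])
    return _ct_frame(rows)


def test_equal_cts_give_ratio_one():
    ct = _flat_table((20.0, 20.0), (18.0, 18.0))
    r = relative_expression(ct, "tgt", "trt", "cal")
    assert r.ratio == pytest.approx(1.0)
    assert r.se == 0.0


def test_one_cycle_drop_doubles_expression():
    ct = _flat_table((20.0, 19.0), (18.0, 18.0))
    r = relative_expression(ct, "tgt", "trt", "cal")
    assert r.ratio == pytest.approx(2.0)


def test_pfaffl_formula_matches_direct_arithmetic():
    """Independent arithmetic oracle for the efficiency-corrected ratio."""
    et, er = 1.95, 2.0
    dct_t, dct_r = -2.0, 0.5
    ct = _flat_table((20.0, 20.0 + dct_t), (18.0, 18.0 + dct_r), et, er)
    r = relative_expression(ct, "tgt", "trt", "cal")
    assert r.ratio == pytest.approx(et ** (-dct_t) / er ** (-dct_r), rel=1e-12)


def test_calibrator_vs_itself_is_one():
    df, _ = make_ct_table({"g": {"trt": 3.0}}, calibrator="cal",
                          conditions=["cal", "trt"], seed=1)
    r = relative_expression(df, "g", "cal", "cal")
    assert r.ratio == pytest.approx(1.0)


@given(st.floats(-3, 3), st.floats(-3, 3), st.floats(-2, 2))
def test_perfect_efficiency_reduces_to_classic_form(dct_t, dct_r, shift):
    """With E=2 the ratio equals 2^(−ΔΔCt); Ct offsets common to all
    conditions of a gene cancel (scale invariance)."""
    ct = _flat_table((20.0, 20.0 + dct_t), (18.0, 18.0 + dct_r))
    r = relative_expression(ct, "tgt", "trt", "cal")
    assert r.ratio == pytest.approx(2.0 ** (-(dct_t - dct_r)), rel=1e-9)
    shifted = ct.copy()
    shifted.loc[shifted.gene == "tgt", "ct"] += shift
    r2 = relative_expression(shifted, "tgt", "trt", "cal")
    assert r2.ratio == pytest.approx(r.ratio, rel=1e-9)


def test_efficiency_out_of_range_rejected():
    ct = _flat_table((20.0, 19.0), (18.0, 18.0), eff_t=2.2)
    with pytest.raises(ValidationError, match="efficiency"):
        relative_expression(ct, "tgt", "trt", "cal")


def test_missing_calibrator_is_contract_error():
    ct = _flat_table((20.0, 19.0), (18.0, 18.0))
    with pytest.raises(ContractError, match="calibrator"):
        relative_expression(ct, "tgt", "trt", "nonesuch")


def test_noise_free_table_recovers_fold_exactly():
    df, _ = make_ct_table({"g": {"trt": 2.0}}, noise_sd=0.0,
                          calibrator="cal", conditions=["cal", "trt"], seed=0)
    r = relative_expression(df, "g", "trt", "cal")
    assert r.ratio == pytest.approx(2.0, rel=1e-12)


def test_fold_recovery_monte_carlo_matches_closed_form_coverage():
    """True fold 4, noise sd 0.2, triplicates: the fraction of runs within
    ±15% must match the closed-form sampling distribution of the estimator.

    ΔΔCt is a difference of four replicate means, so its sampling sd is
    2·sd/√n cycles and the recovered ratio is 4·2^(−X) with X normal; the
    expected ±15% coverage follows from the normal CDF (about 65% under
    these conditions — a tight band is simply not achievable at n=3).
    """
    from scipy.stats import norm

    sd_ddct = 2 * 0.2 / np.sqrt(3)
    lo, hi = np.log2(1 / 1.15), np.log2(1 / 0.85)
    expected = norm.cdf(hi / sd_ddct) - norm.cdf(lo / sd_ddct)

    ok, n = 0, 500
    for seed in range(n):
        df, _ = make_ct_table({"g": {"trt": 4.0}}, noise_sd=0.2,
                              n_replicates=3, calibrator="cal",
                              conditions=["cal", "trt"], seed=seed)
        r = relative_expression(df, "g", "trt", "cal")
        ok += abs(r.ratio - 4.0) / 4.0 <= 0.15
    binom_sd = np.sqrt(expected * (1 - expected) / n)
    assert abs(ok / n - expected) <= 4 * binom_sd


def test_replicate_scatter_propagates_to_se():
    df, _ = make_ct_table({"g": {"trt": 2.0}}, noise_sd=0.3, seed=9,
                          calibrator="cal", conditions=["cal", "trt"])
    r = relative_expression(df, "g", "trt", "cal")
    assert np.isfinite(r.se) and r.se > 0


# --------------------------------------------------------------------------
# egg counts

def test_eggs_per_female():
    assert normalize_egg_counts(120, 12) == 10.0
    assert normalize_egg_counts(0, 5) == 0.0
    with pytest.raises(ContractError):
        normalize_egg_counts(10, 0)


def test_cage_generator_mean_within_two_se():
    df, truth = make_cage_table({"control": 60.0}, n_cages=30, seed=3)
    per_female = df.eggs / df.females
    se = per_female.std(ddof=1) / np.sqrt(len(per_female))
    assert abs(per_female.mean() - 60.0) <= 2 * se + 1e-9


# --------------------------------------------------------------------------
# significance tests

def test_anova_identical_groups_f_zero():
    f, p = one_way_anova([3.0, 3.0, 3.0], [3.0, 3.0], [3.0, 3.0, 3.0])
    assert f == 0.0 and p == 1.0


def test_anova_two_groups_equals_t_squared():
    a, b = [4.1, 5.2, 3.9, 4.8], [6.0, 5.5, 6.3, 5.9, 6.1]
    f, pf = one_way_anova(a, b)
    t, pt = two_sample_t(a, b)
    assert f == pytest.approx(t ** 2, rel=1e-12)
    assert pf == pytest.approx(pt, rel=1e-12)


def test_anova_matches_sum_of_squares_oracle():
    """Hand-computed between/within mean squares on a fixed 3x5 table."""
    groups = [[12.0, 14.0, 11.0, 13.0, 15.0],
              [16.0, 18.0, 17.0, 15.0, 19.0],
              [11.0, 10.0, 12.0, 13.0, 11.0]]
    arrs = [np.array(g) for g in groups]
    grand = np.concatenate(arrs).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in arrs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrs)
    k, n = 3, 15
    f_oracle = (ssb / (k - 1)) / (ssw / (n - k))
    f, p = one_way_anova(*groups)
    assert abs(f - f_oracle) < 1e-10
    from scipy.stats import f as fdist
    assert abs(p - fdist.sf(f_oracle, k - 1, n - k)) < 1e-10


def test_t_statistic_matches_textbook_formula():
    a = np.array([5.0, 6.0, 5.5, 6.5, 5.2, 6.1])
    b = np.array([7.0, 6.8, 7.5, 7.2, 6.9, 7.4])
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (len(a) + len(b) - 2)
    t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    t, p = two_sample_t(a, b)
    assert abs(t - t_oracle) < 1e-10
    from scipy.stats import t as tdist
    assert abs(p - 2 * tdist.sf(abs(t_oracle), len(a) + len(b) - 2)) < 1e-10


def test_t_degenerate_and_symmetry():
    assert two_sample_t([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
    t1, p1 = two_sample_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    t2, p2 = two_sample_t([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
    assert t1 == -t2 and p1 == p2


def test_group_size_contracts():
    with pytest.raises(ContractError):
        one_way_anova([1.0], [2.0, 3.0])
    with pytest.raises(ContractError):
        two_sample_t([1.0], [2.0, 3.0])
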