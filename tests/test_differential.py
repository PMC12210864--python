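import numpy as np
import pandas as pd
import pytest
from scipy import stats

from guildlink import (
    AbundanceTable,
    SampleMetadata,
    ValueKind,
    autoscale,
    benjamini_hochberg,
    differential_kos,
    differential_metabolites,
    differential_species,
    qc_filter_metabolites,
    student_t,
    wilcoxon_rank_sum,
)


def _table(values, features=None, samples=None, kind=ValueKind.intensity):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return AbundanceTable(pd.DataFrame(values, index=features, columns=samples), kind)


def _meta(n_case, n_control, samples=None):
    samples = samples or [f"s{i}" for i in range(n_case + n_control)]
    df = pd.DataFrame({"group": ["case"] * n_case + ["control"] * n_control},
                      index=pd.Index(samples, name="sample_id"))
    return SampleMetadata(df)


# ---------------------------------------------------------------------------
# QC filter and autoscaling
# ---------------------------------------------------------------------------

def test_qc_filter_cv_rule_boundaries():
    # CVs: 0 (kept), 0.35 (removed), 0.29 (kept); QC mean fixed at 10
    def vals_with_cv(cv):
        # two QC points symmetric about 10 give sd/mean = cv exactly... use 3
        # points [10-d, 10, 10+d]: mean 10, sd = d; cv = d/10
        d = cv * 10
        return [10 - d, 10.0, 10 + d]

    rows = {
        "flat": [5.0, 6.0] + [10.0, 10.0, 10.0],
        "noisy": [5.0, 6.0] + vals_with_cv(0.35),
        "ok": [5.0, 6.0] + vals_with_cv(0.29),
    }
    table = _table(list(rows.values()), features=list(rows),
                   samples=["s0", "s1", "q0", "q1", "q2"])
    out = qc_filter_metabolites(table, ["q0", "q1", "q2"])
    assert out.feature_ids == ["flat", "ok"]
    assert out.sample_ids == ["s0", "s1"]   # QC columns dropped


def test_qc_filter_needs_two_qc_samples():
    table = _table([[1.0, 2.0]], samples=["s0", "q0"])
    with pytest.raises(ValueError):
        qc_filter_metabolites(table, ["q0"])


def test_autoscale_rows_and_idempotence():
    table = _table([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
    scaled = autoscale(table)
    assert np.allclose(scaled.matrix()[0], [-1, 0, 1])
    assert np.allclose(scaled.matrix()[1], [0, 0, 0])
    twice = autoscale(scaled)
    assert np.allclose(twice.matrix(), scaled.matrix(), atol=1e-12)
    assert scaled.value_kind is ValueKind.scaled


# ---------------------------------------------------------------------------
# univariate tests
# ---------------------------------------------------------------------------

def test_student_t_closed_form():
    t, p = student_t([1, 2, 3], [4, 5, 6])
    # pooled sd 1, se = sqrt(2/3); t = -3/se; p from t CDF with 4 df
    se = np.sqrt(2.0 / 3.0)
    t_expected = -3.0 / se
    p_expected = 2 * stats.t.cdf(t_expected, df=4)
    assert t == pytest.approx(t_expected, abs=1e-9)
    assert p == pytest.approx(p_expected, abs=1e-9)
    assert t == pytest.approx(-3.674, abs=1e-3)
    assert p == pytest.approx(0.0214, abs=1e-3)


def test_student_t_degenerate_and_antisymmetric():
    assert student_t([2, 2, 2], [2, 2, 2]) == (0.0, 1.0)
    t0, p0 = student_t([1.0, 1.0], [2.0, 2.0])
    assert p0 == 0.0 and t0 == -np.inf
    t1, p1 = student_t([1, 2, 3], [2, 3, 5])
    t2, p2 = student_t([2, 3, 5], [1, 2, 3])
    assert t1 == pytest.approx(-t2)
    assert p1 == pytest.approx(p2)


def test_wilcoxon_exact_small_sample():
    _, p = wilcoxon_rank_sum([1, 2], [3, 4])
    assert p == pytest.approx(1.0 / 3.0)


def test_wilcoxon_identical_groups_p1():
    _, p = wilcoxon_rank_sum([5, 5, 5], [5, 5, 5])
    assert p == 1.0


def test_wilcoxon_shift_invariance():
    rng = np.random.default_rng(1)
    x = rng.normal(size=10)
    y = rng.normal(size=12)
    w1, p1 = wilcoxon_rank_sum(x, y)
    w2, p2 = wilcoxon_rank_sum(x + 100, y + 100)
    assert (w1, p1) == (w2, p2)


def test_wilcoxon_large_sample_matches_scipy():
    rng = np.random.default_rng(2)
    x = rng.normal(size=30)
    y = rng.normal(0.5, size=25)
    u, p = wilcoxon_rank_sum(x, y)
    ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    assert u == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue, rel=1e-9)


def test_benjamini_hochberg_known_values():
    q = benjamini_hochberg([0.01, 0.04, 0.03, 0.002])
    assert np.allclose(q, [0.02, 0.04, 0.04, 0.008])
    assert np.allclose(benjamini_hochberg([1.0, 1.0]), [1.0, 1.0])
    assert benjamini_hochberg([0.2]) == pytest.approx([0.2])
    with pytest.raises(ValueError):
        benjamini_hochberg([0.5, 1.2])


from hypothesis import given, settings
from hypothesis import strategies as st


@given(st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                min_size=1, max_size=60))
@settings(deadline=None, max_examples=60, derandomize=True)
def test_bh_adjustment_properties(p):
    """BH q-values dominate raw p, stay in [0,1] and are monotone in p."""
    p = np.array(p)
    q = benjamini_hochberg(p)
    assert (q >= p - 1e-15).all()
    assert (q <= 1.0).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()


def test_bh_dominates_raw_p():
    rng = np.random.default_rng(3)
    p = rng.random(100)
    q = benjamini_hochberg(p)
    assert (q >= p - 1e-15).all()
    assert (q <= 1.0).all()


# ---------------------------------------------------------------------------
# selection rules
# ---------------------------------------------------------------------------

def test_metabolite_rule_requires_both_p_and_vip():
    rng = np.random.default_rng(0)
    n1 = n2 = 10
    x = np.vstack([
        np.concatenate([rng.normal(2, 1, n1), rng.normal(0, 1, n2)]),  # strong
        np.concatenate([rng.normal(2, 1, n1), rng.normal(0, 1, n2)]),  # strong, low VIP
        rng.normal(size=n1 + n2),                                      # null
    ])
    table = autoscale(_table(x, kind=ValueKind.scaled))
    meta = _meta(n1, n2)
    vip = pd.Series([1.2, 0.9, 1.5], index=table.feature_ids)
    res = differential_metabolites(table, meta, vip)
    assert res.table.loc["f0", "selected"]
    assert not res.table.loc["f1", "selected"]      # p fine, VIP <= 1
    assert res.table.loc["f0", "direction"] == "case_enriched"
    # q >= p invariant
    assert (res.table["q"] >= res.table["p"] - 1e-15).all()
    with pytest.raises(ValueError, match="aligned"):
        differential_metabolites(table, meta, vip.iloc[:2])


def test_species_rule_abundance_floor():
    n1, n2 = 5, 5
    strong_rare = np.concatenate([np.full(n1, 9e-7), np.full(n2, 1e-8)])
    strong_common = np.concatenate([np.full(n1, 5e-3), np.full(n2, 1e-3)])
    absent = np.zeros(n1 + n2)
    rest_case = 1.0 - strong_rare - strong_common
    table = _table(np.vstack([strong_rare, strong_common, absent, rest_case]),
                   features=["rare", "common", "absent", "filler"],
                   kind=ValueKind.relative_abundance)
    meta = _meta(n1, n2)
    res = differential_species(table, meta)
    assert "absent" not in res.table.index          # excluded before testing
    assert res.table.loc["rare", "p"] < 0.05
    assert not res.table.loc["rare", "selected"]    # fails the 1e-6 floor
    assert res.table.loc["common", "selected"]
    with pytest.raises(ValueError):
        differential_species(_table([[1.0, 2.0]] , samples=["s0", "s1"]), _meta(1, 1))


def test_ko_power_and_direction_on_planted_shifts():
    rng = np.random.default_rng(5)
    n = 20
    planted = 40
    null = 160
    x = rng.standard_normal((planted + null, 2 * n))
    signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(planted)])
    x[:planted, :n] += 2.0 * signs[:, None]
    # no compositional closure here: closing would let the planted shifts
    # leak into every null feature through the shared denominator
    table = _table(np.exp(x), kind=ValueKind.intensity)
    meta = _meta(n, n)
    res = differential_kos(table, meta)
    sel = res.table.iloc[:planted]
    assert sel["selected"].mean() > 0.9             # power on d=2 shifts
    detected = sel[sel["selected"]]
    expected_dir = np.where(signs[sel["selected"].to_numpy()] > 0,
                            "case_enriched", "case_depleted")
    assert (detected["direction"].to_numpy() == expected_dir).all()
    null_frac = res.table.iloc[planted:]["selected"].mean()
    assert null_frac < 0.15


def test_tests_invariant_to_sample_permutation(small_cohort):
    meta = small_cohort.metadata
    table = small_cohort.kos
    res1 = differential_kos(table, meta)
    perm = table.sample_ids[::-1]
    res2 = differential_kos(AbundanceTable(table.values[perm], table.value_kind), meta)
    pd.testing.assert_frame_equal(res1.table, res2.table)
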