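"""Normalization, group profiles, KS, Gini and drought-phase analytics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qwa import intra_annual as ia
from qwa.climate import DroughtCalendar


# --- min-max normalization --------------------------------------------------


def test_minmax_example_and_endpoints():
    out = ia.minmax_normalize([2.0, 4.0, 6.0])
    assert np.allclose(out, [0.0, 0.5, 1.0])
    assert out.min() == 0.0 and out.max() == 1.0


@settings(deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-50, 50), min_size=3, max_size=40).filter(lambda v: max(v) > min(v)),
    st.floats(0.1, 10.0),
    st.floats(-20.0, 20.0),
)
def test_minmax_affine_invariance(vals, a, b):
    x = np.asarray(vals)
    assert np.allclose(ia.minmax_normalize(x), ia.minmax_normalize(a * x + b), atol=1e-12)


def test_constant_profile_rejected():
    with pytest.raises(ValueError, match="constant"):
        ia.minmax_normalize([3.0, 3.0, 3.0])


def test_normalize_profiles_drops_constant_rings():
    prof = pd.DataFrame(
        {
            "tree_id": ["T1"] * 3 + ["T2"] * 3,
            "year": 2000,
            "trait": "AD",
            "sector": [1, 2, 3] * 2,
            "value": [1.0, 2.0, 3.0, 5.0, 5.0, 5.0],
        }
    )
    with pytest.warns(UserWarning, match="excluded 1"):
        out = ia.normalize_profiles(prof)
    assert set(out["tree_id"]) == {"T1"}
    assert np.allclose(out["value"], [0, 0.5, 1])


# --- group profiles ---------------------------------------------------------


def _profile_frame(ring_values: dict):
    rows = []
    for (tree, year), vals in ring_values.items():
        for s, v in enumerate(vals, start=1):
            rows.append(
                {"tree_id": tree, "year": year, "trait": "AD", "sector": s, "value": v}
            )
    return pd.DataFrame(rows)


def test_identical_rings_give_zero_width_band():
    ring = np.linspace(0, 1, 100)
    prof = _profile_frame({("T1", 2000): ring, ("T2", 2000): ring})
    gp = ia.group_mean_profile(prof)
    assert np.allclose(gp.high - gp.low, 0.0, atol=1e-12)
    assert gp.n_rings == 2
    assert np.nanmin(gp.mean) >= -0.05 and np.nanmax(gp.mean) <= 1.05


def test_smoothed_mean_tracks_known_line(rng):
    line = np.linspace(0, 1, 100)
    rings = {
        ("T%d" % i, 2000 + i): np.clip(line + rng.normal(0, 0.1, 100), 0, 1) for i in range(20)
    }
    gp = ia.group_mean_profile(_profile_frame(rings))
    rms = np.sqrt(np.nanmean((gp.mean - line) ** 2))
    assert rms < 0.05


def test_single_ring_refused():
    prof = _profile_frame({("T1", 2000): np.linspace(0, 1, 100)})
    with pytest.raises(ValueError):
        ia.group_mean_profile(prof)


# --- Kolmogorov-Smirnov -----------------------------------------------------


def _oracle_ks_d(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    ts = np.concatenate([a, b])
    return max(abs(np.mean(a <= t) - np.mean(b <= t)) for t in ts)


def test_ks_examples():
    same = [1.0, 2.0, 3.0, 4.0, 5.0]
    res = ia.ks_two_sample(same, same)
    assert res.d_stat == 0.0 and res.p_value == pytest.approx(1.0)
    res = ia.ks_two_sample([1, 2, 3, 4, 5], [10, 11, 12, 13, 14])
    assert res.d_stat == 1.0
    res = ia.ks_two_sample([1, 2, 3, 4, 5], [3, 4, 5, 6, 7])
    assert res.d_stat == pytest.approx(0.4)


def test_ks_rejects_tiny_samples():
    with pytest.raises(ValueError):
        ia.ks_two_sample([1, 2, 3], [1, 2, 3, 4, 5])


def test_ks_statistic_matches_bruteforce_on_random_pairs(rng):
    for _ in range(200):
        a = rng.normal(0, 1, rng.integers(5, 25))
        b = rng.normal(rng.uniform(-1, 1), 1, rng.integers(5, 25))
        assert ia.ks_two_sample(a, b).d_stat == pytest.approx(_oracle_ks_d(a, b), abs=1e-12)
        assert ia._ks_d(a, b) == pytest.approx(_oracle_ks_d(a, b), abs=1e-12)


# --- Gini -------------------------------------------------------------------


def _oracle_gini(x):
    x = np.asarray(x, float)
    n = x.size
    return np.sum(np.abs(x[:, None] - x[None, :])) / (2 * n * n * x.mean())


def test_gini_examples():
    assert ia.gini([5.0] * 10) == 0.0
    assert ia.gini([0.0, 1.0]) == pytest.approx(0.5)
    assert ia.gini([1.0, 2.0, 3.0]) == pytest.approx(8 / 36)


def test_gini_rejects_bad_input():
    with pytest.raises(ValueError):
        ia.gini([-1.0, 2.0])
    with pytest.raises(ValueError):
        ia.gini([0.0, 0.0])


def test_gini_matches_pairwise_oracle(rng):
    for _ in range(1000):
        x = rng.lognormal(0, rng.uniform(0.1, 1.5), size=rng.integers(2, 60))
        assert ia.gini(x) == pytest.approx(_oracle_gini(x), abs=1e-10)


def test_gini_jackknife_matches_direct_leave_one_out(rng):
    x = rng.lognormal(0, 0.7, 40)
    jack = ia._gini_jackknife(x)
    xs = np.sort(x)
    direct = [ia.gini(np.delete(xs, j)) for j in range(40)]
    assert np.allclose(jack, direct, atol=1e-12)


# --- Gini bootstrap ---------------------------------------------------------


def test_constant_vector_bootstrap_collapses():
    with pytest.warns(UserWarning, match="degenerate"):
        est = ia.gini_bootstrap([3.0] * 12, n_boot=100, seed=0)
    assert est.point == 0.0 and est.percentile == (0.0, 0.0) and est.bca == (0.0, 0.0)


def test_bootstrap_is_seed_deterministic(rng):
    x = rng.lognormal(0, 0.8, 60)
    a = ia.gini_bootstrap(x, n_boot=500, seed=11)
    b = ia.gini_bootstrap(x, n_boot=500, seed=11)
    assert a.percentile == b.percentile and a.bca == b.bca


def test_bca_matches_scipy_reference(rng):
    from scipy.stats import bootstrap as scipy_bootstrap

    x = rng.lognormal(0, 0.8, 80)
    est = ia.gini_bootstrap(x, n_boot=4000, seed=5)
    ref = scipy_bootstrap(
        (x,),
        lambda v, axis=-1: np.apply_along_axis(ia.gini, axis, np.atleast_2d(v)),
        n_resamples=4000,
        confidence_level=0.95,
        method="BCa",
        vectorized=True,
        rng=np.random.default_rng(5),
    )
    assert est.bca[0] == pytest.approx(ref.confidence_interval.low, abs=0.01)
    assert est.bca[1] == pytest.approx(ref.confidence_interval.high, abs=0.01)


def test_bca_near_percentile_for_symmetric_bootstrap(rng):
    # large normal-ish sample -> nearly symmetric bootstrap distribution
    x = np.abs(rng.normal(10, 0.5, 400))
    est = ia.gini_bootstrap(x, n_boot=3000, seed=2)
    assert est.bca[0] == pytest.approx(est.percentile[0], abs=0.01)
    assert est.bca[1] == pytest.approx(est.percentile[1], abs=0.01)


def test_ci_width_shrinks_with_sample_size(rng):
    sigma = 0.8
    widths = {}
    for n in (50, 200, 800):
        ws = []
        for rep in range(20):
            x = rng.lognormal(0, sigma, n)
            est = ia.gini_bootstrap(x, n_boot=500, seed=n + rep)
            ws.append(est.bca[1] - est.bca[0])
        widths[n] = np.mean(ws)
    for n1, n2 in [(50, 200), (200, 800)]:
        expected = np.sqrt(n2 / n1)
        ratio = widths[n1] / widths[n2]
        assert expected / 1.5 <= ratio <= expected * 1.5


# --- drought phases ---------------------------------------------------------


def _norm_profiles(years, group="pure", shift_years=(), shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    base = np.linspace(0, 1, 100)
    for year in years:
        for t in range(3):
            vals = np.clip(base + rng.normal(0, 0.05, 100), 0, 1)
            if year in shift_years:
                vals = np.clip(vals + shift, 0, 1)
            for s, v in enumerate(vals, start=1):
                rows.append(
                    {
                        "tree_id": f"{group}{t}",
                        "year": year,
                        "trait": "AD",
                        "sector": s,
                        "value": v,
                        "group": group,
                    }
                )
    return pd.DataFrame(rows)


def test_edge_drought_omits_after_phase():
    years = range(1990, 2001)
    prof = _norm_profiles(years)
    cal = DroughtCalendar(frozenset({2000}))  # no year 2001 in the data
    with pytest.warns(UserWarning, match="after"):
        profiles, contrasts = ia.drought_phase_profiles(
            prof, cal, trait="AD", groups=("pure",), n_perm=99
        )
    assert ("pure", "after") not in profiles
    assert set(contrasts["phase_b"]) <= {"during"}


def test_consecutive_droughts_excluded_from_neighbor_phases():
    years = range(1990, 2001)
    prof = _norm_profiles(years)
    cal = DroughtCalendar(frozenset({1994, 1995}))
    profiles, _ = ia.drought_phase_profiles(
        prof, cal, trait="AD", groups=("pure",), n_perm=99
    )
    # before=1993 only (1994 is itself a drought), after=1996 only
    assert profiles[("pure", "during")].n_rings == 6
    assert profiles[("pure", "before")].n_rings == 3
    assert profiles[("pure", "after")].n_rings == 3


def test_planted_after_shift_detected_and_null_not():
    years = list(range(1980, 2014))
    droughts = {1985, 1992, 1999, 2005, 2010}
    after = {d + 1 for d in droughts}
    cal = DroughtCalendar(frozenset(droughts))
    shifted = _norm_profiles(years, shift_years=after, shift=0.15, seed=1)
    _, con = ia.drought_phase_profiles(shifted, cal, trait="AD", groups=("pure",), seed=3)
    ba = con[(con["phase_a"] == "before") & (con["phase_b"] == "after")].iloc[0]
    assert ba["p_value"] < 0.05 and ba["mean_b"] > ba["mean_a"]
    null = _norm_profiles(years, seed=2)
    _, con0 = ia.drought_phase_profiles(null, cal, trait="AD", groups=("pure",), seed=4)
    ba0 = con0[(con0["phase_a"] == "before") & (con0["phase_b"] == "after")].iloc[0]
    assert ba0["p_value"] >= 0.05


# --- drought vs non-drought Gini table --------------------------------------


def test_gini_table_schema_and_planted_variability(rng):
    years = np.arange(1970, 2012)
    droughts = {1975, 1985, 1995, 2005}
    cal = DroughtCalendar(frozenset(droughts))
    prof = pd.concat(
        [_norm_profiles(years, group=g, seed=i) for i, g in enumerate(("pure", "mixed"))]
    )
    # ring-width indices with inflated spread in drought years
    rows = []
    for g in ("pure", "mixed"):
        for t in range(6):
            for y in years:
                sd = 0.45 if y in droughts else 0.05
                rows.append(
                    {
                        "tree_id": f"{g}{t}",
                        "group": g,
                        "year": y,
                        "rwi": float(np.exp(rng.normal(0, sd))),
                    }
                )
    rwi = pd.DataFrame(rows)
    table = ia.drought_vs_nondrought_gini(
        prof, cal, rwi=rwi, traits=("AD",), n_boot=400, seed=0
    )
    assert list(table.columns[:4]) == ["site", "forest_type", "trait", "drought"]
    assert set(table["trait"]) == {"AD", "RWI"}
    for g in ("pure", "mixed"):
        sub = table[(table["trait"] == "RWI") & (table["forest_type"] == g)]
        yes = sub[sub["drought"] == "YES"].iloc[0]
        no = sub[sub["drought"] == "NO"].iloc[0]
        assert yes["gini"] > no["gini"]
        assert yes["ci_low_bca"] > no["ci_high_bca"]  # non-overlapping intervals
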