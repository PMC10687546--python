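"""Trait formulas, sectorization, Mork classification, outlier fences and
annual aggregation against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qwa import anatomy as an


# --- per-cell formulas ------------------------------------------------------


@pytest.mark.parametrize(
    "lumen, expected",
    [(25 * np.pi, 10.0), (100 * np.pi, 20.0), (500.0, 2 * np.sqrt(500 / np.pi))],
)
def test_hydraulic_diameter_is_equivalent_circle(lumen, expected):
    assert an.cell_hydraulic_diameter(lumen) == pytest.approx(expected, rel=1e-12)


def test_hydraulic_diameter_rejects_nonpositive_lumen():
    with pytest.raises(ValueError):
        an.cell_hydraulic_diameter(0.0)


@pytest.mark.parametrize(
    "d, expected",
    [([10, 10, 10], 10.0), ([10, 20], 3_300_000 / 170_000)],
)
def test_mean_hydraulic_diameter_examples(d, expected):
    assert an.mean_hydraulic_diameter(d) == pytest.approx(expected, rel=1e-12)


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(0.1, 100.0), min_size=1, max_size=50))
def test_mean_hydraulic_diameter_dominates_arithmetic_mean(d):
    assert an.mean_hydraulic_diameter(d) >= np.mean(d) - 1e-9


@pytest.mark.parametrize("rad, tan, expected", [(3, 5, 4), (7, 7, 7), (0, 0, 0)])
def test_cell_wall_thickness_mean(rad, tan, expected):
    assert an.cell_cwt(rad, tan) == pytest.approx(expected)


def test_anatomical_density_examples_and_limits():
    assert an.anatomical_density(30, 70) == pytest.approx(0.30)
    assert an.anatomical_density(5, 0) == 1.0
    assert an.anatomical_density(0, 5) == 0.0
    with pytest.raises(ValueError):
        an.anatomical_density(0, 0)


def test_anatomical_density_increases_with_wall_area():
    ad = [an.anatomical_density(w, 50.0) for w in np.linspace(1, 100, 25)]
    assert all(a < b for a, b in zip(ad, ad[1:]))


# --- sectors and Mork classification ---------------------------------------


@pytest.mark.parametrize("pos, sector", [(0.0, 1), (0.999, 100), (0.5, 51)])
def test_sector_assignment_convention(pos, sector):
    assert an.assign_sectors(pos) == sector


def test_sector_assignment_rejects_out_of_range():
    with pytest.raises(ValueError):
        an.assign_sectors(1.0)


@pytest.mark.parametrize(
    "cwt_rad, lumen_d, expected",
    [(2.0, 8.0, "LW"), (1.0, 8.0, "EW"), (0.0, 8.0, "EW")],
)
def test_mork_classification_with_boundary_as_latewood(cwt_rad, lumen_d, expected):
    assert an.morks_classify(cwt_rad, lumen_d) == expected


@settings(deadline=None, derandomize=True)
@given(
    st.floats(0.01, 10.0),
    st.floats(0.5, 50.0),
    st.floats(0.1, 10.0),
)
def test_mork_classification_is_scale_invariant(cwt_rad, lumen_d, factor):
    assert an.morks_classify(cwt_rad, lumen_d) == an.morks_classify(
        cwt_rad * factor, lumen_d * factor
    )


def test_wall_only_cell_classifies_latewood():
    assert an.morks_classify(2.0, 0.0) == "LW"


# --- outlier filter ---------------------------------------------------------


def _oracle_tukey(x):
    xs = np.sort(np.asarray(x, float))
    n = xs.size

    def quantile(q):  # type-7 linear interpolation
        h = (n - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    return xs[(xs >= q1 - 1.5 * iqr) & (xs <= q3 + 1.5 * iqr)]


def test_tukey_filter_examples():
    kept, log = an.filter_outliers(list(range(1, 11)) + [1000], mode="tukey")
    assert 1000 not in kept and log.n_removed == 1
    kept, _ = an.filter_outliers([5.0] * 6)
    assert list(kept) == [5.0] * 6
    kept, _ = an.filter_outliers([5, 6, 7, 8])
    assert len(kept) == 4


def test_tukey_filter_matches_bruteforce_oracle(rng):
    for _ in range(1000):
        n = rng.integers(4, 40)
        x = rng.lognormal(0, rng.uniform(0.2, 1.5), size=n)
        kept, _ = an.filter_outliers(x, mode="tukey")
        assert np.array_equal(np.sort(kept), _oracle_tukey(x))


def test_short_vectors_pass_through_with_warning():
    kept, log = an.filter_outliers([1.0, 2.0, 300.0])
    assert len(kept) == 3 and log.warnings


def test_literal_mode_falls_back_when_incoherent():
    # narrow positive data: 1.5*Q1 exceeds the median, so the literal lower
    # bound would delete the lower quartile wholesale -> Tukey fallback
    x = np.array([10.0, 10.1, 10.2, 10.3, 10.4])
    kept, log = an.filter_outliers(x, mode="literal")
    assert log.warnings and len(kept) == 5


def test_literal_mode_applies_when_coherent():
    # wide-spread data where 1.5*Q1 < median: literal fences apply as printed
    x = np.array([2.0, 3.0, 10.0, 11.0, 12.0, 40.0])
    kept, log = an.filter_outliers(x, mode="literal")
    q1, q3 = np.percentile(x, [25, 75])
    assert set(kept) == set(x[(x >= 1.5 * q1) & (x <= 1.5 * q3)])
    assert not log.warnings


# --- ring-level aggregation -------------------------------------------------


def _toy_ring(n_ew=70, n_lw=30, ring_width=2.0):
    """Ring whose first n_ew sectors are earlywood (one cell per sector)."""
    sectors = np.arange(100)
    ew = sectors < n_ew
    d = np.where(ew, 24.0, 10.0)
    cwt = np.where(ew, 2.0, 5.0)
    lumen = np.pi * d**2 / 4
    cells = pd.DataFrame(
        {
            "tree_id": "T1",
            "year": 2000,
            "rel_pos": (sectors + 0.5) / 100,
            "lumen_area_um2": lumen,
            "cwt_rad_um": cwt,
            "cwt_tan_um": cwt,
            "cwa_um2": np.pi * (d * cwt + cwt**2),
        }
    )
    rings = pd.DataFrame({"tree_id": ["T1"], "year": [2000], "ring_width_mm": [ring_width]})
    return cells, rings


def test_part_widths_partition_ring_width():
    cells, rings = _toy_ring()
    classified = an.classify_cells(cells)
    annual = an.aggregate_annual(classified, rings).set_index("part")
    assert annual.loc["EW", "width_mm"] + annual.loc["LW", "width_mm"] == pytest.approx(2.0)
    assert annual.loc["EW", "width_mm"] == pytest.approx(1.4)
    assert annual.loc["LW", "width_mm"] == pytest.approx(0.6)


def test_identical_cells_aggregate_to_common_value():
    cells, rings = _toy_ring(n_ew=100, n_lw=0)
    classified = an.classify_cells(cells)
    annual = an.aggregate_annual(classified, rings).set_index("part")
    assert annual.loc["EW", "cwt"] == pytest.approx(2.0)
    assert annual.loc["EW", "dh"] == pytest.approx(24.0)
    assert annual.loc["LW", "n_cells"] == 0 and np.isnan(annual.loc["LW", "dh"])


def test_median_is_robust_to_one_extreme_cell():
    cells, rings = _toy_ring(n_ew=100, n_lw=0)
    spiked = cells.copy()
    spiked.loc[0, "cwt_rad_um"] = 0.1  # extreme but still earlywood
    a = an.aggregate_annual(an.classify_cells(cells), rings).set_index("part")
    b = an.aggregate_annual(an.classify_cells(spiked), rings).set_index("part")
    assert a.loc["EW", "cwt"] == pytest.approx(b.loc["EW", "cwt"])


def test_sector_profiles_missing_and_monotone(rng):
    # cells only in first half of the ring -> sectors 51..100 absent
    half = pd.DataFrame(
        {
            "tree_id": "T1",
            "year": 2000,
            "rel_pos": rng.uniform(0, 0.5, 400),
            "lumen_area_um2": 100.0,
            "cwt_rad_um": 2.0,
            "cwt_tan_um": 2.0,
            "cwa_um2": 80.0,
        }
    )
    prof = an.build_sector_profiles(half)
    assert prof["sector"].max() <= 50
    # dense linear-in-position trait -> profile monotone within noise
    pos = rng.uniform(0, 1, 5000)
    lin = pd.DataFrame(
        {
            "tree_id": "T1",
            "year": 2000,
            "rel_pos": pos,
            "lumen_area_um2": 100.0 + 400 * pos * np.exp(0.05 * rng.standard_normal(5000)),
            "cwt_rad_um": 2.0,
            "cwt_tan_um": 2.0,
            "cwa_um2": 80.0,
        }
    )
    prof = an.build_sector_profiles(lin)
    dh = prof[prof["trait"] == "DH"].sort_values("sector")["value"].to_numpy()
    from scipy.stats import spearmanr

    assert spearmanr(np.arange(dh.size), dh).statistic > 0.95
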