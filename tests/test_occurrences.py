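import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oceansdm as o
from oceansdm import occurrences as occ
from oceansdm.errors import AlignmentError, InputError
from oceansdm.occurrences import OccurrenceRecord


@pytest.fixture()
def geom(small_ocean):
    return small_ocean.annual.reference()


# -- read_occurrences -------------------------------------------------------

def test_read_basic_row(tmp_path):
    p = tmp_path / "occ.csv"
    p.write_text("lon,lat,month,source\n10.5,-50.5,2,GBIF\n")
    recs = occ.read_occurrences(str(p))
    assert recs == [OccurrenceRecord(10.5, -50.5, 2, "GBIF")]


def test_read_empty_month(tmp_path):
    p = tmp_path / "occ.csv"
    p.write_text("lon,lat,month\n10.5,-50.5,\n")
    recs = occ.read_occurrences(str(p))
    assert recs[0].month is None


def test_read_iso_date_reduced_to_month(tmp_path):
    p = tmp_path / "occ.csv"
    p.write_text("lon,lat,date\n0.5,-60.5,1998-08-17\n")
    recs = occ.read_occurrences(str(p))
    assert recs[0].month == 8


def test_read_rejects_bad_latitude(tmp_path, caplog):
    p = tmp_path / "occ.csv"
    p.write_text("lon,lat\n10.0,95.0\n12.0,-50.0\nxx,-40.0\n")
    with caplog.at_level("WARNING"):
        recs = occ.read_occurrences(str(p))
    assert len(recs) == 1
    assert "rejected 2" in caplog.text


def test_read_missing_columns_error(tmp_path):
    p = tmp_path / "occ.csv"
    p.write_text("x,y\n1,2\n")
    with pytest.raises(InputError):
        occ.read_occurrences(str(p))


# -- dedupe -----------------------------------------------------------------

def one_degree_geom():
    from oceansdm.grids import EnvGrid

    lat = -59.5 + np.arange(20)
    lon = 0.5 + np.arange(20)
    return EnvGrid("sst", "degC", lat, lon, np.zeros((20, 20)), np.ones((20, 20), dtype=bool))


def test_dedupe_yearly_vs_monthly_counts():
    g = one_degree_geom()
    records = [
        OccurrenceRecord(10.5, -50.5, 2),
        OccurrenceRecord(10.5, -50.5, 8),
        OccurrenceRecord(12.5, -52.5, 2),
    ]
    assert len(occ.dedupe(records, g, "yearly")) == 2
    assert len(occ.dedupe(records, g, "monthly")) == 3


def test_dedupe_single_cell_single_month():
    g = one_degree_geom()
    records = [OccurrenceRecord(10.5, -50.5, 2)] * 5
    assert len(occ.dedupe(records, g, "yearly")) == 1
    assert len(occ.dedupe(records, g, "monthly")) == 1


def test_dedupe_unknown_month_kept_yearly_dropped_monthly():
    g = one_degree_geom()
    records = [OccurrenceRecord(10.5, -50.5, None), OccurrenceRecord(12.5, -52.5, 3)]
    y = occ.dedupe(records, g, "yearly")
    m = occ.dedupe(records, g, "monthly")
    assert len(y) == 2
    assert len(m) == 1
    assert m.n_dropped_no_month == 1


def test_dedupe_matches_brute_force_binning(rng):
    from oceansdm.grids import EnvGrid

    step = 2.0
    lat = -79.0 + step * np.arange(60)
    lon = -179.0 + step * np.arange(180)
    g = EnvGrid("sst", "degC", lat, lon, np.zeros((60, 180)), np.ones((60, 180), dtype=bool))
    records = [
        OccurrenceRecord(
            float(rng.uniform(-180, 180)), float(rng.uniform(-80, 40)),
            int(rng.integers(1, 13)),
        )
        for _ in range(500)
    ]
    # independent oracle: floor-division binning on the cell edges
    def bin_key(r):
        return (int(np.floor((r.lat - (-80.0)) / step)), int(np.floor((r.lon - (-180.0)) / step)))

    expected_yearly = len({bin_key(r) for r in records})
    expected_monthly = len({(bin_key(r), r.month) for r in records})
    assert len(occ.dedupe(records, g, "yearly")) == expected_yearly
    assert len(occ.dedupe(records, g, "monthly")) == expected_monthly
    assert expected_monthly >= expected_yearly


@given(st.lists(
    st.tuples(
        st.floats(-179.9, 179.9), st.floats(-77.9, 77.9),
        st.one_of(st.none(), st.integers(1, 12)),
    ),
    min_size=1, max_size=60,
))
@settings(max_examples=25, deadline=None)
def test_dedupe_idempotent(raw):
    g = one_degree_geom()
    records = [OccurrenceRecord(a, b, m) for a, b, m in raw]
    once = occ.dedupe(records, g, "yearly")
    if once.records:
        twice = occ.dedupe(once.records, g, "yearly")
        assert twice.records == once.records


# -- extract_covariates -----------------------------------------------------

def test_monthly_extraction_uses_month_stack(small_ocean, geom):
    i, j = map(int, np.argwhere(small_ocean.annual.mask)[0])
    rec = OccurrenceRecord(float(geom.lon[j]), float(geom.lat[i]), 2)
    occset = occ.OccurrenceSet([rec], mode="monthly")
    sm = occ.extract_covariates(occset, small_ocean.annual, small_ocean.monthly, mode="monthly")
    expected = small_ocean.monthly[1].values_at([(i, j)], sm.variables)[0]
    np.testing.assert_array_equal(sm.X[0], expected)


def test_yearly_vs_monthly_sst_differ_by_seasonal_anomaly(small_ocean, geom):
    sh = np.argwhere(small_ocean.annual.mask & (small_ocean.annual.lat[:, None] < 0))[0]
    i, j = map(int, sh)
    rec = OccurrenceRecord(float(geom.lon[j]), float(geom.lat[i]), 2)
    y = occ.extract_covariates(occ.OccurrenceSet([rec], "yearly"), small_ocean.annual, mode="yearly")
    m = occ.extract_covariates(
        occ.OccurrenceSet([rec], "monthly"), small_ocean.annual, small_ocean.monthly, mode="monthly"
    )
    k = y.variables.index("sst")
    # SH February anomaly is +seasonal_amp (2.0 for this ocean)
    assert m.X[0, k] - y.X[0, k] == pytest.approx(2.0)


def test_land_records_dropped(small_ocean, geom):
    land = np.argwhere(~small_ocean.annual.mask)[0]
    i, j = map(int, land)
    recs = [
        OccurrenceRecord(float(geom.lon[j]), float(geom.lat[i]), 1),
        OccurrenceRecord(float(geom.lon[0]), float(geom.lat[0]), 1),
    ]
    ocean_rec = None
    for idx in np.argwhere(small_ocean.annual.mask):
        ocean_rec = OccurrenceRecord(float(geom.lon[idx[1]]), float(geom.lat[idx[0]]), 1)
        break
    occset = occ.OccurrenceSet([recs[0], ocean_rec], "yearly")
    sm = occ.extract_covariates(occset, small_ocean.annual, mode="yearly")
    assert len(sm) == 1


def test_missing_monthly_stack_error(small_ocean):
    rec = OccurrenceRecord(0.0, -60.0, 2)
    with pytest.raises(InputError):
        occ.extract_covariates(
            occ.OccurrenceSet([rec], "monthly"),
            small_ocean.annual, small_ocean.monthly[:6], mode="monthly",
        )


# -- sample_background ------------------------------------------------------

def test_exhaustive_background_draw(small_ocean):
    n_ocean = int(small_ocean.annual.mask.sum())
    sm = occ.sample_background(small_ocean.annual, n=n_ocean, seed=0)
    assert len(sm) == n_ocean
    assert len(set(sm.cell_ids)) == n_ocean  # every ocean cell exactly once


def test_degenerate_bias_single_cell(small_ocean):
    ref = small_ocean.annual.reference()
    cell = tuple(map(int, np.argwhere(small_ocean.annual.mask)[5]))
    b = np.zeros(ref.shape)
    b[cell] = 1.0
    bias = ref.with_values(np.where(ref.mask, b, np.nan), variable="bias", units="1")
    sm = occ.sample_background(small_ocean.annual, n=1, bias=bias, seed=1)
    assert sm.cell_ids == [cell]


def test_bias_two_to_one_ratio(small_ocean):
    ref = small_ocean.annual.reference()
    south = ref.lat[:, None] < 0
    b = np.where(np.broadcast_to(south, ref.shape), 2.0, 1.0)
    bias = ref.with_values(np.where(ref.mask, b, np.nan), variable="bias", units="1")
    # with-replacement-like behavior needs many draws; sample a large fraction
    n = int(small_ocean.annual.mask.sum() * 0.5)
    draws = occ.sample_background(small_ocean.annual, n=n, bias=bias, seed=42)
    got_south = sum(1 for c in draws.cell_ids if ref.lat[c[0]] < 0)
    n_south = int((small_ocean.annual.mask & south).sum())
    n_north = int(small_ocean.annual.mask.sum()) - n_south
    # expected proportion under weighted sampling (approximate for w/o replacement)
    exp = 2 * n_south / (2 * n_south + n_north)
    assert abs(got_south / n - exp) < 0.05


def test_background_uniform_inclusion_probability(small_ocean):
    # exchangeability: estimated per-cell inclusion frequency ~ n / N
    N = int(small_ocean.annual.mask.sum())
    n = N // 4
    freq = {}
    for s in range(40):
        sm = occ.sample_background(small_ocean.annual, n=n, seed=s)
        for c in sm.cell_ids:
            freq[c] = freq.get(c, 0) + 1
    rates = np.array(list(freq.values())) / 40.0
    assert abs(rates.mean() - n / N) < 0.01


def test_background_too_many_points_error(small_ocean):
    with pytest.raises(InputError):
        occ.sample_background(small_ocean.annual, n=10**7, seed=0)


def test_background_bias_geometry_mismatch(small_ocean, ocean):
    bias = ocean.annual.grids["sst"].with_values(
        np.ones(ocean.annual.mask.shape), variable="bias", units="1"
    )
    with pytest.raises(AlignmentError):
        occ.sample_background(small_ocean.annual, n=10, bias=bias)


def test_background_monthly_split(small_ocean):
    sm = occ.sample_background_monthly(small_ocean.monthly, n=120, seed=0)
    assert len(sm) == 120
    months, counts = np.unique(sm.months, return_counts=True)
    assert list(months) == list(range(1, 13))
    assert all(c == 10 for c in counts)


# -- build_bias_grid --------------------------------------------------------

def test_bias_single_record(geom):
    rec = OccurrenceRecord(float(geom.lon[3]), float(geom.lat[2]))
    bias = occ.build_bias_grid([rec], geom, smooth_radius=0, floor_frac=0.0)
    vals = np.nan_to_num(bias.values)
    assert vals.sum() == pytest.approx(1.0)
    assert vals[2, 3] == pytest.approx(1.0) or not geom.mask[2, 3]


def test_bias_no_smoothing_is_raw_counts(geom):
    recs = [OccurrenceRecord(float(geom.lon[3]), float(geom.lat[2]))] * 4
    bias = occ.build_bias_grid(recs, geom, smooth_radius=0, floor_frac=0.0)
    assert np.nanmax(bias.values) == pytest.approx(4.0)


def test_bias_mass_concentrates_in_sampled_basin(geom):
    rng = np.random.default_rng(0)
    recs = [
        OccurrenceRecord(float(rng.uniform(0, 60)), float(rng.uniform(-60, -30)))
        for _ in range(1000)
    ]
    bias = occ.build_bias_grid(recs, geom, smooth_radius=1, floor_frac=1e-6)
    vals = np.nan_to_num(bias.values)
    lon_sel = (geom.lon >= -6) & (geom.lon <= 66)
    lat_sel = (geom.lat >= -66) & (geom.lat <= -24)
    basin = np.ix_(np.nonzero(lat_sel)[0], np.nonzero(lon_sel)[0])
    assert vals[basin].sum() / vals.sum() > 0.8


def test_bias_floor_keeps_whole_ocean_admissible(geom):
    rec = OccurrenceRecord(float(geom.lon[0]), float(geom.lat[0]))
    bias = occ.build_bias_grid([rec], geom, smooth_radius=0)
    assert np.nanmin(np.where(geom.mask, bias.values, np.nan)) > 0
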