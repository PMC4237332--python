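import numpy as np
import pytest
import shapely

from psrb.errors import DataIntegrityError, UndefinedScoreError
from psrb.kba import (
    KBASite,
    ProtectedArea,
    bootstrap_protection_series,
    impute_establishment_dates,
    kba_protection_percent,
    mean_protection,
    protection_annual_rate,
    read_protected_areas,
    read_sites,
    write_protected_areas,
    write_sites,
)
from psrb.kba import ProtectionSeries, SERIES_YEARS


def _site(sid="s1", box=(0, 0, 10, 10), country="C1"):
    return KBASite(sid, "IBA", country, shapely.box(*box))


def _pa(pid, box, year, country="C1"):
    return ProtectedArea(pid, country, shapely.box(*box), year)


class TestProtectionPercent:
    def test_full_containment(self):
        site = _site()
        pa = _pa("p1", (-1, -1, 11, 11), 1980)
        assert kba_protection_percent(site, [pa], 2010) == pytest.approx(100.0)

    def test_union_prevents_double_counting(self):
        site = _site()
        half = (0, 0, 5, 10)
        pas = [_pa("p1", half, 1980), _pa("p2", half, 1990)]
        assert kba_protection_percent(site, pas, 2010) == pytest.approx(50.0)

    def test_nothing_established_yet(self):
        site = _site()
        assert kba_protection_percent(site, [_pa("p1", (0, 0, 5, 10), 2000)], 1990) == 0.0

    def test_undated_pas_ignored(self):
        site = _site()
        pa = ProtectedArea("p1", "C1", shapely.box(0, 0, 10, 10), None)
        assert kba_protection_percent(site, [pa], 2010) == 0.0

    def test_zero_area_site_rejected(self):
        with pytest.raises(DataIntegrityError):
            KBASite("z", "IBA", "C1", shapely.Polygon())

    def test_monte_carlo_oracle_on_random_rectangles(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            sx = np.sort(rng.uniform(0, 10, 2))
            sy = np.sort(rng.uniform(0, 10, 2))
            if sx[1] - sx[0] < 0.5 or sy[1] - sy[0] < 0.5:
                continue
            site = _site(box=(sx[0], sy[0], sx[1], sy[1]))
            pas = []
            for j in range(3):
                px = np.sort(rng.uniform(0, 10, 2))
                py = np.sort(rng.uniform(0, 10, 2))
                pas.append(_pa(f"p{j}", (px[0], py[0], px[1], py[1]), 1980))
            pct = kba_protection_percent(site, pas, 2010)
            # 1e5-point Monte Carlo hit fraction
            xs = rng.uniform(sx[0], sx[1], 100_000)
            ys = rng.uniform(sy[0], sy[1], 100_000)
            union = shapely.unary_union([p.geometry for p in pas])
            hits = shapely.contains_xy(union, xs, ys).mean()
            assert pct == pytest.approx(100 * hits, abs=1.0)


class TestMeanProtection:
    def test_hand_mean(self):
        s1, s2 = _site("a", (0, 0, 10, 10)), _site("b", (20, 0, 30, 10))
        pas = [_pa("p1", (0, 0, 10, 10), 1980)]  # covers s1 fully, s2 not at all
        assert mean_protection([s1, s2], pas, 2010) == pytest.approx(50.0)

    def test_all_fully_covered(self):
        sites = [_site("a", (0, 0, 5, 5)), _site("b", (6, 0, 9, 5))]
        pas = [_pa("p1", (-1, -1, 10, 6), 1970)]
        assert mean_protection(sites, pas, 2010) == pytest.approx(100.0)

    def test_single_site_identity(self):
        site = _site(box=(0, 0, 100, 10))
        pa = _pa("p1", (0, 0, 73.41, 10), 1980)
        assert mean_protection([site], [pa], 2010) == pytest.approx(73.41)

    def test_no_sites_raises(self):
        with pytest.raises(UndefinedScoreError):
            mean_protection([], [], 2010)


class TestImputation:
    def test_no_undated_is_identity(self):
        pas = [_pa("p1", (0, 0, 1, 1), 1990), _pa("p2", (1, 0, 2, 1), 2000)]
        out = impute_establishment_dates(pas, np.random.default_rng(0))
        assert out == pas

    def test_single_support_draw(self):
        pas = [
            _pa("p1", (0, 0, 1, 1), 1990),
            ProtectedArea("p2", "C1", shapely.box(1, 0, 2, 1), None),
        ]
        out = impute_establishment_dates(pas, np.random.default_rng(0))
        assert out[1].establishment_year == 1990

    def test_binomial_sampling_check(self):
        pas = [
            _pa("p1", (0, 0, 1, 1), 1960),
            _pa("p2", (1, 0, 2, 1), 2000),
            ProtectedArea("p3", "C1", shapely.box(2, 0, 3, 1), None),
        ]
        rng = np.random.default_rng(7)
        draws = [impute_establishment_dates(pas, rng)[2].establishment_year for _ in range(1000)]
        freq_1960 = np.mean(np.array(draws) == 1960)
        assert freq_1960 == pytest.approx(0.5, abs=0.05)
        assert set(draws) <= {1960, 2000}

    def test_global_pool_fallback(self):
        pas = [
            _pa("p1", (0, 0, 1, 1), 1975, country="C2"),
            ProtectedArea("p2", "C1", shapely.box(1, 0, 2, 1), None),  # C1 has no dated PA
        ]
        out = impute_establishment_dates(pas, np.random.default_rng(0))
        assert out[1].establishment_year == 1975

    def test_no_dates_anywhere_raises(self):
        pas = [ProtectedArea("p1", "C1", shapely.box(0, 0, 1, 1), None)]
        with pytest.raises(DataIntegrityError):
            impute_establishment_dates(pas, np.random.default_rng(0))


class TestBootstrapSeries:
    def _fixture(self, with_missing=False):
        site = _site(box=(0, 0, 10, 10))
        pas = [
            _pa("p1", (0, 0, 4, 10), 1970),
            _pa("p2", (4, 0, 7, 10), 1995),
        ]
        if with_missing:
            pas.append(ProtectedArea("p3", "C1", shapely.box(7, 0, 9, 10), None))
        return site, pas

    def test_all_dated_band_collapses(self):
        site, pas = self._fixture()
        series = bootstrap_protection_series("C1", [site], pas, n_boot=25, seed=3)
        assert np.allclose(series.ci_low, series.mean_pct)
        assert np.allclose(series.ci_high, series.mean_pct)
        # step values are exact fractions of the site area
        assert series.mean_pct[series.years == 1960][0] == 0.0
        assert series.mean_pct[series.years == 1980][0] == pytest.approx(40.0)
        assert series.mean_pct[series.years == 2010][0] == pytest.approx(70.0)

    def test_n_boot_1_collapses_onto_single_replicate(self):
        site, pas = self._fixture(with_missing=True)
        series = bootstrap_protection_series("C1", [site], pas, n_boot=1, seed=5)
        assert np.allclose(series.ci_low, series.mean_pct)
        assert np.allclose(series.ci_high, series.mean_pct)

    def test_monotone_nondecreasing(self):
        site, pas = self._fixture(with_missing=True)
        series = bootstrap_protection_series("C1", [site], pas, n_boot=40, seed=5)
        for arr in (series.mean_pct, series.ci_low, series.ci_high):
            assert np.all(np.diff(arr) >= -1e-12)

    def test_same_seed_identical(self):
        site, pas = self._fixture(with_missing=True)
        a = bootstrap_protection_series("C1", [site], pas, n_boot=30, seed=9)
        b = bootstrap_protection_series("C1", [site], pas, n_boot=30, seed=9)
        assert np.array_equal(a.mean_pct, b.mean_pct)
        assert np.array_equal(a.ci_low, b.ci_low)

    def test_pa_order_invariance(self):
        site, pas = self._fixture(with_missing=True)
        a = bootstrap_protection_series("C1", [site], pas, n_boot=30, seed=9)
        b = bootstrap_protection_series("C1", [site], list(reversed(pas)), n_boot=30, seed=9)
        assert np.array_equal(a.mean_pct, b.mean_pct)
        assert np.array_equal(a.ci_high, b.ci_high)


class TestAnnualRate:
    def _series(self, v1980, v2010):
        years = SERIES_YEARS
        mean = np.interp(years, [1950, 1980, 2010], [0.0, v1980, v2010])
        return ProtectionSeries("u", years, mean, mean, mean, 1)

    def test_flat_series_zero(self):
        s = self._series(30.0, 30.0)
        assert protection_annual_rate(s) == 0.0

    def test_hand_rate(self):
        assert protection_annual_rate(self._series(20.0, 80.0)) == pytest.approx(2.0)

    def test_lao_magnitude(self):
        assert protection_annual_rate(self._series(37.1, 100.0)) == pytest.approx((100 - 37.1) / 30)


class TestGeoJsonIO:
    def test_round_trip(self, tmp_path, scenario):
        spath, ppath = str(tmp_path / "kba.geojson"), str(tmp_path / "pa.geojson")
        write_sites(scenario.sites, spath)
        write_protected_areas(scenario.pas, ppath)
        sites = read_sites(spath)
        pas = read_protected_areas(ppath)
        assert len(sites) == len(scenario.sites)
        assert len(pas) == len(scenario.pas)
        for a, b in zip(pas, scenario.pas):
            assert a.pa_id == b.pa_id
            assert a.establishment_year == b.establishment_year
            assert a.geometry.equals(b.geometry)
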