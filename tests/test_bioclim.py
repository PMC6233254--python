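import numpy as np
import pytest

from paleodown import (
    ConfigurationError,
    GeoGrid,
    GridSpec,
    MonthlyStack,
    UnitError,
    bioclim_values,
    compute_bioclim,
    encode_temperature,
    quarter_sums_and_means,
)
from paleodown.bioclim import NEEDS_MINMAX, round_half_away
from conftest import uniform_stack


def brute_force_bioclim(tmean, prec, tmin=None, tmax=None, ddof=1):
    """Straight-line scalar reference: explicit sequential loops over
    months and quarters, using only Python floats."""
    t = [float(v) for v in tmean]
    p = [float(v) for v in prec]

    def ssum(xs):
        acc = xs[0]
        for x in xs[1:]:
            acc = acc + x
        return acc

    def sstd(xs):
        import math

        mu = ssum(xs) / len(xs)
        return math.sqrt(ssum([(x - mu) ** 2 for x in xs]) / (len(xs) - ddof))

    out = {}
    out["bio1"] = ssum(t) / 12.0
    out["bio4"] = 100.0 * sstd(t)
    out["bio12"] = ssum(p)
    out["bio13"] = max(p)
    out["bio14"] = min(p)
    out["bio15"] = 100.0 * sstd(p) / (1.0 + out["bio12"] / 12.0)
    qs, qt = [], []
    for k in range(12):
        a, b, c = k % 12, (k + 1) % 12, (k + 2) % 12
        qs.append((p[a] + p[b]) + p[c])
        qt.append(((t[a] + t[b]) + t[c]) / 3.0)
    wet = qs.index(max(qs)); dry = qs.index(min(qs))
    warm = qt.index(max(qt)); cold = qt.index(min(qt))
    out["bio8"], out["bio9"] = qt[wet], qt[dry]
    out["bio10"], out["bio11"] = qt[warm], qt[cold]
    out["bio16"], out["bio17"] = qs[wet], qs[dry]
    out["bio18"], out["bio19"] = qs[warm], qs[cold]
    if tmin is not None:
        tn = [float(v) for v in tmin]; tx = [float(v) for v in tmax]
        out["bio2"] = ssum([a - b for a, b in zip(tx, tn)]) / 12.0
        out["bio5"] = max(tx)
        out["bio6"] = min(tn)
        out["bio7"] = out["bio5"] - out["bio6"]
        out["bio3"] = 100.0 * out["bio2"] / out["bio7"] if out["bio7"] != 0 else 0.0
    return out


class TestQuarterWindows:
    def test_constant_precip_sums(self):
        s, _ = quarter_sums_and_means(np.zeros(12), np.full(12, 100.0))
        assert np.allclose(s, 300.0)

    def test_december_wraps_to_january(self):
        prec = np.zeros(12)
        prec[10] = 10.0  # November
        prec[11] = 20.0  # December
        s, _ = quarter_sums_and_means(np.zeros(12), prec)
        assert s[10] == pytest.approx(30.0)  # Nov+Dec+Jan

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.normal(10, 8, 12)
        p = rng.uniform(0, 300, 12)
        s, m = quarter_sums_and_means(t, p)
        for k in range(12):
            months = [k % 12, (k + 1) % 12, (k + 2) % 12]
            assert s[k] == pytest.approx(sum(p[i] for i in months))
            assert m[k] == pytest.approx(sum(t[i] for i in months) / 3)


class TestEncodeTemperature:
    @pytest.mark.parametrize("value,expected", [(10.34, 103), (-2.55, -26), (0.0, 0)])
    def test_tenths_rounded_half_away_from_zero(self, value, expected):
        spec = GridSpec(1, 0, 1, 1, 1, 1)
        g = GeoGrid(spec, np.array([[value]]), units="°C")
        enc = encode_temperature(g)
        assert enc.values[0, 0] == expected
        assert enc.values.dtype == np.int16

    def test_rejects_non_temperature_units(self):
        spec = GridSpec(1, 0, 1, 1, 1, 1)
        with pytest.raises(UnitError):
            encode_temperature(GeoGrid(spec, np.zeros((1, 1)), units="mm/month"))


@pytest.fixture
def spec():
    return GridSpec(5, 0, 2.5, 2.5, 2, 2)


class TestComputeBioclim:
    def test_constant_climate_reduced_set(self, spec):
        """tmean 10 degC / precip 100 mm without tmin/tmax: 14 variables."""
        bset = compute_bioclim(
            uniform_stack("tmean", spec, 10.0, "°C"),
            uniform_stack("precip", spec, 100.0, "mm/month"),
        )
        assert len(bset.available) == 14
        assert not set(NEEDS_MINMAX) & set(bset.available)
        expect = {
            "bio1": 100, "bio4": 0, "bio8": 100, "bio9": 100, "bio10": 100,
            "bio11": 100, "bio12": 1200, "bio13": 100, "bio14": 100,
            "bio15": 0, "bio16": 300, "bio17": 300, "bio18": 300, "bio19": 300,
        }
        for name, value in expect.items():
            assert np.all(bset[name].values == value), name

    def test_full_set_with_minmax(self, spec):
        t = uniform_stack("tmean", spec, 10.0, "°C")
        bset = compute_bioclim(
            t, uniform_stack("precip", spec, 100.0, "mm/month"),
            tmin=uniform_stack("tmin", spec, 10.0, "°C"),
            tmax=uniform_stack("tmax", spec, 10.0, "°C"),
        )
        assert len(bset.available) == 19
        # degenerate diurnal range
        assert np.all(bset["bio2"].values == 0)
        assert np.all(bset["bio3"].values == 0)
        assert np.array_equal(
            bset["bio7"].values, bset["bio5"].values - bset["bio6"].values
        )

    def test_only_one_of_minmax_rejected(self, spec):
        t = uniform_stack("tmean", spec, 10.0, "°C")
        p = uniform_stack("precip", spec, 100.0, "mm/month")
        with pytest.raises(ConfigurationError):
            compute_bioclim(t, p, tmin=uniform_stack("tmin", spec, 5.0, "°C"))

    def test_nodata_propagates(self, spec):
        cube = np.full((12, 2, 2), 10.0)
        mask = np.zeros((12, 2, 2), bool)
        mask[3, 0, 0] = True  # one missing month kills the pixel
        t = MonthlyStack.from_array("tmean", spec, cube, mask, "°C")
        p = uniform_stack("precip", spec, 100.0, "mm/month")
        bset = compute_bioclim(t, p)
        assert all(bset[n].mask[0, 0] for n in bset.available)
        assert not any(bset[n].mask[1, 1] for n in bset.available)

    def test_quantization_matches_integer_encoded_inputs(self, spec):
        rng = np.random.default_rng(7)
        cube = rng.uniform(-5, 25, (12, 2, 2))
        t = MonthlyStack.from_array("tmean", spec, cube, units="°C")
        p = uniform_stack("precip", spec, 100.0, "mm/month")
        quantized = compute_bioclim(t, p, quantize_input=True)
        pre_rounded = MonthlyStack.from_array(
            "tmean", spec, round_half_away(cube * 10) / 10, units="°C"
        )
        direct = compute_bioclim(pre_rounded, p, quantize_input=False)
        for n in quantized.available:
            assert np.array_equal(quantized[n].values, direct[n].values), n


class TestBioclimProperties:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        n = 200
        t = rng.uniform(-15, 30, (12, n))
        p = rng.uniform(0, 400, (12, n))
        tn = t - rng.uniform(0, 8, (12, n))
        tx = t + rng.uniform(0, 8, (12, n))
        vec = bioclim_values(t, p, tn, tx)
        for i in range(0, n, 17):
            ref = brute_force_bioclim(t[:, i], p[:, i], tn[:, i], tx[:, i])
            for name, val in ref.items():
                assert vec[name][i] == pytest.approx(val, rel=1e-12), name

    def test_cyclic_rotation_invariance(self):
        rng = np.random.default_rng(13)
        t = rng.uniform(-10, 30, 12)
        p = rng.uniform(0, 300, 12)
        base = bioclim_values(t, p)
        for shift in (1, 4, 7):
            rolled = bioclim_values(np.roll(t, shift), np.roll(p, shift))
            for name in ("bio1", "bio4", "bio12", "bio13", "bio14", "bio15",
                         "bio16", "bio17"):
                assert rolled[name] == pytest.approx(base[name]), (name, shift)

    def test_adding_constant_precip(self):
        rng = np.random.default_rng(17)
        t = rng.uniform(0, 25, 12)
        p = rng.uniform(0, 200, 12)
        c = 37.0
        base = bioclim_values(t, p)
        shifted = bioclim_values(t, p + c)
        assert shifted["bio12"] == pytest.approx(base["bio12"] + 12 * c)
        assert shifted["bio4"] == pytest.approx(base["bio4"])

    def test_extreme_ordering_invariants(self):
        rng = np.random.default_rng(19)
        t = rng.uniform(-10, 30, (12, 50))
        p = rng.uniform(0, 300, (12, 50))
        tn = t - rng.uniform(0, 6, (12, 50))
        tx = t + rng.uniform(0, 6, (12, 50))
        v = bioclim_values(t, p, tn, tx)
        assert np.all(v["bio13"] >= v["bio14"])
        assert np.all(v["bio16"] >= v["bio17"])
        assert np.all(v["bio5"] >= v["bio6"])
        # wettest-quarter sum equals the brute-force max over windows
        qs, _ = quarter_sums_and_means(t, p)
        assert np.allclose(v["bio16"], qs.max(axis=0))

    def test_quarter_extremes_bound_annual_total(self):
        from hypothesis import given, settings, strategies as st

        @given(
            st.lists(st.floats(0, 1000, allow_nan=False), min_size=12, max_size=12)
        )
        @settings(max_examples=100, deadline=None, derandomize=True)
        def check(prec):
            p = np.asarray(prec)
            v = bioclim_values(np.zeros(12), p)
            qs, _ = quarter_sums_and_means(np.zeros(12), p)
            assert v["bio17"] <= qs.min() + 1e-9
            assert v["bio16"] >= qs.max() - 1e-9
            # any three months cannot out-rain the year
            assert v["bio16"] <= v["bio12"] + 1e-9
            assert v["bio14"] <= v["bio13"]

        check()

    def test_quarter_tie_breaks_to_earliest_window(self):
        # two equally wet quarters; the January-start one must win
        p = np.zeros(12)
        p[[0, 1, 2]] = 50.0
        p[[6, 7, 8]] = 50.0
        t = np.arange(12, dtype=float)
        v = bioclim_values(t, p)
        assert v["bio8"] == pytest.approx(t[[0, 1, 2]].mean())
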