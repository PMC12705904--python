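"""Generator contracts: determinism, degradation profile, noise scaling,
transect geometry and the logarithmic indentation model."""

import numpy as np
import pytest

from ramident.synthetic import (
    CONTROL_INDENTATION,
    TEST_INDENTATION,
    DegradationModel,
    IndentationParams,
    SpectrumSpec,
    fluorescence_background,
    generate_indentation,
    generate_spectrum,
    generate_transect,
)


def f_of_d(d, lam, floor):
    return floor + (1 - floor) * (1 - np.exp(-d / lam))


class TestGenerateSpectrum:
    def test_deterministic_under_seed(self):
        spec = SpectrumSpec("T05", "B", 300.0, seed=7)
        a = generate_spectrum(spec)
        b = generate_spectrum(spec)
        assert np.array_equal(a.intensity, b.intensity)
        c = generate_spectrum(SpectrumSpec("T05", "B", 300.0, seed=8))
        assert not np.array_equal(a.intensity, c.intensity)

    def test_grid_covers_analysis_range(self):
        s = generate_spectrum(SpectrumSpec("T05", "A", 100.0))
        assert s.wavenumber[0] == 1050.0
        assert s.wavenumber[-1] == 1750.0
        assert len(s) == 701
        assert np.all(np.diff(s.wavenumber) == 1.0)

    def test_control_amide1_constant_over_distance(self):
        heights = []
        for d in (50.0, 500.0, 1500.0):
            s = generate_spectrum(
                SpectrumSpec("C12", "A", d, treatment="control"), noise_sigma0=0.0
            )
            heights.append(s.intensity[s.wavenumber == 1667.0][0])
        assert np.ptp(heights) < 1e-9

    def test_naocl_amide1_height_ratio_matches_degradation_factor(self):
        # zero-noise Amide I net height at 50 vs 1500 um must equal
        # f(50)/f(1500) with f(d) = floor + (1-floor)(1-exp(-d/lambda))
        model = DegradationModel(d_scale=250.0, broaden_max=0.0)
        bg = None
        net = {}
        for d in (50.0, 1500.0):
            s = generate_spectrum(
                SpectrumSpec("T05", "A", d), model=model, noise_sigma0=0.0
            )
            if bg is None:
                bg = fluorescence_background(s.wavenumber)
            net[d] = (s.intensity - bg)[s.wavenumber == 1667.0][0]
        expected = f_of_d(50, 250, 0.35) / f_of_d(1500, 250, 0.35)
        assert net[50.0] / net[1500.0] == pytest.approx(expected, rel=1e-9)

    def test_noise_sd_scales_inverse_sqrt_time(self):
        # Monte Carlo over 150 replicates: sd ratio for 12 vs 24 min ~ sqrt(2)
        def noise_sds(acq, n=150):
            quiet = None
            sds = []
            for i in range(n):
                s = generate_spectrum(
                    SpectrumSpec("T01", "A", 500.0, acq_min=acq, seed=10_000 + i)
                )
                clean = generate_spectrum(
                    SpectrumSpec("T01", "A", 500.0, acq_min=acq), noise_sigma0=0.0
                )
                sds.append((s.intensity - clean.intensity).std())
            return np.mean(sds)

        ratio = noise_sds(12) / noise_sds(24)
        assert ratio == pytest.approx(np.sqrt(2), rel=0.05)

    def test_monotone_degradation_noiseless(self):
        model = DegradationModel()
        dists = np.arange(50.0, 1600.0, 100.0)
        h1, h3 = [], []
        for d in dists:
            s = generate_spectrum(SpectrumSpec("T05", "A", d), model, noise_sigma0=0.0)
            bg = fluorescence_background(s.wavenumber)
            net = s.intensity - bg
            h1.append(net[s.wavenumber == 1667.0][0])
            h3.append(net[s.wavenumber == 1243.0][0])
        assert np.all(np.diff(h1) > 0)
        assert np.all(np.diff(h3) > 0)

    def test_inter_tubular_carbonate_below_quarter_of_background_range(self):
        s = generate_spectrum(
            SpectrumSpec("T01", "A", 500.0, locus="inter_tubular"), noise_sigma0=0.0
        )
        bg = fluorescence_background(s.wavenumber, 20.0)
        carb = (s.intensity - bg)[np.abs(s.wavenumber - 1072) <= 15].max()
        assert carb < 0.25 * np.ptp(bg)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"acq_min": 0.0},
            {"acq_min": -5.0},
            {"distance_um": -1.0},
            {"quadrant": "E"},
            {"locus": "between"},
            {"treatment": "bleach"},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        base = dict(tooth_id="T05", quadrant="A", distance_um=100.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            SpectrumSpec(**base)


class TestDegradationModel:
    def test_factor_monotone_and_saturating(self):
        m = DegradationModel(d_scale=250.0, amide1_floor=0.35)
        d = np.linspace(0, 5000, 200)
        f = np.array([m.factor(x, 0.35) for x in d])
        assert np.all(np.diff(f) >= 0)
        assert f[0] == pytest.approx(0.35)
        assert f[-1] == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize(
        "kwargs", [{"d_scale": 0.0}, {"amide1_floor": 1.5}, {"broaden_max": -0.1}]
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            DegradationModel(**kwargs)


class TestGenerateTransect:
    def test_study_design_distances(self):
        _, mf = generate_transect("T05", "A", 18, 50.0)
        assert list(mf["distance_um"]) == [50.0 * k for k in range(1, 19)]

    def test_control_design_distances(self):
        _, mf = generate_transect("C12", "A", 6, 150.0, treatment="control")
        assert list(mf["distance_um"]) == [150.0 * k for k in range(1, 7)]

    def test_single_point(self):
        sp, mf = generate_transect("T05", "C", 1, 75.0)
        assert len(sp) == 1
        assert mf["distance_um"].iloc[0] == 75.0

    def test_optional_cdj_point(self):
        _, mf = generate_transect("T05", "A", 3, 50.0, cdj_offset_um=1700.0)
        assert list(mf["distance_um"]) == [50.0, 100.0, 150.0, 1700.0]

    def test_deterministic_and_manifest_schema(self):
        sp1, mf1 = generate_transect("T05", "D", 4, 50.0, seed=3)
        sp2, mf2 = generate_transect("T05", "D", 4, 50.0, seed=3)
        assert all(
            np.array_equal(a.intensity, b.intensity) for a, b in zip(sp1, sp2)
        )
        assert mf1.equals(mf2)
        for col in ("file", "tooth_id", "quadrant", "distance_um", "acq_min",
                    "locus", "treatment"):
            assert col in mf1.columns

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            generate_transect("T05", "A", 0, 50.0)
        with pytest.raises(ValueError):
            generate_transect("T05", "A", 3, -1.0)


class TestGenerateIndentation:
    def test_depth_equals_a_when_log_term_zero(self):
        # distance + c = 1  =>  depth = a exactly
        p = IndentationParams(a=80.0, b=5.0, c=0.25, sigma=0.0)
        df = generate_indentation("T05", "test", [0.75], params=p)
        assert df["depth_um"].iloc[0] == pytest.approx(80.0)

    def test_noiseless_depths_match_formula(self):
        p = IndentationParams(a=90.0, b=4.0, c=1.0, sigma=0.0)
        d = [50.0, 200.0, 800.0]
        df = generate_indentation("T05", "test", d, params=p)
        expected = 90.0 - 4.0 * np.log(np.array(d) + 1.0)
        assert np.allclose(df["depth_um"], expected)

    def test_near_lumen_deeper_than_far_monte_carlo(self):
        rng = np.random.default_rng(5)
        near = generate_indentation("T05", "test", rng.uniform(0, 100, 1000), seed=1)
        far = generate_indentation("T05", "test", rng.uniform(800, 900, 1000), seed=2)
        assert near["depth_um"].mean() > far["depth_um"].mean()

    def test_defaults_control_shallower_and_flatter(self):
        assert CONTROL_INDENTATION.a < TEST_INDENTATION.a
        assert CONTROL_INDENTATION.b < TEST_INDENTATION.b

    def test_deterministic(self):
        a = generate_indentation("T05", "test", [10, 50, 90], seed=11)
        b = generate_indentation("T05", "test", [10, 50, 90], seed=11)
        assert a.equals(b)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            IndentationParams(a=80, b=5, c=0.0)
        with pytest.raises(ValueError):
            generate_indentation("T05", "test", [-5.0])
        with pytest.raises(ValueError):
            generate_indentation("T05", "irrigated", [5.0])
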