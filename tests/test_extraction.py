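import numpy as np
import pytest

import metabarcode as mb
from metabarcode.cube import NoiseModel, layout_reflectance, simulate_cube
from metabarcode.extraction import (absorbance_at_resonance, average_doubled,
                                    exclusion_flags,
                                    extract_metapixel_spectra,
                                    per_pixel_absorbance,
                                    reconstruct_absorbance_spectrum,
                                    render_barcode_map, timeseries_absorbance)
from metabarcode.grid import SpectralGrid, model_grid
from metabarcode.kinetics import (KineticsParams, LedEvent, MembraneState,
                                  SwitchProtocol)
from metabarcode.molecular import make_molecular_model
from metabarcode.spectra import AbsorbanceSpectrum, ReflectanceSpectrum

NOISELESS = NoiseModel(additive_sigma=0.0, drift_amplitude=0.0)


@pytest.fixture(scope="module")
def small():
    grid = SpectralGrid(1400.0, 1800.0, 8.0)
    barcode = mb.build_target_barcode(4, (1450.0, 1750.0))
    layout = mb.double_and_randomize(barcode, seed=3)
    return grid, barcode, layout


def spectrum(grid, values, did=0, role="sample"):
    return ReflectanceSpectrum(grid=grid, values=np.asarray(values, float),
                               design_id=did, role=role)


class TestExtraction:
    def test_full_layout_yields_100_spectra(self, grid, layout):
        molecular = make_molecular_model()
        cube = simulate_cube(layout, MembraneState(0.9), molecular,
                             NOISELESS, grid, seed=0, block_px=2)
        spectra = extract_metapixel_spectra(cube, layout)
        assert len(spectra) == 100

    def test_noise_free_round_trip_is_exact(self, small):
        """simulate -> extract -> average reproduces generator spectra."""
        grid, barcode, layout = small
        molecular = make_molecular_model()
        state = MembraneState(0.9, 0.9)
        cube = simulate_cube(layout, state, molecular, NOISELESS, grid,
                             seed=0, block_px=4)
        averaged = average_doubled(extract_metapixel_spectra(cube, layout),
                                   layout)
        expected = layout_reflectance(layout, state, molecular, grid)
        by_slot = {layout.slots[i]: expected[i] for i in range(layout.n_slots)}
        assert len(averaged) == len(barcode)
        for s in averaged:
            assert np.allclose(s.values, by_slot[s.design_id], atol=1e-12)

    def test_hot_pixel_shifts_block_mean_by_value_over_n(self, small):
        grid, _, layout = small
        molecular = make_molecular_model()
        cube = simulate_cube(layout, MembraneState(0.1), molecular,
                             NOISELESS, grid, seed=0, block_px=4)
        base = extract_metapixel_spectra(cube, layout)[0].values.copy()
        iw = 5
        bumped = cube.values.copy()
        delta = bumped[1, 1, iw]  # double one pixel of slot (0, 0)
        bumped[1, 1, iw] *= 2
        cube2 = mb.HyperspectralCube(grid=grid, values=bumped)
        shifted = extract_metapixel_spectra(cube2, layout)[0].values
        assert shifted[iw] - base[iw] == pytest.approx(delta / 16, rel=1e-9)

    def test_block_outside_cube_rejected(self, small):
        grid, _, layout = small
        tiny = mb.HyperspectralCube(grid=grid,
                                    values=np.ones((5, 5, len(grid))))
        with pytest.raises(ValueError):
            extract_metapixel_spectra(tiny, layout, block_px=4)

    def test_extraction_commutes_with_scaling(self, small):
        grid, _, layout = small
        molecular = make_molecular_model()
        cube = simulate_cube(layout, MembraneState(0.9), molecular,
                             NoiseModel(5e-3, 0.0), grid, seed=9, block_px=4)
        scaled = mb.HyperspectralCube(grid=grid, values=2.0 * cube.values)
        a = average_doubled(extract_metapixel_spectra(cube, layout), layout)
        b = average_doubled(extract_metapixel_spectra(scaled, layout), layout)
        for s1, s2 in zip(a, b):
            assert np.allclose(2.0 * s1.values, s2.values, rtol=1e-12)


class TestAverageDoubled:
    def test_mean_of_duplicates(self, small):
        grid, _, layout = small
        spectra = []
        for slot, did in enumerate(layout.slots):
            val = 0.2 if slot % 2 == 0 else 0.4
            spectra.append(spectrum(grid, np.full(len(grid), val), did))
        averaged = average_doubled(spectra, layout)
        for s in averaged:
            close = np.isclose(s.values[:, None], [0.2, 0.3, 0.4],
                               rtol=0, atol=1e-12)
            assert close.any(axis=1).all()

    def test_identical_duplicates_idempotent(self, small):
        grid, _, layout = small
        vals = np.linspace(0.1, 0.5, len(grid))
        spectra = [spectrum(grid, vals, did) for did in layout.slots]
        for s in average_doubled(spectra, layout):
            assert np.array_equal(s.values, vals)

    def test_extras_excluded_and_count_is_49(self, grid, layout):
        spectra = [spectrum(grid, np.ones(len(grid)), did)
                   for did in layout.slots]
        averaged = average_doubled(spectra, layout)
        assert len(averaged) == 49
        assert not {s.design_id for s in averaged} & set(layout.extras)

    def test_duplicate_noise_reduction(self, small):
        """Averaging duplicates halves the variance of i.i.d. pixel noise."""
        grid, _, layout = small
        molecular = make_molecular_model()
        noise = NoiseModel(additive_sigma=0.05, drift_amplitude=0.0)
        iw = 3
        slot = next(s for s, did in enumerate(layout.slots)
                    if did not in layout.extras)
        did = layout.slots[slot]
        singles, avgs = [], []
        for seed in range(100):
            cube = simulate_cube(layout, MembraneState(0.1), molecular,
                                 noise, grid, seed=seed, block_px=2)
            spectra = extract_metapixel_spectra(cube, layout)
            singles.append(spectra[slot].values[iw])
            avg = average_doubled(spectra, layout)
            avgs.append(next(s for s in avg
                             if s.design_id == did).values[iw])
        assert np.var(avgs) < np.var(singles)


class TestAbsorbance:
    def test_identity_ratio_gives_zero(self, grid):
        s = spectrum(grid, np.full(len(grid), 0.3))
        assert absorbance_at_resonance(s, s, 1600.0) == 0.0

    def test_ratio_one_tenth_gives_unity(self, grid):
        ref = spectrum(grid, np.full(len(grid), 0.5), role="reference")
        smp = spectrum(grid, np.full(len(grid), 0.05))
        assert absorbance_at_resonance(smp, ref, 1600.0) == pytest.approx(1.0)

    def test_molecular_loss_gives_positive_absorbance(self, grid, barcode, layout):
        molecular = make_molecular_model()
        membrane = simulate_cube(layout, MembraneState(0.9, 0.9), molecular,
                                 NOISELESS, grid, seed=0, block_px=2)
        d2o = simulate_cube(layout, MembraneState(0.9, coverage=0.0),
                            molecular, NOISELESS, grid, seed=0, block_px=2)
        samples = average_doubled(extract_metapixel_spectra(membrane, layout),
                                  layout)
        refs = average_doubled(extract_metapixel_spectra(d2o, layout), layout)
        pp = per_pixel_absorbance(samples, refs, layout)
        assert len(pp.values) == 49
        assert np.all(pp.values > 0)

    def test_nonpositive_reflectance_rejected(self, grid):
        ref = spectrum(grid, np.zeros(len(grid)), role="reference")
        smp = spectrum(grid, np.full(len(grid), 0.1))
        with pytest.raises(ValueError):
            absorbance_at_resonance(smp, ref, 1600.0)


class TestReconstruction:
    def test_cubic_signal_preserved(self):
        """Order-3 Savitzky-Golay reproduces cubic polynomials exactly."""
        grid = model_grid()
        pos = grid.values  # dense samples: interpolation is the identity
        poly = np.poly1d([2e-8, -1e-5, 3e-3, 0.2])
        pp = AbsorbanceSpectrum(pos, poly(pos - 1300.0))
        rec = reconstruct_absorbance_spectrum(pp, grid)
        assert np.allclose(rec.values, poly(grid.values - 1300.0), rtol=1e-9)

    def test_constant_preserved(self):
        grid = model_grid()
        pp = AbsorbanceSpectrum(np.linspace(1300, 1800, 20), np.full(20, 0.42))
        rec = reconstruct_absorbance_spectrum(pp, grid)
        assert np.allclose(rec.values, 0.42)

    def test_injected_1511_band_recovered(self):
        """End-to-end: per-pixel absorbance of a single 1511 cm^-1 band
        reconstructs with its maximum within 2 grid steps of 1511."""
        grid = model_grid()
        barcode = mb.build_target_barcode()
        layout = mb.double_and_randomize(barcode, seed=0)
        molecular = make_molecular_model(
            trans_bands=(), cis_bands=(mb.AbsorptionBand(1511.0, 15.0, 1.0),),
            density_scale_cis=1.0)
        membrane = simulate_cube(layout, MembraneState(1.0, 0.9), molecular,
                                 NOISELESS, grid, seed=0, block_px=2)
        d2o = simulate_cube(layout, MembraneState(1.0, 0.0), molecular,
                            NOISELESS, grid, seed=0, block_px=2)
        samples = average_doubled(extract_metapixel_spectra(membrane, layout),
                                  layout)
        refs = average_doubled(extract_metapixel_spectra(d2o, layout), layout)
        pp = per_pixel_absorbance(samples, refs, layout)
        rec = reconstruct_absorbance_spectrum(pp, grid)
        peak = grid.values[np.argmax(rec.values)]
        assert abs(peak - 1511.0) <= 2 * grid.step

    def test_window_validation(self):
        pp = AbsorbanceSpectrum(np.linspace(1300, 1800, 10), np.zeros(10))
        with pytest.raises(ValueError):
            reconstruct_absorbance_spectrum(pp, model_grid(), window=3)


class TestBarcodeMap:
    def test_constant_field(self):
        pp = AbsorbanceSpectrum(np.linspace(1400, 1800, 49), np.full(49, 0.7),
                                design_ids=np.arange(49))
        assert np.all(render_barcode_map(pp) == 0.7)

    def test_flatten_round_trips_design_order(self):
        vals = np.arange(49.0)
        pp = AbsorbanceSpectrum(np.linspace(1400, 1800, 49), vals,
                                design_ids=np.arange(49))
        assert np.array_equal(render_barcode_map(pp).ravel(), vals)

    def test_wrong_count_rejected(self):
        pp = AbsorbanceSpectrum(np.linspace(1400, 1800, 10), np.zeros(10))
        with pytest.raises(ValueError):
            render_barcode_map(pp)

    def test_cis_membrane_maxima_at_band_resonant_pixels(self, grid, layout):
        """The molecular barcode of a cis membrane peaks at metapixels
        resonant near the lipid bands (1470-1511 and 1735 cm^-1)."""
        molecular = make_molecular_model()
        membrane = simulate_cube(layout, MembraneState(0.9, 0.9), molecular,
                                 NOISELESS, grid, seed=0, block_px=2)
        d2o = simulate_cube(layout, MembraneState(0.9, 0.0), molecular,
                            NOISELESS, grid, seed=0, block_px=2)
        samples = average_doubled(extract_metapixel_spectra(membrane, layout),
                                  layout)
        refs = average_doubled(extract_metapixel_spectra(d2o, layout), layout)
        pp = per_pixel_absorbance(samples, refs, layout)
        top5 = np.argsort(pp.values)[-5:]
        nus = pp.positions[top5]
        near_band = (np.abs(nus[:, None] -
                            np.array([1470, 1496, 1511, 1735])) < 20).any(axis=1)
        assert near_band.all()


class TestTimeseries:
    def make_cubes(self, grid, layout, states, times):
        molecular = make_molecular_model()
        return [simulate_cube(layout, s, molecular, NOISELESS, grid, seed=0,
                              block_px=2, timestamp_s=t)
                for s, t in zip(states, times)]

    def test_identity_frames_give_zero_series(self, small):
        grid, _, layout = small
        times = np.arange(5) * 64.0
        states = [MembraneState(0.1, 0.0)] * 5
        cubes = self.make_cubes(grid, layout, states, times)
        did = layout.slots[0] if layout.slots[0] not in layout.extras \
            else layout.slots[1]
        df = timeseries_absorbance(cubes, layout, [0, 1], did)
        assert np.allclose(df["absorbance"], 0.0, atol=1e-12)

    def test_empty_reference_rejected(self, small):
        grid, _, layout = small
        cubes = self.make_cubes(grid, layout, [MembraneState(0.1)], [0.0])
        with pytest.raises(ValueError):
            timeseries_absorbance(cubes, layout, [], 0)

    def test_exclusion_window_before_first_led(self):
        """First LED at 70 min: frames in [56, 70) min are excluded."""
        protocol = SwitchProtocol((LedEvent("UV", 70 * 60.0, 270.0),), 64.0)
        times = np.arange(0.0, 80 * 60.0, 64.0)
        flags = exclusion_flags(times, protocol)
        in_window = (times >= 56 * 60.0) & (times < 70 * 60.0)
        on = (times >= 70 * 60.0) & (times < 70 * 60.0 + 270.0)
        assert np.array_equal(flags, in_window | on)

    def test_led_on_frames_excluded(self):
        protocol = SwitchProtocol((LedEvent("UV", 1000.0, 270.0),), 64.0)
        times = np.array([999.0, 1000.0, 1100.0, 1269.0, 1270.0])
        flags = exclusion_flags(times, protocol, pre_window_s=0.0)
        assert flags.tolist() == [False, True, True, True, False]
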