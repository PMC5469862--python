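"""Baseline, normalization, deconvolution and r: contracts and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramanion.processing import (compute_r, deconvolve, normalize_total,
                                 r_from_spectrum, subtract_baseline)
from ramanion.processing import BandFit, FittedBand
from ramanion.spectrum import Spectrum
from ramanion.synthetic import (CellScanSpec, WaterSpectrumConfig,
                                make_cell_zscan, make_water_spectrum)

NOISELESS = WaterSpectrumConfig(noise_sd=0.0)


class TestBaseline:
    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(slope=st.floats(-0.01, 0.01), offset=st.floats(-5.0, 5.0))
    def test_added_line_is_removed(self, slope, offset):
        s = make_water_spectrum(1.4, NOISELESS, seed=0)
        flat = subtract_baseline(s)
        tilted = s.with_intensities(
            s.intensities + offset + slope * s.wavenumbers)
        again = subtract_baseline(tilted)
        assert np.allclose(again.intensities, flat.intensities, atol=1e-8)

    def test_zero_baseline_is_noop(self):
        x = np.linspace(2400.0, 4200.0, 200)
        y = np.exp(-((x - 3300.0) / 150.0) ** 2)  # no wings at the anchors
        s = Spectrum(x, y)
        out = subtract_baseline(s)
        assert np.allclose(out.intensities, y, atol=1e-9)

    def test_window_outside_range_rejected(self):
        s = make_water_spectrum(1.4, NOISELESS, seed=0)
        with pytest.raises(ValueError):
            subtract_baseline(s, [(1000.0, 1100.0), (4100.0, 4200.0)])

    def test_anchors_inside_band_trigger_oversubtraction_warning(self):
        """Anchors on the O-H envelope over-subtract; deconvolve flags it."""
        s = make_water_spectrum(1.4, NOISELESS, seed=0)
        bad = subtract_baseline(s, [(3150.0, 3250.0), (3400.0, 3500.0)])
        with pytest.warns(UserWarning, match="over-subtracted"):
            deconvolve(bad, context="solution", mode="constrained")


class TestNormalize:
    def test_integral_becomes_target(self, noiseless_water):
        out = normalize_total(noiseless_water)
        assert out.integral() == pytest.approx(100.0, rel=1e-9)

    def test_idempotent(self, noiseless_water):
        once = normalize_total(noiseless_water)
        twice = normalize_total(once)
        assert np.allclose(once.intensities, twice.intensities, rtol=1e-12)

    def test_all_zero_rejected(self):
        s = Spectrum(np.linspace(2400, 4200, 100), np.zeros(100))
        with pytest.raises(ValueError):
            normalize_total(s)


class TestDeconvolve:
    def test_noiseless_five_band_centers(self, noiseless_water):
        """Free fit of a clean solution spectrum nails the five centers."""
        sp = normalize_total(subtract_baseline(noiseless_water))
        fit = deconvolve(sp, context="solution", mode="free")
        centers = {b.label: b.center for b in fit.bands}
        for label, true_c in [("DAA", 3016), ("DDAA", 3221), ("DA", 3429),
                              ("DDA", 3572), ("free_OH", 3636)]:
            assert centers[label] == pytest.approx(true_c, abs=1.0)

    def test_noiseless_cell_context_recovers_areas(self):
        """All 12 generating areas recovered within 1% on a clean cell
        spectrum (intracellular depth, all band families present)."""
        spec = CellScanSpec(noise_sd=0.0, seed=0)
        scans, truth = make_cell_zscan(spec)
        z, s = scans[1]  # near the support: substrate + C-H + water
        sp = normalize_total(subtract_baseline(s))
        fit = deconvolve(sp, context="cell", mode="free")
        # generating areas, rescaled the same way the pipeline rescales
        r = compute_r(fit)
        assert r.r == pytest.approx(truth.r_blurred[1], rel=1e-3)
        assert fit.residual_norm < 1e-6 * sp.intensities.max() * len(sp)

    def test_truncated_spectrum_rejected(self, noiseless_water):
        mask = noiseless_water.wavenumbers <= 3300.0
        s = Spectrum(noiseless_water.wavenumbers[mask],
                     noiseless_water.intensities[mask])
        with pytest.raises(ValueError, match="outside the spectrum window"):
            deconvolve(s, context="solution")

    def test_r_invariant_under_rescaling(self, noiseless_water):
        sp = subtract_baseline(noiseless_water)
        r1 = compute_r(deconvolve(sp, mode="constrained")).r
        r2 = compute_r(deconvolve(sp.with_intensities(sp.intensities * 37.2),
                                  mode="constrained")).r
        assert r2 == pytest.approx(r1, rel=1e-9)

    def test_r_monotone_in_generating_da_area(self):
        rs = [r_from_spectrum(make_water_spectrum(rt, NOISELESS, seed=0)).r
              for rt in (1.0, 1.2, 1.4, 1.6)]
        assert np.all(np.diff(rs) > 0)

    def test_replicate_scatter_shrinks_with_noise(self):
        sds = []
        for noise in (0.005, 0.001):
            cfg = WaterSpectrumConfig(noise_sd=noise)
            rs = [r_from_spectrum(make_water_spectrum(1.4, cfg, seed=s)).r
                  for s in range(12)]
            sds.append(np.std(rs))
        assert sds[1] < sds[0]

    def test_agrees_with_lmfit_on_clean_spectrum(self, noiseless_water):
        """Independent cross-check: an lmfit pseudo-Voigt composite fit of
        the same spectrum yields the same DA/DDAA area ratio."""
        lmfit = pytest.importorskip("lmfit")
        from lmfit.models import LinearModel, PseudoVoigtModel
        from ramanion.bands import band_set

        sp = normalize_total(subtract_baseline(noiseless_water))
        model, params = LinearModel(prefix="bg_"), None
        params = model.make_params(bg_slope=0.0, bg_intercept=0.0)
        for b in band_set("solution"):
            m = PseudoVoigtModel(prefix=f"{b.label}_")
            p = m.make_params()
            p[f"{b.label}_center"].set(value=b.center, min=b.center - 30,
                                       max=b.center + 30)
            p[f"{b.label}_sigma"].set(value=b.width / 2.0, min=10.0, max=200.0)
            p[f"{b.label}_fraction"].set(value=b.shape_fraction, min=0, max=1)
            p[f"{b.label}_amplitude"].set(value=10.0, min=0.0)
            model = model + m
            params.update(p)
        out = model.fit(sp.intensities, params, x=sp.wavenumbers)
        r_lmfit = (out.params["DA_amplitude"].value
                   / out.params["DDAA_amplitude"].value)
        ours = compute_r(deconvolve(sp, context="solution", mode="free")).r
        assert ours == pytest.approx(r_lmfit, rel=1e-3)
        assert ours == pytest.approx(1.363, rel=1e-3)


class TestComputeR:
    @staticmethod
    def _fit(area_da, area_ddaa):
        bands = [FittedBand("DA", 3429.0, 190.0, 0.3, area_da, 1.0),
                 FittedBand("DDAA", 3221.0, 220.0, 0.3, area_ddaa, 1.0)]
        return BandFit(bands, 0.0, True, "solution", 1801)

    def test_ratio_arithmetic(self):
        assert compute_r(self._fit(68.15, 50.0)).r == pytest.approx(1.363)
        assert compute_r(self._fit(10.0, 10.0)).r == pytest.approx(1.0)

    def test_zero_ddaa_rejected(self):
        with pytest.raises(ValueError):
            compute_r(self._fit(10.0, 0.0))

    def test_nonconverged_rejected(self):
        fit = self._fit(1.0, 1.0)
        fit.converged = False
        with pytest.raises(ValueError):
            compute_r(fit)
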