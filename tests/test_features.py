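"""Feature derivation: filtering, band power, peaks, abundance, averaging."""

import dataclasses

import numpy as np
import pytest

from slowspec import BANDS, SpectrumSpec, make_spectrum, rotate_spectrum_spec
from slowspec.features import (
    BandDefinition,
    abundance,
    band_power,
    patient_features,
    quality_filter,
    select_band_peak,
)
from slowspec.model import AperiodicParams, FitSettings, Peak, SpectralFit
from slowspec.spectral import PowerSpectrum


def _fit(r2=1.0, peaks=(), exponent=1.0, offset=-12.0):
    return SpectralFit(
        AperiodicParams(offset, exponent), list(peaks), r2, FitSettings()
    )


class TestQualityFilter:
    def test_bad_fit_on_one_side_removes_both(self):
        pre = {"Fz": _fit(0.95), "Pz": _fit(0.95)}
        post = {"Fz": _fit(0.70), "Pz": _fit(0.99)}
        assert quality_filter(pre, post) == ["Pz"]

    def test_perfect_fits_all_retained(self):
        pre = {c: _fit(1.0) for c in "abc"}
        post = {c: _fit(1.0) for c in "abc"}
        assert sorted(quality_filter(pre, post)) == ["a", "b", "c"]

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            quality_filter({"Fz": _fit()}, {"Pz": _fit()})

    def test_noisy_patient_dropped_pipeline_continues(self):
        """Systematic noise on every channel pushes all fits below the
        R^2 bar; the patient vanishes but the table is still built."""
        from slowspec.features import cohort_feature_table
        from slowspec.model import fit_power_spectrum

        def noisy_ps(pid, tp, seed):
            spec = SpectrumSpec(offset=-12, exponent=0.4, noise_sd=1.0)
            chans = [make_spectrum(spec, seed + i).power[0] for i in range(2)]
            return PowerSpectrum(spec.freqs, np.vstack(chans), ["a", "b"], pid, tp)

        fits, spectra = {}, {}
        for pid, seed in (("bad", 0), ("good", 100)):
            spectra[pid] = {}
            fits[pid] = {}
            for k, tp in enumerate(("pre", "post")):
                if pid == "bad":
                    ps = noisy_ps(pid, tp, seed + 10 * k)
                else:
                    spec = SpectrumSpec(offset=-12, exponent=1.0, noise_sd=0.02)
                    ps = PowerSpectrum(
                        spec.freqs,
                        np.vstack([make_spectrum(spec, seed + 10 * k + i).power[0] for i in range(2)]),
                        ["a", "b"], pid, tp,
                    )
                spectra[pid][tp] = ps
                fits[pid][tp] = fit_power_spectrum(ps)
        table = cohort_feature_table(fits, spectra)
        assert list(table["patient"]) == ["good"]


class TestBandPower:
    def test_flat_spectrum_every_band(self):
        ps = make_spectrum(SpectrumSpec(offset=-12, exponent=0), 0)
        for band in BANDS.values():
            assert band_power(ps, band) == pytest.approx(-12.0)

    def test_rotation_raises_delta_band_power(self):
        spec = SpectrumSpec(offset=-12, exponent=1.0)
        rot = rotate_spectrum_spec(spec, 0.6, pivot_hz=30.0)
        assert band_power(make_spectrum(rot, 0), BANDS["delta"]) > band_power(
            make_spectrum(spec, 0), BANDS["delta"]
        )

    def test_added_delta_peak_raises_band_power_with_fixed_exponent(self):
        spec = SpectrumSpec(offset=-12, exponent=1.0)
        withpeak = dataclasses.replace(spec, peaks=((2.5, 0.5, 0.8),))
        assert band_power(make_spectrum(withpeak, 0), BANDS["delta"]) > band_power(
            make_spectrum(spec, 0), BANDS["delta"]
        )

    def test_empty_band_rejected(self):
        ps = make_spectrum(SpectrumSpec(), 0)
        with pytest.raises(ValueError, match="no bins"):
            band_power(ps, BandDefinition("sub", 0.01, 0.02))


class TestSelectBandPeak:
    def test_highest_peak_wins(self):
        fit = _fit(peaks=[Peak(5.0, 0.3, 1.0), Peak(6.0, 0.6, 1.0)])
        assert select_band_peak(fit, BANDS["theta"]).height == 0.6

    def test_no_peak_in_band_returns_none(self):
        fit = _fit(peaks=[Peak(10.0, 0.5, 1.0)])
        assert select_band_peak(fit, BANDS["delta"]) is None

    def test_boundary_4hz_goes_to_theta(self):
        fit = _fit(peaks=[Peak(4.0, 0.5, 1.0)])
        assert select_band_peak(fit, BANDS["delta"]) is None
        assert select_band_peak(fit, BANDS["theta"]) is not None

    def test_boundary_12hz_stays_in_alpha(self):
        fit = _fit(peaks=[Peak(12.0, 0.5, 1.0)])
        assert select_band_peak(fit, BANDS["alpha"]) is not None


class TestAbundance:
    def test_all_and_none(self):
        peaked = [_fit(peaks=[Peak(2.5, 0.4, 1.0)]) for _ in range(5)]
        bare = [_fit() for _ in range(5)]
        assert abundance(peaked, BANDS["delta"]) == 1.0
        assert abundance(bare, BANDS["delta"]) == 0.0

    def test_zero_electrodes_rejected(self):
        with pytest.raises(ValueError, match="zero retained"):
            abundance([], BANDS["delta"])

    def test_order_and_rescaling_invariance(self):
        fits = [_fit(peaks=[Peak(2.5, 0.4, 1.0)]), _fit(), _fit(peaks=[Peak(3.0, 0.2, 1.0)])]
        a = abundance(fits, BANDS["delta"])
        assert abundance(fits[::-1], BANDS["delta"]) == a
        # rescaling power moves the offset, not the peak list
        shifted = [
            dataclasses.replace(f, aperiodic=AperiodicParams(-10.0, 1.0)) for f in fits
        ]
        assert abundance(shifted, BANDS["delta"]) == a

    def test_matches_binomial_expectation(self, rng):
        """Per-electrode emergence probability 0.4 over many patients."""
        vals = []
        for _ in range(50):
            fits = [
                _fit(peaks=[Peak(5.5, 0.5, 1.0)]) if rng.random() < 0.4 else _fit()
                for _ in range(30)
            ]
            vals.append(abundance(fits, BANDS["theta"]))
        assert np.mean(vals) == pytest.approx(0.4, abs=0.05)


class TestPatientFeatures:
    def _spectra(self, pid="p", n=3):
        spec = SpectrumSpec(offset=-12, exponent=1.0)
        power = np.vstack([make_spectrum(spec, 0).power[0]] * n)
        labels = [f"ch{i}" for i in range(n)]
        return (
            PowerSpectrum(spec.freqs, power, labels, pid, "pre"),
            PowerSpectrum(spec.freqs, power, labels, pid, "post"),
            labels,
        )

    def test_identical_electrodes_average_to_value(self):
        pre_ps, post_ps, labels = self._spectra()
        fits = {c: _fit(exponent=1.3) for c in labels}
        row = patient_features(fits, fits, pre_ps, post_ps)
        assert row["exponent_pre"] == pytest.approx(1.3)
        assert row["exponent_diff"] == pytest.approx(0.0)
        assert row["n_electrodes_retained"] == 3

    def test_delta_sign_convention(self):
        """Post-treatment exponent increase gives negative pre-minus-post."""
        pre_ps, post_ps, labels = self._spectra()
        pre = {c: _fit(exponent=0.9) for c in labels}
        post = {c: _fit(exponent=1.25) for c in labels}
        row = patient_features(pre, post, pre_ps, post_ps)
        assert row["exponent_diff"] == pytest.approx(-0.35)

    def test_oscillation_emergence_pre_absent_post_present(self):
        pre_ps, post_ps, labels = self._spectra(n=4)
        pre = {c: _fit() for c in labels}
        post = {
            c: _fit(peaks=[Peak(5.5, 0.6, 1.0)]) if i < 2 else _fit()
            for i, c in enumerate(labels)
        }
        row = patient_features(pre, post, pre_ps, post_ps)
        assert np.isnan(row["theta_osc_pre"])
        assert row["theta_osc_post"] == pytest.approx(0.6)
        assert np.isnan(row["theta_osc_diff"])  # not paired-eligible
        assert row["theta_abundance_pre"] == 0.0
        assert row["theta_abundance_post"] == 0.5

    def test_peakless_electrode_lowers_abundance_not_osc_power(self):
        pre_ps3, post_ps3, labels3 = self._spectra(n=3)
        pre_ps4, post_ps4, labels4 = self._spectra(n=4)
        peak = [Peak(2.5, 0.4, 1.0)]
        f3 = {c: _fit(peaks=peak) for c in labels3}
        f4 = {c: _fit(peaks=peak) for c in labels4}
        f4[labels4[-1]] = _fit()  # extra electrode without a delta peak
        r3 = patient_features(f3, f3, pre_ps3, post_ps3)
        r4 = patient_features(f4, f4, pre_ps4, post_ps4)
        assert r4["delta_osc_pre"] == pytest.approx(r3["delta_osc_pre"])
        assert r4["delta_abundance_pre"] < r3["delta_abundance_pre"]
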