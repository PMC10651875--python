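"""Aperiodic + Gaussian-peaks parameterization of power spectra.

The model, fit in log10-power space over a fixed frequency range:

    L(f) = offset - exponent * log10(f) + sum_n h_n * exp(-(f - c_n)^2 / (2 sd_n^2))

The aperiodic component captures broadband 1/f^chi activity (the
excitation/inhibition-linked "slope" of the spectrum); each Gaussian is a
putative oscillation, its height the power above the aperiodic component.

Fitting procedure:

1. robust aperiodic fit — an ordinary log-log line, refit twice on the
   underside of the spectrum (points whose residual is below the 33rd
   percentile) so oscillation peaks do not drag the slope;
2. iterative peak extraction — repeatedly take the largest positive
   residual (detected on a lightly smoothed residual so single-bin noise
   spikes do not seed peaks), fit a Gaussian to it by moments (center at
   the maximum, sd from the half-height width), subtract; stop at
   ``max_n_peaks`` or once the largest residual falls below
   max(peak_threshold, 2 * residual SD);
3. joint re-fit of all Gaussians on the aperiodic-flattened spectrum;
4. re-fit of the aperiodic line on the peak-subtracted spectrum.

Peaks below the height threshold after the joint re-fit are discarded;
Gaussian sd is bounded so the full width (2 sd) stays within the
configured bandwidth limits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .spectral import PowerSpectrum

__all__ = [
    "FitSettings",
    "AperiodicParams",
    "Peak",
    "SpectralFit",
    "fit_spectrum",
    "fit_power_spectrum",
    "evaluate_fit",
    "fit_r_squared",
    "fits_to_frame",
]


@dataclass(frozen=True)
class FitSettings:
    """Fit range, peak constraints, and quality threshold.

    Defaults: 0.5-30 Hz, no knee, peak height threshold 0.05 log10-power
    units above the aperiodic component, at most 12 peaks with full width
    between 1 and 8 Hz, and R^2 >= 0.8 required downstream.
    """

    fit_lo: float = 0.5
    fit_hi: float = 30.0
    peak_threshold: float = 0.05
    max_n_peaks: int = 12
    bandwidth_lo: float = 1.0
    bandwidth_hi: float = 8.0
    r2_min: float = 0.8

    def __post_init__(self) -> None:
        if self.fit_lo >= self.fit_hi:
            raise ValueError(f"fit_lo ({self.fit_lo}) must be < fit_hi ({self.fit_hi})")
        if self.bandwidth_lo >= self.bandwidth_hi:
            raise ValueError("bandwidth_lo must be < bandwidth_hi")
        if self.max_n_peaks < 0:
            raise ValueError("max_n_peaks must be >= 0")

    @property
    def sd_bounds(self) -> tuple[float, float]:
        # full width = 2 * Gaussian sd
        return self.bandwidth_lo / 2.0, self.bandwidth_hi / 2.0


@dataclass(frozen=True)
class AperiodicParams:
    offset: float    # log10 power at 1 Hz
    exponent: float  # chi, log10-power per decade


@dataclass(frozen=True)
class Peak:
    center_freq: float  # Hz
    height: float       # log10 power above the aperiodic component
    sd: float           # Gaussian sd, Hz

    @property
    def bandwidth(self) -> float:
        return 2.0 * self.sd


@dataclass
class SpectralFit:
    aperiodic: AperiodicParams
    peaks: list[Peak]
    r_squared: float
    settings: FitSettings
    channel: str = ""
    patient_id: str = ""
    timepoint: str = ""
    converged: bool = True


def _gaussian(f: np.ndarray, center: float, height: float, sd: float) -> np.ndarray:
    return height * np.exp(-((f - center) ** 2) / (2.0 * sd**2))


def _gaussian_sum(f: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(f)
    for i in range(0, len(params), 3):
        out += _gaussian(f, params[i], params[i + 1], params[i + 2])
    return out


def _gaussian_sum_jac(f: np.ndarray, *params: float) -> np.ndarray:
    cols = []
    for i in range(0, len(params), 3):
        c, h, s = params[i], params[i + 1], params[i + 2]
        g = np.exp(-((f - c) ** 2) / (2.0 * s**2))
        cols.append(h * g * (f - c) / s**2)         # d/dc
        cols.append(g)                              # d/dh
        cols.append(h * g * (f - c) ** 2 / s**3)    # d/dsd
    return np.column_stack(cols)


def _smooth(x: np.ndarray, half_width: int = 2) -> np.ndarray:
    """Moving average over 2*half_width+1 bins (edge-corrected)."""
    k = np.ones(2 * half_width + 1)
    return np.convolve(x, k, mode="same") / np.convolve(
        np.ones_like(x), k, mode="same"
    )


def _robust_aperiodic(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    """Line fit weighted toward the spectrum's underside.

    Peaks only add power, so points beneath the running fit trace the
    aperiodic component; two percentile-filtered refits suffice.
    """
    slope, intercept = np.polyfit(logf, logp, 1)
    for _ in range(2):
        resid = logp - (intercept + slope * logf)
        keep = resid <= np.percentile(resid, 33)
        if keep.sum() < 3:
            break
        slope, intercept = np.polyfit(logf[keep], logp[keep], 1)
    return intercept, -slope


def _guess_sd(freqs: np.ndarray, resid: np.ndarray, i: int, lo: float, hi: float) -> float:
    """Half-height width of the residual bump at index i, clamped."""
    half = resid[i] / 2.0
    j = i
    while j + 1 < resid.size and resid[j + 1] > half:
        j += 1
    k = i
    while k - 1 >= 0 and resid[k - 1] > half:
        k -= 1
    fwhm = max(freqs[j] - freqs[k], freqs[1] - freqs[0])
    return float(np.clip(fwhm / 2.355, lo, hi))


def fit_spectrum(ps_channel: PowerSpectrum, settings: FitSettings = FitSettings()) -> SpectralFit:
    """Fit the aperiodic + peaks model to one channel's spectrum.

    Non-convergence of the nonlinear stages never raises: the fit is
    returned flagged with ``converged=False`` and ``r_squared=0`` so the
    downstream R^2 filter removes it.
    """
    if ps_channel.n_channels != 1:
        raise ValueError(
            f"fit_spectrum expects a single channel, got {ps_channel.n_channels}"
        )
    mask = (ps_channel.freqs >= settings.fit_lo) & (ps_channel.freqs <= settings.fit_hi)
    if mask.sum() < 4:
        raise ValueError("spectrum does not cover the fit range")
    freqs = ps_channel.freqs[mask]
    power = ps_channel.power[0, mask]
    if np.any(power <= 0):
        raise ValueError("power must be strictly positive over the fit range")
    logf = np.log10(freqs)
    logp = np.log10(power)
    meta = dict(
        channel=ps_channel.channel_labels[0],
        patient_id=ps_channel.patient_id,
        timepoint=ps_channel.timepoint,
    )

    offset, exponent = _robust_aperiodic(logf, logp)
    sd_lo, sd_hi = settings.sd_bounds
    resid = logp - (offset - exponent * logf)
    # the underside fit sits ~1 noise-sd low; re-center so the residual is
    # zero-mean off-peak, otherwise noise rides above the peak threshold
    shift = float(np.median(resid))
    offset += shift
    resid -= shift

    # stage 2: iterative moment-based extraction; detection on a smoothed
    # residual so isolated noisy bins do not seed peaks
    extracted: list[tuple[float, float, float]] = []
    work = resid.copy()
    converged = True
    for _ in range(settings.max_n_peaks):
        sm = _smooth(work)
        i = int(np.argmax(sm))
        if sm[i] < max(settings.peak_threshold, 2.0 * np.std(sm)):
            break
        height = max(work[i], sm[i])
        guess = (freqs[i], height, _guess_sd(freqs, sm, i, sd_lo, sd_hi))
        # local single-Gaussian refinement so the subtraction leaves no
        # shoulder residue that would seed satellite peaks
        win = np.abs(freqs - freqs[i]) <= max(3.0 * guess[2], 1.5)
        lo_b = [max(settings.fit_lo, freqs[i] - 1.0), 0.0, sd_lo]
        hi_b = [min(settings.fit_hi, freqs[i] + 1.0), 2.0 * height + 0.5, sd_hi]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _gaussian, freqs[win], work[win],
                    p0=np.clip(guess, lo_b, hi_b), bounds=(lo_b, hi_b),
                    maxfev=500,
                )
            guess = tuple(popt)
        except RuntimeError:
            pass
        extracted.append(guess)
        work = work - _gaussian(freqs, *guess)

    # stages 3-4, run twice: joint Gaussian re-fit on the flattened
    # spectrum, then aperiodic re-fit on the peak-subtracted spectrum; the
    # second pass polishes both against each other's final estimates
    def _joint_refit(target: np.ndarray, guesses: list[tuple[float, float, float]]):
        nonlocal converged
        p0, lo_b, hi_b = [], [], []
        for c, h, s in guesses:
            p0 += [c, h, s]
            lo_b += [max(settings.fit_lo, c - 1.5), 0.0, sd_lo]
            hi_b += [min(settings.fit_hi, c + 1.5), 2.0 * h + 0.5, sd_hi]
        p0 = np.clip(p0, lo_b, hi_b)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _gaussian_sum, freqs, target, p0=p0,
                    bounds=(lo_b, hi_b), jac=_gaussian_sum_jac,
                    maxfev=3000, xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
        except RuntimeError:
            popt = np.asarray(p0)
            converged = False
        return [tuple(popt[i : i + 3]) for i in range(0, popt.size, 3)]

    def _full_model(f: np.ndarray, *params: float) -> np.ndarray:
        return params[0] + params[1] * np.log10(f) + _gaussian_sum(f, *params[2:])

    def _full_jac(f: np.ndarray, *params: float) -> np.ndarray:
        ones = np.ones_like(f)
        return np.column_stack(
            [ones, np.log10(f), _gaussian_sum_jac(f, *params[2:])]
        )

    params = list(extracted)
    intercept, slope = offset, -exponent
    for _pass in range(2):
        if params:
            flat = logp - (intercept + slope * logf)
            params = _joint_refit(flat, params)
        peak_part = _gaussian_sum(freqs, *np.ravel(params)) if params else np.zeros_like(freqs)
        slope, intercept = np.polyfit(logf, logp - peak_part, 1)

    # final simultaneous fit of aperiodic and peaks, warm-started from the
    # alternating passes; this is what reaches machine-precision round trips
    if params:
        p0 = [intercept, slope]
        lo_b = [-np.inf, -np.inf]
        hi_b = [np.inf, np.inf]
        for c, h, _s in params:
            p0 += [c, h, _s]
            lo_b += [max(settings.fit_lo, c - 1.5), 0.0, sd_lo]
            hi_b += [min(settings.fit_hi, c + 1.5), 2.0 * h + 0.5, sd_hi]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _full_model, freqs, logp, p0=np.clip(p0, lo_b, hi_b),
                    bounds=(lo_b, hi_b), jac=_full_jac,
                    maxfev=3000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            intercept, slope = float(popt[0]), float(popt[1])
            params = [tuple(popt[i : i + 3]) for i in range(2, popt.size, 3)]
        except RuntimeError:
            converged = False
    kept = [p for p in params if p[1] >= settings.peak_threshold]
    if len(kept) != len(params):  # re-fit aperiodic without sub-threshold bumps
        peak_part = (
            _gaussian_sum(freqs, *np.ravel(kept)) if kept else np.zeros_like(freqs)
        )
        slope, intercept = np.polyfit(logf, logp - peak_part, 1)
    else:
        peak_part = (
            _gaussian_sum(freqs, *np.ravel(params)) if params else np.zeros_like(freqs)
        )
    # threshold re-checked after the joint re-fit
    peaks = [Peak(float(c), float(h), float(s)) for c, h, s in kept]
    aperiodic = AperiodicParams(float(intercept), float(-slope))

    model = intercept + slope * logf + peak_part
    r2 = _r_squared(model, logp)
    fit = SpectralFit(
        aperiodic, peaks, r2 if converged else 0.0, settings,
        converged=converged, **meta,
    )
    return fit


def fit_power_spectrum(
    ps: PowerSpectrum, settings: FitSettings = FitSettings()
) -> dict[str, SpectralFit]:
    """Fit every channel; returns label -> SpectralFit."""
    return {label: fit_spectrum(ps.channel(label), settings) for label in ps.channel_labels}


def evaluate_fit(
    fit: SpectralFit, freqs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Model and aperiodic-only log10 power on ``freqs`` (within fit range)."""
    freqs = np.asarray(freqs, dtype=float)
    s = fit.settings
    if np.any(freqs < s.fit_lo) or np.any(freqs > s.fit_hi):
        raise ValueError(f"freqs outside the fit range [{s.fit_lo}, {s.fit_hi}]")
    aperiodic = fit.aperiodic.offset - fit.aperiodic.exponent * np.log10(freqs)
    full = aperiodic.copy()
    for pk in fit.peaks:
        full += _gaussian(freqs, pk.center_freq, pk.height, pk.sd)
    return full, aperiodic


def _r_squared(model: np.ndarray, data: np.ndarray) -> float:
    if np.ptp(data) == 0:
        raise ValueError("R^2 undefined for constant data")
    if np.ptp(model) == 0:
        return 0.0
    r = np.corrcoef(model, data)[0, 1]
    return float(r**2)


def fit_r_squared(fit: SpectralFit, ps_channel: PowerSpectrum) -> float:
    """Squared Pearson correlation of model vs data log10 power."""
    mask = (ps_channel.freqs >= fit.settings.fit_lo) & (
        ps_channel.freqs <= fit.settings.fit_hi
    )
    full, _ = evaluate_fit(fit, ps_channel.freqs[mask])
    return _r_squared(full, np.log10(ps_channel.power[0, mask]))


def fits_to_frame(fits: dict[str, dict[str, dict[str, SpectralFit]]]):
    """Flatten nested {patient: {timepoint: {channel: fit}}} into a table."""
    import pandas as pd

    rows = []
    for patient, tps in fits.items():
        for tp, chans in tps.items():
            for ch, fit in chans.items():
                row = {
                    "patient": patient,
                    "timepoint": tp,
                    "channel": ch,
                    "offset": fit.aperiodic.offset,
                    "exponent": fit.aperiodic.exponent,
                    "r_squared": fit.r_squared,
                    "n_peaks": len(fit.peaks),
                }
                for i, pk in enumerate(fit.peaks):
                    row[f"peak{i}_center"] = pk.center_freq
                    row[f"peak{i}_height"] = pk.height
                    row[f"peak{i}_bw"] = pk.bandwidth
                rows.append(row)
    return pd.DataFrame(rows)


def frame_to_fits(
    df, settings: FitSettings = FitSettings()
) -> dict[str, dict[str, dict[str, SpectralFit]]]:
    """Rebuild the nested fits mapping from a :func:`fits_to_frame` table."""
    import pandas as pd

    out: dict[str, dict[str, dict[str, SpectralFit]]] = {}
    for _, row in df.iterrows():
        peaks = []
        for i in range(int(row["n_peaks"])):
            peaks.append(
                Peak(
                    float(row[f"peak{i}_center"]),
                    float(row[f"peak{i}_height"]),
                    float(row[f"peak{i}_bw"]) / 2.0,
                )
            )
        fit = SpectralFit(
            AperiodicParams(float(row["offset"]), float(row["exponent"])),
            peaks,
            float(row["r_squared"]),
            settings,
            channel=str(row["channel"]),
            patient_id=str(row["patient"]),
            timepoint=str(row["timepoint"]),
        )
        out.setdefault(str(row["patient"]), {}).setdefault(
            str(row["timepoint"]), {}
        )[str(row["channel"])] = fit
    return out
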