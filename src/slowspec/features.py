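"""Patient-level EEG slowing features with exclusion and averaging rules.

Four features per frequency band and timepoint, each averaged across the
retained electrodes of a patient:

* band power — mean log10 spectral power across the band's bins
  (conflates periodic and aperiodic activity; the "canonical" measure);
* oscillation power — height of the tallest fitted peak in the band,
  i.e. power above the aperiodic component; absent when no retained
  electrode carries a band peak (never imputed as zero);
* abundance — fraction of retained electrodes whose fit contains a band
  peak (captures oscillation *emergence* rather than power change);
* plus the aperiodic exponent, band-independent.

Electrode retention requires an adequate model fit (R^2 >= 0.8) at *both*
timepoints; a bad fit on one side removes the electrode from the other as
well, and a patient with no retained electrodes is dropped entirely.

All difference values are pre minus post, so a post-treatment increase
appears as a negative delta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Peak, SpectralFit
from .spectral import PowerSpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "BandDefinition",
    "BANDS",
    "quality_filter",
    "band_power",
    "select_band_peak",
    "abundance",
    "patient_features",
    "cohort_feature_table",
]


@dataclass(frozen=True)
class BandDefinition:
    """Frequency band. Peak membership is closed-left / open-right so a
    peak at exactly 4 Hz belongs to theta, not delta; alpha closes at
    12 Hz. Band-power bin inclusion is closed on both sides."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValueError(f"band {self.name}: lo must be < hi")

    def contains(self, freq: float) -> bool:
        if self.name == "alpha":
            return self.lo <= freq <= self.hi
        return self.lo <= freq < self.hi


BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 7.0),
    "alpha": BandDefinition("alpha", 7.0, 12.0),
}


def quality_filter(
    fits_pre: dict[str, SpectralFit],
    fits_post: dict[str, SpectralFit],
    r2_min: float = 0.8,
) -> list[str]:
    """Electrodes whose model fit reaches ``r2_min`` at both timepoints.

    An electrode failing at either timepoint is removed from both; the
    caller drops patients for whom the returned list is empty.
    """
    if set(fits_pre) != set(fits_post):
        raise ValueError(
            "pre/post electrode labels differ: "
            f"{sorted(set(fits_pre) ^ set(fits_post))}"
        )
    return [
        label
        for label in fits_pre
        if fits_pre[label].r_squared >= r2_min
        and fits_post[label].r_squared >= r2_min
    ]


def band_power(ps_channel: PowerSpectrum, band: BandDefinition) -> float:
    """Mean log10 power over the band's bins (closed on both sides)."""
    if ps_channel.n_channels != 1:
        raise ValueError("band_power expects a single channel")
    mask = (ps_channel.freqs >= band.lo) & (ps_channel.freqs <= band.hi)
    if not mask.any():
        raise ValueError(f"band {band.name} has no bins in the spectrum")
    return float(np.mean(np.log10(ps_channel.power[0, mask])))


def select_band_peak(fit: SpectralFit, band: BandDefinition) -> Peak | None:
    """The tallest fitted peak whose center lies in the band, if any."""
    in_band = [p for p in fit.peaks if band.contains(p.center_freq)]
    if not in_band:
        return None
    return max(in_band, key=lambda p: p.height)


def abundance(fits: list[SpectralFit], band: BandDefinition) -> float:
    """Fraction of (retained) electrodes exhibiting a band peak."""
    if not fits:
        raise ValueError("abundance undefined with zero retained electrodes")
    has = [select_band_peak(f, band) is not None for f in fits]
    return float(np.mean(has))


def patient_features(
    fits_pre: dict[str, SpectralFit],
    fits_post: dict[str, SpectralFit],
    ps_pre: PowerSpectrum,
    ps_post: PowerSpectrum,
    bands: dict[str, BandDefinition] = BANDS,
    r2_min: float = 0.8,
) -> dict[str, float] | None:
    """Electrode-averaged features for one patient, or None if dropped.

    Oscillation power averages only over electrodes that carry a band
    peak (peakless electrodes are never counted as zero power); its delta
    exists only when both timepoints have at least one peak-bearing
    electrode. Abundance and exponent use all retained electrodes.
    """
    retained = quality_filter(fits_pre, fits_post, r2_min)
    if not retained:
        logger.warning(
            "patient %s: no electrode with R^2 >= %.2f at both timepoints; "
            "patient removed",
            ps_pre.patient_id,
            r2_min,
        )
        return None
    row: dict[str, float] = {"n_electrodes_retained": len(retained)}
    for tp, fits, ps in (("pre", fits_pre, ps_pre), ("post", fits_post, ps_post)):
        sel = [fits[ch] for ch in retained]
        row[f"exponent_{tp}"] = float(
            np.mean([f.aperiodic.exponent for f in sel])
        )
        for band in bands.values():
            row[f"{band.name}_power_{tp}"] = float(
                np.mean([band_power(ps.channel(ch), band) for ch in retained])
            )
            heights = [
                pk.height
                for f in sel
                if (pk := select_band_peak(f, band)) is not None
            ]
            row[f"{band.name}_osc_{tp}"] = (
                float(np.mean(heights)) if heights else np.nan
            )
            row[f"{band.name}_abundance_{tp}"] = abundance(sel, band)
    for name in ["exponent"] + [
        f"{b}_{kind}" for b in bands for kind in ("power", "osc", "abundance")
    ]:
        row[f"{name}_diff"] = row[f"{name}_pre"] - row[f"{name}_post"]
    return row


def cohort_feature_table(
    fits: dict[str, dict[str, dict[str, SpectralFit]]],
    spectra: dict[str, dict[str, PowerSpectrum]],
    bands: dict[str, BandDefinition] = BANDS,
    r2_min: float = 0.8,
) -> pd.DataFrame:
    """One feature row per retained patient.

    ``fits`` is {patient: {timepoint: {channel: fit}}}, ``spectra`` is
    {patient: {timepoint: PowerSpectrum}}.
    """
    rows = []
    for patient, tps in fits.items():
        row = patient_features(
            tps["pre"], tps["post"],
            spectra[patient]["pre"], spectra[patient]["post"],
            bands, r2_min,
        )
        if row is not None:
            rows.append({"patient": patient, **row})
    return pd.DataFrame(rows)
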