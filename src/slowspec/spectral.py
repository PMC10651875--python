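"""Recordings and power spectra.

Spectral estimation follows the convention used for resting-state clinical
EEG: Welch's method with a 4 s Hamming window and 2 s overlap, yielding a
0.25 Hz frequency grid, one-sided density scaling in V^2/Hz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal


@dataclass
class Recording:
    """Multichannel time-domain EEG segment.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in volts.
    fs : float
        Sampling frequency in Hz.
    channel_labels : list of str
        Unique electrode labels.
    patient_id, timepoint : str
        Metadata carried through the pipeline ("pre" / "post").
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    patient_id: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass
class PowerSpectrum:
    """Per-channel power spectral density on a uniform frequency grid.

    ``power`` is in linear units (V^2/Hz) and strictly positive; model
    fitting happens downstream in log10 space.
    """

    freqs: np.ndarray
    power: np.ndarray
    channel_labels: list[str] = field(default_factory=list)
    patient_id: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.power.shape[1] != self.freqs.size:
            raise ValueError(
                f"power has {self.power.shape[1]} bins but freqs has "
                f"{self.freqs.size}"
            )
        if np.any(self.power <= 0):
            raise ValueError("power must be strictly positive everywhere")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.power.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.power.shape[0]

    def channel(self, label: str) -> "PowerSpectrum":
        """Single-channel view (copy) by electrode label."""
        idx = self.channel_labels.index(label)
        return PowerSpectrum(
            self.freqs,
            self.power[idx : idx + 1],
            [label],
            self.patient_id,
            self.timepoint,
        )


def welch_psd(
    rec: Recording, window_s: float = 4.0, overlap_s: float = 2.0
) -> PowerSpectrum:
    """Welch PSD with a Hamming taper, per channel.

    Defaults (4 s window, 2 s = 50% overlap) give a 0.25 Hz grid at any
    sampling rate. Segments are mean-detrended; scaling is one-sided
    density (V^2/Hz). The zero-frequency bin is dropped so the output
    satisfies the strict-positivity contract of :class:`PowerSpectrum`.
    """
    if overlap_s >= window_s:
        raise ValueError(f"overlap_s ({overlap_s}) must be < window_s ({window_s})")
    nperseg = int(round(window_s * rec.fs))
    noverlap = int(round(overlap_s * rec.fs))
    if rec.samples.shape[1] < nperseg:
        raise ValueError(
            f"recording of {rec.duration:.1f} s is shorter than the "
            f"{window_s:.1f} s window"
        )
    freqs, power = signal.welch(
        rec.samples,
        fs=rec.fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    keep = freqs > 0
    return PowerSpectrum(
        freqs[keep],
        power[:, keep],
        list(rec.channel_labels),
        rec.patient_id,
        rec.timepoint,
    )


# --- plain-text I/O -------------------------------------------------------

def spectra_to_frame(spectra: list[PowerSpectrum]) -> pd.DataFrame:
    """Long-format table: patient, timepoint, channel, freq, power."""
    rows = []
    for ps in spectra:
        for ch, label in enumerate(ps.channel_labels):
            rows.append(
                pd.DataFrame(
                    {
                        "patient": ps.patient_id,
                        "timepoint": ps.timepoint,
                        "channel": label,
                        "freq": ps.freqs,
                        "power": ps.power[ch],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def frame_to_spectra(df: pd.DataFrame) -> list[PowerSpectrum]:
    """Inverse of :func:`spectra_to_frame`."""
    out = []
    for (patient, timepoint), grp in df.groupby(
        ["patient", "timepoint"], sort=False
    ):
        labels = list(dict.fromkeys(grp["channel"]))
        freqs = np.sort(grp["freq"].unique())
        power = np.empty((len(labels), freqs.size))
        for i, label in enumerate(labels):
            sub = grp[grp["channel"] == label].sort_values("freq")
            power[i] = sub["power"].to_numpy()
        out.append(PowerSpectrum(freqs, power, labels, str(patient), str(timepoint)))
    return out


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as a channels x time CSV plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, rec.samples, delimiter=",")
    sidecar = {
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "patient_id": rec.patient_id,
        "timepoint": rec.timepoint,
        "units": "V",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path: str | Path) -> Recording:
    """Read a CSV + JSON-sidecar recording written by :func:`write_recording`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    samples = np.loadtxt(path, delimiter=",", ndmin=2)
    return Recording(
        samples,
        meta["fs"],
        meta["channel_labels"],
        meta.get("patient_id", ""),
        meta.get("timepoint", ""),
    )


def read_edf(path: str | Path, patient_id: str = "", timepoint: str = "") -> Recording:
    """Read a multichannel EDF recording (requires the optional mne extra)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        raw.get_data(), raw.info["sfreq"], raw.ch_names, patient_id, timepoint
    )
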