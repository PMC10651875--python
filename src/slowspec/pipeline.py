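"""End-to-end orchestration: generate -> fit -> featurize -> test.

A run takes one or two cohort arms (e.g. an ECT-like and an MST-like
cohort), fits every spectrum, derives patient features, and applies the
statistical battery:

* per arm, the eight-test EEG family (exponent; delta band power; delta,
  theta, alpha oscillation power; delta, theta, alpha abundance) under a
  single Holm-Bonferroni correction;
* per arm, the three band-power regressions (delta/theta/alpha band-power
  change on exponent, abundance, and oscillation-power changes);
* clinical change test and remission rate per arm;
* across arms (when both are present), the exhaustive outcome search
  predicting normalized post HAM-D from the fixed effects plus the best
  EEG-feature subset, re-fit with HC3 covariance.

Outputs are CSV tables plus a JSON report stamped with the seed and a
hash of the configuration; synthetic-mode reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as st
from .features import BANDS, cohort_feature_table, quality_filter
from .model import FitSettings, fit_power_spectrum, fits_to_frame
from .spectral import spectra_to_frame
from .synthetic import CohortConfig, SyntheticCohort, make_cohort

logger = logging.getLogger(__name__)

EEG_FAMILY = [
    ("exponent", "exponent"),
    ("delta_power", "delta_power"),
    ("delta_osc", "delta_osc"),
    ("delta_abundance", "delta_abundance"),
    ("theta_osc", "theta_osc"),
    ("theta_abundance", "theta_abundance"),
    ("alpha_osc", "alpha_osc"),
    ("alpha_abundance", "alpha_abundance"),
]


@dataclass
class RunConfig:
    cohorts: list[CohortConfig] = field(default_factory=list)
    fit: FitSettings = field(default_factory=FitSettings)
    alpha: float = 0.05
    seed: int = 0
    outdir: str = "slowspec_run"
    write_spectra: bool = False
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        from .synthetic import BandOscillation

        cohorts = []
        for c in d.get("cohorts", []):
            c = dict(c)
            c["bands"] = {
                name: BandOscillation(**b) for name, b in c.get("bands", {}).items()
            }
            for key in ("hamd_pre_range", "n_treatments_range"):
                if key in c:
                    c[key] = tuple(c[key])
            cohorts.append(CohortConfig(**c))
        fit = FitSettings(**d.get("fit", {}))
        rest = {
            k: d[k]
            for k in ("alpha", "seed", "outdir", "write_spectra", "log_level")
            if k in d
        }
        return cls(cohorts=cohorts, fit=fit, **rest)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location and log
        verbosity excluded, so relocated reruns stay byte-identical)."""
        d = self.to_dict()
        d.pop("outdir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def eeg_feature_tests(
    features: pd.DataFrame, alpha: float = 0.05
) -> tuple[list[st.TestResult], st.HolmResult]:
    """The eight-test family on one arm's feature table.

    Oscillation-power tests use only patients with a band peak at both
    timepoints; abundance and exponent tests use all patients. A test
    with fewer than 3 eligible pairs, or with all differences zero, is
    skipped (logged) and the Holm family shrinks accordingly.
    """
    results = []
    for name, col in EEG_FAMILY:
        pair = features[[f"{col}_pre", f"{col}_post"]].dropna()
        if len(pair) < 3:
            logger.warning("test %s skipped: only %d eligible pairs", name, len(pair))
            continue
        try:
            res = st.paired_test(
                pair[f"{col}_pre"].to_numpy(), pair[f"{col}_post"].to_numpy(), name=name
            )
        except ValueError as err:
            logger.warning("test %s skipped: %s", name, err)
            continue
        results.append(res)
    holm = st.holm_bonferroni(
        [r.p for r in results], [r.name for r in results], alpha
    )
    return results, holm


def merge_clinical(features: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Attach clinical columns and derived normalized scores / coding."""
    df = features.merge(clinical, on="patient", how="left")
    df["norm_hamd_pre"] = [
        st.normalize_hamd(r, v) if pd.notna(r) else np.nan
        for r, v in zip(df["hamd_pre"], df["hamd_version"])
    ]
    df["norm_hamd_post"] = [
        st.normalize_hamd(r, v) if pd.notna(r) else np.nan
        for r, v in zip(df["hamd_post"], df["hamd_version"])
    ]
    df["treatment_code"] = (df["treatment"] == "MST").astype(float)
    return df


def _test_to_dict(r: st.TestResult) -> dict:
    return {
        "name": r.name, "test": r.test, "statistic": r.statistic, "n": r.n,
        "p": r.p, "effect_type": r.effect_type, "effect": r.effect,
        "descriptives": r.descriptives,
    }


def _reg_to_dict(r: st.RegressionResult) -> dict:
    return {
        "terms": {
            name: {
                "beta": float(r.params[name]),
                "ci": [float(r.conf_int.loc[name, "lower"]),
                       float(r.conf_int.loc[name, "upper"])],
                "p": float(r.pvalues[name]),
            }
            for name in r.params.index
        },
        "r_squared": r.r_squared,
        "r_squared_adj": r.r_squared_adj,
        "f": r.f_statistic,
        "f_p": r.f_pvalue,
        "df": [r.df_model, r.df_resid],
        "cov_type": r.cov_type,
        "n": r.n,
    }


def analyze_arm(
    cohort: SyntheticCohort, fit_settings: FitSettings, alpha: float = 0.05
) -> dict:
    """Fit, featurize, and test one cohort arm; returns the report chunk
    plus the merged feature table under the key "features"."""
    fits = {
        pat.patient_id: {
            tp: fit_power_spectrum(pat.spectra[tp], fit_settings)
            for tp in ("pre", "post")
        }
        for pat in cohort.patients
    }
    spectra = {pat.patient_id: pat.spectra for pat in cohort.patients}
    features = cohort_feature_table(fits, spectra, BANDS, fit_settings.r2_min)
    features = merge_clinical(features, cohort.clinical)
    tests, holm = eeg_feature_tests(features, alpha)
    regressions = {}
    for band in BANDS:
        try:
            reg, reg_holm = st.band_power_regression(features, band, alpha)
            regressions[band] = {
                **_reg_to_dict(reg),
                "holm": reg_holm.table.to_dict(orient="records"),
            }
        except ValueError as err:
            regressions[band] = {"skipped": str(err)}
    clin = features[["hamd_pre", "hamd_post"]].dropna()
    clinical = {}
    if len(clin) >= 3:
        ct = st.paired_test(
            clin["hamd_pre"].to_numpy(), clin["hamd_post"].to_numpy(),
            name="hamd",
        )
        clinical = {
            "test": _test_to_dict(ct),
            "remission_rate": st.remission_rate(
                clin["hamd_pre"].to_numpy(), clin["hamd_post"].to_numpy()
            ),
            "n_complete": int(len(clin)),
        }
    # electrode-wise exponent topography (uncorrected per-electrode tests)
    labels = cohort.patients[0].spectra["pre"].channel_labels
    exp_pre, exp_post = {}, {}
    for pat in cohort.patients:
        pid = pat.patient_id
        retained = quality_filter(fits[pid]["pre"], fits[pid]["post"], fit_settings.r2_min)
        exp_pre[pid] = {
            ch: fits[pid]["pre"][ch].aperiodic.exponent for ch in retained
        }
        exp_post[pid] = {
            ch: fits[pid]["post"][ch].aperiodic.exponent for ch in retained
        }
    pre_df = pd.DataFrame.from_dict(exp_pre, orient="index").reindex(columns=labels)
    post_df = pd.DataFrame.from_dict(exp_post, orient="index").reindex(columns=labels)
    try:
        topography = st.electrode_topography_tests(pre_df, post_df).to_dict(
            orient="records"
        )
    except ValueError as err:
        topography = {"skipped": str(err)}
    return {
        "treatment": cohort.config.treatment,
        "n_patients": len(features),
        "features": features,
        "fits": fits,
        "eeg_tests": [_test_to_dict(t) for t in tests],
        "holm": holm.table.to_dict(orient="records"),
        "band_regressions": regressions,
        "exponent_topography": topography,
        "clinical": clinical,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full synthetic run and write its outputs.

    Returns the report dict (also written to ``outdir/report.json``).
    """
    logging.basicConfig(level=config.log_level)
    if not config.cohorts:
        raise ValueError("config.cohorts is empty")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "arms": [],
    }
    frames, fit_frames, feat_frames = [], [], []
    arm_tables = []
    for i, cc in enumerate(config.cohorts):
        cc = dataclasses.replace(cc, seed=cc.seed + config.seed)
        logger.info("arm %d: %s, %d patients", i, cc.treatment, cc.n_patients)
        cohort = make_cohort(cc)
        arm = analyze_arm(cohort, config.fit, config.alpha)
        features = arm.pop("features")
        fits = arm.pop("fits")
        report["arms"].append(arm)
        feat_frames.append(features)
        fit_frames.append(fits_to_frame(fits))
        arm_tables.append(features)
        if config.write_spectra:
            frames.extend(
                spectra_to_frame([pat.spectra[tp] for tp in ("pre", "post")])
                for pat in cohort.patients
            )
    all_features = pd.concat(feat_frames, ignore_index=True)
    if len({a["treatment"] for a in report["arms"]}) >= 2:
        subset, reg = st.exhaustive_outcome_search(all_features)
        report["outcome_search"] = {
            "selected": list(subset),
            "model": _reg_to_dict(reg),
        }
    all_features.to_csv(outdir / "features.csv", index=False)
    pd.concat(fit_frames, ignore_index=True).to_csv(outdir / "fits.csv", index=False)
    if config.write_spectra and frames:
        pd.concat(frames, ignore_index=True).to_csv(outdir / "spectra.csv", index=False)
    (outdir / "config.json").write_text(
        json.dumps(config.to_dict(), indent=1, sort_keys=True, default=str)
    )
    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=float)
    )
    return report
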