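"""Seeded synthetic morphometry cohorts.

Generates tabular cohorts with the statistical structure the downstream
analysis assumes: a per-subject latent severity ordered AD > MCI-c >
MCI-nc > CTL, a group-mean shift concentrated in medial-temporal regions,
inter-regional correlation (one shared global factor plus a per-block
factor), ICV scaling of volumes, per-group 12-month decline along the
atrophy profile, and an extra severity shift for APOE e4 carriers within
the MCI group.

On the standardized (z) scale each feature is

    z = severity * effect + g * correlation_strength
        + b_block * block_correlation + eps * noise_sd

with ``g`` shared across all features of a subject, ``b_block`` shared
within the thickness or volume block, and ``eps`` i.i.d.  Raw features are
``mean + z * sd`` from a versioned population-statistics fixture; volumes
are additionally scaled by the subject's ICV relative to the reference
head size, so ICV normalisation downstream is a meaningful step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import (
    ALL_FEATURES,
    BASELINE,
    FOLLOWUP,
    ICV_COLUMN,
    ID_COLUMN,
    MEDIAL_TEMPORAL_REGIONS,
    THICKNESS_FEATURES,
    TIMEPOINT_COLUMN,
    VOLUME_FEATURES,
    load_population_stats,
)

REFERENCE_ICV = 1.5e6  # mm^3

#: Standardized AD-vs-CTL shifts (SD units) for the dominant regions.  The
#: ventricle enlarges (+); grey-matter structures shrink (-).  Artifact
#: defaults, ordered so the largest |shift| is the hippocampus.
_KEY_REGION_SHIFTS: dict[str, float] = {
    "hippocampus": -1.50,
    "entorhinal": -1.40,
    "amygdala": -1.30,
    "temporal_pole": -1.20,
    "superior_temporal": -1.15,
    "inferior_lateral_ventricle": +1.10,
    "middle_temporal": -1.05,
    "fusiform": -1.00,
    "inferior_temporal": -0.95,
    "parahippocampal": -0.90,
}

_VENTRICULAR = {"third_ventricle", "fourth_ventricle", "lateral_ventricle", "csf"}
_SPARED = {"brainstem", "cerebellum_cortex", "cerebellum_white_matter"}


def default_effect_profile(scale: float = 1.0) -> dict[str, float]:
    """Default per-feature standardized group-mean shift (AD vs CTL).

    The ten medial-temporal-dominated regions carry the largest |shift|
    (hippocampus ranked first); remaining ventricular/CSF spaces enlarge
    mildly, largely-spared posterior-fossa structures shift least, and all
    other regions atrophy mildly.  ``scale`` multiplies every entry.
    """
    profile: dict[str, float] = {}
    for feat in ALL_FEATURES:
        if feat in _KEY_REGION_SHIFTS:
            shift = _KEY_REGION_SHIFTS[feat]
        elif feat in _VENTRICULAR:
            shift = +0.20
        elif feat in _SPARED:
            shift = -0.10
        else:
            shift = -0.25
        profile[feat] = shift * scale
    return profile


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for one synthetic cohort."""

    n_ad: int = 119
    n_ctl: int = 110
    n_mci_c: int = 21
    n_mci_nc: int = 98
    effect_profile: dict[str, float] | None = None  # None -> default profile
    mci_fraction_c: float = 0.80    # converters sit close to the AD mean
    mci_fraction_nc: float = 0.35
    annual_decline: dict[str, float] = field(
        default_factory=lambda: {"AD": 0.22, "MCI-c": 0.16, "MCI-nc": 0.10, "CTL": 0.08}
    )
    apoe_effect: float = 0.25       # extra severity for e4 carriers within MCI
    apoe_carrier_rate: float = 0.5
    correlation_strength: float = 0.55
    block_correlation: float = 0.45
    noise_sd: float = 0.60
    severity_sd: float = 0.25
    longitudinal_noise_sd: float = 0.12
    followup_rate: dict[str, float] = field(
        default_factory=lambda: {
            "AD": 62 / 119,
            "CTL": 79 / 110,
            "MCI-c": 13 / 21,
            "MCI-nc": 60 / 98,
        }
    )
    icv_mean: float = REFERENCE_ICV
    icv_sd: float = 1.2e5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ad", "n_ctl", "n_mci_c", "n_mci_nc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mci_fraction_c < self.mci_fraction_nc:
            raise ValueError("mci_fraction_c must be >= mci_fraction_nc")
        if self.effect_profile is not None:
            if set(self.effect_profile) != set(ALL_FEATURES):
                raise ValueError(
                    "effect_profile must have exactly one entry per canonical feature"
                )

    def resolved_profile(self) -> np.ndarray:
        prof = self.effect_profile or default_effect_profile()
        return np.array([prof[f] for f in ALL_FEATURES], dtype=float)


@dataclass
class SyntheticCohort:
    """Generated cohort: long-format data table plus generation truth."""

    data: pd.DataFrame          # one row per subject x timepoint
    spec: CohortSpec
    severity: pd.DataFrame      # subject_id, severity_baseline, severity_m12

    @property
    def baseline(self) -> pd.DataFrame:
        return self.data[self.data[TIMEPOINT_COLUMN] == BASELINE].reset_index(drop=True)

    @property
    def followup(self) -> pd.DataFrame:
        return self.data[self.data[TIMEPOINT_COLUMN] == FOLLOWUP].reset_index(drop=True)


_GROUPS = ("AD", "CTL", "MCI-c", "MCI-nc")


def _group_mu(spec: CohortSpec, group: str) -> float:
    return {
        "AD": 1.0,
        "CTL": 0.0,
        "MCI-c": spec.mci_fraction_c,
        "MCI-nc": spec.mci_fraction_nc,
    }[group]


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw one cohort; bit-identical for identical spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    stats = load_population_stats()
    pop_mean = stats["mean"].to_numpy()
    pop_sd = stats["sd"].to_numpy()
    effect = spec.resolved_profile()
    p = len(ALL_FEATURES)
    thickness_mask = np.array([f in set(THICKNESS_FEATURES) for f in ALL_FEATURES])

    counts = {
        "AD": spec.n_ad,
        "CTL": spec.n_ctl,
        "MCI-c": spec.n_mci_c,
        "MCI-nc": spec.n_mci_nc,
    }
    rows = []
    sev_rows = []
    sid = 0
    for group in _GROUPS:
        n = counts[group]
        if n == 0:
            continue
        dx = "MCI" if group.startswith("MCI") else group
        mu = _group_mu(spec, group)
        carriers = rng.random(n) < spec.apoe_carrier_rate
        severity = rng.normal(mu, spec.severity_sd, size=n)
        if dx == "MCI" and spec.apoe_effect:
            severity = severity + spec.apoe_effect * carriers
        decline = spec.annual_decline.get(group, 0.0)
        severity_m12 = severity + decline + rng.normal(0, 0.03, size=n)

        g = rng.normal(0, 1, size=n)
        b_thk = rng.normal(0, 1, size=n)
        b_vol = rng.normal(0, 1, size=n)
        eps = rng.normal(0, 1, size=(n, p))
        block = np.where(thickness_mask, b_thk[:, None], b_vol[:, None])
        z_base = (
            severity[:, None] * effect[None, :]
            + spec.correlation_strength * g[:, None]
            + spec.block_correlation * block
            + spec.noise_sd * eps
        )
        z_m12 = (
            z_base
            + (severity_m12 - severity)[:, None] * effect[None, :]
            + spec.longitudinal_noise_sd * rng.normal(0, 1, size=(n, p))
        )
        icv = rng.normal(spec.icv_mean, spec.icv_sd, size=n)
        icv = np.clip(icv, 0.5 * spec.icv_mean, None)
        age = rng.normal(75.0, 6.0, size=n)
        has_followup = rng.random(n) < spec.followup_rate.get(group, 1.0)

        for tp, z, sev in ((BASELINE, z_base, severity), (FOLLOWUP, z_m12, severity_m12)):
            x = pop_mean[None, :] + z * pop_sd[None, :]
            x = np.where(
                thickness_mask[None, :], x, x * (icv[:, None] / REFERENCE_ICV)
            )
            mmse = np.clip(29.0 - 5.5 * sev + rng.normal(0, 1.2, size=n), 0, 30)
            adas1 = np.clip(2.5 + 4.5 * sev + rng.normal(0, 1.2, size=n), 0, 10)
            cdr = np.clip(4.0 * sev + rng.normal(0, 0.8, size=n), 0, 18)
            for i in range(n):
                if tp == FOLLOWUP and not has_followup[i]:
                    continue
                row = {
                    ID_COLUMN: f"S{sid + i:04d}",
                    TIMEPOINT_COLUMN: tp,
                    "dx": dx,
                    "mci_status": group[4:] if dx == "MCI" else "",
                    "apoe_e4": int(carriers[i]),
                    "age": round(float(age[i]), 1),
                    "mmse": round(float(mmse[i]), 1),
                    "cdr_sob": round(float(cdr[i]), 1),
                    "adas1": round(float(adas1[i]), 1),
                    ICV_COLUMN: float(icv[i]),
                }
                row.update({f: float(v) for f, v in zip(ALL_FEATURES, x[i])})
                rows.append(row)
        for i in range(n):
            sev_rows.append(
                {
                    ID_COLUMN: f"S{sid + i:04d}",
                    "group": group,
                    "severity_baseline": float(severity[i]),
                    "severity_m12": float(severity_m12[i]),
                    "has_followup": bool(has_followup[i]),
                }
            )
        sid += n

    columns = (
        [ID_COLUMN, TIMEPOINT_COLUMN, "dx", "mci_status", "apoe_e4", "age",
         "mmse", "cdr_sob", "adas1", ICV_COLUMN]
        + list(ALL_FEATURES)
    )
    data = pd.DataFrame(rows, columns=columns)
    severity = pd.DataFrame(sev_rows)
    return SyntheticCohort(data=data, spec=spec, severity=severity)
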