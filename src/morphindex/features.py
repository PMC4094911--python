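"""Canonical regional-morphometry feature registry.

The model operates on 57 bilaterally-averaged FreeSurfer-style measures:
34 cortical thickness features (mm) and 23 subcortical/global volume
features (mm^3), plus estimated intracranial volume (``icv``).  Column
order is canonical everywhere so serialized models are portable across
tables written by different tools.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Cortical thickness features (mm), canonical order.
THICKNESS_FEATURES: tuple[str, ...] = (
    "bankssts",
    "caudal_anterior_cingulate",
    "caudal_middle_frontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferior_parietal",
    "inferior_temporal",
    "isthmus_cingulate",
    "lateral_occipital",
    "lateral_orbitofrontal",
    "lingual",
    "medial_orbitofrontal",
    "middle_temporal",
    "parahippocampal",
    "paracentral",
    "pars_opercularis",
    "pars_orbitalis",
    "pars_triangularis",
    "pericalcarine",
    "postcentral",
    "posterior_cingulate",
    "precentral",
    "precuneus",
    "rostral_anterior_cingulate",
    "rostral_middle_frontal",
    "superior_frontal",
    "superior_parietal",
    "superior_temporal",
    "supramarginal",
    "frontal_pole",
    "temporal_pole",
    "transverse_temporal",
    "insula",
)

#: Subcortical and global volume features (mm^3), canonical order.
VOLUME_FEATURES: tuple[str, ...] = (
    "third_ventricle",
    "fourth_ventricle",
    "brainstem",
    "cc_anterior",
    "cc_central",
    "cc_mid_anterior",
    "cc_mid_posterior",
    "cc_posterior",
    "csf",
    "accumbens",
    "amygdala",
    "caudate",
    "cerebellum_cortex",
    "cerebellum_white_matter",
    "hippocampus",
    "inferior_lateral_ventricle",
    "putamen",
    "cerebral_cortex",
    "cerebral_white_matter",
    "lateral_ventricle",
    "pallidum",
    "thalamus_proper",
    "ventral_dc",
)

#: All model features in canonical order (thickness block then volume block).
ALL_FEATURES: tuple[str, ...] = THICKNESS_FEATURES + VOLUME_FEATURES

#: Midline structures reported once per subject (no left/right pair).
MIDLINE_FEATURES: frozenset[str] = frozenset(
    {
        "third_ventricle",
        "fourth_ventricle",
        "brainstem",
        "cc_anterior",
        "cc_central",
        "cc_mid_anterior",
        "cc_mid_posterior",
        "cc_posterior",
        "csf",
    }
)

#: Paired structures: reported per hemisphere, averaged before modelling.
PAIRED_FEATURES: tuple[str, ...] = tuple(
    f for f in ALL_FEATURES if f not in MIDLINE_FEATURES
)

#: Medial-temporal-dominated region set that drives the default synthetic
#: effect profile; the ventricle in the set enlarges rather than shrinks.
MEDIAL_TEMPORAL_REGIONS: tuple[str, ...] = (
    "hippocampus",
    "entorhinal",
    "amygdala",
    "temporal_pole",
    "superior_temporal",
    "inferior_lateral_ventricle",
    "middle_temporal",
    "fusiform",
    "inferior_temporal",
    "parahippocampal",
)

ICV_COLUMN = "icv"
ID_COLUMN = "subject_id"
TIMEPOINT_COLUMN = "timepoint"
BASELINE = "baseline"
FOLLOWUP = "m12"
TIMEPOINTS = (BASELINE, FOLLOWUP)

DIAGNOSES = ("AD", "MCI", "CTL")
META_COLUMNS = ("dx", "mci_status", "apoe_e4", "age", "mmse", "cdr_sob", "adas1")

assert len(THICKNESS_FEATURES) == 34
assert len(VOLUME_FEATURES) == 23
assert len(ALL_FEATURES) == 57


def load_population_stats() -> pd.DataFrame:
    """Load the versioned per-feature population mean/SD fixture.

    Returns a DataFrame indexed by feature name with columns ``mean`` and
    ``sd`` (thickness in mm, volumes in mm^3 at the reference head size).
    """
    ref = resources.files("morphindex.data").joinpath("population_stats.tsv")
    with resources.as_file(ref) as path:
        stats = pd.read_csv(path, sep="\t", index_col="feature")
    missing = set(ALL_FEATURES) - set(stats.index)
    if missing:
        raise ValueError(f"population stats fixture missing features: {sorted(missing)}")
    return stats.loc[list(ALL_FEATURES)]
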