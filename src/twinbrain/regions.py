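"""Region registries: full-parcellation counts and the 20-region modeling set."""

from __future__ import annotations

#: Parcel counts of the three atlases combined for functional-connectivity
#: parcellation: a 400-region cortical surface atlas, 32 laterally symmetric
#: subcortical regions, and 14 cerebellar regions.
ATLAS_PARCEL_COUNTS = {
    "cortical": 400,
    "subcortical": 32,
    "cerebellar": 14,
}

RIGHT_AMYGDALA = "R_amygdala"

#: The 20 regions retained for BOLD modeling: bilateral anterior prefrontal
#: cortex, ventrolateral prefrontal cortex, premotor cortex, primary motor
#: cortex, primary sensory cortex, superior parietal cortex, auditory cortex,
#: higher visual cortex, primary visual cortex, and amygdala.
MODEL_REGIONS_20 = [
    "L_aPFC", "R_aPFC",
    "L_VLPFC", "R_VLPFC",
    "L_premotor", "R_premotor",
    "L_M1", "R_M1",
    "L_S1", "R_S1",
    "L_sup_parietal", "R_sup_parietal",
    "L_auditory", "R_auditory",
    "L_HVC", "R_HVC",
    "L_V1", "R_V1",
    "L_amygdala", RIGHT_AMYGDALA,
]


def total_parcels() -> int:
    """Total parcel count across the cortical, subcortical and cerebellar atlases."""
    return sum(ATLAS_PARCEL_COUNTS.values())


def right_amygdala_index(region_labels: list[str]) -> int:
    """Index of the right amygdala in ``region_labels``; raises if absent."""
    try:
        return region_labels.index(RIGHT_AMYGDALA)
    except ValueError:
        raise ValueError(
            f"region list does not contain {RIGHT_AMYGDALA!r}: {region_labels}"
        ) from None
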