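"""Mass and biomass prediction from fitted allometric parameters.

Individual masses come straight from the published formula

    ln(mass) = (reference intercept + family intercept adj.)
             + ln(length) * (reference slope + family slope adj.)

species-level expected masses use the midpoint of a field guide's printed
forewing-length range, and sample biomass is the count-weighted sum of
species masses.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .params import AllometricParameters, load_reference_parameters

logger = logging.getLogger(__name__)

__all__ = [
    "predict_mass",
    "species_expected_mass",
    "species_mass_table",
    "sample_biomass",
    "dataset_prediction_offset",
    "load_reference_parameters",
]


def predict_mass(
    forewing_length_mm, family, params: AllometricParameters
) -> float | np.ndarray:
    """Predicted dry mass (mg) of a moth from forewing length and family.

    Unknown families resolve to the pooled "other" group (with a logged
    warning): the reference parameters exist precisely to cover families
    absent from the training data.
    """
    lengths = np.asarray(forewing_length_mm, dtype=float)
    scalar = lengths.ndim == 0
    lengths = np.atleast_1d(lengths)
    families = np.atleast_1d(np.asarray(family, dtype=object))
    if families.size == 1 and lengths.size > 1:
        families = np.repeat(families, lengths.size)
    if np.any(lengths <= 0):
        raise ValueError("forewing length must be positive")

    unknown = sorted(
        {str(f) for f in families if str(f) not in params.grouping.mapping}
    )
    if unknown:
        logger.warning(
            "families not seen in training mapped to %r: %s",
            params.grouping.other_label,
            ", ".join(unknown),
        )
    ln_mass = params.linear_predictor(np.log(lengths), families)
    mass = np.exp(ln_mass)
    return float(mass[0]) if scalar else mass


def species_expected_mass(
    forewing_min_mm: float,
    forewing_max_mm: float,
    family: str,
    params: AllometricParameters,
) -> float:
    """Expected species mass (mg) from a field-guide forewing-length range.

    The arithmetic midpoint (min+max)/2 is taken *before* the log transform.
    """
    if not (0 < forewing_min_mm <= forewing_max_mm):
        raise ValueError("need 0 < forewing_min_mm <= forewing_max_mm")
    midpoint = 0.5 * (forewing_min_mm + forewing_max_mm)
    return float(predict_mass(midpoint, family, params))


def species_mass_table(
    guide: pd.DataFrame, params: AllometricParameters
) -> pd.Series:
    """Predicted mass (mg) for every species in a field-guide table.

    ``guide`` needs columns species, family, forewing_min_mm, forewing_max_mm;
    returns a Series indexed by species, plus convenience columns available
    via :func:`species_mass_frame`.
    """
    return species_mass_frame(guide, params)["predicted_mass_mg"]


def species_mass_frame(
    guide: pd.DataFrame, params: AllometricParameters
) -> pd.DataFrame:
    """As :func:`species_mass_table` but with group and midpoint columns."""
    required = {"species", "family", "forewing_min_mm", "forewing_max_mm"}
    missing = required - set(guide.columns)
    if missing:
        raise ValueError(f"field guide missing columns: {sorted(missing)}")
    lo = guide["forewing_min_mm"].to_numpy(dtype=float)
    hi = guide["forewing_max_mm"].to_numpy(dtype=float)
    if np.any(lo <= 0) or np.any(lo > hi):
        raise ValueError("field-guide ranges must satisfy 0 < min <= max")
    mid = 0.5 * (lo + hi)
    mass = predict_mass(mid, guide["family"].to_numpy(dtype=object), params)
    out = pd.DataFrame(
        {
            "species": guide["species"].to_numpy(),
            "family_group": [
                params.grouping.group_of(str(f)) for f in guide["family"]
            ],
            "expected_forewing_mm": mid,
            "predicted_mass_mg": np.atleast_1d(mass),
        }
    )
    return out.set_index("species", drop=False)


def sample_biomass(counts: Mapping[str, int], masses: Mapping[str, float]) -> float:
    """Total predicted biomass (mg) of one mixed-species sample.

    ``counts`` maps species -> abundance in the sample; ``masses`` maps
    species -> predicted per-individual mass (mg).
    """
    missing = [s for s in counts if s not in masses]
    if missing:
        raise KeyError(f"species missing from mass table: {sorted(missing)}")
    return float(sum(n * masses[s] for s, n in counts.items()))


def dataset_prediction_offset(
    records: pd.DataFrame, masses: Mapping[str, float]
) -> float:
    """Whole-dataset prediction offset, percent.

    100 * (total predicted - total measured) / total measured over all
    individuals; negative means the model under-predicts biomass.
    """
    if len(records) == 0:
        raise ValueError("no records")
    missing = sorted(set(records["species"]) - set(pd.Series(dict(masses)).index))
    if missing:
        raise KeyError(f"species missing from mass table: {missing}")
    measured = records["dry_mass_mg"].to_numpy(dtype=float)
    total_measured = float(measured.sum())
    if total_measured <= 0:
        raise ValueError("total measured biomass must be positive")
    lookup = dict(masses)
    total_predicted = float(sum(lookup[s] for s in records["species"]))
    return 100.0 * (total_predicted - total_measured) / total_measured
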