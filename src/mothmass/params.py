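"""Allometric parameter sets, family grouping, and their on-disk representation.

The predictive model lives on the natural-log scale:

    ln(dry mass, mg) = (b0 + b0_f) + (b1 + b1_f) * ln(forewing length, mm)

where ``b0``/``b1`` are the reference ("other families") intercept and slope and
``b0_f``/``b1_f`` are per-family refinements for families that were sampled
richly enough to earn their own adjustment.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "FamilyGrouping",
    "AllometricParameters",
    "load_reference_parameters",
]


@dataclass(frozen=True)
class FamilyGrouping:
    """Mapping from taxonomic family to model group label.

    A family keeps its own label iff it contributed at least ``threshold``
    distinct species to the training data; all remaining families share
    ``other_label``. Families never seen in training also resolve to
    ``other_label`` (the reference prediction).
    """

    mapping: Mapping[str, str]
    threshold: int = 5
    other_label: str = "other"

    def group_of(self, family: str) -> str:
        return self.mapping.get(family, self.other_label)

    @property
    def groups(self) -> list[str]:
        """All group labels, reference (``other_label``) first."""
        retained = sorted(set(self.mapping.values()) - {self.other_label})
        return [self.other_label] + retained

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass
class AllometricParameters:
    """Fitted (or published) parameters of the forewing-length -> mass model.

    ``family_adjustments`` maps group label -> (slope_adjustment,
    intercept_adjustment), to be *added* to the reference values. Groups
    absent from the mapping get zero adjustment, i.e. the reference
    prediction.
    """

    reference_slope: float
    reference_intercept: float
    family_adjustments: dict[str, tuple[float, float]]
    grouping: FamilyGrouping
    provenance: dict = field(default_factory=dict)

    def effective(self, group: str) -> tuple[float, float]:
        """(slope, intercept) actually applied for a group label."""
        ds, di = self.family_adjustments.get(group, (0.0, 0.0))
        return self.reference_slope + ds, self.reference_intercept + di

    def linear_predictor(self, ln_length, family) -> np.ndarray:
        """ln(mass) for arrays of ln(length) and family names."""
        ln_length = np.asarray(ln_length, dtype=float)
        family = np.asarray(family, dtype=object)
        out = np.empty_like(ln_length)
        for i, (ll, fam) in enumerate(zip(ln_length.ravel(), family.ravel())):
            slope, intercept = self.effective(self.grouping.group_of(str(fam)))
            out.ravel()[i] = intercept + slope * ll
        return out

    # ---- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "reference_slope": float(self.reference_slope),
            "reference_intercept": float(self.reference_intercept),
            "family_adjustments": {
                g: {"slope": float(s), "intercept": float(i)}
                for g, (s, i) in sorted(self.family_adjustments.items())
            },
            "grouping": {
                "threshold": int(self.grouping.threshold),
                "other_label": self.grouping.other_label,
                "mapping": dict(sorted(self.grouping.mapping.items())),
            },
            "provenance": dict(self.provenance),
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8"
        )

    @classmethod
    def from_dict(cls, d: Mapping) -> "AllometricParameters":
        g = d["grouping"]
        grouping = FamilyGrouping(
            mapping=dict(g.get("mapping", {})),
            threshold=int(g.get("threshold", 5)),
            other_label=str(g.get("other_label", "other")),
        )
        adjustments = {
            name: (float(v["slope"]), float(v["intercept"]))
            for name, v in d.get("family_adjustments", {}).items()
        }
        return cls(
            reference_slope=float(d["reference_slope"]),
            reference_intercept=float(d["reference_intercept"]),
            family_adjustments=adjustments,
            grouping=grouping,
            provenance=dict(d.get("provenance", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AllometricParameters":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def load_reference_parameters() -> AllometricParameters:
    """Load the packaged published parameter set for British moths.

    These are the point estimates from a peer-reviewed UK light-trap study
    (600 individuals, 94 species, 11 families) with refined slopes and
    intercepts for Crambidae, Erebidae, Geometridae and Noctuidae; they are
    the package's reference prediction behaviour.
    """
    ref = importlib.resources.files("mothmass").joinpath("data/uk_moths_2018.yaml")
    return AllometricParameters.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))
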