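"""CSV readers/writers and the record-exclusion filters.

All tabular interchange is plain UTF-8 CSV with a header row. Specimen files
carry one measured moth per row; a below-detection dry mass (under the 0.005
mg balance limit) is written as the sentinel ``<0.005`` so the exclusion
filter is testable from files.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SPECIMEN_COLUMNS",
    "GUIDE_COLUMNS",
    "ABUNDANCE_COLUMNS",
    "BELOW_DETECTION_SENTINEL",
    "FilterReport",
    "read_specimens",
    "write_specimens",
    "read_field_guide",
    "write_field_guide",
    "read_abundance",
    "filter_records",
]

SPECIMEN_COLUMNS = (
    "specimen_id",
    "species",
    "family",
    "site",
    "date",
    "forewing_length_mm",
    "dry_mass_mg",
)
GUIDE_COLUMNS = ("species", "family", "forewing_min_mm", "forewing_max_mm")
ABUNDANCE_COLUMNS = ("site", "date", "species", "count")

BELOW_DETECTION_SENTINEL = "<0.005"
DETECTION_LIMIT_MG = 0.005


@dataclass
class FilterReport:
    """Bookkeeping for the record-exclusion filters."""

    n_input: int
    n_excluded_unidentified: int
    n_excluded_below_detection: int
    n_retained: int
    excluded_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        total = (
            self.n_retained
            + self.n_excluded_unidentified
            + self.n_excluded_below_detection
        )
        if total != self.n_input:
            raise ValueError("filter report counts do not add up")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")


def read_specimens(path: str | Path) -> pd.DataFrame:
    """Read a specimen CSV into typed records.

    Dates are parsed as ISO 8601; a dry mass equal to the sentinel
    ``<0.005`` (or an empty field) becomes NaN with ``below_detection`` set.
    Malformed values raise with the 1-based file line number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, SPECIMEN_COLUMNS, path)

    lengths = np.empty(len(df), dtype=float)
    masses = np.full(len(df), np.nan)
    below = np.zeros(len(df), dtype=bool)
    dates = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        raw_len = getattr(row, "forewing_length_mm").strip()
        try:
            lengths[i] = float(raw_len)
        except ValueError:
            raise ValueError(
                f"{path}:{line}: non-numeric forewing_length_mm {raw_len!r}"
            ) from None
        raw_mass = getattr(row, "dry_mass_mg").strip()
        if raw_mass in ("", BELOW_DETECTION_SENTINEL) or raw_mass.startswith("<"):
            below[i] = True
        else:
            try:
                masses[i] = float(raw_mass)
            except ValueError:
                raise ValueError(
                    f"{path}:{line}: non-numeric dry_mass_mg {raw_mass!r}"
                ) from None
        raw_date = getattr(row, "date").strip()
        try:
            dates.append(_dt.date.fromisoformat(raw_date))
        except ValueError:
            raise ValueError(
                f"{path}:{line}: date {raw_date!r} is not ISO 8601"
            ) from None

    out = pd.DataFrame(
        {
            "specimen_id": df["specimen_id"].str.strip(),
            "species": df["species"].str.strip(),
            "family": df["family"].str.strip(),
            "site": df["site"].str.strip(),
            "date": [d.isoformat() for d in dates],
            "forewing_length_mm": lengths,
            "dry_mass_mg": masses,
            "below_detection": below,
        }
    )
    return out


def write_specimens(records: pd.DataFrame, path: str | Path) -> None:
    """Write specimen records; below-detection masses become the sentinel."""
    df = records.copy()
    below = (
        df["below_detection"].to_numpy(dtype=bool)
        if "below_detection" in df
        else df["dry_mass_mg"].isna().to_numpy()
    )
    mass_txt = [
        BELOW_DETECTION_SENTINEL if b else f"{m:.2f}"
        for b, m in zip(below, df["dry_mass_mg"])
    ]
    out = pd.DataFrame(
        {
            "specimen_id": df["specimen_id"],
            "species": df["species"],
            "family": df["family"],
            "site": df["site"],
            "date": df["date"].astype(str),
            "forewing_length_mm": df["forewing_length_mm"].map(
                lambda v: f"{v:g}"
            ),
            "dry_mass_mg": mass_txt,
        }
    )
    out.to_csv(path, index=False)


def read_field_guide(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, GUIDE_COLUMNS, path)
    df["forewing_min_mm"] = df["forewing_min_mm"].astype(float)
    df["forewing_max_mm"] = df["forewing_max_mm"].astype(float)
    bad = df[
        (df["forewing_min_mm"] <= 0)
        | (df["forewing_min_mm"] > df["forewing_max_mm"])
    ]
    if len(bad):
        raise ValueError(
            f"{path}: invalid forewing ranges for species {list(bad['species'][:5])}"
        )
    return df


def write_field_guide(guide: pd.DataFrame, path: str | Path) -> None:
    guide.loc[:, list(GUIDE_COLUMNS)].to_csv(path, index=False)


def read_abundance(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ABUNDANCE_COLUMNS, path)
    df["count"] = df["count"].astype(int)
    if (df["count"] < 0).any():
        raise ValueError(f"{path}: negative abundance counts")
    return df


def filter_records(records: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the study's record-exclusion rules.

    Excluded are (1) individuals not identified to species (empty species
    field), and (2) individuals below the balance detection limit (flagged
    below-detection or mass < 0.005 mg). A record failing both rules counts
    as unidentified.
    """
    species = records["species"].fillna("").astype(str).str.strip()
    unidentified = species == ""
    below = records.get(
        "below_detection", pd.Series(False, index=records.index)
    ).astype(bool) | (records["dry_mass_mg"] < DETECTION_LIMIT_MG) | records[
        "dry_mass_mg"
    ].isna()
    below = below & ~unidentified
    keep = ~unidentified & ~below

    excluded = records.loc[~keep]
    ids = (
        excluded["specimen_id"].astype(str).tolist()
        if "specimen_id" in records
        else []
    )
    report = FilterReport(
        n_input=len(records),
        n_excluded_unidentified=int(unidentified.sum()),
        n_excluded_below_detection=int(below.sum()),
        n_retained=int(keep.sum()),
        excluded_ids=ids,
    )
    if report.n_retained < len(records):
        logger.info(
            "excluded %d unidentified and %d below-detection records; %d retained",
            report.n_excluded_unidentified,
            report.n_excluded_below_detection,
            report.n_retained,
        )
    return records.loc[keep].copy(), report
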