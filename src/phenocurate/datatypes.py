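"""Domain types for genebank regeneration phenotype data.

A regeneration *campaign* is a field grow-out of accessions in one year;
phenotype records are kept in long format, one row per (accession, year,
trait) observation. Accessions are identified by the standard triplet of
FAO-WIEWS institute code, genus and accession number.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

#: canonical long-format columns of the record table
RECORD_COLUMNS = [
    "institute_code",
    "genus",
    "accession_number",
    "year",
    "location",
    "seasonal_type",
    "trait",
    "value",
]


@dataclass(frozen=True)
class AccessionIdentifier:
    """Unique germplasm identifier: FAO-WIEWS institute code + genus + accession number.

    ``agent_id`` and ``doi`` are optional auxiliary identifiers and do not
    participate in equality.
    """

    institute_code: str
    genus: str
    accession_number: str
    agent_id: Optional[str] = dataclasses.field(default=None, compare=False)
    doi: Optional[str] = dataclasses.field(default=None, compare=False)

    def __post_init__(self) -> None:
        for f in ("institute_code", "genus", "accession_number"):
            if not str(getattr(self, f)).strip():
                raise ValueError(f"AccessionIdentifier.{f} must be non-empty")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.institute_code, self.genus, self.accession_number)

    def __str__(self) -> str:  # e.g. "CHE001:Triticum:12345"
        return ":".join(self.key)


@dataclass(frozen=True)
class TraitDefinition:
    """An observation variable with its unit and plausibility window.

    ``plausible_min``/``plausible_max`` bound physically credible values and
    drive the range filter (bounds inclusive). ``method_note`` carries
    protocol conventions that must never be harmonised away, e.g. whether
    heading date counts days from January 1st or from sowing.
    """

    code: str
    label: str = ""
    unit: str = ""
    plausible_min: float = -np.inf
    plausible_max: float = np.inf
    method_note: str = ""

    def __post_init__(self) -> None:
        if not str(self.unit).strip():
            raise ValueError("TraitDefinition.unit must be non-empty")
        if not self.plausible_min < self.plausible_max:
            raise ValueError("plausible_min must be < plausible_max")


#: the three core traits with their deliberately lax plausibility windows
TRAIT_PRESETS: dict[str, TraitDefinition] = {
    "HD": TraitDefinition(
        code="HD",
        label="heading date",
        unit="days",
        plausible_min=50.0,
        plausible_max=250.0,
        method_note="days until 50% of plants reach BBCH 59; reference "
        "(Jan 1 vs sowing) varies by genebank and is never converted",
    ),
    "PH": TraitDefinition(
        code="PH",
        label="plant height",
        unit="cm",
        plausible_min=5.0,
        plausible_max=250.0,
        method_note="soil surface to top of the ear",
    ),
    "TKW": TraitDefinition(
        code="TKW",
        label="thousand kernel weight",
        unit="g",
        plausible_min=5.0,
        plausible_max=100.0,
        method_note="grams per 1000 grains at ~15% grain moisture",
    ),
}


@dataclass(frozen=True)
class StudyMetadata:
    """One regeneration campaign: genebank, year and location."""

    genebank: str
    campaign_year: int
    location_name: str = ""
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    seasonal_type: str = "unclassified"
    start_date: Optional[str] = None
    end_date: Optional[str] = None

    def __post_init__(self) -> None:
        if not 1900 <= int(self.campaign_year) <= pd.Timestamp.now().year:
            raise ValueError(f"campaign_year {self.campaign_year} out of range")
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            raise ValueError(f"latitude {self.latitude} out of range")
        if self.longitude is not None and not -180 <= self.longitude <= 180:
            raise ValueError(f"longitude {self.longitude} out of range")
        if self.seasonal_type not in ("spring", "winter", "unclassified"):
            raise ValueError(f"unknown seasonal_type {self.seasonal_type!r}")


class PhenotypeDataset:
    """Long-format collection of phenotype records with incidence queries.

    Wraps a :class:`pandas.DataFrame` with the columns in
    :data:`RECORD_COLUMNS` plus a trait catalogue and campaign metadata.
    The accession key is the identifier triplet; ``accession_id`` is its
    colon-joined string form, added as a derived column.

    Parameters
    ----------
    records : DataFrame
        One row per observation; missing optional columns are added empty.
    traits : mapping of code -> TraitDefinition
    studies : iterable of StudyMetadata, optional
    provenance : str
        Free-text source tag.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        traits: Mapping[str, TraitDefinition] | None = None,
        studies: Iterable[StudyMetadata] = (),
        provenance: str = "",
    ) -> None:
        df = records.copy()
        for col in RECORD_COLUMNS:
            if col not in df.columns:
                if col in ("location", "seasonal_type"):
                    df[col] = "" if col == "location" else "unclassified"
                else:
                    raise ValueError(f"records missing mandatory column {col!r}")
        df = df[RECORD_COLUMNS].reset_index(drop=True)
        df["year"] = df["year"].astype(int)
        df["value"] = df["value"].astype(float)
        if not np.isfinite(df["value"]).all():
            raise ValueError("record values must be finite")
        df["accession_id"] = (
            df["institute_code"].astype(str)
            + ":"
            + df["genus"].astype(str)
            + ":"
            + df["accession_number"].astype(str)
        )
        self.df = df
        self.traits: dict[str, TraitDefinition] = dict(traits or {})
        unknown = set(df["trait"]) - set(self.traits)
        if self.traits and unknown:
            # tolerated at construction; validate_dataset reports it
            pass
        self.studies = list(studies)
        self.provenance = provenance

    # -- basic protocol ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        """Record-multiset and trait-catalogue equality.

        Values compare to within one part in 1e12 (spreadsheet formats cap
        floats at ~16 significant digits); all other fields are exact.
        """
        if not isinstance(other, PhenotypeDataset):
            return NotImplemented
        if self.traits != other.traits:
            return False
        a, b = self.record_multiset(), other.record_multiset()
        if a.shape != b.shape:
            return False
        other_cols = [c for c in a.columns if c != "value"]
        if not a[other_cols].equals(b[other_cols]):
            return False
        return bool(np.allclose(a["value"], b["value"], rtol=1e-12, atol=1e-12))

    def copy(self) -> "PhenotypeDataset":
        return PhenotypeDataset(
            self.df[RECORD_COLUMNS], self.traits, self.studies, self.provenance
        )

    def record_multiset(self) -> pd.DataFrame:
        """Canonical sorted record table, for order-insensitive comparison."""
        return (
            self.df[RECORD_COLUMNS]
            .sort_values(RECORD_COLUMNS, kind="mergesort")
            .reset_index(drop=True)
        )

    def with_records(self, df: pd.DataFrame) -> "PhenotypeDataset":
        """New dataset sharing catalogue/metadata with a different record table."""
        return PhenotypeDataset(
            df[RECORD_COLUMNS], self.traits, self.studies, self.provenance
        )

    # -- incidence queries ------------------------------------------------
    @property
    def accessions(self) -> pd.Index:
        return pd.Index(self.df["accession_id"].unique())

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.df["year"].unique())

    def years_per_accession(self) -> pd.Series:
        """Number of distinct campaign years per accession."""
        return self.df.groupby("accession_id")["year"].nunique()

    def points_per_year(self) -> pd.Series:
        """Number of records per campaign year."""
        return self.df.groupby("year").size()

    def mean_years_per_accession(self) -> float:
        """Arithmetic mean over accessions of distinct years with data (N̄_Y)."""
        if len(self.df) == 0:
            raise ValueError("empty dataset has no mean years per accession")
        return float(self.years_per_accession().mean())

    def duplicate_keys(self) -> pd.DataFrame:
        """Rows sharing an (accession, year, trait) key (replicate collisions)."""
        key = ["accession_id", "year", "trait"]
        return self.df[self.df.duplicated(key, keep=False)]


@dataclass
class FilterLog:
    """Reconciliation record for one curation stage.

    ``records_in - records_removed`` always equals the size of the stage
    output; per-record reasons let a curator audit every removal.
    """

    rule: str
    records_in: int
    records_removed: int
    accessions_removed: int = 0
    years_removed: int = 0
    reasons: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["accession_id", "year", "trait", "value", "reason"]
        )
    )

    @property
    def records_out(self) -> int:
        return self.records_in - self.records_removed

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "records_in": int(self.records_in),
            "records_removed": int(self.records_removed),
            "records_out": int(self.records_out),
            "accessions_removed": int(self.accessions_removed),
            "years_removed": int(self.years_removed),
        }
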