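"""Tabular exchange I/O for regeneration phenotype workbooks.

The exchange dialect has three logical sections per genebank file:

* ``study`` — one row per campaign (genebank, year, location, coordinates,
  seasonal type, dates), keyed by ``study_id``;
* ``observation_variables`` — trait definitions with units and plausibility
  bounds;
* ``data`` — long-format records: ``study_id`` plus the accession identifier
  triplet (FAO-WIEWS institute code, genus, accession number), trait code
  and value.

An ``.xlsx`` path holds the sections as sheets; any other path is taken as
a directory with ``study.csv``, ``variables.csv`` and ``data.csv``. Curated
output adds ``blues`` and ``summary`` sections. Empty cells and the literal
token ``NA`` mean "value absent"; any other non-numeric value cell is
skipped with a logged complaint, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .datatypes import PhenotypeDataset, StudyMetadata, TraitDefinition

__all__ = [
    "WorkbookLayout",
    "FormatError",
    "IdentityConflictError",
    "ValidationIssue",
    "ValidationReport",
    "read_workbook",
    "validate_dataset",
    "write_curated",
]

logger = logging.getLogger(__name__)

_STUDY_COLS = ["study_id", "genebank", "campaign_year", "location_name",
               "latitude", "longitude", "seasonal_type", "start_date", "end_date"]
_VAR_COLS = ["code", "label", "unit", "plausible_min", "plausible_max", "method_note"]
_DATA_COLS = ["study_id", "institute_code", "genus", "accession_number",
              "trait", "value"]


class FormatError(ValueError):
    """A mandatory sheet or column of the exchange layout is missing."""


class IdentityConflictError(ValueError):
    """The same accession triplet appears with conflicting metadata."""


@dataclass
class WorkbookLayout:
    """Maps the logical sections and columns onto a concrete file layout.

    The deposited templates do not pin exact column headers, so the mapping
    is externalised: ``columns`` maps logical name -> actual header, per
    section; unlisted columns keep their logical names.
    """

    sheets: dict = field(default_factory=lambda: {
        "study": "study", "variables": "observation_variables",
        "data": "data", "blues": "blues", "summary": "summary",
    })
    columns: dict = field(default_factory=dict)  # section -> {logical: actual}

    @classmethod
    def from_yaml(cls, path) -> "WorkbookLayout":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        layout = cls()
        layout.sheets.update(raw.get("sheets", {}))
        layout.columns = raw.get("columns", {})
        return layout

    def rename(self, section: str, df: pd.DataFrame) -> pd.DataFrame:
        mapping = {v: k for k, v in self.columns.get(section, {}).items()}
        return df.rename(columns=mapping)


def _read_sections(path: Path, layout: WorkbookLayout) -> dict[str, pd.DataFrame]:
    sections = {}
    if path.suffix.lower() == ".xlsx":
        if not path.exists():
            raise FileNotFoundError(path)
        book = pd.read_excel(path, sheet_name=None, dtype=object)
        for logical in ("study", "variables", "data"):
            name = layout.sheets[logical]
            if name not in book:
                raise FormatError(f"workbook is missing mandatory sheet {name!r}")
            sections[logical] = layout.rename(logical, book[name])
    else:
        if not path.is_dir():
            raise FileNotFoundError(path)
        for logical, fname in (("study", "study.csv"),
                               ("variables", "variables.csv"),
                               ("data", "data.csv")):
            f = path / fname
            if not f.exists():
                raise FormatError(f"directory is missing mandatory file {fname!r}")
            sections[logical] = layout.rename(logical, pd.read_csv(f, dtype=object))
    return sections


def _require(df: pd.DataFrame, cols, section: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"section {section!r} is missing column(s) {missing}")


def _opt_float(x) -> Optional[float]:
    if x is None or (isinstance(x, float) and np.isnan(x)) or str(x).strip() in ("", "NA"):
        return None
    return float(x)


def read_workbook(path, layout: WorkbookLayout | None = None) -> PhenotypeDataset:
    """Read an exchange workbook (or CSV directory) into a PhenotypeDataset.

    Value cells that are empty or ``NA`` are treated as absent; other
    non-numeric cells are skipped and recorded in ``ds.read_log``. The same
    accession triplet carrying conflicting auxiliary identity metadata
    raises :class:`IdentityConflictError`.
    """
    layout = layout or WorkbookLayout()
    path = Path(path)
    sections = _read_sections(path, layout)

    study = sections["study"]
    _require(study, ["study_id", "genebank", "campaign_year", "seasonal_type"], "study")
    variables = sections["variables"]
    _require(variables, ["code", "unit"], "variables")
    data = sections["data"]
    _require(data, _DATA_COLS, "data")

    traits: dict[str, TraitDefinition] = {}
    for _, row in variables.iterrows():
        lo = _opt_float(row.get("plausible_min"))
        hi = _opt_float(row.get("plausible_max"))
        traits[str(row["code"])] = TraitDefinition(
            code=str(row["code"]),
            label=str(row.get("label", "") or ""),
            unit=str(row["unit"]),
            plausible_min=lo if lo is not None else -np.inf,
            plausible_max=hi if hi is not None else np.inf,
            method_note=str(row.get("method_note", "") or ""),
        )

    study = study.copy()
    study["campaign_year"] = study["campaign_year"].astype(int)
    studies = []
    for _, row in study.iterrows():
        try:
            studies.append(StudyMetadata(
                genebank=str(row["genebank"]),
                campaign_year=int(row["campaign_year"]),
                location_name=str(row.get("location_name", "") or ""),
                latitude=_opt_float(row.get("latitude")),
                longitude=_opt_float(row.get("longitude")),
                seasonal_type=str(row["seasonal_type"]),
                start_date=row.get("start_date") or None,
                end_date=row.get("end_date") or None,
            ))
        except ValueError as exc:  # kept readable; validate_dataset reports it
            logger.warning("study %s has invalid metadata: %s", row["study_id"], exc)

    merged = data.merge(
        study[["study_id", "campaign_year", "location_name", "seasonal_type"]],
        on="study_id", how="left", validate="many_to_one",
    )
    unknown_study = merged["campaign_year"].isna()
    if unknown_study.any():
        bad = sorted(merged.loc[unknown_study, "study_id"].unique())
        raise FormatError(f"data rows reference undefined study_id(s) {bad}")

    read_log: list[dict] = []
    values = np.full(len(merged), np.nan)
    keep = np.zeros(len(merged), dtype=bool)
    for k, raw in enumerate(merged["value"]):
        txt = "" if raw is None else str(raw).strip()
        if txt in ("", "NA", "nan"):
            continue  # absent by convention
        try:
            values[k] = float(txt)
            keep[k] = True
        except ValueError:
            read_log.append({"row": int(k), "value": raw,
                             "reason": "non-numeric value cell"})
            logger.warning("skipping non-numeric value %r in data row %d", raw, k)

    # identity conflict: same triplet, conflicting auxiliary identifiers
    aux_cols = [c for c in ("agent_id", "doi") if c in merged.columns]
    if aux_cols:
        trip = ["institute_code", "genus", "accession_number"]
        conflict = (
            merged[trip + aux_cols].fillna("").astype(str)
            .drop_duplicates().groupby(trip).size()
        )
        bad = conflict[conflict > 1]
        if len(bad):
            raise IdentityConflictError(
                f"conflicting metadata for accession triplet(s) {list(bad.index)[:5]}"
            )

    records = pd.DataFrame({
        "institute_code": merged["institute_code"].astype(str),
        "genus": merged["genus"].astype(str),
        "accession_number": merged["accession_number"].astype(str),
        "year": merged["campaign_year"],
        "location": merged["location_name"].fillna("").astype(str),
        "seasonal_type": merged["seasonal_type"].astype(str),
        "trait": merged["trait"].astype(str),
        "value": values,
    }).loc[keep]
    records["year"] = records["year"].astype(int)

    ds = PhenotypeDataset(records, traits=traits, studies=studies,
                          provenance=str(path))
    ds.read_log = read_log
    ds.study_table = study
    return ds


# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationIssue:
    code: str
    record: str
    detail: str = ""


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    def codes(self) -> list[str]:
        return [i.code for i in self.issues]

    def __len__(self) -> int:
        return len(self.issues)


def validate_dataset(ds: PhenotypeDataset) -> ValidationReport:
    """Enumerate identifier, coordinate, trait and duplicate-key problems.

    Pure reporting: the dataset is never modified, and two calls yield
    identical reports.
    """
    issues: list[ValidationIssue] = []
    df = ds.df
    for col, code in (("institute_code", "MISSING_INSTITUTE"),
                      ("genus", "MISSING_GENUS"),
                      ("accession_number", "MISSING_ACCESSION_NUMBER")):
        bad = df[col].astype(str).str.strip() == ""
        for i in df.index[bad]:
            issues.append(ValidationIssue(code, f"record {i}"))

    study = getattr(ds, "study_table", None)
    if study is not None:
        for _, row in study.iterrows():
            lat, lon = _opt_float(row.get("latitude")), _opt_float(row.get("longitude"))
            if lat is not None and not -90 <= lat <= 90:
                issues.append(ValidationIssue(
                    "COORD_RANGE", f"study {row['study_id']}", f"latitude {lat}"))
            if lon is not None and not -180 <= lon <= 180:
                issues.append(ValidationIssue(
                    "COORD_RANGE", f"study {row['study_id']}", f"longitude {lon}"))

    if ds.traits:
        unknown = df.loc[~df["trait"].isin(ds.traits.keys())]
        for i, row in unknown.iterrows():
            issues.append(ValidationIssue("UNKNOWN_TRAIT", f"record {i}",
                                          str(row["trait"])))

    dup = ds.duplicate_keys()
    for key, grp in dup.groupby(["accession_id", "year", "trait"]):
        issues.append(ValidationIssue(
            "DUPLICATE_KEY", f"records {list(grp.index)}", "/".join(map(str, key))))

    return ValidationReport(issues)


# ---------------------------------------------------------------------------

def _sections_from_dataset(ds: PhenotypeDataset) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    df = ds.df
    study_src = getattr(ds, "study_table", None)
    key_cols = ["institute_code", "year", "location", "seasonal_type"]
    keys = df[key_cols].drop_duplicates().sort_values(key_cols).reset_index(drop=True)
    keys["study_id"] = [
        f"{r.institute_code}_{r.year}_{r.seasonal_type}_{k}"
        for k, r in enumerate(keys.itertuples())
    ]
    study = pd.DataFrame({
        "study_id": keys["study_id"],
        "genebank": keys["institute_code"],
        "campaign_year": keys["year"],
        "location_name": keys["location"],
        "latitude": None, "longitude": None,
        "seasonal_type": keys["seasonal_type"],
        "start_date": None, "end_date": None,
    })
    if study_src is not None and set(_STUDY_COLS) <= set(study_src.columns):
        study = study_src[_STUDY_COLS].copy()
        keys = study.rename(columns={
            "genebank": "institute_code", "campaign_year": "year",
            "location_name": "location",
        })[["institute_code", "year", "location", "seasonal_type", "study_id"]]
        keys["year"] = keys["year"].astype(int)
        keys["location"] = keys["location"].fillna("").astype(str)

    data = df.merge(keys, on=key_cols, how="left")
    data = data[["study_id", "institute_code", "genus", "accession_number",
                 "trait", "value"]]
    variables = pd.DataFrame([
        {
            "code": t.code, "label": t.label, "unit": t.unit,
            "plausible_min": None if np.isneginf(t.plausible_min) else t.plausible_min,
            "plausible_max": None if np.isposinf(t.plausible_max) else t.plausible_max,
            "method_note": t.method_note,
        }
        for t in ds.traits.values()
    ], columns=_VAR_COLS)
    return study, variables, data


def write_curated(ds: PhenotypeDataset, blues: pd.DataFrame | None,
                  report=None, path=None,
                  layout: WorkbookLayout | None = None) -> Path:
    """Write the curated dataset plus BLUEs (and summary) to an exchange file.

    ``blues`` is keyed by the accession triplet (or its joined
    ``accession_id``); an empty table still produces the sheet. Numeric
    cells keep full precision; column order is deterministic.
    """
    layout = layout or WorkbookLayout()
    path = Path(path)
    study, variables, data = _sections_from_dataset(ds)
    if blues is None:
        blues = pd.DataFrame(columns=["accession_id", "blue", "se"])
    blues = blues.reset_index() if blues.index.name == "accession_id" else blues.copy()
    summary = pd.DataFrame([report.to_row()]) if report is not None else pd.DataFrame()

    if path.suffix.lower() == ".xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as xl:
            study.to_excel(xl, sheet_name=layout.sheets["study"], index=False)
            variables.to_excel(xl, sheet_name=layout.sheets["variables"], index=False)
            data.to_excel(xl, sheet_name=layout.sheets["data"], index=False)
            blues.to_excel(xl, sheet_name=layout.sheets["blues"], index=False)
            summary.to_excel(xl, sheet_name=layout.sheets["summary"], index=False)
    else:
        path.mkdir(parents=True, exist_ok=True)
        study.to_csv(path / "study.csv", index=False)
        variables.to_csv(path / "variables.csv", index=False)
        data.to_csv(path / "data.csv", index=False)
        blues.to_csv(path / "blues.csv", index=False)
        if len(summary):
            summary.to_csv(path / "summary.csv", index=False)
    return path
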