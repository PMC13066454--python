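"""Pre-model curation filters: plausibility trimming and connectivity.

The range filter removes physically implausible values using deliberately
lax, trait-specific windows (e.g. 5-250 cm for plant height). The
connectivity filter then drops accessions tested in fewer than
``min_years_per_accession`` distinct years and campaign years holding fewer
than ``min_points_per_year`` records. Because removing a sparse year can
strand an accession in a single remaining year (and vice versa), the two
rules are iterated to a fixed point, which is the only order-independent
reading of their interaction.
"""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import FilterLog, PhenotypeDataset, TraitDefinition

__all__ = [
    "RangeFilter",
    "ConnectivityFilter",
    "apply_range_filter",
    "apply_connectivity_filter",
]


def _log_from_removal(rule: str, ds_in: PhenotypeDataset, kept: pd.Series,
                      reason: str | pd.Series) -> FilterLog:
    df = ds_in.df
    removed = df.loc[~kept]
    acc_lost = set(df["accession_id"].unique()) - set(df.loc[kept, "accession_id"].unique())
    yr_lost = set(df["year"].unique()) - set(df.loc[kept, "year"].unique())
    reasons = removed[["accession_id", "year", "trait", "value"]].copy()
    reasons["reason"] = reason
    return FilterLog(
        rule=rule,
        records_in=len(df),
        records_removed=int((~kept).sum()),
        accessions_removed=len(acc_lost),
        years_removed=len(yr_lost),
        reasons=reasons.reset_index(drop=True),
    )


class RangeFilter(BaseEstimator, TransformerMixin):
    """Drop records outside a trait's plausibility window (bounds inclusive).

    Parameters
    ----------
    trait : TraitDefinition, optional
        Bounds source. When None, each record's trait code is looked up in
        the dataset's own trait catalogue.

    Attributes
    ----------
    log_ : FilterLog
        Reconciliation of the last ``transform``; removal reason OUT_OF_RANGE.
    """

    def __init__(self, trait: TraitDefinition | None = None) -> None:
        self.trait = trait

    def fit(self, X: PhenotypeDataset, y=None) -> "RangeFilter":
        return self

    def transform(self, X: PhenotypeDataset) -> PhenotypeDataset:
        df = X.df
        if self.trait is not None:
            lo, hi = self.trait.plausible_min, self.trait.plausible_max
            kept = (df["value"] >= lo) & (df["value"] <= hi)
        else:
            lo = df["trait"].map(
                lambda c: X.traits[c].plausible_min if c in X.traits else float("-inf")
            )
            hi = df["trait"].map(
                lambda c: X.traits[c].plausible_max if c in X.traits else float("inf")
            )
            kept = (df["value"] >= lo) & (df["value"] <= hi)
        self.log_ = _log_from_removal("range_filter", X, kept, "OUT_OF_RANGE")
        return X.with_records(df.loc[kept])


class ConnectivityFilter(BaseEstimator, TransformerMixin):
    """Iterate accession-year exclusion rules to a fixed point.

    Parameters
    ----------
    min_years_per_accession : int
        Accessions observed in fewer distinct years are removed (default 2,
        i.e. single-year accessions are excluded).
    min_points_per_year : int
        Years with fewer records are removed (default 2, i.e. single-point
        years are excluded).
    strict_plus_one : bool
        Raise both thresholds by one; an occasional stricter setting used to
        improve average connectivity on very sparse collections.

    Attributes
    ----------
    log_ : FilterLog
        Removal reasons are FEW_YEARS or SPARSE_YEAR; ``n_passes_`` counts
        the sweeps needed to stabilise. An empty output is legal and exposed
        as ``emptied_``.
    """

    def __init__(self, min_years_per_accession: int = 2,
                 min_points_per_year: int = 2,
                 strict_plus_one: bool = False) -> None:
        self.min_years_per_accession = min_years_per_accession
        self.min_points_per_year = min_points_per_year
        self.strict_plus_one = strict_plus_one

    def fit(self, X: PhenotypeDataset, y=None) -> "ConnectivityFilter":
        if self.min_years_per_accession < 1 or self.min_points_per_year < 1:
            raise ValueError("connectivity thresholds must be >= 1")
        return self

    def transform(self, X: PhenotypeDataset) -> PhenotypeDataset:
        self.fit(X)
        min_years = self.min_years_per_accession + (1 if self.strict_plus_one else 0)
        min_points = self.min_points_per_year + (1 if self.strict_plus_one else 0)

        df = X.df
        kept = pd.Series(True, index=df.index)
        reasons = pd.Series("", index=df.index, dtype=object)
        passes = 0
        while True:
            passes += 1
            cur = df.loc[kept]
            ny = cur.groupby("accession_id")["year"].transform("nunique")
            bad_acc = ny < min_years
            if bad_acc.any():
                idx = bad_acc.index[bad_acc]
                kept.loc[idx] = False
                reasons.loc[idx] = "FEW_YEARS"
                cur = df.loc[kept]
            npt = cur.groupby("year")["value"].transform("size")
            bad_year = npt < min_points
            if bad_year.any():
                idx = bad_year.index[bad_year]
                kept.loc[idx] = False
                reasons.loc[idx] = "SPARSE_YEAR"
            if not (bad_acc.any() or bad_year.any()):
                break

        log = _log_from_removal("connectivity_filter", X, kept,
                                reasons.loc[~kept])
        self.log_ = log
        self.n_passes_ = passes
        self.emptied_ = not kept.any()
        return X.with_records(df.loc[kept])


def apply_range_filter(
    ds: PhenotypeDataset, trait: TraitDefinition | None = None
) -> tuple[PhenotypeDataset, FilterLog]:
    """Remove records outside the trait's plausible [min, max] window."""
    f = RangeFilter(trait=trait)
    out = f.fit(ds).transform(ds)
    return out, f.log_


def apply_connectivity_filter(
    ds: PhenotypeDataset,
    min_years_per_accession: int = 2,
    min_points_per_year: int = 2,
    strict_plus_one: bool = False,
) -> tuple[PhenotypeDataset, FilterLog]:
    """Exclude single-year accessions and single-point years, to a fixed point."""
    f = ConnectivityFilter(min_years_per_accession, min_points_per_year,
                           strict_plus_one)
    out = f.fit(ds).transform(ds)
    return out, f.log_
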