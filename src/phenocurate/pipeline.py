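"""End-to-end curation of one genebank x seasonal-type x trait slice.

Stage order: plausibility trimming -> connectivity filtering -> campaign
removal by standardized coefficient of variation -> fixed-accession refit
and Holm-flagged point removal -> random-accession refit for variance
components -> BLUEs and entry-mean heritability

    h2 = sigma2_G / (sigma2_G + sigma2_e / N_bar_Y)

where sigma2_e collapses the year-specific residual variances (unweighted
mean over retained years by default) and N_bar_Y is the mean number of
years with data per accession on the curated dataset. The curation report
reconciles every removal against the raw counts; a slice where no data
survive is an explicit report state, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import FilterLog, PhenotypeDataset, TraitDefinition
from .filters import ConnectivityFilter, RangeFilter
from .outliers import campaign_cv_scores, drop_outlier_campaigns, flag_outlier_points
from .reml import IdentifiabilityError, MixedModelREML, VarianceComponents

__all__ = [
    "PipelineConfig",
    "CurationReport",
    "CurationPipeline",
    "mean_years_per_accession",
    "heritability",
    "run_pipeline",
    "summarize_collections",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Settings of one curation run; defaults are the standard procedure."""

    trait: Optional[TraitDefinition] = None
    min_years_per_accession: int = 2
    min_points_per_year: int = 2
    strict_plus_one: bool = False
    cv_threshold: float = 3.5
    alpha: float = 0.05
    campaign_stage: bool = True
    point_stage: bool = True
    error_variance_summary: str = "unweighted"
    label: str = ""


@dataclass
class CurationReport:
    """One summary row: raw and kept counts, retention, heritability."""

    label: str
    raw_points: int
    raw_accessions: int
    kept_points: int
    kept_accessions: int
    heritability: Optional[float] = None
    n_bar_years: Optional[float] = None
    components: Optional[VarianceComponents] = None
    converged: bool = True
    no_data_remained: bool = False
    logs: list[FilterLog] = field(default_factory=list)

    @property
    def pct_points_kept(self) -> Optional[float]:
        return 100.0 * self.kept_points / self.raw_points if self.raw_points else None

    @property
    def pct_accessions_kept(self) -> Optional[float]:
        return (100.0 * self.kept_accessions / self.raw_accessions
                if self.raw_accessions else None)

    def to_row(self) -> dict:
        """Render as a summary-table row (percentages to one decimal)."""
        def pct(x):
            return "NA" if x is None or self.no_data_remained else f"{x:.1f}%"
        h = self.heritability
        return {
            "dataset": self.label,
            "data_points": self.raw_points,
            "accessions": self.raw_accessions,
            "data_points_kept": pct(self.pct_points_kept),
            "accessions_kept": pct(self.pct_accessions_kept),
            "heritability": "NA" if h is None else f"{100.0 * h:.1f}%",
            "mean_years_per_accession": (
                "NA" if self.n_bar_years is None else round(self.n_bar_years, 3)
            ),
        }


def mean_years_per_accession(ds: PhenotypeDataset) -> float:
    """Mean over accessions of the number of distinct years with data (N̄_Y)."""
    return ds.mean_years_per_accession()


def heritability(components: VarianceComponents, n_bar: float,
                 summary: str = "unweighted") -> float:
    """Entry-mean heritability from a random-genotype fit.

    h2 = sigma2_G / (sigma2_G + sigma2_e / n_bar), with sigma2_e the
    collapsed year-specific error variance. All-zero variances give 0.
    """
    if components.sigma2_G is None:
        raise ValueError("heritability requires a random-genotype fit")
    if n_bar < 1:
        raise ValueError("n_bar must be >= 1")
    s2g = components.sigma2_G
    s2e = components.mean_error_variance(summary)
    denom = s2g + s2e / n_bar
    if denom == 0:
        import warnings
        warnings.warn("all variance components are zero; heritability set to 0")
        return 0.0
    return float(s2g / denom)


class CurationPipeline(BaseEstimator):
    """Full curation of one collection slice, scikit-learn style.

    ``fit(ds)`` runs the staged procedure and exposes:

    Attributes
    ----------
    curated_ : PhenotypeDataset
        Records surviving all stages.
    blues_ : DataFrame (accession_id, blue, se)
    report_ : CurationReport
    logs_ : list of FilterLog, one per removal stage
    campaign_scores_ : list of CampaignScore
    point_flags_ : list of PointFlag (indices into the step-V fit data)
    """

    def __init__(self, trait: Optional[TraitDefinition] = None,
                 min_years_per_accession: int = 2,
                 min_points_per_year: int = 2,
                 strict_plus_one: bool = False,
                 cv_threshold: float = 3.5,
                 alpha: float = 0.05,
                 campaign_stage: bool = True,
                 point_stage: bool = True,
                 error_variance_summary: str = "unweighted",
                 label: str = "") -> None:
        self.trait = trait
        self.min_years_per_accession = min_years_per_accession
        self.min_points_per_year = min_points_per_year
        self.strict_plus_one = strict_plus_one
        self.cv_threshold = cv_threshold
        self.alpha = alpha
        self.campaign_stage = campaign_stage
        self.point_stage = point_stage
        self.error_variance_summary = error_variance_summary
        self.label = label

    # ------------------------------------------------------------------
    def _empty_report(self, ds: PhenotypeDataset, logs) -> CurationReport:
        return CurationReport(
            label=self.label, raw_points=len(ds.df),
            raw_accessions=len(ds.accessions),
            kept_points=0, kept_accessions=0,
            no_data_remained=True, logs=logs,
        )

    def fit(self, X: PhenotypeDataset, y=None) -> "CurationPipeline":
        ds = X
        raw_points = len(ds.df)
        raw_acc = len(ds.accessions)
        logs: list[FilterLog] = []
        self.campaign_scores_ = []
        self.point_flags_ = []

        rf = RangeFilter(trait=self.trait)
        ds = rf.fit(ds).transform(ds)
        logs.append(rf.log_)

        cf = ConnectivityFilter(self.min_years_per_accession,
                                self.min_points_per_year,
                                self.strict_plus_one)
        ds = cf.fit(ds).transform(ds)
        logs.append(cf.log_)

        if len(ds.df) == 0:
            self._finalize_empty(X, raw_points, raw_acc, logs)
            return self

        converged = True
        if self.campaign_stage:
            try:
                scores = campaign_cv_scores(ds)
            except IdentifiabilityError:
                self._finalize_empty(X, raw_points, raw_acc, logs)
                return self
            self.campaign_scores_ = scores
            ds, log = drop_outlier_campaigns(ds, scores, self.cv_threshold)
            logs.append(log)
            if len(ds.df) == 0:
                self._finalize_empty(X, raw_points, raw_acc, logs)
                return self

        blues = None
        if self.point_stage:
            try:
                fit_fixed = MixedModelREML(genotype_role="fixed").fit(ds)
            except IdentifiabilityError:
                self._finalize_empty(X, raw_points, raw_acc, logs)
                return self
            converged &= fit_fixed.converged_
            flags = flag_outlier_points(fit_fixed, self.alpha)
            self.point_flags_ = flags
            flagged_pos = [f.record for f in flags if f.flagged]
            df = ds.df
            removed = df.iloc[flagged_pos]
            reasons = removed[["accession_id", "year", "trait", "value"]].copy()
            reasons["reason"] = "POINT_HOLM"
            kept_mask = np.ones(len(df), dtype=bool)
            kept_mask[flagged_pos] = False
            kept_df = df.iloc[kept_mask]
            logs.append(FilterLog(
                rule="point_holm", records_in=len(df),
                records_removed=len(flagged_pos),
                accessions_removed=len(set(df["accession_id"].unique())
                                       - set(kept_df["accession_id"].unique())),
                years_removed=len(set(df["year"].unique())
                                  - set(kept_df["year"].unique())),
                reasons=reasons.reset_index(drop=True),
            ))
            ds = ds.with_records(kept_df)
            if len(ds.df) == 0:
                self._finalize_empty(X, raw_points, raw_acc, logs)
                return self

        # BLUEs from the fixed-genotype fit on fully curated data
        try:
            fit_blue = MixedModelREML(genotype_role="fixed").fit(ds)
            converged &= fit_blue.converged_
            blues = fit_blue.blues().reset_index()
        except IdentifiabilityError:
            blues = pd.DataFrame(columns=["accession_id", "blue", "se"])

        # variance components from the random-genotype fit on curated data
        h2 = None
        n_bar = ds.mean_years_per_accession()
        components = None
        try:
            fit_rand = MixedModelREML(genotype_role="random").fit(ds)
            converged &= fit_rand.converged_
            components = fit_rand.components_
            h2 = heritability(components, n_bar, self.error_variance_summary)
        except IdentifiabilityError:
            converged = False

        self.curated_ = ds
        self.blues_ = blues if blues is not None else pd.DataFrame(
            columns=["accession_id", "blue", "se"])
        self.logs_ = logs
        self.report_ = CurationReport(
            label=self.label, raw_points=raw_points, raw_accessions=raw_acc,
            kept_points=len(ds.df), kept_accessions=len(ds.accessions),
            heritability=h2, n_bar_years=n_bar, components=components,
            converged=converged, no_data_remained=False, logs=logs,
        )
        return self

    def _finalize_empty(self, X, raw_points, raw_acc, logs) -> None:
        self.curated_ = X.with_records(X.df.iloc[0:0])
        self.blues_ = pd.DataFrame(columns=["accession_id", "blue", "se"])
        self.logs_ = logs
        self.report_ = CurationReport(
            label=self.label, raw_points=raw_points, raw_accessions=raw_acc,
            kept_points=0, kept_accessions=0, no_data_remained=True, logs=logs,
        )


def run_pipeline(
    ds: PhenotypeDataset, config: PipelineConfig = PipelineConfig()
) -> tuple[PhenotypeDataset, pd.DataFrame, CurationReport]:
    """Curate one collection slice; returns (curated, BLUEs, report)."""
    pipe = CurationPipeline(
        trait=config.trait,
        min_years_per_accession=config.min_years_per_accession,
        min_points_per_year=config.min_points_per_year,
        strict_plus_one=config.strict_plus_one,
        cv_threshold=config.cv_threshold,
        alpha=config.alpha,
        campaign_stage=config.campaign_stage,
        point_stage=config.point_stage,
        error_variance_summary=config.error_variance_summary,
        label=config.label,
    ).fit(ds)
    return pipe.curated_, pipe.blues_, pipe.report_


def summarize_collections(reports: list[CurationReport]) -> pd.DataFrame:
    """One row per dataset, sorted by label; percentages to one decimal."""
    cols = ["dataset", "data_points", "accessions", "data_points_kept",
            "accessions_kept", "heritability", "mean_years_per_accession"]
    if not reports:
        return pd.DataFrame(columns=cols)
    rows = [r.to_row() for r in reports]
    return (pd.DataFrame(rows, columns=cols)
            .sort_values("dataset", kind="mergesort")
            .reset_index(drop=True))
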