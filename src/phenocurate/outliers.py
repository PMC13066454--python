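"""Two-stage outlier removal for regeneration campaigns.

Stage one scores whole campaigns: a mixed model with campaign fixed and
accession random (year-specific error variances) yields a per-campaign
residual standard deviation; its ratio to the absolute campaign mean is the
campaign's coefficient of variation, which is z-standardised across
campaigns, and campaigns exceeding a threshold (default 3.5) are dropped.

Stage two scores single records: a fixed-accession / random-campaign refit
provides standardized residuals, whose two-sided normal p-values are
Holm-adjusted; records with adjusted p below alpha (default 0.05) are
flagged for removal. The step-down adjustment keeps the familywise error of
the point stage at alpha despite thousands of simultaneous tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import FilterLog, PhenotypeDataset
from .reml import MixedModelREML

__all__ = [
    "CampaignScore",
    "PointFlag",
    "campaign_cv_scores",
    "drop_outlier_campaigns",
    "holm_adjust",
    "flag_outlier_points",
]


@dataclass(frozen=True)
class CampaignScore:
    """Quality score of one campaign year."""

    year: int
    mean: float
    sigma2_e: float
    cv: float
    cv_standardized: float


@dataclass(frozen=True)
class PointFlag:
    """Outlier assessment of one record (index into the fitted data)."""

    record: int
    standardized_residual: float
    p_value: float
    p_holm: float
    flagged: bool


def campaign_cv_scores(ds: PhenotypeDataset,
                       fit: MixedModelREML | None = None) -> list[CampaignScore]:
    """Score campaigns by their standardized coefficient of variation.

    Fits campaign-fixed / accession-random with heterogeneous errors (unless
    a compatible ``fit`` is supplied), computes CV_j = sigma_e,j / |mean_j|
    and standardises the CVs to z-scores across campaigns (sample SD).
    """
    if fit is None:
        fit = MixedModelREML(genotype_role="random", year_role="fixed").fit(ds)
    if fit.year_role != "fixed":
        raise ValueError("campaign CV requires a campaign-fixed fit")
    years = fit.year_effects_.index.to_numpy()
    means = fit.year_effects_.to_numpy(dtype=float)
    if np.any(means == 0):
        bad = years[means == 0]
        raise ZeroDivisionError(
            f"campaign mean is zero for year(s) {bad.tolist()}; CV undefined"
        )
    s2 = np.array([fit.sigma2_e_by_year_[int(y)] for y in years])
    cv = np.sqrt(s2) / np.abs(means)
    if len(cv) >= 2 and cv.std(ddof=1) > 0:
        z = (cv - cv.mean()) / cv.std(ddof=1)
    else:
        z = np.zeros_like(cv)
    return [
        CampaignScore(int(y), float(m), float(v), float(c), float(zz))
        for y, m, v, c, zz in zip(years, means, s2, cv, z)
    ]


def drop_outlier_campaigns(
    ds: PhenotypeDataset,
    scores: list[CampaignScore],
    threshold: float = 3.5,
) -> tuple[PhenotypeDataset, FilterLog]:
    """Remove all records of campaigns whose standardized CV exceeds threshold.

    One-sided: only unusually dispersed campaigns are removed; unusually
    uniform ones are not an error signal.
    """
    by_year = {s.year: s for s in scores}
    missing = set(int(y) for y in ds.years) - set(by_year)
    if missing:
        raise ValueError(f"scores missing for campaign(s) {sorted(missing)}")
    bad_years = {y for y, s in by_year.items() if s.cv_standardized > threshold}
    df = ds.df
    kept = ~df["year"].isin(bad_years)
    removed = df.loc[~kept]
    reasons = removed[["accession_id", "year", "trait", "value"]].copy()
    reasons["reason"] = "CAMPAIGN_CV"
    log = FilterLog(
        rule="campaign_cv",
        records_in=len(df),
        records_removed=int((~kept).sum()),
        accessions_removed=len(set(df["accession_id"].unique())
                              - set(df.loc[kept, "accession_id"].unique())),
        years_removed=len(bad_years),
        reasons=reasons.reset_index(drop=True),
    )
    return ds.with_records(df.loc[kept]), log


def holm_adjust(pvalues) -> np.ndarray:
    """Step-down Holm adjustment, returned in input order.

    Sorted ascending, p_(k) is multiplied by (m - k + 1), a running maximum
    enforces monotonicity and values are capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=0.05, method="holm")[1]


def flag_outlier_points(fit: MixedModelREML, alpha: float = 0.05,
                        robust_rescale: bool = True) -> list[PointFlag]:
    """Holm-flag records whose standardized residual is extreme under N(0,1).

    Requires the fixed-accession / random-campaign fit, whose residuals are
    free of genotype shrinkage. Flagged means adjusted p < alpha (strict).

    With ``robust_rescale`` (default) the standardized residuals are
    re-scaled by their median and MAD before computing p-values. The REML
    error variances are themselves inflated by any outliers present, which
    deflates the standardized residuals exactly when they matter; the
    median/MAD re-scaling restores a unit scale from the clean bulk of the
    residual distribution.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if fit.genotype_role != "fixed":
        raise ValueError("point flagging requires a fixed-genotype fit")
    z = np.asarray(fit.standardized_residuals_, dtype=float)
    if robust_rescale and len(z) >= 10:
        mad = stats.median_abs_deviation(z, scale="normal")
        if mad > 0:
            z = (z - np.median(z)) / mad
    p = 2.0 * stats.norm.sf(np.abs(z))
    padj = holm_adjust(p)
    flagged = padj < alpha
    return [
        PointFlag(int(i), float(zi), float(pi), float(ai), bool(fi))
        for i, (zi, pi, ai, fi) in enumerate(zip(z, p, padj, flagged))
    ]
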