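"""Simulator for non-orthogonal genebank regeneration phenotypes.

Emulates the structure of multi-decade regeneration records: a sparse
accession x campaign incidence in which most accessions are grown in only
one or two years, additive accession and year effects, year-specific
residual noise, and optional contamination by shifted single records
(point outliers) and whole campaigns with inflated residual variance
(campaign outliers). Every draw is recorded in a :class:`SyntheticTruth`
so that filter, model and outlier stages can be tested for recovery.

The model generating a record for accession *i* in year *j* is

    y_ij = mu + g_i + a_j + e_ij,
    g_i ~ N(0, sigma2_G),  a_j ~ N(0, sigma2_A),  e_ij ~ N(0, sigma_e[j]^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import TRAIT_PRESETS, PhenotypeDataset, TraitDefinition

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "sample_incidence",
    "simulate_dataset",
    "inject_outliers",
    "simulate",
]

#: right-skewed default for years-per-accession, mirroring the observation
#: that most accessions are regenerated only once or twice
DEFAULT_REPLICATION_PROFILE = (0.55, 0.25, 0.10, 0.05, 0.05)

#: per-trait generating parameters (mean, accession/year variance, base
#: residual SD), all comfortably inside the plausibility windows
_TRAIT_SCALE = {
    "HD": dict(mu=150.0, sigma2_G=20.0, sigma2_A=10.0, sigma_e=3.2),
    "PH": dict(mu=100.0, sigma2_G=100.0, sigma2_A=25.0, sigma_e=6.0),
    "TKW": dict(mu=40.0, sigma2_G=16.0, sigma2_A=4.0, sigma_e=2.0),
}


@dataclass(frozen=True)
class SimulationParams:
    """Generating parameters of one synthetic collection."""

    n_accessions: int = 2000
    n_years: int = 12
    replication_profile: Sequence[float] = DEFAULT_REPLICATION_PROFILE
    mu: float = 150.0
    sigma2_G: float = 20.0
    sigma2_A: float = 10.0
    sigma_e_by_year: Optional[Sequence[float]] = None
    sigma_e_base: float = 3.2
    sigma_e_jitter: tuple[float, float] = (0.8, 1.2)
    point_outlier_rate: float = 0.01
    point_outlier_shift: float = 8.0
    n_outlier_campaigns: int = 1
    campaign_outlier_inflation: float = 25.0
    trait: TraitDefinition = field(default_factory=lambda: TRAIT_PRESETS["HD"])
    first_year: int = 1990
    genebank: str = "SYN001"
    genus: str = "Triticum"
    seasonal_type: str = "winter"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 1 or self.n_years < 1:
            raise ValueError("n_accessions and n_years must be positive")
        prof = np.asarray(self.replication_profile, dtype=float)
        if prof.ndim != 1 or np.any(prof < 0) or not np.isclose(prof.sum(), 1.0):
            raise ValueError("replication_profile must be a probability vector")
        if min(self.sigma2_G, self.sigma2_A) < 0:
            raise ValueError("variances must be non-negative")
        if not 0 <= self.point_outlier_rate <= 1:
            raise ValueError("point_outlier_rate must be in [0, 1]")
        if self.campaign_outlier_inflation < 0:
            raise ValueError("campaign_outlier_inflation must be non-negative")

    @classmethod
    def for_trait(cls, code: str, **overrides) -> "SimulationParams":
        """Preset parameters on the scale of HD (days), PH (cm) or TKW (g)."""
        scale = _TRAIT_SCALE[code]
        kw = dict(
            mu=scale["mu"], sigma2_G=scale["sigma2_G"],
            sigma2_A=scale["sigma2_A"], sigma_e_base=scale["sigma_e"],
            trait=TRAIT_PRESETS[code],
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset.

    ``signal`` stores mu + g_i + a_j per record so that campaign outliers
    can be injected by redrawing only the noise. Outlier labels always
    refer to rows of the emitted record table, in order.
    """

    mu: float
    sigma2_G: float
    sigma2_A: float
    sigma_e_by_year: dict[int, float]
    g: pd.Series
    a: pd.Series
    signal: np.ndarray
    point_outliers: np.ndarray   # boolean per record
    campaign_outliers: list[int]  # years
    n_bar: float

    def true_heritability(self, n_bar: float | None = None,
                          years: Sequence[int] | None = None) -> float:
        """Entry-mean heritability from the generating parameters.

        ``sigma2_e`` is the unweighted mean of the per-year error variances
        (over ``years`` if given), matching the pipeline's convention;
        ``n_bar`` defaults to the realized mean years per accession.
        """
        if n_bar is None:
            n_bar = self.n_bar
        sd = self.sigma_e_by_year
        if years is not None:
            sd = {y: sd[y] for y in years}
        s2e = float(np.mean([v**2 for v in sd.values()]))
        denom = self.sigma2_G + s2e / n_bar
        return self.sigma2_G / denom if denom > 0 else 0.0


def _rng(params: SimulationParams, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([params.seed, stream]))


def sample_incidence(params: SimulationParams) -> np.ndarray:
    """Draw the accession x year incidence as an array of (i, j) index pairs.

    Each accession's number of distinct years comes from the replication
    profile (truncated and renormalised if it names more years than exist),
    and its years are sampled without replacement; one record per pair.
    """
    if params.n_years < 2:
        raise ValueError("need at least 2 years to sample an incidence")
    prof = np.asarray(params.replication_profile, dtype=float)
    if len(prof) > params.n_years:
        warnings.warn(
            "replication profile longer than n_years; truncating and renormalising",
            stacklevel=2,
        )
        prof = prof[: params.n_years]
        prof = prof / prof.sum()
    rng = _rng(params, 0)
    counts = rng.choice(np.arange(1, len(prof) + 1), size=params.n_accessions, p=prof)
    pairs = np.empty((int(counts.sum()), 2), dtype=np.int64)
    pos = 0
    for i, k in enumerate(counts):
        yrs = rng.choice(params.n_years, size=k, replace=False)
        pairs[pos:pos + k, 0] = i
        pairs[pos:pos + k, 1] = np.sort(yrs)
        pos += k
    return pairs


def simulate_dataset(params: SimulationParams) -> tuple[PhenotypeDataset, SyntheticTruth]:
    """Generate a clean dataset (no contamination) plus its ground truth."""
    pairs = sample_incidence(params)
    i_idx, j_idx = pairs[:, 0], pairs[:, 1]
    rng = _rng(params, 1)

    if params.sigma_e_by_year is not None:
        sd = np.asarray(params.sigma_e_by_year, dtype=float)
        if len(sd) != params.n_years:
            raise ValueError("sigma_e_by_year must have one entry per year")
    else:
        lo, hi = params.sigma_e_jitter
        sd = params.sigma_e_base * rng.uniform(lo, hi, size=params.n_years)
    if np.any(sd < 0):
        raise ValueError("residual SDs must be non-negative")

    g = rng.normal(0.0, np.sqrt(params.sigma2_G), size=params.n_accessions)
    a = rng.normal(0.0, np.sqrt(params.sigma2_A), size=params.n_years)
    e = rng.normal(0.0, sd[j_idx])
    signal = params.mu + g[i_idx] + a[j_idx]
    values = signal + e

    years = params.first_year + np.arange(params.n_years)
    acc_numbers = np.array([f"ACC{i:06d}" for i in range(params.n_accessions)])
    df = pd.DataFrame(
        {
            "institute_code": params.genebank,
            "genus": params.genus,
            "accession_number": acc_numbers[i_idx],
            "year": years[j_idx],
            "location": "synthetic site",
            "seasonal_type": params.seasonal_type,
            "trait": params.trait.code,
            "value": values,
        }
    )
    ds = PhenotypeDataset(
        df, traits={params.trait.code: params.trait}, provenance="synthetic"
    )
    acc_ids = np.array([f"{params.genebank}:{params.genus}:{n}" for n in acc_numbers])
    truth = SyntheticTruth(
        mu=params.mu,
        sigma2_G=params.sigma2_G,
        sigma2_A=params.sigma2_A,
        sigma_e_by_year={int(y): float(s) for y, s in zip(years, sd)},
        g=pd.Series(g, index=pd.Index(acc_ids, name="accession_id")),
        a=pd.Series(a, index=pd.Index(years, name="year")),
        signal=signal,
        point_outliers=np.zeros(len(df), dtype=bool),
        campaign_outliers=[],
        n_bar=ds.mean_years_per_accession(),
    )
    return ds, truth


def inject_outliers(
    ds: PhenotypeDataset, truth: SyntheticTruth, params: SimulationParams
) -> tuple[PhenotypeDataset, SyntheticTruth]:
    """Contaminate a simulated dataset with labelled outliers.

    Campaign outliers: ``n_outlier_campaigns`` years get their residuals
    redrawn with variance multiplied by ``campaign_outlier_inflation``.
    Point outliers: round(rate * n) records outside those campaigns are
    shifted by +/- ``point_outlier_shift`` x sigma_e of their year (fair
    coin for the sign). Labels are recorded in the returned truth.
    """
    if params.n_outlier_campaigns > len(ds.years):
        raise ValueError(
            f"requested {params.n_outlier_campaigns} outlier campaigns but "
            f"dataset has {len(ds.years)} years"
        )
    rng = _rng(params, 2)
    df = ds.df.copy()
    values = df["value"].to_numpy(dtype=float).copy()
    year_col = df["year"].to_numpy()
    sd_year = np.array([truth.sigma_e_by_year[int(y)] for y in year_col])

    bad_years: list[int] = []
    if params.n_outlier_campaigns > 0 and params.campaign_outlier_inflation != 1.0:
        bad_years = sorted(
            int(y) for y in rng.choice(ds.years, size=params.n_outlier_campaigns,
                                       replace=False)
        )
        in_bad = np.isin(year_col, bad_years)
        infl_sd = sd_year[in_bad] * np.sqrt(params.campaign_outlier_inflation)
        values[in_bad] = truth.signal[in_bad] + rng.normal(0.0, infl_sd)

    point_mask = np.zeros(len(df), dtype=bool)
    n_points = int(round(params.point_outlier_rate * len(df)))
    if n_points > 0:
        eligible = np.where(~np.isin(year_col, bad_years))[0]
        chosen = rng.choice(eligible, size=min(n_points, len(eligible)),
                            replace=False)
        signs = rng.choice([-1.0, 1.0], size=len(chosen))
        values[chosen] = values[chosen] + signs * params.point_outlier_shift * sd_year[chosen]
        point_mask[chosen] = True

    df["value"] = values
    out = ds.with_records(df)
    new_truth = replace(
        truth,
        point_outliers=point_mask,
        campaign_outliers=bad_years,
        signal=truth.signal.copy(),
    )
    return out, new_truth


def simulate(params: SimulationParams) -> tuple[PhenotypeDataset, SyntheticTruth]:
    """Clean simulation followed by contamination, as configured in params."""
    ds, truth = simulate_dataset(params)
    return inject_outliers(ds, truth, params)
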