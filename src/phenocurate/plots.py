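"""Diagnostic figures for curated collections."""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .datatypes import PhenotypeDataset
from .pipeline import CurationReport

__all__ = ["plot_reports"]


def plot_reports(reports: list[CurationReport],
                 curated: list[PhenotypeDataset],
                 out_dir) -> list[Path]:
    """Write incidence, heritability and BLUE/value distribution panels.

    Returns the figure paths. Empty curated datasets are skipped from the
    distribution panel with a warning.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # years-per-accession histogram across all curated datasets
    fig, ax = plt.subplots(figsize=(6, 4))
    counts = []
    for ds in curated:
        if len(ds.df):
            counts.append(ds.years_per_accession().to_numpy())
    if counts:
        allc = np.concatenate(counts)
        bins = np.arange(0.5, allc.max() + 1.5)
        ax.hist(allc, bins=bins, color="#4878d0", edgecolor="white")
    ax.set_xlabel("years with data per accession")
    ax.set_ylabel("accessions")
    ax.set_title("Regeneration incidence")
    f = out / "years_per_accession.png"
    fig.tight_layout(); fig.savefig(f, dpi=120); plt.close(fig)
    written.append(f)

    # heritability bars
    fig, ax = plt.subplots(figsize=(6, 4))
    labs = [r.label or f"dataset {k}" for k, r in enumerate(reports)]
    vals = [np.nan if r.heritability is None else 100 * r.heritability
            for r in reports]
    ax.bar(range(len(vals)), vals, color="#ee854a")
    ax.set_xticks(range(len(labs)))
    ax.set_xticklabels(labs, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("heritability (%)")
    ax.set_ylim(0, 100)
    f = out / "heritability.png"
    fig.tight_layout(); fig.savefig(f, dpi=120); plt.close(fig)
    written.append(f)

    # curated value distributions per trait
    traits = sorted({t for ds in curated for t in ds.df["trait"].unique()})
    nonempty = [ds for ds in curated if len(ds.df)]
    if not nonempty:
        warnings.warn("all curated datasets are empty; no distribution panel")
        return written
    fig, axes = plt.subplots(1, max(len(traits), 1),
                             figsize=(4 * max(len(traits), 1), 4), squeeze=False)
    for k, tr in enumerate(traits):
        ax = axes[0][k]
        for ds in nonempty:
            v = ds.df.loc[ds.df["trait"] == tr, "value"]
            if len(v):
                ax.hist(v, bins=30, alpha=0.5)
        unit = ""
        for ds in nonempty:
            if tr in ds.traits:
                unit = ds.traits[tr].unit
                break
        ax.set_xlabel(f"{tr} ({unit})" if unit else tr)
        ax.set_ylabel("records")
    f = out / "trait_distributions.png"
    fig.tight_layout(); fig.savefig(f, dpi=120); plt.close(fig)
    written.append(f)
    return written
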