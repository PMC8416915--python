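"""Packaged reference datasets: the bok choy G×E trial summaries.

Two small CSVs ship with the package so the variance-partition analysis runs
offline:

``bokchoy_gxe_cells.csv``
    Per-cell anthocyanin summaries (mean ± SD, n = 4 replicate means of five
    plants each) for four bok choy cultivars under four treatments —
    non-stimulation vs stimulation growing conditions (NC/SC) crossed with
    growth stages at 2 and 4 weeks (GS1/GS2) — measured destructively
    (wet chemistry, mg/g DW), by hyperspectral imaging (mg/g DW), and as the
    purple-area percentage from RGB photographs.  The cultivar sold as
    "purple magic" is tabulated under its synonym "Purple Stem".

``bokchoy_gxe_partition.csv``
    The published percentage partition of that trial's anthocyanin variation
    into genotype / environment / G×E / residual, per measurement channel,
    with its significance stars.

The published partition was computed from raw per-plant data that were not
released; reconstruction from the cell summaries therefore recovers the
genotype : environment : G×E proportions but understates the residual (the
replicate-mean SDs hide the within-replicate plant-to-plant variance).  See
:func:`reconstruct_partition` and docs/methods.md.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .gxe import AnovaPartition, anova_from_summaries

__all__ = [
    "load_gxe_cells",
    "load_gxe_summaries",
    "load_published_partition",
    "reconstruct_partition",
]

CHANNELS = ("destructive", "hyperspectral", "rgb_pct")


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("anthoscan.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_gxe_cells() -> pd.DataFrame:
    """The per-cell trial summaries for all three measurement channels."""
    return _read_packaged("bokchoy_gxe_cells.csv")


def load_gxe_summaries(channel: str = "destructive") -> pd.DataFrame:
    """One channel's summaries in genotype/treatment/mean/sd/n layout."""
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; one of {CHANNELS}")
    cells = load_gxe_cells()
    return cells.rename(
        columns={f"{channel}_mean": "mean", f"{channel}_sd": "sd"}
    )[["genotype", "treatment", "mean", "sd", "n"]]


def load_published_partition() -> pd.DataFrame:
    """The published percentage partition (with significance stars)."""
    return _read_packaged("bokchoy_gxe_partition.csv")


def reconstruct_partition(channel: str = "destructive") -> AnovaPartition:
    """Reconstruct the published G×E partition from the cell summaries.

    Uses the multi-environment-trial conventions the published table is
    consistent with: percentages on the variance-component basis, and main
    effects F-tested against the G×E mean square (which is what renders the
    environment effect non-significant despite the tiny within-cell error).
    """
    return anova_from_summaries(
        load_gxe_summaries(channel),
        percent_of="variance_components",
        test_against="interaction",
    )
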