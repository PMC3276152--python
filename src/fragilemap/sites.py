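"""Calling significant break/ssDNA sites and peaks from a smoothed profile.

Two rules are provided.  The counting rule used for association testing
is *above-median*: a probe is a significant site when its smoothed ratio
is strictly greater than the genome-wide median of the profile's
smoothed values.  The display/validation rule is *local-peak*: local
maxima of the smoothed profile per chromosome with a minimum prominence,
used to check recovery of planted cut sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .profiles import RatioProfile

__all__ = ["SiteSet", "call_significant_sites", "call_peaks", "merge_nearby"]

logger = logging.getLogger(__name__)


@dataclass
class SiteSet:
    """Called sites at probe resolution.

    ``sites`` columns: chrom, midpoint, smoothed_ratio; sorted by
    (chrom, midpoint) with no duplicate coordinates.  ``threshold`` and
    ``rule`` record how the sites were selected.
    """

    sites: pd.DataFrame
    threshold: float
    rule: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.rule not in ("above_median", "local_peak"):
            raise ValueError(f"unknown site rule {self.rule!r}")

    def __len__(self) -> int:
        return len(self.sites)


def _require_smoothed(profile: RatioProfile) -> pd.DataFrame:
    if not profile.smoothed:
        raise ValueError("profile must be smoothed before site calling")
    return profile.data.sort_values(
        ["chrom", "midpoint"], kind="stable", ignore_index=True
    )


def call_significant_sites(profile: RatioProfile) -> SiteSet:
    """Probes whose smoothed ratio exceeds the genome-wide median.

    The threshold is the median over all chromosomes of this profile (so
    site calls are invariant to uniform rescaling of the data); the
    comparison is strict, hence a constant profile yields no sites.
    """
    d = _require_smoothed(profile)
    threshold = float(np.median(d["smoothed_ratio"].to_numpy()))
    keep = d["smoothed_ratio"] > threshold
    sites = d.loc[keep, ["chrom", "midpoint", "smoothed_ratio"]].reset_index(drop=True)
    if sites.empty:
        logger.warning("no sites above the median (constant profile?)")
    return SiteSet(sites, threshold=threshold, rule="above_median",
                   source=profile.sample_id)


def call_peaks(profile: RatioProfile, min_prominence: float | None = None) -> SiteSet:
    """Local maxima of the smoothed profile per chromosome.

    ``min_prominence`` defaults to half the interquartile range of the
    smoothed values, a scale-free choice that ignores baseline wiggle but
    keeps well-separated enrichment peaks.
    """
    d = _require_smoothed(profile)
    vals = d["smoothed_ratio"].to_numpy()
    if min_prominence is None:
        q1, q3 = np.percentile(vals, [25, 75])
        # floor at a relative epsilon so float jitter on flat stretches
        # never counts as a peak
        min_prominence = max(0.5 * (q3 - q1), 1e-6 * float(np.abs(vals).max()))
    rows = []
    for _, grp in d.groupby("chrom", sort=False):
        y = grp["smoothed_ratio"].to_numpy()
        idx, _ = find_peaks(y, prominence=min_prominence)
        rows.append(grp.iloc[idx][["chrom", "midpoint", "smoothed_ratio"]])
    sites = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "midpoint", "smoothed_ratio"]
    )
    return SiteSet(sites, threshold=float(min_prominence), rule="local_peak",
                   source=profile.sample_id)


def merge_nearby(site_set: SiteSet, within_bp: float) -> SiteSet:
    """Collapse runs of sites closer than *within_bp* into single sites.

    Each merged run is represented by its highest-ratio member.  Off by
    default in the pipeline: the analysis counts sites at probe
    resolution.
    """
    merged_rows = []
    for _, grp in site_set.sites.groupby("chrom", sort=False):
        grp = grp.sort_values("midpoint", ignore_index=True)
        gap = grp["midpoint"].diff().fillna(np.inf)
        cluster = (gap > within_bp).cumsum()
        for _, run in grp.groupby(cluster):
            merged_rows.append(run.loc[run["smoothed_ratio"].idxmax()])
    sites = (
        pd.DataFrame(merged_rows).reset_index(drop=True)
        if merged_rows
        else site_set.sites.iloc[:0]
    )
    return SiteSet(sites, threshold=site_set.threshold, rule=site_set.rule,
                   source=site_set.source)
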