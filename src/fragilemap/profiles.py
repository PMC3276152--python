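"""Ratio profiles: normalization, fixed-window Lowess smoothing, correlation.

A :class:`RatioProfile` is the per-probe experimental/control ratio along
chromosome coordinates.  QC-flagged spots are removed first; each
channel's background-subtracted intensities are normalized to sum to one
genome-wide; the ratio of the normalized channels is then smoothed per
chromosome with locally weighted linear regression (Lowess, degree 1,
tricube weights, no robustness iterations) over a fixed genomic window —
6 kb by default, meaning all probes within +/- 3 kb of the target probe's
midpoint.  Smoothing never crosses chromosome boundaries.

The window is defined in base pairs rather than as a fraction of probe
count so that the effective resolution is constant along the genome and
matches the 6 kb proximity cutoff used by the association tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .synthetic import ArraySample

__all__ = ["RatioProfile", "compute_ratios", "lowess_smooth", "profile_correlation"]

logger = logging.getLogger(__name__)


@dataclass
class RatioProfile:
    """Per-probe normalized ratios, raw and (optionally) smoothed.

    ``data`` columns: probe_id, chrom, start, end, midpoint, raw_ratio and,
    after smoothing, smoothed_ratio.  ``normalization`` records the channel
    totals used and the probes dropped on the way.
    """

    data: pd.DataFrame
    window_bp: int | None = None
    normalization: dict = field(default_factory=dict)
    sample_id: str = ""

    @property
    def smoothed(self) -> bool:
        return "smoothed_ratio" in self.data.columns

    def values(self, which: str = "auto") -> pd.Series:
        """Profile values: ``smoothed_ratio`` if present else ``raw_ratio``."""
        if which == "auto":
            which = "smoothed_ratio" if self.smoothed else "raw_ratio"
        return self.data[which]


def compute_ratios(sample: ArraySample, sample_id: str = "") -> RatioProfile:
    """Background-subtract, normalize per channel, and form per-probe ratios.

    Flagged probes are removed.  Per remaining probe, ``net = signal - bg``
    in each channel; each channel is divided by its genome-wide total so
    both normalized channels sum to one exactly; the raw ratio is the
    normalized experimental over normalized control value.  Probes with
    non-positive control net signal cannot yield a ratio and are dropped
    with a logged count (never imputed).
    """
    d = sample.data
    flagged = d["flagged"].astype(bool)
    n_flagged = int(flagged.sum())
    d = d.loc[~flagged].copy()
    if d.empty:
        raise ValueError("no unflagged probes in sample")
    net_exp = d["exp_signal"] - d["exp_bg"]
    net_ctl = d["ctl_signal"] - d["ctl_bg"]
    bad = net_ctl <= 0
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.info("dropping %d probes with non-positive control signal", n_dropped)
    d, net_exp, net_ctl = d.loc[~bad], net_exp[~bad], net_ctl[~bad]
    if d.empty:
        raise ValueError("all probes dropped (non-positive control signal)")
    exp_total = float(net_exp.sum())
    ctl_total = float(net_ctl.sum())
    if exp_total <= 0:
        raise ValueError("experimental channel total is non-positive")
    raw = (net_exp / exp_total) / (net_ctl / ctl_total)
    out = pd.DataFrame(
        {
            "probe_id": d["probe_id"].to_numpy(),
            "chrom": d["chrom"].to_numpy(),
            "start": d["start"].to_numpy(),
            "end": d["end"].to_numpy(),
            "midpoint": ((d["start"] + d["end"]) / 2.0).to_numpy(),
            "raw_ratio": raw.to_numpy(),
        }
    )
    out = out.sort_values(["chrom", "midpoint"], kind="stable", ignore_index=True)
    norm = {
        "exp_total": exp_total,
        "ctl_total": ctl_total,
        "n_flagged_removed": n_flagged,
        "n_nonpositive_dropped": n_dropped,
    }
    return RatioProfile(out, normalization=norm, sample_id=sample_id)


def _lowess_fixed_window(x: np.ndarray, y: np.ndarray, half: float) -> np.ndarray:
    """Local linear regression at each x[i] over points within +/- half,
    tricube weights on genomic distance; x must be sorted ascending."""
    n = len(x)
    out = np.empty(n)
    lo = np.searchsorted(x, x - half, side="left")
    hi = np.searchsorted(x, x + half, side="right")
    for i in range(n):
        a, b = lo[i], hi[i]
        if b - a == 1:
            out[i] = y[i]
            continue
        dx = x[a:b] - x[i]
        u = np.abs(dx) / half
        w = (1.0 - u**3) ** 3
        np.maximum(w, 0.0, out=w)
        sw = w.sum()
        if sw <= 0:  # only boundary probes in the window
            out[i] = y[i]
            continue
        yy = y[a:b]
        swx = w @ dx
        swy = w @ yy
        swxx = w @ (dx * dx)
        swxy = w @ (dx * yy)
        denom = sw * swxx - swx * swx
        # fall back to a weighted mean when the design is degenerate
        if denom <= 1e-12 * max(sw * swxx, 1e-300):
            out[i] = swy / sw
        else:
            out[i] = (swxx * swy - swx * swxy) / denom
    return out


def lowess_smooth(profile: RatioProfile, window_bp: int = 6000) -> RatioProfile:
    """Smooth the raw ratios chromosome by chromosome.

    Each probe's smoothed value is the intercept of a tricube-weighted
    linear fit over probes within ``window_bp / 2`` of its midpoint on the
    same chromosome.  A probe alone in its window keeps its raw value
    (with a logged warning).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    d = profile.data.sort_values(["chrom", "midpoint"], kind="stable", ignore_index=True)
    half = window_bp / 2.0
    smoothed = np.empty(len(d))
    n_single = 0
    for _, grp in d.groupby("chrom", sort=False):
        x = grp["midpoint"].to_numpy(dtype=float)
        y = grp["raw_ratio"].to_numpy(dtype=float)
        lo = np.searchsorted(x, x - half, side="left")
        hi = np.searchsorted(x, x + half, side="right")
        n_single += int(np.sum(hi - lo == 1))
        smoothed[grp.index] = _lowess_fixed_window(x, y, half)
    if n_single:
        logger.warning(
            "%d probes had a single-probe smoothing window; raw values kept",
            n_single,
        )
    d = d.copy()
    d["smoothed_ratio"] = smoothed
    return RatioProfile(
        d,
        window_bp=window_bp,
        normalization=dict(profile.normalization),
        sample_id=profile.sample_id,
    )


def profile_correlation(
    a: RatioProfile,
    b: RatioProfile,
    method: Literal["pearson", "spearman"] = "pearson",
) -> float:
    """Correlation of two smoothed profiles over their shared probes.

    Profiles are intersected on probe id (QC filtering may have removed
    different probes from each); the coefficient is computed over the
    shared probes' smoothed values.
    """
    col_a = "smoothed_ratio" if a.smoothed else "raw_ratio"
    col_b = "smoothed_ratio" if b.smoothed else "raw_ratio"
    merged = a.data[["probe_id", col_a]].merge(
        b.data[["probe_id", col_b]], on="probe_id", suffixes=("_a", "_b")
    )
    if merged.empty:
        raise ValueError("profiles share no probes")
    va = merged.iloc[:, 1].to_numpy(dtype=float)
    vb = merged.iloc[:, 2].to_numpy(dtype=float)
    for v in (va, vb):
        if np.std(v) <= 1e-12 * max(1.0, abs(float(np.mean(v)))):
            raise ValueError("correlation undefined: a profile has zero variance")
    if method == "pearson":
        return float(np.corrcoef(va, vb)[0, 1])
    if method == "spearman":
        from scipy.stats import spearmanr

        return float(spearmanr(va, vb).statistic)
    raise ValueError(f"unknown correlation method {method!r}")
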