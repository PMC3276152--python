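"""Synthetic two-channel microarray data with planted enrichment structure.

The generator emulates the measurement layer of a two-color genomic
hybridization: a probe grid tiling the genome at array-like density, a
control channel of constant expected intensity, an experimental channel
whose expectation is a flat baseline plus localized enrichment peaks
(origin-proximal ssDNA/breakage signal or restriction-cut end-label
signal), independent multiplicative log-normal noise per channel, a
constant additive background, and a random subset of QC-flagged spots.

The noise model: each channel's signal is its expectation times
``exp(N(-sigma^2/2, sigma^2))`` with ``sigma^2 = ln(1 + cv^2)``, i.e. a
mean-one log-normal with coefficient of variation ``noise_cv``.  This is
the standard assumption for fluorescence intensities and makes the
log-ratio analytically checkable: with no peaks it is Normal with mean 0
and variance ``2 sigma^2``.

Everything is bit-reproducible given an explicit integer seed; there is
no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeLayout, PROBE_COLUMNS, probe_midpoints

__all__ = [
    "Peak",
    "SyntheticTruth",
    "ArraySample",
    "make_probe_grid",
    "simulate_sample",
    "simulate_cut_sites",
    "mini_genome",
    "yeast_like_layout",
]

PEAK_SHAPES = ("gaussian", "point")


@dataclass(frozen=True)
class Peak:
    """One planted enrichment peak.

    ``amplitude`` is fold-enrichment over baseline at the peak center
    (the expected ratio there is ``1 + amplitude``); ``width`` is the
    Gaussian sigma in bp.  Shape ``point`` loads the whole amplitude onto
    the single nearest probe instead.
    """

    chrom: str
    center: float
    amplitude: float
    width: float = 1000.0
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.shape not in PEAK_SHAPES:
            raise ValueError(f"unknown peak shape {self.shape!r}")
        if self.amplitude < 0:
            raise ValueError("peak amplitude must be non-negative")
        if self.shape == "gaussian" and self.width <= 0:
            raise ValueError("gaussian peak needs width > 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for a simulated sample: planted peaks and baseline."""

    peaks: tuple[Peak, ...] = ()
    baseline_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_ratio <= 0:
            raise ValueError("baseline_ratio must be positive")

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "baseline_ratio": self.baseline_ratio,
            "peaks": [
                {
                    "chrom": p.chrom,
                    "center": p.center,
                    "amplitude": p.amplitude,
                    "width": p.width,
                    "shape": p.shape,
                }
                for p in self.peaks
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        peaks = tuple(Peak(**p) for p in doc.get("peaks", []))
        return cls(peaks=peaks, baseline_ratio=doc.get("baseline_ratio", 1.0))


#: Measurement columns of an ArraySample table, in file order.
SAMPLE_COLUMNS = (
    "probe_id",
    "chrom",
    "start",
    "end",
    "flagged",
    "exp_signal",
    "exp_bg",
    "ctl_signal",
    "ctl_bg",
)


@dataclass
class ArraySample:
    """Per-probe two-channel signal/background measurements.

    ``data`` has one row per probe in probe-universe order with columns
    :data:`SAMPLE_COLUMNS`.  For unflagged probes signal >= background.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        unflagged = self.data.loc[~self.data["flagged"].astype(bool)]
        for sig, bg in (("exp_signal", "exp_bg"), ("ctl_signal", "ctl_bg")):
            if (unflagged[bg] < 0).any() or (unflagged[sig] < unflagged[bg]).any():
                raise ValueError(
                    f"unflagged probes must satisfy {sig} >= {bg} >= 0"
                )

    def __len__(self) -> int:
        return len(self.data)


def make_probe_grid(
    layout: GenomeLayout,
    spacing: int = 290,
    probe_length: int = 60,
    seed: int = 0,
    flag_fraction: float = 0.01,
) -> pd.DataFrame:
    """Tile each chromosome with probes of *probe_length* every *spacing* bp.

    Probe i on a chromosome occupies ``[i*spacing, i*spacing + probe_length)``;
    a chromosome of length L carries ``floor(L / spacing)`` probes.  A random
    *flag_fraction* subset of probes is marked QC-flagged.  The default
    spacing emulates a ~44k-probe array on a ~12 Mb genome.
    """
    if not (0 < probe_length <= spacing):
        raise ValueError("need 0 < probe_length <= spacing")
    if not (0 <= flag_fraction < 1):
        raise ValueError("flag_fraction must be in [0, 1)")
    smallest = min(length for _, length in layout.chromosomes)
    if spacing > smallest:
        raise ValueError(
            f"spacing {spacing} exceeds the smallest chromosome ({smallest} bp)"
        )
    frames = []
    for name, length in layout.chromosomes:
        n = length // spacing
        starts = np.arange(n, dtype=np.int64) * spacing
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": [f"{name}:{s}" for s in starts],
                    "chrom": name,
                    "start": starts,
                    "end": starts + probe_length,
                    "flagged": False,
                }
            )
        )
    probes = pd.concat(frames, ignore_index=True)
    rng = np.random.default_rng(seed)
    n_flag = int(round(flag_fraction * len(probes)))
    if n_flag:
        idx = rng.choice(len(probes), size=n_flag, replace=False)
        probes.loc[probes.index[idx], "flagged"] = True
    return probes[list(PROBE_COLUMNS)]


def _expected_ratio(probes: pd.DataFrame, truth: SyntheticTruth) -> np.ndarray:
    """Expected exp/ctl enrichment per probe: baseline * (1 + sum of peaks)."""
    mid = probe_midpoints(probes).to_numpy(dtype=float)
    chroms = probes["chrom"].to_numpy()
    enrich = np.zeros(len(probes))
    for peak in truth.peaks:
        on = chroms == peak.chrom
        if not on.any():
            continue
        if peak.shape == "gaussian":
            d = mid[on] - peak.center
            enrich[on] += peak.amplitude * np.exp(-(d * d) / (2.0 * peak.width**2))
        else:  # point: the single nearest probe on the chromosome
            j = np.flatnonzero(on)[np.argmin(np.abs(mid[on] - peak.center))]
            enrich[j] += peak.amplitude
    return truth.baseline_ratio * (1.0 + enrich)


def _lognormal_factor(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log1p(cv * cv)
    return np.exp(rng.normal(-sigma2 / 2.0, math.sqrt(sigma2), size=n))


def simulate_sample(
    probes: pd.DataFrame,
    truth: SyntheticTruth,
    noise_cv: float = 0.1,
    background_level: float = 50.0,
    seed: int = 0,
    ctl_level: float = 1000.0,
) -> ArraySample:
    """Simulate one two-channel hybridization over the probe grid.

    The control channel's expected net intensity is ``ctl_level`` at every
    probe; the experimental channel's is ``ctl_level`` times the expected
    enrichment from *truth*.  Both channels get independent mean-one
    log-normal noise with coefficient of variation *noise_cv*, then a
    constant *background_level* is added to signal and reported as the
    per-probe background.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    n = len(probes)
    exp_net = ctl_level * _expected_ratio(probes, truth) * _lognormal_factor(rng, n, noise_cv)
    ctl_net = ctl_level * _lognormal_factor(rng, n, noise_cv)
    data = probes[list(PROBE_COLUMNS)].copy()
    data["exp_signal"] = exp_net + background_level
    data["exp_bg"] = float(background_level)
    data["ctl_signal"] = ctl_net + background_level
    data["ctl_bg"] = float(background_level)
    return ArraySample(data)


def simulate_cut_sites(
    probes: pd.DataFrame,
    sites: pd.DataFrame,
    amplitude: float = 6.0,
    width: float = 1000.0,
    noise_cv: float = 0.1,
    seed: int = 0,
    background_level: float = 50.0,
) -> ArraySample:
    """Positive-control sample: Gaussian end-label peaks at known cut sites.

    *sites* is a feature table (``chrom``/``midpoint`` columns) of
    category ``cut_site``; an empty table yields a flat sample.  Emulates
    mapping of restriction or HO-endonuclease cleavage products.
    """
    peaks = tuple(
        Peak(chrom=row.chrom, center=row.midpoint, amplitude=amplitude, width=width)
        for row in sites.itertuples(index=False)
    )
    truth = SyntheticTruth(peaks=peaks, baseline_ratio=1.0)
    return simulate_sample(
        probes, truth, noise_cv=noise_cv, background_level=background_level, seed=seed
    )


def mini_genome(
    n_chrom: int = 2, chrom_length: int = 200_000, spacing: int = 500, seed: int = 0,
    flag_fraction: float = 0.01,
) -> tuple[GenomeLayout, pd.DataFrame]:
    """Small test genome: *n_chrom* chromosomes of *chrom_length* bp with a
    probe grid, sized for sub-second pipeline runs."""
    layout = GenomeLayout(
        tuple((f"chr{i + 1}", chrom_length) for i in range(n_chrom))
    )
    probes = make_probe_grid(
        layout, spacing=spacing, probe_length=min(60, spacing), seed=seed,
        flag_fraction=flag_fraction,
    )
    return layout, probes


def yeast_like_layout() -> GenomeLayout:
    """The 16-chromosome budding-yeast layout for full-scale emulation."""
    from .genome import BUDDING_YEAST_CHROM_SIZES

    return GenomeLayout(tuple(BUDDING_YEAST_CHROM_SIZES.items()))
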