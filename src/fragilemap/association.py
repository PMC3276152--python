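"""Break-site / feature association statistics.

Distances between break sites and chromosomal features are measured
midpoint to midpoint; features on other chromosomes are infinitely far.
The association statistic is the number of sites whose nearest feature
of a category lies within a cutoff (6 kb by default, matching the
smoothing window, with an inclusive boundary).  Its significance comes
from a randomization test: break sites are re-drawn uniformly without
replacement from the unflagged probe positions of the microarray, the
within-cutoff count is recomputed for each of ``n_sims`` draws (10,000
by default), and the p-value is the upper-tail fraction of null counts
greater than or equal to the observed count — reported as the plain
proportion ``k / n_sims``, so a completely saturated test prints exactly
``P = 1``.

For small universes an exhaustive enumeration of all site placements
gives the exact null distribution and serves as an oracle for the Monte
Carlo path.  A continuity-corrected two-sample proportion test (Pearson
chi-square on the 2x2 table with Yates correction) is also provided for
comparing within-cutoff fractions between two feature categories.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .sites import SiteSet

__all__ = [
    "AssociationResult",
    "ProportionTestResult",
    "nearest_feature_distance",
    "nearest_feature_distances",
    "count_within",
    "proportion_test",
    "random_simulation_test",
    "exhaustive_null",
]


def _sites_frame(sites) -> pd.DataFrame:
    if isinstance(sites, SiteSet):
        return sites.sites
    return sites


@dataclass
class AssociationResult:
    """Outcome of the randomization test for one feature category."""

    observed_count: int
    n_sites: int
    n_features: int
    cutoff_bp: float
    n_sims: int
    null_counts: np.ndarray
    p_upper: float
    seed: int

    def __post_init__(self) -> None:
        assert 0 <= self.observed_count <= self.n_sites
        assert len(self.null_counts) == self.n_sims

    @property
    def observed_fraction(self) -> float:
        return self.observed_count / self.n_sites if self.n_sites else 0.0

    def to_dict(self) -> dict:
        bins = np.bincount(self.null_counts, minlength=self.n_sites + 1)
        return {
            "observed_count": int(self.observed_count),
            "n_sites": int(self.n_sites),
            "n_features": int(self.n_features),
            "cutoff_bp": float(self.cutoff_bp),
            "n_sims": int(self.n_sims),
            "p_upper": float(self.p_upper),
            "seed": int(self.seed),
            "null_count_histogram": {
                str(k): int(v) for k, v in enumerate(bins) if v
            },
        }


@dataclass(frozen=True)
class ProportionTestResult:
    """Two-sample test for equality of proportions with continuity correction."""

    x1: int
    n1: int
    x2: int
    n2: int
    chi2_statistic: float
    p_value: float

    @property
    def p1_hat(self) -> float:
        return self.x1 / self.n1

    @property
    def p2_hat(self) -> float:
        return self.x2 / self.n2


def nearest_feature_distances(
    chroms: np.ndarray, midpoints: np.ndarray, features: pd.DataFrame
) -> np.ndarray:
    """Distance from each (chrom, midpoint) query to its nearest feature.

    Vectorized midpoint-to-midpoint nearest distance; queries on
    chromosomes with no features get ``inf``.
    """
    midpoints = np.asarray(midpoints, dtype=float)
    chroms = np.asarray(chroms)
    out = np.full(len(midpoints), np.inf)
    if len(features) == 0:
        return out
    by_chrom = {
        str(c): np.sort(g["midpoint"].to_numpy(dtype=float))
        for c, g in features.groupby("chrom", sort=False)
    }
    for chrom, feats in by_chrom.items():
        sel = chroms == chrom
        if not sel.any():
            continue
        m = midpoints[sel]
        j = np.searchsorted(feats, m)
        left = np.where(j > 0, np.abs(m - feats[np.maximum(j - 1, 0)]), np.inf)
        right = np.where(j < len(feats), np.abs(feats[np.minimum(j, len(feats) - 1)] - m), np.inf)
        out[sel] = np.minimum(left, right)
    return out


def nearest_feature_distance(
    site: tuple[str, float], features: pd.DataFrame
) -> float:
    """Nearest-feature distance for a single (chrom, midpoint) site."""
    chrom, midpoint = site
    return float(
        nearest_feature_distances(
            np.array([chrom]), np.array([midpoint], dtype=float), features
        )[0]
    )


def count_within(sites, features: pd.DataFrame, cutoff_bp: float = 6000) -> int:
    """Number of sites with a feature within *cutoff_bp* (inclusive)."""
    if cutoff_bp <= 0:
        raise ValueError("cutoff_bp must be positive")
    frame = _sites_frame(sites)
    d = nearest_feature_distances(
        frame["chrom"].to_numpy(), frame["midpoint"].to_numpy(), features
    )
    return int(np.count_nonzero(d <= cutoff_bp))


def proportion_test(x1: int, n1: int, x2: int, n2: int) -> ProportionTestResult:
    """Pearson chi-square on the 2x2 table with Yates continuity correction.

    Mirrors the textbook two-sample proportion test: the correction shrinks
    each |observed - expected| by 0.5 but never past zero, and the
    two-sided p-value comes from the chi-square distribution with 1 df.
    Degenerate tables (pooled proportion 0 or 1) give statistic 0, p 1.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2) or n1 <= 0 or n2 <= 0:
        raise ValueError("need 0 <= x_i <= n_i with n_i > 0")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ProportionTestResult(x1, n1, x2, n2, 0.0, 1.0)
    observed = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row @ col / observed.sum()
    adj = np.sign(expected - observed) * np.minimum(0.5, np.abs(expected - observed))
    stat = float((((observed + adj) - expected) ** 2 / expected).sum())
    p = float(chi2.sf(stat, df=1))
    return ProportionTestResult(x1, n1, x2, n2, stat, p)


def _universe_positions(probe_universe: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    unflagged = probe_universe.loc[~probe_universe["flagged"].astype(bool)]
    mid = ((unflagged["start"] + unflagged["end"]) / 2.0).to_numpy(dtype=float)
    return unflagged["chrom"].to_numpy(), mid


def _near_mask(
    probe_universe: pd.DataFrame, features: pd.DataFrame, cutoff_bp: float
) -> np.ndarray:
    chroms, mid = _universe_positions(probe_universe)
    return nearest_feature_distances(chroms, mid, features) <= cutoff_bp


def random_simulation_test(
    sites,
    features: pd.DataFrame,
    probe_universe: pd.DataFrame,
    cutoff_bp: float = 6000,
    n_sims: int = 10_000,
    seed: int = 0,
) -> AssociationResult:
    """Upper-tail randomization test of site/feature proximity.

    Null sites are equal-sized draws of distinct unflagged probe positions
    from the microarray; ``p_upper`` is the exact fraction of draws whose
    within-cutoff count is >= the observed count (ties included, no
    smoothing term).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    frame = _sites_frame(sites)
    n_sites = len(frame)
    mask = _near_mask(probe_universe, features, cutoff_bp)
    n_universe = len(mask)
    if n_sites > n_universe:
        raise ValueError(
            f"{n_sites} sites exceed the {n_universe}-probe unflagged universe"
        )
    observed = count_within(frame, features, cutoff_bp)
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_sims, dtype=np.int64)
    if n_sites == 0:
        null_counts[:] = 0
    else:
        # Batched sampling without replacement: the n_sites smallest of
        # n_universe random keys index a uniform subset.
        block = max(1, int(2e7) // max(n_universe, 1))
        done = 0
        while done < n_sims:
            b = min(block, n_sims - done)
            keys = rng.random((b, n_universe))
            idx = np.argpartition(keys, n_sites - 1, axis=1)[:, :n_sites]
            null_counts[done : done + b] = mask[idx].sum(axis=1)
            done += b
    p_upper = float(np.count_nonzero(null_counts >= observed)) / n_sims
    return AssociationResult(
        observed_count=observed,
        n_sites=n_sites,
        n_features=len(features),
        cutoff_bp=cutoff_bp,
        n_sims=n_sims,
        null_counts=null_counts,
        p_upper=p_upper,
        seed=seed,
    )


def exhaustive_null(
    n_sites: int,
    features: pd.DataFrame,
    probe_universe: pd.DataFrame,
    cutoff_bp: float = 6000,
    max_placements: int = 10**6,
) -> dict[int, float]:
    """Exact null pmf of the within-cutoff count over all site placements.

    Enumerates every size-``n_sites`` subset of the unflagged probe
    universe; usable only while C(universe, n_sites) stays small (at most
    *max_placements*), otherwise a Monte Carlo run is the way to go.
    Returns ``{count: probability}``.
    """
    mask = _near_mask(probe_universe, features, cutoff_bp)
    n_universe = len(mask)
    if n_sites > n_universe:
        raise ValueError("n_sites exceeds universe size")
    n_placements = math.comb(n_universe, n_sites)
    if n_placements > max_placements:
        raise ValueError(
            f"{n_placements} placements exceed {max_placements}; "
            "use the Monte Carlo random_simulation_test instead"
        )
    counts: dict[int, int] = {}
    for combo in itertools.combinations(range(n_universe), n_sites):
        c = int(sum(mask[i] for i in combo))
        counts[c] = counts.get(c, 0) + 1
    return {c: k / n_placements for c, k in sorted(counts.items())}


def exact_upper_p(null_pmf: dict[int, float], observed: int) -> float:
    """Upper-tail probability P(count >= observed) from an exact pmf."""
    return sum(p for c, p in null_pmf.items() if c >= observed)
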