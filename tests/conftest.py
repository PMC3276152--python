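import numpy as np
import pandas as pd
import pytest

import fragilemap as fm


@pytest.fixture(scope="session")
def mini():
    """2 x 200 kb genome with a 500 bp probe grid (1% flagged)."""
    layout, probes = fm.mini_genome(seed=0)
    return layout, probes


@pytest.fixture(scope="session")
def mini_clean():
    """Same mini genome without any flagged probes."""
    layout, probes = fm.mini_genome(seed=0, flag_fraction=0.0)
    return layout, probes


@pytest.fixture(scope="session")
def flat_sample(mini_clean):
    """Noiseless flat sample: expected ratio 1 everywhere."""
    _, probes = mini_clean
    return fm.simulate_sample(probes, fm.SyntheticTruth(), noise_cv=0.0, seed=0)


def probe_mid_frame(probes: pd.DataFrame) -> pd.DataFrame:
    """chrom/midpoint frame for a probe subset, as site-like input."""
    return pd.DataFrame(
        {
            "chrom": probes["chrom"].to_numpy(),
            "midpoint": ((probes["start"] + probes["end"]) / 2.0).to_numpy(),
        }
    )


def random_instance(rng: np.random.Generator, n_probes=10, n_sites=3, n_feats=2,
                    chrom_len=10_000, cutoff=1500):
    """Small random site/feature/universe instance for oracle checks."""
    layout = fm.GenomeLayout((("chrA", chrom_len),))
    spacing = chrom_len // n_probes
    probes = fm.make_probe_grid(layout, spacing=spacing, probe_length=min(60, spacing),
                                seed=int(rng.integers(2**31)), flag_fraction=0.0)
    feats = fm.features_from_records(
        [("chrA", float(rng.uniform(0, chrom_len)), "other", f"f{i}")
         for i in range(n_feats)],
        layout,
    )
    site_idx = rng.choice(len(probes), size=n_sites, replace=False)
    sites = probe_mid_frame(probes.iloc[np.sort(site_idx)])
    return layout, probes, feats, sites, cutoff
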