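"""File formats and end-to-end run orchestration.

Formats: UCSC ``chrom.sizes`` for layouts, BED3/6 for features and called
sites, bedGraph for smoothed profiles, a documented TSV dialect for array
samples (with a configurable column map for feature-extraction-style
exports), YAML for run configs, JSON for statistical reports.  Parsers
reject malformed rows rather than coercing them, and every filtering
action (flagged spots removed, non-positive control probes dropped) is
logged because it silently changes site counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import proportion_test, random_simulation_test
from .genome import GenomeLayout, load_features, load_layout, validate_probes
from .profiles import RatioProfile, compute_ratios, lowess_smooth, profile_correlation
from .sites import SiteSet, call_peaks, call_significant_sites, merge_nearby
from .synthetic import SAMPLE_COLUMNS, ArraySample

logger = logging.getLogger(__name__)

__all__ = [
    "read_sample",
    "write_sample",
    "write_bedgraph",
    "read_bedgraph",
    "write_sites_bed",
    "read_sites_bed",
    "RunConfig",
    "run_profile_command",
    "run_full_analysis",
]

#: Default column map of the native sample TSV dialect.
DEFAULT_COLUMN_MAP = {c: c for c in SAMPLE_COLUMNS}


def write_sample(sample: ArraySample, path: str | Path) -> None:
    sample.data[list(SAMPLE_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_sample(path: str | Path, column_map: dict[str, str] | None = None) -> ArraySample:
    """Read an array-sample TSV; *column_map* maps our canonical column
    names to the file's header names for foreign dialects."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    try:
        raw = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: not a readable TSV: {exc}") from exc
    missing = [src for src in cmap.values() if src not in raw.columns]
    if missing:
        raise ValueError(
            f"{path}: missing columns {missing}; expected a header with "
            f"{sorted(cmap.values())}"
        )
    data = pd.DataFrame({ours: raw[theirs] for ours, theirs in cmap.items()})
    for col in ("start", "end"):
        data[col] = data[col].astype(np.int64)
    if data["flagged"].dtype == object:
        data["flagged"] = data["flagged"].map(
            {"True": True, "False": False, "1": True, "0": False}
        )
        if data["flagged"].isna().any():
            raise ValueError(f"{path}: unparseable values in 'flagged' column")
    data["flagged"] = data["flagged"].astype(bool)
    for col in ("exp_signal", "exp_bg", "ctl_signal", "ctl_bg"):
        data[col] = pd.to_numeric(data[col], errors="raise")
    return ArraySample(data)


def write_bedgraph(profile: RatioProfile, path: str | Path, column: str = "auto") -> None:
    """Write a profile as bedGraph (chrom, start, end, value)."""
    if column == "auto":
        column = "smoothed_ratio" if profile.smoothed else "raw_ratio"
    d = profile.data
    with open(path, "w") as fh:
        for chrom, start, end, val in zip(d["chrom"], d["start"], d["end"], d[column]):
            fh.write(f"{chrom}\t{start}\t{end}\t{val:.6g}\n")


def read_bedgraph(path: str | Path) -> RatioProfile:
    """Read a bedGraph back as a profile (values land in both raw and
    smoothed columns; adequate for correlation and site calling)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: not a bedGraph line: {line!r}")
            rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
    if not rows:
        raise ValueError(f"{path}: empty bedGraph")
    d = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    d["probe_id"] = d["chrom"] + ":" + d["start"].astype(str)
    d["midpoint"] = (d["start"] + d["end"]) / 2.0
    d["raw_ratio"] = d["value"]
    d["smoothed_ratio"] = d["value"]
    d = d.drop(columns="value")
    return RatioProfile(d, sample_id=str(path))


def write_sites_bed(site_set: SiteSet, path: str | Path) -> None:
    """Called sites as BED with the smoothed ratio in the score column."""
    with open(path, "w") as fh:
        for row in site_set.sites.itertuples(index=False):
            start = int(np.floor(row.midpoint - 0.5))
            end = int(np.ceil(row.midpoint + 0.5))
            fh.write(
                f"{row.chrom}\t{max(start, 0)}\t{end}\tsite\t{row.smoothed_ratio:.6g}\n"
            )


def read_sites_bed(path: str | Path, rule: str = "above_median") -> SiteSet:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: not a BED line: {line!r}")
            start, end = int(parts[1]), int(parts[2])
            score = float(parts[4]) if len(parts) > 4 else np.nan
            rows.append((parts[0], (start + end) / 2.0, score))
    sites = pd.DataFrame(rows, columns=["chrom", "midpoint", "smoothed_ratio"])
    return SiteSet(sites, threshold=float("nan"), rule=rule, source=str(path))


@dataclass
class RunConfig:
    """Serializable configuration of a full analysis run."""

    layout: str
    samples: dict[str, str] = field(default_factory=dict)  # sample id -> TSV path
    features: dict[str, str] = field(default_factory=dict)  # category -> BED path
    probes: str | None = None  # probe-universe TSV (defaults to first sample)
    window_bp: int = 6000
    cutoff_bp: int = 6000
    n_sims: int = 10_000
    seed: int = 0
    rule: str = "above_median"
    merge_within_bp: int = 0
    outdir: str = "fragilemap_out"
    column_map: dict[str, str] = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**doc)


def _load_and_profile(
    sample_path: str | Path,
    layout: GenomeLayout,
    window_bp: int,
    sample_id: str,
    column_map: dict[str, str] | None = None,
) -> RatioProfile:
    sample = read_sample(sample_path, column_map=column_map or None)
    validate_probes(sample.data, layout)
    profile = compute_ratios(sample, sample_id=sample_id)
    return lowess_smooth(profile, window_bp=window_bp)


def run_profile_command(config: RunConfig) -> dict[str, RatioProfile]:
    """Profile every sample in the config; write bedGraph + TSV per sample.

    Deterministic for fixed inputs; the echoed config and a log of
    normalization totals and dropped-probe counts land in the output
    directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    layout = load_layout(config.layout)
    profiles: dict[str, RatioProfile] = {}
    for sample_id, path in config.samples.items():
        prof = _load_and_profile(
            path, layout, config.window_bp, sample_id, config.column_map
        )
        write_bedgraph(prof, outdir / f"{sample_id}.bedGraph")
        prof.data.to_csv(outdir / f"{sample_id}.profile.tsv", sep="\t", index=False)
        logger.info(
            "sample %s: %d probes profiled, %d flagged removed, %d dropped "
            "(exp_total=%.6g, ctl_total=%.6g)",
            sample_id,
            len(prof.data),
            prof.normalization["n_flagged_removed"],
            prof.normalization["n_nonpositive_dropped"],
            prof.normalization["exp_total"],
            prof.normalization["ctl_total"],
        )
        profiles[sample_id] = prof
    return profiles


def run_full_analysis(config: RunConfig) -> dict:
    """Profile samples, call sites, run association tests per feature
    category, and correlate profiles pairwise.

    Returns (and writes to ``<outdir>/report.json``) a report shaped like
    a per-category association table: observed within-cutoff counts and
    simulation p-values for each feature category, plus pairwise profile
    correlations.  A human-readable table lands in ``report.txt``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profiles = run_profile_command(config)
    layout = load_layout(config.layout)
    report: dict = {
        "seed": config.seed,
        "window_bp": config.window_bp,
        "cutoff_bp": config.cutoff_bp,
        "n_sims": config.n_sims,
        "samples": {},
        "correlations": {},
    }

    # pairwise profile correlations
    ids = list(profiles)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            try:
                r = profile_correlation(profiles[a], profiles[b])
            except ValueError as exc:
                logger.warning("correlation %s vs %s skipped: %s", a, b, exc)
                continue
            report["correlations"][f"{a}__vs__{b}"] = r

    # probe universe for the randomization null
    if config.probes:
        universe = read_sample(config.probes, column_map=config.column_map or None).data
    else:
        first = next(iter(config.samples.values()))
        universe = read_sample(first, column_map=config.column_map or None).data
    validate_probes(universe, layout)

    feature_sets = {
        cat: load_features(path, layout, category=cat)
        for cat, path in config.features.items()
    }

    for sample_id, prof in profiles.items():
        if config.rule == "local_peak":
            site_set = call_peaks(prof)
        else:
            site_set = call_significant_sites(prof)
        if config.merge_within_bp:
            site_set = merge_nearby(site_set, config.merge_within_bp)
        write_sites_bed(site_set, outdir / f"{sample_id}.sites.bed")
        entry: dict = {
            "n_sites": len(site_set),
            "rule": site_set.rule,
            "threshold": site_set.threshold,
            "associations": {},
        }
        if len(site_set) == 0:
            logger.warning("sample %s: no sites called; association skipped", sample_id)
            for cat in feature_sets:
                entry["associations"][cat] = {
                    "observed_count": 0,
                    "p_upper": 1.0,
                    "n_sims": 0,
                }
        else:
            for cat, feats in feature_sets.items():
                res = random_simulation_test(
                    site_set,
                    feats,
                    universe,
                    cutoff_bp=config.cutoff_bp,
                    n_sims=config.n_sims,
                    seed=config.seed,
                )
                entry["associations"][cat] = res.to_dict()
        report["samples"][sample_id] = entry

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    _write_text_report(report, outdir / "report.txt")
    return report


def _write_text_report(report: dict, path: Path) -> None:
    lines = ["Association of called sites with feature categories", ""]
    header = f"{'sample':<16}{'category':<20}{'sites':>7}{'near':>7}{'P':>10}"
    lines.append(header)
    lines.append("-" * len(header))
    for sample_id, entry in report["samples"].items():
        for cat, assoc in entry["associations"].items():
            lines.append(
                f"{sample_id:<16}{cat:<20}{entry['n_sites']:>7}"
                f"{assoc['observed_count']:>7}{assoc['p_upper']:>10.4g}"
            )
    if report["correlations"]:
        lines += ["", "Pairwise profile correlations (Pearson, smoothed)"]
        for pair, r in report["correlations"].items():
            lines.append(f"  {pair.replace('__vs__', ' vs ')}: r = {r:.3f}")
    path.write_text("\n".join(lines) + "\n")
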