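"""Genome coordinate system, probe universe, and point features.

Everything downstream of this module works in a single coordinate
universe: a :class:`GenomeLayout` of named chromosomes with lengths,
BED-style 0-based half-open intervals for probes, and real-valued point
midpoints for genomic features (replication origins, centromeres,
restriction/endonuclease cut sites).  Features are reduced to midpoints
on load because every distance in the analysis is measured midpoint to
midpoint; strand is ignored throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FEATURE_CATEGORIES",
    "GenomeLayout",
    "BUDDING_YEAST_CHROM_SIZES",
    "load_layout",
    "write_layout",
    "load_features",
    "features_from_records",
    "write_features",
    "PROBE_COLUMNS",
    "validate_probes",
]

#: Closed vocabulary of feature categories used by the association tests.
FEATURE_CATEGORIES = (
    "checked_origin",
    "unchecked_origin",
    "centromere",
    "cut_site",
    "other",
)

#: Chromosome sizes (bp) of the 16 Saccharomyces cerevisiae nuclear
#: chromosomes (sacCer3 assembly), used for full-genome emulations.
BUDDING_YEAST_CHROM_SIZES = {
    "chrI": 230218,
    "chrII": 813184,
    "chrIII": 316620,
    "chrIV": 1531933,
    "chrV": 576874,
    "chrVI": 270161,
    "chrVII": 1090940,
    "chrVIII": 562643,
    "chrIX": 439888,
    "chrX": 745751,
    "chrXI": 666816,
    "chrXII": 1078177,
    "chrXIII": 924431,
    "chrXIV": 784333,
    "chrXV": 1091291,
    "chrXVI": 948066,
}

#: Required columns of a probe-universe DataFrame.
PROBE_COLUMNS = ("probe_id", "chrom", "start", "end", "flagged")


class LayoutError(ValueError):
    """Raised for malformed genome layouts or out-of-bounds coordinates."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered set of named chromosomes with lengths in base pairs.

    Iteration order is the construction order and is stable, so that
    every stage of the pipeline processes chromosomes identically.
    """

    chromosomes: tuple[tuple[str, int], ...]
    _lengths: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise LayoutError("a genome layout needs at least one chromosome")
        lengths: dict[str, int] = {}
        for name, length in self.chromosomes:
            if name in lengths:
                raise LayoutError(f"duplicate chromosome name: {name!r}")
            if not isinstance(length, int) or isinstance(length, bool) or length <= 0:
                raise LayoutError(
                    f"chromosome {name!r} has non-positive or non-integer "
                    f"length {length!r}"
                )
            lengths[name] = length
        object.__setattr__(self, "_lengths", lengths)

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(sizes.items()))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise LayoutError(f"unknown chromosome: {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __len__(self) -> int:
        return len(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())


def load_layout(path: str | Path) -> GenomeLayout:
    """Read a UCSC-style ``chrom.sizes`` file (two whitespace-separated
    columns: chromosome name, length in bp)."""
    entries: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise LayoutError(f"{path}:{lineno}: expected 'name length', got {line!r}")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError:
                raise LayoutError(
                    f"{path}:{lineno}: length is not an integer: {parts[1]!r}"
                ) from None
            entries.append((name, length))
    if not entries:
        raise LayoutError(f"{path}: no chromosomes found")
    return GenomeLayout(tuple(entries))


def write_layout(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\n")


def _check_category(category: str) -> str:
    if category not in FEATURE_CATEGORIES:
        raise ValueError(
            f"unknown feature category {category!r}; expected one of "
            f"{FEATURE_CATEGORIES}"
        )
    return category


def features_from_records(
    records: Iterable[tuple[str, float, str, str]], layout: GenomeLayout
) -> pd.DataFrame:
    """Build a feature table from ``(chrom, midpoint, category, name)``
    tuples, validating coordinates against *layout*."""
    rows = []
    for chrom, midpoint, category, name in records:
        if chrom not in layout:
            raise LayoutError(f"feature {name!r} on unknown chromosome {chrom!r}")
        if not (0 <= midpoint <= layout.length_of(chrom)):
            raise LayoutError(
                f"feature {name!r} midpoint {midpoint} outside {chrom} "
                f"[0, {layout.length_of(chrom)}]"
            )
        rows.append((chrom, float(midpoint), _check_category(category), name))
    return pd.DataFrame(rows, columns=["chrom", "midpoint", "category", "name"])


def load_features(
    path: str | Path,
    layout: GenomeLayout,
    category: str | None = None,
) -> pd.DataFrame:
    """Read a BED3+ file of features and reduce intervals to midpoints.

    The midpoint of a BED interval [start, end) is (start + end) / 2, a
    real number.  If *category* is given it is attached to every feature;
    otherwise the BED name column (4th) must carry a category label from
    :data:`FEATURE_CATEGORIES`.
    """
    if category is not None:
        _check_category(category)
    records: list[tuple[str, float, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: not a BED3+ line: {line!r}")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer BED coordinates: {line!r}"
                ) from None
            if chrom not in layout:
                raise LayoutError(
                    f"{path}:{lineno}: unknown chromosome {chrom!r}: {line!r}"
                )
            if not (0 <= start < end <= layout.length_of(chrom)):
                raise LayoutError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside "
                    f"{chrom} bounds: {line!r}"
                )
            name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
            cat = category if category is not None else _check_category(name)
            records.append((chrom, (start + end) / 2.0, cat, name))
    return features_from_records(records, layout)


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    """Write features as BED6-ish lines whose interval midpoint equals the
    stored midpoint exactly (requires 2*midpoint integral and midpoint >= 0.5)."""
    with open(path, "w") as fh:
        for row in features.itertuples(index=False):
            twice = 2.0 * row.midpoint
            if twice != int(twice) or row.midpoint < 0.5:
                raise ValueError(
                    f"midpoint {row.midpoint} not representable as a BED "
                    "interval midpoint"
                )
            start = math.floor(row.midpoint - 0.5)
            end = math.ceil(row.midpoint + 0.5)
            # category goes in the BED name column so a plain re-load
            # recovers it; the feature's own name rides in column 7
            fh.write(f"{row.chrom}\t{start}\t{end}\t{row.category}\t0\t.\t{row.name}\n")


def validate_probes(probes: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    """Validate a probe-universe table against a layout; returns the input.

    Probes are BED-convention intervals with a ``flagged`` QC boolean;
    midpoints are (start + end) / 2.
    """
    missing = [c for c in PROBE_COLUMNS if c not in probes.columns]
    if missing:
        raise ValueError(f"probe table missing columns: {missing}")
    unknown = set(probes["chrom"]) - set(layout.names)
    if unknown:
        raise LayoutError(f"probes on unknown chromosomes: {sorted(unknown)}")
    for chrom, grp in probes.groupby("chrom", sort=False):
        clen = layout.length_of(str(chrom))
        if (grp["start"] < 0).any() or (grp["end"] > clen).any():
            raise LayoutError(f"probe outside bounds of {chrom}")
        if (grp["start"] >= grp["end"]).any():
            raise LayoutError(f"probe with start >= end on {chrom}")
    return probes


def probe_midpoints(probes: pd.DataFrame) -> pd.Series:
    """Midpoint of each probe interval, as a float Series."""
    return (probes["start"] + probes["end"]) / 2.0
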