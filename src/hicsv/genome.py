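"""Genome binning: fixed-resolution bins over a chromosome-sizes table.

Hi-C analysis works on a binned genome: each chromosome is cut into
consecutive windows of ``resolution`` bp (the last window may be shorter).
Bins use 0-based half-open coordinates, matching BED conventions.
chrY and chrM are excluded by default: both are problematic for coverage
statistics (chrY is absent/variable across samples, chrM is tiny and
hyper-covered).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

DEFAULT_EXCLUDED = frozenset({"chrY", "chrM"})


class GenomeError(ValueError):
    """Invalid chromosome table / bin addressing."""


@dataclass(frozen=True)
class GenomeBins:
    """Fixed-resolution binning of a genome.

    Parameters
    ----------
    chrom_sizes
        Ordered mapping chromosome name -> length in bp. The input order is
        preserved and defines the global bin order.
    resolution
        Bin width in bp.
    excluded_chroms
        Chromosomes dropped from the binning (default chrY, chrM).
    """

    chrom_sizes: Mapping[str, int]
    resolution: int
    excluded_chroms: frozenset = DEFAULT_EXCLUDED

    # derived, filled in __post_init__
    chroms: tuple = field(init=False, repr=False)
    _n_bins: dict = field(init=False, repr=False)
    _offsets: dict = field(init=False, repr=False)
    n_total: int = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise GenomeError(f"resolution must be > 0, got {self.resolution}")
        seen = set()
        for name, size in self.chrom_sizes.items():
            if name in seen:
                raise GenomeError(f"duplicate chromosome name: {name}")
            seen.add(name)
            if size <= 0:
                raise GenomeError(f"chromosome {name} has non-positive length {size}")
        chroms = tuple(c for c in self.chrom_sizes if c not in self.excluded_chroms)
        n_bins = {c: -(-int(self.chrom_sizes[c]) // self.resolution) for c in chroms}
        offsets, off = {}, 0
        for c in chroms:
            offsets[c] = off
            off += n_bins[c]
        object.__setattr__(self, "chroms", chroms)
        object.__setattr__(self, "_n_bins", n_bins)
        object.__setattr__(self, "_offsets", offsets)
        object.__setattr__(self, "n_total", off)

    # -- addressing -------------------------------------------------------

    def n_bins(self, chrom: str) -> int:
        self._check(chrom)
        return self._n_bins[chrom]

    def offset(self, chrom: str) -> int:
        """Global index of the chromosome's first bin."""
        self._check(chrom)
        return self._offsets[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        off = self.offset(chrom)
        return slice(off, off + self._n_bins[chrom])

    def bin_index(self, chrom: str, pos: int) -> int:
        """Local bin index of a bp position on ``chrom``."""
        self._check(chrom)
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise GenomeError(f"position {pos} outside {chrom} "
                              f"[0, {self.chrom_sizes[chrom]})")
        return pos // self.resolution

    def bin_bounds(self, chrom: str, i: int) -> tuple:
        """(start, end) in bp of local bin ``i``."""
        self._check(chrom)
        if not 0 <= i < self._n_bins[chrom]:
            raise GenomeError(f"bin index {i} out of range for {chrom}")
        start = i * self.resolution
        return start, min(start + self.resolution, int(self.chrom_sizes[chrom]))

    def _check(self, chrom: str) -> None:
        if chrom not in self._n_bins:
            raise GenomeError(f"unknown or excluded chromosome: {chrom}")

    # -- iteration / export -----------------------------------------------

    def __iter__(self) -> Iterator[tuple]:
        for c in self.chroms:
            for i in range(self._n_bins[c]):
                yield (c, *self.bin_bounds(c, i))

    @property
    def bins(self) -> list:
        return list(self)

    def chrom_of_global(self, g: int) -> tuple:
        """Map a global bin index back to (chrom, local index)."""
        if not 0 <= g < self.n_total:
            raise GenomeError(f"global bin index {g} out of range")
        for c in self.chroms:
            off = self._offsets[c]
            if g < off + self._n_bins[c]:
                return c, g - off
        raise GenomeError(f"global bin index {g} out of range")  # pragma: no cover

    def same_bins(self, other: "GenomeBins") -> bool:
        return (self.resolution == other.resolution
                and self.chroms == other.chroms
                and all(self.chrom_sizes[c] == other.chrom_sizes[c] for c in self.chroms))

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def bin_genome(chrom_sizes: Mapping[str, int], resolution: int,
               excluded: Iterable[str] | None = None) -> GenomeBins:
    """Bin a genome at a fixed resolution.

    ``excluded=None`` applies the default chrY/chrM exclusion; pass an empty
    iterable to keep every chromosome.
    """
    exc = DEFAULT_EXCLUDED if excluded is None else frozenset(excluded)
    return GenomeBins(dict(chrom_sizes), int(resolution), exc)


def read_chrom_sizes(path) -> dict:
    """Read a two-column ``chrom<TAB>size`` table (UCSC chrom.sizes style)."""
    sizes: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise GenomeError(f"{path}:{ln}: expected 'chrom size', got {line!r}")
            name, size = parts[0], parts[1]
            if name in sizes:
                raise GenomeError(f"{path}:{ln}: duplicate chromosome {name}")
            sizes[name] = int(size)
    return sizes
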