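"""Contact-matrix data model and I/O.

A :class:`ContactMatrix` stores one dense block per chromosome pair, keyed
``(chromA, chromB)`` in genome order with A <= B. Intra-chromosomal blocks
are kept fully symmetric in memory. Two kinds exist:

* ``counts`` — raw contact counts; finite, non-negative.
* ``ratios`` — background-adjusted frequencies; masked (missing) cells are
  stored as NaN and excluded from downstream statistics.

The text interchange format is a tab-separated sparse COO listing
(``chromA  binA  chromB  binB  count``) with a header carrying the
resolution and chromosome sizes; intra-chromosomal entries are written
upper-triangle only and mirrored on read. Reading ``.cool`` files (plain
HDF5) is supported through h5py.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .genome import GenomeBins, GenomeError, bin_genome

log = logging.getLogger(__name__)

_SYM_TOL = 1e-9


class MatrixFormatError(ValueError):
    """Malformed matrix file or inconsistent blocks."""


@dataclass
class ContactMatrix:
    """Binned genome-wide contact matrix, one dense block per chromosome pair."""

    bins: GenomeBins
    blocks: dict = field(default_factory=dict)
    kind: str = "counts"  # "counts" | "ratios"

    def __post_init__(self) -> None:
        order = {c: i for i, c in enumerate(self.bins.chroms)}
        fixed = {}
        for (ca, cb), block in self.blocks.items():
            if ca not in order or cb not in order:
                raise MatrixFormatError(f"block ({ca},{cb}) names unknown chromosome")
            if order[ca] > order[cb]:
                ca, cb, block = cb, ca, np.asarray(block).T
            block = np.asarray(block, dtype=float)
            shape = (self.bins.n_bins(ca), self.bins.n_bins(cb))
            if block.shape != shape:
                raise MatrixFormatError(
                    f"block ({ca},{cb}) has shape {block.shape}, expected {shape}")
            if ca == cb:
                if not np.allclose(block, block.T, atol=_SYM_TOL, equal_nan=True):
                    block = 0.5 * (block + block.T)
            fixed[(ca, cb)] = block
        self.blocks = fixed
        self.validate()

    # -- access -----------------------------------------------------------

    def block(self, ca: str, cb: str) -> np.ndarray:
        """Dense block for a chromosome pair (zeros if absent); transposed
        on the fly when asked for in the reverse order."""
        order = {c: i for i, c in enumerate(self.bins.chroms)}
        if ca not in order or cb not in order:
            raise GenomeError(f"unknown or excluded chromosome in ({ca},{cb})")
        if order[ca] <= order[cb]:
            b = self.blocks.get((ca, cb))
            if b is None:
                b = np.zeros((self.bins.n_bins(ca), self.bins.n_bins(cb)))
            return b
        return self.block(cb, ca).T

    def set_block(self, ca: str, cb: str, values: np.ndarray) -> None:
        order = {c: i for i, c in enumerate(self.bins.chroms)}
        if order[ca] > order[cb]:
            ca, cb, values = cb, ca, np.asarray(values).T
        self.blocks[(ca, cb)] = np.asarray(values, dtype=float)

    def chrom_pairs(self) -> list:
        """All unordered inter-chromosomal pairs, in genome order."""
        cs = self.bins.chroms
        return [(cs[i], cs[j]) for i in range(len(cs)) for j in range(i + 1, len(cs))]

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(self.bins, {k: v.copy() for k, v in self.blocks.items()},
                             self.kind)

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        for key, block in self.blocks.items():
            if self.kind == "counts":
                if not np.all(np.isfinite(block)):
                    raise MatrixFormatError(f"non-finite values in counts block {key}")
                if np.any(block < 0):
                    raise MatrixFormatError(f"negative values in counts block {key}")
            else:
                vals = block[np.isfinite(block)]
                if np.any(vals < 0):
                    raise MatrixFormatError(f"negative values in ratios block {key}")

    def mass(self) -> float:
        """Total contact mass: upper triangle (incl. diagonal) of intra blocks
        plus all inter-block cells. Equals the number of read pairs for a
        matrix built from valid pairs."""
        total = 0.0
        for (ca, cb), block in self.blocks.items():
            vals = np.nan_to_num(block, nan=0.0)
            if ca == cb:
                total += np.triu(vals).sum()
            else:
                total += vals.sum()
        return float(total)


@dataclass
class CoverageProfile:
    """Per-bin 1D coverage: row+column sums of a contact matrix."""

    bins: GenomeBins
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.bins.n_total,):
            raise MatrixFormatError(
                f"profile length {self.values.shape} != #bins {self.bins.n_total}")

    def chrom(self, chrom: str) -> np.ndarray:
        return self.values[self.bins.chrom_slice(chrom)]


# -- operations ------------------------------------------------------------


def coverage_1d(m: ContactMatrix) -> CoverageProfile:
    """Row/column sums of a contact matrix, per bin, over every block that
    involves the bin's chromosome; the diagonal counts once."""
    values = np.zeros(m.bins.n_total)
    for (ca, cb), block in m.blocks.items():
        vals = np.nan_to_num(block, nan=0.0)
        if ca == cb:
            values[m.bins.chrom_slice(ca)] += vals.sum(axis=1)
        else:
            values[m.bins.chrom_slice(ca)] += vals.sum(axis=1)
            values[m.bins.chrom_slice(cb)] += vals.sum(axis=0)
    return CoverageProfile(m.bins, values)


def build_background(matrices: Iterable[ContactMatrix]) -> ContactMatrix:
    """Average several contact maps into a background matrix.

    Each input is first rescaled to the mean total mass of the inputs so
    that deeper libraries do not dominate, then averaged cell-wise.
    """
    mats = list(matrices)
    if not mats:
        raise ValueError("need at least one matrix")
    bins = mats[0].bins
    for m in mats[1:]:
        if not bins.same_bins(m.bins):
            raise MatrixFormatError("matrices have mismatched bins/resolution")
    masses = [m.mass() for m in mats]
    target = float(np.mean(masses))
    keys = set()
    for m in mats:
        keys.update(m.blocks)
    out = {}
    for key in keys:
        acc = np.zeros((bins.n_bins(key[0]), bins.n_bins(key[1])))
        for m, mass in zip(mats, masses):
            scale = target / mass if mass > 0 else 0.0
            acc += np.nan_to_num(m.block(*key), nan=0.0) * scale
        out[key] = acc / len(mats)
    return ContactMatrix(bins, out, kind="ratios")


def adjust_by_background(obs: ContactMatrix, bg: ContactMatrix,
                         pseudocount: float = 0.0) -> ContactMatrix:
    """Cell-wise ratio (obs + pc) / (bg + pc).

    Cells whose denominator is zero are masked (NaN) and excluded from
    downstream statistics; a warning is logged when observed signal is
    lost that way.
    """
    if not obs.bins.same_bins(bg.bins):
        raise MatrixFormatError("observed and background bins differ")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    out = {}
    n_lost = 0
    keys = set(obs.blocks) | set(bg.blocks)
    for key in keys:
        o = obs.block(*key)
        b = bg.block(*key)
        denom = b + pseudocount
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (o + pseudocount) / denom
        masked = denom == 0
        n_lost += int(np.sum(masked & (np.nan_to_num(o) > 0)))
        r[masked] = np.nan
        out[key] = r
    if n_lost:
        log.warning("adjust_by_background: %d cells with observed signal but "
                    "zero background were masked", n_lost)
    return ContactMatrix(obs.bins, out, kind="ratios")


# -- COO text I/O ----------------------------------------------------------


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def write_matrix(m: ContactMatrix, path) -> None:
    """Write the sparse COO text format (gzip-transparent by suffix)."""
    with _open(path, "wt") as fh:
        fh.write("#hicsv-matrix\tv1\n")
        fh.write(f"#resolution\t{m.bins.resolution}\n")
        fh.write(f"#kind\t{m.kind}\n")
        if m.bins.excluded_chroms:
            fh.write("#excluded\t" + ",".join(sorted(m.bins.excluded_chroms)) + "\n")
        for c, size in m.bins.chrom_sizes.items():
            fh.write(f"#chromsize\t{c}\t{size}\n")
        for (ca, cb), block in sorted(
                m.blocks.items(),
                key=lambda kv: (m.bins.offset(kv[0][0]), m.bins.offset(kv[0][1]))):
            rows, cols = np.nonzero(~np.isnan(block) & (block != 0))
            for i, j in zip(rows, cols):
                if ca == cb and i > j:
                    continue  # symmetric storage: upper triangle only
                v = block[i, j]
                txt = str(int(v)) if float(v).is_integer() else repr(float(v))
                fh.write(f"{ca}\t{i}\t{cb}\t{j}\t{txt}\n")


def read_matrix(path) -> ContactMatrix:
    """Read the sparse COO text format written by :func:`write_matrix`."""
    sizes: dict = {}
    resolution = None
    kind = "counts"
    excluded: frozenset | None = None
    entries = []
    with _open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t")
                if parts[0] == "resolution":
                    resolution = int(parts[1])
                elif parts[0] == "kind":
                    kind = parts[1]
                elif parts[0] == "chromsize":
                    sizes[parts[1]] = int(parts[2])
                elif parts[0] == "excluded":
                    excluded = frozenset(x for x in parts[1].split(",") if x)
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise MatrixFormatError(f"{path}:{ln}: expected 5 fields, "
                                        f"got {len(parts)}")
            try:
                ca, ia, cb, ib = parts[0], int(parts[1]), parts[2], int(parts[3])
                v = float(parts[4])
            except ValueError as e:
                raise MatrixFormatError(f"{path}:{ln}: {e}") from None
            if v < 0:
                raise MatrixFormatError(f"{path}:{ln}: negative count {v}")
            entries.append((ca, ia, cb, ib, v, ln))
    if resolution is None or not sizes:
        raise MatrixFormatError(f"{path}: missing #resolution/#chromsize header")
    bins = bin_genome(sizes, resolution,
                      excluded if excluded is not None else frozenset())
    order = {c: i for i, c in enumerate(bins.chroms)}
    blocks: dict = {}
    for ca, ia, cb, ib, v, ln in entries:
        if ca not in order or cb not in order:
            raise MatrixFormatError(f"{path}:{ln}: unknown chromosome in entry")
        if order[ca] > order[cb]:
            ca, cb, ia, ib = cb, ca, ib, ia
        key = (ca, cb)
        if key not in blocks:
            blocks[key] = np.zeros((bins.n_bins(ca), bins.n_bins(cb)))
        try:
            blocks[key][ia, ib] = v
            if ca == cb and ia != ib:
                blocks[key][ib, ia] = v  # mirror
        except IndexError:
            raise MatrixFormatError(f"{path}:{ln}: bin index out of range") from None
    return ContactMatrix(bins, blocks, kind=kind)


def read_cool(path) -> ContactMatrix:
    """Read a single-resolution ``.cool`` file (HDF5) into a ContactMatrix.

    Only the standard groups (chroms, bins, pixels) are consumed; weights
    and metadata are ignored. No chromosome is excluded, so bin ids map
    one-to-one onto the file's bin table.
    """
    import h5py

    with h5py.File(path, "r") as f:
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in f["chroms/name"][:]]
        lengths = [int(x) for x in f["chroms/length"][:]]
        resolution = int(f.attrs["bin-size"])
        bin1 = np.asarray(f["pixels/bin1_id"][:], dtype=np.int64)
        bin2 = np.asarray(f["pixels/bin2_id"][:], dtype=np.int64)
        count = np.asarray(f["pixels/count"][:], dtype=float)
    bins = bin_genome(dict(zip(names, lengths)), resolution, excluded=())
    blocks: dict = {}
    for b1, b2, v in zip(bin1, bin2, count):
        ca, ia = bins.chrom_of_global(int(b1))
        cb, ib = bins.chrom_of_global(int(b2))
        key = (ca, cb)
        if key not in blocks:
            blocks[key] = np.zeros((bins.n_bins(ca), bins.n_bins(cb)))
        blocks[key][ia, ib] = v
        if ca == cb and ia != ib:
            blocks[key][ib, ia] = v
    return ContactMatrix(bins, blocks, kind="counts")
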