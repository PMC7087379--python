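"""Synthetic Hi-C data: backbone maps, matrix-level translocations,
biased CNV coverage and chimeric read pairs.

The backbone emulates the two dominant features of a normal Hi-C map:
power-law distance decay within chromosomes (expected count
``scale * (|i-j|+1)**-decay``) and a weak uniform inter-chromosomal
background. Translocations are simulated at the matrix level by relocating
contact expectations under the coordinate rearrangement implied by the
fusion: a balanced exchange moves the broken intra-chromosomal contacts
into two diagonally opposite inter-chromosomal quadrants (the "butterfly"),
an unbalanced fusion paints a single quadrant. Everything is seeded and
bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .genome import GenomeBins, bin_genome
from .matrix import ContactMatrix, CoverageProfile
from .pairs import AMBIGUOUS, AlignedSegment, Clip, ReadPair
from .cnv import BiasCovariates

log = logging.getLogger(__name__)

CHIMERA_SPREAD = 50_000  # primary alignments fall within +-50 kb of the breakpoint


def humanlike_chrom_sizes(n_chroms: int = 22, largest: int = 100_000_000,
                          smallest: int = 45_000_000,
                          resolution: int = 1_000_000) -> dict:
    """Chromosome sizes linearly spaced from ``largest`` down to
    ``smallest`` (rounded to whole bins), named chr1..chrN."""
    sizes = np.linspace(largest, smallest, n_chroms)
    return {f"chr{i + 1}": int(round(s / resolution)) * resolution
            for i, s in enumerate(sizes)}


@dataclass
class SyntheticGenomeSpec:
    """Parameters of the synthetic Hi-C backbone."""

    chrom_sizes: Mapping[str, int]
    resolution: int = 1_000_000
    intra_decay_exponent: float = 1.0
    intra_scale: float = 1000.0
    inter_rate: float = 20.0
    noise: bool = True  # Poisson-sample the expectations
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.chrom_sizes.values()):
            raise ValueError("chromosome sizes must be > 0")
        if self.intra_scale < 0 or self.inter_rate < 0:
            raise ValueError("rates must be >= 0")

    def make_bins(self) -> GenomeBins:
        return bin_genome(self.chrom_sizes, self.resolution)


@dataclass
class TranslocationSpec:
    """One engineered interchromosomal translocation."""

    chromA: str
    posA: int
    chromB: str
    posB: int
    balanced: bool = False
    zygosity: str = "homozygous"  # homozygous | heterozygous

    def __post_init__(self) -> None:
        if self.chromA == self.chromB:
            raise ValueError("translocation must join two distinct chromosomes")
        if self.zygosity not in ("homozygous", "heterozygous"):
            raise ValueError(f"bad zygosity {self.zygosity!r}")


@dataclass
class TranslocationTruth:
    """Bin-level truth record for a simulated translocation."""

    chromA: str
    binA: int
    posA: int
    chromB: str
    binB: int
    posB: int
    balanced: bool
    zygosity: str


def _decay(spec: SyntheticGenomeSpec, d: np.ndarray) -> np.ndarray:
    return spec.intra_scale * (np.abs(d) + 1.0) ** (-spec.intra_decay_exponent)


def synth_backbone(spec: SyntheticGenomeSpec) -> ContactMatrix:
    """Expected (noise=False) or Poisson-sampled (noise=True) backbone map."""
    bins = spec.make_bins()
    rng = np.random.default_rng(spec.seed)
    blocks = {}
    chroms = bins.chroms
    for ai, ca in enumerate(chroms):
        na = bins.n_bins(ca)
        i = np.arange(na)
        blocks[(ca, ca)] = _decay(spec, i[:, None] - i[None, :])
        for cb in chroms[ai + 1:]:
            blocks[(ca, cb)] = np.full((na, bins.n_bins(cb)), spec.inter_rate)
    m = ContactMatrix(bins, blocks, kind="counts")
    if spec.noise:
        m = poisson_sample(m, rng)
    return m


def poisson_sample(m: ContactMatrix, rng) -> ContactMatrix:
    """Poisson-sample a matrix of expectations, keeping intra blocks
    symmetric (upper triangle sampled, mirrored)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    blocks = {}
    for (ca, cb), exp in m.blocks.items():
        draw = rng.poisson(np.nan_to_num(exp, nan=0.0)).astype(float)
        if ca == cb:
            draw = np.triu(draw) + np.triu(draw, 1).T
        blocks[(ca, cb)] = draw
    return ContactMatrix(m.bins, blocks, kind="counts")


# -- translocation rearrangement ------------------------------------------


def _diag_mean(M: np.ndarray, d: int) -> float:
    """Mean of the d-th superdiagonal of an intra block, clamped to the
    largest available separation; the source of fallback contact levels."""
    d = min(abs(int(d)), M.shape[0] - 1)
    return float(np.mean(np.diagonal(M, offset=d)))


def simulate_translocation(m: ContactMatrix, t: TranslocationSpec) -> tuple:
    """Plant one interchromosomal translocation in a contact map.

    Breakpoints snap to bin boundaries. The derivative chromosome
    ``A[:ia] + B[ib:]`` places its fused-neighbourhood contacts in the
    inter-block quadrant (rows < ia, cols >= ib); a balanced exchange adds
    the reciprocal derivative's quadrant (rows >= ia, cols < ib) and
    downgrades the broken intra-chromosomal contacts to inter-chromosomal
    background. Unbalanced events are modelled as a gained derivative on
    top of intact homologs, so only the one quadrant changes. Heterozygous
    output is the cell-wise mean of the original and the homozygous
    rearrangement. Returns ``(matrix, truth)``.
    """
    bins = m.bins
    for c in (t.chromA, t.chromB):
        if c not in bins.chroms:
            raise ValueError(f"breakpoint on excluded/unknown chromosome {c}")
    order = {c: i for i, c in enumerate(bins.chroms)}
    ca, cb = t.chromA, t.chromB
    posA, posB = t.posA, t.posB
    if order[ca] > order[cb]:  # canonical orientation
        ca, cb, posA, posB = cb, ca, posB, posA
    ia, ib = bins.bin_index(ca, posA), bins.bin_index(cb, posB)
    na, nb = bins.n_bins(ca), bins.n_bins(cb)
    A = m.block(ca, ca)
    B = m.block(cb, cb)
    AB = m.block(ca, cb).copy()
    inter_level = float(np.nanmean(m.block(ca, cb)))
    newA, newB = A.copy(), B.copy()

    # derivative A[:ia] + B[ib:] -> quadrant rows < ia, cols >= ib
    for k in range(nb - ib):
        src = ia + k
        if src < na:
            AB[:ia, ib + k] = A[:ia, src]
        else:
            d = (ia - np.arange(ia)) + k  # derivative distance in bins
            AB[:ia, ib + k] = [_diag_mean(B, dd) for dd in d]
    if t.balanced:
        # reciprocal derivative B[:ib] + A[ia:] -> quadrant rows >= ia, cols < ib
        for mm in range(na - ia):
            src = ib + mm
            if src < nb:
                AB[ia + mm, :ib] = B[:ib, src]
            else:
                d = (ib - np.arange(ib)) + mm
                AB[ia + mm, :ib] = [_diag_mean(A, dd) for dd in d]
        # broken intra contacts become trans: background level
        newA[:ia, ia:] = inter_level
        newA[ia:, :ia] = inter_level
        newB[:ib, ib:] = inter_level
        newB[ib:, :ib] = inter_level

    out = m.copy()
    out.set_block(ca, cb, AB)
    out.set_block(ca, ca, newA)
    out.set_block(cb, cb, newB)
    if t.zygosity == "heterozygous":
        mixed = m.copy()
        for key in ((ca, cb), (ca, ca), (cb, cb)):
            mixed.set_block(*key, 0.5 * m.block(*key) + 0.5 * out.block(*key))
        out = mixed
    truth = TranslocationTruth(t.chromA, bins.bin_index(t.chromA, t.posA), t.posA,
                               t.chromB, bins.bin_index(t.chromB, t.posB), t.posB,
                               t.balanced, t.zygosity)
    return out, truth


def random_translocations(bins: GenomeBins, n: int, rng,
                          balanced_frac: float = 0.5,
                          het_frac: float = 0.5,
                          margin: float = 0.2) -> list:
    """Draw ``n`` translocations on distinct chromosome pairs with
    breakpoints in the central (1 - 2*margin) span of each chromosome,
    cycling through all four balanced x zygosity combinations."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    pairs = [(a, b) for i, a in enumerate(bins.chroms)
             for b in bins.chroms[i + 1:]]
    if n > len(pairs):
        raise ValueError(f"cannot place {n} translocations on {len(pairs)} "
                         "distinct chromosome pairs")
    chosen = rng.choice(len(pairs), size=n, replace=False)
    combos = [(False, "homozygous"), (False, "heterozygous"),
              (True, "homozygous"), (True, "heterozygous")]
    out = []
    for j, idx in enumerate(chosen):
        ca, cb = pairs[idx]
        la, lb = bins.chrom_sizes[ca], bins.chrom_sizes[cb]
        posA = int(rng.integers(int(margin * la), int((1 - margin) * la)))
        posB = int(rng.integers(int(margin * lb), int((1 - margin) * lb)))
        bal, zyg = combos[j % len(combos)]
        out.append(TranslocationSpec(ca, posA, cb, posB, bal, zyg))
    return out


def simulate_study(spec: SyntheticGenomeSpec, translocations: Iterable,
                   n_background: int = 5) -> tuple:
    """Full simulation: translocated sample, background and truth set.

    The sample is built by planting every translocation in the noiseless
    backbone expectation and Poisson-sampling once; the background is the
    average of ``n_background`` independent Poisson replicate libraries of
    the *unmodified* backbone (the normal-cell panel). Returns
    ``(sample, background, truths)``.
    """
    from .matrix import build_background

    base = synth_backbone(SyntheticGenomeSpec(
        dict(spec.chrom_sizes), spec.resolution, spec.intra_decay_exponent,
        spec.intra_scale, spec.inter_rate, noise=False, seed=spec.seed))
    truths = []
    sample_exp = base
    for t in translocations:
        sample_exp, truth = simulate_translocation(sample_exp, t)
        truths.append(truth)
    rng = np.random.default_rng(spec.seed)
    sample = poisson_sample(sample_exp, rng) if spec.noise else sample_exp
    replicates = [poisson_sample(base, rng) if spec.noise else base
                  for _ in range(n_background)]
    background = build_background(replicates)
    return sample, background, truths


# -- CNV coverage ----------------------------------------------------------


def default_gc_effect(gc: np.ndarray) -> np.ndarray:
    """Unimodal GC bias on the log scale, peaking near GC = 0.45."""
    return -6.0 * (np.asarray(gc) - 0.45) ** 2


def random_covariates(bins: GenomeBins, seed: int = 0) -> BiasCovariates:
    """Plausible random covariate tracks: GC around 0.42, mappability high
    with a low-mappability tail, restriction-site counts ~ Poisson(8)."""
    rng = np.random.default_rng(seed)
    n = bins.n_total
    gc = np.clip(rng.normal(0.42, 0.06, n), 0.25, 0.65)
    mapp = np.clip(rng.beta(8, 1.2, n), 0.0, 1.0)
    sites = rng.poisson(8.0, n).astype(float)
    return BiasCovariates(bins, gc, mapp, sites)


def simulate_cnv_coverage(bins: GenomeBins, covariates: BiasCovariates,
                          segments: Iterable = (), base_rate: float = 400.0,
                          seed: int = 0, gc_effect=default_gc_effect) -> tuple:
    """Poisson 1D coverage with known biases and piecewise copy ratios.

    ``segments`` is an iterable of ``((chrom, start, end), copy_ratio)``;
    copy ratio defaults to 1 elsewhere. Expected coverage is
    ``base_rate * ratio * exp(gc_effect(gc)) * mappability * sites/mean``.
    Returns ``(CoverageProfile, ratio_truth array)``.
    """
    rng = np.random.default_rng(seed)
    ratio = np.ones(bins.n_total)
    for (chrom, start, end), r in segments:
        i0 = bins.bin_index(chrom, start)
        i1 = bins.bin_index(chrom, min(end, bins.chrom_sizes[chrom]) - 1)
        off = bins.offset(chrom)
        ratio[off + i0: off + i1 + 1] = r
    sites = covariates.n_restriction_sites
    site_factor = np.where(sites > 0, sites / max(sites.mean(), 1e-9), 0.0)
    mu = (base_rate * ratio * np.exp(gc_effect(covariates.gc))
          * covariates.mappability * site_factor)
    values = rng.poisson(mu).astype(float)
    return CoverageProfile(bins, values), ratio


# -- chimeric reads --------------------------------------------------------


def generate_chimeric_reads(t: TranslocationSpec, n: int, read_len: int = 100,
                            seed: int = 0, jitter: int = 0,
                            clip_len: int = 30) -> list:
    """Ambiguous chimeric read pairs spanning a translocation breakpoint.

    Each pair's end1 is split: the primary alignment ends exactly at
    ``posA`` (right-clipped, ``clip_len`` bp) and the clipped part maps at
    ``posB`` on the partner chromosome (plus optional jitter); the mate
    maps near ``posA`` on the same chromosome, which makes the pair an
    ambiguous chimera. refine_breakpoint on the output recovers
    ``(posA, posB)`` exactly when jitter is 0.
    """
    rng = np.random.default_rng(seed)
    aln_len = read_len - clip_len
    out = []
    for i in range(n):
        dx = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        dy = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        bpA, bpB = t.posA + dx, t.posB + dy
        primary = AlignedSegment(
            f"chimera_{t.chromA}_{t.chromB}_{i}", t.chromA,
            bpA - aln_len, "+", mapq=60,
            clip=Clip("right", clip_len, mapped_to=(t.chromB, bpB)),
            aln_len=aln_len)
        # keep the mate clear of the split loci so the pair stays ambiguous
        mate_pos = bpA
        while abs(mate_pos - bpA) < 2000:
            mate_pos = int(rng.integers(max(bpA - CHIMERA_SPREAD, 0),
                                        bpA + CHIMERA_SPREAD))
        mate = AlignedSegment(primary.read_id, t.chromA, mate_pos, "-",
                              mapq=60, aln_len=read_len)
        out.append(ReadPair([primary], [mate], pair_class=AMBIGUOUS))
    return out


def score_calls_against_truth(calls: Iterable, truths: Iterable[TranslocationTruth]) -> tuple:
    """Count recovered translocations and spurious calls.

    A planted translocation is recovered when some call names its
    chromosome pair and both reported breakpoint regions contain the
    planted breakpoint coordinates. Every call that matches no planted
    event this way is spurious. Returns ``(n_recovered, n_spurious)``.
    """
    truths = list(truths)
    matched = set()
    n_spurious = 0
    for c in calls:
        hit = False
        for i, t in enumerate(truths):
            if ((c.chromA, c.chromB) == (t.chromA, t.chromB)
                    and t.posA in c.regionA and t.posB in c.regionB):
                matched.add(i)
                hit = True
        if not hit:
            n_spurious += 1
    return len(matched), n_spurious


def write_truth_bedpe(truths: Iterable[TranslocationTruth], bins: GenomeBins,
                      path) -> None:
    """Truth set as BEDPE of the breakpoint bins."""
    with open(path, "w") as fh:
        for i, t in enumerate(truths, 1):
            a0, a1 = bins.bin_bounds(t.chromA, t.binA)
            b0, b1 = bins.bin_bounds(t.chromB, t.binB)
            kind = "balanced" if t.balanced else "unbalanced"
            fh.write(f"{t.chromA}\t{a0}\t{a1}\t{t.chromB}\t{b0}\t{b1}\t"
                     f"truth_{i}\t{t.posA}\t{t.posB}\t{kind}\t{t.zygosity}\n")
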