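"""Hi-C read-pair classification and contact-matrix construction.

Read pairs from a Hi-C library fall into four classes:

* **normal** — both ends map uniquely to single loci; valid.
* **unambiguous chimera** — one end is split across the ligation junction
  (mapping to locus A and locus B) while the mate maps uniquely to locus B;
  a normal product of Hi-C ligation, also valid.
* **ambiguous chimera** — any other split-read configuration (e.g. split
  A/C with the mate at B). Often caused by structural variation; excluded
  from the matrix but retained for base-pair breakpoint refinement.
* **discarded** — any end unmapped, multi-mapped or PCR-duplicate flagged.

"Maps to locus B" is decided with a ``join_window`` tolerance (default
1 kb), far below any analysis bin size.
"""

from __future__ import annotations

import logging
from collections import Counter, OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome import GenomeBins, GenomeError
from .matrix import ContactMatrix

log = logging.getLogger(__name__)

JOIN_WINDOW = 1000

NORMAL = "normal"
UNAMBIGUOUS = "unambiguous_chimera"
AMBIGUOUS = "ambiguous_chimera"
DISCARDED = "discarded"

PAIR_CLASSES = (NORMAL, UNAMBIGUOUS, AMBIGUOUS, DISCARDED)


@dataclass
class Clip:
    """Soft-clip on an aligned segment; ``mapped_to`` is where the clipped
    sequence itself aligns, when known."""

    side: str  # "left" | "right"
    length: int
    mapped_to: tuple | None = None  # (chrom, pos)

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"clip side must be left/right, got {self.side!r}")
        if self.length < 0:
            raise ValueError("clip length must be >= 0")


@dataclass
class AlignedSegment:
    """One alignment record of one read end (SAM-like, minimal fields)."""

    read_id: str
    chrom: str
    pos: int  # 0-based leftmost
    strand: str = "+"
    mapq: int = 60
    is_primary: bool = True
    clip: Clip | None = None
    is_duplicate: bool = False
    is_unmapped: bool = False
    is_multimapped: bool = False
    aln_len: int | None = None  # aligned reference span, bp

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("pos must be >= 0")

    @property
    def is_split(self) -> bool:
        return self.clip is not None and self.clip.mapped_to is not None

    def loci(self) -> list:
        """All loci this end touches: primary plus clipped-part mapping."""
        out = [(self.chrom, self.pos)]
        if self.is_split:
            out.append(self.clip.mapped_to)
        return out

    def clip_boundary(self) -> int:
        """Breakpoint coordinate implied by the clip on the primary chrom:
        the reference position where the alignment is cut."""
        if self.clip is None:
            raise ValueError("segment has no clip")
        if self.clip.side == "right":
            if self.aln_len is None:
                raise ValueError("aln_len required for a right clip boundary")
            return self.pos + self.aln_len
        return self.pos


@dataclass
class ReadPair:
    end1: list
    end2: list
    pair_class: str | None = None

    def __post_init__(self) -> None:
        if not self.end1 or not self.end2:
            raise ValueError("both ends of a read pair must be present")

    @property
    def read_id(self) -> str:
        return self.end1[0].read_id


def _end_loci(end: Sequence[AlignedSegment]) -> list:
    loci = []
    for seg in end:
        loci.extend(seg.loci())
    # dedupe, keep order
    seen, out = set(), []
    for l in loci:
        if l not in seen:
            seen.add(l)
            out.append(l)
    return out


def _end_is_split(end: Sequence[AlignedSegment]) -> bool:
    return len(_end_loci(end)) > 1


def _near(a: tuple, b: tuple, window: int) -> bool:
    return a[0] == b[0] and abs(a[1] - b[1]) <= window


def classify_pair(p: ReadPair, join_window: int = JOIN_WINDOW) -> str:
    """Assign one of the four pair classes (total function).

    The class is also stored on the pair.
    """
    segs = list(p.end1) + list(p.end2)
    if any(s.is_unmapped or s.is_multimapped or s.is_duplicate for s in segs):
        p.pair_class = DISCARDED
        return DISCARDED
    split1, split2 = _end_is_split(p.end1), _end_is_split(p.end2)
    if not split1 and not split2:
        p.pair_class = NORMAL
        return NORMAL
    if split1 != split2:
        split_loci = _end_loci(p.end1 if split1 else p.end2)
        mate_locus = _end_loci(p.end2 if split1 else p.end1)[0]
        if len(split_loci) == 2 and any(_near(mate_locus, l, join_window)
                                        for l in split_loci):
            p.pair_class = UNAMBIGUOUS
            return UNAMBIGUOUS
    p.pair_class = AMBIGUOUS
    return AMBIGUOUS


def _dedup_key(p: ReadPair) -> tuple:
    a = p.end1[0]
    b = p.end2[0]
    ka = (a.chrom, a.pos, a.strand)
    kb = (b.chrom, b.pos, b.strand)
    return (ka, kb) if ka <= kb else (kb, ka)


def select_valid_pairs(pairs: Iterable[ReadPair],
                       join_window: int = JOIN_WINDOW) -> tuple:
    """Split classified pairs into (valid, ambiguous).

    Valid = normal + unambiguous chimeras, after removal of PCR duplicates
    (identical 5' positions/strands of both ends; first occurrence kept).
    Ambiguous chimeras are returned separately for breakpoint refinement;
    discarded pairs are dropped. Class counts are logged.
    """
    valid, ambiguous = [], []
    counts: Counter = Counter()
    seen = set()
    for p in pairs:
        cls = p.pair_class or classify_pair(p, join_window)
        counts[cls] += 1
        if cls in (NORMAL, UNAMBIGUOUS):
            key = _dedup_key(p)
            if key in seen:
                counts["duplicate_removed"] += 1
                continue
            seen.add(key)
            valid.append(p)
        elif cls == AMBIGUOUS:
            ambiguous.append(p)
    log.info("pair classes: %s", dict(counts))
    return valid, ambiguous


def representative_loci(p: ReadPair) -> tuple:
    """One (chrom, pos) per end for matrix assignment: the unique 5' mapped
    position of each end's primary segment."""
    return ((p.end1[0].chrom, p.end1[0].pos), (p.end2[0].chrom, p.end2[0].pos))


def pairs_to_matrix(valid: Iterable[ReadPair], bins: GenomeBins) -> ContactMatrix:
    """Build a contact-count matrix from valid pairs.

    Each pair contributes exactly one count, so total matrix mass equals the
    number of pairs. A locus on an unknown (or excluded) chromosome, or
    outside it, raises :class:`GenomeError`.
    """
    blocks: dict = {}
    order = {c: i for i, c in enumerate(bins.chroms)}
    n = 0
    for p in valid:
        (ca, pa), (cb, pb) = representative_loci(p)
        ia, ib = bins.bin_index(ca, pa), bins.bin_index(cb, pb)
        if order[ca] > order[cb] or (ca == cb and ia > ib):
            ca, cb, ia, ib = cb, ca, ib, ia
        key = (ca, cb)
        if key not in blocks:
            blocks[key] = np.zeros((bins.n_bins(ca), bins.n_bins(cb)))
        blocks[key][ia, ib] += 1
        if ca == cb and ia != ib:
            blocks[key][ib, ia] += 1  # symmetric storage
        n += 1
    m = ContactMatrix(bins, blocks, kind="counts")
    log.info("matrix built from %d valid pairs", n)
    return m


# -- text table I/O --------------------------------------------------------

_TABLE_COLS = ("read_id chrom1 pos1 strand1 chrom2 pos2 strand2 class "
               "clip_chrom clip_pos clip_side clip_len aln_len").split()


def write_pairs_table(pairs: Iterable[ReadPair], path) -> None:
    """Write classified pairs as a tab-separated table.

    The last five columns carry the clipped-segment mapping and aligned
    span of end1's primary alignment (``.`` when absent); refinement of
    translocation breakpoints needs them for ambiguous chimeras.
    """
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_TABLE_COLS) + "\n")
        for p in pairs:
            a, b = p.end1[0], p.end2[0]
            if a.is_split:
                cc, cp = a.clip.mapped_to
                clip_cols = [cc, str(cp), a.clip.side, str(a.clip.length),
                             "." if a.aln_len is None else str(a.aln_len)]
            else:
                clip_cols = [".", ".", ".", ".", "."]
            fh.write("\t".join([p.read_id, a.chrom, str(a.pos), a.strand,
                                b.chrom, str(b.pos), b.strand,
                                p.pair_class or "unclassified", *clip_cols]) + "\n")


def read_pairs_table(path) -> list:
    """Read the table written by :func:`write_pairs_table`."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}:{ln}: expected >= 8 columns")
            (rid, c1, p1, s1, c2, p2, s2, cls) = parts[:8]
            clip = None
            aln_len = None
            if len(parts) >= 12 and parts[8] != ".":
                clip = Clip(side=parts[10], length=int(parts[11]),
                            mapped_to=(parts[8], int(parts[9])))
                if len(parts) >= 13 and parts[12] != ".":
                    aln_len = int(parts[12])
            a = AlignedSegment(rid, c1, int(p1), s1, clip=clip,
                               aln_len=aln_len)
            b = AlignedSegment(rid, c2, int(p2), s2)
            pair = ReadPair([a], [b], pair_class=cls if cls in PAIR_CLASSES else None)
            out.append(pair)
    return out


# -- SAM input -------------------------------------------------------------


def _clip_from_cigar(rec) -> Clip | None:
    """Largest soft/hard clip of a pysam record, with the SA-tag mapping of
    the clipped part when available."""
    cig = rec.cigartuples
    if not cig:
        return None
    left = cig[0][1] if cig[0][0] in (4, 5) else 0
    right = cig[-1][1] if cig[-1][0] in (4, 5) else 0
    if max(left, right) == 0:
        return None
    side = "left" if left >= right else "right"
    mapped_to = None
    if rec.has_tag("SA"):
        sa = rec.get_tag("SA").split(";")[0].split(",")
        mapped_to = (sa[0], int(sa[1]) - 1)  # SA tag is 1-based
    return Clip(side=side, length=max(left, right), mapped_to=mapped_to)


def read_sam_pairs(path, min_mapq_unique: int = 1) -> list:
    """Group a name-sorted SAM/BAM file into :class:`ReadPair` objects.

    A record with ``mapq == 0`` (below ``min_mapq_unique``) is treated as
    multi-mapped, matching BWA-MEM conventions. Secondary alignments are
    taken as evidence of multi-mapping; supplementary alignments mark
    chimeric (split) reads and are folded into the primary segment's clip.
    """
    import pysam

    groups: "OrderedDict[str, dict]" = OrderedDict()
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            g = groups.setdefault(rec.query_name, {1: [], 2: []})
            end = 1 if rec.is_read1 or not rec.is_read2 else 2
            if rec.is_unmapped:
                seg = AlignedSegment(rec.query_name, rec.reference_name or "*",
                                     max(rec.reference_start, 0),
                                     is_unmapped=True)
                g[end].append(seg)
                continue
            if rec.is_supplementary:
                continue  # represented via the primary's SA tag
            seg = AlignedSegment(
                rec.query_name, rec.reference_name, rec.reference_start,
                "-" if rec.is_reverse else "+", rec.mapping_quality,
                is_primary=not rec.is_secondary,
                clip=_clip_from_cigar(rec),
                is_duplicate=rec.is_duplicate,
                is_multimapped=(rec.mapping_quality < min_mapq_unique
                                or rec.is_secondary),
                aln_len=rec.reference_length)
            g[end].append(seg)
    pairs = []
    for rid, g in groups.items():
        if g[1] and g[2]:
            pairs.append(ReadPair(g[1], g[2]))
        else:
            log.debug("read %s lacks one end; skipped", rid)
    return pairs
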