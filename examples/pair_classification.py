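"""Classify Hi-C read pairs and build a contact matrix.

Hi-C libraries contain normal pairs, chimeric reads crossing the ligation
junction (unambiguous chimeras, still valid) and other split-read
configurations (ambiguous chimeras, often SV-derived). Valid pairs feed
the contact matrix; ambiguous chimeras are kept for breakpoint refinement.
"""

from hicsv import (AlignedSegment, Clip, ReadPair, bin_genome,
                   pairs_to_matrix, select_valid_pairs)

pairs = [
    # a normal pair: both ends unique
    ReadPair([AlignedSegment("n1", "chr1", 10_000)],
             [AlignedSegment("n1", "chr1", 75_000)]),
    # ligation-junction chimera: end1 split chr1/chr2, mate at the same
    # chr2 locus -> unambiguous, valid
    ReadPair([AlignedSegment("u1", "chr1", 20_000, aln_len=70,
                             clip=Clip("right", 30, ("chr2", 40_000)))],
             [AlignedSegment("u1", "chr2", 40_200)]),
    # SV-flavoured chimera: mate maps elsewhere -> ambiguous
    ReadPair([AlignedSegment("a1", "chr1", 30_000, aln_len=70,
                             clip=Clip("right", 30, ("chr2", 90_000)))],
             [AlignedSegment("a1", "chr1", 35_000)]),
    # PCR duplicate of the first pair
    ReadPair([AlignedSegment("d1", "chr1", 10_000)],
             [AlignedSegment("d1", "chr1", 75_000)]),
]

valid, ambiguous = select_valid_pairs(pairs)
print(f"{len(valid)} valid pairs, {len(ambiguous)} ambiguous chimeras "
      f"(kept for breakpoint refinement)")

bins = bin_genome({"chr1": 100_000, "chr2": 100_000}, 50_000)
m = pairs_to_matrix(valid, bins)
print(f"matrix mass = {m.mass():.0f} (one count per valid pair)")
print("chr1 intra block:\n", m.block("chr1", "chr1"))
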