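"""Refine a rough translocation call to single base-pair resolution.

Ambiguous chimeric read pairs whose primary alignment stops exactly at
the breakpoint (soft-clipped) and whose clipped part maps to the partner
chromosome pin the fusion coordinates. Five synthetic chimeras are
generated for a planted event; the modal clip boundary recovers the
breakpoint exactly.
"""

from hicsv import (BreakpointRegion, TranslocationCall,
                   generate_chimeric_reads, refine_breakpoint)
from hicsv.simulate import TranslocationSpec

event = TranslocationSpec("chr3", 31_415_926, "chr5", 27_182_818)
rough = TranslocationCall(
    "chr3", "chr5",
    BreakpointRegion("chr3", 31_400_000, 31_500_000),
    BreakpointRegion("chr5", 27_100_000, 27_200_000, "column"),
    "unbalanced")

chimeras = generate_chimeric_reads(event, 5, seed=1)
call = refine_breakpoint(rough, chimeras)
print(f"supporting chimeras: {call.n_support_chimeras}")
print(f"refined breakpoint: {call.regionA.chrom}:{call.refined[0]:,} <-> "
      f"{call.regionB.chrom}:{call.refined[1]:,}")
print(f"planted breakpoint: {event.chromA}:{event.posA:,} <-> "
      f"{event.chromB}:{event.posB:,}")
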