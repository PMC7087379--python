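"""Copy-number calling from bias-corrected Hi-C 1D coverage.

Simulates 2000 bins of 50 kb coverage with a known GC bias, a 40-bin
copy gain (log2 ratio +1) and a 60-bin loss (log2 ratio -1), then runs
the Poisson GAM bias regression and BIC-penalized segmentation. The
printed segment means should sit near +1/-1 with breakpoints within a
couple of bins of the planted ones.
"""

from hicsv import (bin_genome, fit_bias_model, residuals_to_log2ratio,
                   segment_profile)
from hicsv.simulate import random_covariates, simulate_cnv_coverage

bins = bin_genome({"chr1": 100_000_000}, 50_000)
covariates = random_covariates(bins, seed=3)
spikes = [(("chr1", 10_000_000, 12_000_000), 2.0),   # gain, log2 = +1
          (("chr1", 60_000_000, 63_000_000), 0.5)]   # loss, log2 = -1
coverage, _ = simulate_cnv_coverage(bins, covariates, spikes, seed=4)

fit = fit_bias_model(coverage, covariates)
print(f"bias model deviance explained: {fit.fit_quality:.3f}")

segments = segment_profile(residuals_to_log2ratio(fit))
print(f"{len(segments)} segments:")
for s in segments:
    print(f"  {s.chrom}:{s.start // 10**6}-{s.end // 10**6} Mb  "
          f"mean log2 {s.mean_log2_ratio:+.3f}  {s.call}")
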