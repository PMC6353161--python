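"""Find Gabriel haplotype blocks inside a simulated LD-block span.

The simulator injects spans where genotypes come from a small pool of
haplotype templates; the confidence-interval block finder should recover a
block over that span, and the EM haplotype frequencies should match the
template frequencies.
"""

import numpy as np

from divscan import gabriel_blocks, six_breed_preset, simulate_panel
from divscan.ld import blocks_frame

markers, samples, genotypes, truth = simulate_panel(six_breed_preset(seed=2019))

blk = truth.ld_blocks[0]  # injected span on chromosome 2
lo, hi = blk["start_bp"], blk["stop_bp"]
print(f"injected LD block: chrom {blk['chrom']} {lo:,}-{hi:,} "
      f"(template freqs {blk['template_freqs']})")

breed_rows = samples.indices_of("HC")
cols = np.flatnonzero(
    (markers.chrom == blk["chrom"])
    & (markers.pos_bp >= lo - 100_000) & (markers.pos_bp <= hi + 100_000)
)
sub = genotypes.subset(sample_idx=breed_rows, snp_idx=cols)
blocks = gabriel_blocks(sub.markers, sub)
print(blocks_frame(blocks).to_string(index=False))
# The recovered block spans the injected markers and its most common
# haplotype frequency approximates the leading template frequency.
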