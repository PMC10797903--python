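"""Build a prior network from TF binding peaks and gene annotations.

A peak (by its midpoint) is linked to a gene when it falls in the
strand-oriented window 50 kb upstream to 2 kb downstream of the TSS and
no other gene body lies between the peak and the TSS; signal values are
summed per (gene, TF) and each TF column is sparsified to its strongest
entries.
"""

import pandas as pd

import primegrn as pg

genes = pd.DataFrame(
    {
        "chromosome": ["chr1", "chr1", "chr2"],
        "tss": [115_000, 160_000, 40_000],
        "strand": ["+", "+", "-"],
        "start": [115_000, 160_000, 30_000],
        "end": [125_000, 170_000, 40_000],
    },
    index=["gA", "gB", "gC"],
)

peaks = [
    pg.PeakRecord("chr1", 98_900, 99_100, "TF1", 7.5),   # 16 kb upstream of gA
    pg.PeakRecord("chr1", 112_000, 112_400, "TF2", 2.0),  # gA blocks gB here
    pg.PeakRecord("chr1", 158_500, 158_700, "TF1", 3.0),  # 1.4 kb upstream of gB
    pg.PeakRecord("chr2", 41_000, 41_200, "TF2", 4.0),    # upstream on - strand
]

prior = pg.peaks_to_prior(peaks, genes)
print("summed-signal prior (genes x TFs):")
print(prior.to_frame())

sparse = pg.sparsify_prior(prior, keep_fraction_per_tf=0.34)
print("\nafter per-TF sparsification (strongest entry per TF kept):")
print(sparse.to_frame())
# TF2's chr1 peak links only to gA: gA's gene body sits between the peak
# and gB's TSS, so the more distal association is discarded.
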