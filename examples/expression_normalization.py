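"""Normalize a small count matrix: FPKM, per-gene Z-scores, sample correlation.

FPKM = 1e9 * C / (N * L) rescales a read count C by transcript length L (bp)
and library depth N; Z-scoring each gene row (mean 0, sd 1, n-1 denominator)
is what expression heat maps display; the sample correlation matrix is the
usual replicate-quality check.
"""

import numpy as np
import pandas as pd

import panicle as pn

counts = pn.ExpressionMatrix(
    values=pd.DataFrame(
        [[1000, 1200, 900, 400, 380, 420],
         [500, 520, 480, 800, 790, 810],
         [9_000_000, 8_000_000, 9_500_000, 9_200_000, 9_100_000, 8_900_000]],
        index=["flowering_gene", "stress_gene", "background"],
        columns=["DP1", "DP2", "DP3", "SP1", "SP2", "SP3"]),
    value_kind="counts")
lengths = {"flowering_gene": 2000, "stress_gene": 1500, "background": 3000}

fpkm = pn.compute_fpkm(counts, lengths)
print("FPKM (length- and depth-normalized expression):")
print(fpkm.values.round(2))

z, constant = pn.zscore_rows(fpkm)
print("\nRow Z-scores (what a heat map would display; each row mean 0, sd 1):")
print(z.values.round(2))

# correlate on Z-scores so highly expressed genes do not dominate
corr = pn.sample_correlation(z)
print("\nSample Pearson correlation (replicates of a condition should cluster):")
print(corr.round(3))
print("\nDP and SP replicates correlate within condition; the flowering gene's "
      "negative Z-scores in SP mark its drop under the aborting condition.")
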