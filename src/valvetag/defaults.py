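"""Analysis constants shared across modules.

All thresholds used by the pipeline live here so a configuration file can
override them in one place.
"""

#: Chastity-style quality filter threshold (Illumina convention).
CHASTITY_THRESHOLD = 0.6

#: A tag/gene is "expressed" in a library iff its raw count is > 5.
MIN_EXPRESSED_COUNT = 6

#: Fixed negative-binomial dispersion for the exact test (replicate-free design).
DISPERSION = 0.12

#: Significance level for differential-expression calls.
ALPHA = 0.05

#: Prior count added per library when computing fold changes.
PRIOR_COUNT = 0.5

#: Mismatch-collapse: a satellite tag is removed when a Hamming-1 parent has
#: count >= COLLAPSE_PARENT_MIN and count >= COLLAPSE_RATIO x satellite count.
COLLAPSE_RATIO = 100.0
COLLAPSE_PARENT_MIN = 1000

#: ChIP peak filtering.
PEAK_H_MIN = 10          # minimum peak height (FDR-derived default)
PEAK_H_HIGH = 30         # high-confidence peak height
PEAK_WINDOW = 400        # +/- window (bp) for local control statistics
PEAK_Z_MIN = 1.8         # local z-score threshold
PEAK_FOLD_MIN = 1.75     # ChIP/control fold-change threshold
PEAK_FDR = 0.01

#: Regulatory-domain (basal + extension) peak-to-gene association.
BASAL_UPSTREAM = 5_000
BASAL_DOWNSTREAM = 1_000
MAX_EXTENSION = 1_000_000
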