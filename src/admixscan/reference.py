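"""Reference constants from the published three-cohort African-American
application of this scan design (CARe, FBPP and WHI, genotyping-array local
ancestry in 400-kb bins over 22 autosomes).

These numbers are bookkeeping inputs for reproducing the published
multiple-testing arithmetic; nothing in the scan machinery depends on them.
"""

# Unrelated sample sizes after relatedness and ancestry-proportion filtering.
UNRELATED_COHORT_SIZES = {
    "CARe": 6238,
    "FBPP": 1864,
    "WHI": 8150,
}

# Cross-chromosome null-scale estimates reported per cohort.
COHORT_SIGMA_HAT = {
    "CARe": 0.015,
    "FBPP": 0.027,
    "WHI": 0.012,
}

# Effective number of independent within-chromosome pair tests across the
# 22 autosomes (Li-Ji effective bins, summed k_i * (k_i - 1) / 2).
TOTAL_INDEPENDENT_TESTS = 61_616


def total_unrelated_samples() -> int:
    """Summed unrelated cohort sizes used in the combined analysis."""
    return sum(UNRELATED_COHORT_SIZES.values())
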