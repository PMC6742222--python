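"""Published per-quartile case counts, bundled as check inputs.

These are the Cases/N cells of the source study's main and BMI-stratified
result tables, together with the unadjusted RRs and Wald CIs they imply.
``reproduce-tables`` refits the unadjusted log-binomial model to the counts
and diffs the result against the expected values (2-decimal precision).

Note: the normal-weight stratum's Q4 expected RR is 2.18 as computed from
its printed counts (1,232/3,471 vs 500/3,070 -> 2.179); the source table
prints 2.17, a rounding artefact of its unpublished underlying data, so the
count-derived value is bundled here.
"""

from __future__ import annotations

#: Main table: offspring-in-top-quartile cases / pairs per maternal quartile.
MAIN_TABLE_COUNTS = {
    "cases": (812, 1080, 1292, 1726),
    "n": (4879, 4948, 4898, 4857),
}
#: Expected unadjusted RR (Q1 reference) and Q2..Q4 Wald 95% CIs.
MAIN_TABLE_EXPECTED = {
    "rr": (1.00, 1.31, 1.58, 2.14),
    "ci": {"Q2": (1.21, 1.42), "Q3": (1.47, 1.71), "Q4": (1.98, 2.30)},
}

#: Prepregnancy-BMI strata: counts and expected unadjusted RRs.
BMI_STRATA_TABLES = {
    "underweight": {
        "cases": (27, 34, 56, 93), "n": (178, 191, 205, 228),
        "rr": (1.00, 1.17, 1.80, 2.69),
    },
    "normal": {
        "cases": (500, 720, 903, 1232), "n": (3070, 3249, 3380, 3471),
        "rr": (1.00, 1.36, 1.64, 2.18),  # count-derived; see module docstring
    },
    "overweight": {
        "cases": (192, 213, 215, 223), "n": (1003, 972, 828, 661),
        "rr": (1.00, 1.14, 1.36, 1.76),
    },
    "obese": {
        "cases": (61, 68, 59, 78), "n": (404, 326, 265, 230),
        "rr": (1.00, 1.38, 1.47, 2.25),
    },
}
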