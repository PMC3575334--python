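"""Published reference values from the motivating p53 codon 72 genotyping study.

The study genotyped the rs1042522 polymorphism in 911 women by four
laboratory methods (DHPLC, DBH, RFLP-1, RFLP-2) and reported, for every
pair of methods, the 3x3 cross-tabulation of calls stratified by cytology
status (negative vs. any-grade SIL within two years).  Those pairwise
counts, together with the published classification-probability estimates
and per-genotype SIL risks, are the only machine-usable numbers available:
the full 4-way joint table was never released.  They are collected here as
plain constants so that fixtures, generator defaults and analyses can use
them as inputs.

Category coding throughout the package: 1 = Arg/Arg, 2 = Arg/Pro,
3 = Pro/Pro.  Outcome coding: 1 = negative cytology, 2 = any-grade SIL.
"""

from __future__ import annotations

import numpy as np

TEST_NAMES = ("DHPLC", "DBH", "RFLP-1", "RFLP-2")
CATEGORY_LABELS = ("Arg/Arg", "Arg/Pro", "Pro/Pro")
OUTCOME_LABELS = {1: "negative", 2: "sil"}

# Pairwise cross-tabulations of genotype calls, one block per ordered test
# pair.  "counts" rows index the first test's call (1..3), columns the
# second test's; "missing_second" counts subjects whose first-test call was
# observed but the second test's was not.
PAIRWISE_CROSSTABS: dict[tuple[str, str], dict[str, object]] = {
    ("DHPLC", "DBH"): {
        "negative": [[308, 5, 8], [9, 365, 9], [3, 4, 139]],
        "negative_missing": [0, 0, 0],
        "sil": [[31, 0, 1], [1, 21, 1], [0, 0, 6]],
        "sil_missing": [0, 0, 0],
    },
    ("DHPLC", "RFLP-1"): {
        "negative": [[299, 15, 7], [18, 360, 5], [5, 15, 126]],
        "negative_missing": [0, 0, 0],
        "sil": [[30, 1, 1], [1, 21, 1], [0, 1, 5]],
        "sil_missing": [0, 0, 0],
    },
    ("DHPLC", "RFLP-2"): {
        "negative": [[258, 49, 13], [9, 361, 13], [4, 2, 140]],
        "negative_missing": [1, 0, 0],
        "sil": [[29, 1, 2], [0, 22, 1], [0, 0, 6]],
        "sil_missing": [0, 0, 0],
    },
    ("DBH", "RFLP-1"): {
        "negative": [[302, 16, 2], [16, 355, 3], [4, 19, 133]],
        "negative_missing": [0, 0, 0],
        "sil": [[31, 1, 0], [0, 21, 0], [0, 1, 7]],
        "sil_missing": [0, 0, 0],
    },
    ("DBH", "RFLP-2"): {
        "negative": [[262, 50, 7], [7, 354, 13], [2, 8, 146]],
        "negative_missing": [1, 0, 0],
        "sil": [[29, 2, 1], [0, 21, 0], [0, 0, 8]],
        "sil_missing": [0, 0, 0],
    },
    ("RFLP-1", "RFLP-2"): {
        "negative": [[266, 46, 9], [3, 365, 22], [2, 1, 135]],
        "negative_missing": [1, 0, 0],
        "sil": [[28, 2, 1], [1, 21, 1], [0, 0, 7]],
        "sil_missing": [0, 0, 0],
    },
}

# Published classification probabilities theta_t[r, c] = P(call = r | true
# class = c) for the four main methods (conditional-independence latent
# class fit).  The DBH Arg/Arg column prints 0.997/0.020/0.006, which sums
# to 1.023; the 0.997 entry is inconsistent with the complement of the
# other two and 0.974 is used instead so that the column is stochastic.
# Columns summing to 1.001 from rounding are renormalized by the consumer.
CLASSIFICATION_PROBS: dict[str, list[list[float]]] = {
    "DHPLC": [[0.964, 0.006, 0.040],
              [0.028, 0.994, 0.037],
              [0.008, 0.000, 0.923]],
    "DBH": [[0.974, 0.011, 0.000],
            [0.020, 0.978, 0.026],
            [0.006, 0.012, 0.974]],
    "RFLP-1": [[0.957, 0.023, 0.013],
               [0.037, 0.977, 0.102],
               [0.006, 0.000, 0.886]],
    "RFLP-2": [[0.839, 0.000, 0.006],
               [0.138, 0.978, 0.014],
               [0.023, 0.022, 0.980]],
}

# Published cumulative two-year SIL risk per true genotype (Arg/Arg,
# Arg/Pro, Pro/Pro) from the outcome-augmented latent class model.
SIL_RISKS = (0.090, 0.054, 0.050)

# True-genotype prevalences were not published.  This default matches the
# observed marginal call distribution of the study panel (~0.39/0.45/0.17)
# and, combined with SIL_RISKS, yields ~61 expected SIL cases among 911
# women, the study's case count.
DEFAULT_PREVALENCE = (0.39, 0.44, 0.17)


def classification_matrices(test_names: tuple[str, ...] = TEST_NAMES) -> np.ndarray:
    """Stack the published classification matrices, columns renormalized
    to sum exactly to one.  Shape (T, C, C); element [t, r, c] is
    P(test t calls r | true class c)."""
    thetas = np.array([CLASSIFICATION_PROBS[t] for t in test_names], dtype=float)
    return thetas / thetas.sum(axis=1, keepdims=True)
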