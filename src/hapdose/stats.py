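"""Shared statistical kernels: z-tests, Bonferroni, Fisher's exact, empirical p."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def z_test_two_tailed(x: float, mu: float, sigma: float) -> float:
    """Two-tailed z-test p-value, p = 2 * Phi(-|x - mu| / sigma)."""
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return float(2.0 * sps.norm.sf(abs(x - mu) / sigma))


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-corrected p-value, min(1, p * n_tests)."""
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return float(min(1.0, p * n_tests))


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Uses the probability-mass convention: the p-value sums hypergeometric
    probabilities of every table with the same margins whose probability does
    not exceed that of the observed table (scipy's two-sided definition).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    if t.sum() == 0:
        raise ValueError("table is all zero; no data to test")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def empirical_p(null: np.ndarray, observed: float, alternative: str = "less") -> float:
    """Empirical permutation p with the +1 correction (never returns 0).

    ``alternative='less'`` counts null values <= observed (a depletion test);
    ``'greater'`` counts >= observed.
    """
    null = np.asarray(null, dtype=float)
    n = null.size
    if n == 0:
        raise ValueError("empty null distribution")
    if alternative == "less":
        k = int(np.sum(null <= observed))
    elif alternative == "greater":
        k = int(np.sum(null >= observed))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (1.0 + k) / (1.0 + n)
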