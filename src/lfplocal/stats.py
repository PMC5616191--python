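"""Frequency-wise paired condition comparison with FDR control.

Power, coherence and Granger values are not normally distributed across
sessions, so conditions are compared with a one-sided paired Wilcoxon
signed-rank test at every grid frequency, and the resulting p-value family is
corrected with the Benjamini-Hochberg step-up procedure at level q.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import wilcoxon
from statsmodels.stats.multitest import multipletests

__all__ = ["PairedSpectraSet", "wilcoxon_paired", "fdr_correct"]

log = logging.getLogger(__name__)


@dataclass
class PairedSpectraSet:
    """Per-session spectra under two paired conditions (run vs baseline)."""

    freqs: np.ndarray
    run: np.ndarray  # (n_sessions, n_freqs)
    baseline: np.ndarray  # (n_sessions, n_freqs)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        self.run = np.atleast_2d(np.asarray(self.run, float))
        self.baseline = np.atleast_2d(np.asarray(self.baseline, float))
        if self.run.shape != self.baseline.shape:
            raise ValueError("run and baseline must be paired (same sessions x freqs)")
        if self.run.shape[1] != self.freqs.size:
            raise ValueError("values and freqs disagree on the number of frequencies")

    @property
    def n_sessions(self) -> int:
        return self.run.shape[0]


def wilcoxon_paired(
    pairs: PairedSpectraSet, alternative: str = "greater"
) -> np.ndarray:
    """One-sided paired Wilcoxon signed-rank p-value at every frequency.

    Zero differences are dropped (Wilcoxon's rule); the exact null
    distribution is used for small samples, the continuity-corrected normal
    approximation otherwise (scipy's ``method="auto"``). A frequency where
    every difference is zero gets p = 1 with a log entry.
    """
    if pairs.n_sessions < 5:
        raise ValueError(f"need at least 5 paired sessions, got {pairs.n_sessions}")
    pvals = np.ones(pairs.freqs.size)
    for k in range(pairs.freqs.size):
        d = pairs.run[:, k] - pairs.baseline[:, k]
        if np.all(d == 0):
            log.warning("all-zero differences at %.3g Hz: p = 1", pairs.freqs[k])
            continue
        pvals[k] = wilcoxon(
            pairs.run[:, k],
            pairs.baseline[:, k],
            alternative=alternative,
            zero_method="wilcox",
            method="auto",
        ).pvalue
    return pvals


def fdr_correct(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up correction over the frequency grid.

    Returns
    -------
    mask : ndarray of bool
        Significant frequencies at FDR level q.
    p_threshold : float
        The adaptive threshold: the largest p(i) <= i*q/m (0.0 when nothing
        is rejected).
    """
    pvals = np.asarray(pvals, float)
    if pvals.size == 0:
        raise ValueError("empty p-value array")
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    mask = multipletests(pvals, alpha=q, method="fdr_bh")[0]
    p_threshold = float(pvals[mask].max()) if mask.any() else 0.0
    return mask, p_threshold
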