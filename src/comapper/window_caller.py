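"""Bayesian haplotype calling over SNV windows and skeleton-bin construction.

Within a window of n non-missing haplotype labels for one individual, the
number k of labels discordant with haplotype 1 is binomial with the genotyping
error rate E_T if the individual truly carries haplotype 1, and the n - k
concordant labels are the discordances if it carries haplotype 2:

    P(k | hap1) = C(n, k) E_T^k (1 - E_T)^(n-k)
    P(k | hap2) = C(n, n-k) E_T^(n-k) (1 - E_T)^k

With a flat prior P(hap1) = P(hap2) = 1/2, Bayes' theorem gives the posterior
of each haplotype and the call is the argmax (P_max).  Windows advance in SNV
index space (default 50 SNVs, step 5, at least 5 non-missing labels per
window).  Adjacent windows whose cross-individual call vectors are identical
are merged into uniquely segregating *skeleton bins*, the units between which
crossovers are sought.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from comapper.variants import SNVMatrix, MISSING

log = logging.getLogger(__name__)


def binom_likelihood(n, k, error_rate):
    """Binomial probability of k discordant labels out of n at error rate E_T.

    Computed in log space; vectorized over any argument.
    """
    n = np.asarray(n)
    k = np.asarray(k)
    if np.any(k > n) or np.any(k < 0):
        raise ValueError("k must satisfy 0 <= k <= n")
    if np.any((np.asarray(error_rate) < 0) | (np.asarray(error_rate) > 1)):
        raise ValueError("error rate must be in [0, 1]")
    return np.exp(binom.logpmf(k, n, error_rate))


def posterior(n, k, error_rate, prior: float = 0.5):
    """Posterior probabilities (p1, p2) of the two haplotypes given k of n
    discordances with haplotype 1.

    p1 = L1 * prior / (L1 * prior + L2 * (1 - prior)) with
    L1 = Binom(k; n, E_T) and L2 = Binom(n - k; n, E_T).  Degenerate evidence
    (both likelihoods zero) returns (1/2, 1/2) with a warning.  Vectorized.
    """
    n = np.asarray(n)
    k = np.asarray(k)
    if np.any(k > n) or np.any(k < 0):
        raise ValueError("k must satisfy 0 <= k <= n")
    with np.errstate(divide="ignore", invalid="ignore"):
        l1 = binom.logpmf(k, n, error_rate) + np.log(prior)
        l2 = binom.logpmf(n - k, n, error_rate) + np.log1p(-prior)
    both_zero = np.isneginf(l1) & np.isneginf(l2)
    if np.any(both_zero):
        warnings.warn("zero likelihood under both haplotypes; returning the prior", stacklevel=2)
        l1 = np.where(both_zero, 0.0, l1)
        l2 = np.where(both_zero, 0.0, l2)
    # p1 = exp(l1) / (exp(l1) + exp(l2)) computed stably
    m_ = np.maximum(l1, l2)
    e1 = np.exp(l1 - m_)
    e2 = np.exp(l2 - m_)
    p1 = e1 / (e1 + e2)
    return p1, 1.0 - p1


@dataclass
class WindowCalls:
    """Per-window haplotype calls for one population.

    ``windows``: DataFrame with chrom, start_idx, end_idx (inclusive site
    indices into the source matrix), start_pos, end_pos, mid_pos.
    ``calls``: (n_windows, n_individuals) int8 in {0, 1, -1}.
    ``n``/``k``/``p_max``: same shape support arrays.
    """

    windows: pd.DataFrame
    calls: np.ndarray
    n: np.ndarray
    k: np.ndarray
    p_max: np.ndarray
    error_rate: float = 0.0


def call_windows(
    m: SNVMatrix,
    labels: np.ndarray,
    error_rate: float,
    window: int = 50,
    step: int = 5,
    min_calls: int = 5,
) -> WindowCalls:
    """Call the haplotype of every individual in sliding SNV windows.

    ``labels``: per-individual per-SNV haplotype labels from phasing.  Windows
    with fewer than ``min_calls`` non-missing labels, or with exactly
    symmetric evidence (k = n/2, no information), are MISSING.
    """
    n_ind = labels.shape[0]
    rows, call_rows, n_rows, k_rows, p_rows = [], [], [], [], []
    pos_all = m.sites["pos"].to_numpy()
    for chrom in m.chroms:
        idx = m.chrom_index(chrom)
        if idx.size < window:
            log.warning("chromosome %s shorter than one window; truncated", chrom)
            starts = np.array([0])
        else:
            starts = np.arange(0, idx.size - window + 1, step)
            if starts[-1] != idx.size - window:  # cover the chromosome tail
                starts = np.append(starts, idx.size - window)
        for s in starts:
            span = idx[s : s + window]
            lab = labels[:, span]
            nm = lab != MISSING
            n_vec = nm.sum(axis=1)
            k_vec = ((lab == 1) & nm).sum(axis=1)
            p1, p2 = posterior(np.maximum(n_vec, 1), np.minimum(k_vec, np.maximum(n_vec, 1)), error_rate)
            call = np.where(p1 > p2, 0, np.where(p2 > p1, 1, MISSING)).astype(np.int8)
            pmax = np.maximum(p1, p2)
            bad = n_vec < min_calls
            call[bad] = MISSING
            pmax = np.where(bad, np.nan, pmax)
            rows.append(
                (chrom, int(span[0]), int(span[-1]), int(pos_all[span[0]]),
                 int(pos_all[span[-1]]), 0.5 * (pos_all[span[0]] + pos_all[span[-1]])),
            )
            call_rows.append(call)
            n_rows.append(n_vec)
            k_rows.append(k_vec)
            p_rows.append(pmax)
    windows = pd.DataFrame(
        rows, columns=["chrom", "start_idx", "end_idx", "start_pos", "end_pos", "mid_pos"]
    )
    return WindowCalls(
        windows=windows,
        calls=np.asarray(call_rows, dtype=np.int8).reshape(len(rows), n_ind),
        n=np.asarray(n_rows).reshape(len(rows), n_ind),
        k=np.asarray(k_rows).reshape(len(rows), n_ind),
        p_max=np.asarray(p_rows, dtype=float).reshape(len(rows), n_ind),
        error_rate=error_rate,
    )


@dataclass
class SkeletonBins:
    """Maximal runs of adjacent windows with identical segregation patterns.

    ``bins``: DataFrame with chrom, start_win, end_win (window row indices),
    start_idx, end_idx (site indices), start_pos, end_pos.
    ``patterns``: (n_bins, n_individuals) call vectors; missing calls bridged
    by each individual's last confident call (flagged in ``bridged``).
    """

    bins: pd.DataFrame
    patterns: np.ndarray
    bridged: np.ndarray = field(default=None)


def build_skeleton(wc: WindowCalls) -> SkeletonBins:
    """Merge adjacent same-pattern windows into uniquely segregating bins.

    Low-coverage windows can be MISSING for an individual without the
    underlying haplotype changing; such gaps are bridged by carrying the
    individual's last confident call forward so bins stay contiguous.
    Merging is idempotent: re-merging the bin patterns yields the same bins.
    """
    calls = wc.calls.copy()
    bridged = np.zeros_like(calls, dtype=bool)
    rows, pattern_rows = [], []
    for chrom, grp in wc.windows.groupby("chrom", sort=False):
        widx = grp.index.to_numpy()
        c = calls[widx]
        for j in range(c.shape[1]):
            col = c[:, j]
            last = MISSING
            for i in range(col.size):
                if col[i] == MISSING:
                    if last != MISSING:
                        col[i] = last
                        bridged[widx[i], j] = True
                else:
                    last = col[i]
        run_start = 0
        for i in range(1, c.shape[0] + 1):
            if i == c.shape[0] or not np.array_equal(c[i], c[run_start]):
                w0, w1 = widx[run_start], widx[i - 1]
                rows.append(
                    (chrom, int(w0), int(w1),
                     int(wc.windows.at[w0, "start_idx"]), int(wc.windows.at[w1, "end_idx"]),
                     int(wc.windows.at[w0, "start_pos"]), int(wc.windows.at[w1, "end_pos"])),
                )
                pattern_rows.append(c[run_start].copy())
                run_start = i
    bins = pd.DataFrame(
        rows,
        columns=["chrom", "start_win", "end_win", "start_idx", "end_idx", "start_pos", "end_pos"],
    )
    return SkeletonBins(bins=bins, patterns=np.asarray(pattern_rows, dtype=np.int8), bridged=bridged)
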