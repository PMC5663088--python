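"""Crossover detection between skeleton bins and logistic-regression localization.

A crossover candidate is an individual whose call differs between two adjacent
skeleton bins.  The SNV-level haplotype labels inside the two flanking bins are
then modelled by logistic regression of label on genomic coordinate; because a
crossover can only fall between adjacent SNVs, the crossover probability of an
SNV pair is the absolute difference of their fitted probabilities.  Starting
from the pair with the largest probability, the interval grows one SNV at a
time towards whichever side most increases the endpoint-pair probability,
stopping once it exceeds the confidence threshold (default 0.95).  The
returned interval is the bounding SNV pair; its width is the resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from comapper.variants import MISSING
from comapper.window_caller import SkeletonBins

log = logging.getLogger(__name__)

CO_COLUMNS = ["individual", "chrom", "left_pos", "right_pos", "probability",
              "resolution", "low_confidence", "population"]


@dataclass
class Transition:
    individual: int
    chrom: str
    left_bin: int  # row index into bins
    right_bin: int


def find_transitions(skeleton: SkeletonBins) -> list:
    """Candidate crossovers: per individual, adjacent bin pairs with differing calls.

    Candidates whose flanking bins do not physically overlap or touch (a guard
    against misplaced scaffolds on real assemblies) are discarded and logged.
    """
    out = []
    bins = skeleton.bins
    pat = skeleton.patterns
    for chrom, grp in bins.groupby("chrom", sort=False):
        bidx = grp.index.to_numpy()
        for b0, b1 in zip(bidx[:-1], bidx[1:]):
            left, right = pat[b0], pat[b1]
            movers = np.flatnonzero((left != right) & (left != MISSING) & (right != MISSING))
            if movers.size and bins.at[b1, "start_idx"] > bins.at[b0, "end_idx"] + 1:
                log.warning(
                    "discarding %d candidate(s): bins %d/%d on %s do not overlap",
                    movers.size, b0, b1, chrom,
                )
                continue
            for j in movers:
                out.append(Transition(int(j), chrom, int(b0), int(b1)))
    return out


@dataclass
class CrossoverFit:
    """Logistic fit of haplotype label on position within the flanking bins."""

    positions: np.ndarray
    labels: np.ndarray
    fitted: np.ndarray  # p(x_i), probability of label 1
    intercept: float
    slope: float

    @property
    def pair_probability(self) -> np.ndarray:
        """Crossover probability of each adjacent SNV pair: |p(x_{i+1}) - p(x_i)|."""
        return np.abs(np.diff(self.fitted))


def fit_logistic(positions: np.ndarray, labels: np.ndarray, ridge: float = 1e-4) -> CrossoverFit:
    """Fit label ~ position with a small L2 penalty.

    Clean step data makes the unpenalized MLE diverge (perfect separation); the
    ridge bounds the coefficients while leaving the fitted step effectively 0/1
    at the extremes.  Positions are standardized internally so Mb-scale
    coordinates do not overflow.
    """
    positions = np.asarray(positions, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need both haplotype classes to localize a crossover")
    mu, sd = positions.mean(), positions.std()
    sd = sd if sd > 0 else 1.0
    x = ((positions - mu) / sd).reshape(-1, 1)
    clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=2000)
    clf.fit(x, labels)
    p = clf.predict_proba(x)[:, 1]
    return CrossoverFit(
        positions=positions,
        labels=labels,
        fitted=p,
        intercept=float(clf.intercept_[0] - clf.coef_[0, 0] * mu / sd),
        slope=float(clf.coef_[0, 0] / sd),
    )


def localize(
    positions: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.95,
    ridge: float = 1e-4,
) -> dict:
    """Localize one crossover to a bounding SNV pair.

    Returns a dict with ``left_pos``, ``right_pos``, ``probability``,
    ``low_confidence``.  Missing labels must already be removed.
    """
    order = np.argsort(positions)
    positions = np.asarray(positions)[order]
    labels = np.asarray(labels)[order]
    fit = fit_logistic(positions, labels, ridge=ridge)
    dp = fit.pair_probability
    i = int(np.argmax(dp))
    j = i + 1
    prob = float(dp[i])
    p = fit.fitted
    while prob <= threshold:
        left_val = abs(p[j] - p[i - 1]) if i > 0 else -np.inf
        right_val = abs(p[j + 1] - p[i]) if j + 1 < p.size else -np.inf
        if not np.isfinite(left_val) and not np.isfinite(right_val):
            log.warning("crossover probability never exceeded %.2f; widest pair returned", threshold)
            return dict(
                left_pos=int(positions[0]), right_pos=int(positions[-1]),
                probability=prob, low_confidence=True,
            )
        if left_val >= right_val:
            i -= 1
            prob = float(left_val)
        else:
            j += 1
            prob = float(right_val)
    return dict(
        left_pos=int(positions[i]), right_pos=int(positions[j]),
        probability=prob, low_confidence=False,
    )


def detect_crossovers(
    skeleton: SkeletonBins,
    labels: np.ndarray,
    sites: pd.DataFrame,
    threshold: float = 0.95,
    ridge: float = 1e-4,
    population: str = "sim",
) -> pd.DataFrame:
    """Full detection: transitions between skeleton bins, each localized to an
    SNV interval.  Returns a crossover table (one row per event)."""
    pos_all = sites["pos"].to_numpy()
    rows = []
    for tr in find_transitions(skeleton):
        s = int(skeleton.bins.at[tr.left_bin, "start_idx"])
        e = int(skeleton.bins.at[tr.right_bin, "end_idx"])
        span = np.arange(s, e + 1)
        lab = labels[tr.individual, span]
        keep = lab != MISSING
        if keep.sum() < 2 or np.unique(lab[keep]).size < 2:
            log.warning("transition for individual %d on %s has one-class labels; skipped",
                        tr.individual, tr.chrom)
            continue
        res = localize(pos_all[span][keep], lab[keep], threshold=threshold, ridge=ridge)
        rows.append(
            (tr.individual, tr.chrom, res["left_pos"], res["right_pos"], res["probability"],
             res["right_pos"] - res["left_pos"], res["low_confidence"], population)
        )
    return pd.DataFrame(rows, columns=CO_COLUMNS)


def merge_fine(*crossover_tables: pd.DataFrame, max_span: int = 5_000) -> pd.DataFrame:
    """Concatenate population crossover tables and keep fine-resolution events
    (resolution strictly less than ``max_span`` bp); population labels are kept."""
    if not crossover_tables:
        return pd.DataFrame(columns=CO_COLUMNS)
    allco = pd.concat(crossover_tables, ignore_index=True)
    return allco[allco["resolution"] < max_span].reset_index(drop=True)


def crossovers_to_bed(co: pd.DataFrame) -> pd.DataFrame:
    """Crossover intervals as BED (0-based half-open: left_pos - 1 .. right_pos)."""
    return pd.DataFrame(
        {
            "chrom": co["chrom"],
            "start": co["left_pos"].astype(int) - 1,
            "end": co["right_pos"].astype(int),
            "name": [f"{p}_ind{int(i):03d}" for p, i in zip(co["population"], co["individual"])],
            "score": co["probability"],
            "strand": ".",
        }
    )
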