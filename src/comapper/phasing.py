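"""Sliding-window LD phasing of the heterozygous parent's haplotypes.

Each segregating SNV is heterozygous in one parent, so an F1 genotype (hom-ref
vs het, coded 0/1 after hom-alt conversion) reveals which parental allele was
inherited.  Phasing decides, for every SNV, which allele sits on haplotype 1
(the *orientation* bit).  The first SNV of a chromosome is oriented
arbitrarily; each subsequent SNV is oriented against the already-phased SNV
with the highest r^2 among the trailing window of 99, by aligning the two
highest-frequency allelic pairings; the window then slides by one SNV so the
orientation propagates chromosome-wide.  A global flip of every orientation
bit (and hence every label) is an equivalent phasing; all downstream crossover
calls are invariant under it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from comapper.variants import SNVMatrix, MISSING

log = logging.getLogger(__name__)


@dataclass
class PhasedAssignments:
    """Orientation bit per SNV (1 = ALT on haplotype 1; -1 = unphaseable)
    and per-individual haplotype labels (0 = hap1, 1 = hap2, -1 = missing)."""

    orientation: np.ndarray  # (n_sites,) int8 in {0, 1, -1}
    labels: np.ndarray  # (n_individuals, n_sites) int8 in {0, 1, -1}

    def flipped(self) -> "PhasedAssignments":
        o = np.where(self.orientation == MISSING, MISSING, 1 - self.orientation).astype(np.int8)
        l = np.where(self.labels == MISSING, MISSING, 1 - self.labels).astype(np.int8)
        return PhasedAssignments(orientation=o, labels=l)


def phase_chromosome(m: SNVMatrix, window: int = 100, min_shared: int = 2) -> np.ndarray:
    """Orient every SNV of every chromosome; returns the orientation array.

    ``window`` is the sliding-window size in SNVs (each new SNV is compared
    against the trailing ``window - 1`` already-phased SNVs).  SNVs with no
    informative partner (too few co-observed individuals, or zero covariance
    with every partner) get orientation -1 and are logged.
    """
    if m.n_sites < 2:
        raise ValueError("need at least 2 SNVs to phase")
    orient = np.full(m.n_sites, MISSING, dtype=np.int8)
    allele = np.where(m.genotypes == MISSING, np.nan, np.minimum(m.genotypes, 1)).astype(float)
    for chrom in m.chroms:
        idx = m.chrom_index(chrom)
        if idx.size == 0:
            continue
        a = allele[:, idx]
        o = _phase_block(a, window=window, min_shared=min_shared)
        orient[idx] = o
        n_un = int((o == MISSING).sum())
        if n_un:
            log.warning("%d of %d SNVs unphaseable on %s", n_un, idx.size, chrom)
    return orient


def _phase_block(a: np.ndarray, window: int, min_shared: int) -> np.ndarray:
    """Phase one chromosome's allele-indicator matrix (individuals x sites)."""
    n_sites = a.shape[1]
    orient = np.full(n_sites, MISSING, dtype=np.int8)
    if n_sites == 0:
        return orient
    orient[0] = 1  # arbitrary anchor: ALT on haplotype 1
    finite = np.isfinite(a)
    for j in range(1, n_sites):
        lo = max(0, j - (window - 1))
        phased = np.flatnonzero(orient[lo:j] != MISSING) + lo
        if phased.size == 0:
            # restart a fresh phase set (disconnected block)
            orient[j] = 1
            continue
        x = a[:, j]
        Y = a[:, phased]
        valid = finite[:, j][:, None] & finite[:, phased]
        n = valid.sum(axis=0)
        xv = np.where(valid, x[:, None], 0.0)
        yv = np.where(valid, Y, 0.0)
        sx, sy = xv.sum(axis=0), yv.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = n * (xv * yv).sum(axis=0) - sx * sy
            varx = n * (xv**2).sum(axis=0) - sx**2
            vary = n * (yv**2).sum(axis=0) - sy**2
            r2 = cov**2 / (varx * vary)
        r2[(n < min_shared) | (varx <= 0) | (vary <= 0)] = np.nan
        if not np.any(np.isfinite(r2)):
            log.debug("SNV %d has no informative phased partner", j)
            continue
        best = np.nanargmax(r2)
        c = cov[best]
        anchor = orient[phased[best]]
        if c > 0:
            # ALT_j co-segregates with ALT_anchor: same haplotype carries both
            orient[j] = anchor
        elif c < 0:
            orient[j] = 1 - anchor
        else:
            # exact tie between the two pairings: deterministic fallback
            orient[j] = 0
            log.debug("pairing tie at SNV %d; orientation set to 0", j)
    return orient


def genotype_to_haplotype(m: SNVMatrix, orientation: np.ndarray) -> np.ndarray:
    """Map each individual's genotype to the parental haplotype label it carries.

    With orientation ``o`` (ALT on hap1 iff o == 1) and inherited-allele
    indicator ``a`` (1 = ALT), the label is 0 (hap1) when a == o and 1 (hap2)
    otherwise; MISSING genotypes and unphaseable SNVs propagate as -1.
    """
    a = np.minimum(m.genotypes, 1)
    labels = (a != orientation[None, :]).astype(np.int8)
    labels[m.genotypes == MISSING] = MISSING
    labels[:, orientation == MISSING] = MISSING
    return labels


def phase(m: SNVMatrix, window: int = 100) -> PhasedAssignments:
    """Convenience wrapper: orient all SNVs and derive the label matrix."""
    orientation = phase_chromosome(m, window=window)
    labels = genotype_to_haplotype(m, orientation)
    return PhasedAssignments(orientation=orientation, labels=labels)


def switch_error_rate(orientation: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of adjacent phased SNV pairs whose relative orientation disagrees
    with truth (invariant to the global flip)."""
    ok = (orientation != MISSING) & (truth != MISSING)
    o, t = orientation[ok], truth[ok]
    if o.size < 2:
        return 0.0
    rel_o = o[1:] != o[:-1]
    rel_t = t[1:] != t[:-1]
    return float(np.mean(rel_o != rel_t))
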