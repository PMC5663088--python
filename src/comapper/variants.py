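"""Genotype matrix container, VCF I/O, and the SNV filtering cascade.

The cascade (applied in this fixed order) prepares a raw testcross genotype
matrix for haplotype phasing:

1. ``mask_repeats``        -- drop SNVs inside repeat-masked intervals
2. ``filter_segregation``  -- chi-square 1:1 segregation test, BH FDR
3. ``filter_ld``           -- sampled-median-r2 linkage filter
4. ``apply_depth_missing`` -- hom-ref calls below a depth floor become missing
5. ``filter_missingness``  -- drop SNVs with too many missing calls
6. ``convert_homalt``      -- recode hom-alt calls as het; their frequency is
   the empirical genotyping error rate E_T used downstream by the window
   caller.

Genotype codes: 0 = HOM_REF, 1 = HET, 2 = HOM_ALT, -1 = MISSING.  In a
pseudo-testcross the heterozygous parent's two haplotypes carry complementary
alleles at every segregating SNV, the inbred parent contributes the reference
allele, so true F1 genotypes are only HOM_REF or HET; HOM_ALT calls can only
arise through error and allele-sampling artifacts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from comapper._intervals import points_in_intervals

log = logging.getLogger(__name__)

HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1


@dataclass
class SNVMatrix:
    """Per-site x per-individual genotype codes with read depth.

    Attributes
    ----------
    sites : pandas.DataFrame
        Columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt``; positions are
        strictly increasing within each chromosome.
    genotypes : numpy.ndarray
        ``(n_individuals, n_sites)`` int8 codes.
    depth : numpy.ndarray
        ``(n_individuals, n_sites)`` non-negative read depths.
    samples : list of str
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    depth: np.ndarray
    samples: list = field(default_factory=list)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        if self.genotypes.shape != self.depth.shape:
            raise ValueError("genotype and depth arrays must be congruent in shape")
        if self.genotypes.shape[1] != len(self.sites):
            raise ValueError("site table and genotype columns disagree")
        if not self.samples:
            self.samples = [f"ind{i:03d}" for i in range(self.genotypes.shape[0])]
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                bad = pos[1:][np.diff(pos) <= 0][0]
                raise ValueError(f"positions not strictly increasing on {chrom} near {bad}")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def take_sites(self, index: np.ndarray) -> "SNVMatrix":
        """Subset to site columns given by boolean mask or integer index."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SNVMatrix(
            sites=self.sites.iloc[index].reset_index(drop=True),
            genotypes=self.genotypes[:, index],
            depth=self.depth[:, index],
            samples=list(self.samples),
        )

    def chrom_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.sites["chrom"] == chrom).to_numpy())

    @property
    def chroms(self) -> list:
        return list(dict.fromkeys(self.sites["chrom"]))


@dataclass
class ErrorRate:
    """Empirical genotyping error rate E_T = hom-alt calls / non-missing calls."""

    numerator: int
    denominator: int

    @property
    def E_T(self) -> float:
        return self.numerator / self.denominator

    def __float__(self) -> float:
        return self.E_T


# ---------------------------------------------------------------------------
# VCF I/O (pysam)
# ---------------------------------------------------------------------------

def load_genotypes(vcf_path: str) -> SNVMatrix:
    """Load a VCF with per-sample GT (and optionally DP) into an SNVMatrix.

    Raises on duplicate positions; sites without DP get depth 0 with a warning.
    """
    import pysam

    vcf = pysam.VariantFile(str(vcf_path))
    samples = list(vcf.header.samples)
    chroms, poss, refs, alts = [], [], [], []
    gt_rows, dp_rows = [], []
    seen = set()
    missing_dp = False
    for rec in vcf:
        key = (rec.chrom, rec.pos)
        if key in seen:
            raise ValueError(f"duplicate position {rec.chrom}:{rec.pos} in {vcf_path}")
        seen.add(key)
        chroms.append(rec.chrom)
        poss.append(rec.pos)
        refs.append(rec.ref)
        alts.append(rec.alts[0] if rec.alts else ".")
        codes = np.empty(len(samples), dtype=np.int8)
        dps = np.zeros(len(samples), dtype=np.int32)
        for i, name in enumerate(samples):
            smp = rec.samples[name]
            gt = smp.get("GT")
            if gt is None or any(a is None for a in gt):
                codes[i] = MISSING
            else:
                codes[i] = {0: HOM_REF, 1: HET, 2: HOM_ALT}[int(sum(gt))]
            dp = smp.get("DP")
            if dp is None:
                missing_dp = True
            else:
                dps[i] = int(dp)
        gt_rows.append(codes)
        dp_rows.append(dps)
    vcf.close()
    if missing_dp:
        warnings.warn("VCF lacks DP for some calls; depth recorded as 0", stacklevel=2)
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    return SNVMatrix(
        sites=sites,
        genotypes=np.array(gt_rows, dtype=np.int8).T if gt_rows else np.zeros((len(samples), 0), np.int8),
        depth=np.array(dp_rows, dtype=np.int32).T if dp_rows else np.zeros((len(samples), 0), np.int32),
        samples=samples,
    )


def write_vcf(m: SNVMatrix, path: str, contig_lengths: dict | None = None) -> None:
    """Write the matrix as an uncompressed VCF with GT and DP per sample."""
    import pysam

    header = pysam.VariantHeader()
    lengths = contig_lengths or {}
    for chrom in m.chroms:
        maxpos = int(m.sites.loc[m.sites["chrom"] == chrom, "pos"].max())
        header.contigs.add(chrom, length=int(lengths.get(chrom, maxpos + 1)))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for s in m.samples:
        header.add_sample(s)
    gt_map = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in range(m.n_sites):
            row = m.sites.iloc[j]
            rec = out.new_record(
                contig=row["chrom"], start=int(row["pos"]) - 1, stop=int(row["pos"]),
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            for i, s in enumerate(m.samples):
                rec.samples[s]["GT"] = gt_map[int(m.genotypes[i, j])]
                rec.samples[s]["DP"] = int(m.depth[i, j])
            out.write(rec)


# ---------------------------------------------------------------------------
# Filtering cascade
# ---------------------------------------------------------------------------

def mask_repeats(m: SNVMatrix, repeats: pd.DataFrame) -> SNVMatrix:
    """Remove SNVs whose 1-bp position intersects any repeat interval.

    ``repeats``: BED-style DataFrame (chrom, start, end), 0-based half-open.
    """
    keep = np.ones(m.n_sites, dtype=bool)
    for chrom, grp in repeats.groupby("chrom", sort=False):
        idx = m.chrom_index(chrom)
        if idx.size == 0:
            continue
        pos0 = m.sites["pos"].to_numpy()[idx] - 1  # to 0-based points
        hit = points_in_intervals(pos0, grp["start"].to_numpy(), grp["end"].to_numpy())
        keep[idx[hit]] = False
    if not keep.any():
        warnings.warn("repeat mask removed every site", stacklevel=2)
    return m.take_sites(keep)


def filter_segregation(m: SNVMatrix, fdr: float = 0.05, expected_ratio="1:1"):
    """Chi-square segregation test per site with BH correction.

    HOM_ALT calls are pooled with HET (het mis-calls under the testcross
    model).  ``expected_ratio`` is the null HOM_REF fraction: ``"1:1"`` (or
    0.5) is the Mendelian expectation for error-free calls; ``"auto"``
    estimates the genome-wide mean hom-ref call fraction and tests each site
    against it, which is the appropriate null when one-sided allele dropout
    at low coverage shifts raw calls away from 1:1 uniformly along the genome
    (distortion then shows up as *local* deviation, as on a distorted
    chromosome).  Returns ``(filtered, pvalues)`` where ``pvalues`` is per
    input site (NaN for untestable sites, which are retained).
    """
    g = m.genotypes
    n_ref = (g == HOM_REF).sum(axis=0)
    n_het = ((g == HET) | (g == HOM_ALT)).sum(axis=0)
    total = n_ref + n_het
    if expected_ratio == "auto":
        p0 = n_ref.sum() / max(total.sum(), 1)
        log.info("segregation null hom-ref fraction estimated as %.3f", p0)
    elif expected_ratio == "1:1":
        p0 = 0.5
    else:
        p0 = float(expected_ratio)
    if not 0 < p0 < 1:
        raise ValueError("expected hom-ref fraction must be in (0, 1)")
    pvals = np.full(m.n_sites, np.nan)
    testable = total >= 2
    with np.errstate(invalid="ignore"):
        chi2 = (n_ref - total * p0) ** 2 / np.maximum(total * p0, 1e-300) + (
            n_het - total * (1 - p0)
        ) ** 2 / np.maximum(total * (1 - p0), 1e-300)
    pvals[testable] = stats.chi2.sf(chi2[testable], df=1)
    keep = np.ones(m.n_sites, dtype=bool)
    if testable.any():
        rej, _, _, _ = multipletests(pvals[testable], alpha=fdr, method="fdr_bh")
        keep[np.flatnonzero(testable)[rej]] = False
    return m.take_sites(keep), pvals


def filter_ld(
    m: SNVMatrix,
    n_sample: int = 25,
    min_dist: int = 1_000,
    max_dist: int = 10_000_000,
    min_median_r2: float = 0.2,
    seed: int | None = None,
    min_shared: int = 10,
):
    """Remove sites in weak linkage with sampled neighbours.

    For each site, up to ``n_sample`` partner sites are drawn uniformly (without
    replacement) from the same chromosome at distance ``min_dist``..``max_dist``;
    r2 is the squared Pearson correlation of allele indicators over individuals
    non-missing at both sites (pairs with fewer than ``min_shared`` shared
    observations are skipped).  A site is removed iff its median r2 falls below
    the threshold.  Sites with no partner in the band are retained and flagged.

    Returns ``(filtered, median_r2)`` with NaN for partnerless sites.
    """
    rng = np.random.default_rng(seed)
    alleles = np.where(m.genotypes == MISSING, np.nan, np.minimum(m.genotypes, 1)).astype(float)
    med = np.full(m.n_sites, np.nan)
    for chrom in m.chroms:
        idx = m.chrom_index(chrom)
        pos = m.sites["pos"].to_numpy()[idx].astype(np.int64)
        a = alleles[:, idx]
        for local_j in range(idx.size):
            d = np.abs(pos - pos[local_j])
            band = np.flatnonzero((d >= min_dist) & (d <= max_dist))
            if band.size == 0:
                log.debug("no LD partners in band for %s:%d", chrom, pos[local_j])
                continue
            if band.size > n_sample:
                band = rng.choice(band, size=n_sample, replace=False)
            x = a[:, local_j]
            Y = a[:, band]
            r2 = _masked_r2(x, Y, min_shared)
            r2 = r2[np.isfinite(r2)]
            if r2.size:
                med[idx[local_j]] = np.median(r2)
    keep = ~(med < min_median_r2)  # NaN (partnerless / all pairs skipped) -> keep
    return m.take_sites(keep), med


def _masked_r2(x: np.ndarray, Y: np.ndarray, min_shared: int) -> np.ndarray:
    """Squared Pearson correlation of x against each column of Y, pairwise-complete."""
    valid = np.isfinite(x)[:, None] & np.isfinite(Y)
    n = valid.sum(axis=0)
    xv = np.where(valid, x[:, None], 0.0)
    yv = np.where(valid, Y, 0.0)
    sx, sy = xv.sum(axis=0), yv.sum(axis=0)
    sxx, syy = (xv**2).sum(axis=0), (yv**2).sum(axis=0)
    sxy = (xv * yv).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx**2
        vary = n * syy - sy**2
        r2 = cov**2 / (varx * vary)
    r2[(n < min_shared) | (varx <= 0) | (vary <= 0)] = np.nan
    return r2


def apply_depth_missing(m: SNVMatrix, min_depth: int) -> SNVMatrix:
    """Set HOM_REF calls with depth below ``min_depth`` to MISSING.

    At low coverage a het site often shows only the reference allele, so a
    confident hom-ref call needs a depth floor; other codes are untouched.
    """
    g = m.genotypes.copy()
    g[(g == HOM_REF) & (m.depth < min_depth)] = MISSING
    return replace(m, genotypes=g)


def filter_missingness(m: SNVMatrix, max_missing_fraction: float) -> SNVMatrix:
    """Remove sites whose missing-call fraction exceeds the threshold."""
    frac = (m.genotypes == MISSING).mean(axis=0)
    return m.take_sites(frac <= max_missing_fraction)


def convert_homalt(m: SNVMatrix):
    """Recode every HOM_ALT as HET; return ``(converted, ErrorRate)``.

    In a testcross hom-alt calls are impossible without error, so their
    pre-conversion fraction among non-missing calls estimates the genotyping
    error rate E_T consumed by the Bayesian window caller.
    """
    non_missing = int((m.genotypes != MISSING).sum())
    if non_missing == 0:
        raise ValueError("no non-missing calls; cannot estimate error rate")
    n_homalt = int((m.genotypes == HOM_ALT).sum())
    g = m.genotypes.copy()
    g[g == HOM_ALT] = HET
    return replace(m, genotypes=g), ErrorRate(n_homalt, non_missing)


@dataclass
class CascadeResult:
    matrix: SNVMatrix
    error_rate: ErrorRate
    stage_counts: dict
    site_stats: pd.DataFrame


def run_cascade(
    m: SNVMatrix,
    repeats: pd.DataFrame | None = None,
    fdr: float = 0.05,
    expected_ratio="auto",
    ld_kwargs: dict | None = None,
    min_depth: int = 2,
    max_missing_fraction: float = 0.4,
    seed: int | None = None,
) -> CascadeResult:
    """Apply the full filter cascade in the pipeline's fixed order."""
    counts = {"input": m.n_sites}
    if repeats is not None and len(repeats):
        m = mask_repeats(m, repeats)
    counts["repeats"] = m.n_sites
    m, pvals = filter_segregation(m, fdr=fdr, expected_ratio=expected_ratio)
    counts["segregation"] = m.n_sites
    m, med_r2 = filter_ld(m, seed=seed, **(ld_kwargs or {}))
    counts["ld"] = m.n_sites
    m = apply_depth_missing(m, min_depth)
    counts["depth_missing"] = m.n_sites
    m = filter_missingness(m, max_missing_fraction)
    counts["missingness"] = m.n_sites
    m, err = convert_homalt(m)
    counts["final"] = m.n_sites
    stats_df = m.sites.copy()
    stats_df["missing_fraction"] = (m.genotypes == MISSING).mean(axis=0)
    return CascadeResult(matrix=m, error_rate=err, stage_counts=counts, site_stats=stats_df)
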