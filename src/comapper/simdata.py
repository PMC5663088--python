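"""Pseudo-testcross population simulator with ground truth.

Emulates the cross of a heterozygous parent by an inbred parent: every
segregating SNV is heterozygous in parent 1 (its two haplotypes carry
complementary alleles) and homozygous reference in parent 2, so each F1
genotype directly reveals which parental haplotype was inherited.  Meiosis
draws a Poisson number of crossovers per chromosome with positions from a
configurable density on [0, 1] (default: a mild symmetric U-shape standing in
for the distal bias of crossover landscapes in large plant genomes).
Shotgun genotyping draws per-site depth ~ Poisson(coverage), samples reads
from the individual's two alleles with a per-read error rate, and calls hard
genotypes from read counts; i.i.d. missingness can be layered on top.

Everything is driven by a single seed; identical seeds give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from comapper.variants import SNVMatrix, HOM_REF, HET, HOM_ALT, MISSING


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths (bp) of the simulated genome."""

    chrom_names: tuple
    chrom_lengths: tuple

    def __post_init__(self):
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("names and lengths differ in count")

    @classmethod
    def uniform(cls, n_chrom: int, length: int, prefix: str = "chr") -> "GenomeLayout":
        return cls(tuple(f"{prefix}{i + 1:02d}" for i in range(n_chrom)), (length,) * n_chrom)

    def as_dict(self) -> dict:
        return dict(zip(self.chrom_names, self.chrom_lengths))


class DensityProfile:
    """Crossover position density on relative position [0, 1].

    Stored as a discretized non-negative curve; sampling is by inverse CDF
    interpolation.  ``DensityProfile.u_shape()`` gives the default distally
    biased profile u(x) = 0.5 + 1.5 (2x - 1)^2 (integrates to 1, edge density
    four times the centromeric minimum).
    """

    def __init__(self, curve: np.ndarray):
        curve = np.asarray(curve, dtype=float)
        if curve.ndim != 1 or curve.size < 2 or np.any(curve < 0) or curve.sum() <= 0:
            raise ValueError("density curve must be a non-negative 1-D array with mass")
        self.curve = curve / (curve.sum() / curve.size)  # mean 1 => integrates to 1
        cdf = np.concatenate([[0.0], np.cumsum(self.curve)])
        self._cdf = cdf / cdf[-1]
        self._grid = np.linspace(0.0, 1.0, curve.size + 1)

    @classmethod
    def uniform(cls, bins: int = 512) -> "DensityProfile":
        return cls(np.ones(bins))

    @classmethod
    def u_shape(cls, bins: int = 512) -> "DensityProfile":
        x = (np.arange(bins) + 0.5) / bins
        return cls(0.5 + 1.5 * (2 * x - 1) ** 2)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(n)
        return np.interp(u, self._cdf, self._grid)


@dataclass
class ParentalHaplotypes:
    """Segregating SNV sites and the heterozygous parent's two haplotypes.

    ``hap1_allele[j] = 1`` means the ALT allele of site ``j`` sits on
    haplotype 1 (haplotype 2 carries the complementary allele).
    """

    layout: GenomeLayout
    sites: pd.DataFrame  # chrom, pos (1-based), ref, alt
    hap1_allele: np.ndarray  # 0/1 per site

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def chrom_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.sites["chrom"] == chrom).to_numpy())


@dataclass
class SimTruth:
    """Ground truth retained by the simulator.

    ``labels``: (n_individuals, n_sites) inherited parental haplotype per SNV
    (0 = hap1, 1 = hap2).  ``breakpoints``: one row per observable crossover
    (individual, chrom, left_pos, right_pos) where left/right are the adjacent
    SNVs bounding the exchange.  Crossovers outside the terminal SNVs, or
    cancelling pairwise within one inter-SNV gap, are not observable in marker
    space and are not recorded, so the number of haplotype switches along each
    chromosome equals the number of recorded crossovers exactly.
    """

    labels: np.ndarray
    breakpoints: pd.DataFrame
    params: dict = field(default_factory=dict)

    def count_per_individual(self) -> np.ndarray:
        n = self.labels.shape[0]
        counts = np.zeros(n, dtype=int)
        if len(self.breakpoints):
            vc = self.breakpoints["individual"].value_counts()
            counts[vc.index.to_numpy()] = vc.to_numpy()
        return counts


_BASES = np.array(["A", "C", "G", "T"])


def simulate_parents(layout: GenomeLayout, snv_density: float, seed=None) -> ParentalHaplotypes:
    """Place segregating SNVs along the genome and phase them onto two haplotypes.

    ``snv_density`` is in SNVs per Mb; per-chromosome counts are Poisson with
    that intensity and the ALT allele lands on haplotype 1 with probability 1/2.
    """
    if snv_density <= 0:
        raise ValueError("snv_density must be positive")
    rng = np.random.default_rng(seed)
    chroms, poss = [], []
    for name, length in zip(layout.chrom_names, layout.chrom_lengths):
        n = rng.poisson(snv_density * length / 1e6)
        n = min(n, length)
        pos = np.sort(rng.choice(length, size=n, replace=False)) + 1  # 1-based
        chroms.extend([name] * n)
        poss.append(pos)
    pos_all = np.concatenate(poss) if poss else np.array([], dtype=int)
    n_sites = pos_all.size
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": pos_all, "ref": _BASES[ref_idx], "alt": _BASES[alt_idx]}
    )
    hap1_allele = rng.integers(0, 2, size=n_sites).astype(np.int8)
    return ParentalHaplotypes(layout=layout, sites=sites, hap1_allele=hap1_allele)


def simulate_meiosis(
    parents: ParentalHaplotypes,
    lambda_co: float,
    density_profile: DensityProfile | None = None,
    seed=None,
    rng: np.random.Generator | None = None,
    obligate_co: bool = False,
):
    """Draw one gamete of the heterozygous parent.

    Crossover counts per chromosome are Poisson(``lambda_co``) (optionally
    forced >= 1 with ``obligate_co``); positions are i.i.d. from the density
    profile and realized between the two flanking SNVs.  Returns
    ``(labels, breakpoints)`` where ``labels`` is the inherited haplotype
    (0/1) per SNV and ``breakpoints`` a DataFrame of observable exchanges.
    """
    if lambda_co < 0:
        raise ValueError("lambda_co must be non-negative")
    rng = rng if rng is not None else np.random.default_rng(seed)
    profile = density_profile or DensityProfile.u_shape()
    labels = np.empty(parents.n_sites, dtype=np.int8)
    rows = []
    for name, length in zip(parents.layout.chrom_names, parents.layout.chrom_lengths):
        idx = parents.chrom_index(name)
        start_hap = rng.integers(0, 2)
        if idx.size == 0:
            continue
        pos = parents.sites["pos"].to_numpy()[idx].astype(np.int64)
        n_co = rng.poisson(lambda_co)
        if obligate_co and n_co == 0:
            n_co = 1
        switch_gaps = []
        if n_co and idx.size >= 2:
            bp = profile.sample(n_co, rng) * length
            inside = (bp > pos[0]) & (bp < pos[-1])
            gaps = np.searchsorted(pos, bp[inside])  # gap g: between pos[g-1], pos[g]
            for g, cnt in zip(*np.unique(gaps, return_counts=True)):
                if cnt % 2 == 1:  # even parity cancels: no observable switch
                    switch_gaps.append(int(g))
        hap = np.full(idx.size, start_hap, dtype=np.int8)
        for g in sorted(switch_gaps):
            hap[g:] = 1 - hap[g:]
            rows.append({"chrom": name, "left_pos": int(pos[g - 1]), "right_pos": int(pos[g])})
        labels[idx] = hap
    breakpoints = pd.DataFrame(rows, columns=["chrom", "left_pos", "right_pos"])
    return labels, breakpoints


def simulate_population(
    parents: ParentalHaplotypes,
    n_individuals: int,
    lambda_co: float = 1.0,
    coverage: float = 2.0,
    base_error: float = 0.01,
    missing_rate: float = 0.0,
    depth_floor: int = 0,
    density_profile: DensityProfile | None = None,
    obligate_co: bool = False,
    seed=None,
):
    """Simulate an F1 population with low-coverage genotyping.

    Per site per individual: depth ~ Poisson(``coverage``); reads are drawn
    from the two alleles of the true genotype with per-read error
    ``base_error``.  Hard calls follow the testcross read model: any mixture of
    alleles is HET; at a truly heterozygous site any ALT read is taken as HET
    (dropout of the ALT allele yields a wrong HOM_REF call); at a truly hom-ref
    site all-reads-ALT (every read an error) yields a spurious HOM_ALT call.
    Calls with depth < ``depth_floor`` and an i.i.d. ``missing_rate`` fraction
    are MISSING.  Returns ``(SNVMatrix, SimTruth)``.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0 <= base_error < 0.5:
        raise ValueError("base_error must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n_sites = parents.n_sites
    labels = np.empty((n_individuals, n_sites), dtype=np.int8)
    bp_frames = []
    for i in range(n_individuals):
        lab, bp = simulate_meiosis(
            parents, lambda_co, density_profile=density_profile, rng=rng, obligate_co=obligate_co
        )
        labels[i] = lab
        if len(bp):
            bp.insert(0, "individual", i)
            bp_frames.append(bp)
    breakpoints = (
        pd.concat(bp_frames, ignore_index=True)
        if bp_frames
        else pd.DataFrame(columns=["individual", "chrom", "left_pos", "right_pos"])
    )

    # inherited allele from het parent: hap1 -> hap1_allele, hap2 -> complement
    allele = np.where(labels == 0, parents.hap1_allele[None, :], 1 - parents.hap1_allele[None, :])
    truly_het = allele == 1  # inbred parent contributes REF

    depth = rng.poisson(coverage, size=(n_individuals, n_sites)).astype(np.int32)
    # read ALT probability: 1/2 at het sites (error flips are symmetric), e at hom-ref
    p_alt = np.where(truly_het, 0.5, base_error)
    n_alt = rng.binomial(depth, p_alt)

    geno = np.full((n_individuals, n_sites), MISSING, dtype=np.int8)
    covered = depth > 0
    geno[covered & truly_het & (n_alt > 0)] = HET
    geno[covered & truly_het & (n_alt == 0)] = HOM_REF
    hom = covered & ~truly_het
    geno[hom & (n_alt == 0)] = HOM_REF
    geno[hom & (n_alt > 0) & (n_alt < depth)] = HET
    geno[hom & (n_alt == depth)] = HOM_ALT  # every read an error
    if depth_floor > 0:
        geno[depth < depth_floor] = MISSING
    if missing_rate > 0:
        geno[rng.random(geno.shape) < missing_rate] = MISSING

    matrix = SNVMatrix(sites=parents.sites.copy(), genotypes=geno, depth=depth)
    truth = SimTruth(
        labels=labels,
        breakpoints=breakpoints,
        params=dict(
            lambda_co=lambda_co, coverage=coverage, base_error=base_error,
            missing_rate=missing_rate, depth_floor=depth_floor, seed=seed,
        ),
    )
    return matrix, truth


def expected_homalt_rate(coverage: float, base_error: float, het_fraction: float = 0.5) -> float:
    """Closed-form spurious hom-alt call rate under the read model.

    A hom-alt call needs a truly hom-ref site with every read an error:
    P = (1 - het_fraction) * (e^{c(e-1)} - e^{-c}) / (1 - e^{-c}),
    conditioning on at least one read (missing calls excluded).
    """
    num = np.exp(coverage * (base_error - 1)) - np.exp(-coverage)
    return (1 - het_fraction) * num / (1 - np.exp(-coverage))


# ---------------------------------------------------------------------------
# Annotation simulator
# ---------------------------------------------------------------------------

def simulate_annotation(
    layout: GenomeLayout,
    n_genes: int,
    stowaway_tss_bias: float = 0.5,
    n_te: int | None = None,
    seed=None,
    gene_length_range: tuple = (2_000, 5_000),
    spacing_jitter: float = 0.25,
    te_median_length: int = 224,
) -> pd.DataFrame:
    """Generate gene models, promoters, Stowaway-class TEs and intergenic space.

    Genes are placed non-overlapping on a jittered grid; each gene body is an
    exact partition 5'UTR | (exon intron)* exon | 3'UTR.  Promoters are the
    1 kb upstream of each TSS, downstream regions the 1 kb past each TTS.
    Stowaway TEs (length ~ lognormal, median ``te_median_length`` bp) land
    inside a random promoter with probability ``stowaway_tss_bias`` and
    uniformly on the genome otherwise.  Intergenic regions are >= 2 kb from
    gene TSS/TTS, excluding TEs.  Returns a BED-style DataFrame (chrom, start,
    end, feature, strand, name) on 0-based half-open coordinates.
    """
    rng = np.random.default_rng(seed)
    genome = sum(layout.chrom_lengths)
    max_len = gene_length_range[1]
    if n_genes * (max_len + 2_200) > genome:
        raise ValueError(
            f"cannot place {n_genes} genes of up to {max_len} bp plus flanks "
            f"without overlap in a {genome} bp genome"
        )
    # allocate genes proportionally to chromosome length
    alloc = np.floor(n_genes * np.asarray(layout.chrom_lengths) / genome).astype(int)
    for i in range(n_genes - alloc.sum()):
        alloc[i % alloc.size] += 1

    rows = []
    gene_counter = 0
    for name, length, k in zip(layout.chrom_names, layout.chrom_lengths, alloc):
        if k == 0:
            continue
        spacing = length // k
        for g in range(k):
            glen = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
            slack = spacing - glen - 2_200
            base = g * spacing + 1_100
            off = int(rng.integers(0, max(1, int(slack * spacing_jitter)) + 1)) if slack > 0 else 0
            start = base + off
            end = start + glen
            if end + 1_100 > (g + 1) * spacing or end > length:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene{gene_counter:05d}"
            gene_counter += 1
            rows.extend(_gene_parts(name, start, end, strand, gid, rng))
    features = pd.DataFrame(rows, columns=["chrom", "start", "end", "feature", "strand", "name"])

    genes = features[features["feature"] == "gene"]
    # Stowaway TEs
    if n_te is None:
        n_te = max(1, gene_counter * 2)
    te_len = np.maximum(
        50, np.round(rng.lognormal(np.log(te_median_length), 0.25, size=n_te))
    ).astype(int)
    promoters = features[features["feature"] == "promoter"].reset_index(drop=True)
    te_rows = []
    chrom_arr = np.asarray(layout.chrom_names)
    lengths_arr = np.asarray(layout.chrom_lengths)
    p_chrom = lengths_arr / lengths_arr.sum()
    for L in te_len:
        if len(promoters) and rng.random() < stowaway_tss_bias:
            p = promoters.iloc[int(rng.integers(0, len(promoters)))]
            lo, hi = int(p["start"]), int(p["end"]) - int(L)
            if hi <= lo:
                hi = lo + 1
            s = int(rng.integers(lo, hi))
            te_rows.append((p["chrom"], s, s + int(L), "te", p["strand"], "Stowaway"))
        else:
            ci = rng.choice(chrom_arr.size, p=p_chrom)
            s = int(rng.integers(0, max(1, lengths_arr[ci] - L)))
            te_rows.append((chrom_arr[ci], s, s + int(L), "te", "+", "Stowaway"))
    te_df = pd.DataFrame(te_rows, columns=features.columns)
    features = pd.concat([features, te_df], ignore_index=True)

    # intergenic: >= 2 kb from any gene TSS/TTS, excluding TEs
    inter_rows = []
    for name, length in zip(layout.chrom_names, layout.chrom_lengths):
        sub = genes[genes["chrom"] == name]
        blocked_s = np.concatenate([sub["start"].to_numpy() - 2_000, [length]])
        blocked_e = np.concatenate([sub["end"].to_numpy() + 2_000, [length]])
        tes = te_df[te_df["chrom"] == name]
        blocked_s = np.concatenate([blocked_s, tes["start"].to_numpy()])
        blocked_e = np.concatenate([blocked_e, tes["end"].to_numpy()])
        from comapper._intervals import merge_intervals

        ms, me = merge_intervals(np.clip(blocked_s, 0, length), np.clip(blocked_e, 0, length))
        prev = 0
        for s, e in zip(ms, me):
            if s > prev:
                inter_rows.append((name, prev, int(s), "intergenic", "+", "."))
            prev = max(prev, int(e))
        if prev < length:
            inter_rows.append((name, prev, length, "intergenic", "+", "."))
    features = pd.concat(
        [features, pd.DataFrame(inter_rows, columns=features.columns)], ignore_index=True
    )
    return features.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def _gene_parts(chrom, start, end, strand, gid, rng):
    """Partition a gene body into 5'UTR | exon (intron exon)* | 3'UTR exactly."""
    glen = end - start
    utr5, utr3 = 200, 300
    body = glen - utr5 - utr3
    n_exons = int(rng.integers(1, 5))
    # body = sum(exons) + sum(introns); draw cut points
    n_parts = 2 * n_exons - 1
    cuts = np.sort(rng.choice(np.arange(1, body), size=n_parts - 1, replace=False)) if n_parts > 1 else np.array([], int)
    part_lens = np.diff(np.concatenate([[0], cuts, [body]]))
    parts = []
    for i, L in enumerate(part_lens):
        parts.append(("exon" if i % 2 == 0 else "intron", int(L)))
    if strand == "+":
        ordered = [("five_prime_utr", utr5)] + parts + [("three_prime_utr", utr3)]
        promoter = (start - 1_000, start)
        downstream = (end, end + 1_000)
    else:
        ordered = [("three_prime_utr", utr3)] + parts[::-1] + [("five_prime_utr", utr5)]
        promoter = (end, end + 1_000)
        downstream = (start - 1_000, start)
    rows = [(chrom, start, end, "gene", strand, gid)]
    cursor = start
    for feat, L in ordered:
        rows.append((chrom, cursor, cursor + L, feat, strand, gid))
        cursor += L
    assert cursor == end
    rows.append((chrom, promoter[0], promoter[1], "promoter", strand, gid))
    rows.append((chrom, downstream[0], downstream[1], "downstream", strand, gid))
    return rows


# ---------------------------------------------------------------------------
# Writers (plain-text genomics formats)
# ---------------------------------------------------------------------------

def write_truth_bed(truth: SimTruth, path: str) -> None:
    """True crossover gaps as BED6 (0-based half-open: left_pos-1 .. right_pos)."""
    bp = truth.breakpoints
    with open(path, "w") as fh:
        for _, r in bp.iterrows():
            fh.write(
                f"{r['chrom']}\t{int(r['left_pos']) - 1}\t{int(r['right_pos'])}\t"
                f"ind{int(r['individual']):03d}\t.\t+\n"
            )


def write_gff3(features: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in features.iterrows():
            attrs = f"ID={r['name']}" if r["name"] != "." else "."
            fh.write(
                f"{r['chrom']}\tcomapper_sim\t{r['feature']}\t{int(r['start']) + 1}\t"
                f"{int(r['end'])}\t.\t{r['strand']}\t.\t{attrs}\n"
            )


def write_bedgraph(track: pd.DataFrame, path: str) -> None:
    track[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


def simulate_signal_track(
    layout: GenomeLayout, bin_size: int = 1_000, mean: float = 10.0, seed=None,
    smooth: int = 5,
) -> pd.DataFrame:
    """Smooth non-negative coverage-like signal in fixed bins (bedGraph layout)."""
    rng = np.random.default_rng(seed)
    rows = []
    for name, length in zip(layout.chrom_names, layout.chrom_lengths):
        n = int(np.ceil(length / bin_size))
        raw = rng.gamma(shape=2.0, scale=mean / 2.0, size=n)
        if smooth > 1:
            kernel = np.ones(smooth) / smooth
            raw = np.convolve(raw, kernel, mode="same")
        starts = np.arange(n) * bin_size
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends, "value": raw}))
    return pd.concat(rows, ignore_index=True)
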