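"""Interval-level crossover enrichment statistics.

Covers overlap counting against annotated feature classes, Monte-Carlo shuffle
nulls, matched recombination "cold regions", TE-family Fisher tests, aggregate
(metagene-style) signal profiles, binned rank correlations, Poisson
goodness-of-fit of per-chromosome crossover counts, a crossover-count GLM, and
promoter/Stowaway quartile analyses.

Conventions: all intervals are BED-style 0-based half-open DataFrames with at
least ``chrom``, ``start``, ``end``; a 1-bp overlap counts, and a query
touching several feature classes counts towards each of them (per-class rates
therefore need not sum to 1).  Empirical p-values use the add-one estimator
(1 + r) / (1 + N), bounded below by 1 / (N + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from comapper._intervals import count_overlaps, overlaps_any, gap_distance

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Signal tracks (step functions from bedGraph-style tables)
# ---------------------------------------------------------------------------

class SignalTrack:
    """Piecewise-constant genomic signal with fast interval integrals.

    Built from a bedGraph-style DataFrame (chrom, start, end, value) whose
    intervals must not overlap within a chromosome.  Regions not covered by
    any interval have signal 0.
    """

    def __init__(self, track: pd.DataFrame):
        self._chrom = {}
        for chrom, grp in track.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            s = grp["start"].to_numpy(dtype=np.int64)
            e = grp["end"].to_numpy(dtype=np.int64)
            v = grp["value"].to_numpy(dtype=float)
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"overlapping signal intervals on {chrom}")
            cum = np.concatenate([[0.0], np.cumsum(v * (e - s))])
            self._chrom[chrom] = (s, e, v, cum)

    def integral(self, chrom: str, a, b) -> np.ndarray:
        """Integral of the signal over [a, b) (vectorized; float bounds allowed)."""
        a = np.atleast_1d(np.asarray(a, dtype=float))
        b = np.atleast_1d(np.asarray(b, dtype=float))
        if chrom not in self._chrom:
            return np.zeros(a.shape)
        s, e, v, cum = self._chrom[chrom]
        lo = np.searchsorted(e, a, side="right")
        hi = np.searchsorted(s, b, side="left")
        total = cum[hi] - cum[lo]
        has = lo < hi
        lo_c = np.minimum(lo, s.size - 1)
        hi_c = np.maximum(hi - 1, 0)
        head = np.where(has, v[lo_c] * np.maximum(0.0, a - s[lo_c]), 0.0)
        tail = np.where(has, v[hi_c] * np.maximum(0.0, e[hi_c] - b), 0.0)
        out = total - head - tail
        return out

    def mean(self, chrom: str, a, b) -> np.ndarray:
        """Per-base mean signal over [a, b)."""
        a = np.atleast_1d(np.asarray(a, dtype=float))
        b = np.atleast_1d(np.asarray(b, dtype=float))
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.integral(chrom, a, b) / (b - a)


# ---------------------------------------------------------------------------
# Overlap counting and shuffle Monte Carlo
# ---------------------------------------------------------------------------

def overlap_counts(queries: pd.DataFrame, features: pd.DataFrame,
                   class_column: str = "feature") -> pd.DataFrame:
    """Per-class overlap counts and rates (1-bp minimum overlap).

    Returns a DataFrame indexed by feature class with columns ``n_overlap``,
    ``n_queries``, ``rate``; a query counts toward every class it touches.
    """
    classes = list(dict.fromkeys(features[class_column]))
    nq = len(queries)
    rows = {}
    for cls in classes:
        sub = features[features[class_column] == cls]
        hit = np.zeros(nq, dtype=bool)
        for chrom, fgrp in sub.groupby("chrom", sort=False):
            qi = np.flatnonzero((queries["chrom"] == chrom).to_numpy())
            if qi.size == 0:
                continue
            hit[qi] = overlaps_any(
                queries["start"].to_numpy()[qi], queries["end"].to_numpy()[qi],
                fgrp["start"].to_numpy(), fgrp["end"].to_numpy(),
            )
        rows[cls] = int(hit.sum())
    out = pd.DataFrame({"n_overlap": pd.Series(rows)})
    out["n_queries"] = nq
    out["rate"] = out["n_overlap"] / nq if nq else np.nan
    return out


def _random_placement(queries: pd.DataFrame, chrom_lengths: dict,
                      rng: np.random.Generator) -> pd.DataFrame:
    lens = queries["end"].to_numpy() - queries["start"].to_numpy()
    limits = queries["chrom"].map(chrom_lengths).to_numpy(dtype=np.int64)
    if np.any(lens > limits):
        raise ValueError("query interval longer than its chromosome")
    starts = (rng.random(len(queries)) * (limits - lens)).astype(np.int64)
    return pd.DataFrame({"chrom": queries["chrom"].to_numpy(),
                         "start": starts, "end": starts + lens})


def shuffle_mc(
    queries: pd.DataFrame,
    chrom_lengths: dict,
    features: pd.DataFrame,
    n_perm: int = 10_000,
    seed=None,
    class_column: str = "feature",
) -> pd.DataFrame:
    """Empirical enrichment/depletion p-values against a shuffled null.

    Each permutation re-places every query uniformly at random on its own
    chromosome with length preserved.  Per class the table reports the
    observed count/rate, the null mean and SD of the rate, and add-one
    empirical p-values for enrichment (null >= observed) and depletion.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    obs = overlap_counts(queries, features, class_column)
    classes = obs.index.to_list()
    null_counts = np.zeros((n_perm, len(classes)), dtype=np.int64)
    for p in range(n_perm):
        placed = _random_placement(queries, chrom_lengths, rng)
        cnt = overlap_counts(placed, features, class_column)
        null_counts[p] = cnt["n_overlap"].reindex(classes).to_numpy()
    obs_counts = obs["n_overlap"].to_numpy()
    ge = (null_counts >= obs_counts[None, :]).sum(axis=0)
    le = (null_counts <= obs_counts[None, :]).sum(axis=0)
    nq = max(len(queries), 1)
    out = obs.copy()
    out["null_mean_rate"] = null_counts.mean(axis=0) / nq
    out["null_sd_rate"] = null_counts.std(axis=0, ddof=1) / nq if n_perm > 1 else np.nan
    out["p_enrich"] = (1 + ge) / (1 + n_perm)
    out["p_deplete"] = (1 + le) / (1 + n_perm)
    return out


# ---------------------------------------------------------------------------
# Matched cold regions
# ---------------------------------------------------------------------------

class ColdRegionError(RuntimeError):
    def __init__(self, message: str, report: pd.DataFrame | None = None):
        super().__init__(message)
        self.report = report


def _snv_count(snv_pos_by_chrom: dict, chrom: str, start: int, end: int) -> int:
    pos = snv_pos_by_chrom.get(chrom)
    if pos is None:
        return 0
    # pos is 1-based; interval 0-based half-open covers bases start+1..end
    return int(np.searchsorted(pos, end, "right") - np.searchsorted(pos, start, "right"))


def sample_cold_regions(
    crossovers: pd.DataFrame,
    chrom_lengths: dict,
    gc: "SignalTrack",
    snvs: pd.DataFrame,
    seed=None,
    max_tries: int = 2_000,
    min_dist: int = 10_000,
    max_dist: int = 1_000_000,
    gc_tol: float = 0.10,
    snv_tol: float = 0.10,
) -> pd.DataFrame:
    """Rejection-sample one matched non-crossover control per crossover.

    Criteria per control: (i) GC within ``gc_tol`` (relative) of its matched
    crossover; (ii) between ``min_dist`` and ``max_dist`` from any crossover;
    (iii) identical length; (iv) SNV density within ``snv_tol`` (relative);
    (v) same chromosome.  Fails loudly after ``max_tries`` proposals for any
    crossover, naming the criterion that failed most often.
    """
    rng = np.random.default_rng(seed)
    snv_by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in snvs.groupby("chrom", sort=False)}
    co_by_chrom = {
        c: (g["start"].to_numpy(np.int64), g["end"].to_numpy(np.int64))
        for c, g in crossovers.groupby("chrom", sort=False)
    }
    rows, failures = [], []
    for qid, q in crossovers.reset_index(drop=True).iterrows():
        chrom, qs, qe = q["chrom"], int(q["start"]), int(q["end"])
        L = qe - qs
        limit = int(chrom_lengths[chrom])
        gc_q = float(gc.mean(chrom, qs, qe)[0])
        snv_q = _snv_count(snv_by_chrom, chrom, qs, qe)
        fail = {"bounds": 0, "distance": 0, "gc": 0, "snv_density": 0}
        placed = None
        for _ in range(max_tries):
            d = int(rng.integers(min_dist, max_dist + 1))
            if rng.random() < 0.5:
                cs = qs - d - L
            else:
                cs = qe + d
            ce = cs + L
            if cs < 0 or ce > limit:
                fail["bounds"] += 1
                continue
            dist = int(gap_distance([cs], [ce], *co_by_chrom[chrom])[0])
            if not (min_dist <= dist <= max_dist):
                fail["distance"] += 1
                continue
            gc_c = float(gc.mean(chrom, cs, ce)[0])
            gc_ref = gc_q if gc_q > 0 else 1e-9
            if abs(gc_c - gc_q) > gc_tol * gc_ref:
                fail["gc"] += 1
                continue
            snv_c = _snv_count(snv_by_chrom, chrom, cs, ce)
            if snv_q == 0:
                ok_snv = snv_c == 0
            else:
                ok_snv = abs(snv_c - snv_q) <= snv_tol * snv_q
            if not ok_snv:
                fail["snv_density"] += 1
                continue
            placed = (cs, ce, gc_c, snv_c, dist)
            break
        if placed is None:
            worst = max(fail, key=fail.get)
            failures.append({"match_id": qid, "chrom": chrom, **fail, "worst": worst})
            continue
        cs, ce, gc_c, snv_c, dist = placed
        rows.append(
            {"chrom": chrom, "start": cs, "end": ce, "match_id": qid,
             "gc": gc_c, "snv_density": snv_c / L, "distance": dist}
        )
    if failures:
        report = pd.DataFrame(failures)
        worst = report["worst"].mode().iat[0]
        raise ColdRegionError(
            f"could not match {len(failures)} crossover(s) after {max_tries} tries each; "
            f"most violated criterion: {worst}", report,
        )
    return pd.DataFrame(rows)


def validate_cold_regions(
    cold: pd.DataFrame,
    crossovers: pd.DataFrame,
    gc: "SignalTrack",
    snvs: pd.DataFrame,
    min_dist: int = 10_000,
    max_dist: int = 1_000_000,
    gc_tol: float = 0.10,
    snv_tol: float = 0.10,
) -> pd.DataFrame:
    """Independent post-hoc checker of criteria (i)-(v) for every cold region."""
    snv_by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in snvs.groupby("chrom", sort=False)}
    co = crossovers.reset_index(drop=True)
    rows = []
    for _, r in cold.iterrows():
        q = co.iloc[int(r["match_id"])]
        chrom = r["chrom"]
        cs, ce = int(r["start"]), int(r["end"])
        qs, qe = int(q["start"]), int(q["end"])
        on_chrom = co[co["chrom"] == chrom]
        dist = int(
            gap_distance([cs], [ce], on_chrom["start"].to_numpy(), on_chrom["end"].to_numpy())[0]
        )
        gc_c = float(gc.mean(chrom, cs, ce)[0])
        gc_q = float(gc.mean(chrom, qs, qe)[0])
        snv_c = _snv_count(snv_by_chrom, chrom, cs, ce)
        snv_q = _snv_count(snv_by_chrom, chrom, qs, qe)
        rows.append(
            {
                "gc_ok": abs(gc_c - gc_q) <= gc_tol * (gc_q if gc_q > 0 else 1e-9),
                "distance_ok": min_dist <= dist <= max_dist,
                "length_ok": (ce - cs) == (qe - qs),
                "snv_ok": (snv_c == snv_q == 0)
                or (snv_q > 0 and abs(snv_c - snv_q) <= snv_tol * snv_q),
                "chrom_ok": chrom == q["chrom"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TE-family Fisher tests
# ---------------------------------------------------------------------------

def te_family_fisher(
    crossovers: pd.DataFrame,
    cold: pd.DataFrame,
    te_features: pd.DataFrame,
    family_column: str = "family",
) -> pd.DataFrame:
    """Two-sided Fisher's exact test per TE family, crossovers vs cold regions.

    Contingency per family: regions containing >= 1 element vs not, in each
    set.  Bonferroni correction across tested families; families absent from
    both sets are skipped.
    """
    families = list(dict.fromkeys(te_features[family_column]))
    rows = []
    for fam in families:
        sub = te_features[te_features[family_column] == fam]
        a = _n_containing(crossovers, sub)
        b = len(crossovers) - a
        c = _n_containing(cold, sub)
        d = len(cold) - c
        if a == 0 and c == 0:
            continue
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"family": fam, "co_with": a, "co_without": b,
                     "cold_with": c, "cold_without": d, "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out


def _n_containing(regions: pd.DataFrame, features: pd.DataFrame) -> int:
    total = 0
    for chrom, fgrp in features.groupby("chrom", sort=False):
        sub = regions[regions["chrom"] == chrom]
        if not len(sub):
            continue
        total += int(
            overlaps_any(
                sub["start"].to_numpy(), sub["end"].to_numpy(),
                fgrp["start"].to_numpy(), fgrp["end"].to_numpy(),
            ).sum()
        )
    return total


def element_counts(regions: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    """Number of feature elements overlapping each region."""
    out = np.zeros(len(regions), dtype=np.int64)
    for chrom, fgrp in features.groupby("chrom", sort=False):
        qi = np.flatnonzero((regions["chrom"] == chrom).to_numpy())
        if qi.size == 0:
            continue
        out[qi] = count_overlaps(
            regions["start"].to_numpy()[qi], regions["end"].to_numpy()[qi],
            fgrp["start"].to_numpy(), fgrp["end"].to_numpy(),
        )
    return out


# ---------------------------------------------------------------------------
# Aggregate profiles
# ---------------------------------------------------------------------------

@dataclass
class AggregateProfile:
    """Mean per-nucleotide-normalized signal around anchors.

    ``profile`` has length 2 * n_flank_bins + body_bins (upstream flank, body,
    downstream flank, 5'->3' after strand flipping).  ``null_mean``/``null_sd``
    give the permutation band (anchors re-placed uniformly on their own
    chromosome); +-2 SD is the conventional envelope.
    """

    profile: np.ndarray
    body_bins: int
    flank_bins: int
    n_anchors: int
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None


def aggregate_profile(
    anchors: pd.DataFrame,
    signal: SignalTrack,
    body_bins: int = 50,
    flank: int = 5_000,
    flank_bin: int = 10,
    n_perm: int = 0,
    chrom_lengths: dict | None = None,
    seed=None,
) -> AggregateProfile:
    """Average signal over anchors scaled to ``body_bins`` windows plus fixed
    ``flank_bin``-bp flank bins out to ``flank`` bp each side.

    Unstranded anchors ('.' or missing strand) are treated as plus strand;
    minus-strand anchors are flipped.  Anchors shorter than ``body_bins`` bp
    are skipped (logged).  With ``n_perm`` > 0 a permutation null band is
    computed (requires ``chrom_lengths``).
    """
    rng = np.random.default_rng(seed)
    mat = _profile_matrix(anchors, signal, body_bins, flank, flank_bin)
    if mat.shape[0] == 0:
        raise ValueError("no usable anchors")
    prof = AggregateProfile(
        profile=mat.mean(axis=0), body_bins=body_bins,
        flank_bins=flank // flank_bin, n_anchors=mat.shape[0],
    )
    if n_perm > 0:
        if chrom_lengths is None:
            raise ValueError("chrom_lengths required for the permutation band")
        null = np.empty((n_perm, prof.profile.size))
        for p in range(n_perm):
            placed = _random_placement(anchors, chrom_lengths, rng)
            placed["strand"] = anchors.get("strand", pd.Series(["+"] * len(anchors))).to_numpy()
            null[p] = _profile_matrix(placed, signal, body_bins, flank, flank_bin).mean(axis=0)
        prof.null_mean = null.mean(axis=0)
        prof.null_sd = null.std(axis=0, ddof=1)
    return prof


def _profile_matrix(anchors, signal, body_bins, flank, flank_bin):
    n_flank = flank // flank_bin
    out = []
    strands = anchors["strand"] if "strand" in anchors else pd.Series(["+"] * len(anchors))
    for (_, a), strand in zip(anchors.iterrows(), strands):
        s, e = int(a["start"]), int(a["end"])
        if e - s < body_bins:
            log.info("anchor %s:%d-%d shorter than %d bp; skipped", a["chrom"], s, e, body_bins)
            continue
        chrom = a["chrom"]
        body_edges = s + (e - s) * np.arange(body_bins + 1) / body_bins
        body = signal.mean(chrom, body_edges[:-1], body_edges[1:])
        up_edges = s - flank + flank_bin * np.arange(n_flank + 1)
        up = signal.mean(chrom, up_edges[:-1], up_edges[1:])
        down_edges = e + flank_bin * np.arange(n_flank + 1)
        down = signal.mean(chrom, down_edges[:-1], down_edges[1:])
        vec = np.concatenate([up, body, down])
        if strand == "-":
            vec = vec[::-1]
        out.append(vec)
    return np.asarray(out) if out else np.zeros((0, 2 * n_flank + body_bins))


# ---------------------------------------------------------------------------
# Distance-banded signal Monte Carlo
# ---------------------------------------------------------------------------

def signal_mc(
    queries: pd.DataFrame,
    signal: SignalTrack,
    chrom_lengths: dict,
    n_perm: int = 10_000,
    seed=None,
    min_dist: int = 10_000,
    max_dist: int = 1_000_000,
) -> dict:
    """Empirical p for the mean per-base signal over queries vs length-matched
    regions sampled 10-1000 kb away (same chromosome).

    Returns observed mean, null mean/SD, and add-one p-values for enrichment
    and depletion.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    obs = _mean_signal(queries, signal)
    # precompute feasible placement bands per query
    bands = []
    for _, q in queries.iterrows():
        L = int(q["end"]) - int(q["start"])
        limit = int(chrom_lengths[q["chrom"]])
        segs = []
        lo, hi = int(q["start"]) - max_dist - L, int(q["start"]) - min_dist - L
        lo, hi = max(lo, 0), min(hi, limit - L)
        if hi > lo:
            segs.append((lo, hi))
        lo, hi = int(q["end"]) + min_dist, int(q["end"]) + max_dist
        lo, hi = max(lo, 0), min(hi, limit - L)
        if hi > lo:
            segs.append((lo, hi))
        if not segs:
            raise ValueError(f"no feasible placement band for query at {q['chrom']}:{q['start']}")
        bands.append((q["chrom"], L, segs))
    null = np.empty(n_perm)
    for p in range(n_perm):
        vals = np.empty(len(bands))
        for i, (chrom, L, segs) in enumerate(bands):
            w = np.array([h - l for l, h in segs], dtype=float)
            k = rng.choice(len(segs), p=w / w.sum())
            s = int(rng.integers(segs[k][0], segs[k][1]))
            vals[i] = signal.mean(chrom, s, s + L)[0]
        null[p] = vals.mean()
    return {
        "observed": obs,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)) if n_perm > 1 else np.nan,
        "p_enrich": float((1 + (null >= obs).sum()) / (1 + n_perm)),
        "p_deplete": float((1 + (null <= obs).sum()) / (1 + n_perm)),
    }


def _mean_signal(regions: pd.DataFrame, signal: SignalTrack) -> float:
    vals = [
        float(signal.mean(r["chrom"], int(r["start"]), int(r["end"]))[0])
        for _, r in regions.iterrows()
    ]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Binned correlations
# ---------------------------------------------------------------------------

def bin_positions(positions: pd.DataFrame, chrom_lengths: dict, bin_size: int) -> pd.DataFrame:
    """Count 1-based point positions (chrom, pos) into fixed bins."""
    rows = []
    for chrom, length in chrom_lengths.items():
        edges = np.arange(0, int(length) + bin_size, bin_size)
        edges[-1] = min(edges[-1], int(length))
        sub = positions[positions["chrom"] == chrom]
        cnt, _ = np.histogram(sub["pos"].to_numpy() - 1, bins=edges)
        rows.append(pd.DataFrame({"chrom": chrom, "start": edges[:-1], "end": edges[1:], "value": cnt}))
    return pd.concat(rows, ignore_index=True)


def bin_track(signal: SignalTrack, chrom_lengths: dict, bin_size: int, how: str = "sum") -> pd.DataFrame:
    """Sum or average a signal track over fixed bins (sum for read counts,
    mean for methylation levels)."""
    rows = []
    for chrom, length in chrom_lengths.items():
        edges = np.arange(0, int(length) + bin_size, bin_size, dtype=float)
        edges[-1] = min(edges[-1], float(length))
        if how == "sum":
            val = signal.integral(chrom, edges[:-1], edges[1:])
        else:
            val = signal.mean(chrom, edges[:-1], edges[1:])
        rows.append(pd.DataFrame({"chrom": chrom, "start": edges[:-1].astype(int),
                                  "end": edges[1:].astype(int), "value": val}))
    return pd.concat(rows, ignore_index=True)


@dataclass
class BinnedCorrelation:
    rho: pd.DataFrame
    pvalues: pd.DataFrame
    per_chrom: dict = field(default_factory=dict)


def binned_stats(tracks: dict, min_bins: int = 10) -> BinnedCorrelation:
    """Spearman rank correlations between binned tracks (ties mid-ranked).

    ``tracks`` maps name -> DataFrame (chrom, start, [end,] value) on a common
    binning.  Constant tracks give NaN correlations (flagged in the log).
    Returns genome-wide and per-chromosome correlation matrices.
    """
    names = list(tracks)
    base = tracks[names[0]][["chrom", "start"]].copy()
    for name in names:
        t = tracks[name]
        base = base.merge(
            t[["chrom", "start", "value"]].rename(columns={"value": name}),
            on=["chrom", "start"], how="inner",
        )
    if len(base) < min_bins:
        raise ValueError(f"need at least {min_bins} shared bins, got {len(base)}")
    for name in names:
        if base[name].nunique() <= 1:
            log.warning("track %s is constant; correlations will be NaN", name)

    def _matrix(df):
        k = len(names)
        rho = np.full((k, k), np.nan)
        pv = np.full((k, k), np.nan)
        for i in range(k):
            for j in range(i, k):
                xi, xj = df[names[i]], df[names[j]]
                if xi.nunique() > 1 and xj.nunique() > 1:
                    r, p = stats.spearmanr(xi, xj)
                    rho[i, j] = rho[j, i] = r
                    pv[i, j] = pv[j, i] = p
                elif i == j:
                    rho[i, j] = 1.0 if xi.nunique() > 1 else np.nan
        return (pd.DataFrame(rho, index=names, columns=names),
                pd.DataFrame(pv, index=names, columns=names))

    rho, pv = _matrix(base)
    per_chrom = {}
    for chrom, grp in base.groupby("chrom", sort=False):
        if len(grp) >= min_bins:
            per_chrom[chrom] = _matrix(grp)[0]
    return BinnedCorrelation(rho=rho, pvalues=pv, per_chrom=per_chrom)


# ---------------------------------------------------------------------------
# Poisson goodness-of-fit of crossover counts
# ---------------------------------------------------------------------------

@dataclass
class PoissonFit:
    lam: float
    categories: list
    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    pvalue: float
    small_sample: bool = False


def poisson_fit_counts(counts, max_category: int = 3) -> PoissonFit:
    """Fit Poisson(lambda = mean) to per-individual crossover counts and test
    the fit with a multinomial chi-square over categories 0..max_category-1
    and a pooled >= max_category tail."""
    counts = np.asarray(counts, dtype=int)
    n = counts.size
    lam = float(counts.mean())
    cats = list(range(max_category)) + [max_category]
    probs = np.array([stats.poisson.pmf(c, lam) for c in range(max_category)]
                     + [stats.poisson.sf(max_category - 1, lam)])
    expected = probs * n
    observed = np.array([(counts == c).sum() for c in range(max_category)]
                        + [(counts >= max_category).sum()])
    small = n < 20
    if small:
        log.warning("only %d individuals; goodness-of-fit test may be unreliable", n)
    if lam == 0:
        return PoissonFit(lam, cats, observed, expected, 0.0, 1.0, small)
    keep = expected > 0
    stat = float(((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum())
    dof = int(keep.sum()) - 1 - 1  # one estimated parameter
    pvalue = float(stats.chi2.sf(stat, max(dof, 1)))
    return PoissonFit(lam, cats, observed, expected, stat, pvalue, small)


# ---------------------------------------------------------------------------
# Crossover-count GLM
# ---------------------------------------------------------------------------

@dataclass
class GLMResult:
    model: object
    anova: pd.DataFrame
    dropped: list
    overdispersion: float


def glm_crossovers(data: pd.DataFrame, response: str, covariates: list,
                   family: str = "poisson") -> GLMResult:
    """Poisson log-link GLM of window crossover counts on genomic/chromatin
    covariates, with a sequential (type-I) deviance ANOVA.

    Rank-deficient designs drop the offending columns with a warning.  The
    Pearson overdispersion ratio is reported; a quasi-Poisson-style rescaling
    is left to the caller if it is large.
    """
    import statsmodels.api as sm

    fam = {"poisson": sm.families.Poisson()}[family]
    kept = []
    for c in covariates:
        X = data[kept + [c]].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(X)), X])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            log.warning("covariate %s is collinear with earlier terms; dropped", c)
            continue
        kept.append(c)
    y = data[response].to_numpy(dtype=float)
    devs = []
    prev = sm.GLM(y, np.ones((len(y), 1)), family=fam).fit()
    rows = []
    for i, c in enumerate(kept):
        X = sm.add_constant(data[kept[: i + 1]].to_numpy(dtype=float))
        fit = sm.GLM(y, X, family=fam).fit()
        ddev = prev.deviance - fit.deviance
        rows.append({"term": c, "df": 1, "deviance": ddev,
                     "resid_deviance": fit.deviance,
                     "p": float(stats.chi2.sf(max(ddev, 0.0), 1))})
        prev = fit
        devs.append(ddev)
    anova = pd.DataFrame(rows)
    overdisp = float(prev.pearson_chi2 / prev.df_resid) if prev.df_resid > 0 else np.nan
    if overdisp > 2:
        log.warning("overdispersion ratio %.2f; consider quasi-Poisson scaling", overdisp)
    return GLMResult(model=prev, anova=anova,
                     dropped=[c for c in covariates if c not in kept],
                     overdispersion=overdisp)


# ---------------------------------------------------------------------------
# Promoter / Stowaway quartile analyses
# ---------------------------------------------------------------------------

def promoter_quartile_analysis(
    promoters: pd.DataFrame,
    stowaway: pd.DataFrame,
    recomb_track: pd.DataFrame,
    n_perm: int = 10_000,
    seed=None,
    match_dist: int = 500_000,
) -> dict:
    """Two reciprocal promoter/TE analyses against the recombination-rate track.

    (a) Stowaway counts per promoter, compared between promoters overlying
        top-quartile vs bottom-quartile recombination windows (two-sided
        Wilcoxon rank-sum).
    (b) Mean window-scaled recombination rate of promoters carrying >= 1
        Stowaway vs a permutation null drawing, per carrier, one nearby
        (<= ``match_dist``) promoter without a Stowaway.
    """
    rng = np.random.default_rng(seed)
    prom = promoters.reset_index(drop=True).copy()
    prom["te_count"] = element_counts(prom, stowaway)
    prom["mid"] = (prom["start"] + prom["end"]) // 2
    # rate of the window containing the promoter midpoint
    rates = np.full(len(prom), np.nan)
    for chrom, grp in recomb_track.groupby("chrom", sort=False):
        qi = np.flatnonzero((prom["chrom"] == chrom).to_numpy())
        if qi.size == 0:
            continue
        starts = grp["start"].to_numpy()
        idx = np.clip(np.searchsorted(starts, prom["mid"].to_numpy()[qi], "right") - 1, 0, len(grp) - 1)
        rates[qi] = grp["rate"].to_numpy()[idx]
    prom["rate"] = rates

    q1, q3 = np.nanquantile(recomb_track["rate"], [0.25, 0.75])
    top = prom[prom["rate"] >= q3]
    bottom = prom[prom["rate"] <= q1]
    if not len(top) or not len(bottom):
        raise ValueError("empty recombination quartile group")
    u_stat, u_p = stats.mannwhitneyu(top["te_count"], bottom["te_count"], alternative="two-sided")

    carriers = prom[prom["te_count"] >= 1]
    empty = prom[prom["te_count"] == 0]
    matched_pools = []
    used = []
    for _, c in carriers.iterrows():
        pool = empty[(empty["chrom"] == c["chrom"]) & ((empty["mid"] - c["mid"]).abs() <= match_dist)]
        if len(pool):
            matched_pools.append(pool["rate"].to_numpy())
            used.append(c["rate"])
    result_b = None
    if matched_pools:
        obs = float(np.mean(used))
        null = np.empty(n_perm)
        for p in range(n_perm):
            null[p] = float(np.mean([pool[rng.integers(0, pool.size)] for pool in matched_pools]))
        result_b = {
            "observed_mean_rate": obs,
            "null_mean": float(null.mean()),
            "p_enrich": float((1 + (null >= obs).sum()) / (1 + n_perm)),
            "n_pairs": len(matched_pools),
        }
    return {
        "quartile_test": {"statistic": float(u_stat), "p": float(u_p),
                          "n_top": len(top), "n_bottom": len(bottom),
                          "mean_top": float(top["te_count"].mean()),
                          "mean_bottom": float(bottom["te_count"].mean())},
        "carrier_test": result_b,
    }
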