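"""Genetic maps, Marey maps and interpolated recombination-rate tracks.

Each haplotype window is a genetic marker in physical order (the assembly is
assumed collinear with the genetic map).  The recombination fraction r between
adjacent markers is the fraction of informative individuals whose calls
differ; a map function (Haldane by default, Kosambi optional) converts r to a
cM increment, and the cumulative genetic position against the marker's
physical midpoint forms the Marey map.  A cubic spline of cM against bp,
evaluated on fixed windows (default 100 kb), yields the local recombination
rate in cM/Mb; negative spline wiggles are clipped to zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, UnivariateSpline

from comapper.variants import MISSING
from comapper.window_caller import WindowCalls

log = logging.getLogger(__name__)

_R_MAX = 0.4999999


def haldane(r):
    """Haldane map distance in cM: d = -50 ln(1 - 2r) (no interference)."""
    r = np.minimum(np.asarray(r, dtype=float), _R_MAX)
    return -50.0 * np.log1p(-2.0 * r)


def kosambi(r):
    """Kosambi map distance in cM: d = 25 ln((1 + 2r) / (1 - 2r))."""
    r = np.minimum(np.asarray(r, dtype=float), _R_MAX)
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


_MAP_FUNCTIONS = {"haldane": haldane, "kosambi": kosambi}


def genetic_positions(wc: WindowCalls, map_function: str = "haldane") -> pd.DataFrame:
    """Marey map: per marker chrom, physical midpoint (bp) and cM position.

    cM starts at 0 on each chromosome and is non-decreasing by construction.
    Marker pairs with zero informative individuals contribute a 0 cM increment
    and are flagged in the log.
    """
    fn = _MAP_FUNCTIONS[map_function]
    out = []
    for chrom, grp in wc.windows.groupby("chrom", sort=False):
        widx = grp.index.to_numpy()
        calls = wc.calls[widx].copy()
        # bridge missing calls so a haplotype switch across a low-coverage or
        # tied window is still counted exactly once
        for j in range(calls.shape[1]):
            col = calls[:, j]
            last = MISSING
            for i in range(col.size):
                if col[i] == MISSING:
                    col[i] = last
                else:
                    last = col[i]
        mids = grp["mid_pos"].to_numpy()
        cm = np.zeros(widx.size)
        for i in range(1, widx.size):
            a, b = calls[i - 1], calls[i]
            inf = (a != MISSING) & (b != MISSING)
            n_inf = int(inf.sum())
            if n_inf == 0:
                log.warning("no informative individuals between markers %d/%d on %s", i - 1, i, chrom)
                inc = 0.0
            else:
                r = float((a[inf] != b[inf]).mean())
                inc = float(fn(r))
            cm[i] = cm[i - 1] + inc
        out.append(pd.DataFrame({"chrom": chrom, "pos": mids, "cm": cm}))
    return pd.concat(out, ignore_index=True)


def map_length(marey: pd.DataFrame) -> pd.Series:
    """Total genetic length (cM) per chromosome."""
    return marey.groupby("chrom", sort=False)["cm"].max()


def interpolate_rate(
    marey: pd.DataFrame,
    chrom_lengths: dict,
    window: int = 100_000,
    smoothing: float | None = None,
) -> pd.DataFrame:
    """Interpolate recombination rate (cM/Mb) onto fixed windows.

    A cubic spline of cumulative cM vs bp is evaluated at window edges; the
    rate is the cM increment divided by the window size in Mb.  With
    ``smoothing=None`` the interpolating cubic spline is used (conserves map
    length exactly up to clipping); a positive value fits a smoothing spline
    with that residual budget.  Chromosomes with fewer than 4 markers fall
    back to piecewise-linear interpolation (flagged).  Windows outside the
    marker span get rate 0.
    """
    rows = []
    for chrom, grp in marey.groupby("chrom", sort=False):
        length = int(chrom_lengths[chrom])
        pos = grp["pos"].to_numpy(dtype=float)
        cm = grp["cm"].to_numpy(dtype=float)
        pos, idx = np.unique(pos, return_index=True)
        cm = cm[idx]
        edges = np.arange(0, length + window, window, dtype=float)
        edges[-1] = min(edges[-1], length)
        if pos.size < 2:
            rate = np.zeros(edges.size - 1)
        else:
            if pos.size < 4:
                log.warning("chromosome %s has <4 markers; linear interpolation", chrom)
                cm_at = np.interp(np.clip(edges, pos[0], pos[-1]), pos, cm)
            elif smoothing is None:
                spl = CubicSpline(pos, cm)
                cm_at = spl(np.clip(edges, pos[0], pos[-1]))
            else:
                spl = UnivariateSpline(pos, cm, k=3, s=smoothing)
                cm_at = spl(np.clip(edges, pos[0], pos[-1]))
            rate = np.diff(cm_at) / (np.diff(edges) / 1e6)
            n_neg = int((rate < 0).sum())
            if n_neg:
                log.info("clipping %d negative rate window(s) on %s", n_neg, chrom)
            rate = np.maximum(rate, 0.0)
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": edges[:-1].astype(int),
                 "end": edges[1:].astype(int), "rate": rate}
            )
        )
    return pd.concat(rows, ignore_index=True)
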