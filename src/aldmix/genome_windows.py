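"""Genetic maps and the fixed-width window tiling of the genome.

Markers are placed on the centimorgan (cM) scale by piecewise-linear
interpolation of a genetic map, and each chromosome is tiled into
equally sized windows (default 0.1 cM) that group markers for the
principal-component analysis of local LD.  Windows -- not individual
markers -- are the unit of analysis of the ancestry HMM; the genetic
distance between consecutive window midpoints, ``d``, drives its
transition probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "WindowSet",
    "normalize_chrom",
    "read_genetic_map",
    "interpolate_cm",
    "build_windows",
]


def normalize_chrom(label) -> str:
    """Normalize a chromosome label: 'chr20' and '20' are the same chromosome."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper()  # 'x' -> 'X'


@dataclass
class GeneticMap:
    """Marker coordinates in base pairs and centimorgans.

    One row per map point: ``id``, ``chromosome`` (normalized label),
    ``position_bp`` (1-based, as in VCF) and ``position_cm``.  Within a
    chromosome cM must be non-decreasing in bp and ids unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "chromosome", "position_bp", "position_cm"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"genetic map missing columns: {sorted(missing)}")
        tab = self.table.copy()
        tab["chromosome"] = tab["chromosome"].map(normalize_chrom)
        tab = tab.sort_values(["chromosome", "position_bp"], kind="mergesort")
        tab = tab.reset_index(drop=True)
        for chrom, sub in tab.groupby("chromosome", sort=False):
            cm = sub["position_cm"].to_numpy(float)
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM not non-decreasing on chromosome {chrom}")
            if sub["id"].duplicated().any():
                raise ValueError(f"duplicate marker ids on chromosome {chrom}")
        self.table = tab

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chromosome"]))

    def chrom_slice(self, chromosome) -> pd.DataFrame:
        chrom = normalize_chrom(chromosome)
        sub = self.table[self.table["chromosome"] == chrom]
        if sub.empty:
            raise KeyError(f"unknown chromosome label: {chromosome!r}")
        return sub


def read_genetic_map(path) -> GeneticMap:
    """Read a 3- or 4-column whitespace/tab genetic map.

    Accepted dialects: ``chromosome bp cM`` or ``chromosome id bp cM``,
    with or without a header line.  Chromosome labels are normalized.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    # drop a header row if the bp column is not numeric
    first = df.iloc[0]
    if not str(first.iloc[-2]).replace(".", "", 1).lstrip("-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] == 3:
        df.columns = ["chromosome", "position_bp", "position_cm"]
        df["id"] = [f"m{i}" for i in range(len(df))]
    elif df.shape[1] == 4:
        df.columns = ["chromosome", "id", "position_bp", "position_cm"]
    else:
        raise ValueError(f"expected 3 or 4 columns in genetic map, got {df.shape[1]}")
    df["position_bp"] = df["position_bp"].astype(np.int64)
    df["position_cm"] = df["position_cm"].astype(float)
    return GeneticMap(df[["id", "chromosome", "position_bp", "position_cm"]])


def interpolate_cm(gmap: GeneticMap, positions_bp, chromosome) -> np.ndarray:
    """Interpolate bp positions to cM on one chromosome.

    Piecewise linear between flanking map points; positions beyond the
    map ends are extrapolated at the terminal interval's cM/bp rate.
    Output is non-decreasing for non-decreasing input.
    """
    sub = gmap.chrom_slice(chromosome)
    xp = sub["position_bp"].to_numpy(float)
    fp = sub["position_cm"].to_numpy(float)
    pos = np.asarray(positions_bp, dtype=float)
    if xp.size == 1:
        return np.full(pos.shape, fp[0])
    out = np.interp(pos, xp, fp)
    # linear extrapolation at the nearest interval's rate
    lo_rate = (fp[1] - fp[0]) / max(xp[1] - xp[0], 1.0)
    hi_rate = (fp[-1] - fp[-2]) / max(xp[-1] - xp[-2], 1.0)
    below = pos < xp[0]
    above = pos > xp[-1]
    out[below] = fp[0] + (pos[below] - xp[0]) * lo_rate
    out[above] = fp[-1] + (pos[above] - xp[-1]) * hi_rate
    return out


@dataclass
class WindowSet:
    """Fixed-width window tiling of sorted markers.

    ``table`` has one row per non-empty window: chromosome, start_cm,
    end_cm (half-open), midpoint_cm (mean cM of member markers),
    width_cm, n_markers, start (index of first member marker), stop
    (one past last) and d_cm, the distance to the previous window's
    midpoint (NaN for the first window of each chromosome).  Member
    markers of a window form a contiguous index range because markers
    are sorted by (chromosome, cM).
    """

    table: pd.DataFrame
    window_cm: float
    marker_cm: np.ndarray = field(repr=False)
    marker_chrom: np.ndarray = field(repr=False)

    @property
    def n_windows(self) -> int:
        return len(self.table)

    def members(self, j: int) -> np.ndarray:
        row = self.table.iloc[j]
        return np.arange(int(row["start"]), int(row["stop"]))

    @property
    def d_cm(self) -> np.ndarray:
        return self.table["d_cm"].to_numpy(float)

    @property
    def marker_window(self) -> np.ndarray:
        """Window index of every marker."""
        counts = self.table["n_markers"].to_numpy(int)
        return np.repeat(np.arange(self.n_windows), counts)

    def chrom_first(self) -> np.ndarray:
        """Boolean mask: window is the first of its chromosome."""
        chroms = self.table["chromosome"].to_numpy()
        first = np.ones(self.n_windows, dtype=bool)
        first[1:] = chroms[1:] != chroms[:-1]
        return first


def build_windows(marker_chrom, marker_cm, window_cm: float = 0.1) -> WindowSet:
    """Tile markers into fixed-width cM windows.

    Windows are ``[k*w, (k+1)*w)`` anchored at the first marker's cM of
    each chromosome, so a leading empty window never occurs; empty
    windows are dropped.  Every marker lands in exactly one window.
    """
    if window_cm <= 0:
        raise ValueError("window_cm must be positive")
    cm = np.asarray(marker_cm, dtype=float)
    if cm.size == 0:
        raise ValueError("no markers to window")
    chroms = np.asarray([normalize_chrom(c) for c in np.atleast_1d(marker_chrom)])
    if chroms.size == 1 and cm.size > 1:
        chroms = np.repeat(chroms, cm.size)
    if chroms.shape != cm.shape:
        raise ValueError("marker_chrom and marker_cm lengths differ")

    rows = []
    order = np.lexsort((cm, chroms))
    if not np.array_equal(order, np.arange(cm.size)):
        # keep chromosome blocks in first-appearance order but require sorted cM
        for c in dict.fromkeys(chroms):
            sub = cm[chroms == c]
            if np.any(np.diff(sub) < 0):
                raise ValueError(f"marker cM not sorted within chromosome {c}")
    idx = 0
    for c in dict.fromkeys(chroms):
        mask = chroms == c
        where = np.nonzero(mask)[0]
        if where[-1] - where[0] + 1 != where.size:
            raise ValueError(f"markers of chromosome {c} are not contiguous")
        sub = cm[mask]
        anchor = sub[0]
        bins = np.floor((sub - anchor) / window_cm).astype(int)
        # guard against float round-down at exact window edges
        bins = np.maximum(bins, 0)
        prev_mid = None
        for b in np.unique(bins):
            members = np.nonzero(bins == b)[0]
            mid = float(sub[members].mean())
            d = np.nan if prev_mid is None else mid - prev_mid
            rows.append(
                {
                    "chromosome": c,
                    "start_cm": anchor + b * window_cm,
                    "end_cm": anchor + (b + 1) * window_cm,
                    "midpoint_cm": mid,
                    "width_cm": window_cm,
                    "n_markers": len(members),
                    "start": idx + members[0],
                    "stop": idx + members[-1] + 1,
                    "d_cm": d,
                }
            )
            prev_mid = mid
        idx += mask.sum()
    table = pd.DataFrame(rows)
    bad = table["d_cm"].to_numpy() <= 0
    if np.any(bad & ~np.isnan(table["d_cm"].to_numpy())):
        raise ValueError("non-positive inter-window distance; markers unsorted?")
    return WindowSet(table=table, window_cm=window_cm, marker_cm=cm, marker_chrom=chroms)
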