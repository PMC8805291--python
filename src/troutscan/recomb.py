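"""Linkage-map anchoring and local recombination-rate estimation.

A linkage map (marker, linkage group, cM) is anchored onto physical
coordinates through tabular sequence-similarity hits (12-column outfmt-6
dialect).  Hits are filtered at e-value < 1e-30 and identity > 95% (both
strict), one best hit per marker.  Anchored markers yield per-interval
recombination rates (delta-cM / delta-Mb); local rates around query intervals
are length-weighted means over the marker intervals overlapping the interval
extended by a 1 or 5 Mb flank, NA when nothing overlaps.

Markers that violate cM monotonicity along the chromosome (map-vs-assembly
conflicts) are dropped by keeping the longest monotone subsequence; maps
anchored in reverse orientation are handled by testing both directions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits(path: str) -> pd.DataFrame:
    """Read 12-column tabular similarity hits; malformed rows are skipped."""
    rows = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 12:
                n_bad += 1
                continue
            try:
                rows.append(
                    [
                        parts[0], parts[1], float(parts[2]), int(parts[3]),
                        int(parts[4]), int(parts[5]), int(parts[6]), int(parts[7]),
                        int(parts[8]), int(parts[9]), float(parts[10]), float(parts[11]),
                    ]
                )
            except ValueError:
                n_bad += 1
    if n_bad:
        logger.warning("read_hits: skipped %d malformed rows", n_bad)
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def filter_hits(hits: pd.DataFrame, e_max: float = 1e-30, id_min: float = 95.0) -> pd.DataFrame:
    """Keep hits with evalue < e_max and identity > id_min (strict); best hit per marker.

    Best = lowest e-value, then highest identity, then highest bit-score.
    """
    ok = hits[(hits["evalue"] < e_max) & (hits["pident"] > id_min)]
    ok = ok.sort_values(
        ["qseqid", "evalue", "pident", "bitscore"],
        ascending=[True, True, False, False],
    )
    return ok.drop_duplicates("qseqid", keep="first").reset_index(drop=True)


def _longest_monotone(cm: np.ndarray) -> np.ndarray:
    """Indices of the longest non-decreasing subsequence (O(n^2), maps are small)."""
    n = len(cm)
    best = np.ones(n, dtype=int)
    prev = np.full(n, -1)
    for i in range(n):
        for j in range(i):
            if cm[j] <= cm[i] and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
                prev[i] = j
    i = int(best.argmax())
    out = []
    while i >= 0:
        out.append(i)
        i = prev[i]
    return np.array(out[::-1])


def anchor_map(linkage_map: pd.DataFrame, hits: pd.DataFrame) -> pd.DataFrame:
    """Anchor linkage-map markers onto physical coordinates.

    ``linkage_map`` columns: marker, linkage_group, cM.  ``hits`` is the
    filtered best-hit table (qseqid = marker, sseqid = chromosome,
    sstart = bp).  Linkage groups hitting several chromosomes are
    majority-assigned; markers landing on duplicate bp keep the lower cM;
    cM-vs-bp monotonicity conflicts are dropped (longest monotone
    subsequence per chromosome, orientation auto-detected).
    """
    merged = linkage_map.merge(hits, left_on="marker", right_on="qseqid", how="inner")
    if merged.empty:
        raise ValueError("no marker anchored (empty map/hit intersection)")
    merged = merged.rename(columns={"sseqid": "chrom"})
    merged["bp"] = merged[["sstart", "send"]].min(axis=1)
    # majority chromosome per linkage group
    keep_parts = []
    for lg, grp in merged.groupby("linkage_group", sort=False):
        major = grp["chrom"].value_counts().idxmax()
        dropped = int((grp["chrom"] != major).sum())
        if dropped:
            logger.info("anchor_map: LG %s: dropped %d minority anchors", lg, dropped)
        keep_parts.append(grp[grp["chrom"] == major])
    anchors = pd.concat(keep_parts, ignore_index=True)
    anchors = anchors.sort_values(["chrom", "bp", "cM"])
    dup = anchors.duplicated(subset=["chrom", "bp"], keep="first")
    if dup.any():
        logger.info("anchor_map: dropped %d duplicate-bp anchors", int(dup.sum()))
    anchors = anchors[~dup]
    cleaned = []
    for chrom, grp in anchors.groupby("chrom", sort=False):
        grp = grp.sort_values("bp").reset_index(drop=True)
        cm = grp["cM"].to_numpy(dtype=float)
        fwd = _longest_monotone(cm)
        rev = _longest_monotone(-cm)
        keep = fwd if len(fwd) >= len(rev) else rev
        if len(keep) < len(grp):
            logger.info(
                "anchor_map: chrom %s: dropped %d non-monotone anchors",
                chrom, len(grp) - len(keep),
            )
        cleaned.append(grp.iloc[keep])
    out = pd.concat(cleaned, ignore_index=True)
    return out[["marker", "linkage_group", "cM", "chrom", "bp", "evalue", "pident"]]


def _interval_rates(grp: pd.DataFrame) -> pd.DataFrame:
    """Adjacent-anchor intervals with rate |delta cM| / delta Mb."""
    grp = grp.sort_values("bp")
    bp = grp["bp"].to_numpy(dtype=float)
    cm = grp["cM"].to_numpy(dtype=float)
    if len(bp) < 2:
        return pd.DataFrame(columns=["lo", "hi", "rate"])
    return pd.DataFrame(
        {
            "lo": bp[:-1],
            "hi": bp[1:],
            "rate": np.abs(np.diff(cm)) / (np.diff(bp) / 1e6),
        }
    )


def local_rate(
    anchors: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    flank: int = 1_000_000,
    chrom_length: int | None = None,
) -> tuple[float, int]:
    """Length-weighted mean recombination rate over [start - flank, end + flank).

    Returns ``(rate_cM_per_Mb, n_intervals)``; rate is NaN when no anchored
    marker interval overlaps the flanked query (clipped to the chromosome).
    """
    lo = max(1, start - flank)
    hi = end + flank
    if chrom_length is not None:
        hi = min(hi, chrom_length + 1)
    grp = anchors[anchors["chrom"] == chrom]
    iv = _interval_rates(grp)
    if iv.empty:
        return float("nan"), 0
    ov_lo = np.maximum(iv["lo"].to_numpy(), lo)
    ov_hi = np.minimum(iv["hi"].to_numpy(), hi)
    w = np.maximum(ov_hi - ov_lo, 0)
    used = w > 0
    if not used.any():
        return float("nan"), 0
    rate = float(np.average(iv["rate"].to_numpy()[used], weights=w[used]))
    return rate, int(used.sum())


def chromosome_rate(anchors: pd.DataFrame, chrom: str) -> float:
    """Whole-chromosome rate: cM span / Mb span between first and last anchor (NaN if < 2)."""
    grp = anchors[anchors["chrom"] == chrom].sort_values("bp")
    if len(grp) < 2:
        return float("nan")
    bp = grp["bp"].to_numpy(dtype=float)
    cm = grp["cM"].to_numpy(dtype=float)
    return float(abs(cm[-1] - cm[0]) / ((bp[-1] - bp[0]) / 1e6))


def region_rates(
    anchors: pd.DataFrame, regions: pd.DataFrame, flanks=(1_000_000, 5_000_000)
) -> pd.DataFrame:
    """Local rates at each flank plus the chromosome-average rate per region."""
    rows = []
    for _, reg in regions.iterrows():
        row = {"chrom": reg["chrom"], "start": int(reg["start"]), "end": int(reg["end"])}
        for fl in flanks:
            rate, n_iv = local_rate(anchors, reg["chrom"], reg["start"], reg["end"], fl)
            row[f"rate_flank_{fl // 1_000_000}Mb"] = rate
            row[f"n_intervals_{fl // 1_000_000}Mb"] = n_iv
        row["chrom_rate"] = chromosome_rate(anchors, reg["chrom"])
        rows.append(row)
    return pd.DataFrame(rows)


def het_vs_recomb(window_het: pd.DataFrame, anchors: pd.DataFrame) -> dict:
    """OLS of window mean heterozygosity on window recombination rate.

    ``window_het`` columns: chrom, start, end, he.  Windows without a defined
    local rate (flank 0) are dropped; returns slope, R^2 and the two-sided
    slope p-value, or NaNs when the rate has no variance or < 3 windows remain.
    """
    rates, hets = [], []
    for _, w in window_het.iterrows():
        r, _ = local_rate(anchors, w["chrom"], int(w["start"]), int(w["end"]), flank=0)
        if r == r and w["he"] == w["he"]:
            rates.append(r)
            hets.append(float(w["he"]))
    rates = np.asarray(rates)
    hets = np.asarray(hets)
    if len(rates) < 3 or np.ptp(rates) == 0:
        return {"slope": float("nan"), "r2": float("nan"), "p": float("nan"), "n": len(rates)}
    res = stats.linregress(rates, hets)
    return {
        "slope": float(res.slope),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "n": len(rates),
    }
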