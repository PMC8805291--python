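"""Genome scans for putative signatures of selection.

Three procedures, sharing one region-calling and resampling-null machinery:

1. **Windowed ZHp** — pooled heterozygosity Hp per sliding window (default
   1 Mb windows, 200 kb step), Z-standardized genome-wide; windows with
   |ZHp| >= 2.81 (two-tailed p <= 0.005) are significant; >= 2 overlapping
   significant windows of the same direction form a candidate region.
2. **SNP p-value runs** — for an externally computed per-SNP p-value track
   (e.g. a haplotype-differentiation test), runs of >= 2 consecutive SNPs at
   p <= 0.01 form regions.
3. **Windowed IBD kinship** — mean between-population kinship per 5 Mb /
   2.5 Mb window (method-of-moments IBD inside the window); windows at
   phi >= 0.05 flagged, >= 2 overlapping flagged windows form a region.

The resampling null permutes the observed statistic values uniformly over
genomic slots (window slots or SNP positions) and re-calls regions; empirical
p for an observed region of m units is (1 + #resamples with a same-direction
region of >= m units) / (n + 1).  Regions with p < 0.05 are retained.

Windows are half-open [start, end) bp, anchored at position 1; the final
partial window of a chromosome is kept.  Windows with no SNPs are NA and are
excluded from standardization and from the permutation slots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, GenotypeError

logger = logging.getLogger(__name__)

Z_THRESHOLD = 2.81  # two-tailed standard-normal cutoff at p = 0.005
SNP_P_THRESHOLD = 0.01
KINSHIP_THRESHOLD = 0.05
N_RESAMPLES = 1000
RETAIN_P = 0.05


@dataclass
class WindowScheme:
    """Sliding-window layout over a genome given per-chromosome lengths (bp)."""

    window_length: int
    step: int
    chrom_lengths: dict[str, int]

    def __post_init__(self):
        if self.step > self.window_length:
            raise GenotypeError("step must not exceed window length")

    def n_windows(self, chrom: str) -> int:
        return (self.chrom_lengths[chrom] - 1) // self.step + 1

    def windows(self, chrom: str) -> pd.DataFrame:
        L = self.chrom_lengths[chrom]
        starts = 1 + self.step * np.arange(self.n_windows(chrom))
        ends = np.minimum(starts + self.window_length, L + 1)
        return pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})

    @classmethod
    def from_genotypes(cls, G: GenotypeMatrix, window_length: int, step: int) -> "WindowScheme":
        lengths = {
            str(c): int(g["pos"].max()) for c, g in G.snps.groupby("chrom", sort=False)
        }
        return cls(window_length, step, lengths)


def _window_hits(scheme: WindowScheme, chrom: str, pos: np.ndarray):
    """(snp index, window index) pairs for every window containing each SNP."""
    n_win = scheme.n_windows(chrom)
    base = (pos - 1) // scheme.step
    reach = -(-scheme.window_length // scheme.step) - 1  # ceil - 1
    snp_idx, win_idx = [], []
    for r in range(reach + 1):
        k = base - r
        valid = (k >= 0) & (k < n_win) & (pos - 1 - k * scheme.step < scheme.window_length)
        snp_idx.append(np.flatnonzero(valid))
        win_idx.append(k[valid])
    return np.concatenate(snp_idx), np.concatenate(win_idx)


# ---------------------------------------------------------------------------
# Pooled heterozygosity (Hp) and ZHp
# ---------------------------------------------------------------------------

def _pool_counts(G: GenotypeMatrix, pool: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP major- and minor-allele counts within a pool of individuals."""
    calls = G.calls[np.asarray(pool)]
    ok = calls != MISSING
    tot = 2 * ok.sum(axis=0)
    alt = np.where(ok, calls, 0).sum(axis=0)
    maj = np.maximum(alt, tot - alt)
    return maj, tot - maj


def pooled_het_track(
    G: GenotypeMatrix, pool: np.ndarray, scheme: WindowScheme
) -> pd.DataFrame:
    """Per-window pooled heterozygosity Hp for a pool of individuals.

    Hp = 2 * S_maj * S_min / (S_maj + S_min)^2 where S_maj, S_min sum the
    major- and minor-allele counts (within the pool) of the SNPs in the
    window.  Windows without genotyped SNPs get NaN.
    """
    maj, mino = _pool_counts(G, pool)
    tot = maj + mino
    chrom_arr = G.snps["chrom"].to_numpy()
    pos_arr = G.snps["pos"].to_numpy()
    frames = []
    any_snps = False
    for chrom in scheme.chrom_lengths:
        win = scheme.windows(chrom)
        s_maj = np.zeros(len(win))
        s_min = np.zeros(len(win))
        n_snps = np.zeros(len(win), dtype=int)
        on_chrom = np.flatnonzero(chrom_arr == chrom)
        if on_chrom.size:
            si, wi = _window_hits(scheme, chrom, pos_arr[on_chrom])
            snp = on_chrom[si]
            typed = tot[snp] > 0
            np.add.at(s_maj, wi[typed], maj[snp][typed])
            np.add.at(s_min, wi[typed], mino[snp][typed])
            np.add.at(n_snps, wi[typed], 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            hp = 2 * s_maj * s_min / np.maximum(s_maj + s_min, 1) ** 2
        win["n_snps"] = n_snps
        win["value"] = np.where(n_snps > 0, hp, np.nan)
        frames.append(win)
        any_snps = any_snps or bool(n_snps.sum())
    if not any_snps:
        raise GenotypeError("pool has no genotyped SNPs in any window")
    return pd.concat(frames, ignore_index=True)


def zhp_track(hp: pd.DataFrame) -> pd.DataFrame:
    """Genome-wide Z-standardization of an Hp track (non-NA windows)."""
    vals = hp["value"].to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    if ok.sum() < 2:
        raise GenotypeError("need at least 2 non-NA windows to standardize")
    mu = vals[ok].mean()
    sd = vals[ok].std(ddof=0)
    if sd <= 1e-12 * max(1.0, abs(mu)):
        raise GenotypeError("degenerate Hp track (zero spread)")
    out = hp.copy()
    out["value"] = (vals - mu) / sd
    return out


# ---------------------------------------------------------------------------
# Region calling
# ---------------------------------------------------------------------------

def directions_z(values: np.ndarray, z_thresh: float = Z_THRESHOLD) -> np.ndarray:
    """'low' where value <= -z_thresh, 'high' where value >= +z_thresh (inclusive)."""
    out = np.full(values.shape, "", dtype=object)
    with np.errstate(invalid="ignore"):
        out[values <= -z_thresh] = "low"
        out[values >= z_thresh] = "high"
    return out


def directions_ge(values: np.ndarray, thresh: float = KINSHIP_THRESHOLD) -> np.ndarray:
    """'high' where value >= thresh (inclusive, one-sided)."""
    out = np.full(values.shape, "", dtype=object)
    with np.errstate(invalid="ignore"):
        out[values >= thresh] = "high"
    return out


def significant_windows(track: pd.DataFrame, z_thresh: float = Z_THRESHOLD) -> pd.DataFrame:
    """Flag windows with |Z| >= z_thresh; adds a 'direction' column and drops the rest."""
    out = track.copy()
    out["direction"] = directions_z(out["value"].to_numpy(dtype=float), z_thresh)
    return out[out["direction"] != ""].reset_index(drop=True)


def merge_regions(flagged: pd.DataFrame, min_units: int = 2) -> pd.DataFrame:
    """Chains of >= min_units transitively overlapping same-direction windows.

    Windows are half-open intervals; sorted by start within (chrom, direction),
    a window joins the current chain iff it starts before the chain's maximal
    end.  The region spans the union of member windows.
    """
    cols = ["chrom", "start", "end", "n_units", "mean_stat", "direction"]
    if flagged.empty:
        return pd.DataFrame(columns=cols)
    regions = []
    for (chrom, direction), grp in flagged.groupby(["chrom", "direction"], sort=False):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        vals = grp["value"].to_numpy(dtype=float)
        chain = [0]
        max_end = ends[0]
        def flush(chain, max_end):
            if len(chain) >= min_units:
                regions.append(
                    {
                        "chrom": chrom,
                        "start": int(starts[chain[0]]),
                        "end": int(max_end),
                        "n_units": len(chain),
                        "mean_stat": float(vals[list(chain)].mean()),
                        "direction": direction,
                    }
                )
        for i in range(1, len(grp)):
            if starts[i] < max_end:
                chain.append(i)
                max_end = max(max_end, ends[i])
            else:
                flush(chain, max_end)
                chain = [i]
                max_end = ends[i]
        flush(chain, max_end)
    out = pd.DataFrame(regions, columns=cols)
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def _max_units(
    chrom_codes: np.ndarray, starts: np.ndarray, ends: np.ndarray, mask: np.ndarray
) -> int:
    """Largest transitive-overlap chain among flagged windows (numpy sweep).

    Same interval logic as :func:`merge_regions`, specialized to the maximal
    chain size for the permutation null.
    """
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return 0
    best = cur = 1
    max_end = ends[idx[0]]
    prev_c = chrom_codes[idx[0]]
    for i in idx[1:]:
        if chrom_codes[i] == prev_c and starts[i] < max_end:
            cur += 1
            max_end = max(max_end, ends[i])
        else:
            cur = 1
            max_end = ends[i]
            prev_c = chrom_codes[i]
        best = max(best, cur)
    return best


def resample_window_null(
    track: pd.DataFrame,
    direction_fn,
    n_resamples: int = N_RESAMPLES,
    seed: int = 0,
    retain_p: float = RETAIN_P,
    min_units: int = 2,
) -> pd.DataFrame:
    """Call regions and attach empirical p from a window-position permutation null.

    ``direction_fn`` maps the value vector to per-window direction labels.
    Per resample, non-NA values are permuted uniformly over the non-NA window
    slots and regions re-called; empirical p for an observed region with m
    units = (1 + #resamples with any same-direction region of >= m units)
    / (n_resamples + 1).  Adds ``empirical_p`` and ``retained`` columns.
    """
    if n_resamples < 1:
        raise GenotypeError("n_resamples must be >= 1")
    vals = track["value"].to_numpy(dtype=float)
    dirs = direction_fn(vals)
    flagged = track.assign(direction=dirs)
    flagged = flagged[flagged["direction"] != ""]
    observed = merge_regions(flagged, min_units=min_units)
    if observed.empty:
        observed["empirical_p"] = pd.Series(dtype=float)
        observed["retained"] = pd.Series(dtype=bool)
        return observed
    rng = np.random.default_rng(seed)
    ok = ~np.isnan(vals)
    slots = np.flatnonzero(ok)
    pool_vals = vals[slots]
    chrom_codes = pd.factorize(track["chrom"])[0]
    starts = track["start"].to_numpy()
    ends = track["end"].to_numpy()
    null_max = {"low": np.zeros(n_resamples, int), "high": np.zeros(n_resamples, int)}
    for b in range(n_resamples):
        perm = np.full(len(vals), np.nan)
        perm[slots] = rng.permutation(pool_vals)
        d = direction_fn(perm)
        null_max["low"][b] = _max_units(chrom_codes, starts, ends, d == "low")
        null_max["high"][b] = _max_units(chrom_codes, starts, ends, d == "high")
    emp = [
        (1 + int((null_max[row.direction] >= row.n_units).sum())) / (n_resamples + 1)
        for row in observed.itertuples(index=False)
    ]
    observed["empirical_p"] = emp
    observed["retained"] = observed["empirical_p"] < retain_p
    return observed


def _window_matrix(scheme: WindowScheme, snps: pd.DataFrame):
    """Sparse window-membership matrix (windows x SNPs) plus the window table."""
    from scipy import sparse

    chrom_arr = snps["chrom"].to_numpy()
    pos_arr = snps["pos"].to_numpy()
    rows, cols, frames = [], [], []
    offset = 0
    for chrom in scheme.chrom_lengths:
        win = scheme.windows(chrom)
        on_chrom = np.flatnonzero(chrom_arr == chrom)
        if on_chrom.size:
            si, wi = _window_hits(scheme, chrom, pos_arr[on_chrom])
            rows.append(wi + offset)
            cols.append(on_chrom[si])
        frames.append(win)
        offset += len(win)
    windows = pd.concat(frames, ignore_index=True)
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
    else:
        rows = cols = np.zeros(0, dtype=int)
    M = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(offset, len(snps))
    )
    return M, windows


def _zhp_snp_null(
    G: GenotypeMatrix,
    pool: np.ndarray,
    scheme: WindowScheme,
    observed: pd.DataFrame,
    z_thresh: float,
    n_resamples: int,
    seed: int,
    retain_p: float,
) -> pd.DataFrame:
    """Empirical p for ZHp regions from a SNP-position permutation null.

    Per resample the per-SNP allele-count summaries are permuted over SNP
    positions and the whole windowed pipeline (window sums, Z-standardization,
    thresholding, chaining) is re-run.  Unlike permuting window values over
    window slots, this preserves the autocorrelation that overlapping windows
    inherit from shared SNPs, so the null matches the observed track's
    dependence structure and the retained-region rate holds its nominal level.
    """
    maj, mino = _pool_counts(G, pool)
    typed = ((maj + mino) > 0).astype(float)
    M, windows = _window_matrix(scheme, G.snps)
    chrom_codes = pd.factorize(windows["chrom"])[0]
    starts = windows["start"].to_numpy()
    ends = windows["end"].to_numpy()
    rng = np.random.default_rng(seed)
    null_max = {"low": np.zeros(n_resamples, int), "high": np.zeros(n_resamples, int)}
    maj = maj.astype(float)
    mino = mino.astype(float)
    for b in range(n_resamples):
        perm = rng.permutation(len(typed))
        s_maj = M @ maj[perm]
        s_min = M @ mino[perm]
        n_typed = M @ typed[perm]
        with np.errstate(invalid="ignore", divide="ignore"):
            hp = 2 * s_maj * s_min / np.maximum(s_maj + s_min, 1) ** 2
        hp = np.where(n_typed > 0, hp, np.nan)
        ok = ~np.isnan(hp)
        if ok.sum() < 2:
            continue
        sd = hp[ok].std(ddof=0)
        if sd == 0:
            continue
        z = (hp - hp[ok].mean()) / sd
        with np.errstate(invalid="ignore"):
            null_max["low"][b] = _max_units(chrom_codes, starts, ends, z <= -z_thresh)
            null_max["high"][b] = _max_units(chrom_codes, starts, ends, z >= z_thresh)
    observed = observed.copy()
    observed["empirical_p"] = [
        (1 + int((null_max[row.direction] >= row.n_units).sum())) / (n_resamples + 1)
        for row in observed.itertuples(index=False)
    ]
    observed["retained"] = observed["empirical_p"] < retain_p
    return observed


def zhp_scan(
    G: GenotypeMatrix,
    pool: np.ndarray,
    scheme: WindowScheme,
    z_thresh: float = Z_THRESHOLD,
    n_resamples: int = N_RESAMPLES,
    seed: int = 0,
    retain_p: float = RETAIN_P,
    null_model: str = "snp",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full ZHp scan for one pool: returns (ZHp track, candidate regions).

    ``null_model`` selects the resampling null: ``"snp"`` (default) permutes
    per-SNP summaries over SNP positions and rebuilds the windowed track,
    keeping the overlap-induced autocorrelation of neighboring windows;
    ``"window"`` permutes window values over window slots.
    """
    z = zhp_track(pooled_het_track(G, pool, scheme))
    if null_model == "window":
        regions = resample_window_null(
            z, lambda v: directions_z(v, z_thresh), n_resamples, seed, retain_p
        )
    elif null_model == "snp":
        flagged = significant_windows(z, z_thresh)
        observed = merge_regions(flagged, min_units=2)
        if observed.empty:
            observed["empirical_p"] = pd.Series(dtype=float)
            observed["retained"] = pd.Series(dtype=bool)
            regions = observed
        else:
            regions = _zhp_snp_null(
                G, pool, scheme, observed, z_thresh, n_resamples, seed, retain_p
            )
    else:
        raise GenotypeError(f"unknown null_model {null_model!r}")
    regions["approach"] = "ZHp"
    return z, regions


# ---------------------------------------------------------------------------
# SNP p-value run caller (imported per-SNP test output)
# ---------------------------------------------------------------------------

def _max_run(sig: np.ndarray, chrom_starts: np.ndarray) -> int:
    """Longest run of True not crossing a chromosome boundary.

    ``chrom_starts`` holds the indices where a new chromosome begins; a False
    is inserted there so runs cannot span chromosomes.
    """
    ext = np.insert(sig, chrom_starts, False)
    ext = np.concatenate([[False], ext, [False]])
    gaps = np.flatnonzero(~ext)
    return int((np.diff(gaps) - 1).max())


def _chrom_starts(chrom_codes: np.ndarray) -> np.ndarray:
    change = np.flatnonzero(chrom_codes[1:] != chrom_codes[:-1]) + 1
    return change


def snp_p_regions(
    track: pd.DataFrame,
    p_thresh: float = SNP_P_THRESHOLD,
    n_resamples: int = N_RESAMPLES,
    seed: int = 0,
    retain_p: float = RETAIN_P,
    min_units: int = 2,
) -> pd.DataFrame:
    """Regions of >= 2 consecutive SNPs at p <= p_thresh, with permutation null.

    ``track`` columns: chrom, pos, p (genome-ordered).  The null permutes the
    p-values over SNP positions; empirical p is keyed on run length.
    """
    pvals = track["p"].to_numpy(dtype=float)
    if ((pvals < 0) | (pvals > 1)).any():
        raise GenotypeError("p-values outside [0, 1]")
    chrom_arr = track["chrom"].to_numpy()
    pos_arr = track["pos"].to_numpy()
    sig = pvals <= p_thresh
    regions = []
    for chrom in dict.fromkeys(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        s = sig[idx]
        bounded = np.concatenate([[False], s, [False]]).astype(int)
        d = np.diff(bounded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for a, b in zip(starts, ends):
            if b - a >= min_units:
                first, last = idx[a], idx[b - 1]
                regions.append(
                    {
                        "chrom": chrom,
                        "start": int(pos_arr[first]),
                        "end": int(pos_arr[last]) + 1,
                        "n_units": int(b - a),
                        "mean_stat": float(pvals[idx[a]:idx[b - 1] + 1].mean()),
                        "direction": "n/a",
                    }
                )
    observed = pd.DataFrame(
        regions, columns=["chrom", "start", "end", "n_units", "mean_stat", "direction"]
    )
    if observed.empty:
        observed["empirical_p"] = pd.Series(dtype=float)
        observed["retained"] = pd.Series(dtype=bool)
        observed["approach"] = pd.Series(dtype=object)
        return observed
    rng = np.random.default_rng(seed)
    starts = _chrom_starts(chrom_arr)
    null_max = np.zeros(n_resamples, int)
    for b in range(n_resamples):
        perm_sig = rng.permutation(sig)
        null_max[b] = _max_run(perm_sig, starts)
    observed["empirical_p"] = [
        (1 + int((null_max >= m).sum())) / (n_resamples + 1) for m in observed["n_units"]
    ]
    observed["retained"] = observed["empirical_p"] < retain_p
    observed["approach"] = "SNP-p"
    return observed.sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Windowed IBD-kinship scan
# ---------------------------------------------------------------------------

def _mom_window_kinship(
    calls: np.ndarray, freqs: np.ndarray, between_mask: np.ndarray
) -> np.ndarray:
    """Method-of-moments (IBS-based) pairwise kinship inside one window.

    Returns the full n x n phi matrix (only entries under ``between_mask``
    are meaningful to the caller).  Expected IBS-state counts under IBD state
    0/1/2 are accumulated pair-specifically over mutually non-missing SNPs.
    """
    ok = calls != MISSING
    p = np.clip(freqs, 1e-9, 1 - 1e-9)
    q = 1 - p
    e0_0 = 2 * p**2 * q**2
    e1_0 = 4 * p**3 * q + 4 * p * q**3
    e2_0 = p**4 + q**4 + 4 * p**2 * q**2
    e1_1 = 2 * p * q
    e2_1 = p**2 + q**2
    okf = ok.astype(float)
    A = [(calls == g).astype(float) for g in (0, 1, 2)]
    n_tot = okf @ okf.T
    n2 = sum(a @ a.T for a in A)
    n0 = A[0] @ A[2].T + A[2] @ A[0].T
    n1 = n_tot - n0 - n2
    E0_0 = (okf * e0_0) @ okf.T
    E1_0 = (okf * e1_0) @ okf.T
    E2_0 = (okf * e2_0) @ okf.T
    E1_1 = (okf * e1_1) @ okf.T
    E2_1 = (okf * e2_1) @ okf.T
    with np.errstate(invalid="ignore", divide="ignore"):
        k0 = np.clip(n0 / np.maximum(E0_0, 1e-12), 0, 1)
        k1 = np.clip((n1 - k0 * E1_0) / np.maximum(E1_1, 1e-12), 0, 1)
        k2 = np.clip((n2 - k0 * E2_0 - k1 * E2_1) / np.maximum(n_tot, 1e-12), 0, 1)
    tot = k0 + k1 + k2
    tot = np.where(tot > 0, tot, 1.0)
    k1n, k2n = k1 / tot, k2 / tot
    phi = k2n / 2 + k1n / 4
    phi[n_tot < 2] = np.nan
    return phi


def kinship_window_scan(
    G: GenotypeMatrix,
    populations: dict[str, np.ndarray],
    scheme: WindowScheme,
    phi_thresh: float = KINSHIP_THRESHOLD,
    min_snps: int = 30,
    n_resamples: int = N_RESAMPLES,
    seed: int = 0,
    retain_p: float = RETAIN_P,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Between-population mean kinship per window; regions of shared haplotypes.

    Per window (>= ``min_snps`` SNPs, else NA): kinship for every
    between-population individual pair from the window's SNPs, averaged within
    each population pair, then averaged over population pairs.  Windows at
    phi >= ``phi_thresh`` (inclusive) are flagged; >= 2 overlapping flagged
    windows form a region, with the window-permutation null as for ZHp.
    """
    labels = list(populations)
    if len(labels) < 2:
        raise GenotypeError("kinship_window_scan needs >= 2 populations")
    n = G.n_samples
    member = np.full(n, -1)
    for li, lab in enumerate(labels):
        member[np.asarray(populations[lab])] = li
    between = (member[:, None] != member[None, :]) & (member[:, None] >= 0) & (member[None, :] >= 0)
    between &= np.tri(n, k=-1, dtype=bool).T  # upper triangle only
    pair_group = {}
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            mask = between & (
                ((member[:, None] == a) & (member[None, :] == b))
                | ((member[:, None] == b) & (member[None, :] == a))
            )
            pair_group[(a, b)] = mask
    freqs = G.allele_freq()
    chrom_arr = G.snps["chrom"].to_numpy()
    pos_arr = G.snps["pos"].to_numpy()
    frames = []
    for chrom in scheme.chrom_lengths:
        win = scheme.windows(chrom)
        values = np.full(len(win), np.nan)
        n_snps = np.zeros(len(win), dtype=int)
        on_chrom = np.flatnonzero(chrom_arr == chrom)
        if on_chrom.size:
            si, wi = _window_hits(scheme, chrom, pos_arr[on_chrom])
            for w in range(len(win)):
                snp = on_chrom[si[wi == w]]
                n_snps[w] = snp.size
                if snp.size < min_snps:
                    continue
                phi = _mom_window_kinship(G.calls[:, snp], freqs[snp], between)
                means = []
                for mask in pair_group.values():
                    vals = phi[mask]
                    vals = vals[~np.isnan(vals)]
                    if vals.size:
                        means.append(vals.mean())
                if means:
                    values[w] = float(np.mean(means))
        win["n_snps"] = n_snps
        win["value"] = values
        frames.append(win)
    track = pd.concat(frames, ignore_index=True)
    regions = resample_window_null(
        track, lambda v: directions_ge(v, phi_thresh), n_resamples, seed, retain_p
    )
    regions["approach"] = "IBD"
    return track, regions


# ---------------------------------------------------------------------------
# Cross-approach overlap and stratified scans
# ---------------------------------------------------------------------------

def overlap_regions(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Pairs of regions from two lists with >= 1 bp interval overlap."""
    rows = []
    for i, ra in a.iterrows():
        for j, rb in b.iterrows():
            if ra["chrom"] != rb["chrom"]:
                continue
            lo = max(ra["start"], rb["start"])
            hi = min(ra["end"], rb["end"])
            if hi > lo:
                rows.append(
                    {
                        "chrom": ra["chrom"],
                        "a_start": int(ra["start"]),
                        "a_end": int(ra["end"]),
                        "b_start": int(rb["start"]),
                        "b_end": int(rb["end"]),
                        "overlap_bp": int(hi - lo),
                    }
                )
    return pd.DataFrame(
        rows, columns=["chrom", "a_start", "a_end", "b_start", "b_end", "overlap_bp"]
    )


def stratified_scan(
    scan_fn,
    strata: dict[str, np.ndarray],
    base_regions: pd.DataFrame | None = None,
    min_stratum_size: int = 5,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame | None]:
    """Run a scan per stratum and annotate base regions with re-detections.

    ``scan_fn(sample_index)`` must return a region table.  Strata smaller than
    ``min_stratum_size`` are skipped with a warning.  When ``base_regions`` is
    given, a ``strata`` column lists (comma-joined) the strata whose retained
    regions overlap each base region by >= 1 bp.
    """
    results = {}
    for name, idx in strata.items():
        idx = np.asarray(idx)
        if idx.size < min_stratum_size:
            logger.warning("stratum %s below minimum size (%d); skipped", name, idx.size)
            continue
        results[name] = scan_fn(idx)
    annotated = None
    if base_regions is not None:
        annotated = base_regions.copy()
        hits = []
        for _, reg in annotated.iterrows():
            found = []
            for name, regs in results.items():
                sub = regs[regs.get("retained", pd.Series(dtype=bool)) == True]  # noqa: E712
                ov = overlap_regions(pd.DataFrame([reg]), sub)
                if len(ov):
                    found.append(name)
            hits.append(",".join(found))
        annotated["strata"] = hits
    return results, annotated
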