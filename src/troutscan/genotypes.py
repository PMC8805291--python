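"""Genotype matrices, post-genotyping quality filters, LD pruning and F_ST.

The central container is :class:`GenotypeMatrix`: a samples x SNPs table of
biallelic genotype calls coded as alt-allele dosage {0, 1, 2} with ``-1`` for
missing, plus a parallel per-entry sequencing-depth matrix.  All downstream
statistics (diversity, kinship, window scans) operate on this container.

Quality filters mirror the standard RAD-seq post-genotyping recipe:

* drop samples whose mean coverage is below 5x,
* mask individual genotype entries covered by fewer than 5 reads,
* keep only SNPs informative (non-missing) in at least 50% of samples,
* remove SNPs heterozygous in more than 80% of genotyped samples,
* optional minor-allele-frequency floor and r^2-based LD pruning.

Boundary conventions are exact: "lower than 5x" is strict, "at least 50%"
inclusive, "more than 80%" strict, r^2 "greater than" the cap strict, and
F_ST "> 0.95" strict for diagnostic SNPs.  Positions are 1-based (VCF
convention); window intervals elsewhere in the package are half-open
[start, end) in bp.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

LINEAGES = ("AT", "CA", "MA", "MI", "MM")
ORIGINS = ("farmed", "river", "unknown")


class GenotypeError(ValueError):
    """Fatal genotype-input or filter condition (e.g. all samples removed)."""


@dataclass
class SampleInfo:
    """Per-sample metadata: lineage, sampling origin and mean coverage."""

    sample_id: str
    lineage: str
    origin: str = "unknown"
    subpopulation: str | None = None
    mean_coverage: float = float("nan")

    def __post_init__(self):
        if self.lineage not in LINEAGES:
            raise GenotypeError(f"unknown lineage code {self.lineage!r}")
        if self.origin not in ORIGINS:
            raise GenotypeError(f"unknown origin {self.origin!r}")
        if self.mean_coverage == self.mean_coverage and self.mean_coverage < 0:
            raise GenotypeError("mean_coverage must be >= 0")


@dataclass
class GenotypeMatrix:
    """Samples x biallelic SNPs with dosage calls and per-entry read depth.

    Attributes
    ----------
    sample_ids : list of str
    snps : pandas.DataFrame with columns (chrom, pos, ref, alt); pos 1-based,
        strictly increasing within each chromosome.
    calls : int8 array (n_samples, n_snps); alt-allele dosage, -1 = missing.
    depth : int32 array like ``calls`` or None when the source had no depth
        field (coverage filters then refuse to run).
    """

    sample_ids: list[str]
    snps: pd.DataFrame
    calls: np.ndarray
    depth: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def validate(self) -> None:
        if self.calls.shape != (self.n_samples, self.n_snps):
            raise GenotypeError("calls shape does not match samples x snps")
        if not np.isin(self.calls, (MISSING, 0, 1, 2)).all():
            raise GenotypeError("calls outside {missing, 0, 1, 2}")
        if self.depth is not None:
            if self.depth.shape != self.calls.shape:
                raise GenotypeError("depth shape mismatch")
            if (self.depth < 0).any():
                raise GenotypeError("negative depth")
        for _, grp in self.snps.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise GenotypeError("positions not strictly increasing within chromosome")

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            snps=self.snps.copy(),
            calls=self.calls[index],
            depth=None if self.depth is None else self.depth[index],
        )

    def take_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snps=self.snps.iloc[mask].reset_index(drop=True)
            if mask.dtype != bool
            else self.snps.loc[mask].reset_index(drop=True),
            calls=self.calls[:, mask],
            depth=None if self.depth is None else self.depth[:, mask],
        )

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in ids], dtype=int)

    def allele_freq(self, sample_index: np.ndarray | None = None) -> np.ndarray:
        """Alt-allele frequency per SNP over non-missing calls (NaN if none)."""
        calls = self.calls if sample_index is None else self.calls[sample_index]
        ok = calls != MISSING
        n = 2 * ok.sum(axis=0)
        alt = np.where(ok, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF (plain or gzip) with GT and DP/AD into a GenotypeMatrix.

    Sites that are not biallelic SNPs are skipped (a count is logged).
    Missing GT becomes the MISSING sentinel.  If no per-genotype depth field
    exists anywhere, ``depth`` is None and coverage filters will refuse to run.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, poss, refs, alts = [], [], [], []
    call_cols, depth_cols = [], []
    n_skipped = 0
    any_depth = False
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        g = v.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g[g == 3] = MISSING
        dp = v.format("DP")
        if dp is None:
            ad = v.format("AD")
            dp = None if ad is None else np.where(ad < 0, 0, ad).sum(axis=1)
        if dp is not None:
            any_depth = True
            dp = np.asarray(dp).reshape(len(samples)).astype(np.int32)
            dp = np.where(dp < 0, 0, dp)  # cyvcf2 codes missing as negative
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        call_cols.append(g)
        depth_cols.append(dp)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP sites", n_skipped)
    snps = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    snps["pos"] = snps["pos"].astype(np.int64) if len(snps) else snps.get("pos", pd.Series(dtype=np.int64))
    if call_cols:
        calls = np.stack(call_cols, axis=1).astype(np.int8)
        if any_depth:
            depth = np.stack(
                [np.zeros(len(samples), np.int32) if d is None else d for d in depth_cols],
                axis=1,
            )
        else:
            depth = None
    else:
        calls = np.zeros((len(samples), 0), np.int8)
        depth = np.zeros((len(samples), 0), np.int32)
    G = GenotypeMatrix(sample_ids=samples, snps=snps, calls=calls, depth=depth)
    G.validate()
    return G


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF with GT and DP that round-trips through read_vcf."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in dict.fromkeys(G.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.sample_ids) + "\n")
        has_dp = G.depth is not None
        fmt = "GT:DP" if has_dp else "GT"
        for j, rec in enumerate(G.snps.itertuples(index=False)):
            fields = [rec.chrom, str(rec.pos), ".", rec.ref, rec.alt, ".", "PASS", ".", fmt]
            for i in range(G.n_samples):
                gt = _GT_STR[int(G.calls[i, j])]
                fields.append(f"{gt}:{int(G.depth[i, j])}" if has_dp else gt)
            fh.write("\t".join(fields) + "\n")


def read_metadata(path: str) -> list[SampleInfo]:
    """Read the sample metadata TSV (sample_id, lineage, origin, subpopulation, mean_coverage)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for rec in df.itertuples(index=False):
        sub = getattr(rec, "subpopulation", None)
        out.append(
            SampleInfo(
                sample_id=str(rec.sample_id),
                lineage=str(rec.lineage),
                origin=str(rec.origin),
                subpopulation=None if sub is None or pd.isna(sub) else str(sub),
                mean_coverage=float(rec.mean_coverage),
            )
        )
    return out


def write_metadata(meta: list[SampleInfo], path: str) -> None:
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "lineage": [m.lineage for m in meta],
            "origin": [m.origin for m in meta],
            "subpopulation": [m.subpopulation or "" for m in meta],
            "mean_coverage": [m.mean_coverage for m in meta],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def drop_low_coverage_samples(
    G: GenotypeMatrix, meta: list[SampleInfo], min_mean: float = 5.0
) -> tuple[GenotypeMatrix, list[SampleInfo]]:
    """Remove samples with mean coverage strictly below ``min_mean`` (default 5x)."""
    by_id = {m.sample_id: m for m in meta}
    missing_meta = [s for s in G.sample_ids if s not in by_id]
    if missing_meta:
        raise GenotypeError(f"no metadata for samples: {missing_meta[:5]}")
    keep, removed = [], []
    for i, s in enumerate(G.sample_ids):
        cov = by_id[s].mean_coverage
        if cov != cov:
            raise GenotypeError(f"mean_coverage unknown for sample {s}")
        (removed if cov < min_mean else keep).append(i)
    if not keep:
        raise GenotypeError("all samples fall below the coverage threshold")
    if removed:
        logger.info(
            "drop_low_coverage_samples: removed %d samples: %s",
            len(removed),
            [G.sample_ids[i] for i in removed],
        )
    G2 = G.take_samples(np.array(keep))
    meta2 = [by_id[s] for s in G2.sample_ids]
    return G2, meta2


def mask_low_coverage(G: GenotypeMatrix, min_depth: int = 5) -> GenotypeMatrix:
    """Set calls with depth strictly below ``min_depth`` to missing (depth kept for audit)."""
    if G.depth is None:
        raise GenotypeError("depth unknown; coverage masking refused")
    calls = np.where(G.depth < min_depth, np.int8(MISSING), G.calls)
    return replace(G, calls=calls.astype(np.int8), snps=G.snps.copy())


def filter_missingness(G: GenotypeMatrix, min_informative_frac: float = 0.5) -> GenotypeMatrix:
    """Keep SNPs informative in at least ``min_informative_frac`` of samples (inclusive)."""
    frac = (G.calls != MISSING).mean(axis=0)
    mask = frac >= min_informative_frac
    if not mask.any():
        raise GenotypeError("no SNP passes the informativeness filter")
    n_removed = int((~mask).sum())
    if n_removed:
        logger.info("filter_missingness: removed %d SNPs", n_removed)
    return G.take_snps(mask)


def filter_excess_het(G: GenotypeMatrix, max_het_frac: float = 0.8) -> GenotypeMatrix:
    """Remove SNPs heterozygous in strictly more than ``max_het_frac`` of genotyped samples."""
    ok = G.calls != MISSING
    n = ok.sum(axis=0)
    het = (G.calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n > 0, het / np.maximum(n, 1), 0.0)
    mask = frac <= max_het_frac
    n_removed = int((~mask).sum())
    if n_removed:
        logger.info("filter_excess_het: removed %d SNPs", n_removed)
    return G.take_snps(mask)


def filter_maf(G: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Remove SNPs with minor-allele frequency <= ``min_maf``.

    ``min_maf = 0`` removes only monomorphic sites (MAF exactly 0).
    """
    if not 0 <= min_maf <= 0.5:
        raise GenotypeError("min_maf must lie in [0, 0.5]")
    p = G.allele_freq()
    maf = np.fmin(p, 1 - p)
    mask = maf > min_maf
    mask &= ~np.isnan(maf)
    n_removed = int((~mask).sum())
    if n_removed:
        logger.info("filter_maf(%.3g): removed %d SNPs", min_maf, n_removed)
    return G.take_snps(mask)


def _standardized_dosage(calls: np.ndarray) -> np.ndarray:
    """Columns centered on the observed mean, missing imputed to the mean (0 after centering)."""
    ok = calls != MISSING
    n = ok.sum(axis=0)
    x = np.where(ok, calls, 0).astype(float)
    mean = x.sum(axis=0) / np.maximum(n, 1)
    z = np.where(ok, calls - mean, 0.0)
    return z


def pairwise_r2(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """Composite-genotype r^2 between two dosage vectors (mean-imputed)."""
    z = _standardized_dosage(np.stack([calls_a, calls_b], axis=1))
    na, nb = np.linalg.norm(z[:, 0]), np.linalg.norm(z[:, 1])
    if na == 0 or nb == 0:
        return 0.0
    r = float(z[:, 0] @ z[:, 1] / (na * nb))
    return r * r


def ld_prune(G: GenotypeMatrix, r2_max: float = 0.2, scan_window: int = 500) -> GenotypeMatrix:
    """Greedy in-genome-order LD pruning at composite-genotype r^2 > ``r2_max``.

    A SNP is kept unless its r^2 with an already-kept SNP among the previous
    ``scan_window`` SNPs of the same chromosome exceeds ``r2_max`` (strict).
    Deterministic given input order.
    """
    if not 0 < r2_max <= 1:
        raise GenotypeError("r2_max must lie in (0, 1]")
    keep = np.zeros(G.n_snps, dtype=bool)
    chrom_codes = G.snps["chrom"].to_numpy()
    z = _standardized_dosage(G.calls)
    norms = np.linalg.norm(z, axis=0)
    for chrom in dict.fromkeys(chrom_codes):
        idx = np.flatnonzero(chrom_codes == chrom)
        kept_local: list[int] = []
        for rank, j in enumerate(idx):
            cand = [k for k in kept_local if rank - k <= scan_window]
            ok = True
            if cand and norms[j] > 0:
                cols = idx[cand]
                cols = cols[norms[cols] > 0]
                if len(cols):
                    r = (z[:, cols].T @ z[:, j]) / (norms[cols] * norms[j])
                    if (r * r > r2_max).any():
                        ok = False
            if ok:
                keep[j] = True
                kept_local.append(rank)
    logger.info("ld_prune: kept %d of %d SNPs", int(keep.sum()), G.n_snps)
    return G.take_snps(keep)


# ---------------------------------------------------------------------------
# F_ST and diagnostic SNPs
# ---------------------------------------------------------------------------

def hudson_fst_components(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hudson two-population F_ST numerator/denominator per SNP.

    ``p`` are alt-allele frequencies, ``n`` allele (not individual) counts.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def per_snp_fst(G: GenotypeMatrix, populations: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-SNP Hudson F_ST; for >2 populations the mean over population pairs.

    ``populations`` maps label -> sample index array.  SNPs where any member of
    a pair has zero non-missing calls get NaN for that pair; a SNP is NaN
    overall if no pair is defined.
    """
    labels = list(populations)
    if len(labels) < 2:
        raise GenotypeError("per_snp_fst needs at least two populations")
    freqs, counts = {}, {}
    for lab, idx in populations.items():
        calls = G.calls[np.asarray(idx)]
        ok = calls != MISSING
        n = 2 * ok.sum(axis=0)
        alt = np.where(ok, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[lab] = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        counts[lab] = n.astype(float)
    vals = []
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            la, lb = labels[a], labels[b]
            num, den = hudson_fst_components(freqs[la], counts[la], freqs[lb], counts[lb])
            with np.errstate(invalid="ignore", divide="ignore"):
                fst = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
            fst = np.where((counts[la] >= 4) & (counts[lb] >= 4), fst, np.nan)
            vals.append(fst)
    stacked = np.stack(vals)
    defined = (~np.isnan(stacked)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_fst = np.where(
            defined > 0, np.nansum(stacked, axis=0) / np.maximum(defined, 1), np.nan
        )
    return pd.DataFrame(
        {
            "chrom": G.snps["chrom"],
            "pos": G.snps["pos"],
            "value": mean_fst,
            "role": "fst",
        }
    )


def hudson_fst_global(G: GenotypeMatrix, populations: dict[str, np.ndarray]) -> float:
    """Genome-wide Hudson F_ST as the ratio of summed numerator/denominator.

    For more than two populations, the mean of the per-pair ratios of sums.
    The ratio-of-sums aggregation is the standard low-bias genome-wide
    estimate (per-SNP ratios carry a Jensen bias when averaged).
    """
    labels = list(populations)
    if len(labels) < 2:
        raise GenotypeError("hudson_fst_global needs at least two populations")
    freqs, counts = {}, {}
    for lab, idx in populations.items():
        calls = G.calls[np.asarray(idx)]
        ok = calls != MISSING
        n = 2 * ok.sum(axis=0)
        alt = np.where(ok, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[lab] = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        counts[lab] = n.astype(float)
    ratios = []
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            la, lb = labels[a], labels[b]
            num, den = hudson_fst_components(freqs[la], counts[la], freqs[lb], counts[lb])
            ok = (counts[la] >= 4) & (counts[lb] >= 4) & np.isfinite(num) & (den > 0)
            if ok.any():
                ratios.append(float(num[ok].sum() / den[ok].sum()))
    return float(np.mean(ratios))


def select_diagnostic_snps(
    fst_track: pd.DataFrame, G: GenotypeMatrix, fst_min: float = 0.95, r2_max: float = 0.2
) -> pd.DataFrame:
    """Diagnostic SNPs for hybrid classification: F_ST > ``fst_min``, LD-pruned.

    Returns the (chrom, pos) table of retained SNPs; empty with a warning when
    nothing clears the F_ST bar.
    """
    if len(fst_track) != G.n_snps:
        raise GenotypeError("F_ST track not aligned to genotype matrix")
    mask = (fst_track["value"].to_numpy() > fst_min) & ~fst_track["value"].isna().to_numpy()
    if not mask.any():
        logger.warning("select_diagnostic_snps: no SNP with F_ST > %.2f", fst_min)
        return G.snps.iloc[:0][["chrom", "pos"]].copy()
    sub = G.take_snps(mask)
    pruned = ld_prune(sub, r2_max=r2_max)
    return pruned.snps[["chrom", "pos"]].copy()
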