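"""Diversity, inbreeding and relatedness statistics.

Implements per-SNP observed/expected heterozygosity with the >=10-genotyped
informativeness rule, F_IS = 1 - Ho/He (ratio of means), nucleotide diversity
pi = sum(He) / sequenced bases, maximum-likelihood IBD kinship via EM on the
(k0, k1, k2) simplex, maximum-likelihood inbreeding via a two-component EM,
and admixture (maxQ) flagging.

The kinship coefficient convention is phi = k2/2 + k1/4, so duplicated
samples give 0.5 and parent-offspring pairs 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, GenotypeError

MIN_GENOTYPED = 10  # per-group informativeness rule for He/Ho
LOW_CONFIDENCE_SNPS = 50  # fewer overlapping SNPs -> flag the pair estimate


@dataclass
class KinshipEstimate:
    """Pairwise IBD coefficients (k0, k1, k2), kinship phi and bookkeeping."""

    id1: str
    id2: str
    k0: float
    k1: float
    k2: float
    phi: float
    n_snps: int
    log_lik: float
    low_confidence: bool = False


# ---------------------------------------------------------------------------
# Heterozygosity, F_IS, pi
# ---------------------------------------------------------------------------

def het_per_snp(
    G: GenotypeMatrix, group: np.ndarray, min_genotyped: int = MIN_GENOTYPED
) -> pd.DataFrame:
    """Per-SNP observed and expected heterozygosity within a sample group.

    SNPs genotyped in fewer than ``min_genotyped`` group members are NaN
    (uninformative).  He = 2 p (1 - p) with p the alt-allele frequency among
    non-missing calls.
    """
    group = np.asarray(group)
    if group.size == 0:
        raise GenotypeError("empty group")
    calls = G.calls[group]
    ok = calls != MISSING
    n = ok.sum(axis=0)
    alt = np.where(ok, calls, 0).sum(axis=0)
    het = (calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / np.maximum(2 * n, 1)
        ho = het / np.maximum(n, 1)
    he = 2 * p * (1 - p)
    informative = n >= min_genotyped
    return pd.DataFrame(
        {
            "chrom": G.snps["chrom"],
            "pos": G.snps["pos"],
            "ho": np.where(informative, ho, np.nan),
            "he": np.where(informative, he, np.nan),
            "n_genotyped": n,
        }
    )


def fis(G: GenotypeMatrix, group: np.ndarray, min_genotyped: int = MIN_GENOTYPED) -> float:
    """F_IS = 1 - mean(Ho)/mean(He) over informative polymorphic SNPs (NaN if He sums to 0)."""
    het = het_per_snp(G, group, min_genotyped)
    poly = het["he"] > 0
    sum_he = het.loc[poly, "he"].sum()
    if sum_he == 0:
        return float("nan")
    return float(1 - het.loc[poly, "ho"].sum() / sum_he)


def nucleotide_diversity(
    G: GenotypeMatrix, group: np.ndarray, sequenced_bases: float,
    min_genotyped: int = MIN_GENOTYPED,
) -> float:
    """pi = sum of per-SNP expected heterozygosity over informative SNPs / sequenced bases."""
    if sequenced_bases <= 0:
        raise GenotypeError("sequenced_bases must be positive")
    het = het_per_snp(G, group, min_genotyped)
    return float(het["he"].sum(skipna=True) / sequenced_bases)


def diversity_summary(
    G: GenotypeMatrix,
    groups: dict[str, np.ndarray],
    sequenced_bases: float,
    min_genotyped: int = MIN_GENOTYPED,
) -> pd.DataFrame:
    """Per-group Ho/He means, pi and F_IS (one row per group label)."""
    rows = []
    for label, idx in groups.items():
        het = het_per_snp(G, idx, min_genotyped)
        informative = het["he"].notna()
        rows.append(
            {
                "group": label,
                "n_samples": len(np.asarray(idx)),
                "n_informative_snps": int(informative.sum()),
                "Ho": float(het["ho"].mean(skipna=True)),
                "He": float(het["he"].mean(skipna=True)),
                "pi": float(het["he"].sum(skipna=True) / sequenced_bases),
                "Fis": fis(G, idx, min_genotyped),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Maximum-likelihood IBD (EM over the k-simplex)
# ---------------------------------------------------------------------------

def _pair_ibd_likelihoods(g1: np.ndarray, g2: np.ndarray, p: np.ndarray):
    """P(g1, g2 | IBD=m, p) for m = 0, 1, 2 at each SNP.

    Under the non-inbred model: IBD0 -> independent HWE genotypes; IBD1 -> one
    shared allele plus one independent allele each; IBD2 -> identical genotypes.
    """
    q = 1 - p
    hwe = np.stack([q * q, 2 * p * q, p * p])  # P(g) indexed by dosage
    pg1 = hwe[g1, np.arange(g1.size)]
    pg2 = hwe[g2, np.arange(g2.size)]
    l0 = pg1 * pg2
    # P(g | shared allele = alt) and (= ref): remaining allele drawn from HWE
    a = np.stack([np.zeros_like(p), q, p])  # shared alt
    r = np.stack([q, p, np.zeros_like(p)])  # shared ref
    idx = np.arange(g1.size)
    l1 = p * a[g1, idx] * a[g2, idx] + q * r[g1, idx] * r[g2, idx]
    l2 = np.where(g1 == g2, pg1, 0.0)
    return l0, l1, l2


def ml_ibd(
    G: GenotypeMatrix,
    pair: tuple,
    allele_freqs: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    return_trace: bool = False,
) -> KinshipEstimate:
    """Maximum-likelihood (k0, k1, k2) IBD estimate for one sample pair via EM.

    ``pair`` holds two sample indices or ids.  Allele frequencies default to
    the full-cohort estimate.  Genotypes are assumed conditionally independent
    given the IBD state probabilities (LD-pruned input expected).
    """
    i, j = pair
    if isinstance(i, str):
        i, j = G.sample_index([i, j])
    if allele_freqs is None:
        allele_freqs = G.allele_freq()
    g1, g2 = G.calls[i], G.calls[j]
    ok = (g1 != MISSING) & (g2 != MISSING) & ~np.isnan(allele_freqs)
    p = np.clip(allele_freqs[ok], 1e-6, 1 - 1e-6)
    g1, g2 = g1[ok].astype(int), g2[ok].astype(int)
    n_snps = int(ok.sum())
    if n_snps == 0:
        raise GenotypeError("no overlapping non-missing SNPs for pair")
    l0, l1, l2 = _pair_ibd_likelihoods(g1, g2, p)
    k = np.array([1 / 3, 1 / 3, 1 / 3])
    ll_old = -np.inf
    trace = []
    for _ in range(max_iter):
        mix = k[0] * l0 + k[1] * l1 + k[2] * l2
        mix = np.maximum(mix, 1e-300)
        ll = float(np.log(mix).sum())
        trace.append(ll)
        if ll - ll_old < tol and ll >= ll_old:
            break
        ll_old = ll
        k = np.array(
            [
                (k[0] * l0 / mix).mean(),
                (k[1] * l1 / mix).mean(),
                (k[2] * l2 / mix).mean(),
            ]
        )
        k = np.clip(k, 0, 1)
        k /= k.sum()
    est = KinshipEstimate(
        id1=G.sample_ids[i],
        id2=G.sample_ids[j],
        k0=float(k[0]),
        k1=float(k[1]),
        k2=float(k[2]),
        phi=float(k[2] / 2 + k[1] / 4),
        n_snps=n_snps,
        log_lik=trace[-1],
        low_confidence=n_snps < LOW_CONFIDENCE_SNPS,
    )
    if return_trace:
        return est, trace
    return est


def ml_inbreeding(
    G: GenotypeMatrix,
    sample,
    allele_freqs: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    f_init: float = 0.01,
) -> float:
    """Maximum-likelihood inbreeding F for one sample via a 2-component EM.

    Each locus is autozygous with probability F (genotype homozygous, allele
    drawn at the population frequency) or allozygous (HWE) with 1 - F.
    Returns NaN when only monomorphic loci are available.
    """
    if isinstance(sample, str):
        sample = G.sample_index([sample])[0]
    if allele_freqs is None:
        allele_freqs = G.allele_freq()
    g = G.calls[sample]
    ok = (g != MISSING) & ~np.isnan(allele_freqs)
    p = allele_freqs[ok]
    g = g[ok].astype(int)
    poly = (p > 0) & (p < 1)
    p, g = p[poly], g[poly]
    if p.size == 0:
        return float("nan")
    p = np.clip(p, 1e-6, 1 - 1e-6)
    q = 1 - p
    idx = np.arange(g.size)
    hwe = np.stack([q * q, 2 * p * q, p * p])[g, idx]
    auto = np.stack([q, np.zeros_like(p), p])[g, idx]
    f = f_init
    ll_old = -np.inf
    for _ in range(max_iter):
        mix = f * auto + (1 - f) * hwe
        mix = np.maximum(mix, 1e-300)
        ll = float(np.log(mix).sum())
        if ll - ll_old < tol and ll >= ll_old:
            break
        ll_old = ll
        f = float((f * auto / mix).mean())
        f = min(max(f, 0.0), 1.0)
    return f


def _block_em(
    gi: np.ndarray, gj: np.ndarray, p: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-pair EM over the (k0,k1,k2) simplex for a block of pairs.

    Same model as :func:`ml_ibd`; SNPs missing in either member contribute a
    neutral likelihood and are excluded from the E-step averaging.  Returns
    (k array of shape (B, 3), n_snps per pair).
    """
    q = 1 - p
    m = p.size
    idx = np.arange(m)
    hwe = np.stack([q * q, 2 * p * q, p * p])
    a = np.stack([np.zeros_like(p), q, p])
    r = np.stack([q, p, np.zeros_like(p)])
    miss = (gi == MISSING) | (gj == MISSING)
    gi0 = np.where(miss, 0, gi)
    gj0 = np.where(miss, 0, gj)
    pg1 = hwe[gi0, idx]
    pg2 = hwe[gj0, idx]
    l0 = pg1 * pg2
    l1 = p * a[gi0, idx] * a[gj0, idx] + q * r[gi0, idx] * r[gj0, idx]
    l2 = np.where(gi0 == gj0, pg1, 0.0)
    for arr in (l0, l1, l2):
        arr[miss] = 1.0
    n_obs = (~miss).sum(axis=1).astype(float)
    B = gi.shape[0]
    k = np.full((B, 3), 1 / 3)
    ll_old = np.full(B, -np.inf)
    active = n_obs > 0
    for _ in range(max_iter):
        if not active.any():
            break
        mix = k[:, 0:1] * l0 + k[:, 1:2] * l1 + k[:, 2:3] * l2
        np.maximum(mix, 1e-300, out=mix)
        ll = np.log(mix).sum(axis=1)
        done = active & (ll - ll_old < tol) & (ll >= ll_old)
        active &= ~done
        ll_old = ll
        if not active.any():
            break
        sub = np.flatnonzero(active)
        # neutral (missing) SNPs contribute exactly k to the sum; subtract them
        new = np.stack(
            [
                ((k[sub, 0:1] * l0[sub] / mix[sub]).sum(axis=1) - (m - n_obs[sub]) * k[sub, 0]),
                ((k[sub, 1:2] * l1[sub] / mix[sub]).sum(axis=1) - (m - n_obs[sub]) * k[sub, 1]),
                ((k[sub, 2:3] * l2[sub] / mix[sub]).sum(axis=1) - (m - n_obs[sub]) * k[sub, 2]),
            ],
            axis=1,
        ) / n_obs[sub, None]
        new = np.clip(new, 0, 1)
        new /= new.sum(axis=1, keepdims=True)
        k[sub] = new
    return k, n_obs.astype(int)


def kinship_matrix(
    G: GenotypeMatrix,
    groups: dict[str, np.ndarray] | None = None,
    allele_freqs: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    block_size: int = 128,
) -> pd.DataFrame:
    """All-pairs ML kinship table (id1, id2, k0, k1, k2, phi, n_snps, group).

    Pairs are processed in vectorized EM blocks (identical model to
    :func:`ml_ibd`, which serves as the single-pair reference).  ``groups``
    (label -> sample index array) annotates within-group pairs; between-group
    pairs get group = "between".  Use :func:`kinship_medians` for summaries.
    """
    if G.n_samples < 2:
        raise GenotypeError("kinship_matrix needs at least 2 samples")
    if allele_freqs is None:
        allele_freqs = G.allele_freq()
    member = {}
    if groups:
        for lab, idx in groups.items():
            for i in np.asarray(idx):
                member[int(i)] = lab
    ok_snp = ~np.isnan(allele_freqs)
    p = np.clip(allele_freqs[ok_snp], 1e-6, 1 - 1e-6)
    calls = G.calls[:, ok_snp]
    pairs = list(combinations(range(G.n_samples), 2))
    rows = []
    for lo in range(0, len(pairs), block_size):
        block = pairs[lo:lo + block_size]
        I = np.array([i for i, _ in block])
        J = np.array([j for _, j in block])
        k, n_obs = _block_em(calls[I], calls[J], p, max_iter, tol)
        for b, (i, j) in enumerate(block):
            gi, gj = member.get(i), member.get(j)
            group = gi if (gi is not None and gi == gj) else "between"
            rows.append(
                {
                    "id1": G.sample_ids[i],
                    "id2": G.sample_ids[j],
                    "k0": float(k[b, 0]),
                    "k1": float(k[b, 1]),
                    "k2": float(k[b, 2]),
                    "phi": float(k[b, 2] / 2 + k[b, 1] / 4),
                    "n_snps": int(n_obs[b]),
                    "low_confidence": bool(n_obs[b] < LOW_CONFIDENCE_SNPS),
                    "group": group,
                }
            )
    return pd.DataFrame(rows)


def kinship_medians(pairs: pd.DataFrame) -> pd.DataFrame:
    """Median phi per group label plus the all-pairs median (label 'all')."""
    rows = [
        {"group": lab, "median_phi": float(sub["phi"].median()), "n_pairs": len(sub)}
        for lab, sub in pairs.groupby("group")
    ]
    rows.append({"group": "all", "median_phi": float(pairs["phi"].median()), "n_pairs": len(pairs)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Admixture proportions
# ---------------------------------------------------------------------------

def read_q_matrix(q_path: str, samples_path: str) -> pd.DataFrame:
    """Read a whitespace-delimited K-column ancestry matrix plus sample-order file."""
    q = pd.read_csv(q_path, sep=r"\s+", header=None)
    with open(samples_path) as fh:
        ids = [line.strip().split()[0] for line in fh if line.strip()]
    if len(ids) != len(q):
        raise GenotypeError("sample-order file length does not match Q matrix")
    q.index = ids
    q.columns = [f"Q{i + 1}" for i in range(q.shape[1])]
    return q


def flag_admixed(Q: pd.DataFrame, threshold: float = 0.95, row_sum_tol: float = 1e-3) -> pd.DataFrame:
    """Per-sample maxQ and admixed flag (admixed <=> maxQ < threshold)."""
    arr = Q.to_numpy(dtype=float)
    sums = arr.sum(axis=1)
    if np.abs(sums - 1).max() > row_sum_tol:
        raise GenotypeError("ancestry rows do not sum to 1")
    maxq = arr.max(axis=1)
    return pd.DataFrame(
        {"sample_id": Q.index, "maxQ": maxq, "admixed": maxq < threshold}
    ).reset_index(drop=True)
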