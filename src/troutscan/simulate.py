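"""Synthetic structured-cohort generator with known ground truth.

Emulates the statistical structure of a multi-lineage brown-trout RAD-seq
cohort: five differentiated lineages with unequal sample sizes drawn under
the Balding-Nichols island model (population allele frequencies Beta-
distributed around an ancestral frequency with divergence F), one lineage
receiving admixture from another, per-entry sequencing depth (negative
binomial) so coverage filters fire, planted low-heterozygosity sweep regions,
planted cross-population shared-haplotype (IBD) regions, a marker linkage map
with a configurable recombination-rate profile, and an annotation table with
one KEGG term enriched inside chosen regions.

Everything is reproducible from the config seed; planted structures are
emitted as ground truth for recovery tests.  Sites are unlinked except inside
planted IBD-share blocks, where a founder haplotype copied across populations
creates the local identity the windowed kinship scan detects; the analyses
this generator feeds operate on allele frequencies and IBD sharing, not
fine-scale LD, so no coalescent machinery is used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, SampleInfo, GenotypeError

DEFAULT_CHROMS = {f"chr{i}": 20_000_000 for i in range(1, 6)}
DEFAULT_POP_SIZES = {"AT": 10, "CA": 17, "MA": 25, "MI": 14, "MM": 25}
DEFAULT_POP_FST = {"AT": 0.25, "CA": 0.35, "MA": 0.30, "MI": 0.20, "MM": 0.15}
# origin composition (farmed, river, unknown) mirroring the study design
DEFAULT_ORIGINS = {
    "AT": (10, 0, 0),
    "CA": (17, 0, 0),
    "MA": (22, 0, 3),
    "MI": (0, 13, 1),
    "MM": (0, 25, 0),
}


@dataclass
class SweepSpec:
    """A planted selection structure: interval, type, affected pops, intensity.

    ``low_het`` pushes affected-population allele frequencies toward the major
    allele (intensity 1 = fixation, He 0).  ``ibd_share`` copies a single
    founder haplotype into all affected populations: each individual carries
    Binomial(2, f) founder copies across the whole block, f = 0.8 + 0.1 *
    intensity, creating genuine identity-by-descent between populations.
    """

    chrom: str
    start: int
    end: int
    kind: str  # "low_het" | "ibd_share"
    pops: tuple = ()
    intensity: float = 1.0


@dataclass
class AdmixtureSpec:
    target: str
    source: str
    fraction: float = 0.3
    n_individuals: int = 17


@dataclass
class SimConfig:
    seed: int = 0
    chrom_lengths: dict = field(default_factory=lambda: dict(DEFAULT_CHROMS))
    n_snps: int = 20_000
    pop_sizes: dict = field(default_factory=lambda: dict(DEFAULT_POP_SIZES))
    pop_fst: dict = field(default_factory=lambda: dict(DEFAULT_POP_FST))
    admixture: list = field(default_factory=lambda: [AdmixtureSpec("MM", "AT")])
    sweeps: list = field(default_factory=list)
    origins: dict = field(default_factory=lambda: dict(DEFAULT_ORIGINS))
    depth_mean: float = 15.0
    depth_shape: float = 5.0  # negative-binomial dispersion (larger = tighter)
    n_low_coverage: int = 0  # samples forced to ~low_coverage_mean reads/site
    low_coverage_mean: float = 3.0
    pi_target: float | None = None
    bases_per_snp: float = 130.0  # locus length backing the pi denominator

    def validate(self) -> None:
        for pop, size in self.pop_sizes.items():
            if size < 0:
                raise GenotypeError(f"negative size for pop {pop}")
            if not 0 < self.pop_fst.get(pop, 0.2) < 1:
                raise GenotypeError(f"divergence F for {pop} must lie in (0, 1)")
        for sw in self.sweeps:
            if sw.chrom not in self.chrom_lengths:
                raise GenotypeError(f"sweep on unknown chromosome {sw.chrom}")
            if not 1 <= sw.start < sw.end <= self.chrom_lengths[sw.chrom] + 1:
                raise GenotypeError(f"sweep interval outside chromosome: {sw}")
            if sw.kind not in ("low_het", "high_het", "ibd_share"):
                raise GenotypeError(f"unknown sweep kind {sw.kind}")
            for p in sw.pops:
                if p not in self.pop_sizes:
                    raise GenotypeError(f"sweep names unknown pop {p}")


@dataclass
class Cohort:
    genotypes: GenotypeMatrix
    meta: list
    ancestry: pd.DataFrame
    truth: pd.DataFrame
    sequenced_bases: float
    config: SimConfig


def _snp_positions(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    total = sum(config.chrom_lengths.values())
    chroms, counts = list(config.chrom_lengths), []
    assigned = 0
    for i, c in enumerate(chroms):
        if i == len(chroms) - 1:
            counts.append(config.n_snps - assigned)
        else:
            k = round(config.n_snps * config.chrom_lengths[c] / total)
            counts.append(k)
            assigned += k
    frames = []
    for chrom, k in zip(chroms, counts):
        L = config.chrom_lengths[chrom]
        pos = np.unique(rng.integers(1, L + 1, size=int(k * 1.3) + 16))
        while pos.size < k:
            pos = np.unique(np.concatenate([pos, rng.integers(1, L + 1, size=k)]))
        pos = np.sort(rng.choice(pos, size=k, replace=False))
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    snps = pd.concat(frames, ignore_index=True)
    ref_alt = np.array(list("ACGT"))
    r = rng.integers(0, 4, size=len(snps))
    a = (r + 1 + rng.integers(0, 3, size=len(snps))) % 4
    snps["ref"] = ref_alt[r]
    snps["alt"] = ref_alt[a]
    return snps


def _sweep_mask(snps: pd.DataFrame, sw: SweepSpec) -> np.ndarray:
    return (
        (snps["chrom"].to_numpy() == sw.chrom)
        & (snps["pos"].to_numpy() >= sw.start)
        & (snps["pos"].to_numpy() < sw.end)
    )


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate genotypes, metadata, ancestry matrix and ground truth from a config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    snps = _snp_positions(config, rng)
    m = len(snps)
    anc = rng.uniform(0.05, 0.95, size=m)
    pop_freq = {}
    for pop in config.pop_sizes:
        F = config.pop_fst.get(pop, 0.2)
        a = anc * (1 - F) / F
        b = (1 - anc) * (1 - F) / F
        pop_freq[pop] = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
    # planted structures
    for sw in config.sweeps:
        mask = _sweep_mask(snps, sw)
        pops = sw.pops or tuple(config.pop_sizes)
        if sw.kind == "low_het":
            # the favored allele is the ancestral major, shared across pops,
            # so a full-intensity sweep drives cohort-level He to zero
            major = anc[mask] >= 0.5
            for pop in pops:
                p = pop_freq[pop][mask]
                pop_freq[pop][mask] = np.where(
                    major, p + sw.intensity * (1 - p), p - sw.intensity * p
                )
        elif sw.kind == "high_het":
            for pop in pops:
                p = pop_freq[pop][mask]
                pop_freq[pop][mask] = p + sw.intensity * (0.5 - p)
        # ibd_share is applied at the genotype level below (haplotype copying)
    # sample bookkeeping
    admix_by_target = {a.target: a for a in config.admixture}
    sample_ids, lineages, origins_list, q_rows = [], [], [], []
    ind_freqs = []  # per-individual expected allele frequency vectors
    pop_labels = list(config.pop_sizes)
    for pop in pop_labels:
        size = config.pop_sizes[pop]
        farmed, river, unknown = config.origins.get(pop, (0, 0, size))
        origin_seq = ["farmed"] * farmed + ["river"] * river + ["unknown"] * unknown
        origin_seq += ["unknown"] * max(0, size - len(origin_seq))
        adm = admix_by_target.get(pop)
        for i in range(size):
            sid = f"{pop}{i + 1:02d}"
            sample_ids.append(sid)
            lineages.append(pop)
            origins_list.append(origin_seq[i])
            is_admixed = adm is not None and i >= size - adm.n_individuals
            q = {p: 0.0 for p in pop_labels}
            if is_admixed:
                per_locus_src = rng.random(m) < adm.fraction
                ind_freqs.append(
                    np.where(per_locus_src, pop_freq[adm.source], pop_freq[pop])
                )
                q[pop] = 1 - adm.fraction
                q[adm.source] = adm.fraction
            else:
                ind_freqs.append(pop_freq[pop])
                q[pop] = 1.0
            q_rows.append(q)
    n = len(sample_ids)
    calls = np.empty((n, m), dtype=np.int8)
    for i in range(n):
        calls[i] = rng.binomial(2, ind_freqs[i]).astype(np.int8)
    # planted cross-population haplotype sharing: copy one founder haplotype
    # into carriers; the founder-copy count is a per-individual latent shared
    # across the block, so carrier pairs are identical-by-descent there
    for sw in config.sweeps:
        if sw.kind != "ibd_share":
            continue
        mask = _sweep_mask(snps, sw)
        founder = (rng.random(int(mask.sum())) < anc[mask]).astype(np.int8)
        f = 0.8 + 0.1 * sw.intensity
        pops = sw.pops or tuple(config.pop_sizes)
        for i, lin in enumerate(lineages):
            if lin not in pops:
                continue
            c = int(rng.binomial(2, f))
            residual = rng.binomial(2 - c, ind_freqs[i][mask]) if c < 2 else 0
            calls[i, mask] = (c * founder + residual).astype(np.int8)
    # per-entry depth
    means = rng.gamma(10.0, config.depth_mean / 10.0, size=n)
    if config.n_low_coverage:
        # the low-coverage design is exact: the chosen samples sit at
        # low_coverage_mean and the rest are kept clear of the 5x filter
        means = np.maximum(means, 6.0)
        low_idx = np.linspace(0, n - 1, config.n_low_coverage).astype(int)
        means[low_idx] = config.low_coverage_mean
    depth = np.empty((n, m), dtype=np.int32)
    r = config.depth_shape
    for i in range(n):
        depth[i] = rng.negative_binomial(r, r / (r + means[i]), size=m)
    G = GenotypeMatrix(sample_ids=sample_ids, snps=snps, calls=calls, depth=depth)
    G.validate()
    meta = [
        SampleInfo(
            sample_id=sid,
            lineage=lin,
            origin=orig,
            subpopulation=None,
            mean_coverage=float(depth[i].mean()),
        )
        for i, (sid, lin, orig) in enumerate(zip(sample_ids, lineages, origins_list))
    ]
    ancestry = pd.DataFrame(q_rows, index=sample_ids)[pop_labels]
    truth = pd.DataFrame(
        [
            {
                "chrom": sw.chrom,
                "start": sw.start,
                "end": sw.end,
                "kind": sw.kind,
                "pops": ",".join(sw.pops or tuple(config.pop_sizes)),
                "intensity": sw.intensity,
            }
            for sw in config.sweeps
        ],
        columns=["chrom", "start", "end", "kind", "pops", "intensity"],
    )
    # expected cohort-average heterozygosity backs the pi denominator
    pbar = np.mean(np.stack([f for f in ind_freqs]), axis=0)
    he_sum = float((2 * pbar * (1 - pbar)).sum())
    if config.pi_target:
        sequenced_bases = he_sum / config.pi_target
    else:
        sequenced_bases = config.n_snps * config.bases_per_snp
    return Cohort(G, meta, ancestry, truth, sequenced_bases, config)


# ---------------------------------------------------------------------------
# Linkage map + similarity hits
# ---------------------------------------------------------------------------

@dataclass
class MapConfig:
    seed: int = 0
    chrom_lengths: dict = field(default_factory=lambda: dict(DEFAULT_CHROMS))
    marker_spacing: int = 500_000
    # per-chromosome piecewise-constant rate profile: list of (start, end, cM/Mb);
    # a plain float means a constant profile on every chromosome
    rate_profile: dict | float = 0.7
    evalue: float = 1e-50
    pident: float = 99.0
    tag_length: int = 150
    fail_fraction: float = 0.0  # fraction of hits planted to fail the filters


def _profile_for(config: MapConfig, chrom: str) -> list[tuple[int, int, float]]:
    L = config.chrom_lengths[chrom]
    if isinstance(config.rate_profile, (int, float)):
        return [(1, L + 1, float(config.rate_profile))]
    return config.rate_profile[chrom]


def _cm_at(profile, bp: np.ndarray) -> np.ndarray:
    """Cumulative genetic position (cM) at physical positions under the profile."""
    cm = np.zeros(len(bp))
    for start, end, rate in profile:
        lo = np.clip(bp, start, end) - start
        cm += np.maximum(lo, 0) / 1e6 * rate
    return cm


def simulate_map_and_hits(config: MapConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marker linkage map plus 12-column similarity hits anchoring it.

    Markers are placed every ``marker_spacing`` bp; cM positions integrate the
    configured rate profile.  A ``fail_fraction`` of hits is planted with a
    weak e-value (1e-20) so hit filters demonstrably fire.
    """
    rng = np.random.default_rng(config.seed)
    map_rows, hit_rows = [], []
    for ci, (chrom, L) in enumerate(config.chrom_lengths.items()):
        bp = np.arange(config.marker_spacing, L + 1, config.marker_spacing)
        cm = _cm_at(_profile_for(config, chrom), bp)
        lg = f"LG{ci + 1}"
        for k, (b, c) in enumerate(zip(bp, cm)):
            marker = f"{lg}_M{k + 1:04d}"
            map_rows.append({"marker": marker, "linkage_group": lg, "cM": round(float(c), 6)})
            fail = rng.random() < config.fail_fraction
            hit_rows.append(
                {
                    "qseqid": marker,
                    "sseqid": chrom,
                    "pident": config.pident,
                    "length": config.tag_length,
                    "mismatch": 1,
                    "gapopen": 0,
                    "qstart": 1,
                    "qend": config.tag_length,
                    "sstart": int(b),
                    "send": int(b) + config.tag_length - 1,
                    "evalue": 1e-20 if fail else config.evalue,
                    "bitscore": 280.0,
                }
            )
    return pd.DataFrame(map_rows), pd.DataFrame(hit_rows)


# ---------------------------------------------------------------------------
# Annotation table with a planted enriched term
# ---------------------------------------------------------------------------

def simulate_annotation(
    chrom_lengths: dict,
    enriched_term: str = "map05168 Herpes simplex virus 1 infection",
    regions: pd.DataFrame | None = None,
    seed: int = 0,
    gene_spacing: int = 100_000,
    gene_length: int = 20_000,
    p_in: float = 0.8,
    p_bg: float = 0.05,
    n_background_terms: int = 20,
) -> pd.DataFrame:
    """Gene annotation TSV shape with one KEGG pathway enriched inside regions.

    Genes are tiled every ``gene_spacing`` bp; the enriched term is assigned
    with probability ``p_in`` to genes overlapping any of ``regions`` and
    ``p_bg`` elsewhere.  Filler pathway/class/GO terms are drawn at random so
    background occurrence counts vary.
    """
    rng = np.random.default_rng(seed)
    bg_terms = [f"map{10000 + i} background pathway {i}" for i in range(n_background_terms)]
    classes = ["Metabolism", "Genetic Information Processing", "Organismal Systems"]
    rows = []
    gid = 0
    for chrom, L in chrom_lengths.items():
        for start in range(1, L - gene_length, gene_spacing):
            gid += 1
            end = start + gene_length - 1
            in_region = False
            if regions is not None and len(regions):
                sub = regions[regions["chrom"] == chrom]
                in_region = bool(
                    ((sub["start"] < end + 1) & (sub["end"] > start)).any()
                ) if len(sub) else False
            terms = [t for t in bg_terms if rng.random() < 0.08]
            if rng.random() < (p_in if in_region else p_bg):
                terms.append(enriched_term)
            rows.append(
                {
                    "gene": f"gene{gid:05d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "kegg_class": ";".join(
                        [c for c in classes if rng.random() < 0.2]
                    ),
                    "kegg_pathway": ";".join(terms),
                    "go": f"GO:{rng.integers(1, 9999999):07d}" if rng.random() < 0.5 else "",
                    "uniprot": f"P{rng.integers(10000, 99999)}" if rng.random() < 0.5 else "",
                }
            )
    return pd.DataFrame(rows)


def simulate_snp_pvalues(
    snps: pd.DataFrame,
    regions: pd.DataFrame | None = None,
    seed: int = 0,
    low_p_max: float = 0.005,
) -> pd.DataFrame:
    """Per-SNP p-value track: Uniform(0,1) null with planted low-p runs.

    Stands in for the per-SNP output of an external haplotype-differentiation
    test; SNPs inside ``regions`` draw p ~ Uniform(0, low_p_max).
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(0, 1, size=len(snps))
    if regions is not None:
        for _, reg in regions.iterrows():
            mask = (
                (snps["chrom"] == reg["chrom"])
                & (snps["pos"] >= reg["start"])
                & (snps["pos"] < reg["end"])
            ).to_numpy()
            p[mask] = rng.uniform(0, low_p_max, size=int(mask.sum()))
    return pd.DataFrame({"chrom": snps["chrom"], "pos": snps["pos"], "p": p})
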