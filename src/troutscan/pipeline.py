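"""End-to-end orchestration: filter -> stats -> scans -> anchoring -> enrichment.

One :class:`RunConfig` (YAML-loadable, unknown keys rejected) drives every
stage with the package defaults (5x coverage filters, 50% informativeness,
0.8 heterozygote cap, 0.2 LD cap, 1 Mb / 200 kb ZHp windows at |Z| >= 2.81,
SNP runs at p <= 0.01, 5 Mb / 2.5 Mb IBD windows at phi >= 0.05, 1000
resamples, retention p < 0.05, maxQ 0.95).  Outputs are TSVs in a run
directory plus a manifest (parameters, seed, input hashes) making a rerun
with the same config byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genotypes as gt
from . import popgen, scan, recomb, enrich
from . import simulate as sim

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 0
    # inputs: either a synthetic block or explicit paths
    simulate: dict | None = None
    vcf: str | None = None
    metadata: str | None = None
    q_matrix: str | None = None
    q_samples: str | None = None
    snp_pvalues: str | None = None
    linkage_map: str | None = None
    hits: str | None = None
    annotation: str | None = None
    sequenced_bases: float | None = None
    # filter parameters
    min_sample_cov: float = 5.0
    min_depth: int = 5
    min_informative: float = 0.5
    max_het: float = 0.8
    maf: float = 0.0
    ld_r2: float = 0.2
    # scan parameters
    zhp_window: int = 1_000_000
    zhp_step: int = 200_000
    z_thresh: float = 2.81
    snp_p_thresh: float = 0.01
    ibd_window: int = 5_000_000
    ibd_step: int = 2_500_000
    kin_thresh: float = 0.05
    n_resamples: int = 1000
    retain_p: float = 0.05
    maxq: float = 0.95
    min_stratum_size: int = 5
    strata: list = field(default_factory=lambda: ["lineage", "farm_river", "q95"])
    run_kinship_matrix: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise gt.GenotypeError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _prepare_inputs(config: RunConfig, outdir: Path) -> dict:
    """Simulate or load the inputs; returns a dict of in-memory objects."""
    inputs: dict = {}
    if config.simulate is not None:
        simdir = outdir / "inputs"
        simdir.mkdir(parents=True, exist_ok=True)
        raw = dict(config.simulate)
        sweeps = [sim.SweepSpec(**s) for s in raw.pop("sweeps", [])]
        admix = [sim.AdmixtureSpec(**a) for a in raw.pop("admixture", [{"target": "MM", "source": "AT"}])]
        sim_cfg = sim.SimConfig(seed=raw.pop("seed", config.seed), sweeps=sweeps, admixture=admix, **raw)
        cohort = sim.simulate_cohort(sim_cfg)
        gt.write_vcf(cohort.genotypes, simdir / "genotypes.vcf")
        gt.write_metadata(cohort.meta, simdir / "samples.tsv")
        cohort.ancestry.to_csv(simdir / "ancestry.Q", sep=" ", header=False, index=False)
        (simdir / "ancestry.samples").write_text("\n".join(cohort.genotypes.sample_ids) + "\n")
        _write(cohort.truth, simdir / "truth.tsv")
        inputs["G"] = cohort.genotypes
        inputs["meta"] = cohort.meta
        inputs["Q"] = cohort.ancestry
        inputs["truth"] = cohort.truth
        inputs["sequenced_bases"] = cohort.sequenced_bases
        # companion tracks generated from the same truth
        regions_truth = cohort.truth[cohort.truth["kind"] == "ibd_share"]
        inputs["pvalues"] = sim.simulate_snp_pvalues(
            cohort.genotypes.snps, regions_truth if len(regions_truth) else None,
            seed=sim_cfg.seed + 1,
        )
        map_cfg = sim.MapConfig(seed=sim_cfg.seed + 2, chrom_lengths=sim_cfg.chrom_lengths)
        lmap, hits = sim.simulate_map_and_hits(map_cfg)
        inputs["linkage_map"], inputs["hits"] = lmap, hits
        inputs["annotation"] = sim.simulate_annotation(
            sim_cfg.chrom_lengths,
            regions=cohort.truth if len(cohort.truth) else None,
            seed=sim_cfg.seed + 3,
        )
        inputs["chrom_lengths"] = sim_cfg.chrom_lengths
    else:
        if not config.vcf or not config.metadata:
            raise gt.GenotypeError("either a simulate block or vcf+metadata paths are required")
        inputs["G"] = gt.read_vcf(config.vcf)
        inputs["meta"] = gt.read_metadata(config.metadata)
        inputs["Q"] = (
            popgen.read_q_matrix(config.q_matrix, config.q_samples)
            if config.q_matrix
            else None
        )
        inputs["truth"] = None
        inputs["sequenced_bases"] = config.sequenced_bases
        inputs["pvalues"] = (
            pd.read_csv(config.snp_pvalues, sep="\t") if config.snp_pvalues else None
        )
        inputs["linkage_map"] = (
            pd.read_csv(config.linkage_map, sep="\t") if config.linkage_map else None
        )
        inputs["hits"] = recomb.read_hits(config.hits) if config.hits else None
        inputs["annotation"] = (
            enrich.read_annotation(config.annotation) if config.annotation else None
        )
        inputs["chrom_lengths"] = None
    return inputs


def run_all(config: RunConfig, outdir: str | Path) -> Path:
    """Execute every stage in dependency order; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    counts = {}
    try:
        inputs = _prepare_inputs(config, outdir)
        G, meta = inputs["G"], inputs["meta"]
        counts["samples_in"] = G.n_samples
        counts["snps_in"] = G.n_snps

        stage = "filter"
        G, meta = gt.drop_low_coverage_samples(G, meta, config.min_sample_cov)
        counts["samples_after_coverage"] = G.n_samples
        G = gt.mask_low_coverage(G, config.min_depth)
        G = gt.filter_missingness(G, config.min_informative)
        counts["snps_after_missingness"] = G.n_snps
        G = gt.filter_excess_het(G, config.max_het)
        counts["snps_after_het"] = G.n_snps
        G = gt.filter_maf(G, config.maf)
        counts["snps_after_maf"] = G.n_snps
        gt.write_vcf(G, outdir / "filtered.vcf")
        gt.write_metadata(meta, outdir / "samples_filtered.tsv")

        lineage_groups = {
            lab: np.array([i for i, m in enumerate(meta) if m.lineage == lab])
            for lab in dict.fromkeys(m.lineage for m in meta)
        }
        farm_river = {
            lab: np.array([i for i, m in enumerate(meta) if m.origin == lab])
            for lab in ("farmed", "river")
        }

        stage = "stats"
        seq_bases = inputs["sequenced_bases"] or G.n_snps * 130.0
        groups = {"all": np.arange(G.n_samples), **lineage_groups, **farm_river}
        groups = {k: v for k, v in groups.items() if len(v)}
        diversity = popgen.diversity_summary(G, groups, seq_bases)
        _write(diversity, outdir / "diversity.tsv")
        admixed = None
        if inputs["Q"] is not None:
            Qf = inputs["Q"].loc[[s for s in G.sample_ids if s in inputs["Q"].index]]
            admixed = popgen.flag_admixed(Qf, config.maxq)
            _write(admixed, outdir / "admixture_flags.tsv")
        pruned = gt.ld_prune(gt.filter_maf(G, 0.0), r2_max=config.ld_r2)
        counts["snps_ld_pruned"] = pruned.n_snps
        if config.run_kinship_matrix:
            pairs = popgen.kinship_matrix(pruned, lineage_groups)
            _write(pairs, outdir / "kinship_pairs.tsv")
            _write(popgen.kinship_medians(pairs), outdir / "kinship_medians.tsv")
            freqs = pruned.allele_freq()
            inb = pd.DataFrame(
                {
                    "sample_id": pruned.sample_ids,
                    "F": [
                        popgen.ml_inbreeding(pruned, i, freqs)
                        for i in range(pruned.n_samples)
                    ],
                }
            )
            _write(inb, outdir / "inbreeding.tsv")

        stage = "zhp_scan"
        chrom_lengths = inputs["chrom_lengths"] or {
            str(c): int(g["pos"].max())
            for c, g in G.snps.groupby("chrom", sort=False)
        }
        scheme = scan.WindowScheme(config.zhp_window, config.zhp_step, chrom_lengths)
        ztrack, zregions = scan.zhp_scan(
            G, np.arange(G.n_samples), scheme, config.z_thresh,
            config.n_resamples, config.seed, config.retain_p,
        )
        _write(ztrack, outdir / "zhp_track.tsv")
        strata = {}
        if "lineage" in config.strata:
            strata.update(lineage_groups)
        if "farm_river" in config.strata:
            strata.update(farm_river)
        if "q95" in config.strata and admixed is not None:
            keep_ids = set(admixed.loc[~admixed["admixed"], "sample_id"])
            strata["q95"] = np.array([i for i, s in enumerate(G.sample_ids) if s in keep_ids])
        def zhp_for(idx):
            return scan.zhp_scan(
                G, idx, scheme, config.z_thresh, config.n_resamples,
                config.seed, config.retain_p,
            )[1]
        _, zannot = scan.stratified_scan(
            zhp_for, strata, zregions, config.min_stratum_size
        )
        _write(zannot if zannot is not None else zregions, outdir / "zhp_regions.tsv")

        stage = "snp_p_scan"
        sregions = None
        if inputs["pvalues"] is not None:
            sregions = scan.snp_p_regions(
                inputs["pvalues"], config.snp_p_thresh, config.n_resamples,
                config.seed, config.retain_p,
            )
            _write(sregions, outdir / "snp_p_regions.tsv")

        stage = "ibd_scan"
        ischeme = scan.WindowScheme(config.ibd_window, config.ibd_step, chrom_lengths)
        itrack, iregions = scan.kinship_window_scan(
            G, lineage_groups, ischeme, config.kin_thresh,
            n_resamples=config.n_resamples, seed=config.seed, retain_p=config.retain_p,
        )
        _write(itrack, outdir / "ibd_track.tsv")
        _write(iregions, outdir / "ibd_regions.tsv")

        stage = "overlaps"
        retained_z = zregions[zregions["retained"]] if len(zregions) else zregions
        retained_i = iregions[iregions["retained"]] if len(iregions) else iregions
        common = scan.overlap_regions(retained_z, retained_i)
        if sregions is not None and len(sregions):
            common = pd.concat(
                [common, scan.overlap_regions(sregions[sregions["retained"]], retained_i)],
                ignore_index=True,
            )
        _write(common, outdir / "region_overlaps.tsv")

        stage = "recombination"
        anchors = None
        if inputs["linkage_map"] is not None and inputs["hits"] is not None:
            anchors = recomb.anchor_map(
                inputs["linkage_map"], recomb.filter_hits(inputs["hits"])
            )
            _write(anchors, outdir / "anchored_map.tsv")
            all_regions = pd.concat(
                [r for r in (retained_z, sregions, retained_i) if r is not None and len(r)],
                ignore_index=True,
            ) if any(r is not None and len(r) for r in (retained_z, sregions, retained_i)) else pd.DataFrame(columns=["chrom", "start", "end"])
            if len(all_regions):
                _write(recomb.region_rates(anchors, all_regions), outdir / "region_recomb_rates.tsv")
            het_all = popgen.het_per_snp(G, np.arange(G.n_samples))
            win_he = _window_mean_he(het_all, scheme)
            fit = recomb.het_vs_recomb(win_he, anchors)
            (outdir / "het_vs_recomb.json").write_text(json.dumps(fit, indent=1))

        stage = "enrichment"
        if inputs["annotation"] is not None:
            tables = []
            for name, regs in (
                ("ZHp", retained_z),
                ("SNP-p", sregions[sregions["retained"]] if sregions is not None and len(sregions) else None),
                ("IBD", retained_i),
            ):
                if regs is None or not len(regs):
                    continue
                table, _ = enrich.region_enrichment(regs, inputs["annotation"])
                table.insert(0, "approach", name)
                tables.append(table)
            if tables:
                _write(pd.concat(tables, ignore_index=True), outdir / "enrichment.tsv")

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "parameters": {
                k: v for k, v in dataclasses.asdict(config).items() if k != "simulate"
            },
            "simulate": config.simulate,
            "counts": counts,
            "outputs": {
                p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv"))
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return outdir


def _window_mean_he(het: pd.DataFrame, scheme: scan.WindowScheme) -> pd.DataFrame:
    """Mean per-SNP He per (non-overlapping) window of the scheme's length."""
    rows = []
    for chrom in scheme.chrom_lengths:
        sub = het[het["chrom"] == chrom]
        L = scheme.chrom_lengths[chrom]
        for start in range(1, L + 1, scheme.window_length):
            end = min(start + scheme.window_length, L + 1)
            vals = sub[(sub["pos"] >= start) & (sub["pos"] < end)]["he"]
            rows.append(
                {"chrom": chrom, "start": start, "end": end,
                 "he": float(vals.mean()) if vals.notna().any() else float("nan")}
            )
    return pd.DataFrame(rows)


def summarize(outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Build report tables from a completed run directory.

    Returns (and writes) a per-lineage diversity table and the annotated
    region tables; missing stage outputs produce warnings, not errors.
    """
    outdir = Path(outdir)
    report: dict[str, pd.DataFrame] = {}
    div_path = outdir / "diversity.tsv"
    meta_path = outdir / "samples_filtered.tsv"
    if div_path.exists() and meta_path.exists():
        div = pd.read_csv(div_path, sep="\t")
        meta = pd.read_csv(meta_path, sep="\t")
        adm_path = outdir / "admixture_flags.tsv"
        adm = pd.read_csv(adm_path, sep="\t") if adm_path.exists() else None
        rows = []
        for lineage, sub in meta.groupby("lineage"):
            row = {
                "lineage": lineage,
                "farmed": int((sub["origin"] == "farmed").sum()),
                "river": int((sub["origin"] == "river").sum()),
                "unknown": int((sub["origin"] == "unknown").sum()),
            }
            if adm is not None:
                a = adm[adm["sample_id"].isin(sub["sample_id"])]
                row["n_admixed"] = int(a["admixed"].sum())
                row["avg_maxQ"] = float(a["maxQ"].mean()) if len(a) else float("nan")
            d = div[div["group"] == lineage]
            row["pi"] = float(d["pi"].iloc[0]) if len(d) else float("nan")
            rows.append(row)
        report["diversity_table"] = pd.DataFrame(rows)
        _write(report["diversity_table"], outdir / "report_diversity.tsv")
    else:
        logger.warning("summarize: diversity outputs missing")
    for name in ("zhp_regions", "snp_p_regions", "ibd_regions"):
        path = outdir / f"{name}.tsv"
        if path.exists():
            report[name] = pd.read_csv(path, sep="\t")
        else:
            logger.warning("summarize: %s missing", name)
    return report
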