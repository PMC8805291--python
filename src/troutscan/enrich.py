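"""KEGG-term over-representation in candidate regions.

Candidate regions are mapped to annotated genes by any-overlap; each KEGG
term (class or pathway level) present in more than ``min_occurrence``
background genes is tested with a one-sided hypergeometric test for
over-representation among region genes.  The gene universe is all genes
carrying at least one annotation at the tested level.  Raw p < 0.05 marks
significance (a Benjamini-Hochberg column is emitted for reference but not
used for filtering).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

ANNOT_COLUMNS = ["gene", "chrom", "start", "end", "kegg_class", "kegg_pathway", "go", "uniprot"]


def read_annotation(path: str) -> pd.DataFrame:
    """Annotation TSV: gene, chrom, start, end, kegg_class, kegg_pathway, go, uniprot.

    List-valued fields are semicolon-delimited (empty string = no annotation).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}).fillna("")
    missing = set(ANNOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df


def _terms(cell: str) -> list[str]:
    return [t for t in str(cell).split(";") if t]


def genes_in_regions(regions: pd.DataFrame, annotation: pd.DataFrame) -> set[str]:
    """Genes overlapping any region by >= 1 bp.

    Gene coordinates are inclusive [start, end]; regions half-open [start, end).
    """
    hit: set[str] = set()
    if regions.empty:
        return hit
    for chrom, regs in regions.groupby("chrom"):
        genes = annotation[annotation["chrom"] == chrom]
        if genes.empty:
            continue
        gs = genes["start"].to_numpy()
        ge = genes["end"].to_numpy()
        for _, reg in regs.iterrows():
            ov = (gs < reg["end"]) & (ge >= reg["start"])
            hit.update(genes.loc[ov, "gene"])
    return hit


def term_enrichment(
    region_genes: set[str],
    annotation: pd.DataFrame,
    level: str = "kegg_pathway",
    min_occurrence: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of terms among region genes.

    Only terms whose background occurrence K is strictly greater than
    ``min_occurrence`` are tested.  Returns the full table (term, level, k, n,
    K, N, p, p_bh, significant); filter on ``significant`` for the p < alpha
    view.
    """
    if level not in ("kegg_class", "kegg_pathway"):
        raise ValueError("level must be 'kegg_class' or 'kegg_pathway'")
    annotated = annotation[annotation[level].map(lambda c: len(_terms(c)) > 0)]
    universe = set(annotated["gene"])
    N = len(universe)
    in_set = region_genes & universe
    n = len(in_set)
    term_genes: dict[str, set[str]] = {}
    for rec in annotated.itertuples(index=False):
        for t in _terms(getattr(rec, level)):
            term_genes.setdefault(t, set()).add(rec.gene)
    rows = []
    for term, genes in sorted(term_genes.items()):
        K = len(genes)
        if K <= min_occurrence:
            continue
        k = len(genes & in_set)
        p = float(hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        rows.append(
            {"term": term, "level": level.removeprefix("kegg_"), "k": k, "n": n,
             "K": K, "N": N, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows, columns=["term", "level", "k", "n", "K", "N", "p"])
    if len(out):
        out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p"] < alpha
    else:
        out["p_bh"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out.sort_values("p").reset_index(drop=True)


def region_enrichment(
    regions: pd.DataFrame,
    annotation: pd.DataFrame,
    level: str = "kegg_pathway",
    min_occurrence: int = 3,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, set[str]]:
    """Convenience: map regions to genes, then test term over-representation."""
    genes = genes_in_regions(regions, annotation)
    return term_enrichment(genes, annotation, level, min_occurrence, alpha), genes
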