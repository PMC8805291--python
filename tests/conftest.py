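"""Shared fixtures: small genotype matrices built programmatically."""

import numpy as np
import pandas as pd
import pytest

from troutscan.genotypes import MISSING, GenotypeMatrix, SampleInfo


def make_matrix(calls, depth=None, chrom="chr1", positions=None, sample_ids=None):
    """GenotypeMatrix from a nested list/array of dosage calls (-1 = missing)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    chroms = [chrom] * m if isinstance(chrom, str) else list(chrom)
    snps = pd.DataFrame(
        {"chrom": chroms, "pos": np.asarray(positions, dtype=np.int64),
         "ref": ["A"] * m, "alt": ["G"] * m}
    )
    if sample_ids is None:
        sample_ids = [f"s{i:02d}" for i in range(n)]
    depth_arr = None if depth is None else np.asarray(depth, dtype=np.int32)
    G = GenotypeMatrix(sample_ids=sample_ids, snps=snps, calls=calls, depth=depth_arr)
    G.validate()
    return G


def hwe_matrix(rng, n_samples, freqs, chrom="chr1", positions=None):
    """Random HWE genotypes at the given alt-allele frequencies."""
    calls = rng.binomial(2, freqs, size=(n_samples, len(freqs)))
    return make_matrix(calls, chrom=chrom, positions=positions)


def simple_meta(G, coverages=None, lineage="MM", origin="river"):
    cov = coverages if coverages is not None else [10.0] * G.n_samples
    return [
        SampleInfo(sample_id=s, lineage=lineage, origin=origin, mean_coverage=c)
        for s, c in zip(G.sample_ids, cov)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20220131)
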