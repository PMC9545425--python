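"""Shared fixtures: small synthetic genotype matrices and popmaps."""

import numpy as np
import pandas as pd
import pytest

from knotpop.io_core import MISSING, VARIANT_META_COLUMNS, GenotypeMatrix, PopulationMap


def make_matrix(
    calls: np.ndarray,
    sample_ids=None,
    locus_ids=None,
    is_indel=None,
    contigs=None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix around a dosage array with generated metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_variants = calls.shape
    sample_ids = sample_ids or [f"s{i:03d}" for i in range(n_samples)]
    if contigs is None:
        contigs = [f"locus_{j:05d}" for j in range(n_variants)]
    if locus_ids is None:
        locus_ids = list(contigs)
    meta = pd.DataFrame(
        {
            "contig": contigs,
            "pos": np.arange(1, n_variants + 1),
            "ref": "A",
            "alt": "T",
            "locus_id": locus_ids,
            "is_indel": is_indel if is_indel is not None else [False] * n_variants,
        }
    )[VARIANT_META_COLUMNS]
    return GenotypeMatrix(sample_ids, meta, calls)


def random_matrix(
    rng: np.random.Generator,
    n_samples: int,
    n_variants: int,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Random biallelic dosages from per-variant allele frequencies."""
    p = rng.uniform(0.05, 0.95, size=n_variants)
    calls = rng.binomial(1, p, size=(n_samples, n_variants)) + rng.binomial(
        1, p, size=(n_samples, n_variants)
    )
    calls = calls.astype(np.int8)
    if missing_rate > 0:
        calls[rng.random((n_samples, n_variants)) < missing_rate] = MISSING
    return make_matrix(calls)


def split_popmap(g: GenotypeMatrix, n_pops: int = 2) -> PopulationMap:
    """Assign samples to n_pops equal blocks in matrix order."""
    per = g.n_samples // n_pops
    assignments = {}
    for i, s in enumerate(g.sample_ids):
        assignments[s] = f"pop{min(i // per, n_pops - 1)}"
    return PopulationMap(assignments)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
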