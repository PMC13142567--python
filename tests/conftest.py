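import numpy as np
import pytest
from hypothesis import settings

from grexstream.engine import MatchedIndex
from grexstream.fixtures import FixtureSpec, generate_cohort
from grexstream.genotype_io import DosageChunk, DosageSource

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


class ArraySource(DosageSource):
    """In-memory dosage source for engine unit tests (samples x variants)."""

    def __init__(self, matrix):
        self._matrix = np.asarray(matrix, dtype=np.float64)
        self.n_samples, self.n_variants = self._matrix.shape
        self.imputed_per_variant = {}

    def read_dosage_chunk(self, start, length):
        self._check_range(start, length)
        return DosageChunk(
            variant_ordinals=np.arange(start, start + length, dtype=np.int64),
            values=self._matrix[:, start : start + length].copy(),
        )


class CollectingSink:
    """Writer stand-in that keeps columns in memory."""

    def __init__(self):
        self.columns = {}

    def write_column(self, ordinal, values):
        if ordinal in self.columns:
            raise AssertionError(f"column {ordinal} written twice")
        self.columns[ordinal] = np.array(values, dtype=np.float64)

    def as_matrix(self, n_rows, n_cols):
        out = np.zeros((n_rows, n_cols))
        for c, v in self.columns.items():
            out[:, c] = v
        return out


def random_problem(rng, n=40, m=100, k=12, density=5, flip_fraction=0.3):
    """A random dosage matrix plus a random MatchedIndex over it."""
    dosages = rng.integers(0, 3, size=(n, m)).astype(np.float64)
    entries = []
    used = set()
    for col in range(k):
        ordinals = rng.choice(m, size=density, replace=False)
        for o in ordinals:
            if (int(o), col) in used:
                continue
            used.add((int(o), col))
            w = float(rng.normal() * 0.3) or 0.1
            entries.append((int(o), col, w, bool(rng.random() < flip_fraction)))
    matched = MatchedIndex.from_entries(entries, n_columns=k)
    return dosages, matched


@pytest.fixture(scope="session")
def small_spec():
    return FixtureSpec(
        n_samples=60,
        n_variants_per_chrom=120,
        chromosomes=("chr1", "chr2"),
        n_models=3,
        genes_per_model=6,
        variants_per_gene=5,
        maf_range=(0.05, 0.5),
        missing_rate=0.05,
        frac_swapped=0.2,
        frac_complemented=0.2,
        frac_ambiguous_sites=0.15,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec, tmp_path_factory):
    return generate_cohort(small_spec, tmp_path_factory.mktemp("small_cohort"))
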