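import numpy as np
import pytest

from lxeflow.io import HaplotypeAlignment


def make_alignment(rows: list[str], gene_id="g1", species_split=None, frame_offset=0):
    """Alignment from row strings; first half species1, second half species2."""
    n = len(rows)
    assert n % 2 == 0
    if species_split is None:
        species_split = n // 2
    mat = np.array([list(r) for r in rows], dtype="S1")
    samples = [f"s{i}" for i in range(n // 2)]
    species = ["species1"] * species_split + ["species2"] * (n - species_split)
    return HaplotypeAlignment(gene_id, mat, samples, species, frame_offset)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_alignment(rng, n_rows=6, n_cols=30, missing_frac=0.0, gene_id="g1"):
    bases = np.frombuffer(b"ACGT", dtype="S1")
    mat = bases[rng.integers(0, 4, size=(n_rows, n_cols))]
    if missing_frac > 0:
        mask = rng.random((n_rows, n_cols)) < missing_frac
        mat[mask] = b"N"
    samples = [f"s{i}" for i in range(n_rows // 2)]
    species = ["species1"] * (n_rows // 2) + ["species2"] * (n_rows - n_rows // 2)
    return HaplotypeAlignment(gene_id, mat, samples, species)
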