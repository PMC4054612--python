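import numpy as np
import pytest

from srnakit.config import RunConfig
from srnakit.io import ReadRecord
from srnakit.synthetic import (
    GenomeDesign,
    LibraryDesign,
    build_truth,
    make_genome_and_annotation,
)


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig(seed=1)


@pytest.fixture(scope="session")
def small_genome():
    """Compact genome/annotation for fast unit tests."""
    design = GenomeDesign(genome_length=20_000, n_mirna=12, n_snorna=3, n_trf=2,
                         n_exon=4, n_multicopy=1, multicopy_loci=3)
    return make_genome_and_annotation(design, seed=7)


@pytest.fixture(scope="session")
def small_design() -> LibraryDesign:
    return LibraryDesign(n_pairs=4, reads_per_library=3000)


@pytest.fixture(scope="session")
def small_truth(small_genome, small_design):
    _, annotation = small_genome
    return build_truth(annotation, small_design, n_spiked=4, seed=7)


def make_read(seq: str, quality=None, read_id: str = "r") -> ReadRecord:
    if quality is None:
        quality = np.full(len(seq), 40)
    return ReadRecord(read_id, seq, np.asarray(quality))
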