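import sys
from pathlib import Path

import pytest

# make tests/oracles.py importable regardless of invocation directory
sys.path.insert(0, str(Path(__file__).parent))

from rtchimera.annotation_io import AnnotationSet, GeneModel

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def toy_annotation() -> AnnotationSet:
    """Three genes on two chromosomes, both strands, with known lengths."""
    genes = [
        GeneModel("geneA", "chr1", 1000, 3000, "+"),
        GeneModel("geneB", "chr1", 5000, 6000, "-"),
        GeneModel("geneC", "chr2", 100, 700, "+"),
    ]
    return AnnotationSet(genes, chrom_lengths={"chr1": 10_000, "chr2": 900})
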