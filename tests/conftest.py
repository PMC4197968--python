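import numpy as np
import pytest

from intronret.annotation_model import GenomeAnnotation, TranscriptModel
from intronret.synthetic_data import SimulationConfig, simulate_annotation


def random_genome(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture
def toy_annotation():
    """One plus-strand 3-exon transcript: exons (100,200),(300,400),(900,1000)."""
    t = TranscriptModel(
        transcript_id="t1", gene_id="g1", chrom="chr1", strand="+",
        exons=[(100, 200), (300, 400), (900, 1000)],
    )
    genome = {"chr1": random_genome(1200, seed=7)}
    ann = GenomeAnnotation(
        transcripts={"t1": t}, chrom_lengths={"chr1": 1200}, genome=genome
    )
    return ann


@pytest.fixture
def toy_gtf(tmp_path):
    path = tmp_path / "toy.gtf"
    lines = [
        'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
        'chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
        'chr1\tsrc\texon\t901\t1000\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def toy_fasta(tmp_path):
    path = tmp_path / "toy.fa"
    path.write_text(">chr1\n" + random_genome(1200, seed=7) + "\n")
    return path


@pytest.fixture(scope="session")
def small_simulation():
    """A 40-gene simulated dataset shared across tests (annotation + truth)."""
    config = SimulationConfig(seed=11, n_genes=40, depth=60_000)
    annotation, genome, truth = simulate_annotation(config)
    return config, annotation, genome, truth
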