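import pytest

from editscope.editcall import EditCallConfig, call_edits, intersect_replicates
from editscope.refmodel import GeneModelIndex, GenomeSeq, TranscriptModel
from editscope.synthetic_data import SimConfig, simulate_reference, simulate_tribe_pileups


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic experiment shared across tests."""
    cfg = SimConfig(seed=11)
    genome, models, truth = simulate_reference(cfg)
    pileups = simulate_tribe_pileups(genome, models, truth, cfg)
    return cfg, genome, models, truth, pileups


@pytest.fixture(scope="session")
def called_edits(default_sim):
    cfg, genome, models, truth, pileups = default_sim
    ecfg = EditCallConfig()
    reps = [
        call_edits(pileups[f"rep{i + 1}"], pileups["control"], ecfg).sites
        for i in range(cfg.n_replicates)
    ]
    return intersect_replicates(reps)


@pytest.fixture
def toy_transcript():
    """Two-exon plus-strand coding transcript used in coordinate tests."""
    return TranscriptModel(
        transcript_id="t1", gene_id="g1", contig="chr1", strand="+",
        exons=[(100, 200), (300, 400)], cds_span=(150, 350),
    )


@pytest.fixture
def toy_genome():
    seq = "".join("ACGT"[(i * 7 + i // 3) % 4] for i in range(600))
    return GenomeSeq({"chr1": seq})
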