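import pytest

from termtte.formats_io import GenomeSequence, TranscriptionUnitAnnotation
from termtte.pipeline import RunConfig, run_full
from termtte.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture
def toy_genome():
    # 120 nt, fixed sequence with a planted TTTT at positions 61-64
    seq = (
        "ATGCATGCATGCATGCATGCATGCATGCATGCATGCATGCATGCATGCATGCATGCATGC"
        "TTTTACGACGACGACGACGACGACGACGACGACGACGACGACGACGACGACGACGACGA"
    )
    return GenomeSequence("chr", seq)


@pytest.fixture
def toy_tu_plus():
    return TranscriptionUnitAnnotation(
        tu_id="tuA", chrom="chr", strand="+", span_start=1, span_end=40,
        stop3=40, biotype="coding")


@pytest.fixture(scope="session")
def recovery_run(tmp_path_factory):
    """One full simulated run at the recovery-study conditions:
    200 TUs, plateau depth 500, two replicates, fixed seed."""
    outdir = tmp_path_factory.mktemp("recovery")
    cfg = {"n_tus": 200, "depth_lambda": 500.0, "seed": 11}
    return run_full(RunConfig({"sim": cfg, "outdir": str(outdir),
                               "seed": 11}))


@pytest.fixture(scope="session")
def small_dataset():
    """A small deterministic dataset shared by structure-level tests."""
    return simulate_dataset(SimConfig(n_tus=40, depth_lambda=200.0, seed=7))
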