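import numpy as np
import pytest

from pamscreen import (
    AmpliconDesign,
    EndogenousAmplicon,
    ErrorModel,
    IndelModel,
    PAMActivityModel,
    SimConfig,
    simulate_endogenous,
    simulate_screen,
    write_fastq,
)
from pamscreen.simulate import random_dna


@pytest.fixture(scope="session")
def design() -> AmpliconDesign:
    return AmpliconDesign()


@pytest.fixture(scope="session")
def synthetic_amplicon() -> EndogenousAmplicon:
    """A synthetic 160-nt genomic target with a central cut site."""
    rng = np.random.default_rng(20_456)
    return EndogenousAmplicon(
        name="synthetic_locus", sequence=random_dna(rng, 160), cut_index=80
    )


@pytest.fixture(scope="session")
def sorted_screen(design, tmp_path_factory):
    """A GFP-sorted screen simulated under a known N4CC-type ground truth.

    20,000 cells, dinucleotide consensus NNNNCCNN, sequencing error on;
    shared across tests that only read it.
    """
    activity = PAMActivityModel(
        kind="consensus", consensus="NNNNCCNN", p_match=0.8, p_mismatch=0.01
    )
    cfg = SimConfig(n_reads=20_000, seed=11, sort_mode="gfp_sorted")
    records, truth = simulate_screen(
        design, activity, IndelModel(), ErrorModel(sub_rate=0.001), cfg
    )
    path = tmp_path_factory.mktemp("screen") / "sorted.fastq"
    write_fastq(records, path)
    return {"fastq": path, "records": records, "truth": truth, "design": design}


@pytest.fixture(scope="session")
def endogenous_reads(synthetic_amplicon):
    """3,000 amplicon reads edited at a true efficiency of 0.30."""
    records, truth = simulate_endogenous(
        synthetic_amplicon,
        0.30,
        IndelModel(),
        ErrorModel(sub_rate=0.001),
        SimConfig(n_reads=3_000, seed=5),
    )
    return {"records": records, "truth": truth, "amplicon": synthetic_amplicon}
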