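import numpy as np
import pytest

import phylopp as pp


@pytest.fixture
def tiny_aln() -> pp.Alignment:
    return pp.Alignment.from_sequences(
        ["t1", "t2", "t3", "t4"],
        ["ACDEF", "ACDEL", "ACKEF", "GCDEF"],
    )


@pytest.fixture
def identical_rows_aln() -> pp.Alignment:
    return pp.Alignment.from_sequences(["a", "b", "c"], ["ACDE", "ACDE", "ACDE"])


@pytest.fixture
def quartet() -> pp.PhyloTree:
    return pp.PhyloTree.from_newick(
        "((t1:0.1,t2:0.2):0.05,t3:0.15,t4:0.3);"
    )


@pytest.fixture
def lg_model() -> pp.ModelSpec:
    return pp.single_model("LG", alpha=0.7, K=4)


@pytest.fixture
def poisson_model() -> pp.ModelSpec:
    return pp.single_model("poisson", alpha=1.0, K=2)


@pytest.fixture
def sim_aln(quartet, lg_model) -> pp.Alignment:
    return pp.simulate_alignment(quartet, lg_model, 60, seed=42)
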