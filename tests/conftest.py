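import numpy as np
import pandas as pd
import pytest

from midriver import io_formats, synthetic


@pytest.fixture
def tiny_maf(tmp_path):
    """3-row minimal-TSV mutation table: 2 samples, TP53 twice, KRAS once."""
    path = tmp_path / "tiny.maf.tsv"
    path.write_text(
        "sample_id\tgene\tvariant_class\n"
        "S1\tTP53\tnonsynonymous\n"
        "S1\tTP53\tsynonymous\n"
        "S2\tKRAS\tstopgain\n"
    )
    return path


@pytest.fixture
def sl_pairs():
    return io_formats.SLPairSet(
        pairs={frozenset(("A", "B")), frozenset(("C", "D"))}
    )


@pytest.fixture
def planted_cohort():
    """100-gene cohort pair with 10 planted mutation-intolerant genes."""
    migs = [f"G{i:04d}" for i in range(10)]
    spec = synthetic.CohortSpec(planted_migs=migs, seed=7)
    healthy, tumor, truth, lengths = synthetic.simulate_cohort_pair(spec)
    return spec, healthy, tumor, truth, lengths


@pytest.fixture
def small_dependence():
    genes = ["A", "B", "C"]
    scores = pd.DataFrame(
        [[0.95, 0.97], [0.85, 0.80], [np.nan, np.nan]],
        index=genes,
        columns=["L1", "L2"],
    )
    return io_formats.DependenceMatrix(
        scores=scores, lineages={"L1": "LUAD", "L2": "LUAD"}
    )
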