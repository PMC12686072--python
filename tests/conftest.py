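import numpy as np
import pandas as pd
import pytest

from ehbmt import ExpressionMatrix, SampleTable, SimulationParams, default_panel


@pytest.fixture
def panel():
    return default_panel()


@pytest.fixture
def toy_expr_file(tmp_path):
    """3-gene x 2-sample TSV."""
    path = tmp_path / "expr.tsv"
    path.write_text("gene\ts1\ts2\nA\t1\t2\nB\t3\t4\nC\t5\t6\n")
    return path


@pytest.fixture
def toy_meta_file(tmp_path):
    path = tmp_path / "meta.tsv"
    path.write_text(
        "sample_id\tpatient_id\ttissue\tos_time\tos_event\tlauren\n"
        "s1\tp1\ttumor\t12.5\t1\tIntestinal\n"
        "s2\tp1\tnormal\t30\t0\t\n"
    )
    return path


@pytest.fixture
def zmatrix():
    """Small z-scored matrix over a 2+2 toy panel plus background genes."""
    rng = np.random.default_rng(0)
    genes = ["CDH1", "EPCAM", "VIM", "ZEB1", "BG1", "BG2"]
    vals = rng.normal(size=(6, 12))
    vals = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1, keepdims=True)
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=genes, columns=[f"s{i}" for i in range(12)]),
        normalized="zscore",
    )


@pytest.fixture
def default_params():
    return SimulationParams()


def make_meta(rows) -> SampleTable:
    return SampleTable(data=pd.DataFrame(rows))
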