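import numpy as np
import pandas as pd
import pytest

from hpameth.preprocess import MethylationMatrix


@pytest.fixture
def tiny_annotation() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": ["cg0001", "cg0002", "cg0003", "cg0004", "cg0005"],
            "gene": ["NR3C1", "NR3C1", "FKBP5", "BDNF", "CRH"],
            "transcript": ["AJ877169", "AJ877169x", "NM_004117", "NM_170735", "NM_000756"],
            "tss_distance": [1999, -2001, 0, 0, 500],
        }
    )


@pytest.fixture
def annotation_tsv(tmp_path, tiny_annotation):
    path = tmp_path / "annotation.tsv"
    tiny_annotation.to_csv(path, sep="\t", index=False)
    return path


def make_matrix(values: np.ndarray, scale: str = "M") -> MethylationMatrix:
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=[f"cg{i:04d}" for i in range(values.shape[0])],
        columns=[f"S{j:03d}" for j in range(values.shape[1])],
    )
    return MethylationMatrix(df, scale=scale)
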