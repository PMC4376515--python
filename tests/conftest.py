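import numpy as np
import pandas as pd
import pytest

from exprepro import ExpressionDataset, GeneLengthTable


@pytest.fixture
def micro_dataset() -> ExpressionDataset:
    """2 treatments x 2 replicates x 2 genes, hand-enumerable.

    T1's replicates are identical; T2's replicate 1 is twice replicate 2.
    """
    values = pd.DataFrame(
        {"s1": [10.0, 20.0], "s2": [10.0, 20.0], "s3": [20.0, 40.0], "s4": [10.0, 20.0]},
        index=pd.Index(["g1", "g2"], name="gene"),
    )
    layout = {"s1": ("T1", "R1"), "s2": ("T1", "R2"), "s3": ("T2", "R1"), "s4": ("T2", "R2")}
    return ExpressionDataset(values=values, layout=layout)


@pytest.fixture
def table2() -> pd.DataFrame:
    """The worked 8-gene protein-correction example (TF, ORF bp, PF)."""
    return pd.DataFrame(
        {
            "TF": [2.0] * 8,
            "ORF": [1000 * (i + 1) for i in range(8)],
            "PF": [10.0, 9.0, 8.0, 7.0, 6.0, 5.0, 4.0, 3.0],
        },
        index=pd.Index([str(i + 1) for i in range(8)], name="gene"),
    )


@pytest.fixture
def small_matrix_files(tmp_path):
    """3-gene, 4-sample TSV matrix plus sidecar layout on disk."""
    matrix = tmp_path / "matrix.tsv"
    matrix.write_text(
        "gene\ts1\ts2\ts3\ts4\n"
        "g1\t1.5\t2.5\t3.5\t4.5\n"
        "g2\t10\t20\t30\t40\n"
        "g3\t100\t100\t100\t100\n"
    )
    layout = tmp_path / "layout.tsv"
    layout.write_text(
        "sample\ttreatment\treplicate\n"
        "s1\tT1\tR1\ns2\tT1\tR2\ns3\tT2\tR1\ns4\tT2\tR2\n"
    )
    return matrix, layout


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140513)


def make_dataset(values_by_sample, layout, gene_prefix="g") -> ExpressionDataset:
    n = len(next(iter(values_by_sample.values())))
    frame = pd.DataFrame(
        {k: np.asarray(v, dtype=float) for k, v in values_by_sample.items()},
        index=pd.Index([f"{gene_prefix}{i + 1}" for i in range(n)], name="gene"),
    )
    return ExpressionDataset(values=frame, layout=layout)


@pytest.fixture
def lengths_1k_2k() -> GeneLengthTable:
    return GeneLengthTable({"g1": 1000, "g2": 2000})
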