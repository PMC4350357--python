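import numpy as np
import pandas as pd
import pytest

from accsig import ExpressionMatrix, SampleSheet, SimConfig, generate_cohort


def make_matrix(values, probes=None, samples=None, scale="log2", assay="mRNA"):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"g{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples),
                            scale=scale, assay=assay)


def make_paired_sheet(n_pairs, prefix="P"):
    rows = []
    for i in range(n_pairs):
        pid = f"{prefix}{i+1:02d}"
        rows.append((f"{pid}_T", pid, "tumor", "ACC", "negative"))
        rows.append((f"{pid}_N", pid, "normal", "ACC", "unknown"))
    return SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "tissue", "subtype",
                       "fusion_annotation"]))


def paired_matrix_from_deltas(deltas, baseline=10.0, scale="log2"):
    """One matrix per probe-row of log2 tumor-normal deltas, normals at baseline."""
    deltas = np.atleast_2d(np.asarray(deltas, dtype=float))
    n_pairs = deltas.shape[1]
    sheet = make_paired_sheet(n_pairs)
    cols, data = [], []
    for j in range(n_pairs):
        cols += [f"P{j+1:02d}_T", f"P{j+1:02d}_N"]
        data += [baseline + deltas[:, j], np.full(deltas.shape[0], baseline)]
    values = np.column_stack(data)
    if scale == "linear":
        values = 2.0 ** values
    m = make_matrix(values, samples=cols, scale=scale)
    return m, sheet


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort at reduced gene count for fast unit tests."""
    return generate_cohort(SimConfig(seed=11, n_genes=800, n_mirna=120,
                                     n_mirna_down=6, n_mirna_up=2))


@pytest.fixture(scope="session")
def noise_free_cohort():
    return generate_cohort(SimConfig(seed=5, n_genes=800, noise_sd=0.0,
                                     n_mirna=120, n_mirna_down=6, n_mirna_up=2))
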