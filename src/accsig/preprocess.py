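"""Normalization and the two pre-test gene filters.

Pipeline order follows array practice: quantile normalization on the linear
scale, log2 transform, then the baseline filter (linear intensities) and the
variation filter (log2 paired fold change) ahead of differential testing.
Default thresholds: intensity >= 50 (mRNA) or >= 800 (miRNA) for the baseline
filter, |fold change| >= 2 for the variation filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, PairingError, StateError
from .types import ExpressionMatrix, SampleSheet

MRNA_BASELINE = 50.0
MIRNA_BASELINE = 800.0
DEFAULT_MIN_FOLD = 2.0


@dataclass
class FilterReport:
    """Per-probe pass/fail flags and the thresholds that produced them."""

    flags: pd.DataFrame          # columns: passed_baseline and/or passed_variation
    thresholds: dict
    n_input: int
    n_passed: int


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample's value distribution onto the vector of rank means.

    After normalization the sorted value vector of every sample is identical
    and equals the across-sample mean of order statistics. Ties within a
    sample receive the mean of the normalized values they span, which makes
    the transform idempotent. A single-sample matrix is returned unchanged
    with a warning.
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile_normalize: single-sample matrix left unchanged")
        return matrix
    values = matrix.data.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average the reference values spanned by tied input values
        s = pd.Series(assigned).groupby(col).transform("mean")
        out[:, j] = s.to_numpy()
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        scale=matrix.scale, assay=matrix.assay,
    )


def log2_transform(matrix: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """log2(max(value, floor)); flips the scale flag to log2."""
    if matrix.scale != "linear":
        raise StateError("log2_transform requires a linear-scale matrix")
    if floor <= 0:
        raise ConfigError("floor must be positive")
    out = np.log2(np.maximum(matrix.data.to_numpy(dtype=float), floor))
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        scale="log2", assay=matrix.assay,
    )


def baseline_filter(matrix: ExpressionMatrix,
                    min_intensity: float = MRNA_BASELINE
                    ) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep probes whose maximum intensity across samples reaches the threshold.

    The max-across-samples rule keeps probes expressed in any sample, so a
    tumor-specific gene absent from normals (or from one MYB-low tumor)
    survives. Probe order is preserved.
    """
    if matrix.scale != "linear":
        raise StateError("baseline_filter operates on the linear scale")
    if min_intensity <= 0:
        raise ConfigError("min_intensity must be positive")
    passed = matrix.data.max(axis=1) >= min_intensity
    report = FilterReport(
        flags=pd.DataFrame({"passed_baseline": passed}),
        thresholds={"min_intensity": min_intensity},
        n_input=len(passed), n_passed=int(passed.sum()),
    )
    return matrix.subset_probes(matrix.data.index[passed]), report


def paired_log2_deltas(matrix: ExpressionMatrix, sheet: SampleSheet,
                       patients=None) -> pd.DataFrame:
    """Probe x pair matrix of tumor-minus-normal log2 differences."""
    if matrix.scale != "log2":
        raise StateError("paired deltas require a log2 matrix")
    pairs = sheet.pairs(patients)
    pairs = pairs[pairs["tumor"].isin(matrix.data.columns)
                  & pairs["normal"].isin(matrix.data.columns)]
    if pairs.empty:
        raise PairingError("no resolvable tumor/normal pairs in the matrix")
    t = matrix.data[list(pairs["tumor"])].to_numpy()
    n = matrix.data[list(pairs["normal"])].to_numpy()
    return pd.DataFrame(t - n, index=matrix.data.index,
                        columns=list(pairs["patient_id"]))


def variation_filter(matrix: ExpressionMatrix, sheet: SampleSheet,
                     min_fold: float = DEFAULT_MIN_FOLD,
                     aggregation: str = "mean",
                     patients=None) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep probes with |paired log2 fold change| >= log2(min_fold).

    ``aggregation`` selects the statistic the threshold is applied to: the
    mean paired delta (default, matching the downstream paired t-test) or the
    maximum absolute pairwise delta.
    """
    if min_fold <= 0:
        raise ConfigError("min_fold must be positive")
    if aggregation not in ("mean", "max"):
        raise ConfigError(f"unknown aggregation {aggregation!r}")
    deltas = paired_log2_deltas(matrix, sheet, patients)
    if aggregation == "mean":
        stat = deltas.mean(axis=1).abs()
    else:
        stat = deltas.abs().max(axis=1)
    passed = stat >= np.log2(min_fold)
    report = FilterReport(
        flags=pd.DataFrame({"passed_variation": passed, "log2_fc_stat": stat}),
        thresholds={"min_fold": min_fold, "aggregation": aggregation},
        n_input=len(passed), n_passed=int(passed.sum()),
    )
    return matrix.subset_probes(matrix.data.index[passed]), report
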