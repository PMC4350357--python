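"""Core in-memory containers.

All containers are thin, validated wrappers around :class:`pandas.DataFrame`.
Validation happens at construction; downstream code may assume invariants hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InputError, PairingError

LINEAR = "linear"
LOG2 = "log2"
SCALES = (LINEAR, LOG2)
ASSAYS = ("mRNA", "miRNA", "exon")
TISSUES = ("tumor", "normal")
SUBTYPES = ("ACC", "MEC", "ADC")
FUSION_ANNOTATIONS = ("positive", "negative", "unknown")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise FormatError(f"duplicate {what} identifier: {dup!r}")


@dataclass
class ExpressionMatrix:
    """Probe sets x samples intensity matrix with an explicit scale flag.

    Parameters
    ----------
    data
        DataFrame indexed by probe-set ID with one column per sample ID.
    scale
        ``"linear"`` (non-negative intensities) or ``"log2"``.
    assay
        One of ``"mRNA"``, ``"miRNA"``, ``"exon"``.
    """

    data: pd.DataFrame
    scale: str
    assay: str = "mRNA"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise FormatError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.assay not in ASSAYS:
            raise FormatError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        _check_unique(self.data.index, "probe")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value at probe {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )
        if self.scale == LINEAR and values.size and values.min() < 0:
            i, j = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative value on linear scale at probe {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_probes(self, probes) -> "ExpressionMatrix":
        """Row subset preserving this matrix's probe order."""
        wanted = set(probes)
        keep = [p for p in self.probe_ids if p in wanted]
        return ExpressionMatrix(self.data.loc[keep], self.scale, self.assay)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)], self.scale, self.assay)


@dataclass
class SampleSheet:
    """Per-sample metadata defining tumor/normal pairing and fusion annotation."""

    data: pd.DataFrame

    REQUIRED = ("sample_id", "patient_id", "tissue", "subtype", "fusion_annotation")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise FormatError(f"sample sheet missing column(s): {', '.join(missing)}")
        _check_unique(pd.Index(self.data["sample_id"]), "sample")
        for col, vocab in (
            ("tissue", TISSUES),
            ("subtype", SUBTYPES),
            ("fusion_annotation", FUSION_ANNOTATIONS),
        ):
            bad = set(self.data[col]) - set(vocab)
            if bad:
                raise FormatError(
                    f"invalid {col} value(s) {sorted(bad)}; allowed: {list(vocab)}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def tissue_of(self, sample_id: str) -> str:
        row = self.data.loc[self.data["sample_id"] == sample_id]
        if row.empty:
            raise InputError(f"unknown sample {sample_id!r}")
        return row["tissue"].iloc[0]

    def tumor_samples(self) -> list[str]:
        return list(self.data.loc[self.data["tissue"] == "tumor", "sample_id"])

    def normal_samples(self) -> list[str]:
        return list(self.data.loc[self.data["tissue"] == "normal", "sample_id"])

    def pairs(self, patients=None) -> pd.DataFrame:
        """Resolve the patient -> (tumor sample, normal sample) pairing index.

        Returns a DataFrame with columns ``patient_id``, ``tumor``, ``normal`` in
        the sheet's patient order. Raises :class:`PairingError` listing every
        tumor-bearing patient without exactly one matched normal.
        """
        df = self.data
        if patients is not None:
            df = df.loc[df["patient_id"].isin(set(patients))]
        rows, orphans = [], []
        for pid in df["patient_id"].drop_duplicates():
            sub = df.loc[df["patient_id"] == pid]
            tumors = list(sub.loc[sub["tissue"] == "tumor", "sample_id"])
            normals = list(sub.loc[sub["tissue"] == "normal", "sample_id"])
            if not tumors:
                continue
            if len(tumors) != 1 or len(normals) != 1:
                orphans.append(pid)
            else:
                rows.append((pid, tumors[0], normals[0]))
        if orphans:
            raise PairingError(
                "unpaired tumor sample(s) for patient(s): " + ", ".join(map(str, orphans))
            )
        return pd.DataFrame(rows, columns=["patient_id", "tumor", "normal"])

    def fusion_annotation_of(self, sample_id: str) -> str:
        row = self.data.loc[self.data["sample_id"] == sample_id]
        if row.empty:
            raise InputError(f"unknown sample {sample_id!r}")
        return row["fusion_annotation"].iloc[0]


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (unique names, non-empty, deduplicated)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            seen: set[str] = set()
            deduped = []
            for m in members:
                if m not in seen:
                    seen.add(m)
                    deduped.append(m)
            self.sets[name] = deduped

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ExonIntensityProfile:
    """Ordered 5'->3' exon-level linear intensities for one focal gene.

    ``data`` is indexed by exon ID in transcript order with one column per sample.
    """

    gene: str
    data: pd.DataFrame
    sheet: SampleSheet | None = None

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "exon")
        _check_unique(self.data.columns, "sample")
        if len(self.data) < 5:
            raise FormatError(
                f"exon profile for {self.gene!r} has {len(self.data)} exons; need >= 5"
            )
        values = self.data.to_numpy()
        if not np.all(np.isfinite(values)) or (values.size and values.min() < 0):
            raise FormatError(
                f"exon profile for {self.gene!r} must be finite and non-negative"
            )

    @property
    def exon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_exons(self) -> int:
        return len(self.data)
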