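"""In-memory containers for the molecular layers and clinical annotations.

The pipeline works on three molecular layers (mRNA expression, miRNA
expression, gene-level methylation scores), each represented as an
:class:`OmicsMatrix` — a features x samples matrix with per-sample
condition (tumor/normal), originating dataset and patient labels.
Clinical outcomes and covariates live in a :class:`ClinicalTable` keyed by
patient. miRNA->gene interactions with confidence scores form an
:class:`InteractionTable`; named gene sets (GMT) a :class:`GeneSetCollection`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError

LAYERS = ("mRNA", "miRNA", "methylation")
CONDITIONS = ("tumor", "normal")

VASCULAR_INVASION_LEVELS = ("yes", "no", "unknown")
STAGE_LEVELS = ("I", "II", "III", "unknown")
GRADE_LEVELS = ("G1", "G2", "G3", "unknown")
T_SIZE_LEVELS = ("T1", "T2", "T3", "unknown")


@dataclass
class OmicsMatrix:
    """One molecular layer: features x samples plus sample annotations.

    Parameters
    ----------
    layer:
        One of ``"mRNA"``, ``"miRNA"``, ``"methylation"``.
    values:
        DataFrame, rows = feature ids, columns = sample ids. Missing entries
        are NaN; all finite otherwise.
    condition:
        Per-sample label in ``{"tumor", "normal"}``, indexed like the
        columns of ``values``.
    dataset_id:
        Per-sample originating-dataset label (pseudo-dataset for synthetic
        cohorts), same index.
    patient_id:
        Per-sample patient label; may be missing (NaN) for normal samples.
    """

    layer: str
    values: pd.DataFrame
    condition: pd.Series
    dataset_id: pd.Series
    patient_id: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise FormatError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r} in {self.layer} matrix")
        cols = self.values.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r} in {self.layer} matrix")
        if self.patient_id is None:
            self.patient_id = pd.Series(pd.NA, index=cols, dtype="object")
        for name, series in (
            ("condition", self.condition),
            ("dataset_id", self.dataset_id),
            ("patient_id", self.patient_id),
        ):
            missing = cols.difference(series.index)
            if len(missing):
                raise FormatError(
                    f"sample {missing[0]!r} in {self.layer} matrix has no {name} annotation"
                )
            setattr(self, name, series.reindex(cols))
        bad = set(self.condition.dropna().unique()) - set(CONDITIONS)
        if bad:
            raise FormatError(f"unknown condition label(s) {sorted(bad)}")
        if self.condition.isna().any():
            s = self.condition.index[self.condition.isna()][0]
            raise FormatError(f"condition undefined for sample {s!r}")
        vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise FormatError(f"non-finite (inf) value in {self.layer} matrix")

    # -- convenience accessors -------------------------------------------------
    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def tumor_samples(self) -> pd.Index:
        return self.samples[(self.condition == "tumor").to_numpy()]

    def normal_samples(self) -> pd.Index:
        return self.samples[(self.condition == "normal").to_numpy()]

    def subset_samples(self, samples) -> "OmicsMatrix":
        samples = pd.Index(samples)
        missing = samples.difference(self.samples)
        if len(missing):
            raise AlignmentError(f"sample {missing[0]!r} not in {self.layer} matrix")
        return OmicsMatrix(
            layer=self.layer,
            values=self.values.loc[:, samples],
            condition=self.condition.loc[samples],
            dataset_id=self.dataset_id.loc[samples],
            patient_id=self.patient_id.loc[samples],
        )

    def split_by_dataset(self) -> list["OmicsMatrix"]:
        """One OmicsMatrix per originating dataset, in sorted label order."""
        return [
            self.subset_samples(self.samples[(self.dataset_id == d).to_numpy()])
            for d in sorted(self.dataset_id.unique())
        ]

    def annotation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.samples,
                "condition": self.condition.to_numpy(),
                "dataset_id": self.dataset_id.to_numpy(),
                "patient_id": self.patient_id.to_numpy(),
            }
        )


@dataclass
class ClinicalTable:
    """Per-patient clinical outcomes and covariates.

    ``data`` is indexed by patient id with columns ``os_time``, ``os_event``,
    ``rfs_time``, ``rfs_event``, ``vascular_invasion``, ``stage``, ``grade``,
    ``t_size``. For each endpoint, time and event are either both present or
    both missing; times are strictly positive.
    """

    data: pd.DataFrame

    COLUMNS = (
        "os_time",
        "os_event",
        "rfs_time",
        "rfs_event",
        "vascular_invasion",
        "stage",
        "grade",
        "t_size",
    )

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate patient id {dup!r} in clinical table")
        for col in self.COLUMNS:
            if col not in df.columns:
                raise FormatError(f"clinical table missing column {col!r}")
        for endpoint in ("os", "rfs"):
            t = df[f"{endpoint}_time"]
            e = df[f"{endpoint}_event"]
            mismatch = t.isna() != e.isna()
            if mismatch.any():
                pid = df.index[mismatch][0]
                raise FormatError(
                    f"patient {pid!r}: {endpoint} time/event must both be present or both absent"
                )
            if (t.dropna() <= 0).any():
                pid = t.index[t <= 0][0]
                raise FormatError(f"patient {pid!r}: non-positive {endpoint}_time")
            bad_ev = ~e.dropna().isin((0, 1))
            if bad_ev.any():
                pid = bad_ev.index[bad_ev][0]
                raise FormatError(f"patient {pid!r}: {endpoint}_event must be 0 or 1")
        for col, levels in (
            ("vascular_invasion", VASCULAR_INVASION_LEVELS),
            ("stage", STAGE_LEVELS),
            ("grade", GRADE_LEVELS),
            ("t_size", T_SIZE_LEVELS),
        ):
            bad = set(df[col].dropna().unique()) - set(levels)
            if bad:
                raise FormatError(f"unknown {col} level(s) {sorted(bad)}")

    @property
    def patients(self) -> pd.Index:
        return self.data.index

    def endpoint(self, which: str = "os") -> pd.DataFrame:
        """Complete (time, event) rows for endpoint ``which`` in {os, rfs}."""
        if which not in ("os", "rfs"):
            raise FormatError(f"unknown survival endpoint {which!r}")
        cols = [f"{which}_time", f"{which}_event"]
        out = self.data[cols].dropna()
        return out.rename(columns={cols[0]: "time", cols[1]: "event"})


@dataclass
class InteractionTable:
    """miRNA -> gene interactions with an opaque confidence score in [0, 1]."""

    data: pd.DataFrame  # columns: mirna_id, gene_id, confidence

    def __post_init__(self) -> None:
        df = self.data
        for col in ("mirna_id", "gene_id", "confidence"):
            if col not in df.columns:
                raise FormatError(f"interaction table missing column {col!r}")
        dup = df.duplicated(subset=["mirna_id", "gene_id"])
        if dup.any():
            row = df.loc[dup.idxmax()]
            raise FormatError(
                f"duplicate interaction ({row['mirna_id']!r}, {row['gene_id']!r})"
            )
        conf = df["confidence"].astype(float)
        if ((conf < 0) | (conf > 1)).any() or conf.isna().any():
            bad = conf[(conf < 0) | (conf > 1) | conf.isna()].iloc[0]
            raise FormatError(f"interaction confidence {bad!r} outside [0, 1]")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)
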