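"""Core containers for paired methylation / expression analysis.

The package works on two assays from the same patients: an Illumina
450K-style methylation array summarised as a probes x samples beta matrix
(beta = methylated fraction in [0, 1]) and an expression array summarised as
a probes x samples intensity matrix with per-cell detection p-values.
Both are wrapped together with their annotation and a shared-format sample
sheet (patient ID, case/control group, season, sex, symptom score).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, ValidationError

GROUPS = ("AR", "HC")
SEASONS = ("pollen", "non-pollen")

SAMPLE_SHEET_COLUMNS = ("patient_id", "group", "season", "sex", "symptom_score")

FEATURE_LABELS = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "IGR")
ISLAND_LABELS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
DESIGN_TYPES = ("I", "II")

ANNOTATION_COLUMNS = ("gene", "feature", "island", "design_type")


@dataclass
class SampleSheet:
    """Sample metadata table indexed by sample ID.

    One row per array sample.  ``(patient_id, season)`` identifies at most
    one sample per assay, which is what makes cross-assay matching by
    patient well defined.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"sample sheet is missing columns {missing}")
        if not self.data.index.is_unique:
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"sample IDs must be unique; duplicated: {dup}")
        dup = self.data.duplicated(subset=["patient_id", "season"])
        if dup.any():
            offenders = self.data.loc[dup, ["patient_id", "season"]]
            raise ValidationError(
                "duplicate (patient_id, season) rows in sample sheet: "
                f"{offenders.to_records(index=False).tolist()}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        ids = list(sample_ids)
        unknown = [s for s in ids if s not in self.data.index]
        if unknown:
            raise ValidationError(f"unknown sample IDs: {unknown[:5]}")
        return SampleSheet(self.data.loc[ids].copy())

    def select(self, group: str | None = None, season: str | None = None) -> list[str]:
        """Sample IDs matching the given group and/or season."""
        mask = pd.Series(True, index=self.data.index)
        if group is not None:
            mask &= self.data["group"] == group
        if season is not None:
            mask &= self.data["season"] == season
        return list(self.data.index[mask])

    def group_labels(self, sample_ids: Sequence[str] | None = None) -> pd.Series:
        ids = list(sample_ids) if sample_ids is not None else self.sample_ids
        return self.data.loc[ids, "group"]


def _check_matrix(m: pd.DataFrame, name: str) -> None:
    if not isinstance(m, pd.DataFrame):
        raise ValidationError(f"{name} must be a pandas DataFrame (features x samples)")
    if not m.index.is_unique:
        raise ValidationError(f"{name} has duplicated feature IDs")


@dataclass
class MethylationSet:
    """Beta matrix plus probe annotation and sample sheet.

    ``beta`` holds values in [0, 1] (NaN = missing).  ``annotation`` is
    indexed by probe with columns ``gene``, ``feature`` (genic feature
    label), ``island`` (CpG island relation) and ``design_type`` (Infinium
    I or II).  Optional raw methylated / unmethylated intensity matrices
    can be carried so beta can be recomputed with a different offset.
    """

    beta: pd.DataFrame
    annotation: pd.DataFrame
    samples: SampleSheet
    meth: pd.DataFrame | None = None
    unmeth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_matrix(self.beta, "beta")
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("beta values must lie in [0, 1] where present")
        unknown = [c for c in self.beta.columns if c not in self.samples.data.index]
        if unknown:
            raise ValidationError(f"beta columns not in sample sheet: {unknown[:5]}")
        for col in ANNOTATION_COLUMNS:
            if col not in self.annotation.columns:
                raise ValidationError(f"probe annotation is missing column {col!r}")
        for m, name in ((self.meth, "meth"), (self.unmeth, "unmeth")):
            if m is not None and m.shape != self.beta.shape:
                raise DimensionError(f"{name} intensity shape {m.shape} != beta shape {self.beta.shape}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    def subset_probes(self, probes: Iterable[str]) -> "MethylationSet":
        idx = self.beta.index.intersection(pd.Index(probes))
        return replace(
            self,
            beta=self.beta.loc[idx],
            meth=None if self.meth is None else self.meth.loc[idx],
            unmeth=None if self.unmeth is None else self.unmeth.loc[idx],
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "MethylationSet":
        ids = [s for s in sample_ids if s in self.beta.columns]
        return replace(
            self,
            beta=self.beta[ids],
            samples=self.samples.subset(ids),
            meth=None if self.meth is None else self.meth[ids],
            unmeth=None if self.unmeth is None else self.unmeth[ids],
        )


@dataclass
class ExpressionSet:
    """Expression matrix with detection p-values and a probe-to-gene map.

    ``expr`` is probes x samples.  ``log2_scale`` records whether the
    matrix has already been background-corrected and log2 transformed;
    raw array intensities start with ``log2_scale=False``.
    ``probe_to_gene`` may be many-to-one; unannotated probes carry NaN.
    """

    expr: pd.DataFrame
    detection_p: pd.DataFrame
    probe_to_gene: pd.Series
    samples: SampleSheet
    log2_scale: bool = False

    def __post_init__(self) -> None:
        _check_matrix(self.expr, "expr")
        if self.detection_p.shape != self.expr.shape:
            raise DimensionError(
                f"detection_p shape {self.detection_p.shape} != expr shape {self.expr.shape}"
            )
        if not self.detection_p.index.equals(self.expr.index) or not self.detection_p.columns.equals(
            self.expr.columns
        ):
            raise DimensionError("detection_p must share index and columns with expr")
        pv = self.detection_p.to_numpy(dtype=float)
        finite = pv[np.isfinite(pv)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("detection p-values must lie in [0, 1]")
        unknown = [c for c in self.expr.columns if c not in self.samples.data.index]
        if unknown:
            raise ValidationError(f"expr columns not in sample sheet: {unknown[:5]}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.expr.index)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionSet":
        ids = [s for s in sample_ids if s in self.expr.columns]
        return replace(
            self,
            expr=self.expr[ids],
            detection_p=self.detection_p[ids],
            samples=self.samples.subset(ids),
        )
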