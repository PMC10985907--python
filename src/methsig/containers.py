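"""In-memory containers for methylation matrices and their metadata.

The central object is :class:`BetaMatrix`: a probes x samples matrix of
methylation fractions (beta values, in [0, 1], NaN = missing) together with a
sample sheet describing each column (patient, tissue type, cancer type,
purity, clinical fields).  Probe annotation travels separately as a plain
DataFrame validated by :func:`validate_probe_annotation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TISSUE_TYPES = ("tumor", "normal")
ISLAND_RELATIONS = ("island", "shore", "shelf", "open_sea")
REGIONS = ("TSS", "gene_body", "other")

#: Sample-sheet columns; all but the first three may be missing (NaN).
SAMPLE_SHEET_COLUMNS = (
    "patient_id",
    "tissue_type",
    "cancer_type",
    "purity",
    "age",
    "stage_group",
    "os_time",
    "os_event",
    "response",
)


@dataclass
class BetaMatrix:
    """Probes x samples beta-value matrix plus per-sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by probe id, columns by sample id.  Entries are
        methylation fractions in [0, 1]; NaN marks a missing measurement.
    samples : pandas.DataFrame
        One row per sample, indexed by sample id, with (a subset of) the
        columns in :data:`SAMPLE_SHEET_COLUMNS`.  Every matrix column must
        have a sample-sheet row and vice versa.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("probe ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        missing = self.values.columns.difference(self.samples.index)
        if len(missing):
            raise ValueError(
                f"samples absent from sample sheet: {list(missing[:5])}"
            )
        # align sheet to matrix column order, dropping unreferenced rows
        self.samples = self.samples.loc[self.values.columns]
        arr = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("beta values must lie in [0, 1]")
        bad = set(self.samples["tissue_type"]) - set(TISSUE_TYPES)
        if bad:
            raise ValueError(f"unknown tissue_type values: {sorted(bad)}")
        if "purity" in self.samples:
            pur = pd.to_numeric(self.samples["purity"], errors="coerce")
            if ((pur < 0) | (pur > 1)).any():
                raise ValueError("purity must lie in [0, 1] when present")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        """Return a copy restricted to ``sample_ids`` (order preserved)."""
        return BetaMatrix(
            self.values.loc[:, sample_ids].copy(),
            self.samples.loc[sample_ids].copy(),
        )

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(
            self.values.loc[probe_ids].copy(), self.samples.copy()
        )

    def pairs(self) -> pd.DataFrame:
        """Matched tumor/normal sample ids, one row per patient.

        Raises
        ------
        ValueError
            If any tumor sample lacks a normal with the same patient id
            (listing the offending patients).
        """
        sheet = self.samples
        tumors = sheet[sheet["tissue_type"] == "tumor"]
        normals = sheet[sheet["tissue_type"] == "normal"]
        norm_by_patient = pd.Series(
            normals.index.to_numpy(), index=normals["patient_id"].to_numpy()
        )
        unmatched = [
            p for p in tumors["patient_id"] if p not in norm_by_patient.index
        ]
        if unmatched:
            raise ValueError(
                f"tumor samples without a matched normal: {unmatched[:10]}"
            )
        return pd.DataFrame(
            {
                "patient_id": tumors["patient_id"].to_numpy(),
                "tumor": tumors.index.to_numpy(),
                "normal": norm_by_patient.loc[
                    tumors["patient_id"]
                ].to_numpy(),
            }
        )


def validate_probe_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate a probe annotation table and return it indexed by probe id.

    Required columns: ``probe_id`` (or an index of probe ids), ``chrom``,
    ``pos``, ``island_relation``, ``region``, ``snp_flag``; ``gene`` is
    optional.
    """
    ann = ann.copy()
    if "probe_id" in ann.columns:
        ann = ann.set_index("probe_id")
    if not ann.index.is_unique:
        raise ValueError("probe annotation ids must be unique")
    for col in ("chrom", "pos", "island_relation", "region", "snp_flag"):
        if col not in ann.columns:
            raise ValueError(f"probe annotation missing column {col!r}")
    bad = set(ann["island_relation"]) - set(ISLAND_RELATIONS)
    if bad:
        raise ValueError(f"unknown island_relation values: {sorted(bad)}")
    bad = set(ann["region"]) - set(REGIONS)
    if bad:
        raise ValueError(f"unknown region values: {sorted(bad)}")
    ann["snp_flag"] = ann["snp_flag"].astype(bool)
    return ann


@dataclass
class GroundTruth:
    """Planted truth emitted alongside every simulated dataset."""

    hyper_idx: np.ndarray = field(default_factory=lambda: np.array([], int))
    hypo_idx: np.ndarray = field(default_factory=lambda: np.array([], int))
    true_E: np.ndarray | None = None
    true_H: np.ndarray | None = None
    determinant_genes: np.ndarray = field(
        default_factory=lambda: np.array([], int)
    )
    causal_beta: float | None = None
    survival_params: tuple[float, float] | None = None
    unusable_genes: np.ndarray = field(
        default_factory=lambda: np.array([], int)
    )

    def __post_init__(self) -> None:
        if np.intersect1d(self.hyper_idx, self.hypo_idx).size:
            raise ValueError("hyper and hypo probe sets must be disjoint")
        if self.true_E is not None:
            if np.any(self.true_E < 0):
                raise ValueError("true_E must be nonnegative")
            sums = self.true_E.sum(axis=0)
            if not np.allclose(sums, 1.0):
                raise ValueError("true_E columns must sum to 1")
        if self.true_H is not None and np.any(self.true_H < 0):
            raise ValueError("true_H must be nonnegative")
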