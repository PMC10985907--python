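"""TSV readers and writers for every pipeline artifact.

All matrices are tab-separated with the first column holding row ids
(``probe_id`` for beta matrices, ``gene`` for omics matrices, the signature
name for activity matrices); missing values are encoded as ``NA``.  Floats
are written with a fixed ``%.10g`` format so a rerun with the same seed is
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BetaMatrix, GroundTruth

_FLOAT_FMT = "%.10g"


def write_matrix(df: pd.DataFrame, path, index_label: str = "probe_id") -> None:
    df.to_csv(
        path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT,
        index_label=index_label,
    )


def read_matrix(path, index_col: str | int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=["NA"])


def write_beta_matrix(m: BetaMatrix, beta_path, samples_path) -> None:
    write_matrix(m.values, beta_path, index_label="probe_id")
    m.samples.to_csv(
        samples_path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT,
        index_label="sample_id",
    )


def read_beta_matrix(beta_path, samples_path) -> BetaMatrix:
    values = read_matrix(beta_path)
    samples = pd.read_csv(
        samples_path, sep="\t", index_col="sample_id", na_values=["NA"]
    )
    return BetaMatrix(values, samples)


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", na_rep="NA", index=False)


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_ground_truth(truth: GroundTruth, outdir) -> None:
    """Key/value JSON plus TSV matrices for the planted factorization."""
    outdir = Path(outdir)
    meta = {
        "hyper_idx": [int(i) for i in truth.hyper_idx],
        "hypo_idx": [int(i) for i in truth.hypo_idx],
        "determinant_genes": [int(i) for i in truth.determinant_genes],
        "causal_beta": truth.causal_beta,
        "survival_params": (
            list(truth.survival_params) if truth.survival_params else None
        ),
        "unusable_genes": [int(i) for i in truth.unusable_genes],
    }
    (outdir / "ground_truth.json").write_text(
        json.dumps(meta, sort_keys=True, indent=1) + "\n"
    )
    if truth.true_E is not None:
        write_matrix(
            pd.DataFrame(truth.true_E), outdir / "true_E.tsv",
            index_label="probe_index",
        )
    if truth.true_H is not None:
        write_matrix(
            pd.DataFrame(truth.true_H), outdir / "true_H.tsv",
            index_label="signature_index",
        )


def read_ground_truth(outdir) -> GroundTruth:
    outdir = Path(outdir)
    meta = json.loads((outdir / "ground_truth.json").read_text())
    true_E = true_H = None
    if (outdir / "true_E.tsv").exists():
        true_E = read_matrix(outdir / "true_E.tsv").to_numpy(float)
    if (outdir / "true_H.tsv").exists():
        true_H = read_matrix(outdir / "true_H.tsv").to_numpy(float)
    return GroundTruth(
        hyper_idx=np.array(meta["hyper_idx"], int),
        hypo_idx=np.array(meta["hypo_idx"], int),
        true_E=true_E,
        true_H=true_H,
        determinant_genes=np.array(meta["determinant_genes"], int),
        causal_beta=meta["causal_beta"],
        survival_params=(
            tuple(meta["survival_params"])
            if meta["survival_params"]
            else None
        ),
        unusable_genes=np.array(meta["unusable_genes"], int),
    )


def write_key_values(d: dict, path) -> None:
    Path(path).write_text(json.dumps(d, sort_keys=True, indent=1) + "\n")
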