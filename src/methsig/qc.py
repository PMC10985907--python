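"""Sample- and probe-level quality control and imputation.

The QC chain, in the order it is applied:

1. drop tumor samples whose purity is missing or not strictly greater than
   the threshold (normals are retained regardless — they carry no tumor
   purity by definition);
2. drop SNP-flagged probes, sex-chromosome probes, and probes whose missing
   fraction (computed after sample filtering) is strictly greater than the
   allowed maximum;
3. replace each remaining missing entry by that probe's median across all
   retained samples.

The chain is idempotent and its output contains no missing values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import BetaMatrix, validate_probe_annotation

_SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


def filter_samples_by_purity(
    m: BetaMatrix, threshold: float = 0.6
) -> BetaMatrix:
    """Keep tumor samples with purity strictly greater than ``threshold``.

    Tumors with missing purity are dropped; normal samples always survive.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    sheet = m.samples
    purity = pd.to_numeric(sheet.get("purity"), errors="coerce")
    keep = (sheet["tissue_type"] != "tumor") | (purity > threshold)
    survivors = sheet.index[keep]
    if len(survivors) == 0:
        raise ValueError(
            f"no sample passes the purity threshold {threshold}"
        )
    return m.subset_samples(survivors)


def filter_probes(
    m: BetaMatrix, ann: pd.DataFrame, max_missing_frac: float = 0.10
) -> BetaMatrix:
    """Remove SNP probes, sex-chromosome probes, and high-missingness probes.

    A probe is dropped for missingness only when its missing fraction is
    strictly greater than ``max_missing_frac``.
    """
    ann = validate_probe_annotation(ann)
    unannotated = m.probe_ids.difference(ann.index)
    if len(unannotated):
        raise ValueError(
            f"probes without annotation: {list(unannotated[:10])}"
        )
    ann = ann.loc[m.probe_ids]
    keep = ~ann["snp_flag"].to_numpy()
    keep &= ~ann["chrom"].isin(_SEX_CHROMS).to_numpy()
    missing_frac = m.values.isna().mean(axis=1).to_numpy()
    keep &= ~(missing_frac > max_missing_frac)
    return m.subset_probes(m.probe_ids[keep])


def impute_missing(m: BetaMatrix) -> BetaMatrix:
    """Fill missing entries with the per-probe median across all samples."""
    arr = m.values.to_numpy(dtype=float)
    if np.isnan(arr).all(axis=1).any():
        bad = m.probe_ids[np.isnan(arr).all(axis=1)]
        raise ValueError(
            f"probes with no observed value (filter first): {list(bad[:10])}"
        )
    med = np.nanmedian(arr, axis=1)
    out = np.where(np.isnan(arr), med[:, None], arr)
    return BetaMatrix(
        pd.DataFrame(out, index=m.probe_ids, columns=m.sample_ids),
        m.samples.copy(),
    )


def run_qc(
    m: BetaMatrix,
    ann: pd.DataFrame,
    purity_threshold: float = 0.6,
    max_missing_frac: float = 0.10,
) -> BetaMatrix:
    """Full QC chain: purity filter, probe filters, median imputation."""
    m = filter_samples_by_purity(m, purity_threshold)
    m = filter_probes(m, ann, max_missing_frac)
    return impute_missing(m)
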