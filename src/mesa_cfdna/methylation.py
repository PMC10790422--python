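"""Per-CpG and per-region methylation ratios, plus spike-in conversion QC.

Methylation call tables have the shape produced by methylation-ratio callers:
one row per CpG with ``chrom``, ``pos`` (0-based cytosine position),
``n_meth`` and ``n_total`` counts. The conversion-efficiency QC pools calls
on the unmethylated lambda spike-in contig: any apparent methylation there is
un-converted cytosine, so the pooled lambda ratio must stay at or below 1%
(conversion rate >= 99%) for a sample to pass.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .io import TargetRegion

CALL_COLUMNS = ("chrom", "pos", "n_meth", "n_total")


@dataclass(frozen=True)
class QcReport:
    """Spike-in conversion QC outcome for one sample.

    ``status`` is ``"pass"``, ``"fail"`` or ``"indeterminate"`` (no lambda
    calls available). ``conversion_rate`` is 1 − pooled lambda ratio.
    """

    sample_id: str
    lambda_meth_ratio: float
    conversion_rate: float
    status: str

    @property
    def passed(self) -> bool:
        return self.status == "pass"


def _validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValidationError(f"methylation calls missing columns: {missing}")
    if (calls["n_meth"] < 0).any() or (calls["n_total"] < 0).any():
        raise ValidationError("methylation counts must be non-negative")
    if (calls["n_meth"] > calls["n_total"]).any():
        bad = calls[calls["n_meth"] > calls["n_total"]].iloc[0]
        raise ValidationError(
            f"n_meth > n_total at {bad['chrom']}:{bad['pos']} "
            f"({bad['n_meth']} > {bad['n_total']})")
    return calls


def read_calls(path) -> pd.DataFrame:
    """Read a methylation call TSV (chrom, pos, n_meth, n_total; strand optional)."""
    if not os.path.exists(path):
        raise DataError(f"methylation call file not found: {path}")
    calls = pd.read_csv(path, sep="\t")
    return _validate_calls(calls)


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.loc[:, list(CALL_COLUMNS)].to_csv(path, sep="\t", index=False)


def write_ratio_bedgraph(calls: pd.DataFrame, path) -> None:
    """bedGraph of per-site ratios (zero-coverage sites are skipped)."""
    sites = site_methylation(calls)
    sites = sites[sites["ratio"].notna()]
    with open(path, "w") as fh:
        for _, row in sites.iterrows():
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{int(row['pos']) + 1}"
                     f"\t{row['ratio']:.6g}\n")


def site_methylation(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-site methylation ratio ``n_meth / n_total``.

    Zero-coverage sites get ``NaN``, which propagates downstream as a missing
    feature value (and is then subject to the training-side NA filter).
    """
    calls = _validate_calls(calls)
    out = calls.copy()
    total = out["n_total"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = out["n_meth"].to_numpy(dtype=float) / total
    ratio[total == 0] = np.nan
    out["ratio"] = ratio
    return out


def region_methylation(calls: pd.DataFrame, region: TargetRegion) -> float:
    """Count-weighted pooled ratio over CpGs inside ``region``.

    Pools counts first (Σ n_meth / Σ n_total) rather than averaging site
    ratios, so low-coverage sites do not dominate. ``NaN`` when the region
    has no covered CpG.
    """
    calls = _validate_calls(calls)
    inside = calls[(calls["chrom"] == region.chrom)
                   & (calls["pos"] >= region.start)
                   & (calls["pos"] < region.end)]
    total = int(inside["n_total"].sum())
    if total == 0:
        return float("nan")
    return float(inside["n_meth"].sum() / total)


def pooled_ratio(calls: pd.DataFrame) -> float:
    """Σ n_meth / Σ n_total over all rows; NaN when total coverage is zero."""
    calls = _validate_calls(calls)
    total = int(calls["n_total"].sum())
    if total == 0:
        return float("nan")
    return float(calls["n_meth"].sum() / total)


def spike_in_qc(lambda_calls: pd.DataFrame, sample_id: str = "",
                max_ratio: float = 0.01) -> QcReport:
    """Conversion QC on unmethylated lambda spike-in calls.

    A sample fails when its pooled lambda methylation ratio exceeds
    ``max_ratio`` (strictly more than 1% by default); a ratio exactly at the
    threshold passes. With no lambda coverage the report is indeterminate and
    the caller decides (default downstream behaviour: exclude unless an
    explicit override is given).
    """
    ratio = pooled_ratio(lambda_calls) if len(lambda_calls) else float("nan")
    if np.isnan(ratio):
        return QcReport(sample_id, float("nan"), float("nan"), "indeterminate")
    status = "pass" if ratio <= max_ratio else "fail"
    return QcReport(sample_id, ratio, 1.0 - ratio, status)
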