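"""End-to-end orchestration: QC -> feature extraction -> selection -> model.

``extract_cohort_features`` turns per-sample fragment sets and methylation
call tables into one :class:`FeatureMatrix` per modality; ``run_pipeline``
drives the whole protocol from a :class:`RunConfig` into a deterministic run
directory (``qc/``, ``features/``, ``selection/``, ``models/``,
``reports/``) whose reports are bit-identical across reruns with the same
config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import (ModelConfig, derive_seed, loocv_multimodal,
                       probability_correlations)
from .config import RunConfig
from .errors import DataError, UsageError
from .features import FeatureMatrix, assemble, boruta_select
from .io import (FragmentSet, TargetRegion, filter_fragments, make_windows,
                 read_fragments, read_regions, read_sample_sheet)
from .methylation import read_calls, site_methylation, spike_in_qc
from .nucleosome import (call_nucleosomes, compute_occupancy, panel_norm_factor,
                         region_fuzziness_feature, region_occupancy_feature)
from .wps import compute_wps, region_wps_feature

log = logging.getLogger("mesa")

NUC_MODALITIES = ("occupancy", "fuzziness", "wps")


def extract_sample_features(frags: FragmentSet, calls: pd.DataFrame | None,
                            meth_panel: Sequence[TargetRegion],
                            nuc_panel: Sequence[TargetRegion], *,
                            mode: str = "region", window: int = 1000,
                            step: int = 10, wps_window: int = 120,
                            min_summit_occ: float = 0.5,
                            smooth_window: int = 73,
                            modalities: Sequence[str] = ("methylation",) + NUC_MODALITIES,
                            wps_frags: FragmentSet | None = None,
                            ) -> dict[str, pd.Series]:
    """All modality features for one sample (fragments already size-filtered).

    ``mode="region"`` emits one feature per target region; ``mode="window"``
    tiles each nucleosome region with 1-kb/10-bp sliding windows and emits
    one feature per window (the long-region panel convention). ``wps_frags``
    optionally supplies a differently size-filtered fragment set for the
    protection score (e.g. the stricter 120–180 bp variant).
    """
    if mode not in ("region", "window"):
        raise UsageError(f"unknown extraction mode {mode!r}")
    out: dict[str, dict[str, float]] = {m: {} for m in modalities}

    if "methylation" in out:
        if calls is None:
            raise DataError("methylation modality requested without call table")
        sites = site_methylation(calls)
        for region in meth_panel:
            inside = sites[(sites["chrom"] == region.chrom)
                           & (sites["pos"] >= region.start)
                           & (sites["pos"] < region.end)]
            for _, row in inside.iterrows():
                out["methylation"][f"{region.name}:{int(row['pos'])}"] = row["ratio"]

    nuc_wanted = [m for m in NUC_MODALITIES if m in out]
    if nuc_wanted:
        norm = panel_norm_factor(frags, list(nuc_panel))
        for region in nuc_panel:
            windows = (make_windows(region, window, step)
                       if mode == "window" else [region])
            profile = compute_occupancy(frags, region, norm_factor=norm)
            peaks = (call_nucleosomes(frags, profile, min_summit_occ,
                                      smooth_window=smooth_window)
                     if "fuzziness" in out else [])
            wps_profile = (compute_wps(frags if wps_frags is None else wps_frags,
                                       region, wps_window)
                           if "wps" in out else None)
            for w in windows:
                if "occupancy" in out:
                    out["occupancy"][w.name] = region_occupancy_feature(profile, w)
                if "fuzziness" in out:
                    out["fuzziness"][w.name] = region_fuzziness_feature(peaks, w)
                if "wps" in out:
                    out["wps"][w.name] = region_wps_feature(wps_profile, w)
    return {m: pd.Series(v, dtype=float) for m, v in out.items()}


def mean_fragments_per_region(fragments: Mapping[str, FragmentSet],
                              nuc_panel: Sequence[TargetRegion]) -> float:
    """Mean fragment count per nucleosome region across samples."""
    if not fragments or not nuc_panel:
        return 0.0
    totals = []
    for frags in fragments.values():
        n = sum(len(frags.overlapping(r.chrom, r.start, r.end)[0])
                for r in nuc_panel)
        totals.append(n / len(nuc_panel))
    return float(np.mean(totals))


def extract_cohort_features(fragments: Mapping[str, FragmentSet],
                            methylation: Mapping[str, pd.DataFrame],
                            sample_sheet: pd.DataFrame,
                            meth_panel: Sequence[TargetRegion],
                            nuc_panel: Sequence[TargetRegion], *,
                            modalities: Sequence[str] = ("methylation",) + NUC_MODALITIES,
                            min_frag_len: int = 80, max_frag_len: int = 200,
                            mode: str = "region", window: int = 1000,
                            step: int = 10, wps_window: int = 120,
                            min_summit_occ: float = 0.5,
                            smooth_window: int = 73,
                            min_fuzziness_support: int = 20,
                            wps_frag_range: tuple[int, int] | None = None,
                            ) -> dict[str, FeatureMatrix]:
    """Per-modality feature matrices for a whole cohort.

    Fragments are size-filtered here; ``wps_frag_range`` applies a separate
    (stricter) size filter to the protection-score modality only. The
    fuzziness modality is dropped (with a warning) when mean coverage per
    nucleosome region falls below ``min_fuzziness_support`` fragments —
    positional dispersion cannot be estimated reliably from a handful of
    midpoints.
    """
    modalities = list(modalities)
    filtered = {sid: filter_fragments(fr, min_frag_len, max_frag_len)
                for sid, fr in fragments.items()}
    wps_filtered = None
    if wps_frag_range is not None:
        wps_filtered = {sid: filter_fragments(fr, *wps_frag_range)
                        for sid, fr in fragments.items()}
    if "fuzziness" in modalities:
        support = mean_fragments_per_region(filtered, nuc_panel)
        if support < min_fuzziness_support:
            log.warning("fuzziness disabled: mean %.1f fragments/region < %d",
                        support, min_fuzziness_support)
            modalities = [m for m in modalities if m != "fuzziness"]
    per_sample: dict[str, dict[str, pd.Series]] = {}
    for sid in sample_sheet["sample_id"]:
        if sid not in filtered:
            raise DataError(f"sample {sid!r} has no fragment data")
        per_sample[sid] = extract_sample_features(
            filtered[sid], methylation.get(sid), meth_panel, nuc_panel,
            mode=mode, window=window, step=step, wps_window=wps_window,
            min_summit_occ=min_summit_occ, smooth_window=smooth_window,
            modalities=modalities,
            wps_frags=None if wps_filtered is None else wps_filtered[sid])
    return {m: assemble({sid: feats[m] for sid, feats in per_sample.items()},
                        sample_sheet, m)
            for m in modalities}


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _run_qc(sheet: pd.DataFrame, cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    for sid in sheet["sample_id"]:
        path = sheet.loc[sid, "lambda"] if "lambda" in sheet.columns else None
        if path is None or pd.isna(path):
            report = spike_in_qc(pd.DataFrame(columns=["chrom", "pos", "n_meth",
                                                       "n_total"]), sid,
                                 cfg.qc_max_lambda)
        else:
            report = spike_in_qc(read_calls(path), sid, cfg.qc_max_lambda)
        log.info("QC %s: %s (lambda ratio %.4f)", sid, report.status,
                 report.lambda_meth_ratio)
        rows.append(dataclasses.asdict(report))
    qc = pd.DataFrame(rows)
    keep_status = {"pass"} | ({"indeterminate"} if cfg.qc_override else set())
    kept = sheet[qc.set_index("sample_id").loc[sheet["sample_id"],
                                               "status"].isin(keep_status).to_numpy()]
    return qc, kept


def run_pipeline(cfg: RunConfig) -> str:
    """Run ingest -> QC -> extraction -> selection -> stacked LOOCV.

    Returns the run directory. Re-running with the same config and seed
    reproduces identical reports.
    """
    out = cfg.outdir
    for sub in ("qc", "features", "selection", "models", "reports"):
        os.makedirs(os.path.join(out, sub), exist_ok=True)
    sheet = read_sample_sheet(cfg.sample_sheet)
    qc, sheet = _run_qc(sheet, cfg)
    qc.to_csv(os.path.join(out, "qc", "qc_report.tsv"), sep="\t", index=False)
    if sheet["label"].nunique() < 2:
        raise DataError("fewer than 2 classes remain after QC")

    meth_panel = read_regions(cfg.meth_panel, default_type="cpg_marker")
    nuc_panel = read_regions(cfg.nuc_panel, default_type="tss")
    fragments = {sid: read_fragments(sheet.loc[sid, "fragments"],
                                     _sniff_format(sheet.loc[sid, "fragments"]),
                                     sid)
                 for sid in sheet["sample_id"]}
    methylation = {sid: read_calls(sheet.loc[sid, "methylation"])
                   for sid in sheet["sample_id"]}
    fms = extract_cohort_features(
        fragments, methylation, sheet, meth_panel, nuc_panel,
        modalities=cfg.modalities, min_frag_len=cfg.min_frag_len,
        max_frag_len=cfg.max_frag_len, mode=cfg.mode, window=cfg.window,
        step=cfg.step, wps_window=cfg.wps_window,
        min_summit_occ=cfg.min_summit_occ, smooth_window=cfg.smooth_window,
        min_fuzziness_support=cfg.min_fuzziness_support,
        wps_frag_range=None if cfg.wps_frag_range is None
        else tuple(cfg.wps_frag_range))
    for name, fm in fms.items():
        fm.to_tsv(os.path.join(out, "features", f"{name}.tsv"))

    if cfg.selection_report:
        for m, (name, fm) in enumerate(sorted(fms.items())):
            complete = fm.values.dropna(axis=1)
            complete = complete.loc[:, complete.var(axis=0, ddof=0)
                                    > cfg.model.var_threshold]
            res = boruta_select(
                complete, fm.labels.to_numpy(), k=cfg.model.top_k,
                max_iter=cfg.model.boruta_max_iter, alpha=cfg.model.boruta_alpha,
                seed=derive_seed(cfg.seed, 55, m),
                n_estimators=cfg.model.boruta_trees or cfg.model.trees,
                max_depth=cfg.model.boruta_depth)
            res.to_frame().to_csv(
                os.path.join(out, "selection", f"{name}.tsv"), sep="\t",
                index=False)

    result = loocv_multimodal(fms, cfg.model, cfg.seed)
    _write_reports(result, fms, cfg, out)
    manifest = {"config": cfg.to_dict(), "config_digest": cfg.digest(),
                "seed": cfg.seed, "version": __version__,
                "n_samples": int(len(sheet)),
                "modalities": sorted(fms)}
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _sniff_format(path: str) -> str:
    if str(path).endswith(".bam"):
        return "bam"
    if str(path).endswith((".bedpe", ".bedpe.txt")):
        return "bedpe"
    return "bed"


def _write_reports(result, fms, cfg: RunConfig, out: str) -> None:
    reports = os.path.join(out, "reports")
    probs = result.base_probs.copy()
    probs.insert(0, "label", result.labels)
    probs["final"] = result.final_probs
    probs.to_csv(os.path.join(reports, "probabilities.tsv"), sep="\t",
                 index_label="sample_id")
    metrics = {"multimodal": result.report.to_dict(),
               "per_modality": {n: r.to_dict()
                                for n, r in result.base_reports.items()}}
    with open(os.path.join(reports, "metrics.json"), "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    corr = probability_correlations(result.base_probs)
    corr.to_csv(os.path.join(reports, "correlations.tsv"), sep="\t")
    result.report.confusion.to_csv(os.path.join(reports, "confusion.tsv"),
                                   sep="\t")
    _roc_points(result).to_csv(os.path.join(reports, "roc_points.tsv"),
                               sep="\t", index=False)
    with open(os.path.join(out, "models", "model_summary.json"), "w") as fh:
        json.dump({"model": dataclasses.asdict(cfg.model)}, fh, indent=2,
                  sort_keys=True)


def _roc_points(result) -> pd.DataFrame:
    labels = result.labels
    classes = sorted(labels.unique())
    if len(classes) != 2:
        return pd.DataFrame(columns=["threshold", "fpr", "tpr"])
    pos = "cancer" if "cancer" in classes else classes[1]
    y = (labels == pos).to_numpy()
    p = result.final_probs.to_numpy()
    rows = []
    for t in np.concatenate([[np.inf], np.unique(p)[::-1]]):
        pred = p >= t
        tpr = float(pred[y].mean()) if y.any() else float("nan")
        fpr = float(pred[~y].mean()) if (~y).any() else float("nan")
        rows.append({"threshold": float(t), "fpr": fpr, "tpr": tpr})
    return pd.DataFrame(rows)
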