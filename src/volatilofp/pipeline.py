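"""End-to-end orchestration of the UT fingerprinting workflow.

Glues the stage modules together for the common case: detect peaks on every
chromatogram, register all samples to a reference, build the template from
reliable cross-sample features, extract a complete samples × features
response matrix, and normalize it over the internal standards.  Each stage
remains individually accessible; this module only sequences them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromatogram import ChromatogramGrid
from .detection import PeakTable, detect_peaks
from .fingerprinting import (
    FeatureMatrix,
    Template,
    WarpModel,
    apply_template,
    apply_warp_grid,
    apply_warp_peaks,
    build_cumulative,
    build_template,
    choose_reference,
    fit_warp,
    match_across,
    normalize,
    reliable_features,
)
from .synthetic_data import GroundTruth, StudyData

__all__ = ["PipelineResult", "run_ut_pipeline", "match_features_to_truth"]


@dataclass
class PipelineResult:
    tables: list[PeakTable]
    warps: dict[str, WarpModel]
    reference_index: int
    reliable_sets: list
    cumulative: ChromatogramGrid
    template: Template
    responses: pd.DataFrame          # samples × features, volume units
    istd_feature_ids: list[str]
    feature_matrix: FeatureMatrix


def _anchor_pairs(sets, ref_id: str, sample_id: str) -> tuple[np.ndarray, np.ndarray]:
    ref_pts, smp_pts = [], []
    for s in sets:
        if ref_id in s and sample_id in s:
            rp, sp = s[ref_id], s[sample_id]
            ref_pts.append((rp.apex_1t_min, rp.apex_2t_s))
            smp_pts.append((sp.apex_1t_min, sp.apex_2t_s))
    return np.asarray(ref_pts), np.asarray(smp_pts)


def run_ut_pipeline(
    study: StudyData,
    *,
    snr_min: float = 50.0,
    rt_window: tuple[float, float] = (0.25, 0.25),
    mf_min: float = 700.0,
    min_fraction: float = 0.5,
    missing: str = "region",
) -> PipelineResult:
    """Run detection → registration → template → extraction → normalization.

    Registration anchors come from an initial cross-sample matching pass;
    after warping, matching is repeated in the registered space, reliable
    features (present in at least ``min_fraction`` of samples) seed the
    template, and every sample is extracted against it.  Internal-standard
    template features are located by proximity to the study's known spiked
    IS positions and used for normalization.
    """
    tables = [detect_peaks(g, snr_min=snr_min) for g in study.grids]
    ref_idx = choose_reference(tables)
    ref_id = tables[ref_idx].sample_id

    first_pass = match_across(tables, rt_window, mf_min, reference_index=ref_idx)
    warps: dict[str, WarpModel] = {ref_id: WarpModel.identity()}
    warped_tables: list[PeakTable] = []
    warped_grids: list[ChromatogramGrid] = []
    for t_idx, table in enumerate(tables):
        if t_idx == ref_idx:
            warps[ref_id] = WarpModel.identity()
            warped_tables.append(table)
            warped_grids.append(study.grids[t_idx])
            continue
        ref_pts, smp_pts = _anchor_pairs(first_pass, ref_id, table.sample_id)
        warp = (
            fit_warp(ref_pts, smp_pts) if len(ref_pts) >= 4 else WarpModel.identity()
        )
        warps[table.sample_id] = warp
        warped_tables.append(apply_warp_peaks(table, warp))
        warped_grids.append(apply_warp_grid(study.grids[t_idx], warp))

    sets = match_across(warped_tables, rt_window, mf_min, reference_index=ref_idx)
    reliable = reliable_features(sets, len(tables), min_fraction)
    cumulative = build_cumulative(warped_grids)
    template = build_template(cumulative, reliable, len(tables))

    responses = pd.DataFrame(
        [
            apply_template(
                template, study.grids[t_idx], tables[t_idx],
                warp=warps[tables[t_idx].sample_id], mf_min=mf_min, missing=missing,
            )
            for t_idx in range(len(tables))
        ]
    )
    responses.index = [t.sample_id for t in tables]

    istd_ids = _locate_istd_features(template, study.ground_truth)
    labels = study.metadata.set_index("sample_id").loc[responses.index]
    matrix = normalize(responses, istd_ids, labels)
    return PipelineResult(
        tables=tables, warps=warps, reference_index=ref_idx,
        reliable_sets=reliable, cumulative=cumulative, template=template,
        responses=responses, istd_feature_ids=istd_ids, feature_matrix=matrix,
    )


def _locate_istd_features(template: Template, gt: GroundTruth) -> list[str]:
    """Template features nearest to the known spiked internal standards."""
    ids = []
    istd = gt.compounds[gt.compounds["is_istd"]]
    for _, row in istd.iterrows():
        t1, t2 = row.rt1_s / 60.0, row.rt2_s
        best, best_d = None, np.inf
        for f in template.features:
            d = np.hypot((f.apex_1t_min - t1) / 0.5, (f.apex_2t_s - t2) / 0.5)
            if d < best_d:
                best, best_d = f.feature_id, d
        if best is not None and best not in ids:
            ids.append(best)
    if not ids:
        raise ValueError("no template feature matches an internal standard")
    return ids


def match_features_to_truth(
    template: Template,
    gt: GroundTruth,
    *,
    tol_1t_min: float = 0.15,
    tol_2t_s: float = 0.2,
) -> dict[str, str]:
    """Greedy map template feature id → planted compound by apex proximity."""
    pairs = []
    for f in template.features:
        for name, row in gt.compounds.iterrows():
            d1 = abs(f.apex_1t_min - row.rt1_s / 60.0)
            d2 = abs(f.apex_2t_s - row.rt2_s)
            if d1 <= tol_1t_min and d2 <= tol_2t_s:
                pairs.append((np.hypot(d1 / tol_1t_min, d2 / tol_2t_s), f.feature_id, name))
    pairs.sort()
    out: dict[str, str] = {}
    used: set[str] = set()
    for _, fid, name in pairs:
        if fid in out or name in used:
            continue
        out[fid] = name
        used.add(name)
    return out
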