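"""Template-based untargeted-targeted (UT) fingerprinting across samples.

The workflow mirrors template-driven GC×GC fingerprinting: peaks detected in
a set of representative chromatograms are matched across samples under
retention-window and spectral-similarity constraints (DMF and RMF ≥ 700);
correspondences present in at least half the chromatograms become *reliable
features*; chromatograms are registered to a reference by a low-order warp;
their pixel-wise mean forms the *cumulative image*; and a template of peak
objects plus delineated peak regions is drawn from it.  Applying the template
to any registered sample yields a complete response vector — a matched peak
contributes its volume, and where no confident peak match exists the region
integral is used instead, so co-eluting or weak features still produce a
response.

Responses are normalized per sample over the internal standards and then
converted to percent of the total normalized response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Point, Polygon
from shapely import affinity

from .chromatogram import ChromatogramGrid, MassSpectrum
from .detection import Peak2D, PeakTable
from .identification import Annotation, match_factor, reverse_match_factor

__all__ = [
    "WarpModel",
    "TemplateFeature",
    "Template",
    "FeatureMatrix",
    "choose_reference",
    "match_across",
    "reliable_features",
    "fit_warp",
    "apply_warp_peaks",
    "apply_warp_grid",
    "build_cumulative",
    "build_template",
    "apply_template",
    "normalize",
]


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

@dataclass
class WarpModel:
    """Retention-plane registration: sample space → reference space.

    ``^1t_R`` maps through a quadratic polynomial (shift + stretch +
    curvature); ``^2t_R`` through a constant offset.  Coefficients are stored
    highest-power-first (``numpy.polyval`` convention) for both the forward
    and the inverse direction, each least-squares fitted to the anchors.
    """

    poly1: np.ndarray          # forward ^1t coefficients (minutes)
    inv_poly1: np.ndarray      # inverse ^1t coefficients
    d2_s: float                # forward ^2t offset (seconds)
    method: str = "quadratic"  # "quadratic" | "shift" | "identity"
    rms_before: float = 0.0
    rms_after: float = 0.0

    def forward(self, rt1_min, rt2_s):
        return np.polyval(self.poly1, np.asarray(rt1_min, dtype=float)), (
            np.asarray(rt2_s, dtype=float) + self.d2_s
        )

    def inverse(self, rt1_min, rt2_s):
        return np.polyval(self.inv_poly1, np.asarray(rt1_min, dtype=float)), (
            np.asarray(rt2_s, dtype=float) - self.d2_s
        )

    @classmethod
    def identity(cls) -> "WarpModel":
        one = np.array([1.0, 0.0])
        return cls(one, one.copy(), 0.0, method="identity")


def fit_warp(
    ref_points: np.ndarray, sample_points: np.ndarray, *, degree: int = 2
) -> WarpModel:
    """Least-squares warp from anchor pairs (sample apexes vs reference apexes).

    Points are (n, 2) arrays of (^1t_R minutes, ^2t_R seconds).  Falls back
    to a shift-only model with a warning when anchors are too few or
    degenerate (no spread in ^1t); returns the exact identity when anchors
    already coincide.
    """
    ref = np.asarray(ref_points, dtype=float)
    samp = np.asarray(sample_points, dtype=float)
    if ref.shape != samp.shape or ref.ndim != 2 or ref.shape[1] != 2:
        raise ValueError("anchor arrays must be matching (n, 2)")
    n = ref.shape[0]
    dof = degree + 2  # polynomial coefficients + ^2t offset
    resid_before = np.sqrt(np.mean((ref - samp) ** 2))
    if np.allclose(ref, samp, atol=1e-12):
        m = WarpModel.identity()
        m.rms_before = float(resid_before)
        m.rms_after = 0.0
        return m
    d2 = float(np.mean(ref[:, 1] - samp[:, 1]))
    spread = np.ptp(samp[:, 0])
    if n < max(4, dof) or spread < 1e-9:
        if spread < 1e-9:
            warnings.warn(
                "anchors degenerate in ^1t; falling back to shift-only warp",
                stacklevel=2,
            )
        shift = float(np.mean(ref[:, 0] - samp[:, 0]))
        poly = np.array([1.0, shift])
        inv = np.array([1.0, -shift])
        model = WarpModel(poly, inv, d2, method="shift")
    else:
        poly = np.polyfit(samp[:, 0], ref[:, 0], deg=degree)
        inv = np.polyfit(ref[:, 0], samp[:, 0], deg=degree)
        model = WarpModel(poly, inv, d2, method=f"poly{degree}")
    w1, w2 = model.forward(samp[:, 0], samp[:, 1])
    model.rms_before = float(resid_before)
    resid = np.concatenate([ref[:, 0] - w1, ref[:, 1] - w2])
    model.rms_after = float(np.sqrt(np.mean(resid**2)))
    return model


def apply_warp_peaks(table: PeakTable, warp: WarpModel) -> PeakTable:
    """Transform every peak apex of a table into reference space."""
    peaks = []
    for p in table:
        r1, r2 = warp.forward(p.apex_1t_min, p.apex_2t_s)
        peaks.append(
            Peak2D(
                id=p.id, apex_1t_min=float(r1), apex_2t_s=float(r2),
                height=p.height, volume=p.volume, snr=p.snr,
                apex_pixel=p.apex_pixel, footprint=p.footprint,
                spectrum=p.spectrum,
            )
        )
    return PeakTable(table.sample_id, peaks, table.snr_min)


def apply_warp_grid(grid: ChromatogramGrid, warp: WarpModel) -> ChromatogramGrid:
    """Resample a grid into reference space (linear interpolation)."""
    from scipy.ndimage import map_coordinates

    ii = np.arange(grid.n_modulations)
    jj = np.arange(grid.n_points_per_period)
    rt1 = np.asarray(grid.rt1_min(ii))
    rt2 = np.asarray(grid.rt2_s(jj))
    src1, _ = warp.inverse(rt1, np.zeros_like(rt1))
    _, src2 = warp.inverse(np.zeros_like(rt2), rt2)
    src_i = (np.asarray(src1) * 60.0 - grid.t0_s) / grid.pm_s
    src_j = np.asarray(src2) * grid.rate_hz
    I, J = np.meshgrid(src_i, src_j, indexing="ij")
    out = map_coordinates(grid.intensities, [I, J], order=1, mode="nearest")
    return ChromatogramGrid(
        out, grid.pm_s, grid.rate_hz, grid.t0_s, sample_id=grid.sample_id,
        spectra=grid.spectra,
    )


# ---------------------------------------------------------------------------
# Cross-sample matching and reliability
# ---------------------------------------------------------------------------

def choose_reference(tables: list[PeakTable]) -> int:
    """Index of the reference sample: the table with median total volume."""
    totals = [t.total_volume() for t in tables]
    order = np.argsort(totals)
    return int(order[len(order) // 2])


def match_across(
    tables: list[PeakTable],
    rt_window: tuple[float, float] = (0.2, 0.25),
    mf_min: float = 700,
    *,
    reference_index: int | None = None,
) -> list[dict[str, Peak2D]]:
    """Match peaks across samples into correspondence sets.

    Candidate pairs lie within ``rt_window`` (Δ^1t_R minutes, Δ^2t_R seconds)
    of a reference peak and must agree spectrally (DMF ≥ ``mf_min`` and
    RMF ≥ ``mf_min``).  Matching is greedy one-to-one per sample, preferring
    higher DMF then smaller retention distance; each peak joins at most one
    correspondence set.  Returns one ``{sample_id: peak}`` dict per set,
    ordered by reference apex.
    """
    if len(tables) < 2:
        raise ValueError("need at least two peak tables")
    d1, d2 = rt_window
    if d1 <= 0 or d2 <= 0:
        raise ValueError("rt_window must be positive in both dimensions")
    ref_idx = choose_reference(tables) if reference_index is None else reference_index
    ref = tables[ref_idx]
    sets: list[dict[str, Peak2D]] = [{ref.sample_id: p} for p in ref]
    for t_idx, table in enumerate(tables):
        if t_idx == ref_idx:
            continue
        candidates = []
        for si, s in enumerate(sets):
            rp = next(iter(s.values()))
            for p in table:
                dd1 = abs(p.apex_1t_min - rp.apex_1t_min)
                dd2 = abs(p.apex_2t_s - rp.apex_2t_s)
                if dd1 > d1 or dd2 > d2:
                    continue
                if rp.spectrum is None or p.spectrum is None:
                    continue
                dmf = match_factor(p.spectrum, rp.spectrum)
                if dmf < mf_min:
                    continue
                if reverse_match_factor(p.spectrum, rp.spectrum) < mf_min:
                    continue
                dist = np.hypot(dd1 / d1, dd2 / d2)
                candidates.append((-dmf, dist, si, p))
        candidates.sort(key=lambda c: (c[0], c[1]))
        used_sets: set[int] = set()
        used_peaks: set[str] = set()
        for _, _, si, p in candidates:
            if si in used_sets or p.id in used_peaks:
                continue
            sets[si][table.sample_id] = p
            used_sets.add(si)
            used_peaks.add(p.id)
    return sets


def reliable_features(
    sets: list[dict[str, Peak2D]], n_samples: int, min_fraction: float = 0.5
) -> list[dict[str, Peak2D]]:
    """Keep correspondence sets present in ≥ ``min_fraction`` of samples.

    The boundary is inclusive ("at least 50%"): a set seen in 3 of 6 samples
    survives the default threshold.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    return [s for s in sets if len(s) / n_samples >= min_fraction - 1e-12]


# ---------------------------------------------------------------------------
# Cumulative image and template
# ---------------------------------------------------------------------------

def build_cumulative(grids: list[ChromatogramGrid]) -> ChromatogramGrid:
    """Pixel-wise mean of registered chromatograms (the cumulative image)."""
    if not grids:
        raise ValueError("need at least one grid")
    shape = grids[0].intensities.shape
    for g in grids[1:]:
        if g.intensities.shape != shape:
            raise ValueError("grids must share dimensions after registration")
    mean = np.mean([g.intensities for g in grids], axis=0)
    g0 = grids[0]
    return ChromatogramGrid(mean, g0.pm_s, g0.rate_hz, g0.t0_s, sample_id="cumulative")


@dataclass
class TemplateFeature:
    feature_id: str
    apex_1t_min: float
    apex_2t_s: float
    consensus_spectrum: MassSpectrum | None
    region: Polygon
    occurrence_fraction: float
    kind: str = "untargeted"          # "untargeted" | "targeted"
    annotation: Annotation | None = None


@dataclass
class Template:
    features: list[TemplateFeature]
    n_samples: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [f.feature_id for f in self.features]
        if len(set(ids)) != len(ids):
            raise ValueError("feature ids must be unique")

    def __len__(self) -> int:
        return len(self.features)

    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]


def _region_from_footprints(
    pixels: set[tuple[int, int]], grid: ChromatogramGrid
) -> Polygon:
    """Convex hull of footprint pixels, dilated by one pixel, in rt units.

    Geometry is built in pixel space (isotropic dilation) and then scaled to
    (^1t_R minutes, ^2t_R seconds).
    """
    pts = MultiPoint([(i, j) for i, j in pixels])
    hull = pts.convex_hull.buffer(1.0)
    sx = grid.pm_s / 60.0       # minutes per row
    sy = 1.0 / grid.rate_hz     # seconds per column
    poly = affinity.scale(hull, xfact=sx, yfact=sy, origin=(0, 0))
    return affinity.translate(poly, xoff=grid.t0_s / 60.0, yoff=0.0)


def _trim_overlaps(features: list[TemplateFeature], grid: ChromatogramGrid) -> None:
    """Clip overlapping regions by the perpendicular bisector of their apexes.

    Distances are measured in pixel units so the two retention dimensions are
    commensurate.
    """
    sx = grid.pm_s / 60.0
    sy = 1.0 / grid.rate_hz
    big = 1e4
    for a in range(len(features)):
        for b in range(a + 1, len(features)):
            fa, fb = features[a], features[b]
            if not fa.region.intersects(fb.region):
                continue
            pa = np.array([fa.apex_1t_min / sx, fa.apex_2t_s / sy])
            pb = np.array([fb.apex_1t_min / sx, fb.apex_2t_s / sy])
            d = pb - pa
            nd = np.linalg.norm(d)
            if nd < 1e-9:
                continue
            d = d / nd
            mid = (pa + pb) / 2.0
            perp = np.array([-d[1], d[0]])
            c1 = mid + perp * big
            c2 = mid - perp * big
            half_a = Polygon(
                [tuple(c1), tuple(c2), tuple(c2 - d * big), tuple(c1 - d * big)]
            )
            half_b = Polygon(
                [tuple(c1), tuple(c2), tuple(c2 + d * big), tuple(c1 + d * big)]
            )
            to_rt = lambda g: affinity.scale(g, xfact=sx, yfact=sy, origin=(0, 0))
            fa.region = fa.region.intersection(to_rt(half_a))
            fb.region = fb.region.intersection(to_rt(half_b))


def build_template(
    cumulative: ChromatogramGrid,
    reliable_sets: list[dict[str, Peak2D]],
    n_samples: int,
    annotations: dict[str, Annotation] | None = None,
) -> Template:
    """Build the UT template from reliable correspondence sets.

    One feature per set: the expected apex is the median member apex (after
    registration), the consensus spectrum the per-m/z intensity median, and
    the region the dilated convex hull of the member footprints; overlapping
    regions are trimmed along the apex bisector.  A feature whose member
    peak carries a *targeted* annotation (keyed by peak id) is marked
    targeted.
    """
    if not reliable_sets:
        raise ValueError("reliable_sets must be non-empty")
    annotations = annotations or {}
    feats: list[TemplateFeature] = []
    order = sorted(
        range(len(reliable_sets)),
        key=lambda k: (
            np.median([p.apex_1t_min for p in reliable_sets[k].values()]),
            np.median([p.apex_2t_s for p in reliable_sets[k].values()]),
        ),
    )
    for rank, k in enumerate(order):
        members = list(reliable_sets[k].values())
        apex1 = float(np.median([p.apex_1t_min for p in members]))
        apex2 = float(np.median([p.apex_2t_s for p in members]))
        specs = [p.spectrum for p in members if p.spectrum is not None]
        consensus = MassSpectrum.median_consensus(specs) if specs else None
        pixels: set[tuple[int, int]] = set()
        for p in members:
            pixels |= p.footprint
        region = _region_from_footprints(pixels, cumulative)
        if not region.contains(Point(apex1, apex2)):
            region = region.union(Point(apex1, apex2).buffer(cumulative.pm_s / 60.0))
        ann = next(
            (annotations[p.id] for p in members if p.id in annotations), None
        )
        kind = "targeted" if ann is not None and ann.status == "targeted" else "untargeted"
        feats.append(
            TemplateFeature(
                feature_id=f"F{rank:03d}",
                apex_1t_min=apex1,
                apex_2t_s=apex2,
                consensus_spectrum=consensus,
                region=region,
                occurrence_fraction=len(members) / n_samples,
                kind=kind,
                annotation=ann if kind == "targeted" else None,
            )
        )
    _trim_overlaps(feats, cumulative)
    return Template(feats, n_samples)


def write_template(template: Template, path) -> None:
    """Write a template as JSON: apexes, kinds, region vertices, spectra."""
    import json
    from pathlib import Path as _P

    feats = []
    for f in template.features:
        feats.append(
            {
                "feature_id": f.feature_id,
                "apex_1t_min": f.apex_1t_min,
                "apex_2t_s": f.apex_2t_s,
                "kind": f.kind,
                "occurrence_fraction": f.occurrence_fraction,
                "region": [list(xy) for xy in f.region.exterior.coords],
                "consensus_spectrum": None
                if f.consensus_spectrum is None
                else {
                    "mz": f.consensus_spectrum.mz.tolist(),
                    "intensity": f.consensus_spectrum.intensity.tolist(),
                },
                "annotation": None
                if f.annotation is None
                else {"compound": f.annotation.compound, "status": f.annotation.status},
            }
        )
    _P(path).write_text(
        json.dumps({"n_samples": template.n_samples, "features": feats}, indent=1)
    )


def apply_template(
    template: Template,
    grid: ChromatogramGrid,
    table: PeakTable,
    warp: WarpModel | None = None,
    *,
    mf_min: float = 700,
    missing: str = "region",
) -> pd.Series:
    """Extract one response per template feature from a sample.

    A detected peak whose (registered) apex falls inside the feature region
    and whose spectrum matches the consensus (DMF ≥ ``mf_min``) contributes
    its volume.  Otherwise the fallback depends on ``missing``: ``"region"``
    integrates the baseline-corrected grid over the region (so partially
    co-eluting or sub-threshold signal still yields a response), ``"zero"``
    reports 0.  The result is always complete — no missing entries.
    """
    if missing not in ("region", "zero"):
        raise ValueError("missing must be 'region' or 'zero'")
    warped = apply_warp_peaks(table, warp) if warp is not None else table
    baseline = np.median(grid.intensities, axis=1)
    z = grid.intensities - baseline[:, None]
    ii = np.arange(grid.n_modulations)
    jj = np.arange(grid.n_points_per_period)
    rt1_px = np.asarray(grid.rt1_min(ii))
    rt2_px = np.asarray(grid.rt2_s(jj))

    tol1 = grid.pm_s / 60.0          # one modulation, minutes
    tol2 = 3.0 / grid.rate_hz        # three detector points, seconds
    values: dict[str, float] = {}
    for feat in template.features:
        best_vol: float | None = None
        best_dmf = -1
        for p in warped:
            # inside the region, or within a pixel of the expected apex
            # (region boundaries are trimmed between neighbors, so a 1-pixel
            # apex jitter must not knock a genuine match into the fallback)
            if not feat.region.contains(Point(p.apex_1t_min, p.apex_2t_s)) and not (
                abs(p.apex_1t_min - feat.apex_1t_min) <= tol1
                and abs(p.apex_2t_s - feat.apex_2t_s) <= tol2
            ):
                continue
            if feat.consensus_spectrum is None or p.spectrum is None:
                dmf = mf_min  # no spectral evidence either way: accept by position
            else:
                dmf = match_factor(p.spectrum, feat.consensus_spectrum)
            if dmf >= mf_min and dmf > best_dmf:
                best_dmf = dmf
                best_vol = p.volume
        if best_vol is not None:
            values[feat.feature_id] = best_vol
        elif missing == "zero":
            values[feat.feature_id] = 0.0
        else:
            # region integration fallback in sample space
            region = feat.region
            if warp is not None:
                verts = np.asarray(region.exterior.coords)
                v1, v2 = warp.inverse(verts[:, 0], verts[:, 1])
                region = Polygon(np.column_stack([v1, v2]))
            minx, miny, maxx, maxy = region.bounds
            isel = np.nonzero((rt1_px >= minx - 1e-9) & (rt1_px <= maxx + 1e-9))[0]
            jsel = np.nonzero((rt2_px >= miny - 1e-9) & (rt2_px <= maxy + 1e-9))[0]
            if isel.size == 0 or jsel.size == 0:
                values[feat.feature_id] = 0.0
                continue
            X, Y = np.meshgrid(rt1_px[isel], rt2_px[jsel], indexing="ij")
            inside = shapely.contains_xy(region, X.ravel(), Y.ravel()).reshape(X.shape)
            sub = z[np.ix_(isel, jsel)]
            values[feat.feature_id] = float(max(sub[inside].sum(), 0.0) * grid.pixel_area_s2)
    return pd.Series(values, name=table.sample_id)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Samples × features responses with ISTD-normalized and percent views.

    ``normalized`` divides each sample's responses by the mean response of
    its internal-standard features; ``percent`` converts the normalized view
    to percent of the per-sample total over non-ISTD features (rows sum to
    100 wherever the total is nonzero).
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame
    percent: pd.DataFrame
    labels: pd.DataFrame
    istd_features: list[str]


def normalize(
    raw: pd.DataFrame,
    istd_features: list[str],
    labels: pd.DataFrame,
) -> FeatureMatrix:
    """ISTD-normalize then convert to percent of total normalized response.

    ``raw`` is samples × features (volume units); ``istd_features`` names the
    internal-standard columns (mean of the ISTD responses is the per-sample
    normalization factor, following the two-IS spiking scheme);
    ``labels`` is indexed like ``raw`` with columns such as arm/timepoint.
    """
    missing = [c for c in istd_features if c not in raw.columns]
    if missing:
        raise ValueError(f"ISTD features not in matrix: {missing}")
    if (raw < 0).any().any():
        raise ValueError("responses must be non-negative")
    is_mean = raw[istd_features].mean(axis=1)
    bad = is_mean[is_mean <= 0].index.tolist()
    if bad:
        raise ValueError(f"zero internal-standard response in samples: {bad}")
    normalized = raw.div(is_mean, axis=0)
    rest = normalized.drop(columns=istd_features)
    totals = rest.sum(axis=1)
    percent = rest.div(totals.where(totals > 0, np.inf), axis=0) * 100.0
    return FeatureMatrix(
        raw=raw.copy(),
        normalized=normalized,
        percent=percent,
        labels=labels.copy(),
        istd_features=list(istd_features),
    )
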