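"""Synthetic GC×GC-TOFMS studies with full ground truth.

Emulates a two-arm (placebo ``VP0`` vs probiotic ``VP1``), two-timepoint
(``T1``/``T2``) fecal-volatilome study: each sample is a 2D chromatogram with
planted bivariate-Gaussian peaks, compound-specific stick spectra, two
internal standards at fixed positions, smooth per-sample retention drift in
both dimensions, and additive Gaussian baseline noise.  A subset of compounds
carries a class effect (volumes differing by ``effect_log2fc`` between arms).
An n-alkane ladder chromatogram (n-C9…n-C25) accompanies every study for
retention-index calibration.

Everything is deterministic under the configured seed, and the generator
returns the complete ground truth (true apexes, per-sample volumes, drift
fields, discriminant flags) so every downstream stage can be scored exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chromatogram import (
    ChromatogramGrid,
    LibraryEntry,
    MassSpectrum,
    SpectralLibrary,
    write_grid,
    write_msp,
)
from .identification import RICalibration, compute_ri

__all__ = [
    "SyntheticStudyConfig",
    "GroundTruth",
    "StudyData",
    "generate_library",
    "generate_study",
    "sample_ground_truth",
    "render_peak",
    "make_alkane_ladder",
    "write_study",
]

MZ_MIN, MZ_MAX = 40, 350

ISTD_NAMES = ("alpha/beta-Thujone (ISTD)", "Methyl 2-octynoate (ISTD)")


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Study design and instrument parameters for the generator.

    Defaults mirror the acquisition the pipeline targets (4 s modulation
    period, 100 Hz detector) at desk scale: a 16-minute window with 60
    resolvable compounds per chromatogram and six samples per
    (arm, timepoint) cell.
    """

    n_samples_per_group: int = 6
    groups: tuple[tuple[str, str], ...] = (
        ("VP0", "T1"), ("VP0", "T2"), ("VP1", "T1"), ("VP1", "T2"),
    )
    n_compounds: int = 60
    n_discriminant: int = 8
    effect_log2fc: float = 1.5
    drift_1d_max: float = 6.0
    drift_2d_max: float = 0.06
    noise_sd: float = 1.0
    snr_range: tuple[float, float] = (80.0, 500.0)
    seed: int = 0
    # instrument geometry
    pm_s: float = 4.0
    rate_hz: float = 100.0
    n_modulations: int = 240
    sigma1_s: float = 4.0
    sigma2_s: float = 0.06
    biological_sigma: float = 0.30  # lognormal sd (ln scale) of true volumes

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 1 or self.n_compounds < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.n_discriminant <= self.n_compounds:
            raise ValueError("n_discriminant must be <= n_compounds")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.drift_1d_max < 0 or self.drift_2d_max < 0:
            raise ValueError("drift magnitudes must be non-negative")
        if not (0 < self.snr_range[0] <= self.snr_range[1]):
            raise ValueError("snr_range must be positive and ordered")

    @property
    def run_time_s(self) -> float:
        return self.n_modulations * self.pm_s


@dataclass
class GroundTruth:
    """Planted truth of a synthetic study.

    ``compounds`` has one row per compound (true apex in seconds, tabulated
    I^T, discriminant flag/direction, internal-standard flag, base volume);
    ``volumes`` holds the true per-sample volume of every compound;
    ``drift`` holds each sample's drift-field parameters (quadratic ^1t
    coefficient in seconds, constant ^2t offset in seconds).
    """

    compounds: pd.DataFrame
    volumes: pd.DataFrame
    drift: pd.DataFrame
    istd_names: tuple[str, str]
    config: SyntheticStudyConfig

    def drifted_apex(self, sample_id: str, compound: str) -> tuple[float, float]:
        row = self.compounds.loc[compound]
        return self.apply_drift(sample_id, float(row.rt1_s), float(row.rt2_s))

    def apply_drift(self, sample_id: str, t1_s: float, t2_s: float) -> tuple[float, float]:
        c1 = float(self.drift.loc[sample_id, "d1_coeff_s"])
        c2 = float(self.drift.loc[sample_id, "d2_offset_s"])
        T = self.config.run_time_s
        return t1_s + c1 * (t1_s / T) ** 2, t2_s + c2

    def invert_drift(self, sample_id: str, t1_s: float, t2_s: float) -> tuple[float, float]:
        """Inverse of the drift field (fixed-point iteration on ^1t)."""
        c1 = float(self.drift.loc[sample_id, "d1_coeff_s"])
        c2 = float(self.drift.loc[sample_id, "d2_offset_s"])
        T = self.config.run_time_s
        t = t1_s
        for _ in range(50):
            t_new = t1_s - c1 * (t / T) ** 2
            if abs(t_new - t) < 1e-10:
                t = t_new
                break
            t = t_new
        return t, t2_s - c2

    def discriminant_names(self) -> list[str]:
        return self.compounds.index[self.compounds["discriminant"]].tolist()

    def realized_snr(self, sample_id: str) -> pd.Series:
        """Per-compound realized apex SNR in one sample.

        The rendered apex height is volume / (2π σ1 σ2); dividing by the
        configured noise sd gives the SNR the detector actually sees (before
        sub-pixel quantization), which differs from the drawn target SNR by
        the biological volume variability and any class effect.
        """
        c = self.config
        heights = self.volumes.loc[sample_id] / (2 * math.pi * c.sigma1_s * c.sigma2_s)
        return heights / c.noise_sd


@dataclass
class StudyData:
    grids: list[ChromatogramGrid]
    alkane_grid: ChromatogramGrid
    ladder: RICalibration
    library: SpectralLibrary
    ground_truth: GroundTruth
    metadata: pd.DataFrame


def generate_library(n_compounds: int, seed: int) -> SpectralLibrary:
    """Random stick-spectrum library of ``n_compounds`` entries.

    Each entry carries 5–40 integer m/z sticks in [40, 350] with the base
    peak at 999, a unique name and CAS-like id, and a tabulated retention
    index in [600, 2800].  Bit-identical under the same seed.
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    rng = np.random.default_rng(seed)
    entries: list[LibraryEntry] = []
    for k in range(n_compounds):
        n_sticks = int(rng.integers(5, 41))
        mz = np.sort(rng.choice(np.arange(MZ_MIN, MZ_MAX + 1), size=n_sticks, replace=False))
        inten = rng.exponential(scale=1.0, size=n_sticks) + 0.01
        spec = MassSpectrum(mz, inten).normalized()
        ri = float(np.round(rng.uniform(600, 2800), 1))
        entries.append(
            LibraryEntry(
                name=f"SYN-{k:04d}",
                spectrum=spec,
                casno=f"{9000 + k}-{k % 100:02d}-{k % 10}",
                ri=ri,
            )
        )
    return SpectralLibrary(entries)


def render_peak(
    grid: ChromatogramGrid,
    apex_t1_s: float,
    apex_t2_s: float,
    volume: float,
    spectrum: MassSpectrum | None,
    sigma1_s: float,
    sigma2_s: float,
    *,
    spectra_fraction: float = 0.1,
    extent_sigmas: float = 4.0,
) -> tuple[slice, slice, np.ndarray]:
    """Add one bivariate-Gaussian peak to a grid (in place).

    The peak integrates to ``volume`` in intensity × s² units: the rendered
    pixel intensity is the bivariate-Gaussian density — intensities are
    densities, so ``sum(patch) * pixel_area ≈ volume`` (within 2% for apexes
    at least ``extent_sigmas`` σ from the window edge).  When ``spectrum`` is
    given, per-pixel spectra are the compound spectrum scaled by the local
    intensity, summed linearly onto whatever is already stored (co-elution).

    Returns the (row slice, column slice, patch) actually added.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    T = grid.t0_s + grid.n_modulations * grid.pm_s
    if not (grid.t0_s <= apex_t1_s <= T) or not (0 <= apex_t2_s < grid.pm_s):
        raise ValueError(
            f"apex ({apex_t1_s:g} s, {apex_t2_s:g} s) outside acquisition window"
        )
    i_apex = (apex_t1_s - grid.t0_s) / grid.pm_s
    j_apex = apex_t2_s * grid.rate_hz
    si = sigma1_s / grid.pm_s        # sigma in row units
    sj = sigma2_s * grid.rate_hz     # sigma in column units
    i0 = max(0, int(math.ceil(i_apex - extent_sigmas * si)))
    i1 = min(grid.n_modulations - 1, int(math.floor(i_apex + extent_sigmas * si)))
    j0 = max(0, int(math.ceil(j_apex - extent_sigmas * sj)))
    j1 = min(grid.n_points_per_period - 1, int(math.floor(j_apex + extent_sigmas * sj)))
    ii = np.arange(i0, i1 + 1)
    jj = np.arange(j0, j1 + 1)
    amp = volume / (2 * math.pi * sigma1_s * sigma2_s)
    g1 = np.exp(-0.5 * ((ii - i_apex) / si) ** 2)
    g2 = np.exp(-0.5 * ((jj - j_apex) / sj) ** 2)
    patch = amp * np.outer(g1, g2)
    rows, cols = slice(i0, i1 + 1), slice(j0, j1 + 1)
    grid.intensities[rows, cols] += patch
    if spectrum is not None and patch.size:
        top = patch.max()
        base = spectrum.base_intensity or 1.0
        mask = patch >= spectra_fraction * top
        for di, dj in zip(*np.nonzero(mask)):
            px = (int(ii[di]), int(jj[dj]))
            contrib = spectrum.scaled(float(patch[di, dj]) / base)
            prev = grid.spectra.get(px)
            grid.spectra[px] = (
                contrib if prev is None else MassSpectrum.combine([prev, contrib])
            )
    return rows, cols, patch


def make_alkane_ladder(config: SyntheticStudyConfig) -> RICalibration:
    """n-C9…n-C25 ladder spanning the acquisition with mild curvature."""
    n = np.arange(9, 26)
    x = (n - 9) / 16.0
    t_start = 0.08 * config.run_time_s
    t_end = 0.94 * config.run_time_s
    t = t_start + (t_end - t_start) * (x + 0.12 * x * (1 - x))
    return RICalibration(n, t)


def _place_apexes(
    rng: np.random.Generator,
    config: SyntheticStudyConfig,
    ladder: RICalibration,
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Rejection-sample resolvable apex positions plus the two IS apexes."""
    span = ladder.t_max - ladder.t_min
    istd = [
        (ladder.t_min + 0.30 * span, 1.20),
        (ladder.t_min + 0.65 * span, 2.60),
    ]
    margin = 4.0 * config.sigma1_s
    lo = ladder.t_min + 2.0
    hi = ladder.t_max - 2.0
    if hi - lo < margin:
        raise ValueError("acquisition window too small for any compound")
    # resolvable placement: elliptical separation in peak-width units, so the
    # 10%-height contours of neighbors stay disjoint even diagonally
    s1, s2 = config.sigma1_s, config.sigma2_s
    min_sep, istd_sep = 6.5, 9.0

    def _near(t1, t2, p1, p2, sep):
        return ((t1 - p1) / s1) ** 2 + ((t2 - p2) / s2) ** 2 < sep**2

    placed: list[tuple[float, float]] = []
    for c in range(config.n_compounds):
        ok = False
        for _ in range(4000):
            t1 = float(rng.uniform(lo, hi))
            t2 = float(rng.uniform(0.5, 3.5))
            clash = any(
                _near(t1, t2, p1, p2, min_sep) for p1, p2 in placed
            ) or any(
                _near(t1, t2, p1, p2, istd_sep) for p1, p2 in istd
            )
            if not clash:
                placed.append((t1, t2))
                ok = True
                break
        if not ok:
            raise ValueError(
                f"acquisition window too small: compound index {c} "
                f"(of {config.n_compounds}) does not fit"
            )
    return placed, istd


def sample_ground_truth(
    config: SyntheticStudyConfig,
) -> tuple[GroundTruth, pd.DataFrame, SpectralLibrary, RICalibration]:
    """Draw the study's ground truth without rendering chromatograms.

    Returns (ground truth, sample metadata, spectral library with ladder-
    consistent tabulated I^T, alkane ladder).  :func:`generate_study` renders
    grids on top of exactly this truth.
    """
    rng = np.random.default_rng(config.seed)
    ladder = make_alkane_ladder(config)
    library = generate_library(config.n_compounds, config.seed)
    apexes, istd_apexes = _place_apexes(rng, config, ladder)

    # internal standards: fixed apexes, distinctive spectra, constant response
    istd_entries = []
    for name, seed_off in zip(ISTD_NAMES, (10_001, 10_002)):
        lib1 = generate_library(1, config.seed + seed_off)
        e = lib1.entries[0]
        istd_entries.append(LibraryEntry(name=name, spectrum=e.spectrum, casno=e.casno, ri=None))

    names = [e.name for e in library.entries]
    rows = []
    snr_lo, snr_hi = config.snr_range
    discriminant = set(rng.choice(config.n_compounds, size=config.n_discriminant, replace=False).tolist())
    for k, (entry, (t1, t2)) in enumerate(zip(library.entries, apexes)):
        ri_true = compute_ri(t1, ladder)
        it_tab = float(np.round(ri_true + np.clip(rng.normal(0, 4), -12, 12)))
        entry.ri = it_tab
        snr = float(np.exp(rng.uniform(np.log(snr_lo), np.log(snr_hi))))
        height = snr * config.noise_sd
        base_volume = height * 2 * math.pi * config.sigma1_s * config.sigma2_s
        rows.append(
            {
                "name": entry.name, "rt1_s": t1, "rt2_s": t2,
                "ri_tab": it_tab, "target_snr": snr,
                "base_volume": base_volume,
                "discriminant": k in discriminant,
                "direction": int(rng.choice([-1, 1])) if k in discriminant else 0,
                "is_istd": False,
            }
        )
    for entry, (t1, t2) in zip(istd_entries, istd_apexes):
        ri_true = compute_ri(t1, ladder)
        entry.ri = float(np.round(ri_true))
        height = 300.0 * config.noise_sd
        rows.append(
            {
                "name": entry.name, "rt1_s": t1, "rt2_s": t2,
                "ri_tab": entry.ri, "target_snr": 300.0,
                "base_volume": height * 2 * math.pi * config.sigma1_s * config.sigma2_s,
                "discriminant": False, "direction": 0, "is_istd": True,
            }
        )
    compounds = pd.DataFrame(rows).set_index("name")
    full_library = SpectralLibrary(library.entries + istd_entries)

    sample_ids = []
    meta_rows = []
    for arm, tp in config.groups:
        for k in range(config.n_samples_per_group):
            sid = f"{arm}_{tp}_{k:02d}"
            sample_ids.append(sid)
            meta_rows.append({"sample_id": sid, "arm": arm, "timepoint": tp})
    metadata = pd.DataFrame(meta_rows)

    fc = 2.0 ** config.effect_log2fc
    vol = np.zeros((len(sample_ids), len(compounds)))
    for s, sid in enumerate(sample_ids):
        arm = metadata.loc[s, "arm"]
        for c, (cname, crow) in enumerate(compounds.iterrows()):
            v = crow.base_volume
            if crow.is_istd:
                vol[s, c] = v  # constant true response
                continue
            if crow.discriminant and arm == "VP1":
                v = v * fc ** crow.direction
            vol[s, c] = v * float(np.exp(rng.normal(0.0, config.biological_sigma)))
    volumes = pd.DataFrame(vol, index=pd.Index(sample_ids, name="sample_id"), columns=compounds.index)

    drift = pd.DataFrame(
        {
            "d1_coeff_s": rng.uniform(-1, 1, len(sample_ids)) * config.drift_1d_max,
            "d2_offset_s": rng.uniform(-1, 1, len(sample_ids)) * config.drift_2d_max,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    gt = GroundTruth(compounds, volumes, drift, ISTD_NAMES, config)
    return gt, metadata, full_library, ladder


def generate_study(config: SyntheticStudyConfig) -> StudyData:
    """Render the full synthetic study: one chromatogram per sample.

    Discriminant compounds differ in group-mean volume by ``effect_log2fc``
    between arms; each grid holds the two internal standards, per-sample
    retention drift applied to every apex, and additive Gaussian baseline
    noise of standard deviation ``noise_sd`` on a small positive offset.
    """
    gt, metadata, library, ladder = sample_ground_truth(config)
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31))
    spec_by_name = {e.name: e.spectrum for e in library.entries}
    offset = 8.0 * config.noise_sd

    grids: list[ChromatogramGrid] = []
    for sid in gt.volumes.index:
        base = offset + rng.normal(0.0, config.noise_sd, (config.n_modulations, int(round(config.pm_s * config.rate_hz))))
        grid = ChromatogramGrid(base, config.pm_s, config.rate_hz, 0.0, sample_id=sid)
        for cname, crow in gt.compounds.iterrows():
            t1, t2 = gt.apply_drift(sid, float(crow.rt1_s), float(crow.rt2_s))
            t2 = float(np.clip(t2, 0.0, config.pm_s - 1e-9))
            render_peak(
                grid, t1, t2, float(gt.volumes.loc[sid, cname]),
                spec_by_name[cname], config.sigma1_s, config.sigma2_s,
            )
        grids.append(grid)

    alk = ChromatogramGrid(
        offset + rng.normal(0.0, config.noise_sd, (config.n_modulations, int(round(config.pm_s * config.rate_hz)))),
        config.pm_s, config.rate_hz, 0.0, sample_id="alkane_ladder",
    )
    alk_vol = 400.0 * config.noise_sd * 2 * math.pi * config.sigma1_s * config.sigma2_s
    alkane_spec = MassSpectrum(np.array([43, 57, 71, 85]), np.array([999.0, 850.0, 500.0, 250.0]))
    for t in ladder.times_s:
        render_peak(alk, float(t), 1.0, alk_vol, alkane_spec, config.sigma1_s, config.sigma2_s)

    return StudyData(grids, alk, ladder, library, gt, metadata)


def write_study(study: StudyData, outdir: str | Path) -> None:
    """Write a study to disk: grid containers, MSP library, alkanes CSV,
    metadata CSV and ground-truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for g in study.grids:
        write_grid(g, out / g.sample_id)
    write_grid(study.alkane_grid, out / "alkane_ladder")
    write_msp(study.library, out / "library.msp")
    pd.DataFrame(
        {"carbon_number": study.ladder.carbon_numbers, "t_r_seconds": study.ladder.times_s}
    ).to_csv(out / "alkanes.csv", index=False)
    study.metadata.to_csv(out / "metadata.csv", index=False)
    gt = study.ground_truth
    truth = {
        "config": asdict(gt.config),
        "istd_names": list(gt.istd_names),
        "compounds": gt.compounds.reset_index().to_dict(orient="records"),
        "volumes": gt.volumes.reset_index().to_dict(orient="records"),
        "drift": gt.drift.reset_index().to_dict(orient="records"),
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1, default=float))
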