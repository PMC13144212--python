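"""Data model and I/O for comprehensive two-dimensional (GC×GC) chromatograms.

A GC×GC detector produces a single long signal trace; the modulator re-injects
first-column effluent every ``P_M`` seconds, so the trace folds into a 2D grid
whose rows are modulation events (first-dimension retention, ``^1t_R``) and
whose columns are positions within one modulation period (second-dimension
retention, ``^2t_R``).  Conventionally ``^1t_R`` is reported in minutes and
``^2t_R`` in seconds.

The on-disk interchange container is deliberately plain text: a ``*.meta.json``
header, a ``*.grid.csv`` intensity matrix, and an optional ``*.spectra.msp``
sidecar holding sparse per-pixel mass spectra in NIST MSP dialect keyed by
pixel index.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MassSpectrum",
    "ChromatogramGrid",
    "LibraryEntry",
    "SpectralLibrary",
    "wrap_signal",
    "unwrap_signal",
    "read_grid",
    "write_grid",
    "read_msp",
    "write_msp",
]

BASE_PEAK = 999.0


@dataclass(frozen=True)
class MassSpectrum:
    """A centroided (stick) mass spectrum with integer m/z values.

    m/z values are strictly increasing; intensities are non-negative.  A
    *normalized* spectrum has its base (most intense) peak scaled to 999,
    the NIST library convention.
    """

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=int)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.ndim != 1 or inten.ndim != 1 or mz.size != inten.size:
            raise ValueError("mz and intensity must be 1D arrays of equal length")
        if mz.size and np.any(np.diff(mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def base_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0

    def normalized(self) -> "MassSpectrum":
        """Return a copy with the base peak scaled to 999."""
        top = self.base_intensity
        if top <= 0:
            return self
        return MassSpectrum(self.mz, self.intensity * (BASE_PEAK / top))

    def scaled(self, k: float) -> "MassSpectrum":
        if k < 0:
            raise ValueError("scale factor must be non-negative")
        return MassSpectrum(self.mz, self.intensity * k)

    @staticmethod
    def combine(spectra: list["MassSpectrum"]) -> "MassSpectrum":
        """Linear sum of spectra on the union m/z axis (co-elution model)."""
        if not spectra:
            raise ValueError("need at least one spectrum")
        acc: dict[int, float] = {}
        for s in spectra:
            for m, i in zip(s.mz, s.intensity):
                acc[int(m)] = acc.get(int(m), 0.0) + float(i)
        mz = np.array(sorted(acc), dtype=int)
        return MassSpectrum(mz, np.array([acc[m] for m in mz]))

    @staticmethod
    def median_consensus(spectra: list["MassSpectrum"]) -> "MassSpectrum":
        """Per-m/z intensity median across normalized spectra, renormalized.

        Used to build a template feature's consensus spectrum; m/z absent from
        a contributing spectrum counts as zero intensity.
        """
        if not spectra:
            raise ValueError("need at least one spectrum")
        normed = [s.normalized() for s in spectra]
        all_mz = sorted({int(m) for s in normed for m in s.mz})
        stack = np.zeros((len(normed), len(all_mz)))
        index = {m: k for k, m in enumerate(all_mz)}
        for row, s in enumerate(normed):
            for m, i in zip(s.mz, s.intensity):
                stack[row, index[int(m)]] = i
        med = np.median(stack, axis=0)
        keep = med > 0
        if not keep.any():  # degenerate: all-zero consensus
            return MassSpectrum(np.array(all_mz), med)
        return MassSpectrum(np.array(all_mz)[keep], med[keep]).normalized()


@dataclass
class ChromatogramGrid:
    """A GC×GC chromatogram as a 2D intensity grid.

    ``intensities[i, j]`` is the detector response of the ``j``-th point inside
    the ``i``-th modulation period.  ``^1t_R`` of row ``i`` is the period start
    time ``t0_s + i * pm_s`` (start-time convention, 0-based); ``^2t_R`` of
    column ``j`` is ``j / rate_hz`` seconds.
    """

    intensities: np.ndarray
    pm_s: float
    rate_hz: float
    t0_s: float = 0.0
    sample_id: str = ""
    spectra: dict[tuple[int, int], MassSpectrum] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2D array")
        if self.pm_s <= 0:
            raise ValueError("modulation period pm_s must be positive")
        if self.rate_hz <= 0:
            raise ValueError("acquisition rate rate_hz must be positive")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        n_pp = int(round(self.pm_s * self.rate_hz))
        if self.intensities.shape[1] != n_pp:
            raise ValueError(
                f"grid has {self.intensities.shape[1]} points per period, "
                f"expected round(pm_s * rate_hz) = {n_pp}"
            )

    @property
    def n_modulations(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points_per_period(self) -> int:
        return self.intensities.shape[1]

    @property
    def pixel_area_s2(self) -> float:
        """Area of one pixel in retention space (s^2): P_M × detector step."""
        return self.pm_s / self.rate_hz

    def rt1_min(self, i: np.ndarray | float) -> np.ndarray | float:
        """First-dimension retention (minutes) of modulation index i."""
        return (self.t0_s + np.asarray(i, dtype=float) * self.pm_s) / 60.0

    def rt2_s(self, j: np.ndarray | float) -> np.ndarray | float:
        """Second-dimension retention (seconds) of in-period index j."""
        return np.asarray(j, dtype=float) / self.rate_hz

    def pixel_of(self, t1_s: float, t2_s: float) -> tuple[int, int]:
        """Nearest pixel for a (first-dim seconds, second-dim seconds) point."""
        i = int(round((t1_s - self.t0_s) / self.pm_s))
        j = int(round(t2_s * self.rate_hz))
        return i, j


def wrap_signal(
    signal: np.ndarray,
    pm_s: float,
    rate_hz: float,
    t0_s: float = 0.0,
    *,
    sample_id: str = "",
    pad: str | None = None,
) -> ChromatogramGrid:
    """Fold a 1D detector trace into a GC×GC grid by the modulation period.

    ``intensities[i, j] = signal[i * n_pp + j]`` with ``n_pp = round(pm_s *
    rate_hz)``.  If the trace length is not a multiple of ``n_pp``, the
    trailing partial modulation is dropped with a warning, or zero-padded when
    ``pad='zero'``; any other value raises.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    n_pp = int(round(pm_s * rate_hz))
    if n_pp <= 0:
        raise ValueError("pm_s * rate_hz must round to a positive point count")
    rem = signal.size % n_pp
    if rem:
        if pad is None:
            warnings.warn(
                f"signal length {signal.size} not divisible by {n_pp}; "
                "dropping trailing partial modulation",
                stacklevel=2,
            )
            signal = signal[: signal.size - rem]
        elif pad == "zero":
            signal = np.concatenate([signal, np.zeros(n_pp - rem)])
        else:
            raise ValueError(
                f"signal length {signal.size} is not a multiple of {n_pp} "
                "points per period (pass pad='zero' to pad)"
            )
    grid = signal.reshape(-1, n_pp)
    return ChromatogramGrid(grid, pm_s, rate_hz, t0_s, sample_id=sample_id)


def unwrap_signal(grid: ChromatogramGrid) -> np.ndarray:
    """Inverse of :func:`wrap_signal`: flatten the grid back to a 1D trace."""
    return grid.intensities.ravel().copy()


# ---------------------------------------------------------------------------
# Grid container I/O: *.meta.json + *.grid.csv + optional *.spectra.msp
# ---------------------------------------------------------------------------

def _paths(prefix: str | Path) -> tuple[Path, Path, Path]:
    prefix = Path(prefix)
    return (
        prefix.with_suffix(".meta.json"),
        prefix.with_suffix(".grid.csv"),
        prefix.with_suffix(".spectra.msp"),
    )


def write_grid(grid: ChromatogramGrid, prefix: str | Path) -> None:
    """Write a grid container under ``prefix`` (three sibling text files)."""
    meta_p, grid_p, spec_p = _paths(prefix)
    meta_p.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "sample_id": grid.sample_id,
        "pm_s": grid.pm_s,
        "rate_hz": grid.rate_hz,
        "t0_s": grid.t0_s,
        "n_modulations": grid.n_modulations,
        "n_points_per_period": grid.n_points_per_period,
    }
    meta_p.write_text(json.dumps(meta, indent=1))
    np.savetxt(grid_p, grid.intensities, fmt="%.8g", delimiter=",")
    if grid.spectra:
        lib = SpectralLibrary(
            [
                LibraryEntry(name=f"pixel_{i}_{j}", spectrum=s)
                for (i, j), s in sorted(grid.spectra.items())
            ]
        )
        write_msp(lib, spec_p, renormalize=False)
    elif spec_p.exists():
        spec_p.unlink()


def read_grid(prefix: str | Path) -> ChromatogramGrid:
    """Read a grid container written by :func:`write_grid`."""
    meta_p, grid_p, spec_p = _paths(prefix)
    try:
        meta = json.loads(meta_p.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed grid header {meta_p}: {exc}") from exc
    for key in ("pm_s", "rate_hz", "t0_s"):
        if key not in meta:
            raise ValueError(f"grid header {meta_p} is missing field '{key}'")
    if meta["pm_s"] <= 0:
        raise ValueError(f"grid header {meta_p}: pm_s must be positive")
    intensities = np.loadtxt(grid_p, delimiter=",", ndmin=2)
    spectra: dict[tuple[int, int], MassSpectrum] = {}
    if spec_p.exists():
        for entry in read_msp(spec_p, renormalize=False).entries:
            tag = entry.name
            if not tag.startswith("pixel_"):
                raise ValueError(f"{spec_p}: unexpected spectrum key '{tag}'")
            _, i, j = tag.split("_")
            spectra[(int(i), int(j))] = entry.spectrum
    return ChromatogramGrid(
        intensities,
        pm_s=float(meta["pm_s"]),
        rate_hz=float(meta["rate_hz"]),
        t0_s=float(meta["t0_s"]),
        sample_id=str(meta.get("sample_id", "")),
        spectra=spectra,
    )


# ---------------------------------------------------------------------------
# NIST MSP text libraries
# ---------------------------------------------------------------------------

@dataclass
class LibraryEntry:
    """One reference compound: a named spectrum plus optional CAS and I^T."""

    name: str
    spectrum: MassSpectrum
    casno: str | None = None
    ri: float | None = None


@dataclass
class SpectralLibrary:
    entries: list[LibraryEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_name(self, name: str) -> LibraryEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)


def write_msp(
    library: SpectralLibrary, path: str | Path, *, renormalize: bool = True
) -> None:
    """Write a library in the NIST MSP text dialect."""
    lines: list[str] = []
    for e in library.entries:
        spec = e.spectrum.normalized() if renormalize else e.spectrum
        lines.append(f"Name: {e.name}")
        if e.casno is not None:
            lines.append(f"CASNO: {e.casno}")
        if e.ri is not None:
            lines.append(f"RI: {e.ri:g}")
        lines.append(f"Num Peaks: {len(spec)}")
        pairs = [f"{int(m)} {i:g};" for m, i in zip(spec.mz, spec.intensity)]
        for k in range(0, len(pairs), 5):
            lines.append(" ".join(pairs[k : k + 5]))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_msp(path: str | Path, *, renormalize: bool = True) -> SpectralLibrary:
    """Parse a NIST MSP text library.

    Recognizes ``Name:``, ``CASNO:``, ``RI:`` and ``Num Peaks:`` headers
    followed by whitespace/semicolon-separated ``mz intensity`` pairs.  By
    default intensities are renormalized to base peak 999 on read.
    """
    entries: list[LibraryEntry] = []
    name: str | None = None
    casno: str | None = None
    ri: float | None = None
    n_peaks: int | None = None
    tokens: list[str] = []

    def flush() -> None:
        nonlocal name, casno, ri, n_peaks, tokens
        if name is None:
            return
        if n_peaks is None:
            raise ValueError(f"entry '{name}': missing 'Num Peaks' header")
        if len(tokens) % 2:
            raise ValueError(f"entry '{name}': odd number of peak values")
        pairs = [
            (int(float(tokens[k])), float(tokens[k + 1]))
            for k in range(0, len(tokens), 2)
        ]
        if len(pairs) != n_peaks:
            raise ValueError(
                f"entry '{name}': Num Peaks says {n_peaks} but "
                f"{len(pairs)} pairs were found"
            )
        pairs.sort(key=lambda p: p[0])
        spec = MassSpectrum(
            np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs])
        )
        if renormalize:
            spec = spec.normalized()
        entries.append(LibraryEntry(name=name, spectrum=spec, casno=casno, ri=ri))
        name, casno, ri, n_peaks, tokens = None, None, None, None, []

    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        low = line.lower()
        if low.startswith("name:"):
            flush()
            name = line.split(":", 1)[1].strip()
        elif low.startswith("casno:") or low.startswith("cas#:"):
            casno = line.split(":", 1)[1].strip()
        elif low.startswith("ri:") or low.startswith("retentionindex:"):
            ri = float(line.split(":", 1)[1].strip())
        elif low.startswith("num peaks:"):
            n_peaks = int(line.split(":", 1)[1].strip())
        elif ":" in line and not line[0].isdigit():
            continue  # unknown header, tolerated
        else:
            if name is None:
                raise ValueError(f"{path}:{lineno}: peak data before any Name:")
            tokens.extend(line.replace(";", " ").split())
    flush()
    return SpectralLibrary(entries)
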