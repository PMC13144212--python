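"""Spectral similarity, linear retention indices, and the targeted gate.

Similarity follows the NIST identity-search convention: sticks are weighted by
``w(m, I) = I**0.6 * m**3`` (intensity damped, high masses emphasized) and two
spectra are compared by the squared cosine of their weighted vectors, scaled to
0–999.  The direct match factor (DMF) uses the full query spectrum; the reverse
match factor (RMF) first discards query ions absent from the library spectrum,
so contaminant ions in the query do not penalize the comparison — hence
RMF ≥ DMF always.

Retention indexing uses the van den Dool–Kratz linear form for
temperature-programmed runs: between bracketing n-alkanes with carbon numbers
``n`` and ``n+1``,

    I^T = 100*n + 100 * (t_r - t_n) / (t_{n+1} - t_n).

A peak is *targeted* when DMF ≥ 950, RMF ≥ 950 and its experimental I^T falls
within ±20 index units of the library's tabulated value; when only the
spectral gates pass, the compound class alone is considered trustworthy
(*class_only*).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chromatogram import MassSpectrum, SpectralLibrary

__all__ = [
    "MatchResult",
    "RICalibration",
    "Annotation",
    "match_factor",
    "reverse_match_factor",
    "compute_ri",
    "annotate",
]

# Stein–Scott identity-search weighting exponents.
INTENSITY_EXPONENT = 0.6
MASS_EXPONENT = 3.0


@dataclass(frozen=True)
class MatchResult:
    dmf: int
    rmf: int
    library_entry: str

    def __post_init__(self) -> None:
        if not (0 <= self.dmf <= 999 and 0 <= self.rmf <= 999):
            raise ValueError("match factors must lie in [0, 999]")


def _weighted(spec: MassSpectrum) -> dict[int, float]:
    return {
        int(m): float(i) ** INTENSITY_EXPONENT * float(m) ** MASS_EXPONENT
        for m, i in zip(spec.mz, spec.intensity)
        if i > 0
    }


def match_factor(query: MassSpectrum, lib: MassSpectrum) -> int:
    """Direct match factor: weighted squared-cosine similarity, 0–999.

    Symmetric in its arguments and invariant to scaling either spectrum.
    """
    if len(query) == 0 or len(lib) == 0:
        raise ValueError("spectra must be non-empty")
    wq = _weighted(query)
    wl = _weighted(lib)
    if not wq or not wl:
        raise ValueError("spectra must contain nonzero intensities")
    dot = sum(w * wl[m] for m, w in wq.items() if m in wl)
    nq = sum(w * w for w in wq.values())
    nl = sum(w * w for w in wl.values())
    return int(round(999.0 * dot * dot / (nq * nl)))


def reverse_match_factor(query: MassSpectrum, lib: MassSpectrum) -> int:
    """Reverse match factor: DMF after deleting query-only m/z sticks."""
    if len(query) == 0 or len(lib) == 0:
        raise ValueError("spectra must be non-empty")
    lib_mz = set(int(m) for m in lib.mz)
    keep = np.array([int(m) in lib_mz for m in query.mz], dtype=bool)
    if not keep.any():
        return 0
    trimmed = MassSpectrum(query.mz[keep], query.intensity[keep])
    if trimmed.base_intensity <= 0:
        return 0
    return match_factor(trimmed, lib)


def match_against(query: MassSpectrum, library: SpectralLibrary) -> MatchResult:
    """Best library hit by DMF; ties broken by RMF then entry order."""
    if len(library) == 0:
        raise ValueError("library is empty")
    best: MatchResult | None = None
    for entry in library:
        dmf = match_factor(query, entry.spectrum)
        rmf = reverse_match_factor(query, entry.spectrum)
        cand = MatchResult(dmf, rmf, entry.name)
        if best is None or (cand.dmf, cand.rmf) > (best.dmf, best.rmf):
            best = cand
    return best


@dataclass(frozen=True)
class RICalibration:
    """Alkane-ladder calibration: (carbon number, retention time in seconds).

    The synthetic studies ladder n-C9 through n-C25; retention times must be
    strictly increasing with carbon number.
    """

    carbon_numbers: np.ndarray
    times_s: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.carbon_numbers, dtype=int)
        t = np.asarray(self.times_s, dtype=float)
        if n.size != t.size or n.size < 2:
            raise ValueError("ladder needs >= 2 (carbon, time) pairs")
        order = np.argsort(n)
        n, t = n[order], t[order]
        if np.any(np.diff(n) <= 0):
            raise ValueError("carbon numbers must be distinct")
        if np.any(np.diff(t) <= 0):
            raise ValueError("ladder times must increase with carbon number")
        object.__setattr__(self, "carbon_numbers", n)
        object.__setattr__(self, "times_s", t)

    @classmethod
    def from_dataframe(cls, df) -> "RICalibration":
        return cls(
            df["carbon_number"].to_numpy(), df["t_r_seconds"].to_numpy()
        )

    @property
    def t_min(self) -> float:
        return float(self.times_s[0])

    @property
    def t_max(self) -> float:
        return float(self.times_s[-1])


def compute_ri(
    t_r_s: float, ladder: RICalibration, *, extrapolate: bool = False
) -> float:
    """Van den Dool–Kratz linear retention index of a first-dimension time.

    Raises ``ValueError`` outside the ladder span unless ``extrapolate`` is
    set, in which case the terminal bracket's slope is extended.
    """
    n = ladder.carbon_numbers
    t = ladder.times_s
    if not extrapolate and not (t[0] <= t_r_s <= t[-1]):
        raise ValueError(
            f"retention time {t_r_s:g} s outside alkane ladder "
            f"[{t[0]:g}, {t[-1]:g}] s (extrapolation disabled)"
        )
    k = int(np.clip(np.searchsorted(t, t_r_s, side="right") - 1, 0, t.size - 2))
    # Within a bracket the index is linear in time; carbon steps may exceed 1.
    span_n = n[k + 1] - n[k]
    return float(100.0 * n[k] + 100.0 * span_n * (t_r_s - t[k]) / (t[k + 1] - t[k]))


@dataclass
class Annotation:
    """Identification outcome for one detected peak.

    status is ``targeted`` (all gates pass), ``class_only`` (spectral gates
    pass, retention-index gate fails), or ``unannotated``.
    """

    peak_id: str
    compound: str
    dmf: int
    rmf: int
    it_exp: float | None
    it_tab: float | None
    status: str


def gate_status(
    dmf: float,
    rmf: float,
    it_exp: float | None,
    it_tab: float | None,
    *,
    dmf_min: float = 950,
    rmf_min: float = 950,
    ri_tol: float = 20,
) -> str:
    """Pure threshold logic for the targeted-annotation gate."""
    if dmf < dmf_min or rmf < rmf_min:
        return "unannotated"
    if it_exp is None or it_tab is None or abs(it_exp - it_tab) > ri_tol:
        return "class_only"
    return "targeted"


def annotations_to_dataframe(annotations: list["Annotation"]):
    """Annotation table with the usual report columns (one row per peak)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "peak_id": [a.peak_id for a in annotations],
            "compound": [a.compound for a in annotations],
            "dmf": [a.dmf for a in annotations],
            "rmf": [a.rmf for a in annotations],
            "it_exp": [a.it_exp for a in annotations],
            "it_tab": [a.it_tab for a in annotations],
            "status": [a.status for a in annotations],
        }
    )


def annotate(
    peaks,
    library: SpectralLibrary,
    ladder: RICalibration,
    *,
    dmf_min: float = 950,
    rmf_min: float = 950,
    ri_tol: float = 20,
) -> list[Annotation]:
    """Annotate detected peaks against a library with the targeted gate.

    ``peaks`` is an iterable of objects with ``id``, ``apex_1t_min`` and
    ``spectrum`` attributes (see :class:`volatilofp.detection.Peak2D`).  The
    experimental I^T is computed on the first-dimension retention time only.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    out: list[Annotation] = []
    for peak in peaks:
        hit = match_against(peak.spectrum, library)
        entry = library.by_name(hit.library_entry)
        t1_s = peak.apex_1t_min * 60.0
        try:
            it_exp: float | None = compute_ri(t1_s, ladder)
        except ValueError:
            it_exp = None
        it_tab = entry.ri
        status = gate_status(
            hit.dmf, hit.rmf, it_exp, it_tab,
            dmf_min=dmf_min, rmf_min=rmf_min, ri_tol=ri_tol,
        )
        out.append(
            Annotation(
                peak_id=peak.id,
                compound=entry.name,
                dmf=hit.dmf,
                rmf=hit.rmf,
                it_exp=it_exp,
                it_tab=it_tab,
                status=status,
            )
        )
    return out
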