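"""In-memory containers for centroided MS/MS spectra.

A :class:`Spectrum` stores one centroided MS2 scan as parallel numpy arrays.
Construction canonicalizes the peak list: peaks are sorted ascending by m/z
and peaks closer than ``MERGE_TOL_DA`` (1e-6 Da) are merged by intensity sum
(intensity-weighted m/z), so downstream greedy peak matching can assume
strictly increasing, unique m/z values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Peaks within this m/z distance are treated as duplicates and merged.
MERGE_TOL_DA = 1e-6

POLARITIES = ("positive", "negative")


@dataclass
class Spectrum:
    """One centroided MS/MS scan.

    Parameters
    ----------
    scan_id:
        Opaque unique identifier.
    precursor_mz:
        Precursor m/z in Th; must be positive.
    polarity:
        ``"positive"`` or ``"negative"``; required before query evaluation.
    mz, intensity:
        Parallel peak arrays (Da / arbitrary counts).  Canonicalized on
        construction (sorted, duplicates merged, non-negative intensities).
    retention_time:
        Optional retention time in seconds.
    charge:
        Absolute precursor charge; defaults to 1 (neutral-loss arithmetic
        assumes singly charged precursors).
    source_file:
        Provenance string.
    metadata:
        Free-form annotations (compound name, consensus membership, ...).
    """

    scan_id: str
    precursor_mz: float
    polarity: str
    mz: np.ndarray
    intensity: np.ndarray
    retention_time: float | None = None
    charge: int = 1
    source_file: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}, got {self.polarity!r}")
        if not self.precursor_mz > 0:
            raise ValueError(f"precursor_mz must be positive, got {self.precursor_mz}")
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(mz <= 0):
            raise ValueError("all peak m/z values must be positive")
        if np.any(inten < 0):
            raise ValueError("peak intensities must be non-negative")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if mz.size > 1 and np.any(np.diff(mz) <= MERGE_TOL_DA):
            mz, inten = _merge_duplicate_peaks(mz, inten)
        self.mz = mz
        self.intensity = inten
        self.charge = abs(int(self.charge)) if self.charge else 1

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0

    def relative_intensity(self) -> np.ndarray:
        """Intensities as percent of the base peak (base peak = 100)."""
        base = self.base_peak_intensity
        if base <= 0:
            raise ValueError(f"spectrum {self.scan_id!r} has no peak with intensity > 0")
        # divide first so the base peak maps to exactly 100.0
        return self.intensity / base * 100.0

    def copy(self, **changes) -> "Spectrum":
        out = replace(self, **changes)
        out.metadata = dict(changes.get("metadata", self.metadata))
        return out


def _merge_duplicate_peaks(mz: np.ndarray, inten: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge runs of peaks whose consecutive spacing is <= MERGE_TOL_DA."""
    group = np.zeros(mz.size, dtype=int)
    group[1:] = np.cumsum(np.diff(mz) > MERGE_TOL_DA)
    n = group[-1] + 1
    sums = np.bincount(group, weights=inten, minlength=n)
    # Intensity-weighted centroid; fall back to plain mean for all-zero runs.
    wmz = np.bincount(group, weights=inten * mz, minlength=n)
    counts = np.bincount(group, minlength=n)
    plain = np.bincount(group, weights=mz, minlength=n) / counts
    with np.errstate(invalid="ignore", divide="ignore"):
        merged_mz = np.where(sums > 0, wmz / np.where(sums > 0, sums, 1.0), plain)
    return merged_mz, sums


def normalize_intensities(spectrum: Spectrum) -> Spectrum:
    """Return a copy whose intensities are percent of the base peak (max 100).

    Raises ``ValueError`` when every intensity is zero.  Idempotent and
    invariant to uniform scaling of the raw intensities.
    """
    return spectrum.copy(intensity=spectrum.relative_intensity())


@dataclass
class SpectrumCollection:
    """Ordered list of spectra with unique scan ids and per-file provenance."""

    spectra: list[Spectrum] = field(default_factory=list)
    provenance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.scan_id for s in self.spectra]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate scan_id in collection: {dup!r}")
        if not self.provenance:
            self.provenance = {}
            for s in self.spectra:
                if s.source_file:
                    self.provenance[s.source_file] = self.provenance.get(s.source_file, 0) + 1

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, idx: int) -> Spectrum:
        return self.spectra[idx]

    def get(self, scan_id: str) -> Spectrum:
        for s in self.spectra:
            if s.scan_id == scan_id:
                return s
        raise KeyError(scan_id)

    def scan_ids(self) -> list[str]:
        return [s.scan_id for s in self.spectra]

    def subset(self, scan_ids: Sequence[str]) -> "SpectrumCollection":
        wanted = set(scan_ids)
        return SpectrumCollection([s for s in self.spectra if s.scan_id in wanted])
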