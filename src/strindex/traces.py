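"""Fragment-analyzer peak traces and their conversion to repeat-unit ladders.

A PCR across a trinucleotide repeat yields a cluster of fragment peaks spaced
one repeat unit (nominally 3 bp) apart.  This module parses tabular peak
exports (fragment size in bp, peak height in RFU) and anchors each peak to an
integer repeat offset ΔCAG relative to the constitutive "main" allele — the
tallest peak of the tail trace, the reference tissue that does not undergo
somatic expansion.  Expansions are positive Δ, contractions negative.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "PeakTrace",
    "RepeatLadder",
    "EmptyTraceError",
    "PeakTableFormatError",
    "read_peak_table",
    "read_manifest",
    "write_peak_table",
    "detect_main_allele",
    "build_ladder",
    "recalibrate_spacing",
]


class PeakTableFormatError(ValueError):
    """The peak table is missing required columns or cannot be parsed."""


class EmptyTraceError(ValueError):
    """A trace contains no usable peaks."""


class Peak(NamedTuple):
    """One fragment peak: size in base pairs, height in RFU."""

    size: float
    height: float


@dataclass(frozen=True)
class PeakTrace:
    """Ordered fragment peaks for one sample/lane.

    Peaks are stored sorted by fragment size.  ``tissue`` is a free-text
    label ("striatum", "tail", ...); ``sample_id`` identifies the lane.
    """

    sample_id: str
    tissue: str
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.peaks, key=lambda p: p.size))
        for p in ordered:
            if p.size <= 0:
                raise ValueError(f"peak size must be positive, got {p.size}")
            if p.height < 0:
                raise ValueError(f"peak height must be non-negative, got {p.height}")
        object.__setattr__(self, "peaks", ordered)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([p.size for p in self.peaks], dtype=float)

    @property
    def heights(self) -> np.ndarray:
        return np.array([p.height for p in self.peaks], dtype=float)


@dataclass(frozen=True)
class RepeatLadder:
    """Heights indexed by signed repeat offset ΔCAG from the main allele.

    ``main_allele_repeats`` is the constitutive CAG count (the tail's tallest
    peak); ``entries`` maps Δ (expansions positive) to summed peak height.
    The Δ = 0 entry may be absent from a tissue trace whose distribution has
    shifted away from the constitutive allele.
    """

    main_allele_repeats: int
    entries: dict[int, float]
    unit_spacing: float = 3.0

    def __post_init__(self) -> None:
        for delta, h in self.entries.items():
            if h < 0:
                raise ValueError(f"ladder height at Δ={delta} is negative")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def deltas(self) -> np.ndarray:
        return np.array(sorted(self.entries), dtype=int)

    @property
    def heights(self) -> np.ndarray:
        return np.array([self.entries[d] for d in sorted(self.entries)], dtype=float)

    def max_entry(self) -> tuple[int, float]:
        """(Δ, height) of the tallest rung; exact ties resolve to smaller Δ."""
        if not self.entries:
            raise EmptyTraceError("ladder has no entries")
        best = max(sorted(self.entries), key=lambda d: (self.entries[d], -d))
        return best, self.entries[best]


_DIALECTS = {
    "generic_csv": {"sep": ",", "size_col": "size", "height_col": "height"},
    "genemapper_tsv": {"sep": "\t", "size_col": "Size", "height_col": "Height"},
}


def read_peak_table(
    path: str | Path,
    dialect: str = "generic_csv",
    sample_id: str | None = None,
    tissue: str = "",
) -> PeakTrace:
    """Read a tabular peak export into a :class:`PeakTrace`.

    ``generic_csv`` expects a header ``size,height``; ``genemapper_tsv`` is
    tab-separated with ``Size``/``Height`` columns (extra columns ignored).
    Rows with missing or negative height are dropped with a logged count.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    fmt = _DIALECTS[dialect]
    try:
        table = pd.read_csv(path, sep=fmt["sep"])
    except pd.errors.EmptyDataError:
        raise EmptyTraceError(f"{path}: empty peak table") from None
    for col in (fmt["size_col"], fmt["height_col"]):
        if col not in table.columns:
            raise PeakTableFormatError(f"{path}: missing required column {col!r}")
    size = pd.to_numeric(table[fmt["size_col"]], errors="coerce")
    height = pd.to_numeric(table[fmt["height_col"]], errors="coerce")
    ok = size.notna() & height.notna() & (height >= 0) & (size > 0)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: dropped %d row(s) with missing/invalid size or height", path, n_bad)
    peaks = tuple(Peak(s, h) for s, h in zip(size[ok], height[ok]))
    if not peaks:
        raise EmptyTraceError(f"{path}: no valid peaks")
    return PeakTrace(sample_id=sample_id or path.stem, tissue=tissue, peaks=peaks)


def write_peak_table(trace: PeakTrace, path: str | Path, dialect: str = "generic_csv") -> None:
    """Write a trace in the same dialect :func:`read_peak_table` consumes."""
    fmt = _DIALECTS[dialect]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=fmt["sep"])
        writer.writerow([fmt["size_col"], fmt["height_col"]])
        for p in trace.peaks:
            writer.writerow([f"{p.size:.6g}", f"{p.height:.6g}"])


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest CSV: ``sample_id,tissue,role,path`` (+ optional ``subject_id``).

    ``role`` is ``tail`` or ``tissue``.  ``subject_id`` groups tissue rows with
    their own tail; with a single tail row and no ``subject_id`` column the
    tail serves every tissue sample.
    """
    manifest = pd.read_csv(path, dtype=str)
    required = {"sample_id", "tissue", "role", "path"}
    missing = required - set(manifest.columns)
    if missing:
        raise PeakTableFormatError(f"{path}: manifest missing columns {sorted(missing)}")
    bad_roles = set(manifest["role"]) - {"tail", "tissue"}
    if bad_roles:
        raise PeakTableFormatError(f"{path}: unknown role(s) {sorted(bad_roles)}")
    return manifest


def detect_main_allele(tail_trace: PeakTrace) -> Peak:
    """Locate the constitutive allele: the tallest peak of the tail trace.

    On an exact height tie the smallest fragment size wins, consistent with
    the constitutive allele preceding its expansion products.
    """
    if len(tail_trace) == 0:
        raise EmptyTraceError(f"{tail_trace.sample_id}: empty trace")
    return max(tail_trace.peaks, key=lambda p: (p.height, -p.size))


def build_ladder(
    trace: PeakTrace,
    main_size: float,
    main_repeats: int,
    unit_spacing: float = 3.0,
    tolerance: float = 1.0,
    recalibrate: bool = False,
) -> RepeatLadder:
    """Assign each peak an integer repeat offset Δ = round((size − main)/spacing).

    Peaks whose residual from the nearest rung exceeds ``tolerance`` bp are
    rejected (logged, not fatal).  Two peaks mapping to the same Δ — a split
    peak — have their heights summed, conserving signal.  With
    ``recalibrate=True`` a single least-squares refinement of the spacing
    (size regressed on assigned Δ) absorbs electrophoretic mobility drift
    before a final assignment pass.
    """
    if unit_spacing <= 0:
        raise ValueError("unit_spacing must be positive")
    if not tolerance < unit_spacing / 2:
        raise ValueError("tolerance must be below half the unit spacing")

    def assign(spacing: float) -> tuple[dict[int, float], int]:
        entries: dict[int, float] = {}
        rejected = 0
        for p in trace.peaks:
            delta = round((p.size - main_size) / spacing)
            residual = abs(p.size - main_size - delta * spacing)
            if residual > tolerance:
                rejected += 1
                continue
            entries[delta] = entries.get(delta, 0.0) + p.height
        return entries, rejected

    spacing = unit_spacing
    entries, rejected = assign(spacing)
    if recalibrate and len(entries) >= 2:
        spacing = recalibrate_spacing(trace, main_size, spacing, tolerance)
        entries, rejected = assign(spacing)
    if rejected:
        logger.warning(
            "%s: rejected %d peak(s) beyond ±%.2f bp of the repeat ladder",
            trace.sample_id, rejected, tolerance,
        )
    return RepeatLadder(main_allele_repeats=main_repeats, entries=entries, unit_spacing=spacing)


def recalibrate_spacing(
    trace: PeakTrace,
    main_size: float,
    unit_spacing: float = 3.0,
    tolerance: float = 1.0,
) -> float:
    """One-pass least-squares re-estimate of bp-per-repeat from accepted peaks.

    Fits size ≈ main_size + spacing·Δ through the peaks accepted under the
    nominal spacing; falls back to the nominal value when fewer than two
    distinct rungs are available or the fit degenerates.
    """
    deltas, sizes = [], []
    for p in trace.peaks:
        delta = round((p.size - main_size) / unit_spacing)
        if abs(p.size - main_size - delta * unit_spacing) <= tolerance:
            deltas.append(delta)
            sizes.append(p.size - main_size)
    deltas_arr = np.asarray(deltas, dtype=float)
    sizes_arr = np.asarray(sizes, dtype=float)
    if len(np.unique(deltas_arr)) < 2:
        return unit_spacing
    denom = float(deltas_arr @ deltas_arr)
    if denom == 0.0:
        return unit_spacing
    fitted = float(deltas_arr @ sizes_arr) / denom
    return fitted if fitted > 0 else unit_spacing
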