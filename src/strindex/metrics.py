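"""Instability metrics computed from repeat ladders.

The central statistic is the instability index: after discarding peaks below
a relative height threshold (a fixed fraction, default 20%, of the tallest
peak in the same analysis), peak heights are normalized to their sum and each
is multiplied by its signed repeat offset Δ from the constitutive main
allele; the products are summed.  The result is the mean CAG length change
from the main allele per cell.  A symmetric spread of contraction and
expansion therefore scores exactly zero, and multiplying every height by a
constant (more or less template DNA) leaves the index unchanged.

The same thresholding supports a family of companion measurements:
expansion/contraction indices (the Δ>0 and Δ<0 parts of the same sum), peak
counts, the percentage composition of contracted/unchanged/expanded signal,
the shift of the tallest tissue peak relative to the tail, and a small-pool
PCR index computed from per-molecule repeat-length frequencies anchored at
the modal length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .traces import (
    EmptyTraceError,
    PeakTrace,
    RepeatLadder,
    build_ladder,
    detect_main_allele,
    read_manifest,
    read_peak_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdConfig",
    "InstabilityProfile",
    "RepeatLengthDistribution",
    "apply_threshold",
    "instability_index",
    "expansion_contraction_indices",
    "peak_counts",
    "composition",
    "main_allele_shift",
    "small_pool_index",
    "read_small_pool_csv",
    "quantify_sample",
    "quantify_batch",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """Relative peak-height threshold: fraction of the tallest peak.

    0.20 is a conservative default that keeps only peaks with good signal
    intensity; 0.10 or 0.05 give more sensitive quantification when peak
    signals are strong.
    """

    threshold_factor: float = 0.20

    def __post_init__(self) -> None:
        if not 0 < self.threshold_factor <= 1:
            raise ValueError("threshold_factor must lie in (0, 1]")


@dataclass(frozen=True)
class InstabilityProfile:
    """The full metric family for one tissue analysis."""

    sample_id: str
    tissue: str
    instability_index: float
    expansion_index: float
    contraction_index: float
    n_contracted: int
    n_expanded: int
    pct_contracted: float
    pct_unchanged: float
    pct_expanded: float
    main_allele_shift: int
    threshold_factor: float

    def as_row(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class RepeatLengthDistribution:
    """Per-molecule CAG length counts (or frequencies), e.g. from SP-PCR.

    ``main_repeats``, when known (synthetic data), records the constitutive
    length so the distribution's exact mean Δ is recoverable.
    """

    counts: dict[int, float]
    main_repeats: int | None = None

    def __post_init__(self) -> None:
        if not self.counts or not any(v > 0 for v in self.counts.values()):
            raise ValueError("distribution needs at least one positive entry")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")

    @property
    def lengths(self) -> np.ndarray:
        return np.array(sorted(self.counts), dtype=int)

    def frequencies(self) -> dict[int, float]:
        total = sum(self.counts.values())
        return {length: c / total for length, c in sorted(self.counts.items())}

    def modal_length(self) -> int:
        """Most frequent length; exact ties resolve to the smaller length."""
        return max(sorted(self.counts), key=lambda length: (self.counts[length], -length))

    def mean_delta(self, anchor: int | None = None) -> float:
        """Frequency-weighted mean repeat change from ``anchor``.

        Defaults to the recorded constitutive length, falling back to the
        modal length when none was recorded.
        """
        if anchor is None:
            anchor = self.main_repeats if self.main_repeats is not None else self.modal_length()
        return sum(f * (length - anchor) for length, f in self.frequencies().items())


def apply_threshold(ladder: RepeatLadder, cfg: ThresholdConfig = ThresholdConfig()) -> RepeatLadder:
    """Drop rungs below ``threshold_factor`` × the ladder's own tallest rung.

    The tallest rung always survives (equality is kept), so the result is
    never empty.
    """
    if len(ladder) == 0:
        raise EmptyTraceError("cannot threshold an empty ladder")
    cutoff = cfg.threshold_factor * max(ladder.entries.values())
    kept = {d: h for d, h in ladder.entries.items() if h >= cutoff}
    return RepeatLadder(
        main_allele_repeats=ladder.main_allele_repeats,
        entries=kept,
        unit_spacing=ladder.unit_spacing,
    )


def _normalized(ladder: RepeatLadder, cfg: ThresholdConfig) -> tuple[np.ndarray, np.ndarray]:
    """(Δ, normalized height) over above-threshold rungs; weights sum to 1."""
    kept = apply_threshold(ladder, cfg)
    deltas = kept.deltas
    heights = kept.heights
    return deltas, heights / heights.sum()


def instability_index(ladder: RepeatLadder, cfg: ThresholdConfig = ThresholdConfig()) -> float:
    """Mean CAG change from the main allele per cell: Σ_Δ (h_Δ/Σh)·Δ.

    Defined as expansion_index + contraction_index, each an exactly rounded
    sum, so additivity holds to the bit and a height-symmetric ladder scores
    exactly zero.
    """
    expansion, contraction = expansion_contraction_indices(ladder, cfg)
    return expansion + contraction


def expansion_contraction_indices(
    ladder: RepeatLadder, cfg: ThresholdConfig = ThresholdConfig()
) -> tuple[float, float]:
    """Δ>0 and Δ<0 parts of the index, over a shared denominator.

    Both terms normalize by the sum over ALL above-threshold rungs, so
    expansion_index + contraction_index == instability_index exactly.
    """
    deltas, weights = _normalized(ladder, cfg)
    expansion = math.fsum(w * d for d, w in zip(deltas, weights) if d > 0)
    contraction = math.fsum(w * d for d, w in zip(deltas, weights) if d < 0)
    return expansion, contraction


def peak_counts(
    ladder: RepeatLadder, cfg: ThresholdConfig = ThresholdConfig()
) -> tuple[int, int]:
    """(n_contracted, n_expanded): above-threshold rungs with Δ<0 and Δ>0."""
    deltas, _ = _normalized(ladder, cfg)
    return int((deltas < 0).sum()), int((deltas > 0).sum())


def composition(
    ladder: RepeatLadder, cfg: ThresholdConfig = ThresholdConfig()
) -> tuple[float, float, float]:
    """Percentages of above-threshold signal at Δ<0, Δ=0, Δ>0; sums to 100."""
    deltas, weights = _normalized(ladder, cfg)
    pct_contracted = 100.0 * float(weights[deltas < 0].sum())
    pct_unchanged = 100.0 * float(weights[deltas == 0].sum())
    pct_expanded = 100.0 * float(weights[deltas > 0].sum())
    return pct_contracted, pct_unchanged, pct_expanded


def main_allele_shift(
    tissue_ladder: RepeatLadder,
    cfg: ThresholdConfig = ThresholdConfig(),
    tail_ladder: RepeatLadder | None = None,
) -> int:
    """Δ of the tissue's tallest above-threshold rung (ties → smaller Δ).

    Because the ladder is anchored to the tail's main allele, this is the
    shift of the tissue's major allele relative to the constitutive one; 0
    means no shift, +1 a one-repeat gain.  If a ``tail_ladder`` is supplied
    its own tallest rung is checked to sit at Δ = 0.
    """
    if tail_ladder is not None:
        tail_mode, _ = apply_threshold(tail_ladder, cfg).max_entry()
        if tail_mode != 0:
            logger.warning("tail ladder's tallest rung is at Δ=%d, not 0", tail_mode)
    shifted, _ = apply_threshold(tissue_ladder, cfg).max_entry()
    return shifted


def small_pool_index(dist: RepeatLengthDistribution) -> float:
    """Instability index from per-molecule repeat-length frequencies.

    Frequencies are normalized to sum 1 and each is multiplied by the signed
    repeat change from the modal length; the products are summed.
    """
    return dist.mean_delta(anchor=dist.modal_length())


def read_small_pool_csv(path: str | Path) -> RepeatLengthDistribution:
    """Read a two-column CSV ``cag_length,count``."""
    table = pd.read_csv(path)
    for col in ("cag_length", "count"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    counts: dict[int, float] = {}
    for length, c in zip(table["cag_length"], table["count"]):
        counts[int(length)] = counts.get(int(length), 0.0) + float(c)
    return RepeatLengthDistribution(counts=counts)


def quantify_sample(
    tissue_trace: PeakTrace,
    tail_trace: PeakTrace,
    main_repeats: int,
    cfg: ThresholdConfig = ThresholdConfig(),
    unit_spacing: float = 3.0,
    tolerance: float = 1.0,
    recalibrate: bool = False,
) -> InstabilityProfile:
    """Full per-sample pipeline: tail main allele → ladder → metric family.

    The tail trace is thresholded with the same factor before main-allele
    detection (harmless — the tallest peak always survives — but uniform),
    the tissue ladder is anchored to the tail's main allele, and the
    threshold is then computed from the tissue ladder's own tallest rung.
    """
    tail_kept = [
        p for p in tail_trace.peaks
        if p.height >= cfg.threshold_factor * max(q.height for q in tail_trace.peaks)
    ]
    main = detect_main_allele(PeakTrace(tail_trace.sample_id, tail_trace.tissue, tuple(tail_kept)))
    ladder = build_ladder(
        tissue_trace, main.size, main_repeats,
        unit_spacing=unit_spacing, tolerance=tolerance, recalibrate=recalibrate,
    )
    index = instability_index(ladder, cfg)
    expansion, contraction = expansion_contraction_indices(ladder, cfg)
    n_con, n_exp = peak_counts(ladder, cfg)
    pct_con, pct_unc, pct_exp = composition(ladder, cfg)
    shift = main_allele_shift(ladder, cfg)
    return InstabilityProfile(
        sample_id=tissue_trace.sample_id,
        tissue=tissue_trace.tissue,
        instability_index=index,
        expansion_index=expansion,
        contraction_index=contraction,
        n_contracted=n_con,
        n_expanded=n_exp,
        pct_contracted=pct_con,
        pct_unchanged=pct_unc,
        pct_expanded=pct_exp,
        main_allele_shift=shift,
        threshold_factor=cfg.threshold_factor,
    )


def quantify_batch(
    manifest_path: str | Path,
    main_repeats: int,
    cfg: ThresholdConfig = ThresholdConfig(),
    unit_spacing: float = 3.0,
    tolerance: float = 1.0,
    dialect: str = "generic_csv",
) -> pd.DataFrame:
    """Quantify every tissue sample in a manifest against its tail.

    Tissue rows pair with the tail row sharing their ``subject_id``; with a
    single tail and no ``subject_id`` column, that tail serves all samples.
    A tissue sample without a tail is a fatal error naming the sample.
    """
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    has_subject = "subject_id" in manifest.columns
    tails = manifest[manifest["role"] == "tail"]
    tissues = manifest[manifest["role"] == "tissue"]

    def tail_for(row: pd.Series) -> pd.Series:
        if has_subject:
            matches = tails[tails["subject_id"] == row["subject_id"]]
        else:
            matches = tails
        if len(matches) == 0:
            raise ValueError(f"no tail sample paired with {row['sample_id']!r}")
        if len(matches) > 1:
            raise ValueError(f"ambiguous tail pairing for {row['sample_id']!r}")
        return matches.iloc[0]

    def load(row: pd.Series) -> PeakTrace:
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        return read_peak_table(p, dialect=dialect, sample_id=row["sample_id"], tissue=row["tissue"])

    rows = []
    for _, row in tissues.iterrows():
        tail_row = tail_for(row)
        profile = quantify_sample(
            load(row), load(tail_row), main_repeats,
            cfg=cfg, unit_spacing=unit_spacing, tolerance=tolerance,
        )
        rows.append(profile.as_row())
    return pd.DataFrame(rows)
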