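"""Meiotic crossover (MCO) detection from per-cell phase switches.

For one cell and one chromosome, every phased fragment on which the cell was
observed contributes one point to the cell's phase track: the cell is on
haplotype A at that point when (fragment phased A and consensus bit 1) or
(fragment phased B and consensus bit 0), else on B. A crossover is a switch in
the run-length encoding of that track; a switch only counts when the new phase
persists for at least ``min_run`` consecutive informative points, which
suppresses single-point flickers from amplification errors (``min_run=1``
reproduces the literal switch rule with no smoothing).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .barcode import BarcodeProfile
from .errors import InputError
from .phase import HAP_A, HAP_B, UNPHASED, PhaseCall


@dataclass
class PhaseTrack:
    """Ordered (position, cell phase) points of one cell on one chromosome."""

    cell: int
    chromosome: str
    positions: np.ndarray  # float64, ascending
    phases: np.ndarray  # '<U1', 'A' or 'B'

    @property
    def n_points(self) -> int:
        return int(self.positions.size)


def build_phase_track(
    calls: Sequence[PhaseCall],
    profiles: Mapping[str, BarcodeProfile],
    cell: int,
    chromosome: str,
) -> PhaseTrack:
    """Project one cell's haplotype along a chromosome from phased fragments."""
    pts: list[tuple[float, str]] = []
    for c in calls:
        if c.call == UNPHASED or c.chromosome != chromosome:
            continue
        prof = profiles[c.fragment_id]
        if not (0 <= cell < prof.width):
            raise InputError(f"unknown cell id {cell} (width {prof.width})")
        if prof.observed_mask.bit(cell) == 0:
            continue
        if c.position is None:
            raise InputError(f"fragment {c.fragment_id} has no position")
        bit = prof.consensus.bit(cell)
        phase = c.call if bit == 1 else (HAP_B if c.call == HAP_A else HAP_A)
        pts.append((c.position, phase))
    pts.sort(key=lambda t: t[0])
    return PhaseTrack(
        cell,
        chromosome,
        np.array([p for p, _ in pts], dtype=np.float64),
        np.array([h for _, h in pts], dtype="<U1"),
    )


@dataclass
class CrossoverEvent:
    """One accepted phase switch; the breakpoint lies in (left, right]."""

    cell: int
    chromosome: str
    left: float  # last informative position of the old phase
    right: float  # first informative position of the new phase
    from_phase: str
    to_phase: str

    @property
    def midpoint(self) -> float:
        return (self.left + self.right) / 2.0


def _rle(values: np.ndarray) -> list[tuple[str, int, int]]:
    """Run-length encode: (value, first index, last index) per run."""
    runs = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            runs.append((str(values[start]), start, i - 1))
            start = i
    return runs


def detect_crossovers(track: PhaseTrack, min_run: int = 2) -> list[CrossoverEvent]:
    """Accepted switches of a phase track.

    Runs shorter than ``min_run`` (including terminal runs, whose evidence
    cannot be distinguished from noise) are suppressed; adjacent surviving runs
    of equal phase are merged before switches are emitted.
    """
    if min_run < 1:
        raise InputError("min_run must be >= 1")
    if track.n_points == 0:
        return []
    runs = [r for r in _rle(track.phases) if r[2] - r[1] + 1 >= min_run]
    merged: list[list] = []
    for phase, i0, i1 in runs:
        if merged and merged[-1][0] == phase:
            merged[-1][2] = i1
        else:
            merged.append([phase, i0, i1])
    events = []
    for (p1, _, last1), (p2, first2, _) in zip(merged, merged[1:]):
        events.append(
            CrossoverEvent(
                cell=track.cell,
                chromosome=track.chromosome,
                left=float(track.positions[last1]),
                right=float(track.positions[first2]),
                from_phase=p1,
                to_phase=p2,
            )
        )
    return events


@dataclass
class CrossoverSummary:
    n_events: int
    n_cells: int
    n_chromosomes: int
    mean_per_chromosome: float
    per_cell: Counter
    per_chromosome: Counter


def crossover_summary(
    events: Sequence[CrossoverEvent], n_cells: int, n_chromosomes: int
) -> CrossoverSummary:
    """Totals and the mean number of events per (cell, chromosome) pair."""
    if n_cells <= 0 or n_chromosomes <= 0:
        raise InputError("n_cells and n_chromosomes must be positive")
    return CrossoverSummary(
        n_events=len(events),
        n_cells=n_cells,
        n_chromosomes=n_chromosomes,
        mean_per_chromosome=len(events) / (n_cells * n_chromosomes),
        per_cell=Counter(e.cell for e in events),
        per_chromosome=Counter(e.chromosome for e in events),
    )


@dataclass
class Landscape:
    bin_counts: np.ndarray
    terminal_fraction: float
    n_bins: int
    terminal_cut: float = 0.2


def crossover_landscape(
    events: Sequence[CrossoverEvent],
    chromosome_lengths: Mapping[str, int],
    n_bins: int = 10,
) -> Landscape:
    """Relative-position histogram of event midpoints plus the fraction falling
    in the outer 20% of each chromosome end."""
    counts = np.zeros(n_bins, dtype=np.int64)
    terminal = 0
    for e in events:
        rel = e.midpoint / chromosome_lengths[e.chromosome]
        counts[min(int(rel * n_bins), n_bins - 1)] += 1
        if rel <= 0.2 or rel >= 0.8:
            terminal += 1
    frac = terminal / len(events) if events else float("nan")
    return Landscape(counts, frac, n_bins)


# ---------------------------------------------------------------------------
# Simulation-mode evaluation helpers
# ---------------------------------------------------------------------------


def detectable_breakpoints(
    breakpoints: np.ndarray,
    informative_positions: np.ndarray,
    min_run: int = 2,
) -> np.ndarray:
    """Truth breakpoints resolvable at this track's resolution.

    A breakpoint is detectable when, between it and each neighboring breakpoint
    (or chromosome end), at least ``min_run`` informative points lie strictly
    on that side — otherwise the persistence rule cannot possibly accept it.
    """
    bp = np.sort(np.asarray(breakpoints, dtype=float))
    pos = np.sort(np.asarray(informative_positions, dtype=float))
    out = []
    for j, x in enumerate(bp):
        lo = bp[j - 1] if j > 0 else -np.inf
        hi = bp[j + 1] if j + 1 < bp.size else np.inf
        n_left = int(((pos > lo) & (pos < x)).sum())
        n_right = int(((pos >= x) & (pos < hi)).sum())
        if n_left >= min_run and n_right >= min_run:
            out.append(x)
    return np.array(out, dtype=float)


@dataclass
class CrossoverMatch:
    n_truth: int
    n_detected: int
    n_matched: int  # detected events bracketing a truth breakpoint
    n_detectable: int
    n_detectable_matched: int

    @property
    def missed_detectable(self) -> int:
        return self.n_detectable - self.n_detectable_matched

    @property
    def spurious(self) -> int:
        return self.n_detected - self.n_matched


def match_events_to_breakpoints(
    events: Sequence[CrossoverEvent],
    breakpoints: np.ndarray,
    informative_positions: np.ndarray,
    min_run: int = 2,
    slack_points: int = 0,
) -> CrossoverMatch:
    """Greedy one-to-one matching of detected events to truth breakpoints.

    An event matches a breakpoint lying in (left, right]; ``slack_points``
    widens the interval by that many informative points on each side, because
    a fragment whose midpoint falls within the SNP-sampling noise of the
    breakpoint can legitimately vote for either side.
    """
    pos = np.sort(np.asarray(informative_positions, dtype=float))
    bp = np.sort(np.asarray(breakpoints, dtype=float))
    intervals = []
    for e in sorted(events, key=lambda e: e.left):
        lo, hi = e.left, e.right
        if slack_points > 0 and pos.size:
            i_lo = np.searchsorted(pos, lo, side="left") - slack_points
            i_hi = np.searchsorted(pos, hi, side="right") - 1 + slack_points
            lo = pos[max(i_lo, 0)] - 1.0 if i_lo >= 0 else -np.inf
            hi = pos[min(i_hi, pos.size - 1)] + 1.0 if i_hi < pos.size else np.inf
        intervals.append((lo, hi))
    used = [False] * len(intervals)
    n_matched_bp = np.zeros(bp.size, dtype=bool)
    for j, x in enumerate(bp):
        for i, (lo, hi) in enumerate(intervals):
            if not used[i] and lo < x <= hi:
                used[i] = True
                n_matched_bp[j] = True
                break
    detectable = detectable_breakpoints(bp, pos, min_run)
    det_idx = np.isin(bp, detectable)
    return CrossoverMatch(
        n_truth=int(bp.size),
        n_detected=len(events),
        n_matched=int(sum(used)),
        n_detectable=int(det_idx.sum()),
        n_detectable_matched=int((n_matched_bp & det_idx).sum()),
    )
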