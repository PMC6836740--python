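"""Partition anchored fragments into the two haplotype families of each chromosome.

Fragments from the same haplotype carry nearby barcodes; fragments from the
opposite haplotype carry (near-)complementary ones. Because meiotic
recombination flips individual cells' bits along the chromosome, each family's
barcode is piecewise-constant in position rather than global. The algorithm is
a greedy positional chain with a windowed majority consensus and a second
re-scoring pass:

1. sort fragments by anchor midpoint;
2. the first phaseable fragment's consensus seeds family A, its complement
   family B;
3. each subsequent fragment joins the family with the smaller hamming distance
   provided the margin |dA - dB| reaches ``min_margin``, else it is left
   unphased as ambiguous;
4. the winning family's current barcode is refreshed as the bitwise majority
   over its last ``window`` members, letting it drift across crossovers;
5. a second pass re-scores every fragment against the final piecewise family
   barcodes at its own position; calls that flip between passes are demoted to
   unphased.

Family labels per chromosome are arbitrary (gamete data carries no
trans-chromosome linkage); evaluation against simulated truth always optimizes
the label orientation per chromosome before scoring.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .anchor import AnchorAssignment
from .barcode import Barcode, BarcodeProfile, complement, hamming, masked_hamming
from .errors import InputError
from .sim import BacRecord

logger = logging.getLogger(__name__)

HAP_A = "A"
HAP_B = "B"
UNPHASED = "UNPHASED"

REASON_SINGLE_CELL = "single_cell_support"
REASON_AMBIGUOUS = "ambiguous_distance"
REASON_TOO_FEW_SNPS = "too_few_snps"
REASON_UNANCHORED = "unanchored"


@dataclass(frozen=True)
class PhaseParams:
    """Tunables of the chaining algorithm.

    ``min_top_type_fraction`` optionally unphases fragments whose most common
    barcode type is rarer than the threshold; it defaults to off because a
    fragment straddling a crossover of a single cell legitimately carries two
    barcode types at comparable frequency.
    """

    min_margin: int = 1
    window: int = 5
    min_snps: int = 3
    min_top_type_fraction: float = 0.0
    masked_distance: bool = False


@dataclass
class PhaseCall:
    fragment_id: str
    chromosome: str | None
    call: str  # HAP_A, HAP_B or UNPHASED
    reason: str | None = None
    margin: int | None = None
    n_snps: int = 0
    position: float | None = None


@dataclass
class HaplotypeFamily:
    """One haplotype's members and its piecewise-constant barcode track."""

    chromosome: str | None
    label: str
    members: list[tuple[float, str]] = field(default_factory=list)
    barcode_track: list[tuple[float, Barcode]] = field(default_factory=list)

    def barcode_at(self, position: float) -> Barcode | None:
        if not self.barcode_track:
            return None
        i = bisect_right([p for p, _ in self.barcode_track], position) - 1
        return self.barcode_track[max(i, 0)][1]


def _distance(profile: BarcodeProfile, family: Barcode, params: PhaseParams) -> int:
    if params.masked_distance:
        return masked_hamming(profile.consensus, family, profile.observed_mask)
    return hamming(profile.consensus, family)


def _window_majority(codes: Sequence[Barcode], prev: Barcode) -> Barcode:
    """Bitwise majority over a window of barcodes; ties keep the previous bit."""
    width = prev.width
    ones = [0] * width
    for code in codes:
        for c in range(width):
            ones[c] += code.bit(c)
    n = len(codes)
    bits = []
    for c in range(width):
        if 2 * ones[c] > n:
            bits.append(1)
        elif 2 * ones[c] < n:
            bits.append(0)
        else:
            bits.append(prev.bit(c))
    return Barcode.from_bits(bits)


def phase_chromosome(
    profiles: Sequence[BarcodeProfile],
    positions: Mapping[str, float],
    params: PhaseParams | None = None,
    chromosome: str | None = None,
) -> tuple[list[PhaseCall], tuple[HaplotypeFamily, HaplotypeFamily]]:
    """Assign each profile of one chromosome to family A or B (or unphased)."""
    params = params or PhaseParams()
    fam_a = HaplotypeFamily(chromosome, HAP_A)
    fam_b = HaplotypeFamily(chromosome, HAP_B)
    if not profiles:
        return [], (fam_a, fam_b)

    order = sorted(profiles, key=lambda p: positions[p.fragment_id])
    preflag: dict[str, str] = {}
    for p in order:
        if p.observed_mask.popcount() <= 1:
            preflag[p.fragment_id] = REASON_SINGLE_CELL
        elif p.n_informative_snps < params.min_snps:
            preflag[p.fragment_id] = REASON_TOO_FEW_SNPS
        elif (
            params.min_top_type_fraction > 0.0
            and p.top_fraction < params.min_top_type_fraction
        ):
            preflag[p.fragment_id] = REASON_AMBIGUOUS
    phaseable = [p for p in order if p.fragment_id not in preflag]

    calls: dict[str, PhaseCall] = {}
    for p in order:
        reason = preflag.get(p.fragment_id)
        if reason is not None:
            calls[p.fragment_id] = PhaseCall(
                p.fragment_id,
                chromosome,
                UNPHASED,
                reason=reason,
                n_snps=p.n_informative_snps,
                position=positions[p.fragment_id],
            )
    if not phaseable:
        logger.warning(
            "chromosome %s: no phaseable fragments among %d", chromosome, len(order)
        )
        return [calls[p.fragment_id] for p in order], (fam_a, fam_b)

    # ---- pass 1: greedy chain with windowed consensus -----------------------
    width = phaseable[0].consensus.width
    cur: dict[str, Barcode] = {}
    window_members: dict[str, list[Barcode]] = {HAP_A: [], HAP_B: []}
    pass1: dict[str, str | None] = {}
    snapshots: list[tuple[float, Barcode, Barcode]] = []
    for p in phaseable:
        if not cur:
            cur[HAP_A] = p.consensus
            cur[HAP_B] = complement(p.consensus)
            win: str | None = HAP_A
        else:
            d_a = _distance(p, cur[HAP_A], params)
            d_b = _distance(p, cur[HAP_B], params)
            if abs(d_a - d_b) >= params.min_margin:
                win = HAP_A if d_a < d_b else HAP_B
            else:
                win = None
        pass1[p.fragment_id] = win
        if win is not None:
            window_members[win].append(p.consensus)
            cur[win] = _window_majority(window_members[win][-params.window :], cur[win])
        snapshots.append((positions[p.fragment_id], cur[HAP_A], cur[HAP_B]))

    # ---- pass 2: re-score against the final piecewise family barcodes -------
    snap_pos = [s[0] for s in snapshots]
    for p in phaseable:
        i = max(bisect_right(snap_pos, positions[p.fragment_id]) - 1, 0)
        _, bar_a, bar_b = snapshots[i]
        d_a = _distance(p, bar_a, params)
        d_b = _distance(p, bar_b, params)
        margin = abs(d_a - d_b)
        if margin >= params.min_margin:
            call2: str | None = HAP_A if d_a < d_b else HAP_B
        else:
            call2 = None
        call1 = pass1[p.fragment_id]
        if call2 is None or (call1 is not None and call1 != call2):
            calls[p.fragment_id] = PhaseCall(
                p.fragment_id,
                chromosome,
                UNPHASED,
                reason=REASON_AMBIGUOUS,
                n_snps=p.n_informative_snps,
                position=positions[p.fragment_id],
            )
        else:
            calls[p.fragment_id] = PhaseCall(
                p.fragment_id,
                chromosome,
                call2,
                margin=margin,
                n_snps=p.n_informative_snps,
                position=positions[p.fragment_id],
            )

    # ---- final families ------------------------------------------------------
    fam = {HAP_A: fam_a, HAP_B: fam_b}
    cur2: dict[str, Barcode] = {}
    window2: dict[str, list[Barcode]] = {HAP_A: [], HAP_B: []}
    for p in phaseable:
        c = calls[p.fragment_id]
        if c.call == UNPHASED:
            continue
        if c.call not in cur2:
            cur2[c.call] = p.consensus
        window2[c.call].append(p.consensus)
        cur2[c.call] = _window_majority(window2[c.call][-params.window :], cur2[c.call])
        fam[c.call].members.append((positions[p.fragment_id], p.fragment_id))
        fam[c.call].barcode_track.append((positions[p.fragment_id], cur2[c.call]))
    return [calls[p.fragment_id] for p in order], (fam_a, fam_b)


def complementarity_violations(
    fam_a: HaplotypeFamily, fam_b: HaplotypeFamily
) -> list[tuple[float, int]]:
    """Diagnostic: (position, cell) bits where the family barcodes are not
    complementary.

    Because each family's barcode is sampled at its own member positions, a
    genuine crossover of cell c produces a transient violation at bit c between
    the two families' next window updates; violations anywhere else indicate
    mis-assigned fragments. With no recombination this list is empty.
    """
    out: list[tuple[float, int]] = []
    for pos, _ in sorted(fam_a.members + fam_b.members):
        a = fam_a.barcode_at(pos)
        b = fam_b.barcode_at(pos)
        if a is None or b is None:
            continue
        mism = a.value ^ complement(b).value
        for cell in range(a.width):
            if (mism >> (a.width - 1 - cell)) & 1:
                out.append((pos, cell))
    return out


@dataclass
class PhaseSummary:
    n_total: int
    n_phased_a: int
    n_phased_b: int
    n_unphased: int
    per_chromosome: dict[str, tuple[int, int]]
    unphased_reasons: Counter

    @property
    def n_phased(self) -> int:
        return self.n_phased_a + self.n_phased_b

    @property
    def phased_fraction(self) -> float:
        return self.n_phased / self.n_total if self.n_total else 0.0

    @property
    def phased_pct(self) -> float:
        return round(100.0 * self.phased_fraction, 2)

    @property
    def unphased_pct(self) -> float:
        return round(100.0 * self.n_unphased / self.n_total, 2) if self.n_total else 0.0


def summarize_calls(calls: Sequence[PhaseCall]) -> PhaseSummary:
    per_chrom: dict[str, list[int]] = {}
    n_a = n_b = n_u = 0
    reasons: Counter = Counter()
    for c in calls:
        if c.call == HAP_A:
            n_a += 1
        elif c.call == HAP_B:
            n_b += 1
        else:
            n_u += 1
            if c.reason:
                reasons[c.reason] += 1
        if c.chromosome is not None and c.call != UNPHASED:
            slot = per_chrom.setdefault(c.chromosome, [0, 0])
            slot[0 if c.call == HAP_A else 1] += 1
    return PhaseSummary(
        n_total=len(calls),
        n_phased_a=n_a,
        n_phased_b=n_b,
        n_unphased=n_u,
        per_chromosome={k: (v[0], v[1]) for k, v in per_chrom.items()},
        unphased_reasons=reasons,
    )


def phase_genome(
    anchors: Sequence[AnchorAssignment],
    profiles: Mapping[str, BarcodeProfile],
    params: PhaseParams | None = None,
) -> tuple[list[PhaseCall], PhaseSummary, dict[str, tuple[HaplotypeFamily, HaplotypeFamily]]]:
    """Run phase_chromosome per chromosome; unanchored fragments stay unphased."""
    params = params or PhaseParams()
    calls: list[PhaseCall] = []
    by_chrom: dict[str, list[tuple[AnchorAssignment, BarcodeProfile]]] = {}
    for a in anchors:
        if a.chromosome is None:
            calls.append(
                PhaseCall(a.fragment_id, None, UNPHASED, reason=REASON_UNANCHORED)
            )
        elif a.fragment_id not in profiles:
            logger.info("fragment %s anchored but has no profile", a.fragment_id)
            calls.append(
                PhaseCall(
                    a.fragment_id, a.chromosome, UNPHASED, reason=REASON_TOO_FEW_SNPS
                )
            )
        else:
            by_chrom.setdefault(a.chromosome, []).append((a, profiles[a.fragment_id]))
    families: dict[str, tuple[HaplotypeFamily, HaplotypeFamily]] = {}
    for chrom in sorted(by_chrom):
        pairs = by_chrom[chrom]
        positions = {
            a.fragment_id: (a.position if a.position is not None else 0.0)
            for a, _ in pairs
        }
        chrom_calls, fams = phase_chromosome(
            [p for _, p in pairs], positions, params, chromosome=chrom
        )
        calls.extend(chrom_calls)
        families[chrom] = fams
    return calls, summarize_calls(calls), families


@dataclass
class PhasingEvaluation:
    accuracy: float
    unphased_rate: float
    switch_errors: int
    n_phased: int
    n_total: int
    orientation: dict[str, str]  # chromosome -> "identity" | "swapped"


def evaluate_phasing(
    calls: Sequence[PhaseCall], truth: Sequence[BacRecord]
) -> PhasingEvaluation:
    """Score calls against simulated truth, optimizing label orientation per
    chromosome (a global A/B swap on a chromosome is not an error)."""
    truth_by_id = {b.id: b for b in truth}
    by_chrom: dict[str, list[tuple[float, str, str]]] = {}
    n_unphased = 0
    for c in calls:
        if c.call == UNPHASED:
            n_unphased += 1
            continue
        rec = truth_by_id.get(c.fragment_id)
        if rec is None or rec.truth_haplotype is None:
            raise InputError(f"no truth record for fragment {c.fragment_id}")
        by_chrom.setdefault(rec.chromosome, []).append(
            (rec.midpoint, c.call, rec.truth_haplotype)
        )
    n_phased = sum(len(v) for v in by_chrom.values())
    agree_total = 0
    switch_errors = 0
    orientation: dict[str, str] = {}
    for chrom, rows in by_chrom.items():
        agree = sum(1 for _, call, th in rows if call == th)
        if agree >= len(rows) - agree:
            orientation[chrom] = "identity"
            agree_total += agree
        else:
            orientation[chrom] = "swapped"
            agree_total += len(rows) - agree
        rows.sort(key=lambda r: r[0])
        for (_, c1, t1), (_, c2, t2) in zip(rows, rows[1:]):
            if (c1 == c2) != (t1 == t2):
                switch_errors += 1
    accuracy = agree_total / n_phased if n_phased else float("nan")
    n_total = len(calls)
    return PhasingEvaluation(
        accuracy=accuracy,
        unphased_rate=n_unphased / n_total if n_total else 0.0,
        switch_errors=switch_errors,
        n_phased=n_phased,
        n_total=n_total,
        orientation=orientation,
    )
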