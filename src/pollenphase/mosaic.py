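"""Detect mosaic gene assemblies by three-way haplotype comparison.

A collapsed diploid assembly can alternate between the two parental alleles
within a single locus. Given a gene's reference sequence and the corresponding
haplotype A and B sequences, each haplotype is globally aligned to the
reference (affine gap penalties); positions where the aligned A and B bases
are both present and differ are *diagnostic sites*. A gene whose reference
matches haplotype A at some diagnostic sites and haplotype B at others is
mosaic; the minority haplotype's sites are the mosaic errors, located in exons
or introns via the gene's exon intervals.

Indel-only differences between the haplotypes (gap columns) are not diagnostic
sites; genes where the reference matches neither haplotype at most diagnostic
sites are reported unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align

from .errors import InputError

MATCHES_A = "matches_A"
MATCHES_B = "matches_B"
NEITHER = "neither"

CONSISTENT_A = "consistent_A"
CONSISTENT_B = "consistent_B"
IDENTICAL_AB = "identical_AB"
MOSAIC_EXON = "mosaic_exon"
MOSAIC_INTRON = "mosaic_intron"
UNRESOLVED = "unresolved"

MOSAIC_CLASSES = (MOSAIC_EXON, MOSAIC_INTRON)
ALL_CLASSES = (
    CONSISTENT_A,
    CONSISTENT_B,
    IDENTICAL_AB,
    MOSAIC_EXON,
    MOSAIC_INTRON,
    UNRESOLVED,
)

MAX_GENE_LENGTH = 50_000


@dataclass(frozen=True)
class AlignScoring:
    """Affine-gap scoring; a gap of length L costs gap_open + L * gap_extend."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 4.0
    gap_extend: float = 1.0


@dataclass(frozen=True)
class GeneTriplet:
    """Reference gene plus its two haplotype counterparts and exon intervals
    (0-based half-open, on reference coordinates, forward strand)."""

    gene_id: str
    ref: str
    hap_a: str
    hap_b: str
    exons: list[tuple[int, int]] = field(default_factory=list)


@dataclass(frozen=True)
class DiagnosticSite:
    position: int  # reference coordinate
    state: str  # MATCHES_A / MATCHES_B / NEITHER
    in_exon: bool


@dataclass
class MosaicCall:
    gene_id: str
    klass: str
    n_sites_a: int
    n_sites_b: int
    n_neither: int
    switch_positions: list[tuple[int, int]]


@dataclass
class AlignmentResult:
    score: float
    ref_map: np.ndarray  # '<U1' per reference position; '-' = gap in haplotype


def _aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # Biopython charges open_gap_score for the first gap column and
    # extend_gap_score for each further one; shift so a length-L gap costs
    # gap_open + L * gap_extend.
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def align_to_ref(
    ref: str, hap: str, scoring: AlignScoring | None = None
) -> AlignmentResult:
    """Global affine-gap alignment of a haplotype gene to its reference copy.

    Returns the optimal score and, per reference position, the aligned
    haplotype base ('-' where the haplotype has a gap). Ties among co-optimal
    alignments are broken deterministically by the aligner's first alignment.
    """
    if not ref or not hap:
        raise InputError("empty sequence")
    if len(ref) > MAX_GENE_LENGTH or len(hap) > MAX_GENE_LENGTH:
        raise InputError(f"sequence longer than {MAX_GENE_LENGTH} bp (gene scale only)")
    scoring = scoring or AlignScoring()
    alignment = _aligner(scoring).align(ref, hap)[0]
    indices = alignment.indices  # (2, n_columns); -1 marks a gap
    ref_map = np.full(len(ref), "-", dtype="<U1")
    ref_idx = indices[0]
    hap_idx = indices[1]
    cols = ref_idx >= 0
    mapped = hap_idx[cols]
    hap_arr = np.frombuffer(hap.encode("ascii"), dtype="S1").astype("<U1")
    ref_map[ref_idx[cols]] = np.where(mapped >= 0, hap_arr[np.maximum(mapped, 0)], "-")
    return AlignmentResult(float(alignment.score), ref_map)


def diagnostic_sites(
    triplet: GeneTriplet, scoring: AlignScoring | None = None
) -> list[DiagnosticSite]:
    """Reference positions where the aligned A and B bases differ (both non-gap)."""
    map_a = align_to_ref(triplet.ref, triplet.hap_a, scoring).ref_map
    map_b = align_to_ref(triplet.ref, triplet.hap_b, scoring).ref_map
    ref_arr = np.frombuffer(triplet.ref.encode("ascii"), dtype="S1").astype("<U1")
    diff = (map_a != "-") & (map_b != "-") & (map_a != map_b)
    sites = []
    for pos in np.flatnonzero(diff):
        pos = int(pos)
        if ref_arr[pos] == map_a[pos]:
            state = MATCHES_A
        elif ref_arr[pos] == map_b[pos]:
            state = MATCHES_B
        else:
            state = NEITHER
        in_exon = any(s <= pos < e for s, e in triplet.exons)
        sites.append(DiagnosticSite(pos, state, in_exon))
    return sites


def classify_gene(
    sites: Sequence[DiagnosticSite], gene_id: str = "", min_sites: int = 1
) -> MosaicCall:
    """Classify a gene from its diagnostic sites.

    identical_AB with no sites; unresolved when NEITHER sites exceed half of
    all sites; mosaic when both haplotypes are matched at >= min_sites each
    (mosaic_exon if any minority-haplotype site is exonic, else mosaic_intron);
    otherwise consistent with the single matched haplotype. A count tie takes
    the haplotype of the segment after the first switch as the minority.
    """
    n_a = sum(1 for s in sites if s.state == MATCHES_A)
    n_b = sum(1 for s in sites if s.state == MATCHES_B)
    n_n = sum(1 for s in sites if s.state == NEITHER)
    informative = sorted(
        (s for s in sites if s.state != NEITHER), key=lambda s: s.position
    )
    switches: list[tuple[int, int]] = []
    for s1, s2 in zip(informative, informative[1:]):
        if s1.state != s2.state:
            switches.append((s1.position, s2.position))

    if not sites:
        klass = IDENTICAL_AB
    elif 2 * n_n > len(sites):
        klass = UNRESOLVED
    elif n_a >= min_sites and n_b >= min_sites:
        if n_a < n_b:
            minority = MATCHES_A
        elif n_b < n_a:
            minority = MATCHES_B
        else:
            # tie: the segment entered at the first switch is the error
            minority = informative[0].state
            for s in informative:
                if s.state != informative[0].state:
                    minority = s.state
                    break
        minority_sites = [s for s in informative if s.state == minority]
        klass = (
            MOSAIC_EXON
            if any(s.in_exon for s in minority_sites)
            else MOSAIC_INTRON
        )
    elif n_a > n_b:
        klass = CONSISTENT_A
    elif n_b > n_a:
        klass = CONSISTENT_B
    else:
        klass = UNRESOLVED
    return MosaicCall(gene_id, klass, n_a, n_b, n_n, switches)


def classify_triplet(
    triplet: GeneTriplet,
    scoring: AlignScoring | None = None,
    min_sites: int = 1,
) -> MosaicCall:
    """Convenience: diagnostic_sites followed by classify_gene."""
    return classify_gene(diagnostic_sites(triplet, scoring), triplet.gene_id, min_sites)


@dataclass
class MosaicReport:
    counts: dict[str, int]
    n_genes: int

    @property
    def n_mosaic(self) -> int:
        return sum(self.counts.get(k, 0) for k in MOSAIC_CLASSES)

    @property
    def mosaic_fraction(self) -> float:
        return self.n_mosaic / self.n_genes if self.n_genes else 0.0

    @property
    def mosaic_pct(self) -> float:
        return round(100.0 * self.mosaic_fraction, 2)


def mosaic_report(calls: Sequence[MosaicCall]) -> MosaicReport:
    counts = {k: 0 for k in ALL_CLASSES}
    for c in calls:
        counts[c.klass] = counts.get(c.klass, 0) + 1
    return MosaicReport(counts, len(calls))
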