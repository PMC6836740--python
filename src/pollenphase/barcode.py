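"""Per-SNP binary barcodes over pollen cells and per-fragment barcode profiles.

Each SNP row of a fragment's genotype matrix is summarized as a fixed-width
bit vector (one bit per cell): bit c is 1 when cell c's observed allele equals
the fragment's own allele at that site, and 0 when it differs or the site was
not observed in that cell (the no-call collapse). The tri-state matrix and an
observed-cell mask are retained so that a masked distance over mutually
observed bits remains available as an option.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Sequence

import numpy as np

from .errors import InputError
from .sim import BacRecord, PollenObservation, SnpSite, SnpTable


class Call(IntEnum):
    """Tri-state genotype call of one cell at one fragment SNP row."""

    NOCALL = -1
    MISMATCH = 0
    MATCH = 1


MATCH = Call.MATCH
MISMATCH = Call.MISMATCH
NOCALL = Call.NOCALL


@dataclass(frozen=True)
class Barcode:
    """Fixed-width bit vector over cells; cell 0 is the leftmost bit."""

    width: int
    value: int

    def __post_init__(self) -> None:
        if self.width < 1:
            raise InputError("barcode width must be >= 1")
        if not (0 <= self.value < (1 << self.width)):
            raise InputError("barcode value out of range for width")

    @classmethod
    def from_bits(cls, bits: Sequence[int]) -> "Barcode":
        value = 0
        for b in bits:
            value = (value << 1) | (1 if b else 0)
        return cls(len(bits), value)

    @classmethod
    def from_string(cls, s: str) -> "Barcode":
        if not s or set(s) - {"0", "1"}:
            raise InputError(f"not a binary barcode string: {s!r}")
        return cls(len(s), int(s, 2))

    def bit(self, cell: int) -> int:
        if not (0 <= cell < self.width):
            raise InputError(f"cell index {cell} out of range for width {self.width}")
        return (self.value >> (self.width - 1 - cell)) & 1

    def bits(self) -> tuple[int, ...]:
        return tuple((self.value >> (self.width - 1 - c)) & 1 for c in range(self.width))

    def popcount(self) -> int:
        return self.value.bit_count()

    def __str__(self) -> str:
        return format(self.value, f"0{self.width}b")


def hamming(a: Barcode, b: Barcode) -> int:
    """Number of differing bits: exclusive disjunction, then popcount."""
    if a.width != b.width:
        raise InputError(f"barcode width mismatch: {a.width} != {b.width}")
    return (a.value ^ b.value).bit_count()


def complement(a: Barcode) -> Barcode:
    """Flip every bit; fragments from opposite haplotypes carry complementary codes."""
    return Barcode(a.width, a.value ^ ((1 << a.width) - 1))


def masked_hamming(a: Barcode, b: Barcode, mask: Barcode) -> int:
    """Hamming distance restricted to the set bits of ``mask``."""
    if not (a.width == b.width == mask.width):
        raise InputError("barcode width mismatch")
    return ((a.value ^ b.value) & mask.value).bit_count()


@dataclass
class GenotypeMatrix:
    """Tri-state SNP x cell calls for one fragment (rows ascending by position)."""

    fragment_id: str
    positions: np.ndarray  # int64 (n_rows,)
    calls: np.ndarray  # int8 (n_rows, n_cells) with Call values

    @property
    def n_rows(self) -> int:
        return int(self.positions.size)

    @property
    def n_cells(self) -> int:
        return int(self.calls.shape[1])


def genotype_fragment(
    fragment: BacRecord,
    sites: SnpTable | Sequence[SnpSite],
    observations: Sequence[PollenObservation],
) -> GenotypeMatrix:
    """Compare each cell's observed allele with the fragment's own base.

    MATCH when the cell observed the fragment's base, MISMATCH when it observed
    a different base, NOCALL when the site dropped out in that cell. A fragment
    with no overlapping SNP sites yields an empty (0-row) matrix.
    """
    if fragment.chromosome is None or fragment.start is None or fragment.end is None:
        raise InputError(f"fragment {fragment.id} is not anchored to an interval")
    if not isinstance(sites, SnpTable):
        sites = SnpTable.from_sites(fragment.chromosome, sites)
    chrom = fragment.chromosome
    i0, i1 = np.searchsorted(sites.positions, [fragment.start, fragment.end])
    positions = sites.positions[i0:i1]
    n_cells = len(observations)
    if positions.size == 0:
        return GenotypeMatrix(
            fragment.id,
            positions.astype(np.int64),
            np.zeros((0, n_cells), dtype=np.int8),
        )
    frag_arr = np.frombuffer(fragment.sequence.encode("ascii"), dtype="S1").astype("<U1")
    frag_bases = frag_arr[positions - fragment.start]
    calls = np.full((positions.size, n_cells), int(NOCALL), dtype=np.int8)
    for obs in observations:
        if not (0 <= obs.cell < n_cells):
            raise InputError(f"cell id {obs.cell} out of range")
        observed = obs.bases[chrom][i0:i1]
        called = observed != "."
        calls[:, obs.cell] = np.where(
            called,
            np.where(observed == frag_bases, int(MATCH), int(MISMATCH)),
            int(NOCALL),
        )
    return GenotypeMatrix(fragment.id, positions.astype(np.int64), calls)


def filter_min_support(matrix: GenotypeMatrix, min_cells: int = 2) -> GenotypeMatrix:
    """Drop SNP rows observed in fewer than ``min_cells`` cells (order preserved).

    The minimum-support rule guards the no-call-to-0 collapse: a genotype seen
    in a single cell cannot be distinguished from amplification noise.
    """
    support = (matrix.calls != int(NOCALL)).sum(axis=1)
    keep = support >= min_cells
    return GenotypeMatrix(
        matrix.fragment_id, matrix.positions[keep], matrix.calls[keep]
    )


def snp_barcodes(matrix: GenotypeMatrix) -> list[Barcode]:
    """One barcode per retained SNP row: MATCH -> 1, MISMATCH/NOCALL -> 0."""
    out = []
    for row in matrix.calls == int(MATCH):
        out.append(Barcode.from_bits(row.astype(int).tolist()))
    return out


@dataclass
class BarcodeProfile:
    """Summary of a fragment's SNP barcodes.

    ``consensus`` bit c is the majority over the non-NOCALL entries of column
    c (ties break to 0 and are flagged in ``low_confidence_mask``);
    ``observed_mask`` bit c is set when cell c observed at least one site on
    this fragment.
    """

    fragment_id: str
    type_counts: dict[Barcode, int]
    consensus: Barcode
    n_informative_snps: int
    n_supporting_cells: int
    observed_mask: Barcode
    low_confidence_mask: Barcode

    @property
    def width(self) -> int:
        return self.consensus.width

    @property
    def top_type(self) -> Barcode | None:
        if not self.type_counts:
            return None
        # deterministic: highest count, then smallest barcode value
        return min(self.type_counts, key=lambda b: (-self.type_counts[b], b.value))

    @property
    def top_count(self) -> int:
        t = self.top_type
        return self.type_counts[t] if t is not None else 0

    @property
    def top_fraction(self) -> float:
        return self.top_count / self.n_informative_snps if self.n_informative_snps else 0.0


def profile_fragment(barcodes: Sequence[Barcode], matrix: GenotypeMatrix) -> BarcodeProfile:
    """Tally barcode types and compute the column-majority consensus."""
    n_cells = matrix.n_cells
    n_match = (matrix.calls == int(MATCH)).sum(axis=0)
    n_mismatch = (matrix.calls == int(MISMATCH)).sum(axis=0)
    consensus_bits = (n_match > n_mismatch).astype(int)
    observed = (n_match + n_mismatch) > 0
    low_conf = observed & (n_match == n_mismatch)
    counts = Counter(barcodes)
    return BarcodeProfile(
        fragment_id=matrix.fragment_id,
        type_counts=dict(counts),
        consensus=Barcode.from_bits(consensus_bits.tolist()),
        n_informative_snps=len(barcodes),
        n_supporting_cells=int(observed.sum()),
        observed_mask=Barcode.from_bits(observed.astype(int).tolist()),
        low_confidence_mask=Barcode.from_bits(low_conf.astype(int).tolist()),
    )


def build_profile(
    fragment: BacRecord,
    sites: SnpTable | Sequence[SnpSite],
    observations: Sequence[PollenObservation],
    min_cells: int = 2,
) -> BarcodeProfile:
    """Genotype -> min-support filter -> barcodes -> profile, in one call."""
    matrix = filter_min_support(
        genotype_fragment(fragment, sites, observations), min_cells
    )
    return profile_fragment(snp_barcodes(matrix), matrix)
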