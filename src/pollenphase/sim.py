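"""Synthetic diploid genomes, meioses, and single-pollen-cell observations.

This module generates every input the downstream stages consume, together with
full ground truth, so that anchoring, barcoding, phasing, crossover calling and
mosaic classification are all testable offline.

The defaults emulate a highly heterozygous outcrossing tree genome sampled
through a dozen amplified pollen cells:

* heterozygosity ~1.02% (one SNP per ~98 bp),
* 12 haploid cells, each observing a uniform-random fraction of SNP sites in
  [0.50, 0.78] (whole-genome amplification drops sites independently),
* a small per-observation genotype error rate (1e-3) that flips the call to
  the other allele,
* Poisson(1.3) crossovers per chromosome per gamete, with positions drawn from
  a symmetric Beta(end_bias, end_bias) density (end_bias < 1 concentrates
  crossovers near the chromosome ends),
* haplotype-pure fragments of 10-120 kb, the units that get phased.

All coordinates are 0-based, half-open, forward strand. Every generator is a
pure function of its config (including the seed): identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import ConfigError

BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype="S1")

# Sub-stream labels so each stage draws from its own deterministic stream.
_STREAM_GENOME = 0
_STREAM_GAMETES = 1
_STREAM_CALLS = 2
_STREAM_BACS = 3
_STREAM_GENES = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    ``coverage_range`` is the per-cell breadth-of-coverage window: each cell
    draws one fraction p from it and then observes every SNP site
    independently with probability p.
    """

    n_chromosomes: int = 2
    chrom_length: int = 200_000
    het_rate: float = 0.0102
    n_cells: int = 12
    coverage_range: tuple[float, float] = (0.50, 0.78)
    genotype_error_rate: float = 1e-3
    co_rate: float = 1.3
    end_bias: float = 0.5
    n_fragments: int = 300
    fragment_length_range: tuple[int, int] = (10_000, 120_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")
        if self.chrom_length < 1:
            raise ConfigError("chrom_length must be >= 1")
        if not (0.0 <= self.het_rate < 1.0):
            raise ConfigError("het_rate must lie in [0, 1)")
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        lo, hi = self.coverage_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigError("coverage_range must satisfy 0 < low <= high <= 1")
        if not (0.0 <= self.genotype_error_rate < 1.0):
            raise ConfigError("genotype_error_rate must lie in [0, 1)")
        if self.co_rate < 0:
            raise ConfigError("co_rate must be >= 0")
        if self.end_bias <= 0:
            raise ConfigError("end_bias must be > 0")
        if self.n_fragments < 0:
            raise ConfigError("n_fragments must be >= 0")
        fmin, fmax = self.fragment_length_range
        if not (1 <= fmin <= fmax):
            raise ConfigError("fragment_length_range must satisfy 1 <= min <= max")
        if fmin > self.chrom_length:
            raise ConfigError("fragment_length_range min exceeds chrom_length")


@dataclass(frozen=True)
class SnpSite:
    """A heterozygous site: the two haplotypes differ here and nowhere else."""

    chromosome: str
    position: int  # 0-based
    allele_a: str
    allele_b: str


@dataclass(frozen=True)
class SnpTable:
    """Array view of all SNP sites of one chromosome (positions ascending)."""

    chromosome: str
    positions: np.ndarray  # int64, strictly increasing
    allele_a: np.ndarray  # '<U1'
    allele_b: np.ndarray  # '<U1'

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def sites(self) -> list[SnpSite]:
        return [
            SnpSite(self.chromosome, int(p), str(a), str(b))
            for p, a, b in zip(self.positions, self.allele_a, self.allele_b)
        ]

    @classmethod
    def from_sites(cls, chromosome: str, sites: Sequence[SnpSite]) -> "SnpTable":
        sites = sorted(
            (s for s in sites if s.chromosome == chromosome), key=lambda s: s.position
        )
        return cls(
            chromosome,
            np.array([s.position for s in sites], dtype=np.int64),
            np.array([s.allele_a for s in sites], dtype="<U1"),
            np.array([s.allele_b for s in sites], dtype="<U1"),
        )


@dataclass
class DiploidGenome:
    """Two haplotype sequences per chromosome plus the table of SNP sites."""

    hap_a: dict[str, str]
    hap_b: dict[str, str]
    snp_tables: dict[str, SnpTable]

    @property
    def chromosomes(self) -> list[str]:
        return list(self.hap_a)

    def chrom_length(self, chromosome: str) -> int:
        return len(self.hap_a[chromosome])

    def snp_table(self, chromosome: str) -> SnpTable:
        return self.snp_tables[chromosome]

    def sites(self) -> Iterator[SnpSite]:
        for chrom in self.chromosomes:
            yield from self.snp_tables[chrom].sites()

    def n_snps(self) -> int:
        return sum(t.n_sites for t in self.snp_tables.values())


@dataclass
class GameteTruth:
    """Ground-truth recombination structure of one gamete (one pollen cell).

    Each chromosome is a partition of [0, L) into alternating A/B segments;
    ``breakpoints`` are the segment starts strictly inside (0, L) and
    ``start_hap`` is the source haplotype of the first segment.
    """

    cell: int
    breakpoints: dict[str, np.ndarray]
    start_hap: dict[str, str]

    def source_at(self, chromosome: str, positions: np.ndarray) -> np.ndarray:
        """Source haplotype ('A'/'B') of this gamete at each position."""
        bp = self.breakpoints[chromosome]
        seg = np.searchsorted(bp, np.asarray(positions), side="right")
        first = self.start_hap[chromosome]
        other = "B" if first == "A" else "A"
        return np.where(seg % 2 == 0, first, other)

    def segments(self, chromosome: str, length: int) -> list[tuple[int, int, str]]:
        bp = self.breakpoints[chromosome]
        bounds = [0, *bp.tolist(), length]
        first = self.start_hap[chromosome]
        other = "B" if first == "A" else "A"
        return [
            (bounds[i], bounds[i + 1], first if i % 2 == 0 else other)
            for i in range(len(bounds) - 1)
        ]


@dataclass
class PollenObservation:
    """Observed SNP alleles of one cell, aligned to the genome's SNP tables.

    ``bases[chrom][i]`` is the observed base at the i-th SNP site of that
    chromosome, or '.' when the site dropped out. ``error_flags`` marks the
    calls that were flipped by the simulated genotype error (truth only).
    """

    cell: int
    bases: dict[str, np.ndarray]  # '<U1', '.' = no call
    error_flags: dict[str, np.ndarray]  # bool

    def n_called(self) -> int:
        return sum(int((b != ".").sum()) for b in self.bases.values())

    def n_sites(self) -> int:
        return sum(b.size for b in self.bases.values())

    def called_fraction(self) -> float:
        n = self.n_sites()
        return self.n_called() / n if n else float("nan")

    def n_errors(self) -> int:
        return sum(int(f.sum()) for f in self.error_flags.values())


@dataclass
class BacRecord:
    """A long haplotype-pure fragment (BAC/contig), the unit that gets phased.

    Real-mode fragments read from FASTA leave chromosome/start/end/truth
    haplotype as None; the simulator fills them in as ground truth.
    """

    id: str
    sequence: str
    chromosome: str | None = None
    start: int | None = None
    end: int | None = None
    truth_haplotype: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def midpoint(self) -> float:
        if self.start is None or self.end is None:
            raise ValueError(f"fragment {self.id} has no interval")
        return (self.start + self.end) / 2.0


def simulate_diploid_genome(config: SimConfig) -> DiploidGenome:
    """Draw two haplotypes per chromosome differing at Binomial(L, het_rate) sites."""
    rng = _rng(config.seed, _STREAM_GENOME)
    hap_a: dict[str, str] = {}
    hap_b: dict[str, str] = {}
    tables: dict[str, SnpTable] = {}
    for i in range(config.n_chromosomes):
        name = f"chr{i + 1}"
        codes = rng.integers(0, 4, size=config.chrom_length, dtype=np.int8)
        positions = np.flatnonzero(rng.random(config.chrom_length) < config.het_rate)
        offsets = rng.integers(1, 4, size=positions.size, dtype=np.int8)
        codes_b = codes.copy()
        codes_b[positions] = (codes[positions] + offsets) % 4
        hap_a[name] = _BASE_BYTES[codes].tobytes().decode("ascii")
        hap_b[name] = _BASE_BYTES[codes_b].tobytes().decode("ascii")
        tables[name] = SnpTable(
            name,
            positions.astype(np.int64),
            _BASE_BYTES[codes[positions]].astype("<U1"),
            _BASE_BYTES[codes_b[positions]].astype("<U1"),
        )
    return DiploidGenome(hap_a, hap_b, tables)


def simulate_gametes(genome: DiploidGenome, config: SimConfig) -> list[GameteTruth]:
    """One gamete per cell: Poisson(co_rate) crossovers per chromosome with
    end-biased Beta(end_bias, end_bias) positions; first segment by fair coin."""
    rng = _rng(config.seed, _STREAM_GAMETES)
    gametes = []
    for cell in range(config.n_cells):
        breakpoints: dict[str, np.ndarray] = {}
        start_hap: dict[str, str] = {}
        for chrom in genome.chromosomes:
            length = genome.chrom_length(chrom)
            n_co = int(rng.poisson(config.co_rate))
            pos = np.floor(
                rng.beta(config.end_bias, config.end_bias, size=n_co) * length
            ).astype(np.int64)
            pos = np.unique(np.clip(pos, 1, length - 1))
            breakpoints[chrom] = pos
            start_hap[chrom] = "A" if rng.integers(0, 2) == 0 else "B"
        gametes.append(GameteTruth(cell, breakpoints, start_hap))
    return gametes


def simulate_pollen_calls(
    genome: DiploidGenome, gametes: Sequence[GameteTruth], config: SimConfig
) -> list[PollenObservation]:
    """Observe each SNP site independently at the cell's drawn coverage, then
    flip the call to the other allele with probability genotype_error_rate."""
    rng = _rng(config.seed, _STREAM_CALLS)
    lo, hi = config.coverage_range
    observations = []
    for gamete in gametes:
        p = rng.uniform(lo, hi)
        bases: dict[str, np.ndarray] = {}
        flags: dict[str, np.ndarray] = {}
        for chrom in genome.chromosomes:
            table = genome.snp_table(chrom)
            n = table.n_sites
            observed = rng.random(n) < p
            source = gamete.source_at(chrom, table.positions)
            allele = np.where(source == "A", table.allele_a, table.allele_b)
            other = np.where(source == "A", table.allele_b, table.allele_a)
            err = (rng.random(n) < config.genotype_error_rate) & observed
            out = np.full(n, ".", dtype="<U1")
            out[observed] = np.where(err, other, allele)[observed]
            bases[chrom] = out
            flags[chrom] = err
        observations.append(PollenObservation(gamete.cell, bases, flags))
    return observations


def simulate_bacs(genome: DiploidGenome, config: SimConfig) -> list[BacRecord]:
    """Haplotype-pure fragments: chromosome ∝ length, haplotype by fair coin,
    length uniform in fragment_length_range, start uniform over valid starts."""
    fmin, fmax = config.fragment_length_range
    lengths = np.array([genome.chrom_length(c) for c in genome.chromosomes], dtype=float)
    if fmin > lengths.min():
        raise ConfigError("fragment_length_range min exceeds chrom_length")
    rng = _rng(config.seed, _STREAM_BACS)
    n = config.n_fragments
    if n == 0:
        return []
    chrom_idx = rng.choice(len(lengths), size=n, p=lengths / lengths.sum())
    haps = rng.integers(0, 2, size=n)
    records = []
    for i in range(n):
        chrom = genome.chromosomes[int(chrom_idx[i])]
        chrom_len = genome.chrom_length(chrom)
        length = int(rng.integers(fmin, min(fmax, chrom_len) + 1))
        start = int(rng.integers(0, chrom_len - length + 1))
        hap = "A" if haps[i] == 0 else "B"
        seq_source = genome.hap_a if hap == "A" else genome.hap_b
        records.append(
            BacRecord(
                id=f"frag{i:05d}",
                sequence=seq_source[chrom][start : start + length],
                chromosome=chrom,
                start=start,
                end=start + length,
                truth_haplotype=hap,
            )
        )
    return records


def simulate_all(config: SimConfig):
    """Convenience: genome, gametes, observations, fragments in one call."""
    genome = simulate_diploid_genome(config)
    gametes = simulate_gametes(genome, config)
    observations = simulate_pollen_calls(genome, gametes, config)
    bacs = simulate_bacs(genome, config)
    return genome, gametes, observations, bacs


def simulate_gene_triplets(
    n_genes: int,
    seed: int,
    gene_length: int = 3_000,
    het_rate: float = 0.0102,
    n_exons: int = 3,
    exon_fraction: float = 0.4,
    class_probs: Mapping[str, float] | None = None,
):
    """Synthetic (reference, haplotype A, haplotype B) gene triplets with truth.

    A "mosaic" reference splices a haplotype-A prefix onto a haplotype-B suffix
    at a uniform switch point in the middle half of the gene, emulating a
    collapsed diploid assembly that alternates between parental alleles. The
    returned truth label is derived from the realized construction (a drawn
    mosaic with no differing site on one side of the switch is in truth
    consistent with a single haplotype, and is labeled as such).

    Returns (triplets, truth) where truth maps gene id -> expected class.
    """
    from .mosaic import (
        CONSISTENT_A,
        CONSISTENT_B,
        IDENTICAL_AB,
        MOSAIC_EXON,
        MOSAIC_INTRON,
        GeneTriplet,
    )

    probs = dict(class_probs or {
        "consistent_A": 0.3,
        "consistent_B": 0.3,
        "identical_AB": 0.1,
        "mosaic": 0.3,
    })
    labels = list(probs)
    weights = np.array([probs[k] for k in labels], dtype=float)
    weights = weights / weights.sum()

    # Fixed exon layout: n_exons equal exons, one at the head of each segment.
    segment = gene_length // n_exons
    exon_len = max(1, int(round(segment * exon_fraction)))
    exons = [(i * segment, i * segment + exon_len) for i in range(n_exons)]

    rng = _rng(seed, _STREAM_GENES)
    drawn = rng.choice(len(labels), size=n_genes, p=weights)
    triplets: list[GeneTriplet] = []
    truth: dict[str, str] = {}
    for g in range(n_genes):
        gene_id = f"gene{g:04d}"
        codes_a = rng.integers(0, 4, size=gene_length, dtype=np.int8)
        intent = labels[int(drawn[g])]
        if intent == "identical_AB":
            codes_b = codes_a.copy()
        else:
            positions = np.flatnonzero(rng.random(gene_length) < het_rate)
            offsets = rng.integers(1, 4, size=positions.size, dtype=np.int8)
            codes_b = codes_a.copy()
            codes_b[positions] = (codes_a[positions] + offsets) % 4
        hap_a = _BASE_BYTES[codes_a].tobytes().decode("ascii")
        hap_b = _BASE_BYTES[codes_b].tobytes().decode("ascii")
        diffs = np.flatnonzero(codes_a != codes_b)

        if intent == "mosaic":
            switch = int(rng.uniform(0.25, 0.75) * gene_length)
            ref = hap_a[:switch] + hap_b[switch:]
            n_left = int((diffs < switch).sum())  # ref matches A there
            n_right = int(diffs.size) - n_left  # ref matches B there
            if diffs.size == 0:
                label = IDENTICAL_AB
            elif n_left == 0:
                label = CONSISTENT_B
            elif n_right == 0:
                label = CONSISTENT_A
            else:
                # minority haplotype's sites are the mosaic errors; on a count
                # tie the later (post-switch, B-matching) segment is the error.
                if n_left < n_right:
                    minority = diffs[diffs < switch]
                else:
                    minority = diffs[diffs >= switch]
                exonic = any(
                    any(s <= int(p) < e for (s, e) in exons) for p in minority
                )
                label = MOSAIC_EXON if exonic else MOSAIC_INTRON
        elif intent == "consistent_A":
            ref = hap_a
            label = CONSISTENT_A if diffs.size else IDENTICAL_AB
        elif intent == "consistent_B":
            ref = hap_b
            label = CONSISTENT_B if diffs.size else IDENTICAL_AB
        else:
            ref = hap_a
            label = IDENTICAL_AB

        triplets.append(GeneTriplet(gene_id, ref, hap_a, hap_b, list(exons)))
        truth[gene_id] = label
    return triplets, truth
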