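"""Assign fragments to reference chromosomes by breadth of coverage.

A fragment is anchored to the chromosome on which at least 80% of its own
positions are covered by matching canonical k-mers (interval union, never a
sum), mirroring the breadth-of-coverage rule used with whole-fragment
alignments. k-mer voting is deterministic and adequate at desk scale; PAF
input (``read_paf_anchors``) supports real aligner output instead.

Repetitive k-mers (more than ``max_hits`` locations in the whole reference)
are dropped from the index so repeats cannot dominate the vote — more than
half of a typical heterozygous tree genome is repetitive sequence.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import ConfigError, InputError, ParseError
from .sim import BacRecord

UNANCHORED = "UNANCHORED"

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i


def _canonical_kmers(sequence: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (min of forward / reverse-complement) k-mers of a sequence.

    Returns (kmers uint64, start positions int64); windows containing non-ACGT
    characters are dropped.
    """
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    invalid = codes < 0
    clean = np.where(invalid, 0, codes).astype(np.uint64)
    n_win = n - k + 1
    fwd = np.zeros(n_win, dtype=np.uint64)
    for j in range(k):  # Horner over the window, 4 bits.. base-4 digits
        fwd = fwd * np.uint64(4) + clean[j : j + n_win]
    rc_codes = (np.uint64(3) - clean)[::-1]
    rev = np.zeros(n_win, dtype=np.uint64)
    for j in range(k):
        rev = rev * np.uint64(4) + rc_codes[j : j + n_win]
    rev = rev[::-1]
    canonical = np.minimum(fwd, rev)
    bad = np.concatenate([[0], np.cumsum(invalid)])
    valid = (bad[k:] - bad[:-k]) == 0
    positions = np.flatnonzero(valid).astype(np.int64)
    return canonical[valid], positions


class KmerIndex:
    """Canonical k-mer -> (chromosome, position) map with a repeat cutoff."""

    def __init__(
        self,
        k: int,
        max_hits: int,
        per_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
        n_positions: int,
    ):
        self.k = k
        self.max_hits = max_hits
        self._per_chrom = per_chrom  # chrom -> (kmers sorted, positions parallel)
        self.n_positions = n_positions

    @property
    def chromosomes(self) -> list[str]:
        return list(self._per_chrom)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """All indexed locations of a k-mer (canonical form), for diagnostics."""
        if len(kmer) != self.k:
            raise InputError(f"k-mer length {len(kmer)} != k={self.k}")
        km, _ = _canonical_kmers(kmer, self.k)
        if km.size == 0:
            return []
        hits = []
        for chrom, (arr, pos) in self._per_chrom.items():
            lo, hi = np.searchsorted(arr, km[0], side="left"), np.searchsorted(
                arr, km[0], side="right"
            )
            hits.extend((chrom, int(p)) for p in pos[lo:hi])
        return hits


def build_kmer_index(
    reference: Mapping[str, str],
    k: int = 21,
    max_hits: int = 10,
    chrom_of: Callable[[str], str] | None = None,
) -> KmerIndex:
    """Index every canonical k-mer of the reference, dropping repetitive ones.

    ``chrom_of`` maps record names to chromosome ids, so a diploid reference
    (records "chr1_A"/"chr1_B") can be indexed under its chromosome names.
    """
    if k % 2 == 0:
        raise ConfigError("k must be odd")
    if not (11 <= k <= 31):
        raise ConfigError("k must lie in [11, 31]")
    if max_hits < 1:
        raise ConfigError("max_hits must be >= 1")
    if not reference:
        raise InputError("empty reference")

    by_chrom: dict[str, list[np.ndarray]] = {}
    pos_by_chrom: dict[str, list[np.ndarray]] = {}
    all_kmers = []
    for name, seq in reference.items():
        chrom = chrom_of(name) if chrom_of else name
        km, pos = _canonical_kmers(seq, k)
        by_chrom.setdefault(chrom, []).append(km)
        pos_by_chrom.setdefault(chrom, []).append(pos)
        all_kmers.append(km)
    concat = np.concatenate(all_kmers) if all_kmers else np.empty(0, dtype=np.uint64)
    uniq, counts = np.unique(concat, return_counts=True)
    repetitive = uniq[counts > max_hits]

    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    n_positions = 0
    for chrom in by_chrom:
        km = np.concatenate(by_chrom[chrom])
        pos = np.concatenate(pos_by_chrom[chrom])
        if repetitive.size:
            idx = np.searchsorted(repetitive, km)
            idx = np.clip(idx, 0, repetitive.size - 1)
            keep = repetitive[idx] != km
            km, pos = km[keep], pos[keep]
        order = np.argsort(km, kind="stable")
        per_chrom[chrom] = (km[order], pos[order])
        n_positions += km.size
    return KmerIndex(k, max_hits, per_chrom, n_positions)


@dataclass
class AnchorAssignment:
    """Best-chromosome call for one fragment; position is the estimated midpoint."""

    fragment_id: str
    chromosome: str | None
    coverage: float
    runner_up_coverage: float
    position: float | None = None
    reason: str | None = None

    @property
    def anchored(self) -> bool:
        return self.chromosome is not None


def _union_coverage(positions: np.ndarray, k: int, length: int) -> float:
    """Length of the union of [p, p+k) intervals divided by fragment length."""
    if positions.size == 0:
        return 0.0
    d = np.diff(positions)
    covered = int(np.minimum(d, k).sum()) + k
    return covered / length


def anchor_fragment(
    fragment: BacRecord, index: KmerIndex, min_coverage: float = 0.80
) -> AnchorAssignment:
    """Anchor one fragment by canonical k-mer breadth of coverage.

    Ties between the two best chromosomes are reported UNANCHORED with reason
    "ambiguous" rather than guessed.
    """
    k = index.k
    if fragment.length < k:
        warnings.warn(
            f"fragment {fragment.id} shorter than k={k}; left unanchored",
            stacklevel=2,
        )
        return AnchorAssignment(fragment.id, None, 0.0, 0.0, None, "too_short")
    km, frag_pos = _canonical_kmers(fragment.sequence, k)
    order = np.argsort(km, kind="stable")  # sorted needles keep the search cache-local
    km_s, pos_s = km[order], frag_pos[order]
    scored: list[tuple[float, str, np.ndarray, np.ndarray]] = []
    for chrom, (arr, ref_pos) in index._per_chrom.items():
        if arr.size == 0:
            scored.append((0.0, chrom, pos_s[:0], arr[:0]))
            continue
        lo = np.searchsorted(arr, km_s, side="left")
        hit = (lo < arr.size) & (arr[np.minimum(lo, arr.size - 1)] == km_s)
        p = np.sort(pos_s[hit])
        cov = _union_coverage(p, k, fragment.length)
        scored.append((cov, chrom, pos_s[hit], ref_pos[lo[hit]]))
    scored.sort(key=lambda t: (-t[0], t[1]))
    best_cov, best_chrom, best_p, best_ref = scored[0] if scored else (0.0, None, None, None)
    runner = scored[1][0] if len(scored) > 1 else 0.0
    if best_cov == 0.0:
        return AnchorAssignment(fragment.id, None, 0.0, runner, None, "no_hits")
    if best_cov < min_coverage:
        return AnchorAssignment(
            fragment.id, None, best_cov, runner, None, "below_min_coverage"
        )
    if len(scored) > 1 and scored[1][0] == best_cov:
        return AnchorAssignment(fragment.id, None, best_cov, runner, None, "ambiguous")
    start_est = float(np.median(best_ref - best_p))
    return AnchorAssignment(
        fragment.id, best_chrom, best_cov, runner, start_est + fragment.length / 2.0
    )


def anchor_fragments(
    fragments: Sequence[BacRecord], index: KmerIndex, min_coverage: float = 0.80
) -> list[AnchorAssignment]:
    return [anchor_fragment(f, index, min_coverage) for f in fragments]


def read_paf_anchors(path, min_coverage: float = 0.80) -> list[AnchorAssignment]:
    """Anchor fragments from PAF alignments (minimap2-style, 12+ tab fields).

    Breadth of coverage of a (query, target) pair is the union of the query
    intervals divided by the query length; the same >= min_coverage best-
    chromosome rule applies.
    """
    per_query: dict[str, dict[str, list[tuple[int, int, int, int]]]] = {}
    qlen_of: dict[str, int] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"PAF line {lineno}: expected >= 12 fields, got {len(fields)}")
            try:
                qname = fields[0]
                qlen = int(fields[1])
                qstart, qend = int(fields[2]), int(fields[3])
                tname = fields[5]
                tstart, tend = int(fields[7]), int(fields[8])
            except ValueError as exc:
                raise ParseError(f"PAF line {lineno}: {exc}") from exc
            if qname not in per_query:
                order.append(qname)
            if qlen_of.setdefault(qname, qlen) != qlen:
                raise ParseError(f"PAF line {lineno}: inconsistent query length for {qname}")
            per_query.setdefault(qname, {}).setdefault(tname, []).append(
                (qstart, qend, tstart, tend)
            )
    out = []
    for qname in order:
        qlen = qlen_of[qname]
        scored = []
        for tname, rows in per_query[qname].items():
            merged = _merge_intervals([(s, e) for s, e, _, _ in rows])
            cov = sum(e - s for s, e in merged) / qlen
            t_lo = min(r[2] for r in rows)
            t_hi = max(r[3] for r in rows)
            scored.append((cov, tname, (t_lo + t_hi) / 2.0))
        scored.sort(key=lambda t: (-t[0], t[1]))
        best_cov, best_t, best_mid = scored[0]
        runner = scored[1][0] if len(scored) > 1 else 0.0
        if best_cov < min_coverage:
            out.append(
                AnchorAssignment(qname, None, best_cov, runner, None, "below_min_coverage")
            )
        elif len(scored) > 1 and scored[1][0] == best_cov:
            out.append(AnchorAssignment(qname, None, best_cov, runner, None, "ambiguous"))
        else:
            out.append(AnchorAssignment(qname, best_t, best_cov, runner, best_mid))
    return out


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


@dataclass
class AnchorSummary:
    n_total: int
    n_anchored: int
    n_unanchored: int
    per_chromosome: Counter

    @property
    def anchored_fraction(self) -> float:
        return self.n_anchored / self.n_total if self.n_total else 0.0


def summarize_anchors(assignments: Sequence[AnchorAssignment]) -> AnchorSummary:
    per_chrom: Counter = Counter(
        a.chromosome for a in assignments if a.chromosome is not None
    )
    n_anchored = sum(per_chrom.values())
    return AnchorSummary(
        n_total=len(assignments),
        n_anchored=n_anchored,
        n_unanchored=len(assignments) - n_anchored,
        per_chromosome=per_chrom,
    )
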