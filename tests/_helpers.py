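"""Shared fixtures-free helpers and independent brute-force oracles."""

import numpy as np

from pollenphase import Barcode, BarcodeProfile, PhaseTrack

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def random_seq(n: int, rng) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_profile(frag_id, code, n_snps=10, observed=None, low_conf=None):
    consensus = Barcode.from_string(code)
    observed = Barcode.from_string(observed or "1" * consensus.width)
    low_conf = Barcode.from_string(low_conf or "0" * consensus.width)
    return BarcodeProfile(
        fragment_id=frag_id,
        type_counts={consensus: n_snps},
        consensus=consensus,
        n_informative_snps=n_snps,
        n_supporting_cells=observed.popcount(),
        observed_mask=observed,
        low_confidence_mask=low_conf,
    )


def make_track(phases, positions=None, cell=0, chrom="chr1"):
    positions = positions or list(range(1, len(phases) + 1))
    return PhaseTrack(
        cell,
        chrom,
        np.array(positions, dtype=float),
        np.array(list(phases), dtype="<U1"),
    )


def brute_force_events(phases, positions, min_run):
    """Independent run-length oracle: drop short runs, merge, emit switches."""
    runs = []
    for i, h in enumerate(phases):
        if runs and runs[-1][0] == h:
            runs[-1][2] = i
        else:
            runs.append([h, i, i])
    runs = [r for r in runs if r[2] - r[1] + 1 >= min_run]
    merged = []
    for r in runs:
        if merged and merged[-1][0] == r[0]:
            merged[-1][2] = r[2]
        else:
            merged.append(list(r))
    return [
        (positions[a[2]], positions[b[1]], a[0], b[0])
        for a, b in zip(merged, merged[1:])
    ]


def brute_force_coverage(fragment: str, reference: dict, k: int) -> dict:
    """Position-set oracle for breadth of coverage (canonical k-mer matching)."""
    out = {}
    for chrom, seq in reference.items():
        kmers = set()
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            kmers.add(min(km, revcomp(km)))
        covered = set()
        for i in range(len(fragment) - k + 1):
            km = fragment[i : i + k]
            if min(km, revcomp(km)) in kmers:
                covered.update(range(i, i + k))
        out[chrom] = len(covered) / len(fragment)
    return out


def brute_force_affine_score(
    a: str, b: str, match=1.0, mismatch=-1.0, gap_open=4.0, gap_extend=1.0
) -> float:
    """Exhaustive affine-gap global alignment score by memoized recursion.

    A gap of length L costs gap_open + L * gap_extend. States: 0 = free,
    1 = extending a gap in a (deletion from b), 2 = extending a gap in b.
    """
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        scores = []
        if i < len(a) and j < len(b):
            sub = match if a[i] == b[j] else mismatch
            scores.append(sub + best(i + 1, j + 1, 0))
        if i < len(a):  # a[i] aligned to a gap
            open_cost = 0.0 if state == 1 else gap_open
            scores.append(-(open_cost + gap_extend) + best(i + 1, j, 1))
        if j < len(b):  # b[j] aligned to a gap
            open_cost = 0.0 if state == 2 else gap_open
            scores.append(-(open_cost + gap_extend) + best(i, j + 1, 2))
        return max(scores)

    return best(0, 0, 0)
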