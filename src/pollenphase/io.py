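"""Readers and writers for the standard formats touched by the pipeline.

Conventions: all genomic intervals are 0-based half-open (BED); VCF positions
are converted at the boundary only. The cell order fixed in the run
configuration is authoritative for barcode bit semantics and is stamped into
every header that carries per-cell columns.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .anchor import UNANCHORED, AnchorAssignment
from .barcode import Barcode, BarcodeProfile, Call, GenotypeMatrix
from .errors import ParseError, SchemaError
from .mco import CrossoverEvent
from .phase import UNPHASED, PhaseCall
from .sim import (
    BacRecord,
    DiploidGenome,
    GameteTruth,
    PollenObservation,
    SnpSite,
    SnpTable,
)

logger = logging.getLogger(__name__)

_ACGT = set("ACGT")


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------


def write_fasta(records: Mapping[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_haplotype_fasta(genome: DiploidGenome, path) -> None:
    """Two records per chromosome, ids "<chrom>_A" / "<chrom>_B"."""
    records: dict[str, str] = {}
    for chrom in genome.chromosomes:
        records[f"{chrom}_A"] = genome.hap_a[chrom]
        records[f"{chrom}_B"] = genome.hap_b[chrom]
    write_fasta(records, path)


# --------------------------------------------------------------------------
# VCF (SNP truth / real-mode SNP input)
# --------------------------------------------------------------------------


def write_snps_vcf(
    sites: Sequence[SnpSite], contig_lengths: Mapping[str, int], path
) -> None:
    """Minimal VCF: REF is the haplotype-A allele, ALT the haplotype-B allele."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sites:
            fh.write(
                f"{s.chromosome}\t{s.position + 1}\t.\t{s.allele_a}\t{s.allele_b}\t.\tPASS\t.\n"
            )


def read_vcf_snps(path) -> list[SnpSite]:
    """Biallelic SNP records as SnpSite (0-based); indels and multi-allelic
    records are skipped with a counted warning."""
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    sites: list[SnpSite] = []
    skipped = 0
    with vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or rec.ref is None
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref.upper() not in _ACGT
                or alts[0].upper() not in _ACGT
            ):
                skipped += 1
                continue
            sites.append(SnpSite(rec.chrom, rec.start, rec.ref.upper(), alts[0].upper()))
    if skipped:
        logger.warning("skipped %d non-biallelic-SNP records in %s", skipped, path)
    return sites


# --------------------------------------------------------------------------
# Per-cell SNP calls (TSV: chrom, pos0, cell, base)
# --------------------------------------------------------------------------


def write_pollen_calls_tsv(
    observations: Sequence[PollenObservation],
    genome: DiploidGenome,
    path,
    cell_order: Sequence[str],
) -> None:
    rows = []
    for obs in observations:
        cell_name = cell_order[obs.cell]
        for chrom in genome.chromosomes:
            table = genome.snp_table(chrom)
            bases = obs.bases[chrom]
            for i in np.flatnonzero(bases != "."):
                rows.append((chrom, int(table.positions[i]), cell_name, bases[i]))
    pd.DataFrame(rows, columns=["chrom", "pos", "cell", "base"]).to_csv(
        path, sep="\t", index=False
    )


def read_pollen_calls_tsv(
    path, snp_tables: Mapping[str, SnpTable], cell_order: Sequence[str]
) -> list[PollenObservation]:
    """Rebuild site-aligned observations from the sparse per-cell call table."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "cell": str, "base": str})
    cell_index = {name: i for i, name in enumerate(cell_order)}
    unknown = set(df["cell"]) - set(cell_index)
    if unknown:
        raise SchemaError(f"unknown cells in {path}: {sorted(unknown)}")
    observations = [
        PollenObservation(
            i,
            {c: np.full(t.n_sites, ".", dtype="<U1") for c, t in snp_tables.items()},
            {c: np.zeros(t.n_sites, dtype=bool) for c, t in snp_tables.items()},
        )
        for i in range(len(cell_order))
    ]
    for chrom, sub in df.groupby("chrom"):
        table = snp_tables[str(chrom)]
        idx = np.searchsorted(table.positions, sub["pos"].to_numpy())
        valid = (idx < table.n_sites) & (
            table.positions[np.minimum(idx, table.n_sites - 1)]
            == sub["pos"].to_numpy()
        )
        if not valid.all():
            bad = sub["pos"].to_numpy()[~valid][0]
            raise SchemaError(f"call at {chrom}:{bad} is not a known SNP site")
        for (cell_name, i_site, base) in zip(sub["cell"], idx, sub["base"]):
            observations[cell_index[cell_name]].bases[str(chrom)][i_site] = base
    return observations


# --------------------------------------------------------------------------
# Fragments (FASTA + truth BED) and gamete truth BED
# --------------------------------------------------------------------------


def write_fragments(bacs: Sequence[BacRecord], fasta_path, bed_path=None) -> None:
    write_fasta({b.id: b.sequence for b in bacs}, fasta_path)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for b in bacs:
                hap = b.truth_haplotype or "."
                fh.write(f"{b.chromosome}\t{b.start}\t{b.end}\t{b.id}:{hap}\t0\t+\n")


def read_fragments_fasta(path) -> list[BacRecord]:
    return [BacRecord(id=name, sequence=seq) for name, seq in read_fasta(path).items()]


def read_fragments_bed(path) -> list[BacRecord]:
    """Truth intervals written by write_fragments (sequences not restored)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path} line {lineno}: expected >= 4 BED fields")
            name, _, hap = fields[3].partition(":")
            out.append(
                BacRecord(
                    id=name,
                    sequence="",
                    chromosome=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    truth_haplotype=hap or None,
                )
            )
    return out


def write_gamete_bed(gamete: GameteTruth, genome: DiploidGenome, path) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chromosomes:
            for start, end, hap in gamete.segments(chrom, genome.chrom_length(chrom)):
                fh.write(f"{chrom}\t{start}\t{end}\t{hap}\t0\t+\n")


# --------------------------------------------------------------------------
# Genotype matrices (TSV dialect: fragment, pos, one column per cell; 1/0/.)
# --------------------------------------------------------------------------

_CALL_TO_CHAR = {int(Call.MATCH): "1", int(Call.MISMATCH): "0", int(Call.NOCALL): "."}
_CHAR_TO_CALL = {v: k for k, v in _CALL_TO_CHAR.items()}


def write_genotype_matrix(
    matrices: Sequence[GenotypeMatrix], cell_order: Sequence[str], path
) -> None:
    with open(path, "w") as fh:
        fh.write("fragment\tpos\t" + "\t".join(cell_order) + "\n")
        for m in matrices:
            for pos, row in zip(m.positions, m.calls):
                cells = "\t".join(_CALL_TO_CHAR[int(v)] for v in row)
                fh.write(f"{m.fragment_id}\t{int(pos)}\t{cells}\n")


def read_genotype_matrix(path, cell_order: Sequence[str]) -> dict[str, GenotypeMatrix]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["fragment", "pos"]:
        raise SchemaError(f"{path}: first columns must be fragment, pos")
    header_cells = list(df.columns[2:])
    unknown = set(header_cells) - set(cell_order)
    if unknown:
        raise SchemaError(f"{path}: unknown cells in header: {sorted(unknown)}")
    missing = set(cell_order) - set(header_cells)
    if missing:
        raise SchemaError(f"{path}: cells missing from header: {sorted(missing)}")
    dup = df.duplicated(subset=["fragment", "pos"])
    if dup.any():
        row = df[dup].iloc[0]
        raise SchemaError(
            f"{path}: duplicated row for fragment {row['fragment']} pos {row['pos']}"
        )
    out: dict[str, GenotypeMatrix] = {}
    for frag, sub in df.groupby("fragment", sort=False):
        sub = sub.sort_values("pos", key=lambda s: s.astype(int))
        calls = np.full((len(sub), len(cell_order)), int(Call.NOCALL), dtype=np.int8)
        for j, cell in enumerate(cell_order):
            col = sub[cell].fillna(".")
            try:
                calls[:, j] = [_CHAR_TO_CALL[v] for v in col]
            except KeyError as exc:
                raise SchemaError(f"{path}: bad genotype value {exc} for cell {cell}")
        out[str(frag)] = GenotypeMatrix(
            str(frag), sub["pos"].astype(int).to_numpy(dtype=np.int64), calls
        )
    return out


# --------------------------------------------------------------------------
# Barcode profiles
# --------------------------------------------------------------------------


def write_profiles(
    profiles: Sequence[BarcodeProfile], cell_order: Sequence[str], path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# cells=" + ",".join(cell_order) + "\n"
            "fragment\tn_snps\tn_cells\tconsensus\tobserved_mask\t"
            "low_confidence_mask\ttype_counts\n"
        )
        for p in profiles:
            counts = ",".join(
                f"{code}:{n}"
                for code, n in sorted(
                    p.type_counts.items(), key=lambda kv: (-kv[1], kv[0].value)
                )
            )
            fh.write(
                f"{p.fragment_id}\t{p.n_informative_snps}\t{p.n_supporting_cells}\t"
                f"{p.consensus}\t{p.observed_mask}\t{p.low_confidence_mask}\t{counts}\n"
            )


def read_profiles(path) -> tuple[dict[str, BarcodeProfile], list[str]]:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("# cells="):
            raise SchemaError(f"{path}: missing '# cells=' header line")
        cell_order = first[len("# cells=") :].split(",")
        header = fh.readline().rstrip("\n").split("\t")
        expected = [
            "fragment", "n_snps", "n_cells", "consensus", "observed_mask",
            "low_confidence_mask", "type_counts",
        ]
        if header != expected:
            raise SchemaError(f"{path}: unexpected profile columns {header}")
        out: dict[str, BarcodeProfile] = {}
        for lineno, line in enumerate(fh, 3):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 7:
                raise ParseError(f"{path} line {lineno}: expected 7 fields")
            frag, n_snps, n_cells, cons, obs, low, counts_s = fields
            type_counts = {}
            if counts_s:
                for item in counts_s.split(","):
                    code, _, n = item.partition(":")
                    type_counts[Barcode.from_string(code)] = int(n)
            out[frag] = BarcodeProfile(
                fragment_id=frag,
                type_counts=type_counts,
                consensus=Barcode.from_string(cons),
                n_informative_snps=int(n_snps),
                n_supporting_cells=int(n_cells),
                observed_mask=Barcode.from_string(obs),
                low_confidence_mask=Barcode.from_string(low),
            )
    return out, cell_order


# --------------------------------------------------------------------------
# Anchor and phase tables, crossover BED
# --------------------------------------------------------------------------


def write_anchor_table(assignments: Sequence[AnchorAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("fragment\tchromosome\tcoverage\trunner_up\tposition\treason\n")
        for a in assignments:
            chrom = a.chromosome if a.chromosome is not None else UNANCHORED
            pos = f"{a.position:.1f}" if a.position is not None else "."
            fh.write(
                f"{a.fragment_id}\t{chrom}\t{a.coverage:.6f}\t"
                f"{a.runner_up_coverage:.6f}\t{pos}\t{a.reason or '.'}\n"
            )


def read_anchor_table(path) -> list[AnchorAssignment]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        chrom = None if row["chromosome"] == UNANCHORED else row["chromosome"]
        out.append(
            AnchorAssignment(
                fragment_id=row["fragment"],
                chromosome=chrom,
                coverage=float(row["coverage"]),
                runner_up_coverage=float(row["runner_up"]),
                position=None if row["position"] == "." else float(row["position"]),
                reason=None if row["reason"] == "." else row["reason"],
            )
        )
    return out


def write_phase_table(calls: Sequence[PhaseCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("fragment\tchromosome\tcall\treason\tmargin\tn_snps\tposition\n")
        for c in calls:
            fh.write(
                f"{c.fragment_id}\t{c.chromosome or '.'}\t{c.call}\t"
                f"{c.reason or '.'}\t{c.margin if c.margin is not None else '.'}\t"
                f"{c.n_snps}\t"
                f"{f'{c.position:.1f}' if c.position is not None else '.'}\n"
            )


def read_phase_table(path) -> list[PhaseCall]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        out.append(
            PhaseCall(
                fragment_id=row["fragment"],
                chromosome=None if row["chromosome"] == "." else row["chromosome"],
                call=row["call"],
                reason=None if row["reason"] == "." else row["reason"],
                margin=None if row["margin"] == "." else int(row["margin"]),
                n_snps=int(row["n_snps"]),
                position=None if row["position"] == "." else float(row["position"]),
            )
        )
    return out


def write_events_bed(
    events: Sequence[CrossoverEvent], path, cell_order: Sequence[str] | None = None
) -> None:
    """Events as BED: chrom, left, right, name=cell, score=0, strand=."""
    with open(path, "w") as fh:
        for e in sorted(events, key=lambda e: (e.chromosome, e.left, e.cell)):
            name = cell_order[e.cell] if cell_order else f"cell{e.cell:02d}"
            fh.write(
                f"{e.chromosome}\t{int(e.left)}\t{int(np.ceil(e.right))}\t{name}\t0\t.\n"
            )


def read_exons_bed(path) -> dict[str, list[tuple[int, int]]]:
    """Gene-relative exon intervals: columns gene, start, end."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path} line {lineno}: expected >= 3 fields")
            out.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    return {g: sorted(v) for g, v in out.items()}
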