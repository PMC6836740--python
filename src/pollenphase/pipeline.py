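"""End-to-end simulated run: genome -> gametes -> cells -> fragments ->
anchoring -> barcodes -> phasing -> crossovers -> evaluation against truth."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import anchor as anchor_mod
from . import barcode as barcode_mod
from . import mco as mco_mod
from . import phase as phase_mod
from . import sim as sim_mod
from .config import RunConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: RunConfig
    genome: sim_mod.DiploidGenome
    gametes: list[sim_mod.GameteTruth]
    observations: list[sim_mod.PollenObservation]
    bacs: list[sim_mod.BacRecord]
    anchors: list[anchor_mod.AnchorAssignment]
    anchor_summary: anchor_mod.AnchorSummary
    profiles: dict[str, barcode_mod.BarcodeProfile]
    calls: list[phase_mod.PhaseCall]
    phase_summary: phase_mod.PhaseSummary
    families: dict[str, tuple[phase_mod.HaplotypeFamily, phase_mod.HaplotypeFamily]]
    tracks: dict[tuple[int, str], mco_mod.PhaseTrack]
    events: list[mco_mod.CrossoverEvent]
    crossover_summary: mco_mod.CrossoverSummary
    landscape: mco_mod.Landscape
    phasing_eval: phase_mod.PhasingEvaluation
    crossover_match: mco_mod.CrossoverMatch
    projected_tracks: dict[tuple[int, str], mco_mod.PhaseTrack]
    projection: "ProjectionComparison"
    truth_crossovers: int = 0


def _strip_hap_suffix(name: str) -> str:
    return name.rsplit("_", 1)[0]


def truth_projected_tracks(
    genome: sim_mod.DiploidGenome,
    gametes: list[sim_mod.GameteTruth],
    observations: list[sim_mod.PollenObservation],
    bacs: list[sim_mod.BacRecord],
    calls: list[phase_mod.PhaseCall],
    min_cells: int = 2,
) -> dict[tuple[int, str], mco_mod.PhaseTrack]:
    """Project ground truth onto the pipeline's fragment resolution.

    For every phased fragment and cell, the cell's expected vote is the
    majority gamete source over the fragment's SNP sites that the cell
    observed (restricted to sites observed in >= min_cells cells, mirroring
    the minimum-support filter); a tie collapses to the non-fragment
    haplotype, exactly as a no-call-heavy consensus bit does. Crossovers that
    never flip any fragment's majority vote — e.g. a double-crossover segment
    shorter than the fragments spanning it — are invisible at fragment
    resolution to any detector, and the projected tracks define precisely
    which switches are expressed in the observable data.
    """
    bac_by_id = {b.id: b for b in bacs}
    tracks: dict[tuple[int, str], list[tuple[float, str]]] = {}
    support: dict[str, np.ndarray] = {}
    for chrom in genome.chromosomes:
        stack = np.stack([obs.bases[chrom] != "." for obs in observations])
        support[chrom] = stack.sum(axis=0)
    for c in calls:
        if c.call == phase_mod.UNPHASED or c.chromosome is None:
            continue
        frag = bac_by_id[c.fragment_id]
        chrom = frag.chromosome
        table = genome.snp_table(chrom)
        i0, i1 = np.searchsorted(table.positions, [frag.start, frag.end])
        kept = support[chrom][i0:i1] >= min_cells
        for cell, (gamete, obs) in enumerate(zip(gametes, observations)):
            observed = (obs.bases[chrom][i0:i1] != ".") & kept
            if not observed.any():
                continue
            src = gamete.source_at(chrom, table.positions[i0:i1][observed])
            n_own = int((src == frag.truth_haplotype).sum())
            n_other = int(src.size) - n_own
            if n_own > n_other:
                phase = frag.truth_haplotype
            else:  # tie collapses to 0, i.e. the other haplotype
                phase = "B" if frag.truth_haplotype == "A" else "A"
            tracks.setdefault((cell, chrom), []).append((c.position, phase))
    out: dict[tuple[int, str], mco_mod.PhaseTrack] = {}
    for cell in range(len(gametes)):
        for chrom in genome.chromosomes:
            pts = sorted(tracks.get((cell, chrom), []))
            out[(cell, chrom)] = mco_mod.PhaseTrack(
                cell,
                chrom,
                np.array([p for p, _ in pts], dtype=np.float64),
                np.array([h for _, h in pts], dtype="<U1"),
            )
    return out


def _intervals_overlap(a: mco_mod.CrossoverEvent, b: mco_mod.CrossoverEvent) -> bool:
    return a.left <= b.right and b.left <= a.right


@dataclass
class ProjectionComparison:
    """Pipeline events vs the truth-projection events, per run."""

    n_projected: int
    n_pipeline: int
    n_projected_matched: int  # projected events overlapped by a pipeline event
    n_pipeline_unmatched: int

    @property
    def all_projected_detected(self) -> bool:
        return self.n_projected_matched == self.n_projected


def compare_to_projection(
    events: list[mco_mod.CrossoverEvent],
    projected: dict[tuple[int, str], mco_mod.PhaseTrack],
    min_run: int,
) -> ProjectionComparison:
    by_track: dict[tuple[int, str], list[mco_mod.CrossoverEvent]] = {}
    for e in events:
        by_track.setdefault((e.cell, e.chromosome), []).append(e)
    n_proj = n_pipe = n_matched = n_unmatched = 0
    for key, track in projected.items():
        proj_events = mco_mod.detect_crossovers(track, min_run)
        pipe_events = by_track.get(key, [])
        n_proj += len(proj_events)
        n_pipe += len(pipe_events)
        used = [False] * len(pipe_events)
        for pe in proj_events:
            for i, ev in enumerate(pipe_events):
                if not used[i] and _intervals_overlap(pe, ev):
                    used[i] = True
                    n_matched += 1
                    break
        n_unmatched += used.count(False)
    return ProjectionComparison(n_proj, n_pipe, n_matched, n_unmatched)


def run_simulated_pipeline(
    config: RunConfig, slack_points: int = 1
) -> PipelineResult:
    """Run every stage on simulated data and score it against ground truth."""
    sim = config.sim
    genome, gametes, observations, bacs = sim_mod.simulate_all(sim)
    logger.info("simulated %d SNPs, %d fragments", genome.n_snps(), len(bacs))

    # anchor against the diploid reference: either haplotype record maps to
    # the same chromosome id; haplotype identity is the phasing module's job.
    reference = {}
    for chrom in genome.chromosomes:
        reference[f"{chrom}_A"] = genome.hap_a[chrom]
        reference[f"{chrom}_B"] = genome.hap_b[chrom]
    index = anchor_mod.build_kmer_index(
        reference, k=config.anchor.k, max_hits=config.anchor.max_hits,
        chrom_of=_strip_hap_suffix,
    )
    anchors = anchor_mod.anchor_fragments(bacs, index, config.anchor.min_coverage)
    anchor_summary = anchor_mod.summarize_anchors(anchors)

    bac_by_id = {b.id: b for b in bacs}
    profiles: dict[str, barcode_mod.BarcodeProfile] = {}
    for a in anchors:
        if a.chromosome is None:
            continue
        frag = bac_by_id[a.fragment_id]
        profiles[a.fragment_id] = barcode_mod.build_profile(
            frag, genome.snp_table(frag.chromosome), observations,
            min_cells=config.barcode.min_cells,
        )

    calls, phase_summary, families = phase_mod.phase_genome(
        anchors, profiles, config.phase
    )
    phasing_eval = phase_mod.evaluate_phasing(calls, bacs)

    tracks: dict[tuple[int, str], mco_mod.PhaseTrack] = {}
    events: list[mco_mod.CrossoverEvent] = []
    for cell in range(sim.n_cells):
        for chrom in genome.chromosomes:
            track = mco_mod.build_phase_track(calls, profiles, cell, chrom)
            tracks[(cell, chrom)] = track
            events.extend(mco_mod.detect_crossovers(track, config.mco.min_run))
    co_summary = mco_mod.crossover_summary(events, sim.n_cells, sim.n_chromosomes)
    landscape = mco_mod.crossover_landscape(
        events,
        {c: genome.chrom_length(c) for c in genome.chromosomes},
        config.mco.n_bins,
    )

    # score detected events against the simulated breakpoints
    totals = dict(n_truth=0, n_detected=0, n_matched=0, n_detectable=0,
                  n_detectable_matched=0)
    truth_total = 0
    by_track: dict[tuple[int, str], list[mco_mod.CrossoverEvent]] = {}
    for e in events:
        by_track.setdefault((e.cell, e.chromosome), []).append(e)
    for cell in range(sim.n_cells):
        for chrom in genome.chromosomes:
            bp = gametes[cell].breakpoints[chrom]
            truth_total += bp.size
            m = mco_mod.match_events_to_breakpoints(
                by_track.get((cell, chrom), []),
                bp,
                tracks[(cell, chrom)].positions,
                min_run=config.mco.min_run,
                slack_points=slack_points,
            )
            for k in totals:
                totals[k] += getattr(m, k)
    crossover_match = mco_mod.CrossoverMatch(**totals)

    projected = truth_projected_tracks(
        genome, gametes, observations, bacs, calls, config.barcode.min_cells
    )
    projection = compare_to_projection(events, projected, config.mco.min_run)

    return PipelineResult(
        config=config,
        genome=genome,
        gametes=gametes,
        observations=observations,
        bacs=bacs,
        anchors=anchors,
        anchor_summary=anchor_summary,
        profiles=profiles,
        calls=calls,
        phase_summary=phase_summary,
        families=families,
        tracks=tracks,
        events=events,
        crossover_summary=co_summary,
        landscape=landscape,
        phasing_eval=phasing_eval,
        crossover_match=crossover_match,
        projected_tracks=projected,
        projection=projection,
        truth_crossovers=truth_total,
    )
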