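"""Prophage detection in bacterial host genomes.

Host CDS are scanned with the family model libraries; loci are called from
runs of consecutive hit genes (consecutiveness measured in gene ordinals,
tolerant of a bounded number of intervening non-hit genes) and classified
with the same evidence rule as free phage genomes.  Called loci can be
benchmarked against an external prophage-coordinate table (e.g. another
predictor's output) by interval overlap.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .genome_io import ProteinRecord, Replicon, extract_cds_proteins
from .profile_hmm import HmmHit, ProfileHMM, filter_hits, scan
from .taxonomy import FamilyModelSet, classify_from_hits

logger = logging.getLogger("classiphage")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneHit:
    """A filtered model hit placed on a host gene."""

    hit: HmmHit
    replicon_id: str
    start: int
    end: int
    strand: str
    ordinal: int  # gene index on the replicon, by start coordinate


@dataclass
class ProphageLocus:
    replicon_id: str
    start: int
    end: int
    supporting_hits: list[GeneHit]
    n_consecutive: int
    family_call: str = "unresolved"
    mean_norm_score: float = 0.0


@dataclass(frozen=True)
class ExternalRegion:
    replicon_id: str
    start: int
    end: int
    completeness_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")


# ---------------------------------------------------------------------------
# host scanning
# ---------------------------------------------------------------------------

def scan_host(
    host_replicons: Sequence[Replicon],
    model_sets: Sequence[FamilyModelSet],
    genome_id: str = "host",
    min_coverage: float = 0.5,
    max_evalue: float = 1.5e-8,
) -> list[GeneHit]:
    """Filtered hits of every family model against the host's CDS proteins,
    mapped back to gene coordinates and per-replicon ordinals."""
    proteins = extract_cds_proteins(host_replicons, genome_id)
    if not proteins:
        return []
    all_models = [m for s in model_sets for m in s.models]
    if not all_models:
        return []
    hits = filter_hits(scan(proteins, all_models),
                       min_coverage=min_coverage, max_evalue=max_evalue)
    placement: dict[str, tuple[str, int, int, str, int]] = {}
    for rep in host_replicons:
        rep_prots = [p for p in proteins if p.coords and p.coords[0] == rep.id]
        rep_prots.sort(key=lambda p: (p.coords[1], p.coords[2]))
        for ordinal, p in enumerate(rep_prots):
            placement[p.id] = (rep.id, p.coords[1], p.coords[2], p.coords[3], ordinal)
    out = []
    for h in hits:
        rep_id, start, end, strand, ordinal = placement[h.target_id]
        out.append(GeneHit(hit=h, replicon_id=rep_id, start=start, end=end,
                           strand=strand, ordinal=ordinal))
    out.sort(key=lambda g: (g.replicon_id, g.ordinal, g.hit.model_id))
    return out


# ---------------------------------------------------------------------------
# locus calling
# ---------------------------------------------------------------------------

def _runs(ordinals: list[int], max_gene_gap: int) -> list[list[int]]:
    runs: list[list[int]] = []
    for o in ordinals:
        if runs and o - runs[-1][-1] <= max_gene_gap + 1:
            runs[-1].append(o)
        else:
            runs.append([o])
    return runs


def call_loci(
    gene_hits: Sequence[GeneHit],
    min_consecutive: int = 4,
    max_gene_gap: int = 2,
    replicons: Optional[Sequence[Replicon]] = None,
) -> list[ProphageLocus]:
    """Call prophage loci from runs of hit genes on each replicon.

    A run groups hit genes whose ordinals are separated by at most
    ``max_gene_gap`` non-hit genes; runs shorter than ``min_consecutive``
    hit genes (default 4: strictly more than three) are discarded.  On
    circular replicons a run touching the last gene joins one touching the
    first, and the wrap-around locus's ``end`` extends past the origin.
    """
    by_rep: dict[str, list[GeneHit]] = {}
    for g in gene_hits:
        by_rep.setdefault(g.replicon_id, []).append(g)
    rep_info = {r.id: r for r in replicons or []}
    loci: list[ProphageLocus] = []
    for rep_id in sorted(by_rep):
        hits = sorted(by_rep[rep_id], key=lambda g: g.ordinal)
        by_ordinal: dict[int, list[GeneHit]] = {}
        for g in hits:
            by_ordinal.setdefault(g.ordinal, []).append(g)
        ordinals = sorted(by_ordinal)
        runs = _runs(ordinals, max_gene_gap)
        rep = rep_info.get(rep_id)
        wrapped = False
        if rep is not None and rep.topology == "circular" and len(runs) > 1:
            n_genes = len(rep.features)
            gap_across = (n_genes - 1 - runs[-1][-1]) + runs[0][0]
            if gap_across <= max_gene_gap:
                runs[0] = runs.pop() + runs[0]
                wrapped = True
        for i, run in enumerate(runs):
            if len(run) < min_consecutive:
                continue
            support = [g for o in run for g in by_ordinal[o]]
            if wrapped and i == 0:
                L = len(rep.sequence)
                start = min(g.start for g in support if g.ordinal >= run[0])
                end = max(g.end for g in support if g.ordinal <= run[-1]) + L
            else:
                start = min(g.start for g in support)
                end = max(g.end for g in support)
            scores = [g.hit.norm_score for g in support]
            loci.append(
                ProphageLocus(
                    replicon_id=rep_id, start=start, end=end,
                    supporting_hits=support, n_consecutive=len(run),
                    mean_norm_score=sum(scores) / len(scores),
                )
            )
    return loci


def assign_locus_family(
    locus: ProphageLocus,
    model_sets: Sequence[FamilyModelSet],
    min_distinct_models: int = 2,
) -> str:
    """Family call for a locus from its supporting hits (same rule as genome
    classification); 'unresolved' on ties or insufficient distinct models."""
    result = classify_from_hits(
        [g.hit for g in locus.supporting_hits], model_sets,
        genome_id=locus.replicon_id, min_distinct_models=min_distinct_models,
    )
    call = result.call
    return "unresolved" if call in ("unassigned", "ambiguous") else call


def call_and_classify(
    gene_hits: Sequence[GeneHit],
    model_sets: Sequence[FamilyModelSet],
    min_consecutive: int = 4,
    max_gene_gap: int = 2,
    min_distinct_models: int = 2,
    replicons: Optional[Sequence[Replicon]] = None,
) -> list[ProphageLocus]:
    loci = call_loci(gene_hits, min_consecutive, max_gene_gap, replicons)
    for locus in loci:
        locus.family_call = assign_locus_family(locus, model_sets, min_distinct_models)
    return loci


# ---------------------------------------------------------------------------
# comparison with an external coordinate table
# ---------------------------------------------------------------------------

def read_regions_tsv(path: str | Path) -> list[ExternalRegion]:
    """Read a TSV with columns replicon, start, end[, completeness] (header
    optional); coordinates are taken as 0-based half-open."""
    regions = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "replicon":
                continue
            regions.append(
                ExternalRegion(
                    replicon_id=row[0], start=int(row[1]), end=int(row[2]),
                    completeness_label=row[3] if len(row) > 3 else None,
                )
            )
    return regions


def _overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    shorter = min(a[1] - a[0], b[1] - b[0])
    return max(inter, 0) / shorter if shorter > 0 else 0.0


def compare_to_regions(
    loci: Sequence[ProphageLocus],
    external_regions: Sequence[ExternalRegion],
    min_overlap_fraction: float = 0.5,
    replicon_ids: Optional[set[str]] = None,
) -> dict:
    """Overlap report between called loci and an external region table.

    A locus and a region match when they share a replicon and overlap by at
    least ``min_overlap_fraction`` of the shorter interval.  Loci are labeled
    confirmed/novel, regions confirmed/missed; the summary carries the
    confirmed / additional (novel) / missed counts.  When ``replicon_ids``
    (the scanned genome's replicons) is given, external rows naming other
    replicons are skipped with a warning.
    """
    usable = []
    for r in external_regions:
        if replicon_ids is not None and r.replicon_id not in replicon_ids:
            logger.warning("external region on unknown replicon %s skipped", r.replicon_id)
            continue
        usable.append(r)
    locus_status = []
    region_confirmed = [False] * len(usable)
    for locus in loci:
        confirmed = False
        for i, r in enumerate(usable):
            if r.replicon_id != locus.replicon_id:
                continue
            if _overlap_fraction((locus.start, locus.end), (r.start, r.end)) >= min_overlap_fraction:
                confirmed = True
                region_confirmed[i] = True
        locus_status.append("confirmed" if confirmed else "novel")
    region_status = ["confirmed" if c else "missed" for c in region_confirmed]
    return {
        "locus_status": locus_status,
        "region_status": region_status,
        "n_confirmed_regions": sum(region_confirmed),
        "n_novel_loci": locus_status.count("novel"),
        "n_missed_regions": region_status.count("missed"),
    }
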