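"""Model refinement: consensus-coverage pruning, scan-update-merge iteration
to a fixpoint, and recovery of unannotated CDS from intergenic regions.

The membership update follows three rules applied to each model's filtered
hits against the master protein set: proteins hit but not yet assigned to
any model are added; member proteins no longer hit are removed; proteins
previously removed as redundant are never re-added.  Models whose hit-or-
member sets coincide exactly are merged.  The loop repeats until a full
round changes nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .clustering import ProteinCluster, RedundancyMap
from .genome_io import (
    NucleotideRegion,
    ProteinRecord,
    Replicon,
    extract_intergenic_regions,
    six_frame_translate,
)
from .profile_hmm import HmmHit, MSA, ProfileHMM, align_cluster, build_hmm, filter_hits, scan

logger = logging.getLogger("classiphage")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RefinementState:
    models: list[ProfileHMM]
    redundancy: RedundancyMap
    master_proteins: list[ProteinRecord]
    round: int = 0
    changed: bool = False


@dataclass(frozen=True)
class RecoveredCDS:
    """A six-frame candidate protein recovered by a filtered model hit."""

    protein: ProteinRecord
    hit: HmmHit


# ---------------------------------------------------------------------------
# consensus-coverage pruning
# ---------------------------------------------------------------------------

def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"
    return aligner


def consensus_coverage(consensus: str, member: str, side: str = "consensus") -> float:
    """Fraction of the consensus (or, with ``side='member'``, of the member)
    covered by the best local alignment between the two."""
    if not consensus or not member:
        return 0.0
    aln = _local_aligner().align(consensus, member)[0]
    which = 0 if side == "consensus" else 1
    covered = sum(end - start for start, end in aln.aligned[which])
    return covered / (len(consensus) if side == "consensus" else len(member))


def prune_by_consensus_coverage(
    cluster: ProteinCluster,
    consensus: str,
    coverage_threshold: float = 0.5,
    side: str = "consensus",
) -> ProteinCluster:
    """Drop members whose alignment to the consensus covers less than the
    threshold fraction of it (``side='member'`` measures coverage of the
    member instead).  Callers retire clusters left with < 2 members."""
    kept = [
        m
        for m in cluster.members
        if consensus_coverage(consensus, m.sequence, side) >= coverage_threshold
    ]
    if len(kept) < len(cluster.members):
        logger.info(
            "%s: consensus-coverage pruning removed %d of %d members",
            cluster.cluster_id, len(cluster.members) - len(kept), len(cluster.members),
        )
    if not kept:  # ProteinCluster forbids emptiness; signal retirement upstream
        return ProteinCluster(cluster.cluster_id, cluster.members[:1], cluster.family_label)
    return ProteinCluster(cluster.cluster_id, kept, cluster.family_label)


# ---------------------------------------------------------------------------
# membership refinement
# ---------------------------------------------------------------------------

def refine_membership(
    model: ProfileHMM,
    scan_hits: Iterable[HmmHit],
    redundancy: RedundancyMap,
    assigned_ids: set[str],
) -> tuple[set[str], bool]:
    """One membership update for one model.

    ``scan_hits`` are this model's *filtered* hits against the master set;
    ``assigned_ids`` is the union of every current model's members.  Returns
    the new member-id set and whether it differs from the old one.
    """
    targets = {h.target_id for h in scan_hits if h.model_id == model.model_id}
    removed = redundancy.removed_ids
    new_members = (model.member_ids & targets) | (targets - assigned_ids - removed)
    return new_members, new_members != model.member_ids


def _rebuild(model_id: str, family: Optional[str], members: list[ProteinRecord]) -> ProfileHMM:
    cluster = ProteinCluster(model_id, members, family)
    msa = align_cluster(cluster)
    return build_hmm(msa, model_id=model_id, family_label=family)


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def merge_equivalent_models(
    models: Sequence[ProfileHMM],
    hitsets: dict[str, set[str]],
    master_by_id: dict[str, ProteinRecord],
    min_jaccard: float = 1.0,
) -> tuple[list[ProfileHMM], bool]:
    """Merge models whose hit-target-plus-member sets are exactly equal.

    Merged groups are rebuilt from the union of their members under the
    lexicographically smallest model id; everything else is untouched.
    ``min_jaccard < 1`` relaxes equality to a Jaccard-similarity threshold
    (greedy, in model-id order); the default keeps the exact-set rule.
    """
    keyed = [
        (m, frozenset(hitsets.get(m.model_id, set()) | m.member_ids))
        for m in sorted(models, key=lambda m: m.model_id)
    ]
    groups: dict[frozenset, list[ProfileHMM]] = {}
    if min_jaccard >= 1.0:
        for m, key in keyed:
            groups.setdefault(key, []).append(m)
    else:
        anchors: list[tuple[frozenset, frozenset]] = []  # (anchor key, group key)
        for m, key in keyed:
            for i, (anchor, gkey) in enumerate(anchors):
                if _jaccard(anchor, key) >= min_jaccard:
                    groups[gkey].append(m)
                    break
            else:
                anchors.append((key, key))
                groups[key] = [m]
    out: list[ProfileHMM] = []
    changed = False
    for key, group in sorted(groups.items(), key=lambda kv: kv[1][0].model_id):
        if len(group) == 1:
            out.append(group[0])
            continue
        changed = True
        member_ids = sorted(set().union(*(g.member_ids for g in group)))
        merged_id = min(g.model_id for g in group)
        logger.info("merging models %s -> %s", [g.model_id for g in group], merged_id)
        members = [master_by_id[i] for i in member_ids]
        out.append(_rebuild(merged_id, group[0].family_label, members))
    out.sort(key=lambda m: m.model_id)
    return out, changed


# ---------------------------------------------------------------------------
# fixpoint iteration
# ---------------------------------------------------------------------------

def _state_fingerprint(models: Sequence[ProfileHMM]) -> frozenset:
    return frozenset(frozenset(m.member_ids) for m in models)


def refine_to_fixpoint(
    state: RefinementState,
    max_rounds: int = 20,
    min_coverage: float = 0.5,
    max_evalue: float = 1.5e-8,
) -> RefinementState:
    """Iterate scan -> filter -> membership update -> merge until stable.

    Stops early when one full round leaves every model's membership (and the
    model set) unchanged, when a previously seen state recurs (oscillation),
    or after ``max_rounds`` with a warning.  Models falling below 2 members
    are retired.  Deterministic: models are processed in model-id order.
    """
    if max_rounds < 1:
        logger.warning("refine_to_fixpoint called with max_rounds=%d; no-op", max_rounds)
        return state
    master_by_id = {p.id: p for p in state.master_proteins}
    models = sorted(state.models, key=lambda m: m.model_id)
    history = [_state_fingerprint(models)]
    rounds_run = 0
    last_round_changed = False
    for rnd in range(1, max_rounds + 1):
        rounds_run = rnd
        all_hits = filter_hits(
            scan(state.master_proteins, models),
            min_coverage=min_coverage, max_evalue=max_evalue,
        )
        hits_by_model: dict[str, list[HmmHit]] = {}
        for h in all_hits:
            hits_by_model.setdefault(h.model_id, []).append(h)
        assigned = set().union(*(m.member_ids for m in models)) if models else set()
        round_changed = False
        updated: list[ProfileHMM] = []
        for m in models:
            new_ids, changed = refine_membership(
                m, hits_by_model.get(m.model_id, []), state.redundancy, assigned
            )
            if not changed:
                updated.append(m)
                continue
            round_changed = True
            assigned = (assigned - m.member_ids) | new_ids
            if len(new_ids) < 2:
                logger.warning("model %s retired (%d member(s) left)", m.model_id, len(new_ids))
                continue
            updated.append(
                _rebuild(m.model_id, m.family_label, [master_by_id[i] for i in sorted(new_ids)])
            )
        hitsets = {
            mid: {h.target_id for h in hs} for mid, hs in hits_by_model.items()
        }
        merged, did_merge = merge_equivalent_models(updated, hitsets, master_by_id)
        round_changed = round_changed or did_merge
        models = merged
        last_round_changed = round_changed
        if not round_changed:
            break
        fp = _state_fingerprint(models)
        if fp in history:
            logger.warning("refinement oscillation detected at round %d; stopping", rnd)
            break
        history.append(fp)
        history = history[-4:]
    else:
        logger.warning("refinement did not stabilize within %d rounds", max_rounds)
    return RefinementState(
        models=models,
        redundancy=state.redundancy,
        master_proteins=state.master_proteins,
        round=rounds_run,
        changed=last_round_changed,
    )


# ---------------------------------------------------------------------------
# intergenic CDS recovery
# ---------------------------------------------------------------------------

def recover_missing_cds(
    genomes: Sequence[tuple[str, Sequence[Replicon]]],
    models: Sequence[ProfileHMM],
    min_intergenic_nt: int = 90,
    min_orf_aa: int = 30,
    min_coverage: float = 0.5,
    max_evalue: float = 1.5e-8,
) -> list[RecoveredCDS]:
    """Scan six-frame translations of intergenic regions with refined models.

    ``genomes`` is a list of (genome_id, replicons).  Only candidates whose
    best hit passes the rejection cut-offs (coverage >= 50%, positive bits,
    E <= 1.5e-8) are returned, with genomic coordinates attached.
    """
    candidates: list[ProteinRecord] = []
    for genome_id, replicons in genomes:
        for rep in replicons:
            for region in extract_intergenic_regions(rep, min_intergenic_nt):
                cands = six_frame_translate(region, min_orf_aa, source_genome=genome_id)
                candidates.extend(
                    ProteinRecord(
                        id=f"{genome_id}|{c.id}", sequence=c.sequence,
                        source_genome=genome_id, coords=c.coords,
                    )
                    for c in cands
                )
    if not candidates or not models:
        return []
    hits = filter_hits(
        scan(candidates, models), min_coverage=min_coverage, max_evalue=max_evalue
    )
    by_id = {c.id: c for c in candidates}
    best: dict[str, RecoveredCDS] = {}
    for h in hits:
        prev = best.get(h.target_id)
        if prev is None or h.bit_score > prev.hit.bit_score:
            best[h.target_id] = RecoveredCDS(protein=by_id[h.target_id], hit=h)
    return sorted(best.values(), key=lambda r: r.protein.id)


def integrate_and_rebuild(
    model: ProfileHMM,
    recovered: Sequence[RecoveredCDS],
    master_by_id: dict[str, ProteinRecord],
) -> tuple[ProfileHMM, pd.DataFrame]:
    """Fold recovered CDS targeting this model into its MSA and rebuild.

    Returns the rebuilt model and a before/after report of bit scores on the
    previous members, for judging whether the extra sequences changed the
    model's behaviour (on well-sampled families they typically do not).
    """
    mine = [r for r in recovered if r.hit.model_id == model.model_id]
    members = [master_by_id[i] for i in sorted(model.member_ids)]
    if not mine:
        return model, pd.DataFrame(
            columns=["member", "bit_before", "bit_after"]
        )
    before = {h.target_id: h.bit_score for h in scan(members, [model])}
    extra = [r.protein for r in mine]
    cluster = ProteinCluster(model.model_id, members + extra, model.family_label)
    msa = align_cluster(cluster)
    rebuilt = build_hmm(msa, model_id=model.model_id, family_label=model.family_label)
    # the member registry keeps only master proteins; recovered CDS are inputs
    rebuilt.member_ids = set(model.member_ids)
    after = {h.target_id: h.bit_score for h in scan(members, [rebuilt])}
    report = pd.DataFrame(
        {
            "member": sorted(model.member_ids),
            "bit_before": [before.get(i) for i in sorted(model.member_ids)],
            "bit_after": [after.get(i) for i in sorted(model.member_ids)],
        }
    )
    return rebuilt, report
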