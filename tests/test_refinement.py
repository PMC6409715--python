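"""Consensus-coverage pruning, membership refinement, merging, fixpoint
iteration, and intergenic CDS recovery."""

import random

import pytest

import classiphage as cp
from classiphage import synthetic_fixtures as sf
from classiphage.clustering import ProteinCluster, RedundancyMap
from classiphage.genome_io import ProteinRecord
from classiphage.refinement import consensus_coverage

AA = "ACDEFGHIKLMNPQRSTVWY"


def _prot(pid, seq):
    return ProteinRecord(id=pid, sequence=seq, source_genome="g")


def _hit(model_id, target_id, evalue=1e-20, bits=80.0):
    return cp.HmmHit(model_id, target_id, evalue, bits, 1, 50, 1, 50, 1.0, bits / 300)


class TestConsensusCoveragePruning:
    def test_member_identical_to_consensus_kept(self):
        rng = random.Random(0)
        consensus = "".join(rng.choice(AA) for _ in range(100))
        cluster = ProteinCluster("c", [_prot("a", consensus), _prot("b", consensus)])
        pruned = cp.prune_by_consensus_coverage(cluster, consensus, 0.5)
        assert pruned.member_ids == {"a", "b"}

    def test_short_shared_segment_removed(self):
        """A member sharing only 20 of 100 consensus residues covers 0.2 < 0.5."""
        rng = random.Random(1)
        consensus = "".join(rng.choice(AA) for _ in range(100))
        fragment_member = consensus[40:60] + "".join(rng.choice(AA) for _ in range(40))
        cov = consensus_coverage(consensus, fragment_member)
        assert cov < 0.5  # alignment oracle on constructed sequences
        cluster = ProteinCluster(
            "c", [_prot("full", consensus), _prot("frag", fragment_member)]
        )
        pruned = cp.prune_by_consensus_coverage(cluster, consensus, 0.5)
        assert pruned.member_ids == {"full"}

    def test_member_side_coverage_option(self):
        """A short fragment fully contained in the consensus covers all of
        itself but little of the consensus."""
        rng = random.Random(7)
        consensus = "".join(rng.choice(AA) for _ in range(100))
        fragment = consensus[10:40]
        assert consensus_coverage(consensus, fragment) < 0.5
        assert consensus_coverage(consensus, fragment, side="member") > 0.95

    def test_zero_threshold_is_identity(self):
        rng = random.Random(2)
        members = [_prot(f"p{i}", "".join(rng.choice(AA) for _ in range(60)))
                   for i in range(3)]
        cluster = ProteinCluster("c", members)
        consensus = members[0].sequence
        pruned = cp.prune_by_consensus_coverage(cluster, consensus, 0.0)
        assert pruned.member_ids == cluster.member_ids


class TestRefineMembership:
    def _model(self, member_ids):
        rng = random.Random(3)
        anc = "".join(rng.choice(AA) for _ in range(60))
        msa = cp.MSA("m1", [(i, anc) for i in sorted(member_ids)])
        return cp.build_hmm(msa, "m1", "familyA")

    def test_fixpoint_case_unchanged(self):
        model = self._model({"a", "b", "c"})
        hits = [_hit("m1", t) for t in "abc"]
        new_ids, changed = cp.refine_membership(model, hits, RedundancyMap(), {"a", "b", "c"})
        assert new_ids == {"a", "b", "c"} and not changed

    def test_unhit_member_removed(self):
        model = self._model({"a", "b", "c"})
        hits = [_hit("m1", "a"), _hit("m1", "b")]
        new_ids, changed = cp.refine_membership(model, hits, RedundancyMap(), {"a", "b", "c"})
        assert new_ids == {"a", "b"} and changed

    def test_unassigned_hit_added(self):
        model = self._model({"a", "b"})
        hits = [_hit("m1", t) for t in ("a", "b", "x")]
        new_ids, _ = cp.refine_membership(model, hits, RedundancyMap(), {"a", "b"})
        assert new_ids == {"a", "b", "x"}

    def test_assigned_elsewhere_not_added(self):
        model = self._model({"a", "b"})
        hits = [_hit("m1", t) for t in ("a", "b", "y")]
        new_ids, changed = cp.refine_membership(
            model, hits, RedundancyMap(), {"a", "b", "y"}
        )
        assert new_ids == {"a", "b"} and not changed

    def test_redundancy_removed_never_added(self):
        model = self._model({"a", "b"})
        rmap = RedundancyMap(removed_by_rep={"a": {"r"}})
        hits = [_hit("m1", t) for t in ("a", "b", "r")]
        new_ids, changed = cp.refine_membership(model, hits, rmap, {"a", "b"})
        assert new_ids == {"a", "b"} and not changed


class TestMergeEquivalentModels:
    def _models_from_cluster(self, seed, ids):
        rng = random.Random(seed)
        anc = "".join(rng.choice(AA) for _ in range(70))
        members = []
        for i in range(5):
            seq = "".join(
                rng.choice([a for a in AA if a != c]) if rng.random() < 0.1 else c
                for c in anc
            )
            members.append(_prot(f"p{i}", seq))
        models = []
        for mid in ids:
            cluster = ProteinCluster(mid, members, "familyA")
            models.append(cp.build_hmm(cp.align_cluster(cluster), mid, "familyA"))
        return members, models

    def test_identical_sets_merge_under_smallest_id(self):
        members, models = self._models_from_cluster(4, ["m_b", "m_a"])
        hitset = {m.id for m in members}
        merged, changed = cp.merge_equivalent_models(
            models, {"m_a": hitset, "m_b": hitset}, {m.id: m for m in members}
        )
        assert changed and len(merged) == 1
        assert merged[0].model_id == "m_a"
        assert merged[0].member_ids == hitset

    def test_sets_differing_by_one_do_not_merge(self):
        members, models = self._models_from_cluster(5, ["m_a", "m_b"])
        full = {m.id for m in members}
        merged, changed = cp.merge_equivalent_models(
            models, {"m_a": full, "m_b": full | {"extra"}}, {m.id: m for m in members}
        )
        assert not changed and len(merged) == 2

    def test_no_models_noop(self):
        merged, changed = cp.merge_equivalent_models([], {}, {})
        assert merged == [] and not changed

    def test_jaccard_relaxation_merges_near_equal_sets(self):
        members, models = self._models_from_cluster(6, ["m_a", "m_b"])
        full = {m.id for m in members}
        hitsets = {"m_a": full, "m_b": full | {"extra"}}  # Jaccard 5/6
        by_id = {m.id: m for m in members}
        strict, changed = cp.merge_equivalent_models(models, hitsets, by_id)
        assert not changed and len(strict) == 2
        relaxed, changed = cp.merge_equivalent_models(
            models, hitsets, by_id, min_jaccard=0.8
        )
        assert changed and len(relaxed) == 1 and relaxed[0].model_id == "m_a"


class TestRefineToFixpoint:
    def test_stable_state_returns_immediately(self, small):
        state = cp.RefinementState(
            models=list(small.models), redundancy=small.rmap,
            master_proteins=small.proteins,
        )
        result = cp.refine_to_fixpoint(state, max_rounds=5)
        assert not result.changed
        assert result.round <= 2
        assert {m.model_id for m in result.models} == {m.model_id for m in small.models}

    def test_dropped_member_reinstated(self, small):
        """A model rebuilt without one member still hits it, so the fixpoint
        restores the protein to the model (hand-traceable on one model)."""
        victim_model = small.models[0]
        dropped = sorted(victim_model.member_ids)[0]
        remaining = sorted(victim_model.member_ids - {dropped})
        by_id = {p.id: p for p in small.proteins}
        shrunk = cp.build_hmm(
            cp.align_cluster(
                ProteinCluster(victim_model.model_id, [by_id[i] for i in remaining],
                               victim_model.family_label)
            ),
            victim_model.model_id, victim_model.family_label,
        )
        models = [shrunk] + [m for m in small.models[1:]]
        state = cp.refine_to_fixpoint(
            cp.RefinementState(models=models, redundancy=small.rmap,
                               master_proteins=small.proteins),
            max_rounds=5,
        )
        fixed = {m.model_id: m for m in state.models}[victim_model.model_id]
        assert dropped in fixed.member_ids
        assert not state.changed

    def test_max_rounds_zero_is_noop_with_warning(self, small, caplog):
        state = cp.RefinementState(
            models=list(small.models), redundancy=small.rmap,
            master_proteins=small.proteins,
        )
        result = cp.refine_to_fixpoint(state, max_rounds=0)
        assert result is state
        assert any("no-op" in r.message for r in caplog.records)


class TestRecoverMissingCds:
    def test_delete_and_recover_round_trip(self, small):
        fx = small.fixtures[1]
        deleted = sf.delete_random_cds(fx, 1, seed=21)
        lost = deleted.deleted_cds[0]
        recovered = cp.recover_missing_cds(
            [(fx.genome_id, [deleted.replicon])], small.models
        )
        spans = [
            (r.protein.coords[1], r.protein.coords[2]) for r in recovered
        ]
        assert any(s < lost.end and e > lost.start for s, e in spans)
        for r in recovered:
            h = r.hit
            assert h.coverage >= 0.5 and h.bit_score > 0 and h.evalue <= 1.5e-8

    def test_fully_annotated_genome_recovers_nothing(self, small):
        fx = small.fixtures[0]
        recovered = cp.recover_missing_cds([(fx.genome_id, [fx.replicon])], small.models)
        assert recovered == []


class TestIntegrateAndRebuild:
    def test_zero_recovered_identity(self, small):
        model = small.models[0]
        rebuilt, report = cp.integrate_and_rebuild(model, [], {p.id: p for p in small.proteins})
        assert rebuilt is model and report.empty

    def test_rebuilt_model_still_hits_members(self, small):
        fx = small.fixtures[1]
        deleted = sf.delete_random_cds(fx, 1, seed=21)
        recovered = cp.recover_missing_cds(
            [(fx.genome_id, [deleted.replicon])], small.models
        )
        assert recovered  # round-trip fixture guarantees at least one
        target_model_id = recovered[0].hit.model_id
        model = {m.model_id: m for m in small.models}[target_model_id]
        by_id = {p.id: p for p in small.proteins}
        rebuilt, report = cp.integrate_and_rebuild(model, recovered, by_id)
        members = [by_id[i] for i in sorted(model.member_ids)]
        hits = cp.filter_hits(cp.scan(members, [rebuilt]))
        assert {h.target_id for h in hits} == model.member_ids
        assert rebuilt.member_ids == model.member_ids
        assert set(report.member) == model.member_ids
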