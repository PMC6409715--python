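"""Shared fixtures: a small dataset for unit tests and the full-size
synthetic study (4 families x 12 genomes, 10 protein families, divergence
0.3, seed 42) for the end-to-end checks.  Both are generated in-process;
training runs once per session."""

from __future__ import annotations

from types import SimpleNamespace

import pytest

import classiphage as cp
from classiphage import synthetic_fixtures as sf

STUDY = dict(
    n_families=4, n_protein_families=10, divergence=0.3, presence_prob=0.9, seed=42
)
GENOMES_PER_FAMILY = 12
HOLDOUT_PER_FAMILY = 2  # ~20% of 12, stratified


def _extract_all(fixtures, labeled=True):
    proteins = []
    for fx in fixtures:
        proteins += cp.extract_cds_proteins(
            [fx.replicon], fx.genome_id, fx.family_label if labeled else None
        )
    return proteins


def _proteomes_by_family(fixtures):
    out: dict[str, list] = {}
    for fx in fixtures:
        out.setdefault(fx.family_label, []).extend(
            cp.extract_cds_proteins([fx.replicon], fx.genome_id, fx.family_label)
        )
    return out


@pytest.fixture(scope="session")
def small():
    """2 families x 6 genomes, 5 protein families: fast unit-test substrate."""
    specs = sf.generate_families(n_families=2, n_protein_families=5, seed=7)
    fixtures = sf.generate_genomes(specs, genomes_per_family=6, seed=7)
    proteins = _extract_all(fixtures)
    clusters, rmap, summary = cp.cluster_proteins_by_family(proteins)
    models = [cp.build_hmm(cp.align_cluster(c), c.cluster_id, c.family_label)
              for c in clusters]
    return SimpleNamespace(
        specs=specs, fixtures=fixtures, proteins=proteins, clusters=clusters,
        rmap=rmap, models=models, model_sets=cp.group_models_by_family(models),
        by_family=_proteomes_by_family(fixtures),
    )


@pytest.fixture(scope="session")
def study():
    specs = sf.generate_families(**STUDY)
    fixtures = sf.generate_genomes(specs, genomes_per_family=GENOMES_PER_FAMILY,
                                   seed=STUDY["seed"])
    return SimpleNamespace(
        specs=specs, fixtures=fixtures, proteins=_extract_all(fixtures),
        by_family=_proteomes_by_family(fixtures),
    )


@pytest.fixture(scope="session")
def study_trained(study):
    cfg = cp.PipelineConfig(seed=STUDY["seed"])
    clusters, rmap, state, summary = cp.build_and_refine(study.proteins, cfg)
    return SimpleNamespace(
        config=cfg, clusters=clusters, rmap=rmap, state=state, summary=summary,
        models=state.models, model_sets=cp.group_models_by_family(state.models),
    )


@pytest.fixture(scope="session")
def holdout_trained(study):
    """Models trained with the last 2 genomes of each family held out."""
    held = [fx for fx in study.fixtures
            if int(fx.genome_id.rsplit("g", 1)[1]) >= GENOMES_PER_FAMILY - HOLDOUT_PER_FAMILY]
    held_ids = {fx.genome_id for fx in held}
    train = [fx for fx in study.fixtures if fx.genome_id not in held_ids]
    proteins = _extract_all(train)
    cfg = cp.PipelineConfig(seed=STUDY["seed"])
    _, _, state, _ = cp.build_and_refine(proteins, cfg)
    return SimpleNamespace(
        held=held, train=train, state=state, config=cfg,
        model_sets=cp.group_models_by_family(state.models),
    )
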