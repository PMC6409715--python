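"""Taxon-specificity evaluation and family classification.

A model is a taxonomic indicator when its own family both supplies at least
``min_hits`` filtered hits and out-scores (mean normalized bit score) every
other family.  Genomes are classified by aggregating filtered hits per
family: the primary criterion is the number of distinct models hit (robust
against one promiscuous protein), summed normalized score breaks ties, and a
single model hit is never sufficient for a call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd
from scipy.stats import mannwhitneyu

from .genome_io import ProteinRecord
from .profile_hmm import HmmHit, ProfileHMM, filter_hits, scan

logger = logging.getLogger("classiphage")


@dataclass
class FamilyModelSet:
    family_label: str
    models: list[ProfileHMM]

    def __post_init__(self) -> None:
        ids = [m.model_id for m in self.models]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate model ids in family set")
        for m in self.models:
            if m.family_label != self.family_label:
                raise ValueError(
                    f"model {m.model_id} labeled {m.family_label}, "
                    f"expected {self.family_label}"
                )


@dataclass
class SpecificityVerdict:
    model_id: str
    per_family: pd.DataFrame  # columns: family, n_hits, mean_norm_score
    indicator: bool


@dataclass
class ClassificationResult:
    genome_id: str
    per_family: pd.DataFrame  # family, n_models, n_hits, sum_norm_score
    call: str  # family label, "unassigned" or "ambiguous"
    evidence: list[HmmHit] = field(default_factory=list)


def group_models_by_family(models: Sequence[ProfileHMM]) -> list[FamilyModelSet]:
    by_fam: dict[str, list[ProfileHMM]] = {}
    for m in models:
        by_fam.setdefault(m.family_label or "unlabeled", []).append(m)
    return [
        FamilyModelSet(f, sorted(ms, key=lambda m: m.model_id))
        for f, ms in sorted(by_fam.items())
    ]


def _filtered_hits(
    proteins: Sequence[ProteinRecord],
    models: Sequence[ProfileHMM],
    min_coverage: float,
    max_evalue: float,
) -> list[HmmHit]:
    if not proteins or not models:
        return []
    return filter_hits(scan(proteins, models), min_coverage=min_coverage,
                       max_evalue=max_evalue)


# ---------------------------------------------------------------------------
# specificity
# ---------------------------------------------------------------------------

def evaluate_specificity(
    model: ProfileHMM,
    proteomes_by_family: Mapping[str, Sequence[ProteinRecord]],
    min_hits: int = 5,
    min_coverage: float = 0.5,
    max_evalue: float = 1.5e-8,
    test: Optional[str] = None,
) -> SpecificityVerdict:
    """Score one model against every family's proteome.

    The indicator is true when the model's own family yields at least
    ``min_hits`` filtered hits and a strictly greater mean normalized score
    than every other family (families without proteins score 0).  With
    ``test='mannwhitney'`` a one-sided rank test on the per-hit normalized
    scores must additionally reject (p < 0.05) for every foreign family that
    has hits.
    """
    rows = []
    scores_by_family: dict[str, list[float]] = {}
    for family in sorted(proteomes_by_family):
        hits = _filtered_hits(
            list(proteomes_by_family[family]), [model], min_coverage, max_evalue
        )
        scores = [h.norm_score for h in hits]
        scores_by_family[family] = scores
        rows.append(
            {
                "family": family,
                "n_hits": len(hits),
                "mean_norm_score": sum(scores) / len(scores) if scores else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    own = model.family_label
    own_row = table[table.family == own]
    indicator = False
    if not own_row.empty:
        own_mean = float(own_row.mean_norm_score.iloc[0])
        own_hits = int(own_row.n_hits.iloc[0])
        others = table[table.family != own]
        indicator = own_hits >= min_hits and bool(
            (others.mean_norm_score < own_mean).all()
        )
        if indicator and test == "mannwhitney":
            own_scores = scores_by_family[own]
            for fam, scores in scores_by_family.items():
                if fam == own or not scores:
                    continue
                p = mannwhitneyu(own_scores, scores, alternative="greater").pvalue
                if p >= 0.05:
                    indicator = False
                    break
    return SpecificityVerdict(model_id=model.model_id, per_family=table,
                              indicator=indicator)


# ---------------------------------------------------------------------------
# cross-match matrix
# ---------------------------------------------------------------------------

def cross_match_matrix(
    model_sets: Sequence[FamilyModelSet],
    proteomes_by_family: Mapping[str, Sequence[ProteinRecord]],
    groups: Optional[Mapping[str, str]] = None,
    min_coverage: float = 0.5,
    max_evalue: float = 1.5e-8,
) -> dict:
    """Per-protein accounting of which families' models hit it.

    Returns overall fractions over all hit proteins — matched exclusively by
    the source family's models, cross-matched within the same group (e.g.
    among tailed-phage families), and cross-matched between groups — plus a
    source-family x model-family count matrix.  ``groups`` maps each family
    to a higher-order group; by default every family is its own group.
    """
    groups = dict(groups or {})
    all_models = [m for s in model_sets for m in s.models]
    matrix_counts: dict[str, dict[str, int]] = {}
    n_exclusive = n_within = n_between = 0
    n_hit_total = 0
    for source_family in sorted(proteomes_by_family):
        proteins = list(proteomes_by_family[source_family])
        hits = _filtered_hits(proteins, all_models, min_coverage, max_evalue)
        fam_of_model = {m.model_id: s.family_label for s in model_sets for m in s.models}
        hit_families: dict[str, set[str]] = {}
        for h in hits:
            hit_families.setdefault(h.target_id, set()).add(fam_of_model[h.model_id])
        row = matrix_counts.setdefault(source_family, {})
        for fams in hit_families.values():
            n_hit_total += 1
            for f in sorted(fams):
                row[f] = row.get(f, 0) + 1
            if fams == {source_family}:
                n_exclusive += 1
            else:
                src_group = groups.get(source_family, source_family)
                foreign = fams - {source_family}
                if all(groups.get(f, f) == src_group for f in foreign):
                    n_within += 1
                else:
                    n_between += 1
    denom = n_hit_total or 1
    return {
        "fraction_exclusive": n_exclusive / denom,
        "fraction_cross_within_group": n_within / denom,
        "fraction_cross_between_groups": n_between / denom,
        "n_hit_proteins": n_hit_total,
        "matrix": pd.DataFrame(matrix_counts).T.fillna(0).astype(int),
    }


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_genome(
    genome_proteins: Sequence[ProteinRecord],
    model_sets: Sequence[FamilyModelSet],
    genome_id: str = "",
    min_distinct_models: int = 2,
    min_coverage: float = 0.5,
    max_evalue: float = 1.5e-8,
) -> ClassificationResult:
    """Call a phage family for one genome from aggregated filtered hits.

    Primary criterion: distinct models hit per family; tie-break: summed
    normalized score.  The winner must reach ``min_distinct_models`` and
    strictly beat the runner-up, otherwise the call is "ambiguous" (exact
    tie) or "unassigned" (insufficient evidence).
    """
    gid = genome_id or (genome_proteins[0].source_genome if genome_proteins else "")
    all_models = [m for s in model_sets for m in s.models]
    hits = _filtered_hits(list(genome_proteins), all_models, min_coverage, max_evalue)
    return classify_from_hits(hits, model_sets, gid, min_distinct_models)


def classify_from_hits(
    hits: Sequence[HmmHit],
    model_sets: Sequence[FamilyModelSet],
    genome_id: str,
    min_distinct_models: int = 2,
) -> ClassificationResult:
    """Classification rule applied to pre-computed filtered hits."""
    fam_of_model = {m.model_id: s.family_label for s in model_sets for m in s.models}
    agg: dict[str, dict] = {
        s.family_label: {"models": set(), "n_hits": 0, "sum_norm": 0.0}
        for s in model_sets
    }
    for h in hits:
        fam = fam_of_model.get(h.model_id)
        if fam is None:
            continue
        agg[fam]["models"].add(h.model_id)
        agg[fam]["n_hits"] += 1
        agg[fam]["sum_norm"] += h.norm_score
    table = pd.DataFrame(
        [
            {
                "family": f,
                "n_models": len(a["models"]),
                "n_hits": a["n_hits"],
                "sum_norm_score": a["sum_norm"],
            }
            for f, a in sorted(agg.items())
        ]
    )
    call = "unassigned"
    if not table.empty and table.n_models.max() >= min_distinct_models:
        ranked = table.sort_values(
            ["n_models", "sum_norm_score", "family"], ascending=[False, False, True]
        ).reset_index(drop=True)
        best = ranked.iloc[0]
        if len(ranked) == 1:
            call = best.family
        else:
            second = ranked.iloc[1]
            if (best.n_models, best.sum_norm_score) == (
                second.n_models, second.sum_norm_score,
            ):
                call = "ambiguous"
            else:
                call = best.family
    return ClassificationResult(
        genome_id=genome_id, per_family=table, call=call, evidence=list(hits)
    )
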