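"""Pipeline configuration and stage orchestration.

``PipelineConfig`` houses every tunable with its documented range;
``run_pipeline`` chains extract -> cluster -> build -> refine and the
downstream applications (classify / recover-cds / scan-host), persisting
each stage's outputs plus a config snapshot, and skipping stages whose
inputs and configuration are unchanged since the last run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import clustering, genome_io, profile_hmm, refinement, taxonomy
from . import prophage_scan as prophage
from .clustering import RedundancyMap

logger = logging.getLogger("classiphage")


def setup_logging(logfile: Optional[str | Path] = None, level: int = logging.INFO) -> None:
    """Log to stderr (and optionally a file) with stage timings."""
    logger.setLevel(level)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s", "%H:%M:%S")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    if logfile:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


_RANGES = {
    "identity_threshold": (0.5, 1.0),
    "evalue_cutoff": (0.0, 10.0),
    "inflation": (1.0, 10.0),
    "min_cluster_size": (1, 1000),
    "coverage_threshold": (0.0, 1.0),
    "min_hit_coverage": (0.0, 1.0),
    "max_evalue": (0.0, 1.0),
    "min_distinct_models": (1, 100),
    "min_consecutive": (1, 1000),
    "max_gene_gap": (0, 100),
    "max_rounds": (0, 1000),
    "min_intergenic_nt": (1, 10_000),
    "min_orf_aa": (1, 10_000),
    "seed": (0, 2**31 - 1),
}


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with validated ranges."""

    identity_threshold: float = 0.9    # redundancy removal (global identity)
    evalue_cutoff: float = 1e-5        # similarity-graph edge threshold
    inflation: float = 2.0             # MCL inflation
    min_cluster_size: int = 5          # protein floor per model
    coverage_threshold: float = 0.5    # consensus-coverage pruning
    min_hit_coverage: float = 0.5      # hit rejection: model coverage
    max_evalue: float = 1.5e-8         # hit rejection: E-value ceiling
    min_distinct_models: int = 2       # classification evidence floor
    min_consecutive: int = 4           # prophage locus: > 3 consecutive hits
    max_gene_gap: int = 2              # tolerated non-hit genes inside a locus
    max_rounds: int = 20               # refinement fixpoint bound
    min_intergenic_nt: int = 90
    min_orf_aa: int = 30
    seed: int = 42
    norm_unit: str = "bp"              # bit-score normalization unit

    def __post_init__(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.norm_unit not in ("bp", "aa"):
            raise ValueError("norm_unit must be 'bp' or 'aa'")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# stage cache
# ---------------------------------------------------------------------------

def _digest(items) -> str:
    h = hashlib.sha256()
    for it in items:
        h.update(repr(it).encode())
    return h.hexdigest()


def _input_digest(paths: list[Path]) -> str:
    parts = []
    for p in sorted(paths):
        parts.append((str(p), p.stat().st_size, p.read_bytes()[:1 << 16].hex()))
    return _digest(parts)


class _StageCache:
    def __init__(self, root: Path):
        self.root = root
        self.root.mkdir(parents=True, exist_ok=True)

    def fresh(self, stage: str, key: str, outputs: list[Path]) -> bool:
        marker = self.root / f"{stage}.key"
        return (
            marker.exists()
            and marker.read_text() == key
            and all(o.exists() for o in outputs)
        )

    def mark(self, stage: str, key: str) -> None:
        (self.root / f"{stage}.key").write_text(key)


# ---------------------------------------------------------------------------
# training chain
# ---------------------------------------------------------------------------

def build_and_refine(
    all_proteins: list,
    config: PipelineConfig,
) -> tuple[list, RedundancyMap, "refinement.RefinementState", dict]:
    """Cluster labeled proteins, build models, prune by consensus coverage,
    and refine to a fixpoint.  Returns (clusters, redundancy map, refined
    state, per-family count summary)."""
    clusters, rmap, summary = clustering.cluster_proteins_by_family(
        all_proteins,
        identity_threshold=config.identity_threshold,
        evalue_cutoff=config.evalue_cutoff,
        inflation=config.inflation,
        min_cluster_size=config.min_cluster_size,
    )
    models = []
    for cl in clusters:
        model = profile_hmm.build_model_from_cluster(cl)
        pruned = refinement.prune_by_consensus_coverage(
            cl, model.consensus, config.coverage_threshold
        )
        if len(pruned.members) < 2:
            logger.warning("model %s retired after pruning", cl.cluster_id)
            continue
        if pruned.member_ids != cl.member_ids:
            model = profile_hmm.build_model_from_cluster(pruned)
        models.append(model)
    state = refinement.RefinementState(
        models=models, redundancy=rmap, master_proteins=all_proteins
    )
    state = refinement.refine_to_fixpoint(
        state, max_rounds=config.max_rounds,
        min_coverage=config.min_hit_coverage, max_evalue=config.max_evalue,
    )
    logger.info("refinement fixpoint after %d round(s), %d models",
                state.round, len(state.models))
    return clusters, rmap, state, summary


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    config: PipelineConfig,
    phage_dir: str | Path,
    out_dir: str | Path,
    classify_dir: Optional[str | Path] = None,
    host_dir: Optional[str | Path] = None,
    regions_tsv: Optional[str | Path] = None,
    recover: bool = False,
) -> Path:
    """Run the full pipeline; returns the artifact directory.

    ``phage_dir`` holds labeled training GenBank files; optional
    ``classify_dir`` (unlabeled phages), ``host_dir`` (bacterial genomes)
    and ``regions_tsv`` (external prophage coordinates) trigger the
    corresponding downstream stages.  A stage whose inputs and configuration
    are unchanged since the previous run is skipped.
    """
    phage_dir, out = Path(phage_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1))
    cache = _StageCache(out / ".cache")
    gbk_files = sorted(phage_dir.glob("*.gbk")) + sorted(phage_dir.glob("*.gb"))
    if not gbk_files:
        raise FileNotFoundError(f"no GenBank files in {phage_dir}")

    # -- extract ------------------------------------------------------------
    proteins_faa = out / "proteins.faa"
    key = _digest([config.to_dict(), _input_digest(gbk_files), "extract"])
    genomes: list[tuple[str, list]] = []
    labels: dict[str, str] = {}
    all_proteins = []
    for path in gbk_files:
        try:
            replicons, meta = genome_io.read_genbank(path)
        except genome_io.GenBankFormatError as exc:
            raise RuntimeError(f"stage extract failed on {path.name}: {exc}") from exc
        genomes.append((meta.genome_id, replicons))
        labels[meta.genome_id] = meta.family_label
        all_proteins.extend(
            genome_io.extract_cds_proteins(replicons, meta.genome_id, meta.family_label)
        )
    if not cache.fresh("extract", key, [proteins_faa]):
        logger.info("stage extract: %d genomes, %d proteins", len(genomes), len(all_proteins))
        genome_io.write_multifasta(all_proteins, proteins_faa)
        cache.mark("extract", key)
    else:
        logger.info("stage extract: cached")

    # -- cluster + build + refine ------------------------------------------
    models_dir = out / "models"
    key = _digest([config.to_dict(), _input_digest([proteins_faa]), "models"])
    if not cache.fresh("models", key, [models_dir / "registry.json"]):
        clusters, rmap, state, summary = build_and_refine(all_proteins, config)
        logger.info("stage cluster: %s", summary)
        (out / "clusters.tsv").write_text(
            "cluster_id\tfamily\tmembers\n"
            + "".join(
                f"{c.cluster_id}\t{c.family_label}\t{','.join(sorted(c.member_ids))}\n"
                for c in clusters
            )
        )
        profile_hmm.save_models(state.models, models_dir)
        (out / "redundancy.tsv").write_text(
            "representative\tremoved\n"
            + "".join(
                f"{rep}\t{','.join(sorted(removed))}\n"
                for rep, removed in sorted(rmap.removed_by_rep.items())
            )
        )
        cache.mark("models", key)
    else:
        logger.info("stage models: cached")
    models = profile_hmm.load_models(models_dir)
    model_sets = taxonomy.group_models_by_family(models)

    # -- classify ----------------------------------------------------------
    if classify_dir is not None:
        rows = []
        for path in sorted(Path(classify_dir).glob("*.gbk")):
            replicons, meta = genome_io.read_genbank(path)
            prots = genome_io.extract_cds_proteins(replicons, meta.genome_id)
            result = taxonomy.classify_genome(
                prots, model_sets, genome_id=meta.genome_id,
                min_distinct_models=config.min_distinct_models,
                min_coverage=config.min_hit_coverage, max_evalue=config.max_evalue,
            )
            per_fam = {
                r.family: (r.n_models, r.n_hits, round(r.sum_norm_score, 4))
                for r in result.per_family.itertuples()
            }
            rows.append(f"{meta.genome_id}\t{result.call}\t{json.dumps(per_fam)}\n")
        (out / "calls.tsv").write_text("genome\tcall\tevidence\n" + "".join(rows))
        logger.info("stage classify: %d genomes", len(rows))

    # -- recover intergenic CDS --------------------------------------------
    if recover:
        recovered = refinement.recover_missing_cds(
            genomes, models,
            min_intergenic_nt=config.min_intergenic_nt,
            min_orf_aa=config.min_orf_aa,
            min_coverage=config.min_hit_coverage, max_evalue=config.max_evalue,
        )
        genome_io.write_hits_tsv([r.hit for r in recovered], out / "recovered.tsv")
        logger.info("stage recover-cds: %d candidate CDS", len(recovered))

    # -- host scan ----------------------------------------------------------
    if host_dir is not None:
        all_loci = []
        for path in sorted(Path(host_dir).glob("*.gbk")):
            replicons, meta = genome_io.read_genbank(path)
            gene_hits = prophage.scan_host(
                replicons, model_sets, genome_id=meta.genome_id,
                min_coverage=config.min_hit_coverage, max_evalue=config.max_evalue,
            )
            loci = prophage.call_and_classify(
                gene_hits, model_sets,
                min_consecutive=config.min_consecutive,
                max_gene_gap=config.max_gene_gap,
                min_distinct_models=config.min_distinct_models,
                replicons=replicons,
            )
            all_loci.extend(loci)
        genome_io.write_loci_gff(all_loci, out / "loci.gff3")
        logger.info("stage scan-host: %d loci", len(all_loci))
        if regions_tsv is not None:
            regions = prophage.read_regions_tsv(regions_tsv)
            report = prophage.compare_to_regions(all_loci, regions)
            (out / "overlap_report.json").write_text(json.dumps(
                {k: v for k, v in report.items() if not isinstance(v, list)}, indent=1
            ))
    return out
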