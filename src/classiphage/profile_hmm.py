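"""Profile HMM construction and search.

Models are built from mafft multiple alignments of protein clusters with
HMMER's default plan7 architecture (via pyhmmer), each carrying its emitted
consensus sequence and a registry of the member proteins that built it.
Hits report the full-sequence E-value and bit score together with the
best-scoring domain's alignment coordinates; ``coverage`` is measured on the
model and ``norm_score`` divides the bit score by the consensus size in
base pairs (3 x model length), which puts models of different lengths on a
common scale.
"""

from __future__ import annotations

import json
import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pyhmmer
from pyhmmer import easel, plan7

from .clustering import ProteinCluster
from .genome_io import ProteinRecord

logger = logging.getLogger("classiphage")

#: fixed hmmbuild RNG seed so rebuilding from the same MSA is byte-identical
BUILDER_SEED = 42


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MSA:
    """A multiple sequence alignment of one cluster ('-' is the gap symbol)."""

    cluster_id: str
    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"MSA {self.cluster_id}: rows have unequal lengths")

    def ungapped(self, row_id: str) -> str:
        for rid, seq in self.rows:
            if rid == row_id:
                return seq.replace("-", "")
        raise KeyError(row_id)


@dataclass
class ProfileHMM:
    """A built profile with consensus sequence and member registry."""

    model_id: str
    family_label: Optional[str]
    member_ids: set[str]
    consensus: str
    model_length: int
    hmm: plan7.HMM  # backing model handle

    def __post_init__(self) -> None:
        if self.model_length != len(self.consensus):
            raise ValueError(
                f"{self.model_id}: consensus length {len(self.consensus)} "
                f"!= model length {self.model_length}"
            )


@dataclass(frozen=True)
class HmmHit:
    """One model-vs-protein match."""

    model_id: str
    target_id: str
    evalue: float
    bit_score: float
    ali_from: int  # 1-based inclusive on target
    ali_to: int
    hmm_from: int  # 1-based inclusive on model
    hmm_to: int
    coverage: float
    norm_score: float

    def __post_init__(self) -> None:
        if self.ali_to < self.ali_from:
            raise ValueError("ali_to < ali_from")
        if not 0 < self.coverage <= 1 + 1e-9:
            raise ValueError(f"coverage {self.coverage} outside (0,1]")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_cluster(cluster: ProteinCluster, mafft_path: str = "mafft") -> MSA:
    """Align all cluster members with mafft (``--auto``).

    Deterministic for a fixed member order.  A singleton cluster degenerates
    to a single-row, gap-free alignment.
    """
    if len(cluster.members) == 1:
        m = cluster.members[0]
        return MSA(cluster_id=cluster.cluster_id, rows=[(m.id, m.sequence)])
    if shutil.which(mafft_path) is None:
        raise RuntimeError(f"mafft executable not found ({mafft_path!r})")
    with tempfile.NamedTemporaryFile("w", suffix=".faa", delete=False) as fh:
        # mafft mangles long ids; pass ordinals and map back afterwards
        for i, m in enumerate(cluster.members):
            fh.write(f">{i}\n{m.sequence}\n")
        tmp = fh.name
    try:
        proc = subprocess.run(
            [mafft_path, "--quiet", "--auto", "--amino", tmp],
            capture_output=True, text=True, check=True,
        )
    finally:
        Path(tmp).unlink(missing_ok=True)
    rows: list[tuple[str, str]] = []
    name, chunks = None, []
    for line in proc.stdout.splitlines() + [">"]:
        if line.startswith(">"):
            if name is not None:
                rows.append((cluster.members[int(name)].id, "".join(chunks).upper()))
            name, chunks = line[1:].split()[0] if len(line) > 1 else None, []
        else:
            chunks.append(line.strip())
    for (rid, aligned), member in zip(rows, cluster.members):
        if aligned.replace("-", "") != member.sequence:
            raise RuntimeError(f"mafft altered sequence of {rid}")
    return MSA(cluster_id=cluster.cluster_id, rows=rows)


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def build_hmm(
    msa: MSA, model_id: str, family_label: Optional[str] = None
) -> ProfileHMM:
    """Build a plan7 profile from an MSA with default construction/weighting.

    The consensus (most probable match-state residues, as hmmemit reports)
    is stored uppercase; model length equals the number of match states.
    """
    abc = easel.Alphabet.amino()
    seqs = [
        easel.TextSequence(name=str(i).encode(), sequence=seq)
        for i, (_, seq) in enumerate(msa.rows)
    ]
    text_msa = easel.TextMSA(name=model_id.encode(), sequences=seqs)
    digital = text_msa.digitize(abc)
    builder = plan7.Builder(abc, seed=BUILDER_SEED)
    background = plan7.Background(abc)
    hmm, _, _ = builder.build_msa(digital, background)
    hmm.name = model_id.encode()
    consensus = (hmm.consensus or "").upper()
    return ProfileHMM(
        model_id=model_id,
        family_label=family_label,
        member_ids={rid for rid, _ in msa.rows},
        consensus=consensus,
        model_length=hmm.M,
        hmm=hmm,
    )


def build_model_from_cluster(cluster: ProteinCluster) -> ProfileHMM:
    msa = align_cluster(cluster)
    return build_hmm(msa, model_id=cluster.cluster_id, family_label=cluster.family_label)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_models(models: Iterable[ProfileHMM], out_dir: str | Path) -> None:
    """Write each model as HMMER3 ASCII plus a JSON registry of members."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    registry = {}
    for m in models:
        m.hmm.name = m.model_id.encode()
        with open(out_dir / f"{m.model_id}.hmm", "wb") as fh:
            m.hmm.write(fh, binary=False)
        registry[m.model_id] = {
            "family_label": m.family_label,
            "member_ids": sorted(m.member_ids),
            "consensus": m.consensus,
        }
    with open(out_dir / "registry.json", "w") as fh:
        json.dump(registry, fh, indent=1, sort_keys=True)


def load_models(model_dir: str | Path) -> list[ProfileHMM]:
    model_dir = Path(model_dir)
    with open(model_dir / "registry.json") as fh:
        registry = json.load(fh)
    models = []
    for model_id in sorted(registry):
        entry = registry[model_id]
        with plan7.HMMFile(model_dir / f"{model_id}.hmm") as hf:
            hmm = hf.read()
        models.append(
            ProfileHMM(
                model_id=model_id,
                family_label=entry["family_label"],
                member_ids=set(entry["member_ids"]),
                consensus=entry["consensus"],
                model_length=hmm.M,
                hmm=hmm,
            )
        )
    return models


# ---------------------------------------------------------------------------
# scanning and hit filtering
# ---------------------------------------------------------------------------

def scan(
    proteins: Sequence[ProteinRecord],
    model_library: Sequence[ProfileHMM],
    report_evalue: float = 10.0,
    norm_unit: str = "bp",
) -> list[HmmHit]:
    """Search every model against the protein set.

    Per (model, target) pair only the best-scoring domain contributes the
    alignment coordinates; the E-value is the full-sequence E-value against
    the scanned database size.  ``norm_unit='bp'`` divides bit scores by
    3 x model length (consensus size in base pairs); ``'aa'`` divides by the
    model length itself.
    """
    if not model_library:
        raise ValueError("empty model library")
    if not proteins:
        raise ValueError("no proteins to scan")
    if norm_unit not in ("bp", "aa"):
        raise ValueError(f"unknown norm_unit {norm_unit!r}")
    abc = easel.Alphabet.amino()
    block = easel.DigitalSequenceBlock(
        abc,
        [
            easel.TextSequence(name=p.id.encode(), sequence=p.sequence).digitize(abc)
            for p in proteins
        ],
    )
    models = sorted(model_library, key=lambda m: m.model_id)
    hits: list[HmmHit] = []
    for model, tophits in zip(
        models, pyhmmer.hmmer.hmmsearch((m.hmm for m in models), block, cpus=1,
                                        E=report_evalue)
    ):
        denom = 3 * model.model_length if norm_unit == "bp" else model.model_length
        for hit in tophits:
            if hit.evalue > report_evalue:
                continue
            dom = hit.best_domain
            ali = dom.alignment
            span = ali.hmm_to - ali.hmm_from + 1
            hits.append(
                HmmHit(
                    model_id=model.model_id,
                    target_id=hit.name if isinstance(hit.name, str) else hit.name.decode(),
                    evalue=float(hit.evalue),
                    bit_score=float(hit.score),
                    ali_from=ali.target_from,
                    ali_to=ali.target_to,
                    hmm_from=ali.hmm_from,
                    hmm_to=ali.hmm_to,
                    coverage=span / model.model_length,
                    norm_score=float(hit.score) / denom,
                )
            )
    hits.sort(key=lambda h: (h.model_id, h.evalue, h.target_id))
    return hits


def filter_hits(
    hits: Iterable[HmmHit],
    min_coverage: float = 0.5,
    max_evalue: float = 1.5e-8,
    require_positive_bits: bool = True,
) -> list[HmmHit]:
    """Apply the three rejection cut-offs, preserving input order.

    A hit is discarded if its model coverage is below ``min_coverage``, its
    bit score is not positive, or its E-value exceeds ``max_evalue``
    (defaults: 50% coverage, positive bits, 1.5e-8).
    """
    return [
        h
        for h in hits
        if h.coverage >= min_coverage
        and h.evalue <= max_evalue
        and (h.bit_score > 0 or not require_positive_bits)
    ]
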