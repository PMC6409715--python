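"""Deterministic synthetic phage families, genomes and hosts.

The generator emulates the structure the pipeline exploits in real data:
each phage family owns a repertoire of ancestral protein families; every
genome of the family carries a random subset of those repertoires, each copy
diverged from its ancestor by point substitutions; bacterial hosts consist
of unrelated background genes with an optional contiguous implanted block of
phage genes.  Ancestors are drawn from a uniform amino-acid model, so
different families share only background identity (~1/20) and any
cross-family model hit signals a bug rather than shared ancestry.

Evolution is substitution-only (no indels) so that alignment coverage stays
near 1 and threshold logic is exercised in isolation from aligner quality;
``indel_rate`` is available for stress tests.  Everything derives from a
single integer seed through named child seeds, so one seed reproduces every
fixture byte-for-byte.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .genome_io import CdsFeature, Replicon

AA = "ACDEFGHIKLMNPQRSTVWY"

#: codons per amino acid, translation table 11 (stop codons excluded)
_CODONS: dict[str, list[str]] = {}
for _c in [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]:
    _aa = str(Seq(_c).translate(table=11))
    if _aa != "*":
        _CODONS.setdefault(_aa, []).append(_c)

_STOPS = ["TAA", "TAG", "TGA"]


def _rng(seed: int, *tags) -> random.Random:
    """Child RNG keyed by the master seed and a name path (stable across runs)."""
    return random.Random("|".join([str(seed), *map(str, tags)]))


# ---------------------------------------------------------------------------
# specs and manifests
# ---------------------------------------------------------------------------

@dataclass
class FamilySpec:
    family_label: str
    ancestors: list[str]  # one protein per protein family
    presence_prob: float = 0.9
    divergence: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.presence_prob <= 1:
            raise ValueError("presence_prob must be in (0,1]")
        if not 0 <= self.divergence < 0.8:
            raise ValueError("divergence must be in [0, 0.8)")
        for a in self.ancestors:
            if len(a) < 60:
                raise ValueError("ancestral proteins must be >= 60 aa")


@dataclass
class PhageFixture:
    """An in-memory synthetic phage genome with its truth data."""

    genome_id: str
    family_label: str
    replicon: Replicon
    carried_families: list[int]  # indices into FamilySpec.ancestors
    deleted_cds: list[CdsFeature] = field(default_factory=list)


@dataclass
class HostFixture:
    genome_id: str
    replicons: list[Replicon]
    implants: list[dict] = field(default_factory=list)  # truth records


# ---------------------------------------------------------------------------
# family and genome generation
# ---------------------------------------------------------------------------

def generate_families(
    n_families: int = 4,
    n_protein_families: int = 10,
    length_range: tuple[int, int] = (80, 200),
    presence_prob: float = 0.9,
    divergence: float = 0.3,
    seed: int = 42,
) -> list[FamilySpec]:
    """Ancestral repertoires for ``n_families`` synthetic phage families."""
    if n_families < 2:
        raise ValueError("need at least 2 families for classification tests")
    specs = []
    for fi in range(n_families):
        label = f"family{chr(ord('A') + fi)}"
        ancestors = []
        for pi in range(n_protein_families):
            r = _rng(seed, "ancestor", label, pi)
            length = r.randint(*length_range)
            ancestors.append("".join(r.choice(AA) for _ in range(length)))
        specs.append(
            FamilySpec(family_label=label, ancestors=ancestors,
                       presence_prob=presence_prob, divergence=divergence)
        )
    return specs


def mutate_protein(protein: str, divergence: float, rng: random.Random,
                   indel_rate: float = 0.0) -> str:
    """Uniform point substitutions at the divergence rate (optional indels)."""
    out = []
    for c in protein:
        if indel_rate and rng.random() < indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(rng.choice(AA))  # insertion before the site
        if rng.random() < divergence:
            out.append(rng.choice([a for a in AA if a != c]))
        else:
            out.append(c)
    return "".join(out)


def _reverse_translate(protein: str, rng: random.Random) -> str:
    return "".join(rng.choice(_CODONS[c]) for c in protein) + rng.choice(_STOPS)


def _random_nt(length: int, rng: random.Random) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def _assemble_replicon(
    rep_id: str,
    genes: Sequence[tuple[str, str, str, str]],  # (locus_tag, protein, product, strand)
    rng: random.Random,
    spacer_range: tuple[int, int] = (50, 200),
    topology: str = "linear",
) -> Replicon:
    seq_parts: list[str] = []
    features: list[CdsFeature] = []
    pos = 0
    for tag, protein, product, strand in genes:
        spacer = _random_nt(rng.randint(*spacer_range), rng)
        seq_parts.append(spacer)
        pos += len(spacer)
        nt = _reverse_translate(protein, rng)
        if strand == "-":
            nt = str(Seq(nt).reverse_complement())
        features.append(
            CdsFeature(locus_tag=tag, start=pos, end=pos + len(nt), strand=strand,
                       product=product, translation=protein)
        )
        seq_parts.append(nt)
        pos += len(nt)
    seq_parts.append(_random_nt(rng.randint(*spacer_range), rng))
    return Replicon(id=rep_id, sequence="".join(seq_parts), topology=topology,
                    features=features)


def evolve_genome(spec: FamilySpec, genome_id: str, seed: int) -> PhageFixture:
    """One phage genome of the family: a mutated copy of each carried
    ancestral protein family, reverse-translated and separated by random
    spacers.  At least one protein family is always carried."""
    r = _rng(seed, "genome", genome_id)
    carried = [i for i in range(len(spec.ancestors)) if r.random() < spec.presence_prob]
    if not carried:
        carried = [r.randrange(len(spec.ancestors))]
    genes = []
    for i in carried:
        protein = mutate_protein(spec.ancestors[i], spec.divergence, r)
        strand = r.choice("+-")
        genes.append(
            (f"{genome_id}_p{i:02d}", protein,
             f"{spec.family_label} protein family {i}", strand)
        )
    replicon = _assemble_replicon(genome_id, genes, r)
    return PhageFixture(
        genome_id=genome_id, family_label=spec.family_label,
        replicon=replicon, carried_families=carried,
    )


def generate_genomes(
    specs: Sequence[FamilySpec], genomes_per_family: int = 12, seed: int = 42
) -> list[PhageFixture]:
    return [
        evolve_genome(spec, f"{spec.family_label}_g{gi:02d}", seed)
        for spec in specs
        for gi in range(genomes_per_family)
    ]


# ---------------------------------------------------------------------------
# host genomes with implanted prophages
# ---------------------------------------------------------------------------

def implant_prophage(
    host_length: int,
    phage_fixture: Optional[PhageFixture],
    position: int,
    seed: int,
    host_id: str = "host",
    background_gene_length: tuple[int, int] = (80, 200),
) -> HostFixture:
    """A host replicon of about ``host_length`` nt of background genes, with
    the phage's gene block inserted contiguously at ``position`` (clamped to
    the nearest background-gene boundary).  The manifest records the truth
    coordinates and ordinal span of the implant."""
    if phage_fixture is not None and not 0 <= position <= host_length:
        raise ValueError(f"implant position {position} outside host of {host_length} nt")
    r = _rng(seed, "host", host_id)
    background: list[tuple[str, str, str, str]] = []
    est = 0
    bi = 0
    while est < host_length:
        length = r.randint(*background_gene_length)
        protein = "".join(r.choice(AA) for _ in range(length))
        background.append(
            (f"{host_id}_b{bi:03d}", protein, "hypothetical protein", r.choice("+-"))
        )
        est += 3 * length + 125  # mean spacer
        bi += 1
    implants: list[dict] = []
    genes = list(background)
    if phage_fixture is not None:
        frac = position / host_length if host_length else 0.0
        at = min(len(background), round(frac * len(background)))
        phage_genes = [
            (f"{host_id}|{f.locus_tag}", f.translation, f.product, f.strand)
            for f in phage_fixture.replicon.features
        ]
        genes = background[:at] + phage_genes + background[at:]
    replicon = _assemble_replicon(host_id, genes, r)
    if phage_fixture is not None:
        n_phage = len(phage_fixture.replicon.features)
        block = replicon.features[at : at + n_phage]
        implants.append(
            {
                "replicon_id": host_id,
                "source_genome": phage_fixture.genome_id,
                "family_label": phage_fixture.family_label,
                "start": block[0].start,
                "end": block[-1].end,
                "first_gene_ordinal": at,
                "last_gene_ordinal": at + n_phage - 1,
                "n_genes": n_phage,
            }
        )
    return HostFixture(genome_id=host_id, replicons=[replicon], implants=implants)


def delete_random_cds(fixture: PhageFixture, k: int, seed: int) -> PhageFixture:
    """Remove ``k`` CDS from the annotation (sequence untouched); the removed
    features are recorded so recovery can be checked against them."""
    if k == 0:
        return fixture
    r = _rng(seed, "delete", fixture.genome_id)
    features = list(fixture.replicon.features)
    if k > len(features):
        raise ValueError("cannot delete more CDS than annotated")
    doomed = sorted(r.sample(range(len(features)), k))
    removed = [features[i] for i in doomed]
    kept = [f for i, f in enumerate(features) if i not in set(doomed)]
    replicon = Replicon(
        id=fixture.replicon.id, sequence=fixture.replicon.sequence,
        topology=fixture.replicon.topology, features=kept,
    )
    return PhageFixture(
        genome_id=fixture.genome_id, family_label=fixture.family_label,
        replicon=replicon, carried_families=list(fixture.carried_families),
        deleted_cds=list(fixture.deleted_cds) + removed,
    )


# ---------------------------------------------------------------------------
# GenBank output and manifests
# ---------------------------------------------------------------------------

def _to_seqrecord(replicon: Replicon, genome_id: str,
                  taxonomy: Optional[list[str]] = None) -> SeqRecord:
    rec = SeqRecord(
        Seq(replicon.sequence), id=replicon.id, name=replicon.id[:16],
        description=f"synthetic genome {genome_id}",
        annotations={
            "molecule_type": "DNA",
            "topology": replicon.topology,
            "taxonomy": taxonomy or [],
        },
    )
    for f in replicon.features:
        rec.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, strand=1 if f.strand == "+" else -1),
                type="CDS",
                qualifiers={
                    "locus_tag": [f.locus_tag],
                    "product": [f.product],
                    "translation": [f.translation],
                    "transl_table": ["11"],
                },
            )
        )
    return rec


def write_genbank(fixture: PhageFixture | HostFixture, path: str | Path) -> None:
    if isinstance(fixture, PhageFixture):
        records = [_to_seqrecord(fixture.replicon, fixture.genome_id,
                                 taxonomy=["Viruses", fixture.family_label])]
    else:
        records = [_to_seqrecord(rep, fixture.genome_id) for rep in fixture.replicons]
    SeqIO.write(records, str(path), "genbank")


def generate_dataset(
    out_dir: str | Path,
    n_families: int = 4,
    genomes_per_family: int = 12,
    n_protein_families: int = 10,
    divergence: float = 0.3,
    presence_prob: float = 0.9,
    seed: int = 42,
) -> dict:
    """Write a full phage fixture set as GenBank files plus a truth manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    specs = generate_families(
        n_families, n_protein_families, presence_prob=presence_prob,
        divergence=divergence, seed=seed,
    )
    fixtures = generate_genomes(specs, genomes_per_family, seed=seed)
    manifest = {
        "seed": seed,
        "families": {
            s.family_label: {
                "n_protein_families": len(s.ancestors),
                "presence_prob": s.presence_prob,
                "divergence": s.divergence,
            }
            for s in specs
        },
        "genomes": {},
    }
    for fx in fixtures:
        write_genbank(fx, out_dir / f"{fx.genome_id}.gbk")
        manifest["genomes"][fx.genome_id] = {
            "family_label": fx.family_label,
            "carried_families": fx.carried_families,
        }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
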