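"""GenBank ingestion, CDS/intergenic extraction and flat-file output.

All genomic coordinates are 0-based half-open internally; GFF3 output
converts to the 1-based inclusive convention of that format.  Amino-acid
sequences use the 20-letter alphabet plus ``X``; stop symbols are stripped
on extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("classiphage")

#: translation table for CDS lacking a /translation qualifier
#: (bacterial/plastid code, the standard for phage and host genomes)
TRANSLATION_TABLE = 11

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


class GenBankFormatError(ValueError):
    """Raised when a GenBank flat file cannot be parsed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CdsFeature:
    """One annotated coding sequence on a replicon."""

    locus_tag: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str  # '+' or '-'
    product: str = ""
    translation: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"CDS {self.locus_tag}: end must exceed start")
        if self.strand not in "+-":
            raise ValueError(f"CDS {self.locus_tag}: strand must be '+' or '-'")


@dataclass
class Replicon:
    """One GenBank record: a chromosome, plasmid or phage genome."""

    id: str
    sequence: str
    topology: str = "linear"  # or "circular"
    features: list[CdsFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        n = len(self.sequence)
        for f in self.features:
            if f.start < 0 or f.end > n:
                raise ValueError(
                    f"feature {f.locus_tag} [{f.start},{f.end}) outside replicon "
                    f"{self.id} of length {n}"
                )


@dataclass
class GenomeMetadata:
    genome_id: str
    family_label: Optional[str] = None
    host: Optional[str] = None
    genome_size_bp: int = 0
    isolation_source: Optional[str] = None


@dataclass(frozen=True)
class ProteinRecord:
    """One annotated or recovered protein with genomic provenance."""

    id: str
    sequence: str
    source_genome: str
    family_label: Optional[str] = None
    coords: Optional[tuple[str, int, int, str]] = None  # replicon, start, end, strand


@dataclass(frozen=True)
class NucleotideRegion:
    """A stretch of a replicon not covered by any annotated CDS.

    For a wrap-around gap on a circular replicon ``end`` may exceed the
    replicon length; the sequence is the concatenation across the origin and
    ``len(sequence) == end - start`` still holds.
    """

    replicon_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError("region sequence length disagrees with coordinates")


# ---------------------------------------------------------------------------
# GenBank reading
# ---------------------------------------------------------------------------

def _clean_protein(seq: str) -> str:
    """Strip stop symbols and map non-standard letters onto X."""
    seq = seq.upper().replace("*", "")
    return "".join(c if c in VALID_AA else "X" for c in seq)


def _translate_span(nt: str) -> str:
    """Translate a nucleotide span with the bacterial code; trailing stop dropped."""
    trimmed = nt[: len(nt) - len(nt) % 3]
    return _clean_protein(str(Seq(trimmed).translate(table=TRANSLATION_TABLE)))


def read_genbank(path: str | Path) -> tuple[list[Replicon], GenomeMetadata]:
    """Parse a (possibly multi-record) GenBank flat file.

    Returns one :class:`Replicon` per record plus genome-level metadata drawn
    from the first record's annotations and source feature.  CDS features
    keep their /translation qualifier verbatim when present and are otherwise
    translated from the genomic span.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # biopython raises bare ValueError with line info
        raise GenBankFormatError(f"{path}: {exc}") from exc
    if not records:
        raise GenBankFormatError(f"{path}: no GenBank records found")

    replicons: list[Replicon] = []
    meta = GenomeMetadata(genome_id=path.stem)
    for idx, rec in enumerate(records):
        feats: list[CdsFeature] = []
        for fi, feat in enumerate(rec.features):
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            tag = quals.get("locus_tag", quals.get("protein_id", [f"cds{fi}"]))[0]
            start, end = int(feat.location.start), int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            if "translation" in quals:
                aa = _clean_protein(quals["translation"][0])
            else:
                aa = _clean_protein(
                    str(feat.extract(rec.seq).translate(table=TRANSLATION_TABLE))
                )
            if not aa:
                logger.warning("%s: CDS %s has empty translation, skipped", path, tag)
                continue
            feats.append(
                CdsFeature(
                    locus_tag=tag,
                    start=start,
                    end=end,
                    strand=strand,
                    product=quals.get("product", [""])[0],
                    translation=aa,
                )
            )
        topology = rec.annotations.get("topology", "linear")
        replicons.append(
            Replicon(id=rec.id or f"{path.stem}_{idx}", sequence=str(rec.seq).upper(),
                     topology=topology, features=feats)
        )
        if not feats:
            logger.warning("%s: record %s contains no CDS features", path, rec.id)
        if idx == 0:
            meta.genome_id = rec.annotations.get("accessions", [path.stem])[0] or path.stem
            taxonomy = rec.annotations.get("taxonomy", [])
            for taxon in taxonomy:
                if taxon.endswith("viridae"):
                    meta.family_label = taxon
            if meta.family_label is None and len(taxonomy) > 1:
                # deepest taxon below the superkingdom carries the family
                meta.family_label = taxonomy[-1]
            for feat in rec.features:
                if feat.type == "source":
                    q = feat.qualifiers
                    meta.host = q.get("host", q.get("lab_host", [None]))[0]
                    meta.isolation_source = q.get("isolation_source", [None])[0]
    meta.genome_size_bp = sum(len(r.sequence) for r in replicons)
    return replicons, meta


# ---------------------------------------------------------------------------
# protein extraction
# ---------------------------------------------------------------------------

def extract_cds_proteins(
    replicons: Iterable[Replicon],
    genome_id: str,
    family_label: Optional[str] = None,
) -> list[ProteinRecord]:
    """One ProteinRecord per annotated CDS, with globally unique ids.

    Ids are ``genome_id|replicon_id|locus_tag``; duplicated locus tags within
    a replicon are disambiguated with ordinal suffixes (``_1``, ``_2``, ...).
    """
    records: list[ProteinRecord] = []
    for rep in replicons:
        tag_counts: dict[str, int] = {}
        for f in rep.features:
            tag_counts[f.locus_tag] = tag_counts.get(f.locus_tag, 0) + 1
        seen: dict[str, int] = {}
        for f in rep.features:
            tag = f.locus_tag
            if tag_counts[tag] > 1:
                seen[tag] = seen.get(tag, 0) + 1
                logger.warning(
                    "%s/%s: duplicate locus_tag %r disambiguated", genome_id, rep.id, tag
                )
                tag = f"{tag}_{seen[tag]}"
            records.append(
                ProteinRecord(
                    id=f"{genome_id}|{rep.id}|{tag}",
                    sequence=_clean_protein(f.translation),
                    source_genome=genome_id,
                    family_label=family_label,
                    coords=(rep.id, f.start, f.end, f.strand),
                )
            )
    return records


# ---------------------------------------------------------------------------
# intergenic regions and six-frame translation
# ---------------------------------------------------------------------------

def _merged_cds_spans(replicon: Replicon) -> list[tuple[int, int]]:
    spans: list[tuple[int, int]] = []
    for f in replicon.features:
        if spans and f.start <= spans[-1][1]:
            spans[-1] = (spans[-1][0], max(spans[-1][1], f.end))
        else:
            spans.append((f.start, f.end))
    return spans


def extract_intergenic_regions(
    replicon: Replicon, min_len_nt: int = 90
) -> list[NucleotideRegion]:
    """Maximal gaps between annotated CDS spans, at least ``min_len_nt`` long.

    Linear replicons contribute the 5'/3' flanks as regions; on circular
    replicons the two flanks are merged into a single wrap-around region whose
    ``end`` coordinate runs past the origin.
    """
    n = len(replicon.sequence)
    spans = _merged_cds_spans(replicon)
    if not spans:
        if n >= min_len_nt:
            return [NucleotideRegion(replicon.id, 0, n, replicon.sequence)]
        return []

    regions: list[NucleotideRegion] = []
    for (s0, e0), (s1, _) in zip(spans, spans[1:]):
        if s1 - e0 >= min_len_nt:
            regions.append(
                NucleotideRegion(replicon.id, e0, s1, replicon.sequence[e0:s1])
            )
    head, tail = spans[0][0], spans[-1][1]
    if replicon.topology == "circular":
        wrap = (n - tail) + head
        if wrap >= min_len_nt:
            regions.append(
                NucleotideRegion(
                    replicon.id, tail, n + head,
                    replicon.sequence[tail:] + replicon.sequence[:head],
                )
            )
    else:
        if head >= min_len_nt:
            regions.append(NucleotideRegion(replicon.id, 0, head, replicon.sequence[:head]))
        if n - tail >= min_len_nt:
            regions.append(
                NucleotideRegion(replicon.id, tail, n, replicon.sequence[tail:])
            )
    return sorted(regions, key=lambda r: r.start)


def six_frame_translate(
    region: NucleotideRegion, min_orf_aa: int = 30, source_genome: str = ""
) -> list[ProteinRecord]:
    """Candidate proteins from all six reading frames of a region.

    Every maximal stop-free amino-acid stretch of at least ``min_orf_aa``
    residues is emitted (no start-codon requirement: annotation-independent
    recovery must find gene fragments too).  Coordinates are mapped back to
    the replicon; reverse-strand candidates carry strand '-'.
    """
    nt = region.sequence.upper()
    L = len(nt)
    if L < 3 * min_orf_aa:
        return []
    out: list[ProteinRecord] = []
    rc = str(Seq(nt).reverse_complement())
    for strand, seq in (("+", nt), ("-", rc)):
        for frame in range(3):
            sub = seq[frame:]
            aa = str(Seq(sub[: len(sub) - len(sub) % 3]).translate(table=TRANSLATION_TABLE))
            pos = 0
            for chunk in aa.split("*"):
                if len(chunk) >= min_orf_aa:
                    # aa index range [pos, pos+len) -> nt offsets within `seq`
                    nt_lo = frame + 3 * pos
                    nt_hi = frame + 3 * (pos + len(chunk))
                    if strand == "+":
                        start, end = region.start + nt_lo, region.start + nt_hi
                    else:
                        start, end = region.start + L - nt_hi, region.start + L - nt_lo
                    out.append(
                        ProteinRecord(
                            id=f"{region.replicon_id}:{start}-{end}({strand})",
                            sequence=_clean_protein(chunk),
                            source_genome=source_genome,
                            coords=(region.replicon_id, start, end, strand),
                        )
                    )
                pos += len(chunk) + 1
    out.sort(key=lambda r: (r.coords[1], r.coords[2], r.coords[3]))
    return out


# ---------------------------------------------------------------------------
# flat-file output
# ---------------------------------------------------------------------------

def write_multifasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records as FASTA; description carries genome and family."""
    with open(path, "w") as fh:
        for r in records:
            desc = r.source_genome
            if r.family_label:
                desc += f" family={r.family_label}"
            fh.write(f">{r.id} {desc}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")


def read_multifasta(path: str | Path) -> list[ProteinRecord]:
    """Read FASTA written by :func:`write_multifasta` (ids and sequences exact)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()
        family = None
        genome = parts[1] if len(parts) > 1 else ""
        for p in parts[1:]:
            if p.startswith("family="):
                family = p[len("family="):]
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq), source_genome=genome,
                          family_label=family)
        )
    return records


def write_hits_tsv(hits: Sequence, path: str | Path) -> None:
    """Tab-separated hit table (model, target, evalue, bitscore, coverage, norm_score, coords)."""
    cols = ["model", "target", "evalue", "bitscore", "coverage", "norm_score",
            "ali_from", "ali_to", "hmm_from", "hmm_to"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for h in hits:
            fh.write(
                f"{h.model_id}\t{h.target_id}\t{h.evalue:.3g}\t{h.bit_score:.2f}\t"
                f"{h.coverage:.4f}\t{h.norm_score:.5f}\t"
                f"{h.ali_from}\t{h.ali_to}\t{h.hmm_from}\t{h.hmm_to}\n"
            )


def write_loci_gff(loci: Sequence, path: str | Path) -> None:
    """Prophage loci as GFF3 (1-based inclusive); family call in the attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, locus in enumerate(loci):
            strands = {h.strand for h in locus.supporting_hits}
            strand = strands.pop() if len(strands) == 1 else "."
            attrs = (
                f"ID=prophage{i+1};family={locus.family_call};"
                f"n_consecutive={locus.n_consecutive};"
                f"mean_norm_score={locus.mean_norm_score:.4f}"
            )
            fh.write(
                f"{locus.replicon_id}\tclassiphage\tprophage_region\t"
                f"{locus.start + 1}\t{locus.end}\t.\t{strand}\t.\t{attrs}\n"
            )
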