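"""Genome data model and readers/writers for FASTA and GFF3.

All coordinates are 1-based inclusive, following the GFF3/GenBank
convention.  A feature on a circular genome may wrap the origin only when
``wraps_origin`` is set, in which case its span is
``length - start + 1 + end``.

IS-relatedness is an annotation property, not a sequence classifier: a
feature is flagged when its GFF3 type is ``mobile_element``, when it
carries an explicit IS attribute, or when its product matches a small
keyword list (``transposase``, ``insertion sequence``, or an IS-family
name such as ``IS256``).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import AlphabetError, CoordinateError, EmptyInputError

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

_IS_PRODUCT_RE = re.compile(
    r"transposase|insertion\s+sequence|\bIS\d+", re.IGNORECASE
)


@dataclass
class SequenceRecord:
    """A single named sequence over the DNA or protein alphabet."""

    id: str
    residues: str
    alphabet: str = "dna"
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise AlphabetError(f"record {self.id!r}: empty sequence")
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in allowed:
                raise AlphabetError(
                    f"record {self.id!r}: illegal {self.alphabet} residue "
                    f"{ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


FEATURE_TYPES = ("CDS", "pseudogene", "tRNA", "rRNA", "CRISPR_repeat", "other")


@dataclass
class GeneFeature:
    """A typed, stranded genome feature in 1-based inclusive coordinates."""

    locus_tag: str
    ftype: str
    start: int
    end: int
    strand: str = "+"
    product: str = ""
    is_IS_related: bool = False
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            self.ftype = "other"
        if not self.is_IS_related and self.product:
            self.is_IS_related = is_related_product(self.product)
        if not self.wraps_origin and self.start > self.end:
            raise CoordinateError(
                f"feature {self.locus_tag}: start {self.start} > end {self.end}"
            )

    def span(self, genome_length: int | None = None) -> int:
        if self.wraps_origin:
            if genome_length is None:
                raise CoordinateError(
                    f"feature {self.locus_tag}: wraps origin, need genome length"
                )
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def midpoint(self, genome_length: int | None = None) -> float:
        if self.wraps_origin:
            if genome_length is None:
                raise CoordinateError("wrapping feature needs genome length")
            m = self.start + self.span(genome_length) / 2.0
            return m if m <= genome_length else m - genome_length
        return (self.start + self.end) / 2.0


@dataclass
class GenomeAnnotation:
    """Ordered feature list plus genome length and topology."""

    genome_id: str
    length: int
    topology: str = "circular"  # or "linear"
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features.sort(key=lambda f: (f.start, f.end))
        seen: set[str] = set()
        for f in self.features:
            if f.locus_tag in seen:
                raise CoordinateError(f"duplicate locus_tag {f.locus_tag}")
            seen.add(f.locus_tag)
            if f.wraps_origin and self.topology != "circular":
                raise CoordinateError(
                    f"feature {f.locus_tag} wraps origin on linear genome"
                )
            if not f.wraps_origin and (f.start < 1 or f.end > self.length):
                raise CoordinateError(
                    f"feature {f.locus_tag} [{f.start},{f.end}] outside "
                    f"genome of length {self.length}"
                )

    def by_type(self, ftype: str) -> list[GeneFeature]:
        return [f for f in self.features if f.ftype == ftype]

    def get(self, locus_tag: str) -> GeneFeature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(locus_tag)


@dataclass
class Proteome:
    """Protein sequences of one genome, keyed by locus tag."""

    genome_id: str
    proteins: dict[str, SequenceRecord] = field(default_factory=dict)
    translation_warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self):
        return iter(self.proteins.items())


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq),
                alphabet=alphabet,
                description=rec.description[len(rec.id):].strip(),
            )
        )
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, width: int = 70
) -> Path:
    """Write records as wrapped FASTA; round-trips through :func:`read_fasta`."""
    path = Path(path)
    bio_records = []
    for rec in records:
        if any(c.isspace() for c in rec.id):
            warnings.warn(
                f"record id {rec.id!r} contains whitespace; it will be "
                "truncated at the first space on re-read"
            )
        bio_records.append(
            _BioSeqRecord(Seq(rec.residues), id=rec.id, description=rec.description)
        )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio_records)
    return path


# ---------------------------------------------------------------------------
# GFF3

_GFF_TYPE_MAP = {
    "CDS": "CDS",
    "pseudogene": "pseudogene",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "direct_repeat": "CRISPR_repeat",
    "repeat_region": "CRISPR_repeat",
}


def _attr_first(feature, key: str, default: str = "") -> str:
    vals = feature.attributes.get(key, [])
    return vals[0] if vals else default


def is_related_product(product: str) -> bool:
    """True when a product string marks an insertion-sequence protein."""
    return bool(_IS_PRODUCT_RE.search(product))


def read_gff3(path: str | Path, genome_length: int | None = None) -> GenomeAnnotation:
    """Read a GFF3 file into a :class:`GenomeAnnotation`.

    Genome length is taken from the ``##sequence-region`` directive unless
    given explicitly.  A CDS with a ``pseudo`` attribute becomes a
    pseudogene; ``mobile_element`` features and transposase products are
    flagged IS-related.
    """
    path = Path(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genome_id = None
    topology = "circular"
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            parts = directive.split()
            genome_id = parts[1]
            if genome_length is None:
                genome_length = int(parts[3])
    if genome_length is None:
        raise CoordinateError(
            f"{path}: no ##sequence-region directive and no explicit length"
        )

    features: list[GeneFeature] = []
    for f in db.all_features():
        if genome_id is None:
            genome_id = f.seqid
        ftype = _GFF_TYPE_MAP.get(f.featuretype)
        is_flag = f.featuretype == "mobile_element"
        if ftype is None and not is_flag:
            continue
        product = _attr_first(f, "product")
        pseudo = "pseudo" in f.attributes or _attr_first(f, "pseudogene") != ""
        if ftype == "CDS" and pseudo:
            ftype = "pseudogene"
        if is_flag:
            ftype = ftype or "other"
        locus = _attr_first(f, "locus_tag") or f.id or f"{f.featuretype}_{f.start}"
        wraps = _attr_first(f, "wraps_origin") in ("true", "1")
        feat = GeneFeature(
            locus_tag=locus,
            ftype=ftype,
            start=f.start,
            end=f.end,
            strand=f.strand if f.strand in "+-" else "+",
            product=product,
            is_IS_related=is_flag or is_related_product(product),
            wraps_origin=wraps,
        )
        features.append(feat)
    return GenomeAnnotation(
        genome_id=genome_id or path.stem,
        length=genome_length,
        topology=topology,
        features=features,
    )


def write_gff3(ann: GenomeAnnotation, path: str | Path) -> Path:
    """Write an annotation as GFF3 (inverse of :func:`read_gff3`)."""
    path = Path(path)
    type_back = {"CRISPR_repeat": "direct_repeat", "other": "region"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {ann.genome_id} 1 {ann.length}\n")
        for f in ann.features:
            gff_type = type_back.get(f.ftype, f.ftype)
            attrs = [f"ID={f.locus_tag}", f"locus_tag={f.locus_tag}"]
            if f.product:
                attrs.append(f"product={f.product}")
            if f.ftype == "pseudogene":
                gff_type = "pseudogene"
            if f.is_IS_related and not is_related_product(f.product):
                attrs.append("is_element=true")
            if f.wraps_origin:
                attrs.append("wraps_origin=true")
            fh.write(
                "\t".join(
                    [
                        ann.genome_id,
                        "cladecore",
                        gff_type,
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        "0" if gff_type in ("CDS", "pseudogene") else ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
    return path


# ---------------------------------------------------------------------------
# Translation


def feature_dna(feature: GeneFeature, genome: SequenceRecord) -> str:
    """Coding-strand DNA of a feature (reverse-complemented for '-')."""
    if feature.wraps_origin:
        raw = genome.residues[feature.start - 1 :] + genome.residues[: feature.end]
    else:
        raw = genome.residues[feature.start - 1 : feature.end]
    if feature.strand == "-":
        raw = str(Seq(raw).reverse_complement())
    return raw


def extract_proteome(ann: GenomeAnnotation, genome: SequenceRecord) -> Proteome:
    """Translate all non-pseudogene CDS features (table 11).

    The trailing stop codon is removed.  An internal stop truncates the
    protein at the stop and records a translation warning, mirroring
    pseudogene semantics without changing the feature type.
    """
    if len(genome) != ann.length:
        raise CoordinateError(
            f"genome length {len(genome)} != annotation length {ann.length}"
        )
    proteome = Proteome(genome_id=ann.genome_id)
    for f in ann.by_type("CDS"):
        dna = feature_dna(f, genome)
        if len(dna) % 3 != 0:
            raise CoordinateError(
                f"CDS {f.locus_tag}: length {len(dna)} not divisible by 3"
            )
        aa = str(Seq(dna).translate(table=11))
        if aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa:
            aa = aa.split("*", 1)[0]
            proteome.translation_warnings.append(
                f"{f.locus_tag}: internal stop codon; protein truncated"
            )
        if not aa:
            proteome.translation_warnings.append(
                f"{f.locus_tag}: translation empty after truncation; skipped"
            )
            continue
        proteome.proteins[f.locus_tag] = SequenceRecord(
            id=f.locus_tag,
            residues=aa,
            alphabet="protein",
            description=f.product,
        )
    return proteome


def read_proteome_fasta(path: str | Path, genome_id: str | None = None) -> Proteome:
    """Read a protein FASTA keyed by locus tag into a :class:`Proteome`."""
    path = Path(path)
    records = read_fasta(path, alphabet="protein")
    proteome = Proteome(genome_id=genome_id or path.stem)
    for rec in records:
        if rec.id in proteome.proteins:
            raise CoordinateError(f"duplicate locus_tag {rec.id} in {path}")
        proteome.proteins[rec.id] = rec
    return proteome


def write_proteome_fasta(proteome: Proteome, path: str | Path) -> Path:
    return write_fasta(proteome.proteins.values(), path)
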