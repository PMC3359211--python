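"""Sequence and annotation data model for single-chromosome bacterial genomes.

Coordinates are 1-based inclusive throughout (GFF3 convention).  Genomes are
circular by default but features spanning the replication origin are rejected:
the downstream diff engine compares the two chromosomes linearised at
position 1, and origin-spanning features would reintroduce wrap-around
ambiguity for no benefit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_BASES = frozenset("ACGT")
#: start codons rendered as methionine at codon 1 (bacterial table 11 practice)
START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class Genome:
    """A named nucleotide sequence over the strict {A,C,G,T} alphabet."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        bad = next((i for i, b in enumerate(self.sequence) if b not in _VALID_BASES), None)
        if bad is not None:
            raise ValueError(
                f"invalid symbol {self.sequence[bad]!r} at position {bad + 1} "
                f"in genome {self.id!r} (only A/C/G/T accepted)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_content(self) -> float:
        if not self.sequence:
            return 0.0
        gc = self.sequence.count("G") + self.sequence.count("C")
        return gc / len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Subsequence at 1-based inclusive coordinates [start, end]."""
        if not (1 <= start <= end <= self.length):
            raise ValueError(f"slice {start}-{end} outside genome of length {self.length}")
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding feature with 1-based inclusive coordinates."""

    locus_tag: str
    start: int
    end: int
    strand: str
    product: str = ""
    cog_category: str | None = None
    core: bool | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.locus_tag}: strand must be '+' or '-'")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.locus_tag}: require 1 <= start <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def in_frame(self) -> bool:
        return self.length % 3 == 0

    def coding_sequence(self, genome: Genome) -> str:
        """CDS nucleotides on the coding strand (reverse-complemented for '-')."""
        seg = genome.slice(self.start, self.end)
        return seg if self.strand == "+" else str(Seq(seg).reverse_complement())

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


def read_fasta(path) -> Genome:
    """Read a single-record FASTA file into a :class:`Genome`.

    The sequence is uppercased; ambiguity codes are rejected with the
    offending position because the anchor-based diff requires an exact
    alphabet.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected 1 record, found {len(records)} in {path}")
    rec = records[0]
    return Genome(id=rec.id, sequence=str(rec.seq).upper())


def write_fasta(genome: Genome, path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    SeqIO.write([rec], str(path), "fasta")


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise ValueError(f"malformed GFF3 attribute {chunk!r}")
        key, value = chunk.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff(path, genome: Genome) -> list[CdsFeature]:
    """Read CDS rows of a GFF3 file, validated against *genome*.

    Only rows of type ``CDS`` are consumed; each must carry a ``locus_tag``
    attribute (unique per genome).  Recognised optional attributes:
    ``product``, ``cog`` and ``core`` (true/false).
    """
    features: list[CdsFeature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated columns")
            if cols[2] != "CDS":
                continue
            start, end = int(cols[3]), int(cols[4])
            attrs = _parse_gff_attributes(cols[8])
            if "locus_tag" not in attrs:
                raise ValueError(f"{path}:{lineno}: CDS row lacks locus_tag attribute")
            tag = attrs["locus_tag"]
            if tag in seen:
                raise ValueError(f"duplicate locus_tag {tag!r}")
            seen.add(tag)
            if end > genome.length:
                raise ValueError(
                    f"CDS {tag} ends at {end}, beyond genome length {genome.length}"
                )
            core = attrs.get("core")
            features.append(
                CdsFeature(
                    locus_tag=tag,
                    start=start,
                    end=end,
                    strand=cols[6],
                    product=attrs.get("product", ""),
                    cog_category=attrs.get("cog"),
                    core=None if core is None else core.lower() in {"true", "1", "yes"},
                )
            )
    features.sort(key=lambda f: f.start)
    return features


def write_gff(features: list[CdsFeature], genome: Genome, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for f in sorted(features, key=lambda x: x.start):
            attrs = [f"locus_tag={f.locus_tag}"]
            if f.product:
                attrs.append(f"product={f.product}")
            if f.cog_category is not None:
                attrs.append(f"cog={f.cog_category}")
            if f.core is not None:
                attrs.append(f"core={'true' if f.core else 'false'}")
            fh.write(
                f"{genome.id}\tstrainomics\tCDS\t{f.start}\t{f.end}\t.\t{f.strand}\t0\t"
                + ";".join(attrs)
                + "\n"
            )


def read_bed_intervals(path) -> list[tuple[int, int]]:
    """Read BED intervals as sorted 1-based half-open (start, end) tuples.

    BED is 0-based half-open; both bounds are shifted by +1 so that a genome
    position p belongs to an interval iff start <= p < end.
    """
    intervals: list[tuple[int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            intervals.append((int(cols[1]) + 1, int(cols[2]) + 1))
    intervals.sort()
    for (s1, e1), (s2, _) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping BED intervals near {s2}")
    return intervals


def translate_cds(feature: CdsFeature, genome: Genome) -> str:
    """Translate a CDS under the bacterial code (NCBI table 11).

    Alternative starts (GTG/TTG) render as M at codon 1 only.  Internal stop
    codons render as ``*`` and translation continues, so nonsense positions
    remain visible.  A trailing stop codon is dropped, matching the usual
    "length in amino acids" convention (a 861-nt CDS yields a 286-aa protein).
    """
    if feature.length % 3 != 0:
        raise ValueError(f"CDS {feature.locus_tag}: length {feature.length} not a multiple of 3")
    if feature.length < 6:
        raise ValueError(f"CDS {feature.locus_tag}: length {feature.length} < 6")
    coding = feature.coding_sequence(genome)
    protein = str(Seq(coding).translate(table=11))
    if coding[:3] in START_CODONS:
        protein = "M" + protein[1:]
    if protein.endswith("*"):
        protein = protein[:-1]
    return protein


def with_features_on_revcomp(
    features: list[CdsFeature], genome_length: int
) -> list[CdsFeature]:
    """Remap features onto the reverse complement of their genome (test aid)."""
    out = []
    for f in features:
        out.append(
            replace(
                f,
                start=genome_length - f.end + 1,
                end=genome_length - f.start + 1,
                strand="-" if f.strand == "+" else "+",
            )
        )
    return sorted(out, key=lambda f: f.start)
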