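"""Map variants onto coding sequences and classify their protein-level effects.

Classification follows the conventions of comparative-genomics mutation
tables for bacterial strain pairs:

* positions in notation are nucleotide positions on the coding strand of the
  CDS (so a frameshift at "-C 717" can exceed the protein length);
* ``Missense (G38S)``, ``Nonsense (Y30*)``, ``Frameshift (-C 717)``,
  ``Frameshift (+T 2003/2004)``, ``In frame deletion (V196-, H197-)``,
  ``In frame insertion (-102D, -103A)``;
* several SNVs falling in one codon are applied jointly before translation;
* silent variants are recorded but excluded from the "affected proteins"
  tally, as are intergenic variants.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .compare import Variant
from .genome import CdsFeature, Genome, START_CODONS

#: (ref_aa, residue position, alt_aa); "-" on either side marks indel entries
ProteinChange = tuple[str, int, str]

EFFECT_CLASSES = {
    "missense",
    "nonsense",
    "silent",
    "frameshift",
    "in_frame_insertion",
    "in_frame_deletion",
    "duplication",
    "transposon_insertion",
    "intergenic",
}


@dataclass
class EffectRecord:
    """Consequence of one variant (or one jointly-evaluated codon) on a CDS."""

    locus_tag: str | None
    effect_class: str
    cds_position: int | None = None
    protein_changes: list[ProteinChange] = field(default_factory=list)
    indel_bases: str = ""  # coding-strand bases of an indel, for notation
    flanking: tuple[str | None, str | None] | None = None  # intergenic only
    variant: Variant | None = None

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")

    @property
    def notation(self) -> str:
        return format_effect(self)


def _translate_codon(codon: str, codon_number: int) -> str:
    """Single-codon translation; codon 1 alternative starts render as M."""
    if codon_number == 1 and codon in START_CODONS:
        return "M"
    return str(Seq(codon).translate(table=11))


def format_effect(e: EffectRecord) -> str:
    """Render the table-style notation string for an effect record."""
    if e.effect_class == "intergenic":
        left, right = e.flanking or (None, None)
        return f"Intergenic (between {left or 'start'} and {right or 'end'})"
    if e.effect_class == "missense":
        body = ", ".join(f"{r}{p}{a}" for r, p, a in e.protein_changes)
        return f"Missense ({body})"
    if e.effect_class == "nonsense":
        body = ", ".join(f"{r}{p}*" for r, p, _ in e.protein_changes)
        return f"Nonsense ({body})"
    if e.effect_class == "silent":
        body = ", ".join(f"{r}{p}{a}" for r, p, a in e.protein_changes)
        return f"Silent ({body})"
    if e.effect_class == "frameshift":
        assert e.variant is not None
        if e.variant.type == "deletion":
            return f"Frameshift (-{e.indel_bases} {e.cds_position})"
        return f"Frameshift (+{e.indel_bases} {e.cds_position}/{e.cds_position + 1})"
    if e.effect_class == "in_frame_deletion":
        body = ", ".join(
            f"{r}{p}-" if a == "-" else f"{r}{p}{a}" for r, p, a in e.protein_changes
        )
        return f"In frame deletion ({body})"
    if e.effect_class == "in_frame_insertion":
        body = ", ".join(
            f"-{p}{a}" if r == "-" else f"{r}{p}{a}" for r, p, a in e.protein_changes
        )
        return f"In frame insertion ({body})"
    if e.effect_class == "duplication":
        return f"Duplication of {e.locus_tag}"
    if e.effect_class == "transposon_insertion":
        return f"Insertion of mobile element at {e.cds_position}"
    raise AssertionError(e.effect_class)


def _cds_position(cds: CdsFeature, genome_pos: int) -> int:
    """Coding-strand CDS position (1-based) of a genome coordinate."""
    if cds.strand == "+":
        return genome_pos - cds.start + 1
    return cds.end - genome_pos + 1


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def _diff_proteins(ref_aa: str, alt_aa: str, offset: int) -> list[ProteinChange]:
    """Difference list between two residue strings.

    ``offset`` is the residue number of the first character of ``ref_aa``.
    The common prefix and then the common suffix are trimmed; in runs of
    identical residues this places the change at the most C-terminal
    position (the HGVS protein convention).  What remains is emitted as
    substitutions (paired positions), deletions (ref surplus) and insertions
    (alt surplus, numbered by mutant-protein position).
    """
    i = 0
    while i < len(ref_aa) and i < len(alt_aa) and ref_aa[i] == alt_aa[i]:
        i += 1
    j = 0
    while (
        j < len(ref_aa) - i and j < len(alt_aa) - i and ref_aa[-1 - j] == alt_aa[-1 - j]
    ):
        j += 1
    core_ref = ref_aa[i : len(ref_aa) - j]
    core_alt = alt_aa[i : len(alt_aa) - j]
    changes: list[ProteinChange] = []
    n = min(len(core_ref), len(core_alt))
    for t in range(n):
        changes.append((core_ref[t], offset + i + t, core_alt[t]))
    for t in range(n, len(core_ref)):
        changes.append((core_ref[t], offset + i + t, "-"))
    for t in range(n, len(core_alt)):
        # inserted residues numbered by their position in the mutant protein
        changes.append(("-", offset + i + t, core_alt[t]))
    return changes


def _snv_effect(
    cds: CdsFeature, genome: Genome, snvs: list[Variant]
) -> EffectRecord:
    """Joint effect of all SNVs of one codon of one CDS."""
    coding = cds.coding_sequence(genome)
    pos0 = _cds_position(cds, snvs[0].ref_pos)
    codon_number = (pos0 - 1) // 3 + 1
    c0 = (codon_number - 1) * 3
    ref_codon = coding[c0 : c0 + 3]
    alt = list(ref_codon)
    for v in snvs:
        p = _cds_position(cds, v.ref_pos)
        base = v.alt_allele if cds.strand == "+" else _revcomp(v.alt_allele)
        alt[p - 1 - c0] = base
    alt_codon = "".join(alt)
    ref_aa = _translate_codon(ref_codon, codon_number)
    alt_aa = _translate_codon(alt_codon, codon_number)
    n_codons = len(coding) // 3
    if alt_aa == ref_aa:
        klass = "silent"
    elif alt_aa == "*" and codon_number < n_codons:
        klass = "nonsense"
    else:
        klass = "missense"
    return EffectRecord(
        locus_tag=cds.locus_tag,
        effect_class=klass,
        cds_position=pos0,
        protein_changes=[(ref_aa, codon_number, alt_aa)],
        variant=snvs[0],
    )


def _indel_effect(cds: CdsFeature, genome: Genome, v: Variant) -> EffectRecord:
    """Effect of an indel on a CDS (frameshift or in-frame)."""
    coding = cds.coding_sequence(genome)
    net = len(v.alt_allele) - len(v.ref_allele)
    if v.type == "deletion":
        # clip the deleted run to the CDS interval
        d_start = max(v.ref_pos, cds.start)
        d_end = min(v.ref_pos + len(v.ref_allele) - 1, cds.end)
        in_cds = genome.slice(d_start, d_end)
        if cds.strand == "+":
            cds_pos = _cds_position(cds, d_start)
            bases = in_cds
        else:
            cds_pos = _cds_position(cds, d_end)
            bases = _revcomp(in_cds)
        net = -len(bases)
        edited = coding[: cds_pos - 1] + coding[cds_pos - 1 + len(bases) :]
    else:
        # insertion after genome position v.ref_pos, strictly inside the CDS
        if cds.strand == "+":
            cds_pos = _cds_position(cds, v.ref_pos)  # base after which it sits
            bases = v.alt_allele
        else:
            cds_pos = cds.end - v.ref_pos  # coding-strand base preceding the insert
            bases = _revcomp(v.alt_allele)
        net = len(bases)
        edited = coding[:cds_pos] + bases + coding[cds_pos:]

    if net % 3 != 0:
        return EffectRecord(
            locus_tag=cds.locus_tag,
            effect_class="frameshift",
            cds_position=cds_pos,
            indel_bases=bases,
            variant=v,
        )
    klass = "in_frame_deletion" if net < 0 else "in_frame_insertion"
    ref_aa = str(Seq(coding).translate(table=11))
    alt_aa = str(Seq(edited[: len(edited) - len(edited) % 3]).translate(table=11))
    changes = _diff_proteins(ref_aa, alt_aa, 1)
    return EffectRecord(
        locus_tag=cds.locus_tag,
        effect_class=klass,
        cds_position=cds_pos,
        indel_bases=bases,
        protein_changes=changes,
        variant=v,
    )


def _overlapping_cds(
    v: Variant, cds_list: list[CdsFeature]
) -> list[CdsFeature]:
    lo, hi = v.ref_span
    if v.is_insertion_like:
        # an insertion between ref_pos and ref_pos+1 hits a CDS only when the
        # junction is strictly inside it
        return [c for c in cds_list if c.start <= v.ref_pos < c.end]
    return [c for c in cds_list if c.start <= hi and lo <= c.end]


def _flanking_tags(
    v: Variant, cds_list: list[CdsFeature]
) -> tuple[str | None, str | None]:
    starts = [c.start for c in cds_list]
    i = bisect_right(starts, v.ref_pos)
    left = cds_list[i - 1].locus_tag if i > 0 else None
    right = cds_list[i].locus_tag if i < len(cds_list) else None
    return left, right


def annotate_variant(
    v: Variant,
    cds_list: list[CdsFeature],
    ref_genome: Genome,
    qry_genome: Genome | None = None,
) -> list[EffectRecord]:
    """Effect records of one variant: one per overlapped CDS.

    A variant overlapping no CDS yields a single intergenic record naming the
    flanking locus tags.  Duplications are attributed to the CDS their copied
    interval overlaps (the duplicated gene) when they fall between genes.
    """
    if v.ref_pos > ref_genome.length or v.ref_span[1] > ref_genome.length:
        raise ValueError(f"variant at {v.ref_pos} beyond genome length {ref_genome.length}")
    hits = _overlapping_cds(v, cds_list)
    records: list[EffectRecord] = []
    if v.type == "SNV":
        for cds in hits:
            records.append(_snv_effect(cds, ref_genome, [v]))
    elif v.type in {"insertion", "deletion"}:
        for cds in hits:
            records.append(_indel_effect(cds, ref_genome, v))
    elif v.type == "duplication":
        targets = hits
        if not targets and v.source_match is not None:
            s, e = v.source_match
            targets = [c for c in cds_list if c.start <= e and s <= c.end]
        for cds in targets:
            records.append(
                EffectRecord(
                    locus_tag=cds.locus_tag,
                    effect_class="duplication",
                    cds_position=None,
                    variant=v,
                )
            )
    elif v.type == "transposition":
        for cds in hits:
            records.append(
                EffectRecord(
                    locus_tag=cds.locus_tag,
                    effect_class="transposon_insertion",
                    cds_position=_cds_position(cds, v.ref_pos),
                    variant=v,
                )
            )
    if not records:
        records.append(
            EffectRecord(
                locus_tag=None,
                effect_class="intergenic",
                flanking=_flanking_tags(v, cds_list),
                variant=v,
            )
        )
    return records


def annotate_variants(
    variants: list[Variant],
    cds_list: list[CdsFeature],
    ref_genome: Genome,
    qry_genome: Genome | None = None,
) -> list[EffectRecord]:
    """Annotate a call set; SNVs sharing a codon are evaluated jointly."""
    records: list[EffectRecord] = []
    codon_groups: dict[tuple[str, int], list[Variant]] = defaultdict(list)
    snv_cds: dict[tuple[str, int], CdsFeature] = {}
    for v in variants:
        if v.type == "SNV":
            hits = _overlapping_cds(v, cds_list)
            if hits:
                for cds in hits:
                    codon = (_cds_position(cds, v.ref_pos) - 1) // 3
                    codon_groups[(cds.locus_tag, codon)].append(v)
                    snv_cds[(cds.locus_tag, codon)] = cds
            else:
                records.extend(annotate_variant(v, cds_list, ref_genome, qry_genome))
        else:
            records.extend(annotate_variant(v, cds_list, ref_genome, qry_genome))
    for key in sorted(codon_groups, key=lambda k: (k[0], k[1])):
        records.append(_snv_effect(snv_cds[key], ref_genome, codon_groups[key]))
    records.sort(key=lambda r: (r.variant.ref_pos if r.variant else 0))
    return records


def classify_region(position: int, core_intervals: list[tuple[int, int]]) -> str:
    """core/noncore membership of a genome position (half-open intervals)."""
    if position < 1:
        raise ValueError(f"position {position} out of range")
    starts = [s for s, _ in core_intervals]
    i = bisect_right(starts, position)
    if i > 0:
        s, e = core_intervals[i - 1]
        if s <= position < e:
            return "core"
    return "noncore"


def summarize_counts(
    effects: list[EffectRecord], variants: list[Variant]
) -> dict[str, int]:
    """Headline inventory: per-class site counts and distinct affected proteins.

    "Affected proteins" counts distinct locus tags over non-silent,
    non-intergenic effect records, the accounting under which disjoint class
    counts (e.g. 144 SNV CDSs + 71 frameshift + 4 duplicated + 7 transposon
    + 1 excision) sum to the total.
    """
    by_type = defaultdict(int)
    for v in variants:
        by_type[v.type] += 1
    tags = lambda classes: {
        e.locus_tag for e in effects if e.effect_class in classes and e.locus_tag
    }
    affected = {
        e.locus_tag
        for e in effects
        if e.locus_tag and e.effect_class not in {"silent", "intergenic"}
    }
    return {
        "deletion_sites": by_type["deletion"],
        "insertion_sites": by_type["insertion"],
        "transposition_sites": by_type["transposition"],
        "duplication_sites": by_type["duplication"],
        "snv_sites": by_type["SNV"],
        "snv_cds": len(tags({"missense", "nonsense", "silent"})),
        "missense": sum(e.effect_class == "missense" for e in effects),
        "nonsense": sum(e.effect_class == "nonsense" for e in effects),
        "frameshift_cds": len(tags({"frameshift"})),
        "duplicated_cds": len(tags({"duplication"})),
        "transposon_cds": len(tags({"transposon_insertion"})),
        "affected_proteins": len(affected),
    }


def effects_table(effects: list[EffectRecord]) -> "pd.DataFrame":
    """Mutation table in the style of strain-comparison papers."""
    import pandas as pd

    rows = []
    for e in effects:
        rows.append(
            {
                "locus_tag": e.locus_tag or "",
                "effect_class": e.effect_class,
                "variation": format_effect(e),
                "ref_pos": e.variant.ref_pos if e.variant else None,
            }
        )
    return pd.DataFrame(rows)
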