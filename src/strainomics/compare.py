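"""Anchor-based comparison of two collinear bacterial chromosomes.

The engine follows the classical MUM/anchor strategy: find maximal exact
matches seeded by k-mers unique in both genomes, chain the heaviest strictly
collinear subset, then globally align every inter-anchor gap pair (unit
match/mismatch/gap costs) and read variants off the alignment.  Large
insertions whose sequence occurs elsewhere in the reference are re-classified
as transpositions (mobile-element copies) or tandem duplications.

All coordinates are 1-based inclusive; insertions are anchored to the
reference base *after which* the new material sits, and indels are
left-aligned (shifted to the lowest reference position consistent with the
alignment, the VCF normalisation convention) so output is deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import pandas as pd

from .genome import Genome

#: minimum inserted length considered for transposition/duplication status
MOBILE_MIN_LEN = 100
#: minimum identity between an insertion and its putative reference source
MOBILE_MIN_IDENTITY = 0.95
#: largest inter-anchor gap the global aligner will accept
MAX_GAP = 50_000

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


@dataclass(frozen=True)
class Anchor:
    """A maximal exact match unique in both genomes (1-based starts)."""

    ref_start: int
    qry_start: int
    length: int

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length - 1

    @property
    def qry_end(self) -> int:
        return self.qry_start + self.length - 1


@dataclass(frozen=True)
class Variant:
    """One difference between reference and query.

    ``ref_pos`` is the first reference base of the event; for insertions it
    is the reference base after which material is inserted.  ``source_match``
    (transposition/duplication only) is the 1-based inclusive reference
    interval the inserted copy derives from.
    """

    type: str  # SNV | insertion | deletion | transposition | duplication
    ref_pos: int
    ref_allele: str
    alt_allele: str
    source_match: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.type == "SNV":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("SNV alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise ValueError("SNV alleles must differ")
        elif self.type == "deletion":
            if self.alt_allele or not self.ref_allele:
                raise ValueError("deletion needs ref_allele only")
        elif self.type in {"insertion", "transposition", "duplication"}:
            if self.ref_allele or not self.alt_allele:
                raise ValueError(f"{self.type} needs alt_allele only")
            if self.type != "insertion" and self.source_match is None:
                raise ValueError(f"{self.type} requires source_match")
        else:
            raise ValueError(f"unknown variant type {self.type!r}")

    @property
    def length(self) -> int:
        return max(len(self.ref_allele), len(self.alt_allele))

    @property
    def ref_span(self) -> tuple[int, int]:
        """Reference interval covered (insertion-like events span nothing)."""
        if self.ref_allele:
            return (self.ref_pos, self.ref_pos + len(self.ref_allele) - 1)
        return (self.ref_pos, self.ref_pos)

    @property
    def is_insertion_like(self) -> bool:
        return self.type in {"insertion", "transposition", "duplication"}


def _seed_index(seq: str, k: int) -> dict[str, int]:
    """Map each k-mer to its unique 0-based position, or -1 if repeated."""
    idx: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in idx:
            idx[km] = -1
        else:
            idx[km] = i
    return idx


def find_anchors(ref: Genome, qry: Genome, k: int = 20) -> list[Anchor]:
    """All maximal exact matches seeded by a k-mer unique in both genomes.

    k below 12 is refused: on GC-rich actinomycete genomes shorter seeds
    collide too often to be informative.
    """
    if k < 12:
        raise ValueError(f"k={k} too small (minimum 12)")
    return _find_anchors_str(ref.sequence, qry.sequence, k)


def _find_anchors_str(r: str, q: str, k: int) -> list[Anchor]:
    ridx = _seed_index(r, k)
    qidx = _seed_index(q, k)
    anchors: list[Anchor] = []
    # ref-end (0-based, exclusive) of the last maximal match per diagonal,
    # used to skip seeds interior to an already-extended match
    diag_end: dict[int, int] = {}
    for i in range(len(r) - k + 1):
        km = r[i : i + k]
        if ridx[km] != i:  # repeated in ref (or seen at earlier position)
            continue
        j = qidx.get(km, -1)
        if j < 0:
            continue
        d = i - j
        if diag_end.get(d, -1) >= i + k:
            continue
        a, b = i, j
        while a > 0 and b > 0 and r[a - 1] == q[b - 1]:
            a -= 1
            b -= 1
        e, f = i + k, j + k
        while e < len(r) and f < len(q) and r[e] == q[f]:
            e += 1
            f += 1
        diag_end[d] = e
        anchors.append(Anchor(ref_start=a + 1, qry_start=b + 1, length=e - a))
    anchors.sort(key=lambda x: (x.ref_start, x.qry_start))
    return anchors


def chain_anchors(anchors: list[Anchor]) -> tuple[list[Anchor], list[Anchor]]:
    """Heaviest strictly increasing, non-overlapping chain of anchors.

    Weight is total anchored bases (longest-increasing-subsequence dynamic
    programme).  Ties are broken toward the lexicographically smallest
    sequence of ref_start values so results are deterministic.  Anchors left
    out of the chain are returned separately; a displaced copy of a mobile
    element shows up there.
    """
    if not anchors:
        return [], []
    order = sorted(anchors, key=lambda a: (a.ref_start, a.qry_start))
    n = len(order)
    score = [a.length for a in order]
    pred: list[int | None] = [None] * n

    def chain_key(i: int | None) -> tuple[int, ...]:
        keys: list[int] = []
        while i is not None:
            keys.append(order[i].ref_start)
            i = pred[i]
        return tuple(reversed(keys))

    for i in range(n):
        ai = order[i]
        for j in range(i):
            aj = order[j]
            if ai.ref_start > aj.ref_end and ai.qry_start > aj.qry_end:
                cand = score[j] + ai.length
                if cand > score[i] or (
                    cand == score[i] and chain_key(j) + (ai.ref_start,) < chain_key(i)
                ):
                    score[i] = cand
                    pred[i] = j
    best = max(range(n), key=lambda i: (score[i], tuple(-v for v in chain_key(i))))
    chain: list[Anchor] = []
    cur: int | None = best
    chosen: set[int] = set()
    while cur is not None:
        chain.append(order[cur])
        chosen.add(cur)
        cur = pred[cur]
    chain.reverse()
    off_chain = [order[i] for i in range(n) if i not in chosen]
    return chain, off_chain


def _left_align_deletion(ref: str, pos: int, deleted: str) -> tuple[int, str]:
    """Shift a deletion of *deleted* at 1-based ref position *pos* leftward."""
    L = len(deleted)
    while pos > 1 and ref[pos - 2] == deleted[-1]:
        deleted = ref[pos - 2] + deleted[:-1]
        pos -= 1
    return pos, deleted


def _left_align_insertion(ref: str, after: int, inserted: str) -> tuple[int, str]:
    """Shift an insertion (after 1-based position *after*) leftward."""
    while after > 0 and ref[after - 1] == inserted[-1]:
        inserted = ref[after - 1] + inserted[:-1]
        after -= 1
    return after, inserted


def _align_gap(
    ref_seg: str, qry_seg: str, ref_offset: int
) -> list[tuple[str, int, str, str]]:
    """Edit operations for one gap pair as (kind, ref_pos, ref, alt) tuples.

    ``ref_offset`` is the 1-based reference position of the first base of
    ``ref_seg``; insertion positions refer to the base after which the
    material sits (0 allowed when inserting before position 1).
    """
    if not ref_seg and not qry_seg:
        return []
    if not qry_seg:
        return [("deletion", ref_offset, ref_seg, "")]
    if not ref_seg:
        return [("insertion", ref_offset - 1, "", qry_seg)]
    # Fast path for copy-number gaps: when one segment contains the other
    # verbatim (tandem duplication or mobile-element copy next to flanking
    # sequence), a unit-cost global alignment has many co-optimal paths that
    # fragment the insert; emit the contiguous surplus instead.
    if len(qry_seg) > len(ref_seg) and ref_seg in qry_seg:
        m = qry_seg.index(ref_seg)
        ops = []
        if m:
            ops.append(("insertion", ref_offset - 1, "", qry_seg[:m]))
        tail = qry_seg[m + len(ref_seg) :]
        if tail:
            ops.append(("insertion", ref_offset + len(ref_seg) - 1, "", tail))
        return ops
    if len(ref_seg) > len(qry_seg) and qry_seg in ref_seg:
        m = ref_seg.index(qry_seg)
        ops = []
        if m:
            ops.append(("deletion", ref_offset, ref_seg[:m], ""))
        tail = ref_seg[m + len(qry_seg) :]
        if tail:
            ops.append(("deletion", ref_offset + m + len(qry_seg), tail, ""))
        return ops
    res = edlib.align(qry_seg, ref_seg, mode="NW", task="path")
    ops: list[tuple[str, int, str, str]] = []
    ri = 0  # 0-based offset into ref_seg
    qi = 0
    for count, kind in _CIGAR_RE.findall(res["cigar"]):
        c = int(count)
        if kind == "=":
            ri += c
            qi += c
        elif kind == "X":
            for t in range(c):
                ops.append(
                    ("SNV", ref_offset + ri + t, ref_seg[ri + t], qry_seg[qi + t])
                )
            ri += c
            qi += c
        elif kind == "D":  # present in ref (target), absent from qry
            ops.append(("deletion", ref_offset + ri, ref_seg[ri : ri + c], ""))
            ri += c
        elif kind == "I":  # present in qry, absent from ref
            ops.append(("insertion", ref_offset + ri - 1, "", qry_seg[qi : qi + c]))
            qi += c
    return ops


def _resolve_gap(
    ref_seg: str, qry_seg: str, ref_offset: int, k: int, depth: int = 8
) -> list[tuple[str, int, str, str]]:
    """Recursively re-anchor a gap pair before falling back to alignment.

    A gap between chain anchors can span several events when a mobile copy
    destroys k-mer uniqueness genome-wide; within the gap pair those k-mers
    are unique again, so local anchoring splits the gap into single-event
    sub-gaps and keeps large inserts contiguous (the classic recursive
    anchor-refinement strategy).
    """
    if depth <= 0 or (len(ref_seg) < 3 * k or len(qry_seg) < 3 * k):
        return _align_gap(ref_seg, qry_seg, ref_offset)
    sub = _find_anchors_str(ref_seg, qry_seg, k)
    chain, _ = chain_anchors(sub)
    # require the local chain to make progress, else fall back
    if not chain or sum(a.length for a in chain) < k:
        return _align_gap(ref_seg, qry_seg, ref_offset)
    ops: list[tuple[str, int, str, str]] = []
    first = chain[0]
    ops += _resolve_gap(
        ref_seg[: first.ref_start - 1], qry_seg[: first.qry_start - 1], ref_offset, k, depth - 1
    )
    for a, b in zip(chain, chain[1:]):
        ops += _resolve_gap(
            ref_seg[a.ref_end : b.ref_start - 1],
            qry_seg[a.qry_end : b.qry_start - 1],
            ref_offset + a.ref_end,
            k,
            depth - 1,
        )
    last = chain[-1]
    ops += _resolve_gap(
        ref_seg[last.ref_end :], qry_seg[last.qry_end :], ref_offset + last.ref_end, k, depth - 1
    )
    return ops


def _classify_insertion(
    alt: str, ref_pos: int, ref: Genome
) -> tuple[str, tuple[int, int] | None]:
    """Decide insertion vs transposition vs duplication for a large insert."""
    if len(alt) < MOBILE_MIN_LEN:
        return "insertion", None
    res = edlib.align(alt, ref.sequence, mode="HW", task="locations")
    if res["editDistance"] < 0:
        return "insertion", None
    identity = 1.0 - res["editDistance"] / len(alt)
    if identity < MOBILE_MIN_IDENTITY:
        return "insertion", None
    start0, end0 = res["locations"][0]
    src = (start0 + 1, end0 + 1)
    # a copy inserted adjacent to (or inside) its source is a tandem duplication
    if src[0] - 2 <= ref_pos <= src[1] + 2:
        return "duplication", src
    return "transposition", src


def call_variants(
    chain: list[Anchor], ref: Genome, qry: Genome, k: int = 20
) -> list[Variant]:
    """Variants implied by the collinear chain over two genomes.

    Every inter-anchor gap pair (including the flanks before the first and
    after the last anchor) is globally aligned with unit costs; runs of
    mismatches become SNVs and runs of gaps become left-aligned indels.
    An insertion of at least 100 bp matching the reference elsewhere at
    >= 95% identity is promoted to a transposition, or to a duplication when
    the copy sits adjacent to its source (a tandem repeat).
    """
    if not chain:
        raise ValueError("empty anchor chain: genomes are not collinear enough")
    covered = sum(a.length for a in chain)
    if covered < 0.5 * ref.length or covered < 0.5 * qry.length:
        raise ValueError(
            f"anchor chain covers {covered} bp, under 50% of one genome: "
            "genomes are not collinear enough"
        )
    gaps: list[tuple[str, str, int]] = []
    first = chain[0]
    gaps.append((ref.sequence[: first.ref_start - 1], qry.sequence[: first.qry_start - 1], 1))
    for a, b in zip(chain, chain[1:]):
        gaps.append(
            (
                ref.sequence[a.ref_end : b.ref_start - 1],
                qry.sequence[a.qry_end : b.qry_start - 1],
                a.ref_end + 1,
            )
        )
    last = chain[-1]
    gaps.append((ref.sequence[last.ref_end :], qry.sequence[last.qry_end :], last.ref_end + 1))

    variants: list[Variant] = []
    for ref_seg, qry_seg, offset in gaps:
        if len(ref_seg) > MAX_GAP or len(qry_seg) > MAX_GAP:
            raise ValueError(
                f"gap pair at ref position {offset} exceeds {MAX_GAP} bp alignment band"
            )
        for kind, pos, ra, aa in _resolve_gap(ref_seg, qry_seg, offset, k):
            if kind == "SNV":
                variants.append(Variant("SNV", pos, ra, aa))
            elif kind == "deletion":
                p, alleles = _left_align_deletion(ref.sequence, pos, ra)
                variants.append(Variant("deletion", p, alleles, ""))
            else:
                p, ins = _left_align_insertion(ref.sequence, pos, aa)
                vtype, src = _classify_insertion(ins, p, ref)
                variants.append(Variant(vtype, p, "", ins, source_match=src))
    variants.sort(key=lambda v: (v.ref_pos, v.type))
    return variants


def compare_genomes(ref: Genome, qry: Genome, k: int = 20) -> list[Variant]:
    """Convenience wrapper: anchors -> chain -> variant calls."""
    anchors = find_anchors(ref, qry, k=k)
    chain, _ = chain_anchors(anchors)
    return call_variants(chain, ref, qry, k=k)


def dotplot_data(anchors: list[Anchor]) -> pd.DataFrame:
    """Anchor table in dot-plot form (ref_start, qry_start, length)."""
    return pd.DataFrame(
        [(a.ref_start, a.qry_start, a.length) for a in anchors],
        columns=["ref_start", "qry_start", "length"],
    )


PROBE_LENGTH = 25


def verify_probes(probes: list[str], genome: Genome) -> pd.DataFrame:
    """Check each 25-mer probe for a perfect full-length match in the genome.

    Both strands are searched; on circular genomes the origin junction is
    included.  Returns one row per probe with a boolean ``perfect_match``;
    the summary fraction is ``df["perfect_match"].mean()``.
    """
    from Bio.Seq import Seq

    target = genome.sequence
    if genome.circular and genome.length >= PROBE_LENGTH:
        target = genome.sequence + genome.sequence[: PROBE_LENGTH - 1]
    rows = []
    for probe in probes:
        probe = probe.upper()
        if len(probe) != PROBE_LENGTH:
            raise ValueError(f"probe length {len(probe)} != {PROBE_LENGTH}")
        rc = str(Seq(probe).reverse_complement())
        hit = target.find(probe) >= 0 or target.find(rc) >= 0
        rows.append((probe, hit))
    return pd.DataFrame(rows, columns=["probe", "perfect_match"])


def write_variants_vcf(variants: list[Variant], ref: Genome, path) -> None:
    """Write calls as VCF 4.2 with the anchored-base indel convention."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref.id},length={ref.length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural class">\n')
        fh.write('##INFO=<ID=SOURCE,Number=1,Type=String,Description="Copy source interval">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = "."
            if v.type == "SNV":
                pos, refa, alta = v.ref_pos, v.ref_allele, v.alt_allele
            elif v.type == "deletion":
                pos = v.ref_pos - 1
                anchor = ref.sequence[pos - 1] if pos >= 1 else "N"
                refa, alta = anchor + v.ref_allele, anchor
            else:  # insertion-like: anchored at the base after which it sits
                pos = max(v.ref_pos, 1)
                anchor = ref.sequence[pos - 1]
                refa, alta = anchor, anchor + v.alt_allele
                if v.type == "duplication":
                    info = "SVTYPE=DUP"
                elif v.type == "transposition":
                    info = "SVTYPE=INS"
                if v.source_match is not None:
                    info += f";SOURCE={v.source_match[0]}-{v.source_match[1]}"
            fh.write(f"{ref.id}\t{pos}\t.\t{refa}\t{alta}\t.\tPASS\t{info}\n")
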