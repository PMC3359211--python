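"""Synthetic strain pairs and time-course expression matrices with known truth.

The genomic generator emulates a pair of nearly identical collinear circular
actinomycete chromosomes (GC around 71%): a random CDS-dense reference plus a
mutated copy carrying planted SNVs, short and long indels, mobile-element
insertions (copies of existing reference segments, transposase-style) and
tandem CDS duplications.  Events are planted with a minimum spacing so each
one is individually identifiable, which makes recovery tests exact in a way
real neighbouring mutations need not be.

The expression generator emulates a two-phase-structured fermentation time
course on the log scale (post-normalisation): per-gene baselines, a
phase-shaped bump for differentially expressed genes, chromosomally
contiguous co-modulated blocks, and i.i.d. Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionStudy
from .genome import CdsFeature, Genome, STOP_CODONS

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class MutationPlan:
    """Counts and geometry of events to plant into a reference genome."""

    n_snv: int = 0
    n_small_indel: int = 0
    n_large_indel: int = 0
    n_mobile_insertion: int = 0
    n_duplication: int = 0
    small_indel_max: int = 4
    large_indel_range: tuple[int, int] = (100, 1200)
    mobile_length_range: tuple[int, int] = (300, 1000)
    min_spacing: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_snv", "n_small_indel", "n_large_indel", "n_mobile_insertion", "n_duplication"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_spacing < 40:
            raise ValueError("min_spacing must be >= 40 (twice the anchor seed length)")

    @property
    def total(self) -> int:
        return (
            self.n_snv
            + self.n_small_indel
            + self.n_large_indel
            + self.n_mobile_insertion
            + self.n_duplication
        )


@dataclass(frozen=True)
class TruthRecord:
    type: str  # SNV | insertion | deletion | mobile_insertion | duplication
    ref_position: int
    ref_allele: str
    alt_allele: str
    affected_locus_tag: str | None = None
    source: tuple[int, int] | None = None

    @property
    def length(self) -> int:
        return max(len(self.ref_allele), len(self.alt_allele))


def random_genome(
    length: int, gc: float, seed: int, cds_fraction_target: float = 0.85
) -> tuple[Genome, list[CdsFeature]]:
    """An i.i.d. random genome at the requested GC, tiled with plausible ORFs.

    CDSs of 300-1500 nt (ATG ... stop, both strands, non-overlapping) cover
    roughly 85% of the sequence.  ORF grammar is imposed by minimally editing
    the random bases (start codon, in-frame stop removal, terminal stop), so
    the empirical GC stays within 1% of target for genomes >= 100 kb.
    """
    if not (0.0 < gc < 1.0):
        raise ValueError(f"gc={gc} outside (0, 1)")
    if length < 10_000:
        raise ValueError("length must be >= 10,000")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    seq = rng.choice(_BASES, size=length, p=probs).copy()

    features: list[CdsFeature] = []
    pos = int(rng.integers(30, 150))  # leading intergenic gap (0-based)
    idx = 0
    while True:
        n_codons = int(rng.integers(100, 501))
        cds_len = 3 * n_codons
        if pos + cds_len > length - 60:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        coding = seq[pos : pos + cds_len].copy()
        if strand == "-":
            coding = _revcomp_array(coding)
        _impose_orf(coding, rng)
        block = coding if strand == "+" else _revcomp_array(coding)
        seq[pos : pos + cds_len] = block
        idx += 1
        features.append(
            CdsFeature(
                locus_tag=f"SYN_{idx:04d}",
                start=pos + 1,
                end=pos + cds_len,
                strand=strand,
                product="hypothetical protein",
            )
        )
        gap = int(rng.integers(50, 220))
        # stretch gaps if we are tiling denser than the target fraction
        if cds_fraction_target < 0.999:
            gap = max(gap, int(cds_len * (1 - cds_fraction_target) / cds_fraction_target) - 100)
        pos += cds_len + gap
    genome = Genome(id=f"synthetic_{seed}", sequence=seq.tobytes().decode())
    return genome, features


_COMP = {65: 84, 67: 71, 71: 67, 84: 65}  # A<->T, C<->G on byte values


def _revcomp_array(arr: np.ndarray) -> np.ndarray:
    b = arr.view(np.uint8)
    out = np.empty_like(b)
    out[b == 65] = 84
    out[b == 84] = 65
    out[b == 67] = 71
    out[b == 71] = 67
    return out[::-1].view("S1")


def _impose_orf(coding: np.ndarray, rng: np.random.Generator) -> None:
    """Edit a coding-strand byte array in place into start...stop form."""
    coding[0:3] = np.frombuffer(b"ATG", dtype="S1")
    n = len(coding)
    # remove in-frame internal stops by swapping their first base T -> C
    for c0 in range(3, n - 3, 3):
        codon = coding[c0 : c0 + 3].tobytes().decode()
        if codon in STOP_CODONS:
            coding[c0] = b"C"
    stop = b"TGA" if rng.random() < 0.7 else b"TAA"
    coding[n - 3 : n] = np.frombuffer(stop, dtype="S1")


def _locate_cds(position: int, features: list[CdsFeature]) -> str | None:
    for f in features:
        if f.contains(position):
            return f.locus_tag
    return None


def mutate_genome(
    genome: Genome, plan: MutationPlan, features: list[CdsFeature] | None = None
) -> tuple[Genome, list[TruthRecord]]:
    """Plant the planned events; return the mutated genome and its truth table.

    Mobile insertions copy an existing reference segment (>= 300 bp) to a new
    site so the comparison engine can recognise them; duplications
    tandem-copy a whole annotated CDS.  Events keep ``min_spacing`` bases
    apart end-to-start, so the truth is unambiguous.
    """
    features = features or []
    rng = np.random.default_rng(plan.seed)
    L = genome.length
    margin = max(plan.min_spacing, 2000)

    if plan.n_duplication > 0 and not features:
        raise ValueError("duplications require an annotated CDS list")

    # --- decide event specs (type, reference span) up front ----------------
    # span: reference bases the event occupies; duplications reserve room for
    # a CDS picked downstream of the allocated position (snap window + unit)
    DUP_SNAP = 2500
    DUP_UNIT_MAX = 1500
    events: list[dict] = []
    for _ in range(plan.n_snv):
        events.append({"type": "SNV", "span": 1})
    for _ in range(plan.n_small_indel):
        ln = int(rng.integers(1, plan.small_indel_max + 1))
        kind = "deletion" if rng.random() < 0.5 else "insertion"
        events.append({"type": kind, "len": ln, "span": ln if kind == "deletion" else 1})
    for _ in range(plan.n_large_indel):
        lo, hi = plan.large_indel_range
        ln = int(rng.integers(lo, hi + 1))
        kind = "deletion" if rng.random() < 0.5 else "insertion"
        events.append({"type": kind, "len": ln, "span": ln if kind == "deletion" else 1})
    for _ in range(plan.n_mobile_insertion):
        lo, hi = plan.mobile_length_range
        events.append({"type": "mobile_insertion", "len": int(rng.integers(lo, hi + 1)), "span": 1})
    for _ in range(plan.n_duplication):
        events.append({"type": "duplication", "span": DUP_SNAP + DUP_UNIT_MAX})

    usable = L - 2 * margin
    required = sum(e["span"] + plan.min_spacing for e in events)
    if required > usable:
        raise ValueError(
            "cannot satisfy min_spacing with these event counts on this genome; "
            "lower the counts or the spacing"
        )

    # --- allocate positions by stick-breaking: feasible by construction ----
    # shuffle event order along the chromosome, then distribute the leftover
    # slack over the n+1 inter-event gaps
    truths: list[TruthRecord] = []
    order = [events[i] for i in rng.permutation(len(events))]
    used_dups: set[str] = set()
    for _attempt in range(100):
        ok = True
        truths = []
        used_dups = set()
        slack = usable - required
        extra = rng.dirichlet(np.ones(len(order) + 1)) * slack if order else []
        cur = margin
        for ev, gap in zip(order, extra):
            pos = int(cur + gap)
            cur = pos + ev["span"] + plan.min_spacing
            if ev["type"] == "duplication":
                # tandem-duplicate a whole CDS starting within the snap window
                cands = [
                    f
                    for f in features
                    if pos <= f.start <= pos + DUP_SNAP
                    and f.end <= pos + DUP_SNAP + DUP_UNIT_MAX
                    and f.locus_tag not in used_dups
                ]
                if not cands:
                    ok = False
                    break
                cds = cands[0]
                used_dups.add(cds.locus_tag)
                unit = genome.slice(cds.start, cds.end)
                truths.append(
                    TruthRecord(
                        type="duplication",
                        ref_position=cds.end,
                        ref_allele="",
                        alt_allele=unit,
                        affected_locus_tag=cds.locus_tag,
                        source=(cds.start, cds.end),
                    )
                )
                continue
            tag = _locate_cds(pos, features)
            if ev["type"] == "SNV":
                ref_b = genome.sequence[pos - 1]
                alt_b = str(rng.choice([b for b in "ACGT" if b != ref_b]))
                truths.append(TruthRecord("SNV", pos, ref_b, alt_b, tag))
            elif ev["type"] == "deletion":
                truths.append(
                    TruthRecord("deletion", pos, genome.slice(pos, pos + ev["len"] - 1), "", tag)
                )
            elif ev["type"] == "insertion":
                ins = "".join(
                    rng.choice(list("ACGT"), size=ev["len"], p=[0.145, 0.355, 0.355, 0.145])
                )
                truths.append(TruthRecord("insertion", pos, "", ins, tag))
            else:  # mobile_insertion: copy a distant existing segment
                for _try2 in range(2000):
                    src = int(rng.integers(1, L - ev["len"]))
                    if abs(src - pos) > 5 * plan.min_spacing:
                        break
                seg = genome.slice(src, src + ev["len"] - 1)
                truths.append(
                    TruthRecord(
                        "mobile_insertion", pos, "", seg, tag, source=(src, src + ev["len"] - 1)
                    )
                )
        if ok:
            break
    else:
        raise ValueError("cannot satisfy min_spacing; lower the event counts")

    truths.sort(key=lambda t: t.ref_position)

    # --- realise the edits right-to-left ------------------------------------
    seq = genome.sequence
    for t in reversed(truths):
        p = t.ref_position
        if t.type == "SNV":
            seq = seq[: p - 1] + t.alt_allele + seq[p:]
        elif t.type == "deletion":
            seq = seq[: p - 1] + seq[p - 1 + len(t.ref_allele) :]
        else:  # insertion-like: material goes after position p
            seq = seq[:p] + t.alt_allele + seq[p:]
    mutated = Genome(id=genome.id + "_mut", sequence=seq)
    return mutated, truths


def write_truth_vcf(truths: list[TruthRecord], genome: Genome, path) -> None:
    """Truth table as VCF 4.2 against the reference genome."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genome.id},length={genome.length}>\n")
        fh.write('##INFO=<ID=TYPE,Number=1,Type=String,Description="Planted event type">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for t in truths:
            if t.type == "SNV":
                pos, ref, alt = t.ref_position, t.ref_allele, t.alt_allele
            elif t.type == "deletion":
                pos = t.ref_position - 1
                anchor = genome.sequence[pos - 1]
                ref, alt = anchor + t.ref_allele, anchor
            else:
                pos = t.ref_position
                anchor = genome.sequence[pos - 1]
                ref, alt = anchor, anchor + t.alt_allele
            fh.write(f"{genome.id}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tTYPE={t.type}\n")


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Shape of a simulated fermentation time-course expression study."""

    n_genes: int = 2000
    time_points: tuple[float, ...] = (12, 24, 32, 48, 60, 72)
    replicates: int = 2
    #: contiguous phases as (name, first_time, last_time), inclusive
    phase_boundaries: tuple[tuple[str, float, float], ...] = (
        ("a", 0, 32),
        ("b", 33, 60),
        ("c", 61, 96),
    )
    frac_deg: float = 0.0
    effect_sd: float = 2.0  # bump amplitude in units of noise_sd
    n_region_blocks: int = 0
    block_size: int = 30
    block_effect_sd: float = 2.0  # block offset in units of noise_sd
    #: (baseline phase, offset phase): block genes are shifted in the second
    block_contrast: tuple[str, str] = ("a", "b")
    noise_sd: float = 0.25  # log-units
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_deg <= 1.0):
            raise ValueError("frac_deg must be in [0, 1]")
        for t in self.time_points:
            if self.phase_of(t) is None:
                raise ValueError(f"time point {t} falls outside every phase")
        names = {p[0] for p in self.phase_boundaries}
        if not set(self.block_contrast) <= names:
            raise ValueError("block_contrast phases must name defined phases")

    def phase_of(self, t: float) -> str | None:
        for name, lo, hi in self.phase_boundaries:
            if lo <= t <= hi:
                return name
        return None


def default_gene_positions(n_genes: int, genome_length: int = 8_212_111) -> pd.DataFrame:
    """Evenly spaced gene coordinates alternating strands, as a gene sheet."""
    step = genome_length // (n_genes + 1)
    return pd.DataFrame(
        {
            "gene": [f"G{i:05d}" for i in range(n_genes)],
            "position_bp": [(i + 1) * step for i in range(n_genes)],
            "strand": ["+" if i % 2 == 0 else "-" for i in range(n_genes)],
        }
    ).set_index("gene")


def simulate_timecourse(
    spec: ExpressionSimSpec,
    gene_positions: pd.DataFrame | None = None,
    strain: str = "sim",
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Simulate a log-scale time-course matrix plus per-gene truth labels.

    Truth columns: ``label`` (null/deg/block), ``phase`` (bump phase for
    DEGs), ``block_id`` and ``block_direction`` (+1 up / -1 down) for genes
    in chromosomally contiguous co-modulated blocks.  Block genes get a
    constant offset in the second phase of ``spec.block_contrast`` relative
    to the first, the between-class contrast a positional (LAP-style)
    analysis tests.
    """
    if spec.replicates < 2:
        raise ValueError(
            "replicates must be >= 2: each time-point replicate enters as an "
            "independent sample"
        )
    if gene_positions is None:
        gene_positions = default_gene_positions(spec.n_genes)
    if len(gene_positions) != spec.n_genes:
        raise ValueError("gene_positions must have n_genes rows")
    rng = np.random.default_rng(spec.seed)
    genes = gene_positions.index.to_numpy()
    times = np.repeat(np.asarray(spec.time_points, dtype=float), spec.replicates)
    reps = np.tile(np.arange(1, spec.replicates + 1), len(spec.time_points))
    sample_ids = [f"{strain}_t{int(t)}_r{r}" for t, r in zip(times, reps)]
    n_s = len(sample_ids)
    phase_names = [p[0] for p in spec.phase_boundaries]
    sample_phase = np.array([spec.phase_of(t) for t in times])

    truth = pd.DataFrame(
        {
            "label": "null",
            "phase": "",
            "block_id": -1,
            "block_direction": 0,
        },
        index=pd.Index(genes, name="gene"),
    )

    # contiguous blocks in chromosome order within each strand
    order = gene_positions.sort_values(["strand", "position_bp"]).index.to_numpy()
    free = np.ones(spec.n_genes, dtype=bool)
    block_offset = np.zeros(spec.n_genes)
    pos_of = {g: i for i, g in enumerate(genes)}
    starts_used: list[tuple[int, int]] = []
    for b in range(spec.n_region_blocks):
        for _try in range(5000):
            s = int(rng.integers(0, spec.n_genes - spec.block_size))
            strand_run = gene_positions.loc[order[s : s + spec.block_size], "strand"]
            if strand_run.nunique() != 1:
                continue
            if any(s < e0 + spec.block_size and s0 < s + spec.block_size for s0, e0 in starts_used):
                continue
            starts_used.append((s, s + spec.block_size))
            direction = 1 if rng.random() < 0.5 else -1
            for g in order[s : s + spec.block_size]:
                i = pos_of[g]
                free[i] = False
                block_offset[i] = direction * spec.block_effect_sd * spec.noise_sd
                truth.loc[g, ["label", "block_id", "block_direction"]] = ["block", b, direction]
            break
        else:
            raise ValueError("could not place non-overlapping region blocks")

    n_deg = int(round(spec.frac_deg * spec.n_genes))
    candidates = np.flatnonzero(free)
    if n_deg > len(candidates):
        raise ValueError("frac_deg too high given the block allocation")
    deg_idx = rng.choice(candidates, size=n_deg, replace=False)
    deg_phase = rng.choice(phase_names, size=n_deg)
    for i, ph in zip(deg_idx, deg_phase):
        truth.iloc[i, truth.columns.get_loc("label")] = "deg"
        truth.iloc[i, truth.columns.get_loc("phase")] = ph

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
    mat = np.tile(baseline[:, None], (1, n_s))
    bump = spec.effect_sd * spec.noise_sd
    for i, ph in zip(deg_idx, deg_phase):
        mat[i, sample_phase == ph] += bump
    # block offset applies in the second phase of the designated contrast
    mat[:, sample_phase == spec.block_contrast[1]] += block_offset[:, None]
    mat += rng.normal(0.0, spec.noise_sd, size=mat.shape)

    values = pd.DataFrame(mat, index=truth.index, columns=sample_ids)
    samples = pd.DataFrame(
        {"strain": strain, "time_h": times, "replicate": reps}, index=pd.Index(sample_ids, name="sample")
    )
    study = ExpressionStudy(values=values, samples=samples, genes=gene_positions.copy())
    return study, truth
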