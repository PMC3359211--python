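import itertools

import numpy as np
import pytest

from strainomics import (
    Anchor,
    Genome,
    MutationPlan,
    chain_anchors,
    call_variants,
    compare_genomes,
    find_anchors,
    mutate_genome,
)
from strainomics.compare import dotplot_data, verify_probes, write_variants_vcf

from conftest import revcomp


# ---------------------------------------------------------------- oracles --
def brute_force_mums(r: str, q: str, k: int) -> set[tuple[int, int, int]]:
    """All maximal exact matches whose seed k-mer is unique in both strings."""
    def kmers(s):
        out = {}
        for i in range(len(s) - k + 1):
            out.setdefault(s[i : i + k], []).append(i)
        return out

    rk, qk = kmers(r), kmers(q)
    found = set()
    for km, rpos in rk.items():
        if len(rpos) != 1 or len(qk.get(km, [])) != 1:
            continue
        i, j = rpos[0], qk[km][0]
        while i > 0 and j > 0 and r[i - 1] == q[j - 1]:
            i, j = i - 1, j - 1
        e, f = i, j
        while e < len(r) and f < len(q) and r[e] == q[f]:
            e, f = e + 1, f + 1
        found.add((i + 1, j + 1, e - i))
    return found


def nw_score(a: str, b: str) -> int:
    """Unit-cost edit distance by plain dynamic programming."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def best_chain_weight(anchors):
    """Exhaustive search over all collinear anchor subsets (n <= 10)."""
    best = 0
    for r in range(1, len(anchors) + 1):
        for sub in itertools.combinations(sorted(anchors, key=lambda a: a.ref_start), r):
            ok = all(
                b.ref_start > a.ref_end and b.qry_start > a.qry_end
                for a, b in zip(sub, sub[1:])
            )
            if ok:
                best = max(best, sum(a.length for a in sub))
    return best


def apply_truth(ref_seq: str, truths) -> str:
    """Independent reconstruction of the mutated sequence from the truth table."""
    seq = ref_seq
    for t in sorted(truths, key=lambda t: -t.ref_position):
        p = t.ref_position
        if t.type == "SNV":
            seq = seq[: p - 1] + t.alt_allele + seq[p:]
        elif t.type == "deletion":
            seq = seq[: p - 1] + seq[p - 1 + len(t.ref_allele) :]
        else:
            seq = seq[:p] + t.alt_allele + seq[p:]
    return seq


# ---------------------------------------------------------------- anchors --
class TestAnchors:
    def test_identical_sequences_single_anchor(self):
        rng = np.random.default_rng(0)
        s = "".join(rng.choice(list("ACGT"), size=100))
        g = Genome("a", s)
        anchors = find_anchors(g, Genome("b", s))
        assert anchors == [Anchor(1, 1, 100)]

    def test_single_snv_splits_anchor(self):
        rng = np.random.default_rng(1)
        s = list("".join(rng.choice(list("ACGT"), size=100)))
        q = s.copy()
        q[49] = "A" if s[49] != "A" else "C"
        anchors = find_anchors(Genome("a", "".join(s)), Genome("b", "".join(q)))
        assert {(a.ref_start, a.qry_start, a.length) for a in anchors} == {
            (1, 1, 49),
            (51, 51, 50),
        }

    def test_no_shared_kmer_gives_empty(self):
        a = Genome("a", "A" * 50)
        b = Genome("b", "C" * 50)
        assert find_anchors(a, b) == []

    def test_small_k_rejected(self):
        g = Genome("g", "ACGT" * 10)
        with pytest.raises(ValueError, match="too small"):
            find_anchors(g, g, k=11)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        r = "".join(rng.choice(list("ACGT"), size=300))
        # query: r with a deletion and an SNV
        q = r[:90] + r[95:200] + ("A" if r[200] != "A" else "C") + r[201:]
        got = {
            (a.ref_start, a.qry_start, a.length)
            for a in find_anchors(Genome("r", r), Genome("q", q), k=12)
        }
        assert got == brute_force_mums(r, q, 12)


class TestChaining:
    def test_collinear_input_unchanged(self):
        anchors = [Anchor(1, 1, 10), Anchor(20, 20, 10), Anchor(40, 45, 10)]
        chain, off = chain_anchors(anchors)
        assert chain == anchors and off == []

    def test_displaced_anchor_reported_off_chain(self):
        anchors = [Anchor(1, 1, 10), Anchor(20, 500, 12), Anchor(40, 45, 30)]
        chain, off = chain_anchors(anchors)
        assert off == [Anchor(20, 500, 12)]
        assert chain == [Anchor(1, 1, 10), Anchor(40, 45, 30)]

    def test_empty_input(self):
        assert chain_anchors([]) == ([], [])

    @pytest.mark.parametrize("seed", range(10))
    def test_weight_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        anchors = [
            Anchor(int(r), int(q), int(l))
            for r, q, l in zip(
                rng.integers(1, 500, 8), rng.integers(1, 500, 8), rng.integers(5, 30, 8)
            )
        ]
        chain, _ = chain_anchors(anchors)
        assert sum(a.length for a in chain) == best_chain_weight(anchors)


# --------------------------------------------------------------- variants --
class TestCallVariants:
    def _pair(self, edit):
        rng = np.random.default_rng(3)
        r = "".join(rng.choice(list("ACGT"), size=400))
        return Genome("r", r), Genome("q", edit(r))

    def test_identity_yields_no_variants(self, small_genome_pair):
        genome, _ = small_genome_pair
        assert compare_genomes(genome, genome) == []

    def test_single_deletion_called(self):
        ref, qry = self._pair(lambda r: r[:200] + r[201:])
        (v,) = compare_genomes(ref, qry)
        assert v.type == "deletion" and len(v.ref_allele) == 1
        # left-alignment: position is the lowest compatible with the alignment
        p = v.ref_pos
        assert p < 2 or ref.sequence[p - 2] != ref.sequence[p - 1 + len(v.ref_allele) - 1]

    def test_single_snv_called(self):
        def edit(r):
            alt = "A" if r[200] != "A" else "C"
            return r[:200] + alt + r[201:]

        ref, qry = self._pair(edit)
        (v,) = compare_genomes(ref, qry)
        assert v.type == "SNV" and v.ref_pos == 201

    def test_gap_alignment_matches_nw_oracle_score(self):
        # implied edit count of the call set equals the DP edit distance
        rng = np.random.default_rng(5)
        for _ in range(20):
            r = "".join(rng.choice(list("ACGT"), size=200))
            q = list(r)
            i = int(rng.integers(60, 140))
            q[i] = "A" if q[i] != "A" else "G"
            j = int(rng.integers(20, 50))
            q = q[:j] + q[j + int(rng.integers(1, 4)) :]
            q = "".join(q)
            variants = compare_genomes(Genome("r", r), Genome("q", q), k=12)
            implied = sum(
                len(v.ref_allele) + len(v.alt_allele) if v.type != "SNV" else 1
                for v in variants
            )
            assert implied == nw_score(r, q)

    def test_copied_insertion_becomes_transposition(self):
        rng = np.random.default_rng(8)
        r = "".join(rng.choice(list("ACGT"), size=2000))
        seg = r[100:450]  # 350-bp mobile copy
        q = r[:1500] + seg + r[1500:]
        variants = compare_genomes(Genome("r", r), Genome("q", q))
        (v,) = [v for v in variants if v.type == "transposition"]
        assert v.alt_allele == seg or len(v.alt_allele) == len(seg)
        assert v.source_match is not None

    def test_novel_large_insertion_stays_insertion(self):
        rng = np.random.default_rng(9)
        r = "".join(rng.choice(list("ACGT"), size=2000))
        rng2 = np.random.default_rng(10)
        seg = "".join(rng2.choice(list("ACGT"), size=300))
        q = r[:1500] + seg + r[1500:]
        variants = compare_genomes(Genome("r", r), Genome("q", q))
        types = {v.type for v in variants}
        assert "insertion" in types and "transposition" not in types

    def test_length_conservation(self, small_genome_pair):
        genome, cds = small_genome_pair
        plan = MutationPlan(
            n_snv=20, n_small_indel=10, n_large_indel=3, n_mobile_insertion=1,
            n_duplication=1, min_spacing=1000, seed=42,
        )
        qry, _ = mutate_genome(genome, plan, cds)
        variants = compare_genomes(genome, qry)
        delta = sum(len(v.alt_allele) for v in variants if v.is_insertion_like) - sum(
            len(v.ref_allele) for v in variants if v.type == "deletion"
        )
        assert genome.length + delta == qry.length

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError, match="not collinear"):
            call_variants([], Genome("r", "ACGT" * 100), Genome("q", "ACGT" * 100))


def test_dotplot_table_shapes():
    assert dotplot_data([]).empty
    df = dotplot_data([Anchor(1, 1, 100)])
    assert df.iloc[0].tolist() == [1, 1, 100]


class TestProbes:
    def test_probes_sampled_from_genome_all_match(self, small_genome_pair):
        genome, _ = small_genome_pair
        rng = np.random.default_rng(2)
        probes = []
        for _ in range(50):
            i = int(rng.integers(0, genome.length - 25))
            p = genome.sequence[i : i + 25]
            probes.append(p if rng.random() < 0.5 else revcomp(p))
        report = verify_probes(probes, genome)
        assert report["perfect_match"].all() and report["perfect_match"].mean() == 1.0

    def test_planted_mismatch_reported_unmatched(self, small_genome_pair):
        genome, _ = small_genome_pair
        p = list(genome.sequence[1000:1025])
        p[12] = "A" if p[12] != "A" else "C"
        probe = "".join(p)
        report = verify_probes([probe], genome)
        if genome.sequence.find(probe) < 0 and genome.sequence.find(revcomp(probe)) < 0:
            assert not report["perfect_match"].iloc[0]

    def test_empty_probe_list(self, small_genome_pair):
        genome, _ = small_genome_pair
        assert len(verify_probes([], genome)) == 0

    def test_wrong_length_rejected(self, small_genome_pair):
        genome, _ = small_genome_pair
        with pytest.raises(ValueError, match="25"):
            verify_probes(["ACGT"], genome)


def test_vcf_output_is_readable_text(tmp_path, small_genome_pair):
    genome, cds = small_genome_pair
    plan = MutationPlan(n_snv=5, n_small_indel=3, min_spacing=1000, seed=1)
    qry, _ = mutate_genome(genome, plan, cds)
    variants = compare_genomes(genome, qry)
    out = tmp_path / "calls.vcf"
    write_variants_vcf(variants, genome, out)
    lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
    assert len(lines) == len(variants)
    for line in lines:
        chrom, pos, _, ref, alt = line.split("\t")[:5]
        pos = int(pos)
        # REF field must match the reference sequence at POS
        assert genome.sequence[pos - 1 : pos - 1 + len(ref)] == ref
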