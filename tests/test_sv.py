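"""SV detection, filtering boundaries, and SURVIVOR-style merge semantics
checked against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from superpan.genome import revcomp
from superpan.sv import (
    MergedSV, StructuralVariant, anchor_chain_align, call_svs,
    call_svs_from_blocks, filter_svs, merge_svs, presence_matrix,
)


def _rs(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestAnchorChain:
    def test_identical_sequences_single_forward_block(self, rng):
        ref = _rs(rng, 50_000)
        bs = anchor_chain_align(ref, ref, 21)
        bb = bs.backbone()
        assert len(bb) == 1
        assert bb[0].rstart == 0 and bb[0].rend == 50_000
        assert bb[0].orientation == "+"

    def test_central_inversion_gives_minus_block(self, rng):
        ref = _rs(rng, 30_000)
        q = ref[:14_000] + revcomp(ref[14_000:16_000]) + ref[16_000:]
        bs = anchor_chain_align(ref, q, 21)
        minus = [b for b in bs.blocks if b.orientation == "-"]
        assert len(minus) == 1
        assert abs(minus[0].rstart - 14_000) <= 21
        assert abs(minus[0].rend - 16_000) <= 21
        assert len(bs.backbone()) == 2

    def test_disjoint_sequences_no_blocks(self, rng):
        a, b = _rs(rng, 5_000), _rs(rng, 5_000)
        bs = anchor_chain_align(a, b, 21)
        assert all(x.n_anchors < 3 for x in bs.blocks)

    def test_short_sequence_empty(self):
        assert anchor_chain_align("ACGT", "ACGT", 21).blocks == []

    def test_k_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            anchor_chain_align("A" * 100, "A" * 100, 9)


class TestCalling:
    def test_identical_genomes_empty_call_set(self, rng):
        ref = _rs(rng, 20_000)
        assert call_svs(ref, ref) == []

    @pytest.mark.parametrize("svlen", [100, 1000])
    def test_deletion_breakpoints_within_k(self, rng, svlen):
        ref = _rs(rng, 40_000)
        q = ref[:15_000] + ref[15_000 + svlen:]
        calls = call_svs(ref, q, k=21)
        dels = [c for c in calls if c.svtype == "DEL"]
        assert len(dels) == 1
        assert abs(dels[0].start - 15_000) <= 21
        assert abs(dels[0].length - svlen) <= 21

    def test_insertion_recovered(self, rng):
        ref = _rs(rng, 40_000)
        ins = _rs(rng, 500)
        q = ref[:20_000] + ins + ref[20_000:]
        calls = call_svs(ref, q, k=21)
        inss = [c for c in calls if c.svtype == "INS"]
        assert len(inss) == 1
        assert abs(inss[0].start - 20_000) <= 21
        assert abs(inss[0].length - 500) <= 21

    def test_tandem_duplication_copy_ratio_two(self, rng):
        ref = _rs(rng, 30_000)
        q = ref[:8_000] + ref[7_000:8_000] + ref[8_000:]
        calls = call_svs(ref, q, k=21)
        dups = [c for c in calls if c.svtype == "DUP"]
        assert len(dups) == 1
        assert dups[0].copy_ratio == 2.0

    def test_copy_loss_ratio_half(self, rng):
        """Reference carries a tandem pair; query kept one copy."""
        unit = _rs(rng, 800)
        left, right = _rs(rng, 10_000), _rs(rng, 10_000)
        ref = left + unit + unit + right
        q = left + unit + right
        calls = call_svs(ref, q, k=21)
        dups = [c for c in calls if c.svtype == "DUP"]
        assert len(dups) == 1
        assert dups[0].copy_ratio == 0.5

    def test_translocation_source_span(self, rng):
        ref = _rs(rng, 50_000)
        seg = ref[10_000:11_000]
        q = ref[:10_000] + ref[11_000:40_000] + seg + ref[40_000:]
        calls = call_svs(ref, q, k=21)
        tras = [c for c in calls if c.svtype == "TRA"]
        assert len(tras) == 1
        assert abs(tras[0].start - 10_000) <= 21
        assert abs(tras[0].end - 11_000) <= 21

    def test_recall_on_simulated_truth(self, sv_clade):
        _cfg, anc, genomes, truth = sv_clade
        k = 21
        for g in genomes:
            calls = call_svs(anc.seq, g.seq, sample=g.name, k=k)
            true_events = truth.svs_for(g.name)
            found = 0
            for t in true_events:
                hit = any(
                    c.svtype == t.svtype
                    and abs(c.start - t.start) <= k
                    and abs(c.length - t.length) <= 2 * k
                    for c in calls)
                found += hit
            assert found >= 0.9 * len(true_events)


class TestFilter:
    def _sv(self, svtype, length, seq="", ratio=None):
        end = 100 if svtype == "INS" else 100 + length
        return StructuralVariant("s", svtype, "c", 100, end, length,
                                 seq=seq or "A" * length, copy_ratio=ratio)

    @pytest.mark.parametrize("length,kept", [(50, False), (51, True)])
    def test_indel_min_size_strictly_greater_than_50(self, length, kept):
        for svtype in ("INS", "DEL", "TRA"):
            out = filter_svs([self._sv(svtype, length)])
            assert bool(out) is kept, svtype

    @pytest.mark.parametrize("length,kept", [
        (999_999, True), (1_000_000, False)])
    def test_inversion_max_size_strictly_below_1mb(self, length, kept):
        out = filter_svs([self._sv("INV", length, seq="ACGT")])
        assert bool(out) is kept

    @pytest.mark.parametrize("ratio,kept", [
        (1.5, False), (2.0, True), (2.5, True), (0.5, True), (0.6, False)])
    def test_cnv_ratio_bounds(self, ratio, kept):
        out = filter_svs([self._sv("DUP", 200, ratio=ratio)])
        assert bool(out) is kept

    def test_n_content_removed(self):
        sv = self._sv("DEL", 200, seq="A" * 100 + "N" + "A" * 99)
        assert filter_svs([sv]) == []

    def test_filtered_is_subset(self, rng):
        svs = [self._sv(t, int(rng.integers(10, 200)))
               for t in ("INS", "DEL", "INV") for _ in range(10)]
        out = filter_svs(svs)
        assert all(o in svs for o in out)


def _mk(start, end, sample="s", caller="c", chrom="chr1", svtype="DEL"):
    return StructuralVariant(sample, svtype, chrom, start, end,
                             max(1, end - start), caller=caller)


def _brute_force_clusters(svs, max_dist=50, require_type=False):
    n = len(svs)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            a, b = svs[i], svs[j]
            adj[i][j] = (a.chrom == b.chrom
                         and abs(a.start - b.start) <= max_dist
                         and abs(a.end - b.end) <= max_dist
                         and (not require_type or a.svtype == b.svtype))
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], set()
        while stack:
            x = stack.pop()
            if seen[x]:
                continue
            seen[x] = True
            comp.add(x)
            stack.extend(y for y in range(n) if adj[x][y] and not seen[y])
        comps.append(frozenset(comp))
    return set(comps)


class TestMerge:
    def test_identical_call_two_callers_support_two(self):
        m = merge_svs([[_mk(100, 300, "a", "c1")], [_mk(100, 300, "a", "c2")]])
        assert len(m) == 1 and m[0].support == 2

    def test_offset_51_does_not_link(self):
        m = merge_svs([[_mk(100, 300)], [_mk(151, 351, sample="t")]])
        assert len(m) == 2

    def test_offset_50_links(self):
        m = merge_svs([[_mk(100, 300)], [_mk(150, 350, sample="t")]])
        assert len(m) == 1

    def test_single_linkage_chain(self):
        m = merge_svs([[_mk(100, 300, "a")], [_mk(140, 340, "b")],
                       [_mk(180, 380, "c")]])
        assert len(m) == 1 and m[0].samples == {"a", "b", "c"}

    def test_mixed_chromosomes_never_link(self):
        m = merge_svs([[_mk(100, 300, chrom="chr1")],
                       [_mk(100, 300, sample="t", chrom="chr2")]])
        assert len(m) == 2

    def test_matches_brute_force_union_find_oracle(self, rng):
        for trial in range(20):
            n = int(rng.integers(3, 12))
            svs = []
            for i in range(n):
                start = int(rng.integers(0, 300))
                length = int(rng.integers(60, 200))
                svs.append(StructuralVariant(
                    f"s{i}", "DEL", "chr1", start, start + length, length,
                    caller="c"))
            merged = merge_svs([[s] for s in svs])
            got = {frozenset(id(x) for x in m.members) for m in merged}
            key = {id(s): i for i, s in enumerate(svs)}
            got_idx = {frozenset(key[x] for x in fs) for fs in got}
            assert got_idx == _brute_force_clusters(svs)

    def test_boundary_triple_chain_50_50_100(self):
        a, b, c = _mk(100, 300, "a"), _mk(150, 350, "b"), _mk(200, 400, "c")
        merged = merge_svs([[a], [b], [c]])
        assert len(merged) == 1  # A-B and B-C link; A-C joins transitively

    def test_idempotent(self, rng):
        svs = [_mk(int(rng.integers(0, 500)), int(rng.integers(600, 800)),
                   sample=f"s{i}") for i in range(15)]
        first = merge_svs([[s] for s in svs])
        again = merge_svs([m.members for m in first])
        assert [(m.chrom, m.start, m.end, frozenset(id(x) for x in m.members))
                for m in first] == \
               [(m.chrom, m.start, m.end, frozenset(id(x) for x in m.members))
                for m in again]

    def test_permutation_invariant(self, rng):
        svs = [_mk(int(rng.integers(0, 400)), int(rng.integers(500, 900)),
                   sample=f"s{i}") for i in range(12)]
        base = merge_svs([[s] for s in svs])
        for _ in range(5):
            perm = list(rng.permutation(len(svs)))
            shuffled = merge_svs([[svs[i]] for i in perm])
            assert [(m.chrom, m.start, m.end, m.svtype, m.length)
                    for m in base] == \
                   [(m.chrom, m.start, m.end, m.svtype, m.length)
                    for m in shuffled]

    def test_representative_median_length(self):
        calls = [[_mk(100, 100 + L, sample=f"s{L}")] for L in (100, 120, 140)]
        m = merge_svs(calls, max_dist=50)
        assert m[0].length == 120

    def test_min_support_drops_singletons(self):
        m = merge_svs([[_mk(100, 300, "a")], [_mk(1000, 1300, "b")],
                       [_mk(120, 320, "c")]], min_support=2)
        assert len(m) == 1 and m[0].samples == {"a", "c"}


class TestPresenceMatrix:
    def _merged(self):
        return merge_svs([[_mk(100, 300, "a"), _mk(1000, 1200, "a")],
                          [_mk(110, 310, "b")]])

    def test_dimensions_and_membership(self):
        pm = presence_matrix(self._merged(), ["a", "b"])
        assert pm.shape == (2, 2)
        row_ab = pm.loc[pm.sum(axis=1) == 2].iloc[0]
        assert row_ab["a"] == 1 and row_ab["b"] == 1

    def test_absent_sample_zero(self):
        pm = presence_matrix(self._merged(), ["a", "b"])
        solo = pm.loc[pm.sum(axis=1) == 1].iloc[0]
        assert solo["a"] == 1 and solo["b"] == 0

    def test_row_sums_equal_sample_support(self):
        merged = self._merged()
        pm = presence_matrix(merged, ["a", "b"])
        for m in merged:
            assert pm.loc[m.sv_id].sum() == len(m.samples)

    def test_empty_input_fails(self):
        with pytest.raises(ValueError):
            presence_matrix([], ["a"])


@settings(max_examples=40, deadline=None)
@given(st.lists(
    st.tuples(st.integers(0, 400), st.integers(1, 200)), min_size=1,
    max_size=10))
def test_merge_property_matches_oracle(pairs):
    svs = [StructuralVariant(f"s{i}", "DEL", "chr1", a, a + L, L, caller="c")
           for i, (a, L) in enumerate(pairs)]
    merged = merge_svs([[s] for s in svs])
    key = {id(s): i for i, s in enumerate(svs)}
    got = {frozenset(key[id(x)] for x in m.members) for m in merged}
    assert got == _brute_force_clusters(svs)
    # every member within the linkage distance chain of its representative
    assert sum(len(m.members) for m in merged) == len(svs)
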