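"""Pangenome classification: clustering, the rescue rule with its strict
>80% boundaries, core/dispensable/specific partition, and growth curves."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from superpan.genome import AnnotatedGenome, GeneModel
from superpan.pangene import (
    ABSENT, ANNOTATED, RESCUED, classify_families, cluster_families,
    families_from_annotations, growth_curves, presence_matrix_from_families,
    rescue_unannotated,
)

MUT = {"A": "C", "C": "G", "G": "T", "T": "A"}


def _rs(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestClustering:
    def test_dissimilar_genes_stay_singletons(self, rng):
        prot = {"g1": {"a": _rs(rng, 300), "b": _rs(rng, 300), "c": _rs(rng, 300)}}
        fam = cluster_families(prot)
        assert fam.n_families == 3
        assert all(len(m) == 1 for m in fam.members.values())

    def test_two_identical_proteomes_pair_every_family(self, rng):
        genes = {f"g{i}": _rs(rng, 300) for i in range(5)}
        fam = cluster_families({"A": genes, "B": dict(genes)})
        assert fam.n_families == 5
        assert all(len(m) == 2 for m in fam.members.values())

    def test_zero_gain_loss_clade_recovers_ancestral_family_count(self):
        from superpan.simulate import CladeConfig, evolve_clade, simulate_ancestor

        cfg = CladeConfig(n_genomes=3, genome_length=40_000, n_genes=12,
                          substitution_rate_per_branch=0.002,
                          family_loss_prob=0.0, family_gain_rate=0.0, seed=8)
        anc = simulate_ancestor(cfg)
        genomes, _ = evolve_clade(anc, cfg)
        prot = {g.name: {x.gene_id: x.cds_sequence(g.seq) for x in g.genes}
                for g in genomes}
        fam = cluster_families(prot)
        assert fam.n_families == cfg.n_genes
        assert all(len(m) == 3 for m in fam.members.values())

    def test_empty_input_fails(self):
        with pytest.raises(ValueError):
            cluster_families({})


def _one_gene_genome(name, seq, gene_start, gene_len, family="famX",
                     extra_genes=()):
    genes = [GeneModel(gene_id=f"{name}.g1", chrom=name, start=gene_start,
                       end=gene_start + gene_len, strand="+",
                       exons=((gene_start, gene_start + gene_len),),
                       family=family)]
    genes += list(extra_genes)
    return AnnotatedGenome(name=name, seq=seq, genes=genes)


class TestRescue:
    """Fixtures place a 1000-bp gene in a donor genome and control exactly
    how much of it, and at what identity, survives in the target genome."""

    GENE_LEN = 999  # divisible by 3

    def _donor(self, rng):
        flank = _rs(rng, 2000)
        gene_seq = _rs(rng, self.GENE_LEN)
        seq = flank + gene_seq + _rs(rng, 2000)
        return _one_gene_genome("donor", seq, 2000, self.GENE_LEN), gene_seq

    def _fam(self):
        from superpan.pangene import FamilyAssignment

        fam = FamilyAssignment()
        fam.members["famX"] = [("donor", "donor.g1")]
        return fam

    @pytest.mark.parametrize("frac,expected", [
        (0.79, ABSENT), (0.80, ABSENT), (0.81, RESCUED)])
    def test_coverage_boundary_strictly_greater(self, rng, frac, expected):
        donor, gene_seq = self._donor(rng)
        kept = int(round(self.GENE_LEN * frac))
        # poison the junction so chance matches cannot extend the aligned
        # span beyond the planted fraction
        poison = "".join(MUT[c] for c in gene_seq[kept:kept + 50])
        target_seq = _rs(rng, 3000) + gene_seq[:kept] + poison + _rs(rng, 3000)
        target = AnnotatedGenome(name="target", seq=target_seq, genes=[])
        pam = rescue_unannotated(self._fam(), {"donor": donor, "target": target})
        assert pam.loc["famX", "target"] == expected

    @pytest.mark.parametrize("n_mut,expected", [
        (210, ABSENT), (200, ABSENT), (190, RESCUED)])  # identity .79/.80/.81
    def test_identity_boundary_strictly_greater(self, rng, n_mut, expected):
        donor, gene_seq = self._donor(rng)
        L = self.GENE_LEN
        mutated = list(gene_seq)
        # evenly spaced interior mutations: the local aligner cannot trim
        # or gap its way to a higher identity, so identity = (L-n)/L exactly
        pos = sorted({10 + int(round(i * (L - 21) / (n_mut - 1)))
                      for i in range(n_mut)})
        assert len(pos) == n_mut
        for p in pos:
            mutated[p] = MUT[mutated[p]]
        target_seq = _rs(rng, 3000) + "".join(mutated) + _rs(rng, 3000)
        target = AnnotatedGenome(name="target", seq=target_seq, genes=[])
        pam = rescue_unannotated(self._fam(), {"donor": donor, "target": target})
        assert pam.loc["famX", "target"] == expected

    def test_intact_unannotated_copy_is_rescued_with_full_scores(self, rng):
        donor, gene_seq = self._donor(rng)
        target = AnnotatedGenome(
            name="target", seq=_rs(rng, 1500) + gene_seq + _rs(rng, 1500),
            genes=[])
        pam = rescue_unannotated(self._fam(), {"donor": donor, "target": target})
        assert pam.loc["famX", "target"] == RESCUED

    def test_overlap_with_annotated_gene_vetoes_rescue(self, rng):
        donor, gene_seq = self._donor(rng)
        # perfect copy present, but another annotated gene covers the span
        other = GeneModel(gene_id="t.g9", chrom="target", start=1600,
                          end=1600 + 500, strand="+",
                          exons=((1600, 2100),), family="famOther")
        target = AnnotatedGenome(
            name="target", seq=_rs(rng, 1500) + gene_seq + _rs(rng, 1500),
            genes=[other])
        pam = rescue_unannotated(self._fam(), {"donor": donor, "target": target})
        assert pam.loc["famX", "target"] == ABSENT

    def test_missing_genome_sequence_fails_naming_it(self, rng):
        donor, _ = self._donor(rng)
        target = AnnotatedGenome(name="target", seq="", genes=[])
        with pytest.raises(ValueError, match="target"):
            rescue_unannotated(self._fam(), {"donor": donor, "target": target})

    def test_rescue_fires_on_identical_genome_when_unannotated(self, small_clade):
        """Soundness: drop one gene's annotation from a copy of its own
        genome — the alignment must rescue it (coverage = identity = 1)."""
        _cfg, _anc, genomes, _truth = small_clade
        g = genomes[0]
        victim = g.sorted_genes()[3]
        twin = AnnotatedGenome(
            name="twin", seq=g.seq,
            genes=[x for x in g.genes if x.gene_id != victim.gene_id])
        fam = families_from_annotations([g])
        pam = rescue_unannotated(fam, {g.name: g, "twin": twin})
        assert pam.loc[victim.family, "twin"] == RESCUED


class TestClassification:
    def _pam(self, rows, n_genomes):
        data = [[ANNOTATED if j < r else ABSENT for j in range(n_genomes)]
                for r in rows]
        return pd.DataFrame(data, index=[f"f{i}" for i in range(len(rows))],
                            columns=[f"g{j}" for j in range(n_genomes)])

    def test_present_in_all_is_core(self):
        cls = classify_families(self._pam([13], 13))
        assert cls.core == {"f0"}

    def test_present_in_one_is_specific(self):
        cls = classify_families(self._pam([1], 13))
        assert cls.specific == {"f0"}

    def test_intermediate_is_dispensable_vs_row_count_oracle(self, rng):
        n = 13
        counts = rng.integers(1, n + 1, size=40)
        pam = self._pam(list(counts), n)
        cls = classify_families(pam)
        for fam_id, c in zip(pam.index, counts):
            present = sum(v in (ANNOTATED, RESCUED) for v in pam.loc[fam_id])
            assert present == c
            if c == n:
                assert fam_id in cls.core
            elif c == 1:
                assert fam_id in cls.specific
            else:
                assert fam_id in cls.dispensable

    def test_rescued_counts_as_present(self):
        pam = pd.DataFrame([[ANNOTATED, RESCUED, RESCUED]],
                           index=["f0"], columns=["a", "b", "c"])
        assert classify_families(pam).core == {"f0"}

    def test_partition_and_proportions(self, rng):
        pam = self._pam(list(rng.integers(1, 9, size=60)), 8)
        cls = classify_families(pam)
        assert len(cls.core) + len(cls.dispensable) + len(cls.specific) == 60
        assert abs(sum(cls.proportions.values()) - 1.0) < 1e-9

    def test_recovery_on_simulated_clade_matches_truth(self, small_clade):
        """With complete annotations and no rescue, classification equals
        what the recorded gain/loss events imply."""
        cfg, anc, genomes, truth = small_clade
        fam = families_from_annotations(genomes)
        pam = presence_matrix_from_families(fam, [g.name for g in genomes])
        cls = classify_families(pam)
        n = len(genomes)
        truth_presence = {}
        for g in genomes:
            for gene in g.genes:
                truth_presence.setdefault(gene.family, set()).add(g.name)
        for family, present in truth_presence.items():
            if len(present) == n:
                assert family in cls.core
            elif len(present) == 1:
                assert family in cls.specific
            else:
                assert family in cls.dispensable


class TestGrowthCurves:
    def _random_pam(self, rng, n_fam=30, n_gen=6):
        m = rng.random((n_fam, n_gen)) < 0.6
        m[:, 0] |= ~m.any(axis=1)  # every family present somewhere
        return pd.DataFrame(np.where(m, ANNOTATED, ABSENT),
                            index=[f"f{i}" for i in range(n_fam)],
                            columns=[f"g{j}" for j in range(n_gen)])

    def test_pan_at_full_k_equals_total_families(self, rng):
        pam = self._random_pam(rng)
        gc = growth_curves(pam, n_permutations=20, seed=0)
        assert (gc.pan_per_perm[:, -1] == len(pam)).all()

    def test_monotone_every_permutation(self, rng):
        pam = self._random_pam(rng)
        gc = growth_curves(pam, n_permutations=50, seed=1)
        assert (np.diff(gc.pan_per_perm, axis=1) >= 0).all()
        assert (np.diff(gc.core_per_perm, axis=1) <= 0).all()

    def test_all_present_matrix_constant_curves(self):
        pam = pd.DataFrame(ANNOTATED, index=["f0", "f1"], columns=list("abcd"))
        gc = growth_curves(pam, n_permutations=5, seed=2)
        assert (gc.pan_per_perm == 2).all() and (gc.core_per_perm == 2).all()

    def test_exhaustive_four_genome_enumeration_oracle(self, rng):
        """Mean over many sampled permutations converges to the exact mean
        over all 24 orderings of 4 genomes."""
        pam = self._random_pam(rng, n_fam=25, n_gen=4)
        present = pam.isin([ANNOTATED, RESCUED]).to_numpy()
        exact_pan = np.zeros(4)
        exact_core = np.zeros(4)
        for order in permutations(range(4)):
            u = np.zeros(len(pam), dtype=bool)
            i = np.ones(len(pam), dtype=bool)
            for j, g in enumerate(order):
                u |= present[:, g]
                i &= present[:, g]
                exact_pan[j] += u.sum()
                exact_core[j] += i.sum()
        exact_pan /= 24
        exact_core /= 24
        gc = growth_curves(pam, n_permutations=3000, seed=3)
        assert np.allclose(gc.pan_mean, exact_pan, atol=0.35)
        assert np.allclose(gc.core_mean, exact_core, atol=0.35)

    def test_core_at_full_k_matches_classification(self, rng):
        pam = self._random_pam(rng)
        gc = growth_curves(pam, n_permutations=5, seed=4)
        cls = classify_families(pam)
        assert (gc.core_per_perm[:, -1] == len(cls.core)).all()


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_growth_monotonicity_property(seed):
    rng = np.random.default_rng(seed)
    n_fam, n_gen = int(rng.integers(5, 40)), int(rng.integers(2, 8))
    m = rng.random((n_fam, n_gen)) < rng.uniform(0.2, 0.9)
    m[:, 0] |= ~m.any(axis=1)
    pam = pd.DataFrame(np.where(m, ANNOTATED, ABSENT),
                       index=[f"f{i}" for i in range(n_fam)],
                       columns=[f"g{j}" for j in range(n_gen)])
    gc = growth_curves(pam, n_permutations=10, seed=seed % 2**31)
    assert (np.diff(gc.pan_per_perm, axis=1) >= 0).all()
    assert (np.diff(gc.core_per_perm, axis=1) <= 0).all()
    assert (gc.pan_per_perm[:, -1] == n_fam).all()
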