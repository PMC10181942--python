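"""Gene-family presence/absence analysis.

Families are built by single-linkage clustering of pairwise CDS identity
(k-mer prefilter, then global alignment).  A family absent from a genome's
annotation can be *rescued* when a member CDS still aligns to that genome
with coverage and identity both strictly above 80% and the aligned span
overlaps no annotated gene — such families count as present, not missing.
Families present in all N genomes are core; in exactly one, specific; in
2..N-1, dispensable.  Growth curves report pan (cumulative union) and core
(cumulative intersection) sizes over random genome orderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio import Align

from superpan.genome import AnnotatedGenome

ANNOTATED, RESCUED, ABSENT = "A", "R", "0"


@dataclass
class FamilyAssignment:
    """family id -> list of (genome, gene_id) members."""

    members: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def genomes_with(self, family: str) -> set[str]:
        return {g for g, _ in self.members[family]}

    @property
    def n_families(self) -> int:
        return len(self.members)


def _kmer_set(seq: str, k: int = 12) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _identity(a: str, b: str) -> float:
    """Global-alignment identity: 1 - editdist / max(len)."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def cluster_families(proteomes: dict[str, dict[str, str]],
                     identity_threshold: float = 0.8,
                     k: int = 12,
                     min_kmer_jaccard: float = 0.05) -> FamilyAssignment:
    """Single-linkage families over pairwise CDS identity.

    ``proteomes`` maps genome -> {gene_id: CDS sequence}.  A k-mer Jaccard
    prefilter skips hopeless pairs; surviving pairs are scored by global
    alignment and linked when identity >= threshold.  Components are
    labelled deterministically by their lexicographically smallest member.
    """
    if not proteomes:
        raise ValueError("no genomes given")
    items: list[tuple[str, str, str]] = []  # (genome, gene_id, seq)
    for genome in sorted(proteomes):
        genes = proteomes[genome]
        if any(not s for s in genes.values()):
            raise ValueError(f"empty sequence in genome {genome}")
        for gid in sorted(genes):
            items.append((genome, gid, genes[gid]))

    n = len(items)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    kmers = [_kmer_set(seq, k) for _, _, seq in items]
    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            inter = len(kmers[i] & kmers[j])
            if inter == 0:
                continue
            jac = inter / (len(kmers[i]) + len(kmers[j]) - inter)
            if jac < min_kmer_jaccard:
                continue
            if _identity(items[i][2], items[j][2]) >= identity_threshold:
                union(i, j)

    comps: dict[int, list[tuple[str, str]]] = {}
    for idx, (genome, gid, _seq) in enumerate(items):
        comps.setdefault(find(idx), []).append((genome, gid))
    fam = FamilyAssignment()
    for root in sorted(comps, key=lambda r: (items[r][0], items[r][1])):
        label = f"F{items[root][0]}.{items[root][1]}"
        fam.members[label] = sorted(comps[root])
    return fam


def families_from_annotations(genomes: list[AnnotatedGenome]) -> FamilyAssignment:
    """Families taken directly from the simulator's family labels.

    Shortcut for synthetic clades where family identity is known; the
    clustering route is for sequences without labels.
    """
    fam = FamilyAssignment()
    for genome in sorted(genomes, key=lambda g: g.name):
        for gene in genome.sorted_genes():
            if gene.family is None:
                raise ValueError(f"gene {gene.gene_id} lacks a family label")
            fam.members.setdefault(gene.family, []).append((genome.name, gene.gene_id))
    fam.members = {f: sorted(m) for f, m in sorted(fam.members.items())}
    return fam


# ------------------------------------------------------------------ rescue

_aligner = Align.PairwiseAligner(
    mode="local", match_score=1, mismatch_score=-2,
    open_gap_score=-6, extend_gap_score=-2,
)


def _best_local_alignment(query: str, target: str) -> tuple[float, float, int, int]:
    """(coverage, identity, target_start, target_end) of the best local hit.

    Candidate windows come from exact k-mer seeding so the quadratic local
    alignment only runs on a region ~3x the query length.
    """
    if not query or len(target) < 10:
        return 0.0, 0.0, 0, 0
    # locate the best approximate occurrence with a fast infix alignment,
    # then refine with a proper local alignment on that window only
    loc = edlib.align(query, target, mode="HW", task="locations")
    if loc["editDistance"] < 0 or not loc["locations"]:
        return 0.0, 0.0, 0, 0
    ls, le = loc["locations"][0]
    ws = max(0, ls - len(query) // 2)
    we = min(len(target), (le + 1) + len(query) // 2)
    window = target[ws:we]
    alns = _aligner.align(query, window)
    if len(alns) == 0:
        return 0.0, 0.0, 0, 0
    aln = alns[0]
    qa = aln.aligned[0]
    ta = aln.aligned[1]
    matches = 0
    aligned_cols = 0
    for (qs, qe), (ts, te) in zip(qa, ta):
        aligned_cols += qe - qs
        matches += sum(1 for a, b in zip(query[qs:qe], window[ts:te]) if a == b)
    if aligned_cols == 0:
        return 0.0, 0.0, 0, 0
    # internal gap columns count against identity: gapping away mismatches
    # must not look like a cleaner alignment
    gap_cols = ((qa[-1][1] - qa[0][0]) - aligned_cols) + \
               ((ta[-1][1] - ta[0][0]) - aligned_cols)
    coverage = (qa[-1][1] - qa[0][0]) / len(query)
    identity = matches / (aligned_cols + gap_cols)
    return coverage, identity, ws + int(ta[0][0]), ws + int(ta[-1][1])


def rescue_unannotated(
    fam: FamilyAssignment,
    genomes: dict[str, AnnotatedGenome],
    min_coverage: float = 0.80,
    min_identity: float = 0.80,
) -> pd.DataFrame:
    """Presence/absence matrix with the alignment rescue rule applied.

    For each (family, genome) cell with no annotated member, each member
    CDS is aligned to that genome; the cell becomes rescued iff some member
    achieves coverage AND identity strictly greater than the thresholds and
    the aligned genomic span overlaps no annotated gene.  Cells with an
    annotated member are 'A'; everything else is absent ('0').
    """
    genome_names = sorted(genomes)
    missing = [g for g in genome_names if genomes[g].seq == ""]
    if missing:
        raise ValueError(f"genome sequence missing for: {missing}")
    seqs = {name: {g.gene_id: g for g in genomes[name].genes} for name in genome_names}

    pam = pd.DataFrame(ABSENT, index=sorted(fam.members), columns=genome_names)
    for family, members in fam.members.items():
        present = {g for g, _ in members}
        for gname in present:
            pam.loc[family, gname] = ANNOTATED
        for gname in genome_names:
            if gname in present:
                continue
            target = genomes[gname]
            rescued = False
            for src_genome, gene_id in members:
                gene = seqs[src_genome][gene_id]
                cds = gene.cds_sequence(genomes[src_genome].seq)
                cov, ident, ts, te = _best_local_alignment(cds, target.seq)
                if cov > min_coverage and ident > min_identity:
                    overlaps = any(g.start < te and g.end > ts for g in target.genes)
                    if not overlaps:
                        rescued = True
                        break
            if rescued:
                pam.loc[family, gname] = RESCUED
    return pam


def presence_matrix_from_families(fam: FamilyAssignment,
                                  genome_names: list[str]) -> pd.DataFrame:
    """Annotation-only presence/absence matrix (no rescue)."""
    pam = pd.DataFrame(ABSENT, index=sorted(fam.members), columns=sorted(genome_names))
    for family, members in fam.members.items():
        for g, _ in members:
            pam.loc[family, g] = ANNOTATED
    return pam


# ------------------------------------------------------------- classification

@dataclass
class PangenomeClassification:
    core: set[str]
    dispensable: set[str]
    specific: set[str]

    @property
    def proportions(self) -> dict[str, float]:
        total = len(self.core) + len(self.dispensable) + len(self.specific)
        if total == 0:
            return {"core": 0.0, "dispensable": 0.0, "specific": 0.0}
        return {
            "core": len(self.core) / total,
            "dispensable": len(self.dispensable) / total,
            "specific": len(self.specific) / total,
        }


def classify_families(pam: pd.DataFrame) -> PangenomeClassification:
    """Partition families into core / dispensable / specific.

    Present means annotated or rescued.  Core: present in all N genomes;
    specific: present in exactly one; dispensable: 2..N-1.
    """
    n = pam.shape[1]
    if n < 2:
        raise ValueError("classification needs >= 2 genomes")
    present = pam.isin([ANNOTATED, RESCUED]).sum(axis=1)
    core = set(pam.index[present == n])
    specific = set(pam.index[present == 1])
    dispensable = set(pam.index[(present >= 2) & (present < n)])
    cls = PangenomeClassification(core, dispensable, specific)
    total = len(core) + len(dispensable) + len(specific)
    if total != pam.shape[0]:
        # families present in zero genomes cannot occur by construction
        raise AssertionError("classification does not partition the families")
    assert abs(sum(cls.proportions.values()) - 1.0) < 1e-9 or total == 0
    return cls


# ------------------------------------------------------------- growth curves

@dataclass
class GrowthCurve:
    k: np.ndarray                 # 1..N
    pan_mean: np.ndarray
    core_mean: np.ndarray
    pan_per_perm: np.ndarray      # (n_perm, N)
    core_per_perm: np.ndarray
    n_permutations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.k, "pan_mean": self.pan_mean, "core_mean": self.core_mean,
        })


def growth_curves(pam: pd.DataFrame, n_permutations: int = 100,
                  seed: int = 0) -> GrowthCurve:
    """Pangenome / core-genome size as genomes are added in random order."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    present = pam.isin([ANNOTATED, RESCUED]).to_numpy()  # families x genomes
    n_fam, n_gen = present.shape
    pan = np.empty((n_permutations, n_gen), dtype=int)
    core = np.empty((n_permutations, n_gen), dtype=int)
    for p in range(n_permutations):
        order = rng.permutation(n_gen)
        cum_union = np.zeros(n_fam, dtype=bool)
        cum_inter = np.ones(n_fam, dtype=bool)
        for j, gi in enumerate(order):
            cum_union |= present[:, gi]
            cum_inter &= present[:, gi]
            pan[p, j] = int(cum_union.sum())
            core[p, j] = int(cum_inter.sum())
    return GrowthCurve(
        k=np.arange(1, n_gen + 1), pan_mean=pan.mean(axis=0),
        core_mean=core.mean(axis=0), pan_per_perm=pan, core_per_perm=core,
        n_permutations=n_permutations, seed=seed,
    )
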