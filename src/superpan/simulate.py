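"""Synthetic clade simulator with recoverable ground truth.

Generates an annotated ancestor genome, evolves it down a bifurcating tree
with per-branch substitutions and gene-family gain/loss, implants structural
variants of all five classes (INS, DEL, INV, DUP, TRA) with truth recorded,
simulates LTR retrotransspon pairs whose end-to-end divergence reflects a
known insertion age, and draws population presence/absence genotypes and
SV-linked quantitative phenotypes.

Every stochastic step runs off a single :class:`numpy.random.Generator`
seeded from the config, so identical (config, seed) pairs give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from superpan.genome import AnnotatedGenome, GeneModel, revcomp

SV_TYPES = ("INS", "DEL", "INV", "DUP", "TRA")

#: accession counts of the four tomato-like population groups:
#: non-SP wild species, S. pimpinellifolium, S. lycopersicum var.
#: cerasiforme and big-fruited S. lycopersicum var. lycopersicum.
DEFAULT_GROUP_SIZES = {"wild": 19, "SP": 22, "SLC": 24, "SLL": 47}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class CladeConfig:
    """Parameters of one simulated clade.

    Rates are per branch of the genome tree; ``mu`` is the per-site,
    per-year base substitution rate used both to diverge LTR ends and,
    downstream, to date them (default 1.3e-8 for Solanum).
    """

    n_genomes: int = 8
    genome_length: int = 100_000
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (300, 1200)
    substitution_rate_per_branch: float = 0.002
    family_loss_prob: float = 0.03
    family_gain_rate: float = 1.0
    sv_counts_per_branch: dict[str, int] = field(
        default_factory=lambda: {t: 0 for t in SV_TYPES}
    )
    sv_size_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {t: (100, 2000) for t in SV_TYPES}
    )
    sv_target_cds: bool = False
    #: minimum gap between implanted SVs so each event's truth is
    #: well-defined and independently recoverable
    sv_min_separation: int = 300
    n_ltr_elements: int = 0
    ltr_length: int = 500
    ltr_age_range: tuple[float, float] = (0.0, 3.0)  # Myr
    mu: float = 1.3e-8  # substitutions / site / year
    seed: int = 0

    def validate(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if min(self.gene_length_range) < 30:
            raise ValueError("minimum gene length must be >= 30 bp")
        if self.n_genes < 0 or self.n_ltr_elements < 0:
            raise ValueError("counts must be >= 0")
        if self.genome_length <= self.n_genes * max(self.gene_length_range):
            raise ValueError(
                "genome_length must exceed n_genes x max gene length "
                f"({self.n_genes} x {max(self.gene_length_range)})"
            )
        for p in (self.substitution_rate_per_branch, self.family_loss_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0,1]")
        if any(c < 0 for c in self.sv_counts_per_branch.values()):
            raise ValueError("SV counts must be >= 0")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")


@dataclass
class SVTruth:
    sample: str
    svtype: str
    start: int  # on the pre-SV coordinate frame of that branch
    end: int
    length: int
    seq: str = ""
    dest: int | None = None  # TRA destination (pre-SV frame)


@dataclass
class LTRTruth:
    element_id: str
    genome: str
    age_myr: float
    superfamily: str
    seq5: str
    seq3: str


@dataclass
class TruthRecord:
    """Complete record of every implanted event, for benchmarking."""

    true_svs: list[SVTruth] = field(default_factory=list)
    true_family_events: list[tuple[str, str, str]] = field(default_factory=list)
    true_ltr_ages: dict[str, float] = field(default_factory=dict)
    causal_markers: list[tuple[str, float]] = field(default_factory=list)
    ltr_elements: list[LTRTruth] = field(default_factory=list)

    def svs_for(self, sample: str) -> list[SVTruth]:
        return [s for s in self.true_svs if s.sample == sample]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each site independently with probability ``rate``."""
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n = rng.binomial(len(arr), rate)
    if n == 0:
        return seq
    pos = rng.choice(len(arr), size=n, replace=False)
    for p in np.sort(pos):
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_ancestor(config: CladeConfig) -> AnnotatedGenome:
    """Build the ancestral annotated genome.

    Genes are non-overlapping, each with 1-3 exons and a CDS length
    divisible by 3; every gene founds its own family.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    seq = _random_seq(rng, config.genome_length)
    genes: list[GeneModel] = []
    if config.n_genes > 0:
        lo, hi = config.gene_length_range
        bodies = []
        for i in range(config.n_genes):
            cds_len = int(rng.integers(lo, hi + 1)) // 3 * 3
            n_exons = int(rng.integers(1, 4))
            n_exons = min(n_exons, cds_len // 30)
            cuts = np.sort(rng.choice(np.arange(1, cds_len // 3), size=n_exons - 1,
                                      replace=False)) * 3 if n_exons > 1 else np.array([], int)
            exon_lens = np.diff(np.concatenate([[0], cuts, [cds_len]])).astype(int)
            intron_lens = rng.integers(50, 201, size=n_exons - 1)
            bodies.append((exon_lens, intron_lens))
        total = sum(int(e.sum() + i.sum()) for e, i in bodies)
        min_gap = 100
        free = config.genome_length - total - (config.n_genes + 1) * min_gap
        if free < 0:
            raise ValueError(
                "cannot place genes without overlap: total gene span "
                f"{total} + minimal gaps exceeds genome_length {config.genome_length}"
            )
        gaps = min_gap + rng.multinomial(free, np.full(config.n_genes + 1,
                                                       1 / (config.n_genes + 1)))
        pos = 0
        for i, (exon_lens, intron_lens) in enumerate(bodies):
            pos += int(gaps[i])
            exons = []
            p = pos
            for j, el in enumerate(exon_lens):
                exons.append((p, p + int(el)))
                p += int(el)
                if j < len(intron_lens):
                    p += int(intron_lens[j])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(
                gene_id=f"g{i:05d}", chrom="ancestor", start=pos, end=p,
                strand=strand, exons=tuple(exons), family=f"fam{i:05d}",
            ))
            pos = p
    return AnnotatedGenome(name="ancestor", seq=seq, genes=genes)


def _balanced_tree(names: list[str]) -> object:
    """Balanced bifurcating tree as nested tuples of leaf names."""
    if len(names) == 1:
        return names[0]
    mid = (len(names) + 1) // 2
    return (_balanced_tree(names[:mid]), _balanced_tree(names[mid:]))


def parse_newick(text: str) -> object:
    """Parse a Newick topology (branch lengths ignored) into nested tuples."""
    text = text.strip().rstrip(";")
    pos = 0

    def node() -> object:
        nonlocal pos
        if text[pos] == "(":
            pos += 1
            children = [node()]
            while text[pos] == ",":
                pos += 1
                children.append(node())
            if text[pos] != ")":
                raise ValueError(f"unbalanced newick at position {pos}")
            pos += 1
            while pos < len(text) and text[pos] not in ",()":
                pos += 1  # skip internal label / branch length
            return tuple(children) if len(children) > 1 else children[0]
        start = pos
        while pos < len(text) and text[pos] not in ",()":
            pos += 1
        label = text[start:pos].split(":")[0]
        if not label:
            raise ValueError("empty leaf label in newick")
        return label

    return node()


def _tree_leaves(tree: object) -> list[str]:
    if isinstance(tree, str):
        return [tree]
    out: list[str] = []
    for child in tree:
        out.extend(_tree_leaves(child))
    return out


@dataclass
class _Lineage:
    seq: str
    genes: list[GeneModel]


class _Editor:
    """Applies length-changing edits to a sequence and shifts gene models.

    Edits are (start, end, replacement) on the current frame, non-overlapping.
    Genes overlapping a length-changing edit are dropped (pseudogenized);
    genes downstream are shifted.
    """

    @staticmethod
    def apply(seq: str, genes: list[GeneModel],
              edits: list[tuple[int, int, str]]) -> tuple[str, list[GeneModel]]:
        edits = sorted(edits)
        for (s1, e1, _), (s2, _e2, _r) in zip(edits, edits[1:]):
            if s2 < e1:
                raise ValueError("overlapping edits")
        parts = []
        pos = 0
        for s, e, rep in edits:
            parts.append(seq[pos:s])
            parts.append(rep)
            pos = e
        parts.append(seq[pos:])
        new_seq = "".join(parts)

        new_genes: list[GeneModel] = []
        for g in genes:
            shift = 0
            dropped = False
            for s, e, rep in edits:
                if e <= g.start:
                    shift += len(rep) - (e - s)
                elif s >= g.end:
                    continue
                else:
                    if len(rep) == (e - s):  # in-place (INV): keep the model
                        continue
                    dropped = True
                    break
            if not dropped:
                new_genes.append(g.shifted(shift))
        return new_seq, new_genes


def _subtract(regions: list[tuple[int, int]],
              occupied: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Free sub-segments of ``regions`` after removing ``occupied``."""
    out = []
    for s, e in regions:
        cuts = sorted((max(s, a), min(e, b)) for a, b in occupied if a < e and b > s)
        pos = s
        for a, b in cuts:
            if a > pos:
                out.append((pos, a))
            pos = max(pos, b)
        if pos < e:
            out.append((pos, e))
    return out


def _place_intervals(rng: np.random.Generator, regions: list[tuple[int, int]],
                     lengths: list[int], occupied: list[tuple[int, int]],
                     sep: int = 0) -> list[int]:
    """Pick non-overlapping start positions so [start, start+len) fits a region.

    ``sep`` pads every placed interval on both sides so successive events
    keep a minimum distance.  Deterministic: free space is recomputed
    exactly after each placement, so the only randomness is which free
    segment and offset is drawn.
    """
    starts = []
    for li, length in enumerate(lengths):
        free = [(s, e) for s, e in _subtract(regions, occupied)
                if e - s >= length + 2]
        if not free:
            raise RuntimeError(
                f"could not place event #{li} of length {length}: no free "
                "segment large enough (placement collision)"
            )
        s, e = free[int(rng.integers(len(free)))]
        start = int(rng.integers(s + 1, e - length))
        occupied.append((start - sep, start + length + sep))
        starts.append(start)
    return starts


def _implant_svs(rng: np.random.Generator, lineage: _Lineage, sample: str,
                 config: CladeConfig, truth: TruthRecord) -> _Lineage:
    counts = {t: int(config.sv_counts_per_branch.get(t, 0)) for t in SV_TYPES}
    if sum(counts.values()) == 0:
        return lineage
    genome = AnnotatedGenome(name=sample, seq=lineage.seq, genes=lineage.genes)
    if config.sv_target_cds and genome.genes:
        regions = [(g.start, g.end) for g in genome.sorted_genes()]
    else:
        regions = genome.intergenic_intervals()

    events: list[tuple[str, int, int]] = []  # (type, start, length)
    occupied: list[tuple[int, int]] = []
    for svtype in SV_TYPES:
        n = counts[svtype]
        if n == 0:
            continue
        lo, hi = config.sv_size_ranges[svtype]
        lens = [int(np.exp(rng.uniform(np.log(lo), np.log(hi + 1)))) for _ in range(n)]
        lens = [max(lo, min(hi, L)) for L in lens]
        sep = config.sv_min_separation
        if svtype == "INS":
            # insertion point needs no span on the reference
            starts = _place_intervals(rng, regions, [1] * n, occupied, sep=sep)
        else:
            starts = _place_intervals(rng, regions, lens, occupied, sep=sep)
        events.extend((svtype, s, L) for s, L in zip(starts, lens))

    edits: list[tuple[int, int, str]] = []
    seq = lineage.seq
    tra_moves: list[tuple[int, int, int]] = []  # (src_start, length, dest)
    for svtype, start, length in sorted(events, key=lambda t: t[1]):
        if svtype == "INS":
            ins = _random_seq(rng, length)
            edits.append((start, start, ins))
            truth.true_svs.append(SVTruth(sample, "INS", start, start, length, ins))
        elif svtype == "DEL":
            truth.true_svs.append(
                SVTruth(sample, "DEL", start, start + length, length,
                        seq[start:start + length]))
            edits.append((start, start + length, ""))
        elif svtype == "INV":
            seg = seq[start:start + length]
            edits.append((start, start + length, revcomp(seg)))
            truth.true_svs.append(SVTruth(sample, "INV", start, start + length, length))
        elif svtype == "DUP":
            seg = seq[start:start + length]
            edits.append((start, start + length, seg + seg))
            truth.true_svs.append(SVTruth(sample, "DUP", start, start + length, length))
        elif svtype == "TRA":
            dest = _place_intervals(rng, regions, [1], occupied,
                                    sep=config.sv_min_separation)[0]
            tra_moves.append((start, length, dest))
            truth.true_svs.append(
                SVTruth(sample, "TRA", start, start + length, length, dest=dest))
    for src, length, dest in tra_moves:
        seg = seq[src:src + length]
        edits.append((src, src + length, ""))
        edits.append((dest, dest, seg))
    new_seq, new_genes = _Editor.apply(seq, lineage.genes, edits)
    return _Lineage(seq=new_seq, genes=new_genes)


def evolve_clade(
    ancestor: AnnotatedGenome,
    config: CladeConfig,
    tree: str | None = None,
) -> tuple[list[AnnotatedGenome], TruthRecord]:
    """Evolve the ancestor down a tree; return leaf genomes and the truth.

    Substitutions and gene-family gain/loss act on every branch; structural
    variants and LTR elements are implanted on the terminal branches, with
    truth coordinates recorded on each branch's pre-SV frame (equal to the
    ancestor frame when gain/loss rates are zero, since substitutions
    preserve length).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    names = [f"genome{i:02d}" for i in range(config.n_genomes)]
    topo = parse_newick(tree) if tree is not None else _balanced_tree(names)
    leaves = _tree_leaves(topo)
    if sorted(leaves) != sorted(set(leaves)) or (tree is None and len(leaves) != config.n_genomes):
        raise ValueError("tree leaves must be unique and match n_genomes")

    truth = TruthRecord()
    gain_counter = [0]
    genomes: list[AnnotatedGenome] = []

    def branch(lineage: _Lineage, branch_name: str) -> _Lineage:
        seq = _mutate(rng, lineage.seq, config.substitution_rate_per_branch)
        genes = list(lineage.genes)
        edits: list[tuple[int, int, str]] = []
        survivors: list[GeneModel] = []
        for g in sorted(genes, key=lambda g: g.start):
            if config.family_loss_prob > 0 and rng.random() < config.family_loss_prob:
                truth.true_family_events.append((branch_name, g.family, "loss"))
                edits.append((g.start, g.end, ""))
            else:
                survivors.append(g)
        n_gain = rng.poisson(config.family_gain_rate) if config.family_gain_rate > 0 else 0
        genome_now = AnnotatedGenome(name=branch_name, seq=seq, genes=survivors)
        gains: list[tuple[int, int, str]] = []  # (insert pos, length, family)
        if n_gain > 0:
            regions = genome_now.intergenic_intervals()
            occupied = [(s, e) for s, e, _ in edits]
            lo, hi = config.gene_length_range
            # cap gained-gene length to what the largest free gap can hold
            cap = max((e - s - 2 for s, e in _subtract(regions, occupied)),
                      default=0) // 3 * 3
            hi_eff = max(lo, min(hi, cap))
            lens = [min(int(rng.integers(lo, hi + 1)), hi_eff) // 3 * 3
                    for _ in range(n_gain)]
            starts = _place_intervals(rng, regions, lens, occupied)
            for s, L in zip(starts, lens):
                gain_counter[0] += 1
                fam = f"famN{gain_counter[0]:04d}"
                edits.append((s, s, _random_seq(rng, L)))
                gains.append((s, L, fam))
                truth.true_family_events.append((branch_name, fam, "gain"))
        new_seq, shifted = _Editor.apply(seq, survivors, edits)
        # place gained gene models at their post-edit coordinates
        shift = 0
        gain_positions: dict[int, int] = {}
        for s, e, rep in sorted(edits):
            if (s, len(rep)) in {(gs, gl) for gs, gl, _ in gains} and s == e:
                gain_positions[s] = s + shift
            shift += len(rep) - (e - s)
        for s, L, fam in gains:
            ns = gain_positions[s]
            shifted.append(GeneModel(
                gene_id=fam.replace("fam", "g"), chrom="ancestor",
                start=ns, end=ns + L, strand="+", exons=((ns, ns + L),),
                family=fam))
        shifted.sort(key=lambda g: g.start)
        return _Lineage(seq=new_seq, genes=shifted)

    def walk(node: object, lineage: _Lineage) -> None:
        """Apply one branch of evolution per edge, depth-first and in a
        fixed child order so results are reproducible."""
        if isinstance(node, str):
            lin = branch(lineage, node)
            lin = _implant_svs(rng, lin, node, config, truth)
            genes = [replace(g, chrom=node) for g in lin.genes]
            genomes.append(AnnotatedGenome(name=node, seq=lin.seq, genes=genes))
            _simulate_ltrs(rng, node, config, truth)
            return
        for child in node:
            label = (child if isinstance(child, str)
                     else "anc(" + _tree_leaves(child)[0] + "...)")
            walk(child, branch(lineage, label) if not isinstance(child, str)
                 else lineage)

    # leaf branches get their own `branch()` call inside walk(); internal
    # edges get one on descent, so every edge of the tree evolves once.
    walk(topo, _Lineage(ancestor.seq, list(ancestor.genes)))
    genomes.sort(key=lambda g: g.name)
    return genomes, truth


def _simulate_ltrs(rng: np.random.Generator, sample: str, config: CladeConfig,
                   truth: TruthRecord) -> None:
    """Draw LTR pairs: identical at insertion, each end then diverges at mu."""
    for i in range(config.n_ltr_elements):
        age = float(rng.uniform(*config.ltr_age_range))
        years = age * 1e6
        anc = _random_seq(rng, config.ltr_length)
        p = min(1.0, config.mu * years)
        seq5 = _mutate(rng, anc, p)
        seq3 = _mutate(rng, anc, p)
        eid = f"{sample}.ltr{i:04d}"
        superfam = "Gypsy" if i % 2 == 0 else "Copia"
        truth.true_ltr_ages[eid] = age
        truth.ltr_elements.append(LTRTruth(eid, sample, age, superfam, seq5, seq3))


@dataclass
class PopulationTables:
    """Sample grouping, SV presence/absence genotypes and phenotype."""

    genotypes: pd.DataFrame  # SVs x samples; 1 present, 0 absent, -1 missing
    group_map: dict[str, str]
    phenotype: pd.Series | None = None


def simulate_population(
    sv_ids,
    group_sizes: dict[str, int] | None = None,
    freq_spec: dict | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
    default_freq: float = 0.5,
) -> PopulationTables:
    """Draw presence/absence/missing genotype calls per sample per SV.

    ``freq_spec`` maps SV id -> {group: presence probability}; SVs not
    listed use ``default_freq`` in every group.  Missing calls are a third
    state (-1), never conflated with absence.
    """
    sv_ids = [getattr(s, "sv_id", s) for s in sv_ids]
    if group_sizes is None:
        group_sizes = dict(DEFAULT_GROUP_SIZES)
    if any(n < 1 for n in group_sizes.values()):
        raise ValueError("group sizes must be >= 1")
    freq_spec = freq_spec or {}
    unknown = set(freq_spec) - set(sv_ids)
    if unknown:
        raise KeyError(f"freq_spec refers to unknown SVs: {sorted(unknown)}")
    for spec in freq_spec.values():
        for p in spec.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"frequency {p} outside [0,1]")

    rng = np.random.default_rng(seed)
    samples: list[str] = []
    group_map: dict[str, str] = {}
    for group in sorted(group_sizes):
        for i in range(group_sizes[group]):
            name = f"{group}_{i:03d}"
            samples.append(name)
            group_map[name] = group

    mat = np.zeros((len(sv_ids), len(samples)), dtype=np.int8)
    for r, sv in enumerate(sv_ids):
        spec = freq_spec.get(sv, {})
        for c, s in enumerate(samples):
            p = spec.get(group_map[s], default_freq)
            mat[r, c] = 1 if rng.random() < p else 0
    if missing_rate > 0:
        miss = rng.random(mat.shape) < missing_rate
        mat[miss] = -1
    geno = pd.DataFrame(mat, index=pd.Index(sv_ids, name="sv"), columns=samples)
    return PopulationTables(genotypes=geno, group_map=group_map)


def simulate_phenotype(
    genotypes: pd.DataFrame,
    causal: list[tuple[str, float]],
    noise_sd: float = 1.0,
    n_confounder_pcs: int = 0,
    seed: int = 0,
    truth: TruthRecord | None = None,
) -> pd.Series:
    """Phenotype = sum(beta * genotype) + structured confounder + noise.

    Missing genotype calls (-1) are mean-imputed before forming the genetic
    value.  The confounder, when requested, is the sum of the top principal
    components of the genotype matrix itself, so that it is genuinely
    confounded with genetic structure (and removable by PC covariates).
    """
    rng = np.random.default_rng(seed)
    for marker, _beta in causal:
        if marker not in genotypes.index:
            raise KeyError(f"causal marker {marker!r} not in genotype matrix")
    g = genotypes.to_numpy(dtype=float)
    g = np.where(g < 0, np.nan, g)
    col_mean = np.nanmean(np.where(np.isnan(g), np.nan, g), axis=1, keepdims=True)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    g = np.where(np.isnan(g), np.broadcast_to(col_mean, g.shape), g)

    y = np.zeros(genotypes.shape[1])
    for marker, beta in causal:
        y += beta * g[genotypes.index.get_loc(marker)]
    if n_confounder_pcs > 0:
        centered = (g - g.mean(axis=1, keepdims=True)).T  # samples x markers
        _u, _s, vt = np.linalg.svd(centered, full_matrices=False)
        scores = centered @ vt[:n_confounder_pcs].T
        y += scores.sum(axis=1)
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=y.shape)
    if truth is not None:
        truth.causal_markers.extend(causal)
    return pd.Series(y, index=genotypes.columns, name="phenotype")
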