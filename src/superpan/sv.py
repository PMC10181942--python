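"""Structural-variant detection, filtering and cross-sample merging.

Detection compares two genomes through unique k-mer anchors chained into
collinear blocks: gaps between consecutive backbone blocks yield insertions,
deletions and copy-number changes; reverse-orientation blocks yield
inversions; collinear blocks that fall off the main chain yield
translocations.  Filtering applies the size, copy-ratio and N-content
rules; merging performs single-linkage clustering of calls whose start and
end breakpoints both lie within a distance tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from statistics import median_low

import edlib

from superpan.genome import revcomp

SVTYPES = ("INS", "DEL", "INV", "DUP", "TRA")


@dataclass
class StructuralVariant:
    """One SV call on the reference frame (0-based, half-open; INS: end==start)."""

    sample: str
    svtype: str
    chrom: str
    start: int
    end: int
    length: int
    seq: str = ""            # inserted / deleted / affected reference sequence
    caller: str = "superpan"
    copy_ratio: float | None = None
    sv_id: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end < start")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.svtype == "DUP" and self.copy_ratio is not None and self.copy_ratio <= 0:
            raise ValueError("copy ratio must be positive")

    @property
    def callset(self) -> str:
        return f"{self.sample}:{self.caller}"


@dataclass(frozen=True)
class CollinearBlock:
    rstart: int
    rend: int
    qstart: int
    qend: int
    orientation: str  # '+' or '-'
    n_anchors: int
    backbone: bool = False


@dataclass
class CollinearBlockSet:
    blocks: list[CollinearBlock]

    def backbone(self) -> list[CollinearBlock]:
        return [b for b in self.blocks if b.backbone]


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        c = counts.get(km, 0)
        counts[km] = c + 1
        if c == 0:
            pos[km] = i
    return {km: p for km, p in pos.items() if counts[km] == 1}


def anchor_chain_align(reference: str, query: str, k: int = 21,
                       max_anchor_gap: int = 500) -> CollinearBlockSet:
    """Chain unique k-mer anchors into collinear blocks.

    Anchors are k-mers occurring exactly once in the reference and exactly
    once in the query (in either orientation, not both).  Forward anchors
    sharing a diagonal (q - r) form forward blocks; reverse anchors sharing
    an anti-diagonal (q + r) form '-' blocks.  The backbone is the
    maximum-anchor-weight subset of forward blocks that is increasing in
    both genomes.
    """
    if k < 11:
        raise ValueError("anchor length k must be >= 11")
    if len(reference) < k or len(query) < k:
        return CollinearBlockSet(blocks=[])
    ref_pos = _unique_kmer_positions(reference, k)
    q_pos = _unique_kmer_positions(query, k)
    qrc = revcomp(query)
    qrc_pos = _unique_kmer_positions(qrc, k)

    fwd: list[tuple[int, int]] = []
    rev: list[tuple[int, int]] = []
    for km, r in ref_pos.items():
        in_f = km in q_pos
        in_r = km in qrc_pos
        if in_f and not in_r:
            fwd.append((r, q_pos[km]))
        elif in_r and not in_f:
            rev.append((r, len(query) - k - qrc_pos[km]))
    fwd.sort()
    rev.sort()

    blocks: list[CollinearBlock] = []

    def flush(run: list[tuple[int, int]], orientation: str) -> None:
        if not run:
            return
        rs = run[0][0]
        re_ = run[-1][0] + k
        qs_vals = [q for _, q in run]
        if orientation == "+":
            qs, qe = run[0][1], run[-1][1] + k
        else:
            qs, qe = min(qs_vals), max(qs_vals) + k
        blocks.append(CollinearBlock(rs, re_, qs, qe, orientation, len(run)))

    # a length-preserving rearrangement (e.g. an inversion) leaves the
    # flanking diagonals equal, so same-diagonal runs also split at large
    # anchor gaps to keep reference intervals non-overlapping
    run: list[tuple[int, int]] = []
    for r, q in fwd:
        if run and ((q - r) != (run[-1][1] - run[-1][0])
                    or r - run[-1][0] > max_anchor_gap):
            flush(run, "+")
            run = []
        run.append((r, q))
    flush(run, "+")

    run = []
    for r, q in rev:
        if run and ((q + r) != (run[-1][1] + run[-1][0])
                    or r - run[-1][0] > max_anchor_gap):
            flush(run, "-")
            run = []
        run.append((r, q))
    flush(run, "-")

    blocks.sort(key=lambda b: (b.rstart, b.qstart))

    # backbone: maximum-weight chain of forward blocks increasing in query
    fwd_blocks = [b for b in blocks if b.orientation == "+"]
    n = len(fwd_blocks)
    best = [0.0] * n
    prev = [-1] * n
    for i in range(n):
        best[i] = float(fwd_blocks[i].n_anchors)
        for j in range(i):
            # chance anchors spanning an SV junction can extend a block by
            # up to k-1 bp into its neighbour; tolerate that much overlap
            if (fwd_blocks[j].qend - k <= fwd_blocks[i].qstart
                    and fwd_blocks[j].rend - k <= fwd_blocks[i].rstart
                    and fwd_blocks[j].rstart < fwd_blocks[i].rstart
                    and best[j] + fwd_blocks[i].n_anchors > best[i]):
                best[i] = best[j] + fwd_blocks[i].n_anchors
                prev[i] = j
    chain: set[int] = set()
    if n:
        i = max(range(n), key=lambda x: best[x])
        while i != -1:
            chain.add(i)
            i = prev[i]
    backbone_ids = {id(fwd_blocks[i]) for i in chain}
    final = [replace(b, backbone=(id(b) in backbone_ids)) for b in blocks]
    return CollinearBlockSet(blocks=final)


def _is_tandem_multiple(gap_seq: str, unit_seq: str, m: int, tol: float = 0.2) -> bool:
    """Does gap_seq look like m tandem copies of unit_seq?"""
    if not unit_seq or m < 2:
        return False
    d = edlib.align(gap_seq, unit_seq * m, task="distance")["editDistance"]
    return d / max(1, len(gap_seq)) < tol


def call_svs_from_blocks(
    blocks: CollinearBlockSet,
    reference: str,
    query: str,
    sample: str = "query",
    chrom: str = "ref",
    caller: str = "superpan",
    min_block_anchors: int = 2,
    min_emit: int = 20,
) -> list[StructuralVariant]:
    """Derive SV calls from the collinear block structure.

    Between consecutive backbone blocks: a longer query gap is an INS, a
    longer reference gap a DEL, and gaps on both sides whose query side is
    an integer tandem multiple (or submultiple) of the reference side are
    DUP/CNV with the corresponding copy ratio.  Reverse blocks are INV;
    forward blocks off the backbone are TRA (their reference span is the
    moved segment).  ``min_emit`` suppresses micro-gaps caused by anchor
    attrition around substitutions.
    """
    svs: list[StructuralVariant] = []
    usable = [b for b in blocks.blocks if b.n_anchors >= min_block_anchors]
    backbone = sorted((b for b in usable if b.backbone), key=lambda b: b.rstart)
    inv_blocks = [b for b in usable if b.orientation == "-"]
    tra_blocks = [b for b in usable if b.orientation == "+" and not b.backbone]

    for b in inv_blocks:
        svs.append(StructuralVariant(
            sample, "INV", chrom, b.rstart, b.rend, b.rend - b.rstart,
            seq=reference[b.rstart:b.rend], caller=caller))
    for b in tra_blocks:
        svs.append(StructuralVariant(
            sample, "TRA", chrom, b.rstart, b.rend, b.rend - b.rstart,
            seq=reference[b.rstart:b.rend], caller=caller))

    # sentinel blocks pin the walk to the sequence ends
    sent_l = CollinearBlock(0, 0, 0, 0, "+", 0, True)
    sent_r = CollinearBlock(len(reference), len(reference), len(query), len(query),
                            "+", 0, True)
    walk = [sent_l] + backbone + [sent_r]
    covered = [(b.rstart, b.rend) for b in inv_blocks + tra_blocks]
    covered_q = [(b.qstart, b.qend) for b in inv_blocks + tra_blocks]

    for prev_b, nxt in zip(walk, walk[1:]):
        rgap = max(0, nxt.rstart - prev_b.rend)
        qgap = max(0, nxt.qstart - prev_b.qend)
        rint = (min(prev_b.rend, nxt.rstart), nxt.rstart)
        qint = (min(prev_b.qend, nxt.qstart), nxt.qstart)
        # gap explained by an inversion or translocation block?
        r_expl = sum(max(0, min(rint[1], e) - max(rint[0], s)) for s, e in covered)
        q_expl = sum(max(0, min(qint[1], e) - max(qint[0], s)) for s, e in covered_q)
        rgap_eff = rgap - r_expl
        qgap_eff = qgap - q_expl
        if rgap_eff >= min_emit and qgap_eff >= min_emit:
            ref_gap = reference[rint[0]:rint[1]]
            q_gap = query[qint[0]:qint[1]]
            m_up = round(qgap_eff / rgap_eff)
            m_dn = round(rgap_eff / qgap_eff) if qgap_eff else 0
            if m_up >= 2 and _is_tandem_multiple(q_gap, ref_gap, m_up):
                svs.append(StructuralVariant(
                    sample, "DUP", chrom, rint[0], rint[1], rgap,
                    seq=ref_gap, caller=caller, copy_ratio=float(m_up)))
                continue
            if m_dn >= 2 and _is_tandem_multiple(ref_gap, q_gap, m_dn):
                svs.append(StructuralVariant(
                    sample, "DUP", chrom, rint[0], rint[1], rgap,
                    seq=ref_gap, caller=caller, copy_ratio=1.0 / m_dn))
                continue
        diff = qgap_eff - rgap_eff
        if diff >= min_emit:
            ins_start = qint[0] + max(0, rgap_eff) // 2
            svs.append(StructuralVariant(
                sample, "INS", chrom, rint[0], rint[0], diff,
                seq=query[ins_start:ins_start + diff], caller=caller))
        elif -diff >= min_emit:
            del_start = rint[0] + max(0, qgap_eff) // 2
            svs.append(StructuralVariant(
                sample, "DEL", chrom, del_start, del_start - diff, -diff,
                seq=reference[del_start:del_start - diff], caller=caller))
    svs.sort(key=lambda s: (s.chrom, s.start, s.end, s.svtype))
    return svs


def call_svs(reference: str, query: str, sample: str = "query",
             chrom: str = "ref", k: int = 21, caller: str | None = None,
             **kwargs) -> list[StructuralVariant]:
    """Convenience: anchor-chain then call, tagging the caller with k."""
    blocks = anchor_chain_align(reference, query, k=k)
    return call_svs_from_blocks(
        blocks, reference, query, sample=sample, chrom=chrom,
        caller=caller or f"superpan-k{k}", **kwargs)


# ----------------------------------------------------------------- filtering

def filter_svs(
    svs: list[StructuralVariant],
    min_len: int = 50,
    max_inv_len: int = 1_000_000,
    cnv_ratio_bounds: tuple[float, float] = (0.5, 2.0),
) -> list[StructuralVariant]:
    """Apply the size, copy-ratio and N-content retention rules.

    INS/DEL/TRA are kept when strictly longer than ``min_len``; INV when
    strictly shorter than ``max_inv_len``; DUP/CNV when strictly longer
    than ``min_len`` with copy ratio >= upper or <= lower bound; any SV
    whose recorded sequence contains an N is dropped.
    """
    lo, hi = cnv_ratio_bounds
    kept = []
    for sv in svs:
        if "N" in sv.seq.upper():
            continue
        if sv.svtype in ("INS", "DEL", "TRA"):
            if sv.length <= min_len:
                continue
        elif sv.svtype == "INV":
            if sv.length >= max_inv_len:
                continue
        elif sv.svtype == "DUP":
            if sv.length <= min_len:
                continue
            if sv.copy_ratio is not None and lo < sv.copy_ratio < hi:
                continue
        kept.append(sv)
    return kept


# ------------------------------------------------------------------- merging

@dataclass
class MergedSV:
    sv_id: str
    chrom: str
    start: int
    end: int
    svtype: str
    length: int
    members: list[StructuralVariant] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len({m.callset for m in self.members})

    @property
    def samples(self) -> set[str]:
        return {m.sample for m in self.members}


def merge_svs(
    call_sets: list[list[StructuralVariant]],
    max_dist: int = 50,
    min_support: int = 1,
    min_size: int = 0,
    require_type: bool = False,
    require_strand: bool = False,
) -> list[MergedSV]:
    """Single-linkage breakpoint merging across call sets.

    Two calls on the same chromosome link when |start1-start2| <= max_dist
    AND |end1-end2| <= max_dist (and same type when ``require_type``).  The
    cluster representative is the member of median length, ties broken by
    lowest (chrom, start).  Clusters below ``min_support`` distinct call-set
    identities or whose representative is shorter than ``min_size`` drop.
    ``require_strand`` is accepted for parameter-set compatibility; calls
    carry no strand so it has no effect.
    """
    del require_strand
    all_svs = sorted(
        (sv for cs in call_sets for sv in cs),
        key=lambda s: (s.chrom, s.start, s.end, s.svtype, s.sample, s.caller))
    n = len(all_svs)
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

    # sorted by start: pairs further than max_dist in start can stop early
    for i in range(n):
        a = all_svs[i]
        for j in range(i + 1, n):
            b = all_svs[j]
            if b.chrom != a.chrom or b.start - a.start > max_dist:
                break
            if abs(a.end - b.end) > max_dist:
                continue
            if require_type and a.svtype != b.svtype:
                continue
            union(i, j)

    clusters: dict[int, list[StructuralVariant]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(all_svs[i])

    merged: list[MergedSV] = []
    for members in clusters.values():
        med_len = median_low(sorted(m.length for m in members))
        rep = min((m for m in members if m.length == med_len),
                  key=lambda m: (m.chrom, m.start, m.end))
        rec = MergedSV(
            sv_id="", chrom=rep.chrom, start=rep.start, end=rep.end,
            svtype=rep.svtype, length=rep.length, members=members)
        if rec.support < min_support or rep.length < min_size:
            continue
        merged.append(rec)
    merged.sort(key=lambda m: (m.chrom, m.start, m.end, m.svtype))
    for i, m in enumerate(merged):
        m.sv_id = f"msv{i:06d}"
    return merged


def presence_matrix(merged: list[MergedSV], samples: list[str]):
    """SV x sample presence/absence (1/0) matrix from merge membership."""
    import pandas as pd

    if not merged:
        raise ValueError("no merged SVs")
    data = {
        m.sv_id: [1 if s in m.samples else 0 for s in samples] for m in merged
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=list(samples)) \
        .rename_axis("sv")
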