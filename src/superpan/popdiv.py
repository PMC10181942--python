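"""Population presence-frequency divergence and SV consequence annotation.

Presence frequency of an SV in a group counts only genotyped accessions
(missing calls leave both numerator and denominator).  The divergence scan
compares the wild group against the pooled cultivated (SLC + SLL) groups
with a two-sided Fisher exact test on the present/absent x group table;
p-values are Benjamini-Hochberg adjusted and SVs with FDR strictly below
0.01 are flagged as highly divergent.  Consequence annotation classifies
coding indels by length modulo 3 and whole-exon coverage, and reports
upstream hits within a promoter-proximal window of the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from superpan.genome import GeneModel

MISSING = -1

WILD_GROUP = "wild"
CULTIVATED_GROUPS = ("SLC", "SLL")


def group_frequencies(genotypes: pd.DataFrame,
                      group_map: dict[str, str]) -> pd.DataFrame:
    """Per-SV, per-group presence counts and frequency.

    Returns a frame indexed by SV with columns ``{group}_present``,
    ``{group}_absent``, ``{group}_missing`` and ``{group}_freq`` (NaN when
    every call in the group is missing).
    """
    unassigned = [s for s in genotypes.columns if s not in group_map]
    if unassigned:
        raise ValueError(f"samples not assigned to any group: {unassigned}")
    out = {}
    for group in sorted(set(group_map.values())):
        cols = [s for s in genotypes.columns if group_map[s] == group]
        sub = genotypes[cols]
        present = (sub == 1).sum(axis=1)
        absent = (sub == 0).sum(axis=1)
        miss = (sub == MISSING).sum(axis=1)
        denom = present + absent
        with np.errstate(invalid="ignore"):
            freq = present / denom.replace(0, np.nan)
        out[f"{group}_present"] = present
        out[f"{group}_absent"] = absent
        out[f"{group}_missing"] = miss
        out[f"{group}_freq"] = freq
    return pd.DataFrame(out, index=genotypes.index)


def fisher_scan(freqs: pd.DataFrame,
                group_a: str = WILD_GROUP,
                groups_b: tuple[str, ...] = CULTIVATED_GROUPS) -> pd.DataFrame:
    """Two-sided Fisher exact p per SV, group_a vs pooled groups_b.

    The 2x2 table is (present, absent) x (group_a, pooled b).  An SV with
    an empty table (no genotyped sample on one side) gets p = 1 and a
    warning flag.
    """
    a_p = freqs[f"{group_a}_present"]
    a_a = freqs[f"{group_a}_absent"]
    b_p = sum(freqs[f"{g}_present"] for g in groups_b)
    b_a = sum(freqs[f"{g}_absent"] for g in groups_b)
    pvals = np.ones(len(freqs))
    flagged = np.zeros(len(freqs), dtype=bool)
    for i, (ap, aa, bp, ba) in enumerate(zip(a_p, a_a, b_p, b_a)):
        if (ap + aa) == 0 or (bp + ba) == 0:
            flagged[i] = True
            continue
        _, p = stats.fisher_exact([[ap, aa], [bp, ba]], alternative="two-sided")
        pvals[i] = min(1.0, p)
    if flagged.any():
        warnings.warn(f"{int(flagged.sum())} SVs had an empty group and got p=1",
                      stacklevel=2)
    return pd.DataFrame({
        "a_present": a_p, "a_absent": a_a,
        "b_present": b_p, "b_absent": b_a,
        "p": pvals, "empty_group": flagged,
    }, index=freqs.index)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, reported in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.min(p) <= 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def divergent_svs(qvalues, threshold: float = 0.01) -> np.ndarray:
    """Highly divergent flag: q strictly below the FDR threshold."""
    return np.asarray(qvalues) < threshold


@dataclass
class DivergenceResult:
    table: pd.DataFrame  # counts, p, q, divergent

    @property
    def n_divergent(self) -> int:
        return int(self.table["divergent"].sum())


def divergence_scan(genotypes: pd.DataFrame, group_map: dict[str, str],
                    fdr: float = 0.01) -> DivergenceResult:
    """Full scan: frequencies -> Fisher -> BH -> divergence flags."""
    freqs = group_frequencies(genotypes, group_map)
    fisher = fisher_scan(freqs)
    q = bh_fdr(fisher["p"].to_numpy())
    table = pd.concat([freqs, fisher.drop(columns="empty_group")], axis=1)
    table["q"] = q
    table["divergent"] = divergent_svs(q, fdr)
    table["empty_group"] = fisher["empty_group"]
    return DivergenceResult(table=table)


def frequency_spectrum(freqs: pd.DataFrame, bin_width: float = 0.25) -> pd.DataFrame:
    """Histogram of presence frequencies per group.

    Bins are half-open ([0,w), [w,2w), ...) except the last, which closes
    at 1.0; undefined (all-missing) frequencies are excluded.
    """
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    groups = sorted({c[:-5] for c in freqs.columns if c.endswith("_freq")})
    counts = {}
    for g in groups:
        vals = freqs[f"{g}_freq"].dropna().to_numpy()
        h, _ = np.histogram(vals, bins=edges)
        counts[g] = h
    labels = [f"[{a:g},{b:g})" for a, b in zip(edges[:-2], edges[1:-1])]
    labels.append(f"[{edges[-2]:g},1]")
    return pd.DataFrame(counts, index=pd.Index(labels, name="bin"))


# ------------------------------------------------------- consequence rules

@dataclass(frozen=True)
class Consequence:
    sv_id: str
    gene_id: str
    region: str       # 'CDS' or 'upstream'
    effect: str       # frameshift | exon_loss | inframe_insertion |
                      # inframe_deletion | none
    detail: str = ""


def _classify_one(sv, gene: GeneModel) -> Consequence | None:
    """CDS overlap rules for one SV/gene pair; None when no hit."""
    s, e = sv.start, sv.end
    if sv.svtype == "INS":
        cds_hit = any(xs <= s < xe for xs, xe in gene.exons)
        if cds_hit:
            if sv.length % 3:
                return Consequence(sv.sv_id, gene.gene_id, "CDS", "frameshift",
                                   f"len%3={sv.length % 3}")
            return Consequence(sv.sv_id, gene.gene_id, "CDS", "inframe_insertion",
                               "len%3=0")
    elif sv.svtype == "DEL":
        lost = [i for i, (xs, xe) in enumerate(gene.exons) if s <= xs and e >= xe]
        overlap = sum(max(0, min(e, xe) - max(s, xs)) for xs, xe in gene.exons)
        if lost:
            return Consequence(sv.sv_id, gene.gene_id, "CDS", "exon_loss",
                               f"exons={','.join(map(str, lost))}")
        if overlap > 0:
            if overlap % 3:
                return Consequence(sv.sv_id, gene.gene_id, "CDS", "frameshift",
                                   f"len%3={overlap % 3}")
            return Consequence(sv.sv_id, gene.gene_id, "CDS", "inframe_deletion",
                               "len%3=0")
    else:  # INV / DUP / TRA: report the overlap, no frame arithmetic
        overlap = sum(max(0, min(e, xe) - max(s, xs)) for xs, xe in gene.exons)
        if overlap > 0:
            return Consequence(sv.sv_id, gene.gene_id, "CDS", "none",
                               f"{sv.svtype}_overlap={overlap}")
    return None


def annotate_consequences(svs, genes: list[GeneModel],
                          upstream_window: int = 3000) -> list[Consequence]:
    """Classify SV effects on gene models.

    Coding indels: length mod 3 != 0 is a frameshift; mod 3 == 0 an
    in-frame insertion/deletion; a deletion covering at least one whole
    coding exon is exon_loss (precedence over frame arithmetic).  SVs
    within ``upstream_window`` bp of the TSS on the gene's 5' side are
    upstream hits with effect 'none'.  One record per (SV, gene) pair.
    """
    out: list[Consequence] = []
    for sv in svs:
        for gene in genes:
            if gene.chrom != sv.chrom:
                continue
            if not gene.exons:
                warnings.warn(f"gene {gene.gene_id} has no CDS; skipped",
                              stacklevel=2)
                continue
            hit = _classify_one(sv, gene)
            if hit is not None:
                out.append(hit)
                continue
            # upstream: window 5' of the TSS on the gene's strand
            if gene.strand == "+":
                ws, we = gene.start - upstream_window, gene.start
            else:
                ws, we = gene.end, gene.end + upstream_window
            sv_lo, sv_hi = sv.start, max(sv.end, sv.start + 1)
            if sv_lo < we and sv_hi > ws and not (sv_lo < gene.end and sv_hi > gene.start):
                out.append(Consequence(sv.sv_id, gene.gene_id, "upstream", "none"))
    return out


def consequences_frame(cons: list[Consequence]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.sv_id, c.gene_id, c.region, c.effect, c.detail) for c in cons],
        columns=["sv", "gene", "region", "effect", "detail"])
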