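"""Readers and writers for the standard formats.

Internal coordinates are 0-based half-open; GFF3 and VCF are converted at
the boundary (1-based, closed for GFF3; 1-based POS for VCF).  FASTA goes
through Biopython; sequences are normalised to upper case on read.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from superpan.genome import AnnotatedGenome, GeneModel

log = logging.getLogger("superpan")


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered id -> sequence dict.  Duplicate ids fail."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq)
        if not seq.isupper():
            log.info("FASTA %s: normalising lowercase bases to uppercase", rec.id)
            seq = seq.upper()
        records[rec.id] = seq
    return records


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path), "fasta",
    )


# ---------------------------------------------------------------- GFF3

def write_gff3(path: str | Path, genome: AnnotatedGenome) -> None:
    """Write gene/mRNA/exon/CDS features (1-based closed, per the format)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.name} 1 {genome.length}\n")
        for g in genome.sorted_genes():
            chrom = g.chrom
            attrs = f"ID={g.gene_id}"
            if g.family:
                attrs += f";family={g.family}"
            fh.write(f"{chrom}\tsuperpan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            mrna = f"{g.gene_id}.1"
            fh.write(f"{chrom}\tsuperpan\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n")
            # CDS phase: bases to remove from the reading-frame start
            exons = list(g.exons) if g.strand == "+" else list(g.exons)[::-1]
            phase = 0
            rows = []
            for s, e in exons:
                rows.append((s, e, phase))
                phase = (3 - ((e - s) - phase) % 3) % 3
            for i, (s, e, ph) in enumerate(sorted(rows)):
                fh.write(f"{chrom}\tsuperpan\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={mrna}.exon{i + 1};Parent={mrna}\n")
            for s, e, ph in sorted(rows):
                fh.write(f"{chrom}\tsuperpan\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                         f"{ph}\tID={mrna}.cds;Parent={mrna}\n")


def read_gff3(path: str | Path, seq: str | None = None,
              name: str | None = None) -> AnnotatedGenome:
    """Parse gene models from GFF3 (gene/mRNA/CDS hierarchy).

    CDS intervals become the gene's exon set (this package models coding
    exons only).  A CDS or mRNA whose Parent was never declared fails with
    the offending line number.
    """
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            a = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            s, e = int(start) - 1, int(end)
            if ftype == "gene":
                genes[a["ID"]] = {
                    "chrom": chrom, "start": s, "end": e, "strand": strand,
                    "family": a.get("family"), "cds": [],
                }
            elif ftype == "mRNA":
                parent = a.get("Parent")
                if parent not in genes:
                    raise ValueError(f"{path}:{lineno}: mRNA parent {parent!r} undeclared")
                mrna_parent[a["ID"]] = parent
            elif ftype == "CDS":
                parent = a.get("Parent")
                gene_id = mrna_parent.get(parent, parent)
                if gene_id not in genes:
                    raise ValueError(f"{path}:{lineno}: CDS parent {parent!r} undeclared")
                genes[gene_id]["cds"].append((s, e))
    models = []
    for gid, g in genes.items():
        exons = tuple(sorted(g["cds"])) or ((g["start"], g["end"]),)
        models.append(GeneModel(
            gene_id=gid, chrom=g["chrom"], start=g["start"], end=g["end"],
            strand=g["strand"], exons=exons, family=g["family"]))
    models.sort(key=lambda m: (m.chrom, m.start))
    genome_name = name or (models[0].chrom if models else Path(path).stem)
    return AnnotatedGenome(name=genome_name, seq=seq or "", genes=models)


# ---------------------------------------------------------------- VCF (SVs)

VCF_HEADER = """\
##fileformat=VCFv4.2
##source=superpan
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length in bp">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive)">
##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting call sets">
##ALT=<ID=INS,Description="Insertion">
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=INV,Description="Inversion">
##ALT=<ID=DUP,Description="Duplication/CNV">
##ALT=<ID=TRA,Description="Translocation">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Presence (1) / absence (0)">
"""


def write_sv_vcf(path: str | Path, svs, samples: list[str] | None = None,
                 genotypes: pd.DataFrame | None = None,
                 contigs: dict[str, int] | None = None) -> None:
    """Write SVs (optionally multi-sample presence/absence) as VCF 4.2.

    ``svs`` is an iterable with ``chrom``, ``start``, ``end``, ``svtype``,
    ``length`` and optionally ``sv_id``/``support`` attributes (both the
    caller's StructuralVariant and MergedSV qualify).  Genotypes, when
    given, are an SV x sample frame of 1/0/-1 (missing written as '.').
    """
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if samples:
            cols += ["FORMAT"] + list(samples)
        fh.write("\t".join(cols) + "\n")
        for i, sv in enumerate(svs):
            sv_id = getattr(sv, "sv_id", None) or f"sv{i:06d}"
            end_1 = max(sv.end, sv.start + 1)  # INS: END = POS
            info = (f"SVTYPE={sv.svtype};SVLEN={sv.length};END={end_1}")
            support = getattr(sv, "support", None)
            if support is not None:
                info += f";SUPPORT={support}"
            row = [sv.chrom, str(sv.start + 1), sv_id, "N", f"<{sv.svtype}>",
                   ".", "PASS", info]
            if samples:
                row.append("GT")
                if genotypes is None:
                    raise ValueError("samples given without genotypes")
                for s in samples:
                    v = genotypes.loc[sv_id, s]
                    row.append("." if v < 0 else str(int(v)))
            fh.write("\t".join(row) + "\n")


def read_sv_vcf(path: str | Path):
    """Read an SV VCF into (records, genotype frame or None).

    Records are dicts with internal 0-based half-open coordinates; genotype
    values are 1/0/-1.  A record without SVTYPE fails.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    geno_rows = []
    for var in vcf:
        svtype = var.INFO.get("SVTYPE")
        if svtype is None:
            raise ValueError(f"record {var.CHROM}:{var.POS} lacks SVTYPE")
        end_1 = var.INFO.get("END", var.POS)
        svlen = var.INFO.get("SVLEN")
        length = abs(int(svlen)) if svlen is not None else int(end_1) - var.POS + 1
        start0 = var.POS - 1
        end0 = start0 if svtype == "INS" else int(end_1)
        records.append({
            "sv_id": var.ID, "chrom": var.CHROM, "start": start0,
            "end": end0, "svtype": svtype, "length": length,
            "support": var.INFO.get("SUPPORT"),
        })
        if samples:
            row = []
            for gt in var.genotypes:
                allele = gt[0]
                row.append(-1 if allele in (-1, None) else int(allele))
            geno_rows.append(row)
    geno = None
    if samples:
        geno = pd.DataFrame(
            geno_rows, index=[r["sv_id"] for r in records], columns=samples,
            dtype=int)
        geno.index.name = "sv"
    return records, geno


# ---------------------------------------------------------------- TSV helpers

def write_tsv(path: str | Path, frame: pd.DataFrame, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_group_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("group table needs sample and group columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
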