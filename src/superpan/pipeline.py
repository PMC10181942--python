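"""End-to-end pipeline: simulate -> pangene -> sv -> divergence -> ltr -> gwas.

Every stage writes plain TSV/FASTA/GFF3/VCF artifacts plus a JSON
provenance sidecar (parameters, seed, package version), and the whole run
is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

import superpan
from superpan import assoc, io, ltr, pangene, popdiv, sv as svmod
from superpan.simulate import (
    DEFAULT_GROUP_SIZES, SV_TYPES, CladeConfig, evolve_clade,
    simulate_ancestor, simulate_phenotype, simulate_population,
)

log = logging.getLogger("superpan")


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StageToggles(_Block):
    simulate: bool = True
    pangene: bool = True
    sv: bool = True
    divergence: bool = True
    ltrdate: bool = True
    gwas: bool = True


class SimulateParams(_Block):
    n_genomes: int = 6
    genome_length: int = 120_000
    n_genes: int = 40
    substitution_rate_per_branch: float = 0.002
    family_loss_prob: float = 0.05
    family_gain_rate: float = 1.0
    sv_per_type_per_branch: int = 2
    sv_min_len: int = 100
    sv_max_len: int = 2_000
    n_ltr_elements: int = 30
    ltr_age_min_myr: float = 0.0
    ltr_age_max_myr: float = 3.0
    tree: str | None = None


class PangeneParams(_Block):
    n_permutations: int = 100
    use_rescue: bool = False
    min_coverage: float = 0.80
    min_identity: float = 0.80


class SVParams(_Block):
    k_values: tuple[int, ...] = (21, 31)
    min_len: int = 50
    max_inv_len: int = 1_000_000
    cnv_ratio_low: float = 0.5
    cnv_ratio_high: float = 2.0
    merge_max_dist: int = 50
    merge_min_support: int = 1


class DivergenceParams(_Block):
    fdr: float = 0.01
    upstream_window: int = 3000
    missing_rate: float = 0.05
    n_divergent: int = 5
    wild_freq: float = 0.1
    cultivated_freq: float = 0.9
    group_sizes: dict[str, int] = dict(DEFAULT_GROUP_SIZES)


class LtrParams(_Block):
    mu: float = 1.3e-8
    method: str = "uncorrected"
    bin_width_years: float = 250_000.0


class GwasParams(_Block):
    maf_min: float = 0.01
    missing_max: float = 0.1
    n_pcs: int = 5
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.1
    peak_flank: int = 800_000
    causal_beta: float = 0.8
    noise_sd: float = 1.0


class PipelineConfig(_Block):
    out_dir: str = "superpan_out"
    seed: int = 0
    log_level: str = "INFO"
    stages: StageToggles = StageToggles()
    simulate: SimulateParams = SimulateParams()
    pangene: PangeneParams = PangeneParams()
    sv: SVParams = SVParams()
    divergence: DivergenceParams = DivergenceParams()
    ltrdate: LtrParams = LtrParams()
    gwas: GwasParams = GwasParams()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)


def _sidecar(path: Path, stage: str, params: dict, seed: int) -> None:
    doc = {
        "stage": stage,
        "parameters": params,
        "seed": seed,
        "superpan_version": superpan.__version__,
    }
    path.write_text(json.dumps(doc, indent=2, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the toggled stages; returns the artifact directory.

    A stage that is toggled off leaves no outputs; downstream stages read
    the in-memory products of earlier stages, so turning an upstream stage
    off disables its dependants too.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    t0 = time.time()
    sp = config.simulate
    clade_cfg = CladeConfig(
        n_genomes=sp.n_genomes, genome_length=sp.genome_length,
        n_genes=sp.n_genes,
        substitution_rate_per_branch=sp.substitution_rate_per_branch,
        family_loss_prob=sp.family_loss_prob,
        family_gain_rate=sp.family_gain_rate,
        sv_counts_per_branch={t: sp.sv_per_type_per_branch for t in SV_TYPES},
        sv_size_ranges={t: (sp.sv_min_len, sp.sv_max_len) for t in SV_TYPES},
        n_ltr_elements=sp.n_ltr_elements,
        ltr_age_range=(sp.ltr_age_min_myr, sp.ltr_age_max_myr),
        seed=config.seed,
    )

    genomes = truth = ancestor = None
    if config.stages.simulate:
        log.info("stage simulate: %d genomes of %d bp", sp.n_genomes,
                 sp.genome_length)
        ancestor = simulate_ancestor(clade_cfg)
        genomes, truth = evolve_clade(ancestor, clade_cfg, tree=sp.tree)
        sim_dir = out / "simulate"
        sim_dir.mkdir(exist_ok=True)
        io.write_fasta(sim_dir / "ancestor.fa", {ancestor.name: ancestor.seq})
        io.write_gff3(sim_dir / "ancestor.gff3", ancestor)
        for g in genomes:
            io.write_fasta(sim_dir / f"{g.name}.fa", {g.name: g.seq})
            io.write_gff3(sim_dir / f"{g.name}.gff3", g)
        pd.DataFrame(
            [(s.sample, s.svtype, s.start, s.end, s.length) for s in truth.true_svs],
            columns=["sample", "type", "start", "end", "length"],
        ).to_csv(sim_dir / "truth_svs.tsv", sep="\t", index=False)
        pd.DataFrame(
            truth.true_family_events, columns=["branch", "family", "event"],
        ).to_csv(sim_dir / "truth_family_events.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(e.element_id, e.genome, e.superfamily, e.age_myr, e.seq5, e.seq3)
             for e in truth.ltr_elements],
            columns=["element", "genome", "superfamily", "age_myr", "seq5", "seq3"],
        ).to_csv(sim_dir / "ltr_pairs.tsv", sep="\t", index=False)
        _sidecar(sim_dir / "provenance.json", "simulate",
                 sp.model_dump(), config.seed)

    if config.stages.pangene and genomes is not None:
        log.info("stage pangene")
        pg_dir = out / "pangene"
        pg_dir.mkdir(exist_ok=True)
        fam = pangene.families_from_annotations(genomes)
        if config.pangene.use_rescue:
            pam = pangene.rescue_unannotated(
                fam, {g.name: g for g in genomes},
                min_coverage=config.pangene.min_coverage,
                min_identity=config.pangene.min_identity)
        else:
            pam = pangene.presence_matrix_from_families(
                fam, [g.name for g in genomes])
        cls = pangene.classify_families(pam)
        curve = pangene.growth_curves(
            pam, n_permutations=config.pangene.n_permutations, seed=config.seed)
        pam.to_csv(pg_dir / "presence_absence.tsv", sep="\t")
        pd.DataFrame({
            "class": ["core", "dispensable", "specific"],
            "n_families": [len(cls.core), len(cls.dispensable), len(cls.specific)],
            "proportion": [cls.proportions[k] for k in
                           ("core", "dispensable", "specific")],
        }).to_csv(pg_dir / "classification.tsv", sep="\t", index=False)
        curve.to_frame().to_csv(pg_dir / "growth_curves.tsv", sep="\t", index=False)
        _sidecar(pg_dir / "provenance.json", "pangene",
                 config.pangene.model_dump(), config.seed)

    merged = None
    if config.stages.sv and genomes is not None:
        log.info("stage sv: %d genomes x k=%s", len(genomes),
                 list(config.sv.k_values))
        sv_dir = out / "sv"
        sv_dir.mkdir(exist_ok=True)
        call_sets = []
        for g in genomes:
            for k in config.sv.k_values:
                calls = svmod.call_svs(ancestor.seq, g.seq, sample=g.name,
                                       chrom="ancestor", k=k)
                call_sets.append(svmod.filter_svs(
                    calls, min_len=config.sv.min_len,
                    max_inv_len=config.sv.max_inv_len,
                    cnv_ratio_bounds=(config.sv.cnv_ratio_low,
                                      config.sv.cnv_ratio_high)))
        merged = svmod.merge_svs(call_sets,
                                 max_dist=config.sv.merge_max_dist,
                                 min_support=config.sv.merge_min_support)
        samples = [g.name for g in genomes]
        pres = svmod.presence_matrix(merged, samples) if merged else None
        if pres is not None:
            io.write_sv_vcf(sv_dir / "merged.vcf", merged, samples=samples,
                            genotypes=pres,
                            contigs={"ancestor": ancestor.length})
            pres.to_csv(sv_dir / "presence.tsv", sep="\t")
        pd.DataFrame(
            [(m.sv_id, m.chrom, m.start, m.end, m.svtype, m.length, m.support)
             for m in merged],
            columns=["sv", "chrom", "start", "end", "type", "length", "support"],
        ).to_csv(sv_dir / "merged.tsv", sep="\t", index=False)
        _sidecar(sv_dir / "provenance.json", "sv", config.sv.model_dump(),
                 config.seed)

    pop = None
    if config.stages.divergence and merged:
        log.info("stage divergence: %d merged SVs", len(merged))
        dv_dir = out / "divergence"
        dv_dir.mkdir(exist_ok=True)
        dp = config.divergence
        rng = np.random.default_rng(config.seed + 11)
        ids = [m.sv_id for m in merged]
        chosen = list(rng.choice(ids, size=min(dp.n_divergent, len(ids)),
                                 replace=False))
        freq_spec = {s: {"wild": dp.wild_freq, "SLC": dp.cultivated_freq,
                         "SLL": dp.cultivated_freq} for s in chosen}
        pop = simulate_population(
            ids, group_sizes=dp.group_sizes, freq_spec=freq_spec,
            missing_rate=dp.missing_rate, seed=config.seed + 12)
        res = popdiv.divergence_scan(pop.genotypes, pop.group_map, fdr=dp.fdr)
        res.table.to_csv(dv_dir / "divergence.tsv", sep="\t")
        div_ids = set(res.table.index[res.table["divergent"]])
        div_svs = [m for m in merged if m.sv_id in div_ids]
        cons = popdiv.annotate_consequences(
            div_svs, ancestor.genes, upstream_window=dp.upstream_window)
        popdiv.consequences_frame(cons).to_csv(
            dv_dir / "consequences.tsv", sep="\t", index=False)
        pd.DataFrame({"sample": list(pop.group_map),
                      "group": list(pop.group_map.values())}).to_csv(
            dv_dir / "groups.tsv", sep="\t", index=False)
        _sidecar(dv_dir / "provenance.json", "divergence", dp.model_dump(),
                 config.seed)

    if config.stages.ltrdate and truth is not None and truth.ltr_elements:
        log.info("stage ltrdate: %d elements", len(truth.ltr_elements))
        lt_dir = out / "ltrdate"
        lt_dir.mkdir(exist_ok=True)
        elements = ltr.elements_from_truth(truth)
        dated = ltr.date_elements(elements, mu=config.ltrdate.mu,
                                  method=config.ltrdate.method)
        ltr.write_ltr_tables(str(lt_dir / "ltr"), dated,
                             bin_width=config.ltrdate.bin_width_years)
        _sidecar(lt_dir / "provenance.json", "ltrdate",
                 config.ltrdate.model_dump(), config.seed)

    if config.stages.gwas and pop is not None and len(pop.genotypes) >= 2:
        log.info("stage gwas")
        gw_dir = out / "gwas"
        gw_dir.mkdir(exist_ok=True)
        gp = config.gwas
        rng = np.random.default_rng(config.seed + 21)
        causal_id = str(rng.choice(pop.genotypes.index))
        pheno = simulate_phenotype(
            pop.genotypes, [(causal_id, gp.causal_beta)],
            noise_sd=gp.noise_sd, seed=config.seed + 22)
        ms = assoc.MarkerSet(pop.genotypes)
        ms = assoc.filter_markers(ms, maf_min=gp.maf_min,
                                  missing_max=gp.missing_max)
        n_pcs = min(gp.n_pcs, max(1, ms.genotypes.shape[0] - 1))
        cov = assoc.pca_covariates(ms, n_pcs) if len(ms.genotypes) > n_pcs else None
        results = assoc.AssociationModel(ms, pheno, covariates=cov).fit()
        n_eff, threshold = assoc.effective_tests(
            ms, window=gp.prune_window, step=gp.prune_step, r2_max=gp.prune_r2)
        peaks = results.peaks(threshold, window=gp.peak_flank)
        results.table.to_csv(gw_dir / "association.tsv", sep="\t")
        pd.DataFrame(
            [(p.chrom, p.lead_pos, p.lead_marker, p.lead_p, p.source,
              len(p.members)) for p in peaks],
            columns=["chrom", "lead_pos", "lead_marker", "lead_p", "source",
                     "n_members"],
        ).to_csv(gw_dir / "peaks.tsv", sep="\t", index=False)
        pd.DataFrame({
            "n_eff": [n_eff], "threshold": [threshold],
            "causal_marker": [causal_id], "causal_beta": [gp.causal_beta],
        }).to_csv(gw_dir / "threshold.tsv", sep="\t", index=False)
        _sidecar(gw_dir / "provenance.json", "gwas", gp.model_dump(),
                 config.seed)

    log.info("pipeline complete in %.1fs -> %s", time.time() - t0, out)
    return out
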