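"""End-to-end orchestration and sequencing summary statistics.

``run_pipeline`` drives the whole synthetic study: simulate the
sib-structured population, predict breeding values and pick the extreme
bulks, simulate pooled depths, score and filter loci, run the chi-square
bulk screen with multiplicity control, test candidate genotypes against
the trait (ANOVA, frequencies, effect decomposition), search SNP
networks, and compare relative expression between genotype groups of the
top candidate.  Every output file carries the package version, the run
seed and a configuration hash in its header; two runs with the same
configuration are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, bsa, expression, networks, quantgen, simulate
from .config import RunConfig
from .io import (
    config_hash,
    standard_metadata,
    write_json_report,
    write_phenotypes,
    write_table,
)

logger = logging.getLogger("slafbsa")


@dataclass
class SequencingSummary:
    """Combined per-bulk sequencing statistics (Table-style accounting)."""

    total_depths: list[float]
    tag_count: float
    gc_percents: list[float]
    q30_percents: list[float]
    combined_average_depth: float
    mean_gc: float
    mean_q30: float


def summarize_sequencing(
    total_depths: list[float],
    tag_count: float,
    gc_percents: list[float] | None = None,
    q30_percents: list[float] | None = None,
) -> SequencingSummary:
    """Combine per-bulk sequencing statistics.

    The combined average depth is the sum of per-bulk total depths over
    the distinct SLAF tag count; GC and Q30 combine as arithmetic means
    of the per-bulk percentages.
    """
    if tag_count <= 0:
        raise ValueError("tag count must be positive")
    if any(d < 0 for d in total_depths):
        raise ValueError("total depths must be non-negative")
    gc = list(gc_percents or [])
    q30 = list(q30_percents or [])
    return SequencingSummary(
        total_depths=list(total_depths),
        tag_count=tag_count,
        gc_percents=gc,
        q30_percents=q30,
        combined_average_depth=sum(total_depths) / tag_count,
        mean_gc=float(np.mean(gc)) if gc else float("nan"),
        mean_q30=float(np.mean(q30)) if q30 else float("nan"),
    )


@dataclass
class PipelineResult:
    """Paths and key in-memory products of one pipeline run."""

    out_dir: Path
    files: dict[str, Path]
    sib_results: quantgen.SibResults | None = None
    candidates: list[str] | None = None
    networks: list[networks.SnpNetworkModel] | None = None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the stages toggled in ``config`` (see module docstring)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    known = {"simulate", "ebv", "score", "test", "assoc", "networks", "express"}
    unknown = stages - known
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    order = ["simulate", "ebv", "score", "test", "assoc", "networks", "express"]
    requires = {
        "ebv": "simulate",
        "score": "ebv",
        "test": "score",
        "assoc": "test",
        "networks": "assoc",
        "express": "networks",
    }
    for stage, dep in requires.items():
        if stage in stages and dep not in stages:
            raise ValueError(f"stage '{stage}' requires stage '{dep}'")

    cfg_dict = asdict(config)
    cfg_dict.pop("out_dir", None)  # hash the analysis config, not the paths
    chash = config_hash(cfg_dict)
    meta = standard_metadata(config.seed, chash)
    files: dict[str, Path] = {}
    result = PipelineResult(out_dir=out_dir, files=files)

    if "simulate" not in stages:
        return result
    sim_cfg = config.simulation
    pop = simulate.simulate_population(sim_cfg)
    logger.info("simulated %d progeny at %d loci", sim_cfg.n_progeny, sim_cfg.n_loci)
    ped_path = out_dir / "phenotypes.csv"
    write_phenotypes(pop.pedigree, ped_path, meta)
    files["phenotypes"] = ped_path
    geno_path = out_dir / "genotypes.tsv"
    geno = pop.genotype_strings().reset_index().rename(columns={"index": "id"})
    write_table(geno, geno_path, meta)
    files["genotypes"] = geno_path

    if "ebv" not in stages:
        return result
    w, p_norm = quantgen.check_normality(pop.progeny["mw"])
    logger.info("trait normality (Shapiro-Wilk): W=%.4f p=%.3g", w, p_norm)
    sib = quantgen.SibModel.from_population(pop, sex=None, adjust_sex=True).fit(
        config.h2w_definition
    )
    result.sib_results = sib
    ebv_path = out_dir / "ebv.csv"
    write_phenotypes(sib.ebv, ebv_path, meta)
    files["ebv"] = ebv_path
    # bulks are drawn from the male stratum, as in the emulated design
    male_ids = set(pop.progeny.loc[pop.progeny["sex"] == "M", "id"])
    male_ebv = sib.ebv[sib.ebv["id"].isin(male_ids)]
    low_ids, high_ids = quantgen.select_extreme_groups(male_ebv, sim_cfg.bulk_size)
    logger.info(
        "h2=%.3f h2w=%.3f; extreme bulks of %d", sib.h2, sib.h2_w, sim_cfg.bulk_size
    )

    if "score" not in stages:
        return result
    depths = simulate.simulate_bulk_depths(
        pop,
        low_ids,
        high_ids,
        sim_cfg.mean_depth_per_bulk,
        sim_cfg.sequencing_error_rate,
        seed=sim_cfg.seed + 1,
    )
    depth_path = out_dir / "locus_depths.tsv"
    write_table(depths, depth_path, meta)
    files["locus_depths"] = depth_path
    scored = bsa.score_table(depths, config.ed_min, config.delta_min, config.q_min)
    scored_path = out_dir / "scored_loci.tsv"
    write_table(scored, scored_path, meta)
    files["scored_loci"] = scored_path
    n_in, n_pass = len(scored), int(scored["passes_filter"].sum())
    logger.info("filter: %d loci in, %d pass, %d rejected", n_in, n_pass, n_in - n_pass)

    if "test" not in stages:
        return result
    passed = scored[scored["passes_filter"]]
    assoc = association.screen_bulk_loci(passed, config.alpha)
    assoc_path = out_dir / "bulk_association.tsv"
    write_table(assoc, assoc_path, meta)
    files["bulk_association"] = assoc_path
    bonf_hits = association.select_candidates(
        assoc, "bonferroni_hits", alpha=config.alpha
    )
    candidates = association.select_candidates(
        assoc, "top_k", k=min(config.top_k, len(assoc))
    )
    # stage logic: prefer Bonferroni survivors, cap at top_k
    selected = [c for c in candidates if c in set(bonf_hits)] or candidates
    result.candidates = selected
    logger.info(
        "bulk screen: %d testable, %d Bonferroni hits, %d selected",
        len(assoc), len(bonf_hits), len(selected),
    )

    if "assoc" not in stages:
        return result
    males = pop.progeny[pop.progeny["sex"] == "M"]
    male_rows = pop.row_of(males["id"])
    mw = males["mw"].to_numpy(float)
    locus_pos = {l: i for i, l in enumerate(pop.loci["locus_id"])}
    dosages = pd.DataFrame(
        {l: pop.genotypes[male_rows, locus_pos[l]] for l in selected},
        index=males["id"],
    )
    geno_strings = pop.genotype_strings().loc[males["id"], selected]
    assoc_rows = []
    for locus in selected:
        dos = dosages[locus].to_numpy()
        if np.ptp(dos) == 0:
            continue
        try:
            res = quantgen.genotype_trait_anova(geno_strings[locus], mw, config.alpha)
        except ValueError:
            continue
        allele_f, geno_f = quantgen.compute_frequencies(geno_strings[locus])
        try:
            eff = quantgen.genotypic_effects(dos, mw, locus)
            eff_fields = {
                "additive": eff.additive.effect,
                "additive_p": eff.additive.p,
                "dominance": eff.dominance.effect,
                "dominance_p": eff.dominance.p,
                "recessive": eff.recessive.effect,
                "recessive_p": eff.recessive.p,
            }
        except ValueError:
            eff_fields = {}
        assoc_rows.append(
            {
                "locus_id": locus,
                "F": res.f,
                "p": res.p,
                "group_means": ";".join(
                    f"{g}:{m:.4f}{res.letters.get(g, '')}"
                    for g, m in res.group_means.items()
                ),
                "allele_freqs": ";".join(f"{a}:{f:.4f}" for a, f in sorted(allele_f.items())),
                **eff_fields,
            }
        )
    assoc_report = pd.DataFrame(assoc_rows)
    report_path = out_dir / "genotype_association.tsv"
    write_table(assoc_report, report_path, meta)
    files["genotype_association"] = report_path

    if "networks" not in stages:
        return result
    sig_loci = assoc_report.loc[assoc_report["p"] < config.alpha, "locus_id"].tolist()
    nets = networks.stepwise_network_search(
        dosages, mw, sig_loci, direction="forward", alpha=config.alpha
    )
    result.networks = nets
    net_path = out_dir / "snp_networks.json"
    write_json_report([n.to_dict() for n in nets], net_path, meta)
    files["snp_networks"] = net_path
    if sig_loci:
        codings = {
            l: networks.fit_single_snp_modes(dosages[l], mw, l)[0] for l in sig_loci
        }
        coded = networks.code_genotypes(dosages[sig_loci], codings)
        coded = coded.assign(mw=mw)
        corr, order = networks.spearman_matrix(coded)
        corr_out = corr.loc[order, order].reset_index().rename(columns={"index": "name"})
        corr_path = out_dir / "spearman_matrix.tsv"
        write_table(corr_out, corr_path, meta)
        files["spearman_matrix"] = corr_path
    logger.info("networks: %d significant loci, %d networks", len(sig_loci), len(nets))

    if "express" not in stages:
        return result
    # expression stage: genotype groups of the top candidate locus, with a
    # planted fold change between the homozygote classes
    top = selected[0] if selected else None
    if top is not None:
        fc = config.expression_fold_change
        ct = simulate.simulate_expression(
            groups=["ref_hom", "alt_hom"],
            fold_changes=[1.0, fc],
            ct_noise_sd=config.expression_ct_noise_sd,
            n_per_group=config.expression_n_per_group,
            seed=sim_cfg.seed + 2,
            gene=f"gene_{top}",
        )
        ct_path = out_dir / "ct_table.csv"
        write_phenotypes(ct, ct_path, meta)
        files["ct_table"] = ct_path
        rq = expression.relative_quantity(ct, calibrator="ref_hom")
        cmp_res = expression.compare_groups(rq, "ref_hom", "alt_hom")
        expr_report = pd.DataFrame(
            [
                {
                    "gene": cmp_res.gene,
                    "group_a": cmp_res.group_a,
                    "group_b": cmp_res.group_b,
                    "mean_rq_a": cmp_res.mean_rq_a,
                    "mean_rq_b": cmp_res.mean_rq_b,
                    "t": cmp_res.t,
                    "p": cmp_res.p,
                    "direction": cmp_res.direction,
                }
            ]
        )
        expr_path = out_dir / "expression.csv"
        write_phenotypes(expr_report, expr_path, meta)
        files["expression"] = expr_path
    return result
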