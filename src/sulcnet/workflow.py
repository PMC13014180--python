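"""Configuration and the stage-chaining workflows.

Three workflows mirror the study design: ``cohort`` (simulate or load
case-control cohorts, build SPNs and complexity scores, fit effect maps,
run the contraction test, cross-syndrome similarity and PCA), ``gwas``
(phenotype preparation, Nyholt thresholds, association scan, clumping and
gene mapping on simulated genotypes) and ``modules`` (expression
normalization, module fitting, co-expression ranking and GSEA).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as wio
from ._atlas import CANONICAL_SULCI, default_annotation
from .effects import DEFAULT_COVARIATES, contraction_test, effect_map, residualize
from .fetal import coexpression_ranking, fit_modules, flatten_profiles, gsea_preranked, zscore_by_timepoint
from .gwas import (
    ancestry_pcs,
    assoc_scan,
    clump_leads,
    map_snps_to_genes,
    nyholt_meff,
    prepare_phenotype,
    significance_thresholds,
)
from .spatial import cross_syndrome_similarity, delta_pca
from .spn import complexity_scores, eigen_fold_index, mean_spn, subject_spns
from .synthetic import (
    CohortSpec,
    ExpressionSpec,
    GenotypeSpec,
    GeneSetSpec,
    ModuleSpec,
    simulate_cohort,
    simulate_expression,
    simulate_genotypes,
    simulate_parcellation,
)

log = logging.getLogger("sulcnet")

__all__ = ["RunConfig", "cohort_complexity", "cohort_analysis", "run_workflow"]


@dataclass
class RunConfig:
    """Validated run configuration; defaults match the printed settings."""

    seed: int = 0
    out_dir: str = "sulcnet_run"
    n_spins: int = 10_000
    n_perm: int = 1_000
    clump_r2: float = 0.1
    gene_window: int = 10_000
    sd_limit: float = 5.0
    base_snp_threshold: float = 5e-8
    base_gene_alpha: float = 0.05
    n_genes_genome: int = 19_299
    rint_offset: float = 0.375
    include_diagonal: bool = False
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    n_syndromes: int = 9
    n_cases: int = 100
    n_controls: int = 100
    noise_sd: float = 0.5
    contraction: float = 0.0
    effect_sd: float = 0.5
    n_subjects_gwas: int = 1_000
    n_snps: int = 200
    block_size: int = 10
    within_block_r: float = 0.8
    causal_effect: float = 0.4
    n_expression_genes: int = 40
    n_ancestry_pcs: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.n_spins < 100 or cfg.n_perm < 100:
            raise ValueError("n_spins and n_perm must be >= 100")
        if not (0 < cfg.clump_r2 <= 1):
            raise ValueError("clump_r2 must lie in (0, 1]")
        return cfg

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariates"] = list(self.covariates)
        return d


def cohort_complexity(table: pd.DataFrame, annotation: pd.DataFrame | None = None,
                      include_diagonal: bool = False):
    """Subject SPNs -> mean control SPN -> eigen-fold index -> complexity.

    The eigen-fold sign is anchored to the annotation's complexity axis
    (complex pole positive), so higher scores mean more complex. Returns a
    dict with the per-subject SPNs, mean control SPN, eigen-fold index, a
    subjects x sulci Fisher-Z score frame and a long-format score table
    suitable for :func:`sulcnet.effects.effect_map`.
    """
    ann = default_annotation() if annotation is None else annotation
    sulci = [s for s in ann.index if s in set(table["sulcus"])]
    spns = subject_spns(table, sulci)
    groups = table.drop_duplicates("subject").set_index("subject")["group"]
    controls = [s for s in spns if groups.get(s) == "control"]
    if not controls:
        raise ValueError("no control subjects")
    ref = mean_spn([spns[s] for s in controls])
    efi = eigen_fold_index(ref, reference_axis=ann["axis"])
    z = pd.DataFrame({
        subj: complexity_scores(spn, efi, include_diagonal=include_diagonal)["fisher_z"]
        for subj, spn in spns.items()
    }).T
    z.index.name = "subject"
    long = z.stack().rename("value").reset_index()
    long.columns = ["subject", "sulcus", "value"]
    long["phenotype"] = "complexity"
    meta_cols = [c for c in ("cohort", "group", "age", "sex", "site", "TTV", "EN")
                 if c in table.columns]
    meta = table[["subject"] + meta_cols].drop_duplicates("subject")
    long = long.merge(meta, on="subject", how="left")
    return {"spns": spns, "mean_control_spn": ref, "eigen_fold": efi,
            "scores": z, "score_table": long}


def cohort_analysis(table: pd.DataFrame, annotation: pd.DataFrame | None = None,
                    covariates=DEFAULT_COVARIATES, include_diagonal: bool = False):
    """Effect map of complexity plus the contraction test for one cohort."""
    ann = default_annotation() if annotation is None else annotation
    cx = cohort_complexity(table, ann, include_diagonal=include_diagonal)
    emap = effect_map(cx["score_table"], "complexity", covariate_list=covariates)
    cov = cx["score_table"].drop_duplicates("subject").reset_index(drop=True)
    resid = residualize(cx["scores"], cov, covariate_list=covariates)
    groups = cov.set_index("subject")["group"]
    contraction = contraction_test(resid, ann["sulcus_class"], groups)
    return {"complexity": cx, "effect_map": emap, "residual_scores": resid,
            "contraction": contraction}


def _stage(name: str, out_dir: Path, params: dict) -> None:
    log.info("stage=%s params=%s", name, params)
    with open(out_dir / "provenance.jsonl", "a") as fh:
        fh.write(json.dumps({"stage": name, **params}, default=str) + "\n")


def _run_cohort(cfg: RunConfig, out: Path, meta: dict) -> dict:
    rng = np.random.default_rng(cfg.seed)
    ann = default_annotation()
    maps = {}
    contractions = {}
    for i in range(cfg.n_syndromes):
        name = f"syn{i + 1:02d}"
        effect = rng.normal(0.0, cfg.effect_sd, len(CANONICAL_SULCI))
        spec = CohortSpec(n_cases=cfg.n_cases, n_controls=cfg.n_controls,
                          cohort=name, effect_map=effect, noise_sd=cfg.noise_sd,
                          contraction=cfg.contraction,
                          seed=int(rng.integers(2 ** 31)))
        sim = simulate_cohort(spec)
        _stage(f"cohort:{name}", out, {"seed": spec.seed})
        res = cohort_analysis(sim.table, ann, covariates=cfg.covariates,
                              include_diagonal=cfg.include_diagonal)
        emap = res["effect_map"]
        wio.write_table(emap.reset_index(), out / f"effect_map_{name}.tsv", **meta)
        maps[name] = emap["beta1"]
        contractions[name] = res["contraction"]
    delta = pd.DataFrame(maps).T
    delta.index.name = "syndrome"
    sim_matrix = cross_syndrome_similarity(delta, n_perm=cfg.n_perm, seed=cfg.seed)
    pca = delta_pca(delta, n_perm=cfg.n_perm, seed=cfg.seed)
    wio.write_table(sim_matrix, out / "cross_syndrome_similarity.tsv", index=True, **meta)
    wio.write_table(
        pd.DataFrame({"variance_explained": pca.variance_explained,
                      "p_perm": pca.p_perm}),
        out / "delta_pca_components.tsv", **meta)
    wio.write_map(pca.score_map(0), out / "delta_pc1_map.tsv", **meta)
    return {"delta": delta, "similarity": sim_matrix, "pca": pca,
            "contractions": contractions}


def _run_gwas(cfg: RunConfig, out: Path, meta: dict) -> dict:
    causal_idx = cfg.n_snps // 2
    gspec = GenotypeSpec(n_subjects=cfg.n_subjects_gwas, n_snps=cfg.n_snps,
                         block_size=cfg.block_size,
                         within_block_r=cfg.within_block_r,
                         causal=((causal_idx, cfg.causal_effect),),
                         seed=cfg.seed)
    sim = simulate_genotypes(gspec)
    _stage("gwas:simulate", out, {"seed": cfg.seed, "causal": causal_idx})
    rng = np.random.default_rng(cfg.seed + 1)
    n = gspec.n_subjects
    raw = pd.Series(sim.phenotype_contribution + rng.normal(0, 1, n),
                    index=sim.subjects)
    cov = pd.DataFrame({"subject": sim.subjects,
                        "age": rng.uniform(45, 80, n),
                        "sex": rng.integers(0, 2, n),
                        "site": rng.integers(0, 2, n).astype(str),
                        "EN": np.round(rng.normal(-80, 30, n)).astype(int)})
    prep = prepare_phenotype(raw, cov, sd_limit=cfg.sd_limit,
                             rint_offset=cfg.rint_offset)
    keep = [s in prep.values.index for s in sim.subjects]
    dos = sim.dosages[np.asarray(keep)]
    subj = [s for s in sim.subjects if s in prep.values.index]
    # with a small simulated panel, genotype-derived PCs can absorb causal
    # signal; they are off by default and opt-in via n_ancestry_pcs
    pcs = ancestry_pcs(dos, k=cfg.n_ancestry_pcs) if cfg.n_ancestry_pcs else None
    assoc = assoc_scan(dos, sim.variants, prep.values, subj, covariates=pcs)
    thr = significance_thresholds(meff=34, n_genes=cfg.n_genes_genome,
                                  base_snp=cfg.base_snp_threshold,
                                  base_gene_alpha=cfg.base_gene_alpha)
    leads = clump_leads(assoc, dos, p_threshold=cfg.base_snp_threshold,
                        r2_threshold=cfg.clump_r2)
    genes = pd.DataFrame({
        "gene": [f"GENE{i}" for i in range(cfg.n_snps // 20)],
        "chrom": "1",
        "start": [200_000 * i + 50_000 for i in range(cfg.n_snps // 20)],
        "end": [200_000 * i + 150_000 for i in range(cfg.n_snps // 20)],
    })
    hits = map_snps_to_genes(leads, genes, window=cfg.gene_window)
    wio.write_table(assoc, out / "assoc.tsv", **meta)
    wio.write_table(leads, out / "leads.tsv", **meta)
    wio.write_table(hits, out / "gene_hits.tsv", **meta)
    return {"assoc": assoc, "leads": leads, "gene_hits": hits,
            "thresholds": thr, "truth": sim.truth}


def _run_modules(cfg: RunConfig, out: Path, meta: dict) -> dict:
    n_mod = max(2, cfg.n_expression_genes // 12)
    per = cfg.n_expression_genes // (n_mod + 1)
    spec = ExpressionSpec(
        n_genes=cfg.n_expression_genes,
        modules=tuple(ModuleSpec(n_genes=per, peak_layer=i % 5,
                                 peak_timepoint=i % 2) for i in range(n_mod)),
        gene_sets=(GeneSetSpec("set_module1", 0, 0.8),
                   GeneSetSpec("set_random", 0, 0.0)),
        seed=cfg.seed,
    )
    sim = simulate_expression(spec)
    _stage("modules:simulate", out, {"seed": cfg.seed, "n_modules": n_mod})
    cube = zscore_by_timepoint(sim.cube)
    profiles = flatten_profiles(cube, regions=spec.regions, layers=spec.layers,
                                timepoints=spec.timepoints)
    result = fit_modules(profiles, seed=cfg.seed)
    ranking = coexpression_ranking(result.prototypes.iloc[0], profiles)
    gsea = gsea_preranked(ranking, sim.gene_sets, n_perm=cfg.n_perm,
                          seed=cfg.seed)
    wio.write_table(result.labels.rename("module").reset_index(),
                    out / "module_labels.tsv", **meta)
    wio.write_table(gsea.table, out / "gsea.tsv", **meta)
    return {"modules": result, "gsea": gsea, "truth_labels": sim.module_labels}


def run_workflow(config: RunConfig | dict, workflow: str) -> dict:
    """Execute one named workflow, writing all outputs under the run dir."""
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_dict(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hash_src = {k: v for k, v in cfg.to_dict().items() if k != "out_dir"}
    cfg_hash = wio.config_hash(hash_src)
    run_id = f"{workflow}-{cfg.seed}"
    meta = {"run_id": run_id, "cfg_hash": cfg_hash}
    (out / "provenance.jsonl").write_text("")
    _stage("start", out, {"workflow": workflow, "config_hash": cfg_hash,
                          "seed": cfg.seed})
    runners = {"cohort": _run_cohort, "gwas": _run_gwas, "modules": _run_modules}
    if workflow not in runners:
        raise ValueError(f"unknown workflow {workflow!r}")
    try:
        result = runners[workflow](cfg, out, {"run_id": run_id, "cfg_hash": cfg_hash})
    except Exception as exc:
        raise RuntimeError(f"workflow {workflow!r} failed: {exc}") from exc
    _stage("done", out, {"workflow": workflow})
    return result
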