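"""End-to-end synthetic study orchestration.

Runs the full pipeline on generated data: a phylogeny with co-evolving
traits and substitution rates, a focal gene whose rate tracks brain size
against a cohort of uncorrelated control genes, a tiled reporter library
quantified back to region activities, a permutation null for the focal
regulatory element, and a proliferation assay linked to the phenotypes by
PGLS.  Every stage draws its randomness from a named child seed of the study
seed, so a configuration reproduces its report exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from coevoscan import mpra, orthocontrols, phylocomp, proliferation, synthdata
from coevoscan.tree import Phylogeny

__all__ = ["StudyConfig", "ConfigError", "validate_config", "run_study"]

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Declarative study parameters; defaults are the emulated study design."""

    seed: int = 1
    n_species: int = 30

    # joint diffusion of (log omega, log brain, log GI, log body)
    trait_variances: tuple = (0.04, 0.25, 0.04, 0.36)
    corr_brain_gi: float = 0.6
    corr_brain_body: float = 0.7
    corr_gi_body: float = 0.4
    focal_corr_omega_brain: float = 0.8
    control_corr_omega_brain: float = 0.0
    n_controls: int = 124

    # codon / dN-dS stage
    n_codons: int = 300
    n_dnds_genes: int = 10

    # MPRA design and noise
    tile_size: int = 94
    step: int = 40
    barcode_length: int = 10
    n_plasmid_reps: int = 3
    cell_lines: dict = field(default_factory=lambda: {"human1": 3, "human2": 3, "macaque1": 3})
    depth: int = 1_000_000
    dispersion: float = 0.05
    dropout: float = 0.0
    n_mpra_species: int = 10
    n_pool_cres: int = 30
    cre_length_range: tuple = (94, 500)
    focal_cre_corr_gi: float = 0.9

    # filters
    min_phred: int = 10
    detection_min_reps: int = 2
    cds_length_range: tuple = (291, 999)
    length_ratio_range: tuple = (0.5, 2.0)
    min_coverage: float = 0.30
    min_back_overlap: float = 0.10
    ds_outlier_sd: float = 3.0

    # statistics
    n_perm: int = 1000
    lrt_alpha: float = 0.05
    adjust_method: str = "bh"

    # proliferation assay
    prolif_true_rates: dict = field(
        default_factory=lambda: {
            "orthA": 0.3,
            "orthB": 0.4,
            "orthC": 0.5,
            "orthD": 0.6,
            "orthE": 0.7,
        }
    )
    prolif_batch_effects: dict = field(
        default_factory=lambda: {"m1": 0.0, "m2": 0.3, "m3": -0.3}
    )
    prolif_cells_per_replicate: int = 200
    prolif_n_replicates: int = 10

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class ConfigError(ValueError):
    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(self.errors))


def validate_config(raw: str | dict | None) -> StudyConfig:
    """Build a :class:`StudyConfig` from YAML/JSON text or a mapping.

    Unknown keys, domain violations and geometric inconsistencies are all
    collected and reported together in a :class:`ConfigError`; an empty
    input yields the full default configuration.
    """
    if raw is None or (isinstance(raw, str) and not raw.strip()):
        data = {}
    elif isinstance(raw, dict):
        data = dict(raw)
    else:
        try:
            data = yaml.safe_load(raw) or {}
        except yaml.YAMLError as exc:
            raise ConfigError([f"unparseable config: {exc}"]) from exc
        if not isinstance(data, dict):
            raise ConfigError(["config must be a mapping"])
    errors = []
    known = {f.name for f in dataclasses.fields(StudyConfig)}
    for key in data:
        if key not in known:
            errors.append(f"{key}: unknown configuration key")
    cfg = StudyConfig(**{k: v for k, v in data.items() if k in known})
    for name in ("cre_length_range", "cds_length_range", "length_ratio_range"):
        val = getattr(cfg, name)
        if isinstance(val, list):
            setattr(cfg, name, tuple(val))

    def check(cond, msg):
        if not cond:
            errors.append(msg)

    check(cfg.n_species >= 2, "n_species: must be >= 2")
    check(cfg.step <= cfg.tile_size, "step: must be <= tile_size (tiles must overlap or abut)")
    check(cfg.step >= 1, "step: must be >= 1")
    check(cfg.tile_size >= 1, "tile_size: must be >= 1")
    check(cfg.min_phred >= 0, "min_phred: must be >= 0")
    check(cfg.barcode_length >= 8, "barcode_length: must be >= 8")
    check(0 <= cfg.dropout < 1, "dropout: must be in [0, 1)")
    check(cfg.dispersion >= 0, "dispersion: must be >= 0")
    check(cfg.depth > 0, "depth: must be > 0")
    check(cfg.n_plasmid_reps >= 2, "n_plasmid_reps: must be >= 2 for the detection filter")
    check(cfg.detection_min_reps >= 1, "detection_min_reps: must be >= 1")
    check(0 < cfg.min_coverage <= 1, "min_coverage: must be in (0, 1]")
    check(0 < cfg.min_back_overlap <= 1, "min_back_overlap: must be in (0, 1]")
    check(cfg.ds_outlier_sd > 0, "ds_outlier_sd: must be > 0")
    check(cfg.n_perm >= 1, "n_perm: must be >= 1")
    check(0 < cfg.lrt_alpha < 1, "lrt_alpha: must be in (0, 1)")
    check(cfg.adjust_method in ("bh", "bonferroni"), "adjust_method: must be 'bh' or 'bonferroni'")
    check(
        -1 <= cfg.focal_corr_omega_brain <= 1,
        "focal_corr_omega_brain: must be in [-1, 1]",
    )
    check(cfg.n_controls >= 2, "n_controls: must be >= 2")
    check(cfg.n_mpra_species >= 3, "n_mpra_species: must be >= 3")
    check(
        cfg.n_mpra_species <= cfg.n_species,
        "n_mpra_species: must be <= n_species",
    )
    check(cfg.cre_length_range[0] >= 1, "cre_length_range: lower bound must be >= 1")
    check(
        cfg.cre_length_range[0] <= cfg.cre_length_range[1],
        "cre_length_range: lower bound must be <= upper bound",
    )
    for cond, rate in cfg.prolif_true_rates.items():
        check(0 < rate < 1, f"prolif_true_rates.{cond}: must be in (0, 1)")
    check(
        len(cfg.prolif_true_rates) <= cfg.n_species,
        "prolif_true_rates: more conditions than species",
    )
    if errors:
        raise ConfigError(errors)
    return cfg


def _stage_seeds(seed: int) -> dict:
    names = ["tree", "traits", "genes", "alignments", "mpra", "permnull", "prolif"]
    state = np.random.SeedSequence(seed).generate_state(len(names))
    return {n: int(s % (2**31)) for n, s in zip(names, state)}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: StudyConfig, seeds: dict):
    tree = synthdata.simulate_tree(cfg.n_species, seeds["tree"])
    scenario = synthdata.EvolScenario.from_correlations(
        cfg.trait_variances,
        corr_brain_gi=cfg.corr_brain_gi,
        corr_brain_body=cfg.corr_brain_body,
        corr_gi_body=cfg.corr_gi_body,
        seed=seeds["traits"],
    )
    sim = synthdata.simulate_traits_and_rates(tree, scenario)
    return tree, sim


def stage_genes(cfg: StudyConfig, tree: Phylogeny, sim, seeds: dict):
    """Focal + control gene rate simulation, correlations and ranking."""
    trait_var = cfg.trait_variances[1]  # log brain dimension
    gene_rhos = {"focal": cfg.focal_corr_omega_brain}
    for i in range(cfg.n_controls):
        gene_rhos[f"ctrl{i:03d}"] = cfg.control_corr_omega_brain
    traits = sim.traits
    summaries = {}
    rng = np.random.SeedSequence(seeds["genes"]).generate_state(len(gene_rhos))
    branch_omegas = {}
    for (gene, rho), gseed in zip(gene_rhos.items(), rng):
        logw, branch_omega = synthdata.simulate_rate_on_traits(
            tree,
            sim.node_states,
            trait_dim=1,
            trait_var=trait_var,
            rho=rho,
            seed=int(gseed % (2**31)),
        )
        branch_omegas[gene] = branch_omega
        marg, part = {}, {}
        cols = {"brain": "log_brain", "gi": "log_gi", "body": "log_body"}
        series = {"omega": logw}
        series.update({k: traits[v] for k, v in cols.items()})
        for trait, col in cols.items():
            marg[trait], _ = phylocomp.pic_correlation(tree, logw.to_dict(), traits[col].to_dict())
        # partial correlations from the contrast correlation matrix
        contr = {
            name: phylocomp._contrasts(tree, s.loc[tree.leaf_labels].to_numpy())
            for name, s in series.items()
        }
        names = list(contr)
        M = np.array([contr[n] for n in names])
        norms = np.sqrt((M * M).sum(axis=1))
        corr = (M @ M.T) / np.outer(norms, norms)
        np.fill_diagonal(corr, 1.0)
        pcorr = phylocomp.partial_correlation(corr)
        for trait in cols:
            part[trait] = float(pcorr[0, names.index(trait)])
        summaries[gene] = phylocomp.GeneEvolSummary(
            gene_id=gene, marginal_r=marg, partial_r=part
        )
    ranking = {
        stat: {
            trait: phylocomp.rank_focal(
                [summaries[g] for g in summaries if g != "focal"],
                summaries["focal"],
                trait,
                stat,
            )
            for trait in ("brain", "gi", "body")
        }
        for stat in ("marginal", "partial")
    }
    return summaries, branch_omegas, ranking


def stage_dnds(cfg: StudyConfig, tree: Phylogeny, branch_omegas: dict, seeds: dict):
    """NG86 omega on the deepest leaf pair for a subset of genes, plus the
    log(dS) outlier filter over that subset."""
    # two leaves spanning the root: max depth from each root child
    depths = tree.depths()
    leaves = tree.leaf_indices()
    pair_labels = []
    for child in tree.children[0][:2]:
        sub = [i for i in leaves if _has_ancestor(tree, i, child)]
        pair_labels.append(tree.labels[max(sub, key=lambda i: depths[i])])
    pruned = tree.prune_to(pair_labels)
    genes = list(branch_omegas)[: cfg.n_dnds_genes]
    seeds_g = np.random.SeedSequence(seeds["alignments"]).generate_state(len(genes))
    records = {}
    ds_map = {}
    for gene, gseed in zip(genes, seeds_g):
        mean_w = float(np.mean(list(branch_omegas[gene].values())))
        pruned_omega = {i: mean_w for i in range(1, pruned.n_nodes)}
        # keep pairwise divergence moderate so counting methods stay in range
        rate = 0.3 / max(pruned.total_branch_length(), 1e-9)
        aln = synthdata.simulate_codon_alignment(
            pruned, pruned_omega, cfg.n_codons, int(gseed % (2**31)), mutation_rate=rate
        )
        res = orthocontrols.ng86_dnds(aln[pair_labels[0]], aln[pair_labels[1]])
        records[gene] = {
            "true_omega": mean_w,
            "ng86_omega": res.omega,
            "dn": res.dn,
            "ds": res.ds,
        }
        if res.ds > 0 and np.isfinite(res.ds):
            ds_map[gene] = res.ds
    retained, removed = orthocontrols.ds_outlier_filter(ds_map, cfg.ds_outlier_sd)
    return records, retained, removed


def _has_ancestor(tree: Phylogeny, node: int, anc: int) -> bool:
    while node >= 0:
        if node == anc:
            return True
        node = tree.parent[node]
    return False


def stage_mpra(cfg: StudyConfig, tree: Phylogeny, sim, seeds: dict):
    """Simulate, quantify and reconstruct the focal element across species."""
    rng = np.random.default_rng(seeds["mpra"])
    species = list(sim.traits.sort_values("log_gi").index[-cfg.n_mpra_species :])
    # focal element: log-activity evolves as Brownian motion whose increments
    # correlate with the GI increments (it co-evolves with gyrification)
    log_act, _ = synthdata.simulate_rate_on_traits(
        tree,
        sim.node_states,
        trait_dim=2,
        trait_var=cfg.trait_variances[2],
        rho=cfg.focal_cre_corr_gi,
        omega_var=0.25,
        root_log_omega=1.0,
        seed=seeds["mpra"],
    )
    focal_activity = np.exp(log_act.loc[species].to_numpy())
    # orthologous elements share a base length with modest per-species jitter
    lo, hi = cfg.cre_length_range
    base_len = int(rng.integers(lo, hi + 1))
    lengths = {
        f"focal_{s}": max(lo, base_len + int(rng.integers(-10, 11))) for s in species
    }
    designs = synthdata.design_library(
        lengths,
        tile_size=cfg.tile_size,
        step=cfg.step,
        barcode_length=cfg.barcode_length,
        seed=seeds["mpra"],
    )
    true_activity = {f"focal_{s}": float(a) for s, a in zip(species, focal_activity)}
    cm, manifest = synthdata.simulate_mpra_counts(
        designs,
        true_activity,
        n_plasmid_reps=cfg.n_plasmid_reps,
        cell_lines=cfg.cell_lines,
        depth=cfg.depth,
        dispersion=cfg.dispersion,
        dropout=cfg.dropout,
        seed=seeds["mpra"] + 1,
    )
    cm = mpra.detection_filter(cm, cfg.detection_min_reps)
    cpm_mat = mpra.cpm(cm)
    # per-line activities averaged across cell lines before reconstruction
    per_line = [
        mpra.tile_activity(cpm_mat, cm.sample_meta, line)["activity"]
        for line in cfg.cell_lines
    ]
    pooled = pd.concat(per_line, axis=1).mean(axis=1)
    acts = pd.DataFrame({"activity": pooled, "defined": pooled.notna()})
    recon = {}
    for d in designs:
        ra = mpra.region_activity(acts, d, "pooled")
        if ra is not None:
            recon[d.cre_id] = ra.activity
    # true region activity under the same reconstruction geometry
    true_tiles = pd.DataFrame(
        {
            "activity": [true_activity[d.cre_id] for d in designs for _ in d.tiles],
            "defined": True,
        },
        index=[t.tile_id for d in designs for t in d.tiles],
    )
    true_region = {
        d.cre_id: mpra.region_activity(true_tiles, d).activity for d in designs
    }
    common = sorted(set(recon) & set(true_region))
    recovery_r = float(
        np.corrcoef([recon[c] for c in common], [true_region[c] for c in common])[0, 1]
    )
    # permutation null of the focal element's GI association
    focal_by_species = {
        s: np.log(recon[f"focal_{s}"]) for s in species if f"focal_{s}" in recon
    }
    # pool elements: phylogenetically coherent activities with no GI linkage
    pool = {}
    pool_seeds = np.random.SeedSequence(seeds["permnull"]).generate_state(cfg.n_pool_cres)
    for i, ps in enumerate(pool_seeds):
        vec, _ = synthdata.simulate_rate_on_traits(
            tree,
            sim.node_states,
            trait_dim=2,
            trait_var=cfg.trait_variances[2],
            rho=0.0,
            omega_var=0.25,
            root_log_omega=1.0,
            seed=int(ps % (2**31)),
        )
        pool[f"pool{i:03d}"] = vec.loc[species].to_dict()
    cov = phylocomp.brownian_cov(tree, list(focal_by_species))
    trait_map = sim.traits["log_gi"].to_dict()
    null = phylocomp.permutation_null(
        focal_by_species,
        trait_map,
        cov,
        pool,
        n_perm=cfg.n_perm,
        seed=seeds["permnull"],
    )
    return {
        "n_tiles_designed": int(sum(len(d.tiles) for d in designs)),
        "n_tiles_detected": int(cm.counts.shape[0]),
        "recovery_pearson_r": recovery_r,
        "observed_p": null.observed_p,
        "empirical_p": null.empirical_p,
        "empirical_p_plus1": null.empirical_p_plus1,
        "species": species,
    }


def stage_proliferation(cfg: StudyConfig, tree: Phylogeny, sim, seeds: dict):
    """Simulated assay -> logistic fit -> rates -> PGLS link to phenotypes."""
    conditions = list(cfg.prolif_true_rates)
    # map conditions to species spanning the brain-size range
    by_brain = sim.traits.sort_values("log_brain").index
    picks = np.linspace(0, len(by_brain) - 1, len(conditions)).astype(int)
    condition_species = {c: by_brain[i] for c, i in zip(conditions, picks)}
    # true rates follow the species' brain size ordering
    ordered_rates = dict(
        zip(conditions, sorted(cfg.prolif_true_rates.values()))
    )
    data = synthdata.simulate_proliferation(
        conditions,
        ordered_rates,
        cfg.prolif_batch_effects,
        cfg.prolif_cells_per_replicate,
        cfg.prolif_n_replicates,
        seed=seeds["prolif"],
    )
    fit0 = proliferation.fit_logistic(data, include_batch=False)
    fit1 = proliferation.fit_logistic(data, include_batch=True)
    chosen, record = proliferation.select_model(fit0, fit1, cfg.lrt_alpha)
    rates = proliferation.backcalc_rates(chosen)
    contrasts = proliferation.pairwise_contrasts(
        chosen, n_mc=20_000, seed=seeds["prolif"]
    )
    link = proliferation.link_to_phenotype(
        rates, condition_species, sim.traits, tree
    )
    rate_err = float(
        np.max(np.abs(rates[conditions].to_numpy() - np.array(list(ordered_rates.values()))))
    )
    return {
        "batch_lrt": record,
        "rates": {c: float(rates[c]) for c in conditions},
        "true_rates": ordered_rates,
        "max_rate_abs_error": rate_err,
        "n_significant_contrasts": int((contrasts["p_adj"] < 0.05).sum()),
        "link": link.reset_index().to_dict(orient="records"),
    }


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_study(cfg: StudyConfig, out_dir: str | None = None) -> dict:
    """Execute all stages in dependency order and return the report bundle.

    The report is a JSON-serialisable dict; with ``out_dir`` set it is also
    written to ``results.json`` alongside trait and ranking tables (TSV).
    Fully reproducible for a fixed config.
    """
    seeds = _stage_seeds(cfg.seed)
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "config": _jsonify(cfg.to_dict()),
        "stage_seeds": seeds,
    }
    stage = "simulate"
    try:
        tree, sim = stage_simulate(cfg, seeds)
        report["tree"] = {
            "newick": tree.to_newick(),
            "n_leaves": tree.n_leaves,
            "total_branch_length": tree.total_branch_length(),
        }
        stage = "genes"
        summaries, branch_omegas, ranking = stage_genes(cfg, tree, sim, seeds)
        report["genes"] = {
            "focal_marginal_r": summaries["focal"].marginal_r,
            "focal_partial_r": summaries["focal"].partial_r,
            "ranking_percentile": ranking,
            "n_controls": cfg.n_controls,
        }
        stage = "dnds"
        dnds, retained, removed = stage_dnds(cfg, tree, branch_omegas, seeds)
        report["dnds"] = {
            "per_gene": dnds,
            "ds_filter_retained": len(retained),
            "ds_filter_removed": removed,
        }
        stage = "mpra"
        report["mpra"] = stage_mpra(cfg, tree, sim, seeds)
        stage = "proliferation"
        report["proliferation"] = stage_proliferation(cfg, tree, sim, seeds)
    except Exception as exc:
        raise RuntimeError(f"study stage {stage!r} failed: {exc}") from exc
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "results.json").write_text(
            json.dumps(_jsonify(report), indent=2, sort_keys=True)
        )
        sim.traits.to_csv(out / "traits.tsv", sep="\t")
        pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    **{f"marginal_{k}": v for k, v in g.marginal_r.items()},
                    **{f"partial_{k}": v for k, v in g.partial_r.items()},
                }
                for g in summaries.values()
            ]
        ).to_csv(out / "gene_summaries.tsv", sep="\t", index=False)
    return report


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
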