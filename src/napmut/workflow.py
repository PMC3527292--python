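"""End-to-end pipeline: simulate -> mask -> changes -> binding -> statistics.

One YAML (or in-memory) configuration drives every stage; per-stage seeds
are derived by hashing (global seed, stage name) so stages are individually
reproducible yet independent.  Each run writes a manifest recording stage
parameters, output files and their SHA-256 digests; re-running an identical
configuration reproduces identical outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import synthetic_data as sd
from .ancestral_changes import (
    COMPLEMENT,
    ChangeSet,
    DataError,
    Phylogeny,
    StrainAlignment,
    call_high_confidence_changes,
    compute_uniqueness_mask,
    estimate_hky,
    extract_analyzable_sites,
    marginal_ancestral_reconstruction,
)
from .binding_profiles import (
    PROTEINS,
    category_summary,
    classify_all_sites,
    load_binding_profiles,
)
from .classifier_randomization import (
    ClassifierParams,
    assemble_dataset,
    binding_randomization_test,
)
from .context_permutation import combos_from_context_table, permutation_pvalue
from .mutability_stats import (
    COUPLES,
    context_mutability,
    couple_of,
    estimate_fdr,
    odds_ratio_ci,
    scan_methylation_contexts,
    tabulate_mutability,
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Paths or simulation parameters for every stage plus a global seed."""

    outdir: str
    seed: int = 0
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    # real-data inputs (required when simulate is off)
    alignment_fasta: str | None = None
    block_index: str | None = None
    tree_file: str | None = None
    binding_dir: str | None = None
    gene_table: str | None = None
    expression_table: str | None = None
    outgroup: str = "outgroup"
    # filters
    mask_enabled: bool = True
    mask_window: int = 300
    mask_step: int = 10
    mask_max_mismatch: int = 2
    posterior_threshold: float = 0.9
    support_threshold: float = 98.0
    # statistics
    permutation_reps: int = 100_000
    rf_enabled: bool = True
    rf_trees: int = 200
    rf_n_rand: int = 10
    rf_alpha: float = 0.1
    rf_mutation_types: tuple = ("C>T", "G>A")

    def validate(self) -> None:
        if not self.simulate:
            for name in ("alignment_fasta", "tree_file", "binding_dir", "gene_table"):
                value = getattr(self, name)
                if value is None:
                    raise ConfigError(f"simulation is off but {name} is not set")
                if not os.path.exists(value):
                    raise ConfigError(f"{name}: no such file {value!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _site_class(genome: sd.Genome) -> np.ndarray:
    out = np.where(
        genome.gene_index < 0,
        "intergenic",
        np.where(
            (genome.degeneracy == 4),
            "fourfold",
            np.where(genome.degeneracy == 2, "twofold", "coding_other"),
        ),
    )
    return out


def _local_gc(codes: np.ndarray, window: int = 500) -> np.ndarray:
    is_gc = ((codes == 1) | (codes == 2)).astype(float)
    kernel = np.ones(window) / window
    return np.convolve(is_gc, kernel, mode="same")


def build_site_frame(
    genome: sd.Genome,
    sites,
    categories: pd.DataFrame,
    expression: pd.DataFrame | None,
) -> pd.DataFrame:
    """Per-analyzable-site features: class, strand, binding, confounders."""
    pos = sites.census.position.to_numpy()
    L = len(genome)
    site_class = _site_class(genome)[pos]
    strand = np.where(
        genome.gene_strand[pos] > 0, "+", np.where(genome.gene_strand[pos] < 0, "-", "")
    )
    frame = pd.DataFrame(
        {
            "position": pos,
            "ref_base": sites.census.ref_base.to_numpy(),
            "polymorphic": sites.census.polymorphic.to_numpy(),
            "site_class": site_class,
            "strand": strand,
        }
    )
    cat_cols = categories.iloc[pos].reset_index(drop=True)
    frame = pd.concat([frame, cat_cols], axis=1)
    frame["any_nap"] = np.where(frame.any_nap_bound, "bound", "never")
    # confounders: replication-strand proxy (origin fixed at coordinate 0 of
    # the circular genome), origin distance, local GC, gene expression
    half = L / 2.0
    on_left_replichore = pos < half
    gene_fwd = genome.gene_strand[pos] > 0
    frame["leading_strand"] = (gene_fwd == on_left_replichore).astype(np.int8)
    frame["origin_distance"] = np.minimum(pos, L - pos) / half
    frame["local_gc"] = _local_gc(genome.codes)[pos]
    if expression is not None:
        gidx = genome.gene_index[pos]
        expr = expression.set_index("gene_id")
        expr_cols = [c for c in expr.columns if c.startswith("expression_")]
        gene_ids = genome.genes.gene_id.to_numpy()
        for c in expr_cols:
            vals = np.zeros(len(pos))
            valid = gidx >= 0
            vals[valid] = expr[c].to_numpy()[gidx[valid]]
            frame[c] = vals
    return frame


def annotate_genome_from_tables(sequence: str, genes: pd.DataFrame) -> sd.Genome:
    """Rebuild per-site annotation arrays from a reference sequence and a
    gene table (real-data mode, where no simulated Genome exists)."""
    L = len(sequence)
    degeneracy = np.full(L, -1, dtype=np.int8)
    gene_strand = np.zeros(L, dtype=np.int8)
    codon_position = np.full(L, -1, dtype=np.int8)
    gene_index = np.full(L, -1, dtype=np.int32)
    for g, row in genes.reset_index(drop=True).iterrows():
        start, end = int(row.start), int(row.end)
        strand = 1 if row.strand == "+" else -1
        gene_strand[start:end] = strand
        gene_index[start:end] = g
        gene_seq = sequence[start:end]
        if strand < 0:
            gene_seq = gene_seq.translate(COMPLEMENT)[::-1]
        for k in range(0, end - start - 2, 3):
            codon = gene_seq[k:k + 3]
            deg = sd._DEGENERACY.get(codon)
            if deg is None:
                continue
            for off in range(3):
                gpos = start + k + off if strand > 0 else end - 1 - (k + off)
                codon_position[gpos] = off
                degeneracy[gpos] = deg if off == 2 else 0
    return sd.Genome(sequence, genes, degeneracy, gene_strand, codon_position, gene_index)


def _sense(base: pd.Series, strand: pd.Series) -> pd.Series:
    return base.where(strand.to_numpy() == "+", base.str.translate(COMPLEMENT))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage in dependency order; returns the manifest."""
    config.validate()
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}}

    def record(stage, params, outputs, summary):
        manifest["stages"][stage] = {
            "params": params,
            "outputs": {os.path.basename(p): _sha256(p) for p in outputs},
            "summary": summary,
        }

    # -- stage 1: inputs (simulated or loaded) -----------------------------
    if config.simulate:
        sim_seed = stage_seed(config.seed, "simulate")
        cfg = sd.SimConfig(**{"seed": sim_seed, **config.sim})
        tree = sd.make_strain_tree(
            cfg.n_strains, seed=sim_seed,
            branch_length_mean=cfg.branch_length_mean,
            support_low_fraction=cfg.support_low_fraction,
            outgroup_length_factor=cfg.outgroup_length_factor,
        )
        genome = sd.simulate_genome(cfg)
        profiles = sd.simulate_binding_profiles(genome, cfg)
        alignment, truth = sd.evolve_alignment(genome, tree, cfg, profiles=profiles)
        expression = sd.simulate_expression(genome, seed=stage_seed(config.seed, "expression"))

        tree_path = os.path.join(outdir, "tree.nwk")
        with open(tree_path, "w") as fh:
            fh.write(tree.to_newick() + "\n")
        aln_path = os.path.join(outdir, "alignment.fasta")
        alignment.write_fasta(aln_path)
        blocks_path = os.path.join(outdir, "blocks.tsv")
        alignment.write_block_index(blocks_path)
        genes_path = os.path.join(outdir, "genes.tsv")
        genome.write_gene_table(genes_path)
        expr_path = os.path.join(outdir, "expression.tsv")
        expression.to_csv(expr_path, sep="\t", index=False)
        truth_path = os.path.join(outdir, "truth.tsv")
        truth.to_tsv(truth_path)
        bed_dir = os.path.join(outdir, "binding")
        os.makedirs(bed_dir, exist_ok=True)
        bed_paths = sd.write_binding_beds(profiles, bed_dir)
        record(
            "simulate",
            {"genome_length": cfg.genome_length, "n_strains": cfg.n_strains,
             "n_genes": cfg.n_genes, "seed": sim_seed},
            [tree_path, aln_path, blocks_path, genes_path, expr_path, truth_path, *bed_paths],
            {"n_true_changes": int(len(truth.true_changes))},
        )
    else:
        tree = Phylogeny.from_newick(
            open(config.tree_file).read(), outgroup=config.outgroup
        )
        alignment = StrainAlignment.from_fasta(
            config.alignment_fasta, config.block_index, outgroup=config.outgroup
        )
        genes = pd.read_csv(config.gene_table, sep="\t")
        ref_seq = "".join(
            b.sequences[alignment.reference] for b in alignment.blocks
        ).replace("-", "A")
        genome = annotate_genome_from_tables(ref_seq, genes)
        profiles = load_binding_profiles(config.binding_dir)
        expression = (
            pd.read_csv(config.expression_table, sep="\t")
            if config.expression_table
            else None
        )
        record("simulate", {"simulate": False}, [], {"inputs": "loaded from disk"})

    reference_sequence = "".join(
        blk.sequences[alignment.reference] for blk in alignment.blocks
    )

    # -- stage 2: uniqueness mask ------------------------------------------
    mask = np.empty((0, 2), dtype=np.int64)
    if config.mask_enabled:
        mask = compute_uniqueness_mask(
            reference_sequence, config.mask_window, config.mask_step,
            config.mask_max_mismatch,
        )
    mask_path = os.path.join(outdir, "mask.bed")
    with open(mask_path, "w") as fh:
        for s, e in mask:
            fh.write(f"genome\t{s}\t{e}\tnon_unique\n")
    record(
        "uniqueness_mask",
        {"window": config.mask_window, "step": config.mask_step,
         "max_mismatch": config.mask_max_mismatch, "enabled": config.mask_enabled},
        [mask_path],
        {"n_intervals": int(len(mask)),
         "masked_bases": int((mask[:, 1] - mask[:, 0]).sum()) if len(mask) else 0},
    )

    # -- stage 3: ancestral changes ----------------------------------------
    sites = extract_analyzable_sites(alignment, mask=mask if len(mask) else None)
    model = estimate_hky(sites)
    reconstruction = marginal_ancestral_reconstruction(sites, tree, model)
    changes = call_high_confidence_changes(
        reconstruction, tree,
        support_threshold=config.support_threshold,
        posterior_threshold=config.posterior_threshold,
    )
    changes_path = os.path.join(outdir, "changes.tsv")
    changes.to_tsv(changes_path)
    census_path = os.path.join(outdir, "census.tsv")
    sites.census.to_csv(census_path, sep="\t", index=False)
    record(
        "ancestral_changes",
        {"posterior_threshold": config.posterior_threshold,
         "support_threshold": config.support_threshold, "model": model.name},
        [changes_path, census_path],
        {"n_sites": int(len(sites.census)),
         "n_polymorphic": int(sites.census.polymorphic.sum()),
         "n_changes": int(len(changes))},
    )

    # -- stage 4: binding categories ---------------------------------------
    categories = classify_all_sites(profiles, len(genome))
    summary = category_summary(categories)
    summary_path = os.path.join(outdir, "binding_categories.tsv")
    summary.to_csv(summary_path, sep="\t", index=False)
    record(
        "binding_categories", {}, [summary_path],
        {"any_nap_bound_bases": int(categories.any_nap_bound.sum())},
    )

    site_frame = build_site_frame(genome, sites, categories, expression)

    # -- stage 5: stratified mutability and odds ratios ---------------------
    est_frames = []
    for site_class in ("fourfold", "coding", "intergenic"):
        est = tabulate_mutability(
            changes.table, site_frame, stratum_col="any_nap",
            site_class=site_class, strand_specific=False,
        )
        est_frames.append(est)
    estimates = pd.concat(est_frames, ignore_index=True)
    mut_path = os.path.join(outdir, "mutability.tsv")
    estimates.to_csv(mut_path, sep="\t", index=False)

    or_rows = []
    four = estimates.loc[estimates.site_class == "fourfold"]
    for cpl in COUPLES:
        bound = four.loc[(four.mutation_type == cpl) & (four.stratum == "bound")]
        unbound = four.loc[(four.mutation_type == cpl) & (four.stratum == "never")]
        if len(bound) and len(unbound):
            res = odds_ratio_ci(
                int(bound.n_changes.iloc[0]), int(bound.n_at_risk.iloc[0]),
                int(unbound.n_changes.iloc[0]), int(unbound.n_at_risk.iloc[0]),
                numerator="unbound",
            )
            or_rows.append(
                {"contrast": "unbound_vs_bound", "protein": "any", "couple": cpl,
                 "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
                 "ci_high": res.ci_high, "defined": res.defined}
            )
    for protein in PROTEINS:
        timing = tabulate_mutability(
            changes.table, site_frame, stratum_col=f"timing_{protein}",
            site_class="fourfold", strand_specific=False,
        )
        for cpl in COUPLES:
            early = timing.loc[
                (timing.mutation_type == cpl) & (timing.stratum == "exclusively_early")
            ]
            late = timing.loc[
                (timing.mutation_type == cpl) & (timing.stratum == "exclusively_late")
            ]
            if len(early) and len(late):
                res = odds_ratio_ci(
                    int(late.n_changes.iloc[0]), int(late.n_at_risk.iloc[0]),
                    int(early.n_changes.iloc[0]), int(early.n_at_risk.iloc[0]),
                    numerator="exclusively_early",
                )
                or_rows.append(
                    {"contrast": "early_vs_late", "protein": protein, "couple": cpl,
                     "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "defined": res.defined}
                )
    or_table = pd.DataFrame(or_rows)
    or_path = os.path.join(outdir, "odds_ratios.tsv")
    or_table.to_csv(or_path, sep="\t", index=False)
    record(
        "mutability", {"site_classes": ["fourfold", "coding", "intergenic"]},
        [mut_path, or_path],
        {"n_estimates": int(len(estimates)), "n_odds_ratios": int(len(or_table))},
    )

    # -- stage 6: methylation-context permutation test ----------------------
    census_pos = set(site_frame.position.to_numpy().tolist())
    full_census = scan_methylation_contexts(reference_sequence)
    keep = lambda df: df.loc[df.position.isin(census_pos)].reset_index(drop=True)
    from .mutability_stats import ContextCensus

    census_ctx = ContextCensus(ccwgg=keep(full_census.ccwgg), control=keep(full_census.control))
    never_any = ~categories.any_nap_bound.to_numpy()
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # sparse strata are expected at desk scale
        ctx_table = context_mutability(census_ctx, changes.table, categories, never_any)
    ctx_path = os.path.join(outdir, "context_mutability.tsv")
    ctx_table.to_csv(ctx_path, sep="\t", index=False)
    combos = combos_from_context_table(ctx_table)
    perm_out = {"n_combos": len(combos)}
    if combos and all(c.evaluable for c in combos):
        result = permutation_pvalue(
            combos, n_reps=config.permutation_reps,
            seed=stage_seed(config.seed, "permutation"),
        )
        perm_out.update(
            {
                "p_value": result.p_value,
                "n_reps": result.n_reps,
                "n_all_conform": result.n_all_conform,
                "observed_conformity": {
                    f"{nap}/{motif}": bool(v)
                    for (nap, motif), v in result.observed_conformity.items()
                },
            }
        )
    perm_path = os.path.join(outdir, "context_permutation.json")
    with open(perm_path, "w") as fh:
        json.dump(perm_out, fh, indent=1, sort_keys=True)
    record(
        "context_test", {"n_reps": config.permutation_reps},
        [ctx_path, perm_path], perm_out,
    )

    # -- stage 7: classifier randomization test -----------------------------
    if config.rf_enabled:
        rf_rows = []
        rf_seed = stage_seed(config.seed, "rf")
        for mtype in config.rf_mutation_types:
            table = build_classifier_table(site_frame, changes.table, mtype)
            if table is None or table.changed.sum() < 5:
                continue
            ds = assemble_dataset(table, mutation_type=mtype, seed=rf_seed)
            params = ClassifierParams(n_trees=config.rf_trees, seed=rf_seed)
            res = binding_randomization_test(
                ds, params, n_rand=config.rf_n_rand, seed=rf_seed
            )
            rf_rows.append(
                {"mutation_type": mtype, "auc_observed": res.auc_observed,
                 "auc_rand_mean": res.mean_randomized, "auc_rand_sd": res.sd_randomized,
                 "z": res.z, "p_one_tailed": res.p_one_tailed}
            )
        rf_table = pd.DataFrame(rf_rows)
        rf_path = os.path.join(outdir, "rf_randomization.tsv")
        rf_table.to_csv(rf_path, sep="\t", index=False)
        fdr_out = {}
        if len(rf_table):
            k = int((rf_table.p_one_tailed < config.rf_alpha).sum())
            fdr = estimate_fdr(config.rf_alpha, len(rf_table), k) if k else None
            fdr_out = {
                "alpha": config.rf_alpha, "m": int(len(rf_table)), "k": k,
                "fdr": None if fdr is None else fdr.fdr,
            }
        fdr_path = os.path.join(outdir, "rf_fdr.json")
        with open(fdr_path, "w") as fh:
            json.dump(fdr_out, fh, indent=1, sort_keys=True)
        record(
            "rf_test",
            {"n_trees": config.rf_trees, "n_rand": config.rf_n_rand,
             "types": list(config.rf_mutation_types)},
            [rf_path, fdr_path],
            {"n_types_tested": int(len(rf_table)), **fdr_out},
        )

    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def build_classifier_table(
    site_frame: pd.DataFrame, changes: pd.DataFrame, mutation_type: str
) -> pd.DataFrame | None:
    """At-risk site table for one strand-specific mutation type.

    At-risk sites are 4-fold synonymous sites (plus 2-fold for transitions)
    whose sense-strand base matches the type's origin base; the outcome
    marks sites that experienced that sense-strand change.
    """
    a, b = mutation_type[0], mutation_type[2]
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    classes = ["fourfold", "twofold"] if (a, b) in transitions else ["fourfold"]
    sub = site_frame.loc[
        site_frame.site_class.isin(classes) & site_frame.strand.isin(["+", "-"])
    ].copy()
    if not len(sub):
        return None
    sense_base = _sense(sub.ref_base, sub.strand)
    sub = sub.loc[sense_base == a]
    if not len(sub):
        return None
    ch = changes.merge(sub[["position", "strand"]], on="position", how="inner")
    ch_sense_from = _sense(ch.from_base, ch.strand)
    ch_sense_to = _sense(ch.to_base, ch.strand)
    hits = set(ch.loc[(ch_sense_from == a) & (ch_sense_to == b), "position"])
    sub["changed"] = sub.position.isin(hits).astype(np.int8)
    sub["twofold"] = (sub.site_class == "twofold").astype(np.int8)
    feature_cols = (
        [f"cat_{p}" for p in PROTEINS]
        + [c for c in sub.columns if c.startswith("expression_")]
        + ["leading_strand", "origin_distance", "local_gc", "twofold", "changed"]
    )
    return sub[feature_cols].reset_index(drop=True)
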