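"""End-to-end orchestration: data -> infection calls -> trees -> report.

``run_pipeline`` sequences every analysis stage on either a synthetic bundle
(generated in memory from :class:`SyntheticParams`) or a file bundle written
by :func:`cytosym.synthetic.make_fixture_bundle`, and writes per-stage TSV
reports plus one machine-readable ``summary.json``.  Every number in the
summary is produced by a module operation; the report layer only collects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import congruence as cong
from . import coverage as cov
from . import io as cio
from . import markers, popgen, synthetic
from .alignment import build_ungapped_alignment
from .dating import (ChainSettings, lognormal_rate_prior,
                     prepare_dating_alignment, run_dating_mcmc,
                     summarize_posterior)
from .trees import (bootstrap_support, midpoint_root, patristic_distances,
                    tree_to_newick)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and budgets for one pipeline run.

    Thresholds default to the published classification rule (mean depth > 1,
    breadth > 0.90, consensus depth window 10..100).  Simulation budgets are
    deliberately small so a full run stays interactive; raise them for real
    inference.
    """

    synthetic_params: synthetic.SyntheticParams | None = None
    input_dir: str | None = None
    output_dir: str = "cytosym_out"
    depth_min: float = cov.DEPTH_MIN
    breadth_min: float = cov.BREADTH_MIN
    consensus_min_depth: int = cov.CONSENSUS_MIN_DEPTH
    consensus_max_depth: int = cov.CONSENSUS_MAX_DEPTH
    bootstrap_reps: int = 50
    tajima_reps: int = 1000
    kst_permutations: int = 500
    chain: ChainSettings = field(default_factory=lambda: ChainSettings(
        n_iterations=600, burn_in=0.25, thin=2))
    run_dating: bool = True
    run_congruence: bool = True
    seed: int = 0


def _load_inputs(config: PipelineConfig):
    if config.input_dir is not None:
        d = Path(config.input_dir)
        profiles = cio.read_depth_profiles(d / "depth_profiles.tsv")
        counts = cio.read_base_counts(d / "base_counts.tsv")
        meta = cio.read_metadata(d / "metadata.tsv")
        annotations = cio.read_annotation(d / "annotation.tsv")
        truth = None
        if (d / "truth.json").exists():
            truth = cio.read_truth(d / "truth.json")
        return profiles, counts, meta, annotations, truth
    if config.synthetic_params is None:
        raise ValueError("config needs synthetic_params or input_dir")
    data = synthetic.simulate_dataset(config.synthetic_params)
    truth = {"infected": data["infected"],
             "class_rates": data["truth"].class_rates,
             "newick": data["truth"].newick}
    return (data["profiles"], data["base_counts"], data["metadata"],
            data["annotations"], truth)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the summary dict (also written as JSON)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles, counts, meta, annotations, truth = _load_inputs(config)
    strains = sorted({s for s, _ in profiles})
    summary: dict = {"seed": config.seed, "n_strains": len(strains)}

    # ----- stage 1: consensus + infection calls --------------------------
    lengths = {ref: profiles[(strains[0], ref)].depths.size
               for _, ref in profiles if (strains[0], ref) in profiles}
    consensus = {ref: {} for ref in lengths}
    for (s, ref) in counts:
        consensus[ref][s] = cov.call_consensus(
            counts[(s, ref)], lengths[ref], strain_id=s, reference_id=ref,
            min_depth=config.consensus_min_depth,
            max_depth=config.consensus_max_depth)
    for ref in consensus:
        cio.write_fasta(out / f"{ref}_consensus.fasta",
                        {s: consensus[ref][s].sequence
                         for s in sorted(consensus[ref])})
    nuclear_depths = {s: cov.mean_depth(profiles[(s, "nuclear")])
                      for s in strains if (s, "nuclear") in profiles}
    ploidy = dict(zip(meta["strain_id"], meta["ploidy"].astype(int)))
    calls = cov.call_infection_table(
        {s: profiles[(s, "wolbachia")] for s in strains},
        consensus["wolbachia"], nuclear_depths, ploidy,
        depth_min=config.depth_min, breadth_min=config.breadth_min)
    cio.write_infection_calls(out / "infection_calls.tsv", calls)
    infected = dict(zip(calls["strain_id"], calls["status"] == "infected"))
    summary["infected_fraction"] = float(np.mean(list(infected.values())))
    summary["mean_relative_copy_number_wolbachia"] = float(
        calls.loc[calls["status"] == "infected", "relative_copy_number"]
        .mean()) if any(infected.values()) else None
    if truth is not None:
        agree = sum(infected[s] == bool(truth["infected"][s]) for s in strains)
        summary["infection_call_accuracy"] = agree / len(strains)

    # ----- stage 2: alignments ------------------------------------------
    mt_cons = {s: consensus["mtdna"][s].sequence for s in strains}
    mt_aln = build_ungapped_alignment(mt_cons, annotations["mtdna"], "mtdna")
    infected_ids = [s for s in strains if infected[s]]
    wol_aln = None
    if len(infected_ids) >= 3:
        wol_cons = {s: consensus["wolbachia"][s].sequence for s in infected_ids}
        wol_aln = build_ungapped_alignment(wol_cons, annotations["wolbachia"],
                                           "wolbachia")
    summary["mt_alignment_columns"] = int(mt_aln.n_columns)
    summary["wol_alignment_columns"] = (int(wol_aln.n_columns)
                                        if wol_aln is not None else 0)

    from .alignment import variable_sites_table
    var_tables = [variable_sites_table(mt_aln)]
    if wol_aln is not None:
        var_tables.append(variable_sites_table(wol_aln))
    pd.concat(var_tables).to_csv(out / "variable_sites.tsv", sep="\t",
                                 index=False)

    # consensus support at variable mtDNA sites (heteroplasmy proxy)
    var_coords = mt_aln.coords[mt_aln.variable_columns()]
    supports = []
    for s in strains:
        try:
            supports.append(cov.consensus_support(
                counts[(s, "mtdna")], consensus["mtdna"][s], var_coords))
        except ValueError:
            continue
    summary["mean_consensus_support"] = (float(np.mean(supports))
                                         if supports else None)

    # ----- stage 3: genealogies -----------------------------------------
    mt_tree, _ = bootstrap_support(mt_aln, config.bootstrap_reps,
                                   seed=config.seed + 11)
    mt_rooted = midpoint_root(mt_tree)
    (out / "mtdna_tree.nwk").write_text(tree_to_newick(mt_rooted) + "\n")
    if wol_aln is not None:
        wol_tree, _ = bootstrap_support(wol_aln, config.bootstrap_reps,
                                        seed=config.seed + 12)
        (out / "wolbachia_tree.nwk").write_text(
            tree_to_newick(midpoint_root(wol_tree)) + "\n")

    # ----- stage 4: congruence ------------------------------------------
    if config.run_congruence and wol_aln is not None and len(infected_ids) >= 4:
        single, two = cong.fit_topology_models(
            wol_aln, mt_aln.subset_rows(infected_ids))
        comp = cong.model_comparison(single=single, two=two)
        verdict = ("single topology" if comp.delta_aic > 0 else "two topologies")
        summary["congruence"] = {
            "AIC_single": comp.AIC_single, "AIC_two": comp.AIC_two,
            "delta_AIC": comp.delta_aic, "verdict": verdict}
        pd.DataFrame([{
            "lnL_single": comp.lnL_single, "lnL_two": comp.lnL_two,
            "k_single": comp.k_single, "k_two": comp.k_two,
            "AIC_single": comp.AIC_single, "AIC_two": comp.AIC_two,
            "delta_AIC": comp.delta_aic, "verdict": verdict,
        }]).to_csv(out / "congruence.tsv", sep="\t", index=False)

    # ----- stage 5: dating ----------------------------------------------
    if config.run_dating and wol_aln is not None and len(infected_ids) >= 4:
        dated_aln = prepare_dating_alignment(mt_aln.subset_rows(infected_ids),
                                             wol_aln)
        from .alignment import pairwise_distances
        from .trees import neighbor_joining
        topo = midpoint_root(neighbor_joining(
            pairwise_distances(dated_aln, "raw"), dated_aln.ids))
        samples = run_dating_mcmc(dated_aln, topo,
                                  rate_prior=lognormal_rate_prior(),
                                  settings=config.chain,
                                  seed=config.seed + 21)
        post = summarize_posterior(samples)
        root_key = max(post.age_median, key=post.age_median.get)
        summary["dating"] = {
            "rate_median": post.rate_median,
            "root_age_generations": post.age_median[root_key],
            "root_age_years": post.age_median_years[root_key],
            "root_age_ci_years": list(post.age_ci_years[root_key]),
        }
        samples.to_csv(out / "dating_samples.tsv", sep="\t", index=False)
        pd.DataFrame({
            "parameter": (list(post.rate_median)
                          + [f"age:{k}" for k in post.age_median]),
            "median": (list(post.rate_median.values())
                       + list(post.age_median.values())),
            "ci_low": ([post.rate_ci[k][0] for k in post.rate_median]
                       + [post.age_ci[k][0] for k in post.age_median]),
            "ci_high": ([post.rate_ci[k][1] for k in post.rate_median]
                        + [post.age_ci[k][1] for k in post.age_median]),
        }).to_csv(out / "dating_summary.tsv", sep="\t", index=False,
                  float_format="%.6g")

        # dated tree: posterior-median node ages + ML ancestral locations
        from .dating import LOCATIONS, _node_keys, phylogeo_ancestral_states
        from .likelihood import flatten_tree
        dated = topo.clone(depth=1)
        flat = flatten_tree(dated)
        keys = _node_keys(flat)
        for i, node in enumerate(flat.nodes):
            node.age = (post.age_median.get(keys[i], 0.0)
                        if i >= flat.n_tips else 0.0)
        for node in dated.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = max(node.parent_node.age - node.age, 0.0)
        regions = meta.set_index("strain_id")["region"].to_dict()
        try:
            _, node_probs = phylogeo_ancestral_states(dated, regions)
            for i, node in enumerate(flat.nodes):
                if i >= flat.n_tips:
                    p = node_probs[keys[i]]
                    loc = LOCATIONS[int(np.argmax(p))]
                    node.label = f"{loc}_{p.max():.2f}_age_{node.age:.0f}"
            root_probs = node_probs[keys[flat.postorder[-1]]]
            summary["dating"]["root_location_probs"] = {
                loc: float(p) for loc, p in zip(LOCATIONS, root_probs)}
        except ValueError as exc:
            logger.warning("phylogeography skipped: %s", exc)
        (out / "dated_tree.nwk").write_text(tree_to_newick(dated) + "\n")

    # ----- stage 6: diversity + Kst --------------------------------------
    div_rows = []
    for name, aln in (("mtdna_all", mt_aln),
                      ("mtdna_infected", mt_aln.subset_rows(infected_ids)
                       if len(infected_ids) >= 2 else None),
                      ("wolbachia_infected", wol_aln)):
        if aln is None or aln.n_sequences < 2:
            continue
        est = popgen.diversity_summary(aln)
        p = None
        if est.S >= 1 and config.tajima_reps > 0:
            _, p = popgen.conditional_coalescent_null(
                est.n, est.S, config.tajima_reps, seed=config.seed + 31,
                observed_d=est.tajimas_d)
        div_rows.append({"sample": name, "N": est.n, "L": est.L, "S": est.S,
                         "pi": est.pi, "theta": est.theta_w,
                         "tajimas_d": est.tajimas_d, "p": p})
    diversity = pd.DataFrame(div_rows)
    diversity.to_csv(out / "diversity.tsv", sep="\t", index=False,
                     float_format="%.6g")
    summary["diversity"] = div_rows

    labels = np.array(["infected" if infected[s] else "uninfected"
                       for s in strains])
    pops = meta.set_index("strain_id").loc[strains, "population"].to_numpy()
    if len(set(labels)) == 2:
        D, _ = patristic_distances(mt_rooted, strains)
        try:
            kst = popgen.kst_permutation_test(
                D, labels, pops, config.kst_permutations,
                seed=config.seed + 41)
            summary["kst"] = {"weighted_kst": kst.weighted_kst,
                              "p_value": kst.p_value}
        except ValueError as exc:
            summary["kst"] = {"error": str(exc)}

    # ----- stage 7: marker genotyping ------------------------------------
    table = markers.HaplotypeTable({})
    geno_rows = []
    for s in strains:
        seq = consensus["mtdna"][s].sequence
        if len(seq) >= markers.COI_WINDOW[1]:
            hap = markers.assign_coi_haplotype(markers.extract_coi(seq), table)
            hap_id = hap.haplotype_id
        else:
            hap_id = None
        snp = (markers.classify_mt_snp_type(seq)
               if len(seq) >= max(markers.MT_SNP_POSITIONS) else "unknown")
        geno_rows.append({"strain_id": s, "mt_snp_type": snp,
                          "coi_haplotype": hap_id})
    genotypes = pd.DataFrame(geno_rows)
    genotypes.to_csv(out / "genotypes.tsv", sep="\t", index=False)
    summary["coi_haplotypes"] = int(genotypes["coi_haplotype"].nunique())

    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=float))
    return summary
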