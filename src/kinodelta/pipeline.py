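"""End-to-end pipeline orchestration.

A run is described by a config mapping (YAML on disk) with three
sections: ``seed``, ``simulate`` (SimConfig overrides — presence of the
section requests simulation) and ``thresholds``. Threshold defaults are
the analysis defaults of the method: 3/6 SD with log2 floors 0.38/0.5
for calling, |r| ≥ 0.6 with a 25-molecule minimum for strain-pair
correlations, |r| ≥ 0.7 with Bonferroni p ≤ 0.001 and a 50% shared-
strain requirement for covariance edges, 50% strain coverage, 5%
trimming per tail and 1000 permutations. Thresholds live only in the
config; stage functions receive them as arguments.

Every stage's outputs are written under the run directory together with
a machine-readable manifest (seed, thresholds, stage counts); re-running
the same config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

from . import covariance as cov
from . import gene_correlation as gc
from . import io_formats as io
from . import phenotype as ph
from .errors import ConfigError
from .normalize import process_study
from .simulate import SimConfig, build_design, build_truth, \
    simulate_reporter_data

logger = logging.getLogger("kinodelta")

DEFAULT_THRESHOLDS = {
    "sd_mult_both": 3.0,
    "sd_mult_single": 6.0,
    "fc_floor_protein": 0.38,
    "fc_floor_phospho": 0.5,
    "trim_fraction": 0.05,
    "min_coverage": 0.5,
    "gene_r_min": 0.6,
    "gene_min_molecules": 25,
    "cov_r_min": 0.7,
    "cov_p_adj_max": 0.001,
    "cov_min_shared_fraction": 0.5,
    "n_permutations": 1000,
    "enrichment_alpha": 0.01,
}

_TOP_KEYS = {"seed", "simulate", "thresholds"}


def resolve_config(config: dict) -> tuple[SimConfig, dict, int]:
    """Validate a run config; unknown keys fail before any computation."""
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    thresholds = dict(DEFAULT_THRESHOLDS)
    extra = set(config.get("thresholds", {})) - set(DEFAULT_THRESHOLDS)
    if extra:
        raise ConfigError(f"unknown threshold keys: {sorted(extra)}")
    thresholds.update(config.get("thresholds", {}))
    sim_kwargs = dict(config.get("simulate", {}))
    valid = {f.name for f in dataclasses.fields(SimConfig)}
    bad = set(sim_kwargs) - valid
    if bad:
        raise ConfigError(f"unknown simulate keys: {sorted(bad)}")
    sim_kwargs.setdefault("seed", seed)
    if "effect_grid" in sim_kwargs:
        sim_kwargs["effect_grid"] = tuple(sim_kwargs["effect_grid"])
    sim = SimConfig(**sim_kwargs)
    sim.validate()
    return sim, thresholds, seed


def run_pipeline(config: dict, outdir) -> dict:
    """Simulate → normalize → call → gene network → covariance.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    sim_config, thr, seed = resolve_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = build_truth(sim_config)
    design = build_design(sim_config)
    tables = simulate_reporter_data(truth, design, sim_config)
    io.write_simulation(tables, design, truth, outdir / "simulated")

    norm = process_study(tables["protein"], tables["phosphosite"],
                         truth.site_to_protein,
                         min_fraction=thr["min_coverage"],
                         trim_fraction=thr["trim_fraction"])
    io.write_ratio_matrix(norm["protein"], outdir / "ratios_protein.tsv")
    io.write_ratio_matrix(norm["phospho_norm"],
                          outdir / "ratios_phospho_normalized.tsv")

    calls = {}
    merged_by_level = {}
    for level, key, floor in [
            ("protein", "protein", thr["fc_floor_protein"]),
            ("phospho_raw", "phospho_raw", thr["fc_floor_phospho"]),
            ("phospho_norm", "phospho_norm", thr["fc_floor_phospho"])]:
        matrix = norm[key]
        merged, _ = ph.merge_replicates(matrix)
        merged_by_level[level] = merged
        stats = ph.compute_trimmed_stats(merged, thr["trim_fraction"])
        calls[level] = ph.call_regulated_events(
            matrix, stats, fc_floor=floor,
            sd_mult_both=thr["sd_mult_both"],
            sd_mult_single=thr["sd_mult_single"],
            deletion_map=truth.deletion_map,
            site_to_protein=truth.site_to_protein)
        calls[level].to_csv(outdir / f"calls_{level}.tsv", sep="\t",
                            index=False)
    events, attribution = ph.attribute_phospho_events(
        calls["phospho_raw"], calls["phospho_norm"])
    events.to_csv(outdir / "phospho_events_attributed.tsv", sep="\t",
                  index=False)
    impact = ph.impact_factor(calls["protein"], merged_by_level["protein"])
    impact.to_frame("impact_percent").to_csv(
        outdir / "impact_factor_protein.tsv", sep="\t")
    _, reg_summary = ph.build_regulation_network(calls["protein"])
    io.write_network(calls["protein"], outdir / "regulation_protein.sif",
                     dialect="sif")

    prot_masked = gc.mask_deleted(norm["protein"], truth.deletion_map)
    merged_masked, _ = ph.merge_replicates(prot_masked)
    gene_edges, gene_matrix = gc.build_gene_network(
        merged_masked, fc_floor=thr["fc_floor_protein"],
        r_min=thr["gene_r_min"], min_molecules=thr["gene_min_molecules"])
    io.write_network(gene_edges, outdir / "gene_network_protein.tsv")
    order = gc.order_by_clustering(gene_matrix)
    gene_matrix.loc[order, order].to_csv(
        outdir / "gene_correlation_matrix.tsv", sep="\t")

    cov_edges, n_pairs = cov.molecule_pair_correlations(
        merged_masked, min_shared_fraction=thr["cov_min_shared_fraction"],
        r_min=thr["cov_r_min"], p_adj_max=thr["cov_p_adj_max"])
    io.write_network(cov_edges, outdir / "covariance_protein.tsv")
    perm = cov.permutation_false_positive_rate(
        merged_masked, n_perm=thr["n_permutations"],
        min_shared_fraction=thr["cov_min_shared_fraction"],
        r_min=thr["cov_r_min"], p_adj_max=thr["cov_p_adj_max"],
        seed=seed)

    manifest = {
        "seed": seed,
        "thresholds": thr,
        "simulate": dataclasses.asdict(sim_config),
        "counts": {
            "n_plexes": design.n_plexes,
            "n_strains": len(design.strains),
            "protein_calls": int(len(calls["protein"])),
            "phospho_raw_calls": int(len(calls["phospho_raw"])),
            "phospho_norm_calls": int(len(calls["phospho_norm"])),
            "regulation_network": reg_summary,
            "gene_edges": int(len(gene_edges)),
            "covariance_edges": int(len(cov_edges)),
            "covariance_pairs_evaluated": int(n_pairs),
        },
        "phospho_normalizable_fraction": norm["normalizable_fraction"],
        "attribution_fractions": attribution["fractions"],
        "permutation_fpr_percent": perm["rate_percent"],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", outdir)
    return manifest
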