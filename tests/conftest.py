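"""Shared fixtures: a full-scale synthetic study and small builders."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from kinodelta import phenotype as ph
from kinodelta.containers import PlexIntensityTable
from kinodelta.normalize import process_study
from kinodelta.simulate import (SimConfig, build_design, build_truth,
                                simulate_reporter_data)


def make_plex(values, strains=None, bridge_first=True, plex_id="p1",
              level="protein", molecules=None, replicate=1):
    """Build a PlexIntensityTable from a 2-D array; channel 0 is bridge."""
    values = np.asarray(values, dtype=float)
    n_mol, n_ch = values.shape
    molecules = molecules or [f"M{i}" for i in range(n_mol)]
    channels = [f"ch{j + 1:02d}" for j in range(n_ch)]
    strains = strains or [f"S{j}" for j in range(1, n_ch)]
    meta = pd.DataFrame({
        "strain": (["WT"] + list(strains)) if bridge_first else list(strains),
        "replicate": replicate,
        "bridge": [bridge_first] + [False] * (n_ch - 1),
        "batch": 1,
    }, index=channels)
    data = pd.DataFrame(values, index=molecules, columns=channels)
    return PlexIntensityTable(plex_id, level, data, meta)


def call_level(result, truth, key):
    """Run merge → trimmed stats → calling for one matrix of a study."""
    matrix = result[key]
    merged, _ = ph.merge_replicates(matrix)
    stats = ph.compute_trimmed_stats(merged)
    calls = ph.call_regulated_events(
        matrix, stats, deletion_map=truth.deletion_map,
        site_to_protein=truth.site_to_protein)
    return calls, merged


@pytest.fixture(scope="session")
def study():
    """Full-scale synthetic study: 110 strains × duplicates, 2,000
    proteins, 3,000 phosphosites, replicate noise 0.1, planted |log2|
    effects {0.6, 1.0}."""
    config = SimConfig(seed=1)
    truth = build_truth(config)
    design = build_design(config)
    tables = simulate_reporter_data(truth, design, config)
    norm = process_study(tables["protein"], tables["phosphosite"],
                         truth.site_to_protein)
    return SimpleNamespace(config=config, truth=truth, design=design,
                           tables=tables, norm=norm)


@pytest.fixture(scope="session")
def study_calls(study):
    """Regulation calls for all three levels of the session study."""
    out = {}
    for key in ("protein", "phospho_raw", "phospho_norm"):
        calls, merged = call_level(study.norm, study.truth, key)
        out[key] = SimpleNamespace(calls=calls, merged=merged)
    return out


@pytest.fixture(scope="session")
def null_study():
    """Same scale, nothing planted: pure measurement noise."""
    config = SimConfig(seed=9, n_regulators=0, n_modules=0,
                       n_phosphosites=500)
    truth = build_truth(config)
    design = build_design(config)
    tables = simulate_reporter_data(truth, design, config)
    norm = process_study(tables["protein"], tables["phosphosite"],
                         truth.site_to_protein)
    return SimpleNamespace(config=config, truth=truth, norm=norm)


@pytest.fixture(scope="session")
def noiseless_study():
    """Small noiseless study: the chain must be exact on it."""
    config = SimConfig(n_strains=20, n_regulators=4, n_proteins=400,
                       n_phosphosites=300, targets_per_regulator=10,
                       phospho_targets_per_regulator=8, n_modules=1,
                       module_size=5, n_assignment_groups=4,
                       noise_sd=0.0, loading_cv=0.0, missing_rate_plex=0.0,
                       seed=7)
    truth = build_truth(config)
    design = build_design(config)
    tables = simulate_reporter_data(truth, design, config)
    norm = process_study(tables["protein"], tables["phosphosite"],
                         truth.site_to_protein)
    return SimpleNamespace(config=config, truth=truth, tables=tables,
                           norm=norm)
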