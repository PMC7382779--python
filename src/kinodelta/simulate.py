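"""Synthetic multi-plex TMT data with planted regulatory ground truth.

Emulates a kinase/phosphatase deletion-strain panel measured by isobaric
labelling: ~110 single-deletion strains in biological duplicate spread
over 11-channel plexes, each plex carrying one wild-type bridge channel.
The generator plants

* deletion of the cognate gene product (suppressed to near background),
* regulator → target effects on protein abundance,
* regulator → phosphosite effects, a configurable fraction of which are
  purely protein-driven (the phosphosite moves only because its protein
  does),
* co-regulated protein modules driven jointly by several regulators
  (the substrate of covariance-network recovery),
* per-channel loading variation, log-normal measurement noise and
  plex-structured missingness,

and returns machine-readable truth tables so every downstream stage can
be scored against known answers.

Noise model: multiplicative log-normal noise (log2-scale SD ``noise_sd``)
is applied to sample channels; the wild-type bridge is modelled as a
noise-free reference, so ``noise_sd`` directly parameterizes the SD of a
single replicate's log2 ratio and the difference between two biological
replicates has SD ``noise_sd·√2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import PlexDesign, PlexIntensityTable
from .errors import ConfigError, DesignError

__all__ = ["SimConfig", "GroundTruth", "build_truth", "build_design",
           "simulate_reporter_data"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic study.

    Defaults mirror the panel design this package targets: 110 deletion
    strains in biological duplicate over 14 assignment groups of TMT
    11-plexes (28 plexes total), with replicate log2-ratio noise 0.1 and
    planted |log2| effects of 0.6 and 1.0.
    """

    n_strains: int = 110
    n_regulators: int = 10
    n_proteins: int = 2000
    n_phosphosites: int = 3000
    plex_size: int = 11
    n_assignment_groups: int = 14
    replicate_count: int = 2
    noise_sd: float = 0.1          # log2-scale SD of one replicate ratio
    loading_cv: float = 0.1        # CV of per-channel loading factors
    effect_grid: tuple = (0.6, 1.0)  # |log2| planted effect sizes
    missing_rate_plex: float = 0.04  # P(molecule absent from a whole plex)
    targets_per_regulator: int = 30
    phospho_targets_per_regulator: int = 30
    protein_driven_fraction: float = 0.6
    n_modules: int = 3
    module_size: int = 20
    n_shared_pairs: int = 1        # regulator pairs with overlapping targets
    shared_fraction: float = 0.8   # fraction of targets those pairs share
    deletion_log2: float = -5.0    # suppression of the deleted gene product
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_strains": self.n_strains, "n_proteins": self.n_proteins,
            "n_phosphosites": self.n_phosphosites,
            "replicate_count": self.replicate_count,
            "n_assignment_groups": self.n_assignment_groups,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigError(f"{name} must be >= 1, got {value}")
        for name, value in [("n_regulators", self.n_regulators),
                            ("targets_per_regulator", self.targets_per_regulator),
                            ("phospho_targets_per_regulator",
                             self.phospho_targets_per_regulator),
                            ("n_modules", self.n_modules),
                            ("module_size", self.module_size),
                            ("n_shared_pairs", self.n_shared_pairs)]:
            if value < 0:
                raise ConfigError(f"{name} must be >= 0, got {value}")
        if self.plex_size < 3:
            raise ConfigError(f"plex_size must be >= 3, got {self.plex_size}")
        for name, value in [("missing_rate_plex", self.missing_rate_plex),
                            ("protein_driven_fraction", self.protein_driven_fraction),
                            ("shared_fraction", self.shared_fraction)]:
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        for name, value in [("noise_sd", self.noise_sd),
                            ("loading_cv", self.loading_cv)]:
            if value < 0 or not math.isfinite(value):
                raise ConfigError(f"{name} must be finite and >= 0, got {value}")
        if not self.effect_grid or not all(
                math.isfinite(e) for e in self.effect_grid):
            raise ConfigError("effect_grid must be a non-empty list of finite "
                              "effect sizes")
        if self.n_regulators > self.n_strains:
            raise ConfigError("n_regulators cannot exceed n_strains")
        if self.n_strains > self.n_proteins:
            raise ConfigError("n_proteins must cover one deleted gene per strain")


@dataclass
class GroundTruth:
    """Planted regulator → target effect map of one synthetic study."""

    deletion_map: dict            # strain -> deleted gene
    protein_effects: dict         # (strain, protein) -> log2 effect
    phospho_effects: dict         # (strain, site) -> log2 stoichiometry effect
    modules: dict                 # module name -> frozenset of proteins
    site_to_protein: dict         # site -> cognate protein
    module_effects: dict = field(default_factory=dict)   # (module, strain) -> log2
    phospho_target_class: dict = field(default_factory=dict)
    # (strain, site) -> "protein_driven" | "phospho_driven"

    def __post_init__(self) -> None:
        genes = list(self.deletion_map.values())
        if len(set(genes)) != len(genes):
            raise ConfigError("deletion_map must be injective over strains")

    @property
    def regulators(self) -> list[str]:
        regs = {s for s, _ in self.protein_effects}
        regs |= {s for s, _ in self.phospho_effects}
        return sorted(regs)


def _protein_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def build_truth(config: SimConfig) -> GroundTruth:
    """Plant deletions, regulator targets and co-regulated modules."""
    config.validate()
    rng = np.random.default_rng([config.seed, 11])

    proteins = _protein_names(config.n_proteins)
    deleted = proteins[: config.n_strains]
    strains = [f"d{g}" for g in deleted]
    deletion_map = dict(zip(strains, deleted))
    regulators = strains[: config.n_regulators]

    # phosphosites on random proteins, unique (protein, position) keys
    site_to_protein: dict[str, str] = {}
    host_idx = rng.integers(0, config.n_proteins, size=config.n_phosphosites)
    used_positions: dict[str, set] = {}
    residues = np.array(list("STY"))
    for i in range(config.n_phosphosites):
        prot = proteins[host_idx[i]]
        taken = used_positions.setdefault(prot, set())
        pos = int(rng.integers(1, 2000))
        while pos in taken:
            pos = int(rng.integers(1, 2000))
        taken.add(pos)
        res = residues[rng.integers(0, 3)]
        site_to_protein[f"{prot}_p{res}{pos}"] = prot
    sites = list(site_to_protein)

    grid = np.asarray(config.effect_grid, dtype=float)

    def draw_effect() -> float:
        return float(rng.choice(grid) * rng.choice([-1.0, 1.0]))

    # Effect families are planted on disjoint molecule sets so every
    # downstream metric has an unambiguous truth: phospho targets sit on
    # single-site host proteins (the host effect moves exactly one site),
    # while abundance targets and module members are preferentially
    # proteins without any phosphosite (their movement drags no site
    # along at the raw phospho level).
    n_sites_of: dict[str, int] = {}
    for prot in site_to_protein.values():
        n_sites_of[prot] = n_sites_of.get(prot, 0) + 1
    never_deleted = set(proteins[config.n_strains:])

    single_site = [s for s in sites
                   if n_sites_of[site_to_protein[s]] == 1
                   and site_to_protein[s] in never_deleted]
    rng.shuffle(single_site)

    phospho_effects: dict = {}
    phospho_class: dict = {}
    protein_effects: dict = {}
    scursor = 0

    def take_sites(k: int) -> list[str]:
        nonlocal scursor
        if scursor + k > len(single_site):
            raise ConfigError(
                "n_phosphosites too small for the requested phospho targets")
        out = single_site[scursor: scursor + k]
        scursor += k
        return out

    def plant_site(reg: str, site: str, protein_driven: bool,
                   e: float) -> None:
        if protein_driven:
            # protein-driven: the protein moves, stoichiometry does not
            protein_effects[(reg, site_to_protein[site])] = e
            phospho_class[(reg, site)] = "protein_driven"
        else:
            phospho_effects[(reg, site)] = e
            phospho_class[(reg, site)] = "phospho_driven"

    # paired regulators share phospho targets at the same rate as their
    # protein targets so the pair's overall profile overlap equals
    # shared_fraction
    k_sites = config.phospho_targets_per_regulator
    n_pd = round(config.protein_driven_fraction * k_sites)
    paired = min(config.n_shared_pairs, config.n_regulators // 2)
    for p in range(paired):
        a, b = regulators[2 * p], regulators[2 * p + 1]
        k_sh = round(config.shared_fraction * k_sites)
        n_pd_sh = round(config.protein_driven_fraction * k_sh)
        for j, site in enumerate(take_sites(k_sh)):
            e = draw_effect()
            for reg in (a, b):
                plant_site(reg, site, j < n_pd_sh, e)
        for reg in (a, b):
            for j, site in enumerate(take_sites(k_sites - k_sh)):
                plant_site(reg, site, j < n_pd - n_pd_sh, draw_effect())
    for reg in regulators[2 * paired:]:
        for j, site in enumerate(take_sites(k_sites)):
            plant_site(reg, site, j < n_pd, draw_effect())
    phospho_hosts = {site_to_protein[s] for s in single_site[:scursor]}

    pool = [p for p in proteins[config.n_strains:]
            if p not in phospho_hosts]
    siteless = [p for p in pool if n_sites_of.get(p, 0) == 0]
    sited = [p for p in pool if n_sites_of.get(p, 0) > 0]
    rng.shuffle(siteless)
    rng.shuffle(sited)
    eligible = siteless + sited
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        if cursor + k > len(eligible):
            raise ConfigError(
                "n_proteins too small for the requested targets and modules")
        out = eligible[cursor: cursor + k]
        cursor += k
        return out

    # regulator pairs with overlapping target sets (pathway co-membership);
    # the pairs' profile overlap is controlled solely by shared_fraction,
    # so paired regulators are kept out of module regulation below
    n_shared = round(config.shared_fraction * config.targets_per_regulator)
    paired = min(config.n_shared_pairs, config.n_regulators // 2)
    for p in range(paired):
        a, b = regulators[2 * p], regulators[2 * p + 1]
        for t in take(n_shared):
            e = draw_effect()
            protein_effects[(a, t)] = e
            protein_effects[(b, t)] = e
        for reg in (a, b):
            for t in take(config.targets_per_regulator - n_shared):
                protein_effects[(reg, t)] = draw_effect()
    for reg in regulators[2 * paired:]:
        for t in take(config.targets_per_regulator):
            protein_effects[(reg, t)] = draw_effect()

    # co-regulated modules: a block of proteins moved jointly by several
    # regulators — the signal covariance networks should recover
    modules: dict = {}
    module_effects: dict = {}
    module_regs = regulators[2 * paired:]
    n_module_regs = min(len(module_regs),
                        max(3, config.n_regulators // 2))
    for m in range(config.n_modules):
        name = f"module{m + 1:02d}"
        members = take(config.module_size)
        modules[name] = frozenset(members)
        if n_module_regs == 0:
            continue
        regs = rng.choice(len(module_regs), size=n_module_regs,
                          replace=False)
        for ri in regs:
            e = draw_effect()
            module_effects[(name, module_regs[ri])] = e
            for t in members:
                protein_effects[(module_regs[ri], t)] = e

    return GroundTruth(
        deletion_map=deletion_map,
        protein_effects=protein_effects,
        phospho_effects=phospho_effects,
        modules=modules,
        site_to_protein=site_to_protein,
        module_effects=module_effects,
        phospho_target_class=phospho_class,
    )


def build_design(config: SimConfig) -> PlexDesign:
    """Assign strains to plex groups; one bridge channel per plex.

    Each strain is randomly assigned to one of ``n_assignment_groups``
    groups; each group is measured ``replicate_count`` times (replicate
    plexes mirror group membership), e.g. 110 strains in 14 groups with
    duplicates give 28 plexes.
    """
    config.validate()
    capacity = config.n_assignment_groups * (config.plex_size - 1)
    if config.n_strains > capacity:
        raise DesignError(
            f"{config.n_strains} strains exceed the capacity "
            f"{capacity} of {config.n_assignment_groups} groups of "
            f"{config.plex_size - 1} sample channels")
    rng = np.random.default_rng([config.seed, 22])
    strains = [f"dG{i:04d}" for i in range(1, config.n_strains + 1)]
    order = rng.permutation(config.n_strains)
    groups: list[list[str]] = [[] for _ in range(config.n_assignment_groups)]
    for k, idx in enumerate(order):
        groups[k % config.n_assignment_groups].append(strains[idx])
    batches = rng.integers(1, 17, size=(config.n_strains, config.replicate_count))
    batch_of = {(strains[i], r + 1): int(batches[i, r])
                for i in range(config.n_strains)
                for r in range(config.replicate_count)}

    rows = []
    for rep in range(1, config.replicate_count + 1):
        for g, members in enumerate(groups):
            if not members:
                continue
            plex = f"plex_g{g + 1:02d}_r{rep}"
            rows.append({"plex": plex, "channel": "ch01", "strain": "WT",
                         "replicate": rep, "bridge": True, "batch": 0})
            for j, strain in enumerate(members):
                rows.append({"plex": plex, "channel": f"ch{j + 2:02d}",
                             "strain": strain, "replicate": rep,
                             "bridge": False,
                             "batch": batch_of[(strain, rep)]})
    return PlexDesign(pd.DataFrame(rows))


def simulate_reporter_data(truth: GroundTruth, design: PlexDesign,
                           config: SimConfig) -> dict:
    """Generate per-plex reporter-intensity tables at protein and
    phosphosite level.

    intensity = baseline · 2^effect · loading_factor · 2^N(0, noise_sd)
    for sample channels; the bridge carries baseline · loading_factor.
    Baselines are drawn log-uniformly over three orders of magnitude.
    Missingness removes a molecule from all channels of a plex at once.

    Returns ``{"protein": [PlexIntensityTable...],
    "phosphosite": [...]}``; deterministic given ``config.seed``.
    """
    config.validate()
    design_strains = set(design.strains)
    truth_strains = set(truth.deletion_map)
    if not design_strains <= truth_strains:
        raise DesignError("design contains strains absent from the truth: "
                          f"{sorted(design_strains - truth_strains)[:5]}")
    rng = np.random.default_rng([config.seed, 33])

    proteins = _protein_names(config.n_proteins)
    sites = list(truth.site_to_protein)
    base = {
        "protein": pd.Series(10.0 ** rng.uniform(4, 7, len(proteins)),
                             index=proteins),
        "phosphosite": pd.Series(10.0 ** rng.uniform(4, 7, len(sites)),
                                 index=sites),
    }

    # dense planted-effect matrices, molecules × (WT + strains)
    strains = sorted(truth_strains)
    eff_protein = pd.DataFrame(0.0, index=proteins, columns=["WT"] + strains)
    for (strain, prot), e in truth.protein_effects.items():
        eff_protein.loc[prot, strain] += e
    for strain, gene in truth.deletion_map.items():
        eff_protein.loc[gene, strain] += config.deletion_log2
    hosts = [truth.site_to_protein[s] for s in sites]
    eff_phospho = pd.DataFrame(eff_protein.loc[hosts].to_numpy(),
                               index=sites, columns=eff_protein.columns)
    for (strain, site), e in truth.phospho_effects.items():
        eff_phospho.loc[site, strain] += e
    eff = {"protein": eff_protein, "phosphosite": eff_phospho}

    out: dict[str, list[PlexIntensityTable]] = {"protein": [],
                                                "phosphosite": []}
    for plex_id in design.plex_ids:
        channels = design.channels_of(plex_id)
        n_ch = len(channels)
        if config.loading_cv > 0:
            loading = rng.lognormal(0.0, config.loading_cv, size=n_ch)
        else:
            loading = np.ones(n_ch)
        for level in ("protein", "phosphosite"):
            mols = base[level].index
            baseline = base[level].to_numpy()[:, None]
            effects = eff[level][channels["strain"].tolist()].to_numpy()
            intensity = baseline * 2.0 ** effects * loading[None, :]
            if config.noise_sd > 0:
                noise = 2.0 ** rng.normal(
                    0.0, config.noise_sd, size=intensity.shape)
                noise[:, channels["bridge"].to_numpy()] = 1.0
                intensity = intensity * noise
            if config.missing_rate_plex > 0:
                gone = rng.random(len(mols)) < config.missing_rate_plex
                intensity[gone, :] = np.nan
            table = pd.DataFrame(intensity, index=mols,
                                 columns=channels.index)
            out[level].append(
                PlexIntensityTable(plex_id, level, table, channels.copy()))
    return out


def truth_tables(truth: GroundTruth) -> dict[str, pd.DataFrame]:
    """Flatten a GroundTruth into TSV-ready tables."""
    dele = pd.DataFrame({"strain": list(truth.deletion_map),
                         "deleted_gene": list(truth.deletion_map.values())})
    prot = pd.DataFrame(
        [(s, m, e) for (s, m), e in truth.protein_effects.items()],
        columns=["strain", "protein", "log2_effect"])
    phos = pd.DataFrame(
        [(s, m, e, truth.phospho_target_class.get((s, m), "phospho_driven"))
         for (s, m), e in truth.phospho_effects.items()],
        columns=["strain", "phosphosite", "log2_effect", "class"])
    pdriven = pd.DataFrame(
        [(s, m) for (s, m), c in truth.phospho_target_class.items()
         if c == "protein_driven"],
        columns=["strain", "phosphosite"])
    mods = pd.DataFrame(
        [(name, member) for name, members in truth.modules.items()
         for member in sorted(members)],
        columns=["module", "protein"])
    s2p = pd.DataFrame({"phosphosite": list(truth.site_to_protein),
                        "protein": list(truth.site_to_protein.values())})
    return {"deletions": dele, "protein_effects": prot,
            "phospho_effects": phos, "protein_driven_sites": pdriven,
            "modules": mods, "site_to_protein": s2p}
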