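"""Synthetic archipelago generator with known ground truth.

Emulates an island-fragmentation survey: ``n_islands`` islands whose
species richness follows a power-law species-area relationship
S = round(c * A^z), sampled with a fixed number of soil cores per island
and realistic sequencing-depth variation, plus an area-correlated soil
moisture gradient.  Co-occurrence signal is planted through a latent-factor
(Gaussian copula-like) abundance model: the species pool is partitioned
into modules, each sample draws one latent factor per module, and a
species' log-abundance loads on its module's factor with a species-specific
sign.  Spearman correlation then detects within-module structure without
committing to any particular interaction mechanism.

Island composition is drawn by weighted sampling without replacement
(``composition="random"``): each island receives a per-module habitat
suitability, and a species' inclusion weight is exponential in its module's
suitability.  Habitat filtering thus acts on whole modules, so co-occurring
species share islands as well as abundance fluctuations -- the two faces of
one planted signal, both scaled from ``factor_strength``.  With the signal
turned off the draw collapses to uniform random composition, species'
presence patterns become exchangeable given area, and no co-occurrence
structure survives edge calling.  A nested mode (larger islands containing
smaller islands' species plus extras) is provided for robustness checks;
note that nested occupancy thresholds give rarity-matched species nearly
identical presence footprints and thus strong rank correlations even
without any planted factor signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm as _NORMAL

from .tables_io import OtuTable, SampleMetadata


@dataclass
class SynthConfig:
    """Parameters of the synthetic archipelago.

    Defaults describe the emulated survey: 28 islands, 10 soil samples per
    island (280 samples, near the ~284 of a full two-kingdom survey),
    areas log-uniform on [1e2, 1e6] m2, SAR richness S = round(100 * A^0.25),
    and a moisture gradient spanning roughly 6.7-28.7 % across that area
    range.
    """

    n_islands: int = 28
    areas: list | None = None            # m2; log-uniform [1e2, 1e6] if None
    sar_c: float = 100.0
    sar_z: float = 0.25
    richness_sd: float = 0.1             # lognormal island effect around the
                                         # SAR mean (habitat-quality scatter)
    n_modules: int | None = None         # None: one module per ~25 pool species
    samples_per_island: int = 10
    depth_mean: float = 10000.0          # median reads per sample
    depth_sd: float = 0.35               # lognormal sigma (log-reads scale)
    factor_strength: float = 3.5         # latent-factor loading magnitude
    habitat_strength: float | None = None  # module-suitability weight scale;
                                           # None: 0.35 * factor_strength
    positive_loading_frac: float = 0.8   # fraction of species loading positively
    noise_sd: float = 0.5                # residual log-abundance noise
    capture_prob: float = 0.3            # per-core chance a species present on
                                         # the island enters a sample (patchiness)
    capture_noise: float = 2.0           # sd of the species-level part of the
                                         # capture propensity (vs factor part)
    base_sd: float = 1.0                 # species base log-abundance spread
    core_frac: float = 0.035             # fraction of the pool that is "core"
                                         # (high-occupancy); the rest are
                                         # transients seen on only a few islands
    transient_weight: float = 0.01       # inclusion weight of transients
                                         # relative to core species
    transient_abundance_penalty: float = 2.5  # ln-scale deficit of transient
                                              # base abundance (rare biosphere)
    moisture_slope: float = 5.5          # % per decade of area
    moisture_intercept: float = -4.3
    moisture_noise: float = 1.5
    composition: str = "random"          # or "nested"
    replacement_frac: float = 0.1        # nested mode: island-specific turnover
    pool_excess: float = 6.0             # pool size = excess * max richness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sar_z < 0:
            raise ValueError("sar_z must be >= 0")
        if self.composition not in ("random", "nested"):
            raise ValueError("composition must be 'random' or 'nested'")
        if not (0 < self.capture_prob <= 1):
            raise ValueError("capture_prob must be in (0, 1]")
        for name in ("depth_sd", "noise_sd", "base_sd", "moisture_noise",
                     "richness_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """What the generator planted: module labels, per-island richness and
    composition, areas, and the full configuration."""

    module_of: dict
    richness: dict
    species: dict = field(repr=False)
    areas: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)


def generate_archipelago(config: SynthConfig) -> tuple[OtuTable, SampleMetadata, GroundTruth]:
    """Draw one synthetic archipelago; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)

    if config.areas is not None:
        areas = np.asarray(config.areas, dtype=float)
        if len(areas) != config.n_islands:
            raise ValueError("len(areas) inconsistent with n_islands")
    else:
        areas = 10.0 ** rng.uniform(2.0, 6.0, config.n_islands)
    areas = np.sort(areas)
    island_ids = [f"I{i + 1:02d}" for i in range(config.n_islands)]

    island_effect = np.exp(rng.normal(0.0, config.richness_sd, config.n_islands))
    richness = np.maximum(
        2, np.round(config.sar_c * areas ** config.sar_z * island_effect)
    ).astype(int)
    pool = int(math.ceil(richness.max() * config.pool_excess))
    if richness.max() > pool:
        raise ValueError("maximum island richness exceeds the species pool")
    n_core = int(round(config.core_frac * pool))
    n_modules = config.n_modules
    if n_modules is None:
        n_modules = max(2, round(n_core / 15))
    otu_ids = [f"OTU{i:05d}" for i in range(pool)]

    module_of = rng.permutation(np.arange(pool) % n_modules)
    signs = np.where(rng.random(pool) < config.positive_loading_frac, 1.0, -1.0)
    loading = config.factor_strength * signs
    # occupancy classes: core species recur across the archipelago, transients
    # are the long tail that any one island hosts but few share, and they are
    # also locally rare (the "rare biosphere")
    is_core = np.zeros(pool, dtype=bool)
    is_core[rng.choice(pool, size=min(n_core, pool), replace=False)] = True
    occ_weight = np.where(is_core, 1.0, config.transient_weight)
    base = rng.normal(0.0, config.base_sd, size=pool)
    base[~is_core] -= config.transient_abundance_penalty
    gamma = (0.35 * config.factor_strength if config.habitat_strength is None
             else config.habitat_strength)

    species: dict[str, np.ndarray] = {}
    for i, isl in enumerate(island_ids):
        s = richness[i]
        if config.composition == "random":
            suit = rng.normal(0.0, 1.0, n_modules)
            w = occ_weight * np.exp(gamma * suit[module_of])
            sp = rng.choice(pool, size=s, replace=False, p=w / w.sum())
        else:
            sp = np.arange(s)
            n_rep = int(math.floor(config.replacement_frac * s))
            if n_rep and pool > s:
                out = rng.choice(s, size=n_rep, replace=False)
                candidates = np.arange(s, pool)
                repl = rng.choice(candidates, size=min(n_rep, len(candidates)),
                                  replace=False)
                sp = sp.copy()
                sp[out[: len(repl)]] = repl
        species[isl] = np.sort(sp)

    n_samples = config.n_islands * config.samples_per_island
    counts = np.zeros((n_samples, pool), dtype=np.int64)
    sample_ids = []
    meta_rows = []
    log_depth = math.log(config.depth_mean)
    row = 0
    for i, isl in enumerate(island_ids):
        sp = species[isl]
        log_a = math.log10(areas[i])
        for j in range(config.samples_per_island):
            sid = f"{isl}_s{j + 1:02d}"
            sample_ids.append(sid)
            depth = max(1, int(round(rng.lognormal(log_depth, config.depth_sd))))
            factors = rng.normal(0.0, 1.0, n_modules)
            log_ab = (base[sp]
                      + loading[sp] * factors[module_of[sp]]
                      + rng.normal(0.0, config.noise_sd, len(sp)))
            # microhabitat patchiness: a present species enters this core with
            # marginal probability capture_prob, but the propensity loads on
            # the same module factor as abundance -- locally favoured species
            # are the ones a core picks up.  With factor_strength = 0 capture
            # is independent across species and samples.
            z = (loading[sp] * factors[module_of[sp]]
                 + config.capture_noise * rng.normal(0.0, 1.0, len(sp)))
            z_sd = math.sqrt(config.factor_strength ** 2 + config.capture_noise ** 2)
            tau = _NORMAL.isf(config.capture_prob) * z_sd
            captured = z > tau
            if not captured.any():
                captured[:] = True
            w = np.exp(log_ab - log_ab[captured].max()) * captured
            counts[row, sp] = rng.multinomial(depth, w / w.sum())
            moisture = (config.moisture_intercept
                        + config.moisture_slope * log_a
                        + rng.normal(0.0, config.moisture_noise))
            meta_rows.append({
                "sample_id": sid,
                "island_id": isl,
                "area_m2": areas[i],
                "moisture": moisture,
                "toc": 10 ** rng.normal(3.3 + 0.05 * log_a, 0.15),
                "tn": 10 ** rng.normal(2.5 + 0.05 * log_a, 0.15),
                "tp": 10 ** rng.normal(2.0 + 0.03 * log_a, 0.15),
                "available_ca": 10 ** rng.normal(2.8 + 0.10 * log_a, 0.20),
            })
            row += 1

    table = OtuTable(sample_ids, otu_ids, counts)
    meta = SampleMetadata(pd.DataFrame(meta_rows))
    truth = GroundTruth(
        module_of={otu_ids[i]: int(module_of[i]) for i in range(pool)},
        richness={isl: int(richness[i]) for i, isl in enumerate(island_ids)},
        species={isl: [otu_ids[k] for k in sp] for isl, sp in species.items()},
        areas={isl: float(areas[i]) for i, isl in enumerate(island_ids)},
        config=asdict(config),
    )
    return table, meta, truth


# ---------------------------------------------------------------------------
# deterministic small fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("tiny", "modular", "star-stability")


def generate_fixture(name: str):
    """Small deterministic bundles for tests and worked examples.

    - ``"tiny"``: 3 islands x 4 samples, ~30-OTU pool, full archipelago
      bundle (table, metadata, ground truth).
    - ``"modular"``: (table, blocks) whose pairwise Spearman matrix has a
      planted block pattern, |rho| >= 0.8 within blocks (asserted at
      generation time).
    - ``"star-stability"``: dict of small named graphs with hand-computable
      stability metrics.
    """
    if name == "tiny":
        cfg = SynthConfig(
            n_islands=3, areas=[1e2, 1e3, 1e4], sar_c=3.0, sar_z=0.25,
            n_modules=3, samples_per_island=4, depth_mean=500.0,
            depth_sd=0.2, pool_excess=1.2, core_frac=0.5, seed=7,
        )
        return generate_archipelago(cfg)
    if name == "modular":
        return _modular_fixture()
    if name == "star-stability":
        return _stability_graphs()
    raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")


def _modular_fixture() -> tuple[OtuTable, dict]:
    """20 OTUs in 4 blocks of 5, 24 samples; within-block values share one
    latent series (sign-flipped for some members) so within-block |rho| is
    high by construction."""
    rng = np.random.default_rng(20240901)
    n_samples, n_blocks, per_block = 24, 4, 5
    counts = np.zeros((n_samples, n_blocks * per_block), dtype=np.int64)
    blocks: dict[str, int] = {}
    otu_ids = []
    for b in range(n_blocks):
        latent = rng.normal(0.0, 1.0, n_samples)
        for k in range(per_block):
            sign = -1.0 if k % 2 else 1.0
            vals = 2.0 * sign * latent + 0.15 * rng.normal(0.0, 1.0, n_samples)
            col = b * per_block + k
            counts[:, col] = np.round(40.0 * np.exp(0.5 * vals)).astype(np.int64)
            oid = f"B{b}_O{k}"
            otu_ids.append(oid)
            blocks[oid] = b
    table = OtuTable([f"S{i:02d}" for i in range(n_samples)], otu_ids, counts)
    # verify the planted pattern really holds for this seed
    from scipy.stats import spearmanr
    rho = spearmanr(counts).statistic
    for i in range(len(otu_ids)):
        for j in range(i + 1, len(otu_ids)):
            if blocks[otu_ids[i]] == blocks[otu_ids[j]]:
                assert abs(rho[i, j]) >= 0.8, "modular fixture lost its block signal"
    return table, blocks


def planted_hub_graph() -> nx.Graph:
    """Four 12-node modules (one hub + 11 leaves in a ring), hubs mutually
    connected: the hubs are keystones whose removal thins every leaf's
    neighborhood."""
    g = nx.Graph()
    hubs = [f"m{m}_hub" for m in range(4)]
    for m in range(4):
        leaves = [f"m{m}_leaf{j}" for j in range(11)]
        for j, leaf in enumerate(leaves):
            g.add_edge(hubs[m], leaf)
            g.add_edge(leaf, leaves[(j + 1) % 11])
    for a in range(4):
        for b in range(a + 1, 4):
            g.add_edge(hubs[a], hubs[b])
    return g


def _stability_graphs() -> dict:
    graphs = {
        "star10": nx.star_graph(10),
        "path3": nx.path_graph(3),
        "k4": nx.complete_graph(4),
        "k5": nx.complete_graph(5),
        "k8": nx.complete_graph(8),
        "two_triangles": nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3)),
        "er10": nx.gnp_random_graph(10, 0.35, seed=4),
        "er12": nx.gnp_random_graph(12, 0.3, seed=5),
        "planted_hub": planted_hub_graph(),
    }
    for g in graphs.values():
        g.remove_edges_from(nx.selfloop_edges(g))
    return graphs
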