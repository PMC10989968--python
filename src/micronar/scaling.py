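"""Network-area relationship statistics and end-to-end orchestration.

Every per-island network property and stability metric is regressed on
log10 island area by ordinary least squares (with a 95% confidence band
for the conditional mean), and the stability metrics are rank-correlated
with the complexity properties across islands.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy import stats

from . import __version__
from .tables_io import (OtuTable, SampleMetadata, read_otu_table, read_metadata,
                        write_otu_table, write_metadata, rarefy, prevalence_filter,
                        log_transform, island_richness)
from .conet import (spearman_all_pairs, call_edges, extract_island_subnetworks,
                    load_edge_list, write_edge_list, DEFAULT_RHO_MIN, DEFAULT_ALPHA)
from .topology import network_properties
from .stability import (robustness, vulnerability, keystone_removal_test,
                        global_efficiency)
from .synthgen import SynthConfig, generate_archipelago

logger = logging.getLogger(__name__)

#: complexity properties correlated with stability metrics
CORRELATION_PROPERTIES = ("n", "L", "avg_k", "connectance",
                          "relative_modularity", "n_keystone")


@dataclass
class NarRegression:
    """OLS fit of one per-island metric on log10(area)."""

    property_name: str
    slope: float
    intercept: float
    adj_r2: float
    p_value: float
    n_islands: int
    x: np.ndarray = field(repr=False)          # log10 areas used
    fitted: np.ndarray = field(repr=False)
    ci_lower: np.ndarray = field(repr=False)   # 95% band for the mean
    ci_upper: np.ndarray = field(repr=False)


def nar_fit(values, areas, property_name: str = "") -> NarRegression:
    """Regress a per-island metric on log10 island area (areas in m2).

    Missing values are dropped pairwise (with a warning); at least 3
    islands with finite values are required, and the areas must vary.
    """
    values = np.asarray(values, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if (areas <= 0).any():
        raise ValueError("areas must be > 0")
    ok = np.isfinite(values) & np.isfinite(areas)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("nar_fit(%s): dropping %d island(s) with missing values",
                       property_name, n_dropped)
    values, areas = values[ok], areas[ok]
    if len(values) < 3:
        raise ValueError("need at least 3 islands with finite values")
    x = np.log10(areas)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in island areas")
    design = sm.add_constant(x)
    res = sm.OLS(values, design).fit()
    pred = res.get_prediction(design)
    band = pred.conf_int(alpha=0.05)
    p = float(res.pvalues[1])
    p = max(p, np.finfo(float).tiny)  # keep p in (0, 1] even for exact fits
    return NarRegression(
        property_name=property_name,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        adj_r2=float(res.rsquared_adj),
        p_value=p,
        n_islands=len(values),
        x=x,
        fitted=np.asarray(pred.predicted_mean),
        ci_lower=band[:, 0],
        ci_upper=band[:, 1],
    )


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def stability_property_correlations(stability_table: pd.DataFrame,
                                    properties_table: pd.DataFrame,
                                    bh_across_grid: bool = False) -> pd.DataFrame:
    """Spearman correlations of robustness and vulnerability with each
    complexity property across islands.

    Both tables must be keyed by ``island_id``; at least 4 islands are
    required.  Constant metrics yield NaN rho (reported missing).  By
    default no multiple-testing correction is applied across the
    2 x 6 grid; ``bh_across_grid`` switches BH on.
    """
    merged = stability_table.merge(properties_table, on="island_id")
    if len(merged) < 4:
        raise ValueError("need at least 4 islands")
    rows = []
    for metric in ("robustness_mean", "vulnerability"):
        for prop in CORRELATION_PROPERTIES:
            a = merged[metric].to_numpy(dtype=float)
            b = merged[prop].to_numpy(dtype=float)
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 4 or np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
                rho, p = float("nan"), float("nan")
            else:
                r = stats.spearmanr(a[ok], b[ok])
                rho, p = float(r.statistic), float(r.pvalue)
            rows.append({"metric": metric, "property": prop,
                         "rho": rho, "p_value": p})
    out = pd.DataFrame(rows)
    if bh_across_grid:
        from .conet import bh_adjust
        out["p_value"] = bh_adjust(out["p_value"].to_numpy())
    out["stars"] = [significance_stars(p) for p in out["p_value"]]
    return out


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

STAGES = ("simulate", "network", "metrics", "stability", "scaling")


@dataclass
class PipelineConfig:
    """Everything one run needs; YAML-serializable, fully seeded."""

    otu_table: str | None = None       # input paths, or ...
    metadata: str | None = None
    synth: SynthConfig | None = None   # ... a synthetic archipelago spec
    edge_list: str | None = None       # externally filtered edges (hook)
    rarefy_depth: int = 8000
    min_prevalence: int = 12
    rho_min: float = DEFAULT_RHO_MIN
    alpha: float = DEFAULT_ALPHA
    rm_nulls: int = 100
    rm_swaps_per_edge: int = 10
    robustness_fraction: float = 0.5
    robustness_reps: int = 999
    vulnerability_normalization: str = "reduced"
    keystone_test: bool = True
    seed: int = 0
    threads: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        synth = doc.pop("synth", None)
        cfg = cls(**doc)
        if synth is not None:
            cfg.synth = SynthConfig(**synth)
        return cfg

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        return doc


@dataclass
class PipelineResult:
    table: OtuTable
    metadata: SampleMetadata
    meta_network: object
    subnetworks: list
    properties: pd.DataFrame | None = None
    node_roles: pd.DataFrame | None = None
    stability: pd.DataFrame | None = None
    nar_fits: pd.DataFrame | None = None
    correlations: pd.DataFrame | None = None
    richness: pd.Series | None = None


def _island_metrics(args):
    (idx, sub, cfg) = args
    props, roles = network_properties(
        sub.graph, seed=int(np.random.default_rng([cfg.seed, 11, idx]).integers(2 ** 31)),
        n_null=cfg.rm_nulls if sub.graph.number_of_edges() > 1 else 0,
        swaps_per_edge=cfg.rm_swaps_per_edge,
    )
    row = {"island_id": sub.island_id, "area_m2": sub.area_m2,
           **dataclasses.asdict(props)}
    role_rows = [{"island_id": sub.island_id, "otu_id": r.otu_id,
                  "module_id": r.module_id, "zi": r.zi, "pi": r.pi,
                  "role": r.role} for r in roles]
    return row, role_rows


def _island_stability(args):
    (idx, sub, roles, cfg) = args
    g = sub.graph
    row = {"island_id": sub.island_id, "area_m2": sub.area_m2,
           "robustness_mean": float("nan"), "robustness_sd": float("nan"),
           "efficiency": float("nan"), "vulnerability": float("nan"),
           "keystone_t": float("nan"), "keystone_p": float("nan"),
           "n_keystones_removed": 0}
    if g.number_of_nodes() < 2:
        return row
    rob_seed = int(np.random.default_rng([cfg.seed, 23, idx]).integers(2 ** 31))
    rob = robustness(g, fraction=cfg.robustness_fraction,
                     reps=cfg.robustness_reps, seed=rob_seed)
    row["robustness_mean"], row["robustness_sd"] = rob.mean, rob.sd
    row["efficiency"] = global_efficiency(g)
    if g.number_of_nodes() >= 3:
        v, _ = vulnerability(g, normalization=cfg.vulnerability_normalization)
        row["vulnerability"] = v
    if cfg.keystone_test and roles:
        keystones = [r for r in roles if r.role != "peripheral"]
        non_key = g.number_of_nodes() - len(keystones)
        if keystones and non_key >= 2:
            try:
                kr = keystone_removal_test(
                    g, roles, fraction=cfg.robustness_fraction,
                    reps=cfg.robustness_reps, seed=rob_seed + 1)
                row["keystone_t"], row["keystone_p"] = kr.t, kr.p
                row["n_keystones_removed"] = kr.n_keystones
            except ValueError:
                logger.warning("island %s: keystone removal degenerate", sub.island_id)
    return row


def run_full_pipeline(config: PipelineConfig, outdir=None,
                      stop_after: str = "scaling") -> PipelineResult:
    """Run the whole workflow and (optionally) write every artifact.

    Stages: simulate/read -> rarefy -> prevalence filter -> meta-network ->
    island subnetworks -> complexity metrics -> stability -> NAR fits and
    stability/property correlations.  Bitwise reproducible given the
    config (including 1 vs many threads: per-island random streams are
    derived from the master seed, never from scheduling order).
    """
    if stop_after not in STAGES:
        raise ValueError(f"stop_after must be one of {STAGES}")
    stage_idx = STAGES.index(stop_after)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)

    # -- simulate / read ----------------------------------------------------
    if config.synth is not None:
        table, meta, truth = generate_archipelago(config.synth)
    elif config.otu_table and config.metadata:
        table = read_otu_table(config.otu_table)
        meta = read_metadata(config.metadata)
    else:
        raise ValueError("config needs either synth or otu_table+metadata paths")

    table = rarefy(table, config.rarefy_depth, seed=config.seed)
    table = prevalence_filter(table, config.min_prevalence)
    meta = meta.subset(table.sample_ids)
    richness = island_richness(table, meta)

    result = PipelineResult(table, meta, None, [], richness=richness)
    if outdir is not None:
        write_otu_table(table, os.path.join(outdir, "otu_table_processed.tsv"))
        write_metadata(meta, os.path.join(outdir, "metadata.tsv"))
        richness.rename_axis("island_id").to_frame().to_csv(
            os.path.join(outdir, "island_richness.tsv"), sep="\t")
        _write_manifest(config, outdir)
    if stage_idx < 1:
        return result

    # -- meta-network -------------------------------------------------------
    if config.edge_list:
        meta_net = load_edge_list(config.edge_list)
    else:
        corr = spearman_all_pairs(log_transform(table), table.otu_ids)
        meta_net = call_edges(corr, rho_min=config.rho_min, alpha=config.alpha)
    subnets = extract_island_subnetworks(meta_net, table, meta)
    result.meta_network = meta_net
    result.subnetworks = subnets
    if outdir is not None:
        write_edge_list(meta_net, os.path.join(outdir, "meta_edges.tsv"))
    if stage_idx < 2:
        return result

    # -- complexity metrics -------------------------------------------------
    jobs = [(i, sub, config) for i, sub in enumerate(subnets)]
    with ThreadPoolExecutor(max_workers=max(1, config.threads)) as pool:
        metric_out = list(pool.map(_island_metrics, jobs))
    prop_rows = [row for row, _ in metric_out]
    role_rows = [r for _, rows in metric_out for r in rows]
    props_df = pd.DataFrame(prop_rows)
    roles_df = pd.DataFrame(role_rows,
                            columns=["island_id", "otu_id", "module_id",
                                     "zi", "pi", "role"])
    result.properties = props_df
    result.node_roles = roles_df
    if outdir is not None:
        props_df.to_csv(os.path.join(outdir, "island_properties.tsv"),
                        sep="\t", index=False)
        roles_df.to_csv(os.path.join(outdir, "node_roles.tsv"),
                        sep="\t", index=False)
    if stage_idx < 3:
        return result

    # -- stability ----------------------------------------------------------
    from .topology import NodeRole
    roles_by_island = {}
    for r in role_rows:
        roles_by_island.setdefault(r["island_id"], []).append(
            NodeRole(r["otu_id"], r["module_id"], r["zi"], r["pi"], r["role"]))
    sjobs = [(i, sub, roles_by_island.get(sub.island_id, []), config)
             for i, sub in enumerate(subnets)]
    with ThreadPoolExecutor(max_workers=max(1, config.threads)) as pool:
        stab_rows = list(pool.map(_island_stability, sjobs))
    stab_df = pd.DataFrame(stab_rows)
    result.stability = stab_df
    if outdir is not None:
        stab_df.to_csv(os.path.join(outdir, "island_stability.tsv"),
                       sep="\t", index=False)
    if stage_idx < 4:
        return result

    # -- NAR fits and correlations ------------------------------------------
    fits = []
    areas = props_df["area_m2"].to_numpy()
    for prop in ("n", "L", "avg_k", "connectance", "modularity",
                 "relative_modularity", "n_keystone"):
        fits.append(_fit_row(props_df[prop], areas, prop))
    for metric in ("robustness_mean", "vulnerability"):
        fits.append(_fit_row(stab_df[metric], stab_df["area_m2"].to_numpy(), metric))
    fits_df = pd.DataFrame(fits)
    corr_df = stability_property_correlations(stab_df, props_df)
    result.nar_fits = fits_df
    result.correlations = corr_df
    if outdir is not None:
        fits_df.to_csv(os.path.join(outdir, "nar_fits.tsv"), sep="\t", index=False)
        corr_df.to_csv(os.path.join(outdir, "stability_correlations.tsv"),
                       sep="\t", index=False)
    return result


def _fit_row(values, areas, name) -> dict:
    try:
        fit = nar_fit(values, areas, property_name=name)
        return {"property": name, "slope": fit.slope, "intercept": fit.intercept,
                "adj_r2": fit.adj_r2, "p_value": fit.p_value,
                "n_islands": fit.n_islands}
    except ValueError as exc:
        logger.warning("nar_fit(%s) failed: %s", name, exc)
        return {"property": name, "slope": float("nan"),
                "intercept": float("nan"), "adj_r2": float("nan"),
                "p_value": float("nan"), "n_islands": 0}


def _write_manifest(config: PipelineConfig, outdir) -> None:
    cfg = config.to_dict()
    cfg.pop("threads", None)   # execution detail; results are thread-invariant
    doc = {"package": "micronar", "version": __version__,
           "config": cfg,
           "stage_order": list(STAGES),
           "preprocessing_order": ["rarefy", "prevalence_filter"]}
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1)
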