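"""End-to-end orchestration: dating -> NRI/NTI tables (all / woody /
herbaceous) -> trait-signal test -> correlograms -> PCNM filters -> VIF
screen -> ANCOVAs -> variance partitioning.

Every stage logs its settings and seed into a manifest so a run can be
re-executed bit-identically from the manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import community as comm_mod
from .community import CommunityMatrix, nri_nti_table
from .models import ancova, edaphic_dummies, variance_partition, vif_screen
from .spatial import SiteTable, correlogram, pcnm_filters
from .traits import LifeFormTable, read_life_forms, signal_test
from .tree import (AgeTable, Phylogeny, date_tree, patristic_matrix,
                   prune_to_taxa, read_ages, read_newick, write_newick)

__all__ = ["RunConfig", "run_all", "split_growth_forms"]

logger = logging.getLogger("phylostruct")


@dataclass
class RunConfig:
    """Inputs and constants for one full analysis run.

    Defaults follow the standard protocol for this analysis: 1,000 tip-label
    permutations for SES, 999 trait reshuffles for the signal test, 6
    equal-count distance classes, root age 137 My (eudicot crown), ANCOVA
    alpha 0.10 and correlogram alpha 0.05.  Phanerophytes count as woody;
    the other four life forms as herbaceous.
    """

    tree: str
    communities: str
    traits: str
    sites: str
    ages: str | None = None
    n_perm: int = 1000
    n_rand: int = 999
    k_classes: int = 6
    root_age: float = 137.0
    alpha_ancova: float = 0.10
    alpha_correlogram: float = 0.05
    climate_terms: tuple[str, ...] = (
        "annual_mean_temp", "annual_precip", "precip_driest_quarter")
    vif_threshold: float = 10.0
    n_filters_in_model: int = 1
    seed: int = 0
    exclude_species: tuple[str, ...] = ()

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("climate_terms", "exclude_species"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def split_growth_forms(communities: CommunityMatrix, traits: LifeFormTable,
                       log=None) -> tuple[CommunityMatrix, CommunityMatrix]:
    """Partition each site's species into woody (phanerophytes) and
    herbaceous (the other four states) incidence matrices.

    Sites falling below two species in a partition are dropped from that
    partition with a warning; the two partitions together cover every input
    species exactly once.
    """
    missing = sorted(set(communities.species) - set(traits.species))
    if missing:
        raise KeyError(f"species without a life form: {missing}")
    woody, dropped_w = communities.subset_species(traits.woody_species())
    herb, dropped_h = communities.subset_species(traits.herbaceous_species())
    warn = log or logger.warning
    if dropped_w:
        warn(f"sites dropped from the woody partition (<2 species): {dropped_w}")
    if dropped_h:
        warn(f"sites dropped from the herbaceous partition (<2 species): {dropped_h}")
    return woody, herb


def _write(df: pd.DataFrame, path: Path, round_to: int | None) -> None:
    if round_to is not None:
        df = df.round(round_to)
    df.to_csv(path)


def run_all(cfg: RunConfig, out_dir, *, round_to: int | None = None) -> Path:
    """Run the complete analysis and write all report tables.

    Emits into *out_dir*: the dated tree, NRI/NTI tables for the full /
    woody / herbaceous floras, the trait-signal report, correlograms for
    each diversity index and climate covariate, the PCNM filters, the VIF
    screen, one ANCOVA table per index, the variance partition, a manifest
    and a log.  Returns the output directory path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    manifest = {"config": asdict(cfg), "stages": []}

    # --- stage 1: tree dating -------------------------------------------
    pool = read_newick(cfg.tree)
    ages = read_ages(cfg.ages) if cfg.ages else AgeTable({})
    dated = date_tree(pool, ages, root_age=cfg.root_age)
    write_newick(dated, out / "dated_tree.nwk")
    manifest["stages"].append({"stage": "date_tree", "root_age": cfg.root_age,
                               "n_tips": dated.n_tips,
                               "n_constraints": len(ages.ages)})
    log(f"dated tree: {dated.n_tips} tips, root at {cfg.root_age} My")

    # --- stage 2: inputs and reconciliation ------------------------------
    communities = CommunityMatrix.from_csv(cfg.communities)
    traits = read_life_forms(cfg.traits, exclude=cfg.exclude_species, log=log)
    sites = SiteTable.from_csv(cfg.sites)
    problems = []
    tipset = set(dated.tip_names)
    for sp in communities.species:
        if sp not in tipset:
            problems.append(f"{sp}: not a tip of the pool tree")
        if sp not in traits:
            problems.append(f"{sp}: no life form")
    missing_sites = [s for s in communities.sites if s not in set(sites.sites)]
    problems += [f"{s}: site has no coordinates" for s in missing_sites]
    if problems:
        raise ValueError("input reconciliation failed:\n" + "\n".join(problems))

    dist = patristic_matrix(dated)

    # --- stage 3: NRI/NTI ------------------------------------------------
    tables = {}
    tables["all"] = nri_nti_table(communities, dist, n_perm=cfg.n_perm,
                                  seed=cfg.seed)
    woody, herb = split_growth_forms(communities, traits, log=log)
    tables["woody"] = nri_nti_table(woody, dist, n_perm=cfg.n_perm,
                                    seed=cfg.seed)
    tables["herbaceous"] = nri_nti_table(herb, dist, n_perm=cfg.n_perm,
                                         seed=cfg.seed)
    for name, tab in tables.items():
        _write(tab, out / f"nri_nti_{name}.csv", round_to)
    manifest["stages"].append({"stage": "nri_nti", "n_perm": cfg.n_perm,
                               "seed": cfg.seed,
                               "sites": {k: len(v) for k, v in tables.items()}})
    log("NRI/NTI tables written (all, woody, herbaceous)")

    # --- stage 4: trait signal -------------------------------------------
    pool_trait = {sp: traits[sp] for sp in dated.tip_names if sp in traits}
    untyped = [sp for sp in dated.tip_names if sp not in traits]
    if untyped:
        # signal is tested on the community species; prune bare pool tips
        signal_tree = prune_to_taxa(dated, list(pool_trait))
    else:
        signal_tree = dated
    signal = signal_test(signal_tree, pool_trait, n_rand=cfg.n_rand,
                         seed=cfg.seed)
    signal.to_json(out / "signal.json")
    manifest["stages"].append({"stage": "signal", "n_rand": cfg.n_rand,
                               "seed": cfg.seed,
                               "observed": signal.observed,
                               "p": signal.p_value})
    log(f"trait signal: observed {signal.observed} changes, "
        f"null median {signal.null_median}, p = {signal.p_value:.4g}")

    # --- stage 5: correlograms -------------------------------------------
    index_vectors: dict[str, pd.Series] = {}
    for name, tab in tables.items():
        for idx in ("NRI", "NTI"):
            index_vectors[f"{idx}_{name}"] = tab[idx]
    site_order = list(sites.sites)
    corr_dir = out / "correlograms"
    corr_dir.mkdir(exist_ok=True)
    for label, vec in index_vectors.items():
        aligned = vec.reindex(site_order).dropna()
        if len(aligned) < 4:
            log(f"correlogram skipped for {label}: only {len(aligned)} sites")
            continue
        sub_sites = SiteTable(sites.table.loc[aligned.index])
        cg = correlogram(aligned.to_numpy(), sub_sites,
                         k=cfg.k_classes, seed=cfg.seed)
        cg.to_csv(corr_dir / f"{label}.csv")
    for cov in cfg.climate_terms:
        cg = correlogram(sites.covariate(cov).to_numpy(), sites,
                         k=cfg.k_classes, seed=cfg.seed)
        cg.to_csv(corr_dir / f"{cov}.csv")
    manifest["stages"].append({"stage": "correlogram", "k": cfg.k_classes,
                               "seed": cfg.seed,
                               "variables": list(index_vectors) + list(cfg.climate_terms)})
    log(f"correlograms written for {len(index_vectors) + len(cfg.climate_terms)} variables")

    # --- stage 6: PCNM filters -------------------------------------------
    filters = pcnm_filters(sites)
    filters.to_csv(out / "pcnm_filters.csv")
    manifest["stages"].append({"stage": "pcnm",
                               "truncation_km": filters.truncation_km,
                               "n_filters": filters.n_filters,
                               "first_eigenvalue": float(filters.eigenvalues[0])
                               if filters.n_filters else None})
    log(f"PCNM: {filters.n_filters} filters, truncation "
        f"{filters.truncation_km:.1f} km; first filter enters the model")

    # --- stage 7: VIF screen ---------------------------------------------
    climate = sites.table[list(cfg.climate_terms)].astype(float)
    kept, vif_log = vif_screen(climate, threshold=cfg.vif_threshold)
    vif_log.to_csv(out / "vif_screen.csv", index=False)
    manifest["stages"].append({"stage": "vif", "threshold": cfg.vif_threshold,
                               "kept": kept})
    log(f"VIF screen kept climate terms: {kept}")

    # --- stage 8: ANCOVA and variance partition --------------------------
    n_use = min(cfg.n_filters_in_model, filters.n_filters)
    varpart_rows = []
    for label, vec in index_vectors.items():
        aligned = vec.reindex(site_order).dropna()
        keep = aligned.index
        n_terms = 1 + len(kept) + 2 + n_use  # intercept+climate+dummies+filter
        if len(keep) <= n_terms:
            log(f"ANCOVA skipped for {label}: {len(keep)} sites for "
                f"{n_terms} terms")
            continue
        sub_sites = SiteTable(sites.table.loc[keep])
        yv = aligned.to_numpy()
        filt = filters.vectors.loc[keep].iloc[:, 0] if n_use else None
        fit = ancova(yv, sub_sites, kept, spatial_filter=filt,
                     alpha=cfg.alpha_ancova)
        _write(fit.table(), out / f"ancova_{label}.csv", round_to)
        vp = variance_partition(
            yv, sub_sites.table[kept].astype(float),
            edaphic_dummies(sub_sites), r2_flavour="adjusted")
        row = {"index": label, "climate": vp.climate, "edaphic": vp.edaphic,
               "interaction": vp.shared, "adjusted_r2": vp.r2_full}
        varpart_rows.append(row)
    vp_df = pd.DataFrame(varpart_rows).set_index("index")
    _write(vp_df, out / "variance_partition.csv", round_to)
    manifest["stages"].append({"stage": "ancova+varpart",
                               "alpha": cfg.alpha_ancova,
                               "climate_terms": kept,
                               "n_filters_in_model": n_use})
    log("ANCOVA tables and variance partition written")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
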