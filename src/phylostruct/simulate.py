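"""Synthetic study generator: dated pool phylogenies, conserved discrete
traits, niche optima, community assembly under neutral / filtering /
repulsion rules, and spatially autocorrelated site covariates.

The generator emulates the structure of a regional floristic study: an
ultrametric species-pool tree, a five-state life-form character evolved with
low transition rate (hence clade-structured), site assemblages sampled from
the pool, and sites carrying coordinates, a substrate class blocked in
space, and climate covariates drawn from a Gaussian process with
exponential spatial covariance.  Filtering assembly draws species whose
(Brownian) niche optimum matches the site environment, producing
phylogenetic clustering when the niche is conserved; repulsion greedily
maximizes the minimum pairwise patristic distance, producing
overdispersion.  Neutral assembly is a uniform draw and calibrates the null.

All generators take one master seed; sub-streams are derived with hashed
(seed, purpose) keys, so adding one generator call never perturbs the
output of another.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Literal, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .community import CommunityMatrix, _site_rng
from .spatial import EARTH_RADIUS_KM, SiteTable, pair_distance_matrix
from .traits import LIFE_FORMS, LifeFormTable
from .tree import Phylogeny, patristic_matrix

__all__ = [
    "AssemblyConfig",
    "simulate_yule_tree",
    "evolve_discrete_trait",
    "evolve_continuous_niche",
    "assemble_communities",
    "simulate_sites",
    "match_environment_to_niche",
    "make_fixture",
]

AssemblyMode = Literal["neutral", "filtering", "repulsion"]


class _GenericTrait:
    """Trait table with a free state alphabet (duck-types LifeFormTable)."""

    def __init__(self, states: dict[str, str]):
        self.states = states

    def __getitem__(self, sp):
        return self.states[sp]

    def keys(self):
        return self.states.keys()

    def __iter__(self):
        return iter(self.states)

    def __len__(self):
        return len(self.states)


@dataclass(frozen=True)
class AssemblyConfig:
    """Rules for drawing site assemblages from the pool."""

    mode: AssemblyMode = "neutral"
    richness: int = 20
    filter_tolerance: float = 1.0   # niche units, filtering mode only
    seed: int = 0

    def __post_init__(self):
        if self.richness < 2:
            raise ValueError("richness must be >= 2")
        if self.filter_tolerance <= 0:
            raise ValueError("filter tolerance must be > 0")


def simulate_yule_tree(n_tips: int, seed: int = 0) -> Phylogeny:
    """Ultrametric pure-birth (Yule) tree with deterministically named tips.

    Branch lengths are in arbitrary time units; the final pendant interval
    is extended by one further exponential waiting time so the youngest
    split does not sit at the present.
    """
    if n_tips < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips, rng=rng,
    )
    extra = rng.expovariate(n_tips * 1.0)
    for lf in tree.leaf_node_iter():
        lf.edge.length = (lf.edge.length or 0.0) + extra
    # stable, seed-independent-of-simulation-order tip names
    for i, lf in enumerate(sorted(tree.leaf_node_iter(),
                                  key=lambda nd: nd.taxon.label)):
        lf.taxon.label = f"sp{i + 1:04d}"
    phylo = Phylogeny(tree)
    # annotate ages so downstream code can treat the tree as dated
    t = phylo.dendropy_tree
    t.calc_node_ages(ultrametricity_precision=1e-6)
    for nd in t:
        nd.age_my = float(nd.age)
    return phylo


def _branch_iter(tree: Phylogeny):
    for nd in tree.dendropy_tree.preorder_node_iter():
        if nd.parent_node is not None:
            yield nd


def evolve_discrete_trait(tree: Phylogeny, n_states: int = 5,
                          rate: float = 0.1, seed: int = 0) -> LifeFormTable:
    """Symmetric Markov (Mk) trait evolved along the branches.

    Change events arrive as a Poisson process with the given rate per unit
    branch length; each event jumps to a uniformly chosen different state.
    The root state is uniform.  Low rates yield clade-structured (conserved)
    states.  With ``n_states=5`` the states are the Raunkiaer life forms.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    total = sum(nd.edge.length or 0.0 for nd in _branch_iter(tree))
    if total <= 0:
        raise ValueError("tree has zero total branch length")
    rng = _site_rng(seed, "discrete_trait")
    labels = (LIFE_FORMS if n_states == 5
              else tuple(f"state{i}" for i in range(n_states)))
    t = tree.dendropy_tree
    t.seed_node._state = int(rng.integers(n_states))
    states: dict[str, str] = {}
    for nd in t.preorder_node_iter():
        if nd.parent_node is not None:
            s = nd.parent_node._state
            n_events = rng.poisson(rate * (nd.edge.length or 0.0))
            for _ in range(n_events):
                s = (s + 1 + int(rng.integers(n_states - 1))) % n_states
            nd._state = s
        if nd.is_leaf():
            states[nd.taxon.label] = labels[nd._state]
    for nd in t.preorder_node_iter():
        del nd._state
    if n_states == 5:
        return LifeFormTable(states)
    return _GenericTrait(states)


def evolve_continuous_niche(tree: Phylogeny, sigma: float = 1.0,
                            seed: int = 0) -> pd.Series:
    """Brownian-motion niche optimum per species (root value 0).

    Tip covariance equals shared root-to-node path length times sigma^2.
    """
    rng = _site_rng(seed, "continuous_niche")
    t = tree.dendropy_tree
    t.seed_node._x = 0.0
    vals: dict[str, float] = {}
    for nd in t.preorder_node_iter():
        if nd.parent_node is not None:
            ln = nd.edge.length
            if ln is None:
                raise ValueError("tree has unset branch lengths; date it first")
            nd._x = nd.parent_node._x + sigma * np.sqrt(ln) * rng.standard_normal()
        if nd.is_leaf():
            vals[nd.taxon.label] = float(nd._x)
    for nd in t.preorder_node_iter():
        del nd._x
    return pd.Series(vals, name="niche_optimum")


def _repulsion_pick(D: np.ndarray, k: int, start: int) -> np.ndarray:
    """Greedy max-min patristic subset: repeatedly add the species farthest
    (in minimum distance) from the growing sample."""
    chosen = [start]
    n = D.shape[0]
    mind = D[start].copy()
    mind[start] = -np.inf
    for _ in range(k - 1):
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, D[nxt])
        mind[nxt] = -np.inf
    return np.array(chosen)


def assemble_communities(pool: Phylogeny, niche: pd.Series | None,
                         sites: SiteTable, cfg: AssemblyConfig,
                         environment_col: str = "environment"
                         ) -> CommunityMatrix:
    """Draw one assemblage per site from the pool under the configured rule.

    neutral: uniform sample of ``richness`` species.
    filtering: uniform sample among species with |optimum - site env| <=
        tolerance, topped up with nearest-optimum species when too few pass.
    repulsion: greedy pick maximizing the minimum within-sample patristic
        distance, seeded at a random species.
    """
    species = sorted(pool.tip_names)
    n_pool = len(species)
    if cfg.richness > n_pool:
        raise ValueError(
            f"richness {cfg.richness} infeasible for pool of {n_pool}")
    if cfg.mode == "filtering" and niche is None:
        raise ValueError("filtering assembly needs niche optima")
    if cfg.mode == "repulsion":
        Ddf = patristic_matrix(pool)
        D = Ddf.loc[species, species].to_numpy()
    rows = {}
    for site in sites.sites:
        rng = _site_rng(cfg.seed, "assembly", cfg.mode, site)
        if cfg.mode == "neutral":
            pick = rng.choice(n_pool, size=cfg.richness, replace=False)
        elif cfg.mode == "filtering":
            env = float(sites.table.loc[site, environment_col])
            opt = niche.loc[species].to_numpy()
            gap = np.abs(opt - env)
            eligible = np.flatnonzero(gap <= cfg.filter_tolerance)
            if eligible.size >= cfg.richness:
                pick = rng.choice(eligible, size=cfg.richness, replace=False)
            else:  # nearest-optimum fill keeps richness feasible
                pick = np.argsort(gap, kind="stable")[:cfg.richness]
        else:  # repulsion
            pick = _repulsion_pick(D, cfg.richness, int(rng.integers(n_pool)))
        row = np.zeros(n_pool, dtype=int)
        row[pick] = 1
        rows[site] = row
    inc = pd.DataFrame.from_dict(rows, orient="index", columns=species)
    inc = inc.loc[:, inc.sum(axis=0) > 0]
    return CommunityMatrix(inc)


def simulate_sites(n_sites: int, extent_km: float = 800.0,
                   autocorr_range_km: float = 300.0, seed: int = 0,
                   covariates: Sequence[str] = (
                       "annual_mean_temp", "annual_precip", "precip_driest_quarter",
                   ),
                   include_environment: bool = True) -> SiteTable:
    """Sites with uniform coordinates, GP climate covariates and blocked
    substrate classes.

    Coordinates are drawn uniformly on an extent_km square anchored in a
    semi-arid tropical region; each covariate is a zero-mean Gaussian
    process with covariance exp(-d/range) (jitter 1e-8), scaled to realistic
    climate units.  Substrate classes are spatially blocked: longitude
    terciles map to sedimentary / crystalline / inselberg.
    """
    if n_sites < 4:
        raise ValueError("need at least 4 sites")
    rng = _site_rng(seed, "sites")
    lat0, lon0 = -7.0, -39.0  # anchor so haversine distances are realistic
    x = rng.uniform(0, extent_km, size=n_sites)
    y = rng.uniform(0, extent_km, size=n_sites)
    deg_per_km_lat = 360.0 / (2 * np.pi * EARTH_RADIUS_KM)
    deg_per_km_lon = deg_per_km_lat / np.cos(np.radians(lat0))
    table = pd.DataFrame({
        "lat": lat0 + y * deg_per_km_lat,
        "lon": lon0 + x * deg_per_km_lon,
    }, index=[f"site{i + 1:04d}" for i in range(n_sites)])

    st = SiteTable(table)
    D = pair_distance_matrix(st).to_numpy()
    C = np.exp(-D / autocorr_range_km) + 1e-8 * np.eye(n_sites)
    L = np.linalg.cholesky(C)

    scales = {"annual_mean_temp": (25.0, 1.5),
              "annual_precip": (700.0, 150.0),
              "precip_driest_quarter": (30.0, 15.0)}
    for name in covariates:
        z = L @ rng.standard_normal(n_sites)
        mean, sd = scales.get(name, (0.0, 1.0))
        table[name] = mean + sd * z
    if include_environment:
        table["environment"] = L @ rng.standard_normal(n_sites)
    terciles = np.quantile(table["lon"], [1 / 3, 2 / 3])
    cls = np.where(table["lon"] <= terciles[0], "sedimentary",
                   np.where(table["lon"] <= terciles[1], "crystalline",
                            "inselberg"))
    table["substrate"] = cls
    return SiteTable(table)


def match_environment_to_niche(sites: SiteTable, niche: pd.Series,
                               low: float = 0.05, high: float = 0.95
                               ) -> SiteTable:
    """Rescale the ``environment`` column onto the realized niche range.

    Site environments are replaced rank-for-rank by evenly spaced quantiles
    of the species niche optima (from *low* to *high*), so the filtering
    rule actually bites: every site sits inside the trait space the pool
    occupies, and the spatial autocorrelation of the environment (its rank
    order) is preserved.
    """
    env = sites.table["environment"]
    targets = np.quantile(niche.to_numpy(),
                          np.linspace(low, high, len(env)))
    ranks = env.rank(method="first").astype(int) - 1
    table = sites.table.copy()
    table["environment"] = targets[ranks.to_numpy()]
    return SiteTable(table)


def make_fixture(out_dir, n_species: int = 120, n_sites: int = 15,
                 richness: int = 12, mode: AssemblyMode = "filtering",
                 seed: int = 0) -> dict:
    """Emit a complete toy study directory (tree, ages, communities, traits,
    sites) in the formats the pipeline reads.  Returns the path map.
    """
    from pathlib import Path

    from .tree import write_newick

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pool = simulate_yule_tree(n_species, seed=seed)
    trait = evolve_discrete_trait(pool, n_states=5, rate=0.15, seed=seed)
    niche = evolve_continuous_niche(pool, sigma=1.0, seed=seed)
    niche = (niche - niche.mean()) / niche.std()
    sites = simulate_sites(n_sites, seed=seed)
    if mode == "filtering":
        sites = match_environment_to_niche(sites, niche)
    cfg = AssemblyConfig(mode=mode, richness=richness,
                         filter_tolerance=0.25, seed=seed)
    comm = assemble_communities(pool, niche, sites, cfg)

    paths = {
        "tree": out / "pool_tree.nwk",
        "communities": out / "communities.csv",
        "traits": out / "life_forms.csv",
        "sites": out / "sites.csv",
    }
    write_newick(pool, paths["tree"])
    comm.to_csv(paths["communities"])
    trait.to_csv(paths["traits"])
    sites.to_csv(paths["sites"])
    return {k: str(v) for k, v in paths.items()}
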