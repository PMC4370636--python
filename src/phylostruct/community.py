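"""Community phylogenetic structure: MPD, MNTD, standardized effect sizes
under tip-label randomization, and the per-site NRI/NTI table.

MPD (mean pairwise distance) summarizes tree-wide relatedness of the species
co-occurring at a site; MNTD (mean nearest-taxon distance) summarizes
relatedness at the tips.  Both are compared against a null in which tip
labels of the pool phylogeny are reshuffled, which for incidence data is
equivalent to drawing random species sets of the same richness from the
pool.  The standardized effect size SES = (obs - null mean) / null SD; its
negation gives the Net Relatedness Index (NRI, from MPD) and the Nearest
Taxon Index (NTI, from MNTD).  Indices beyond +/-1.96 flag significant
clustering (positive) or overdispersion (negative).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .tree import Phylogeny, patristic_matrix

__all__ = [
    "CommunityMatrix",
    "SESResult",
    "mpd",
    "mntd",
    "ses",
    "nri_nti_table",
]

SIGNIFICANCE_Z = 1.96

Metric = Literal["MPD", "MNTD"]


class CommunityMatrix:
    """Site-by-species incidence (0/1) matrix.

    Wraps a pandas DataFrame with site ids as the index and species names as
    columns.  Every species must occur somewhere and every site must hold at
    least two species (pairwise metrics are undefined below that).
    """

    def __init__(self, incidence: pd.DataFrame):
        df = incidence.copy()
        df = df.astype(int)
        if not df.isin([0, 1]).all().all():
            raise ValueError("incidence entries must be 0/1")
        empty_sp = [c for c in df.columns if df[c].sum() == 0]
        if empty_sp:
            raise ValueError(f"species occurring in no site: {empty_sp}")
        poor = df.index[df.sum(axis=1) < 2].tolist()
        if poor:
            raise ValueError(f"sites with fewer than 2 species: {poor}")
        if df.index.duplicated().any() or df.columns.duplicated().any():
            raise ValueError("duplicate site ids or species names")
        self.incidence = df

    @property
    def sites(self) -> list:
        return list(self.incidence.index)

    @property
    def species(self) -> list[str]:
        return list(self.incidence.columns)

    def species_at(self, site) -> list[str]:
        row = self.incidence.loc[site]
        return list(row.index[row == 1])

    @classmethod
    def from_csv(cls, path) -> "CommunityMatrix":
        """Wide CSV: first column site id, remaining columns 0/1 incidence."""
        df = pd.read_csv(path, index_col=0)
        return cls(df)

    @classmethod
    def from_long(cls, records: pd.DataFrame | Iterable[tuple]) -> "CommunityMatrix":
        """Long-format (site, species) occurrence pairs."""
        if not isinstance(records, pd.DataFrame):
            records = pd.DataFrame(records, columns=["site", "species"])
        df = records.iloc[:, :2].copy()
        df.columns = ["site", "species"]
        wide = pd.crosstab(df["site"], df["species"]).clip(upper=1)
        wide.index.name = None
        wide.columns.name = None
        return cls(wide)

    def to_csv(self, path) -> None:
        self.incidence.to_csv(path)

    def subset_species(self, keep: Iterable[str], min_richness: int = 2
                       ) -> tuple["CommunityMatrix", list]:
        """Restrict to *keep* species; drop sites falling below min_richness.

        Returns the reduced matrix and the list of dropped sites.
        """
        keep = [s for s in self.species if s in set(keep)]
        sub = self.incidence[keep]
        ok = sub.sum(axis=1) >= min_richness
        dropped = list(sub.index[~ok])
        sub = sub.loc[ok]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        return CommunityMatrix(sub), dropped


def _as_distance(dist) -> tuple[np.ndarray, dict[str, int]]:
    if isinstance(dist, pd.DataFrame):
        return dist.to_numpy(dtype=float), {n: i for i, n in enumerate(dist.index)}
    raise TypeError("dist must be a labelled DataFrame (tips x tips)")


def mpd(sample: Iterable[str], dist: pd.DataFrame) -> float:
    """Mean patristic distance over all unordered species pairs (incidence
    weighting)."""
    names = list(dict.fromkeys(sample))
    D, idx = _as_distance(dist)
    missing = [s for s in names if s not in idx]
    if missing:
        raise KeyError(f"sample species not in distance matrix: {missing}")
    if len(names) < 2:
        raise ValueError("MPD undefined for fewer than 2 species")
    ii = np.sort([idx[s] for s in names])  # canonical order: exact symmetry
    sub = D[np.ix_(ii, ii)]
    iu = np.triu_indices(len(ii), k=1)
    return float(sub[iu].mean())


def mntd(sample: Iterable[str], dist: pd.DataFrame) -> float:
    """Mean distance from each species to its nearest other sample member."""
    names = list(dict.fromkeys(sample))
    D, idx = _as_distance(dist)
    missing = [s for s in names if s not in idx]
    if missing:
        raise KeyError(f"sample species not in distance matrix: {missing}")
    if len(names) < 2:
        raise ValueError("MNTD undefined for fewer than 2 species")
    ii = np.sort([idx[s] for s in names])
    sub = D[np.ix_(ii, ii)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _metric_on_indices(D: np.ndarray, idx: np.ndarray, metric: Metric) -> np.ndarray:
    """Vectorized metric over a batch of index sets, shape (R, k) -> (R,)."""
    sub = D[idx[:, :, None], idx[:, None, :]]  # (R, k, k)
    k = idx.shape[1]
    if metric == "MPD":
        iu = np.triu_indices(k, k=1)
        return sub[:, iu[0], iu[1]].mean(axis=1)
    eye = np.eye(k, dtype=bool)
    sub = np.where(eye[None, :, :], np.inf, sub)
    return sub.min(axis=2).mean(axis=1)


def _site_rng(seed: int, *context) -> np.random.Generator:
    """Deterministic per-site stream, independent of site order.

    The sub-seed is derived from a hash of the master seed and the context
    key (site id, metric name), so adding or reordering sites never perturbs
    another site's null draws.
    """
    h = hashlib.sha256(repr((int(seed), *map(str, context))).encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:8], "big"))


@dataclass(frozen=True)
class SESResult:
    metric: str
    observed: float
    null_mean: float
    null_sd: float
    ses: float | None
    p_value: float | None
    n_perm: int
    degenerate: bool = False

    @property
    def index(self) -> float | None:
        """NRI for MPD, NTI for MNTD: the negated SES."""
        return None if self.ses is None else -self.ses


def ses(metric: Metric, sample: Iterable[str], pool: Phylogeny | pd.DataFrame,
        n_perm: int = 1000, seed: int = 0, *, exhaustive: bool = False,
        _context: tuple = ()) -> SESResult:
    """Standardized effect size of MPD or MNTD under tip-label shuffling.

    The null reshuffles tip labels of the pool tree, i.e. each replicate
    scores a uniform random subset of pool tips with the sample's richness.
    SES uses the sample (n-1) SD.  ``exhaustive=True`` enumerates all
    equal-size subsets instead of Monte Carlo sampling (small pools only).
    A one-sided rank p (fraction of null <= observed, add-one smoothed) is
    reported alongside.
    """
    metric = metric.upper()
    if metric not in ("MPD", "MNTD"):
        raise ValueError("metric must be 'MPD' or 'MNTD'")
    dist = pool if isinstance(pool, pd.DataFrame) else patristic_matrix(pool)
    D, idx = _as_distance(dist)
    names = list(dict.fromkeys(sample))
    k = len(names)
    pool_n = D.shape[0]
    func = mpd if metric == "MPD" else mntd
    observed = func(names, dist)

    if exhaustive:
        sets = np.array(list(combinations(range(pool_n), k)), dtype=np.intp)
    else:
        if k >= pool_n:
            # every label shuffle returns the observed value
            return SESResult(metric, observed, observed, 0.0, None, None,
                             n_perm, degenerate=True)
        rng = _site_rng(seed, metric, *_context)
        sets = np.empty((n_perm, k), dtype=np.intp)
        for r in range(n_perm):
            sets[r] = rng.choice(pool_n, size=k, replace=False)
    null = _metric_on_indices(D, sets, metric)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd == 0.0:
        return SESResult(metric, observed, null_mean, 0.0, None, None,
                         len(null), degenerate=True)
    z = (observed - null_mean) / null_sd
    p = (1 + int((null <= observed + 1e-12).sum())) / (len(null) + 1)
    return SESResult(metric, observed, null_mean, null_sd, float(z), float(p),
                     len(null))


def nri_nti_table(communities: CommunityMatrix, pool: Phylogeny | pd.DataFrame,
                  n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-site NRI/NTI table with null summaries and significance flags.

    Returns one row per site with observed MPD/MNTD, null mean/SD, SES,
    NRI = -SES(MPD), NTI = -SES(MNTD), and clustering/overdispersion flags
    at |index| > 1.96.  The randomization pool is the full supplied tree (or
    distance matrix); restrict the pool by passing a pruned tree.
    """
    dist = pool if isinstance(pool, pd.DataFrame) else patristic_matrix(pool)
    missing = sorted(set(communities.species) - set(dist.index))
    if missing:
        raise KeyError(f"community species missing from the pool: {missing}")
    if not communities.sites:
        cols = (["richness"]
                + [f"{m}_{s}" for m in ("MPD", "MNTD")
                   for s in ("obs", "null_mean", "null_sd")]
                + ["SES_MPD", "NRI", "NRI_p", "SES_MNTD", "NTI", "NTI_p"]
                + [f"{i}_{f}" for i in ("NRI", "NTI")
                   for f in ("clustered", "overdispersed")])
        return pd.DataFrame(columns=cols, index=pd.Index([], name="site"))
    rows = []
    for site in communities.sites:
        spp = communities.species_at(site)
        row: dict = {"site": site, "richness": len(spp)}
        for metric, index_name in (("MPD", "NRI"), ("MNTD", "NTI")):
            r = ses(metric, spp, dist, n_perm=n_perm, seed=seed,
                    _context=(site,))
            row[f"{metric}_obs"] = r.observed
            row[f"{metric}_null_mean"] = r.null_mean
            row[f"{metric}_null_sd"] = r.null_sd
            row[f"SES_{metric}"] = r.ses
            row[index_name] = r.index
            row[f"{index_name}_p"] = r.p_value
        rows.append(row)
    df = pd.DataFrame(rows).set_index("site")
    for index_name in ("NRI", "NTI"):
        df[f"{index_name}_clustered"] = df[index_name] > SIGNIFICANCE_Z
        df[f"{index_name}_overdispersed"] = df[index_name] < -SIGNIFICANCE_Z
    return df
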