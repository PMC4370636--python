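"""Raunkiaer life-form harmonization and the phylogenetic-signal test on
parsimony state changes.

Life forms are the five Raunkiaer categories ordered by how exposed the
perennating buds are in the dry season: phanerophyte (buds well above
ground) > chamaephyte (buds close to the ground) > hemicryptophyte (ground
level) > cryptophyte (below ground) > therophyte (survives as seed).
Source floras often use extra categories (succulents, climbers, epiphytes);
`harmonize_life_form` folds these back into the five states with documented
rules, and conflicting multi-site reports resolve to the least-protected
(leftmost) category.

Signal is tested under the fixed-tree, character-reshuffle model: the
observed minimum number of parsimony state changes is compared with the
changes obtained after randomly permuting tip states.  Fewer observed
changes than the null indicates niche conservatism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .community import _site_rng
from .tree import Phylogeny

__all__ = [
    "LIFE_FORMS",
    "LifeFormTable",
    "SignalResult",
    "harmonize_life_form",
    "resolve_conflict",
    "read_life_forms",
    "parsimony_changes",
    "signal_test",
]

# bud protection increases left to right; "less protected" = earlier
LIFE_FORMS = (
    "phanerophyte",
    "chamaephyte",
    "hemicryptophyte",
    "cryptophyte",
    "therophyte",
)
_PRIORITY = {lf: i for i, lf in enumerate(LIFE_FORMS)}

_DIRECT = {
    "aerophyte": "phanerophyte",
    "epiphyte": "phanerophyte",
    "hemiparasite": "phanerophyte",
}
_SIZE_DEPENDENT = {"cactus", "succulent"}


def harmonize_life_form(raw: str, *, size_class: str | None = None,
                        senescent_dry_season: bool | None = None) -> str:
    """Map a source life-form label onto the five Raunkiaer categories.

    Aerophytes, epiphytes and hemiparasites become phanerophytes.  Cacti and
    succulents become phanerophytes when the adult is tall, chamaephytes
    otherwise (``size_class`` in {'tall', 'short'} required).  Climbers
    become therophytes when they senesce in the dry season, otherwise
    phanerophytes or chamaephytes by size.
    """
    label = raw.strip().lower()
    if label in LIFE_FORMS:
        return label
    if label in _DIRECT:
        return _DIRECT[label]
    if label in _SIZE_DEPENDENT:
        if size_class is None:
            raise ValueError(f"{label!r} needs size_class ('tall'/'short')")
        return "phanerophyte" if size_class == "tall" else "chamaephyte"
    if label == "climber":
        if senescent_dry_season is None:
            raise ValueError("'climber' needs senescent_dry_season flag")
        if senescent_dry_season:
            return "therophyte"
        if size_class is None:
            raise ValueError("non-senescent 'climber' needs size_class")
        return "phanerophyte" if size_class == "tall" else "chamaephyte"
    raise ValueError(f"unknown life-form label: {raw!r}")


def resolve_conflict(reports: Iterable[str]) -> str:
    """Pick the final category when sites disagree: least-protected buds win
    (phanerophyte > chamaephyte > hemicryptophyte > cryptophyte >
    therophyte)."""
    cats = list(reports)
    if not cats:
        raise ValueError("no life-form reports to resolve")
    bad = [c for c in cats if c not in _PRIORITY]
    if bad:
        raise ValueError(f"not final Raunkiaer categories: {bad}")
    return min(cats, key=_PRIORITY.__getitem__)


class LifeFormTable:
    """Species -> Raunkiaer category mapping (the discrete character)."""

    def __init__(self, states: Mapping[str, str]):
        bad = {s: c for s, c in states.items() if c not in LIFE_FORMS}
        if bad:
            raise ValueError(f"invalid categories: {bad}")
        self.states = dict(states)

    def __getitem__(self, species: str) -> str:
        return self.states[species]

    def __contains__(self, species: str) -> bool:
        return species in self.states

    def __len__(self) -> int:
        return len(self.states)

    @property
    def species(self) -> list[str]:
        return list(self.states)

    def woody_species(self) -> list[str]:
        """Phanerophytes (the woody growth form)."""
        return [s for s, c in self.states.items() if c == "phanerophyte"]

    def herbaceous_species(self) -> list[str]:
        """The four non-phanerophyte states."""
        return [s for s, c in self.states.items() if c != "phanerophyte"]

    def to_csv(self, path) -> None:
        pd.Series(self.states, name="life_form").rename_axis("species").to_csv(path)


def read_life_forms(path, *, exclude: Iterable[str] = (),
                    log=None) -> LifeFormTable:
    """Read a life-form CSV and harmonize raw labels where needed.

    Columns: species, plus either ``life_form`` (final category) or
    ``raw_label`` with optional ``size_class`` and ``senescent_dry_season``.
    Species named in *exclude* (exotics, ferns/lycophytes, genus-level
    records) are dropped with a logged count.
    """
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValueError("life-form CSV needs a 'species' column")
    exclude = set(exclude)
    n0 = len(df)
    df = df[~df["species"].isin(exclude)]
    if log is not None and n0 - len(df):
        log(f"excluded {n0 - len(df)} species records at life-form load")
    states: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        if "life_form" in df.columns and pd.notna(row.get("life_form")):
            cat = str(row["life_form"]).strip().lower()
            if cat not in LIFE_FORMS:
                raise ValueError(f"invalid final category {cat!r}")
        else:
            size = row.get("size_class")
            sen = row.get("senescent_dry_season")
            cat = harmonize_life_form(
                str(row["raw_label"]),
                size_class=None if pd.isna(size) else str(size),
                senescent_dry_season=None if pd.isna(sen) else bool(sen),
            )
        states.setdefault(str(row["species"]), []).append(cat)
    return LifeFormTable({sp: resolve_conflict(cats) for sp, cats in states.items()})


def _postorder_schedule(tree: Phylogeny) -> tuple[list[list[int]], dict[str, int], int]:
    """Flatten the tree into postorder: children index lists per internal
    node, tip-name -> slot mapping, and the total node count.

    Node slots: tips first (0..n_tips-1 in leaf-iteration order), then
    internal nodes in postorder.
    """
    t = tree.dendropy_tree
    tip_idx: dict[str, int] = {}
    slot: dict[int, int] = {}
    for lf in t.leaf_node_iter():
        slot[id(lf)] = len(tip_idx)
        tip_idx[lf.taxon.label] = slot[id(lf)]
    internals: list[list[int]] = []
    next_slot = len(tip_idx)
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            continue
        internals.append([slot[id(ch)] for ch in nd.child_nodes()])
        slot[id(nd)] = next_slot
        next_slot += 1
    return internals, tip_idx, next_slot


def _hartigan_batch(internals: list[list[int]], n_nodes: int,
                    tip_states: np.ndarray, n_states: int) -> np.ndarray:
    """Minimum parsimony changes for a batch of tip-state assignments.

    ``tip_states``: (R, n_tips) integer state codes.  Bottom-up pass of
    Hartigan's dynamic program, valid for multifurcating trees: at each
    internal node the optimal state set is the set of states carried by the
    maximal number of children, and each child outside that majority costs
    one change.  Returns (R,) change counts.
    """
    R, n_tips = tip_states.shape
    # optimal-state membership per node: (R, n_nodes, n_states) boolean
    member = np.zeros((R, n_nodes, n_states), dtype=bool)
    member[np.arange(R)[:, None], np.arange(n_tips)[None, :], tip_states] = True
    cost = np.zeros(R, dtype=np.int64)
    slot = n_tips
    for children in internals:
        counts = member[:, children, :].sum(axis=1)  # (R, n_states)
        kmax = counts.max(axis=1)                    # (R,)
        member[:, slot, :] = counts == kmax[:, None]
        cost += len(children) - kmax
        slot += 1
    return cost


def parsimony_changes(tree: Phylogeny, trait: LifeFormTable | Mapping[str, str]) -> int:
    """Minimum number of unordered state changes of the trait on the tree.

    Uses Hartigan's set dynamic program, exact on multifurcating trees.
    """
    states = trait.states if isinstance(trait, LifeFormTable) else dict(trait)
    internals, tip_idx, n_nodes = _postorder_schedule(tree)
    untyped = sorted(set(tip_idx) - set(states))
    if untyped:
        raise ValueError(f"tips without a trait state: {untyped}")
    alphabet = sorted(set(states[t] for t in tip_idx))
    code = {s: i for i, s in enumerate(alphabet)}
    tips = np.empty((1, len(tip_idx)), dtype=np.intp)
    for name, i in tip_idx.items():
        tips[0, i] = code[states[name]]
    return int(_hartigan_batch(internals, n_nodes, tips, len(alphabet))[0])


@dataclass(frozen=True)
class SignalResult:
    """Outcome of the fixed-tree, character-reshuffle signal test."""

    observed: int
    null_median: float
    null_min: int
    null_max: int
    n_rand: int
    p_value: float

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def signal_test(tree: Phylogeny, trait: LifeFormTable | Mapping[str, str],
                n_rand: int = 999, seed: int = 0) -> SignalResult:
    """Test for phylogenetic signal in a discrete trait.

    Null replicates permute tip states uniformly (state multiset preserved);
    p = (1 + #{null <= observed}) / (n_rand + 1), one-sided toward
    conservatism (fewer changes than chance).
    """
    states = trait.states if isinstance(trait, LifeFormTable) else dict(trait)
    internals, tip_idx, n_nodes = _postorder_schedule(tree)
    untyped = sorted(set(tip_idx) - set(states))
    if untyped:
        raise ValueError(f"tips without a trait state: {untyped}")
    alphabet = sorted(set(states[t] for t in tip_idx))
    if len(alphabet) < 2:
        raise ValueError("signal test undefined for a single-state trait")
    code = {s: i for i, s in enumerate(alphabet)}
    base = np.empty(len(tip_idx), dtype=np.intp)
    for name, i in tip_idx.items():
        base[i] = code[states[name]]
    observed = int(_hartigan_batch(internals, n_nodes, base[None, :],
                                   len(alphabet))[0])
    rng = _site_rng(seed, "signal_test")
    perms = np.array([rng.permutation(base) for _ in range(n_rand)])
    null = _hartigan_batch(internals, n_nodes, perms, len(alphabet))
    p = (1 + int((null <= observed).sum())) / (n_rand + 1)
    return SignalResult(
        observed=observed,
        null_median=float(np.median(null)),
        null_min=int(null.min()),
        null_max=int(null.max()),
        n_rand=n_rand,
        p_value=float(p),
    )
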