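"""Community merging and SMETANA-style MIP/MRO scoring.

Members are merged into one stoichiometric system with per-member
namespaced compartments. Two coupling regimes are contrasted:

* ``interacting`` — one shared extracellular pool; anything a member
  secretes can be consumed by the others (cross-feeding allowed);
* ``non_interacting`` — each member keeps a private copy of the
  environment, so only externally supplied nutrients are available.

The metabolic interaction potential (MIP) is the number of
environmental nutrients the community can spare through interspecies
exchange: the minimum number of distinct metabolites the environment
must supply for every member to grow without interaction, minus the
same quantity with interaction. The metabolic resource overlap (MRO)
measures competition as the mean pairwise intersection of the members'
individual minimal media divided by the mean individual medium size
(0 = disjoint nutritional needs, 1 = identical needs).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cobra import Metabolite, Model, Reaction

from . import gem, minimal_media as mm

__all__ = [
    "CommunityModel",
    "CommunityScores",
    "merge_community",
    "community_minimal_medium",
    "mip_score",
    "mro_score",
    "individual_minimal_media",
    "score_community",
    "enumerate_communities",
    "score_all",
    "dropout_scan",
    "rank_communities",
]

SEP = "__"
POOL_COMPARTMENT = "pool"


class MergeError(ValueError):
    """Member ids collide after prefixing, or too few members."""


@dataclass(frozen=True)
class CommunityModel:
    """Merged member models sharing (or not) an extracellular pool."""

    member_ids: tuple[str, ...]
    merged: Model
    regime: str  # interacting | non_interacting
    biomass_ids: dict[str, str]
    #: environmental metabolite id -> env exchange reaction ids it opens
    env_groups: dict[str, list[str]]


@dataclass(frozen=True)
class CommunityScores:
    members: frozenset[str]
    mip: int
    mro: float
    media_detail: dict = field(default_factory=dict, repr=False)


def _check_members(models) -> list[str]:
    ids = [m.id for m in models]
    if len(models) < 2:
        raise MergeError("a community needs at least two member models")
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise MergeError(f"duplicate member id(s) after prefixing: {dup}")
    return ids


def merge_community(models, regime: str = "interacting") -> CommunityModel:
    """Merge member models into one namespaced community model.

    Every member metabolite/reaction id is prefixed ``member__``. Member
    exchange reactions become transfers between the member's
    extracellular species and an environment pool (shared across members
    when ``interacting``, private per member otherwise), preserving the
    member's own uptake/secretion bounds. Fresh community exchange
    reactions connect each pool species to the environment with uptake
    closed; medium-setting and the minimal-medium MILP operate on those.
    """
    if regime not in ("interacting", "non_interacting"):
        raise ValueError(f"unknown regime {regime!r}")
    ids = _check_members(models)
    merged = Model(f"community_{regime}")
    biomass_ids: dict[str, str] = {}
    env_groups: dict[str, list[str]] = {}
    pool_mets: dict[str, Metabolite] = {}
    new_reactions = []

    for model in models:
        prefix = f"{model.id}{SEP}"
        member_mets = {
            m.id: Metabolite(
                prefix + m.id, name=m.name, formula=m.formula,
                compartment=prefix + (m.compartment or "c"),
            )
            for m in model.metabolites
        }
        for rxn in model.reactions:
            new = Reaction(prefix + rxn.id, lower_bound=rxn.lower_bound,
                           upper_bound=rxn.upper_bound)
            if gem.is_exchange(rxn):
                met = next(iter(rxn.metabolites))
                pool_key = met.id if regime == "interacting" else prefix + met.id
                if pool_key not in pool_mets:
                    pool_mets[pool_key] = Metabolite(
                        f"{pool_key}{SEP}pool", name=met.name, formula=met.formula,
                        compartment=POOL_COMPARTMENT,
                    )
                    ex = Reaction(f"EX{SEP}{pool_key}", lower_bound=0.0,
                                  upper_bound=gem.DEFAULT_INTERNAL_BOUND)
                    ex.add_metabolites({pool_mets[pool_key]: -1})
                    new_reactions.append(ex)
                    env_groups.setdefault(met.id, []).append(ex.id)
                # member exchange becomes a transfer to/from the pool,
                # keeping the member's own uptake/secretion capability
                new.add_metabolites({
                    member_mets[met.id]: -1, pool_mets[pool_key]: 1,
                })
            else:
                new.add_metabolites({
                    member_mets[m.id]: c for m, c in rxn.metabolites.items()
                })
            new_reactions.append(new)
        biomass_ids[model.id] = prefix + gem.objective_reaction_id(model)

    merged.add_reactions(new_reactions)
    merged.objective = {
        merged.reactions.get_by_id(b): 1.0 for b in biomass_ids.values()
    }
    return CommunityModel(tuple(ids), merged, regime, biomass_ids, env_groups)


def _member_thresholds(models, threshold_frac, uptake_bound) -> dict[str, float]:
    """Growth floor per member: fraction of its max growth in isolation."""
    out = {}
    for model in models:
        opened = gem.exchangeable_metabolites(model)
        full = gem.set_medium(model, opened, uptake_bound)
        sol = gem.fba(full)
        if sol.status != "optimal" or sol.objective_value <= mm.GROWTH_TOL:
            raise mm.GrowthError(
                f"member {model.id!r} cannot grow on the full medium in isolation"
            )
        out[model.id] = threshold_frac * sol.objective_value
    return out


def community_minimal_medium(
    community: CommunityModel,
    thresholds: dict[str, float],
    uptake_bound: float = gem.DEFAULT_UPTAKE_BOUND,
    free: tuple[str, ...] = (),
    lexicographic: bool = True,
) -> mm.MinimalMedium:
    """Minimum-cardinality environmental supply growing every member.

    Counts distinct environmental metabolites: in the non-interacting
    regime one indicator opens the metabolite's exchange for every
    member's private pool simultaneously.
    """
    S, lb, ub, rxn_ids, _ = gem.stoichiometric_arrays(community.merged)
    col = {rid: j for j, rid in enumerate(rxn_ids)}
    groups: dict[str, list[int]] = {}
    # total environmental supply per opened metabolite is U per member in
    # both regimes (one shared exchange vs one private exchange each), so
    # the regimes differ only in cross-feeding, not in supply capacity
    n_members = len(community.member_ids)
    for met_id, ex_ids in community.env_groups.items():
        cols = [col[e] for e in ex_ids]
        per_col = uptake_bound * n_members / len(cols)
        for j in cols:
            lb[j] = -per_col
        if met_id not in set(free):
            groups[met_id] = cols
    for member, thr in thresholds.items():
        j = col[community.biomass_ids[member]]
        lb[j] = max(lb[j], thr - mm.GROWTH_TOL)
    big_m = uptake_bound * n_members
    if lexicographic:
        opened, v = mm.lexicographic_minimum_medium(S, lb, ub, groups, big_m)
    else:
        opened, v, status = mm.solve_medium_milp(S, lb, ub, groups, big_m)
        if status != "optimal":
            raise mm.GrowthError(
                f"community {community.member_ids}: medium MILP infeasible "
                f"({community.regime} regime)"
            )
    growth = float(sum(v[col[b]] for b in community.biomass_ids.values()))
    return mm.MinimalMedium(opened, growth_value=growth)


def mip_score(
    models,
    threshold_frac: float = mm.DEFAULT_THRESHOLD_FRAC,
    uptake_bound: float = gem.DEFAULT_UPTAKE_BOUND,
    free: tuple[str, ...] = (),
    detail: bool = False,
):
    """Metabolic interaction potential of a member set.

    ``|minimal medium, non-interacting| − |minimal medium, interacting|``
    counting distinct environmental metabolites; clamped at 0 if solver
    noise inverts the difference.
    """
    thresholds = _member_thresholds(models, threshold_frac, uptake_bound)
    media = {}
    for regime in ("non_interacting", "interacting"):
        comm = merge_community(models, regime)
        media[regime] = community_minimal_medium(
            comm, thresholds, uptake_bound, free, lexicographic=detail
        )
    mip = media["non_interacting"].size - media["interacting"].size
    if mip < 0:
        warnings.warn(
            f"negative MIP ({mip}) clamped to 0 for members "
            f"{sorted(m.id for m in models)}", stacklevel=2,
        )
        mip = 0
    return (mip, media) if detail else mip


def individual_minimal_media(
    models,
    threshold_frac: float = mm.DEFAULT_THRESHOLD_FRAC,
    uptake_bound: float = gem.DEFAULT_UPTAKE_BOUND,
    free: tuple[str, ...] = (),
    n_alternates: int = 0,
) -> dict[str, list[frozenset[str]]]:
    """Each member's minimal media computed in isolation.

    One lexicographic optimum per member by default; with
    ``n_alternates > 0`` the equally-sized alternates are enumerated for
    alternate-media-averaged MRO.
    """
    out: dict[str, list[frozenset[str]]] = {}
    for model in models:
        if n_alternates > 0:
            media = mm.enumerate_minimal_media(
                model, threshold_frac=threshold_frac, uptake_bound=uptake_bound,
                max_solutions=n_alternates, free=free,
            )
            out[model.id] = [m.metabolite_ids for m in media]
        else:
            out[model.id] = [mm.minimal_medium(
                model, threshold_frac=threshold_frac, uptake_bound=uptake_bound,
                free=free,
            ).metabolite_ids]
    return out


def mro_from_media(media: dict[str, list[frozenset[str]]]) -> float:
    """MRO = mean pairwise |M_i ∩ M_j| / mean individual |M_i|.

    With several alternate media per member, intersection and size are
    averaged over all alternate combinations.
    """
    ids = sorted(media)
    if len(ids) < 2:
        raise ValueError("MRO needs at least two members")
    mean_sizes = [float(np.mean([len(m) for m in media[i]])) for i in ids]
    denom = float(np.mean(mean_sizes))
    if denom == 0:
        return 0.0
    inters = []
    for a, b in itertools.combinations(ids, 2):
        pairwise = [
            len(ma & mb) for ma in media[a] for mb in media[b]
        ]
        inters.append(float(np.mean(pairwise)))
    return float(np.clip(np.mean(inters) / denom, 0.0, 1.0))


def mro_score(
    models,
    threshold_frac: float = mm.DEFAULT_THRESHOLD_FRAC,
    uptake_bound: float = gem.DEFAULT_UPTAKE_BOUND,
    free: tuple[str, ...] = (),
    n_alternates: int = 0,
) -> float:
    """Metabolic resource overlap of a member set (0..1)."""
    _check_members(models)
    media = individual_minimal_media(
        models, threshold_frac, uptake_bound, free, n_alternates
    )
    return mro_from_media(media)


def score_community(
    models,
    threshold_frac: float = mm.DEFAULT_THRESHOLD_FRAC,
    uptake_bound: float = gem.DEFAULT_UPTAKE_BOUND,
    free: tuple[str, ...] = (),
    _media_cache: dict[str, list[frozenset[str]]] | None = None,
) -> CommunityScores:
    mip, media = mip_score(models, threshold_frac, uptake_bound, free, detail=True)
    if _media_cache is not None:
        indiv = {m.id: _media_cache[m.id] for m in models}
    else:
        indiv = individual_minimal_media(models, threshold_frac, uptake_bound, free)
    mro = mro_from_media(indiv)
    return CommunityScores(
        frozenset(m.id for m in models), mip, mro,
        media_detail={
            "non_interacting": media["non_interacting"],
            "interacting": media["interacting"],
            "individual": indiv,
        },
    )


def enumerate_communities(strain_ids, min_size: int = 2, max_size: int | None = None):
    """All member subsets with ``min_size ≤ |S| ≤ max_size``, in
    deterministic lexicographic order."""
    strain_ids = sorted(strain_ids)
    if max_size is None:
        max_size = len(strain_ids)
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if min_size > max_size:
        raise ValueError(f"min_size ({min_size}) > max_size ({max_size})")
    if max_size > len(strain_ids):
        raise ValueError("max_size exceeds the number of strains")
    return [
        tuple(c)
        for size in range(min_size, max_size + 1)
        for c in itertools.combinations(strain_ids, size)
    ]


def score_all(
    models: dict[str, Model],
    subsets,
    threshold_frac: float = mm.DEFAULT_THRESHOLD_FRAC,
    uptake_bound: float = gem.DEFAULT_UPTAKE_BOUND,
    free: tuple[str, ...] = (),
) -> pd.DataFrame:
    """MIP/MRO table for every subset; individual media are computed once
    per member and shared across subsets."""
    needed = sorted({s for subset in subsets for s in subset})
    missing = [s for s in needed if s not in models]
    if missing:
        raise KeyError(f"no model for member(s) {missing}")
    cache = individual_minimal_media(
        [models[s] for s in needed], threshold_frac, uptake_bound, free
    )
    rows = []
    for subset in subsets:
        scores = score_community(
            [models[s] for s in sorted(subset)], threshold_frac, uptake_bound,
            free, _media_cache=cache,
        )
        rows.append({
            "members": ";".join(sorted(subset)),
            "size": len(subset),
            "mip": scores.mip,
            "mro": scores.mro,
            "medium_size_non_interacting":
                scores.media_detail["non_interacting"].size,
            "medium_size_interacting": scores.media_detail["interacting"].size,
        })
    return pd.DataFrame(rows)


def dropout_scan(
    models: dict[str, Model],
    community,
    threshold_frac: float = mm.DEFAULT_THRESHOLD_FRAC,
    uptake_bound: float = gem.DEFAULT_UPTAKE_BOUND,
    free: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Leave-one-out score changes for a community of ≥3 members.

    Row one is the full community; each following row drops one member
    and reports ΔMIP/ΔMRO relative to the full set.
    """
    community = sorted(community)
    if len(community) < 3:
        raise ValueError("dropout scan needs a community of at least 3 members")
    subsets = [tuple(community)] + [
        tuple(s for s in community if s != dropped) for dropped in community
    ]
    table = score_all(models, subsets, threshold_frac, uptake_bound, free)
    table.insert(0, "dropped", [""] + community)
    table["delta_mip"] = table["mip"] - table.loc[0, "mip"]
    table["delta_mro"] = table["mro"] - table.loc[0, "mro"]
    return table


def rank_communities(scores: pd.DataFrame, size_range=None) -> pd.DataFrame:
    """Rank candidate communities: MIP descending, then MRO ascending,
    ties broken lexicographically by member set."""
    if scores.empty:
        raise ValueError("empty score table")
    out = scores.copy()
    if size_range is not None:
        lo, hi = size_range
        out = out[(out["size"] >= lo) & (out["size"] <= hi)]
    out = out.sort_values(
        by=["mip", "mro", "members"], ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out
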