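"""Minimum-cardinality growth media by mixed-integer programming.

A minimal medium is the smallest set of environmental metabolites whose
uptake lets a model reach a growth threshold. The MILP attaches one
binary indicator ``y_m`` per candidate environmental metabolite; every
uptake flux it controls satisfies ``v_e ≥ −U·y_m`` so that ``y_m = 0``
closes the uptake, and ``Σ y_m`` is minimized subject to mass balance
and the growth constraint. Solved with scipy's HiGHS branch-and-bound.

The same engine is reused by the community module, where one indicator
can drive several member-private uptakes of the same environmental
compound. Ties among equal-size media are broken deterministically in
favour of the lexicographically smallest sorted metabolite-id tuple
(greedy include-and-test). Alternate optima can be enumerated with
integer cuts.

A brute-force oracle (:func:`brute_force_minimal_media`) enumerates all
subsets of candidate metabolites; it exists to validate the MILP on
small fixtures and is exponential by design.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from . import gem

__all__ = [
    "MinimalMedium",
    "minimal_medium",
    "enumerate_minimal_media",
    "brute_force_minimal_media",
    "GrowthError",
    "solve_medium_milp",
    "lexicographic_minimum_medium",
    "enumerate_minimum_media",
]

GROWTH_TOL = 1e-9
DEFAULT_THRESHOLD_FRAC = 0.1


class GrowthError(RuntimeError):
    """The model cannot grow even with every uptake open."""


@dataclass(frozen=True)
class MinimalMedium:
    """A minimum-cardinality set of opened environmental metabolites."""

    metabolite_ids: frozenset[str]
    growth_value: float
    alternates: tuple[frozenset[str], ...] = field(default=())

    @property
    def size(self) -> int:
        return len(self.metabolite_ids)

    def sorted_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.metabolite_ids))


# ---------------------------------------------------------------------------
# generic MILP engine (also used for merged community models)


def solve_medium_milp(
    S,
    lb,
    ub,
    groups: dict[str, list[int]],
    uptake_bound: float,
    *,
    cardinality: int | None = None,
    cuts: tuple[frozenset[str], ...] = (),
    fixed: dict[str, int] | None = None,
):
    """Minimize Σy over binary medium indicators.

    ``groups`` maps a medium label (environmental metabolite id) to the
    exchange-reaction column indices it opens. ``lb``/``ub`` must
    already encode growth floors and have candidate uptake lower bounds
    at ``−uptake_bound``. ``cuts`` are no-good cuts on previously found
    supports; ``fixed`` pins selected indicators to 0/1. Returns
    ``(labels_opened, v, status)``.
    """
    labels = sorted(groups)
    n = len(lb)
    g = len(labels)
    U = float(uptake_bound)

    y_lb = np.zeros(g)
    y_ub = np.ones(g)
    if fixed:
        for gi, label in enumerate(labels):
            if label in fixed:
                y_lb[gi] = y_ub[gi] = float(fixed[label])
    lb_full = np.concatenate([lb, y_lb])
    ub_full = np.concatenate([ub, y_ub])
    integrality = np.concatenate([np.zeros(n), np.ones(g)])

    constraints = [LinearConstraint(
        sparse.hstack([S, sparse.csr_matrix((S.shape[0], g))], format="csr"),
        0.0, 0.0,
    )]

    rows, cols, data = [], [], []
    r = 0
    for gi, label in enumerate(labels):
        for col in groups[label]:
            rows += [r, r]
            cols += [col, n + gi]
            data += [1.0, U]
            r += 1
    if r:
        A_ind = sparse.csr_matrix((data, (rows, cols)), shape=(r, n + g))
        constraints.append(LinearConstraint(A_ind, 0.0, np.inf))

    if cardinality is not None:
        row = np.zeros(n + g)
        row[n:] = 1.0
        constraints.append(LinearConstraint(row, cardinality, cardinality))

    for cut in cuts:
        row = np.zeros(n + g)
        for gi, label in enumerate(labels):
            if label in cut:
                row[n + gi] = 1.0
        constraints.append(LinearConstraint(row, 0.0, len(cut) - 1))

    c = np.concatenate([np.zeros(n), np.ones(g)])
    res = milp(
        c, constraints=constraints, bounds=Bounds(lb_full, ub_full),
        integrality=integrality, options={"mip_rel_gap": 0.0},
    )
    if res.status != 0 or res.x is None:
        return None, None, "infeasible"
    y = res.x[n:]
    opened = frozenset(label for gi, label in enumerate(labels) if y[gi] > 0.5)
    return opened, res.x[:n], "optimal"


def lexicographic_minimum_medium(S, lb, ub, groups, uptake_bound):
    """Minimum-cardinality medium; ties → lexicographically smallest set.

    Greedy: after finding the optimum size ``k``, walk the sorted labels
    and keep each one in the medium iff a feasible size-``k`` completion
    containing all kept labels (and excluding all rejected ones) exists.
    Returns ``(opened, v)`` or raises :class:`GrowthError`.
    """
    opened, v, status = solve_medium_milp(S, lb, ub, groups, uptake_bound)
    if status != "optimal":
        raise GrowthError("medium MILP infeasible on the full environment")
    k = len(opened)
    if k == 0:
        return opened, v
    fixed: dict[str, int] = {}
    best = (opened, v)
    n_in = 0
    for label in sorted(groups):
        if n_in == k:
            break
        fixed[label] = 1
        got, vv, status = solve_medium_milp(
            S, lb, ub, groups, uptake_bound, cardinality=k, fixed=fixed
        )
        if status == "optimal":
            n_in += 1
            best = (got, vv)
        else:
            fixed[label] = 0
    return best


def enumerate_minimum_media(S, lb, ub, groups, uptake_bound, max_solutions):
    """All (≤ ``max_solutions``) media of minimum cardinality via integer
    cuts, returned sorted by metabolite ids."""
    first, _, status = solve_medium_milp(S, lb, ub, groups, uptake_bound)
    if status != "optimal":
        raise GrowthError("medium MILP infeasible on the full environment")
    k = len(first)
    found: list[tuple[frozenset[str], np.ndarray]] = []
    cuts: list[frozenset[str]] = []
    while len(found) < max_solutions:
        opened, v, status = solve_medium_milp(
            S, lb, ub, groups, uptake_bound, cardinality=k, cuts=tuple(cuts)
        )
        if status != "optimal":
            break
        found.append((opened, v))
        if k == 0:
            break
        cuts.append(opened)
    found.sort(key=lambda pair: tuple(sorted(pair[0])))
    return found


# ---------------------------------------------------------------------------
# single-model wrappers


def _prepare(model, growth_threshold, threshold_frac, uptake_bound, free):
    """Arrays with the biomass floor set and candidate uptakes open at −U."""
    S, lb, ub, rxn_ids, _ = gem.stoichiometric_arrays(model)
    ex_cols = {
        next(iter(r.metabolites)).id: rxn_ids.index(r.id)
        for r in gem.exchange_reactions(model)
    }
    free = set(free)

    full = lb.copy()
    for col in ex_cols.values():
        full[col] = -uptake_bound
    obj_col = rxn_ids.index(gem.objective_reaction_id(model))
    mu_max = _max_growth(S, full, ub, obj_col)
    if mu_max is None or mu_max <= GROWTH_TOL:
        raise GrowthError(f"model {model.id!r} cannot grow even on the full medium")
    threshold = (
        float(growth_threshold) if growth_threshold is not None
        else threshold_frac * mu_max
    )
    if threshold > mu_max + GROWTH_TOL:
        raise GrowthError(
            f"model {model.id!r}: growth threshold {threshold:.6g} exceeds "
            f"maximum achievable growth {mu_max:.6g}"
        )

    lb = lb.copy()
    groups: dict[str, list[int]] = {}
    for met_id, col in ex_cols.items():
        lb[col] = -uptake_bound
        if met_id not in free:
            groups[met_id] = [col]
    lb[obj_col] = max(lb[obj_col], threshold - GROWTH_TOL)
    return S, lb, ub, groups, obj_col


def _max_growth(S, lb, ub, obj_col):
    from scipy.optimize import linprog

    c = np.zeros(len(lb))
    c[obj_col] = -1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=np.column_stack([lb, ub]), method="highs")
    return -res.fun if res.success else None


def minimal_medium(
    model,
    growth_threshold: float | None = None,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    uptake_bound: float = gem.DEFAULT_UPTAKE_BOUND,
    free: tuple[str, ...] = (),
) -> MinimalMedium:
    """Lexicographically-smallest minimum-cardinality medium for a model.

    ``growth_threshold`` is an absolute biomass-flux floor; when omitted
    it defaults to ``threshold_frac`` of the maximum growth on the full
    medium. Metabolites in ``free`` (e.g. water, protons, metal ions)
    are always open and excluded from the cardinality count.
    """
    S, lb, ub, groups, obj_col = _prepare(
        model, growth_threshold, threshold_frac, uptake_bound, free
    )
    opened, v = lexicographic_minimum_medium(S, lb, ub, groups, uptake_bound)
    return MinimalMedium(opened, growth_value=float(v[obj_col]))


def enumerate_minimal_media(
    model,
    growth_threshold: float | None = None,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    uptake_bound: float = gem.DEFAULT_UPTAKE_BOUND,
    max_solutions: int = 10,
    free: tuple[str, ...] = (),
) -> list[MinimalMedium]:
    """Up to ``max_solutions`` media of minimum cardinality, id-sorted."""
    S, lb, ub, groups, obj_col = _prepare(
        model, growth_threshold, threshold_frac, uptake_bound, free
    )
    found = enumerate_minimum_media(S, lb, ub, groups, uptake_bound, max_solutions)
    alternates = tuple(opened for opened, _ in found)
    return [
        MinimalMedium(opened, growth_value=float(v[obj_col]), alternates=alternates)
        for opened, v in found
    ]


# ---------------------------------------------------------------------------
# oracle


def brute_force_minimal_media(
    model,
    growth_threshold: float | None = None,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    uptake_bound: float = gem.DEFAULT_UPTAKE_BOUND,
    free: tuple[str, ...] = (),
) -> list[frozenset[str]]:
    """Exhaustive-search minimal media (validation oracle, O(2^E))."""
    candidates = sorted(set(gem.exchangeable_metabolites(model)) - set(free))
    if len(candidates) > 16:
        raise ValueError("brute force limited to 16 candidate exchanges")
    full = gem.set_medium(model, candidates + list(free), uptake_bound)
    mu_max = gem.fba(full).objective_value
    if not np.isfinite(mu_max) or mu_max <= GROWTH_TOL:
        raise GrowthError(f"model {model.id!r} cannot grow even on the full medium")
    threshold = (
        float(growth_threshold) if growth_threshold is not None
        else threshold_frac * mu_max
    )
    for size in range(len(candidates) + 1):
        hits = []
        for combo in itertools.combinations(candidates, size):
            medium = gem.set_medium(model, list(combo) + list(free), uptake_bound)
            sol = gem.fba(medium)
            if sol.status == "optimal" and sol.objective_value >= threshold - 1e-6:
                hits.append(frozenset(combo))
        if hits:
            return hits
    raise GrowthError(f"model {model.id!r}: no growth-supporting subset found")
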