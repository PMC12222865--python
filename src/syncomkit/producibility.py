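"""Producibility metric (PM): robustness of metabolite biosynthesis.

Every exchangeable metabolite of a model is treated as a potential
environmental input, included independently with probability ``p_in``.
For each sampled environment, flux balance analysis on a demand (sink)
reaction decides whether the target metabolite can be synthesized; the
fraction of producible environments estimates the output probability
``P_out(p_in)``. Sweeping ``p_in`` over [0, 1] gives a producibility
curve, and

    PM = 1 − P_in,0.5

where ``P_in,0.5`` is the input probability at which ``P_out`` crosses
0.5. A metabolite producible in any environment has PM = 1; one that is
never producible has PM = 0. The Monte-Carlo curve is regularized by
isotonic regression before locating the half-point, since the true
``P_out`` is non-decreasing in ``p_in``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cobra import Model, Reaction
from sklearn.isotonic import IsotonicRegression

from . import gem

__all__ = [
    "ProducibilityCurve",
    "PMResult",
    "sample_environment",
    "producible",
    "producibility_curve",
    "pm_score",
    "pm_panel",
]

DEFAULT_GRID = tuple(np.round(np.linspace(0.0, 1.0, 21), 10))
DEFAULT_SAMPLES = 500
PRODUCIBILITY_TOL = 1e-6
DEMAND_PREFIX = "DM__"


@dataclass(frozen=True)
class ProducibilityCurve:
    metabolite_id: str
    model_id: str
    p_in_grid: tuple[float, ...]
    p_out_hat: tuple[float, ...]
    n_samples: int
    seed: int


@dataclass(frozen=True)
class PMResult:
    metabolite_id: str
    model_id: str
    p_in_half: float
    pm: float


def sample_environment(model: Model, p_in: float, rng: np.random.Generator) -> set[str]:
    """Each exchangeable metabolite included independently w.p. ``p_in``."""
    if not 0.0 <= p_in <= 1.0:
        raise ValueError(f"p_in must be in [0, 1], got {p_in}")
    mets = gem.exchangeable_metabolites(model)
    draws = rng.random(len(mets))
    return {m for m, u in zip(mets, draws) if u < p_in}


def _with_demand(model: Model, target: str) -> tuple[Model, str]:
    """Copy of the model with an unbounded sink on the target species."""
    if target not in model.metabolites:
        raise KeyError(f"unknown target metabolite {target!r}")
    model = model.copy()
    dm_id = DEMAND_PREFIX + target
    if dm_id not in model.reactions:
        dm = Reaction(dm_id, lower_bound=0.0, upper_bound=gem.DEFAULT_INTERNAL_BOUND)
        dm.add_metabolites({model.metabolites.get_by_id(target): -1})
        model.add_reactions([dm])
    return model, dm_id


def producible(
    model: Model, target: str, medium: set[str],
    uptake_bound: float = gem.DEFAULT_UPTAKE_BOUND,
) -> bool:
    """True iff the target's demand flux can exceed tolerance on ``medium``."""
    model, dm_id = _with_demand(model, target)
    gem.set_medium(model, medium, uptake_bound, inplace=True)
    sol = gem.fba(model, maximize=dm_id)
    return sol.status == "optimal" and sol.objective_value > PRODUCIBILITY_TOL or \
        sol.status == "unbounded"


def producibility_curve(
    model: Model,
    target: str,
    grid=DEFAULT_GRID,
    n_samples: int = DEFAULT_SAMPLES,
    seed: int = 0,
    uptake_bound: float = gem.DEFAULT_UPTAKE_BOUND,
) -> ProducibilityCurve:
    """Monte-Carlo estimate of ``P_out`` on each ``p_in`` grid point.

    Deterministic for a fixed seed. The costly FBA per sample is skipped
    at the degenerate grid ends (empty/full environment are constant).
    """
    grid = tuple(float(p) for p in grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("p_in grid must be strictly increasing")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    dm_model, dm_id = _with_demand(model, target)

    # one LP skeleton, re-solved with per-sample uptake bounds: far cheaper
    # than rebuilding the model for each sampled environment
    from scipy.optimize import linprog

    S, lb, ub, rxn_ids, _ = gem.stoichiometric_arrays(dm_model)
    ex = gem.exchange_reactions(dm_model)
    ex_cols = np.array([rxn_ids.index(r.id) for r in ex])
    mets = [next(iter(r.metabolites)).id for r in ex]
    base_lb = lb.copy()
    base_lb[ex_cols] = 0.0
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(dm_id)] = -1.0
    b_eq = np.zeros(S.shape[0])

    cache: dict[bytes, bool] = {}

    def solve(open_mask: np.ndarray) -> bool:
        key = open_mask.tobytes()  # environments repeat; the LP answer is pure
        hit = cache.get(key)
        if hit is not None:
            return hit
        lbs = base_lb.copy()
        lbs[ex_cols[open_mask]] = -uptake_bound
        res = linprog(c, A_eq=S, b_eq=b_eq,
                      bounds=np.column_stack([lbs, ub]), method="highs")
        if res.status == 3:  # unbounded demand: trivially producible
            ok = True
        else:
            ok = bool(res.success and -res.fun > PRODUCIBILITY_TOL)
        cache[key] = ok
        return ok

    n_ex = len(mets)
    end_results = {
        0.0: 1.0 if solve(np.zeros(n_ex, dtype=bool)) else 0.0,
        1.0: 1.0 if solve(np.ones(n_ex, dtype=bool)) else 0.0,
    }
    p_out = []
    for p in grid:
        if p in end_results:
            p_out.append(end_results[p])
            continue
        hits = sum(
            solve(rng.random(n_ex) < p) for _ in range(n_samples)
        )
        p_out.append(hits / n_samples)
    return ProducibilityCurve(target, model.id, grid, tuple(p_out), n_samples, seed)


def pm_score(curve: ProducibilityCurve) -> PMResult:
    """PM = 1 − P_in,0.5 from a producibility curve.

    The curve is made monotone by isotonic regression, then the 0.5
    crossing is located by linear interpolation. A curve everywhere
    ≥ 0.5 gives P_in,0.5 = 0 (PM 1); everywhere < 0.5 gives
    P_in,0.5 = 1 (PM 0).
    """
    if not curve.p_in_grid:
        raise ValueError("empty producibility curve")
    x = np.asarray(curve.p_in_grid)
    y = np.asarray(curve.p_out_hat)
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
    y = iso.fit_transform(x, y)
    if y[0] >= 0.5:
        p_half = 0.0
    elif y[-1] < 0.5:
        p_half = 1.0
    else:
        j = int(np.argmax(y >= 0.5))
        x0, x1, y0, y1 = x[j - 1], x[j], y[j - 1], y[j]
        p_half = x0 if y1 == y0 else x0 + (0.5 - y0) * (x1 - x0) / (y1 - y0)
    return PMResult(curve.metabolite_id, curve.model_id,
                    float(p_half), float(1.0 - p_half))


def _cell_seed(master_seed: int, model_id: str, target: str) -> int:
    """Stable per-cell seed so panel subsets reproduce independently."""
    return zlib.crc32(f"{master_seed}:{model_id}:{target}".encode()) & 0x7FFFFFFF


def pm_panel(
    models: dict[str, Model],
    targets,
    grid=DEFAULT_GRID,
    n_samples: int = DEFAULT_SAMPLES,
    seed: int = 0,
    uptake_bound: float = gem.DEFAULT_UPTAKE_BOUND,
) -> pd.DataFrame:
    """Strains × metabolites PM matrix.

    Targets absent from a model are recorded as NaN (missing), not 0.
    """
    rows = {}
    for model_id, model in models.items():
        row = {}
        for target in targets:
            if target not in model.metabolites:
                row[target] = np.nan
                continue
            curve = producibility_curve(
                model, target, grid, n_samples,
                seed=_cell_seed(seed, model_id, target),
                uptake_bound=uptake_bound,
            )
            row[target] = pm_score(curve).pm
        rows[model_id] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(targets))
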