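"""Constraint-based metabolic models: I/O, flux balance analysis, media.

Models are held as :class:`cobra.Model` objects (the field's standard
container), read from SBML Level 3 / fbc or from a small JSON dialect
used for toy models (see ``docs/methods.md``). Flux balance analysis is
formulated here directly on the stoichiometric arrays and solved with
scipy's HiGHS simplex, which is deterministic run-to-run; cobra's own
optimizer is deliberately not used so that it can serve as an
independent cross-check.

Conventions follow mainstream model repositories: an exchange reaction
touches exactly one extracellular metabolite with coefficient −1, so
negative flux is uptake and positive flux is export/secretion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

import cobra
from cobra import Metabolite, Model, Reaction

__all__ = [
    "read_model",
    "write_model",
    "model_from_dict",
    "model_to_dict",
    "fba",
    "FluxSolution",
    "set_medium",
    "exchange_reactions",
    "exchangeable_metabolites",
    "predicted_width",
    "stoichiometric_arrays",
    "DEFAULT_UPTAKE_BOUND",
    "DEFAULT_INTERNAL_BOUND",
]

DEFAULT_UPTAKE_BOUND = 10.0
DEFAULT_INTERNAL_BOUND = 1000.0
FEASIBILITY_TOL = 1e-7

#: carbon species never counted as organic substrates (element counts of
#: CO2, bicarbonate, carbonate, cyanide, carbon monoxide)
INORGANIC_CARBON_FORMULAS = (
    {"C": 1, "O": 2},
    {"C": 1, "H": 1, "O": 3},
    {"C": 1, "O": 3},
    {"C": 1, "N": 1},
    {"C": 1, "H": 1, "N": 1},
    {"C": 1, "O": 1},
)
INORGANIC_CARBON_NAMES = frozenset({"CO2", "HCO3", "CO3", "CN", "HCN", "CO"})


class ModelFormatError(ValueError):
    """Model file missing required structure (objective, species, ...)."""


# ---------------------------------------------------------------------------
# I/O


def read_model(path) -> Model:
    """Read an SBML L3/fbc model (``.xml``/``.sbml``) or toy JSON (``.json``)."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            return model_from_dict(json.load(fh))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = cobra.io.read_sbml_model(path)
    _require_objective(model)
    return model


def write_model(model: Model, path) -> None:
    path = str(path)
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
    else:
        cobra.io.write_sbml_model(model, path)


def objective_reaction_id(model: Model) -> str:
    rxns = [r.id for r in model.reactions if r.objective_coefficient != 0]
    if not rxns:
        raise ModelFormatError(f"model {model.id!r} has no objective reaction")
    return rxns[0]


def _require_objective(model: Model) -> None:
    objective_reaction_id(model)


def model_from_dict(doc: dict) -> Model:
    """Build a model from the toy JSON dialect.

    Schema: ``{"id", "metabolites": [{"id", "compartment", "name"?,
    "formula"?}], "reactions": [{"id", "stoichiometry": {met: coeff},
    "lower_bound", "upper_bound"}], "objective": reaction-id}``.
    """
    model = Model(doc.get("id", "model"))
    mets = {}
    for m in doc["metabolites"]:
        if not m.get("compartment"):
            raise ModelFormatError(f"metabolite {m.get('id')!r} has no compartment")
        met = Metabolite(
            m["id"], name=m.get("name", m["id"]),
            compartment=m["compartment"], formula=m.get("formula"),
        )
        if met.id in mets:
            raise ModelFormatError(f"duplicate metabolite id {met.id!r}")
        mets[met.id] = met
    rxns = []
    for r in doc["reactions"]:
        rxn = Reaction(
            r["id"],
            lower_bound=float(r.get("lower_bound", -DEFAULT_INTERNAL_BOUND)),
            upper_bound=float(r.get("upper_bound", DEFAULT_INTERNAL_BOUND)),
        )
        try:
            rxn.add_metabolites({mets[mid]: c for mid, c in r["stoichiometry"].items()})
        except KeyError as exc:
            raise ModelFormatError(
                f"reaction {r['id']!r} references unknown species {exc.args[0]!r}"
            ) from None
        rxns.append(rxn)
    model.add_reactions(rxns)
    obj = doc.get("objective")
    if not obj or obj not in model.reactions:
        raise ModelFormatError(f"objective reaction {obj!r} missing from model")
    model.objective = obj
    return model


def model_to_dict(model: Model) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id, "name": m.name, "compartment": m.compartment,
                **({"formula": m.formula} if m.formula else {}),
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": {m.id: c for m, c in r.metabolites.items()},
                "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
            }
            for r in model.reactions
        ],
        "objective": objective_reaction_id(model),
    }


# ---------------------------------------------------------------------------
# structure


def is_exchange(reaction: Reaction) -> bool:
    """Boundary pattern: single metabolite, coefficient −1, extracellular."""
    mets = reaction.metabolites
    if len(mets) != 1:
        return False
    (met, coeff), = mets.items()
    return coeff == -1 and _extracellular(met)


def _extracellular(met: Metabolite) -> bool:
    comp = (met.compartment or "").lower()
    return comp in {"e", "e0", "extracellular", "pool"} or comp.endswith("_e") or \
        met.id.endswith("_e")


def exchange_reactions(model: Model) -> list[Reaction]:
    return [r for r in model.reactions if is_exchange(r)]


def exchangeable_metabolites(model: Model) -> list[str]:
    """Ids of extracellular metabolites with an exchange reaction."""
    return [next(iter(r.metabolites)).id for r in exchange_reactions(model)]


def set_medium(
    model: Model, open_uptakes: Iterable[str],
    uptake_bound: float = DEFAULT_UPTAKE_BOUND, inplace: bool = False,
) -> Model:
    """Open uptake for the listed extracellular metabolites, close the rest.

    Export (upper) bounds are untouched. Returns the modified model
    (a copy unless ``inplace``).
    """
    if not inplace:
        model = model.copy()
    ex_by_met = {next(iter(r.metabolites)).id: r for r in exchange_reactions(model)}
    open_uptakes = set(open_uptakes)
    unknown = open_uptakes - set(ex_by_met)
    if unknown:
        raise KeyError(f"no exchange reaction for metabolite(s) {sorted(unknown)}")
    for met_id, rxn in ex_by_met.items():
        rxn.lower_bound = -float(uptake_bound) if met_id in open_uptakes else 0.0
    return model


# ---------------------------------------------------------------------------
# FBA


@dataclass(frozen=True)
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float]


def stoichiometric_arrays(model: Model):
    """(S sparse CSR, lb, ub, reaction ids, metabolite ids) for the model."""
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rows, cols, data = [], [], []
    lb = np.empty(len(model.reactions))
    ub = np.empty(len(model.reactions))
    rxn_ids = []
    for j, rxn in enumerate(model.reactions):
        rxn_ids.append(rxn.id)
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        for met, coeff in rxn.metabolites.items():
            rows.append(met_index[met.id])
            cols.append(j)
            data.append(float(coeff))
    S = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )
    return S, lb, ub, rxn_ids, [m.id for m in model.metabolites]


def fba(model: Model, maximize: str | None = None) -> FluxSolution:
    """Maximize the named reaction (default: the model objective).

    Infeasibility is reported through ``status``, not raised.
    """
    S, lb, ub, rxn_ids, _ = stoichiometric_arrays(model)
    target = maximize or objective_reaction_id(model)
    try:
        j = rxn_ids.index(target)
    except ValueError:
        raise KeyError(f"unknown reaction {target!r}") from None
    c = np.zeros(len(rxn_ids))
    c[j] = -1.0  # linprog minimizes
    res = linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status == 2:
        return FluxSolution("infeasible", float("nan"), {})
    if res.status == 3:
        return FluxSolution("unbounded", float("inf"), {})
    if not res.success:  # pragma: no cover - numerical failure
        return FluxSolution("infeasible", float("nan"), {})
    return FluxSolution("optimal", -float(res.fun), dict(zip(rxn_ids, res.x)))


# ---------------------------------------------------------------------------
# predicted utilization width


def _parse_formula(formula: str) -> dict[str, int]:
    import re

    counts: dict[str, int] = {}
    for elem, num in re.findall(r"([A-Z][a-z]?)(\d*)", formula or ""):
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    return counts


def _base_name(met: Metabolite) -> str:
    name = met.id
    for suffix in ("_e", "_c", "_p"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name.upper()


def predicted_width(model: Model, organic_only: bool = True) -> int:
    """Genome-predicted carbon utilization width.

    Counts exchange reactions whose extracellular metabolite is a
    carbon-containing organic compound: formula contains both C and H,
    excluding a fixed inorganic list (CO2, HCO3⁻, CO3²⁻, CN⁻, CO).
    With ``organic_only=False`` every carbon-containing exchange is
    counted. Metabolites without a formula are skipped with a warning.
    """
    count = 0
    for rxn in exchange_reactions(model):
        met = next(iter(rxn.metabolites))
        if not met.formula:
            warnings.warn(
                f"metabolite {met.id!r} has no formula; skipped in predicted width",
                stacklevel=2,
            )
            continue
        counts = _parse_formula(met.formula)
        if counts.get("C", 0) == 0:
            continue
        if counts in INORGANIC_CARBON_FORMULAS or \
                _base_name(met) in INORGANIC_CARBON_NAMES:
            continue
        if organic_only and counts.get("H", 0) == 0:
            continue
        count += 1
    return count
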