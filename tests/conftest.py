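"""Shared toy-model fixtures, built by hand (independently of the
synthetic-data generator) so they can serve as oracles for it."""

from __future__ import annotations

import pytest
from cobra import Metabolite, Model, Reaction


def _ext(mid: str, formula: str | None = None) -> Metabolite:
    return Metabolite(f"{mid}_e", compartment="e", formula=formula)


def _cyt(mid: str) -> Metabolite:
    return Metabolite(f"{mid}_c", compartment="c")


def build_chain_model() -> Model:
    """c_e →(uptake, lb −10)→ c_c →(biomass)."""
    m = Model("chain")
    c_e, c_c = _ext("c", "C6H12O6"), _cyt("c")
    ex = Reaction("EX_c", lower_bound=-10, upper_bound=1000)
    ex.add_metabolites({c_e: -1})
    t = Reaction("T_c", lower_bound=0, upper_bound=1000)
    t.add_metabolites({c_e: -1, c_c: 1})
    bio = Reaction("BIOMASS", lower_bound=0, upper_bound=1000)
    bio.add_metabolites({c_c: -1})
    m.add_reactions([ex, t, bio])
    m.objective = "BIOMASS"
    return m


def build_c_or_d_model() -> Model:
    """Biomass reachable from carbon c OR d (two alternative catabolisms)."""
    m = Model("c_or_d")
    c_e, d_e, p = _ext("c"), _ext("d"), _cyt("p")
    rxns = []
    for met, name in ((c_e, "c"), (d_e, "d")):
        ex = Reaction(f"EX_{name}", lower_bound=-10, upper_bound=1000)
        ex.add_metabolites({met: -1})
        cat = Reaction(f"CAT_{name}", lower_bound=0, upper_bound=1000)
        cat.add_metabolites({met: -1, p: 1})
        rxns += [ex, cat]
    bio = Reaction("BIOMASS", lower_bound=0, upper_bound=1000)
    bio.add_metabolites({p: -1})
    rxns.append(bio)
    m.add_reactions(rxns)
    m.objective = "BIOMASS"
    return m


def build_c_and_n_model() -> Model:
    """Biomass requires carbon c AND nitrogen n simultaneously."""
    m = Model("c_and_n")
    c_e, n_e = _ext("c"), _ext("n")
    c_c, n_c = _cyt("c"), _cyt("n")
    rxns = []
    for ext, cyt, name in ((c_e, c_c, "c"), (n_e, n_c, "n")):
        ex = Reaction(f"EX_{name}", lower_bound=-10, upper_bound=1000)
        ex.add_metabolites({ext: -1})
        t = Reaction(f"T_{name}", lower_bound=0, upper_bound=1000)
        t.add_metabolites({ext: -1, cyt: 1})
        rxns += [ex, t]
    bio = Reaction("BIOMASS", lower_bound=0, upper_bound=1000)
    bio.add_metabolites({c_c: -1, n_c: -1})
    rxns.append(bio)
    m.add_reactions(rxns)
    m.objective = "BIOMASS"
    return m


def build_free_growth_model() -> Model:
    """Degenerate fixture: biomass needs no environmental nutrient."""
    m = Model("free")
    x = _cyt("x")
    src = Reaction("SRC_x", lower_bound=0, upper_bound=1000)
    src.add_metabolites({x: 1})
    # an exchange exists but is unnecessary
    w_e = _ext("w")
    ex = Reaction("EX_w", lower_bound=-10, upper_bound=1000)
    ex.add_metabolites({w_e: -1})
    bio = Reaction("BIOMASS", lower_bound=0, upper_bound=1000)
    bio.add_metabolites({x: -1})
    m.add_reactions([src, ex, bio])
    m.objective = "BIOMASS"
    return m


@pytest.fixture
def chain_model():
    return build_chain_model()


@pytest.fixture
def c_or_d_model():
    return build_c_or_d_model()


@pytest.fixture
def c_and_n_model():
    return build_c_and_n_model()


@pytest.fixture
def free_growth_model():
    return build_free_growth_model()
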