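"""Synthetic fixtures with known ground truth.

Three generators cover the pipeline's inputs:

* toy genome-scale models with engineered auxotrophy/secretion
  (cross-feeding) structure and a closed-form expected MIP per member
  subset;
* utilization panels whose Levins niche widths hit prescribed targets
  exactly (constructive inversion of ``W = 1/ΣP_i²``);
* truncated-normal width samples emulating the approximately normal
  width distribution seen across large plant-associated strain panels.

Toy strains share one catabolic currency: every usable carbon source is
funnelled into a precursor ``p_c`` which biomass consumes together with
one unit of each auxotrophic metabolite. A donor synthesizes an
exchanged metabolite from the same precursor (so donating costs carbon)
and secretes it; an auxotroph can only import it. All randomness flows
through explicitly passed seeds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cobra import Metabolite, Model, Reaction
from scipy import stats as sps

from . import phenotype
from .gem import DEFAULT_INTERNAL_BOUND, DEFAULT_UPTAKE_BOUND

__all__ = [
    "CrossFeedSpec",
    "make_crossfeeding_panel",
    "expected_mip",
    "make_width_gradient_panel",
    "make_profile_panel",
    "sample_width_distribution",
]

CARBON_FORMULA = "C6H12O6"
AUX_FORMULA = "C4H8N2O3"


class SpecError(ValueError):
    """Invalid cross-feeding specification."""


@dataclass(frozen=True)
class CrossFeedSpec:
    """Engineered cross-feeding structure for a toy strain panel.

    ``exchanges`` are (donor, recipient, metabolite) triples: the
    recipient is auxotrophic for the metabolite, the donor synthesizes
    and secretes it. Strain ids default to ``S1..Sn``.
    """

    n_strains: int
    exchanges: tuple[tuple[str, str, str], ...]
    shared_carbon: str = "c1"
    seed: int = 0
    strain_ids: tuple[str, ...] = field(default=())

    def __post_init__(self):
        ids = self.strain_ids or tuple(f"S{i + 1}" for i in range(self.n_strains))
        object.__setattr__(self, "strain_ids", ids)
        object.__setattr__(self, "exchanges", tuple(
            (str(d), str(r), str(m)) for d, r, m in self.exchanges
        ))
        if len(ids) != self.n_strains or len(set(ids)) != self.n_strains:
            raise SpecError("strain_ids must be unique and match n_strains")
        seen_mets = set()
        for donor, recipient, met in self.exchanges:
            if donor == recipient:
                raise SpecError(f"exchange of {met!r}: donor == recipient ({donor!r})")
            if donor not in ids or recipient not in ids:
                raise SpecError(f"exchange references unknown strain: {donor, recipient}")
            if met in seen_mets:
                raise SpecError(f"metabolite {met!r} appears in more than one triple")
            if met == self.shared_carbon:
                raise SpecError(f"exchanged metabolite {met!r} collides with shared carbon")
            seen_mets.add(met)

    def to_dict(self) -> dict:
        return {
            "n_strains": self.n_strains,
            "strain_ids": list(self.strain_ids),
            "exchanges": [list(t) for t in self.exchanges],
            "shared_carbon": self.shared_carbon,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "CrossFeedSpec":
        return cls(
            n_strains=int(doc["n_strains"]),
            exchanges=tuple(tuple(t) for t in doc["exchanges"]),
            shared_carbon=doc.get("shared_carbon", "c1"),
            seed=int(doc.get("seed", 0)),
            strain_ids=tuple(doc.get("strain_ids", ())),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "CrossFeedSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _toy_strain(
    strain_id: str,
    carbon_ids,
    aux_mets,
    donor_mets,
    uptake_bound: float = DEFAULT_UPTAKE_BOUND,
) -> Model:
    """One toy strain: carbon catabolism to precursor ``p_c``, biomass
    consuming the precursor plus every auxotrophic metabolite."""
    overlap = set(aux_mets) & set(donor_mets)
    if overlap:
        raise SpecError(
            f"strain {strain_id!r}: metabolite(s) {sorted(overlap)} both "
            "required (auxotrophy) and synthesizable (donor) — impossible spec"
        )
    model = Model(strain_id)
    p = Metabolite("p_c", compartment="c")
    rxns = []
    biomass_stoich = {p: -1.0}

    for cid in carbon_ids:
        ext = Metabolite(f"{cid}_e", compartment="e", formula=CARBON_FORMULA)
        ex = Reaction(f"EX_{cid}", lower_bound=-uptake_bound,
                      upper_bound=DEFAULT_INTERNAL_BOUND)
        ex.add_metabolites({ext: -1})
        cat = Reaction(f"CAT_{cid}", lower_bound=0.0,
                       upper_bound=DEFAULT_INTERNAL_BOUND)
        cat.add_metabolites({ext: -1, p: 1})
        rxns += [ex, cat]

    for met in aux_mets:
        ext = Metabolite(f"{met}_e", compartment="e", formula=AUX_FORMULA)
        cyt = Metabolite(f"{met}_c", compartment="c", formula=AUX_FORMULA)
        ex = Reaction(f"EX_{met}", lower_bound=-uptake_bound,
                      upper_bound=DEFAULT_INTERNAL_BOUND)
        ex.add_metabolites({ext: -1})
        imp = Reaction(f"IMP_{met}", lower_bound=0.0,
                       upper_bound=DEFAULT_INTERNAL_BOUND)
        imp.add_metabolites({ext: -1, cyt: 1})
        rxns += [ex, imp]
        biomass_stoich[cyt] = -1.0

    for met in donor_mets:
        ext = Metabolite(f"{met}_e", compartment="e", formula=AUX_FORMULA)
        cyt = Metabolite(f"{met}_c", compartment="c", formula=AUX_FORMULA)
        # synthesis burns precursor: donating is feasible but not free
        syn = Reaction(f"SYN_{met}", lower_bound=0.0,
                       upper_bound=DEFAULT_INTERNAL_BOUND)
        syn.add_metabolites({p: -1, cyt: 1})
        sec = Reaction(f"SEC_{met}", lower_bound=0.0,
                       upper_bound=DEFAULT_INTERNAL_BOUND)
        sec.add_metabolites({cyt: -1, ext: 1})
        ex = Reaction(f"EX_{met}", lower_bound=0.0,  # export only
                      upper_bound=DEFAULT_INTERNAL_BOUND)
        ex.add_metabolites({ext: -1})
        rxns += [syn, sec, ex]

    bio = Reaction("BIOMASS", lower_bound=0.0, upper_bound=DEFAULT_INTERNAL_BOUND)
    bio.add_metabolites(biomass_stoich)
    rxns.append(bio)
    model.add_reactions(rxns)
    model.objective = "BIOMASS"
    return model


def make_crossfeeding_panel(spec: CrossFeedSpec) -> dict[str, Model]:
    """Toy strain models realizing the engineered exchange structure.

    Every strain consumes the shared carbon; recipients of a triple are
    auxotrophic for its metabolite, donors synthesize and secrete it.
    The expected MIP of any subset is :func:`expected_mip`.
    """
    models = {}
    for sid in spec.strain_ids:
        aux = [m for d, r, m in spec.exchanges if r == sid]
        don = [m for d, r, m in spec.exchanges if d == sid]
        models[sid] = _toy_strain(sid, [spec.shared_carbon], aux, don)
    return models


def expected_mip(spec: CrossFeedSpec, subset) -> int:
    """Ground-truth MIP: distinct exchanged metabolites whose donor and
    recipient are both inside the subset (the environment can spare
    exactly those)."""
    subset = set(subset)
    return len({
        m for d, r, m in spec.exchanges if d in subset and r in subset
    })


def make_width_gradient_panel(
    n_strains: int = 8,
    n_carbons: int = 9,
    seed: int = 0,
) -> tuple[dict[str, Model], pd.Series]:
    """Strain panel mixing narrow- and broad-spectrum toy strains.

    Strain ``i`` utilizes the first ``w_i`` of ``n_carbons`` shared
    carbon sources (nested sets, so minimal carbon requirements
    coincide). Narrow strains carry auxotrophies (2 for ``w ≤ 4``, 1
    for ``w ≤ 7``, none for broader strains) for metabolites that every
    other strain can synthesize and secrete — the cross-feeder role the
    narrow-spectrum strains play. Returns the models plus the widths.
    """
    rng = np.random.default_rng(seed)
    while True:
        widths = rng.integers(2, n_carbons + 1, size=n_strains)
        aux_counts = np.where(widths <= 4, 2, np.where(widths <= 7, 1, 0))
        if len(set(aux_counts.tolist())) == 3:
            break
    ids = [f"S{i + 1}" for i in range(n_strains)]
    aux_of = {
        sid: [f"x_{sid}_{k + 1}" for k in range(int(aux_counts[i]))]
        for i, sid in enumerate(ids)
    }
    all_aux = [m for sid in ids for m in aux_of[sid]]
    models = {}
    for i, sid in enumerate(ids):
        carbons = [f"c{k + 1}" for k in range(int(widths[i]))]
        donors = [m for m in all_aux if m not in aux_of[sid]]
        models[sid] = _toy_strain(sid, carbons, aux_of[sid], donors)
    return models, pd.Series(widths.astype(int), index=ids, name="width")


# ---------------------------------------------------------------------------
# utilization panels with prescribed Levins widths


def _proportions_for_width(width: float, n_resources: int) -> np.ndarray:
    """Proportion vector with exactly the requested Levins width.

    Uses ``m = ceil(width)`` resources: one at proportion ``a`` and the
    rest uniform, with ``a`` solved from ``1/W = a² + (1−a)²/(m−1)``.
    """
    if not 1.0 <= width <= n_resources:
        raise ValueError(
            f"target width {width} outside [1, {n_resources}]"
        )
    m = max(int(math.ceil(width - 1e-12)), 1)
    props = np.zeros(n_resources)
    if m == 1:
        props[0] = 1.0
        return props
    b = m - 1
    disc = 1.0 - (b + 1) * (1.0 - b / width)
    a = (1.0 + math.sqrt(max(disc, 0.0))) / (b + 1)
    props[0] = a
    props[1:m] = (1.0 - a) / b
    return props


def make_profile_panel(
    n_strains: int,
    n_resources: int,
    target_widths,
    seed: int = 0,
) -> phenotype.ProfilePanel:
    """Utilization panel whose per-strain Levins widths equal the targets.

    Resource assignment and signal scale are randomized per strain (the
    width is invariant to both); the panel is built with threshold 0 so
    every positive signal counts as utilized.
    """
    target_widths = list(target_widths)
    if len(target_widths) != n_strains:
        raise ValueError("one target width per strain required")
    rng = np.random.default_rng(seed)
    resources = [f"R{j + 1}" for j in range(n_resources)]
    rows = {}
    for i, w in enumerate(target_widths):
        props = _proportions_for_width(float(w), n_resources)
        perm = rng.permutation(n_resources)
        scale = rng.uniform(200.0, 400.0)
        row = np.zeros(n_resources)
        row[perm] = props
        rows[f"S{i + 1}"] = row * scale
    df = pd.DataFrame.from_dict(rows, orient="index", columns=resources)
    return phenotype.panel_from_frame(df, threshold=0.0)


def sample_width_distribution(
    mu: float, sigma: float, n: int, seed: int = 0
) -> np.ndarray:
    """Truncated-normal (≥ 0) width samples, seed-deterministic."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    a = (0.0 - mu) / sigma
    return sps.truncnorm.rvs(
        a, np.inf, loc=mu, scale=sigma, size=n,
        random_state=np.random.default_rng(seed),
    )
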