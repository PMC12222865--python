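# syncomkit

Tools for the bottom-up design of stable synthetic microbial communities
(SynComs) from two kinds of data a strain collection typically has:
resource-utilization profiles (Biolog/OmniLog phenotype arrays or binary
growth calls) and genome-scale metabolic models (SBML). The package is
aimed at microbial ecologists and microbiome engineers who want to pick,
from a panel of candidate strains, member combinations that cooperate
metabolically instead of competing for the same nutrients.

## What it computes

**Niche indices.** From a strains × carbon-sources signal matrix, with
utilization called at signal > 50 (OmniLog convention) and proportions
P_i renormalized over utilized resources:

* Levins' niche width `W = 1/Σ P_i²` (effective number of resources used),
  its simplified form (substrate count), Pianka's overlap
  `O_jk = Σ P_ij P_ik / √(Σ P_ij² Σ P_ik²)`, per-strain average overlaps,
  and narrow-/broad-spectrum (NSR/BSR) classification from the width tails
  (≤ 7 / ≥ 29 substrates).

**Community scores.** For any member subset, from the members' metabolic
models, via minimal-medium MILPs (HiGHS):

* `MIP = |minimal medium without cross-feeding| − |with cross-feeding|` —
  how many environmental nutrients the community can spare through
  interspecies exchange (cooperative potential);
* `MRO = mean pairwise |M_i ∩ M_j| / mean |M_i|` over the members'
  individual minimal media — how much their nutritional needs collide
  (competitive pressure).

Plus exhaustive enumeration of candidate communities in a size range,
ranking (high MIP, low MRO), and leave-one-out dropout scans.

**Producibility metric.** Per metabolite and model, `PM = 1 − P_in,0.5`,
where `P_in,0.5` is the environment-inclusion probability at which the
metabolite becomes producible (by FBA) in half of random environments —
a 0–1 measure of biosynthetic robustness that flags compounds a strain
likely needs fed by partners.

**Statistics.** Width↔score regressions with confidence bands, Gaussian
fits of width distributions, phylogenetic-distance-binned correlations
(distances from CSV matrices or newick trees), and hierarchical clustering
of PM panels. See `docs/methods.md` for conventions and defaults.

## Worked example

```python
import pandas as pd
from syncomkit import phenotype as ph, community as cm
from syncomkit.synthetic_data import CrossFeedSpec, make_crossfeeding_panel

# --- niche indices from a toy utilization matrix (OmniLog units) ---
df = pd.DataFrame(
    [[210, 160, 120, 0, 0, 55],
     [180, 0, 130, 95, 70, 0],
     [90, 0, 0, 0, 0, 0]],
    index=["SQR9", "G", "E"],
    columns=["fructose", "glucose", "pyruvate", "xylose", "malate", "citrate"],
)
panel = ph.panel_from_frame(df, threshold=50.0)
print(ph.profile_table(panel, low=1, high=5).round(3).to_string())

# --- MIP/MRO of an engineered mutual cross-feeding pair ---
spec = CrossFeedSpec(2, [("S1", "S2", "x"), ("S2", "S1", "y")])
models = make_crossfeeding_panel(spec)
print(cm.score_all(models, [("S1", "S2")]).to_string(index=False))
```

prints

```
           niche_width  simplified_width  average_overlap         class
strain_id
SQR9             3.409                 4            0.715  intermediate
G                3.569                 4            0.718  intermediate
E                1.000                 1            0.714           NSR

members  size  mip  mro  medium_size_non_interacting  medium_size_interacting
  S1;S2     2    2  0.5                            3                        1
```

Strain SQR9 utilizes 4 substrates but unevenly, so its effective width is
3.41, not 4; strain E uses a single substrate (width 1, NSR). The
engineered pair — S1 requires metabolite x secreted by S2 and vice versa,
both on one shared carbon — needs 3 supplied nutrients without
cross-feeding ({carbon, x, y}) but only the carbon when exchange is
allowed, hence MIP = 2; their individual minimal media ({carbon, x} and
{carbon, y}) share 1 of a mean 2 nutrients, hence MRO = 0.5.

The same operations are available from the shell:

```
syncomkit profile-stats panel.csv --threshold 50
syncomkit score-communities --models models/ --min-size 2 --max-size 6
syncomkit dropout --models models/ --members E,SQR9,J,K
syncomkit pm models/E.xml --targets biomass_components.txt --seed 17
syncomkit run config.yaml     # full pipeline + provenance manifest
```

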