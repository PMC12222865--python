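"""End-to-end orchestration: profiles → niche indices → community
scores → regressions → ranked candidate communities, with a
machine-readable run manifest for provenance.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, community, gem, phenotype, producibility, stats

__all__ = ["RunConfig", "PipelineError", "run_full"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class RunConfig:
    """Validated inputs and settings for a full pipeline run."""

    panel_path: str
    models_dir: str
    out_dir: str
    distances_path: str | None = None
    threshold: float = 50.0
    min_size: int = 2
    max_size: int | None = None
    threshold_frac: float = 0.1
    uptake_bound: float = 10.0
    pm_targets: list[str] = field(default_factory=list)
    grid_points: int = 21
    pm_samples: int = 500
    seed: int = 0
    free_metabolites: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def to_dict(self) -> dict:
        return asdict(self)

    def validate(self) -> None:
        if not Path(self.panel_path).is_file():
            raise PipelineError(f"pre-flight: panel file missing: {self.panel_path}")
        mdir = Path(self.models_dir)
        if not mdir.is_dir():
            raise PipelineError(f"pre-flight: models directory missing: {self.models_dir}")
        if not sorted(mdir.glob("*.xml")) + sorted(mdir.glob("*.json")):
            raise PipelineError(f"pre-flight: no model files (*.xml/*.json) in {mdir}")
        if self.distances_path and not Path(self.distances_path).is_file():
            raise PipelineError(f"pre-flight: distance file missing: {self.distances_path}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_models(models_dir: str) -> dict[str, object]:
    files = sorted(Path(models_dir).glob("*.xml")) + sorted(Path(models_dir).glob("*.json"))
    models = {}
    for f in files:
        m = gem.read_model(f)
        models[m.id] = m
    return models


def run_full(config: RunConfig) -> dict:
    """Run the whole workflow; returns the manifest dictionary.

    Outputs written to ``config.out_dir``: per-strain index table,
    overlap matrix, per-community score table, ranked communities,
    regression fits (and distance-binned fits when a distance matrix is
    given), optional PM panel, and ``manifest.json`` capturing config,
    versions, seed and output hashes.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return deco

    @stage("profiles")
    def panel():
        return phenotype.load_panel(config.panel_path, threshold=config.threshold)

    @stage("profiles")
    def _write_profiles():
        table = phenotype.profile_table(panel)
        table.to_csv(out / "strain_indices.csv")
        phenotype.overlap_matrix(panel).to_frame().to_csv(out / "overlap_matrix.csv")
        outputs["strain_indices"] = out / "strain_indices.csv"
        outputs["overlap_matrix"] = out / "overlap_matrix.csv"
        return table

    @stage("models")
    def models():
        m = _load_models(config.models_dir)
        missing = [s for s in panel.strains if s not in m]
        if missing:
            raise PipelineError(
                f"stage 'models': no metabolic model for panel strain(s) {missing}"
            )
        return m

    @stage("scores")
    def scores():
        subsets = community.enumerate_communities(
            list(panel.strains), config.min_size,
            config.max_size or len(panel.strains),
        )
        table = community.score_all(
            models, subsets, threshold_frac=config.threshold_frac,
            uptake_bound=config.uptake_bound, free=tuple(config.free_metabolites),
        )
        table.to_csv(out / "community_scores.csv", index=False)
        outputs["community_scores"] = out / "community_scores.csv"
        return table

    @stage("ranking")
    def ranked():
        r = community.rank_communities(scores)
        r.to_csv(out / "ranked_communities.csv", index=False)
        outputs["ranked_communities"] = out / "ranked_communities.csv"
        return r

    @stage("regressions")
    def fits():
        widths = _write_profiles["niche_width"]
        mean_w = [
            float(widths.loc[list(m.split(";"))].mean())
            for m in scores["members"]
        ]
        tbl = scores.assign(mean_width=mean_w)
        rows = []
        for score_col in ("mip", "mro"):
            fit = stats.linreg(tbl["mean_width"], tbl[score_col])
            rows.append({
                "response": score_col, "slope": fit.slope,
                "intercept": fit.intercept, "r2": fit.r2,
                "p_value": fit.p_value, "n": fit.n,
            })
        frame = pd.DataFrame(rows)
        frame.to_csv(out / "regression_fits.csv", index=False)
        outputs["regression_fits"] = out / "regression_fits.csv"

        if config.distances_path:
            dist = (
                stats.patristic_distances(config.distances_path)
                if str(config.distances_path).endswith((".nwk", ".newick", ".tree"))
                else pd.read_csv(config.distances_path, index_col=0)
            )
            pairs = tbl[tbl["size"] == 2].copy()
            pairs[["strain_a", "strain_b"]] = (
                pairs["members"].str.split(";", expand=True)
            )
            dvals = [
                dist.loc[a, b] for a, b in zip(pairs["strain_a"], pairs["strain_b"])
            ]
            edges = [min(dvals), float(pd.Series(dvals).median()), max(dvals) + 1e-9]
            binned = stats.binned_distance_correlation(
                pairs.rename(columns={"mip": "score"}), dist, edges
            )
            binned.to_csv(out / "distance_binned_fits.csv", index=False)
            outputs["distance_binned_fits"] = out / "distance_binned_fits.csv"
        return frame

    if config.pm_targets:
        @stage("producibility")
        def _pm():
            import numpy as np

            grid = tuple(np.round(np.linspace(0, 1, config.grid_points), 10))
            panel_pm = producibility.pm_panel(
                models, config.pm_targets, grid=grid,
                n_samples=config.pm_samples, seed=config.seed,
                uptake_bound=config.uptake_bound,
            )
            panel_pm.to_csv(out / "pm_panel.csv")
            outputs["pm_panel"] = out / "pm_panel.csv"

    config_doc = config.to_dict()
    config_hash = hashlib.sha256(
        json.dumps(config_doc, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "package": "syncomkit",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": config_doc,
        "config_sha256": config_hash,
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)}
                    for k, p in sorted(outputs.items())},
        "n_strains": len(panel.strains),
        "n_communities": int(len(scores)),
        "top_community": ranked.iloc[0]["members"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
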