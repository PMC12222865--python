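"""Resource-utilization phenotypes and niche indices.

Parses strains × carbon-sources utilization matrices (Biolog/OmniLog
respiration signals or binary growth calls) and computes the classical
ecology indices used to characterise rhizosphere isolates:

* Levins' niche width ``W = 1 / Σ P_i²`` — the effective number of
  resources a strain uses,
* the simplified width — the plain count of utilized substrates,
* Pianka's overlap ``O_jk = Σ P_ij P_ik / sqrt(Σ P_ij² · Σ P_ik²)`` —
  cosine-type similarity of two strains' resource-use proportions.

``P_i`` is the proportion of strain activity on resource *i*: signals at
or below the utilization threshold (OmniLog value > 50 by convention)
are zeroed, and the remaining signals renormalized to sum to one.
Binary 0/1 growth calls therefore give uniform proportions ``1/k`` over
the ``k`` utilized substrates, so Levins' width collapses to the count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UtilizationProfile",
    "ProfilePanel",
    "OverlapMatrix",
    "load_panel",
    "panel_from_frame",
    "niche_width",
    "simplified_width",
    "pianka_overlap",
    "overlap_matrix",
    "average_overlap",
    "classify_nsr_bsr",
    "cas_siderophore_index",
    "profile_table",
]

#: default OmniLog utilization cutoff (strict: signal must exceed it)
DEFAULT_THRESHOLD = 50.0


class PanelError(ValueError):
    """Malformed utilization table (non-numeric cells, duplicate labels...)."""


class UndefinedIndexError(ValueError):
    """An index was requested for a profile with no utilized resource."""


@dataclass(frozen=True)
class UtilizationProfile:
    """One strain's signal across an ordered list of resources.

    ``proportions`` are the P_i of Levins/Pianka: zero wherever ``mask``
    is false, renormalized over the masked signals otherwise.
    """

    strain_id: str
    resource_ids: tuple[str, ...]
    signal: np.ndarray
    mask: np.ndarray = field(repr=False)
    proportions: np.ndarray = field(repr=False)

    @classmethod
    def from_signal(
        cls, strain_id: str, resource_ids: list[str] | tuple[str, ...],
        signal, threshold: float = DEFAULT_THRESHOLD,
    ) -> "UtilizationProfile":
        signal = np.asarray(signal, dtype=float)
        if signal.ndim != 1 or len(signal) != len(resource_ids):
            raise PanelError(
                f"strain {strain_id!r}: signal length {signal.size} does not "
                f"match {len(resource_ids)} resources"
            )
        if np.any(signal < 0) or not np.all(np.isfinite(signal)):
            raise PanelError(f"strain {strain_id!r}: signals must be finite and >= 0")
        mask = signal > threshold
        props = np.zeros_like(signal)
        if mask.any():
            props[mask] = signal[mask] / signal[mask].sum()
        return cls(str(strain_id), tuple(resource_ids), signal, mask, props)

    @property
    def n_utilized(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ProfilePanel:
    """A collection of profiles sharing one resource ordering."""

    strains: tuple[str, ...]
    resources: tuple[str, ...]
    profiles: dict[str, UtilizationProfile]
    threshold: float

    def __getitem__(self, strain_id: str) -> UtilizationProfile:
        try:
            return self.profiles[strain_id]
        except KeyError:
            raise KeyError(f"unknown strain {strain_id!r}") from None

    def __len__(self) -> int:
        return len(self.strains)


@dataclass(frozen=True)
class OverlapMatrix:
    """Symmetric Pianka overlap matrix, diagonal 1 for nonzero profiles."""

    strains: tuple[str, ...]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.strains, columns=self.strains)


def panel_from_frame(df: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> ProfilePanel:
    """Build a panel from a strains × resources DataFrame of signals."""
    if df.empty:
        raise PanelError("empty utilization table")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise PanelError(f"duplicated strain name {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise PanelError(f"duplicated resource name {dup!r}")
    try:
        values = df.astype(float)
    except (TypeError, ValueError):
        for s in df.index:
            for r in df.columns:
                try:
                    float(df.loc[s, r])
                except (TypeError, ValueError):
                    raise PanelError(
                        f"non-numeric cell at strain {s!r}, resource {r!r}: "
                        f"{df.loc[s, r]!r}"
                    ) from None
        raise
    resources = tuple(str(c) for c in df.columns)
    profiles: dict[str, UtilizationProfile] = {}
    for strain in values.index:
        prof = UtilizationProfile.from_signal(
            str(strain), resources, values.loc[strain].to_numpy(), threshold
        )
        if not prof.mask.any():
            warnings.warn(
                f"strain {strain!r} utilizes no resource at threshold {threshold}; "
                "it is retained but excluded from width/overlap statistics",
                stacklevel=2,
            )
        profiles[str(strain)] = prof
    return ProfilePanel(tuple(profiles), resources, profiles, float(threshold))


def load_panel(path, threshold: float = DEFAULT_THRESHOLD, sep: str | None = None) -> ProfilePanel:
    """Read a strains (rows) × resources (columns) CSV/TSV signal table."""
    df = pd.read_csv(path, index_col=0, sep=sep, engine="python")
    return panel_from_frame(df, threshold)


def niche_width(profile: UtilizationProfile) -> float:
    """Levins' niche width ``W = 1 / Σ P_i²`` over the profile's proportions."""
    if not profile.mask.any():
        raise UndefinedIndexError(
            f"niche width undefined: strain {profile.strain_id!r} utilizes no resource"
        )
    return float(1.0 / np.sum(profile.proportions**2))


def simplified_width(profile: UtilizationProfile) -> int:
    """Width simplified to the number of substrates supporting growth."""
    return profile.n_utilized


def pianka_overlap(a: UtilizationProfile, b: UtilizationProfile) -> float:
    """Pianka's niche overlap between two strains, in [0, 1]."""
    if a.resource_ids != b.resource_ids:
        raise PanelError(
            f"profiles {a.strain_id!r} and {b.strain_id!r} have different resource orderings"
        )
    for p in (a, b):
        if not p.mask.any():
            raise UndefinedIndexError(
                f"overlap undefined: strain {p.strain_id!r} utilizes no resource"
            )
    num = float(np.dot(a.proportions, b.proportions))
    den = float(np.sqrt(np.sum(a.proportions**2) * np.sum(b.proportions**2)))
    return float(np.clip(num / den, 0.0, 1.0))


def overlap_matrix(panel: ProfilePanel) -> OverlapMatrix:
    """All-pairs Pianka overlaps; zero-profile strains get NaN rows/columns."""
    n = len(panel.strains)
    vals = np.full((n, n), np.nan)
    for i, si in enumerate(panel.strains):
        if not panel[si].mask.any():
            continue
        vals[i, i] = 1.0
        for j in range(i + 1, n):
            sj = panel.strains[j]
            if not panel[sj].mask.any():
                continue
            o = pianka_overlap(panel[si], panel[sj])
            vals[i, j] = vals[j, i] = o
    return OverlapMatrix(panel.strains, vals)


def average_overlap(panel: ProfilePanel, strain: str) -> float:
    """Mean Pianka overlap of ``strain`` with every other (nonzero) strain."""
    if strain not in panel.profiles:
        raise KeyError(f"unknown strain {strain!r}")
    others = [
        s for s in panel.strains
        if s != strain and panel[s].mask.any()
    ]
    if not others:
        raise UndefinedIndexError("average overlap needs at least one other nonzero strain")
    focal = panel[strain]
    return float(np.mean([pianka_overlap(focal, panel[s]) for s in others]))


def classify_nsr_bsr(widths, low: int = 7, high: int = 29) -> list[str]:
    """Label widths as narrow- (``<= low``), broad- (``>= high``) spectrum
    resource utilizers, or ``intermediate``.

    Defaults are the tails used for phyllosphere strain panels
    (≤7 / ≥29 utilizable compounds).
    """
    if low >= high:
        raise ValueError(f"low ({low}) must be < high ({high})")
    out = []
    for w in widths:
        if w < 0:
            raise ValueError(f"negative width {w}")
        out.append("NSR" if w <= low else "BSR" if w >= high else "intermediate")
    return out


def cas_siderophore_index(sample_abs: float, reference_abs: float) -> float:
    """CAS siderophore production index ``1 − A_s / A_r``.

    ``A_s`` is the sample absorbance at 630 nm, ``A_r`` the uninoculated
    reference; iron-chelation by siderophores decolorizes the CAS dye, so
    larger index means more siderophore.
    """
    if reference_abs <= 0:
        raise ValueError(f"reference absorbance must be > 0, got {reference_abs}")
    if sample_abs < 0:
        raise ValueError(f"sample absorbance must be >= 0, got {sample_abs}")
    return 1.0 - sample_abs / reference_abs


def profile_table(panel: ProfilePanel, low: int = 7, high: int = 29) -> pd.DataFrame:
    """Per-strain summary: Levins width, simplified width, mean overlap, class.

    Zero-profile strains appear with NaN indices and class ``undefined``.
    """
    rows = []
    nonzero = [s for s in panel.strains if panel[s].mask.any()]
    for s in panel.strains:
        prof = panel[s]
        if not prof.mask.any():
            rows.append((s, np.nan, 0, np.nan, "undefined"))
            continue
        w = niche_width(prof)
        sw = simplified_width(prof)
        avg = (
            average_overlap(panel, s)
            if len(nonzero) > 1 else np.nan
        )
        cls = classify_nsr_bsr([sw], low, high)[0]
        rows.append((s, w, sw, avg, cls))
    return pd.DataFrame(
        rows, columns=["strain_id", "niche_width", "simplified_width", "average_overlap", "class"]
    ).set_index("strain_id")
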