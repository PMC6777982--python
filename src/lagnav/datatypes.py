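"""Core data containers: parcellation tables, subjects, connectomes, configs.

Region metadata travels as a plain :class:`pandas.DataFrame` with the columns
in :data:`REGION_COLUMNS`; ``validate_regions`` enforces the structural
invariants (involutive cross-hemispheric homotopic pairing, one subnetwork
label per region). Subject-level clinical data and connectomes are small
dataclasses so their invariants can be checked at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: The seven canonical resting-state subnetworks used to label region pairs.
SUBNETWORKS = (
    "default_mode",
    "executive_control",
    "sensorimotor",
    "fronto_parietal",
    "auditory",
    "visual",
    "subcortical",
)

#: Required columns of a region table.
REGION_COLUMNS = (
    "region_id",
    "hemisphere",
    "homotopic_partner",
    "x",
    "y",
    "z",
    "subnetwork",
    "lesioned",
)

ARAT_MAX = 57


def validate_regions(regions: pd.DataFrame) -> pd.DataFrame:
    """Check a region table and return it indexed by ``region_id``.

    Raises ``ValueError`` if columns are missing, hemisphere labels are not
    left/right, homotopic pairing is not a cross-hemispheric involution, or a
    subnetwork label is unknown.
    """
    missing = set(REGION_COLUMNS) - set(regions.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    tab = regions.set_index("region_id", drop=False) if regions.index.name != "region_id" else regions
    if tab["region_id"].duplicated().any():
        raise ValueError("duplicate region ids")
    hemis = set(tab["hemisphere"].unique())
    if not hemis <= {"left", "right"}:
        raise ValueError(f"hemisphere labels must be left/right, got {hemis}")
    partner = tab["homotopic_partner"]
    for rid, pid in partner.items():
        if pid not in tab.index:
            raise ValueError(f"region {rid}: partner {pid} not in table")
        if tab.at[pid, "homotopic_partner"] != rid:
            raise ValueError(f"homotopic pairing is not an involution at region {rid}")
        if tab.at[pid, "hemisphere"] == tab.at[rid, "hemisphere"]:
            raise ValueError(f"homotopic pair ({rid}, {pid}) is not cross-hemispheric")
    bad = set(tab["subnetwork"].unique()) - set(SUBNETWORKS)
    if bad:
        raise ValueError(f"unknown subnetwork labels: {sorted(bad)}")
    return tab


def homotopic_pairs(regions: pd.DataFrame) -> list[tuple[int, int]]:
    """Return homotopic pairs as ``(right_id, left_id)`` tuples.

    One tuple per pair, ordered by right-hemisphere region id. The pair id
    used in lag tables is the right-hemisphere region id.
    """
    tab = validate_regions(regions)
    pairs = []
    for rid in tab.index[tab["hemisphere"] == "right"]:
        pairs.append((int(rid), int(tab.at[rid, "homotopic_partner"])))
    return sorted(pairs)


@dataclass
class SubjectRecord:
    """Clinical record for one participant.

    ``lesion_centroids`` holds one (x, y, z) coordinate in mm per distinct
    lesion; controls have none. ``arat`` is the Action Research Arm Test
    upper-limb motor score (0–57, higher is better). ``planted_lags`` is
    filled by the synthetic generator with the true pair lags in seconds.
    """

    subject_id: str
    group: str  # "stroke" | "control"
    lesion_centroids: list[tuple[float, float, float]] = field(default_factory=list)
    lesion_regions: set[int] = field(default_factory=set)
    lesion_side: str | None = None
    lesion_radius_mm: float = 0.0
    lesion_locations: list[str] = field(default_factory=list)
    stroke_type: str | None = None
    arat: int | None = None
    onset_years: float | None = None
    age_years: float | None = None
    age_range: str | None = None
    gender: str | None = None
    planted_lags: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("stroke", "control"):
            raise ValueError(f"group must be stroke/control, got {self.group!r}")
        if self.arat is not None and not 0 <= self.arat <= ARAT_MAX:
            raise ValueError(f"ARAT must be in [0, {ARAT_MAX}], got {self.arat}")
        if self.onset_years is not None and self.onset_years < 0:
            raise ValueError("onset_years must be non-negative")
        if self.group == "stroke" and not (
            self.lesion_centroids or self.lesion_regions or self.lesion_locations
        ):
            raise ValueError("stroke subjects need lesion information")
        if self.group == "control" and (self.lesion_centroids or self.lesion_regions):
            raise ValueError("control subjects must have no lesions")


@dataclass
class Connectome:
    """Weighted structural network with spatial embedding.

    ``weights`` is the N x N symmetric, hollow, non-negative streamline-count
    matrix; ``coords`` the N x 3 region centers of mass in mm, row-aligned
    with ``region_ids``.
    """

    weights: np.ndarray
    coords: np.ndarray
    region_ids: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.region_ids = np.asarray(self.region_ids)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square")
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be N x 3 and aligned with weights")
        if self.region_ids.shape != (n,):
            raise ValueError("region_ids must be length N")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("weights must have a zero diagonal")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def copy(self) -> "Connectome":
        return Connectome(self.weights.copy(), self.coords.copy(), self.region_ids.copy())


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate a clinical resting-state acquisition: TR 2 s, 240
    volumes (8 min), 40 homotopic pairs, 14 usable stroke subjects and 12
    controls. The planted lag field is

        tau*(pair) = stroke_base_lag * exp(-d_surface / lesion_decay_mm)
                     + affected_boost_lag * [pair's subnetwork is affected]
                     + homotopic_dist_coef * d_homotopic
                     + baseline_lag

    in seconds, where d_surface is the distance from the ipsilesional
    region's centre of mass to the lesion surface (0 inside the lesion);
    lesion radii vary per subject over ``lesion_radius_range_mm``, coupling
    lesion extent to both the lag burden and the structural damage.
    ``noise_sd`` is in units of the (unit-variance) signal sd.
    """

    n_stroke: int = 14
    n_control: int = 12
    n_pairs: int = 40
    tr_seconds: float = 2.0
    n_timepoints: int = 240
    stroke_base_lag: float = 2.6
    control_base_lag: float = 0.25
    baseline_lag: float = 0.1
    affected_boost_lag: float = 0.25
    homotopic_dist_coef: float = 0.003
    lesion_decay_mm: float = 30.0
    noise_sd: float = 0.1
    band_hz: tuple[float, float] = (0.009, 0.08)
    lesion_radius_range_mm: tuple[float, float] = (10.0, 30.0)
    damage_fraction: float = 0.9
    damage_taper_mm: float = 20.0
    edge_decay_mm: float = 40.0
    weight_scale: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_stroke", "n_control", "n_pairs", "n_timepoints"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 < self.band_hz[0] < self.band_hz[1]:
            raise ValueError("band_hz must satisfy 0 < low < high")

    def replace(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


def euclidean(a: Sequence[float], b: Sequence[float]) -> float:
    """Straight-line distance in mm between two 3D points."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate dimensionality mismatch")
    return float(np.linalg.norm(a - b))
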