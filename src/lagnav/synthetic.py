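"""Synthetic cohorts: parcellation, lagged BOLD pairs, connectomes, lesions.

The generator emulates the study conditions of a clinical stroke cohort at
region level, so the whole analysis pipeline runs without any imaging data:

* a mirror-symmetric parcellation of 2 * n_pairs regions whose homotopic
  pairing is an involution across the x = 0 midplane, labelled by the seven
  canonical resting-state subnetworks;
* per subject, one band-limited (0.009-0.08 Hz) Gaussian signal per pair;
  the right-hemisphere member carries the signal, the left member carries
  the same signal delayed by a planted lag tau* (applied as an exact phase
  rotation in the frequency domain, so fractional-TR lags are exact) plus
  independent band-limited noise;
* for stroke subjects the planted lag field decays with distance from the
  lesion, tau*(pair) = base * exp(-d_lesion / lambda) + baseline, where
  d_lesion is the Euclidean distance from the ipsilesional region's centre
  of mass to the nearest lesion centroid; controls receive a small uniform
  baseline lag;
* spatially embedded connectomes whose edge probability and streamline-like
  integer weights decay with internode distance, patched to be connected at
  full density; focal lesions are spheres that delete edges touching any
  node within the radius;
* ARAT motor scores generated to decrease with the subject's mean planted
  lag, and homotopic functional connectivity correspondingly degraded by
  the planted delay plus noise.

All randomness descends from one integer seed through named
``numpy.random.SeedSequence`` child streams, so subject order cannot change
any draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    SUBNETWORKS,
    CohortConfig,
    Connectome,
    SubjectRecord,
    validate_regions,
    homotopic_pairs,
)
from .lag import BoldMatrix

__all__ = [
    "Cohort",
    "diffuse_damage",
    "gen_parcellation",
    "gen_bold_cohort",
    "gen_bold_subject",
    "gen_pure_shift_bold",
    "gen_connectome",
    "lesion_connectome",
    "demographics_fixture",
    "generate_cohort",
]


@dataclass
class Cohort:
    """In-memory synthetic cohort: geometry, subjects, signals, connectomes."""

    regions: pd.DataFrame
    subjects: list[SubjectRecord]
    bold: dict[str, BoldMatrix]
    connectomes: dict[str, Connectome] = field(default_factory=dict)
    config: CohortConfig | None = None

    @property
    def stroke(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == "stroke"]

    @property
    def controls(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == "control"]


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-based stream: one root seed, fixed integer sub-keys."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def gen_parcellation(n_pairs: int, seed: int = 0) -> pd.DataFrame:
    """Mirror-symmetric parcellation with involutive homotopic pairing.

    Right-hemisphere regions get ids 0..n_pairs-1 and random centres of mass
    in a brain-sized box with x > 0; each left partner (id n_pairs + k) is
    the exact mirror image about the x = 0 plane. Subnetwork labels cycle
    through the seven canonical resting-state networks, both members of a
    pair sharing the label.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be at least 2")
    rng = _rng(seed, 0)
    x = rng.uniform(8.0, 70.0, n_pairs)
    y = rng.uniform(-90.0, 65.0, n_pairs)
    z = rng.uniform(-45.0, 70.0, n_pairs)
    rows = []
    for k in range(n_pairs):
        net = SUBNETWORKS[k % len(SUBNETWORKS)]
        rows.append((k, "right", n_pairs + k, x[k], y[k], z[k], net, False))
        rows.append((n_pairs + k, "left", k, -x[k], y[k], z[k], net, False))
    tab = pd.DataFrame(
        rows,
        columns=[
            "region_id",
            "hemisphere",
            "homotopic_partner",
            "x",
            "y",
            "z",
            "subnetwork",
            "lesioned",
        ],
    )
    return validate_regions(tab)


def _bandlimited_signal(rng, n_timepoints: int, tr: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance periodic Gaussian signal band-limited to ``band`` (Hz)."""
    freqs = np.fft.rfftfreq(n_timepoints, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        # band falls between DFT bins at this T/TR; keep the nearest bin
        keep = np.zeros_like(freqs, dtype=bool)
        keep[np.argmin(np.abs(freqs - 0.5 * (band[0] + band[1])))] = True
    spec = np.zeros(freqs.size, dtype=complex)
    m = int(keep.sum())
    spec[keep] = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    sig = np.fft.irfft(spec, n=n_timepoints)
    sig -= sig.mean()
    sd = sig.std()
    if sd == 0:
        raise RuntimeError("degenerate band-limited draw")
    return sig / sd


def _delay(signal: np.ndarray, tau_seconds: float, tr: float) -> np.ndarray:
    """Delay a periodic signal by ``tau_seconds`` via exact phase rotation."""
    T = signal.size
    freqs = np.fft.rfftfreq(T, d=tr)
    spec = np.fft.rfft(signal) * np.exp(-2j * np.pi * freqs * tau_seconds)
    return np.fft.irfft(spec, n=T)


def _lag_field(
    regions: pd.DataFrame, subject: SubjectRecord, config: CohortConfig
) -> dict[int, float]:
    """Planted lag per pair: decay with distance to the lesion surface,
    plus a uniform boost for pairs in subnetworks touched by the lesion."""
    pairs = homotopic_pairs(regions)
    if subject.group == "control":
        return {rid: config.control_base_lag for rid, _ in pairs}
    centroids = np.asarray(subject.lesion_centroids, dtype=float)
    affected_nets = set(
        regions.loc[regions["region_id"].isin(subject.lesion_regions), "subnetwork"]
    )
    out = {}
    for right_id, left_id in pairs:
        ipsi = right_id if subject.lesion_side == "right" else left_id
        com = regions.loc[ipsi, ["x", "y", "z"]].to_numpy(dtype=float)
        d = float(np.linalg.norm(centroids - com, axis=1).min())
        d_surface = max(0.0, d - subject.lesion_radius_mm)
        tau = config.stroke_base_lag * np.exp(-d_surface / config.lesion_decay_mm)
        if regions.at[right_id, "subnetwork"] in affected_nets:
            tau += config.affected_boost_lag
        com_l = regions.loc[left_id, ["x", "y", "z"]].to_numpy(dtype=float)
        com_r = regions.loc[right_id, ["x", "y", "z"]].to_numpy(dtype=float)
        tau += config.homotopic_dist_coef * float(np.linalg.norm(com_r - com_l))
        out[right_id] = tau + config.baseline_lag
    return out


def gen_bold_subject(
    regions: pd.DataFrame,
    planted_lags: dict[int, float],
    config: CohortConfig,
    rng: np.random.Generator,
) -> BoldMatrix:
    """BOLD matrix for one subject with the given planted pair lags.

    Each pair gets an independent band-limited signal on the right region;
    the left region carries the signal delayed by the pair's planted lag,
    plus independent band-limited noise of sd ``config.noise_sd``.
    """
    tab = validate_regions(regions)
    max_shift = max(planted_lags.values()) / config.tr_seconds
    if config.n_timepoints < 4 * max_shift:
        raise ValueError(
            f"n_timepoints={config.n_timepoints} too short for planted shift of "
            f"{max_shift:.1f} samples (need >= {int(np.ceil(4 * max_shift))})"
        )
    region_ids = tab["region_id"].to_numpy()
    values = np.zeros((region_ids.size, config.n_timepoints))
    row = {rid: k for k, rid in enumerate(region_ids)}
    for right_id, left_id in homotopic_pairs(tab):
        sig = _bandlimited_signal(rng, config.n_timepoints, config.tr_seconds, config.band_hz)
        lagged = _delay(sig, planted_lags[right_id], config.tr_seconds)
        if config.noise_sd > 0:
            lagged = lagged + config.noise_sd * _bandlimited_signal(
                rng, config.n_timepoints, config.tr_seconds, config.band_hz
            )
        values[row[right_id]] = sig
        values[row[left_id]] = lagged
    return BoldMatrix(values, config.tr_seconds, region_ids)


def gen_pure_shift_bold(
    regions: pd.DataFrame,
    shifts_samples: dict[int, int],
    tr: float,
    n_timepoints: int,
    seed: int = 0,
) -> BoldMatrix:
    """BOLD matrix with exact integer-sample shifts between homotopic pairs.

    Signals are random values on even timepoints and zero on odd ones, with
    the support values centred to exact zero mean; the left member is the
    right member circularly shifted by the pair's integer shift. Because
    every lag-odd product of such a signal with its shift vanishes
    identically, the windowed cross-correlogram is exactly symmetric around
    the planted shift and the parabolic peak estimate is exact. Requires an
    even ``n_timepoints``.
    """
    if n_timepoints % 2:
        raise ValueError("n_timepoints must be even")
    tab = validate_regions(regions)
    rng = _rng(seed, 9)
    region_ids = tab["region_id"].to_numpy()
    values = np.zeros((region_ids.size, n_timepoints))
    row = {rid: k for k, rid in enumerate(region_ids)}
    for right_id, left_id in homotopic_pairs(tab):
        k = int(shifts_samples[right_id])
        if abs(k) * 4 >= n_timepoints:
            raise ValueError(f"shift {k} too large for T={n_timepoints}")
        sig = np.zeros(n_timepoints)
        vals = rng.standard_normal(n_timepoints // 2)
        sig[::2] = vals - vals.mean()
        values[row[right_id]] = sig
        values[row[left_id]] = np.roll(sig, k)
    return BoldMatrix(values, tr, region_ids)


def _assign_lesion(
    regions: pd.DataFrame, side: str, radius: float, rng: np.random.Generator
) -> tuple[tuple[float, float, float], set[int]]:
    """Place a spherical lesion at a random region centre of one hemisphere."""
    tab = regions[regions["hemisphere"] == side]
    anchor = tab.iloc[int(rng.integers(len(tab)))]
    centroid = (
        float(anchor["x"] + rng.normal(0, 3.0)),
        float(anchor["y"] + rng.normal(0, 3.0)),
        float(anchor["z"] + rng.normal(0, 3.0)),
    )
    coms = regions[["x", "y", "z"]].to_numpy(dtype=float)
    d = np.linalg.norm(coms - np.asarray(centroid), axis=1)
    hit = set(int(r) for r in regions["region_id"].to_numpy()[d <= radius])
    return centroid, hit


def gen_bold_cohort(
    regions: pd.DataFrame, config: CohortConfig
) -> list[tuple[SubjectRecord, BoldMatrix]]:
    """Generate the full cohort of subjects with planted lag fields.

    Stroke subjects (ids ``S01``...) receive one spherical lesion on a
    pseudo-randomly alternating hemisphere and a lag field decaying with
    distance to it; controls (``C01``...) get the uniform baseline lag.
    ARAT decreases with the subject's mean planted lag. Planted lags are
    recorded on each record's ``planted_lags``.
    """
    tab = validate_regions(regions)
    out = []
    for k in range(config.n_stroke):
        rng = _rng(config.seed, 1, k)
        side = "right" if rng.random() < 2 / 3 else "left"  # clinical stroke cohorts skew right-hemisphere here (10:5)
        lo, hi = config.lesion_radius_range_mm
        radius = float(rng.uniform(lo, hi))
        centroid, hit = _assign_lesion(tab, side, radius, rng)
        rec = SubjectRecord(
            subject_id=f"S{k + 1:02d}",
            group="stroke",
            lesion_centroids=[centroid],
            lesion_regions=hit,
            lesion_side=side,
            lesion_radius_mm=radius,
            stroke_type="I" if rng.random() < 0.5 else "H",
            onset_years=float(np.round(rng.gamma(2.0, 2.0), 2)),
            age_years=float(np.clip(np.round(rng.normal(54, 8)), 30, 85)),
            gender="F" if k == config.n_stroke - 1 else "M",
        )
        rec.planted_lags = _lag_field(tab, rec, config)
        mean_tau = float(np.mean(list(rec.planted_lags.values())))
        rec.arat = int(np.clip(round(30 - 16 * mean_tau + rng.normal(0, 2.0)), 0, 57))
        bold = gen_bold_subject(tab, rec.planted_lags, config, rng)
        out.append((rec, bold))
    for k in range(config.n_control):
        rng = _rng(config.seed, 2, k)
        rec = SubjectRecord(
            subject_id=f"C{k + 1:02d}",
            group="control",
            age_years=float(np.clip(np.round(rng.normal(58, 3)), 30, 85)),
            gender="M" if k % 2 == 0 else "F",
        )
        rec.planted_lags = _lag_field(tab, rec, config)
        bold = gen_bold_subject(tab, rec.planted_lags, config, rng)
        out.append((rec, bold))
    return out


def gen_connectome(regions: pd.DataFrame, config: CohortConfig, seed_key: int = 3) -> Connectome:
    """Spatially embedded random connectome with distance-decaying weights.

    Edge probability and expected streamline count both decay as
    exp(-d / edge_decay_mm); weights are positive integers. Homotopic pairs
    are always connected (callosal backbone) and any residual disconnected
    components are patched by their closest internode edge, so the graph is
    connected at full density.
    """
    tab = validate_regions(regions)
    rng = _rng(config.seed, seed_key)
    coms = tab[["x", "y", "z"]].to_numpy(dtype=float)
    n = len(tab)
    from .comm import euclidean_matrix

    d = euclidean_matrix(coms)
    decay = np.exp(-d / config.edge_decay_mm)
    prob = np.clip(1.2 * decay, 0.02, 1.0)
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < prob[iu, ju]
    lam = config.weight_scale * decay[iu, ju]
    weights = np.where(present, 1 + rng.poisson(lam), 0)
    W = np.zeros((n, n))
    W[iu, ju] = weights
    W += W.T
    ids = tab["region_id"].to_numpy()
    idx = {rid: k for k, rid in enumerate(ids)}
    for right_id, left_id in homotopic_pairs(tab):
        i, j = idx[right_id], idx[left_id]
        if W[i, j] == 0:
            W[i, j] = W[j, i] = 1 + rng.poisson(config.weight_scale * decay[i, j])
    W = _patch_connected(W, d)
    return Connectome(W, coms, ids)


def _patch_connected(W: np.ndarray, d: np.ndarray) -> np.ndarray:
    from scipy.sparse.csgraph import connected_components

    while True:
        n_comp, labels = connected_components(W > 0, directed=False)
        if n_comp == 1:
            return W
        # join the two spatially closest nodes in different components
        cross = labels[:, None] != labels[None, :]
        masked = np.where(cross, d, np.inf)
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        W[i, j] = W[j, i] = 1.0


def diffuse_damage(
    conn: Connectome,
    centroid,
    radius: float,
    damage_fraction: float = 0.9,
    taper_mm: float = 20.0,
) -> Connectome:
    """Distance-tapered structural damage around a focal lesion.

    Emulates degeneration of pathways near an infarct: every node's weights
    are attenuated by ``1 - damage_fraction * exp(-max(0, d - radius) /
    taper_mm)`` (applied to both endpoints of each edge), and edges touching
    nodes inside the lesion sphere are removed entirely. Weights stay
    integer-valued, symmetric and hollow.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    centroid = np.asarray(centroid, dtype=float)
    if centroid.shape != (3,):
        raise ValueError("centroid must be an (x, y, z) coordinate")
    d = np.linalg.norm(conn.coords - centroid, axis=1)
    g = np.exp(-np.maximum(0.0, d - radius) / taper_mm)
    f = 1.0 - damage_fraction * g
    W = np.round(conn.weights * np.outer(f, f))
    hit = d <= radius
    W[hit, :] = 0
    W[:, hit] = 0
    return Connectome(W, conn.coords.copy(), conn.region_ids.copy())


def lesion_connectome(
    conn: Connectome, centroid, radius: float, attenuation: float = 0.0
) -> Connectome:
    """Remove (or attenuate) all edges touching nodes within a lesion sphere.

    Edges with either endpoint within ``radius`` mm of ``centroid`` are
    multiplied by ``attenuation`` (default 0: deleted). The result stays
    symmetric, hollow and non-negative.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    centroid = np.asarray(centroid, dtype=float)
    if centroid.shape != (3,):
        raise ValueError("centroid must be an (x, y, z) coordinate")
    if not 0 <= attenuation < 1:
        raise ValueError("attenuation must be in [0, 1)")
    d = np.linalg.norm(conn.coords - centroid, axis=1)
    hit = d <= radius
    W = conn.weights.copy()
    W[hit, :] *= attenuation
    W[:, hit] *= attenuation
    return Connectome(W, conn.coords.copy(), conn.region_ids.copy())


# --- clinical worked-example fixture -------------------------------------

_CLINICAL_ROWS = [
    # subject, age range, gender, side, locations, type, onset (y), ARAT
    ("S1", "55-59", "M", "right", ["brainstem"], "I", 11, 28),
    ("S2", "60-64", "M", "left", ["PLIC", "putamen"], "I", 11, 14),
    ("S3", "45-49", "M", "right", ["MFG", "SFG", "precentral", "supramarginal", "SMA"], "I", 1, 19),
    ("S4", "65-69", "M", "left", ["insula", "putamen", "IFG", "temporal pole"], "H", 8, 15),
    ("S5", "65-69", "M", "right", ["insula", "ITG", "IOG", "putamen"], "H", 1, 12),
    ("S6", "45-49", "M", "right", ["ITG", "MTG", "STG", "MOG", "angular", "supramarginal"], "H", 0.67, 4),
    ("S7", "60-64", "M", "right", ["insula", "putamen", "rolandic operculum", "IFG"], "I", 3, 15),
    ("S8", "55-59", "M", "left", ["insula", "IFG", "putamen"], "H", 5, 10),
    ("S9", "55-59", "M", "right", ["insula", "IFG", "putamen", "rolandic operculum", "temporal pole"], "I", 7, 8),
    ("S10", "50-54", "M", "left", ["putamen", "caudate nucleus"], "I", 1, 9),
    ("S11", "40-44", "M", "right", ["insula", "rolandic operculum", "IFG", "STG", "putamen", "temporal pole"], "H", 5, 11),
    ("S12", "40-44", "M", "right", ["insula", "MTG", "STG", "putamen", "temporal pole", "rolandic operculum"], "H", 3, 3),
    ("S13", "55-59", "M", "right", ["insula", "rolandic operculum", "IFG"], "I", 6, 16),
    ("S14", "50-54", "F", "left", ["insula", "rolandic operculum", "putamen"], "H", 3, 10),
    ("S15", "45-49", "M", "right", ["insula", "putamen"], "H", 1, 12),
]


def demographics_fixture() -> list[SubjectRecord]:
    """The 15 clinical stroke records of the cohort's demographics table.

    Lesion locations are the anatomical label strings as printed; ages are
    given as 5-year ranges, stored as the range midpoint in ``age_years``.
    """
    out = []
    for sid, age_range, gender, side, locs, stype, onset, arat in _CLINICAL_ROWS:
        lo, hi = (int(v) for v in age_range.split("-"))
        out.append(
            SubjectRecord(
                subject_id=sid,
                group="stroke",
                lesion_side=side,
                lesion_locations=list(locs),
                stroke_type=stype,
                onset_years=float(onset),
                arat=int(arat),
                age_years=(lo + hi) / 2,
                age_range=age_range,
                gender=gender,
            )
        )
    return out


def _jitter_weights(conn: Connectome, rng: np.random.Generator, sd: float = 0.1) -> Connectome:
    """Per-subject multiplicative lognormal jitter of the template weights."""
    n = conn.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    factor = rng.lognormal(0.0, sd, iu.size)
    W = np.zeros_like(conn.weights)
    W[iu, ju] = np.where(
        conn.weights[iu, ju] > 0,
        np.maximum(1, np.round(conn.weights[iu, ju] * factor)),
        0,
    )
    W += W.T
    return Connectome(W, conn.coords.copy(), conn.region_ids.copy())


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Full synthetic cohort: parcellation, subjects, BOLD and connectomes.

    All subjects share one template connectome topology, individualized by
    mild multiplicative weight jitter; stroke subjects additionally have the
    edges within their lesion sphere removed, so between-subject efficiency
    variation is lesion-driven.
    """
    config = config or CohortConfig()
    regions = gen_parcellation(config.n_pairs, config.seed)
    template = gen_connectome(regions, config, seed_key=3)
    subjects_bold = gen_bold_cohort(regions, config)
    bold = {}
    connectomes = {}
    subjects = []
    for k, (rec, bm) in enumerate(subjects_bold):
        subjects.append(rec)
        bold[rec.subject_id] = bm
        conn = _jitter_weights(template, _rng(config.seed, 4, k))
        if rec.group == "stroke":
            conn = diffuse_damage(
                conn,
                rec.lesion_centroids[0],
                rec.lesion_radius_mm,
                config.damage_fraction,
                config.damage_taper_mm,
            )
        connectomes[rec.subject_id] = conn
    return Cohort(regions, subjects, bold, connectomes, config)
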