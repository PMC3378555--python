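"""Synthetic voxel sheets, stimulus protocols, trials, behavior, and BOLD.

Everything downstream (phase mapping, segment ROIs, the concatenated GLM,
group statistics) is exercised on data from this module, with known ground
truth: each simulated voxel carries its true area, quadrant and ring; each
session carries its true trial events and injected delay-period amplitudes.

Conventions
-----------
* Polar angle is measured clockwise from the upper vertical meridian, so
  quadrant 1 (0–90°) is the upper-right quadrant of the display, matching
  the clockwise wedge rotation; quadrants proceed clockwise (Q2 lower
  right, Q3 lower left, Q4 upper left).  Diagonally opposite pairs are
  Q1↔Q3 and Q2↔Q4.
* Stimulus dots occupy the four analysis radii 1.875/3.75/5.625/7.5° of
  visual angle, 10 positions per quadrant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from retinowm import roi as roi_mod
from retinowm.design import boxcar_on_grid, canonical_hrf, convolve_hrf
from retinowm.protocol import (
    AREAS,
    DOT_RADII,
    INSTRUCTIONS,
    OPPOSITE_QUADRANT,
    BoldSeries,
    EffectSpec,
    MappingProtocol,
    TaskTiming,
)
from retinowm.retinotopy import eccentricity_to_lag, polar_to_lag

#: dots per ring within one quadrant (rings 1..4; totals 10 per quadrant).
RING_COUNTS = (2, 3, 2, 3)


@dataclass
class VoxelSheet:
    """Simulated retinotopic voxel sheet for V1, V2, and V3.

    ``table`` columns: voxel_id, area, quadrant, ring (ground truth),
    polar_deg, ecc_deg, gain, noise_sd.
    """

    table: pd.DataFrame
    protocol: MappingProtocol

    @property
    def n_voxels(self) -> int:
        return len(self.table)

    @property
    def voxel_ids(self) -> np.ndarray:
        return self.table["voxel_id"].to_numpy()

    def area_mask(self, area: str) -> np.ndarray:
        return (self.table["area"] == area).to_numpy()

    def quadrant_mask(self, quadrant: int) -> np.ndarray:
        return (self.table["quadrant"] == quadrant).to_numpy()

    def ring_mask(self, ring: int) -> np.ndarray:
        return (self.table["ring"] == ring).to_numpy()


def _cell_counts(n: int, n_cells: int = 16) -> np.ndarray:
    base, extra = divmod(n, n_cells)
    counts = np.full(n_cells, base, dtype=int)
    counts[:extra] += 1
    return counts


def generate_voxel_sheet(
    n_per_area: int,
    protocol: MappingProtocol | None = None,
    seed: int = 0,
    noise_sd: float = 3.0,
    gain: float = 1.0,
    polar_margin_deg: float = 5.0,
    ecc_margin_deg: float = 0.7,
) -> VoxelSheet:
    """Voxels tiling the (quadrant × ring) cells of each visual area.

    Within each of the 16 cells per area, receptive-field centers are drawn
    uniformly, keeping a safety margin from quadrant borders
    (``polar_margin_deg``) and from inter-ring midpoints (via
    ``ecc_margin_deg`` around the ring's stimulus radius) so that noiseless
    phase decoding recovers the ground-truth labels exactly.

    ``noise_sd`` is the per-voxel BOLD noise standard deviation in signal
    units.  The HRF-convolved mapping response at unit gain has a temporal
    SD near 2.6, so the default ``noise_sd`` of 3.0 puts the peak mapping
    correlation near 0.65 — the package's default test signal-to-noise
    condition, typical of good phase-encoded mapping voxels.
    """
    if n_per_area < 16:
        raise ValueError(
            f"n_per_area must be at least 16 so every (quadrant, ring) cell "
            f"is occupied; got {n_per_area}"
        )
    if protocol is None:
        protocol = MappingProtocol()
    rng = np.random.default_rng(seed)
    e_low_cap = protocol.ring_min_ecc + protocol.ring_width / 2.0 + 0.03
    e_high_cap = protocol.ring_max_ecc - 0.08
    rows = []
    vid = 0
    for area in AREAS:
        counts = _cell_counts(n_per_area)
        i = 0
        for quadrant in (1, 2, 3, 4):
            for ring in (1, 2, 3, 4):
                k = counts[i]
                i += 1
                lo = (quadrant - 1) * 90.0 + polar_margin_deg
                hi = quadrant * 90.0 - polar_margin_deg
                polar = rng.uniform(lo, hi, size=k)
                radius = DOT_RADII[ring - 1]
                e_lo = max(radius - ecc_margin_deg, e_low_cap)
                e_hi = min(radius + ecc_margin_deg, e_high_cap)
                ecc = rng.uniform(e_lo, e_hi, size=k)
                for p, e in zip(polar, ecc):
                    rows.append((vid, area, quadrant, ring, p, e, gain, noise_sd))
                    vid += 1
    table = pd.DataFrame(
        rows,
        columns=["voxel_id", "area", "quadrant", "ring", "polar_deg", "ecc_deg", "gain", "noise_sd"],
    )
    return VoxelSheet(table=table, protocol=protocol)


def generate_stimulus_positions(seed: int = 0) -> pd.DataFrame:
    """The 40 cross-dot positions: 10 per quadrant at the four radii.

    Within each quadrant, rings 1..4 carry 2/3/2/3 dots at angles evenly
    spaced strictly inside the quadrant (never on a cross arm).  The layout
    is fixed; ``seed`` is accepted for interface symmetry and ignored.
    """
    rows = []
    pid = 0
    for quadrant in (1, 2, 3, 4):
        lo = (quadrant - 1) * 90.0
        for ring, k in zip((1, 2, 3, 4), RING_COUNTS):
            for i in range(k):
                angle = lo + 90.0 * (i + 1) / (k + 1)
                rows.append((pid, quadrant, ring, DOT_RADII[ring - 1], angle))
                pid += 1
    return pd.DataFrame(
        rows, columns=["position_id", "quadrant", "ring_index", "radius_deg", "angle_deg"]
    )


def _match_candidates(positions: pd.DataFrame, s1: pd.Series, instruction: str) -> pd.DataFrame:
    if instruction == "categorical":
        return positions[positions["quadrant"] == OPPOSITE_QUADRANT[int(s1["quadrant"])]]
    return positions[positions["ring_index"] == int(s1["ring_index"])]


def _nonmatch_candidates(positions: pd.DataFrame, s1: pd.Series, instruction: str) -> pd.DataFrame:
    if instruction == "categorical":
        return positions[positions["quadrant"] != OPPOSITE_QUADRANT[int(s1["quadrant"])]]
    return positions[positions["ring_index"] != int(s1["ring_index"])]


def generate_trial_sequence(
    instruction: str,
    positions: pd.DataFrame,
    seed: int = 0,
    timing: TaskTiming | None = None,
) -> pd.DataFrame:
    """One 80-trial session: 40 match, 30 non-match, 10 catch trials.

    Every position serves as S1 exactly twice (once in a match trial, once
    in a non-match or catch trial) — the most even S1 usage the 40/30/10
    composition permits.  Match S2 follows the instruction's rule
    (diagonally opposite quadrant / same ring); the other stimulus feature
    is drawn at random.  The retention interval is jittered uniformly on a
    1000 ms grid over [3000, 8000] ms.  Catch trials present S1 only.

    Returned table (one row per trial, presentation order) carries the
    S1/S2 geometry, the jitter, and session-clock onsets; ``attrs`` record
    the timing parameters and the total session duration.
    """
    if instruction not in INSTRUCTIONS:
        raise ValueError(f"unknown instruction {instruction!r}; expected one of {INSTRUCTIONS}")
    if timing is None:
        timing = TaskTiming()
    if len(positions) != 40:
        raise ValueError("positions must contain the 40 stimulus positions")
    rng = np.random.default_rng(seed)

    perm = rng.permutation(len(positions))
    nonmatch_idx = perm[:30]
    catch_idx = perm[30:]

    specs: list[tuple[str, pd.Series, pd.Series | None]] = []
    for _, s1 in positions.iterrows():
        cand = _match_candidates(positions, s1, instruction)
        s2 = cand.iloc[rng.integers(len(cand))]
        specs.append(("match", s1, s2))
    for idx in nonmatch_idx:
        s1 = positions.iloc[idx]
        cand = _nonmatch_candidates(positions, s1, instruction)
        s2 = cand.iloc[rng.integers(len(cand))]
        specs.append(("nonmatch", s1, s2))
    for idx in catch_idx:
        specs.append(("catch", positions.iloc[idx], None))

    order = rng.permutation(len(specs))
    jitter_grid = np.arange(timing.jitter_min_ms, timing.jitter_max_ms + 1, timing.jitter_step_ms)

    rows = []
    t = 0.0
    for trial_id, k in enumerate(order):
        trial_type, s1, s2 = specs[k]
        jitter = float(rng.choice(jitter_grid))
        s1_onset = t + timing.fixation_ms
        s2_onset = s1_onset + timing.stim_ms + jitter
        t = s2_onset + timing.stim_ms + timing.response_ms + timing.iti_ms
        correct = {"match": "match", "nonmatch": "nonmatch", "catch": "none"}[trial_type]
        rows.append(
            {
                "trial_id": trial_id,
                "instruction": instruction,
                "trial_type": trial_type,
                "s1_position_id": int(s1["position_id"]),
                "s1_quadrant": int(s1["quadrant"]),
                "s1_ring": int(s1["ring_index"]),
                "s1_radius_deg": float(s1["radius_deg"]),
                "s1_angle_deg": float(s1["angle_deg"]),
                "s2_position_id": int(s2["position_id"]) if s2 is not None else -1,
                "s2_quadrant": int(s2["quadrant"]) if s2 is not None else -1,
                "s2_ring": int(s2["ring_index"]) if s2 is not None else -1,
                "s2_radius_deg": float(s2["radius_deg"]) if s2 is not None else np.nan,
                "jitter_ms": jitter,
                "s1_onset_ms": s1_onset,
                "s2_onset_ms": s2_onset if s2 is not None else np.nan,
                "correct_response": correct,
            }
        )
    trials = pd.DataFrame(rows)
    trials.attrs["session_ms"] = float(t)
    trials.attrs["timing"] = timing
    return trials


def session_volumes(trials: pd.DataFrame) -> int:
    timing: TaskTiming = trials.attrs["timing"]
    return int(np.ceil(trials.attrs["session_ms"] / timing.volume_ms))


# ---------------------------------------------------------------------------
# BOLD simulation


def _noise_and_drift(
    shape: tuple[int, int],
    noise_sd: np.ndarray,
    effects: EffectSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    V, T = shape
    out = np.zeros(shape)
    if np.any(noise_sd > 0):
        eps = rng.standard_normal(shape)
        if effects.ar1_rho > 0:
            from scipy.signal import lfilter

            eps = lfilter([np.sqrt(1 - effects.ar1_rho**2)], [1.0, -effects.ar1_rho], eps, axis=1)
        out += noise_sd[:, None] * eps
    if effects.drift_coeffs:
        t = np.linspace(-1.0, 1.0, T)
        drift = effects.drift_coeffs[0] * t
        for k, c in enumerate(effects.drift_coeffs[1:], start=1):
            drift = drift + c * np.cos(np.pi * k * np.arange(T) / T)
        out += drift[None, :]
    return out


def simulate_mapping_series(
    sheet: VoxelSheet,
    protocol: MappingProtocol | None = None,
    stimulus: str = "wedge",
    effects: EffectSpec | None = None,
    seed: int = 0,
) -> BoldSeries:
    """Noisy BOLD of one mapping run (rotating wedge or expanding ring).

    Each voxel's neural drive is the cyclic on/off vector at the lag
    encoding its receptive-field polar angle (wedge) or eccentricity
    (ring) — i.e. its phase is quantized to the volume grid — convolved
    with the canonical HRF and scaled by the voxel's gain, plus optional
    drift and (AR(1)-filtered) Gaussian noise at the voxel's ``noise_sd``.
    Setting every ``noise_sd`` to 0 and no drift yields the noiseless
    oracle variant used by exact-recovery tests.
    """
    if protocol is None:
        protocol = sheet.protocol
    if effects is None:
        effects = EffectSpec()
    if stimulus not in ("wedge", "ring"):
        raise ValueError("stimulus must be 'wedge' or 'ring'")
    rng = np.random.default_rng(seed)
    hrf = canonical_hrf(protocol.volume_ms)

    if stimulus == "wedge":
        lags = polar_to_lag(sheet.table["polar_deg"].to_numpy(), protocol)
    else:
        lags = eccentricity_to_lag(sheet.table["ecc_deg"].to_numpy(), protocol)

    from retinowm.design import cyclic_neural_vector

    unique_lags, inverse = np.unique(lags, return_inverse=True)
    bank = np.stack([cyclic_neural_vector(protocol, int(l)) for l in unique_lags])
    bank = convolve_hrf(bank, hrf)
    gain = sheet.table["gain"].to_numpy()
    data = gain[:, None] * bank[inverse]
    noise_sd = sheet.table["noise_sd"].to_numpy()
    data = data + _noise_and_drift(data.shape, noise_sd, effects, rng)
    return BoldSeries(data=data, volume_ms=protocol.volume_ms, voxel_ids=sheet.voxel_ids)


def _area_effects(effects, area: str) -> EffectSpec:
    if isinstance(effects, dict):
        return effects[area]
    return effects


def simulate_task_series(
    sheet: VoxelSheet,
    trials: pd.DataFrame,
    effects: EffectSpec | dict[str, EffectSpec] | None = None,
    seed: int = 0,
    include_own_quadrant: bool = False,
    catch_delay_ms: float | None = None,
) -> BoldSeries:
    """Noisy BOLD of one cross-dot task session.

    S1 and S2 add transient impulse responses to the voxels of the
    (quadrant, ring) cell containing the dot.  During each retention
    interval (S1 offset → S2 onset), ``delay_match_amp`` is added to all
    voxels of the instruction-defined matching region and
    ``delay_mismatch_amp`` to the mismatching region(s).  Catch trials
    contribute S1 only, with a retention window of ``catch_delay_ms``
    (default: the median jitter) after S1 offset — the same window the
    first-level model assumes.  ``effects`` may be a single spec or a
    per-area dict (e.g. to confine an injected delay effect to V3).
    """
    if effects is None:
        effects = EffectSpec()
    timing: TaskTiming = trials.attrs["timing"]
    if catch_delay_ms is None:
        catch_delay_ms = float(timing.median_jitter_ms)
    rng = np.random.default_rng(seed)
    T = session_volumes(trials)
    V = sheet.n_voxels
    vol = timing.volume_ms
    neural = np.zeros((V, T))

    area_masks = {a: sheet.area_mask(a) for a in AREAS}
    quad_masks = {q: sheet.quadrant_mask(q) for q in (1, 2, 3, 4)}
    ring_masks = {r: sheet.ring_mask(r) for r in (1, 2, 3, 4)}

    for _, trial in trials.iterrows():
        reg = roi_mod.resolve_regions(trial, include_own_quadrant)
        seg_masks = quad_masks if reg.mode == "quadrant" else ring_masks
        s1_cell = quad_masks[int(trial["s1_quadrant"])] & ring_masks[int(trial["s1_ring"])]
        i_s1 = int(np.floor(trial["s1_onset_ms"] / vol))
        delay_start = trial["s1_onset_ms"] + timing.stim_ms
        if trial["trial_type"] == "catch":
            delay_end = delay_start + catch_delay_ms
            s2_cell = None
            i_s2 = None
        else:
            delay_end = trial["s2_onset_ms"]
            s2_cell = quad_masks[int(trial["s2_quadrant"])] & ring_masks[int(trial["s2_ring"])]
            i_s2 = int(np.floor(trial["s2_onset_ms"] / vol))
        v0 = int(np.floor(delay_start / vol))
        v1 = min(int(np.ceil(delay_end / vol)), T)

        for area, amask in area_masks.items():
            eff = _area_effects(effects, area)
            neural[amask & s1_cell, i_s1] += eff.amp_s1
            if s2_cell is not None:
                neural[amask & s2_cell, i_s2] += eff.amp_s2
            if eff.delay_match_amp != 0.0:
                neural[amask & seg_masks[reg.matching_segment], v0:v1] += eff.delay_match_amp
            if eff.delay_mismatch_amp != 0.0:
                mm = np.zeros(V, dtype=bool)
                for s in reg.mismatching_segments:
                    mm |= seg_masks[s]
                neural[amask & mm, v0:v1] += eff.delay_mismatch_amp

    hrf = canonical_hrf(vol)
    gain = sheet.table["gain"].to_numpy()
    data = gain[:, None] * convolve_hrf(neural, hrf)
    noise_sd = sheet.table["noise_sd"].to_numpy()
    eff0 = _area_effects(effects, AREAS[0])
    data = data + _noise_and_drift(data.shape, noise_sd, eff0, rng)
    return BoldSeries(data=data, volume_ms=vol, voxel_ids=sheet.voxel_ids)


def simulate_behavior(
    trials: pd.DataFrame,
    accuracy: float = 0.9,
    rt_mean_ms: float = 1000.0,
    rt_sd_ms: float = 200.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-trial responses for the 70 scored (non-catch) trials.

    Correctness is Bernoulli(``accuracy``); response times are Gaussian,
    clipped below at 200 ms.  Catch trials require no response and are
    excluded.
    """
    if not 0.0 < accuracy <= 1.0:
        raise ValueError("accuracy must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    scored = trials[trials["trial_type"] != "catch"]
    correct = rng.random(len(scored)) < accuracy
    rt = np.clip(rng.normal(rt_mean_ms, rt_sd_ms, len(scored)), 200.0, None)
    flip = {"match": "nonmatch", "nonmatch": "match"}
    responses = [
        ct if ok else flip[ct]
        for ct, ok in zip(scored["correct_response"], correct)
    ]
    return pd.DataFrame(
        {
            "trial_id": scored["trial_id"].to_numpy(),
            "instruction": scored["instruction"].to_numpy(),
            "trial_type": scored["trial_type"].to_numpy(),
            "response": responses,
            "correct": correct,
            "rt_ms": rt,
        }
    )
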