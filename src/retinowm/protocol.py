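"""Core protocol and container types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

#: Stimulus radii used throughout the analysis (degrees of visual angle).
DOT_RADII = (1.875, 3.75, 5.625, 7.5)

#: Visual areas carried by every voxel sheet.
AREAS = ("V1", "V2", "V3")

#: Diagonally-opposite quadrant map (Q1 upper-right .. Q4 upper-left, clockwise).
OPPOSITE_QUADRANT = {1: 3, 2: 4, 3: 1, 4: 2}

INSTRUCTIONS = ("categorical", "coordinate")


@dataclass(frozen=True)
class MappingProtocol:
    """Timing and geometry of one phase-encoded mapping run.

    A 45° wedge rotates clockwise (polar-angle run) or a ring expands from
    ``ring_min_ecc`` to ``ring_max_ecc`` (eccentricity run), completing
    ``n_cycles`` cycles of ``cycle_ms`` each, with blank fixation periods of
    ``blank_ms`` before and after.  Volumes are acquired every ``volume_ms``.
    The modeled activation of a visual-field point is a boxcar of
    ``on_duration_ms`` per cycle whose onset phase encodes the point's
    polar angle / eccentricity.
    """

    cycle_ms: int = 54_000
    n_cycles: int = 8
    volume_ms: int = 540
    blank_ms: int = 27_000
    wedge_width_deg: float = 45.0
    rotation: str = "clockwise"
    ring_min_ecc: float = 0.4
    ring_max_ecc: float = 7.5
    ring_width_frac: float = 0.2
    on_duration_ms: int = 7_200
    start_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.cycle_ms % self.volume_ms != 0:
            raise ValueError(
                f"cycle_ms ({self.cycle_ms}) must be divisible by "
                f"volume_ms ({self.volume_ms})"
            )
        if self.blank_ms % self.volume_ms != 0:
            raise ValueError("blank_ms must be divisible by volume_ms")
        if not self.on_duration_ms < self.cycle_ms:
            raise ValueError("on_duration_ms must be shorter than cycle_ms")
        if not self.ring_min_ecc < self.ring_max_ecc:
            raise ValueError("ring_min_ecc must be below ring_max_ecc")
        if self.rotation != "clockwise":
            raise ValueError("only clockwise rotation is supported")

    @property
    def volumes_per_cycle(self) -> int:
        return self.cycle_ms // self.volume_ms

    @property
    def blank_volumes(self) -> int:
        return self.blank_ms // self.volume_ms

    @property
    def n_volumes(self) -> int:
        """Total volumes: cycles plus leading and trailing blanks."""
        return self.n_cycles * self.volumes_per_cycle + 2 * self.blank_volumes

    @property
    def on_volumes(self) -> int:
        """Active volumes per cycle (nearest-integer rounding of the boxcar)."""
        return int(round(self.on_duration_ms / self.volume_ms))

    @property
    def ring_width(self) -> float:
        return self.ring_width_frac * self.ring_max_ecc

    @property
    def max_ecc(self) -> float:
        return self.ring_max_ecc


@dataclass(frozen=True)
class TaskTiming:
    """Event timing of one cross-dot trial (milliseconds).

    fixation → S1 → jittered retention interval → S2 → response window,
    followed by an inter-trial interval.  The retention jitter is drawn
    uniformly on a 1000 ms grid over [jitter_min_ms, jitter_max_ms].
    """

    fixation_ms: int = 1_000
    stim_ms: int = 300
    jitter_min_ms: int = 3_000
    jitter_max_ms: int = 8_000
    jitter_step_ms: int = 1_000
    response_ms: int = 2_000
    iti_ms: int = 10_000
    volume_ms: int = 1_500

    @property
    def median_jitter_ms(self) -> int:
        return (self.jitter_min_ms + self.jitter_max_ms) // 2


@dataclass
class EffectSpec:
    """Ground-truth effect amplitudes and noise knobs for simulation.

    Amplitudes are in BOLD signal units (percent-signal-change scale is
    arbitrary; what matters for recovery tests is the known value).
    ``ar1_rho`` adds AR(1) temporal autocorrelation to the noise;
    ``drift_coeffs`` adds a linear trend plus slow cosines.
    """

    amp_s1: float = 1.0
    amp_s2: float = 1.0
    delay_match_amp: float = 0.0
    delay_mismatch_amp: float = 0.0
    ar1_rho: float = 0.0
    drift_coeffs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        vals = [self.amp_s1, self.amp_s2, self.delay_match_amp,
                self.delay_mismatch_amp, self.ar1_rho, *self.drift_coeffs]
        if not np.all(np.isfinite(vals)):
            raise ValueError("EffectSpec values must be finite")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must lie in [0, 1)")


@dataclass
class BoldSeries:
    """A voxel × volume matrix of BOLD signal on a regular volume grid."""

    data: np.ndarray
    volume_ms: float
    voxel_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    onset_offset_ms: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (voxels × volumes)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BoldSeries must not contain missing values")
        if self.voxel_ids is None:
            self.voxel_ids = np.arange(self.data.shape[0])
        else:
            self.voxel_ids = np.asarray(self.voxel_ids)
            if self.voxel_ids.shape[0] != self.data.shape[0]:
                raise ValueError("voxel_ids length must match data rows")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def to_dict_header(self) -> dict:
        return {
            "n_voxels": int(self.n_voxels),
            "n_volumes": int(self.n_volumes),
            "volume_ms": float(self.volume_ms),
            "onset_offset_ms": float(self.onset_offset_ms),
            "voxel_ids": [int(v) for v in self.voxel_ids],
        }


def protocol_to_dict(p: MappingProtocol) -> dict:
    return asdict(p)
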