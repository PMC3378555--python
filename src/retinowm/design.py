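"""Hemodynamic basis functions, regressor construction, and DCT filtering.

All regressors live on the acquisition volume grid.  Neural (pre-convolution)
vectors are boxcars or impulses; boxcar edges are snapped to the grid with a
fixed rule — floor for the onset volume, ceil for the offset volume — so a
300 ms event on a 1500 ms grid occupies exactly one volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.signal import fftconvolve

from retinowm.protocol import MappingProtocol


@dataclass(frozen=True)
class HrfKernel:
    """Sampled hemodynamic impulse response, peak-normalized to 1."""

    samples: np.ndarray
    sampling_ms: float

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class Regressor:
    values: np.ndarray
    label: str


def canonical_hrf(sampling_ms: float, duration_ms: float = 32_000.0) -> HrfKernel:
    """Double-gamma hemodynamic response function.

    Peak gamma density with shape 6 (mode at 5 s, peak of the difference
    near 5 s) minus a 1/6-amplitude undershoot with shape 16, both with a
    1 s time scale; the standard canonical shape.  The kernel is sampled at
    ``sampling_ms`` over ``duration_ms`` (≥ 30 s so the undershoot resolves)
    and normalized to unit peak.

    Parameters
    ----------
    sampling_ms
        Sampling interval in milliseconds (the volume interval).
    duration_ms
        Kernel support; default 32 s.
    """
    if sampling_ms <= 0:
        raise ValueError("sampling_ms must be positive")
    t = np.arange(0.0, duration_ms / 1000.0, sampling_ms / 1000.0)
    peak = sps.gamma.pdf(t, a=6.0, scale=1.0)
    undershoot = sps.gamma.pdf(t, a=16.0, scale=1.0)
    h = peak - undershoot / 6.0
    h = h / np.max(h)
    return HrfKernel(samples=h, sampling_ms=float(sampling_ms))


def convolve_hrf(neural: np.ndarray, hrf: HrfKernel) -> np.ndarray:
    """Linear (non-circular) convolution truncated to the input length.

    Works on a 1-D vector or row-wise on a 2-D (voxels × volumes) array.
    """
    neural = np.asarray(neural, dtype=float)
    if neural.ndim == 1:
        return np.convolve(neural, hrf.samples)[: neural.shape[0]]
    out = fftconvolve(neural, hrf.samples[np.newaxis, :], axes=1)
    return out[:, : neural.shape[1]]


def cyclic_neural_vector(protocol: MappingProtocol, lag_volumes: int) -> np.ndarray:
    """Pre-convolution cyclic activation vector for one phase lag.

    Each cycle contains a contiguous run of ``protocol.on_volumes`` active
    volumes starting ``lag_volumes`` into the cycle (wrapping within the
    cycle); the blank lead and trail stay zero.
    """
    vpc = protocol.volumes_per_cycle
    if not 0 <= lag_volumes < vpc:
        raise ValueError(f"lag_volumes must lie in [0, {vpc}); got {lag_volumes}")
    v = np.zeros(protocol.n_volumes)
    active = (lag_volumes + np.arange(protocol.on_volumes)) % vpc
    for c in range(protocol.n_cycles):
        v[protocol.blank_volumes + c * vpc + active] = 1.0
    return v


def cyclic_regressor(
    protocol: MappingProtocol,
    lag_volumes: int,
    hrf: HrfKernel | None = None,
) -> Regressor:
    """HRF-convolved cyclic activation regressor at a given phase lag.

    This is the template against which voxel time courses are
    cross-correlated; one regressor per lag, 100 lags per cycle at the
    default 54 000 ms cycle / 540 ms volume interval.
    """
    if hrf is None:
        hrf = canonical_hrf(protocol.volume_ms)
    neural = cyclic_neural_vector(protocol, lag_volumes)
    return Regressor(values=convolve_hrf(neural, hrf), label=f"cyclic_lag{lag_volumes}")


def boxcar_on_grid(
    onsets_ms: np.ndarray,
    durations_ms: np.ndarray,
    n_volumes: int,
    volume_ms: float,
    amplitudes: np.ndarray | None = None,
) -> np.ndarray:
    """Neural boxcar/impulse vector on the volume grid (no convolution).

    Zero-duration events become unit impulses at floor(onset / volume).
    Positive durations span floor(onset / volume) .. ceil(offset / volume).
    """
    onsets_ms = np.atleast_1d(np.asarray(onsets_ms, dtype=float))
    durations_ms = np.broadcast_to(
        np.atleast_1d(np.asarray(durations_ms, dtype=float)), onsets_ms.shape
    )
    if amplitudes is None:
        amplitudes = np.ones_like(onsets_ms)
    amplitudes = np.broadcast_to(
        np.atleast_1d(np.asarray(amplitudes, dtype=float)), onsets_ms.shape
    )
    v = np.zeros(n_volumes)
    end_ms = n_volumes * volume_ms
    for onset, dur, amp in zip(onsets_ms, durations_ms, amplitudes):
        if dur < 0:
            raise ValueError("durations must be non-negative")
        if onset >= end_ms or onset < 0:
            raise ValueError(f"onset {onset} ms outside series [0, {end_ms}) ms")
        i0 = int(np.floor(onset / volume_ms))
        if dur == 0:
            v[i0] += amp
        else:
            i1 = min(int(np.ceil((onset + dur) / volume_ms)), n_volumes)
            v[i0:i1] += amp
    return v


def event_regressor(
    onsets_ms,
    durations_ms,
    n_volumes: int,
    volume_ms: float,
    hrf: HrfKernel,
    amplitudes=None,
    label: str = "event",
) -> Regressor:
    """HRF-convolved event/boxcar regressor.

    An empty onset list yields the zero regressor.  The construction is
    linear in amplitude: the regressor of two events is the sum of the two
    single-event regressors.
    """
    onsets_ms = np.atleast_1d(np.asarray(onsets_ms, dtype=float))
    if onsets_ms.size == 0:
        return Regressor(values=np.zeros(n_volumes), label=label)
    neural = boxcar_on_grid(onsets_ms, durations_ms, n_volumes, volume_ms, amplitudes)
    return Regressor(values=convolve_hrf(neural, hrf), label=label)


@dataclass(frozen=True)
class DctBasis:
    """Discrete-cosine high-pass basis (the drift model).

    Column k (k = 1..n_basis) is sqrt(2/N)·cos(π·(2t+1)·k / (2N)), the
    lowest nonzero cosine frequencies on an N-volume grid; mutually
    orthonormal and orthogonal to the constant.
    """

    columns: np.ndarray  # N × n_basis
    n_basis: int

    @property
    def n_volumes(self) -> int:
        return self.columns.shape[0]


def dct_basis(n_volumes: int, n_basis: int = 8) -> DctBasis:
    if n_basis >= n_volumes:
        raise ValueError("n_basis must be smaller than the series length")
    t = np.arange(n_volumes)
    cols = np.stack(
        [
            np.sqrt(2.0 / n_volumes) * np.cos(np.pi * (2 * t + 1) * k / (2 * n_volumes))
            for k in range(1, n_basis + 1)
        ],
        axis=1,
    )
    return DctBasis(columns=cols, n_basis=n_basis)


def dct_highpass_residualize(data: np.ndarray, basis: DctBasis) -> np.ndarray:
    """Remove the constant and the DCT drift columns by OLS projection.

    Accepts a 1-D series or a 2-D (voxels × volumes) array; returns the
    residual, which is orthogonal to every basis column and to the mean.
    Applying the filter twice is a no-op (projection idempotence).
    """
    data = np.asarray(data, dtype=float)
    one_d = data.ndim == 1
    Y = np.atleast_2d(data)
    if Y.shape[1] != basis.n_volumes:
        raise ValueError(
            f"series length {Y.shape[1]} does not match basis ({basis.n_volumes})"
        )
    X = np.column_stack([np.ones(basis.n_volumes), basis.columns])
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ beta).T
    return resid[0] if one_d else resid
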