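"""Phase-encoded retinotopy by lagged cross-correlation.

Each voxel's time course from a wedge (polar angle) or ring (eccentricity)
mapping run is Pearson-correlated against the HRF-convolved cyclic
activation vector at every integer lag within a cycle (100 lags at the
default 54 000 ms cycle / 540 ms volume interval).  The lag of the peak
correlation is the voxel's response phase and decodes to its receptive-field
polar angle or eccentricity.  Because the template is HRF-convolved, the
peak lag maps directly to stimulus phase with no extra hemodynamic-delay
correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from retinowm.design import DctBasis, HrfKernel, canonical_hrf, convolve_hrf, cyclic_neural_vector, dct_highpass_residualize
from retinowm.protocol import BoldSeries, MappingProtocol

# ---------------------------------------------------------------------------
# lag <-> phase conversions


def lag_to_polar(lag: int, protocol: MappingProtocol) -> float:
    """Polar angle (degrees, clockwise from the upper vertical meridian).

    One cycle of lags spans the full 360° wedge rotation, so the bin width
    is 360 / volumes_per_cycle = 3.6° at the default protocol.
    """
    vpc = protocol.volumes_per_cycle
    if not 0 <= lag < vpc:
        raise ValueError(f"lag must lie in [0, {vpc})")
    return float(np.mod(protocol.start_angle_deg + 360.0 * lag / vpc, 360.0))


def polar_to_lag(polar_deg, protocol: MappingProtocol):
    """Nearest-lag inverse of :func:`lag_to_polar` (vectorized)."""
    vpc = protocol.volumes_per_cycle
    frac = np.mod(np.asarray(polar_deg, dtype=float) - protocol.start_angle_deg, 360.0) / 360.0
    return np.mod(np.round(vpc * frac).astype(int), vpc)


def _ecc_origin(protocol: MappingProtocol) -> float:
    # ring-center eccentricity at cycle start: inner edge + half ring width
    return protocol.ring_min_ecc + protocol.ring_width / 2.0


def lag_to_eccentricity(lag: int, protocol: MappingProtocol) -> float:
    """Ring-center eccentricity at a lag: linear from min-edge + half-width
    (lag 0) to the maximum eccentricity (lag = volumes_per_cycle)."""
    vpc = protocol.volumes_per_cycle
    if not 0 <= lag < vpc:
        raise ValueError(f"lag must lie in [0, {vpc})")
    e0 = _ecc_origin(protocol)
    return float(e0 + (protocol.ring_max_ecc - e0) * lag / vpc)


def eccentricity_to_lag(ecc_deg, protocol: MappingProtocol):
    """Nearest-lag inverse of :func:`lag_to_eccentricity`, clipped to range."""
    vpc = protocol.volumes_per_cycle
    e0 = _ecc_origin(protocol)
    frac = (np.asarray(ecc_deg, dtype=float) - e0) / (protocol.ring_max_ecc - e0)
    return np.clip(np.round(vpc * frac).astype(int), 0, vpc - 1)


# ---------------------------------------------------------------------------
# cross-correlation mapping


def _regressor_bank(
    protocol: MappingProtocol,
    hrf: HrfKernel,
    highpass: DctBasis | None,
) -> np.ndarray:
    """n_volumes × volumes_per_cycle matrix of lagged cyclic regressors."""
    vpc = protocol.volumes_per_cycle
    base = np.stack([cyclic_neural_vector(protocol, l) for l in range(vpc)], axis=0)
    bank = convolve_hrf(base, hrf).T  # n_volumes × vpc
    if highpass is not None:
        bank = dct_highpass_residualize(bank.T, highpass).T
    return bank


def crosscorr_map(
    series: BoldSeries,
    protocol: MappingProtocol,
    stimulus: str,
    hrf: HrfKernel | None = None,
    highpass: DctBasis | None = None,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-voxel peak lagged cross-correlation and decoded phase.

    Parameters
    ----------
    series
        Mapping-run BOLD series, already high-pass filtered unless
        ``highpass`` is given (in which case data *and* regressors are
        residualized against it here, identically).
    stimulus
        ``"wedge"`` (decode polar angle) or ``"ring"`` (decode eccentricity).
    meta
        Optional per-voxel metadata (must carry ``voxel_id``; e.g. the
        sheet's ``area`` labels) merged into the output.

    Returns
    -------
    DataFrame with voxel_id, peak_lag, peak_r, p_value, valid, and
    polar_deg or ecc_deg.  Constant (zero-variance) time courses are
    flagged ``valid=False`` with peak_lag −1 and are excluded from maps
    downstream.  Ties in peak correlation break toward the smallest lag.
    """
    if stimulus not in ("wedge", "ring"):
        raise ValueError("stimulus must be 'wedge' or 'ring'")
    if series.n_volumes != protocol.n_volumes:
        raise ValueError(
            f"series has {series.n_volumes} volumes, protocol implies {protocol.n_volumes}"
        )
    if hrf is None:
        hrf = canonical_hrf(protocol.volume_ms)
    bank = _regressor_bank(protocol, hrf, highpass)
    # constant (zero-variance) voxels are invalid regardless of filtering
    valid = series.data.std(axis=1) > 0
    data = series.data
    if highpass is not None:
        data = dct_highpass_residualize(data, highpass)

    # unit-normalize rows/columns -> correlation by matrix product
    D = data - data.mean(axis=1, keepdims=True)
    dnorm = np.linalg.norm(D, axis=1)
    valid &= dnorm > 0
    B = bank - bank.mean(axis=0, keepdims=True)
    bnorm = np.linalg.norm(B, axis=0)
    Dn = np.zeros_like(D)
    Dn[valid] = D[valid] / dnorm[valid, None]
    r = Dn @ (B / bnorm)  # voxels × lags

    peak_lag = np.argmax(r, axis=1)  # argmax ties -> first (smallest lag)
    peak_r = r[np.arange(r.shape[0]), peak_lag]

    T = series.n_volumes
    df_resid = T - 2
    rr = np.clip(peak_r, -1.0, 1.0)
    denom = np.maximum(1.0 - rr**2, 1e-300)
    tstat = rr * np.sqrt(df_resid / denom)
    p = 2.0 * sps.t.sf(np.abs(tstat), df_resid)

    out = pd.DataFrame(
        {
            "voxel_id": series.voxel_ids,
            "peak_lag": np.where(valid, peak_lag, -1),
            "peak_r": np.where(valid, peak_r, np.nan),
            "p_value": np.where(valid, p, np.nan),
            "valid": valid,
        }
    )
    vpc = protocol.volumes_per_cycle
    if stimulus == "wedge":
        decoded = np.mod(protocol.start_angle_deg + 360.0 * out["peak_lag"].to_numpy() / vpc, 360.0)
        out["polar_deg"] = np.where(valid, decoded, np.nan)
    else:
        e0 = _ecc_origin(protocol)
        decoded = e0 + (protocol.ring_max_ecc - e0) * out["peak_lag"].to_numpy() / vpc
        out["ecc_deg"] = np.where(valid, decoded, np.nan)
    if meta is not None:
        out = out.merge(meta, on="voxel_id", how="left")
    return out


def significance_mask(
    estimates: pd.DataFrame,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Bonferroni-corrected activation mask (p ≤ alpha / n_tests).

    ``n_tests`` defaults to the number of voxels tested.  Invalid estimates
    are never significant.  Returns a copy with a boolean ``significant``
    column.
    """
    out = estimates.copy()
    if alpha <= 0:
        out["significant"] = False
        return out
    if n_tests is None:
        n_tests = int(out["valid"].sum()) if "valid" in out else len(out)
    n_tests = max(int(n_tests), 1)
    sig = (out["p_value"].to_numpy() <= alpha / n_tests) & out["valid"].to_numpy()
    out["significant"] = np.where(np.isnan(out["p_value"]), False, sig)
    return out
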