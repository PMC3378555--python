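"""Concatenated-segment first-level GLM for delay-period activity.

The four visual-field segments of one area (quadrants for the categorical
instruction, rings for the coordinate instruction) are averaged into four
mean time courses and concatenated into a single series of length 4·T.
One design matrix models all four segments simultaneously: each trial's
delay boxcar (S1 offset → S2 onset) is placed only in the block of the
segment resolved as *matching* (respectively *mismatching*) for that trial,
and the S1/S2 impulse events are placed in the block of the segment
containing the dot.  Modeling the four segments jointly keeps the delay
factors and the stimulus factors from becoming collinear, which they would
be if each segment were fit on its own.

All neural columns are HRF-convolved within their segment block, so no
hemodynamic spill crosses a concatenation seam; each block carries its own
constant and discrete-cosine high-pass columns so concatenation does not
couple baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from retinowm import roi as roi_mod
from retinowm.design import HrfKernel, boxcar_on_grid, canonical_hrf, convolve_hrf, dct_basis
from retinowm.protocol import BoldSeries, TaskTiming

SEGMENTS = (1, 2, 3, 4)


@dataclass
class SegmentTimecourses:
    """Mean BOLD of the four segments of one area, plus their concatenation."""

    area: str
    mode: str
    series: dict[int, np.ndarray]  # segment -> (T,) mean series
    volume_ms: float

    @property
    def T(self) -> int:
        return len(self.series[1])

    @property
    def concatenated(self) -> np.ndarray:
        """Length 4·T: segment 1 block, then 2, 3, 4."""
        return np.concatenate([self.series[s] for s in SEGMENTS])


def extract_segment_timecourses(
    series: BoldSeries,
    segmap: roi_mod.SegmentMap,
    area: str,
) -> SegmentTimecourses:
    """Average the voxels of each segment of ``area`` at every volume."""
    id_to_row = {int(v): i for i, v in enumerate(series.voxel_ids)}
    out: dict[int, np.ndarray] = {}
    for seg in SEGMENTS:
        vox = segmap.voxels_in(area, seg)
        rows = [id_to_row[int(v)] for v in vox if int(v) in id_to_row]
        if not rows:
            raise ValueError(f"segment {seg} of {area} ({segmap.mode} mode) is empty")
        out[seg] = series.data[rows].mean(axis=0)
    return SegmentTimecourses(area=area, mode=segmap.mode, series=out, volume_ms=series.volume_ms)


@dataclass
class ConcatDesign:
    """Named design matrix over the concatenated (4·T) series."""

    matrix: pd.DataFrame  # 4T × columns
    T: int
    mode: str

    @property
    def neural_columns(self) -> list[str]:
        return [c for c in self.matrix.columns if not c.startswith(("const_", "dct_"))]

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t", index=False)


def _check_no_overlap(trials: pd.DataFrame, timing: TaskTiming) -> None:
    ends = trials["s1_onset_ms"].to_numpy() - timing.fixation_ms
    if np.any(np.diff(ends) <= 0):
        raise ValueError("trials overlap or are out of order")


def _place(block_neural: dict[int, np.ndarray], segs, onset, duration, amp, T, vol):
    for s in np.atleast_1d(segs):
        block_neural[int(s)] += boxcar_on_grid([onset], [duration], T, vol, [amp])


def build_concatenated_design(
    trials: pd.DataFrame,
    T: int,
    mode: str,
    hrf: HrfKernel | None = None,
    include_own_quadrant: bool = False,
    n_dct: int = 8,
    ecc_modulator: bool = True,
    split_s2: bool = False,
    stimulus_contrast: bool = False,
    catch_delay_ms: float | None = None,
) -> ConcatDesign:
    """Five-factor design over the concatenated segment series.

    Factors (before the per-block constant/DCT columns):

    * ``delay_match`` / ``delay_mismatch`` — retention-interval boxcars in
      the matching / mismatching segment blocks of each trial;
    * ``s1`` — impulse at S1 onset in the segment containing S1;
    * ``s2`` — impulse at S2 onset in the segment containing S2 (with
      ``split_s2=True`` this becomes ``s2_match``/``s2_mismatch`` by
      whether S2 fell in the trial's matching region; an all-zero column
      is dropped with a warning);
    * ``ecc_mod`` — the S1+S2 impulses scaled by mean-centered dot
      eccentricity (the cortical-magnification modulator).

    ``mode`` chooses the segmentation the blocks refer to ("quadrant" or
    "ring").  With ``stimulus_contrast=True`` the design instead carries
    ``stim_present`` (every stimulus event in its containing segment) and
    ``stim_absent`` (the same events in the other three segments) plus one
    pooled delay nuisance column across all segments — the design used for
    the ROI-reliability "contrast activation" analysis, where the
    instruction's match/mismatch split need not align with ``mode``.
    """
    if mode not in ("quadrant", "ring"):
        raise ValueError("mode must be 'quadrant' or 'ring'")
    timing: TaskTiming = trials.attrs["timing"]
    vol = timing.volume_ms
    if hrf is None:
        hrf = canonical_hrf(vol)
    if catch_delay_ms is None:
        catch_delay_ms = float(timing.median_jitter_ms)
    _check_no_overlap(trials, timing)

    names = (
        ["stim_present", "stim_absent", "delay_all"]
        if stimulus_contrast
        else ["delay_match", "delay_mismatch", "s1"]
        + (["s2_match", "s2_mismatch"] if split_s2 else ["s2"])
        + (["ecc_mod"] if ecc_modulator else [])
    )
    neural: dict[str, dict[int, np.ndarray]] = {
        n: {s: np.zeros(T) for s in SEGMENTS} for n in names
    }

    # mean-centered eccentricity over all presented stimuli of the session
    eccs = list(trials["s1_radius_deg"]) + list(
        trials.loc[trials["trial_type"] != "catch", "s2_radius_deg"]
    )
    ecc_mean = float(np.mean(eccs)) if eccs else 0.0

    for _, trial in trials.iterrows():
        is_catch = trial["trial_type"] == "catch"
        s1_seg = int(trial["s1_quadrant"] if mode == "quadrant" else trial["s1_ring"])
        s2_seg = None if is_catch else int(
            trial["s2_quadrant"] if mode == "quadrant" else trial["s2_ring"]
        )
        delay_on = trial["s1_onset_ms"] + timing.stim_ms
        delay_dur = (catch_delay_ms if is_catch else trial["s2_onset_ms"] - delay_on)

        if stimulus_contrast:
            others1 = [s for s in SEGMENTS if s != s1_seg]
            _place(neural["stim_present"], s1_seg, trial["s1_onset_ms"], 0, 1.0, T, vol)
            _place(neural["stim_absent"], others1, trial["s1_onset_ms"], 0, 1.0, T, vol)
            if s2_seg is not None:
                others2 = [s for s in SEGMENTS if s != s2_seg]
                _place(neural["stim_present"], s2_seg, trial["s2_onset_ms"], 0, 1.0, T, vol)
                _place(neural["stim_absent"], others2, trial["s2_onset_ms"], 0, 1.0, T, vol)
            _place(neural["delay_all"], SEGMENTS, delay_on, delay_dur, 1.0, T, vol)
            continue

        reg = roi_mod.resolve_regions(trial, include_own_quadrant)
        if reg.mode != mode:
            raise ValueError(
                f"trial {reg.trial_id}: instruction {trial['instruction']!r} resolves "
                f"regions in {reg.mode!r} mode but the design is built in {mode!r} mode; "
                "use stimulus_contrast=True for cross-mode analyses"
            )
        _place(neural["delay_match"], reg.matching_segment, delay_on, delay_dur, 1.0, T, vol)
        _place(neural["delay_mismatch"], reg.mismatching_segments, delay_on, delay_dur, 1.0, T, vol)
        _place(neural["s1"], s1_seg, trial["s1_onset_ms"], 0, 1.0, T, vol)
        if ecc_modulator:
            _place(neural["ecc_mod"], s1_seg, trial["s1_onset_ms"], 0,
                   trial["s1_radius_deg"] - ecc_mean, T, vol)
        if s2_seg is not None:
            if split_s2:
                col = "s2_match" if trial["trial_type"] == "match" else "s2_mismatch"
            else:
                col = "s2"
            _place(neural[col], s2_seg, trial["s2_onset_ms"], 0, 1.0, T, vol)
            if ecc_modulator:
                _place(neural["ecc_mod"], s2_seg, trial["s2_onset_ms"], 0,
                       trial["s2_radius_deg"] - ecc_mean, T, vol)

    cols: dict[str, np.ndarray] = {}
    dropped = []
    for name in names:
        blocks = [convolve_hrf(neural[name][s], hrf) for s in SEGMENTS]
        col = np.concatenate(blocks)
        if not np.any(col):
            dropped.append(name)
            continue
        cols[name] = col
    if dropped:
        warnings.warn(f"dropping all-zero design column(s): {dropped}", stacklevel=2)

    basis = dct_basis(T, n_dct)
    for s in SEGMENTS:
        const = np.zeros(4 * T)
        const[(s - 1) * T : s * T] = 1.0
        cols[f"const_seg{s}"] = const
        for k in range(n_dct):
            c = np.zeros(4 * T)
            c[(s - 1) * T : s * T] = basis.columns[:, k]
            cols[f"dct_seg{s}_{k + 1}"] = c

    return ConcatDesign(matrix=pd.DataFrame(cols), T=T, mode=mode)


@dataclass
class GlmFit:
    """OLS fit of the concatenated design: betas, standard errors, residual."""

    betas: pd.Series
    se: pd.Series
    sigma2: float
    df_resid: int

    def row(self, factor: str) -> tuple[float, float]:
        return float(self.betas[factor]), float(self.se[factor])


def fit_glm(tcs: SegmentTimecourses, design: ConcatDesign) -> GlmFit:
    """Ordinary least squares on the concatenated series.

    Raises on rank deficiency, naming the collinear columns.
    """
    y = tcs.concatenated
    X = design.matrix.to_numpy()
    if len(y) != X.shape[0]:
        raise ValueError(f"series length {len(y)} != design rows {X.shape[0]}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad, cur = [], 0
        for j in range(X.shape[1]):
            r = np.linalg.matrix_rank(X[:, : j + 1])
            if r == cur:
                bad.append(design.matrix.columns[j])
            cur = r
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / df_resid
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    cols = design.matrix.columns
    return GlmFit(
        betas=pd.Series(beta, index=cols),
        se=pd.Series(se, index=cols),
        sigma2=sigma2,
        df_resid=df_resid,
    )


def delay_betas(
    series: BoldSeries,
    segmap: roi_mod.SegmentMap,
    trials: pd.DataFrame,
    area: str,
    **design_kwargs,
) -> pd.DataFrame:
    """Delay-period match/mismatch betas of one (area, instruction) session."""
    tcs = extract_segment_timecourses(series, segmap, area)
    design = build_concatenated_design(trials, tcs.T, mode=segmap.mode, **design_kwargs)
    fit = fit_glm(tcs, design)
    instruction = trials["instruction"].iloc[0]
    rows = []
    for factor, region in (("delay_match", "match"), ("delay_mismatch", "mismatch")):
        b, se = fit.row(factor)
        rows.append(
            {"area": area, "instruction": instruction, "factor": factor,
             "region": region, "beta": b, "se": se}
        )
    return pd.DataFrame(rows)


def stimulus_betas(
    series: BoldSeries,
    segmap: roi_mod.SegmentMap,
    trials: pd.DataFrame,
    area: str,
    **design_kwargs,
) -> pd.DataFrame:
    """S1 / S2-matching-region / S2-mismatching-region betas for one session."""
    tcs = extract_segment_timecourses(series, segmap, area)
    design = build_concatenated_design(
        trials, tcs.T, mode=segmap.mode, split_s2=True, **design_kwargs
    )
    fit = fit_glm(tcs, design)
    instruction = trials["instruction"].iloc[0]
    rows = []
    for factor, label in (("s1", "S1"), ("s2_match", "S2_match"), ("s2_mismatch", "S2_mismatch")):
        if factor not in fit.betas.index:
            continue
        b, se = fit.row(factor)
        rows.append(
            {"area": area, "instruction": instruction, "factor": factor,
             "stimulus": label, "beta": b, "se": se}
        )
    return pd.DataFrame(rows)


def contrast_activation(
    series: BoldSeries,
    segmap: roi_mod.SegmentMap,
    trials: pd.DataFrame,
    area: str,
    hrf: HrfKernel | None = None,
) -> float:
    """Stimulus-present minus stimulus-absent activation for one session.

    The difference between the response where a stimulus was shown and the
    mean response where it was not, under the given segmentation; computed
    for both instructions under both segmentations it yields the four
    ROI-reliability condition means.
    """
    tcs = extract_segment_timecourses(series, segmap, area)
    design = build_concatenated_design(
        trials, tcs.T, mode=segmap.mode, hrf=hrf, stimulus_contrast=True
    )
    fit = fit_glm(tcs, design)
    return float(fit.betas["stim_present"] - fit.betas["stim_absent"])
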