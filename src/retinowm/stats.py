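"""Second-level (group) inference on delay-period and stimulus betas.

All designs here are fully within-subject.  For a balanced subjects × cells
table, every effect of a within-subject factorial is tested through an
orthonormal contrast of the cell means:

* *univariate* repeated-measures F (sphericity assumed), with the
  Greenhouse-Geisser epsilon-corrected variant alongside;
* the *multivariate* test (Hotelling's T² on the contrast variables),
  which for a q-dimensional effect with n subjects gives an exact
  F(q, n − q) under normality.

Both families are emitted because published within-subject F statistics are
frequently reported with either convention and they coincide only for
single-degree-of-freedom effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    method: str  # "univariate" | "greenhouse_geisser" | "multivariate"
    F: float
    df_num: float
    df_den: float
    p: float
    epsilon: float | None = None


@dataclass(frozen=True)
class TTestResult:
    label: str
    t: float
    df: int
    p: float
    mean_diff: float

    @property
    def direction(self) -> str:
        return "first>second" if self.mean_diff > 0 else "second>first"


def _orthonormal_contrasts(n_levels: int) -> np.ndarray:
    """(n_levels−1) × n_levels orthonormal rows, orthogonal to the constant."""
    helmert = np.zeros((n_levels - 1, n_levels))
    for i in range(1, n_levels):
        helmert[i - 1, :i] = 1.0
        helmert[i - 1, i] = -i
    q, _ = np.linalg.qr(helmert.T)
    return q.T


def _cell_matrix(
    data: pd.DataFrame, dv: str, subject: str, within: list[str]
) -> tuple[np.ndarray, list[tuple], list]:
    """subjects × cells matrix in a fixed factorial cell order."""
    levels = [sorted(data[f].unique()) for f in within]
    pivot = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    full_cols = pd.MultiIndex.from_product(levels, names=within) if len(within) > 1 else pd.Index(
        levels[0], name=within[0]
    )
    missing = [c for c in full_cols if c not in pivot.columns]
    if missing or pivot.isna().any().any():
        nan_cells = [c for c in pivot.columns if pivot[c].isna().any()]
        raise ValueError(f"missing cells in within-subject table: {missing + nan_cells}")
    pivot = pivot[full_cols]
    return pivot.to_numpy(dtype=float), list(full_cols), levels


def _effect_contrast(effect: tuple[str, ...], within: list[str], levels: list) -> np.ndarray:
    mats = []
    for f, lv in zip(within, levels):
        if f in effect:
            mats.append(_orthonormal_contrasts(len(lv)))
        else:
            mats.append(np.full((1, len(lv)), 1.0 / len(lv)))
    C = mats[0]
    for m in mats[1:]:
        C = np.kron(C, m)
    return C


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: list[str],
) -> pd.DataFrame:
    """Repeated-measures ANOVA over arbitrary within-subject factorials.

    Emits, per effect (all main effects and interactions), the
    sphericity-assumed univariate F, its Greenhouse-Geisser correction, and
    the multivariate (Hotelling T²) test.  Requires a complete balanced
    table; missing cells raise with the offending cells listed.
    """
    Y, _, levels = _cell_matrix(data, dv, subject, within)
    n = Y.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")
    rows = []
    for k in range(1, len(within) + 1):
        for effect in combinations(within, k):
            C = _effect_contrast(effect, within, levels)
            q = C.shape[0]
            Yc = Y @ C.T  # n × q contrast variables
            ybar = Yc.mean(axis=0)
            resid = Yc - ybar
            S = (resid.T @ resid) / (n - 1)
            name = "*".join(effect)

            ss_eff = n * float(ybar @ ybar)
            ss_err = float(np.trace(resid.T @ resid))
            df1, df2 = q, q * (n - 1)
            tiny = 1e-12 * max(float(np.sum(Y**2)), 1.0)
            if ss_err > tiny:
                F = (ss_eff / df1) / (ss_err / df2)
            else:
                # degenerate data: no effect and no error -> F = 0, else infinite
                F = 0.0 if ss_eff <= tiny else np.inf
            p = float(sps.f.sf(F, df1, df2))
            rows.append(AnovaResult(name, "univariate", F, df1, df2, p))

            if q == 1:
                eps = 1.0
            else:
                trS = float(np.trace(S))
                trS2 = float(np.trace(S @ S))
                eps = trS**2 / (q * trS2) if trS2 > 0 else 1.0
                eps = min(max(eps, 1.0 / q), 1.0)
            p_gg = float(sps.f.sf(F, df1 * eps, df2 * eps))
            rows.append(
                AnovaResult(name, "greenhouse_geisser", F, df1 * eps, df2 * eps, p_gg, eps)
            )

            if n > q:
                try:
                    t2 = n * float(ybar @ np.linalg.solve(S, ybar))
                    Fm = (n - q) / (q * (n - 1)) * t2
                    pm = float(sps.f.sf(Fm, q, n - q))
                    rows.append(AnovaResult(name, "multivariate", Fm, q, n - q, pm))
                except np.linalg.LinAlgError:
                    pass
    return pd.DataFrame([r.__dict__ for r in rows])


def paired_t(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    condition: str,
    first,
    second,
    label: str | None = None,
) -> TTestResult:
    """Paired t-test between two conditions on per-subject means."""
    pivot = data.pivot_table(index=subject, columns=condition, values=dv, aggfunc="mean")
    a, b = pivot[first].to_numpy(), pivot[second].to_numpy()
    if len(a) < 2:
        raise ValueError("paired t-test needs at least two subjects")
    diff = a - b
    if np.all(diff == diff[0]) and diff[0] == 0:
        # identical conditions: define t = 0 rather than 0/0
        t, p = 0.0, 1.0
    else:
        res = sps.ttest_rel(a, b)
        t, p = float(res.statistic), float(res.pvalue)
    return TTestResult(
        label=label or f"{dv}: {first} vs {second}",
        t=t,
        df=len(a) - 1,
        p=p,
        mean_diff=float(np.mean(diff)),
    )


def holm_correction(pvals: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def delay_rm_anova(betas: pd.DataFrame) -> pd.DataFrame:
    """Three-way ROI × instruction × region ANOVA on delay betas.

    ``betas``: one row per subject × area × instruction × region with a
    ``beta`` column (the BetaTable of the first-level stage).
    """
    return rm_anova(betas, dv="beta", subject="subject", within=["area", "instruction", "region"])


def followup_per_roi(betas: pd.DataFrame, area: str) -> dict:
    """2×2 instruction × region ANOVA within one area, plus post-hoc
    match-vs-mismatch paired contrasts per instruction (uncorrected and
    Holm-adjusted)."""
    sub = betas[betas["area"] == area]
    anova = rm_anova(sub, dv="beta", subject="subject", within=["instruction", "region"])
    posthoc_rows = []
    for instruction in sorted(sub["instruction"].unique()):
        cond = sub[sub["instruction"] == instruction]
        res = paired_t(
            cond, dv="beta", subject="subject", condition="region",
            first="match", second="mismatch",
            label=f"{area} {instruction}: match vs mismatch",
        )
        posthoc_rows.append(
            {"area": area, "instruction": instruction, "t": res.t, "df": res.df,
             "p": res.p, "mean_diff": res.mean_diff}
        )
    posthoc = pd.DataFrame(posthoc_rows)
    posthoc["p_holm"] = holm_correction(posthoc["p"].tolist())
    return {"anova": anova, "posthoc": posthoc}


def behavioral_tests(behavior: pd.DataFrame) -> list[TTestResult]:
    """Paired t-tests on accuracy and mean RT, categorical vs coordinate.

    ``behavior``: per-subject scored trials (columns subject, instruction,
    correct, rt_ms); RT means use correct trials only.
    """
    acc = (
        behavior.groupby(["subject", "instruction"])["correct"].mean().mul(100).reset_index()
    )
    rt = (
        behavior[behavior["correct"]]
        .groupby(["subject", "instruction"])["rt_ms"].mean().reset_index()
    )
    t_acc = paired_t(acc, "correct", "subject", "instruction",
                     "categorical", "coordinate", label="accuracy (%)")
    t_rt = paired_t(rt, "rt_ms", "subject", "instruction",
                    "categorical", "coordinate", label="response time (ms)")
    return [t_acc, t_rt]


def contrast_activation_anova(contrasts: pd.DataFrame) -> dict:
    """ROI-reliability check over the four contrast-activation levels.

    ``contrasts``: subject × instruction × mode rows with a ``contrast``
    column.  Emits the one-way ANOVA over the four (instruction, mode)
    levels and the 2×2 instruction × mode ANOVA.
    """
    df = contrasts.copy()
    df["level"] = df["instruction"].astype(str) + ":" + df["mode"].astype(str)
    oneway = rm_anova(df, dv="contrast", subject="subject", within=["level"])
    twoway = rm_anova(df, dv="contrast", subject="subject", within=["instruction", "mode"])
    return {"oneway": oneway, "twoway": twoway}
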