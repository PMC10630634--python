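"""qPCR relative quantification and metabolic-labeling kinetics.

Relative expression follows the comparative-CT (delta-delta-CT) scheme
with an assumed amplification efficiency of 2 (perfect doubling):

    dCT  = CT_target - CT_reference          (per sample)
    ddCT = dCT - mean(dCT | calibrator group)
    relative expression = 2 ** (-ddCT)

Replicate statistics are computed on the dCT scale, where errors are
approximately additive and Gaussian, never on fold changes.

Synthesis rates come from approach-to-equilibrium metabolic labeling:
nascent RNA is pulse-labeled (e.g. 5-ethynyl uridine) for increasing
durations and, well below the transcript's half-life, labeled abundance
grows linearly in time, so the OLS slope of abundance on labeling time
is a synthesis-rate proxy.  Two conditions are compared by the t test
on the condition x time interaction in a pooled linear model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

CT_COLUMNS = ["sample", "group", "target", "reference", "ct_target", "ct_reference", "replicate"]


def validate_ct_table(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValidationError(f"CT table missing columns: {missing}")
    if ct[["ct_target", "ct_reference"]].isna().any().any():
        raise ValidationError("missing CT values")
    if not np.all(np.isfinite(ct[["ct_target", "ct_reference"]].to_numpy(dtype=float))):
        raise ValidationError("non-finite CT values")
    return ct


def ddct(ct: pd.DataFrame, calibrator_group: str) -> pd.DataFrame:
    """Per-sample relative expression by the comparative-CT method.

    The calibrator mean dCT is computed per target gene over the
    calibrator group's samples.  Returns the input rows with
    ``delta_ct``, ``ddct`` and ``rel_expr`` columns appended.
    """
    ct = validate_ct_table(ct).copy()
    if calibrator_group not in set(ct["group"]):
        raise ValidationError(f"calibrator group {calibrator_group!r} not in table")
    ct["delta_ct"] = ct["ct_target"] - ct["ct_reference"]
    cal_means = (
        ct[ct["group"] == calibrator_group].groupby("target")["delta_ct"].mean()
    )
    missing = set(ct["target"]) - set(cal_means.index)
    if missing:
        raise ValidationError(f"targets without calibrator samples: {sorted(missing)}")
    ct["ddct"] = ct["delta_ct"] - ct["target"].map(cal_means)
    ct["rel_expr"] = 2.0 ** (-ct["ddct"])
    return ct


def ttest_bonferroni(
    ct: pd.DataFrame,
    comparisons: Sequence[Tuple[str, str]],
    m: int | None = None,
    target: str | None = None,
) -> pd.DataFrame:
    """Welch t tests on dCT between groups, Bonferroni-adjusted.

    ``m`` is the number of comparisons corrected for; it defaults to
    ``len(comparisons)`` and must not be smaller.  Statistics operate on
    the additive dCT scale.
    """
    ct = validate_ct_table(ct)
    if "delta_ct" not in ct.columns:
        ct = ct.copy()
        ct["delta_ct"] = ct["ct_target"] - ct["ct_reference"]
    if target is not None:
        ct = ct[ct["target"] == target]
    if m is None:
        m = len(comparisons)
    if m < len(comparisons):
        raise ValidationError(f"m={m} is fewer than {len(comparisons)} comparisons")
    rows = []
    for ga, gb in comparisons:
        a = ct.loc[ct["group"] == ga, "delta_ct"].to_numpy(dtype=float)
        b = ct.loc[ct["group"] == gb, "delta_ct"].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValidationError(f"comparison ({ga}, {gb}): need >= 2 samples per group")
        if np.array_equal(np.sort(a), np.sort(b)) and np.ptp(np.concatenate([a, b])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            if not np.isfinite(p):
                t, p = 0.0, 1.0
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "t": float(t),
                "p_raw": float(p),
                "p_adj": min(1.0, m * float(p)),
            }
        )
    return pd.DataFrame(rows)


def timecourse_correlation(
    times: Sequence[float],
    values: Sequence[float],
) -> Tuple[float, float]:
    """Pearson r (and two-sided p) of expression against time.

    Replicate observations are pooled; each (time, value) pair is one
    observation.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.size < 3:
        raise ValidationError("need >= 3 paired (time, value) observations")
    if np.ptp(t) == 0 or np.ptp(v) == 0:
        raise ValidationError("zero variance: correlation undefined")
    r, p = stats.pearsonr(t, v)
    return float(r), float(p)


@dataclass
class LabelingSeries:
    """Labeled-abundance measurements over increasing labeling times."""

    gene_id: str
    condition: str
    times: np.ndarray  # minutes, one entry per observation
    abundances: np.ndarray  # relative units, >= 0
    replicates: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.replicates is None:
            self.replicates = np.zeros(len(self.times), dtype=int)
        self.replicates = np.asarray(self.replicates)
        if not (len(self.times) == len(self.abundances) == len(self.replicates)):
            raise ValidationError("times/abundances/replicates length mismatch")
        if np.any(self.times <= 0):
            raise ValidationError("labeling times must be > 0")
        if np.any(self.abundances < 0):
            raise ValidationError("abundances must be >= 0")

    @property
    def n_distinct_times(self) -> int:
        return len(np.unique(self.times))


@dataclass
class SlopeFit:
    """OLS fit of labeled abundance on labeling time."""

    slope: float  # abundance per minute: the synthesis-rate proxy
    intercept: float
    stderr: float
    r_squared: float


def fit_synthesis_rate(series: LabelingSeries) -> SlopeFit:
    """Ordinary least squares of labeled abundance on time, free intercept."""
    if series.n_distinct_times < 3:
        raise ValidationError("need >= 3 distinct labeling times for a slope fit")
    res = stats.linregress(series.times, series.abundances)
    return SlopeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
        r_squared=float(res.rvalue**2),
    )


def compare_slopes(a: LabelingSeries, b: LabelingSeries) -> Tuple[float, float, float]:
    """Test slope equality via the condition x time interaction.

    Fits the pooled model  abundance ~ time + condition + time:condition
    by OLS and returns ``(slope_diff, t_stat, p)`` where ``slope_diff``
    is slope(b) - slope(a) and ``p`` the two-sided t test on the
    interaction coefficient.
    """
    for s in (a, b):
        if s.n_distinct_times < 3:
            raise ValidationError("both series need >= 3 distinct times")
    t = np.concatenate([a.times, b.times])
    y = np.concatenate([a.abundances, b.abundances])
    cond = np.concatenate([np.zeros(len(a.times)), np.ones(len(b.times))])
    X = np.column_stack([np.ones_like(t), t, cond, t * cond])
    n, k = X.shape
    df = n - k
    if df <= 0:
        raise ValidationError("not enough observations for the interaction test")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise ValidationError("degenerate design (collinear times/conditions)")
    resid = y - X @ coef
    rss = float(resid @ resid)
    if rss <= 1e-24:  # both series exactly linear: identical -> diff 0, p 1
        diff = float(coef[3])
        return diff, 0.0 if abs(diff) < 1e-12 else float("inf"), 1.0 if abs(diff) < 1e-12 else 0.0
    sigma2 = rss / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = float(np.sqrt(cov[3, 3]))
    t_stat = float(coef[3] / se)
    p = float(2.0 * stats.t.sf(abs(t_stat), df))
    return float(coef[3]), t_stat, p


def series_to_frame(series_list: List[LabelingSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for t, v, r in zip(s.times, s.abundances, s.replicates):
            rows.append(
                {"gene": s.gene_id, "condition": s.condition,
                 "time_min": t, "abundance": v, "replicate": int(r)}
            )
    return pd.DataFrame(rows)


def frame_to_series(df: pd.DataFrame) -> List[LabelingSeries]:
    out = []
    for (gene, cond), sub in df.groupby(["gene", "condition"], sort=True):
        out.append(
            LabelingSeries(
                gene_id=gene,
                condition=cond,
                times=sub["time_min"].to_numpy(),
                abundances=sub["abundance"].to_numpy(),
                replicates=sub["replicate"].to_numpy(),
            )
        )
    return out
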