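"""Negative-binomial differential expression for count matrices.

The stage mirrors the classic count-based DE design: filter weakly
expressed features, estimate between-sample scaling factors by the
trimmed mean of M-values (TMM), estimate the NB dispersion phi
(variance = mu + phi*mu^2) by an adjusted profile likelihood with
tagwise shrinkage, test each feature with a log-linear NB GLM
likelihood-ratio test against a single-mean null, and call features
differential at |log2FC| >= 0.7 and Benjamini-Hochberg FDR < 0.01.

All fitting is implemented here (Newton/IRLS on the group-means model);
scipy supplies distributions and statsmodels the BH adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .core import CountMatrix, ValidationError

LFC_CUT = 0.7
FDR_CUT = 0.01

_PHI_MIN = 1e-6
_PHI_MAX = 10.0


# ---------------------------------------------------------------------------
# expression filter
# ---------------------------------------------------------------------------

def filter_expressed(
    cm: CountMatrix,
    min_count: int = 10,
    min_fraction: float = 0.70,
) -> CountMatrix:
    """Keep features with > ``min_count`` counts in >= ``min_fraction``
    of the samples of at least one group."""
    counts = cm.counts
    keep = np.zeros(len(cm.features), dtype=bool)
    for group in set(cm.groups.values()):
        samples = cm.group_samples(group)
        frac = (counts[samples] > min_count).sum(axis=1) / len(samples)
        keep |= (frac >= min_fraction).to_numpy()
    return CountMatrix(counts.loc[keep], cm.groups)


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

@dataclass
class NormFactors:
    """Per-sample TMM scaling factors (geometric mean 1)."""

    factors: pd.Series
    lib_sizes: pd.Series

    def __post_init__(self) -> None:
        if np.any(self.factors <= 0):
            raise ValidationError("TMM factors must be positive")
        log_mean = float(np.mean(np.log(self.factors)))
        if abs(log_mean) > 1e-9:
            raise ValidationError("TMM factors must have geometric mean 1")

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    log_ratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> float:
    """Two-sample TMM factor: doubly trimmed, precision-weighted mean of M.

    M = log2 ratio of normalized counts, A = mean log2 abundance; genes
    zero in either sample are excluded, then the 30% most extreme M and
    5% most extreme A values are trimmed and the remaining M averaged
    with inverse asymptotic-binomial-variance weights.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / lib_obs) / (ref / lib_ref))
        abs_e = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2
        v = (lib_obs - obs) / lib_obs / obs + (lib_ref - ref) / lib_ref / ref
    finite = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[finite], abs_e[finite], v[finite]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * log_ratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * abundance_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not np.any(keep):
        return 1.0
    f = np.nansum(log_r[keep] / v[keep]) / np.nansum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(cm: CountMatrix) -> NormFactors:
    """TMM scaling factors against an automatically chosen reference.

    The reference is the sample whose 75th-percentile count fraction is
    closest to the mean of those fractions across samples.
    """
    counts = cm.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        bad = [s for s, l in zip(cm.samples, lib) if l == 0]
        raise ValidationError(f"samples with all-zero counts: {bad}")
    # upper-quartile fraction of each sample, over its nonzero scale
    q75 = np.array([np.quantile(counts[:, j], 0.75) / lib[j] for j in range(counts.shape[1])])
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    raw = np.array(
        [
            _tmm_pair(counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx])
            for j in range(counts.shape[1])
        ]
    )
    factors = raw / np.exp(np.mean(np.log(raw)))
    return NormFactors(
        factors=pd.Series(factors, index=cm.samples),
        lib_sizes=pd.Series(lib, index=cm.samples),
    )


# ---------------------------------------------------------------------------
# NB likelihood machinery (vectorized across features)
# ---------------------------------------------------------------------------

def _phi_col(phi, n_rows: int) -> np.ndarray:
    """Dispersion as a (n_rows, 1) column, scalar- or vector-valued."""
    arr = np.asarray(phi, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_rows, float(arr))
    return np.maximum(arr, 1e-10)[:, None]


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Row-wise NB log-likelihood; scalar phi < 1e-10 means Poisson."""
    mu = np.maximum(mu, 1e-12)
    if np.ndim(phi) == 0 and phi < 1e-10:
        return np.sum(y * np.log(mu) - mu - special.gammaln(y + 1), axis=-1)
    r = 1.0 / _phi_col(phi, y.shape[0])
    return np.sum(
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu)),
        axis=-1,
    )


def _fit_mean(
    y: np.ndarray,
    offsets: np.ndarray,
    phi,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> np.ndarray:
    """MLE of a single log-scale mean per feature with sample offsets.

    Model: y_ij ~ NB(mu_ij, phi), log mu_ij = beta_i + offset_j.
    Newton iteration on beta (the Fisher scoring step for the log link),
    vectorized over features (rows of ``y``).
    """
    exp_off = np.exp(offsets)
    totals = y.sum(axis=1)
    beta = np.log(np.maximum(totals, 0.5) / exp_off.sum())
    phi_c = _phi_col(phi, y.shape[0]) if np.ndim(phi) > 0 else phi
    for _ in range(max_iter):
        mu = np.exp(beta[:, None] + offsets[None, :])
        w = mu / (1.0 + phi_c * mu)
        score = np.sum((y - mu) / (1.0 + phi_c * mu), axis=1)
        info = np.sum(w, axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _group_design(cm: CountMatrix) -> Tuple[np.ndarray, List[str]]:
    labels = cm.group_labels()
    idx = np.array([labels.index(cm.groups[s]) for s in cm.samples])
    return idx, labels


def _apl(phi: float, y: np.ndarray, offsets: np.ndarray, group_idx: np.ndarray) -> float:
    """Cox-Reid adjusted profile log-likelihood at dispersion ``phi``,
    summed over features, under the group-means model."""
    total = 0.0
    mu_full = np.zeros_like(y, dtype=float)
    adj = np.zeros(y.shape[0])
    for g in np.unique(group_idx):
        cols = group_idx == g
        beta = _fit_mean(y[:, cols], offsets[cols], phi)
        mu = np.exp(beta[:, None] + offsets[None, cols])
        mu_full[:, cols] = mu
        w = mu / (1.0 + phi * mu)
        adj += 0.5 * np.log(np.maximum(w.sum(axis=1), 1e-12))
    total = float(np.sum(_nb_loglik(y, mu_full, phi) - adj))
    return total


def estimate_dispersion(
    cm: CountMatrix,
    norm: NormFactors,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Estimate NB dispersion: common APL maximum + tagwise shrinkage.

    The common dispersion maximizes the Cox-Reid adjusted profile
    likelihood summed over all features.  Per-feature (tagwise) values
    are moment estimates shrunk toward the common value with a fixed
    prior weight of ``prior_df`` residual degrees of freedom, then
    clamped to [1e-6, 10].

    Returns a DataFrame with columns ``phi`` (tagwise) and attributes
    ``common`` accessible via ``df.attrs["common_dispersion"]``.
    """
    group_idx, labels = _group_design(cm)
    n_per_group = np.bincount(group_idx)
    resid_df = len(cm.samples) - len(labels)
    if resid_df <= 0:
        raise ValidationError(
            "dispersion unidentifiable: need replicate samples within groups"
        )
    y = cm.counts.to_numpy(dtype=float)
    offsets = np.log(norm.effective_lib_sizes.to_numpy(dtype=float))

    res = optimize.minimize_scalar(
        lambda t: -_apl(10.0**t, y, offsets, group_idx),
        bounds=(np.log10(_PHI_MIN), np.log10(_PHI_MAX)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    common = float(np.clip(10.0 ** res.x, _PHI_MIN, _PHI_MAX))

    # tagwise moment estimate under fitted group means at the common phi
    mu = np.zeros_like(y)
    for g in np.unique(group_idx):
        cols = group_idx == g
        beta = _fit_mean(y[:, cols], offsets[cols], common)
        mu[:, cols] = np.exp(beta[:, None] + offsets[None, cols])
    # residuals around fitted group means lose p = n_groups degrees of
    # freedom; inflate the squared-residual sum accordingly or the moment
    # estimate is biased low and the LRT runs anti-conservative
    n = len(cm.samples)
    infl = n / resid_df
    with np.errstate(divide="ignore", invalid="ignore"):
        num = infl * np.sum((y - mu) ** 2, axis=1) - np.sum(mu, axis=1)
        den = np.sum(mu**2, axis=1)
        phi_mom = np.where(den > 0, num / den, common)
    phi_mom = np.clip(phi_mom, 0.0, _PHI_MAX)
    phi_tag = (resid_df * phi_mom + prior_df * common) / (resid_df + prior_df)
    phi_tag = np.clip(phi_tag, _PHI_MIN, _PHI_MAX)

    out = pd.DataFrame({"phi": phi_tag}, index=cm.features)
    out.attrs["common_dispersion"] = common
    return out


# ---------------------------------------------------------------------------
# GLM likelihood-ratio test
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """Per-feature differential-expression summary."""

    feature_id: str
    log2_fc: float
    log_cpm: float
    dispersion: float
    p_raw: float
    fdr: float = float("nan")
    status: str = "not_DE"


def nb_lrt(
    cm: CountMatrix,
    norm: NormFactors,
    dispersion: pd.DataFrame | float,
    contrast: Tuple[str, str],
) -> pd.DataFrame:
    """NB GLM likelihood-ratio test of ``contrast = (groupB, groupA)``.

    Per feature, a log-linear NB model with offsets log(effective
    library size) is fit under the null (one mean) and the alternative
    (one mean per group); the LRT statistic 2*(l1 - l0) is referred to
    chi-square with 1 df.  log2FC is groupB over groupA from the fitted
    group means; logCPM is the average log2 counts-per-million.
    """
    group_b, group_a = contrast
    labels = cm.group_labels()
    for g in (group_a, group_b):
        if g not in labels:
            raise ValidationError(f"contrast group {g!r} not in design")
    samples_a = cm.group_samples(group_a)
    samples_b = cm.group_samples(group_b)
    use = samples_a + samples_b
    y = cm.counts[use].to_numpy(dtype=float)
    eff = norm.effective_lib_sizes.loc[use].to_numpy(dtype=float)
    offsets = np.log(eff)
    in_b = np.array([s in set(samples_b) for s in use])

    if isinstance(dispersion, pd.DataFrame):
        phi_vec = dispersion.loc[cm.features, "phi"].to_numpy(dtype=float)
    else:
        phi_vec = np.full(len(cm.features), float(dispersion))

    beta_null = _fit_mean(y, offsets, phi_vec)
    beta_a = _fit_mean(y[:, ~in_b], offsets[~in_b], phi_vec)
    beta_b = _fit_mean(y[:, in_b], offsets[in_b], phi_vec)
    mu_null = np.exp(beta_null[:, None] + offsets[None, :])
    mu_alt = np.empty_like(y)
    mu_alt[:, ~in_b] = np.exp(beta_a[:, None] + offsets[None, ~in_b])
    mu_alt[:, in_b] = np.exp(beta_b[:, None] + offsets[None, in_b])
    ll0 = _nb_loglik(y, mu_null, phi_vec)
    ll1 = _nb_loglik(y, mu_alt, phi_vec)
    stat = np.maximum(2.0 * (ll1 - ll0), 0.0)
    p_raw = stats.chi2.sf(stat, df=1)
    log2_fc = (beta_b - beta_a) / np.log(2.0)

    cpm = y / eff[None, :] * 1e6
    log_cpm = np.log2(cpm.mean(axis=1) + 0.5)
    return pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "log_cpm": log_cpm,
            "dispersion": phi_vec,
            "lr_stat": stat,
            "p_raw": p_raw,
        },
        index=pd.Index(cm.features, name="feature"),
    )


def classify_de(
    results: pd.DataFrame,
    lfc_cut: float = LFC_CUT,
    fdr_cut: float = FDR_CUT,
) -> pd.DataFrame:
    """Benjamini-Hochberg adjust and call up/down/not_DE.

    A feature is ``up`` iff log2FC >= ``lfc_cut`` and FDR < ``fdr_cut``,
    ``down`` iff log2FC <= -``lfc_cut`` and FDR < ``fdr_cut``.  The
    thresholds are inclusive on fold change, exclusive on FDR.
    """
    out = results.copy()
    if len(out) == 0:
        out["fdr"] = pd.Series(dtype=float)
        out["status"] = pd.Series(dtype=object)
        return out
    ok = np.isfinite(out["p_raw"].to_numpy())
    fdr = np.full(len(out), np.nan)
    if ok.any():
        fdr[ok] = multipletests(out["p_raw"].to_numpy()[ok], method="fdr_bh")[1]
    out["fdr"] = fdr
    lfc = out["log2_fc"].to_numpy()
    status = np.where(
        (lfc >= lfc_cut) & (fdr < fdr_cut),
        "up",
        np.where((lfc <= -lfc_cut) & (fdr < fdr_cut), "down", "not_DE"),
    )
    out["status"] = status
    return out


def run_de(
    cm: CountMatrix,
    contrast: Tuple[str, str],
    lfc_cut: float = LFC_CUT,
    fdr_cut: float = FDR_CUT,
    min_count: int = 10,
    min_fraction: float = 0.70,
) -> pd.DataFrame:
    """Full DE pipeline: filter -> TMM -> dispersion -> LRT -> BH calls.

    BH adjustment is computed over the filtered feature set only.
    """
    filtered = filter_expressed(cm, min_count=min_count, min_fraction=min_fraction)
    if len(filtered.features) == 0:
        return classify_de(
            pd.DataFrame(
                columns=["log2_fc", "log_cpm", "dispersion", "lr_stat", "p_raw"]
            )
        )
    norm = tmm_factors(filtered)
    disp = estimate_dispersion(filtered, norm)
    res = nb_lrt(filtered, norm, disp, contrast)
    return classify_de(res, lfc_cut=lfc_cut, fdr_cut=fdr_cut)
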