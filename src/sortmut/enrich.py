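"""Negative-binomial differential abundance of single mutations between pools.

The question: which mutations are over- or under-represented in a sorted
pool (e.g. high fluorescence in the presence of the repressing sRNA) relative
to a baseline pool (all-sorted or unsorted cells), given a handful of
biological replicates per condition?

The machinery is the classic shared-dispersion NB count framework:

* per-sample **size factors** by the median-of-ratios rule,
  ``s_j = median_i k_ij / (prod_v k_iv)^(1/m)`` over rows with all-positive
  counts, which is robust to the minority of genuinely changing rows;
* per-row **dispersions** by method of moments on normalized counts,
  ``alpha_raw = (v - qbar * mean(1/s)) / qbar**2`` (v is the within-condition
  pooled variance of k/s, qbar its grand mean), stabilised by a lowess trend
  alpha(qbar) fitted on the log scale; the working dispersion is the maximum
  of the raw estimate, the trend and a small floor — the conservative choice
  when replicates are few;
* a **conditioned exact test**: given the pooled row total k_S = k_A + k_B,
  the condition sums K_A, K_B are modelled as NB with means and variances
  assembled from the size factors and the row dispersion, and the two-sided
  p-value sums the probabilities of all partitions a + b = k_S at most as
  likely as the observed one, normalized over all partitions;
* Benjamini-Hochberg adjustment across rows, with calls at adjusted p < alpha.

Fitting is exposed statsmodels-style: build a :class:`MutationEnrichment`
model from a count matrix and a contrast, call :meth:`~MutationEnrichment.fit`,
and read estimates, p-values and calls off the returned
:class:`EnrichmentResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, logsumexp
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .core import MutationCountMatrix

DISPERSION_FLOOR = 1e-8
#: relative slack when comparing partition likelihoods, guards against ties
#: being split by floating-point rounding (same convention as R's exact tests)
_LIKE_TOL = 1e-7

OVER = "over"
UNDER = "under"
NS = "ns"


def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, one per sample column.

    Rows containing any zero are excluded from the median (their geometric
    mean is zero); if no all-positive row exists the estimator degenerates
    and we fall back to column-total normalization with a warning.
    """
    k = np.asarray(counts, dtype=float)
    if k.ndim != 2 or k.shape[1] < 1:
        raise ValueError("counts must be a 2-D matrix")
    positive = (k > 0).all(axis=1)
    if positive.any():
        logk = np.log(k[positive])
        log_geo = logk.mean(axis=1, keepdims=True)
        s = np.exp(np.median(logk - log_geo, axis=0))
    else:
        warnings.warn(
            "no row with all-positive counts; falling back to column-total "
            "normalization",
            stacklevel=2,
        )
        totals = k.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("cannot normalize: some columns are entirely zero")
        s = totals / np.exp(np.mean(np.log(totals)))
    return s


def estimate_dispersions(
    counts: pd.DataFrame | np.ndarray,
    conditions,
    size_factors_: np.ndarray,
    floor: float = DISPERSION_FLOOR,
    lowess_frac: float = 0.4,
) -> pd.DataFrame:
    """Per-row NB dispersions: method of moments plus a lowess trend.

    ``conditions`` labels each column; variances are pooled within condition
    so that genuine between-condition differences do not inflate the
    estimate.  Returns a DataFrame with columns ``mean`` (grand mean of
    normalized counts), ``alpha_raw``, ``alpha_trend`` and the working
    ``alpha = max(alpha_raw, alpha_trend, floor)``.  All-zero rows get NaN
    dispersion and are excluded from testing.
    """
    k = np.asarray(counts, dtype=float)
    s = np.asarray(size_factors_, dtype=float)
    cond = np.asarray(conditions)
    if k.shape[1] != len(s) or k.shape[1] != len(cond):
        raise ValueError("conditions/size factors do not match the columns")
    groups = [np.nonzero(cond == c)[0] for c in pd.unique(cond)]
    if max(len(g) for g in groups) < 2:
        raise ValueError("at least one condition needs >= 2 replicates")

    q = k / s[None, :]
    qbar = q.mean(axis=1)

    num = np.zeros(k.shape[0])
    dof = 0
    for g in groups:
        if len(g) >= 2:
            num += q[:, g].var(axis=1, ddof=1) * (len(g) - 1)
            dof += len(g) - 1
    v = num / dof

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = (v - qbar * np.mean(1.0 / s)) / qbar**2
    alpha_raw[qbar == 0] = np.nan

    # trend: local regression of the variance against the mean on the log
    # scale, converted to a dispersion by subtracting the shot-noise term.
    # Fitting the variance (strictly positive) rather than the raw dispersion
    # keeps rows whose raw estimate is zero or negative from dragging the
    # trend toward the floor.
    ok = qbar > 0
    alpha_trend = np.full(k.shape[0], np.nan)
    fit_rows = ok & (v > 0)
    x_all = np.log(qbar[ok])
    if fit_rows.sum() >= 2 and np.ptp(np.log(qbar[fit_rows])) > 0:
        x = np.log(qbar[fit_rows])
        # E[log v] understates log E[v]; remove the chi-square log bias
        # (exact for normal replicates, a good approximation here) so the
        # back-transformed trend is centred on the variance, not below it
        log_bias = digamma(dof / 2.0) - np.log(dof / 2.0)
        y = np.log(v[fit_rows]) - log_bias
        # evaluate the smooth at every tested row's mean
        fit = lowess(y, x, frac=lowess_frac, return_sorted=True)
        v_fit = np.exp(np.interp(x_all, fit[:, 0], fit[:, 1]))
        alpha_trend[ok] = np.clip(
            (v_fit - qbar[ok] * np.mean(1.0 / s)) / qbar[ok] ** 2, floor, None
        )
    elif ok.any():
        alpha_trend[ok] = np.clip(alpha_raw[ok], floor, None)

    alpha = np.fmax(np.fmax(alpha_raw, alpha_trend), floor)
    alpha[~ok] = np.nan
    index = counts.index if isinstance(counts, pd.DataFrame) else None
    return pd.DataFrame(
        {"mean": qbar, "alpha_raw": alpha_raw, "alpha_trend": alpha_trend, "alpha": alpha},
        index=index,
    )


def _nb_logpmf(x: np.ndarray, mu: float, var: float) -> np.ndarray:
    """log pmf of an NB (or Poisson when var <= mu) with given mean/variance."""
    if var <= mu * (1 + 1e-12):
        return stats.poisson.logpmf(x, mu)
    r = mu**2 / (var - mu)
    p = r / (r + mu)
    return stats.nbinom.logpmf(x, r, p)


def nb_exact_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    sf_a: np.ndarray,
    sf_b: np.ndarray,
    dispersion: float,
) -> float:
    """Conditioned two-sided NB exact test for one mutation row.

    ``counts_a``/``counts_b`` are the replicate counts in the two conditions,
    ``sf_a``/``sf_b`` the matching size factors, ``dispersion`` the row's
    working NB dispersion.  Conditions on the pooled total k_S and sums the
    probabilities of all partitions a + b = k_S no more likely than the
    observed one.  Returns NaN if k_S = 0 (nothing to test); otherwise a
    p-value in (0, 1].
    """
    ka = int(np.sum(counts_a))
    kb = int(np.sum(counts_b))
    ks = ka + kb
    if ks == 0:
        return np.nan
    sf_a = np.asarray(sf_a, dtype=float)
    sf_b = np.asarray(sf_b, dtype=float)
    s_a, s_b = sf_a.sum(), sf_b.sum()
    q0 = ks / (s_a + s_b)
    mu_a, mu_b = q0 * s_a, q0 * s_b
    var_a = mu_a + dispersion * q0**2 * np.sum(sf_a**2)
    var_b = mu_b + dispersion * q0**2 * np.sum(sf_b**2)

    a = np.arange(ks + 1)
    logp = _nb_logpmf(a, mu_a, var_a) + _nb_logpmf(ks - a, mu_b, var_b)
    log_obs = logp[ka]
    keep = logp <= log_obs + _LIKE_TOL
    p = np.exp(logsumexp(logp[keep]) - logsumexp(logp))
    return float(min(p, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


class MutationEnrichment:
    """NB differential-abundance model for one two-condition contrast.

    Parameters
    ----------
    counts : DataFrame
        Mutation x sample count matrix (the columns of both conditions).
    condition_cols, baseline_cols : list of str
        Column names of the comparison condition and the baseline.
    """

    def __init__(self, counts: pd.DataFrame, condition_cols, baseline_cols):
        condition_cols = list(condition_cols)
        baseline_cols = list(baseline_cols)
        if not condition_cols or not baseline_cols:
            raise ValueError("both conditions need at least one sample column")
        missing = [c for c in condition_cols + baseline_cols if c not in counts.columns]
        if missing:
            raise ValueError(f"columns not in count matrix: {missing}")
        self.counts = counts[condition_cols + baseline_cols].astype(float)
        self.condition_cols = condition_cols
        self.baseline_cols = baseline_cols

    @classmethod
    def from_count_matrix(
        cls,
        matrix: MutationCountMatrix,
        condition: str,
        baseline: str,
    ) -> "MutationEnrichment":
        """Build the model from a count matrix and ``plasmid:gate`` labels."""
        cond_cols = matrix.columns_for_condition(condition)
        base_cols = matrix.columns_for_condition(baseline)
        if not cond_cols:
            raise ValueError(f"no samples with condition {condition!r}")
        if not base_cols:
            raise ValueError(f"no samples with condition {baseline!r}")
        return cls(matrix.counts, cond_cols, base_cols)

    def fit(self, alpha: float = 0.05) -> "EnrichmentResults":
        """Run size factors -> dispersions -> exact tests -> BH -> calls."""
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        k = self.counts.values
        n_a = len(self.condition_cols)
        sf = size_factors(self.counts)
        sf_a, sf_b = sf[:n_a], sf[n_a:]
        cond = np.array(["condition"] * n_a + ["baseline"] * len(self.baseline_cols))
        disp = estimate_dispersions(self.counts, cond, sf)

        q = k / sf[None, :]
        mean_cond = q[:, :n_a].mean(axis=1)
        mean_base = q[:, n_a:].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            log2_ratio = np.log2(mean_cond / mean_base)

        p = np.full(k.shape[0], np.nan)
        testable = np.nonzero(~np.isnan(disp["alpha"].values))[0]
        for i in testable:
            p[i] = nb_exact_test(
                k[i, :n_a], k[i, n_a:], sf_a, sf_b, float(disp["alpha"].values[i])
            )
        padj = bh_adjust(p)

        call = np.where(
            np.isnan(padj) | (padj >= alpha),
            NS,
            np.where(log2_ratio > 0, OVER, UNDER),
        )
        table = pd.DataFrame(
            {
                "baseline_mean": mean_base,
                "condition_mean": mean_cond,
                "log2_ratio": log2_ratio,
                "p_value": p,
                "p_adjusted": padj,
                "call": call,
            },
            index=self.counts.index,
        )
        return EnrichmentResults(
            model=self, table=table, alpha=alpha, size_factors_=sf, dispersions=disp
        )


@dataclass
class EnrichmentResults:
    """Fitted enrichment results: per-mutation estimates, p-values and calls."""

    model: MutationEnrichment
    table: pd.DataFrame
    alpha: float
    size_factors_: np.ndarray
    dispersions: pd.DataFrame

    @property
    def n_over(self) -> int:
        return int((self.table["call"] == OVER).sum())

    @property
    def n_under(self) -> int:
        return int((self.table["call"] == UNDER).sum())

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["call"] != NS]

    def summary(self, top: int = 10) -> str:
        t = self.table
        tested = int(t["p_value"].notna().sum())
        lines = [
            "Mutation enrichment (conditioned NB exact test)",
            "=" * 47,
            f"condition samples : {', '.join(self.model.condition_cols)}",
            f"baseline samples  : {', '.join(self.model.baseline_cols)}",
            f"rows tested       : {tested} / {len(t)}",
            f"alpha (BH)        : {self.alpha:g}",
            f"over-represented  : {self.n_over}",
            f"under-represented : {self.n_under}",
            "",
            f"top {top} rows by adjusted p-value:",
        ]
        cols = ["baseline_mean", "condition_mean", "log2_ratio", "p_adjusted", "call"]
        head = t.sort_values("p_adjusted").head(top)[cols]
        lines.append(head.to_string(float_format=lambda x: f"{x:.3g}"))
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="mutation")


def enrichment_table(
    matrix: MutationCountMatrix,
    contrast: tuple[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-call convenience: fit the contrast ``(condition, baseline)``.

    Rows keep the canonical per-position mutation order of the matrix.
    """
    condition, baseline = contrast
    model = MutationEnrichment.from_count_matrix(matrix, condition, baseline)
    return model.fit(alpha=alpha).table
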