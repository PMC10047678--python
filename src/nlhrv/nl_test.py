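"""Surrogate-data nonlinearity test and cohort-level statistics.

The decision rule: compute a discriminating statistic (DET or LAM from a
FAN recurrence plot) on the original series and on 99 null surrogates, and
rank the original among the 100 values.  If it falls in the lowest or
highest five ranks -- beyond the fifth percentile of either side -- the
series is classified nonlinear (nominal two-sided level 0.10).  Embedding
parameters are selected once on the original and reused for every
surrogate, so the statistic compares dynamics at a fixed reconstruction.

Cohort helpers: exact Clopper-Pearson binomial intervals for the proportion
of nonlinear series, chi-square / McNemar comparisons of proportions, and
paired t-tests with a Bonferroni adjustment for the group-by-moment layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .embedding import EmbeddingParams, embed, select_embedding
from .preprocess import RRSeries
from .rqa import rqa_measures
from .surrogates import SurrogateEnsemble, generate_ensemble

__all__ = [
    "NonlinearityTest",
    "NonlinearityResult",
    "ProportionCI",
    "surrogate_test",
    "clopper_pearson",
    "compare_proportions_paired",
    "compare_paired_means",
    "bonferroni_adjust",
]


@dataclass
class NonlinearityResult:
    """Outcome of the surrogate-data nonlinearity test on one record."""

    record_id: str
    moment: Optional[str]
    statistic_name: str
    original_value: float
    surrogate_values: np.ndarray
    rank: int
    classified_nonlinear: bool
    embedding: EmbeddingParams
    method: str
    rho: Optional[float]
    seed: int

    @property
    def n_total(self) -> int:
        return int(self.surrogate_values.size) + 1

    def summary(self) -> str:
        lines = [
            "Surrogate-data nonlinearity test",
            "=" * 40,
            f"record:        {self.record_id or '<unnamed>'}"
            + (f" ({self.moment})" if self.moment else ""),
            f"statistic:     {self.statistic_name}",
            f"surrogates:    {self.surrogate_values.size} ({self.method}"
            + (f", rho={self.rho}" if self.rho is not None else "") + ")",
            f"embedding:     m={self.embedding.m}, tau={self.embedding.tau}",
            f"original:      {self.original_value:.4f}",
            f"surrogate range: [{self.surrogate_values.min():.4f}, "
            f"{self.surrogate_values.max():.4f}]",
            f"rank:          {self.rank} / {self.n_total}",
            f"nonlinear:     {'yes' if self.classified_nonlinear else 'no'}",
        ]
        return "\n".join(lines)


class NonlinearityTest:
    """Surrogate-data test for nonlinearity of one RR series.

    Parameters
    ----------
    series : RRSeries or array of intervals (ms)
    statistic : {"DET", "LAM"}
        Discriminating recurrence statistic.
    method : {"pwiaaft", "iaaft"}
        Surrogate generator; PWIAAFT (the default) keeps nonstationary
        structure in the null so trends are not mistaken for nonlinearity.
    n_surrogates, rho, density, l_min, v_min, theiler_window :
        Test and recurrence-plot parameters.
    params : EmbeddingParams, optional
        Pre-selected embedding; selected from the data when omitted.

    Call :meth:`fit` with a seed to run the test.
    """

    def __init__(
        self,
        series: Union[RRSeries, np.ndarray],
        statistic: str = "DET",
        method: str = "pwiaaft",
        n_surrogates: int = 99,
        rho: float = 0.01,
        density: float = 0.07,
        l_min: int = 2,
        v_min: int = 2,
        theiler_window: int = 1,
        params: Optional[EmbeddingParams] = None,
        max_lag: int = 50,
        max_m: int = 10,
    ) -> None:
        if statistic not in ("DET", "LAM"):
            raise ValueError("statistic must be 'DET' or 'LAM'")
        if isinstance(series, RRSeries):
            self.series = series
            self.values = series.intervals
        else:
            self.series = None
            self.values = np.asarray(series, dtype=float)
        self.statistic = statistic
        self.method = method
        self.n_surrogates = n_surrogates
        self.rho = rho
        self.density = density
        self.l_min = l_min
        self.v_min = v_min
        self.theiler_window = theiler_window
        self.max_lag = max_lag
        self.max_m = max_m
        self.params = params

    def _statistic(self, x: np.ndarray, params: EmbeddingParams) -> float:
        det, lam = rqa_measures(
            embed(x, params.m, params.tau),
            density=self.density,
            l_min=self.l_min,
            v_min=self.v_min,
            theiler_window=self.theiler_window,
        )
        return det if self.statistic == "DET" else lam

    def fit(self, seed: int = 0) -> NonlinearityResult:
        """Run the test: embed, generate surrogates, rank the original."""
        params = self.params or select_embedding(
            self.values, max_lag=self.max_lag, max_m=self.max_m
        )
        ens = generate_ensemble(
            self.values,
            n_surrogates=self.n_surrogates,
            method=self.method,
            rho=self.rho,
            seed=seed,
        )
        original_value = self._statistic(self.values, params)
        surrogate_values = np.array(
            [self._statistic(s, params) for s in ens.surrogates]
        )
        ens.statistic_name = self.statistic
        ens.values = np.concatenate([[original_value], surrogate_values])
        rank, nonlinear = _rank_and_classify(original_value, surrogate_values)
        return NonlinearityResult(
            record_id=self.series.record_id if self.series is not None else "",
            moment=self.series.moment if self.series is not None else None,
            statistic_name=self.statistic,
            original_value=original_value,
            surrogate_values=surrogate_values,
            rank=rank,
            classified_nonlinear=nonlinear,
            embedding=params,
            method=self.method,
            rho=self.rho if self.method == "pwiaaft" else None,
            seed=seed,
        )


def _rank_and_classify(original: float, surrogates: np.ndarray, tail: int = 5):
    """Rank of the original among original + surrogates, conservative ties.

    Ties take the rank least favorable to rejection: the low tail uses the
    highest tied rank, the high tail the lowest.  With 99 surrogates the
    two-sided rejection region is rank <= 5 or rank >= 96.
    """
    n_total = surrogates.size + 1
    n_less = int(np.sum(surrogates < original))
    n_tied = int(np.sum(surrogates == original))
    rank_high_end = n_less + n_tied + 1  # used for the low tail
    rank_low_end = n_less + 1            # used for the high tail
    low_cut = tail
    high_cut = n_total - tail + 1
    if rank_high_end <= low_cut:
        return rank_high_end, True
    if rank_low_end >= high_cut:
        return rank_low_end, True
    # not rejected: report the tie-rank nearest the center, clipped into the
    # acceptance region so the reported rank always matches the decision
    mid = n_less + 1 + n_tied / 2.0
    rank = rank_high_end if mid <= (n_total + 1) / 2 else rank_low_end
    return int(np.clip(rank, low_cut + 1, high_cut - 1)), False


def surrogate_test(
    series: Union[RRSeries, np.ndarray],
    statistic: str = "DET",
    n_surrogates: int = 99,
    rho: float = 0.01,
    seed: int = 0,
    method: str = "pwiaaft",
    **kwargs,
) -> NonlinearityResult:
    """Functional wrapper: build a :class:`NonlinearityTest` and fit it."""
    return NonlinearityTest(
        series,
        statistic=statistic,
        method=method,
        n_surrogates=n_surrogates,
        rho=rho,
        **kwargs,
    ).fit(seed=seed)


@dataclass
class ProportionCI:
    """Exact binomial proportion with its Clopper-Pearson interval (percent)."""

    k: int
    n: int
    point: float
    lower: float
    upper: float
    conf: float = 0.95


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> ProportionCI:
    """Exact (Clopper-Pearson) binomial confidence interval, in percent.

    Uses the Beta-quantile characterization of the binomial tail inversion;
    k = 0 gives a lower bound of exactly 0, k = n an upper bound of 100.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n and n >= 1")
    alpha = 1.0 - conf
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return ProportionCI(
        k=k, n=n, point=100.0 * k / n, lower=100.0 * lower, upper=100.0 * upper,
        conf=conf,
    )


def compare_proportions_paired(
    before: Sequence[bool],
    after: Sequence[bool],
    method: str = "chi2",
):
    """Compare two classification proportions on the same subjects.

    ``method="chi2"``: Pearson chi-square treating the two moments as
    independent 2x2 margins.  ``method="mcnemar"``: exact McNemar test on
    the discordant pairs, the appropriate choice for the paired design.
    Returns ``(statistic, p_value)``.
    """
    b = np.asarray(before, dtype=bool)
    a = np.asarray(after, dtype=bool)
    if b.size != a.size or b.size == 0:
        raise ValueError("before/after must be non-empty and equally long")
    if method == "chi2":
        table = np.array(
            [[b.sum(), b.size - b.sum()], [a.sum(), a.size - a.sum()]], dtype=float
        )
        if np.any(table.sum(axis=0) == 0):
            return 0.0, 1.0
        res = stats.chi2_contingency(table, correction=False)
        return float(res.statistic), float(res.pvalue)
    if method == "mcnemar":
        from statsmodels.stats.contingency_tables import mcnemar

        table = np.array(
            [
                [np.sum(b & a), np.sum(b & ~a)],
                [np.sum(~b & a), np.sum(~b & ~a)],
            ]
        )
        if table[0, 1] + table[1, 0] == 0:
            return 0.0, 1.0  # no discordant pairs
        res = mcnemar(table, exact=True)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


def compare_paired_means(
    x_before: Sequence[float], x_after: Sequence[float]
):
    """Classical paired Student t-test; returns ``(t, p_value)``.

    Zero-variance differences are handled explicitly: identical vectors
    give (0, 1); a constant nonzero shift gives (+/-inf, 0).
    """
    xb = np.asarray(x_before, dtype=float)
    xa = np.asarray(x_after, dtype=float)
    if xb.size != xa.size or xb.size < 2:
        raise ValueError("need equally long vectors with >= 2 pairs")
    d = xb - xa
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        return float(np.sign(d[0]) * np.inf), 0.0
    res = stats.ttest_rel(xb, xa)
    return float(res.statistic), float(res.pvalue)


def bonferroni_adjust(p_values: Sequence[float], n_comparisons: Optional[int] = None):
    """Bonferroni-adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = n_comparisons if n_comparisons is not None else p.size
    return np.minimum(p * m, 1.0)
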