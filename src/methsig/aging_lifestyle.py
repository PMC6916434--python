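"""Age-associated methylation drift rates in healthy mucosa and the
methylation-rate-ratio (MRR) statistic.

For each CpG, the drift rate is the ordinary least-squares slope of its
beta value on age expressed in decades (beta change per 10 years), fitted
across healthy-normal-mucosa (HNM) samples.  The MRR between two probe
sets — or between lifestyle-exposure strata on the same probe set — is the
ratio of the median rates, with a two-sided Wilcoxon rank-sum p-value
comparing the two rate distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ProbeMatrix, SampleSheet, ValidationError


@dataclass
class RateTable:
    """Per-probe beta change per 10 years of age.

    ``data`` columns: rate, n_samples, r_squared; indexed by probe id;
    ``stratum`` optionally labels a lifestyle stratum (user / nonuser).
    Probes with fewer than 3 complete cases carry NaN rates.
    """

    data: pd.DataFrame
    stratum: str | None = None

    @property
    def rates(self) -> pd.Series:
        return self.data["rate"].dropna()

    def write(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "stratum", self.stratum if self.stratum is not None else "NA")
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t", na_rep="NA")


class MrrResult(NamedTuple):
    mrr: float
    p_value: float
    n_numerator: int
    n_denominator: int
    undefined: bool


class RankSumResult(NamedTuple):
    statistic: float
    p_two_sided: float


class WelchResult(NamedTuple):
    t: float
    df: float
    p_two_sided: float


def fit_age_rates(
    beta: ProbeMatrix,
    ages: Sequence[float],
    probes: Iterable[str] | None = None,
    stratum: str | None = None,
) -> RateTable:
    """OLS slope of beta on age/10 per probe, complete cases only."""
    if beta.scale != "beta":
        raise ValidationError("fit_age_rates expects a beta-scale matrix")
    ages = np.asarray(ages, dtype=float)
    if ages.shape != (beta.n_samples,):
        raise ValidationError("ages must align with the matrix samples")
    known = np.isfinite(ages)
    if known.sum() < 3:
        raise ValidationError("need >= 3 samples with known age")
    probe_list = list(probes) if probes is not None else list(beta.probe_ids)
    Y = beta.values[beta.probe_index(probe_list)][:, known]
    x = ages[known] / 10.0

    finite = np.isfinite(Y)
    n = finite.sum(axis=1)
    Ym = np.where(finite, Y, 0.0)
    X = np.where(finite, x[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xbar = X.sum(axis=1) / n
        ybar = Ym.sum(axis=1) / n
        sxx = (finite * (X - xbar[:, None]) ** 2).sum(axis=1)
        sxy = (finite * (X - xbar[:, None]) * (Ym - ybar[:, None])).sum(axis=1)
        syy = (finite * (Ym - ybar[:, None]) ** 2).sum(axis=1)
        slope = sxy / sxx
        r2 = np.where(syy > 0, sxy**2 / (sxx * syy), np.where(sxx > 0, 1.0, np.nan))
    bad = (n < 3) | (sxx <= 0)
    slope = np.where(bad, np.nan, slope)
    r2 = np.where(bad, np.nan, r2)
    table = pd.DataFrame(
        {"rate": slope, "n_samples": n, "r_squared": r2}, index=probe_list
    )
    return RateTable(table, stratum=stratum)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midrank ties.

    Exact p when the smaller sample has <= 8 observations and there are no
    ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank-sum test requires nonempty samples")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return RankSumResult(float(res.statistic), float(min(res.pvalue, 1.0)))


def welch_t(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch two-sample t-test with Satterthwaite degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("Welch test requires >= 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return WelchResult(0.0, float(x.size + y.size - 2), 1.0)
        return WelchResult(np.inf if x.mean() > y.mean() else -np.inf, float("nan"), 0.0)
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def mrr(rates_num: RateTable, rates_den: RateTable) -> MrrResult:
    """Methylation rate ratio: median(numerator rates) / median(denominator
    rates), with rank-sum p comparing the two rate distributions.

    A zero denominator median leaves the ratio undefined (flagged); the
    p-value is still computed.
    """
    num = rates_num.rates.to_numpy()
    den = rates_den.rates.to_numpy()
    if num.size == 0 or den.size == 0:
        raise ValidationError("both rate tables must be nonempty")
    med_num = float(np.median(num))
    med_den = float(np.median(den))
    p = wilcoxon_rank_sum(num, den).p_two_sided
    if med_den == 0.0:
        return MrrResult(float("nan"), p, num.size, den.size, True)
    return MrrResult(med_num / med_den, p, num.size, den.size, False)


def lifestyle_mrr(
    beta: ProbeMatrix,
    ages: Sequence[float],
    user_flag: Sequence[str],
    probes: Iterable[str] | None = None,
    min_stratum: int = 3,
) -> MrrResult:
    """User vs nonuser MRR for one lifestyle exposure on one probe set.

    Age rates are fitted separately within the user and nonuser strata on
    the same probes; samples with unknown exposure status are excluded
    (never imputed).  MRR = median-rate_user / median-rate_nonuser.
    """
    flags = np.asarray(user_flag, dtype=object)
    if flags.shape != (beta.n_samples,):
        raise ValidationError("user_flag must align with the matrix samples")
    ages = np.asarray(ages, dtype=float)
    out = {}
    for label, value in (("user", "yes"), ("nonuser", "no")):
        cols = np.flatnonzero((flags == value) & np.isfinite(ages))
        if cols.size < min_stratum:
            raise ValidationError(f"{label} stratum has {cols.size} samples (< {min_stratum})")
        sub = beta.subset(samples=[beta.sample_ids[i] for i in cols])
        out[label] = fit_age_rates(sub, ages[cols], probes=probes, stratum=label)
    return mrr(out["user"], out["nonuser"])


def age_hyper_probes(
    beta: ProbeMatrix,
    ages: Sequence[float],
    p_max: float = 0.01,
) -> set[str]:
    """CpGs with a significant positive age slope in healthy mucosa.

    Per probe, the OLS slope of beta on age/10 is tested with the usual
    t-test on the regression coefficient; probes with slope > 0 and
    p < p_max form the age-hypermethylated set used for drift-enrichment
    comparisons.
    """
    if beta.scale != "beta":
        raise ValidationError("age_hyper_probes expects a beta-scale matrix")
    ages = np.asarray(ages, dtype=float)
    known = np.isfinite(ages)
    x = ages[known] / 10.0
    Y = beta.values[:, known]
    finite = np.isfinite(Y)
    n = finite.sum(axis=1)
    Ym = np.where(finite, Y, 0.0)
    X = np.where(finite, x[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xbar = X.sum(axis=1) / n
        ybar = Ym.sum(axis=1) / n
        sxx = (finite * (X - xbar[:, None]) ** 2).sum(axis=1)
        sxy = (finite * (X - xbar[:, None]) * (Ym - ybar[:, None])).sum(axis=1)
        syy = (finite * (Ym - ybar[:, None]) ** 2).sum(axis=1)
        slope = sxy / sxx
        rss = syy - sxy**2 / sxx
        df = n - 2
        se = np.sqrt(np.maximum(rss, 0.0) / np.maximum(df, 1) / sxx)
        tstat = slope / se
        p = 2.0 * stats.t.sf(np.abs(tstat), np.maximum(df, 1))
    ok = (n >= 3) & (sxx > 0) & np.isfinite(p)
    sig = ok & (slope > 0) & (p < p_max)
    return {p_id for p_id, s in zip(beta.probe_ids, sig) if s}


def rates_long_format(tables: dict[tuple[str, str], RateTable], path: str | Path) -> None:
    """Density-plot-ready long export: probe, class, stratum, rate."""
    rows = []
    for (cls, stratum), table in tables.items():
        for probe, rate in table.data["rate"].items():
            rows.append({"probe_id": probe, "class": cls, "stratum": stratum, "rate": rate})
    pd.DataFrame(rows, columns=["probe_id", "class", "stratum", "rate"]).to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )
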