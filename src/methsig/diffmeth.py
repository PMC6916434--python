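"""Covariate-adjusted differential methylation with empirical-Bayes moderation.

Statistics are computed on M-values (logit2 of beta), the
variance-stabilized scale appropriate for linear modeling, while beta
values are kept for biological interpretation (group means, delta-beta).

The moderation machinery follows the classical empirical-Bayes treatment
of per-probe variances: each probe's residual variance s_g^2 is assumed
to follow a scaled F / inverse-chi-square prior with hyperparameters
(d0, s0^2) estimated across all probes by method of moments on
log-variances, and the per-probe variance is squeezed toward s0^2 before
forming a t-statistic with d0 + d_g degrees of freedom.

Differentially methylated CpGs (DMCs) are then called by joint thresholds
on BH-adjusted p, M-scale logFC (difference of group-average M-values)
and delta-beta (difference of group-average beta values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .core_io import ProbeMatrix, SampleSheet, ValidationError

# ---------------------------------------------------------------------------
# Beta <-> M transforms


def beta_to_m(beta, epsilon: float = 1e-6):
    """logit2 transform: log2(b / (1 - b)) with b clamped to [eps, 1-eps].

    The clamp keeps the transform finite at beta exactly 0 or 1; it is a
    numerical convention, not a biological statement.
    """
    if not 0.0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    b = np.asarray(beta, dtype=float)
    finite = b[np.isfinite(b)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        raise ValueError("beta values must lie in [0, 1]")
    b = np.clip(b, epsilon, 1.0 - epsilon)
    out = np.log2(b / (1.0 - b))
    return out if out.ndim else float(out)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` inside the clamp: 2^m / (1 + 2^m)."""
    m = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-m))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Design matrices


@dataclass
class DesignMatrix:
    """Fixed-effect design: intercept, group indicators, covariate indicators.

    ``group_columns`` maps each non-baseline group to its column index; the
    baseline group is represented by the intercept alone.
    """

    sample_ids: list[str]
    columns: list[str]
    values: np.ndarray
    group_columns: dict[str, int]
    baseline: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.columns)):
            raise ValidationError("design shape does not match sample_ids x columns")
        if np.linalg.matrix_rank(self.values) < len(self.columns):
            raise ValidationError("design matrix is not of full column rank")

    def contrast(self, group_a: str, group_b: str) -> np.ndarray:
        """Contrast vector for mean(group_a) - mean(group_b)."""
        c = np.zeros(len(self.columns))
        for grp, sign in ((group_a, 1.0), (group_b, -1.0)):
            if grp == self.baseline:
                continue
            if grp not in self.group_columns:
                raise KeyError(f"group {grp!r} not in design")
            c[self.group_columns[grp]] += sign
        return c


def build_design(
    sheet: SampleSheet,
    groups: Sequence[str],
    covariates: Sequence[str] = ("location", "batch"),
) -> DesignMatrix:
    """Design over the samples of ``groups``: intercept + group indicators
    + fixed-effect indicator columns for each covariate (first level dropped).

    A covariate with a single observed level is silently omitted (it would
    be collinear with the intercept).
    """
    df = sheet.data[sheet.data["group"].isin(groups)].copy()
    if df.empty:
        raise ValidationError(f"no samples in groups {groups}")
    baseline = groups[0]
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    group_columns: dict[str, int] = {}
    for grp in groups[1:]:
        cols[f"group_{grp}"] = (df["group"] == grp).to_numpy(dtype=float)
    for cov in covariates:
        levels = sorted(df[cov].dropna().astype(str).unique())
        for level in levels[1:]:
            cols[f"{cov}_{level}"] = (df[cov].astype(str) == level).to_numpy(dtype=float)
    names = list(cols)
    values = np.column_stack([cols[c] for c in names])
    for grp in groups[1:]:
        group_columns[grp] = names.index(f"group_{grp}")
    return DesignMatrix(list(df["sample_id"]), names, values, group_columns, baseline)


# ---------------------------------------------------------------------------
# Per-probe least squares


@dataclass
class LinearFit:
    """Per-probe OLS results: coefficients, residual variance and df, and
    the unscaled covariance (X'X)^-1 needed for contrast standard errors.

    Probes with fewer than rank + 1 usable samples are flagged not-ok and
    carry NaN statistics.
    """

    probe_ids: list[str]
    design: DesignMatrix
    coef: np.ndarray          # (G, p)
    s2: np.ndarray            # (G,)
    df_resid: np.ndarray      # (G,)
    xtx_inv: np.ndarray       # (G, p, p)
    ok: np.ndarray            # (G,) bool

    def contrast_stats(self, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(contrast coefficient, unscaled stdev sqrt(c' (X'X)^-1 c)) per probe."""
        coef = self.coef @ c
        var_u = np.einsum("i,gij,j->g", c, self.xtx_inv, c)
        return coef, np.sqrt(np.maximum(var_u, 0.0))


def fit_linear_models(M: ProbeMatrix, design: DesignMatrix) -> LinearFit:
    """Ordinary least squares per probe, using each probe's non-missing samples."""
    if M.scale != "mvalue":
        raise ValidationError("fit_linear_models expects an M-value matrix")
    order = M.sample_index(design.sample_ids)
    Y = M.values[:, order]
    X = design.values
    G, n = Y.shape
    p = X.shape[1]
    coef = np.full((G, p), np.nan)
    s2 = np.full(G, np.nan)
    dfr = np.zeros(G)
    xtx_inv = np.full((G, p, p), np.nan)
    ok = np.zeros(G, dtype=bool)

    finite = np.isfinite(Y)
    complete = finite.all(axis=1)

    def _solve(rows: np.ndarray, Yb: np.ndarray, idx: np.ndarray) -> None:
        Xs = X[rows]
        rank = np.linalg.matrix_rank(Xs)
        if rank < p or Yb.shape[1] < p + 1:
            return
        xtx = Xs.T @ Xs
        inv = np.linalg.inv(xtx)
        B = inv @ Xs.T @ Yb.T          # (p, k)
        resid = Yb.T - Xs @ B
        df = Yb.shape[1] - p
        rss = (resid ** 2).sum(axis=0)
        coef[idx] = B.T
        s2[idx] = rss / df
        dfr[idx] = df
        xtx_inv[idx] = inv
        ok[idx] = True

    if complete.any():
        _solve(np.arange(n), Y[complete], np.flatnonzero(complete))
    for g in np.flatnonzero(~complete):
        rows = np.flatnonzero(finite[g])
        if rows.size < p + 1:
            continue
        _solve(rows, Y[g, rows][None, :], np.array([g]))
    return LinearFit(list(M.probe_ids), design, coef, s2, dfr, xtx_inv, ok)


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation


@dataclass(frozen=True)
class ModerationParams:
    """Scaled-F prior hyperparameters: prior df d0 (may be +inf) and prior
    variance s0_sq."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValidationError("d0 must be positive (or +inf)")
        if not (self.s0_sq > 0):
            raise ValidationError("s0_sq must be positive")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_moderation(s_sq: np.ndarray, d) -> ModerationParams:
    """Method-of-moments fit of the scaled-F prior on log variances.

    With z = log(s_g^2), E[z] = log(s0^2) + digamma(d/2) - log(d/2)
    - (digamma(d0/2) - log(d0/2)) and Var[z] = trigamma(d/2) +
    trigamma(d0/2); matching the sample mean and variance of z yields
    closed-form estimates.  When the excess of Var[z] beyond the
    trigamma(d/2) term is <= 0, d0 = +inf and the prior is a point mass.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    d = np.broadcast_to(np.asarray(d, dtype=float), s_sq.shape)
    use = np.isfinite(s_sq) & (d > 0)
    s_sq, d = s_sq[use], d[use]
    if s_sq.size < 10:
        raise ValidationError("need >= 10 probes with positive residual df")
    if np.all(s_sq <= 0):
        raise ValidationError("all residual variances are zero; moderation undefined")
    pos = s_sq > 0
    s_sq, d = s_sq[pos], d[pos]

    z = np.log(s_sq)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    n = e.size
    evar = ((e - emean) ** 2).sum() / (n - 1) - special.polygamma(1, d / 2.0).mean()
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return ModerationParams(d0=d0, s0_sq=s0_sq)


class ModeratedT(NamedTuple):
    t_mod: np.ndarray
    df_total: np.ndarray
    p_value: np.ndarray


def moderated_t(
    contrast_coef,
    unscaled_stdev,
    s_g_sq,
    d_g,
    params: ModerationParams,
) -> ModeratedT:
    """Moderated t-statistic with posterior variance
    s~^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g) and df d0 + d_g.

    d0 = 0 is accepted as the no-moderation limit (ordinary t);
    d0 = +inf gives s~^2 = s0^2 with normal-reference p-values.
    """
    coef = np.atleast_1d(np.asarray(contrast_coef, dtype=float))
    su = np.atleast_1d(np.asarray(unscaled_stdev, dtype=float))
    s2 = np.atleast_1d(np.asarray(s_g_sq, dtype=float))
    dg = np.atleast_1d(np.asarray(d_g, dtype=float))
    d0, s0 = params.d0, params.s0_sq
    if math.isinf(d0):
        post = np.full_like(s2, s0)
        df_total = np.full_like(s2, np.inf)
    elif d0 == 0:
        post = s2.copy()
        df_total = dg.astype(float)
    else:
        post = (d0 * s0 + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / (su * np.sqrt(post))
    t = np.where(coef == 0.0, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isfinite(t), p, np.nan)
    return ModeratedT(t, df_total, p)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaNs pass through (treated as untested); finite values must be in [0,1].
    The adjusted value is attached to the original position, so the result
    is invariant under permutation of the input.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    q = p[mask]
    if q.size == 0:
        return out
    if q.min() < 0.0 or q.max() > 1.0:
        raise ValueError("p-values must lie in [0, 1]")
    n = q.size
    order = np.argsort(q, kind="stable")
    ranked = q[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(n)
    res[order] = adj
    out[mask] = res
    return out


# ---------------------------------------------------------------------------
# High-level model and DMC calling


@dataclass
class DiffMethResult:
    """Per-probe differential methylation statistics for one contrast.

    ``table`` columns: mean_beta_a, mean_beta_b, logFC (difference of
    group-average M-values), delta_beta, t_mod, p_value, adj_p, df_total.
    """

    group_a: str
    group_b: str
    table: pd.DataFrame

    def write(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def read(cls, path: str | Path, group_a: str = "a", group_b: str = "b") -> "DiffMethResult":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
        return cls(group_a, group_b, df)


class MethylationModel:
    """One covariate-adjusted linear model over several sample groups,
    exposing moderated contrasts between any two of them.

    The model is fitted once on M-values (adjusting for the requested
    covariates); moderation hyperparameters are estimated across probes
    from the pooled residual variances, and every contrast reuses them —
    so e.g. the CIMP-vs-nonCIMP comparison is a third contrast of the same
    fit that produced both cancer-vs-normal comparisons.
    """

    def __init__(
        self,
        beta: ProbeMatrix,
        sheet: SampleSheet,
        groups: Sequence[str],
        covariates: Sequence[str] = ("location", "batch"),
        epsilon: float = 1e-6,
    ) -> None:
        if beta.scale != "beta":
            raise ValidationError("MethylationModel expects a beta-scale matrix")
        self.groups = list(groups)
        self.design = build_design(sheet, groups, covariates)
        self.beta = beta.subset(samples=self.design.sample_ids)
        self.sheet = sheet.subset(self.design.sample_ids)
        self.epsilon = epsilon
        M = ProbeMatrix(
            self.beta.probe_ids,
            self.beta.sample_ids,
            beta_to_m(self.beta.values, epsilon),
            "mvalue",
        )
        self.fit = fit_linear_models(M, self.design)
        self._M = M
        self.moderation = estimate_moderation(self.fit.s2[self.fit.ok], self.fit.df_resid[self.fit.ok])
        self._group_cols = {
            g: self.beta.sample_index(self.sheet.samples_in_group(g)) for g in groups
        }

    def _group_means(self, values: np.ndarray, group: str) -> np.ndarray:
        cols = self._group_cols[group]
        with np.errstate(invalid="ignore"):
            return np.nanmean(values[:, cols], axis=1)

    def contrast(self, group_a: str, group_b: str) -> DiffMethResult:
        """Moderated statistics for group_a vs group_b.

        logFC is the raw difference of group-average M-values and
        delta_beta the difference of group-average beta values (probe-wise
        complete cases); t/p come from the covariate-adjusted model
        contrast with squeezed variances.
        """
        c = self.design.contrast(group_a, group_b)
        coef, su = self.fit.contrast_stats(c)
        t, df_total, p = moderated_t(coef, su, self.fit.s2, self.fit.df_resid, self.moderation)
        bad = ~self.fit.ok
        t, p = t.copy(), p.copy()
        t[bad] = np.nan
        p[bad] = np.nan
        mean_a = self._group_means(self.beta.values, group_a)
        mean_b = self._group_means(self.beta.values, group_b)
        m_a = self._group_means(self._M.values, group_a)
        m_b = self._group_means(self._M.values, group_b)
        table = pd.DataFrame(
            {
                "mean_beta_a": mean_a,
                "mean_beta_b": mean_b,
                "logFC": m_a - m_b,
                "delta_beta": mean_a - mean_b,
                "t_mod": t,
                "p_value": p,
                "adj_p": bh_adjust(p),
                "df_total": df_total,
            },
            index=pd.Index(self.beta.probe_ids, name="probe_id"),
        )
        return DiffMethResult(group_a, group_b, table)


class DmcCalls(NamedTuple):
    hyper: set[str]
    hypo: set[str]
    n_excluded_missing: int


def call_dmc(
    result: DiffMethResult,
    adj_p_max: float = 1e-4,
    abs_logfc_min: float = 2.0,
    abs_dbeta_min: float = 0.10,
) -> DmcCalls:
    """Threshold-based DMC calling with strict inequalities.

    hyper: adj_p < adj_p_max AND logFC > abs_logfc_min AND
    delta_beta > abs_dbeta_min; hypo is the sign-negated rule.  Probes with
    missing statistics are excluded from both sets.
    """
    if not (adj_p_max > 0 and abs_logfc_min > 0 and abs_dbeta_min > 0):
        raise ValueError("thresholds must be positive")
    t = result.table
    usable = t[["adj_p", "logFC", "delta_beta"]].notna().all(axis=1)
    sig = usable & (t["adj_p"] < adj_p_max)
    hyper = sig & (t["logFC"] > abs_logfc_min) & (t["delta_beta"] > abs_dbeta_min)
    hypo = sig & (t["logFC"] < -abs_logfc_min) & (t["delta_beta"] < -abs_dbeta_min)
    return DmcCalls(
        set(t.index[hyper]), set(t.index[hypo]), int((~usable).sum())
    )


def call_dmc_replicate_consistent(
    delta_beta_per_replicate: pd.DataFrame,
    abs_dbeta_min: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Replicate-consistent DMC rule for noisy paired designs: a probe is
    hyper if delta-beta exceeds the threshold in *every* replicate, hypo if
    it falls below the negated threshold in every replicate."""
    df = delta_beta_per_replicate
    if df.shape[1] < 2:
        raise ValueError("need >= 2 replicates")
    hyper = df.gt(abs_dbeta_min).all(axis=1)
    hypo = df.lt(-abs_dbeta_min).all(axis=1)
    return set(df.index[hyper]), set(df.index[hypo])
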