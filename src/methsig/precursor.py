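"""Paired lesion-vs-normal delta-beta analysis and methylation-expression
correlation.

Precursor lesions (tubular adenomas, sessile serrated adenomas/polyps) and
cancers are compared with matched normal mucosa on the same platform: per
CpG, the signed within-pair beta difference is averaged over pairs, and the
median over a CpG signature summarizes how far along the hypermethylation
trajectory a lesion group has moved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aging_lifestyle import wilcoxon_rank_sum
from .core_io import ProbeMatrix, SampleSheet, ValidationError


@dataclass
class PairedDelta:
    """Per-probe mean over pairs of (lesion beta - paired normal beta)."""

    lesion_group: str
    data: pd.DataFrame  # columns: mean_delta, n_pairs; indexed by probe
    signature_label: str | None = None

    @property
    def deltas(self) -> pd.Series:
        return self.data["mean_delta"].dropna()

    def write(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "lesion_group", self.lesion_group)
        out.insert(1, "signature_label", self.signature_label or "NA")
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t", na_rep="NA")


class MedianShiftResult(NamedTuple):
    median: float
    p_value: float


def paired_delta_beta(
    beta: ProbeMatrix,
    sheet: SampleSheet,
    lesion_group: str,
    probes: Iterable[str] | None = None,
    signature_label: str | None = None,
) -> PairedDelta:
    """Mean within-pair delta-beta per probe over all complete pairs of a
    lesion group (complete = both members non-missing for that probe)."""
    pairs = [
        (l, n) for l, n in sheet.pairs(lesion_group)
        if l in set(beta.sample_ids) and n in set(beta.sample_ids)
    ]
    if not pairs:
        raise ValidationError(f"no complete {lesion_group} <-> paired_normal pairs")
    probe_list = list(probes) if probes is not None else list(beta.probe_ids)
    rows = beta.probe_index(probe_list)
    lesion_idx = beta.sample_index([l for l, _ in pairs])
    normal_idx = beta.sample_index([n for _, n in pairs])
    diff = beta.values[np.ix_(rows, lesion_idx)] - beta.values[np.ix_(rows, normal_idx)]
    n_pairs = np.isfinite(diff).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_delta = np.nanmean(diff, axis=1)
    mean_delta = np.where(n_pairs >= 1, mean_delta, np.nan)
    return PairedDelta(
        lesion_group,
        pd.DataFrame({"mean_delta": mean_delta, "n_pairs": n_pairs}, index=probe_list),
        signature_label,
    )


def group_delta_vs_reference(
    beta: ProbeMatrix,
    sheet: SampleSheet,
    group: str,
    reference_group: str = "HNM",
    probes: Iterable[str] | None = None,
) -> pd.Series:
    """Unpaired per-probe delta: mean beta of a group minus the mean of a
    reference group (used where no matched normals exist)."""
    probe_list = list(probes) if probes is not None else list(beta.probe_ids)
    rows = beta.probe_index(probe_list)
    g_idx = beta.sample_index(sheet.samples_in_group(group))
    r_idx = beta.sample_index(sheet.samples_in_group(reference_group))
    if g_idx.size == 0 or r_idx.size == 0:
        raise ValidationError("both groups must have samples in the matrix")
    with np.errstate(invalid="ignore"):
        delta = np.nanmean(beta.values[np.ix_(rows, g_idx)], axis=1) - np.nanmean(
            beta.values[np.ix_(rows, r_idx)], axis=1
        )
    return pd.Series(delta, index=probe_list, name=f"{group}_vs_{reference_group}")


def median_shift_test(
    deltas_a: Sequence[float], deltas_b: Sequence[float] | None = None
) -> MedianShiftResult:
    """Median of a delta vector with a rank-sum p-value against either a
    second delta vector or (when omitted) a zero reference of equal size."""
    a = np.asarray(deltas_a, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise ValidationError("empty delta vector")
    if deltas_b is None:
        b = np.zeros_like(a)
    else:
        b = np.asarray(deltas_b, dtype=float)
        b = b[np.isfinite(b)]
        if b.size == 0:
            raise ValidationError("empty comparison vector")
    res = wilcoxon_rank_sum(a, b)
    return MedianShiftResult(float(np.median(a)), res.p_two_sided)


class CorrelationResult(NamedTuple):
    pearson_r: float
    p_value: float
    n_genes: int
    undefined: bool


def meth_expr_corr(
    methylation: pd.Series,
    expression: pd.Series,
    gene_map: dict[str, Iterable[str]] | None = None,
    probe_level: pd.Series | None = None,
) -> CorrelationResult:
    """Pearson correlation between per-gene methylation and expression.

    Either pass per-gene methylation summaries directly (``methylation``
    indexed by gene), or a probe-level series plus ``gene_map``
    (gene -> probes); gene-level methylation is then the unweighted mean
    over the gene's signature probes.
    """
    if gene_map is not None:
        if probe_level is None:
            probe_level = methylation
        rows = {}
        for gene, probes in gene_map.items():
            vals = probe_level.reindex(list(probes)).dropna()
            if len(vals):
                rows[gene] = vals.mean()
        methylation = pd.Series(rows)
    joined = pd.concat([methylation.rename("meth"), expression.rename("expr")], axis=1).dropna()
    if len(joined) < 3:
        raise ValidationError("need >= 3 mapped genes for correlation")
    if joined["meth"].nunique() == 1 or joined["expr"].nunique() == 1:
        return CorrelationResult(float("nan"), float("nan"), len(joined), True)
    r, p = stats.pearsonr(joined["meth"], joined["expr"])
    return CorrelationResult(float(r), float(p), len(joined), False)
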