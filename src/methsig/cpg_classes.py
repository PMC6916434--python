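"""Assembly of CIMP-CpG and CC-neutral-CpG signatures, plus set enrichment.

The two cancer-vs-healthy-mucosa comparisons yield two hypermethylated CpG
sets.  Their Venn partition (nonCIMP-specific / CIMP-specific / common) is
refined by a reallocation rule: a commonly hypermethylated CpG that is
significantly more methylated in CIMP than in nonCIMP cancers (p < 0.01
and delta-beta > 10%) counts as CIMP-specific.  The final signatures are

* CIMP-CpG = CIMP-specific  ∪  reallocated common CpGs
* CCN-CpG  = nonCIMP-specific  ∪  remaining common CpGs

so every hypermethylated CpG is classified exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

from .core_io import ValidationError

SIGNATURE_LABELS = (
    "CIMP_CpG",
    "CCN_CpG",
    "nonCIMP_specific",
    "CIMP_specific",
    "common",
    "common_reallocated",
)


@dataclass(frozen=True)
class CpGSignature:
    """A labeled probe set with the provenance of the rule that produced it."""

    label: str
    probes: frozenset[str]
    rule_provenance: str

    def __post_init__(self) -> None:
        if self.label not in SIGNATURE_LABELS:
            raise ValidationError(f"unknown signature label {self.label!r}")

    def __len__(self) -> int:
        return len(self.probes)

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for p in sorted(self.probes):
                fh.write(f"{p}\n")


def write_signature_table(signatures: Iterable[CpGSignature], path: str | Path) -> None:
    rows = [
        {"probe_id": p, "label": sig.label, "rule_provenance": sig.rule_provenance}
        for sig in signatures
        for p in sorted(sig.probes)
    ]
    pd.DataFrame(rows, columns=["probe_id", "label", "rule_provenance"]).to_csv(
        path, sep="\t", index=False
    )


class HyperPartition(NamedTuple):
    nonCIMP_specific: frozenset[str]
    CIMP_specific: frozenset[str]
    common: frozenset[str]


def partition_hyper_sets(hyper_nonCIMP: Iterable[str], hyper_CIMP: Iterable[str]) -> HyperPartition:
    """Venn partition of the two hypermethylated sets into specific / common."""
    a, b = frozenset(hyper_nonCIMP), frozenset(hyper_CIMP)
    common = a & b
    return HyperPartition(a - common, b - common, common)


def reallocate_common(
    common: Iterable[str],
    cimp_vs_noncimp_stats: pd.DataFrame,
    p_max: float = 0.01,
    dbeta_min: float = 0.10,
) -> frozenset[str]:
    """Common CpGs significantly more methylated in CIMP than nonCIMP cancers.

    ``cimp_vs_noncimp_stats`` must carry columns ``p_value`` and
    ``delta_beta`` (CIMP minus nonCIMP, from the moderated contrast of the
    same fitted model), indexed by probe id, for every common probe.
    Unadjusted p is used, matching the strictly per-probe reallocation rule.
    """
    common = frozenset(common)
    missing = common - set(cimp_vs_noncimp_stats.index)
    if missing:
        raise ValidationError(f"stats missing for {len(missing)} common probes")
    sub = cimp_vs_noncimp_stats.loc[sorted(common)]
    if sub[["p_value", "delta_beta"]].isna().any().any():
        raise ValidationError("NaN statistics for some common probes")
    keep = (sub["p_value"] < p_max) & (sub["delta_beta"] > dbeta_min)
    return frozenset(sub.index[keep])


def assemble_signatures(
    partition: HyperPartition, common_reallocated: Iterable[str]
) -> tuple[CpGSignature, CpGSignature]:
    """Build the final disjoint CIMP-CpG and CCN-CpG signatures."""
    realloc = frozenset(common_reallocated)
    if not realloc <= partition.common:
        raise ValidationError("reallocated probes must be a subset of the common set")
    cimp = CpGSignature(
        "CIMP_CpG",
        partition.CIMP_specific | realloc,
        "hyper in CIMP-CC vs HNM only, or common and significantly more methylated in CIMP",
    )
    ccn = CpGSignature(
        "CCN_CpG",
        partition.nonCIMP_specific | (partition.common - realloc),
        "hyper in nonCIMP-CC vs HNM only, or common without CIMP excess",
    )
    assert not (cimp.probes & ccn.probes)
    return cimp, ccn


# ---------------------------------------------------------------------------
# Fisher exact enrichment


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 overlap table [[n11, n10], [n01, n00]] with sample odds ratio and
    two-sided Fisher exact p."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float


def fisher_exact_two_sided(n11: int, n10: int, n01: int, n00: int) -> float:
    """Two-sided Fisher exact p by margin-fixed hypergeometric summation.

    Computed in exact integer arithmetic: with row margin r = n11 + n10,
    column margin c = n11 + n01 and total N, every table with the same
    margins has probability C(r, k) C(N-r, c-k) / C(N, c); the two-sided p
    sums all tables no more probable than the observed one.
    """
    if min(n11, n10, n01, n00) < 0:
        raise ValueError("table counts must be nonnegative")
    N = n11 + n10 + n01 + n00
    if N == 0:
        return 1.0
    r = n11 + n10
    c = n11 + n01
    k_min = max(0, c - (N - r))
    k_max = min(r, c)
    weights = [comb(r, k) * comb(N - r, c - k) for k in range(k_min, k_max + 1)]
    observed = weights[n11 - k_min]
    numer = sum(w for w in weights if w <= observed)
    return float(numer / comb(N, c))


def odds_ratio(n11: int, n10: int, n01: int, n00: int) -> float:
    """Sample (cross-product) odds ratio, with Haldane-Anscombe +0.5 added
    to every cell when any cell is zero."""
    cells = [n11, n10, n01, n00]
    if min(cells) == 0:
        n11, n10, n01, n00 = (x + 0.5 for x in cells)
    return (n11 * n00) / (n10 * n01)


def enrichment_or(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> EnrichmentResult:
    """Overlap enrichment of two probe sets within a common universe."""
    a, b, u = set(set_a), set(set_b), set(universe)
    if not u:
        raise ValidationError("universe must be nonempty")
    if not (a <= u and b <= u):
        raise ValidationError("set_a and set_b must be subsets of the universe")
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(u) - n11 - n10 - n01
    return EnrichmentResult(
        table=((n11, n10), (n01, n00)),
        odds_ratio=odds_ratio(n11, n10, n01, n00),
        p_value=fisher_exact_two_sided(n11, n10, n01, n00),
    )


def write_enrichment(results: dict[str, EnrichmentResult], path: str | Path) -> None:
    rows = []
    for name, res in results.items():
        (n11, n10), (n01, n00) = res.table
        rows.append(
            {
                "comparison": name,
                "n11": n11,
                "n10": n10,
                "n01": n01,
                "n00": n00,
                "odds_ratio": res.odds_ratio,
                "p_value": res.p_value,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
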