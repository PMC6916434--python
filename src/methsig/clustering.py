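"""Recursively partitioned beta-mixture clustering of methylation profiles.

Samples are clustered on their beta-value profiles over the most variable
CpGs (across-sample SD above a threshold).  The node model is a mixture of
beta distributions: within a component, probes are treated as independent
beta variables sharing the sample's component assignment, with
per-component per-probe means and a per-component precision pooled across
probes (mean/precision parameterization: Beta(mu*phi, (1-mu)*phi)).
Pooling the precision keeps the parameter count manageable at small
leaves.

A node is split into two children when the Bayesian information criterion
prefers the two-component mixture over the one-component fit and both
children meet the minimum leaf size; recursion is depth-bounded.  EM uses
a safeguarded M-step (moment update followed by Newton refinement, with
step halving) so the log-likelihood is nondecreasing at every iteration.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core_io import ProbeMatrix, SampleSheet, ValidationError
from .cpg_classes import EnrichmentResult, enrichment_or

CLAMP = 1e-3  # beta values clamped to (CLAMP, 1-CLAMP) before likelihoods


def select_variable_probes(beta: ProbeMatrix, sd_min: float = 0.16) -> list[str]:
    """Probes whose across-sample SD (complete cases, ddof=1) strictly
    exceeds ``sd_min``."""
    if beta.n_samples < 2:
        raise ValidationError("need >= 2 samples to rank variability")
    with np.errstate(invalid="ignore"):
        sd = np.array(
            [np.std(row[np.isfinite(row)], ddof=1) if np.isfinite(row).sum() >= 2 else 0.0
             for row in beta.values]
        )
    return [p for p, s in zip(beta.probe_ids, sd) if s > sd_min]


# ---------------------------------------------------------------------------
# Beta mixture EM


@dataclass
class BetaMixtureModel:
    k: int
    weights: np.ndarray          # (k,)
    means: np.ndarray            # (k, J)
    precisions: np.ndarray       # (k,)
    loglik: float
    converged: bool
    n_iter: int
    responsibilities: np.ndarray  # (n, k)

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValidationError("mixture weights must sum to 1")
        if (self.precisions <= 0).any() or (self.means <= 0).any() or (self.means >= 1).any():
            raise ValidationError("beta shapes must be positive")

    def bic(self, n: int) -> float:
        """-2 loglik + p log n with p = k (J + 1) + (k - 1) free parameters
        (per component: J means + 1 pooled precision; plus mixing weights)."""
        J = self.means.shape[1]
        p = self.k * (J + 1) + (self.k - 1)
        return -2.0 * self.loglik + p * np.log(n)

    def labels(self) -> np.ndarray:
        return self.responsibilities.argmax(axis=1)


def _clamp(X: np.ndarray) -> np.ndarray:
    return np.clip(X, CLAMP, 1.0 - CLAMP)


def _component_logdens(X: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Per-sample log density under one component (sum over probes)."""
    a = mu * phi
    b = (1.0 - mu) * phi
    return ((a - 1.0) * np.log(X) + (b - 1.0) * np.log1p(-X) - special.betaln(a, b)).sum(axis=1)


def _total_loglik(X, weights, means, precisions):
    k = len(weights)
    L = np.column_stack(
        [np.log(weights[c]) + _component_logdens(X, means[c], precisions[c]) for c in range(k)]
    )
    return float(special.logsumexp(L, axis=1).sum()), L


def _weighted_mle(X: np.ndarray, w: np.ndarray, mu0: np.ndarray, phi0: float,
                  newton_iters: int = 3) -> tuple[np.ndarray, float]:
    """Weighted beta MLE candidate: moment start, Newton refinement.

    Means solve psi(mu phi) - psi((1-mu) phi) = weighted mean logit of the
    data; the pooled precision solves the phi score equation.  Used as an
    M-step proposal; monotonicity is enforced by the caller's line search.
    """
    W = w.sum()
    if W <= 0:
        return mu0, phi0
    xbar = (w @ X) / W
    v = (w @ (X - xbar) ** 2) / W
    mu = np.clip(xbar, 1e-4, 1.0 - 1e-4)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = v.sum()
        phi = (mu * (1.0 - mu)).sum() / denom - 1.0 if denom > 0 else phi0
    if not np.isfinite(phi):
        phi = phi0
    phi = float(np.clip(phi, 0.5, 1e6))
    lx = (w @ np.log(X)) / W
    l1x = (w @ np.log1p(-X)) / W
    for _ in range(newton_iters):
        f = special.digamma(mu * phi) - special.digamma((1.0 - mu) * phi) - (lx - l1x)
        fp = phi * (special.polygamma(1, mu * phi) + special.polygamma(1, (1.0 - mu) * phi))
        mu = np.clip(mu - f / fp, 1e-4, 1.0 - 1e-4)
        g = (
            mu * lx
            + (1.0 - mu) * l1x
            - mu * special.digamma(mu * phi)
            - (1.0 - mu) * special.digamma((1.0 - mu) * phi)
            + special.digamma(phi)
        ).sum()
        gp = (
            -(mu**2) * special.polygamma(1, mu * phi)
            - (1.0 - mu) ** 2 * special.polygamma(1, (1.0 - mu) * phi)
            + special.polygamma(1, phi)
        ).sum()
        step = g / gp
        if np.isfinite(step):
            phi = float(np.clip(phi - step, 0.5, 1e6))
    return mu, phi


def _em(X, resp0, tol, max_iter):
    n, J = X.shape
    k = resp0.shape[1]
    resp = resp0
    weights = resp.mean(axis=0)
    means = np.empty((k, J))
    precisions = np.empty(k)
    for c in range(k):
        means[c], precisions[c] = _weighted_mle(X, resp[:, c], X.mean(axis=0), 10.0)
    loglik, L = _total_loglik(X, weights, means, precisions)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        resp = np.exp(L - special.logsumexp(L, axis=1, keepdims=True))
        # M-step proposal with line-search safeguard (generalized EM)
        new_w = np.clip(resp.mean(axis=0), 1e-12, None)
        new_w /= new_w.sum()
        new_means = means.copy()
        new_prec = precisions.copy()
        for c in range(k):
            new_means[c], new_prec[c] = _weighted_mle(X, resp[:, c], means[c], precisions[c])
        step = 1.0
        while True:
            w_t = (1 - step) * weights + step * new_w
            m_t = (1 - step) * means + step * new_means
            p_t = (1 - step) * precisions + step * new_prec
            cand, L_cand = _total_loglik(X, w_t, m_t, p_t)
            if cand >= loglik - 1e-9 or step < 1e-4:
                break
            step /= 2.0
        if step < 1e-4 and cand < loglik:
            converged = True
            break
        assert cand >= loglik - 1e-9, "EM log-likelihood decreased"
        delta = cand - loglik
        weights, means, precisions, loglik, L = w_t, m_t, p_t, cand, L_cand
        if delta < tol:
            converged = True
            break
    resp = np.exp(L - special.logsumexp(L, axis=1, keepdims=True))
    return BetaMixtureModel(k, weights, means, precisions, loglik, converged, it, resp)


def fit_beta_mixture(
    values: np.ndarray,
    k: int,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    n_restarts: int = 5,
    init_labels: np.ndarray | None = None,
) -> BetaMixtureModel:
    """Fit a k-component (k in {1, 2}) beta mixture to sample profiles.

    ``values`` is samples x probes in (0, 1) after clamping.  For k = 2 a
    multi-start strategy is used: one k-means-style initialization on the
    sample profiles plus random-assignment restarts; the best
    log-likelihood wins.  Deterministic given ``seed``.
    """
    if k not in (1, 2):
        raise ValidationError("k must be 1 or 2")
    X = _clamp(np.asarray(values, dtype=float))
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValidationError("values must be a nonempty samples x probes array")
    n = X.shape[0]
    if k == 1 or n < 2:
        return _em(X, np.ones((n, 1)), tol, max_iter)

    rng = np.random.default_rng(seed)
    inits: list[np.ndarray] = []
    if init_labels is not None:
        inits.append(np.asarray(init_labels, dtype=int))
    else:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=2, n_init=3, random_state=int(rng.integers(2**31)))
        inits.append(km.fit_predict(X))
    for _ in range(max(0, n_restarts - 1)):
        inits.append(rng.integers(0, 2, size=n))
    best: BetaMixtureModel | None = None
    for lab in inits:
        resp0 = np.full((n, 2), 0.1)
        resp0[np.arange(n), lab % 2] = 0.9
        model = _em(X, resp0, tol, max_iter)
        if best is None or model.loglik > best.loglik:
            best = model
    return best


# ---------------------------------------------------------------------------
# Recursive partitioning


@dataclass
class ClusterNode:
    id: str
    parent: str | None
    sample_ids: list[str]
    split_score: float | None = None  # BIC(k=1) - BIC(k=2) for accepted splits
    children: list[str] = field(default_factory=list)


@dataclass
class ClusterTree:
    nodes: dict[str, ClusterNode]

    @property
    def root(self) -> ClusterNode:
        return self.nodes["r"]

    @property
    def leaves(self) -> list[ClusterNode]:
        return [nd for nd in self.nodes.values() if not nd.children]

    def assignments(self) -> pd.Series:
        out = {}
        for leaf in self.leaves:
            for s in leaf.sample_ids:
                out[s] = leaf.id
        return pd.Series(out, name="leaf").sort_index()

    def to_json(self, path: str | Path) -> None:
        payload = {
            nid: {
                "parent": nd.parent,
                "samples": nd.sample_ids,
                "split_score": nd.split_score,
                "children": nd.children,
            }
            for nid, nd in sorted(self.nodes.items())
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    def to_newick(self) -> str:
        def rec(nid: str) -> str:
            nd = self.nodes[nid]
            if not nd.children:
                return f"{nid}"
            return "(" + ",".join(rec(c) for c in nd.children) + f"){nid}"

        return rec("r") + ";"

    def write_assignments(self, path: str | Path) -> None:
        df = self.assignments().rename_axis("sample_id").reset_index()
        df.to_csv(path, sep="\t", index=False)


def rpmm_cluster(
    beta: ProbeMatrix,
    min_leaf: int = 5,
    max_depth: int = 4,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ClusterTree:
    """Recursive binary beta-mixture splitting of samples.

    At each node, one- and two-component mixtures are fitted over the
    node's samples; the node splits iff BIC(k=2) < BIC(k=1) and both
    children have >= min_leaf samples.  Sample order does not affect the
    partition: profiles are processed in sorted-sample-id order and seeds
    are derived from the node path.
    """
    order = sorted(range(beta.n_samples), key=lambda i: beta.sample_ids[i])
    sample_ids = [beta.sample_ids[i] for i in order]
    X = _clamp(np.nan_to_num(beta.values.T[order], nan=0.5))
    nodes: dict[str, ClusterNode] = {}

    def grow(nid: str, parent: str | None, idx: np.ndarray, depth: int) -> None:
        samples = [sample_ids[i] for i in idx]
        node = ClusterNode(nid, parent, samples)
        nodes[nid] = node
        if depth >= max_depth or idx.size < 2 * min_leaf:
            return
        sub = X[idx]
        node_seed = (seed * 1_000_003 + zlib.crc32(nid.encode()) % 65_521) % (2**31)
        m1 = fit_beta_mixture(sub, 1, tol=tol, max_iter=max_iter, seed=node_seed)
        m2 = fit_beta_mixture(sub, 2, tol=tol, max_iter=max_iter, seed=node_seed)
        score = m1.bic(idx.size) - m2.bic(idx.size)
        if score <= 0:
            return
        lab = m2.labels()
        left, right = idx[lab == 0], idx[lab == 1]
        if left.size < min_leaf or right.size < min_leaf:
            return
        node.split_score = float(score)
        node.children = [nid + "L", nid + "R"]
        grow(nid + "L", nid, left, depth + 1)
        grow(nid + "R", nid, right, depth + 1)

    grow("r", None, np.arange(len(sample_ids)), 0)
    return ClusterTree(nodes)


def ward_cluster(beta: ProbeMatrix, n_clusters: int) -> pd.Series:
    """Hierarchical alternative: Ward linkage on Euclidean beta distance."""
    X = np.nan_to_num(beta.values.T, nan=0.5)
    Z = hierarchy.ward(pdist(X))
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=beta.sample_ids, name="cluster")


def crosstab_clusters(
    tree: ClusterTree, sheet: SampleSheet, field_name: str
) -> tuple[pd.DataFrame, dict[tuple[str, str], EnrichmentResult]]:
    """Leaf x category contingency table plus per-(leaf, category) Fisher
    enrichment over the clustered samples."""
    if field_name not in sheet.data.columns:
        raise KeyError(f"unknown sample-sheet field {field_name!r}")
    assign = tree.assignments()
    meta = sheet.data.set_index("sample_id").loc[assign.index, field_name]
    table = pd.crosstab(assign, meta)
    universe = set(assign.index)
    enrich: dict[tuple[str, str], EnrichmentResult] = {}
    for leaf in table.index:
        leaf_samples = set(assign.index[assign == leaf])
        for cat in table.columns:
            cat_samples = set(meta.index[meta == cat])
            enrich[(leaf, str(cat))] = enrichment_or(leaf_samples, cat_samples, universe)
    return table, enrich
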