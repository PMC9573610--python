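"""Population-structure analysis of germplasm SNP panels.

Covers the standard desk stages applied after diversity screening:

* individual-level allele-sharing distances and group-level Nei (1972)
  standard genetic distance;
* UPGMA clustering with Newick output;
* principal coordinate analysis (PCoA) with per-axis contribution rates;
* a STRUCTURE-style admixture-model Gibbs sampler
  (:class:`AdmixtureModel`) producing admixture proportions Q and a
  log-likelihood trace;
* Evanno delta-K model selection over a range of cluster counts.

The sampler assumes the admixture model with independent per-cluster allele
frequencies: each allele copy of accession *i* originates from cluster *k*
with probability ``Q[i, k]`` and is then drawn from that cluster's
frequency vector.  Priors are Dirichlet(alpha) on each Q row and
Dirichlet(lambda) on each frequency vector; alpha is held fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from peaheat.divstats import GenotypeMatrix, allele_frequencies


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape must match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def allele_sharing_distance(matrix: GenotypeMatrix, markers: Sequence[str] | None = None) -> DistanceMatrix:
    """Individual-level distance d = 1 − shared alleles / (2 × markers compared).

    Per marker the shared-allele count between two genotypes is the multiset
    intersection of their allele pairs (2 for identical genotypes, 1 for one
    allele in common, 0 otherwise).  Pairs are compared over their mutually
    non-missing markers; a pair with no comparable marker gets a NaN
    distance (flagged missing).
    """
    if matrix.n_accessions < 2:
        raise ValueError("need ≥ 2 accessions")
    codes, _ = matrix.encoded(markers)
    codes = np.sort(codes, axis=2)          # unordered pairs → sorted codes
    n = codes.shape[0]
    ok = codes[:, :, 0] >= 0                # non-missing mask per (i, marker)
    d = np.zeros((n, n))
    for i in range(n):
        ai, bi = codes[i, :, 0], codes[i, :, 1]
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                d[i, j] = d[j, i] = np.nan
                continue
            aj, bj = codes[j, :, 0], codes[j, :, 1]
            ident = (ai == aj) & (bi == bj)
            common = (ai == aj) | (ai == bj) | (bi == aj) | (bi == bj)
            shared = np.where(ident, 2, np.where(common, 1, 0))[both].sum()
            d[i, j] = d[j, i] = 1.0 - shared / (2.0 * m)
    return DistanceMatrix(matrix.accession_ids, d)


def nei_distance(matrix: GenotypeMatrix, group_labels: Mapping[str, str],
                 markers: Sequence[str] | None = None) -> DistanceMatrix:
    """Nei (1972) standard genetic distance between groups of accessions.

    D = −ln( J_XY / sqrt(J_X · J_Y) ) with the J terms averaged over loci:
    J_X = mean_l Σ_a x_a², J_XY = mean_l Σ_a x_a y_a, from group allele
    frequencies.  Loci untyped in either group are skipped for that pair;
    a zero between-group identity gives an infinite distance (flagged by
    the ``inf`` value itself).
    """
    groups = sorted(set(group_labels.values()))
    if len(groups) < 2:
        raise ValueError("need ≥ 2 groups")
    if markers is None:
        markers = matrix.marker_ids
    # per-group allele frequency maps per marker (None where untyped)
    freqs: dict[str, list[dict[str, float] | None]] = {}
    for g in groups:
        accs = [a for a in matrix.accession_ids if group_labels.get(a) == g]
        sub = matrix.subset(accessions=accs)
        per_marker = []
        for m in markers:
            col = [p for p in sub.column(m) if p is not None]
            per_marker.append(allele_frequencies(col) if col else None)
        freqs[g] = per_marker
    k = len(groups)
    d = np.zeros((k, k))
    for x in range(k):
        for y in range(x + 1, k):
            jx = jy = jxy = 0.0
            n_loci = 0
            for fx, fy in zip(freqs[groups[x]], freqs[groups[y]]):
                if fx is None or fy is None:
                    continue
                n_loci += 1
                jx += sum(p * p for p in fx.values())
                jy += sum(p * p for p in fy.values())
                jxy += sum(fx[a] * fy.get(a, 0.0) for a in fx)
            if n_loci == 0:
                d[x, y] = d[y, x] = np.nan
                continue
            jx, jy, jxy = jx / n_loci, jy / n_loci, jxy / n_loci
            if jxy <= 0.0:
                d[x, y] = d[y, x] = np.inf
            else:
                d[x, y] = d[y, x] = -math.log(jxy / math.sqrt(jx * jy))
    return DistanceMatrix(groups, d)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    height: float
    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class UltrametricTree:
    """Rooted binary UPGMA tree; node heights are cophenetic half-distances."""

    root: TreeNode
    labels: list[str]

    def newick(self, precision: int = 6) -> str:
        def render(node: TreeNode, parent_height: float | None) -> str:
            if node.is_leaf:
                body = node.label
            else:
                body = "(" + ",".join(render(c, node.height) for c in node.children) + ")"
            if parent_height is None:
                return body
            return f"{body}:{parent_height - node.height:.{precision}f}"

        return render(self.root, None) + ";"

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise leaf distances implied by the tree (2 × join height)."""
        idx = {l: i for i, l in enumerate(self.labels)}
        n = len(self.labels)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> list[str]:
            if node.is_leaf:
                return [node.label]
            groups = [walk(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            d[idx[a], idx[b]] = d[idx[b], idx[a]] = 2.0 * node.height
            return [l for g in groups for l in g]

        walk(self.root)
        return DistanceMatrix(self.labels, d)

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        root_h = self.root.height

        def depth_ok(node: TreeNode) -> bool:
            if node.is_leaf:
                return abs(node.height) <= tol
            return all(c.height <= node.height + tol and depth_ok(c) for c in node.children)

        return depth_ok(self.root) and all(abs(l.height) <= tol for l in self.root.leaves()) and root_h >= -tol


def upgma(d: DistanceMatrix) -> UltrametricTree:
    """UPGMA agglomeration with size-weighted average linkage.

    At each step the pair of clusters at minimal distance joins at height
    d/2; the merged cluster's distance to the rest is the member-count
    weighted mean.  Ties break deterministically on the smallest pair of
    original leaf indices, so the output is invariant to the processing
    order of equal distances.
    """
    if np.isnan(d.values).any():
        raise ValueError("distance matrix contains missing entries")
    n = d.n
    if n < 2:
        raise ValueError("need ≥ 2 taxa")
    nodes = [TreeNode(0.0, label=l) for l in d.labels]
    sizes = [1] * n
    min_leaf = list(range(n))       # smallest original leaf index per cluster
    dist = d.values.astype(float).copy()
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                key = (dist[i, j], min(min_leaf[i], min_leaf[j]), max(min_leaf[i], min_leaf[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (_, _, _), i, j = best
        h = dist[i, j] / 2.0
        new = TreeNode(h, children=[nodes[i], nodes[j]])
        # weighted average linkage update, stored in slot i
        for k in active:
            if k in (i, j):
                continue
            dist[i, k] = dist[k, i] = (sizes[i] * dist[i, k] + sizes[j] * dist[j, k]) / (sizes[i] + sizes[j])
        nodes[i] = new
        sizes[i] += sizes[j]
        min_leaf[i] = min(min_leaf[i], min_leaf[j])
        active.remove(j)
    return UltrametricTree(root=nodes[active[0]], labels=list(d.labels))


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    labels: list[str]
    coordinates: np.ndarray        # samples × positive axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray        # all eigenvalues, descending
    contribution_rates: np.ndarray  # percent, over positive eigenvalues
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def pcoa(d: DistanceMatrix, eig_tol: float = 1e-10) -> PCoAResult:
    """Principal coordinate analysis by Gower double-centering.

    B = −½ J D² J is eigendecomposed; coordinates are eigenvectors scaled by
    the square root of their (positive) eigenvalues, and each positive
    axis's contribution rate is its eigenvalue share of the positive-part
    sum, in percent.
    """
    if np.isnan(d.values).any():
        raise ValueError("distance matrix contains missing entries")
    n = d.n
    d2 = d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = max(abs(evals[0]), 1.0) if evals.size else 1.0
    pos = evals > eig_tol * scale
    if not pos.any():
        return PCoAResult(d.labels, np.zeros((n, 0)), evals, np.zeros(0), degenerate=True)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    rates = 100.0 * evals[pos] / evals[pos].sum()
    return PCoAResult(d.labels, coords, evals, rates)


# ---------------------------------------------------------------------------
# admixture Gibbs sampler
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gibbs_kernel(codes, n_alleles, K, alpha, lam, burnin, reps, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    n, L, _ = codes.shape
    max_a = 0
    for l in range(L):
        if n_alleles[l] > max_a:
            max_a = n_alleles[l]
    Q = np.full((n, K), 1.0 / K)
    P = np.zeros((K, L, max_a))
    for k in range(K):
        for l in range(L):
            for a in range(n_alleles[l]):
                P[k, l, a] = 1.0 / n_alleles[l]
    q_sum = np.zeros((n, K))
    lnl_trace = np.empty(reps)
    probs = np.empty(K)
    for it in range(burnin + reps):
        counts_kla = np.zeros((K, L, max_a))
        counts_ik = np.zeros((n, K))
        lnl = 0.0
        for i in range(n):
            for l in range(L):
                for c in range(2):
                    a = codes[i, l, c]
                    if a < 0:
                        continue
                    tot = 0.0
                    for k in range(K):
                        pr = Q[i, k] * P[k, l, a]
                        probs[k] = pr
                        tot += pr
                    lnl += np.log(tot)
                    u = np.random.random() * tot
                    acc = 0.0
                    kk = K - 1
                    for k in range(K):
                        acc += probs[k]
                        if u <= acc:
                            kk = k
                            break
                    counts_kla[kk, l, a] += 1.0
                    counts_ik[i, kk] += 1.0
        for k in range(K):
            for l in range(L):
                s = 0.0
                for a in range(n_alleles[l]):
                    g = np.random.gamma(lam + counts_kla[k, l, a], 1.0)
                    P[k, l, a] = g
                    s += g
                for a in range(n_alleles[l]):
                    P[k, l, a] /= s
        for i in range(n):
            s = 0.0
            for k in range(K):
                g = np.random.gamma(alpha + counts_ik[i, k], 1.0)
                Q[i, k] = g
                s += g
            for k in range(K):
                Q[i, k] /= s
        if it >= burnin:
            lnl_trace[it - burnin] = lnl
            for i in range(n):
                for k in range(K):
                    q_sum[i, k] += Q[i, k]
    return q_sum / reps, lnl_trace


@dataclass
class AdmixtureResults:
    """Posterior summaries of one admixture-model run."""

    K: int
    seed: int
    labels: list[str]
    Q: np.ndarray                  # posterior-mean admixture proportions, canonical cluster order
    lnl_trace: np.ndarray          # post-burn-in per-iteration log-likelihood
    burnin: int
    reps: int

    @property
    def lnl_mean(self) -> float:
        return float(np.mean(self.lnl_trace))

    @property
    def L_est(self) -> float:
        """Deviance-style marginal-likelihood estimate: mean(lnL) − var(lnL)/2."""
        return float(np.mean(self.lnl_trace) - np.var(self.lnl_trace) / 2.0)

    def q_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Q, index=self.labels, columns=[f"Q{k + 1}" for k in range(self.K)])

    def summary(self) -> str:
        lines = [
            f"Admixture model, K = {self.K} (seed {self.seed})",
            f"MCMC: {self.burnin} burn-in + {self.reps} recorded iterations",
            f"mean lnL = {self.lnl_mean:.2f}   L_est = {self.L_est:.2f}",
            f"mean max membership = {float(np.max(self.Q, axis=1).mean()):.3f}",
        ]
        return "\n".join(lines)


def _canonical_cluster_order(q: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Order clusters by the first accession that reaches > threshold membership."""
    n, k = q.shape
    firsts = np.full(k, n, dtype=int)
    for kk in range(k):
        hits = np.nonzero(q[:, kk] > threshold)[0]
        if hits.size:
            firsts[kk] = hits[0]
    return np.argsort(firsts, kind="stable")


class AdmixtureModel:
    """STRUCTURE-style admixture model over a genotype panel.

    Parameters
    ----------
    matrix : GenotypeMatrix
    K : int
        Number of clusters (populations), ≥ 1 and ≤ number of accessions.
    alpha, lam : float
        Dirichlet prior parameters on admixture proportions and cluster
        allele frequencies.  alpha is fixed (no Metropolis update).
    marker_set : str, optional
        Restrict to one marker set (``NEUTRAL`` / ``HT_RELATED``).
    """

    def __init__(self, matrix: GenotypeMatrix, K: int, alpha: float = 1.0, lam: float = 1.0,
                 marker_set: str | None = None):
        if K < 1:
            raise ValueError("K must be ≥ 1")
        if K > matrix.n_accessions:
            raise ValueError("K cannot exceed the number of accessions")
        self.matrix = matrix
        self.K = K
        self.alpha = alpha
        self.lam = lam
        markers = matrix.markers_in_set(marker_set)
        codes, alleles = matrix.encoded(markers)
        self.codes = codes.astype(np.int8)
        self.n_alleles = np.array([max(len(a), 1) for a in alleles], dtype=np.int64)

    def fit(self, burnin: int = 2000, reps: int = 8000, seed: int = 0) -> AdmixtureResults:
        if reps < 1:
            raise ValueError("reps must be ≥ 1")
        q, trace = _gibbs_kernel(
            self.codes, self.n_alleles, self.K, float(self.alpha), float(self.lam),
            int(burnin), int(reps), int(seed) % (2**32),
        )
        order = _canonical_cluster_order(q)
        return AdmixtureResults(
            K=self.K, seed=seed, labels=self.matrix.accession_ids, Q=q[:, order],
            lnl_trace=trace, burnin=burnin, reps=reps,
        )


def admixture_gibbs(matrix: GenotypeMatrix, K: int, burnin: int = 2000, reps: int = 8000,
                    alpha: float = 1.0, lam: float = 1.0, seed: int = 0,
                    marker_set: str | None = None) -> AdmixtureResults:
    """Functional wrapper around :class:`AdmixtureModel`."""
    return AdmixtureModel(matrix, K, alpha=alpha, lam=lam, marker_set=marker_set).fit(
        burnin=burnin, reps=reps, seed=seed
    )


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

@dataclass
class EvannoTable:
    table: pd.DataFrame            # K, n_runs, mean_L, sd_L, L_prime, abs_L_second, delta_K
    optimal_K: int | None
    ambiguous: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        head = self.table.to_string(index=False, float_format=lambda v: f"{v:.3f}")
        tail = f"\noptimal K = {self.optimal_K}" + (" (ambiguous)" if self.ambiguous else "")
        return head + tail


def evanno_delta_k(runs: Sequence[AdmixtureResults]) -> EvannoTable:
    """Evanno et al. delta-K over replicate runs across a contiguous K range.

    L(K) is the mean of the run-level estimates ``L_est``; L′(K) and
    |L″(K)| are first and second differences; ΔK = |L″(K)| / sd(L_est at
    K), defined for interior K only.  The optimal K is the interior argmax
    of ΔK; an all-zero second difference (or undefined ΔK everywhere) is
    flagged ambiguous.
    """
    by_k: dict[int, list[float]] = {}
    for r in runs:
        by_k.setdefault(r.K, []).append(r.L_est)
    ks = sorted(by_k)
    if len(ks) < 3:
        raise ValueError("need ≥ 3 K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K range must be contiguous")
    for k in ks:
        if len(by_k[k]) < 2:
            raise ValueError(f"need ≥ 2 runs per K (K = {k})")
    mean_l = {k: float(np.mean(by_k[k])) for k in ks}
    sd_l = {k: float(np.std(by_k[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        lp = mean_l[k] - mean_l[k - 1] if k - 1 in mean_l else np.nan
        if k - 1 in mean_l and k + 1 in mean_l:
            ls = abs((mean_l[k + 1] - mean_l[k]) - (mean_l[k] - mean_l[k - 1]))
            dk = ls / sd_l[k] if sd_l[k] > 0 else np.nan
        else:
            ls, dk = np.nan, np.nan
        rows.append(
            {"K": k, "n_runs": len(by_k[k]), "mean_L": mean_l[k], "sd_L": sd_l[k],
             "L_prime": lp, "abs_L_second": ls, "delta_K": dk}
        )
    table = pd.DataFrame(rows)
    interior = table.dropna(subset=["delta_K"])
    if interior.empty or np.allclose(interior["delta_K"], 0.0):
        return EvannoTable(table, optimal_K=None, ambiguous=True)
    best = interior.loc[interior["delta_K"].idxmax()]
    return EvannoTable(table, optimal_K=int(best["K"]))


# ---------------------------------------------------------------------------
# subpopulation assignment
# ---------------------------------------------------------------------------

def assign_subpopulations(result: AdmixtureResults, threshold: float = 0.5,
                          metadata: pd.DataFrame | None = None) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Assign each accession to its argmax cluster and cross-tabulate.

    Accessions whose maximum membership does not exceed ``threshold`` (or
    that tie between clusters) are flagged admixed; ties break to the
    lowest cluster index.  When ``metadata`` (indexed or keyed by
    ``accession``) is given, composition cross-tabs (counts) are returned
    for each of its categorical columns.
    """
    q = result.Q
    cluster = np.argmax(q, axis=1)
    max_q = q[np.arange(q.shape[0]), cluster]
    ties = (q >= max_q[:, None] - 1e-12).sum(axis=1) > 1
    members = pd.DataFrame(
        {
            "accession": result.labels,
            "cluster": [f"SP{c + 1}" for c in cluster],
            "max_q": max_q,
            "admixed": (max_q < threshold) | ties,
        }
    )
    crosstabs: dict[str, pd.DataFrame] = {}
    if metadata is not None:
        meta = metadata.copy()
        if "accession" in meta.columns:
            meta = meta.set_index("accession")
        joined = members.join(meta, on="accession")
        for col in meta.columns:
            crosstabs[col] = pd.crosstab(joined["cluster"], joined[col])
    return members, crosstabs
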