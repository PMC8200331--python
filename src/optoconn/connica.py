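"""Connectome ICA: independent functional connectome components (FCCs).

Each subject's HbO and HbR connectomes (Fisher-z form) are vectorised — the
upper triangle in row-major (i < j) order — and concatenated into one row of
the group edge matrix

    [subjects] x [pairs x 2 chromophores]      (99 x 2070 at 46 channels).

FastICA is applied with subjects as features and edges as observations: the
sources are group-level edge patterns (the FCCs) and the mixing columns are
one weight per subject quantifying the component's prominence in that
individual.  The "hybrid" element is a multi-run recurrence filter: a
component is retained only when, across random restarts, a matching component
(|corr| with the cluster centrotype above ``retain_corr``) appears in at least
``retain_frac`` of runs.  Edge vectors are unit-normalised (weights absorb the
scale) and signed so that the mean of their top-decile edges is positive.

Group comparison runs one test per FCC on the subject weights: one-way F,
BH-FDR across the extracted components, JZS Bayes factor with evidence bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DataError
from .ica import icasso_iq, select_model_order
from .inference import bf_anova_jzs, classify_evidence, fdr_bh, oneway_anova_vec


@dataclass
class GroupEdgeMatrix:
    """Subjects x (pairs * 2 chromophores) edge matrix with pair bookkeeping."""

    X: np.ndarray
    n_channels: int

    def __post_init__(self):
        P = self.n_pairs
        if self.X.shape[1] != 2 * P:
            raise DataError(
                f"edge matrix has {self.X.shape[1]} columns; expected {2 * P} "
                f"for {self.n_channels} channels"
            )

    @property
    def n_pairs(self) -> int:
        return self.n_channels * (self.n_channels - 1) // 2

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def pairs(self) -> np.ndarray:
        i, j = np.triu_indices(self.n_channels, k=1)
        return np.column_stack([i, j])


def vectorize_connectome(M: np.ndarray) -> np.ndarray:
    """Upper triangle (i < j, row-major) of a symmetric matrix as a vector."""
    M = np.asarray(M, float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise DataError("connectome must be square")
    i, j = np.triu_indices(M.shape[0], k=1)
    return M[i, j]


def unvectorize_connectome(v: np.ndarray, n_channels: int, diagonal: float = 0.0):
    """Inverse of ``vectorize_connectome``; exact on symmetric input."""
    v = np.asarray(v, float)
    P = n_channels * (n_channels - 1) // 2
    if v.shape != (P,):
        raise DataError(f"edge vector must have length {P}, got {v.shape}")
    M = np.full((n_channels, n_channels), diagonal)
    i, j = np.triu_indices(n_channels, k=1)
    M[i, j] = v
    M[j, i] = v
    return M


def build_edge_matrix(connectome_pairs) -> GroupEdgeMatrix:
    """Assemble [upper-tri HbO z || upper-tri HbR z] rows across subjects."""
    rows = []
    n_channels = None
    for co, cr in connectome_pairs:
        if n_channels is None:
            n_channels = co.n_channels
        if co.n_channels != n_channels or cr.n_channels != n_channels:
            raise DataError("all subjects must share the channel count")
        rows.append(
            np.concatenate([vectorize_connectome(co.z), vectorize_connectome(cr.z)])
        )
    if not rows:
        raise DataError("no connectomes supplied")
    return GroupEdgeMatrix(X=np.vstack(rows), n_channels=n_channels)


@dataclass
class FunctionalConnectomeComponent:
    """One FCC: unit-norm edge vector, per-subject weights, stability metrics."""

    edges: np.ndarray  # (2 * pairs,)
    weights: np.ndarray  # (subjects,)
    iq: float
    chromophore_similarity: float
    retained: bool
    recurrence: float
    index: int

    def halves(self):
        P = self.edges.size // 2
        return self.edges[:P], self.edges[P:]


def _fix_sign(edges, weights):
    """Orient so the mean of the top-decile |edge| entries is positive."""
    k = max(1, int(np.ceil(0.10 * edges.size)))
    top = np.argsort(np.abs(edges))[-k:]
    if edges[top].mean() < 0:
        return -edges, -weights
    return edges, weights


def extract_fcc(
    edge_matrix,
    n_components: int,
    n_runs: int = 20,
    seed: int = 0,
    retain_corr: float = 0.75,
    retain_frac: float = 0.75,
    **ica_kw,
):
    """FCCs from the group edge matrix via multi-run FastICA with recurrence filter."""
    X = edge_matrix.X if isinstance(edge_matrix, GroupEdgeMatrix) else np.asarray(edge_matrix, float)
    n_sub, n_edges = X.shape
    if n_components > min(n_sub, n_edges):
        raise DataError(
            f"n_components={n_components} exceeds min(subjects, edges) = "
            f"{min(n_sub, n_edges)}"
        )
    rep = icasso_iq(
        X, n_components, n_runs=n_runs, seed=seed, store_sources=True, **ica_kw
    )
    P = n_edges // 2
    fccs = []
    for k in range(n_components):
        edges = rep.centrotype_sources[k].copy()
        weights = rep.centrotype_mixing[:, k].copy()
        norm = np.linalg.norm(edges)
        if norm > 0:
            edges /= norm
            weights *= norm
        edges, weights = _fix_sign(edges, weights)
        # recurrence: runs contributing a member matching the centrotype
        members = np.flatnonzero(rep.assignments == k + 1)
        cent_local = members[
            int(np.argmax(rep.similarity[np.ix_(members, members)].sum(axis=1)))
        ]
        matched = members[rep.similarity[cent_local, members] > retain_corr]
        rec = np.unique(rep.run_ids[matched]).size / n_runs
        cc = float(np.corrcoef(edges[:P], edges[P:])[0, 1])
        fccs.append(
            FunctionalConnectomeComponent(
                edges=edges,
                weights=weights,
                iq=float(rep.iq[k]),
                chromophore_similarity=cc,
                retained=bool(rec >= retain_frac),
                recurrence=float(rec),
                index=k,
            )
        )
    return fccs


def top_edges(
    fcc: FunctionalConnectomeComponent,
    n_channels: int,
    fraction: float = 0.10,
    positive_only: bool = True,
    chromophore: str = "HbO",
):
    """Largest positive edges of one chromophore half, with node degrees.

    Returns a DataFrame of the ceil(fraction * pairs) largest (positive)
    entries sorted descending, plus a per-node degree count; empty (with a
    warning) when no positive edges exist.
    """
    if not 0 < fraction <= 1:
        raise DataError("fraction must lie in (0, 1]")
    half_o, half_r = fcc.halves()
    v = half_o if chromophore == "HbO" else half_r
    i, j = np.triu_indices(n_channels, k=1)
    k = int(np.ceil(fraction * v.size))
    order = np.argsort(v)[::-1][:k]
    if positive_only:
        order = order[v[order] > 0]
    if order.size == 0:
        warnings.warn("no positive edges in component; empty top-edge list")
        return pd.DataFrame(columns=["ch_i", "ch_j", "weight"]), np.zeros(n_channels, int)
    degree = np.zeros(n_channels, int)
    for idx in order:
        degree[i[idx]] += 1
        degree[j[idx]] += 1
    table = pd.DataFrame({"ch_i": i[order], "ch_j": j[order], "weight": v[order]})
    return table, degree


def fcc_group_stats(
    fccs,
    group_labels,
    q: float = 0.05,
    compute_bf: bool = True,
    prior_scale: float = 0.5,
):
    """One test per FCC on subject weights; FDR family = the extracted FCCs."""
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise DataError("need at least 2 groups")
    if min((labels == g).sum() for g in uniq) < 2:
        raise DataError("every group needs at least 2 subjects")
    W = np.column_stack([f.weights for f in fccs])  # (subjects, K)
    groups = [W[labels == g] for g in uniq]
    F, p = oneway_anova_vec(groups, axis=0)
    mask, threshold = fdr_bh(p, q=q)
    rows = []
    for k, f in enumerate(fccs):
        row = {
            "fcc": f.index,
            "retained": f.retained,
            "iq": f.iq,
            "chromophore_similarity": f.chromophore_similarity,
            "F": F[k],
            "p": p[k],
            "fdr_significant": bool(mask[k]),
        }
        if compute_bf:
            bf10, _ = bf_anova_jzs([g[:, k] for g in groups], prior_scale=prior_scale)
            row["bf10"] = bf10
            row["bf01"] = 1.0 / bf10
            row["evidence"] = classify_evidence(bf10).label
        rows.append(row)
    return pd.DataFrame(rows)


class ConnICA(BaseEstimator, TransformerMixin):
    """Connectome-ICA estimator over a subjects x edges matrix.

    ``fit`` extracts FCCs (model order from the PCA variance share unless
    given); fitted attributes: ``fccs_``, ``components_`` (K, edges),
    ``weights_`` (subjects, K), ``retained_``, ``iq_``.  ``transform`` projects
    new subject edge rows onto the fitted components by least squares.
    """

    def __init__(
        self,
        n_components=None,
        variance_target: float = 0.60,
        n_runs: int = 20,
        seed: int = 0,
        retain_corr: float = 0.75,
        retain_frac: float = 0.75,
        nonlinearity: str = "tanh",
        max_iter: int = 500,
        tol: float = 1e-6,
    ):
        self.n_components = n_components
        self.variance_target = variance_target
        self.n_runs = n_runs
        self.seed = seed
        self.retain_corr = retain_corr
        self.retain_frac = retain_frac
        self.nonlinearity = nonlinearity
        self.max_iter = max_iter
        self.tol = tol

    def _as_array(self, X):
        return X.X if isinstance(X, GroupEdgeMatrix) else np.asarray(X, float)

    def fit(self, X, y=None):
        A = self._as_array(X)
        n = self.n_components or select_model_order(A, self.variance_target)
        self.fccs_ = extract_fcc(
            A,
            n,
            n_runs=self.n_runs,
            seed=self.seed,
            retain_corr=self.retain_corr,
            retain_frac=self.retain_frac,
            nonlinearity=self.nonlinearity,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        self.n_components_ = n
        self.components_ = np.vstack([f.edges for f in self.fccs_])
        self.weights_ = np.column_stack([f.weights for f in self.fccs_])
        self.retained_ = np.array([f.retained for f in self.fccs_])
        self.iq_ = np.array([f.iq for f in self.fccs_])
        return self

    def transform(self, X):
        """Subject weights for (possibly new) edge rows via least squares."""
        A = self._as_array(X)
        Ac = A - A.mean(axis=1, keepdims=True)
        W, *_ = np.linalg.lstsq(self.components_.T, Ac.T, rcond=None)
        return W.T

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.weights_
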