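"""Temporal group ICA with dual regression and channelwise group statistics.

Subjects are temporally concatenated after per-channel z-normalisation into a
single group matrix of shape

    [channels x 2 chromophores] x [samples x subjects]

(rows 0..C-1 HbO, rows C..2C-1 HbR; 92 x (5000 * N) in the replication
configuration).  FastICA on this matrix yields group-level temporally
independent time courses whose mixing columns are the functional network (FN)
spatial maps over the 2C rows.  Each map is taken back to the single subject
by dual regression:

    stage 1 (spatial):  data (2C x T) ~ maps (2C x K)  ->  time courses (K x T)
    stage 2 (temporal): data'        ~ tcs'            ->  subject map (K x 2C)

with stage-2 regressors variance-normalised.  Group differences are assessed
channel by channel within each FN (one-way F across groups on the subject map
loadings, BH-FDR within the FN's channels per chromophore, JZS Bayes factors),
plus one-sample t maps of the loadings themselves.

``GroupICA`` packages the procedure as a scikit-learn-style estimator:
``fit`` learns group maps from a list of preprocessed subjects, ``transform``
dual-regresses any subject into (time courses, subject map).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import DataError
from .ica import fastica, icasso_iq, select_model_order
from .inference import bf_anova_jzs, classify_evidence, fdr_bh, oneway_anova_vec
from .montage import HbSeries


@dataclass
class GroupDataset:
    """Concatenated z-scored group matrix plus subject bookkeeping."""

    matrix: np.ndarray  # (2C, T * n_subjects)
    n_channels: int
    n_samples: int
    subject_slices: list  # per-subject column slices

    @property
    def n_subjects(self) -> int:
        return len(self.subject_slices)

    @property
    def hbo_rows(self) -> slice:
        return slice(0, self.n_channels)

    @property
    def hbr_rows(self) -> slice:
        return slice(self.n_channels, 2 * self.n_channels)


@dataclass
class FunctionalNetwork:
    """A group-level network: spatial map over 2C rows plus consistency metrics."""

    map: np.ndarray  # (2C,)
    timecourse: np.ndarray  # group time course over all concatenated samples
    iq: float
    chromophore_consistency: float
    index: int
    subject_maps: np.ndarray = field(default=None)  # (subjects, 2C), via dual regression
    subject_timecourses: np.ndarray = field(default=None)  # (subjects, T)


def _zscore_rows(M, subject="<?>"):
    sd = M.std(axis=1)
    if (sd == 0).any():
        bad = int(np.argmin(sd))
        raise DataError(f"subject {subject!r}: constant channel row {bad}; z-score undefined")
    return (M - M.mean(axis=1, keepdims=True)) / sd[:, None]


def concatenate_group(subjects) -> GroupDataset:
    """Stack z-normalised [HbO; HbR] rows of every subject along time."""
    subjects = list(subjects)
    if not subjects:
        raise DataError("no subjects to concatenate")
    C = subjects[0].n_channels
    T = subjects[0].n_samples
    fs = subjects[0].fs_hz
    labels = subjects[0].montage.labels
    blocks = []
    slices = []
    for s, hb in enumerate(subjects):
        name = hb.meta.get("subject", s)
        if hb.n_channels != C or hb.n_samples != T:
            raise DataError(
                f"subject {name!r} has shape ({hb.n_channels}, {hb.n_samples}), "
                f"expected ({C}, {T})"
            )
        if hb.fs_hz != fs or hb.montage.labels != labels:
            raise DataError(f"subject {name!r} montage or sampling rate mismatch")
        blocks.append(_zscore_rows(hb.stacked(), subject=name))
        slices.append(slice(s * T, (s + 1) * T))
    return GroupDataset(
        matrix=np.hstack(blocks), n_channels=C, n_samples=T, subject_slices=slices
    )


def extract_networks(
    group: GroupDataset,
    n_components: int,
    n_runs: int = 20,
    seed: int = 0,
    compute_iq: bool = True,
    **ica_kw,
):
    """Group-level FNs: ICASSO centrotype maps (or a single run) plus Iq.

    With ``compute_iq`` the maps are the centrotypes of ``n_runs`` restarts and
    each FN carries its cluster quality index; the group time courses are the
    least-squares projection of the group data onto the maps.
    """
    X = group.matrix
    if compute_iq and n_runs >= 2:
        rep = icasso_iq(X, n_components, n_runs=n_runs, seed=seed,
                        store_sources=False, **ica_kw)
        maps = rep.centrotype_mixing
        iqs = rep.iq
    else:
        res = fastica(X, n_components, seed=seed, **ica_kw)
        maps = res.mixing
        iqs = np.full(n_components, np.nan)
    Xc = X - X.mean(axis=1, keepdims=True)
    tcs, *_ = np.linalg.lstsq(maps, Xc, rcond=None)
    C = group.n_channels
    networks = []
    for k in range(n_components):
        cc = float(np.corrcoef(maps[:C, k], maps[C:, k])[0, 1])
        networks.append(
            FunctionalNetwork(
                map=maps[:, k],
                timecourse=tcs[k],
                iq=float(iqs[k]),
                chromophore_consistency=cc,
                index=k,
            )
        )
    return networks


def dual_regression(group_maps: np.ndarray, subject: HbSeries, zscore: bool = True):
    """Two-stage least squares from group maps to one subject.

    Returns ``(timecourses (K, T), subject_map (K, 2C))``.  Stage-2 regressors
    (the stage-1 time courses) are variance-normalised before the fit so map
    amplitudes are comparable across subjects.
    """
    maps = np.asarray(group_maps, float)
    if maps.ndim != 2:
        raise DataError("group_maps must be (2C, K)")
    data = subject.stacked()
    if data.shape[0] != maps.shape[0]:
        raise DataError(
            f"subject stacked rows {data.shape[0]} != map rows {maps.shape[0]}"
        )
    if zscore and data.std(axis=1).min() > 0:
        data = _zscore_rows(data, subject=subject.meta.get("subject", "<?>"))
    rank = np.linalg.matrix_rank(maps)
    if rank < maps.shape[1]:
        raise DataError("collinear group maps; dual regression ill-posed")
    tcs, *_ = np.linalg.lstsq(maps, data, rcond=None)  # stage 1: (K, T)
    sd = tcs.std(axis=1, keepdims=True)
    tcs_norm = np.where(sd > 0, tcs / np.where(sd == 0, 1.0, sd), tcs)
    smap, *_ = np.linalg.lstsq(tcs_norm.T, data.T, rcond=None)  # stage 2: (K, 2C)
    return tcs, smap


def fn_group_stats(
    subject_maps: np.ndarray,
    group_labels,
    n_channels: int,
    q: float = 0.05,
    compute_bf: bool = True,
    prior_scale: float = 0.5,
):
    """Channelwise group statistics for every FN.

    ``subject_maps`` is (subjects, K networks, 2C rows).  Per FN and row:
    one-way F across groups, BH-FDR within the FN's channels (per
    chromophore), a two-sided one-sample t on the loadings, and optionally the
    JZS BF10 with its evidence bin.  Returns ``(table, audit)`` where audit
    holds the test count per chromophore (networks x channels).
    """
    S = np.asarray(subject_maps, float)
    if S.ndim != 3 or S.shape[2] != 2 * n_channels:
        raise DataError("subject_maps must be (subjects, networks, 2 * channels)")
    labels = np.asarray(group_labels)
    if labels.size != S.shape[0]:
        raise DataError("one group label per subject required")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise DataError("need at least 2 groups")
    counts = [(labels == g).sum() for g in uniq]
    if min(counts) < 2:
        raise DataError("every group needs at least 2 subjects")
    K = S.shape[1]
    groups = [S[labels == g] for g in uniq]  # (n_g, K, 2C) each
    F, p = oneway_anova_vec(groups, axis=0)  # (K, 2C)
    tval, tp = stats.ttest_1samp(S, popmean=0.0, axis=0)
    chrom = np.array(["HbO"] * n_channels + ["HbR"] * n_channels)
    rows = []
    for k in range(K):
        for half, sl in (("HbO", slice(0, n_channels)), ("HbR", slice(n_channels, 2 * n_channels))):
            mask, _ = fdr_bh(p[k, sl], q=q)
            for c_local, c in enumerate(range(sl.start, sl.stop)):
                row = {
                    "network": k,
                    "chromophore": half,
                    "channel": c_local,
                    "F": F[k, c],
                    "p": p[k, c],
                    "fdr_significant": bool(mask[c_local]),
                    "t": tval[k, c],
                    "t_p": tp[k, c],
                }
                if compute_bf:
                    bf10, info = bf_anova_jzs(
                        [g[:, k, c] for g in groups], prior_scale=prior_scale
                    )
                    row["bf10"] = bf10
                    row["bf01"] = 1.0 / bf10
                    row["evidence"] = classify_evidence(bf10).label
                rows.append(row)
    table = pd.DataFrame(rows)
    audit = {"n_tests_per_chromophore": K * n_channels, "n_networks": K,
             "n_channels": n_channels, "q": q}
    return table, audit


class GroupICA(BaseEstimator):
    """Temporal group ICA estimator (concatenation -> FastICA -> dual regression).

    Parameters follow the replication configuration: model order chosen as the
    smallest PC count explaining ``variance_target`` of group variance unless
    ``n_components`` is given, ``n_runs`` ICASSO restarts for consistency.

    Fitted attributes: ``maps_`` (2C, K), ``networks_`` (FunctionalNetwork
    list), ``n_components_``, ``group_`` (the concatenated dataset).
    ``transform(subjects)`` returns subject maps (n, K, 2C).
    """

    def __init__(
        self,
        n_components=None,
        variance_target: float = 0.60,
        n_runs: int = 20,
        compute_iq: bool = True,
        seed: int = 0,
        nonlinearity: str = "tanh",
        max_iter: int = 500,
        tol: float = 1e-6,
    ):
        self.n_components = n_components
        self.variance_target = variance_target
        self.n_runs = n_runs
        self.compute_iq = compute_iq
        self.seed = seed
        self.nonlinearity = nonlinearity
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, subjects, y=None):
        group = concatenate_group(subjects)
        n = self.n_components or select_model_order(group.matrix, self.variance_target)
        self.networks_ = extract_networks(
            group,
            n,
            n_runs=self.n_runs,
            seed=self.seed,
            compute_iq=self.compute_iq,
            nonlinearity=self.nonlinearity,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        self.maps_ = np.column_stack([fn.map for fn in self.networks_])
        self.n_components_ = n
        self.group_ = group
        return self

    def transform(self, subjects):
        """Dual-regress each subject; returns subject maps (n, K, 2C)."""
        out = []
        for hb in subjects:
            _, smap = dual_regression(self.maps_, hb)
            out.append(smap)
        return np.stack(out)

    def fit_transform(self, subjects, y=None):
        self.fit(subjects)
        smaps = self.transform(subjects)
        for k, fn in enumerate(self.networks_):
            fn.subject_maps = smaps[:, k, :]
        return smaps
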