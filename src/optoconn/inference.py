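"""Statistical kernel: one-way ANOVA, BH-FDR, JZS Bayes factors, evidence bins.

Frequentist group comparison is the classical one-way between-subjects F-test
(groups fixed, subjects random).  Multiple testing is controlled by the
Benjamini-Hochberg step-up procedure at level q.

The Bayesian counterpart is the default JZS (Jeffreys-Zellner-Siow) Bayes
factor for the one-way fixed-effect design against the grand-mean-only null.
With a g-prior N(0, g sigma^2 (X'X/N)^-1) on the k-1 effect parameters and the
default scaled inverse-chi^2 mixing distribution g ~ InvGamma(1/2, r^2/2)
(prior scale r = 0.5, "medium"), the Bayes factor reduces to a one-dimensional
integral

    BF10 = Int (1 + gN)^(-(k-1)/2) * (1 - h R^2)^(-(N-1)/2) pi(g) dg,
    h = gN / (1 + gN),  R^2 = SS_between / SS_total,

evaluated by adaptive quadrature in log space.  If the quadrature fails, a
BIC-based approximation is returned with ``approximate=True`` flagged.

Evidence strength is labelled on the conventional Bayes-factor ranges
(anecdotal 1-3, substantial 3-10, strong 10-30, very strong 30-100, decisive
>100, mirrored for H0 through BF01 = 1/BF10); interval bounds are closed on
the stronger side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError

EVIDENCE_THRESHOLDS = (3.0, 10.0, 30.0, 100.0)
EVIDENCE_NAMES = ("anecdotal", "substantial", "strong", "very strong", "decisive")


@dataclass(frozen=True)
class EvidenceBin:
    label: str
    bf10: float

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


def _group_arrays(groups):
    gs = [np.asarray(g, float).ravel() for g in groups]
    if len(gs) < 2:
        raise DataError("need at least 2 groups")
    for g in gs:
        if g.size < 2:
            raise DataError("each group needs at least 2 observations")
        if not np.isfinite(g).all():
            raise DataError("non-finite values in a group")
    return gs


def oneway_anova(groups):
    """Classical one-way F-test: returns (F, p, (df_between, df_within))."""
    gs = _group_arrays(groups)
    N = sum(g.size for g in gs)
    k = len(gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    if ssw == 0.0:
        raise DataError("zero within-group variance in every group; F undefined")
    F, p = stats.f_oneway(*gs)
    return float(F), float(p), (k - 1, N - k)


def oneway_anova_vec(groups, axis: int = 0):
    """Vectorised one-way F over stacked per-group arrays (same group axis)."""
    F, p = stats.f_oneway(*groups, axis=axis)
    return np.asarray(F, float), np.asarray(p, float)


def fdr_bh(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up at level q: (reject mask, p threshold).

    The threshold is the largest p-value among rejections (0.0 when nothing is
    rejected); the mask is monotone in p by construction of the step-up rule.
    """
    p = np.asarray(pvals, float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if (p < 0).any() or (p > 1).any():
        raise DataError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else 0.0
    return reject.reshape(np.shape(pvals)), threshold


def bf_anova_jzs(groups, prior_scale: float = 0.5):
    """Default JZS Bayes factor BF10 for a one-way design vs the null.

    Returns ``(bf10, info)`` where info carries the quadrature diagnostics and
    an ``approximate`` flag (True when the BIC fallback was used).
    """
    gs = _group_arrays(groups)
    if prior_scale <= 0:
        raise DataError("prior_scale must be > 0")
    y = np.concatenate(gs)
    N = y.size
    k = len(gs)
    p = k - 1
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    if ss_tot <= 0:
        raise DataError("zero total variance; Bayes factor undefined")
    ss_b = float(sum(g.size * (g.mean() - y.mean()) ** 2 for g in gs))
    R2 = min(ss_b / ss_tot, 1.0 - 1e-12)
    r2 = prior_scale**2

    def log_integrand(u):
        g = np.exp(u)
        h = g * N / (1.0 + g * N)
        log_prior = (
            0.5 * np.log(r2 / 2.0)
            - 0.5 * np.log(np.pi)
            - 1.5 * np.log(g)
            - r2 / (2.0 * g)
        )
        return (
            -p / 2.0 * np.log1p(g * N)
            - (N - 1) / 2.0 * np.log1p(-h * R2)
            + log_prior
            + u  # Jacobian of g = exp(u)
        )

    grid = np.linspace(-25.0, 25.0, 501)
    lg = log_integrand(grid)
    m = float(lg.max())
    try:
        val, err = integrate.quad(
            lambda u: np.exp(log_integrand(u) - m), -35.0, 35.0, limit=300
        )
        if not np.isfinite(val) or val <= 0 or err > 1e-6 * max(val, 1.0):
            raise RuntimeError(f"quadrature unreliable (value {val}, err {err})")
        bf10 = float(np.exp(m) * val)
        return bf10, {"approximate": False, "quad_error": err, "R2": R2}
    except Exception as exc:  # pragma: no cover - exercised only on failure
        F, _, (df1, df2) = oneway_anova(gs)
        # BIC approximation: BF10 ~ exp((BIC0 - BIC1) / 2)
        bic0 = N * np.log(ss_tot / N)
        bic1 = N * np.log((ss_tot - ss_b) / N) + p * np.log(N)
        bf10 = float(np.exp((bic0 - bic1) / 2.0))
        warnings.warn(f"JZS quadrature failed ({exc}); returning BIC approximation")
        return bf10, {"approximate": True, "R2": R2}


def classify_evidence(bf10: float) -> EvidenceBin:
    """Label a Bayes factor on the conventional evidence ranges.

    Interval bounds are assigned to the stronger bin (BF10 = 3 is already
    "substantial"), mirrored for H0 via the reciprocal.
    """
    if not np.isfinite(bf10) or bf10 <= 0:
        raise DataError(f"BF10 must be a positive finite number, got {bf10}")
    if bf10 == 1.0:
        return EvidenceBin(label="no evidence", bf10=1.0)
    hypothesis = "H1" if bf10 > 1 else "H0"
    magnitude = bf10 if bf10 > 1 else 1.0 / bf10
    idx = int(np.searchsorted(EVIDENCE_THRESHOLDS, magnitude, side="right"))
    return EvidenceBin(label=f"{EVIDENCE_NAMES[idx]} evidence for {hypothesis}", bf10=float(bf10))
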