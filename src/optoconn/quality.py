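"""Data-quality assessment: chromophore coupling, spectra, channel clustering.

A physiologically valid recording shows *antiphase* HbO/HbR dynamics: negative
correlation and an instantaneous phase difference concentrated near pi.  The
coupling report quantifies both per channel; a subject passes when the median
channel correlation is negative.  Spectral inspection (Welch PSD) exposes the
cardiac/respiratory/Mayer peaks before filtering and verifies their absence
afterwards.  Hierarchical clustering of channels on correlation distance
replicates the classic spatial-grouping check of infant connectivity studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import DataError
from .montage import HbSeries


@dataclass
class CouplingReport:
    """Per-channel HbO/HbR correlation and mean phase difference (radians)."""

    correlation: np.ndarray
    phase_difference: np.ndarray
    valid: np.ndarray  # False where a channel was constant (corr undefined)
    passed: bool

    def to_frame(self, montage=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "correlation": self.correlation,
                "phase_difference_rad": self.phase_difference,
                "valid": self.valid,
            }
        )
        if montage is not None:
            df.insert(0, "channel", list(montage.labels))
        return df


def hb_coupling(hb: HbSeries) -> CouplingReport:
    """Correlation and circular-mean instantaneous phase difference per channel.

    The phase difference uses the analytic signal of each chromophore; the
    circular mean of angle(HbO) - angle(HbR) lands near pi for antiphase
    dynamics.  Channels with a constant chromophore are flagged invalid and
    excluded from the pass/fail median.
    """
    C = hb.n_channels
    corr = np.full(C, np.nan)
    phase = np.full(C, np.nan)
    valid = np.ones(C, dtype=bool)
    for c in range(C):
        o, r = hb.hbo[c], hb.hbr[c]
        if o.std() == 0 or r.std() == 0:
            valid[c] = False
            continue
        corr[c] = np.corrcoef(o, r)[0, 1]
        dphi = np.angle(signal.hilbert(o - o.mean())) - np.angle(
            signal.hilbert(r - r.mean())
        )
        mean_angle = np.angle(np.exp(1j * dphi).mean())
        # report in (-pi, pi]
        phase[c] = np.pi if np.isclose(mean_angle, -np.pi) else mean_angle
    if not valid.any():
        raise DataError("all channels constant; coupling undefined")
    passed = bool(np.median(corr[valid]) < 0)
    return CouplingReport(correlation=corr, phase_difference=phase, valid=valid, passed=passed)


def channel_psd(hb: HbSeries, nperseg: int = 1024):
    """Welch PSD per channel and chromophore plus a peak-frequency table.

    Returns ``(freqs, psd)`` with ``psd`` shaped (2, channels, freqs) — index 0
    HbO, 1 HbR — and a DataFrame listing each channel's peak frequency.
    """
    nperseg = min(nperseg, hb.n_samples)
    freqs, psd_o = signal.welch(hb.hbo, fs=hb.fs_hz, nperseg=nperseg, axis=-1)
    _, psd_r = signal.welch(hb.hbr, fs=hb.fs_hz, nperseg=nperseg, axis=-1)
    psd = np.stack([psd_o, psd_r])
    peaks = pd.DataFrame(
        {
            "channel": list(hb.montage.labels) * 2,
            "chromophore": ["HbO"] * hb.n_channels + ["HbR"] * hb.n_channels,
            "peak_hz": np.concatenate(
                [freqs[np.argmax(psd_o, axis=-1)], freqs[np.argmax(psd_r, axis=-1)]]
            ),
        }
    )
    return freqs, psd, peaks


def cluster_channels(r: np.ndarray, n_clusters: int = None, distance_cut: float = None,
                     linkage_method: str = "average"):
    """Agglomerative clustering of channels on 1 - r correlation distance.

    Deterministic for a given matrix; returns ``(labels, linkage)`` where
    ``labels`` are flat 1-based cluster assignments from either an explicit
    cluster count or a distance cut, and ``linkage`` is the full dendrogram
    encoding for inspection.
    """
    r = np.asarray(r, float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise DataError(f"correlation matrix must be square, got {r.shape}")
    if not np.allclose(r, r.T, atol=1e-10):
        raise DataError("correlation matrix must be symmetric")
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    if n_clusters is not None:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    elif distance_cut is not None:
        labels = hierarchy.fcluster(Z, t=distance_cut, criterion="distance")
    else:
        raise DataError("specify n_clusters or distance_cut")
    return labels, Z
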