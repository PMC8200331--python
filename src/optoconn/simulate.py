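"""Synthetic infant-cohort generator with known ground truth.

Emulates the structure of a multichannel resting-state fNIRS study in sleeping
infants: ~99 subjects in 3 groups, 46 channels at 8.93 Hz, slow (< 0.09 Hz)
cortical network fluctuations with antiphase HbO/HbR coupling, systemic
physiology (cardiac, respiratory, Mayer waves), slow polynomial drifts, white
sensor noise and sparse motion spikes.  An optional group effect scales the
amplitude of one network in one group so that detection power is testable
end to end.

Signal model per subject, channel c and time t (concentrations in uM):

    hbo(c,t) = sum_k a_k * L_k(c) * s_k(t)            (cortical networks)
             + pulsatile physiology * gain(c) + slow systemic * sgain(c)
             + drift(c,t) + noise + spikes
    hbr(c,t) = -gamma * [network part of hbo] - scaled slow systemic
             + scaled pulsatile physiology with independent phases
             + drift' + noise' + spikes'

Network time courses s_k are *bursty*: a band-passed Gaussian carrier
multiplied by a slow positive envelope, z-scored.  The product stays inside
the pass band (< 0.09 Hz) and is super-Gaussian, which is what makes the
planted sources identifiable by ICA — band-passed Gaussian noise alone would
be Gaussian and no ICA could separate it.

Two network kinds are planted by default, mirroring the component structure
reported for infant cohorts: three bilateral "bump" networks (rank-one spatial
loadings, smooth and mirror-symmetric across hemispheres) and one homotopic
component in which each mirror channel pair shares its own *Gaussian*
band-limited time course, so that connectivity concentrates on homotopic edges
while temporal ICA (correctly) does not see the diffuse background as a
network.

Physiology has two parts: pulsatile oscillations above the 0.09 Hz analysis
cutoff (cardiac, respiration, Mayer) removed by the Fourier nuisance block,
and a slow global vasomotor fluctuation *below* the cutoff — the systemic
signal that global signal regression exists to remove.  The slow component
moves HbO and HbR antiphase (flow-driven washout), so it reinforces the raw
chromophore anticorrelation rather than masking it.

Raw intensities are produced by inverting the modified Beer-Lambert law
(``hb_to_intensity``), so the full preprocessing chain can be exercised from
photon counts onward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ConfigError, SpecError
from .extinction import extinction_matrix
from .montage import HbSeries, Montage, RawRecording, make_montage

DEFAULT_FS_HZ = 8.93


@dataclass(frozen=True)
class NetworkSpec:
    """One planted functional network.

    ``loading`` is a unit-norm spatial vector over channels for ``kind="bump"``
    or a unit-norm amplitude profile over homotopic channel pairs for
    ``kind="homotopic"``.  ``band`` (Hz) bounds the time-course spectrum and
    must sit inside (0, 0.09) so the network survives the high-pass nuisance
    cutoff.  ``amplitude`` is the population-mean uM amplitude; per-subject
    amplitudes are log-normal around it with sigma ``subject_sd``.
    """

    loading: np.ndarray
    band: tuple = (0.01, 0.08)
    kind: str = "bump"
    amplitude: float = 3.0
    subject_sd: float = 0.25
    bursty: bool = True

    def validate(self, fs_hz: float, f_cut: float = 0.09):
        nyq = fs_hz / 2.0
        if not (0.0 < self.band[0] < self.band[1]):
            raise SpecError(f"invalid band {self.band}")
        if self.band[1] > nyq:
            raise SpecError(f"band {self.band} outside Nyquist ({nyq:.3f} Hz)")
        if self.band[1] >= f_cut:
            raise SpecError(
                f"band {self.band} does not sit below the {f_cut} Hz nuisance cutoff"
            )
        if self.kind not in ("bump", "homotopic"):
            raise SpecError(f"unknown network kind {self.kind!r}")
        if not np.isclose(np.linalg.norm(self.loading), 1.0, atol=1e-8):
            raise SpecError("loading must have unit norm")
        if self.amplitude <= 0:
            raise SpecError("amplitude must be positive")


@dataclass(frozen=True)
class PhysiologySpec:
    """Systemic physiological oscillations shared across channels.

    Frequencies (Hz) and uM amplitudes for cardiac pulsation, respiration and
    Mayer waves; representative values for young infants.  Each subject draws
    a +-``freq_jitter`` relative frequency perturbation and a random phase.
    ``hbr_scale`` scales an independent-phase copy injected into HbR.
    """

    cardiac: tuple = (2.3, 0.4)
    respiration: tuple = (0.6, 0.25)
    mayer: tuple = (0.1, 0.3)
    freq_jitter: float = 0.1
    hbr_scale: float = 0.3
    # slow global vasomotor fluctuation: (amplitude uM, f_lo Hz, f_hi Hz); this
    # is the sub-cutoff systemic signal that global signal regression targets
    systemic: tuple = (1.5, 0.01, 0.08)

    @property
    def components(self):
        return (self.cardiac, self.respiration, self.mayer)


@dataclass(frozen=True)
class CohortSpec:
    """Study-level generator configuration (defaults = replication conditions)."""

    n_groups: int = 3
    n_per_group: tuple = (36, 30, 33)
    n_channels: int = 46
    n_samples: int = 6000
    fs_hz: float = DEFAULT_FS_HZ
    networks: tuple = None  # None -> default_networks(n_channels)
    coupling_gamma: float = 0.3
    physiology: PhysiologySpec = field(default_factory=PhysiologySpec)
    drift_order: int = 4
    drift_sd: float = 0.5
    noise_sd: float = 0.3
    hbr_noise_sd: float = 0.2
    spike_rate: float = 0.2  # spikes per channel-minute
    effect: tuple = None  # (network_index, group_index, amplitude multiplier)
    baseline_intensity: float = 1.0
    dpf: tuple = (5.3, 4.2)
    seed: int = 0

    def resolved_networks(self):
        nets = self.networks
        if nets is None:
            nets = default_networks(self.n_channels)
        return tuple(nets)

    @property
    def n_subjects(self) -> int:
        return int(sum(self.n_per_group))

    def group_labels(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_groups), self.n_per_group)

    def validate(self):
        if self.n_groups != len(self.n_per_group):
            raise SpecError("n_per_group length must equal n_groups")
        if any(n <= 0 for n in self.n_per_group):
            raise SpecError("group sizes must be positive")
        if self.n_channels <= 0 or self.n_samples <= 0 or self.fs_hz <= 0:
            raise SpecError("n_channels, n_samples and fs_hz must be positive")
        for net in self.resolved_networks():
            if net.loading is None:
                raise SpecError("network loading missing")
            net.validate(self.fs_hz)
            expected = (
                self.n_channels if net.kind == "bump" else self.n_channels // 2
            )
            if net.loading.shape != (expected,):
                raise SpecError(
                    f"{net.kind} loading must have shape ({expected},), "
                    f"got {net.loading.shape}"
                )
        if self.effect is not None:
            k, g, mult = self.effect
            if not 0 <= k < len(self.resolved_networks()):
                raise SpecError(f"effect network index {k} out of range")
            if not 0 <= g < self.n_groups:
                raise SpecError(f"effect group index {g} out of range")
            if mult <= 0:
                raise SpecError("effect multiplier must be > 0")
        if self.coupling_gamma <= 0:
            raise SpecError("coupling_gamma must be > 0")


def homotopic_pairs(n_channels: int):
    """Mirror channel pairs (i, i + n/2) of the synthetic bilateral layout."""
    half = n_channels // 2
    return [(i, i + half) for i in range(half)]


def _bilateral_bump(n_channels: int, center_frac: float, width: float) -> np.ndarray:
    half = n_channels // 2
    pos = np.arange(half, dtype=float)
    mu = center_frac * (half - 1)
    bump = np.exp(-((pos - mu) ** 2) / (2.0 * width**2))
    loading = np.concatenate([bump, bump]) if 2 * half == n_channels else np.concatenate(
        [bump, bump, [0.0]]
    )
    return loading / np.linalg.norm(loading)


def default_networks(n_channels: int = 46):
    """Three bilateral bump networks plus one homotopic component.

    Bump centers sit at 20%, 50% and 80% of each hemisphere's channel run
    (posterior, middle, anterior by convention); the homotopic component has a
    smooth mid-weighted amplitude profile over mirror pairs.
    """
    half = n_channels // 2
    width = max(1.5, 0.11 * half)
    nets = [
        NetworkSpec(loading=_bilateral_bump(n_channels, f, width), amplitude=3.0)
        for f in (0.2, 0.5, 0.8)
    ]
    profile = np.ones(half) / np.sqrt(half)
    nets.append(
        NetworkSpec(loading=profile, kind="homotopic", amplitude=1.5, bursty=False)
    )
    return tuple(nets)


@dataclass
class GroundTruthSubject:
    """Per-subject ground truth emitted alongside the generated series."""

    group: int
    amplitudes: np.ndarray  # effective per-network amplitude (effect applied)
    timecourses: list  # per network: (T,) for bumps, (n_pairs, T) for homotopic
    true_connectome: np.ndarray  # model correlation of hbo incl. noise floor
    spikes: list  # (channel, sample, amplitude) triples, HbO plane


@dataclass
class GroundTruth:
    spec: CohortSpec
    montage: Montage
    group_labels: np.ndarray
    subjects: list

    @property
    def networks(self):
        return self.spec.resolved_networks()

    def bump_loadings(self) -> np.ndarray:
        """(channels, n_bump_networks) matrix of planted rank-one loadings."""
        cols = [n.loading for n in self.networks if n.kind == "bump"]
        return np.column_stack(cols) if cols else np.zeros((self.spec.n_channels, 0))

    def homotopic_edges(self):
        """Set of (i, j) channel pairs carrying planted homotopic coupling."""
        if not any(n.kind == "homotopic" for n in self.networks):
            return []
        return homotopic_pairs(self.spec.n_channels)


def _timecourse(rng, n, fs, band, bursty=True):
    """Band-limited unit-variance time course.

    ``bursty=True`` multiplies a band-passed Gaussian carrier by a slow
    positive envelope (the product stays inside the band), giving the
    super-Gaussian amplitude structure that makes the source identifiable by
    ICA.  ``bursty=False`` returns plain band-passed Gaussian noise — present
    in the correlation structure but invisible to non-Gaussianity-seeking
    temporal ICA, which is the right model for diffuse background coupling.
    """
    f_lo, f_hi = band
    if bursty:
        env_hi = min(0.015, (f_hi - f_lo) / 4.0)
        carrier_band = (f_lo + env_hi, f_hi - env_hi)
        sos = signal.butter(4, carrier_band, btype="bandpass", fs=fs, output="sos")
        carrier = signal.sosfiltfilt(sos, rng.standard_normal(n))
        sos_env = signal.butter(4, env_hi, btype="lowpass", fs=fs, output="sos")
        env = np.abs(signal.sosfiltfilt(sos_env, rng.standard_normal(n)))
        x = carrier * env
    else:
        sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
        x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    if sd == 0:
        raise SpecError("degenerate time course (zero variance)")
    return (x - x.mean()) / sd


def _legendre_drift(rng, n_channels, n, order, sd):
    t = np.linspace(-1.0, 1.0, n)
    basis = np.polynomial.legendre.legvander(t, order)[:, 1:]  # orders 1..order
    coeffs = rng.normal(0.0, sd, size=(n_channels, basis.shape[1]))
    return coeffs @ basis.T


def _physiology(rng, spec: PhysiologySpec, n, fs):
    t = np.arange(n) / fs
    wave = np.zeros(n)
    for f0, amp in spec.components:
        f = f0 * (1.0 + rng.uniform(-spec.freq_jitter, spec.freq_jitter))
        wave += amp * np.sin(2.0 * np.pi * f * t + rng.uniform(0.0, 2.0 * np.pi))
    return wave


def _spikes(rng, n_channels, n, fs, rate_per_channel_minute, base_sd):
    """Sparse motion spikes; amplitude >= 5x channel SD by construction."""
    minutes = n / fs / 60.0
    out = []
    for c in range(n_channels):
        for _ in range(rng.poisson(rate_per_channel_minute * minutes)):
            t0 = int(rng.integers(0, n))
            amp = float(rng.choice([-1.0, 1.0]) * rng.uniform(5.0, 8.0) * base_sd[c])
            out.append((c, t0, amp))
    return out


def generate_hb(spec: CohortSpec, subject: int):
    """Generate one subject's HbO/HbR series plus its ground-truth slice.

    Deterministic in (spec.seed, subject).  The HbR series is the antiphase
    copy of the neural HbO signal (scale ``-coupling_gamma``) plus its own
    physiology, drift, noise and spikes, so per-channel corr(HbO, HbR) is
    negative in expectation.
    """
    spec.validate()
    if not 0 <= subject < spec.n_subjects:
        raise SpecError(f"subject index {subject} outside cohort of {spec.n_subjects}")
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(subject)]))
    nets = spec.resolved_networks()
    C, n, fs = spec.n_channels, spec.n_samples, spec.fs_hz
    group = int(spec.group_labels()[subject])

    hbo_neuro = np.zeros((C, n))
    amplitudes = np.empty(len(nets))
    timecourses = []
    cov_neuro = np.zeros((C, C))
    pairs = homotopic_pairs(C)
    for k, net in enumerate(nets):
        a = net.amplitude * float(np.exp(rng.normal(0.0, net.subject_sd)))
        if spec.effect is not None and spec.effect[0] == k and group == spec.effect[1]:
            a *= float(spec.effect[2])
        amplitudes[k] = a
        if net.kind == "bump":
            tc = _timecourse(rng, n, fs, net.band, bursty=net.bursty)
            hbo_neuro += a * np.outer(net.loading, tc)
            cov_neuro += (a**2) * np.outer(net.loading, net.loading)
            timecourses.append(tc)
        else:  # homotopic: one shared time course per mirror pair
            tcs = np.empty((len(pairs), n))
            for p, (i, j) in enumerate(pairs):
                tcs[p] = _timecourse(rng, n, fs, net.band, bursty=net.bursty)
                w = a * net.loading[p]
                hbo_neuro[i] += w * tcs[p]
                hbo_neuro[j] += w * tcs[p]
                for u in (i, j):
                    for v in (i, j):
                        cov_neuro[u, v] += w**2
            timecourses.append(tcs)

    physio = _physiology(rng, spec.physiology, n, fs)
    gains = rng.uniform(0.5, 1.5, size=C)
    sys_amp, sys_lo, sys_hi = spec.physiology.systemic
    if sys_amp > 0:
        systemic_o = sys_amp * _timecourse(rng, n, fs, (sys_lo, sys_hi), bursty=False)
    else:
        systemic_o = np.zeros(n)
    # slow vasomotion moves the chromophores antiphase (flow-driven washout)
    systemic_r = -systemic_o
    sgains_o = rng.uniform(0.5, 1.5, size=C)
    sgains_r = rng.uniform(0.5, 1.5, size=C)
    drift_o = _legendre_drift(rng, C, n, spec.drift_order, spec.drift_sd)
    drift_r = _legendre_drift(rng, C, n, spec.drift_order, spec.drift_sd)
    hbo = (
        hbo_neuro
        + np.outer(gains, physio)
        + np.outer(sgains_o, systemic_o)
        + drift_o
        + rng.normal(0.0, spec.noise_sd, size=(C, n))
    )
    physio_r = _physiology(rng, spec.physiology, n, fs)  # independent phases
    gains_r = rng.uniform(0.5, 1.5, size=C)
    hbr = (
        -spec.coupling_gamma * hbo_neuro
        + spec.physiology.hbr_scale * np.outer(gains_r, physio_r)
        + spec.physiology.hbr_scale * np.outer(sgains_r, systemic_r)
        + drift_r
        + rng.normal(0.0, spec.hbr_noise_sd, size=(C, n))
    )

    base_sd_o = hbo.std(axis=1)
    spikes = _spikes(rng, C, n, fs, spec.spike_rate, base_sd_o)
    for c, t0, amp in spikes:
        hbo[c, t0] += amp
        hbr[c, t0] += -spec.coupling_gamma * amp * rng.uniform(0.5, 1.5)

    # realized correlation of the noise-free neural signal: the exact structure
    # an ideal estimator would see for this subject (channels without any
    # network loading get zero off-diagonal correlation via the tiny ridge)
    cov_realized = (hbo_neuro @ hbo_neuro.T) / n - np.outer(
        hbo_neuro.mean(axis=1), hbo_neuro.mean(axis=1)
    )
    var = np.diag(cov_realized) + 1e-12
    true_conn = cov_realized / np.sqrt(np.outer(var, var))
    np.fill_diagonal(true_conn, 1.0)

    montage = make_montage(C, seed=spec.seed)
    hb = HbSeries(
        hbo=hbo,
        hbr=hbr,
        fs_hz=fs,
        montage=montage,
        meta={"subject": subject, "group": group},
    )
    gt = GroundTruthSubject(
        group=group,
        amplitudes=amplitudes,
        timecourses=timecourses,
        true_connectome=true_conn,
        spikes=spikes,
    )
    return hb, gt


def hb_to_intensity(
    hb: HbSeries,
    montage: Montage = None,
    dpf=(5.3, 4.2),
    baseline_intensity=1.0,
    extinction_table=None,
) -> RawRecording:
    """Forward modified Beer-Lambert model: concentrations -> raw intensity.

    I_lambda(t) = baseline * exp(-dOD_lambda(t)) with
    dOD_lambda = (eps_HbO * dHbO + eps_HbR * dHbR) * d * DPF_lambda, channel
    distance d in cm and concentrations in mol/L (series are in uM).  The
    inverse (``preprocess.od_to_hb``) recovers the input to ~1e-12 relative.
    """
    montage = montage or hb.montage
    E = extinction_matrix(table=extinction_table)  # (2, 2): rows wl, cols (HbO, HbR)
    d_cm = np.asarray(montage.distances_mm, float) / 10.0
    conc = np.stack([hb.hbo, hb.hbr]) * 1e-6  # uM -> M, (2, C, T)
    baseline = np.broadcast_to(np.asarray(baseline_intensity, float), (2,)).astype(float)
    dpf = np.asarray(dpf, float)
    if dpf.shape != (2,) or (dpf <= 0).any():
        raise ConfigError(f"dpf must be two positive factors, got {dpf}")
    # dOD[w, c, t] = (E[w] . conc[:, c, t]) * d_cm[c] * dpf[w]
    dod = np.einsum("wk,kct->wct", E, conc)
    dod *= d_cm[None, :, None] * dpf[:, None, None]
    intensity = baseline[:, None, None] * np.exp(-dod)
    rec = RawRecording(
        intensity=intensity,
        fs_hz=hb.fs_hz,
        montage=montage,
        meta=dict(hb.meta, dpf=tuple(dpf), baseline_intensity=tuple(baseline)),
    )
    rec.validate()
    return rec


def generate_cohort(spec: CohortSpec):
    """Generate the full cohort of raw recordings plus ground truth.

    Returns ``(recordings, ground_truth)``; deterministic under a fixed
    ``spec.seed``.  Group labels ride along in each recording's ``meta``.
    """
    spec.validate()
    recordings = []
    subjects = []
    for s in range(spec.n_subjects):
        hb, gt = generate_hb(spec, s)
        rec = hb_to_intensity(
            hb, dpf=spec.dpf, baseline_intensity=spec.baseline_intensity
        )
        rec.meta["subject"] = s
        rec.meta["group"] = gt.group
        recordings.append(rec)
        subjects.append(gt)
    truth = GroundTruth(
        spec=spec,
        montage=recordings[0].montage,
        group_labels=spec.group_labels(),
        subjects=subjects,
    )
    return recordings, truth
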