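"""Synthetic EEG cohorts with known ground-truth coupling.

Real pediatric resting-state EEG is not publicly distributable, so the
pipeline is exercised on simulated cohorts in which the quantity every
downstream stage measures — phase locking within and between frequency
bands — is planted directly and continuously controllable.

Each channel carries one stochastic Kuramoto phase oscillator per band:

    d phi_i = 2 pi f_i dt + sum_j K_ij sin(phi_j - phi_i) dt + sigma dW_i

integrated by Euler-Maruyama at the recording's sampling rate. K_ij (rad/s)
is the within-band coupling matrix, specified per group so that group-level
effects (hyper-/hypoconnectivity) can be planted on chosen bands and edges.
f_i is the band's center frequency plus a per-subject, per-channel jitter.
Optional cross-band links overwrite a target channel's phase in the target
band with (n/m) times a source channel's phase in the source band, plus an
independent Wiener jitter scaled by (1 - strength), planting n:m
cross-frequency locking of adjustable tightness. The recorded signal is the
sum over bands of amplitude * cos(phi) plus 1/f^beta background noise.

The default cohort mirrors a typical pediatric resting-state study: the
eight 10-20 channels, 1000 Hz, 300 s per subject, 36 subjects per group.
No volume conduction / sensor mixing is simulated by default (an optional
linear mixing matrix is accepted) because instantaneous mixing inflates
zero-lag phase locking and would blur the planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .recording import DEFAULT_CHANNELS, EEGRecording
from .spectral import BandSpec, DEFAULT_BANDS

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "BandModel",
    "CrossBandLink",
    "SyntheticTruth",
    "simulate_subject",
    "simulate_cohort",
    "default_truth",
    "planted_truth",
]

DEFAULT_CENTERS = {"delta": 2.5, "theta": 6.0, "alpha": 10.0, "beta": 20.0}


@dataclass
class BandModel:
    """One band's oscillator population and per-group coupling.

    ``coupling`` maps each group label to a symmetric, zero-diagonal,
    nonnegative channels x channels matrix of Kuramoto coupling strengths in
    rad/s. ``sigma`` is the phase-noise intensity in rad/sqrt(s);
    ``f_jitter_sd`` the per-channel center-frequency jitter in Hz.
    """

    band: BandSpec
    f_center: float
    coupling: dict[str, np.ndarray]
    f_jitter_sd: float = 0.2
    sigma: float = 1.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.band.f_lo <= self.f_center <= self.band.f_hi:
            raise ValueError(
                f"center {self.f_center} Hz outside band {self.band.name}"
            )
        for group, K in self.coupling.items():
            K = np.asarray(K, dtype=float)
            if K.ndim != 2 or K.shape[0] != K.shape[1]:
                raise ValueError(f"coupling for {group!r} must be square")
            if not np.allclose(K, K.T):
                raise ValueError(f"coupling for {group!r} must be symmetric")
            if np.any(np.diag(K) != 0):
                raise ValueError(f"coupling for {group!r} must have zero diagonal")
            if np.any(K < 0):
                raise ValueError(f"coupling for {group!r} must be nonnegative")
            self.coupling[group] = K


@dataclass
class CrossBandLink:
    """n:m phase linkage from one band/channel to another.

    The target channel's phase in ``band_to`` becomes
    ``(n / m) * phi_source + (1 - strength) * W(t)`` with W an independent
    Wiener jitter at the target band's sigma; ``strength = 1`` is exact
    harmonic locking. ``groups`` restricts the link to those group labels
    (None = all groups).
    """

    band_from: str
    band_to: str
    channel_from: str
    channel_to: str
    strength: float
    n: int = 1
    m: int = 1
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.strength <= 1:
            raise ValueError("linkage strength must lie in [0, 1]")
        if self.n < 1 or self.m < 1 or self.n != int(self.n) or self.m != int(self.m):
            raise ValueError("n and m must be positive integers")


@dataclass
class SyntheticTruth:
    """Full generative specification of a two-group cohort."""

    bands: list[BandModel]
    groups: dict[str, int]
    channels: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    fs: float = 1000.0
    duration_s: float = 300.0
    links: list[CrossBandLink] = field(default_factory=list)
    noise_amplitude: float = 0.5
    noise_exponent: float = 1.0
    mixing: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("sampling rate and duration must be positive")
        for g, size in self.groups.items():
            if size < 2:
                raise ValueError(f"group {g!r} needs at least 2 subjects")
        C = len(self.channels)
        for bm in self.bands:
            for g in self.groups:
                if g not in bm.coupling:
                    raise ValueError(f"band {bm.band.name} lacks coupling for group {g!r}")
                if bm.coupling[g].shape != (C, C):
                    raise ValueError(
                        f"coupling for {g!r} in band {bm.band.name} has wrong shape"
                    )
        for link in self.links:
            names = [bm.band.name for bm in self.bands]
            if link.band_from not in names or link.band_to not in names:
                raise ValueError("link references unknown band")
            if link.channel_from not in self.channels or link.channel_to not in self.channels:
                raise ValueError("link references unknown channel")

    @property
    def band_specs(self) -> list[BandSpec]:
        return [bm.band for bm in self.bands]

    def to_yaml(self) -> str:
        doc = {
            "channels": list(self.channels),
            "fs": self.fs,
            "duration_s": self.duration_s,
            "groups": dict(self.groups),
            "noise_amplitude": self.noise_amplitude,
            "noise_exponent": self.noise_exponent,
            "seed": self.seed,
            "bands": [
                {
                    "name": bm.band.name,
                    "f_lo": bm.band.f_lo,
                    "f_hi": bm.band.f_hi,
                    "f_center": bm.f_center,
                    "f_jitter_sd": bm.f_jitter_sd,
                    "sigma": bm.sigma,
                    "amplitude": bm.amplitude,
                    "coupling": {g: K.tolist() for g, K in bm.coupling.items()},
                }
                for bm in self.bands
            ],
            "links": [
                {
                    "band_from": lk.band_from, "band_to": lk.band_to,
                    "channel_from": lk.channel_from, "channel_to": lk.channel_to,
                    "strength": lk.strength, "n": lk.n, "m": lk.m,
                    "groups": lk.groups,
                }
                for lk in self.links
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticTruth":
        doc = yaml.safe_load(text)
        bands = [
            BandModel(
                band=BandSpec(b["name"], b["f_lo"], b["f_hi"]),
                f_center=b["f_center"],
                f_jitter_sd=b["f_jitter_sd"],
                sigma=b["sigma"],
                amplitude=b["amplitude"],
                coupling={g: np.asarray(K, dtype=float) for g, K in b["coupling"].items()},
            )
            for b in doc["bands"]
        ]
        links = [CrossBandLink(**lk) for lk in doc.get("links", [])]
        return cls(
            bands=bands,
            groups=doc["groups"],
            channels=doc["channels"],
            fs=doc["fs"],
            duration_s=doc["duration_s"],
            links=links,
            noise_amplitude=doc["noise_amplitude"],
            noise_exponent=doc["noise_exponent"],
            seed=doc["seed"],
        )


def _kuramoto_py(phi0, omega, K, noise, dt):
    n, C = noise.shape
    phi = np.empty((n, C))
    phi[0] = phi0
    for t in range(1, n):
        prev = phi[t - 1]
        drift = omega + (K * np.sin(prev[None, :] - prev[:, None])).sum(axis=1)
        phi[t] = prev + drift * dt + noise[t]
    return phi


if _HAVE_NUMBA:

    @njit(cache=False)
    def _kuramoto_nb(phi0, omega, K, noise, dt):  # pragma: no cover - jit
        n, C = noise.shape
        phi = np.empty((n, C))
        for i in range(C):
            phi[0, i] = phi0[i]
        for t in range(1, n):
            for i in range(C):
                drift = omega[i]
                for j in range(C):
                    kij = K[i, j]
                    if kij != 0.0:
                        drift += kij * np.sin(phi[t - 1, j] - phi[t - 1, i])
                phi[t, i] = phi[t - 1, i] + drift * dt + noise[t, i]
        return phi

    _kuramoto = _kuramoto_nb
else:  # pragma: no cover
    _kuramoto = _kuramoto_py


def _pink_noise(rng: np.random.Generator, n_channels: int, n: int, beta: float) -> np.ndarray:
    """Unit-variance 1/f^beta noise via spectral shaping of white noise."""
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spec * shape[None, :], n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_subject(truth: SyntheticTruth, group: str, subject_seed: int) -> EEGRecording:
    """Simulate one subject of the given group.

    Deterministic in ``(truth, group, subject_seed)``: calling twice with the
    same arguments returns bit-identical recordings.
    """
    if group not in truth.groups:
        raise ValueError(f"unknown group label {group!r}")
    rng = np.random.default_rng(subject_seed)
    C = len(truth.channels)
    n = int(round(truth.duration_s * truth.fs))
    dt = 1.0 / truth.fs
    ch_index = {c: i for i, c in enumerate(truth.channels)}

    phases: dict[str, np.ndarray] = {}
    for bm in truth.bands:
        f = bm.f_center + bm.f_jitter_sd * rng.standard_normal(C)
        f = np.clip(f, bm.band.f_lo, bm.band.f_hi)
        omega = 2.0 * np.pi * f
        phi0 = rng.uniform(-np.pi, np.pi, C)
        noise = bm.sigma * np.sqrt(dt) * rng.standard_normal((n, C))
        phi = _kuramoto(phi0, omega, np.ascontiguousarray(bm.coupling[group]), noise, dt)
        phases[bm.band.name] = phi.T  # (C, n)

    sigma_by_band = {bm.band.name: bm.sigma for bm in truth.bands}
    for link in truth.links:
        if link.groups is not None and group not in link.groups:
            continue
        src = phases[link.band_from][ch_index[link.channel_from]]
        jitter = np.cumsum(
            sigma_by_band[link.band_to] * np.sqrt(dt) * rng.standard_normal(n)
        )
        phases[link.band_to][ch_index[link.channel_to]] = (
            (link.n / link.m) * src + (1.0 - link.strength) * jitter
        )

    data = np.zeros((C, n))
    for bm in truth.bands:
        data += bm.amplitude * np.cos(phases[bm.band.name])
    if truth.noise_amplitude > 0:
        data += truth.noise_amplitude * _pink_noise(rng, C, n, truth.noise_exponent)
    if truth.mixing is not None:
        data = np.asarray(truth.mixing, dtype=float) @ data
    return EEGRecording(
        channel_labels=list(truth.channels),
        fs=truth.fs,
        data=data,
        subject_id=f"{group}-{subject_seed}",
        group=group,
        meta={"subject_seed": int(subject_seed)},
    )


def subject_seed_for(truth: SyntheticTruth, group: str, index: int) -> int:
    """Deterministic per-subject seed derived from the base seed."""
    gidx = sorted(truth.groups).index(group)
    ss = np.random.SeedSequence([int(truth.seed), gidx, int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(truth: SyntheticTruth) -> list[EEGRecording]:
    """Simulate every subject of every group, deterministically seeded."""
    recs = []
    for group in sorted(truth.groups):
        for idx in range(truth.groups[group]):
            seed = subject_seed_for(truth, group, idx)
            rec = simulate_subject(truth, group, seed)
            rec.subject_id = f"{group}{idx:03d}"
            recs.append(rec)
    return recs


def _uniform_coupling(C: int, k: float) -> np.ndarray:
    K = np.full((C, C), float(k))
    np.fill_diagonal(K, 0.0)
    return K


def default_truth(
    n_per_group: int = 36,
    fs: float = 1000.0,
    duration_s: float = 300.0,
    base_coupling: float = 0.3,
    seed: int = 0,
    groups: tuple[str, str] = ("TD", "ASD"),
    bands: list[BandSpec] | None = None,
) -> SyntheticTruth:
    """Null two-group cohort: identical uniform coupling in every band."""
    if bands is None:
        bands = DEFAULT_BANDS
    C = len(DEFAULT_CHANNELS)
    band_models = [
        BandModel(
            band=b,
            f_center=DEFAULT_CENTERS.get(b.name, b.center),
            coupling={g: _uniform_coupling(C, base_coupling) for g in groups},
        )
        for b in bands
    ]
    return SyntheticTruth(
        bands=band_models,
        groups={g: n_per_group for g in groups},
        fs=fs,
        duration_s=duration_s,
        seed=seed,
    )


def planted_truth(
    n_per_group: int = 36,
    fs: float = 1000.0,
    duration_s: float = 300.0,
    base_coupling: float = 0.3,
    delta_hyper: float = 1.2,
    alpha_hypo: float = 0.05,
    cross_band_link: bool = False,
    link_strength: float = 0.9,
    seed: int = 0,
    groups: tuple[str, str] = ("TD", "ASD"),
    bands: list[BandSpec] | None = None,
) -> SyntheticTruth:
    """Cohort with planted group effects on coupling.

    The second group label gets uniformly raised delta-band coupling
    (``delta_hyper``) and lowered alpha-band coupling (``alpha_hypo``)
    relative to the shared baseline, emulating delta hyperconnectivity and
    alpha hypoconnectivity. With ``cross_band_link`` the same group also
    receives a 4:1 delta-to-alpha phase linkage on every channel.
    """
    truth = default_truth(
        n_per_group=n_per_group, fs=fs, duration_s=duration_s,
        base_coupling=base_coupling, seed=seed, groups=groups, bands=bands,
    )
    ctrl, planted = groups
    C = len(truth.channels)
    by_name = {bm.band.name: bm for bm in truth.bands}
    if "delta" in by_name:
        by_name["delta"].coupling[planted] = _uniform_coupling(C, delta_hyper)
    if "alpha" in by_name:
        by_name["alpha"].coupling[planted] = _uniform_coupling(C, alpha_hypo)
    if cross_band_link and "delta" in by_name and "alpha" in by_name:
        ratio = int(round(by_name["alpha"].f_center / by_name["delta"].f_center))
        truth.links = [
            CrossBandLink(
                band_from="delta", band_to="alpha",
                channel_from=ch, channel_to=ch,
                strength=link_strength, n=ratio, m=1, groups=[planted],
            )
            for ch in truth.channels
        ]
    return truth
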