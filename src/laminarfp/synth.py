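"""Synthetic bilateral laminar recordings with known ground truth.

Every downstream stage (separation, CSD, coupling, causality,
deconvolution) is testable against recordings generated here: the mixing
matrices, generator time courses, event lists and the bilateral coupling
graph are all stored alongside the data.

The generative model mirrors the analysis model: each side's recording is a
linear mixture ``V @ s(t)`` of generator time courses through depth-loading
profiles, plus iid Gaussian sensor noise.  Time courses are composed of

* pulse trains of the canonical gamma waveform (Poisson onsets, signed
  weights) on a stable baseline,
* sparse wide high-amplitude pulses emulating sharp waves (always paired
  bilaterally with tightly covarying amplitudes),
* bout-modulated band-limited slow waves (delta/theta/alpha), whose
  bilateral magnitude-squared coherence is set analytically: with a shared
  fraction ``a`` of the slow standard deviation on both sides, the in-band
  coherence is ``a^4``, so ``a = target**(1/4)``.

Directed influences are realized as lagged additive copies of a source
generator's time course on a target generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from .deconv import pulse_template
from .io import BilateralRecording, Recording

__all__ = [
    "ProfileSpec",
    "GeneratorDynamicsSpec",
    "DirectedLink",
    "CouplingSpec",
    "SceneSpec",
    "EventRecord",
    "GroundTruth",
    "ConstructionError",
    "make_profiles",
    "simulate_timecourses",
    "mix_and_record",
    "simulate_scene",
    "default_scene",
    "scene_to_yaml",
    "scene_from_yaml",
    "write_ground_truth",
]

SIDES = ("left", "right")


class ConstructionError(ValueError):
    """The requested scene cannot be realized exactly."""


# ---------------------------------------------------------------------------
# specs

@dataclass
class ProfileSpec:
    """Depth-loading profile shape of one generator.

    ``bump``: localized Gaussian loading; ``reversing``: polarity flips
    exactly once at ``reversal_channel``; ``flat``: identical loading on all
    channels (a volume-conducted remote source).
    """

    kind: str = "bump"             # bump | reversing | flat
    center_channel: float = 0.0
    width_channels: float = 3.0
    reversal_channel: int | None = None
    sign: float = 1.0


@dataclass
class GeneratorDynamicsSpec:
    """Temporal statistics of one generator's activation."""

    baseline: float = 0.0
    gamma_rate: float = 0.0        # events / s (Poisson)
    gamma_delta: float = 0.005     # s, pulse time scale
    gamma_weight_mean: float = 1.0
    gamma_weight_sd: float = 0.3
    slow_band: tuple[float, float] = (1.0, 4.0)
    slow_sd: float = 0.0           # SD of the slow component, activation units
    spw_rate: float = 0.0          # events / s
    spw_weight: float = 3.0
    spw_delta: tuple[float, float] = (0.03, 0.06)   # s, uniform range
    polarity: str = "negative"     # sign of gamma-pulse weights
    scale: float = 1.0             # target SD of the composed time course


@dataclass
class DirectedLink:
    source_side: str
    source_gen: int
    target_side: str
    target_gen: int
    lag: int                       # samples, >= 1
    gain: float

    def __post_init__(self):
        if self.lag < 1:
            raise ValueError("lag must be at least 1 sample")


@dataclass
class CouplingSpec:
    """Bilateral coupling targets, one entry per generator."""

    slow_coherence: list[float] = field(default_factory=list)   # in [0, 1]
    gamma_pairing_prob: list[float] = field(default_factory=list)
    pairing_jitter_sd: float = 0.0       # s
    directed_links: list[DirectedLink] = field(default_factory=list)

    def __post_init__(self):
        for v in list(self.slow_coherence) + list(self.gamma_pairing_prob):
            if not 0 <= v <= 1:
                raise ValueError("probabilities/coherences must lie in [0, 1]")


@dataclass
class SceneSpec:
    n_channels: int = 32
    profiles: list[ProfileSpec] = field(default_factory=list)
    dynamics: list[GeneratorDynamicsSpec] = field(default_factory=list)
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    noise_sd: float = 0.03         # mV per channel
    labels: list[str] = field(default_factory=list)
    inherit: list[tuple[int, int, float]] = field(default_factory=list)
    # inherit: (source_gen, target_gen, corr) -- target's time course takes a
    # fraction `corr` of its SD from the source's (e.g. a soma-layer
    # generator inheriting dynamics from a synaptic one)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EventRecord:
    side: str
    gen: int
    w: float
    tau: float
    delta: float
    kind: str = "gamma"            # gamma | spw
    pair_id: int | None = None     # shared by bilateral partners


@dataclass
class GroundTruth:
    mixing: dict[str, np.ndarray]            # side -> channels x generators
    timecourses: dict[str, np.ndarray]       # side -> generators x time
    events: list[EventRecord]
    pairing: list[tuple[int, int]]           # indices into `events`
    links: list[DirectedLink]
    noise_sd: float
    fs: float
    labels: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# profiles

def make_profiles(specs: list[ProfileSpec], n_channels: int) -> np.ndarray:
    """Build the loading matrix (channels x generators), max |loading| = 1."""
    if n_channels < 4:
        raise ValueError("need at least 4 channels")
    m = np.arange(n_channels)
    cols = []
    for spec in specs:
        if spec.kind == "bump":
            if not 0 <= spec.center_channel <= n_channels - 1:
                raise ValueError("bump center outside the probe")
            v = np.exp(-((m - spec.center_channel) ** 2)
                       / (2 * spec.width_channels**2))
        elif spec.kind == "flat":
            v = np.ones(n_channels)
        elif spec.kind == "reversing":
            rc = spec.reversal_channel
            if rc is None or not 1 <= rc <= n_channels - 1:
                raise ValueError("reversal_channel must be an interior channel")
            center = spec.center_channel or rc
            v = (m - (rc - 0.5)) * np.exp(
                -((m - center) ** 2) / (2 * (2 * spec.width_channels) ** 2)
            )
        else:
            raise ValueError(f"unknown profile kind {spec.kind!r}")
        v = spec.sign * v / np.max(np.abs(v))
        cols.append(v)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# time courses

def _bout_modulated_band(rng, n, fs, band, bout_timescale=1.0, depth=0.8):
    """Band-limited noise with a slowly varying envelope (wave bouts).

    The envelope (mean ~1, SD ``depth``, clipped at zero) makes the series
    super-Gaussian, as real oscillation bouts are, which is what lets ICA
    tell slow-wave generators apart; it is mild enough that the analytic
    shared-fraction coherence construction still holds in-band.
    """
    lo, hi = band
    # extra samples at both ends absorb the zero-phase filters' edge
    # transients, which would otherwise dominate the narrowband output
    pad = int(np.ceil(4 * fs / lo))
    m = n + 2 * pad
    white = rng.standard_normal(m)
    sos = sps.butter(4, (lo, min(hi, 0.45 * fs)), btype="bandpass", fs=fs,
                     output="sos")
    x = sps.sosfiltfilt(sos, white)[pad : pad + n]
    g = sps.sosfiltfilt(
        sps.butter(2, 1.0 / bout_timescale, btype="lowpass", fs=fs,
                   output="sos"),
        rng.standard_normal(m),
    )[pad : pad + n]
    g_sd = g.std()
    if g_sd > 0:
        env = np.clip(1.0 + depth * g / g_sd, 0.0, 1.0 + 3.0 * depth)
        x = x * env
    sd = x.std()
    return x / sd if sd > 0 else x


def _pulse_train(rng, n, fs, rate, delta, weight_mean, weight_sd, polarity,
                 kind, side, gen, events, onsets=None, deltas=None,
                 weights=None, pair_ids=None):
    """Render a pulse train; append the realized events to `events`."""
    t = np.arange(n) / fs
    out = np.zeros(n)
    if onsets is None:
        n_ev = rng.poisson(rate * n / fs)
        onsets = np.sort(rng.uniform(0, n / fs, n_ev))
        deltas = np.full(n_ev, delta)
        w = np.abs(rng.normal(weight_mean, weight_sd, n_ev))
        weights = -w if polarity == "negative" else w
        pair_ids = [None] * n_ev
    idx0 = len(events)
    for w_k, tau_k, d_k, pid in zip(weights, onsets, deltas, pair_ids):
        a = int(tau_k * fs)
        b = min(n, int((tau_k + 5 * d_k) * fs) + 1)
        if a >= n:
            continue
        out[a:b] += w_k * pulse_template(t[a:b] - tau_k, d_k)
        events.append(EventRecord(side=side, gen=gen, w=float(w_k),
                                  tau=float(tau_k), delta=float(d_k),
                                  kind=kind, pair_id=pid))
    return out, idx0


def simulate_timecourses(
    dyn: list[GeneratorDynamicsSpec],
    coupling: CouplingSpec,
    duration: float,
    fs: float,
    seed: int | None = None,
    inherit: list[tuple[int, int, float]] | None = None,
) -> tuple[dict[str, np.ndarray], list[EventRecord], list[tuple[int, int]]]:
    """Simulate bilateral generator time courses with configured coupling.

    Returns per-side (generators x time) arrays, the realized event list
    and the bilateral pairing map (event-index pairs).
    """
    n = int(round(duration * fs))
    if n < 10_000:
        raise ValueError("duration * fs must be at least 10^4 samples")
    rng = np.random.default_rng(seed)
    n_gen = len(dyn)
    coh = list(coupling.slow_coherence) or [0.0] * n_gen
    pair_p = list(coupling.gamma_pairing_prob) or [0.0] * n_gen
    if len(coh) != n_gen or len(pair_p) != n_gen:
        raise ValueError("coupling lists must have one entry per generator")

    tcs = {s: np.zeros((n_gen, n)) for s in SIDES}
    events: list[EventRecord] = []
    pairing: list[tuple[int, int]] = []
    raw = {s: [None] * n_gen for s in SIDES}
    next_pair_id = 0

    for g, d in enumerate(dyn):
        c = coh[g]
        if c == 1.0 and (d.gamma_rate > 0 or d.spw_rate > 0):
            raise ConstructionError(
                "coherence target 1 is unattainable with per-side "
                "independent event trains"
            )
        parts = {s: np.zeros(n) for s in SIDES}

        # slow band: shared + per-side independent, coherence = a^4
        if d.slow_sd > 0:
            a = c ** 0.25
            b = np.sqrt(max(0.0, 1 - a**2))
            shared = _bout_modulated_band(rng, n, fs, d.slow_band)
            for s in SIDES:
                indep = _bout_modulated_band(rng, n, fs, d.slow_band)
                parts[s] += d.slow_sd * (a * shared + b * indep)

        # gamma pulse trains with bilateral pairing
        if d.gamma_rate > 0:
            n_ev = rng.poisson(d.gamma_rate * duration)
            on_l = np.sort(rng.uniform(0, duration, n_ev))
            del_l = np.full(n_ev, d.gamma_delta)
            wmag = np.abs(rng.normal(d.gamma_weight_mean, d.gamma_weight_sd,
                                     n_ev))
            sign = -1.0 if d.polarity == "negative" else 1.0
            w_l = sign * wmag
            is_paired = rng.uniform(size=n_ev) < pair_p[g]
            pids_l = []
            for k in range(n_ev):
                pids_l.append(next_pair_id if is_paired[k] else None)
                next_pair_id += is_paired[k]
            tr_l, i0_l = _pulse_train(
                rng, n, fs, 0, 0, 0, 0, d.polarity, "gamma", "left", g,
                events, onsets=on_l, deltas=del_l, weights=w_l,
                pair_ids=pids_l,
            )
            # right side: partners of paired left events + independent extras
            jit = rng.normal(0, coupling.pairing_jitter_sd, n_ev)
            on_r = on_l[is_paired] + jit[is_paired]
            del_r = del_l[is_paired]
            w_r = sign * np.abs(rng.normal(d.gamma_weight_mean,
                                           d.gamma_weight_sd,
                                           int(is_paired.sum())))
            pids_r = [pids_l[k] for k in range(n_ev) if is_paired[k]]
            n_extra = rng.poisson(d.gamma_rate * duration * (1 - pair_p[g]))
            on_x = rng.uniform(0, duration, n_extra)
            order = np.argsort(np.r_[on_r, on_x])
            on_all = np.r_[on_r, on_x][order]
            del_all = np.r_[del_r, np.full(n_extra, d.gamma_delta)][order]
            w_all = np.r_[w_r, sign * np.abs(
                rng.normal(d.gamma_weight_mean, d.gamma_weight_sd, n_extra)
            )][order]
            pid_all = [(pids_r + [None] * n_extra)[i] for i in order]
            tr_r, i0_r = _pulse_train(
                rng, n, fs, 0, 0, 0, 0, d.polarity, "gamma", "right", g,
                events, onsets=on_all, deltas=del_all, weights=w_all,
                pair_ids=pid_all,
            )
            parts["left"] += tr_l
            parts["right"] += tr_r

        # sharp-wave-like events: bilateral, tightly covarying amplitude
        if d.spw_rate > 0:
            n_spw = rng.poisson(d.spw_rate * duration)
            on = np.sort(rng.uniform(0, duration, n_spw))
            dl = rng.uniform(*d.spw_delta, n_spw)
            w_common = d.spw_weight * (1 + 0.2 * rng.standard_normal(n_spw))
            for s in SIDES:
                w_side = w_common * (1 + 0.05 * rng.standard_normal(n_spw))
                pids = list(range(next_pair_id, next_pair_id + n_spw))
                tr, _ = _pulse_train(
                    rng, n, fs, 0, 0, 0, 0, "positive", "spw", s, g,
                    events, onsets=on, deltas=dl, weights=w_side,
                    pair_ids=pids,
                )
                parts[s] += tr
            next_pair_id += n_spw

        for s in SIDES:
            raw[s][g] = parts[s]

    # inherited dynamics (e.g. soma generator echoing a synaptic input)
    for (src, tgt, corr) in (inherit or []):
        for s in SIDES:
            src_tc = raw[s][src]
            own = raw[s][tgt]
            src_n = src_tc / max(src_tc.std(), 1e-300)
            own_sd = own.std() if own.std() > 0 else 1.0
            raw[s][tgt] = own_sd * (
                corr * src_n
                + np.sqrt(1 - corr**2) * own / own_sd
            )

    # normalize to target SD (event weights scale along), add baseline
    for g, d in enumerate(dyn):
        for s in SIDES:
            x = raw[s][g]
            sd = x.std()
            gamma = d.scale / sd if sd > 0 else 1.0
            tcs[s][g] = d.baseline + gamma * x
            for ev in events:
                if ev.side == s and ev.gen == g:
                    ev.w *= gamma

    # directed lagged influences
    for link in coupling.directed_links:
        src = tcs[link.source_side][link.source_gen]
        shifted = np.zeros(n)
        shifted[link.lag :] = src[: n - link.lag] - src.mean()
        tcs[link.target_side][link.target_gen] += link.gain * shifted

    # realized pairing map
    by_pid: dict[int, dict[str, int]] = {}
    for i, ev in enumerate(events):
        if ev.pair_id is not None:
            by_pid.setdefault(ev.pair_id, {})[ev.side] = i
    for pid, d_ in sorted(by_pid.items()):
        if "left" in d_ and "right" in d_:
            pairing.append((d_["left"], d_["right"]))

    return tcs, events, pairing


# ---------------------------------------------------------------------------
# mixing

def mix_and_record(
    profiles: np.ndarray,
    timecourses: dict[str, np.ndarray],
    noise_sd: float,
    fs: float,
    seed: int | None = None,
    events: list[EventRecord] | None = None,
    pairing: list[tuple[int, int]] | None = None,
    links: list[DirectedLink] | None = None,
    labels: list[str] | None = None,
) -> tuple[BilateralRecording, GroundTruth]:
    """Mix generator time courses through the loading profiles, add sensor
    noise, and return the recording with its ground truth."""
    profiles = np.asarray(profiles, float)
    rng = np.random.default_rng(seed)
    recs = {}
    for s in SIDES:
        tc = np.asarray(timecourses[s], float)
        if tc.shape[0] != profiles.shape[1]:
            raise ValueError("one time course per profile column is required")
        samples = profiles @ tc
        if noise_sd > 0:
            samples = samples + rng.normal(0, noise_sd, samples.shape)
        recs[s] = Recording(samples=samples, fs=fs, side=s)
    gt = GroundTruth(
        mixing={s: profiles.copy() for s in SIDES},
        timecourses={s: np.asarray(timecourses[s]) for s in SIDES},
        events=events or [],
        pairing=pairing or [],
        links=links or [],
        noise_sd=noise_sd,
        fs=fs,
        labels=labels or [],
    )
    return BilateralRecording(left=recs["left"], right=recs["right"]), gt


# ---------------------------------------------------------------------------
# default scene

def default_scene() -> SceneSpec:
    """Six generators per side on a 32-channel probe.

    Emulates the canonical hippocampal set: Schaffer (st. radiatum bump,
    negative-going gamma on a stable baseline, sharp waves), L-M (polarity-
    reversing profile, alpha bouts plus gamma), LPP and MPP (dentate
    molecular-layer bumps; only MPP carries strong bilateral slow
    coherence), GCsom (granule soma layer, dynamics partly inherited from
    the LPP), and a flat-profile volume-conducted remote source.
    """
    profiles = [
        ProfileSpec("bump", center_channel=10, width_channels=3),
        ProfileSpec("reversing", center_channel=16, width_channels=3,
                    reversal_channel=16),
        ProfileSpec("bump", center_channel=22, width_channels=2.5),
        ProfileSpec("bump", center_channel=27, width_channels=2.0),
        ProfileSpec("bump", center_channel=30, width_channels=1.8, sign=-1.0),
        ProfileSpec("flat"),
    ]
    # for the slow-wave generators the gamma weights are kept small: a unit-
    # area pulse train carries flat low-frequency power, and because the two
    # sides' trains are independent it would otherwise dilute the coherent
    # slow band (pulse low-f PSD ~ rate * E[w^2] against slow_sd^2 / bandwidth)
    dynamics = [
        # Schaffer: stable baseline, dense negative gamma, sparse SPWs
        GeneratorDynamicsSpec(gamma_rate=15, gamma_delta=0.005,
                              slow_band=(1, 4), slow_sd=0.25,
                              spw_rate=0.2, spw_weight=4.0,
                              polarity="negative", scale=1.0),
        # L-M: alpha-band bouts + gamma
        GeneratorDynamicsSpec(gamma_rate=10, gamma_delta=0.006,
                              gamma_weight_mean=0.05, gamma_weight_sd=0.02,
                              slow_band=(8, 12), slow_sd=1.0,
                              polarity="negative", scale=0.9),
        # LPP: theta-delta slow + gamma, no bilateral slow coupling
        GeneratorDynamicsSpec(gamma_rate=8, gamma_delta=0.007,
                              gamma_weight_mean=0.05, gamma_weight_sd=0.02,
                              slow_band=(2, 6), slow_sd=1.0,
                              polarity="negative", scale=0.7),
        # MPP: delta slow waves, strong bilateral coherence
        GeneratorDynamicsSpec(gamma_rate=6, gamma_delta=0.006,
                              gamma_weight_mean=0.05, gamma_weight_sd=0.02,
                              slow_band=(1, 4), slow_sd=1.0,
                              polarity="negative", scale=0.5),
        # GCsom: own sparse positive events; inherits 40% SD from LPP
        GeneratorDynamicsSpec(gamma_rate=8, gamma_delta=0.010,
                              gamma_weight_mean=0.06, gamma_weight_sd=0.02,
                              slow_band=(2, 8), slow_sd=1.0,
                              polarity="positive", scale=0.35),
        # remote: volume-conducted delta/theta
        GeneratorDynamicsSpec(gamma_rate=4, gamma_delta=0.012,
                              gamma_weight_mean=0.05, gamma_weight_sd=0.02,
                              slow_band=(1, 8), slow_sd=1.0,
                              polarity="positive", scale=0.6),
    ]
    coupling = CouplingSpec(
        slow_coherence=[0.8, 0.8, 0.0, 0.8, 0.0, 0.9],
        gamma_pairing_prob=[0.9, 0.0, 0.0, 0.0, 0.0, 0.0],
        pairing_jitter_sd=0.002,
    )
    # `scale` is the target SD in channel space: divide by the profile
    # column norm so the relative variance shares come out as intended
    # (the flat remote profile alone has squared norm = n_channels)
    target_sd = [1.0, 0.9, 0.7, 0.5, 0.35, 0.6]
    norms = np.linalg.norm(make_profiles(profiles, 32), axis=0)
    for d, sd, nrm in zip(dynamics, target_sd, norms):
        d.scale = float(sd / nrm)
    return SceneSpec(
        n_channels=32,
        profiles=profiles,
        dynamics=dynamics,
        coupling=coupling,
        noise_sd=0.03,
        labels=["Sch", "LM", "LPP", "MPP", "GCsom", "remote"],
        inherit=[(2, 4, 0.4)],
    )


def simulate_scene(
    scene: SceneSpec | None = None,
    duration: float = 60.0,
    fs: float = 1000.0,
    seed: int | None = None,
) -> tuple[BilateralRecording, GroundTruth]:
    """Generate a bilateral recording from a scene description."""
    scene = scene or default_scene()
    ss = np.random.SeedSequence(seed)
    s_tc, s_mix = ss.spawn(2)
    profiles = make_profiles(scene.profiles, scene.n_channels)
    tcs, events, pairing = simulate_timecourses(
        scene.dynamics, scene.coupling, duration, fs,
        seed=s_tc, inherit=scene.inherit,
    )
    return mix_and_record(
        profiles, tcs, scene.noise_sd, fs, seed=s_mix,
        events=events, pairing=pairing,
        links=scene.coupling.directed_links, labels=scene.labels,
    )


# ---------------------------------------------------------------------------
# scene/ground-truth serialization

def scene_to_yaml(scene: SceneSpec, path) -> None:
    """Write a scene description as YAML (schema mirrors the dataclasses)."""
    import yaml

    with open(path, "w") as f:
        yaml.safe_dump(scene.to_dict(), f, sort_keys=False)


def scene_from_yaml(path) -> SceneSpec:
    import yaml

    with open(path) as f:
        d = yaml.safe_load(f)
    d["profiles"] = [ProfileSpec(**p) for p in d.get("profiles", [])]
    d["dynamics"] = [
        GeneratorDynamicsSpec(**{**g, "slow_band": tuple(g["slow_band"]),
                                 "spw_delta": tuple(g["spw_delta"])})
        for g in d.get("dynamics", [])
    ]
    cp = d.get("coupling", {})
    cp["directed_links"] = [DirectedLink(**l) for l in cp.get("directed_links", [])]
    d["coupling"] = CouplingSpec(**cp)
    d["inherit"] = [tuple(t) for t in d.get("inherit", [])]
    return SceneSpec(**d)


def write_ground_truth(gt: GroundTruth, json_path, events_csv_path) -> None:
    """Ground truth as JSON (mixing, links, noise) + events CSV."""
    import json

    import pandas as pd

    payload = {
        "fs": gt.fs,
        "noise_sd": gt.noise_sd,
        "labels": gt.labels,
        "mixing": {s: m.tolist() for s, m in gt.mixing.items()},
        "pairing": gt.pairing,
        "links": [vars(l) for l in gt.links],
    }
    with open(json_path, "w") as f:
        json.dump(payload, f)
    rows = [
        dict(side=e.side, gen=e.gen, kind=e.kind, w=e.w, tau_s=e.tau,
             delta_s=e.delta, pair_id=e.pair_id)
        for e in gt.events
    ]
    pd.DataFrame(rows).to_csv(events_csv_path, index=False)
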