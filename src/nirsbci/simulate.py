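"""Synthetic study generator: protocol schedules, task-dependent hemodynamic
responses with physiological noise, the optical forward model, and participant
characteristic profiles.

The generator emulates the study conditions end to end: five sessions of
three blocks, each block a 30-s baseline followed by 24 task intervals (20 s
task, 17 s rest), six mental tasks four times per block in random order, nine
channels sampled at 31.25 Hz. Task responses are a canonical double-gamma HRF
convolved with the 20-s task boxcar, scaled by a task- and channel-specific
amplitude map; noise includes the Mayer wave (~0.1 Hz), respiration
(0.2-0.4 Hz), the cardiac cycle (0.5-2.0 Hz), 1/f drift, and white noise.
Every stochastic component draws from a named stream derived from one seed,
so components are individually re-generable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .montage import Montage
from .optics import (
    CHROMOPHORES,
    HemodynamicRecording,
    OpticsError,
    OpticsParameters,
    RawIntensityRecording,
)

TASKS = ("MM", "WG", "HT", "RF", "RS", "RR")
#: Protocol constants (seconds)
BASELINE_S = 30.0
TASK_S = 20.0
REST_S = 17.0
DEFAULT_FS = 31.25


def stream(seed: int, *names: str) -> np.random.Generator:
    """Named, order-independent child RNG stream of a master seed."""
    key = tuple(zlib.crc32(str(n).encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


class ProtocolError(ValueError):
    pass


def generate_protocol(
    n_sessions: int = 5,
    n_blocks: int = 3,
    tasks: tuple[str, ...] = TASKS,
    reps: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Event schedule for the block-design protocol.

    Each block: one 30-s baseline, then ``reps * len(tasks)`` task intervals
    (20 s task + 17 s rest), each task exactly ``reps`` times per block in an
    order randomized within the block. Onsets are absolute within a session
    (blocks run back to back).

    Returns a DataFrame with columns session, block, interval (-1 for
    baseline), onset_s, duration_s, task, phase.
    """
    tasks = tuple(tasks)
    if len(set(tasks)) != len(tasks):
        raise ProtocolError("duplicate task labels")
    n_intervals = reps * len(tasks)
    rows = []
    block_len = BASELINE_S + n_intervals * (TASK_S + REST_S)
    for s in range(n_sessions):
        for b in range(n_blocks):
            rng = stream(seed, "protocol", f"s{s}", f"b{b}")
            order = np.repeat(np.arange(len(tasks)), reps)
            rng.shuffle(order)
            t0 = b * block_len
            rows.append((s, b, -1, t0, BASELINE_S, "", "baseline"))
            t = t0 + BASELINE_S
            for i, ti in enumerate(order):
                rows.append((s, b, i, t, TASK_S, tasks[ti], "task"))
                rows.append((s, b, i, t + TASK_S, REST_S, tasks[ti], "rest"))
                t += TASK_S + REST_S
    return pd.DataFrame(
        rows,
        columns=["session", "block", "interval", "onset_s", "duration_s", "task", "phase"],
    )


def session_duration_s(schedule: pd.DataFrame, session: int) -> float:
    sub = schedule[schedule["session"] == session]
    return float((sub["onset_s"] + sub["duration_s"]).max())


# ---------------------------------------------------------------------------
# Effect and noise specifications
# ---------------------------------------------------------------------------

#: Task-specific spatial signatures of the HbO response over the 9 channels
#: (unitless; multiplied by ``amplitude_uM``). Chosen so that task pairs span
#: a wide range of separability: MM and RF have strong, opposite-signed
#: patterns (the most separable pair), WG shadows MM, RS shadows HT at lower
#: amplitude, and RR is near-silent.
DEFAULT_SIGNATURES = {
    "MM": (1.0, 1.0, 0.8, 0.5, 0.2, 0.0, 0.0, 0.1, 0.3),
    "WG": (0.7, 0.6, 0.5, 0.4, 0.1, 0.1, 0.0, 0.1, 0.2),
    "HT": (0.0, 0.2, 0.4, 0.6, 0.5, 0.3, 0.2, 0.1, 0.0),
    "RF": (-0.2, -0.4, -0.6, -0.9, -1.0, -0.9, -0.6, -0.4, -0.2),
    "RS": (0.0, 0.1, 0.2, 0.3, 0.25, 0.15, 0.1, 0.05, 0.0),
    "RR": (0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05),
}


@dataclass(frozen=True)
class EffectSpec:
    """Task-dependent hemodynamic response amplitudes and HRF shape.

    ``amplitude_uM`` scales the HbO signatures (peak boxcar-response
    amplitude, micromolar); the Hb response mirrors HbO scaled by
    ``hbr_ratio`` (typically negative and smaller, as in real hemodynamics);
    tHb is their sum by construction. Two sources of trial-to-trial
    variability emulate the inconsistency of mental-task activation that
    limits real BCI accuracy: ``amplitude_jitter`` (s.d. of a per-trial
    lognormal scale on the whole pattern) and ``trial_noise_uM`` (s.d. of a
    per-trial, per-channel additive activation that follows the same HRF
    time course, fully correlated across chromophores like a systemic
    component).
    """

    signatures: dict = field(default_factory=lambda: dict(DEFAULT_SIGNATURES))
    amplitude_uM: float = 0.4
    hbr_ratio: float = -0.35
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_ratio: float = 1.0 / 6.0
    amplitude_jitter: float = 0.3
    trial_noise_uM: float = 0.5

    def scaled(self, factor: float) -> "EffectSpec":
        return replace(self, amplitude_uM=self.amplitude_uM * factor)

    @classmethod
    def strong(cls) -> "EffectSpec":
        """High-amplitude preset: the default signatures at three times the
        default amplitude, emulating a consistent strong responder."""
        return cls().scaled(3.0)

    def amplitudes(self, tasks: tuple[str, ...], n_channels: int) -> np.ndarray:
        """(n_tasks, n_channels, 3) amplitude array (HbO, Hb, tHb), uM."""
        amp = np.zeros((len(tasks), n_channels, 3))
        for i, t in enumerate(tasks):
            sig = np.asarray(self.signatures.get(t, np.zeros(n_channels)), dtype=float)
            if sig.size != n_channels:
                raise ValueError(f"signature for task {t!r} has {sig.size} != {n_channels} channels")
            if not np.all(np.isfinite(sig)):
                raise ValueError(f"non-finite amplitude for task {t!r}")
            amp[i, :, 0] = self.amplitude_uM * sig
            amp[i, :, 1] = self.amplitude_uM * self.hbr_ratio * sig
        amp[:, :, 2] = amp[:, :, 0] + amp[:, :, 1]
        return amp


@dataclass(frozen=True)
class NoiseSpec:
    """Physiological and instrumental noise levels.

    Oscillation amplitudes are HbO micromolar; the Hb components are the same
    processes scaled by ``hbr_ratio``. Default center frequencies (0.1, 0.3,
    1.1 Hz) sit inside the Mayer, respiration, and cardiac bands.
    """

    mayer_hz: float = 0.1
    mayer_uM: float = 0.20
    mayer_phase_jitter: float = 0.01  # rad/sample random-walk s.d.
    resp_band_hz: tuple[float, float] = (0.2, 0.4)
    resp_uM: float = 0.10
    cardiac_hz: float = 1.1
    cardiac_uM: float = 0.10
    drift_exponent: float = 1.0
    drift_uM: float = 0.20
    white_uM: float = 0.05
    intensity_rel_sd: float = 1e-3
    hbr_ratio: float = 0.4

    @classmethod
    def silent(cls) -> "NoiseSpec":
        return cls(
            mayer_uM=0.0, resp_uM=0.0, cardiac_uM=0.0,
            drift_uM=0.0, white_uM=0.0, intensity_rel_sd=0.0,
        )


def double_gamma_hrf(t: np.ndarray, peak_s: float = 6.0, undershoot_s: float = 16.0,
                     ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1."""
    t = np.asarray(t, dtype=float)

    def gpdf(t, a, b=1.0):
        out = np.zeros_like(t)
        pos = t > 0
        logp = (a - 1) * np.log(t[pos] * b) + np.log(b) - t[pos] * b - gammaln(a)
        out[pos] = np.exp(logp)
        return out

    h = gpdf(t, peak_s) - ratio * gpdf(t, undershoot_s)
    m = h.max()
    return h / m if m > 0 else h


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1] if n > 1 else 1.0
    spec *= freqs ** (-exponent / 2.0)
    spec[0] = 0.0
    out = np.fft.irfft(spec, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _noise_component(name: str, noise: NoiseSpec, n: int, fs: float,
                     rng: np.random.Generator) -> np.ndarray:
    """One noise process, unit amplitude handled by the caller's scaling."""
    t = np.arange(n) / fs
    if name == "mayer":
        phase = rng.uniform(0, 2 * np.pi) + np.cumsum(
            rng.standard_normal(n) * noise.mayer_phase_jitter
        )
        return np.sin(2 * np.pi * noise.mayer_hz * t + phase)
    if name == "resp":
        f = rng.uniform(*noise.resp_band_hz)
        return np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if name == "cardiac":
        return np.sin(2 * np.pi * noise.cardiac_hz * t + rng.uniform(0, 2 * np.pi))
    if name == "drift":
        return _pink_noise(rng, n, noise.drift_exponent)
    if name == "white":
        return rng.standard_normal(n)
    raise KeyError(name)


_NOISE_AMPS = {
    "mayer": "mayer_uM", "resp": "resp_uM", "cardiac": "cardiac_uM",
    "drift": "drift_uM", "white": "white_uM",
}


def noise_series(noise: NoiseSpec, n: int, fs: float, seed: int, session: int,
                 channel: int, component: str | None = None) -> np.ndarray:
    """(2, n) additive noise for (HbO, Hb) on one channel; components sum.

    ``component`` restricts to a single named process ("mayer", "resp",
    "cardiac", "drift", "white"), reproducing exactly its contribution to the
    full mixture.
    """
    names = [component] if component else list(_NOISE_AMPS)
    out = np.zeros((2, n))
    for name in names:
        amp = getattr(noise, _NOISE_AMPS[name])
        if amp == 0:
            continue
        rng = stream(seed, "noise", name, f"s{session}", f"c{channel}")
        base = _noise_component(name, noise, n, fs, rng)
        rng_h = stream(seed, "noise", name, f"s{session}", f"c{channel}", "hbr")
        base_h = _noise_component(name, noise, n, fs, rng_h)
        out[0] += amp * base
        out[1] += amp * noise.hbr_ratio * base_h
    return out


def simulate_hemodynamics(
    schedule: pd.DataFrame,
    effects: EffectSpec,
    noise: NoiseSpec,
    montage: Montage,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    participant: str = "P0",
) -> list[HemodynamicRecording]:
    """Per-session concentration-change recordings implied by the schedule.

    Each task interval contributes ``amplitude * jitter * (HRF conv boxcar)``
    on every channel, per the effect signatures; noise components add on top.
    tHb is exactly HbO + Hb at every sample.
    """
    if fs <= 2 * noise.cardiac_hz:
        raise ProtocolError(
            f"sampling rate {fs} Hz cannot represent cardiac noise at {noise.cardiac_hz} Hz"
        )
    n_ch = montage.n_channels
    tasks = tuple(sorted(set(schedule.loc[schedule["phase"] == "task", "task"]))) or TASKS
    amps = effects.amplitudes(tasks, n_ch)  # (task, ch, 3)
    recordings = []
    for s in sorted(schedule["session"].unique()):
        sub = schedule[schedule["session"] == s]
        n = int(round(session_duration_s(schedule, s) * fs))
        # HRF kernel out to 32 s
        tk = np.arange(int(round(32 * fs))) / fs
        hrf = double_gamma_hrf(tk, effects.hrf_peak_s, effects.hrf_undershoot_s,
                               effects.hrf_ratio)
        rng_j = stream(seed, "jitter", f"s{s}", participant)
        # per-channel stimulus trains: scaled task pattern plus per-trial,
        # per-channel activation noise (shared across chromophores)
        stim = np.zeros((n_ch, 2, n))
        task_rows = sub[sub["phase"] == "task"].sort_values("onset_s")
        for row in task_rows.itertuples():
            ti = tasks.index(row.task)
            jit = float(np.exp(rng_j.normal(0.0, effects.amplitude_jitter)))
            extra = rng_j.normal(0.0, effects.trial_noise_uM, n_ch)
            i0 = int(round(row.onset_s * fs))
            i1 = min(int(round((row.onset_s + row.duration_s) * fs)), n)
            stim[:, 0, i0:i1] += (amps[ti, :, 0] * jit + extra)[:, None]
            stim[:, 1, i0:i1] += (amps[ti, :, 1] * jit
                                  + effects.hbr_ratio * extra)[:, None]

        data = np.zeros((n_ch, 3, n))
        for ch in range(n_ch):
            nz = noise_series(noise, n, fs, seed, s, ch)
            data[ch, 0] = np.convolve(stim[ch, 0], hrf)[:n] + nz[0]
            data[ch, 1] = np.convolve(stim[ch, 1], hrf)[:n] + nz[1]
        data[:, 2] = data[:, 0] + data[:, 1]
        recordings.append(
            HemodynamicRecording(fs=fs, data=data, session=int(s), participant=participant)
        )
    return recordings


def hemodynamics_to_intensity(
    hemo: HemodynamicRecording,
    optics: OpticsParameters,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    i0: float = 1.0,
) -> RawIntensityRecording:
    """Optical forward model: concentrations to raw dual-wavelength intensity.

    I(t) = I0 * 10^-(eps_HbO * dHbO + eps_Hb * dHb) * d * DPF) * (1 + noise),
    with multiplicative measurement noise of relative s.d.
    ``noise.intensity_rel_sd``. The exact inverse of the MBLL conversion when
    noise is disabled.
    """
    if i0 <= 0:
        raise OpticsError("reference intensity I0 must be positive")
    eps = optics.extinction_matrix()
    L = optics.distance_cm * np.asarray(optics.dpf, dtype=float)
    conc_mM = hemo.data[:, :2, :] * 1e-3  # (ch, 2, n)
    od = np.einsum("wk,ckn->cwn", eps * L[:, None], conc_mM)
    intensity = i0 * np.power(10.0, -od)
    rel_sd = noise.intensity_rel_sd if noise is not None else 0.0
    if rel_sd > 0:
        rng = stream(seed, "intensity-noise", f"s{hemo.session}", hemo.participant)
        factor = 1.0 + rel_sd * rng.standard_normal(intensity.shape)
        intensity = intensity * np.clip(factor, 0.01, None)
    return RawIntensityRecording(
        fs=hemo.fs,
        data=intensity,
        wavelengths=tuple(optics.wavelengths),
        session=hemo.session,
        participant=hemo.participant,
    )


# ---------------------------------------------------------------------------
# Participant cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticipantSpec:
    """Cohort generator settings.

    ``iq_coupling`` links verbal IQ to each participant's effect amplitude
    scale via scale = exp(coupling * z(IQ)); a negative value makes
    lower-IQ participants produce larger hemodynamic responses (the direction
    reported for prefrontal neural-efficiency effects). 0 decouples them.
    """

    n_participants: int = 10
    iq_mean: float = 100.0
    iq_sd: float = 12.0
    likert_means: dict = field(default_factory=lambda: {
        "tiredness": 3.5, "concentration": 4.8, "enjoyment": 5.0,
        "ease_of_session": 4.6, "headgear_comfort": 5.3,
    })
    likert_sd: float = 1.0
    p_female: float = 0.6
    p_right_handed: float = 0.8
    iq_coupling: float = 0.0
    scale_jitter: float = 0.15
    missing_iq: int | None = None  # participant index that skipped the IQ test


LIKERT_ITEMS = ("tiredness", "concentration", "enjoyment", "ease_of_session",
                "headgear_comfort")
AGE_RANGES = ("20-29", "30-39", "40-49")


def simulate_participants(
    spec: ParticipantSpec, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Participant profiles plus per-participant effect amplitude scales.

    Returns (profiles, scales): profiles is a DataFrame with one row per
    participant (verbal IQ, session-averaged Likert items in [1, 7], gender,
    handedness, age range); scales multiplies ``EffectSpec.amplitude_uM``
    for the corresponding participant.
    """
    n = spec.n_participants
    rng = stream(seed, "participants")
    iq = rng.normal(spec.iq_mean, spec.iq_sd, n)
    likert = {
        item: np.clip(rng.normal(spec.likert_means[item], spec.likert_sd, n), 1.0, 7.0)
        for item in LIKERT_ITEMS
    }
    gender = np.where(rng.uniform(size=n) < spec.p_female, "F", "M")
    hand = np.where(rng.uniform(size=n) < spec.p_right_handed, "R", "L")
    age = rng.choice(AGE_RANGES, size=n, p=(0.7, 0.2, 0.1))

    z = (iq - spec.iq_mean) / spec.iq_sd
    scales = np.exp(spec.iq_coupling * z + rng.normal(0.0, spec.scale_jitter, n))

    profiles = pd.DataFrame({
        "participant": [f"P{i + 1}" for i in range(n)],
        "verbal_iq": iq.round(1),
        **{item: likert[item].round(2) for item in LIKERT_ITEMS},
        "gender": gender,
        "handedness": hand,
        "age_range": age,
    })
    if spec.missing_iq is not None:
        profiles.loc[spec.missing_iq, "verbal_iq"] = np.nan
    return profiles, scales


def sample_exclusions(
    schedule: pd.DataFrame, max_per_class: int = 4, seed: int = 0,
    tasks: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Randomly drawn discarded trials (at most ``max_per_class`` per task),
    emulating manual rejection of motion-contaminated intervals.

    Returns a DataFrame (session, block, interval, task, reason).
    """
    rng = stream(seed, "exclusions")
    task_rows = schedule[schedule["phase"] == "task"]
    out = []
    for task in tasks or sorted(task_rows["task"].unique()):
        rows = task_rows[task_rows["task"] == task]
        k = int(rng.integers(0, max_per_class + 1))
        for idx in rng.choice(len(rows), size=min(k, len(rows)), replace=False):
            r = rows.iloc[int(idx)]
            out.append((int(r["session"]), int(r["block"]), int(r["interval"]),
                        task, "motion"))
    return pd.DataFrame(out, columns=["session", "block", "interval", "task", "reason"])
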