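"""Synthetic ERP cohorts with known microstate structure.

The generator emulates the experimental design the analysis targets: 90
trials per participant split over three conditions (Neg: negative
picture + negative description; Rea: negative picture + neutral
description, i.e. reappraisal; Neu: both neutral), a music group of 28
participants and a control group of 24, 64-channel epochs from -200 to
5000 ms.

Each epoch is a piecewise-constant sequence of scalp topographies
(`templates`) multiplied by a smooth positive amplitude envelope, plus
spatially white Gaussian noise scaled to a configured GFP signal-to-
noise ratio. The topographies, the per-sample state sequence and the
pairwise phase-coupling targets are returned as ground truth so every
downstream stage (clustering, model selection, back-fitting, PLV) can
be validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from msconn.config import CONDITIONS, GeneratorConfig
from msconn.preprocess import EpochedData, times_for_window

_CONDITION_VALENCE = {
    # condition -> (picture_valence, description_valence)
    "Neg": ("negative", "negative"),
    "Rea": ("negative", "neutral"),
    "Neu": ("neutral", "neutral"),
}


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery checks."""

    template_maps: np.ndarray  # channels x k, average-referenced, unit GFP
    label_sequence: np.ndarray  # true class per sample (shared across trials)
    envelope: np.ndarray  # µV amplitude per sample
    noise_scale: float
    pairwise_plv: np.ndarray | None = None


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# trial schedule & ratings
# ---------------------------------------------------------------------------

def make_trial_schedule(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Randomized trial order with exact per-condition counts.

    The design pairs every negative picture with either a negative or a
    neutral description (Neg vs Rea) and every neutral picture with a
    neutral description (Neu), 30 trials each by default.
    """
    n = config.n_trials_per_condition
    if n < 0:
        raise ValueError("trial counts must be nonnegative")
    rng = _rng(config.seed if seed is None else seed)
    conditions = np.repeat(list(CONDITIONS), n)
    rng.shuffle(conditions)
    rows = []
    for i, cond in enumerate(conditions):
        pic, desc = _CONDITION_VALENCE[cond]
        rows.append((i, cond, pic, desc))
    return pd.DataFrame(
        rows, columns=["trial_id", "condition", "picture_valence", "description_valence"]
    )


def simulate_ratings(
    cell_means: dict[tuple[str, str], float],
    sd: float,
    n_per_group: dict[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-participant mean ratings, Normal(cell mean, sd) clipped to [1, 9].

    ``cell_means`` maps (group, condition) to the cell mean on the
    9-point rating scale (1 = extremely negative, 9 = highly positive
    for valence; 1 = calm, 9 = aroused for arousal).
    """
    if sd < 0:
        raise ValueError("rating SD must be nonnegative")
    rng = _rng(seed)
    rows = []
    pid = 0
    for group, n in n_per_group.items():
        for _ in range(n):
            participant = f"{group}_{pid:03d}"
            pid += 1
            for cond in CONDITIONS:
                mu = cell_means[(group, cond)]
                val = float(np.clip(rng.normal(mu, sd), 1.0, 9.0))
                rows.append((participant, group, cond, val))
    return pd.DataFrame(rows, columns=["participant", "group", "condition", "value"])


# ---------------------------------------------------------------------------
# topographic templates
# ---------------------------------------------------------------------------

def electrode_positions(n_channels: int) -> np.ndarray:
    """Deterministic 2-D electrode layout: a sunflower spiral on the
    unit disk, a reasonable stand-in for a flattened scalp montage."""
    i = np.arange(n_channels)
    r = np.sqrt((i + 0.5) / n_channels)
    theta = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _smooth_map(xy: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # random cubic polynomial over the layout -> smooth dipolar-like pattern
    x, y = xy[:, 0], xy[:, 1]
    basis = np.column_stack(
        [x, y, x * y, x**2 - y**2, x**2 + y**2, x**3, y**3, x**2 * y, x * y**2]
    )
    return basis @ rng.normal(size=basis.shape[1])


def _normalize_map(m: np.ndarray) -> np.ndarray:
    m = m - m.mean()
    gfp = np.sqrt(np.mean(m**2))
    if gfp == 0:
        raise ValueError("degenerate (constant) map cannot be normalized")
    return m / gfp


def make_template_set(
    n_channels: int,
    k: int,
    seed: int = 0,
    max_corr: float = 0.5,
    max_attempts: int = 2000,
) -> np.ndarray:
    """k average-referenced, unit-GFP topographies with pairwise
    \\|spatial correlation\\| <= ``max_corr`` (channels x k).

    Maps are drawn as random smooth spatial polynomials over the
    electrode layout and redrawn until sufficiently decorrelated, which
    keeps clustering nontrivial but identifiable.
    """
    if k < 2:
        raise ValueError("need at least 2 templates")
    if n_channels < k:
        raise ValueError(f"need n_channels >= k, got {n_channels} < {k}")
    rng = _rng(seed)
    xy = electrode_positions(n_channels)
    maps: list[np.ndarray] = []
    attempts = 0
    while len(maps) < k:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not draw {k} maps with pairwise |r| <= {max_corr} "
                f"in {max_attempts} attempts"
            )
        cand = _normalize_map(_smooth_map(xy, rng))
        if all(abs(float(np.dot(cand, m)) / n_channels) <= max_corr for m in maps):
            maps.append(cand)
    return np.column_stack(maps)


# ---------------------------------------------------------------------------
# epochs
# ---------------------------------------------------------------------------

def _label_sequence(
    times: np.ndarray, k: int, duration_range_ms: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Piecewise-constant class labels; consecutive segments differ."""
    lo, hi = duration_range_ms
    total = times[-1] - times[0]
    labels = np.empty(len(times), dtype=int)
    t0 = times[0]
    prev = -1
    while t0 <= times[-1]:
        dur = rng.uniform(lo, hi)
        choices = [c for c in range(k) if c != prev]
        cls = int(rng.choice(choices))
        labels[(times >= t0) & (times < t0 + dur)] = cls
        prev = cls
        t0 += dur
        if total <= 0:
            break
    return labels


def amplitude_envelope(times: np.ndarray) -> np.ndarray:
    """Smooth, strictly positive ERP-like amplitude profile (µV).

    The pre-stimulus baseline sits at a small floor (so baseline
    correction behaves as on real recordings, where the baseline is
    signal-free, while every sample stays identifiable in the
    noiseless limit); a sigmoid onset ramp followed by Gaussian bumps
    imitates early, mid and late ERP components.
    """
    times = np.asarray(times, dtype=float)
    env = np.full_like(times, 0.05)
    ramp = 1.0 / (1.0 + np.exp(-(times - 80.0) / 40.0))
    bumps = np.zeros_like(times)
    for center, width, amp in ((300.0, 150.0, 4.0), (1000.0, 400.0, 3.0), (2800.0, 900.0, 2.5)):
        bumps += amp * np.exp(-0.5 * ((times - center) / width) ** 2)
    return env + ramp * bumps


def perturb_templates(
    templates: np.ndarray, variability: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Individual variant of a group template set.

    Each map is displaced by ``variability`` times a fresh random
    smooth map and renormalized; 0.3 yields individual-to-group
    spatial correlations around 0.95, in line with how strongly
    individual microstate maps typically resemble their group
    template.
    """
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed)
    templates = np.asarray(templates, dtype=float)
    if variability == 0:
        return templates.copy()
    xy = electrode_positions(templates.shape[0])
    out = np.empty_like(templates)
    for j in range(templates.shape[1]):
        pert = _normalize_map(_smooth_map(xy, rng))
        out[:, j] = _normalize_map(templates[:, j] + variability * pert)
    return out


def simulate_erp(
    templates: np.ndarray,
    schedule: pd.DataFrame,
    config: GeneratorConfig,
    seed: int = 0,
    participant_id: str = "p0",
    group: str = "control",
) -> tuple[EpochedData, GroundTruth]:
    """Epochs for one participant: state sequence x envelope + noise.

    All trials of a participant share one ground-truth label sequence
    (the evoked state sequence is a property of the response, trial
    noise is not), so the per-condition trial average has the same
    microstate structure as each trial.

    Noise is spatially and temporally white Gaussian, scaled such that
    the ratio of mean signal GFP to expected noise GFP equals
    ``config.snr``. ``snr=inf`` yields noiseless epochs.
    """
    if config.snr <= 0:
        raise ValueError("snr must be positive")
    templates = np.asarray(templates, dtype=float)
    if templates.ndim != 2:
        raise ValueError("templates must be channels x k")
    n_channels, k = templates.shape
    if len(schedule) == 0:
        raise ValueError("schedule must contain at least one trial")
    rng = _rng(seed)
    times = times_for_window(config.epoch_window, config.sampling_rate)
    labels = _label_sequence(times, k, config.segment_duration_range, rng)
    env = amplitude_envelope(times)

    signal = templates[:, labels] * env  # channels x samples, GFP(t) = env(t)
    n_trials = len(schedule)
    # centered white noise has expected GFP ~ sigma * sqrt((N-1)/N)
    mean_signal_gfp = float(env.mean())
    sigma = 0.0 if np.isinf(config.snr) else mean_signal_gfp / (
        config.snr * np.sqrt((n_channels - 1) / n_channels)
    )
    noise = sigma * rng.standard_normal((n_trials, n_channels, len(times)))
    data = signal[None] + noise
    if config.average_reference:
        data = data - data.mean(axis=1, keepdims=True)

    epochs = EpochedData(
        data=data,
        sampling_rate=config.sampling_rate,
        times=times,
        conditions=schedule["condition"].to_numpy(),
        participant_id=participant_id,
        group=group,
        trial_ids=schedule["trial_id"].to_numpy(),
    )
    truth = GroundTruth(
        template_maps=templates, label_sequence=labels, envelope=env, noise_scale=sigma
    )
    return epochs, truth


def simulate_cohort(
    config: GeneratorConfig, seed: int | None = None, templates: np.ndarray | None = None
) -> tuple[list[EpochedData], dict[str, GroundTruth], np.ndarray]:
    """A full two-group cohort built around one group template set.

    Each participant receives an individually perturbed variant of the
    group templates (``config.template_variability``; the spread that
    makes averaging individual sets into a global mean template
    meaningful), plus an independent state sequence, trial order and
    noise. Returns ``(cohort, truths, group_templates)``; each
    participant's :class:`GroundTruth` carries their individual maps.
    """
    seed = config.seed if seed is None else seed
    n_total = config.n_participants_music + config.n_participants_control
    children = np.random.SeedSequence(seed).spawn(n_total + 1)
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    if templates is None:
        templates = make_template_set(config.n_channels, config.n_templates, seed=child_seeds[0])
    cohort: list[EpochedData] = []
    truths: dict[str, GroundTruth] = {}
    groups = [("music", config.n_participants_music), ("control", config.n_participants_control)]
    idx = 0
    for group, n in groups:
        for _ in range(n):
            pid = f"{group}_{idx:03d}"
            sub_seed = child_seeds[idx + 1]
            schedule = make_trial_schedule(config, seed=sub_seed)
            individual = perturb_templates(
                templates, config.template_variability, seed=sub_seed + 1
            )
            epochs, truth = simulate_erp(
                individual, schedule, config, seed=sub_seed, participant_id=pid, group=group
            )
            cohort.append(epochs)
            truths[pid] = truth
            idx += 1
    return cohort, truths, templates


# ---------------------------------------------------------------------------
# phase-coupled epochs
# ---------------------------------------------------------------------------

def _mean_resultant_length(kappa: float) -> float:
    # R(kappa) = I1(kappa) / I0(kappa), computed with scaled Bessels for stability
    return float(special.i1e(kappa) / special.i0e(kappa))


def kappa_for_plv(plv_target: float) -> float:
    """Von Mises concentration for which two independently jittered
    channels have expected PLV equal to ``plv_target``.

    With per-trial jitters delta1, delta2 ~ VonMises(0, kappa) the
    population phase-difference coherence is \\|E e^{i(d1-d2)}\\|
    = R(kappa)^2, so kappa solves R(kappa) = sqrt(plv_target).
    """
    if not 0.0 <= plv_target <= 1.0:
        raise ValueError("plv_target must be in [0, 1]")
    if plv_target == 0.0:
        return 0.0
    if plv_target == 1.0:
        return np.inf
    r = np.sqrt(plv_target)
    return float(optimize.brentq(lambda k: _mean_resultant_length(k) - r, 1e-9, 1e6))


def simulate_phase_coupled_epochs(
    n_trials: int,
    plv_target: float,
    n_samples: int,
    seed: int = 0,
    sampling_rate: float = 250.0,
    freq_hz: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-channel oscillatory epochs with a controlled phase-locking value.

    Both channels follow a common 10 Hz oscillator with a random phase
    per trial; each channel adds an independent, trial-constant von
    Mises jitter whose concentration is solved so the expected PLV
    equals ``plv_target``. Returns ``(signals, phases)``, both shaped
    trials x 2 x samples.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    kappa = kappa_for_plv(plv_target)
    rng = _rng(seed)
    t = np.arange(n_samples) / sampling_rate
    common = 2 * np.pi * freq_hz * t[None, :] + rng.uniform(0, 2 * np.pi, size=(n_trials, 1))
    if np.isinf(kappa):
        jitter = np.zeros((n_trials, 2))
    elif kappa == 0.0:
        jitter = rng.uniform(-np.pi, np.pi, size=(n_trials, 2))
    else:
        jitter = rng.vonmises(0.0, kappa, size=(n_trials, 2))
    phases = common[:, None, :] + jitter[:, :, None]
    signals = np.cos(phases)
    wrapped = np.angle(np.exp(1j * phases))
    return signals, wrapped
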