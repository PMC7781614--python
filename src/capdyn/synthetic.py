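"""Synthetic multi-site cohorts with planted recurring coactivation states.

The generator emulates the study design the pipeline targets: two
diagnostic groups scanned at three sites, ~160-frame TR=2 s component
time series in which a small number of whole-brain coactivation states
recur under a first-order Markov switching process. Group membership
changes only how often each state is occupied (via the transition
matrix), not the state patterns themselves, so recovered group effects
can be compared against planted occupancy differences.

Layers
------
``simulate_labels``        latent per-frame state sequences (Markov chain)
``simulate_subject``       one subject's time series = pattern + AR(1) noise
``simulate_participants``  demographics table (group, site, age, sex, handedness)
``simulate_motion``        per-frame FD traces plus matching realignment params
``simulate_cohort``        everything, reproducibly, from one seed
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .cohort import DEFAULT_NETWORKS, HANDEDNESS_LEVELS, ComponentTimeSeries


class SyntheticConfigError(ValueError):
    """Raised for invalid generator parameters."""


# ---------------------------------------------------------------------------
# state patterns


@dataclass(frozen=True)
class StatePatternSet:
    """K planted coactivation patterns over C components.

    ``patterns[k, c]`` is the mean activation of component ``c`` while
    state ``k`` is occupied. Patterns are block-structured over network
    labels: each state activates a distinct subset of networks and
    mildly deactivates another, so states are mutually distinguishable
    and network-organized like empirical CAPs.
    """

    patterns: np.ndarray  # (K, C)
    seed_component: int
    amplitude: float
    network_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "patterns", np.asarray(self.patterns, dtype=float))
        k, c = self.patterns.shape
        if self.amplitude <= 0:
            raise SyntheticConfigError("amplitude must be strictly positive")
        if not (0 <= self.seed_component < c):
            raise SyntheticConfigError("seed_component out of range")
        for i in range(k):
            for j in range(i + 1, k):
                if np.array_equal(self.patterns[i], self.patterns[j]):
                    raise SyntheticConfigError(f"states {i} and {j} are identical")
        if not np.any(self.patterns[:, self.seed_component] > 0):
            raise SyntheticConfigError(
                "seed component must be positively active in at least one state"
            )

    @property
    def n_states(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_components(self) -> int:
        return self.patterns.shape[1]


def make_pattern_set(
    n_components: int,
    n_states: int,
    network_map: Sequence[str] | None = None,
    seed_component: int = 0,
    amplitude: float = 1.0,
    rng: np.random.Generator | None = None,
    seed_active_states: Sequence[int] | None = None,
    jitter: float = 0.1,
) -> StatePatternSet:
    """Construct block-structured state patterns over network labels.

    Each state activates two networks at ``+amplitude`` and deactivates a
    third at ``-amplitude/2``; a small Gaussian jitter (``jitter *
    amplitude``) makes components within a block non-degenerate. The seed
    component is forced to ``+amplitude`` in ``seed_active_states`` (all
    states by default), so supra-threshold frame selection samples every
    state.
    """
    if n_states < 2:
        raise SyntheticConfigError("need at least 2 states")
    if n_components < n_states:
        raise SyntheticConfigError("need n_components >= n_states")
    if not (0 <= seed_component < n_components):
        raise SyntheticConfigError("seed_component out of range")
    if amplitude <= 0:
        raise SyntheticConfigError("amplitude must be strictly positive")
    rng = np.random.default_rng(0) if rng is None else rng
    if network_map is None:
        m = min(len(DEFAULT_NETWORKS), n_components)
        network_map = tuple(DEFAULT_NETWORKS[i % m] for i in range(n_components))
    network_map = tuple(network_map)
    if len(network_map) != n_components:
        raise SyntheticConfigError("network_map length must equal n_components")
    networks = sorted(set(network_map))
    m = len(networks)
    membership = np.array([networks.index(lbl) for lbl in network_map])

    patterns = np.zeros((n_states, n_components))
    for k in range(n_states):
        active = {(2 * k) % m, (2 * k + 1) % m}
        anti = (2 * k + 2) % m
        for c in range(n_components):
            if membership[c] in active:
                patterns[k, c] = amplitude
            elif membership[c] == anti and anti not in active:
                patterns[k, c] = -0.5 * amplitude
        patterns[k] += jitter * amplitude * rng.standard_normal(n_components)

    if seed_active_states is None:
        seed_active_states = range(n_states)
    for k in seed_active_states:
        patterns[k, seed_component] = amplitude

    return StatePatternSet(
        patterns=patterns,
        seed_component=seed_component,
        amplitude=amplitude,
        network_labels=network_map,
    )


# ---------------------------------------------------------------------------
# cohort configuration


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic two-group, multi-site cohort.

    Defaults describe the benchmark: 20 subjects per group, 3 sites,
    160 frames at TR = 2 s (before trimming to 155), 5 latent states
    whose occupancy differs between groups by 0.1 in state 2, Markov
    persistence 0.8, AR(1) observation noise with sd 0.9 against
    pattern amplitude 1 (pattern-RMS-to-noise ratio about 0.5), and
    head motion drawn from a gamma distribution with mean FD 0.16 mm.
    """

    n_subjects_per_group: int = 20
    groups: tuple[str, str] = ("TD", "ASD")
    n_sites: int = 3
    frames_per_subject: int = 160
    tr_seconds: float = 2.0
    occupancy_by_group: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "TD": (0.175, 0.300, 0.175, 0.175, 0.175),
            "ASD": (0.2, 0.2, 0.2, 0.2, 0.2),
        }
    )
    transition_persistence: float = 0.8
    noise_sd: float = 0.9
    ar1_coef: float = 0.3
    site_offset_sd: float = 0.2
    drift_slope_sd: float = 0.01
    spike_prob: float = 0.01
    spike_amp: float = 4.0
    fd_gamma_shape: float = 3.0
    fd_gamma_mean: float = 0.16
    high_motion_fraction: float = 0.0
    high_motion_scale: float = 5.0
    n_noise_components: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1 or self.n_sites < 1:
            raise SyntheticConfigError("need >= 1 subject per group and >= 1 site")
        if len(self.groups) != 2:
            raise SyntheticConfigError("exactly two group labels required")
        if self.tr_seconds <= 0 or self.frames_per_subject < 2:
            raise SyntheticConfigError("invalid scan geometry")
        if not (0 <= self.transition_persistence < 1):
            raise SyntheticConfigError("transition_persistence must lie in [0, 1)")
        if not (-1 < self.ar1_coef < 1):
            raise SyntheticConfigError("ar1_coef must lie in (-1, 1)")
        for name in ("noise_sd", "site_offset_sd", "drift_slope_sd", "spike_amp",
                     "fd_gamma_shape", "fd_gamma_mean"):
            if getattr(self, name) < 0:
                raise SyntheticConfigError(f"{name} must be nonnegative")
        if not (0 <= self.spike_prob <= 1) or not (0 <= self.high_motion_fraction <= 1):
            raise SyntheticConfigError("probabilities must lie in [0, 1]")
        k_ref = None
        for g in self.groups:
            if g not in self.occupancy_by_group:
                raise SyntheticConfigError(f"missing occupancy vector for group {g!r}")
            occ = np.asarray(self.occupancy_by_group[g], dtype=float)
            if np.any(occ < 0) or abs(occ.sum() - 1.0) > 1e-12:
                raise SyntheticConfigError(
                    f"occupancy for {g!r} must be nonnegative and sum to 1"
                )
            if k_ref is None:
                k_ref = occ.size
            elif occ.size != k_ref:
                raise SyntheticConfigError("occupancy vectors disagree on state count")

    @property
    def n_states(self) -> int:
        return len(next(iter(self.occupancy_by_group.values())))


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth: per-subject frame labels plus generator state."""

    true_labels: dict[str, np.ndarray]
    pattern_set: StatePatternSet
    config: CohortConfig

    def __post_init__(self) -> None:
        k = self.pattern_set.n_states
        for sid, lab in self.true_labels.items():
            lab = np.asarray(lab)
            if lab.size and (lab.min() < 0 or lab.max() >= k):
                raise SyntheticConfigError(f"labels for {sid} outside [0, {k})")


@dataclass(frozen=True)
class SyntheticCohort:
    """Bundle returned by :func:`simulate_cohort`."""

    subjects: tuple[ComponentTimeSeries, ...]
    participants: pd.DataFrame
    realignment: dict[str, np.ndarray]  # subject -> (T, 6)
    fd: dict[str, np.ndarray]  # subject -> (T,)
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# simulation layers


def transition_matrix(
    occupancy: Sequence[float], persistence: float
) -> np.ndarray:
    """Row-stochastic matrix with stationary distribution ``occupancy``.

    ``P = d*I + (1-d)*1 pi^T`` — the diagonal loading ``d`` sets dwell
    time while leaving the stationary distribution at ``pi`` exactly.
    """
    pi = np.asarray(occupancy, dtype=float)
    if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-12:
        raise SyntheticConfigError("occupancy must be a probability vector")
    if not (0 <= persistence < 1):
        raise SyntheticConfigError("persistence must lie in [0, 1)")
    k = pi.size
    return persistence * np.eye(k) + (1 - persistence) * np.tile(pi, (k, 1))


def _check_stochastic(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise SyntheticConfigError("transition matrix must be square")
    if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-10):
        raise SyntheticConfigError("transition matrix must be row-stochastic")
    return p


def stationary_distribution(p: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    p = _check_stochastic(p)
    w, v = np.linalg.eig(p.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def sample_markov_chain(
    p: np.ndarray,
    n_frames: int,
    rng: np.random.Generator,
    initial: Sequence[float] | None = None,
) -> np.ndarray:
    """Sample one state sequence; initial state from ``initial`` (default stationary)."""
    p = _check_stochastic(p)
    k = p.shape[0]
    pi0 = stationary_distribution(p) if initial is None else np.asarray(initial, float)
    cum = np.cumsum(p, axis=1)
    u = rng.random(n_frames)
    labels = np.empty(n_frames, dtype=np.int64)
    labels[0] = np.searchsorted(np.cumsum(pi0), u[0], side="right")
    for t in range(1, n_frames):
        labels[t] = np.searchsorted(cum[labels[t - 1]], u[t], side="right")
    return np.minimum(labels, k - 1)


def _ar1_noise(
    shape: tuple[int, int], sd: float, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) noise with marginal sd ``sd``; 50-frame burn-in."""
    if sd == 0:
        return np.zeros(shape)
    burn = 50
    w = rng.standard_normal((shape[0] + burn, shape[1]))
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    e = signal.lfilter([innov_sd], [1.0, -phi], w, axis=0)
    return e[burn:]


def simulate_subject(
    pattern_set: StatePatternSet,
    frames: int,
    transition: np.ndarray,
    noise_sd: float,
    ar1_coef: float,
    rng: np.random.Generator,
    initial: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One subject's frames x components data plus the planted label sequence.

    Frame ``t`` equals ``patterns[state_t]`` plus stationary AR(1)
    Gaussian noise, independently per component.
    """
    p = _check_stochastic(transition)
    if p.shape[0] != pattern_set.n_states:
        raise SyntheticConfigError("transition matrix size must match n_states")
    labels = sample_markov_chain(p, frames, rng, initial=initial)
    data = pattern_set.patterns[labels].copy()
    data += _ar1_noise((frames, pattern_set.n_components), noise_sd, ar1_coef, rng)
    return data, labels


def simulate_labels(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[list[str], list[str], dict[str, np.ndarray]]:
    """Latent layer only: subject ids, group of each subject, label sequences."""
    sids, sgroups, labels = [], [], {}
    i = 0
    for g in config.groups:
        p = transition_matrix(
            config.occupancy_by_group[g], config.transition_persistence
        )
        for _ in range(config.n_subjects_per_group):
            i += 1
            sid = f"sub-{i:03d}"
            sids.append(sid)
            sgroups.append(g)
            labels[sid] = sample_markov_chain(p, config.frames_per_subject, rng)
    return sids, sgroups, labels


def simulate_participants(
    config: CohortConfig,
    subject_ids: Sequence[str],
    subject_groups: Sequence[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Demographics roughly matching a 6-13-year-old, male-predominant sample."""
    n = len(subject_ids)
    sites = [f"site{chr(ord('A') + i % config.n_sites)}" for i in range(n)]
    ages = np.round(rng.uniform(6.0, 13.0, size=n), 1)
    sex = rng.choice(["M", "F"], size=n, p=[0.8, 0.2])
    hand = rng.choice(HANDEDNESS_LEVELS, size=n, p=[0.85, 0.12, 0.03])
    return pd.DataFrame(
        {
            "participant_id": list(subject_ids),
            "group": list(subject_groups),
            "site": sites,
            "age": ages,
            "sex": sex,
            "handedness": hand,
        }
    )


def simulate_motion(
    config: CohortConfig,
    subject_ids: Sequence[str],
    rng: np.random.Generator,
    radius_mm: float = 50.0,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-frame FD traces and 6-column realignment parameters.

    FD values (frame >= 1) are gamma draws; a configurable fraction of
    subjects is scaled up to be deliberately high-motion. Realignment
    parameters are built so their Power-formula FD reproduces the drawn
    trace exactly: each frame's displacement is assigned to one randomly
    chosen axis (rotations converted with the ``radius_mm`` sphere).
    """
    t = config.frames_per_subject
    scale = config.fd_gamma_mean / config.fd_gamma_shape
    fd_by_subject: dict[str, np.ndarray] = {}
    rp_by_subject: dict[str, np.ndarray] = {}
    for sid in subject_ids:
        mult = (
            config.high_motion_scale
            if rng.random() < config.high_motion_fraction
            else 1.0
        )
        fd = np.zeros(t)
        fd[1:] = rng.gamma(config.fd_gamma_shape, scale * mult, size=t - 1)
        axes = rng.integers(0, 6, size=t - 1)
        signs = rng.choice([-1.0, 1.0], size=t - 1)
        deltas = np.zeros((t - 1, 6))
        deltas[np.arange(t - 1), axes] = signs * fd[1:]
        deltas[:, 3:] /= radius_mm  # rotations in radians
        rp = np.zeros((t, 6))
        rp[1:] = np.cumsum(deltas, axis=0)
        fd_by_subject[sid] = fd
        rp_by_subject[sid] = rp
    return fd_by_subject, rp_by_subject


def simulate_cohort(
    config: CohortConfig,
    pattern_set: StatePatternSet | None = None,
) -> SyntheticCohort:
    """Generate the full cohort reproducibly from ``config.rng_seed``.

    Group effects enter only through the transition matrices. Site
    offsets (per site x component constants), per-subject linear drift
    and sporadic spikes are added on top of the state signal when their
    magnitudes are nonzero; with all three at zero each subject reduces
    exactly to :func:`simulate_subject` output.
    """
    master = np.random.default_rng(config.rng_seed)
    if pattern_set is None:
        pattern_set = make_pattern_set(
            n_components=69,
            n_states=config.n_states,
            amplitude=1.0,
            rng=master,
        )
    if pattern_set.n_states != config.n_states:
        raise SyntheticConfigError("pattern set and occupancy disagree on state count")

    c_signal = pattern_set.n_components
    c_total = c_signal + config.n_noise_components
    comp_ids = tuple(f"ic{j + 1:03d}" for j in range(c_total))
    networks = tuple(pattern_set.network_labels) + ("artifact",) * config.n_noise_components
    noise_flags = np.array([False] * c_signal + [True] * config.n_noise_components)
    seed_id = comp_ids[pattern_set.seed_component]

    n_total = 2 * config.n_subjects_per_group
    subject_rngs = master.spawn(n_total)
    motion_rng, demo_rng = master.spawn(2)

    sids, sgroups = [], []
    i = 0
    for g in config.groups:
        for _ in range(config.n_subjects_per_group):
            i += 1
            sids.append(f"sub-{i:03d}")
            sgroups.append(g)

    participants = simulate_participants(config, sids, sgroups, demo_rng)
    site_of = dict(zip(participants["participant_id"], participants["site"]))
    site_names = sorted(set(participants["site"]))
    site_offsets = {
        s: config.site_offset_sd * master.standard_normal(c_total)
        for s in site_names
    }

    subjects: list[ComponentTimeSeries] = []
    labels: dict[str, np.ndarray] = {}
    t = config.frames_per_subject
    for sid, g, srng in zip(sids, sgroups, subject_rngs):
        p = transition_matrix(
            config.occupancy_by_group[g], config.transition_persistence
        )
        core, lab = simulate_subject(
            pattern_set, t, p, config.noise_sd, config.ar1_coef, srng
        )
        data = np.zeros((t, c_total))
        data[:, :c_signal] = core
        if config.n_noise_components:
            data[:, c_signal:] = _ar1_noise(
                (t, config.n_noise_components), max(config.noise_sd, 1.0),
                config.ar1_coef, srng,
            )
        # nuisance structure, drawn after the core so zero magnitudes
        # leave the core draws untouched
        if config.site_offset_sd > 0:
            data += site_offsets[site_of[sid]]
        if config.drift_slope_sd > 0:
            slopes = config.drift_slope_sd * srng.standard_normal(c_total)
            data += np.arange(t)[:, None] * slopes[None, :]
        if config.spike_prob > 0:
            mask = srng.random((t, c_total)) < config.spike_prob
            amps = config.spike_amp * srng.choice([-1.0, 1.0], size=(t, c_total))
            data += mask * amps
        subjects.append(
            ComponentTimeSeries(
                subject_id=sid,
                data=data,
                tr_seconds=config.tr_seconds,
                component_ids=comp_ids,
                noise_flags=noise_flags,
                network_labels=networks,
                seed_component=seed_id,
            )
        )
        labels[sid] = lab

    fd, rp = simulate_motion(config, sids, motion_rng)
    truth = SyntheticTruth(true_labels=labels, pattern_set=pattern_set, config=config)
    return SyntheticCohort(
        subjects=tuple(subjects),
        participants=participants,
        realignment=rp,
        fd=fd,
        truth=truth,
    )
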