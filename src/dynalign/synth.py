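"""Synthetic two-photon-like population recordings from ground-truth circuits.

Recordings emulate chronic calcium imaging of mouse V1 during a go/no-go
visual discrimination task: ~100 neurons with cell-type labels
(PYR/PV/SOM/VIP), trials of 17 frames at 125 ms spacing spanning -1..1 s
around stimulus onset, three conditions (vertical ``V``, angled ``A``,
``gray``), per-trial running-speed traces and lick rasters, and matched
pre-/post-learning sessions.

Activity follows the same first-order autoregressive generative form the
fitting module estimates::

    r_t = (A + I) r_{t-1} + u_t(s) + xi * v_t + e_t,   e_t ~ N(0, Sigma_e)

The interaction matrix is built from an explicit eigenmode specification, so
each generated session has a known slow mode with a controlled alignment to
the stimulus-input discriminant.  Three learning scenarios are supported:

``realignment``
    the slowest mode's activation pattern rotates toward the input
    discriminant after learning; all time constants fixed.
``slowing``
    the discriminant-aligned mode's time constant lengthens after learning;
    all activation patterns fixed.
``null``
    pre and post circuits identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .linnet import network_from_modes

__all__ = [
    "CONDITIONS",
    "N_FRAMES",
    "CELL_TYPES",
    "GroundTruthCircuit",
    "PopulationRecording",
    "ScenarioSpec",
    "scenario_presets",
    "make_ground_truth_pair",
    "generate_recording",
    "generate_behavior",
]

CONDITIONS = ("V", "A", "gray")
N_FRAMES = 17  #: frames per trial, spanning -1..1 s
CELL_TYPES = ("PYR", "PV", "SOM", "VIP")
#: approximate cortical proportions of the four imaged classes
CELL_TYPE_FRACTIONS = (0.85, 0.08, 0.04, 0.03)


def _time_axis(Ts_ms: float, n_frames: int = N_FRAMES) -> np.ndarray:
    half = (n_frames - 1) // 2
    return (np.arange(n_frames) - half) * (Ts_ms / 1000.0)


@dataclass
class GroundTruthCircuit:
    """Known parameters of the generative autoregressive circuit.

    ``A`` is the discrete-time deviation interaction matrix (the transition
    matrix is ``A + I`` and must have spectral radius < 1).  ``u`` holds the
    stimulus-locked input for each condition at predicted frames 2..17
    (shape ``(3, 16, n_neurons)``, condition order ``V, A, gray``).
    """

    A: np.ndarray
    u: np.ndarray
    xi: np.ndarray
    resid_cov: np.ndarray
    Ts: float
    cell_types: np.ndarray
    zeta: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        if self.u.shape != (len(CONDITIONS), N_FRAMES - 1, n):
            raise ValueError("u must have shape (3, 16, n_neurons)")
        rho = np.max(np.abs(np.linalg.eigvals(self.A + np.eye(n))))
        if rho >= 1:
            raise ValueError(
                f"unstable circuit: spectral radius of A + I is {rho:.4f}"
            )
        if not np.allclose(self.resid_cov, self.resid_cov.T, atol=1e-10):
            raise ValueError("resid_cov must be symmetric")

    @property
    def n_neurons(self) -> int:
        return self.A.shape[0]

    @property
    def transition(self) -> np.ndarray:
        return self.A + np.eye(self.n_neurons)

    def baseline_state(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean and covariance of the pre-stimulus stationary distribution.

        Uses the gray-condition (baseline) input; the first trial frame is
        drawn from this distribution since the recursion only defines
        frames 2..17.
        """
        B = self.transition
        u0 = self.u[CONDITIONS.index("gray"), 0]
        mean = linalg.solve(np.eye(self.n_neurons) - B, u0)
        cov = linalg.solve_discrete_lyapunov(B, self.resid_cov)
        return mean, 0.5 * (cov + cov.T)


@dataclass
class PopulationRecording:
    """Trial x time x neuron activity tensor with behavior covariates."""

    activity: np.ndarray
    condition: np.ndarray
    time_axis: np.ndarray
    run_speed: np.ndarray
    licks: np.ndarray
    cell_types: np.ndarray
    Ts: float

    def __post_init__(self) -> None:
        n_trials, n_frames, n_neurons = self.activity.shape
        if self.condition.shape != (n_trials,):
            raise ValueError("one condition label per trial required")
        if self.time_axis.shape != (n_frames,):
            raise ValueError("time_axis must match the frame count")
        if np.any(np.diff(self.time_axis) <= 0):
            raise ValueError("time_axis must be strictly increasing")
        if self.run_speed.shape != (n_trials, n_frames):
            raise ValueError("run_speed must be trial x time")
        if self.licks.shape != (n_trials, n_frames):
            raise ValueError("licks must be trial x time")
        if self.cell_types.shape != (n_neurons,):
            raise ValueError("one cell-type label per neuron required")

    @property
    def n_trials(self) -> int:
        return self.activity.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[2]

    def trials_of(self, condition: str) -> np.ndarray:
        return np.flatnonzero(self.condition == condition)

    @property
    def post_stim_frames(self) -> np.ndarray:
        """Indices of the frames in the 0..1 s post-onset window."""
        return np.flatnonzero(self.time_axis >= -1e-9)


@dataclass
class ScenarioSpec:
    """Parameters of a matched pre/post-learning synthetic experiment.

    Each circuit carries a population of ``n_slow_modes`` slowly decaying
    modes (time constants ``slow_tau_ms`` +/- jitter) on top of a bed of
    fast background modes.  Alignment angles are measured between each slow
    mode's activation pattern and the input discriminant; with isotropic
    residuals a mode's normalized input SNR equals ``cos(angle)``.
    Defaults place the slow modes near 850 ms (the range where learning
    effects concentrate) and move their normalized SNR from ~0.08 to ~0.30
    under the realignment scenario, or their time constants from ~400 to
    ~900 ms at a fixed ~0.18 alignment under the slowing scenario.  The
    realignment endpoint deliberately sits above the 0.25 upper edge of
    the conditional-average analysis range while the slowing alignment
    sits inside it: realigned modes leave the domain of the
    tau-conditioned-on-SNR curve instead of registering there as a
    spurious influx of slow time constants.
    """

    scenario: str
    n_neurons: int = 100
    n_trials_per_condition: int = 500
    n_replicates: int = 8
    n_slow_modes: int = 3
    slow_tau_ms: float = 850.0
    slow_tau_jitter_ms: float = 75.0
    alignment_angle_pre: float = float(np.arccos(0.08))
    alignment_angle_post: float = float(np.arccos(0.30))
    slowing_alignment_angle: float = float(np.arccos(0.18))
    tau_pre_ms: float = 400.0
    tau_post_ms: float = 900.0
    fast_tau_range_ms: tuple[float, float] = (100.0, 300.0)
    delta_input: float = 1.0
    common_input: float = 1.0
    noise_scale: float = 1.0
    Ts: float = 125.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("realignment", "slowing", "null"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if min(self.n_neurons, self.n_trials_per_condition,
               self.n_replicates) < 1:
            raise ValueError("counts must be >= 1")


def scenario_presets(**overrides) -> dict[str, ScenarioSpec]:
    """The three shipped scenario presets, optionally with field overrides."""
    return {
        name: ScenarioSpec(scenario=name, **overrides)
        for name in ("realignment", "slowing", "null")
    }


def _assign_cell_types(n: int, rng: np.random.Generator) -> np.ndarray:
    counts = np.floor(np.asarray(CELL_TYPE_FRACTIONS) * n).astype(int)
    counts[0] += n - counts.sum()  # remainder to PYR
    labels = np.repeat(CELL_TYPES, counts)
    rng.shuffle(labels)
    return labels


def _circuit_from_modes(
    patterns: np.ndarray, taus_ms: np.ndarray, Ts: float
) -> np.ndarray:
    """Discrete deviation matrix from continuous-time modes.

    ``A_disc = exp(A_cont * Ts) - I`` with ``A_cont`` built so that its left
    eigenvectors are the given patterns and decay time constants the given
    taus (in ms).
    """
    net = network_from_modes(patterns, taus_ms)
    return linalg.expm(net.A * Ts) - np.eye(patterns.shape[0])


def make_ground_truth_pair(spec: ScenarioSpec) -> dict[str, GroundTruthCircuit]:
    """Matched pre/post circuits implementing the requested scenario.

    Both circuits share the neurons, stimulus inputs, running coefficients
    and residual covariance; only the eigenstructure of the interaction
    matrix differs, and only in the way the scenario prescribes.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_neurons
    Ts = spec.Ts
    k = spec.n_slow_modes
    if k + 1 >= n:
        raise ValueError("need n_neurons > n_slow_modes + 1")

    # random orthonormal frame: column 0 spans the input-discriminant
    # direction, columns 1..k the in-plane complements of the k slow
    # modes (one per mode, so their alignments are independent)
    Q = np.linalg.qr(rng.standard_normal((n, n)))[0]
    d = Q[:, 0]
    partners = Q[:, 1 : 1 + k].T

    lo, hi = spec.fast_tau_range_ms
    fast_taus = rng.uniform(lo, hi, size=n - k - 1)
    fast_patterns = Q[:, 1 + k :].T
    # One pattern must complete the basis inside the (k+1)-dimensional
    # subspace spanned by the discriminant and the slow-mode planes; the
    # residual of the discriminant after projecting out the slow patterns
    # keeps the basis near-orthogonal.  This "relay" mode carries most of
    # the discriminant input.  Its time constant sits in the scenario's
    # spectral gap, clear of both the planted modes (eigenvalue crowding
    # would smear its large alignment onto them) and the 650-1050 ms
    # window band of the conditional-average analysis (where its high
    # alignment would swamp the window means of both sessions).
    relay_tau = 575.0 if spec.scenario == "slowing" else 450.0
    jit = spec.slow_tau_jitter_ms

    def build(angle: float, center_tau: float,
              tau_offsets: np.ndarray) -> np.ndarray:
        slow_patterns = np.cos(angle) * d[None, :] \
            + np.sin(angle) * partners
        resid = d - slow_patterns.T @ (slow_patterns @ d)
        relay = resid / np.linalg.norm(resid)
        patterns = np.vstack([slow_patterns, relay, fast_patterns])
        taus = np.concatenate([
            center_tau + tau_offsets, [relay_tau], fast_taus
        ])
        return _circuit_from_modes(patterns, taus, Ts)

    offsets = rng.uniform(-jit, jit, size=k)
    if spec.scenario == "realignment":
        A_pre = build(spec.alignment_angle_pre, spec.slow_tau_ms, offsets)
        A_post = build(spec.alignment_angle_post, spec.slow_tau_ms,
                       offsets)
    elif spec.scenario == "slowing":
        A_pre = build(spec.slowing_alignment_angle, spec.tau_pre_ms,
                      offsets)
        A_post = build(spec.slowing_alignment_angle, spec.tau_post_ms,
                       offsets)
    else:  # null
        A_pre = build(spec.alignment_angle_pre, spec.slow_tau_ms, offsets)
        A_post = A_pre.copy()

    sigma = spec.noise_scale
    resid_cov = sigma**2 * np.eye(n)

    # stimulus-locked inputs: a shared baseline, a step response common to
    # both gratings, and a differential component along the discriminant
    u0 = 0.1 * rng.standard_normal(n) / np.sqrt(n)
    common = spec.common_input * Q[:, 2]
    time = _time_axis(Ts)[1:]  # predicted frames 2..17
    env = (time >= -1e-9).astype(float)
    u = np.zeros((len(CONDITIONS), N_FRAMES - 1, n))
    for c, name in enumerate(CONDITIONS):
        u[c] = u0
        if name in ("V", "A"):
            sign = 1.0 if name == "V" else -1.0
            u[c] += env[:, None] * (
                common + sign * 0.5 * spec.delta_input * d
            )

    xi = 0.05 * rng.standard_normal(n)
    cell_types = _assign_cell_types(n, rng)

    def circuit(A: np.ndarray, session: str) -> GroundTruthCircuit:
        return GroundTruthCircuit(
            A=A, u=u.copy(), xi=xi.copy(), resid_cov=resid_cov.copy(),
            Ts=Ts, cell_types=cell_types.copy(),
            meta={
                "scenario": spec.scenario,
                "session": session,
                "discriminant": d.copy(),
                "slow_tau_offsets_ms": offsets.copy(),
                "slow_tau_ms": {
                    "realignment": spec.slow_tau_ms,
                    "null": spec.slow_tau_ms,
                    "slowing": spec.tau_pre_ms if session == "pre"
                    else spec.tau_post_ms,
                }[spec.scenario],
            },
        )

    return {"pre": circuit(A_pre, "pre"), "post": circuit(A_post, "post")}


def generate_behavior(
    n_trials: int,
    conditions: np.ndarray,
    Ts: float,
    seed: int,
    lick_prob: dict | None = None,
    median_lick_s: dict | None = None,
    lick_sigma_log: float = 0.35,
    run_mean: float = 10.0,
    run_ar: float = 0.8,
    run_sd: float = 1.5,
) -> dict:
    """Running-speed traces and first-lick times/rasters for a session.

    Licking is more likely on vertical (go) trials than angled ones, and
    sampled first-lick times are stochastically later on hits than on false
    alarms (log-normal, default medians 1.24 s and 0.87 s).  Running speed
    is a nonnegative AR(1) process.  The raster marks the frame containing
    the first lick when it falls inside the -1..1 s trial window.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    conditions = np.asarray(conditions)
    if conditions.shape != (n_trials,):
        raise ValueError("one condition per trial required")
    lick_prob = {"V": 0.85, "A": 0.35, "gray": 0.05, **(lick_prob or {})}
    median_lick_s = {"V": 1.24, "A": 0.87, "gray": 0.87,
                     **(median_lick_s or {})}
    rng = np.random.default_rng(seed)
    time = _time_axis(Ts)
    n_frames = time.shape[0]

    run = np.empty((n_trials, n_frames))
    run[:, 0] = rng.normal(run_mean, run_sd, size=n_trials)
    for t in range(1, n_frames):
        run[:, t] = (
            run_mean
            + run_ar * (run[:, t - 1] - run_mean)
            + rng.normal(0.0, run_sd, size=n_trials)
        )
    np.clip(run, 0.0, None, out=run)

    licks = np.zeros((n_trials, n_frames), dtype=np.int8)
    first_lick = np.full(n_trials, np.nan)
    for i in range(n_trials):
        cond = str(conditions[i])
        if rng.random() < lick_prob.get(cond, 0.0):
            t_lick = median_lick_s[cond] * np.exp(
                lick_sigma_log * rng.standard_normal()
            )
            first_lick[i] = t_lick
            if t_lick <= time[-1]:
                licks[i, np.searchsorted(time, t_lick)] = 1
    return {"run_speed": run, "licks": licks, "first_lick_time": first_lick}


def generate_recording(
    gt: GroundTruthCircuit, n_trials_per_condition: int, seed: int
) -> PopulationRecording:
    """Simulate a session of trials from a ground-truth circuit.

    Each trial starts from the circuit's pre-stimulus stationary baseline
    distribution and then follows the autoregressive recursion with Gaussian
    residual noise, stimulus-locked input, and running-speed modulation
    (plus lick input when the circuit carries lick coefficients).
    """
    rng = np.random.default_rng(seed)
    n = gt.n_neurons
    n_trials = n_trials_per_condition * len(CONDITIONS)
    condition = np.repeat(CONDITIONS, n_trials_per_condition)

    behavior = generate_behavior(
        n_trials, condition, gt.Ts, seed=int(rng.integers(2**31))
    )
    run, licks = behavior["run_speed"], behavior["licks"]

    base_mean, base_cov = gt.baseline_state()
    sqrt_base = _cov_sqrt(base_cov)
    sqrt_resid = _cov_sqrt(gt.resid_cov)
    B = gt.transition

    activity = np.empty((n_trials, N_FRAMES, n))
    activity[:, 0] = (
        base_mean + rng.standard_normal((n_trials, n)) @ sqrt_base.T
    )
    cond_idx = np.array([CONDITIONS.index(c) for c in condition])
    for t in range(1, N_FRAMES):
        e = rng.standard_normal((n_trials, n)) @ sqrt_resid.T
        drive = gt.u[cond_idx, t - 1] + np.outer(run[:, t], gt.xi) + e
        if gt.zeta is not None:
            drive += np.outer(licks[:, t], gt.zeta)
        activity[:, t] = activity[:, t - 1] @ B.T + drive

    return PopulationRecording(
        activity=activity,
        condition=condition,
        time_axis=_time_axis(gt.Ts),
        run_speed=run,
        licks=licks,
        cell_types=gt.cell_types.copy(),
        Ts=gt.Ts,
    )


def _cov_sqrt(cov: np.ndarray) -> np.ndarray:
    """Matrix square root of a PSD covariance (zero allowed)."""
    if not np.any(cov):
        return np.zeros_like(cov)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    return evecs * np.sqrt(evals)


def spec_to_dict(spec: ScenarioSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["fast_tau_range_ms"] = list(d["fast_tau_range_ms"])
    return d


def spec_from_dict(d: dict) -> ScenarioSpec:
    d = dict(d)
    if "fast_tau_range_ms" in d:
        d["fast_tau_range_ms"] = tuple(d["fast_tau_range_ms"])
    return ScenarioSpec(**d)
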