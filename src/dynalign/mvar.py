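"""Multivariate autoregressive (MVAR) model fitting and mode analysis.

Each frame of population activity is regressed on the previous frame, a
stimulus-locked input that is free per (condition, time) cell, and the
running speed (optionally also a lick indicator)::

    r_t = (A + I) r_{t-1} + u_t(s) + xi * v_t [+ zeta * l_t] + e_t

The fit is ordinary least squares per neuron over frames 2..17 of all
trials of all three conditions.  Every derived statistic operates on the
fitted interaction matrix and inputs: input/output information and their
gain, impulse-response time constants, per-mode input SNRs and their
conditional averages, mode-density change maps, trial-shuffle null
distributions, cell-type loadings and perturbation pathways, behavioral
projections, trial-average SVD, and preferred-stimulus response changes.

Conventions
-----------
* The model is fit over the full -1..1 s window (frames 2..17 have a
  predecessor); all information and covariance statistics use the 9 frames
  in the 0..1 s post-stimulus window.
* The gray condition contributes its own stimulus-input columns to the fit
  but is excluded from discriminants and residual-covariance pooling.
* Near-singular covariances are ridge-regularized with
  ``eps = 1e-6 * mean(diag)`` and a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .synth import CONDITIONS, N_FRAMES, PopulationRecording

__all__ = [
    "MVARFit",
    "ModeStatistics",
    "InformationSummary",
    "fit_mvar",
    "fit_mvar_constrained",
    "discriminants",
    "information_summary",
    "impulse_time_constant",
    "random_discriminant_inputs",
    "mvar_modes",
    "pool_modes",
    "conditional_mode_averages",
    "mode_density_change",
    "shuffle_null",
    "scenario_analysis",
    "celltype_loading",
    "celltype_perturbation_response",
    "behavioral_stats",
    "trial_average_svd",
    "preferred_stim_changes",
]

RIDGE_FACTOR = 1e-6
TAU_CENTERS = np.arange(100.0, 1400.0 + 1e-9, 25.0)
TAU_HALF_WIDTH = 50.0
SNR_CENTERS = np.arange(0.025, 0.25 + 1e-9, 0.025)
SNR_HALF_WIDTH = 0.0125
#: time constants above the conditional-average analysis range are
#: truncated here; an eigenvalue estimated at the stability edge would
#: otherwise contribute an unbounded value to its window mean
TAU_CAP = 2000.0


@dataclass
class MVARFit:
    """Least-squares estimates of the autoregressive model for one session."""

    A: np.ndarray
    u: np.ndarray  # (n_conditions, n_frames - 1, n_neurons)
    xi: np.ndarray
    residuals: np.ndarray  # (n_trials, n_frames - 1, n_neurons)
    resid_cov: np.ndarray  # pooled over V/A trials, post-stimulus frames
    Ts: float
    condition: np.ndarray
    cell_types: np.ndarray
    time_axis: np.ndarray
    zeta: np.ndarray | None = None
    standardized: bool = False

    @property
    def n_neurons(self) -> int:
        return self.A.shape[0]

    @property
    def transition(self) -> np.ndarray:
        return self.A + np.eye(self.n_neurons)

    def mean_input(self, condition: str) -> np.ndarray:
        """Time-mean stimulus input over the post-stimulus window."""
        post = np.flatnonzero(self.time_axis >= -1e-9) - 1
        return self.u[CONDITIONS.index(condition), post].mean(axis=0)


@dataclass
class ModeStatistics:
    """Per-mode statistics of an interaction matrix.

    Restricted to non-oscillatory modes: real eigenvalue with
    ``lambda + 1 > 0`` so the discrete-to-continuous conversion
    ``tau = -Ts / log(lambda + 1)`` yields a real time constant.
    """

    eigenvalue: np.ndarray
    time_constant: np.ndarray  # ms
    input_snr: np.ndarray
    normalized_snr: np.ndarray
    patterns: np.ndarray  # (n_modes, n_neurons) left eigenvectors
    real_valid: np.ndarray

    @property
    def n_modes(self) -> int:
        return self.eigenvalue.shape[0]


@dataclass
class InformationSummary:
    """Input and output linear discriminability and their relative gain."""

    input_info: float
    output_info: float
    gain_percent: float = field(init=False)
    gain_defined: bool = field(init=False)

    def __post_init__(self) -> None:
        self.gain_defined = self.input_info > 0
        self.gain_percent = (
            100.0 * (self.output_info / self.input_info - 1.0)
            if self.gain_defined
            else float("nan")
        )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _check_recording(rec: PopulationRecording) -> None:
    for cond in CONDITIONS:
        n = rec.trials_of(cond).shape[0]
        if n < 2:
            raise ValueError(
                f"need at least 2 trials of condition {cond!r}, found {n}"
            )


def _design(
    activity: np.ndarray,
    cond_idx: np.ndarray,
    run_speed: np.ndarray,
    licks: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked regression design and target over frames 2..n_frames.

    The target is the per-frame increment ``r_t - r_{t-1}`` so the activity
    block's coefficient is the deviation matrix ``A`` itself.
    """
    n_trials, n_frames, n_neurons = activity.shape
    T = n_frames - 1
    prev = activity[:, :-1].reshape(n_trials * T, n_neurons)
    target = (activity[:, 1:] - activity[:, :-1]).reshape(
        n_trials * T, n_neurons
    )
    # condition x time indicator block
    t_idx = np.tile(np.arange(T), n_trials)
    c_idx = np.repeat(cond_idx, T)
    dummies = np.zeros((n_trials * T, len(CONDITIONS) * T))
    dummies[np.arange(n_trials * T), c_idx * T + t_idx] = 1.0
    cols = [prev, dummies, run_speed[:, 1:].reshape(-1, 1)]
    if licks is not None:
        cols.append(licks[:, 1:].reshape(-1, 1).astype(float))
    return np.hstack(cols), target


def _solve_lstsq(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    # normal-equation fast path; SVD fallback for degenerate designs
    gram = X.T @ X
    cond = np.linalg.cond(gram)
    if np.isfinite(cond) and cond < 1e10:
        return linalg.solve(gram, X.T @ Y, assume_a="pos")
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            "rank-deficient design (degenerate activity or behavior "
            "columns); minimum-norm solution used",
            RuntimeWarning,
        )
    return coef

def _pooled_resid_cov(
    residuals: np.ndarray, cond_idx: np.ndarray, post_resid: np.ndarray
) -> np.ndarray:
    va = np.isin(cond_idx, [CONDITIONS.index("V"), CONDITIONS.index("A")])
    e = residuals[va][:, post_resid]
    e2 = e.reshape(-1, e.shape[-1])
    return e2.T @ e2 / e2.shape[0]


def fit_mvar(
    rec: PopulationRecording,
    include_lick: bool = False,
    standardize: bool = False,
) -> MVARFit:
    """Ordinary least squares fit of the MVAR model to one session.

    With ``standardize=True`` each neuron's activity is z-scored before
    fitting and the returned parameters are in standardized units.
    """
    _check_recording(rec)
    activity = rec.activity
    if standardize:
        mu = activity.mean(axis=(0, 1))
        sd = activity.std(axis=(0, 1))
        sd[sd == 0] = 1.0
        activity = (activity - mu) / sd
    cond_idx = np.array([CONDITIONS.index(c) for c in rec.condition])
    licks = rec.licks if include_lick else None
    X, Y = _design(activity, cond_idx, rec.run_speed, licks)
    coef = _solve_lstsq(X, Y)

    n = rec.n_neurons
    T = N_FRAMES - 1
    A = coef[:n].T
    u = coef[n : n + len(CONDITIONS) * T].reshape(len(CONDITIONS), T, n)
    xi = coef[n + len(CONDITIONS) * T]
    zeta = coef[n + len(CONDITIONS) * T + 1] if include_lick else None

    residuals = (Y - X @ coef).reshape(rec.n_trials, T, n)
    post_resid = rec.post_stim_frames - 1
    resid_cov = _pooled_resid_cov(residuals, cond_idx, post_resid)
    return MVARFit(
        A=A, u=u, xi=xi, zeta=zeta, residuals=residuals,
        resid_cov=resid_cov, Ts=rec.Ts, condition=rec.condition.copy(),
        cell_types=rec.cell_types.copy(), time_axis=rec.time_axis.copy(),
        standardized=standardize,
    )


def fit_mvar_constrained(
    rec_pre: PopulationRecording,
    rec_post: PopulationRecording,
    shared: str,
) -> dict[str, MVARFit]:
    """Joint pre/post fit with one parameter block tied across sessions.

    ``shared="A"`` ties the interaction weights; ``shared="u"`` ties the
    stimulus-locked inputs; ``shared="both"`` reduces to a single pooled
    fit.  The running-speed coefficients are tied across sessions in every
    variant, as in the main model, so changes in running behavior can move
    activity only through the shared coefficients.
    """
    if shared not in ("A", "u", "both"):
        raise ValueError("shared must be 'A', 'u' or 'both'")
    if rec_pre.n_neurons != rec_post.n_neurons:
        raise ValueError("pre and post recordings must share neurons")
    _check_recording(rec_pre)
    _check_recording(rec_post)
    n = rec_pre.n_neurons
    T = N_FRAMES - 1
    nd = len(CONDITIONS) * T
    parts = []
    for rec in (rec_pre, rec_post):
        cond_idx = np.array([CONDITIONS.index(c) for c in rec.condition])
        X, Y = _design(rec.activity, cond_idx, rec.run_speed, None)
        parts.append((X, Y, cond_idx, rec))

    rows = [X.shape[0] for X, *_ in parts]
    blocks = []
    for k, (X, _, _, _) in enumerate(parts):
        prev, dummies, v = X[:, :n], X[:, n : n + nd], X[:, n + nd :]
        zero = lambda width: np.zeros((rows[k], width))  # noqa: E731
        row = []
        # interaction block(s)
        if shared in ("A", "both"):
            row.append(prev)
        else:
            row.extend([prev, zero(n)] if k == 0 else [zero(n), prev])
        # stimulus-input block(s)
        if shared in ("u", "both"):
            row.append(dummies)
        else:
            row.extend([dummies, zero(nd)] if k == 0
                       else [zero(nd), dummies])
        # running-speed block, tied across sessions
        row.append(v)
        blocks.append(np.hstack(row))
    X_all = np.vstack(blocks)
    Y_all = np.vstack([Y for _, Y, _, _ in parts])
    coef = _solve_lstsq(X_all, Y_all)

    # unpack per session
    off = 0
    if shared in ("A", "both"):
        A_blocks = [coef[off : off + n].T] * 2
        off += n
    else:
        A_blocks = [coef[off : off + n].T, coef[off + n : off + 2 * n].T]
        off += 2 * n
    if shared in ("u", "both"):
        u_blocks = [coef[off : off + nd].reshape(len(CONDITIONS), T, n)] * 2
        off += nd
    else:
        u_blocks = [
            coef[off : off + nd].reshape(len(CONDITIONS), T, n),
            coef[off + nd : off + 2 * nd].reshape(len(CONDITIONS), T, n),
        ]
        off += 2 * nd
    xi_blocks = [coef[off], coef[off]]

    fits = {}
    for k, (name, (X, Y, cond_idx, rec)) in enumerate(
        zip(("pre", "post"), parts)
    ):
        pred_rows = slice(sum(rows[:k]), sum(rows[: k + 1]))
        residuals = (Y_all[pred_rows] - X_all[pred_rows] @ coef).reshape(
            rec.n_trials, T, n
        )
        post_resid = rec.post_stim_frames - 1
        fits[name] = MVARFit(
            A=A_blocks[k], u=u_blocks[k], xi=xi_blocks[k], zeta=None,
            residuals=residuals,
            resid_cov=_pooled_resid_cov(residuals, cond_idx, post_resid),
            Ts=rec.Ts, condition=rec.condition.copy(),
            cell_types=rec.cell_types.copy(),
            time_axis=rec.time_axis.copy(),
        )
    return fits


# ---------------------------------------------------------------------------
# discriminants and information
# ---------------------------------------------------------------------------

def _ridge_solve(S: np.ndarray, b: np.ndarray, what: str) -> np.ndarray:
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e12:
        eps = RIDGE_FACTOR * np.mean(np.diag(S))
        if eps <= 0:
            eps = RIDGE_FACTOR
        warnings.warn(
            f"{what} is near-singular (cond={cond:.3g}); ridge-regularized "
            f"with eps={eps:.3g}",
            RuntimeWarning,
        )
        S = S + eps * np.eye(S.shape[0])
    return linalg.solve(S, b, assume_a="pos")


def _grand_means(rec: PopulationRecording) -> dict[str, np.ndarray]:
    post = rec.post_stim_frames
    return {
        c: rec.activity[rec.trials_of(c)][:, post].mean(axis=(0, 1))
        for c in ("V", "A")
    }


def _pooled_output_cov(rec: PopulationRecording) -> np.ndarray:
    """Pooled within-condition covariance over the post-stimulus window."""
    post = rec.post_stim_frames
    devs = []
    for c in ("V", "A"):
        act = rec.activity[rec.trials_of(c)][:, post]
        devs.append((act - act.mean(axis=0)).reshape(-1, rec.n_neurons))
    dev = np.vstack(devs)
    return dev.T @ dev / dev.shape[0]


def output_discriminant(rec: PopulationRecording) -> np.ndarray:
    """``w_output = Sigma^{-1} (rbar_V - rbar_A)`` from the recording alone."""
    means = _grand_means(rec)
    return _ridge_solve(
        _pooled_output_cov(rec), means["V"] - means["A"], "output covariance"
    )


def discriminants(rec: PopulationRecording, fit: MVARFit) -> dict:
    """Output and input linear discriminants of the vertical/angled pair."""
    du = fit.mean_input("V") - fit.mean_input("A")
    return {
        "w_output": output_discriminant(rec),
        "w_input": _ridge_solve(fit.resid_cov, du, "residual covariance"),
    }


def information_summary(
    rec: PopulationRecording, fit: MVARFit
) -> InformationSummary:
    """Linear discriminability of responses and of inferred input."""
    means = _grand_means(rec)
    dr = means["V"] - means["A"]
    du = fit.mean_input("V") - fit.mean_input("A")
    i_out = float(dr @ _ridge_solve(_pooled_output_cov(rec), dr,
                                    "output covariance"))
    i_in = float(du @ _ridge_solve(fit.resid_cov, du,
                                   "residual covariance"))
    return InformationSummary(input_info=i_in, output_info=i_out)


# ---------------------------------------------------------------------------
# impulse responses and modes
# ---------------------------------------------------------------------------

def impulse_time_constant(
    fit: MVARFit,
    p: np.ndarray,
    w: np.ndarray,
    horizon: int = 10_000,
    rel_tol: float = 1e-10,
) -> float:
    """Integration time constant of the response to an input pulse.

    The network is initialized at ``r_0 = p`` and run freely,
    ``r_t = (A + I)^t p``; the projection ``q_t = w . r_t`` is summed until
    it has decayed to ``rel_tol`` of its initial magnitude (or ``horizon``
    steps).  The time constant is ``tau = (Ts / 2) (sum q_t)^2 /
    (sum q_t^2)``, which returns ``(Ts/2)(1+lam)/(1-lam)`` for a pure
    geometric decay with multiplier ``lam`` and converges to the continuous
    time constant for slow modes.  Returns NaN (with a warning) when ``w``
    is orthogonal to every excited mode.
    """
    p = np.asarray(p, dtype=float)
    w = np.asarray(w, dtype=float)
    if not np.any(p) or not np.any(w):
        raise ValueError("p and w must be nonzero")
    B = fit.transition
    r = p.copy()
    q0 = abs(float(w @ r))
    scale = max(q0, np.linalg.norm(p) * np.linalg.norm(w))
    s1 = 0.0
    s2 = 0.0
    for _ in range(horizon):
        q = float(w @ r)
        s1 += q
        s2 += q * q
        if not np.isfinite(q) or abs(q) > 1e6 * max(scale, 1.0):
            raise ValueError(
                "impulse response diverges: spectral radius >= 1 along the "
                "excited directions"
            )
        if abs(q) < rel_tol * max(q0, scale * 1e-3) and s2 > 0:
            break
        r = B @ r
    if s2 == 0.0:
        warnings.warn(
            "projection is identically zero (w orthogonal to all excited "
            "modes); time constant undefined",
            RuntimeWarning,
        )
        return float("nan")
    return float(0.5 * fit.Ts * s1 * s1 / s2)


def random_discriminant_inputs(
    fit: MVARFit, rec: PopulationRecording, n: int, seed: int
) -> list[dict[str, np.ndarray]]:
    """Random input/readout pairs mixing the two stimulus patterns.

    Each draw reweights the vertical and angled mean inputs (and response
    means) elementwise with independent standard-normal coefficients before
    whitening, producing a distribution of input patterns that contains the
    discriminant pair (all-ones weights) as a special case.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    means = _grand_means(rec)
    u_v, u_a = fit.mean_input("V"), fit.mean_input("A")
    cov_out = _pooled_output_cov(rec)
    pairs = []
    for _ in range(n):
        eta_v = rng.standard_normal(fit.n_neurons)
        eta_a = rng.standard_normal(fit.n_neurons)
        p = _ridge_solve(fit.resid_cov, eta_v * u_v - eta_a * u_a,
                         "residual covariance")
        w = _ridge_solve(cov_out, eta_v * means["V"] - eta_a * means["A"],
                         "output covariance")
        p_norm = np.linalg.norm(p)
        w_norm = np.linalg.norm(w)
        pairs.append({
            "p": p / p_norm if p_norm else p,
            "w": w / w_norm if w_norm else w,
        })
    return pairs


def mvar_modes(fit: MVARFit) -> ModeStatistics:
    """Eigenmode statistics of the fitted interaction matrix.

    Modes with real eigenvalue and ``lambda + 1 > 0`` get a time constant
    ``tau = -Ts / log(lambda + 1)`` and an input SNR
    ``|m . (u_V - u_A)| / sqrt(m^T Sigma_e m)`` from the left eigenvector
    ``m``; the normalized SNR divides by the input-discriminant SNR and is
    bounded by 1.
    """
    evals, vl = linalg.eig(fit.A, left=True, right=False)
    real = np.abs(evals.imag) <= 1e-10 * (1.0 + np.abs(evals.real))
    valid = real & (evals.real + 1.0 > 0)
    lam = evals.real[valid]
    patterns = vl[:, valid].real.T
    norms = np.linalg.norm(patterns, axis=1, keepdims=True)
    patterns = patterns / norms
    tau = -fit.Ts / np.log(lam + 1.0)

    du = fit.mean_input("V") - fit.mean_input("A")
    num = np.abs(patterns @ du)
    den = np.sqrt(np.einsum("ij,jk,ik->i", patterns, fit.resid_cov, patterns))
    input_snr = num / den
    snr_ld = float(np.sqrt(
        du @ _ridge_solve(fit.resid_cov, du, "residual covariance")
    ))
    order = np.argsort(tau)[::-1]
    return ModeStatistics(
        eigenvalue=lam[order],
        time_constant=tau[order],
        input_snr=input_snr[order],
        normalized_snr=(input_snr / snr_ld if snr_ld > 0
                        else np.full_like(input_snr, np.nan))[order],
        patterns=patterns[order],
        real_valid=np.ones(lam.shape[0], dtype=bool),
    )


def pool_modes(mode_sets: list[ModeStatistics]) -> ModeStatistics:
    """Concatenate mode statistics across fits (e.g. across replicates)."""
    if not mode_sets:
        raise ValueError("need at least one mode set")
    return ModeStatistics(
        eigenvalue=np.concatenate([m.eigenvalue for m in mode_sets]),
        time_constant=np.concatenate([m.time_constant for m in mode_sets]),
        input_snr=np.concatenate([m.input_snr for m in mode_sets]),
        normalized_snr=np.concatenate([m.normalized_snr for m in mode_sets]),
        patterns=np.concatenate([m.patterns for m in mode_sets])
        if len({m.patterns.shape[1] for m in mode_sets}) == 1
        else np.zeros((0, 0)),
        real_valid=np.concatenate([m.real_valid for m in mode_sets]),
    )


def conditional_mode_averages(modes: ModeStatistics) -> dict:
    """Moving-box conditional averages over pooled modes.

    Mean normalized SNR conditioned on time constant (box width 100 ms,
    centers 100..1400 ms in 25 ms steps) and mean time constant
    conditioned on normalized SNR (box width 0.025, centers 0.025..0.25).
    Empty windows yield NaN.  Time constants are truncated at ``TAU_CAP``
    so a mode estimated at the stability edge cannot dominate a window
    mean.
    """
    tau_w = np.minimum(modes.time_constant, TAU_CAP)
    snr_given_tau = np.full(TAU_CENTERS.shape, np.nan)
    for i, c in enumerate(TAU_CENTERS):
        in_win = np.abs(tau_w - c) <= TAU_HALF_WIDTH
        if np.any(in_win):
            snr_given_tau[i] = modes.normalized_snr[in_win].mean()
    tau_given_snr = np.full(SNR_CENTERS.shape, np.nan)
    for i, c in enumerate(SNR_CENTERS):
        in_win = np.abs(modes.normalized_snr - c) <= SNR_HALF_WIDTH
        if np.any(in_win):
            tau_given_snr[i] = tau_w[in_win].mean()
    return {
        "tau_centers": TAU_CENTERS.copy(),
        "snr_given_tau": snr_given_tau,
        "snr_centers": SNR_CENTERS.copy(),
        "tau_given_snr": tau_given_snr,
    }


def mode_density(
    modes: ModeStatistics,
    tau_grid: np.ndarray,
    snr_grid: np.ndarray,
    sigma_tau: float = 100.0,
    sigma_snr: float = 0.025,
) -> np.ndarray:
    """Gaussian-filtered mode count ``n(tau, SNR_norm)`` on a grid."""
    dt = (modes.time_constant[:, None] - tau_grid[None, :]) / sigma_tau
    ds = (modes.normalized_snr[:, None] - snr_grid[None, :]) / sigma_snr
    return np.einsum(
        "it,is->ts", np.exp(-0.5 * dt**2), np.exp(-0.5 * ds**2)
    )


def mode_density_change(
    modes_pre: ModeStatistics,
    modes_post: ModeStatistics,
    sigma_tau: float = 100.0,
    sigma_snr: float = 0.025,
    tau_grid: np.ndarray | None = None,
    snr_grid: np.ndarray | None = None,
) -> dict:
    """Change over learning in the smoothed mode-density map."""
    if tau_grid is None:
        tau_grid = np.arange(0.0, 1500.0 + 1e-9, 25.0)
    if snr_grid is None:
        snr_grid = np.arange(0.0, 0.3 + 1e-9, 0.005)
    n_pre = mode_density(modes_pre, tau_grid, snr_grid, sigma_tau, sigma_snr)
    n_post = mode_density(modes_post, tau_grid, snr_grid, sigma_tau,
                          sigma_snr)
    return {
        "tau_grid": tau_grid, "snr_grid": snr_grid,
        "n_pre": n_pre, "n_post": n_post, "delta": n_post - n_pre,
    }


# ---------------------------------------------------------------------------
# trial-shuffle nulls
# ---------------------------------------------------------------------------

def _shuffled_pair(
    rec_pre: PopulationRecording,
    rec_post: PopulationRecording,
    rng: np.random.Generator,
) -> tuple[PopulationRecording, PopulationRecording]:
    """Resample two pseudo-sessions from the pooled trials, preserving the
    per-condition trial counts of each session."""
    idx_pre: list[np.ndarray] = []
    idx_post: list[np.ndarray] = []
    for cond in CONDITIONS:
        a = rec_pre.trials_of(cond)
        b = rec_post.trials_of(cond)
        pool = np.concatenate([a, b + rec_pre.n_trials])
        perm = rng.permutation(pool)
        idx_pre.append(perm[: a.shape[0]])
        idx_post.append(perm[a.shape[0]:])
    all_pre = np.concatenate(idx_pre)
    all_post = np.concatenate(idx_post)

    def take(indices: np.ndarray) -> PopulationRecording:
        act = np.concatenate([rec_pre.activity, rec_post.activity])
        run = np.concatenate([rec_pre.run_speed, rec_post.run_speed])
        lk = np.concatenate([rec_pre.licks, rec_post.licks])
        cond = np.concatenate([rec_pre.condition, rec_post.condition])
        return PopulationRecording(
            activity=act[indices], condition=cond[indices],
            time_axis=rec_pre.time_axis, run_speed=run[indices],
            licks=lk[indices], cell_types=rec_pre.cell_types, Ts=rec_pre.Ts,
        )

    return take(all_pre), take(all_post)


def _stat_delta_conditional_snr(fit_pre, fit_post, rec_pre, rec_post):
    pre = conditional_mode_averages(mvar_modes(fit_pre))
    post = conditional_mode_averages(mvar_modes(fit_post))
    return post["snr_given_tau"] - pre["snr_given_tau"]


def _stat_delta_conditional_tau(fit_pre, fit_post, rec_pre, rec_post):
    pre = conditional_mode_averages(mvar_modes(fit_pre))
    post = conditional_mode_averages(mvar_modes(fit_post))
    return post["tau_given_snr"] - pre["tau_given_snr"]


def _stat_delta_info_gain(fit_pre, fit_post, rec_pre, rec_post):
    g_pre = information_summary(rec_pre, fit_pre).gain_percent
    g_post = information_summary(rec_post, fit_post).gain_percent
    return np.array(g_post - g_pre)


def _stat_delta_impulse_tau(fit_pre, fit_post, rec_pre, rec_post):
    out = []
    for rec, fit in ((rec_pre, fit_pre), (rec_post, fit_post)):
        d = discriminants(rec, fit)
        out.append(impulse_time_constant(fit, d["w_input"], d["w_output"]))
    return np.array(out[1] - out[0])


SHUFFLE_STATISTICS = {
    "delta_conditional_snr": _stat_delta_conditional_snr,
    "delta_conditional_tau": _stat_delta_conditional_tau,
    "delta_info_gain": _stat_delta_info_gain,
    "delta_impulse_tau": _stat_delta_impulse_tau,
}


def shuffle_null(
    rec_pre: PopulationRecording,
    rec_post: PopulationRecording,
    statistic: str,
    n_shuffles: int,
    seed: int,
) -> dict:
    """Trial-shuffle null distribution of a registered pre/post statistic.

    Trials are pooled across sessions per condition and resampled without
    replacement into two pseudo-sessions of the original sizes; the model
    is refit on each and the statistic recomputed.  Returns the observed
    value, the null draws, and the pointwise [2.5%, 97.5%] interval.
    """
    if statistic not in SHUFFLE_STATISTICS:
        raise KeyError(
            f"unknown statistic {statistic!r}; registered: "
            f"{sorted(SHUFFLE_STATISTICS)}"
        )
    func = SHUFFLE_STATISTICS[statistic]
    observed = func(fit_mvar(rec_pre), fit_mvar(rec_post), rec_pre, rec_post)
    rng = np.random.default_rng(seed)
    null = []
    for _ in range(n_shuffles):
        sp, so = _shuffled_pair(rec_pre, rec_post, rng)
        null.append(func(fit_mvar(sp), fit_mvar(so), sp, so))
    null = np.stack(null)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanpercentile(null, 2.5, axis=0)
        hi = np.nanpercentile(null, 97.5, axis=0)
    return {"observed": observed, "null": null, "ci_low": lo, "ci_high": hi}


def _mc_threshold(null_draws: np.ndarray, level: float = 0.975) -> float:
    """Monte-Carlo test threshold from null draws (order statistic).

    Uses the ``ceil(level * (B + 1))``-th order statistic, the standard
    exact-test convention: under exchangeability the exceedance
    probability is at most ``1 - level`` for any number of draws,
    whereas an interpolated percentile is anti-conservative at small B.
    """
    vals = np.sort(null_draws[~np.isnan(null_draws)])
    if vals.size == 0:
        return float("nan")
    k = min(int(np.ceil(level * (vals.size + 1))), vals.size)
    return float(vals[k - 1])


def _region_mean(curve: np.ndarray, centers: np.ndarray,
                 window: tuple[float, float]) -> float:
    sel = (centers >= window[0]) & (centers <= window[1])
    vals = curve[sel]
    if vals.size == 0 or np.all(np.isnan(vals)):
        return float("nan")
    return float(np.nanmean(vals))


def scenario_analysis(
    recs_pre: list[PopulationRecording],
    recs_post: list[PopulationRecording],
    n_shuffles: int = 100,
    seed: int = 0,
    slow_tau_window: tuple[float, float] = (700.0, 1000.0),
    high_snr_window: tuple[float, float] = (0.125, 0.25),
) -> dict:
    """Pooled-replicate mode-statistics pipeline with shuffle nulls.

    Fits the MVAR to each replicate pre and post, pools modes across
    replicates, and forms the learning-related change in the two
    conditional curves (normalized SNR vs. time constant and time constant
    vs. normalized SNR).  The trial-shuffle null refits every replicate on
    resampled pseudo-sessions.  Alongside pointwise 95% bands, the summary
    averages each curve over its hypothesis region (slow time constants for
    the SNR curve — the 700-1000 ms band where learning effects
    concentrate — and high normalized SNR for the tau curve) and compares
    the average against the 97.5th percentile of the null distribution of
    that same average; aggregating before thresholding calibrates the
    exceedance test for the width of the region.
    """
    if len(recs_pre) != len(recs_post):
        raise ValueError("need matched pre/post replicate lists")
    fits_pre = [fit_mvar(r) for r in recs_pre]
    fits_post = [fit_mvar(r) for r in recs_post]
    modes_pre = pool_modes([mvar_modes(f) for f in fits_pre])
    modes_post = pool_modes([mvar_modes(f) for f in fits_post])
    curves_pre = conditional_mode_averages(modes_pre)
    curves_post = conditional_mode_averages(modes_post)
    d_snr = curves_post["snr_given_tau"] - curves_pre["snr_given_tau"]
    d_tau = curves_post["tau_given_snr"] - curves_pre["tau_given_snr"]

    rng = np.random.default_rng(seed)
    null_snr = np.empty((n_shuffles, TAU_CENTERS.shape[0]))
    null_tau = np.empty((n_shuffles, SNR_CENTERS.shape[0]))
    for s in range(n_shuffles):
        sh_pre, sh_post = [], []
        for rp, ro in zip(recs_pre, recs_post):
            a, b = _shuffled_pair(rp, ro, rng)
            sh_pre.append(mvar_modes(fit_mvar(a)))
            sh_post.append(mvar_modes(fit_mvar(b)))
        cp = conditional_mode_averages(pool_modes(sh_pre))
        co = conditional_mode_averages(pool_modes(sh_post))
        null_snr[s] = co["snr_given_tau"] - cp["snr_given_tau"]
        null_tau[s] = co["tau_given_snr"] - cp["tau_given_snr"]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        bands = {
            "snr": (np.nanpercentile(null_snr, 2.5, axis=0),
                    np.nanpercentile(null_snr, 97.5, axis=0)),
            "tau": (np.nanpercentile(null_tau, 2.5, axis=0),
                    np.nanpercentile(null_tau, 97.5, axis=0)),
        }
        snr_max = _region_mean(d_snr, TAU_CENTERS, slow_tau_window)
        tau_max = _region_mean(d_tau, SNR_CENTERS, high_snr_window)
        null_snr_max = np.array(
            [_region_mean(c, TAU_CENTERS, slow_tau_window)
             for c in null_snr]
        )
        null_tau_max = np.array(
            [_region_mean(c, SNR_CENTERS, high_snr_window)
             for c in null_tau]
        )
        snr_thresh = _mc_threshold(null_snr_max)
        tau_thresh = _mc_threshold(null_tau_max)

    return {
        "tau_centers": TAU_CENTERS.copy(),
        "snr_centers": SNR_CENTERS.copy(),
        "delta_snr_curve": d_snr,
        "delta_tau_curve": d_tau,
        "null_snr": null_snr,
        "null_tau": null_tau,
        "bands": bands,
        "snr_region_max": snr_max,
        "snr_region_max_null975": snr_thresh,
        "snr_exceeds": bool(snr_max > snr_thresh),
        "tau_region_max": tau_max,
        "tau_region_max_null975": tau_thresh,
        "tau_exceeds": bool(tau_max > tau_thresh),
        "modes_pre": modes_pre,
        "modes_post": modes_post,
    }


# ---------------------------------------------------------------------------
# cell types
# ---------------------------------------------------------------------------

def celltype_loading(w: np.ndarray, cell_types: np.ndarray) -> dict:
    """Mean squared loading of each cell class onto a vector.

    ``L(w, X) = (||w_X||^2 / ||w||^2) * (N / N_X)`` — the fraction of the
    squared norm generated by class ``X``, normalized by the fraction of
    cells in the class.  The class-size-weighted average of the loadings
    is identically 1.
    """
    w = np.asarray(w, dtype=float)
    cell_types = np.asarray(cell_types)
    total = float(w @ w)
    if total == 0:
        raise ValueError("w must be nonzero")
    out = {}
    for cls in np.unique(cell_types):
        sel = cell_types == cls
        n_x = int(sel.sum())
        if n_x == 0:
            raise ValueError(f"empty cell class {cls!r}")
        out[str(cls)] = float(
            (w[sel] @ w[sel]) / total * (w.shape[0] / n_x)
        )
    return out


def celltype_perturbation_response(
    fit: MVARFit,
    w: np.ndarray,
    p: np.ndarray,
    cell_types: np.ndarray | None = None,
    horizon: int = 16,
) -> dict:
    """Directed cell-type pathways of the response to an input pulse.

    Entry ``(X, Y)`` at step ``t`` is ``w_X . (A + I)^t p_Y``: the
    projection onto the class-``X`` part of the readout of the response to
    a pulse restricted to class ``Y``.  Summing over all pairs recovers the
    full projection ``w . (A + I)^t p``.
    """
    cell_types = np.asarray(
        fit.cell_types if cell_types is None else cell_types
    )
    w = np.asarray(w, dtype=float)
    p = np.asarray(p, dtype=float)
    classes = [str(c) for c in np.unique(cell_types)]
    B = fit.transition
    out = {
        (x, y): np.empty(horizon + 1) for x in classes for y in classes
    }
    total = np.empty(horizon + 1)
    states = {}
    for y in classes:
        py = np.where(cell_types == y, p, 0.0)
        states[y] = py
    r_full = p.copy()
    for t in range(horizon + 1):
        for y in classes:
            for x in classes:
                wx = np.where(cell_types == x, w, 0.0)
                out[(x, y)][t] = wx @ states[y]
        total[t] = w @ r_full
        for y in classes:
            states[y] = B @ states[y]
        r_full = B @ r_full
    return {"pathways": out, "total": total, "classes": classes}


# ---------------------------------------------------------------------------
# behavioral and non-MVAR analyses
# ---------------------------------------------------------------------------

def _first_lick_frames(rec: PopulationRecording) -> np.ndarray:
    """First post-onset lick frame per trial (-1 when the trial has none)."""
    post0 = int(rec.post_stim_frames[0])
    out = np.full(rec.n_trials, -1, dtype=int)
    for i in range(rec.n_trials):
        hits = np.flatnonzero(rec.licks[i, post0:])
        if hits.size:
            out[i] = post0 + hits[0]
    return out


def behavioral_stats(
    rec: PopulationRecording, w: np.ndarray, window_bins: int = 2
) -> dict:
    """Lick-timing and discriminant-projection statistics for one session.

    Returns hit/false-alarm fractions of first licks per sliding window
    (first post-onset licks on V trials are hits, on A trials false
    alarms), lick-triggered averages of the readout projection, per-trial
    discriminant autocorrelations over the post-stimulus window with their
    area under the curve, and the projection SNR time course.  Lick-based
    outputs are flagged absent when the session contains no licks.
    """
    w = np.asarray(w, dtype=float)
    proj = rec.activity @ w  # (trials, frames)
    cond_mean = {
        c: proj[rec.trials_of(c)].mean(axis=0) for c in ("V", "A")
    }

    # SNR time course from condition means and pooled SD per frame
    var_pool = 0.5 * (
        proj[rec.trials_of("V")].var(axis=0)
        + proj[rec.trials_of("A")].var(axis=0)
    )
    snr_t = np.abs(cond_mean["V"] - cond_mean["A"]) / np.sqrt(var_pool)

    # per-trial autocorrelation over the 0..1 s window, pooled per stimulus
    post = rec.post_stim_frames
    T = post.shape[0] - 1
    autocorr = {}
    auc = {}
    for c in ("V", "A"):
        trials = rec.trials_of(c)
        dev = proj[trials][:, post] - cond_mean[c][post]
        r_sum = np.zeros(T + 1)
        for x in dev:
            full = np.correlate(x, x, mode="full")
            r_sum += full[T:]
        norm = r_sum[0]
        r_norm = r_sum / norm if norm > 0 else np.full(T + 1, np.nan)
        autocorr[c] = r_norm
        auc[c] = float(
            (r_norm[0] + 2.0 * np.sum(r_norm[1:])) / (2 * T + 1)
        )

    out = {
        "snr_timecourse": snr_t,
        "autocorrelation": autocorr,
        "autocorrelation_auc": auc,
        "time_axis": rec.time_axis.copy(),
    }

    first = _first_lick_frames(rec)
    if not np.any(first >= 0):
        out.update({"has_licks": False, "hit_rate": None, "fa_rate": None,
                    "lick_triggered_average": None})
        return out
    out["has_licks"] = True

    is_v = rec.condition == "V"
    is_a = rec.condition == "A"
    post0 = int(post[0])
    n_frames = rec.time_axis.shape[0]
    starts = np.arange(post0, n_frames - window_bins + 1)
    hit_rate = np.full(starts.shape, np.nan)
    fa_rate = np.full(starts.shape, np.nan)
    for k, t0 in enumerate(starts):
        in_win = (first >= t0) & (first < t0 + window_bins)
        n_hit = int(np.sum(in_win & is_v))
        n_fa = int(np.sum(in_win & is_a))
        if n_hit + n_fa > 0:
            hit_rate[k] = n_hit / (n_hit + n_fa)
            fa_rate[k] = n_fa / (n_hit + n_fa)
    out["hit_rate"] = hit_rate
    out["fa_rate"] = fa_rate
    out["rate_window_times"] = rec.time_axis[starts]

    # lick-triggered average of the readout deviation, per trial category
    lags = np.arange(-(n_frames - 1), n_frames)
    lta = {}
    for name, mask in (("false_alarm", is_a), ("hit", is_v)):
        trials = np.flatnonzero(mask & (first >= 0))
        if trials.size == 0:
            lta[name] = None
            continue
        acc = np.zeros(lags.shape)
        cnt = np.zeros(lags.shape)
        cm = cond_mean["A"] if name == "false_alarm" else cond_mean["V"]
        for i in trials:
            tl = first[i]
            for j, lag in enumerate(lags):
                t = tl + lag
                if 0 <= t < n_frames:
                    acc[j] += proj[i, t] - cm[t]
                    cnt[j] += 1
        with np.errstate(invalid="ignore"):
            lta[name] = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    out["lick_triggered_average"] = lta
    out["lta_lags_s"] = lags * rec.Ts / 1000.0
    return out


def trial_average_svd(recs: list[PopulationRecording]) -> dict:
    """SVD of trial-averaged vertical-condition responses across replicates.

    Concatenates each replicate's neurons into a single neurons x time
    matrix over the -0.5..1 s window, decomposes ``X = U S V^T``, and
    reports the two leading temporal modes plus, per replicate, the
    alignment of its subvector of each leading neuron mode with its own
    output discriminant.
    """
    if not recs:
        raise ValueError("need at least one recording")
    t0 = -0.5 - 1e-9
    win = np.flatnonzero(recs[0].time_axis >= t0)
    blocks = []
    for rec in recs:
        avg = rec.activity[rec.trials_of("V")][:, win].mean(axis=0)  # (T, N)
        blocks.append(avg.T)
    X = np.vstack(blocks)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    n_lead = min(2, S.shape[0])
    alignments = np.zeros((len(recs), n_lead))
    row = 0
    for i, rec in enumerate(recs):
        n = rec.n_neurons
        w = output_discriminant(rec)
        w_hat = w / np.linalg.norm(w)
        for j in range(n_lead):
            sub = U[row : row + n, j]
            nrm = np.linalg.norm(sub)
            alignments[i, j] = float(sub @ w_hat / nrm) if nrm > 0 else 0.0
        row += n
    return {
        "U": U, "S": S, "Vt": Vt,
        "temporal_modes": Vt[:n_lead],
        "times": recs[0].time_axis[win],
        "alignments": alignments,
        "X": X,
    }


def preferred_stim_changes(
    rec_pre: PopulationRecording,
    rec_post: PopulationRecording,
    alpha: float = 0.05,
) -> dict:
    """Per-cell response changes to the preferred and non-preferred stimulus.

    A cell is included when a rank-sum test on its per-trial post-stimulus
    responses separates vertical from angled trials at ``p < alpha`` in
    both sessions and its preferred stimulus (larger mean response) is the
    same in both.  For included cells the change over learning in the mean
    response to the preferred and non-preferred stimulus is tabulated with
    mean, variance, SEM and the standard error of the variance (SEV).
    """
    if rec_pre.n_neurons != rec_post.n_neurons:
        raise ValueError("sessions must share neurons")

    def per_trial(rec: PopulationRecording, cond: str) -> np.ndarray:
        post = rec.post_stim_frames
        return rec.activity[rec.trials_of(cond)][:, post].mean(axis=1)

    resp = {
        (s, c): per_trial(r, c)
        for s, r in (("pre", rec_pre), ("post", rec_post))
        for c in ("V", "A")
    }
    n = rec_pre.n_neurons
    rows = []
    for i in range(n):
        sig = {}
        pref = {}
        for s in ("pre", "post"):
            v = resp[(s, "V")][:, i]
            a = resp[(s, "A")][:, i]
            sig[s] = stats.ranksums(v, a).pvalue < alpha
            pref[s] = "V" if v.mean() >= a.mean() else "A"
        included = sig["pre"] and sig["post"] and pref["pre"] == pref["post"]
        p = pref["pre"]
        np_ = "A" if p == "V" else "V"
        d_pref = resp[("post", p)][:, i].mean() - resp[("pre", p)][:, i].mean()
        d_non = (resp[("post", np_)][:, i].mean()
                 - resp[("pre", np_)][:, i].mean())
        rows.append({
            "cell": i, "cell_type": str(rec_pre.cell_types[i]),
            "included": included, "preferred": p,
            "delta_pref": d_pref, "delta_nonpref": d_non,
        })
    table = pd.DataFrame(rows)
    inc = table[table.included]
    if inc.empty:
        warnings.warn("no cells pass the inclusion criteria", RuntimeWarning)
        return {"table": table, "summary": None}
    summary = {}
    for which in ("pref", "nonpref"):
        d = inc[f"delta_{which}"].to_numpy()
        m = d.shape[0]
        var = float(d.var(ddof=1)) if m > 1 else float("nan")
        summary[which] = {
            "mean": float(d.mean()),
            "var": var,
            "sem": float(d.std(ddof=1) / np.sqrt(m)) if m > 1 else float("nan"),
            "sev": var * np.sqrt(2.0 / (m - 1)) if m > 1 else float("nan"),
            "n": m,
        }
    return {"table": table, "summary": summary}
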