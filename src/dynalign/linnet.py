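"""Linearized recurrent network dynamics and information.

A stable linear network ``dr/dt = A r + u(s, t)`` driven by noisy
stimulus-tuned input filters that input through its dynamical modes.  Each
mode pairs a left-eigenvector activation pattern ``m`` with a decay time
constant ``tau = -1 / Re(lambda)``; activity projected onto ``m`` behaves as
a leaky integrator with window ``tau``, so the stationary SNR along an
isolated real mode obeys ``SNR_output(m) = SNR_input(m) * sqrt(2 tau)``.

The module also provides the stationary Lyapunov covariance, the linear
Fisher information of the stationary response (and its value normalized by
the best achievable in any normal network with the same time constants),
information-limiting correlations, Henrici's departure from normality, and
functionally feedforward chain networks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .signal import StimulusEnsemble, projection_stats

__all__ = [
    "LinearNetwork",
    "DynamicalMode",
    "network_from_modes",
    "rotated_pattern",
    "mode_decomposition",
    "stationary_mean",
    "stationary_covariance",
    "mode_output_snr",
    "mode_snr_timecourse",
    "linear_fisher_info",
    "info_limiting_correlations",
    "henrici_nonnormality",
    "feedforward_chain",
    "simulate_linear_sde",
    "impulse_response",
]


@dataclass
class LinearNetwork:
    """Continuous-time linear dynamics ``dr/dt = A r + u``."""

    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be square")

    @property
    def n_neurons(self) -> int:
        return self.A.shape[0]

    @property
    def stable(self) -> bool:
        """True when every eigenvalue has a negative real part."""
        return bool(np.all(np.linalg.eigvals(self.A).real < 0))

    def to_json(self) -> str:
        return json.dumps({"A": self.A.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "LinearNetwork":
        return cls(A=np.array(json.loads(text)["A"]))


@dataclass
class DynamicalMode:
    """A left-eigenvector activation pattern with its decay time constant.

    ``pattern`` is the unit-norm left eigenvector ``m`` (``m^T A =
    lambda m^T``); ``right_pattern`` the matching right eigenvector.  For a
    stable mode ``time_constant = -1 / Re(lambda) > 0``.  Complex-conjugate
    eigenpairs are flagged via ``is_complex`` and carry the complex vectors.
    """

    pattern: np.ndarray
    right_pattern: np.ndarray
    eigenvalue: complex
    time_constant: float
    is_complex: bool = False


def rotated_pattern(theta: float, w: np.ndarray) -> np.ndarray:
    """Unit 2-vector obtained by rotating ``w`` counter-clockwise by ``theta``."""
    w = np.asarray(w, dtype=float)
    if w.shape != (2,):
        raise ValueError("rotated_pattern requires a 2-dimensional vector")
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("w must be nonzero")
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    return R @ (w / norm)


def network_from_modes(patterns, taus) -> LinearNetwork:
    """Unique weight matrix whose modes are the given patterns/time constants.

    The rows of ``M`` are the left-eigenvector activation patterns, so
    ``A = M^{-1} Lambda M`` with ``Lambda = diag(-1/tau_i)``.
    """
    M = np.atleast_2d(np.asarray(patterns, dtype=float))
    taus = np.asarray(taus, dtype=float)
    if M.shape[0] != taus.shape[0]:
        raise ValueError("need one time constant per pattern")
    if np.any(taus <= 0):
        raise ValueError("all time constants must be positive")
    if np.linalg.matrix_rank(M) < M.shape[0]:
        raise ValueError("mode patterns are linearly dependent")
    Lam = np.diag(-1.0 / taus)
    return LinearNetwork(A=linalg.solve(M, Lam @ M))


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    """Fix the arbitrary eigenvector sign: largest-magnitude entry positive."""
    idx = np.argmax(np.abs(v))
    ref = v[idx].real if np.iscomplexobj(v) else v[idx]
    return -v if ref < 0 else v


def mode_decomposition(net: LinearNetwork) -> list[DynamicalMode]:
    """Eigenmodes of ``A``, sorted by descending time constant.

    Activation patterns are the unit-norm *left* eigenvectors.  Complex
    conjugate pairs are retained and flagged.  Near-defective matrices
    trigger a warning and best-effort modes.
    """
    A = net.A
    evals, vl, vr = linalg.eig(A, left=True, right=True)
    # eigenvector-condition check for near-defective A
    overlaps = np.abs(np.sum(vl.conj() * vr, axis=0))
    if np.any(overlaps < 1e-8):
        warnings.warn(
            "matrix is near-defective; mode decomposition is ill-conditioned",
            RuntimeWarning,
        )
    order = np.argsort(evals.real)[::-1]  # slowest decay first
    modes = []
    for i in order:
        lam = evals[i]
        is_complex = bool(abs(lam.imag) > 1e-12 * max(1.0, abs(lam.real)))
        left = vl[:, i]
        right = vr[:, i]
        if not is_complex:
            lam = complex(lam.real)
            left = left.real
            right = right.real
        left = _canonical_sign(left / np.linalg.norm(left))
        right = right / np.linalg.norm(right)
        tau = np.inf if lam.real == 0 else -1.0 / lam.real
        modes.append(
            DynamicalMode(
                pattern=left,
                right_pattern=right,
                eigenvalue=lam,
                time_constant=float(tau),
                is_complex=is_complex,
            )
        )
    return modes


def stationary_mean(net: LinearNetwork, u: np.ndarray) -> np.ndarray:
    """Fixed point ``r_inf = -A^{-1} u`` under constant input ``u``."""
    if not net.stable:
        raise ValueError("network must be stable for a stationary mean")
    return -linalg.solve(net.A, np.asarray(u, dtype=float))


def stationary_covariance(
    net: LinearNetwork, noise_cov: np.ndarray
) -> np.ndarray:
    """Stationary covariance solving ``A S + S A^T + Sigma_eta = 0``."""
    if not net.stable:
        raise ValueError("network must be stable for a stationary covariance")
    Q = np.asarray(noise_cov, dtype=float)
    if not np.allclose(Q, Q.T, atol=1e-10):
        raise ValueError("noise_cov must be symmetric")
    S = linalg.solve_continuous_lyapunov(net.A, -Q)
    return 0.5 * (S + S.T)


def mode_output_snr(mode: DynamicalMode, ens: StimulusEnsemble) -> float:
    """Stationary output SNR along a real mode: ``SNR_input(m) sqrt(2 tau)``."""
    if mode.is_complex:
        raise ValueError(
            "output SNR along a complex (oscillatory) mode is undefined; "
            "use linear_fisher_info for the full-network computation"
        )
    if mode.time_constant <= 0 or not np.isfinite(mode.time_constant):
        raise ValueError("mode must be stable (finite positive time constant)")
    snr_in = projection_stats(mode.pattern, ens).snr
    return snr_in * np.sqrt(2.0 * mode.time_constant)


def mode_snr_timecourse(
    mode: DynamicalMode, ens: StimulusEnsemble, t: np.ndarray
) -> np.ndarray:
    """SNR along a mode as a function of time from stimulus onset (at rest).

    ``SNR(t) = SNR_input(m) sqrt(2 tau (1 - e^{-t/tau}) / (1 + e^{-t/tau}))``,
    the exact Ornstein-Uhlenbeck result; its ``t -> inf`` limit recovers the
    ``sqrt(2 tau)`` law.
    """
    if mode.is_complex:
        raise ValueError("time course is defined for real modes only")
    tau = mode.time_constant
    snr_in = projection_stats(mode.pattern, ens).snr
    t = np.asarray(t, dtype=float)
    e = np.exp(-t / tau)
    return snr_in * np.sqrt(2.0 * tau * (1.0 - e) / (1.0 + e))


def linear_fisher_info(net: LinearNetwork, ens: StimulusEnsemble) -> dict:
    """Linear Fisher information of the stationary network response.

    Returns ``info = dr^T Sigma^{-1} dr`` with ``dr = -A^{-1} dg`` and
    ``Sigma`` the stationary Lyapunov covariance, together with
    ``normalized_info = info / (dg^T Sigma_eta^{-1} dg * 2 tau_1)`` where
    ``tau_1`` is the largest mode time constant — i.e. information relative
    to the best achievable by any normal network with the same time
    constants.
    """
    if not net.stable:
        raise ValueError("network must be stable")
    dg = ens.delta_g
    dr = -linalg.solve(net.A, dg)
    S = stationary_covariance(net, ens.noise_cov)
    try:
        info = float(dr @ linalg.solve(S, dr, assume_a="pos"))
    except linalg.LinAlgError as err:  # strongly amplifying chains etc.
        evals, evecs = np.linalg.eigh(S)
        if evals.max() <= 0:
            raise ValueError("stationary covariance is singular") from err
        keep = evals > 1e-14 * evals.max()
        c = evecs[:, keep].T @ dr
        info = float(np.sum(c * c / evals[keep]))
    tau1 = max(-1.0 / lam.real for lam in np.linalg.eigvals(net.A))
    input_info = float(dg @ linalg.solve(ens.noise_cov, dg, assume_a="pos"))
    if input_info > 0:
        normalized = info / (input_info * 2.0 * tau1)
    else:
        normalized = 0.0 if info == 0 else np.nan
    return {"info": info, "normalized_info": normalized}


def info_limiting_correlations(delta_r: np.ndarray, cov: np.ndarray) -> float:
    """Fraction of response variance along the signal direction.

    ``rho_ILC = dr^T S dr / (dr^T dr * trace(S))``, in ``[0, 1]``; values
    near 1 indicate variability concentrated along the stimulus axis.
    """
    dr = np.asarray(delta_r, dtype=float)
    if not np.any(dr):
        raise ValueError("delta_r must be nonzero")
    S = np.asarray(cov, dtype=float)
    return float(dr @ S @ dr / ((dr @ dr) * np.trace(S)))


def henrici_nonnormality(A: np.ndarray) -> float:
    """Henrici's departure from normality, normalized by the Frobenius norm.

    ``H = sqrt(||A||_F^2 - sum |lambda_i|^2) / ||A||_F``; zero for normal
    matrices, 1 for purely nilpotent ones.  Tiny negative radicands from
    rounding are clamped to zero.
    """
    A = np.asarray(A, dtype=float)
    fro2 = float(np.sum(A * A))
    if fro2 == 0:
        raise ValueError("Henrici index of the zero matrix is undefined")
    lam2 = float(np.sum(np.abs(np.linalg.eigvals(A)) ** 2))
    return float(np.sqrt(max(fro2 - lam2, 0.0) / fro2))


def feedforward_chain(n: int, tau: float, omega: float) -> LinearNetwork:
    """Functionally feedforward chain: leak ``-1/tau`` plus weight ``omega``
    from each unit to the next (``A[i+1, i] = omega``).

    The spectrum is a single eigenvalue ``-1/tau`` of multiplicity ``n``, yet
    for large ``omega`` the chain transiently amplifies input on the first
    unit, extending the effective integration window.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if tau <= 0:
        raise ValueError("tau must be positive")
    A = -np.eye(n) / tau
    idx = np.arange(n - 1)
    A[idx + 1, idx] = omega
    return LinearNetwork(A=A)


def simulate_linear_sde(
    net: LinearNetwork,
    ens: StimulusEnsemble,
    stimulus: int,
    dt: float,
    n_steps: int,
    seed: int,
    r0: np.ndarray | None = None,
) -> np.ndarray:
    """Euler-Maruyama simulation of ``dr/dt = A r + g(s) + eta(t)``.

    Per-step noise has covariance ``Sigma_eta * dt`` so that the discrete
    stationary covariance approaches the continuum Lyapunov solution as
    ``dt -> 0`` (with an ``O(dt)`` bias at finite step).  Returns the
    trajectory of shape ``(n_steps + 1, n)`` including the initial state.
    """
    if stimulus not in (1, 2):
        raise ValueError("stimulus must be 1 or 2")
    taus = [-1.0 / lam.real for lam in np.linalg.eigvals(net.A)
            if lam.real < 0]
    if taus and dt > min(taus) / 10.0:
        warnings.warn(
            f"dt={dt} exceeds min(tau)/10; Euler discretization error may be "
            "large", RuntimeWarning,
        )
    if not net.stable and n_steps * dt > 100.0:
        warnings.warn("long simulation of an unstable network will diverge",
                      RuntimeWarning)
    g = ens.g1 if stimulus == 1 else ens.g2
    n = net.n_neurons
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(ens.noise_cov)
    r = np.zeros(n) if r0 is None else np.asarray(r0, dtype=float).copy()
    out = np.empty((n_steps + 1, n))
    out[0] = r
    sq = np.sqrt(dt)
    A = net.A
    for k in range(n_steps):
        eta = L @ rng.standard_normal(n)
        r = r + (A @ r + g) * dt + eta * sq
        out[k + 1] = r
    return out


def impulse_response(
    net: LinearNetwork, r0: np.ndarray, times
) -> np.ndarray:
    """Deterministic relaxation ``r(t) = exp(A t) r0`` at the given times.

    The projection onto any mode's activation pattern decays as a pure
    exponential with that mode's time constant.
    """
    r0 = np.asarray(r0, dtype=float)
    times = np.asarray(times, dtype=float)
    return np.stack([linalg.expm(net.A * t) @ r0 for t in times])
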