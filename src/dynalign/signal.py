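"""Optimal discrimination of two noisy constant-mean input streams.

A network receives a vector input stream that, under stimulus ``s``, is drawn
i.i.d. per time step from ``N(g(s), Sigma_eta)``.  Two such stimuli are best
separated by projecting onto the linear discriminant
``w = Sigma_eta^{-1} (g2 - g1)`` and, over a window of ``T`` steps, by summing
the projection; the signal-to-noise ratio then grows as ``sqrt(T)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "StimulusEnsemble",
    "ProjectionStats",
    "linear_discriminant",
    "projection_stats",
    "integrated_stats",
    "sample_input_stream",
]

#: refuse to invert noise covariances beyond this condition number;
#: discriminant directions in the (numerical) null space are undefined
MAX_CONDITION = 1e12


@dataclass
class StimulusEnsemble:
    """Means and noise covariance of the feedforward input under two stimuli.

    Parameters
    ----------
    g1, g2:
        Mean input vectors under stimulus 1 and stimulus 2 (rate units).
    noise_cov:
        Stimulus-independent input noise covariance ``Sigma_eta``.
    dt:
        Sampling step of the input stream (time units).  The default of 1
        treats samples as the unit of time.
    """

    g1: np.ndarray
    g2: np.ndarray
    noise_cov: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.g1 = np.asarray(self.g1, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        n = self.g1.shape[0]
        if self.g2.shape != (n,) or self.noise_cov.shape != (n, n):
            raise ValueError(
                "dimension mismatch: g1, g2 and noise_cov must agree"
            )
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-10):
            raise ValueError("noise_cov must be symmetric")
        if np.any(linalg.eigvalsh(self.noise_cov) <= 0):
            raise ValueError("noise_cov must be positive definite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_dims(self) -> int:
        return self.g1.shape[0]

    @property
    def delta_g(self) -> np.ndarray:
        """Mean input difference ``g2 - g1``."""
        return self.g2 - self.g1

    def to_json(self) -> str:
        return json.dumps(
            {
                "g1": self.g1.tolist(),
                "g2": self.g2.tolist(),
                "noise_cov": self.noise_cov.tolist(),
                "dt": self.dt,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StimulusEnsemble":
        d = json.loads(text)
        return cls(
            g1=np.array(d["g1"]),
            g2=np.array(d["g2"]),
            noise_cov=np.array(d["noise_cov"]),
            dt=float(d.get("dt", 1.0)),
        )


@dataclass
class ProjectionStats:
    """Signal, noise and SNR of a linear projection of the input stream.

    ``delta_mu`` is the signed mean separation ``w^T (g2 - g1)``, ``sigma``
    the pooled standard deviation ``sqrt(w^T Sigma_eta w)``, and
    ``snr = |delta_mu| / sigma``.  The sign of ``delta_mu`` is retained for
    directional analyses; the SNR is always reported as a magnitude.
    """

    delta_mu: float
    sigma: float
    snr: float = field(init=False)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        self.snr = abs(self.delta_mu) / self.sigma


def linear_discriminant(ens: StimulusEnsemble) -> np.ndarray:
    """Optimal projection ``w = Sigma_eta^{-1} (g2 - g1)``.

    Maximizes the input SNR over all projection directions.  The returned
    vector is not normalized; every downstream SNR is invariant to its scale.

    Raises
    ------
    ValueError
        If ``noise_cov`` is singular or numerically near-singular
        (condition number above 1e12).
    """
    cond = np.linalg.cond(ens.noise_cov)
    if not np.isfinite(cond) or cond > MAX_CONDITION:
        raise ValueError(
            f"noise_cov is singular or near-singular (cond={cond:.3g}); "
            "the linear discriminant is undefined"
        )
    return linalg.solve(ens.noise_cov, ens.delta_g, assume_a="pos")


def projection_stats(w: np.ndarray, ens: StimulusEnsemble) -> ProjectionStats:
    """Signal, noise and SNR of the instantaneous projection ``w^T u(t)``."""
    w = np.asarray(w, dtype=float)
    if w.shape != (ens.n_dims,):
        raise ValueError("w must match the ensemble dimension")
    if not np.any(w):
        raise ValueError("w must be nonzero")
    delta_mu = float(w @ ens.delta_g)
    sigma = float(np.sqrt(w @ ens.noise_cov @ w))
    return ProjectionStats(delta_mu=delta_mu, sigma=sigma)


def integrated_stats(
    w: np.ndarray, ens: StimulusEnsemble, T: int
) -> ProjectionStats:
    """Stats of the projection summed over ``T`` steps.

    The mean separation grows as ``T`` and the noise as ``sqrt(T)``, so the
    SNR improves by ``sqrt(T)`` relative to the instantaneous projection.
    """
    if T < 1:
        raise ValueError("integration length T must be >= 1")
    inst = projection_stats(w, ens)
    return ProjectionStats(
        delta_mu=inst.delta_mu * T, sigma=inst.sigma * np.sqrt(T)
    )


def sample_input_stream(
    ens: StimulusEnsemble, stimulus: int, n_steps: int, seed: int
) -> np.ndarray:
    """Draw ``n_steps`` i.i.d. samples of input under the given stimulus.

    Returns an array of shape ``(n_steps, n_dims)``; reproducible for a
    fixed integer ``seed``.
    """
    if stimulus not in (1, 2):
        raise ValueError("stimulus must be 1 or 2")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    g = ens.g1 if stimulus == 1 else ens.g2
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(g, ens.noise_cov, size=n_steps,
                                   method="cholesky")
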