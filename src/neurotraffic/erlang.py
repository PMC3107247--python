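"""Erlang serial-server model of message processing.

A server is k exponential stages in series, each with rate mu.  The total
service time — the sum of the k independent stage times — follows the
Erlang distribution, the integer-shape special case of the Gamma
distribution with shape k and scale 1/mu.  Its coefficient of variation,
k**(-1/2), is strictly below 1 whenever k >= 2 (hypoexponential); a
server with parallel branches instead yields CV > 1 (hyperexponential).
A Gamma-distributed inter-departure-time sample with fitted shape k > 1
is therefore consistent with messages traversing a fixed series of
stages rather than alternative parallel routes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ErlangServerSpec",
    "stage_time_pdf",
    "erlang_moments",
    "erlang_cv",
    "total_time_laplace",
    "erlang_pdf",
    "simulate_erlang_server",
    "simulate_hyperexponential",
]


@dataclass(frozen=True)
class ErlangServerSpec:
    """k exponential service stages in series, each with rate mu (1/time)."""

    n_stages: int
    stage_rate: float

    def __post_init__(self) -> None:
        if not (isinstance(self.n_stages, (int, np.integer)) and self.n_stages >= 1):
            raise ValueError("n_stages must be an integer >= 1")
        if self.stage_rate <= 0:
            raise ValueError("stage_rate must be > 0")


def stage_time_pdf(x, spec: ErlangServerSpec) -> np.ndarray | float:
    """Density of one stage's service time: mu * exp(-mu * x); 0 for x < 0."""
    mu = spec.stage_rate
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, mu * np.exp(-mu * x), 0.0)
    return float(out) if out.ndim == 0 else out


def erlang_moments(spec: ErlangServerSpec) -> tuple[float, float]:
    """(mean, variance) of the total service time: (k/mu, k/mu**2).

    Each exponential stage contributes mean 1/mu and variance 1/mu**2;
    independence lets both sum across the k stages.
    """
    k, mu = spec.n_stages, spec.stage_rate
    return k / mu, k / mu**2


def erlang_cv(n_stages: int) -> float:
    """Coefficient of variation of the total service time: k**(-1/2).

    Equals 1 for a single stage (plain exponential) and falls below 1 for
    every k >= 2 — the hypoexponential signature of serial stages.
    Identical to the Gamma CV at shape k.
    """
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    return n_stages ** -0.5


def total_time_laplace(s, spec: ErlangServerSpec):
    """Laplace transform of the total service time: (mu / (mu + s))**k.

    The transform of a sum of independent variables is the product of
    their transforms, so the k identical exponential stages give the
    k-th power of mu/(mu+s).  Defined for Re(s) > -mu.
    """
    k, mu = spec.n_stages, spec.stage_rate
    s = np.asarray(s)
    if np.any(np.real(s) <= -mu):
        raise ValueError(f"transform requires Re(s) > -mu = {-mu}")
    out = (mu / (mu + s)) ** k
    return out.item() if out.ndim == 0 else out


def erlang_pdf(x, spec: ErlangServerSpec) -> np.ndarray | float:
    """Total-service-time density: mu**k x**(k-1) e**(-mu x) / (k-1)!.

    This is exactly the Gamma density with shape k and scale 1/mu,
    obtained by inverting the Laplace transform of the stage sum.
    """
    k, mu = spec.n_stages, spec.stage_rate
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore"):
        val = mu**k * x ** (k - 1) * np.exp(-mu * x) / math.factorial(k - 1)
    out = np.where(x >= 0, val, 0.0)
    if k == 1:  # 0**0 at the origin
        out = np.where(x == 0, mu, out)
    return float(out) if out.ndim == 0 else out


def simulate_erlang_server(
    spec: ErlangServerSpec, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw n total service times as explicit sums of k exponential stages.

    The seed is mandatory; the same seed reproduces the same sample.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    stages = rng.exponential(scale=1.0 / spec.stage_rate, size=(n, spec.n_stages))
    return stages.sum(axis=1)


def simulate_hyperexponential(
    rates: tuple[float, float],
    probs: tuple[float, float],
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Two-branch parallel server: each message takes branch i (rate mu_i)
    with probability p_i.  The mixture of exponentials has CV > 1 whenever
    the branch rates differ — the contrast case to the serial server.
    """
    if not math.isclose(sum(probs), 1.0):
        raise ValueError("branch probabilities must sum to 1")
    if any(r <= 0 for r in rates) or any(p < 0 for p in probs):
        raise ValueError("rates must be > 0 and probabilities >= 0")
    rng = np.random.default_rng(seed)
    branch = rng.random(n) < probs[0]
    scale = np.where(branch, 1.0 / rates[0], 1.0 / rates[1])
    return rng.exponential(scale=scale)


def erlang_as_gamma(spec: ErlangServerSpec) -> stats.rv_continuous:
    """The equivalent frozen Gamma distribution (shape k, scale 1/mu)."""
    return stats.gamma(a=spec.n_stages, scale=1.0 / spec.stage_rate)
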