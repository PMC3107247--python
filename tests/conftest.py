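"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (brute-force scans, direct
convolution, grid searches) so they stay independent of the library code
paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest


def brute_force_troughs(x: np.ndarray, threshold_ratio: float) -> list[int]:
    """O(n^2) reference trough detector.

    Enumerates interior local-minimum runs (plateau -> midpoint rounded
    down), computes each one's topographic prominence by walking outward
    to the first strictly deeper sample on each side (or the series end)
    and taking the lower of the two barrier rises, and keeps troughs with
    prominence >= threshold_ratio * (max - min).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    rng = x.max() - x.min()
    if rng == 0:
        return []
    events = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        # interior run strictly below both neighbors
        if i > 0 and j < n - 1 and x[i - 1] > x[i] and x[j + 1] > x[i]:
            v = x[i]
            deeper_left = np.where(x[:i] < v)[0]
            lstart = deeper_left[-1] + 1 if deeper_left.size else 0
            barrier_left = x[lstart:i].max()
            deeper_right = np.where(x[j + 1:] < v)[0]
            rend = j + 1 + deeper_right[0] if deeper_right.size else n
            barrier_right = x[j + 1:rend].max()
            prominence = min(barrier_left, barrier_right) - v
            if prominence >= threshold_ratio * rng:
                events.append((i + j) // 2)
        i = j + 1
    return events


def gamma_loglik(x: np.ndarray, k: float, theta: float) -> float:
    from scipy.special import gammaln

    n = x.size
    return float(
        (k - 1) * np.sum(np.log(x)) - np.sum(x) / theta
        - n * gammaln(k) - n * k * np.log(theta)
    )


def grid_search_gamma(x: np.ndarray) -> tuple[float, float]:
    """Independent Gamma MLE oracle: coarse grid + local refinement of the
    log-likelihood surface (no digamma equation)."""
    best = (None, -np.inf)
    ks = np.geomspace(0.1, 100, 200)
    mean = x.mean()
    for k in ks:
        ll = gamma_loglik(x, k, mean / k)
        if ll > best[1]:
            best = (k, ll)
    k0 = best[0]
    for width in (0.5, 0.1, 0.02, 0.004, 0.0008):
        ks = np.linspace(k0 * (1 - width), k0 * (1 + width), 41)
        lls = [gamma_loglik(x, k, mean / k) for k in ks]
        k0 = ks[int(np.argmax(lls))]
    return float(k0), float(mean / k0)


def direct_morlet_power(
    signal: np.ndarray, scales: np.ndarray, bandwidth: float, fc: float
) -> np.ndarray:
    """Direct time-domain convolution with the analytic complex Morlet
    psi(t) = (pi*fb)**-0.5 * exp(2j*pi*fc*t) * exp(-t**2/fb)."""
    out = np.empty((len(scales), signal.size))
    for i, a in enumerate(scales):
        half = int(np.ceil(8 * a))
        t = np.arange(-half, half + 1) / a
        psi = (np.pi * bandwidth) ** -0.5 * np.exp(2j * np.pi * fc * t) \
            * np.exp(-t**2 / bandwidth)
        coef = np.convolve(signal, np.conj(psi[::-1]), mode="same") / np.sqrt(a)
        out[i] = np.abs(coef) ** 2
    return out


def make_element_dataset(
    n_subjects: int,
    n_elements: int,
    effect_elements: tuple[int, ...] = (),
    delta: float = 0.0,
    seed: int = 0,
    within_sd: float = 1.0,
):
    """Paired two-condition dataset at the element level: subject + noise,
    with condition 2 shifted by delta * within-subject SD at the chosen
    elements."""
    from neurotraffic.pls import PLSDataset

    rng = np.random.default_rng(seed)
    subject_fx = rng.normal(0, 1, size=(n_subjects, n_elements))
    blocks = []
    for cond in range(2):
        x = subject_fx + rng.normal(0, within_sd, size=(n_subjects, n_elements))
        if cond == 1 and effect_elements:
            x[:, list(effect_elements)] += delta * within_sd
        blocks.append(x)
    data = np.vstack(blocks)
    labels = tuple((c, float(c)) for c in range(n_elements))
    return PLSDataset(
        data=data, n_subjects=n_subjects, n_conditions=2,
        element_labels=labels, condition_labels=("a", "b"),
        subject_labels=tuple(range(n_subjects)),
    )


@pytest.fixture
def trough_oracle():
    return brute_force_troughs


@pytest.fixture
def gamma_oracle():
    return grid_search_gamma


@pytest.fixture
def morlet_oracle():
    return direct_morlet_power


@pytest.fixture
def element_dataset_factory():
    return make_element_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
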