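"""Mean-centered task PLS with permutation significance and bootstrap
salience reliability.

The data matrix stacks subjects within condition blocks (rows) against
channel x frequency elements (columns).  Condition means are centered by
the grand condition mean and decomposed by SVD; each latent variable (LV)
pairs a design salience (condition contrast) with an element salience
pattern, weighted by a singular value s.  Effect size of LV i is
s_i**2 / sum_j s_j**2.  Significance comes from permuting condition
labels within subjects; reliability of element saliences comes from
bootstrap resampling of subjects (with pairing preserved), summarized as
bootstrap ratios salience / SE, reliable when |ratio| >= 2.57 (the
two-sided standard-normal 99% critical value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PLSDataset",
    "PLSResult",
    "build_pls_dataset",
    "mean_centered_pls",
    "permutation_test",
    "bootstrap_saliences",
    "run_pls",
    "BOOTSTRAP_RATIO_THRESHOLD",
]

#: Two-sided standard-normal 99% critical value, rounded to two decimals.
BOOTSTRAP_RATIO_THRESHOLD = 2.57


@dataclass(frozen=True)
class PLSDataset:
    """Subject-by-condition observations over channel x frequency elements.

    ``data`` has ``n_subjects * n_conditions`` rows ordered condition-block
    major — rows [c1: s1..sN, c2: s1..sN, ...] — with identical subject
    order in every block, and one column per element.
    """

    data: np.ndarray
    n_subjects: int
    n_conditions: int
    element_labels: tuple
    condition_labels: tuple = ()
    subject_labels: tuple = ()
    parameter: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] != self.n_subjects * self.n_conditions:
            raise ValueError("data must be (n_subjects * n_conditions) x n_elements")
        if np.any(~np.isfinite(data)):
            raise ValueError("data contains missing or non-finite values")
        if len(self.element_labels) != data.shape[1]:
            raise ValueError("element_labels must match the number of columns")
        object.__setattr__(self, "data", data)

    @property
    def n_elements(self) -> int:
        return self.data.shape[1]

    def by_condition(self) -> np.ndarray:
        """View as (n_conditions, n_subjects, n_elements)."""
        return self.data.reshape(self.n_conditions, self.n_subjects, self.n_elements)

    def condition_means(self) -> np.ndarray:
        return self.by_condition().mean(axis=1)


@dataclass
class PLSResult:
    singular_values: np.ndarray
    design_saliences: np.ndarray      # conditions x LVs
    element_saliences: np.ndarray     # elements x LVs
    effect_sizes: np.ndarray
    element_labels: tuple
    condition_labels: tuple = ()
    permutation_p: np.ndarray | None = None
    bootstrap_ratios: np.ndarray | None = None
    bootstrap_se: np.ndarray | None = None
    reliable: np.ndarray | None = None
    n_permutations: int = 0
    n_bootstraps: int = 0
    reliability_threshold: float = BOOTSTRAP_RATIO_THRESHOLD

    @property
    def n_lvs(self) -> int:
        return len(self.singular_values)

    def lv_table(self) -> pd.DataFrame:
        d = {
            "lv": np.arange(1, self.n_lvs + 1),
            "singular_value": self.singular_values,
            "effect_size": self.effect_sizes,
        }
        if self.permutation_p is not None:
            d["p_value"] = self.permutation_p
        return pd.DataFrame(d)

    def salience_table(self, lv: int = 0) -> pd.DataFrame:
        d = {
            "element": [str(lbl) for lbl in self.element_labels],
            "salience": self.element_saliences[:, lv],
        }
        if self.bootstrap_ratios is not None:
            d["bootstrap_ratio"] = self.bootstrap_ratios[:, lv]
            d["reliable"] = self.reliable[:, lv]
        return pd.DataFrame(d)


def build_pls_dataset(fit_table: pd.DataFrame, parameter: str) -> PLSDataset:
    """Pivot a long fit table into the stacked PLS data matrix.

    Parameters
    ----------
    fit_table : DataFrame
        Columns subject, condition, channel, frequency_hz and the chosen
        parameter column (e.g. ``shape`` or ``scale``), one row per
        subject/condition/channel/frequency cell.
    parameter : str
        Which parameter column to analyze.

    Raises
    ------
    ValueError
        If any subject misses a condition (the design is paired) or any
        cell is empty/NaN.
    """
    if parameter not in fit_table.columns:
        raise ValueError(f"parameter column {parameter!r} not in table")
    subjects = tuple(sorted(fit_table["subject"].unique()))
    conditions = tuple(sorted(fit_table["condition"].unique()))
    missing = [
        s for s in subjects
        if set(fit_table.loc[fit_table["subject"] == s, "condition"]) != set(conditions)
    ]
    if missing:
        raise ValueError(f"subjects missing a condition: {missing}")
    wide = fit_table.pivot_table(
        index=["condition", "subject"],
        columns=["channel", "frequency_hz"],
        values=parameter,
        sort=True,
    )
    if wide.isna().any().any():
        bad = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"empty cells for elements {bad}; impute or drop upstream")
    rows = pd.MultiIndex.from_product([conditions, subjects],
                                      names=["condition", "subject"])
    wide = wide.reindex(rows)
    element_labels = tuple(wide.columns.tolist())
    return PLSDataset(
        data=wide.to_numpy(),
        n_subjects=len(subjects),
        n_conditions=len(conditions),
        element_labels=element_labels,
        condition_labels=conditions,
        subject_labels=subjects,
        parameter=parameter,
    )


def _centered_svd(cube: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD of condition means centered by the grand condition mean.

    Returns (U, s, V) truncated to n_conditions - 1 latent variables —
    the rank bound after removing the grand mean.
    """
    means = cube.mean(axis=1)                       # conditions x elements
    centered = means - means.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    n_lv = max(cube.shape[0] - 1, 1)
    return u[:, :n_lv], s[:n_lv], vt[:n_lv].T


def mean_centered_pls(dataset: PLSDataset) -> PLSResult:
    """Decompose the grand-mean-centered condition means by SVD.

    Latent variables are ordered by descending singular value; with
    identical condition means all singular values are zero (flagged by a
    warning, not an error).
    """
    if dataset.n_conditions < 2:
        raise ValueError("need >= 2 conditions")
    u, s, v = _centered_svd(dataset.by_condition())
    total = float(np.sum(s**2))
    if total == 0.0:
        warnings.warn("identical condition means: all singular values are zero")
        effect = np.zeros_like(s)
    else:
        effect = s**2 / total
    return PLSResult(
        singular_values=s,
        design_saliences=u,
        element_saliences=v,
        effect_sizes=effect,
        element_labels=dataset.element_labels,
        condition_labels=dataset.condition_labels,
    )


def permutation_test(
    dataset: PLSDataset,
    n_permutations: int = 500,
    seed: int | np.random.Generator = 0,
    add_one: bool = False,
) -> np.ndarray:
    """Per-LV permutation p-values.

    Each replication independently reshuffles the condition labels within
    every subject (sampling without replacement) and recomputes the
    singular values; p is the proportion of permuted values >= the
    observed one, per LV.  With ``add_one`` the (b+1)/(n+1) estimator is
    used instead of the plain proportion.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    cube = dataset.by_condition()
    _, s_obs, _ = _centered_svd(cube)
    exceed = np.zeros_like(s_obs)
    nc = dataset.n_conditions
    for _ in range(n_permutations):
        perm = np.empty_like(cube)
        for subj in range(dataset.n_subjects):
            order = rng.permutation(nc)
            perm[:, subj, :] = cube[order, subj, :]
        _, s_perm, _ = _centered_svd(perm)
        exceed += s_perm >= s_obs
    if add_one:
        return (exceed + 1) / (n_permutations + 1)
    return exceed / n_permutations


def bootstrap_saliences(
    dataset: PLSDataset,
    n_bootstraps: int = 500,
    seed: int | np.random.Generator = 0,
    threshold: float = BOOTSTRAP_RATIO_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bootstrap ratios and reliability mask for element saliences.

    Each replication resamples subjects with replacement — the same
    resampled subjects in every condition block, preserving the pairing —
    recomputes the element saliences, aligns each bootstrap LV's sign to
    the original pattern, and accumulates the standard error.  The ratio
    is original salience / bootstrap SE; an element is reliable when
    |ratio| >= threshold.  Elements with zero bootstrap SE are reported
    as +/-inf with a warning.

    Returns
    -------
    (ratios, se, reliable) : each elements x LVs.
    """
    if n_bootstraps < 1:
        raise ValueError("n_bootstraps must be >= 1")
    rng = np.random.default_rng(seed)
    cube = dataset.by_condition()
    _, _, v_obs = _centered_svd(cube)
    boots = np.empty((n_bootstraps,) + v_obs.shape)
    for b in range(n_bootstraps):
        take = rng.integers(0, dataset.n_subjects, size=dataset.n_subjects)
        _, _, v_b = _centered_svd(cube[:, take, :])
        # per-LV sign alignment to the original saliences
        signs = np.sign(np.sum(v_b * v_obs, axis=0))
        signs[signs == 0] = 1.0
        boots[b] = v_b * signs
    se = boots.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(se > 0, v_obs / np.where(se > 0, se, 1.0),
                          np.sign(v_obs) * np.inf)
    if np.any(se == 0):
        warnings.warn("zero bootstrap SE at some elements; ratios set to +/-inf")
    reliable = np.abs(ratios) >= threshold
    return ratios, se, reliable


def run_pls(
    dataset: PLSDataset,
    n_permutations: int = 500,
    n_bootstraps: int = 500,
    seed: int = 0,
    threshold: float = BOOTSTRAP_RATIO_THRESHOLD,
) -> PLSResult:
    """Full mean-centered PLS: decomposition + permutation + bootstrap.

    One seed drives both resampling procedures through independent
    substreams, so the result is reproducible and the two procedures do
    not share draws.
    """
    result = mean_centered_pls(dataset)
    ss = np.random.SeedSequence(seed)
    perm_rng, boot_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    result.permutation_p = permutation_test(dataset, n_permutations, perm_rng)
    ratios, se, reliable = bootstrap_saliences(dataset, n_bootstraps, boot_rng,
                                               threshold)
    result.bootstrap_ratios = ratios
    result.bootstrap_se = se
    result.reliable = reliable
    result.n_permutations = n_permutations
    result.n_bootstraps = n_bootstraps
    result.reliability_threshold = threshold
    return result
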