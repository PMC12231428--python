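"""Label-shuffled permutation inference with Bonferroni correction.

The null distribution re-runs the entire cross-validated prediction
procedure (feature selection inside the folds) after randomly permuting the
behavioural scores, so selection optimism is present under the null exactly
as it is for the observed statistic.  Significance across the eight feature
families (whole brain + seven networks) is Bonferroni-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError
from .prediction import CVConfig, SelectionConfig, repeat_prediction

__all__ = ["PermutationResult", "permutation_test", "apply_bonferroni"]


@dataclass
class PermutationResult:
    """Observed statistic, permutation null and the resulting p-value."""

    observed: float
    null_distribution: np.ndarray
    p_uncorrected: float
    family: str
    n_permutations: int


def permutation_test(
    features: np.ndarray,
    scores: np.ndarray,
    sel: SelectionConfig,
    cv: CVConfig,
    n_perm: int = 500,
    seed: int = 0,
    null_n_repeats: int = 1,
    family: str = "WB",
    observed: float | None = None,
) -> PermutationResult:
    """One-sided permutation test of the mean prediction correlation.

    Each permutation shuffles the scores once and runs the full
    cross-validated prediction (``null_n_repeats`` CV loops; default one loop
    per permutation).  The p-value uses the add-one estimator
    ``(1 + #{null >= observed}) / (1 + n_perm)``, which can never return 0.
    ``observed`` may be supplied to avoid recomputing it.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    if observed is None:
        observed = repeat_prediction(features, scores, sel, cv, family=family).mean_r
    rng = np.random.default_rng(seed)
    perm_seeds = np.random.SeedSequence(seed).generate_state(n_perm) % np.uint32(2**31)
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = rng.permutation(scores)
        cv_null = replace(cv, n_repeats=null_n_repeats, seed=int(perm_seeds[i]))
        null[i] = repeat_prediction(features, shuffled, sel, cv_null, family=family).mean_r
    p = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_perm)
    return PermutationResult(
        observed=float(observed),
        null_distribution=null,
        p_uncorrected=p,
        family=family,
        n_permutations=n_perm,
    )


def apply_bonferroni(
    p_values: dict[str, float], alpha: float = 0.05, m: int | None = None
) -> dict[str, tuple[bool, bool]]:
    """Flag each family as significant before and after Bonferroni correction.

    ``m`` defaults to the number of families tested; the corrected threshold
    is exactly ``alpha / m`` (0.00625 for alpha 0.05 and m 8).
    Returns ``family -> (uncorrected_significant, corrected_significant)``.
    """
    if not p_values:
        raise ConfigError("p_values map is empty")
    for fam, p in p_values.items():
        if not 0 < p <= 1:
            raise ConfigError(f"p-value for {fam!r} outside (0, 1]: {p}")
    m = len(p_values) if m is None else m
    if m < 1:
        raise ConfigError("m must be >= 1")
    threshold = alpha / m
    return {fam: (p < alpha, p < threshold) for fam, p in p_values.items()}


def bonferroni_threshold(alpha: float = 0.05, m: int = 8) -> float:
    """Corrected per-family threshold alpha / m."""
    if m < 1:
        raise ConfigError("m must be >= 1")
    return alpha / m
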