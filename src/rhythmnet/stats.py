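"""Shared inference machinery: permutation nulls, Holm correction, and
distribution-equating stratified subsampling.

Every stochastic routine takes an explicit seed (or numpy Generator) so the
1500-iteration procedures elsewhere in the package reproduce exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null, and the +1-corrected p."""

    observed: float
    null_values: np.ndarray
    p: float
    n_perm: int
    sidedness: str = "greater"
    holm_significant: bool | None = None

    @property
    def floor(self) -> float:
        return 1.0 / (self.n_perm + 1)


def _p_value(observed: float, null: np.ndarray, sidedness: str) -> float:
    n_perm = null.size
    if sidedness == "greater":
        k = int(np.sum(null >= observed))
    elif sidedness == "less":
        k = int(np.sum(null <= observed))
    elif sidedness == "two_sided":
        k = int(np.sum(np.abs(null) >= abs(observed)))
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return (1.0 + k) / (n_perm + 1.0)


def permutation_result(observed: float, null: np.ndarray,
                       sidedness: str = "greater") -> PermutationResult:
    """Package an observed statistic and a precomputed null distribution."""
    null = np.asarray(null, dtype=float)
    if not np.all(np.isfinite(null)) or not np.isfinite(observed):
        bad = np.flatnonzero(~np.isfinite(null))
        raise ValueError(
            f"non-finite statistic (iterations {bad[:5].tolist()}...)"
            if bad.size else "non-finite observed statistic"
        )
    return PermutationResult(
        observed=float(observed), null_values=null,
        p=_p_value(float(observed), null, sidedness),
        n_perm=null.size, sidedness=sidedness,
    )


def permutation_null(observed_fn: Callable[..., float],
                     shuffle_fn: Callable[[np.random.Generator], tuple],
                     n_perm: int,
                     sidedness: str = "greater",
                     seed: int | np.random.Generator = 0) -> PermutationResult:
    """Generic permutation test.

    ``observed_fn(*args)`` evaluates the statistic; ``shuffle_fn(rng)``
    returns the argument tuple for one shuffled replicate.  The observed
    value is ``observed_fn(*shuffle_fn(None))`` -- passing ``None`` asks the
    shuffler for the unshuffled data.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-value floor is "
                      f"{1.0 / (n_perm + 1):.3g}", stacklevel=2)
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    observed = float(observed_fn(*shuffle_fn(None)))
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = observed_fn(*shuffle_fn(rng))
        if not np.isfinite(null[i]):
            raise ValueError(f"statistic non-finite on shuffle {i}")
    return permutation_result(observed, null, sidedness)


def holm_correct(pvalues: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Holm's sequential Bonferroni: boolean rejection flags, original order.

    Sort p ascending and reject while ``p_(i) <= alpha / (m - i)`` (0-based
    i); the first failure stops the ladder.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if p[idx] <= alpha / (m - i):
            reject[idx] = True
        else:
            break
    return reject


@dataclass
class StratifiedSample:
    """Indices retained in each group after histogram equating."""

    kept_a: np.ndarray
    kept_b: np.ndarray
    equated_variable: str = ""

    @property
    def n_kept(self) -> int:
        return self.kept_a.size


def stratify(values_a: np.ndarray, values_b: np.ndarray,
             n_bins: int = 20,
             seed: int | np.random.Generator = 0,
             equated_variable: str = "") -> StratifiedSample:
    """Subsample two groups so a nuisance variable's histograms match.

    A common histogram is built over the pooled range; within every bin both
    groups are subsampled without replacement to the smaller count.  The two
    returned index sets therefore have equal size and bin-for-bin identical
    counts of the equated variable.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    lo = max(a.min(), b.min())
    hi = min(a.max(), b.max())
    if hi < lo:
        raise ValueError("supports do not overlap; nothing to equate")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    edges = np.linspace(min(a.min(), b.min()), max(a.max(), b.max()),
                        n_bins + 1)
    ia = np.clip(np.digitize(a, edges) - 1, 0, n_bins - 1)
    ib = np.clip(np.digitize(b, edges) - 1, 0, n_bins - 1)
    kept_a, kept_b = [], []
    for k in range(n_bins):
        in_a = np.flatnonzero(ia == k)
        in_b = np.flatnonzero(ib == k)
        n = min(in_a.size, in_b.size)
        if n == 0:
            continue
        kept_a.append(rng.choice(in_a, size=n, replace=False))
        kept_b.append(rng.choice(in_b, size=n, replace=False))
    if not kept_a:
        raise ValueError("no histogram bin is populated in both groups")
    return StratifiedSample(
        kept_a=np.sort(np.concatenate(kept_a)),
        kept_b=np.sort(np.concatenate(kept_b)),
        equated_variable=equated_variable,
    )
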