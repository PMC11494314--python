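"""Coincidence probabilities and order-2 (collision) entropies.

The probability of coincidence of a discrete random variable X,

    p_C[X] = sum_x P(x)^2,

is the chance that two independent draws of X agree.  Its reciprocal is the
Simpson diversity D_2 (an effective number of categories) and its negative
log2 is the order-2 Renyi entropy H_2[X], the collision entropy.  From a
sample of independently recombined clones, p_C is estimated without bias by
the fraction of unordered clone pairs that share a feature value.

Conditional coincidence probabilities are averages of within-group values
weighted by rho_2(y) = P(y)^2 / sum_y P(y)^2, which is the weighting that
keeps H_2 additive: H_2[X,Y] = H_2[X] + H_2[Y|X].
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CoincidenceEstimate",
    "pc_exact",
    "rho2_weights",
    "pc_conditional_exact",
    "pc_pairs",
    "pc_conditional",
    "entropy2",
]


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return False


def clean_values(values: Iterable) -> list:
    """Drop missing entries (None / NaN) from a feature column."""
    return [v for v in values if not _is_missing(v)]


@dataclass
class CoincidenceEstimate:
    """A coincidence probability with its pair-counting provenance.

    For unconditional pair estimates ``p_hat == coincident_pairs /
    total_pairs``; for conditional estimates ``p_hat`` is the rho_2-weighted
    average of per-group estimates and the pair counts are bookkeeping sums.
    ``p_hat`` is None when no pairs were available.
    """

    p_hat: float | None
    coincident_pairs: float = 0.0
    total_pairs: float = 0.0
    se: float | None = None
    group_weights: dict | None = None
    n_values: int = 0

    @classmethod
    def from_probability(cls, p: float) -> "CoincidenceEstimate":
        """Wrap an exactly known coincidence probability."""
        return cls(p_hat=float(p))

    @property
    def d2(self) -> float | None:
        """Effective diversity 1 / p_C (Simpson's inverse)."""
        if self.p_hat is None or self.p_hat == 0:
            return None
        return 1.0 / self.p_hat

    @property
    def entropy_bits(self) -> float | None:
        return entropy2(self.p_hat)


def pc_exact(dist: Sequence[float]) -> float:
    """Coincidence probability sum_x P(x)^2 of an exact categorical distribution.

    Parameters
    ----------
    dist
        Probability vector; entries must be non-negative and sum to 1
        within 1e-9.
    """
    p = np.asarray(dist, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any(p < -1e-12):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum():.12f}, expected 1")
    return float(np.sum(p**2))


def rho2_weights(p_group: Sequence[float]) -> np.ndarray:
    """Squared-probability weights rho_2(y) = P(y)^2 / sum P(y)^2."""
    p = np.asarray(p_group, dtype=float)
    sq = p**2
    total = sq.sum()
    if total <= 0:
        raise ValueError("group probabilities are all zero")
    return sq / total


def pc_conditional_exact(
    pc_by_group: Sequence[float], p_group: Sequence[float]
) -> float:
    """Conditional coincidence probability from exact per-group values."""
    rho = rho2_weights(p_group)
    pc = np.asarray(pc_by_group, dtype=float)
    if pc.shape != rho.shape:
        raise ValueError("pc_by_group and p_group differ in length")
    return float(np.sum(rho * pc))


def _pair_counts(values: list) -> tuple[float, float]:
    """(coincident unordered pairs, total unordered pairs) among values."""
    n = len(values)
    total = n * (n - 1) / 2.0
    coincident = sum(c * (c - 1) / 2.0 for c in Counter(values).values())
    return coincident, total


def pc_pairs(
    values: Iterable,
    *,
    bootstrap: int = 0,
    rng: np.random.Generator | int | None = None,
) -> CoincidenceEstimate:
    """Unbiased pair-counting estimate of the coincidence probability.

    p_hat = sum_x n_x (n_x - 1) / (N (N - 1)) over distinct clones.  With
    fewer than two usable values the estimate is returned with
    ``total_pairs == 0`` and ``p_hat`` missing.

    Parameters
    ----------
    bootstrap
        Number of clone-level bootstrap replicates for the standard error
        (0 disables).
    rng
        Seed or Generator for the bootstrap.
    """
    vals = clean_values(values)
    n = len(vals)
    if n < 2:
        return CoincidenceEstimate(p_hat=None, total_pairs=0.0, n_values=n)
    coincident, total = _pair_counts(vals)
    p_hat = coincident / total
    se = None
    if bootstrap > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        arr = np.empty(bootstrap)
        vals_np = np.asarray(vals, dtype=object)
        for b in range(bootstrap):
            idx = gen.integers(0, n, size=n)
            c, t = _pair_counts(list(vals_np[idx]))
            arr[b] = c / t
        se = float(arr.std(ddof=1))
    return CoincidenceEstimate(
        p_hat=p_hat,
        coincident_pairs=coincident,
        total_pairs=total,
        se=se,
        n_values=n,
    )


def _group_probs(
    labels: Sequence, sizes: Mapping, weights: str | Mapping
) -> dict:
    if isinstance(weights, Mapping):
        total = sum(weights[y] for y in labels)
        if total <= 0:
            raise ValueError("explicit group weights sum to zero")
        return {y: weights[y] / total for y in labels}
    if weights == "uniform":
        return {y: 1.0 / len(labels) for y in labels}
    if weights == "size":
        total = sum(sizes[y] for y in labels)
        return {y: sizes[y] / total for y in labels}
    raise ValueError(f"unknown weight scheme {weights!r}")


def pc_conditional(
    groups: Mapping[object, Iterable],
    weights: str | Mapping = "uniform",
    *,
    bootstrap: int = 0,
    rng: np.random.Generator | int | None = None,
) -> CoincidenceEstimate:
    """rho_2-weighted average of per-group pair-counting estimates.

    Parameters
    ----------
    groups
        Mapping from group label (e.g. epitope) to that group's feature
        values.  Groups with fewer than two usable values are dropped with
        a warning.
    weights
        ``"uniform"`` (each retained group has equal P(y)), ``"size"``
        (P(y) proportional to usable clone count), or an explicit mapping
        label -> P(y) (normalized over retained groups).
    """
    cleaned = {y: clean_values(v) for y, v in groups.items()}
    usable = {y: v for y, v in cleaned.items() if len(v) >= 2}
    dropped = sorted(set(cleaned) - set(usable), key=str)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} group(s) with <2 usable values: {dropped}",
            stacklevel=2,
        )
    if not usable:
        return CoincidenceEstimate(p_hat=None, total_pairs=0.0)
    labels = sorted(usable, key=str)
    sizes = {y: len(usable[y]) for y in labels}
    p_y = _group_probs(labels, sizes, weights)
    rho = rho2_weights([p_y[y] for y in labels])
    per_group = [pc_pairs(usable[y]) for y in labels]
    p_hat = float(sum(r * est.p_hat for r, est in zip(rho, per_group)))
    coincident = sum(est.coincident_pairs for est in per_group)
    total = sum(est.total_pairs for est in per_group)
    se = None
    if bootstrap > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        arr = np.empty(bootstrap)
        group_arrays = {y: np.asarray(usable[y], dtype=object) for y in labels}
        for b in range(bootstrap):
            acc = 0.0
            for r, y in zip(rho, labels):
                vals = group_arrays[y]
                idx = gen.integers(0, len(vals), size=len(vals))
                c, t = _pair_counts(list(vals[idx]))
                acc += r * (c / t)
            arr[b] = acc
        se = float(arr.std(ddof=1))
    return CoincidenceEstimate(
        p_hat=p_hat,
        coincident_pairs=coincident,
        total_pairs=total,
        se=se,
        group_weights={y: float(r) for y, r in zip(labels, rho)},
        n_values=sum(sizes.values()),
    )


def entropy2(pc: float | None) -> float | None:
    """Collision entropy H_2 = -log2 p_C in bits.

    Returns None (with a warning) when the coincidence probability is zero
    or missing: without at least one observed coincidence the entropy is
    unbounded from the data.
    """
    if pc is None:
        return None
    if pc < 0 or pc > 1:
        raise ValueError(f"coincidence probability {pc} outside [0, 1]")
    if pc == 0:
        warnings.warn(
            "zero coincidence probability: collision entropy is undefined "
            "without at least one observed coincidence",
            stacklevel=2,
        )
        return None
    return -math.log2(pc)
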