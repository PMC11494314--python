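"""Distance-resolved coincidences and fuzzy-match information.

Exact coincidence generalizes to near-coincidence: the probability that two
independent draws of a feature land at distance Delta of each other,

    p_C[X](Delta) = sum_{x,x'} P(x) P(x') [d(x, x') == Delta].

Its pair-counting analogue is the fraction of unordered distinct-clone
pairs at exactly that distance; summed over Delta these fractions
partition all pairs.  The near-coincidence mutual information

    I_2^Delta = log2( p_C[X|Pi](Delta) / p_C[X](Delta) )

plays the same role for fuzzy matches that relevancy plays for exact ones:
each bit doubles the posterior odds achievable from a match at distance
Delta.  Supported metrics are the CDR3 Levenshtein distances per chain and
their paired-chain sum.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import edlib
import numpy as np
import pandas as pd

from . import coincidence as co
from .coincidence import CoincidenceEstimate
from .features import FeatureSpec, extract
from .information import InformationScore
from .repertoire_io import RepertoireTable

__all__ = [
    "METRICS",
    "DistanceProfile",
    "levenshtein",
    "pair_distance_counts",
    "pc_at_distance",
    "pc_at_distance_exact",
    "near_mi",
    "near_mi_exact",
    "distance_profile",
]

METRICS = ("levenshtein_cdr3a", "levenshtein_cdr3b", "levenshtein_sum")


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if a == b:
        return 0
    return edlib.align(a, b, task="distance")["editDistance"]


def _metric_feature(metric: str) -> FeatureSpec:
    if metric == "levenshtein_cdr3a":
        return FeatureSpec.cdr3("alpha")
    if metric == "levenshtein_cdr3b":
        return FeatureSpec.cdr3("beta")
    if metric == "levenshtein_sum":
        return FeatureSpec.product(FeatureSpec.cdr3("alpha"), FeatureSpec.cdr3("beta"))
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def _value_distance(u, v, metric: str) -> int:
    if metric == "levenshtein_sum":
        return levenshtein(u[0], v[0]) + levenshtein(u[1], v[1])
    return levenshtein(u, v)


def pair_distance_counts(values: Iterable, metric: str) -> Counter:
    """Unordered distinct-clone pair counts per distance.

    Pairs of clones with identical values fall in the Delta=0 class;
    within-clone self-pairs are never counted.  Distances are computed on
    unique values and weighted by count products, so the result is
    independent of record order.
    """
    vals = co.clean_values(values)
    counts = Counter(vals)
    uniq = sorted(counts, key=repr)
    tally: Counter = Counter()
    zero_pairs = sum(c * (c - 1) // 2 for c in counts.values())
    if zero_pairs:
        tally[0] = zero_pairs
    for i in range(len(uniq)):
        ci = counts[uniq[i]]
        for j in range(i + 1, len(uniq)):
            d = _value_distance(uniq[i], uniq[j], metric)
            tally[d] += ci * counts[uniq[j]]
    return tally


def _pc_from_counts(tally: Counter, delta: int) -> CoincidenceEstimate:
    total = sum(tally.values())
    if total == 0:
        return CoincidenceEstimate(p_hat=None, total_pairs=0.0)
    hits = tally.get(delta, 0)
    return CoincidenceEstimate(
        p_hat=hits / total, coincident_pairs=float(hits), total_pairs=float(total)
    )


def pc_at_distance(values: Iterable, metric: str, delta: int) -> CoincidenceEstimate:
    """Fraction of unordered distinct-clone pairs at exactly distance delta."""
    return _pc_from_counts(pair_distance_counts(values, metric), delta)


def pc_at_distance_exact(
    dist: Mapping, delta: int, dist_fn=levenshtein
) -> float:
    """Probability that two independent draws land at exactly distance delta.

    ``dist`` maps outcomes (e.g. CDR3 strings) to probabilities; the double
    sum runs over ordered outcome pairs, so identical draws contribute to
    the delta = 0 class.
    """
    total = 0.0
    items = list(dist.items())
    for x, px in items:
        for y, py in items:
            if dist_fn(x, y) == delta:
                total += px * py
    return total


def near_mi_exact(
    background_dist: Mapping,
    group_dists: list[Mapping],
    p_group,
    delta: int,
    dist_fn=levenshtein,
) -> float | None:
    """Near-coincidence mutual information from exact distributions.

    The conditional side averages per-group distance probabilities with
    rho_2 weights; returns None when either side has no mass at delta.
    """
    rho = co.rho2_weights(p_group)
    pc_spec = float(
        sum(r * pc_at_distance_exact(g, delta, dist_fn) for r, g in zip(rho, group_dists))
    )
    pc_bg = pc_at_distance_exact(background_dist, delta, dist_fn)
    if pc_bg <= 0 or pc_spec <= 0:
        return None
    return math.log2(pc_spec / pc_bg)


def _conditional_distance_pc(
    groups: Mapping[object, Iterable], metric: str, weights: str | Mapping
) -> tuple[dict[int, float], int]:
    """rho_2-weighted per-distance probabilities over epitope groups."""
    tallies = {}
    for y, vals in groups.items():
        t = pair_distance_counts(vals, metric)
        if sum(t.values()) >= 1:
            tallies[y] = t
    if not tallies:
        return {}, 0
    labels = sorted(tallies, key=str)
    sizes = {y: len(co.clean_values(groups[y])) for y in labels}
    p_y = co._group_probs(labels, sizes, weights)
    rho = co.rho2_weights([p_y[y] for y in labels])
    out: dict[int, float] = {}
    for r, y in zip(rho, labels):
        total = sum(tallies[y].values())
        for d, n in tallies[y].items():
            out[d] = out.get(d, 0.0) + r * n / total
    max_d = max(out)
    return out, max_d


@dataclass
class DistanceProfile:
    """Per-distance coincidence probabilities and fuzzy-match information.

    ``table`` has one row per distance class Delta from 0 to the largest
    observed distance: ``delta, pc_bg, pc_spec, mi_bits``.  The two
    probability columns each sum to 1 over all observed classes.
    """

    metric: str
    table: pd.DataFrame
    cumulative: bool = False

    def mi_at(self, delta: int) -> float | None:
        row = self.table[self.table["delta"] == delta]
        if row.empty or not np.isfinite(row["mi_bits"].iloc[0]):
            return None
        return float(row["mi_bits"].iloc[0])


def distance_profile(
    specific: RepertoireTable,
    background: RepertoireTable,
    metric: str,
    delta_max: int | None = None,
    *,
    weights: str | Mapping = "uniform",
    cumulative: bool = False,
) -> DistanceProfile:
    """Distance-resolved coincidence probabilities and MI per distance.

    The specific side averages per-epitope distance distributions with
    rho_2 weights; the background side pools all background pairs.  With
    ``cumulative=True`` classes are "distance <= Delta" instead of the
    default exact binning.  Records missing a chain required by the metric
    are excluded.
    """
    feat = _metric_feature(metric)
    bg_vals = co.clean_values(extract(background, feat))
    bg_tally = pair_distance_counts(bg_vals, metric)
    bg_total = sum(bg_tally.values())
    if bg_total == 0:
        raise ValueError("background has no usable pairs for this metric")

    groups = {
        e: co.clean_values(extract(sub, feat))
        for e, sub in specific.epitope_groups().items()
    }
    spec_pc, spec_max = _conditional_distance_pc(groups, metric, weights)
    if not spec_pc:
        raise ValueError("specific table has no usable pairs for this metric")

    top = max(max(bg_tally), spec_max)
    if delta_max is not None:
        top = min(top, delta_max)
    deltas = np.arange(top + 1)
    p_bg = np.array([bg_tally.get(int(d), 0) / bg_total for d in deltas])
    p_sp = np.array([spec_pc.get(int(d), 0.0) for d in deltas])
    if cumulative:
        p_bg = np.cumsum(p_bg)
        p_sp = np.cumsum(p_sp)
    defined = (p_bg > 0) & (p_sp > 0)
    mi = np.full(len(deltas), np.nan)
    mi[defined] = np.log2(p_sp[defined] / p_bg[defined])
    table = pd.DataFrame(
        {"delta": deltas, "pc_bg": p_bg, "pc_spec": p_sp, "mi_bits": mi}
    )
    return DistanceProfile(metric=metric, table=table, cumulative=cumulative)


def near_mi(
    specific: RepertoireTable,
    background: RepertoireTable,
    metric: str,
    delta: int,
    *,
    weights: str | Mapping = "uniform",
) -> InformationScore:
    """Near-coincidence mutual information at one distance class."""
    profile = distance_profile(specific, background, metric, weights=weights)
    row = profile.table[profile.table["delta"] == delta]
    bits = None
    if not row.empty and np.isfinite(row["mi_bits"].iloc[0]):
        bits = float(row["mi_bits"].iloc[0])
    return InformationScore(
        bits=bits,
        feature=f"{metric}@{delta}",
        scope="global",
        diagnostic=None if bits is not None else "no pairs at this distance",
    )
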