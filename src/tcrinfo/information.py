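"""Coincidence mutual information: relevancy, redundancy, synergy.

The relevancy of a feature X for epitope specificity Pi is the coincidence
mutual information

    I_2(X, Pi) = log2( p_C[X|Pi] / p_C[X] ),

the log-ratio of the conditional coincidence probability among
epitope-specific clones (rho_2-averaged over epitopes) to the coincidence
probability in the background repertoire.  It equals H_2[X] - H_2[X|Pi]
and is symmetric in its arguments.  One bit of relevancy doubles the
posterior odds achievable from a feature match (see
:mod:`tcrinfo.classification`).

Derived quantities:

* local relevancy  i_2(X, pi)            — one epitope only;
* conditional relevancy  I_2(X, Pi | Y)  = H_2[X|Y] - H_2[X|Pi,Y];
* interaction information  I_2,int(X, Y | Pi)
      = I_2([X,Y], Pi) - I_2(X, Pi) - I_2(Y, Pi),
  positive for synergy, negative for redundancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import coincidence as co
from .coincidence import CoincidenceEstimate
from .features import FeatureSpec, extract
from .repertoire_io import RepertoireTable

__all__ = [
    "InformationScore",
    "relevancy",
    "local_relevancy",
    "conditional_relevancy",
    "interaction_information",
    "local_interaction_information",
    "relevancy_matrix",
    "interaction_matrix",
    "relevancy_exact",
    "conditional_relevancy_exact",
    "interaction_information_exact",
]


@dataclass
class InformationScore:
    """An information quantity in bits with provenance and uncertainty."""

    bits: float | None
    feature: FeatureSpec | str | None = None
    conditioning: FeatureSpec | str | None = None
    scope: str = "global"
    ci_low: float | None = None
    ci_high: float | None = None
    n_specific: int | None = None
    n_background: int | None = None
    diagnostic: str | None = None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        b = "NA" if self.bits is None else f"{self.bits:.3f}"
        return f"InformationScore({self.feature}, {b} bits, scope={self.scope})"


def _log2_ratio(num: float | None, den: float | None) -> float | None:
    if num is None or den is None or num <= 0 or den <= 0:
        return None
    return math.log2(num / den)


def _background_pc(background, feature: FeatureSpec):
    """Resolve a background argument to (p_C value, usable clone count)."""
    if isinstance(background, RepertoireTable):
        col = co.clean_values(extract(background, feature))
        est = co.pc_pairs(col)
        return est.p_hat, len(col)
    if isinstance(background, CoincidenceEstimate):
        return background.p_hat, background.n_values or None
    if isinstance(background, (int, float)):
        return float(background), None
    raise TypeError(
        "background must be a RepertoireTable, CoincidenceEstimate, or float"
    )


def _specific_groups(specific: RepertoireTable, feature: FeatureSpec) -> dict:
    return {
        e: co.clean_values(extract(sub, feature))
        for e, sub in specific.epitope_groups().items()
    }


def _bootstrap_ci(point_fn, group_vals, bg_vals, rho, n_boot, rng):
    """Percentile CI from clone-level resampling within each group and
    the background independently."""
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    reps = []
    groups = {y: np.asarray(v, dtype=object) for y, v in group_vals.items()}
    bg = None if bg_vals is None else np.asarray(bg_vals, dtype=object)
    for _ in range(n_boot):
        pc_cond = 0.0
        ok = True
        for y, vals in groups.items():
            idx = gen.integers(0, len(vals), size=len(vals))
            c, t = co._pair_counts(list(vals[idx]))
            pc_cond += rho[y] * (c / t)
        if bg is not None:
            idx = gen.integers(0, len(bg), size=len(bg))
            c, t = co._pair_counts(list(bg[idx]))
            pc_bg = c / t if t else 0.0
        else:
            pc_bg = point_fn
        bits = _log2_ratio(pc_cond, pc_bg)
        if bits is not None:
            reps.append(bits)
    if len(reps) < 2:
        return None, None
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(lo), float(hi)


def relevancy(
    specific: RepertoireTable,
    background,
    feature: FeatureSpec,
    *,
    weights: str | Mapping = "uniform",
    bootstrap: int = 0,
    seed=None,
) -> InformationScore:
    """Relevancy I_2(X, Pi) of a feature across all epitope groups.

    Parameters
    ----------
    specific
        Repertoire whose epitope labels define the groups.
    background
        Background repertoire table, or a precomputed
        :class:`CoincidenceEstimate` / float coincidence probability for
        this feature (useful when the background distribution is known
        exactly, as for synthetic generators).
    weights
        Epitope distribution P(pi) entering the rho_2 weights: "uniform",
        "size", or an explicit mapping.
    bootstrap
        Bootstrap replicates for a percentile CI on the bits (clones are
        resampled within each epitope group and the background
        independently).
    """
    groups = _specific_groups(specific, feature)
    est = co.pc_conditional(groups, weights)
    pc_bg, n_bg = _background_pc(background, feature)
    bits = _log2_ratio(est.p_hat, pc_bg)
    score = InformationScore(
        bits=bits,
        feature=feature,
        scope="global",
        n_specific=est.n_values,
        n_background=n_bg,
    )
    if bits is None:
        score.diagnostic = "zero coincident pairs in specific or background estimate"
        return score
    if bootstrap > 0:
        usable = {y: v for y, v in groups.items() if len(v) >= 2}
        bg_vals = None
        if isinstance(background, RepertoireTable):
            bg_vals = co.clean_values(extract(background, feature))
        score.ci_low, score.ci_high = _bootstrap_ci(
            pc_bg, usable, bg_vals, est.group_weights, bootstrap, seed
        )
    return score


def local_relevancy(
    specific: RepertoireTable,
    background,
    feature: FeatureSpec,
    epitope: str | None = None,
    *,
    bootstrap: int = 0,
    seed=None,
) -> InformationScore:
    """Local relevancy i_2(X, pi) for a single epitope group."""
    if epitope is None:
        eps = specific.epitopes
        if len(eps) != 1:
            raise ValueError("epitope must be named when the table has several")
        epitope = eps[0]
    sub = specific.epitope_groups()[epitope]
    score = relevancy(
        sub, background, feature, weights="uniform", bootstrap=bootstrap, seed=seed
    )
    score.scope = f"local:{epitope}"
    return score


def conditional_relevancy(
    specific: RepertoireTable,
    background: RepertoireTable,
    feature: FeatureSpec,
    given: FeatureSpec,
    *,
    weights: str | Mapping = "uniform",
) -> InformationScore:
    """Conditional relevancy I_2(X, Pi | Y) = H_2[X|Y] - H_2[X|Pi,Y].

    The background conditional entropy groups background clones by their Y
    value with empirical P(y); the specific side groups clones by
    (epitope, Y value) with joint probabilities P(pi) * P(y|pi), P(pi)
    given by ``weights``.  Requires a background table (Y must be
    observable on the background).
    """
    if not isinstance(background, RepertoireTable):
        raise TypeError("conditional_relevancy needs a background RepertoireTable")
    x_bg = extract(background, feature)
    y_bg = extract(background, given)
    bg_groups: dict = {}
    for xv, yv in zip(x_bg.tolist(), y_bg.tolist()):
        if yv is None or xv is None:
            continue
        bg_groups.setdefault(yv, []).append(xv)
    est_bg = co.pc_conditional(bg_groups, "size")

    eps = specific.epitope_groups()
    labels = sorted(eps, key=str)
    if isinstance(weights, Mapping):
        tot = sum(weights[e] for e in labels)
        p_eps = {e: weights[e] / tot for e in labels}
    elif weights == "uniform":
        p_eps = {e: 1.0 / len(labels) for e in labels}
    elif weights == "size":
        sizes = {e: len(eps[e]) for e in labels}
        tot = sum(sizes.values())
        p_eps = {e: sizes[e] / tot for e in labels}
    else:
        raise ValueError(f"unknown weight scheme {weights!r}")

    spec_groups: dict = {}
    joint_p: dict = {}
    for e in labels:
        sub = eps[e]
        xs = extract(sub, feature).tolist()
        ys = extract(sub, given).tolist()
        pairs = [(xv, yv) for xv, yv in zip(xs, ys) if xv is not None and yv is not None]
        if not pairs:
            continue
        n_e = len(pairs)
        by_y: dict = {}
        for xv, yv in pairs:
            by_y.setdefault(yv, []).append(xv)
        for yv, xvals in by_y.items():
            key = (e, yv)
            spec_groups[key] = xvals
            joint_p[key] = p_eps[e] * len(xvals) / n_e
    est_spec = co.pc_conditional(spec_groups, joint_p)

    bits = _log2_ratio(est_spec.p_hat, est_bg.p_hat)
    return InformationScore(
        bits=bits,
        feature=feature,
        conditioning=given,
        scope="global",
        n_specific=est_spec.n_values,
        n_background=est_bg.n_values,
        diagnostic=None if bits is not None else "undefined conditional estimate",
    )


def _shared_mask(table: RepertoireTable, x: FeatureSpec, y: FeatureSpec):
    xv = extract(table, x)
    yv = extract(table, y)
    mask = [a is not None and b is not None for a, b in zip(xv.tolist(), yv.tolist())]
    return table.subset(pd.Series(mask, index=table.df.index))


def interaction_information(
    specific: RepertoireTable,
    background,
    x: FeatureSpec,
    y: FeatureSpec,
    *,
    weights: str | Mapping = "uniform",
) -> InformationScore:
    """Interaction information I_2,int(X, Y | Pi).

    Computed as the relevancy of the product feature minus the sum of the
    single-feature relevancies, all three on the record subset where both
    features are present (so the comparison is like-for-like).  Positive
    values indicate synergy, negative redundancy.

    ``background`` may be a table or a mapping with keys ``"x"``, ``"y"``,
    ``"xy"`` giving precomputed background coincidence probabilities.
    """
    xy = FeatureSpec.product(x, y)
    spec_m = _shared_mask(specific, x, y)
    if isinstance(background, RepertoireTable):
        bg_m = _shared_mask(background, x, y)
        bg_x = bg_y = bg_xy = bg_m
    elif isinstance(background, Mapping):
        bg_x, bg_y, bg_xy = background["x"], background["y"], background["xy"]
    else:
        raise TypeError("background must be a table or a {'x','y','xy'} mapping")
    r_x = relevancy(spec_m, bg_x, x, weights=weights)
    r_y = relevancy(spec_m, bg_y, y, weights=weights)
    r_xy = relevancy(spec_m, bg_xy, xy, weights=weights)
    if None in (r_x.bits, r_y.bits, r_xy.bits):
        return InformationScore(
            bits=None,
            feature=xy,
            scope="global",
            diagnostic="a component relevancy is undefined",
        )
    return InformationScore(
        bits=r_xy.bits - r_x.bits - r_y.bits,
        feature=xy,
        scope="global",
        n_specific=r_xy.n_specific,
        n_background=r_xy.n_background,
    )


def local_interaction_information(
    specific: RepertoireTable,
    background,
    x: FeatureSpec,
    y: FeatureSpec,
    epitope: str | None = None,
) -> InformationScore:
    """Local interaction information i_2,int(X, Y | pi) for one epitope."""
    if epitope is None:
        eps = specific.epitopes
        if len(eps) != 1:
            raise ValueError("epitope must be named when the table has several")
        epitope = eps[0]
    sub = specific.epitope_groups()[epitope]
    score = interaction_information(sub, background, x, y)
    score.scope = f"local:{epitope}"
    return score


def relevancy_matrix(
    specific: RepertoireTable,
    background,
    features: Sequence[FeatureSpec],
    *,
    weights: str | Mapping = "uniform",
) -> pd.DataFrame:
    """Symmetric grid of single-feature (diagonal) and pairwise-combined
    (off-diagonal) relevancies, in bits."""
    names = [f.name for f in features]
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for i, fi in enumerate(features):
        for j, fj in enumerate(features):
            if j < i:
                continue
            spec = fi if i == j else FeatureSpec.product(fi, fj)
            score = relevancy(specific, background, spec, weights=weights)
            val = np.nan if score.bits is None else score.bits
            out.iat[i, j] = val
            out.iat[j, i] = val
    return out


def interaction_matrix(
    specific: RepertoireTable,
    background,
    features: Sequence[FeatureSpec],
    *,
    weights: str | Mapping = "uniform",
) -> pd.DataFrame:
    """Pairwise interaction information grid (off-diagonals of the
    relevancy grid minus the sums of the corresponding diagonals)."""
    names = [f.name for f in features]
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for i, fi in enumerate(features):
        for j, fj in enumerate(features):
            if j <= i:
                continue
            score = interaction_information(
                specific, background, fi, fj, weights=weights
            )
            val = np.nan if score.bits is None else score.bits
            out.iat[i, j] = val
            out.iat[j, i] = val
    return out


# -- exact-distribution evaluation ----------------------------------------


def relevancy_exact(
    p_background: Sequence[float],
    p_specific: Sequence[Sequence[float]],
    p_epitope: Sequence[float],
) -> float:
    """I_2(X, Pi) from exact distributions.

    ``p_specific`` holds one conditional distribution P(X|pi) per row;
    ``p_epitope`` is P(pi).
    """
    pc_bg = co.pc_exact(p_background)
    pc_groups = [co.pc_exact(row) for row in np.asarray(p_specific, dtype=float)]
    pc_cond = co.pc_conditional_exact(pc_groups, p_epitope)
    return math.log2(pc_cond / pc_bg)


def _pc_x_given_y(joint: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-y coincidence probabilities of X and P(y) from P(x, y)."""
    p_y = joint.sum(axis=0)
    keep = p_y > 0
    cond = joint[:, keep] / p_y[keep]
    pc = (cond**2).sum(axis=0)
    return pc, p_y[keep]


def conditional_relevancy_exact(
    p_background_xy: Sequence[Sequence[float]],
    p_specific_xy: Sequence[Sequence[Sequence[float]]],
    p_epitope: Sequence[float],
) -> float:
    """I_2(X, Pi | Y) from exact joint distributions P(x, y).

    ``p_background_xy[x, y]`` is the background joint; ``p_specific_xy`` is
    one joint per epitope group.
    """
    bg = np.asarray(p_background_xy, dtype=float)
    pc_bg_y, p_y = _pc_x_given_y(bg)
    pc_bg = co.pc_conditional_exact(pc_bg_y, p_y)

    p_eps = np.asarray(p_epitope, dtype=float)
    pcs, joint_probs = [], []
    for g, joint in enumerate(np.asarray(p_specific_xy, dtype=float)):
        pc_y, p_y_g = _pc_x_given_y(joint)
        pcs.extend(pc_y)
        joint_probs.extend(p_eps[g] * p_y_g)
    pc_spec = co.pc_conditional_exact(pcs, joint_probs)
    return math.log2(pc_spec / pc_bg)


def interaction_information_exact(
    p_background_xy: Sequence[Sequence[float]],
    p_specific_xy: Sequence[Sequence[Sequence[float]]],
    p_epitope: Sequence[float],
) -> float:
    """I_2,int(X, Y | Pi) from exact joint distributions."""
    bg = np.asarray(p_background_xy, dtype=float)
    spec = np.asarray(p_specific_xy, dtype=float)
    i_xy = relevancy_exact(bg.ravel(), [s.ravel() for s in spec], p_epitope)
    i_x = relevancy_exact(bg.sum(axis=1), [s.sum(axis=1) for s in spec], p_epitope)
    i_y = relevancy_exact(bg.sum(axis=0), [s.sum(axis=0) for s in spec], p_epitope)
    return i_xy - i_x - i_y
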