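"""Bayesian classification bounds from coincidence information.

In the spike-in setting — decide whether a query receptor was drawn from an
epitope-specific distribution or from the recombination background, based
on a feature match with an annotated reference — the posterior odds of
correct classification after a match are

    O_post = 2^{I_2(X, Pi)} * O_prior ,

so each bit of coincidence mutual information doubles the achievable odds.
Inverting this gives the minimal prior probability of specificity needed to
reach a target posterior odds T with I_2 bits of information:

    P_prior(I_2) >= T 2^{-I_2} / (1 + T 2^{-I_2}).

The same relations hold per distance class for fuzzy matches, using the
near-coincidence mutual information of :mod:`tcrinfo.near_coincidence`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "prob_to_odds",
    "odds_to_prob",
    "posterior_odds",
    "min_prior",
    "critical_prior_curve",
    "critical_distance",
]


def prob_to_odds(p: float) -> float:
    """Odds p / (1 - p) of a probability in (0, 1)."""
    if not 0 < p < 1:
        raise ValueError("probability must lie strictly between 0 and 1")
    return p / (1.0 - p)


def odds_to_prob(o: float) -> float:
    """Probability o / (1 + o) of positive odds."""
    if o < 0:
        raise ValueError("odds must be non-negative")
    return o / (1.0 + o)


def posterior_odds(prior_odds: float, bits: float) -> float:
    """Posterior odds 2^bits * prior_odds after an informative match."""
    if prior_odds <= 0:
        raise ValueError("prior odds must be positive")
    return (2.0**bits) * prior_odds


def min_prior(bits: float, T: float = 19.0) -> float:
    """Minimal prior probability for posterior odds >= T given `bits`.

    ``T`` is the target posterior odds (19 corresponds to a posterior
    probability of 0.95).  With zero bits the prior must already equal the
    required posterior.
    """
    if T <= 0:
        raise ValueError("posterior odds threshold T must be positive")
    t2 = T * 2.0 ** (-bits)
    return t2 / (1.0 + t2)


def _profile_frame(profile) -> pd.DataFrame:
    return profile.table if hasattr(profile, "table") else pd.DataFrame(profile)


def critical_prior_curve(profile, T: float = 19.0) -> pd.DataFrame:
    """Minimal prior probability per distance class of a profile.

    Returns columns ``delta, mi_bits, min_prior``; distances with
    undefined near-coincidence information get a missing prior.
    """
    df = _profile_frame(profile)
    out = df[["delta", "mi_bits"]].copy()
    out["min_prior"] = [
        np.nan if not np.isfinite(b) else min_prior(b, T) for b in out["mi_bits"]
    ]
    return out


def critical_distance(profile, prior_probability: float, T: float = 19.0):
    """Largest distance at which a fuzzy match still reaches posterior odds T.

    A distance class qualifies when ``2^mi * prior_odds >= T``; the largest
    qualifying distance is returned, or None when none qualifies (the prior
    is too small for any available match quality).
    """
    o_prior = prob_to_odds(prior_probability)
    df = _profile_frame(profile)
    ok = [
        int(d)
        for d, b in zip(df["delta"], df["mi_bits"])
        if np.isfinite(b) and posterior_odds(o_prior, b) >= T
    ]
    return max(ok) if ok else None
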