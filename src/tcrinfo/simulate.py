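"""Synthetic repertoires with the statistical structure the framework assumes.

Three generators:

* a **background** over (V, J, CDR3) per chain with categorical gene usage,
  a categorical CDR3 length distribution, and i.i.d. amino acid draws
  (chains paired at random, hence independent) — a deliberately simple
  stand-in for a V(D)J recombination model, fully known in closed form;
* **epitope-specific** repertoires drawn from a mixture of *binding modes*,
  each mode anchoring a V/J choice per chain and a CDR3 motif template
  subject to per-position substitution noise, with optional false-positive
  contamination from the background;
* a **spike-in classification experiment** that plants specific sequences
  in a background at a known prior fraction and classifies queries by
  feature match with a reference, to compare empirical posterior
  probabilities against the odds-multiplication prediction.

Because the background distribution factorizes and is known exactly,
background coincidence probabilities of chain-level features are computed
analytically (:func:`background_pc_exact`); sampled backgrounds of any
feasible size contain no full-chain coincidences.

With M disjoint equal-weight modes, each per-chain relevancy falls by one
bit per doubling of M while the alpha-beta interaction information rises by
one bit, so regressing local interaction information on single-chain
relevancy across a mode-count sweep has slope -1 (and paired-chain
relevancy on single-chain relevancy has slope +1).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import warnings

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore", DeprecationWarning)
    import scipy.odr

from . import coincidence as co
from .features import FeatureSpec, extract
from .repertoire_io import AMINO_ACIDS, RepertoireTable

__all__ = [
    "BackgroundConfig",
    "ModeSpec",
    "MixtureConfig",
    "SpikeInConfig",
    "default_background_config",
    "generate_background",
    "generate_specific",
    "background_pc_exact",
    "spike_in_experiment",
    "mixture_sweep",
    "mixture_slopes",
    "odr_slope",
]


def _normalize(d: Mapping) -> dict:
    total = float(sum(d.values()))
    if total <= 0:
        raise ValueError("distribution weights must be positive")
    return {k: v / total for k, v in d.items()}


@dataclass
class BackgroundConfig:
    """Generative model of an unselected background repertoire."""

    v_alpha_usage: dict
    j_alpha_usage: dict
    v_beta_usage: dict
    j_beta_usage: dict
    cdr3_alpha_length_dist: dict
    cdr3_beta_length_dist: dict
    aa_dist: dict
    n_clones: int = 1000
    seed: int | None = None
    lead_cysteine: bool = True

    def __post_init__(self) -> None:
        for name in (
            "v_alpha_usage",
            "j_alpha_usage",
            "v_beta_usage",
            "j_beta_usage",
            "cdr3_alpha_length_dist",
            "cdr3_beta_length_dist",
            "aa_dist",
        ):
            setattr(self, name, _normalize(getattr(self, name)))


# Geometric-like gene usage (a few dominant genes, a long tail) and
# unimodal CDR3 length distributions, loosely shaped on human repertoire
# summaries; exact values are unimportant downstream because analyses are
# ratios to this same background.
def default_background_config(n_clones: int = 1000, seed: int | None = None) -> BackgroundConfig:
    v_alpha = {f"TRAV{i}": 0.88**i for i in range(1, 21)}
    j_alpha = {f"TRAJ{i}": 0.90**i for i in range(1, 16)}
    v_beta = {f"TRBV{i}": 0.88**i for i in range(1, 21)}
    j_beta = {f"TRBJ{i}": 0.90**i for i in range(1, 14)}
    len_alpha = {9: 0.05, 10: 0.10, 11: 0.20, 12: 0.30, 13: 0.20, 14: 0.10, 15: 0.05}
    len_beta = {11: 0.05, 12: 0.10, 13: 0.20, 14: 0.30, 15: 0.20, 16: 0.10, 17: 0.05}
    aa = {
        "G": 0.10, "S": 0.09, "A": 0.06, "L": 0.06, "T": 0.06, "R": 0.05,
        "E": 0.05, "Q": 0.05, "Y": 0.05, "V": 0.05, "N": 0.04, "D": 0.04,
        "F": 0.04, "P": 0.04, "I": 0.03, "K": 0.03, "H": 0.02, "W": 0.02,
        "M": 0.02, "C": 0.01,
    }
    return BackgroundConfig(
        v_alpha_usage=v_alpha,
        j_alpha_usage=j_alpha,
        v_beta_usage=v_beta,
        j_beta_usage=j_beta,
        cdr3_alpha_length_dist=len_alpha,
        cdr3_beta_length_dist=len_beta,
        aa_dist=aa,
        n_clones=n_clones,
        seed=seed,
    )


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _draw_categorical(rng, dist: dict, size: int) -> np.ndarray:
    keys = np.array(list(dist.keys()), dtype=object)
    probs = np.array(list(dist.values()), dtype=float)
    return rng.choice(keys, size=size, p=probs)


def _draw_cdr3s(rng, length_dist: dict, aa_dist: dict, size: int, lead_c: bool) -> list[str]:
    lengths = _draw_categorical(rng, length_dist, size).astype(int)
    letters = np.array(list(aa_dist.keys()))
    probs = np.array(list(aa_dist.values()), dtype=float)
    out = []
    for L in lengths:
        body = rng.choice(letters, size=L - 1 if lead_c else L, p=probs)
        out.append(("C" if lead_c else "") + "".join(body))
    return out


def generate_background(config: BackgroundConfig, rng=None) -> RepertoireTable:
    """Sample a background repertoire; pure function of config and seed."""
    gen = _rng(rng if rng is not None else config.seed)
    n = config.n_clones
    df = pd.DataFrame(
        {
            "clone_id": [f"bg_{i}" for i in range(n)],
            "v_alpha": _draw_categorical(gen, config.v_alpha_usage, n),
            "j_alpha": _draw_categorical(gen, config.j_alpha_usage, n),
            "cdr3_alpha": _draw_cdr3s(
                gen, config.cdr3_alpha_length_dist, config.aa_dist, n, config.lead_cysteine
            ),
            "v_beta": _draw_categorical(gen, config.v_beta_usage, n),
            "j_beta": _draw_categorical(gen, config.j_beta_usage, n),
            "cdr3_beta": _draw_cdr3s(
                gen, config.cdr3_beta_length_dist, config.aa_dist, n, config.lead_cysteine
            ),
            "epitope": None,
            "clone_count": 1,
        }
    )
    return RepertoireTable(df, provenance={"source": "generate_background", "n_input_rows": n})


@dataclass(frozen=True)
class ModeSpec:
    """One binding mode: anchored gene choices and CDR3 motif templates."""

    v_alpha: str
    j_alpha: str
    cdr3_alpha_template: str
    v_beta: str
    j_beta: str
    cdr3_beta_template: str


@dataclass
class MixtureConfig:
    """Mixture-of-binding-modes model of an epitope-specific repertoire."""

    n_modes: int = 1
    mode_weights: Sequence[float] | None = None  # None = equal weights
    cdr3_noise_rate: float = 0.1  # per-position substitution probability
    false_positive_fraction: float = 0.0
    n_clones: int = 1000
    epitope: str = "synthetic-epitope"
    seed: int | None = None
    modes: Sequence[ModeSpec] | None = None  # auto-generated if None
    disjoint: bool = True  # distinct anchor V genes per mode
    # fixed (alpha, beta) template lengths => modes have matched entropy;
    # None draws template lengths from the background distribution
    template_lengths: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.false_positive_fraction < 1:
            raise ValueError("false_positive_fraction must be in [0, 1)")
        if self.mode_weights is not None and len(self.mode_weights) != self.n_modes:
            raise ValueError("mode_weights length must equal n_modes")


def _make_modes(config: MixtureConfig, bg: BackgroundConfig, rng) -> list[ModeSpec]:
    m = config.n_modes
    va = list(bg.v_alpha_usage)
    vb = list(bg.v_beta_usage)
    if config.disjoint and (m > len(va) or m > len(vb)):
        raise ValueError("not enough V genes for disjoint modes")
    v_alphas = rng.choice(np.array(va, dtype=object), size=m, replace=not config.disjoint)
    v_betas = rng.choice(np.array(vb, dtype=object), size=m, replace=not config.disjoint)
    if config.template_lengths is not None:
        la, lb = config.template_lengths
        len_a, len_b = {la: 1.0}, {lb: 1.0}
    else:
        len_a, len_b = bg.cdr3_alpha_length_dist, bg.cdr3_beta_length_dist
    modes = []
    for i in range(m):
        modes.append(
            ModeSpec(
                v_alpha=str(v_alphas[i]),
                j_alpha=str(_draw_categorical(rng, bg.j_alpha_usage, 1)[0]),
                cdr3_alpha_template=_draw_cdr3s(
                    rng, len_a, bg.aa_dist, 1, bg.lead_cysteine
                )[0],
                v_beta=str(v_betas[i]),
                j_beta=str(_draw_categorical(rng, bg.j_beta_usage, 1)[0]),
                cdr3_beta_template=_draw_cdr3s(
                    rng, len_b, bg.aa_dist, 1, bg.lead_cysteine
                )[0],
            )
        )
    return modes


def _mutate(template: str, rate: float, rng, lead_c: bool) -> str:
    letters = list(template)
    start = 1 if lead_c else 0
    aa = AMINO_ACIDS
    for i in range(start, len(letters)):
        if rng.random() < rate:
            letters[i] = aa[rng.integers(0, len(aa))]
    return "".join(letters)


def generate_specific(
    config: MixtureConfig, background: BackgroundConfig, rng=None
) -> RepertoireTable:
    """Sample an epitope-specific repertoire from the mixture of modes.

    Each clone picks a mode (or, with probability
    ``false_positive_fraction``, is a background draw), inherits the
    mode's V/J anchors, and mutates each non-anchor CDR3 position with the
    configured substitution rate.
    """
    gen = _rng(rng if rng is not None else config.seed)
    modes = list(config.modes) if config.modes is not None else _make_modes(config, background, gen)
    weights = (
        np.full(len(modes), 1.0 / len(modes))
        if config.mode_weights is None
        else np.asarray(config.mode_weights, dtype=float) / np.sum(config.mode_weights)
    )
    rows = []
    n_fp = 0
    for i in range(config.n_clones):
        if config.false_positive_fraction and gen.random() < config.false_positive_fraction:
            n_fp += 1
            rows.append(
                {
                    "clone_id": f"sp_{i}",
                    "v_alpha": str(_draw_categorical(gen, background.v_alpha_usage, 1)[0]),
                    "j_alpha": str(_draw_categorical(gen, background.j_alpha_usage, 1)[0]),
                    "cdr3_alpha": _draw_cdr3s(
                        gen, background.cdr3_alpha_length_dist, background.aa_dist, 1,
                        background.lead_cysteine,
                    )[0],
                    "v_beta": str(_draw_categorical(gen, background.v_beta_usage, 1)[0]),
                    "j_beta": str(_draw_categorical(gen, background.j_beta_usage, 1)[0]),
                    "cdr3_beta": _draw_cdr3s(
                        gen, background.cdr3_beta_length_dist, background.aa_dist, 1,
                        background.lead_cysteine,
                    )[0],
                    "epitope": config.epitope,
                    "clone_count": 1,
                }
            )
            continue
        mode = modes[gen.choice(len(modes), p=weights)]
        rows.append(
            {
                "clone_id": f"sp_{i}",
                "v_alpha": mode.v_alpha,
                "j_alpha": mode.j_alpha,
                "cdr3_alpha": _mutate(
                    mode.cdr3_alpha_template, config.cdr3_noise_rate, gen,
                    background.lead_cysteine,
                ),
                "v_beta": mode.v_beta,
                "j_beta": mode.j_beta,
                "cdr3_beta": _mutate(
                    mode.cdr3_beta_template, config.cdr3_noise_rate, gen,
                    background.lead_cysteine,
                ),
                "epitope": config.epitope,
                "clone_count": 1,
            }
        )
    prov = {
        "source": "generate_specific",
        "n_modes": len(modes),
        "n_false_positive": n_fp,
        "n_input_rows": config.n_clones,
    }
    return RepertoireTable(pd.DataFrame(rows), provenance=prov)


# -- exact background coincidence probabilities ---------------------------


def _pc_dict(d: Mapping) -> float:
    p = np.array(list(d.values()), dtype=float)
    return float(np.sum(p**2))


def _cdr3_pc(length_dist: Mapping, aa_dist: Mapping, lead_c: bool) -> float:
    c = _pc_dict(aa_dist)
    return float(
        sum(p**2 * c ** (int(L) - (1 if lead_c else 0)) for L, p in length_dist.items())
    )


def background_pc_exact(config: BackgroundConfig, feature: FeatureSpec) -> float:
    """Exact coincidence probability of a feature under the background model.

    Supported features: gene, length, and cdr3 leaves and products of
    independent leaves (a chain, the full receptor).  A product combining
    a CDR3 with its own length collapses the redundant length factor,
    since CDR3 equality implies length equality.  Other feature kinds have
    no closed form here.
    """
    leaves = feature.components if feature.kind == "product" else (feature,)
    factors: dict[tuple, float] = {}
    for leaf in leaves:
        key = (leaf.kind, leaf.chain, leaf.segment)
        if leaf.kind == "gene":
            usage = getattr(config, f"{leaf.segment}_{leaf.chain}_usage")
            factors[key] = _pc_dict(usage)
        elif leaf.kind == "length":
            factors[key] = _pc_dict(getattr(config, f"cdr3_{leaf.chain}_length_dist"))
        elif leaf.kind == "cdr3":
            factors[key] = _cdr3_pc(
                getattr(config, f"cdr3_{leaf.chain}_length_dist"),
                config.aa_dist,
                config.lead_cysteine,
            )
        else:
            raise ValueError(f"no closed form for feature kind {leaf.kind!r}")
    # CDR3 equality implies length equality within the same chain
    for chain in ("alpha", "beta"):
        if ("cdr3", chain, None) in factors:
            factors.pop(("length", chain, None), None)
    return float(np.prod(list(factors.values())))


# -- spike-in classification experiment -----------------------------------


@dataclass
class SpikeInConfig:
    """Spike-in experiment: prior fraction(s) of specific queries."""

    spike_fraction: float | Sequence[float] = 0.01
    n_queries: int = 100_000
    seed: int | None = None


def spike_in_experiment(
    config: SpikeInConfig,
    specific_dist: Sequence[float],
    background_dist: Sequence[float],
    rng=None,
) -> pd.DataFrame:
    """Empirical vs predicted posterior after one-shot feature matching.

    Queries are drawn from the two-component mixture (specific with the
    spike fraction as prior, background otherwise); each query is
    classified positive when it equals a fresh reference draw from the
    specific distribution.  The empirical posterior is the fraction of
    true spikes among positives; the prediction multiplies the prior odds
    by 2 to the feature's coincidence information.

    Both distributions are categorical over a shared outcome set.
    """
    gen = _rng(rng if rng is not None else config.seed)
    spec = np.asarray(specific_dist, dtype=float)
    bg = np.asarray(background_dist, dtype=float)
    if spec.shape != bg.shape:
        raise ValueError("distributions must share an outcome set")
    pc_spec = co.pc_exact(spec)
    pc_bg = co.pc_exact(bg)
    bits = math.log2(pc_spec / pc_bg)
    fractions = (
        [config.spike_fraction]
        if np.isscalar(config.spike_fraction)
        else list(config.spike_fraction)
    )
    d = len(spec)
    rows = []
    for p in fractions:
        if not 0 < p < 1:
            raise ValueError("spike fractions must be in (0, 1)")
        n = config.n_queries
        is_spike = gen.random(n) < p
        queries = np.empty(n, dtype=int)
        n_spike = int(is_spike.sum())
        queries[is_spike] = gen.choice(d, size=n_spike, p=spec)
        queries[~is_spike] = gen.choice(d, size=n - n_spike, p=bg)
        references = gen.choice(d, size=n, p=spec)
        match = queries == references
        n_match = int(match.sum())
        emp = float(is_spike[match].mean()) if n_match else np.nan
        prior_odds = p / (1 - p)
        post_odds = (2.0**bits) * prior_odds
        pred = post_odds / (1 + post_odds)
        rows.append(
            {
                "prior": p,
                "prior_odds": prior_odds,
                "bits": bits,
                "n_queries": n,
                "n_matches": n_match,
                "empirical_posterior": emp,
                "predicted_posterior": pred,
                "se_binomial": (
                    math.sqrt(pred * (1 - pred) / n_match) if n_match else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


# -- mixture sweep and slope analysis -------------------------------------


def _local_bits(table: RepertoireTable, bg_pc: dict, idx=None) -> dict:
    cols = table._sweep_cols  # cached by mixture_sweep
    out = {}
    for name in ("alpha", "beta", "pair"):
        vals = cols[name] if idx is None else [cols[name][i] for i in idx]
        est = co.pc_pairs(vals)
        out[name] = (
            None if est.p_hat in (None, 0) else math.log2(est.p_hat / bg_pc[name])
        )
    if None in out.values():
        out["int"] = None
    else:
        out["int"] = out["pair"] - out["alpha"] - out["beta"]
    return out


def mixture_sweep(
    mode_counts: Sequence[int],
    background_config: BackgroundConfig,
    *,
    n_clones: int = 2000,
    cdr3_noise_rate: float = 0.1,
    false_positive_fraction: float = 0.0,
    bootstrap: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Local information scores across epitopes differing only in mode count.

    For each M in ``mode_counts`` one epitope-specific repertoire with M
    disjoint equal-weight modes is simulated and its local alpha-chain,
    beta-chain and paired-chain relevancies and alpha-beta interaction
    information are computed against the exact background coincidence
    probabilities.  Mode templates use the modal background CDR3 length
    per chain so that all modes carry matched entropy and epitopes differ
    only in mode count.  Bootstrap standard errors resample clones.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(mode_counts))
    feats = {
        "alpha": FeatureSpec.chain("alpha"),
        "beta": FeatureSpec.chain("beta"),
        "pair": FeatureSpec.tcr(),
    }
    bg_pc = {k: background_pc_exact(background_config, f) for k, f in feats.items()}
    modal = tuple(
        max(dist, key=dist.get)
        for dist in (
            background_config.cdr3_alpha_length_dist,
            background_config.cdr3_beta_length_dist,
        )
    )
    rows = []
    for m, child in zip(mode_counts, children):
        gen = np.random.default_rng(child)
        config = MixtureConfig(
            n_modes=m,
            n_clones=n_clones,
            cdr3_noise_rate=cdr3_noise_rate,
            false_positive_fraction=false_positive_fraction,
            epitope=f"M{m}",
            template_lengths=modal,
        )
        table = generate_specific(config, background_config, rng=gen)
        table._sweep_cols = {
            k: co.clean_values(extract(table, f)) for k, f in feats.items()
        }
        point = _local_bits(table, bg_pc)
        ses = {k: np.nan for k in ("alpha", "beta", "pair", "int")}
        if bootstrap > 0 and None not in point.values():
            reps: dict[str, list] = {k: [] for k in ses}
            n = len(table._sweep_cols["alpha"])
            for _ in range(bootstrap):
                idx = gen.integers(0, n, size=n)
                b = _local_bits(table, bg_pc, idx=idx)
                if None in b.values():
                    continue
                for k in reps:
                    reps[k].append(b[k])
            for k in ses:
                if len(reps[k]) >= 2:
                    ses[k] = float(np.std(reps[k], ddof=1))
        rows.append(
            {
                "M": m,
                "i2_alpha": point["alpha"],
                "i2_beta": point["beta"],
                "i2_pair": point["pair"],
                "i2_int": point["int"],
                "se_alpha": ses["alpha"],
                "se_beta": ses["beta"],
                "se_pair": ses["pair"],
                "se_int": ses["int"],
            }
        )
    return pd.DataFrame(rows)


def odr_slope(
    x: Sequence[float],
    y: Sequence[float],
    x_se: Sequence[float] | None = None,
    y_se: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Weighted orthogonal-distance regression slope and its standard error.

    Minimizes orthogonal residuals weighted by the per-point standard
    errors (unit weights when omitted).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    beta0 = np.polyfit(x, y, 1)
    data = scipy.odr.RealData(x, y, sx=x_se, sy=y_se)
    model = scipy.odr.Model(lambda B, t: B[0] * t + B[1])
    fit = scipy.odr.ODR(data, model, beta0=list(beta0)).run()
    return float(fit.beta[0]), float(fit.sd_beta[0])


def mixture_slopes(sweep: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """ODR slopes of the mode-count sweep variable pairs.

    Returns slopes (with standard errors) of interaction information and
    of paired-chain relevancy, each regressed on alpha-chain relevancy.
    """
    x, sx = sweep["i2_alpha"], sweep["se_alpha"]
    sx = None if sx.isna().any() else sx
    out = {}
    for key, ycol, secol in (
        ("interaction_vs_alpha", "i2_int", "se_int"),
        ("pair_vs_alpha", "i2_pair", "se_pair"),
    ):
        sy = sweep[secol]
        sy = None if sy.isna().any() else sy
        out[key] = odr_slope(x, sweep[ycol], sx, sy)
    return out
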