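"""Distance-resolved coincidences and fuzzy-match information."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrinfo.classification import odds_to_prob, posterior_odds, prob_to_odds
from tcrinfo.features import FeatureSpec
from tcrinfo.information import relevancy
from tcrinfo.near_coincidence import (
    distance_profile,
    levenshtein,
    near_mi,
    pair_distance_counts,
    pc_at_distance,
)

from conftest import make_table
from oracles import brute_distance_fractions, dp_levenshtein

aa_strings = st.text(alphabet="ACDGSTW", min_size=0, max_size=8)


@pytest.mark.parametrize(
    "a, b, d",
    [("CASSLGF", "CASSLGF", 0), ("CASSLGF", "CASSGF", 1), ("kitten", "sitting", 3)],
)
def test_levenshtein_known_values(a, b, d):
    assert levenshtein(a, b) == d
    assert dp_levenshtein(a, b) == d


@settings(deadline=None, max_examples=100)
@given(aa_strings, aa_strings)
def test_levenshtein_matches_dp_oracle(a, b):
    assert levenshtein(a, b) == dp_levenshtein(a, b)


def test_pair_distance_fractions_partition_all_pairs(rng):
    seqs = ["".join(rng.choice(list("ACDG"), size=rng.integers(3, 7))) for _ in range(25)]
    tally = pair_distance_counts(seqs, "levenshtein_cdr3b")
    total = sum(tally.values())
    assert total == 25 * 24 // 2
    fractions = {d: n / total for d, n in tally.items()}
    oracle = brute_distance_fractions(seqs, dp_levenshtein)
    assert fractions == pytest.approx(oracle)
    assert sum(fractions.values()) == pytest.approx(1.0)


def test_pc_at_distance_sample_vs_distribution_distinction():
    """Two equally frequent sequences at distance 1: with one clone of
    each, the only pair is the cross pair, so p(1) = 1 (the exact
    distribution would put 1/2 at distance 0)."""
    est = pc_at_distance(["CASSF", "CASSG"], "levenshtein_cdr3b", 1)
    assert est.p_hat == 1.0
    assert pc_at_distance(["CASSF", "CASSG"], "levenshtein_cdr3b", 0).p_hat == 0.0
    # and beyond any observed distance
    assert pc_at_distance(["CASSF", "CASSG"], "levenshtein_cdr3b", 7).p_hat == 0.0


def test_identical_clones_fall_in_distance_zero():
    tally = pair_distance_counts(["CASSF", "CASSF", "CASSF"], "levenshtein_cdr3b")
    assert tally[0] == 3 and sum(tally.values()) == 3


def test_levenshtein_sum_metric_excludes_unpaired():
    rows = [
        dict(clone_id="a", cdr3_alpha="CAF", cdr3_beta="CGF", epitope="e"),
        dict(clone_id="b", cdr3_alpha="CAF", cdr3_beta="CGW", epitope="e"),
        dict(clone_id="c", cdr3_alpha=None, cdr3_beta="CGW", epitope="e"),
    ]
    spec = make_table(rows)
    feat_vals = [("CAF", "CGF"), ("CAF", "CGW")]
    tally = pair_distance_counts(feat_vals, "levenshtein_sum")
    assert tally == {1: 1}


def _random_tables(rng, n_spec=30, n_bg=60):
    motif = "CASSG"
    def mutate(s):
        out = list(s)
        i = rng.integers(1, len(out))
        out[i] = "ACDGSTW"[rng.integers(7)]
        return "".join(out)
    spec_rows = [
        dict(clone_id=f"s{i}", cdr3_beta=mutate(motif) if rng.random() < 0.5 else motif,
             epitope="ep1" if i % 2 else "ep2")
        for i in range(n_spec)
    ]
    bg_rows = [
        dict(clone_id=f"b{i}",
             cdr3_beta="".join(rng.choice(list("ACDGSTW"), size=rng.integers(4, 7))))
        for i in range(n_bg)
    ]
    return make_table(spec_rows), make_table(bg_rows)


def test_distance_profile_matches_brute_force(rng):
    spec, bg = _random_tables(rng)
    profile = distance_profile(spec, bg, "levenshtein_cdr3b")
    tab = profile.table
    assert tab["pc_bg"].sum() == pytest.approx(1.0)
    assert tab["pc_spec"].sum() == pytest.approx(1.0)
    bg_oracle = brute_distance_fractions(
        [r.cdr3_beta for r in bg.records], dp_levenshtein
    )
    for _, row in tab.iterrows():
        assert row["pc_bg"] == pytest.approx(bg_oracle.get(int(row["delta"]), 0.0))
    # specific side: rho2-weighted average of per-epitope fractions
    groups = {
        e: brute_distance_fractions([r.cdr3_beta for r in sub.records], dp_levenshtein)
        for e, sub in spec.epitope_groups().items()
    }
    for _, row in tab.iterrows():
        d = int(row["delta"])
        oracle = 0.5 * groups["ep1"].get(d, 0.0) + 0.5 * groups["ep2"].get(d, 0.0)
        assert row["pc_spec"] == pytest.approx(oracle)
        if row["pc_spec"] > 0 and row["pc_bg"] > 0:
            assert row["mi_bits"] == pytest.approx(
                math.log2(row["pc_spec"] / row["pc_bg"])
            )


def test_near_mi_at_zero_equals_exact_match_relevancy(rng):
    spec, bg = _random_tables(rng)
    mi0 = near_mi(spec, bg, "levenshtein_cdr3b", 0)
    rel = relevancy(spec, bg, FeatureSpec.cdr3("beta"))
    # delta=0 compares exact-coincidence fractions relative to ALL pairs of
    # the same record sets, which is exactly the relevancy estimator
    assert mi0.bits == pytest.approx(rel.bits, abs=1e-12)


def test_null_specific_profile_is_flat(rng):
    """Specific drawn from the background distribution: MI ~ 0 at every
    well-populated distance."""
    seqs = ["".join(rng.choice(list("ACDG"), size=5)) for _ in range(400)]
    spec = make_table(
        [dict(clone_id=f"s{i}", cdr3_beta=s, epitope="e") for i, s in enumerate(seqs[:200])]
    )
    bg = make_table(
        [dict(clone_id=f"b{i}", cdr3_beta=s) for i, s in enumerate(seqs[200:])]
    )
    profile = distance_profile(spec, bg, "levenshtein_cdr3b")
    tab = profile.table
    common = tab[(tab["pc_bg"] > 0.05) & (tab["pc_spec"] > 0.05)]
    assert (common["mi_bits"].abs() < 0.35).all()


def test_cumulative_profile_option(rng):
    spec, bg = _random_tables(rng)
    exact = distance_profile(spec, bg, "levenshtein_cdr3b")
    cum = distance_profile(spec, bg, "levenshtein_cdr3b", cumulative=True)
    assert cum.table["pc_bg"].iloc[-1] == pytest.approx(1.0)
    assert np.allclose(
        cum.table["pc_bg"], np.cumsum(exact.table["pc_bg"])
    )


def test_fuzzy_match_posterior_odds_validation(rng):
    """Spike-in classification with fuzzy matches: the empirical posterior
    after a match at distance Delta tracks 2^I2(Delta) times the prior
    odds within 3 binomial SE (one bit = a two-fold gain)."""
    # distance-regular feature space: two-letter strings with disjoint
    # per-position alphabets, so Levenshtein == per-position mismatch count
    pos1, pos2 = "ABCD", "wxyz"
    outcomes = [a + b for a in pos1 for b in pos2]
    bg_p = {o: 1 / 16 for o in outcomes}
    spec_set = [a + b for a in "AB" for b in "wx"]
    spec_p = {o: (1 / 4 if o in spec_set else 0.0) for o in outcomes}

    def exact_pc_delta(p, q):
        out = {}
        for x, px in p.items():
            for y, qy in q.items():
                d = dp_levenshtein(x, y)
                out[d] = out.get(d, 0.0) + px * qy
        return out

    pc_spec = exact_pc_delta(spec_p, spec_p)
    pc_bg = exact_pc_delta(bg_p, bg_p)
    prior = 0.05
    n = 150_000
    is_spike = rng.random(n) < prior
    keys = np.array(outcomes)
    spec_vec = np.array([spec_p[o] for o in outcomes])
    bg_vec = np.array([bg_p[o] for o in outcomes])
    queries = np.where(
        is_spike,
        rng.choice(keys, size=n, p=spec_vec),
        rng.choice(keys, size=n, p=bg_vec),
    )
    refs = rng.choice(keys, size=n, p=spec_vec)
    dists = np.array([dp_levenshtein(q, r) for q, r in zip(queries, refs)])
    for delta in (0, 1, 2):
        mi = math.log2(pc_spec[delta] / pc_bg[delta])
        sel = dists == delta
        n_sel = int(sel.sum())
        emp = is_spike[sel].mean()
        pred = odds_to_prob(posterior_odds(prob_to_odds(prior), mi))
        se = math.sqrt(pred * (1 - pred) / n_sel)
        assert abs(emp - pred) < 3 * se
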