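"""Relevancy, conditional relevancy, and interaction information."""

import math

import numpy as np
import pytest

from tcrinfo.features import FeatureSpec
from tcrinfo.information import (
    conditional_relevancy,
    conditional_relevancy_exact,
    interaction_information,
    interaction_information_exact,
    interaction_matrix,
    local_relevancy,
    relevancy,
    relevancy_exact,
    relevancy_matrix,
)

from conftest import make_table
from oracles import (
    brute_pc_conditional,
    brute_pc_pairs,
    exact_conditional_relevancy,
    exact_interaction,
    exact_relevancy,
    random_joint,
)


def test_relevancy_exact_constant_epitopes():
    """Uniform background over 16 values, each epitope constant-valued."""
    bg = np.full(16, 1 / 16)
    groups = [np.eye(16)[i] for i in range(3)]
    assert relevancy_exact(bg, groups, [1 / 3] * 3) == pytest.approx(4.0, abs=1e-12)


def test_relevancy_exact_partial_restriction():
    """Background (.5,.25,.25); epitope uniform on the last two values."""
    bits = relevancy_exact([0.5, 0.25, 0.25], [[0, 0.5, 0.5]], [1.0])
    assert bits == pytest.approx(math.log2(0.5 / 0.375), abs=1e-12)


def test_relevancy_exact_matches_oracle(rng):
    for _ in range(20):
        bg = rng.dirichlet(np.ones(5))
        groups = rng.dirichlet(np.ones(5), size=3)
        p_g = rng.dirichlet(np.ones(3))
        assert relevancy_exact(bg, groups, p_g) == pytest.approx(
            exact_relevancy(bg, groups, p_g), abs=1e-9
        )


def test_relevancy_symmetry_on_exact_joints(rng):
    """I2(X,Y) = I2(Y,X): relevancy is a genuine mutual information."""
    for _ in range(20):
        joint = random_joint(rng, 4, 3)
        p_x, p_y = joint.sum(axis=1), joint.sum(axis=0)
        i_xy = relevancy_exact(p_x, [joint[:, y] / p_y[y] for y in range(3)], p_y)
        i_yx = relevancy_exact(p_y, [joint[x, :] / p_x[x] for x in range(4)], p_x)
        assert i_xy == pytest.approx(i_yx, abs=1e-9)


def test_sampled_relevancy_of_null_specific_covers_zero(rng):
    """Specific groups distributed identically to the background carry no
    information; the bootstrap CI should cover zero."""
    alphabet = list("abcdef")
    p = np.array([0.3, 0.25, 0.15, 0.15, 0.1, 0.05])
    def rows(n, label, tag):
        return [
            dict(clone_id=f"{tag}{i}", v_beta=str(rng.choice(alphabet, p=p)),
                 epitope=label)
            for i in range(n)
        ]
    spec = make_table(rows(150, "ep1", "a") + rows(150, "ep2", "b"))
    bg = make_table(rows(400, None, "c"))
    score = relevancy(spec, bg, FeatureSpec.gene("beta", "v"), bootstrap=200, seed=0)
    assert score.ci_low < 0 < score.ci_high
    assert abs(score.bits) < 0.5


def test_sampled_relevancy_matches_pair_counting_oracle(toy_specific, toy_background):
    feat = FeatureSpec.cdr3("beta")
    score = relevancy(toy_specific, toy_background, feat)
    groups = {
        e: [r.cdr3_beta for r in sub.records]
        for e, sub in toy_specific.epitope_groups().items()
    }
    pc_spec = brute_pc_conditional(groups, {e: 0.5 for e in groups})
    pc_bg = brute_pc_pairs([r.cdr3_beta for r in toy_background.records])
    assert score.bits == pytest.approx(math.log2(pc_spec / pc_bg), abs=1e-12)


def test_local_relevancy_is_single_group_reduction(toy_specific, toy_background):
    feat = FeatureSpec.cdr3("beta")
    loc = local_relevancy(toy_specific, toy_background, feat, epitope="ep2")
    sub = toy_specific.epitope_groups()["ep2"]
    pc_spec = brute_pc_pairs([r.cdr3_beta for r in sub.records])
    pc_bg = brute_pc_pairs([r.cdr3_beta for r in toy_background.records])
    assert loc.bits == pytest.approx(math.log2(pc_spec / pc_bg), abs=1e-12)
    assert loc.scope == "local:ep2"


def test_conditional_relevancy_of_self_is_zero(toy_specific, toy_background):
    feat = FeatureSpec.cdr3("beta")
    score = conditional_relevancy(toy_specific, toy_background, feat, feat)
    assert score.bits == pytest.approx(0.0, abs=1e-12)


def test_conditional_relevancy_on_constant_equals_relevancy(
    toy_specific, toy_background
):
    feat = FeatureSpec.cdr3("beta")
    const = FeatureSpec.gene("beta", "j")
    # make J constant everywhere so conditioning is vacuous
    toy_specific.df["j_beta"] = "TRBJ1"
    toy_background.df["j_beta"] = "TRBJ1"
    cond = conditional_relevancy(toy_specific, toy_background, feat, const, weights="size")
    plain = relevancy(toy_specific, toy_background, feat, weights="size")
    assert cond.bits == pytest.approx(plain.bits, abs=1e-12)


def test_conditional_relevancy_exact_matches_enumeration(rng):
    """X informative only within Y strata: match brute-force evaluation of
    the conditional-entropy difference on enumerated joints."""
    for _ in range(15):
        bg = random_joint(rng, 4, 3)
        specs = [random_joint(rng, 4, 3) for _ in range(2)]
        p_g = [0.6, 0.4]
        assert conditional_relevancy_exact(bg, specs, p_g) == pytest.approx(
            exact_conditional_relevancy(bg, specs, p_g), abs=1e-9
        )


def test_interaction_exact_synergy_construction():
    """Background uniform on {00,01,10,11}; specific uniform on {00,11}:
    marginals are uninformative, the joint carries one bit."""
    bg = np.full((2, 2), 0.25)
    spec = np.array([[0.5, 0.0], [0.0, 0.5]])
    bits = interaction_information_exact(bg, [spec], [1.0])
    assert bits == pytest.approx(1.0, abs=1e-12)


def test_interaction_exact_redundant_copy():
    """Y an exact copy of X carrying 1 bit: fully redundant, -1 bit."""
    bg = np.diag([0.25, 0.25, 0.25, 0.25])  # Y == X, uniform over 4
    spec = np.zeros((4, 4))
    spec[0, 0] = spec[1, 1] = 0.5  # uniform over 2 values -> I2(X) = 1 bit
    bits = interaction_information_exact(bg, [spec], [1.0])
    assert bits == pytest.approx(-1.0, abs=1e-12)


def test_interaction_exact_independent_features(rng):
    """X, Y independent in background and specific: zero interaction."""
    for _ in range(10):
        bx, by = rng.dirichlet(np.ones(3)), rng.dirichlet(np.ones(4))
        sx, sy = rng.dirichlet(np.ones(3)), rng.dirichlet(np.ones(4))
        bits = interaction_information_exact(
            np.outer(bx, by), [np.outer(sx, sy)], [1.0]
        )
        assert bits == pytest.approx(0.0, abs=1e-9)


def test_interaction_exact_matches_oracle(rng):
    for _ in range(15):
        bg = random_joint(rng, 3, 3)
        specs = [random_joint(rng, 3, 3) for _ in range(3)]
        p_g = rng.dirichlet(np.ones(3))
        assert interaction_information_exact(bg, specs, p_g) == pytest.approx(
            exact_interaction(bg, specs, p_g), abs=1e-9
        )


def test_sampled_interaction_consistency(toy_specific, toy_background):
    x = FeatureSpec.gene("beta", "v")
    y = FeatureSpec.cdr3("beta")
    score = interaction_information(toy_specific, toy_background, x, y)
    r_x = relevancy(toy_specific, toy_background, x)
    r_y = relevancy(toy_specific, toy_background, y)
    r_xy = relevancy(toy_specific, toy_background, FeatureSpec.product(x, y))
    assert score.bits == pytest.approx(r_xy.bits - r_x.bits - r_y.bits, abs=1e-12)


def test_relevancy_matrix_grid(toy_specific, toy_background):
    feats = [FeatureSpec.gene("beta", "v"), FeatureSpec.cdr3("beta")]
    grid = relevancy_matrix(toy_specific, toy_background, feats)
    assert grid.shape == (2, 2)
    assert grid.iloc[0, 1] == pytest.approx(grid.iloc[1, 0])  # symmetry
    diag = relevancy(toy_specific, toy_background, feats[0]).bits
    assert grid.iloc[0, 0] == pytest.approx(diag)
    inter = interaction_matrix(toy_specific, toy_background, feats)
    assert inter.iloc[0, 1] == pytest.approx(
        grid.iloc[0, 1] - grid.iloc[0, 0] - grid.iloc[1, 1], abs=1e-12
    )


def test_coarse_graining_can_increase_coincidence_information():
    """Order-2 coincidence information obeys no data-processing inequality:
    merging outcomes can raise exact I2 (unlike Shannon MI)."""
    bg = np.array([0.588, 0.0002, 0.4113, 0.0005])
    bg = bg / bg.sum()
    sp = np.array([0.49, 0.494, 0.011, 0.005])
    sp = sp / sp.sum()
    raw = relevancy_exact(bg, [sp], [1.0])
    merged_bg = np.array([bg[0] + bg[1], bg[2], bg[3]])
    merged_sp = np.array([sp[0] + sp[1], sp[2], sp[3]])
    merged = relevancy_exact(merged_bg, [merged_sp], [1.0])
    assert merged > raw
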