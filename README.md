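# tcrinfo

Coincidence-based information analysis of T cell receptor (TCR) repertoires:
how many bits does a partial TCR feature — a chain, a V/J gene, a CDR3, its
length or charge, a compressed representation, or a fuzzy match — carry about
antigen specificity, and what do those bits buy you in a classification task?

## The problem

A T cell's specificity is set by the binding of its receptor, a heterodimer
of α and β chains, to peptide–MHC ligands. Most sequenced TCRs have no
experimentally known ligand, so specificity is routinely inferred by matching
a query receptor against annotated references — often on partial information
(a single chain from bulk sequencing, a CDR3 only, or an inexact match).
`tcrinfo` quantifies what each kind of partial information is worth, and
bounds how reliable inference from it can be.

## The statistic

A *feature* X maps a clonotype to a discrete category. The probability that
two independent draws agree,

    p_C[X] = Σ_x P(x)²,

is the Simpson index; its negative log₂ is the order-2 Rényi (collision)
entropy H₂[X] = −log₂ p_C[X]. From a sample of N independently recombined
clones, p_C is estimated without bias by the fraction of the N(N−1)/2
unordered clone pairs that share a feature value — which is why this
machinery works at sample sizes where Shannon-entropy estimation fails.

Conditioning uses ρ₂ weights, ρ₂(y) = P(y)²/Σ_y P(y)², which keep H₂
additive (H₂[X,Y] = H₂[X] + H₂[Y|X]). The **relevancy** of a feature for
epitope specificity Π is the coincidence mutual information

    I₂(X, Π) = log₂ ( p_C[X|Π] / p_C[X] ),

the log-ratio of the coincidence probability among epitope-specific clones
(ρ₂-averaged over epitopes) to that in an unselected background. Derived
quantities: local relevancy i₂(X, π) for a single epitope; conditional
relevancy I₂(X, Π | Y); interaction information
I₂,int(X, Y | Π) = I₂([X,Y], Π) − I₂(X, Π) − I₂(Y, Π), positive for synergy
and negative for redundancy; and a near-coincidence analogue I₂^Δ for
matches at Levenshtein distance Δ.

Bits translate directly into classification performance: after a feature
match with an annotated reference, O_post = 2^{I₂} · O_prior — each bit
doubles the posterior odds — and reaching posterior odds T requires a prior
probability of at least T·2^{−I₂}/(1 + T·2^{−I₂}).

## Worked example

Simulate a background repertoire and two epitope-specific repertoires (one
with a single binding mode, one a mixture of four), then score features:

```python
import pandas as pd
import tcrinfo as t
from tcrinfo.features import FeatureSpec

bg_cfg = t.default_background_config(n_clones=2000, seed=0)
background = t.generate_background(bg_cfg)

eps = []
for label, m, seed in [("epA", 1, 1), ("epB", 4, 2)]:
    cfg = t.MixtureConfig(n_modes=m, n_clones=400, epitope=label, seed=seed)
    eps.append(t.generate_specific(cfg, bg_cfg).df)
specific = t.RepertoireTable(pd.concat(eps, ignore_index=True))

vb = FeatureSpec.gene("beta", "v")
score = t.relevancy(specific, background, vb, bootstrap=200, seed=0)
print(f"I2(Vbeta, Pi) = {score.bits:.2f} bits  (95% CI {score.ci_low:.2f}-{score.ci_high:.2f})")

syn = t.interaction_information(specific, background,
                                FeatureSpec.gene("beta", "v"),
                                FeatureSpec.gene("beta", "j"))
print(f"interaction(Vb, Jb) = {syn.bits:.2f} bits")

beta = FeatureSpec.chain("beta")
pc_bg_beta = t.background_pc_exact(bg_cfg, beta)   # background model is known exactly
local = t.local_relevancy(specific, pc_bg_beta, beta, epitope="epA")
print(f"i2(beta, epA) = {local.bits:.1f} bits")
print(f"min prior for 95% posterior with that match: {t.min_prior(local.bits, 19):.2e}")
```

Output:

```
I2(Vbeta, Pi) = 3.07 bits  (95% CI 3.01-3.13)
interaction(Vb, Jb) = 0.58 bits
i2(beta, epA) = 51.7 bits
min prior for 95% posterior with that match: 5.08e-15
```

Reading: knowing the Vβ gene of these synthetic specific clones narrows the
epitope hypothesis by about 3 bits (an 8-fold gain in posterior odds); the
Vβ/Jβ combination carries ~0.6 bits more than the two genes separately
(synergy); and a full β-chain match on the single-mode epitope is so
restrictive here that even a prior of ~10⁻¹⁴ would suffice for confident
classification. The synthetic background is far more uniform than a real
V(D)J repertoire, so absolute bit values are larger than on real data; the
relationships between them are what the framework predicts.

The same analyses run from the shell on paired-chain TSV or AIRR
Rearrangement files: `tcrinfo relevancy`, `interaction`, `fuzzy`,
`alphabet`, `bound`, and `simulate` (see `tcrinfo --help`).

## Layout

- `tcrinfo.repertoire_io` — clonotype table I/O (AIRR TSV, paired-chain TSV)
- `tcrinfo.features` — discrete feature extraction and the feature mini-language
- `tcrinfo.coincidence` — p_C estimators and collision entropy
- `tcrinfo.information` — relevancy, conditional relevancy, interaction information
- `tcrinfo.classification` — posterior odds, minimal priors, critical distances
- `tcrinfo.near_coincidence` — distance-resolved coincidences (edit-distance fuzzy matches)
- `tcrinfo.alphabets` — reduced amino acid alphabets and greedy optimal search
- `tcrinfo.simulate` — synthetic backgrounds, mixture-of-modes epitopes, spike-in experiments

See `docs/methods.md` for the model assumptions, parameter choices, and
known limitations.
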