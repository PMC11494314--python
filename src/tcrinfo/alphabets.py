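"""Reduced amino acid alphabets and information-optimal coarse-graining.

A reduced alphabet is a surjective map from the 20 canonical amino acids
onto k group symbols; remapping a CDR3 through it compresses the sequence
while preserving some of its specificity information.  Alphabets can be
loaded from files, built by hierarchical clustering of a 1-D biophysical
property scale, or searched for greedily so as to maximize the relevancy
retained by the remapped CDR3 feature.

Group symbols are canonical: each group is labeled by its
lexicographically first member, so two alphabets inducing the same
partition compare equal.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from . import coincidence as co
from .features import FeatureSpec, extract
from .repertoire_io import AMINO_ACIDS, RepertoireTable

__all__ = [
    "AlphabetMap",
    "load_property_scales",
    "property_cluster_alphabet",
    "greedy_optimal_alphabet",
    "alphabet_scoreboard",
]


@dataclass(frozen=True)
class AlphabetMap:
    """Total map from the 20 amino acids onto k group symbols."""

    mapping: tuple  # sorted tuple of (amino_acid, group_symbol)
    label: str = "custom"

    @classmethod
    def from_dict(cls, mapping: Mapping[str, str], label: str = "custom") -> "AlphabetMap":
        if set(mapping) != set(AMINO_ACIDS):
            missing = set(AMINO_ACIDS) - set(mapping)
            raise ValueError(f"alphabet must map all 20 amino acids; missing {missing}")
        groups: dict[str, list[str]] = {}
        for aa, sym in mapping.items():
            groups.setdefault(sym, []).append(aa)
        canon = {}
        for members in groups.values():
            symbol = min(members)
            for aa in members:
                canon[aa] = symbol
        return cls(mapping=tuple(sorted(canon.items())), label=label)

    @classmethod
    def from_groups(cls, groups: Iterable[Iterable[str]], label: str = "custom") -> "AlphabetMap":
        mapping = {}
        for members in groups:
            members = list(members)
            for aa in members:
                mapping[aa] = min(members)
        return cls.from_dict(mapping, label=label)

    @classmethod
    def identity(cls) -> "AlphabetMap":
        return cls.from_dict({a: a for a in AMINO_ACIDS}, label="identity")

    @classmethod
    def constant(cls) -> "AlphabetMap":
        return cls.from_dict({a: "A" for a in AMINO_ACIDS}, label="constant")

    @classmethod
    def from_file(cls, path) -> "AlphabetMap":
        """Load a two-column TSV (amino_acid, group)."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        return cls.from_dict(mapping, label=Path(path).stem)

    def to_file(self, path) -> None:
        pd.DataFrame(self.mapping, columns=["amino_acid", "group"]).to_csv(
            path, sep="\t", index=False
        )

    def as_dict(self) -> dict[str, str]:
        return dict(self.mapping)

    @property
    def k(self) -> int:
        return len({sym for _, sym in self.mapping})

    def groups(self) -> list[tuple[str, ...]]:
        by_sym: dict[str, list[str]] = {}
        for aa, sym in self.mapping:
            by_sym.setdefault(sym, []).append(aa)
        return sorted(tuple(sorted(m)) for m in by_sym.values())

    def translation_table(self) -> dict[int, str]:
        return str.maketrans(self.as_dict())

    def remap(self, seq: str) -> str:
        """Remap an amino acid string onto group symbols (length-preserving)."""
        return seq.translate(self.translation_table())

    def compose(self, other: "AlphabetMap") -> "AlphabetMap":
        """Apply ``other`` after ``self`` (coarsen an already reduced map)."""
        d = self.as_dict()
        o = other.as_dict()
        return AlphabetMap.from_dict(
            {aa: o[sym] for aa, sym in d.items()},
            label=f"{self.label}>{other.label}",
        )


def remap(seq: str, alphabet: AlphabetMap) -> str:
    return alphabet.remap(seq)


def load_property_scales() -> pd.DataFrame:
    """Built-in 1-D biophysical property scales, indexed by amino acid.

    Columns: polarity, solvation_free_energy, vdw_volume_normalized,
    radius_of_gyration_sidechain, asa_tripeptide (literature values; see
    the data file header for sources).
    """
    with resources.files("tcrinfo.data").joinpath("aa_property_scales.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return df.set_index("amino_acid")


def property_cluster_alphabet(scale: Mapping[str, float], k: int, label: str | None = None) -> AlphabetMap:
    """Reduced alphabet from complete-linkage clustering of a 1-D scale.

    Complete linkage on a single property produces groups that are
    contiguous intervals of the property value.
    """
    if not 1 <= k <= 20:
        raise ValueError("k must be in 1..20")
    aas = sorted(scale)
    if set(aas) != set(AMINO_ACIDS):
        raise ValueError("scale must cover all 20 amino acids")
    values = np.array([[float(scale[a])] for a in aas])
    if k == 20:
        groups: list[list[str]] = [[a] for a in aas]
    else:
        z = linkage(values, method="complete")
        labels = fcluster(z, t=k, criterion="maxclust")
        groups = [[a for a, l in zip(aas, labels) if l == g] for g in sorted(set(labels))]
    return AlphabetMap.from_groups(groups, label=label or f"property_k{k}")


# -- greedy information-optimal search ------------------------------------


def _counts_for(table: RepertoireTable, feature_base: str) -> list[Counter]:
    """Unique raw CDR3 value counts; one Counter per epitope group (or a
    single one for a background table)."""
    if feature_base == "cdr3a":
        feat = FeatureSpec.cdr3("alpha")
    elif feature_base == "cdr3b":
        feat = FeatureSpec.cdr3("beta")
    elif feature_base == "both":
        feat = FeatureSpec.product(FeatureSpec.cdr3("alpha"), FeatureSpec.cdr3("beta"))
    else:
        raise ValueError("feature_base must be 'cdr3a', 'cdr3b', or 'both'")
    eps = table.epitopes
    if eps:
        return [
            Counter(co.clean_values(extract(sub, feat)))
            for _, sub in sorted(table.epitope_groups().items(), key=lambda kv: str(kv[0]))
        ]
    return [Counter(co.clean_values(extract(table, feat)))]


def _remap_counter(counter: Counter, trans, paired: bool) -> Counter:
    out: Counter = Counter()
    if paired:
        for (a, b), n in counter.items():
            out[(a.translate(trans), b.translate(trans))] += n
    else:
        for s, n in counter.items():
            out[s.translate(trans)] += n
    return out


def _pc_of_counter(counter: Counter) -> float | None:
    n = sum(counter.values())
    if n < 2:
        return None
    coinc = sum(c * (c - 1) for c in counter.values())
    return coinc / (n * (n - 1))


def _score_mapping(
    mapping: dict[str, str],
    spec_counters: Sequence[Counter],
    bg_counters: Sequence[Counter],
    paired: bool,
) -> float | None:
    """Relevancy (uniform epitope weights) of the remapped CDR3 feature."""
    trans = str.maketrans(mapping)
    pcs = []
    for c in spec_counters:
        pc = _pc_of_counter(_remap_counter(c, trans, paired))
        if pc is not None:
            pcs.append(pc)
    if not pcs:
        return None
    rho = co.rho2_weights([1.0 / len(pcs)] * len(pcs))
    pc_spec = float(np.dot(rho, pcs))
    pc_bg = _pc_of_counter(_remap_counter(bg_counters[0], trans, paired))
    if pc_bg is None or pc_bg == 0 or pc_spec == 0:
        return None
    return math.log2(pc_spec / pc_bg)


def greedy_optimal_alphabet(
    specific: RepertoireTable,
    background: RepertoireTable,
    k: int,
    feature_base: str = "cdr3b",
) -> tuple[AlphabetMap, float]:
    """Greedy agglomerative search for a maximally informative alphabet.

    Starts from the 20 singleton groups and repeatedly merges the pair of
    groups whose merge maximizes the relevancy of the remapped CDR3
    feature(s), until k groups remain.  Ties break lexicographically on
    the merged group symbols; a merge whose relevancy is undefined (zero
    coincident pairs) scores -inf.  Returns the final map and its retained
    relevancy in bits.
    """
    if not 1 <= k <= 20:
        raise ValueError("k must be in 1..20")
    paired = feature_base == "both"
    spec_counters = _counts_for(specific, feature_base)
    bg_counters = _counts_for(background, feature_base)
    groups: list[tuple[str, ...]] = [(a,) for a in AMINO_ACIDS]

    def mapping_of(groups_list) -> dict[str, str]:
        m = {}
        for g in groups_list:
            sym = min(g)
            for aa in g:
                m[aa] = sym
        return m

    score = _score_mapping(mapping_of(groups), spec_counters, bg_counters, paired)
    while len(groups) > k:
        best = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                merged = groups[:i] + groups[i + 1 : j] + groups[j + 1 :]
                merged.append(tuple(sorted(groups[i] + groups[j])))
                s = _score_mapping(mapping_of(merged), spec_counters, bg_counters, paired)
                if s is None:
                    warnings.warn(
                        "candidate merge has undefined relevancy (zero "
                        "coincident pairs); scored -inf",
                        stacklevel=2,
                    )
                    s = -math.inf
                key = (-s, min(groups[i]), min(groups[j]))
                if best is None or key < best[0]:
                    best = (key, merged, s)
        _, groups, score = best
    amap = AlphabetMap.from_groups(groups, label=f"greedy_k{k}")
    return amap, (score if score is not None else float("nan"))


def alphabet_scoreboard(
    specific: RepertoireTable,
    background: RepertoireTable,
    alphabets: Sequence[AlphabetMap],
    feature_base: str = "cdr3b",
) -> pd.DataFrame:
    """Retained relevancy per alphabet, with Pareto-optimality flags.

    An alphabet is Pareto-optimal within the given list when no other
    alphabet is at least as compressed (k' <= k) and strictly more
    informative, or more compressed and at least as informative.
    """
    paired = feature_base == "both"
    spec_counters = _counts_for(specific, feature_base)
    bg_counters = _counts_for(background, feature_base)
    rows = []
    for amap in alphabets:
        bits = _score_mapping(amap.as_dict(), spec_counters, bg_counters, paired)
        rows.append({"alphabet": amap.label, "k": amap.k, "bits": bits})
    df = pd.DataFrame(rows, columns=["alphabet", "k", "bits"])
    pareto = []
    for _, r in df.iterrows():
        dominated = False
        if r["bits"] is None or pd.isna(r["bits"]):
            dominated = True
        else:
            for _, o in df.iterrows():
                if o["bits"] is None or pd.isna(o["bits"]):
                    continue
                if (o["k"] <= r["k"] and o["bits"] > r["bits"]) or (
                    o["k"] < r["k"] and o["bits"] >= r["bits"]
                ):
                    dominated = True
                    break
        pareto.append(not dominated)
    df["pareto"] = pareto
    return df
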