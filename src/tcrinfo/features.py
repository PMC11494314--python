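"""Discrete TCR features — the random variables of the coincidence framework.

A feature maps a clonotype to a hashable category: a gene segment choice,
a CDR3 amino acid string, a physical property (length, net charge, amino
acid content), a compressed representation (bag of words, reduced-alphabet
remap), or a product of other features.  Two clones coincide in a product
feature exactly when they coincide in every component.

Records missing a required field yield a missing value for that feature and
are excluded from coincidence counting feature-by-feature, so single-chain
features use every record that carries the chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import pandas as pd

from .repertoire_io import AMINO_ACIDS, RepertoireTable

__all__ = [
    "FeatureSpec",
    "FeatureError",
    "extract",
    "net_charge",
    "bag_of_words",
    "aa_content",
    "parse_feature",
]


class FeatureError(ValueError):
    """Unknown feature kind or malformed specification."""


_LEAF_KINDS = {
    "gene",
    "cdr3",
    "length",
    "net_charge",
    "aa_content",
    "bag_of_words",
    "alphabet_remap",
}


@dataclass(frozen=True)
class FeatureSpec:
    """Specification of a discrete feature of a TCR clonotype.

    Use the classmethod constructors (:meth:`gene`, :meth:`cdr3`,
    :meth:`chain`, :meth:`tcr`, :meth:`product`, ...) rather than building
    instances by hand.
    """

    name: str
    kind: str
    chain: str | None = None
    segment: str | None = None  # for kind == "gene": "v" or "j"
    aa: str | None = None  # for kind == "aa_content"
    alphabet: object = None  # for kind == "alphabet_remap": an AlphabetMap
    base: "FeatureSpec | None" = None  # for alphabet_remap / bag_of_words
    components: tuple = ()  # for kind == "product"
    histidine_weight: float = 0.0

    # -- constructors ------------------------------------------------------
    @classmethod
    def gene(cls, chain: str, segment: str) -> "FeatureSpec":
        _check_chain(chain)
        if segment not in ("v", "j"):
            raise FeatureError("segment must be 'v' or 'j'")
        return cls(name=f"{segment}_{chain}", kind="gene", chain=chain, segment=segment)

    @classmethod
    def cdr3(cls, chain: str) -> "FeatureSpec":
        _check_chain(chain)
        return cls(name=f"cdr3_{chain}", kind="cdr3", chain=chain)

    @classmethod
    def length(cls, chain: str) -> "FeatureSpec":
        _check_chain(chain)
        return cls(name=f"length_{chain}", kind="length", chain=chain)

    @classmethod
    def net_charge(cls, chain: str, histidine_weight: float = 0.0) -> "FeatureSpec":
        _check_chain(chain)
        return cls(
            name=f"charge_{chain}",
            kind="net_charge",
            chain=chain,
            histidine_weight=histidine_weight,
        )

    @classmethod
    def aa_count(cls, chain: str, aa: str) -> "FeatureSpec":
        _check_chain(chain)
        if aa not in AMINO_ACIDS:
            raise FeatureError(f"{aa!r} is not a canonical amino acid")
        return cls(name=f"count_{aa}_{chain}", kind="aa_content", chain=chain, aa=aa)

    @classmethod
    def bag_of_words(cls, chain: str) -> "FeatureSpec":
        if chain == "both":
            return cls.product(cls.bag_of_words("alpha"), cls.bag_of_words("beta"))
        _check_chain(chain)
        return cls(name=f"bow_{chain}", kind="bag_of_words", chain=chain)

    @classmethod
    def remap(cls, alphabet, base: "FeatureSpec") -> "FeatureSpec":
        if base.kind != "cdr3":
            raise FeatureError("alphabet remap applies to cdr3 features")
        label = getattr(alphabet, "label", "alphabet")
        return cls(
            name=f"remap[{label}]_{base.name}",
            kind="alphabet_remap",
            chain=base.chain,
            alphabet=alphabet,
            base=base,
        )

    @classmethod
    def product(cls, *components: "FeatureSpec") -> "FeatureSpec":
        flat: list[FeatureSpec] = []
        for c in components:
            if c.kind == "product":
                flat.extend(c.components)
            else:
                flat.append(c)
        if len(flat) == 1:
            return flat[0]
        name = "+".join(c.name for c in flat)
        return cls(name=name, kind="product", components=tuple(flat))

    @classmethod
    def chain(cls, chain: str) -> "FeatureSpec":
        """Whole-chain feature: the product (V, J, CDR3) of one chain."""
        _check_chain(chain)
        return cls.product(cls.gene(chain, "v"), cls.gene(chain, "j"), cls.cdr3(chain))

    @classmethod
    def tcr(cls) -> "FeatureSpec":
        """Full paired-chain receptor: product of both whole chains."""
        return cls.product(cls.chain("alpha"), cls.chain("beta"))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def _check_chain(chain: str) -> None:
    if chain not in ("alpha", "beta"):
        raise FeatureError("chain must be 'alpha' or 'beta'")


def net_charge(cdr3: str, histidine_weight: float = 0.0) -> float | int:
    """Net charge of a CDR3 loop: (#K + #R) - (#D + #E), H configurable.

    With the default histidine weight of 0 the value is an integer;
    fractional weights are binned to one decimal so values stay hashable.
    """
    charge = sum(cdr3.count(a) for a in "KR") - sum(cdr3.count(a) for a in "DE")
    charge = charge + histidine_weight * cdr3.count("H")
    if float(histidine_weight).is_integer():
        return int(charge)
    return round(charge, 1)


def bag_of_words(cdr3: str) -> tuple[int, ...]:
    """20-component amino acid count vector of a CDR3, order-insensitive."""
    return tuple(cdr3.count(a) for a in AMINO_ACIDS)


def aa_content(cdr3: str, aa: str) -> int:
    """Number of occurrences of one amino acid in a CDR3."""
    if aa not in AMINO_ACIDS:
        raise FeatureError(f"{aa!r} is not a canonical amino acid")
    return cdr3.count(aa)


def _leaf_extractor(spec: FeatureSpec) -> tuple[str, Callable]:
    """(source column, per-value transform) for a leaf feature."""
    if spec.kind == "gene":
        return f"{spec.segment}_{spec.chain}", lambda v: v
    col = f"cdr3_{spec.chain}"
    if spec.kind == "cdr3":
        return col, lambda v: v
    if spec.kind == "length":
        return col, len
    if spec.kind == "net_charge":
        hw = spec.histidine_weight
        return col, lambda v: net_charge(v, hw)
    if spec.kind == "aa_content":
        aa = spec.aa
        return col, lambda v: v.count(aa)
    if spec.kind == "bag_of_words":
        return col, bag_of_words
    if spec.kind == "alphabet_remap":
        table = spec.alphabet.translation_table()
        return col, lambda v: v.translate(table)
    raise FeatureError(f"unknown feature kind {spec.kind!r}")


def extract(table: RepertoireTable, spec: FeatureSpec) -> pd.Series:
    """Evaluate a feature on every record of a repertoire.

    Returns an object Series aligned with the table, with ``None`` where
    the record lacks the fields the feature requires.  Values are hashable
    and canonical: the same input always yields the identical value.
    """
    if spec.kind == "product":
        cols = [extract(table, c) for c in spec.components]
        def tup(row):
            if any(v is None for v in row):
                return None
            return tuple(row)
        values = [tup(row) for row in zip(*(c.tolist() for c in cols))]
        return pd.Series(values, index=table.df.index, dtype=object, name=spec.name)
    if spec.kind not in _LEAF_KINDS:
        raise FeatureError(f"unknown feature kind {spec.kind!r}")
    col, fn = _leaf_extractor(spec)
    raw = table.df[col]
    values = [None if v is None or (isinstance(v, float) and pd.isna(v)) else fn(v)
              for v in raw.tolist()]
    return pd.Series(values, index=table.df.index, dtype=object, name=spec.name)


# -- CLI feature mini-language --------------------------------------------

_SHORTHAND = {
    "va": lambda: FeatureSpec.gene("alpha", "v"),
    "ja": lambda: FeatureSpec.gene("alpha", "j"),
    "vb": lambda: FeatureSpec.gene("beta", "v"),
    "jb": lambda: FeatureSpec.gene("beta", "j"),
    "cdr3a": lambda: FeatureSpec.cdr3("alpha"),
    "cdr3b": lambda: FeatureSpec.cdr3("beta"),
    "alpha": lambda: FeatureSpec.chain("alpha"),
    "beta": lambda: FeatureSpec.chain("beta"),
    "tcr": lambda: FeatureSpec.tcr(),
    "lena": lambda: FeatureSpec.length("alpha"),
    "lenb": lambda: FeatureSpec.length("beta"),
    "chargea": lambda: FeatureSpec.net_charge("alpha"),
    "chargeb": lambda: FeatureSpec.net_charge("beta"),
    "bowa": lambda: FeatureSpec.bag_of_words("alpha"),
    "bowb": lambda: FeatureSpec.bag_of_words("beta"),
    "bowab": lambda: FeatureSpec.bag_of_words("both"),
}


def parse_feature(text: str) -> FeatureSpec:
    """Parse the CLI mini-language: shorthand names joined by ``+``.

    Examples: ``vb``, ``vb+cdr3b``, ``remap:groups.tsv:cdr3b``,
    ``count:R:cdr3b``.
    """
    parts = [p.strip() for p in text.split("+")]
    specs = []
    for p in parts:
        if p in _SHORTHAND:
            specs.append(_SHORTHAND[p]())
        elif p.startswith("remap:"):
            from .alphabets import AlphabetMap

            _, path, base = p.split(":")
            amap = AlphabetMap.from_file(path)
            specs.append(FeatureSpec.remap(amap, _SHORTHAND[base]()))
        elif p.startswith("count:"):
            _, aa, base = p.split(":")
            chain = "alpha" if base.endswith("a") else "beta"
            specs.append(FeatureSpec.aa_count(chain, aa))
        else:
            raise FeatureError(f"unknown feature {p!r}")
    return FeatureSpec.product(*specs)
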