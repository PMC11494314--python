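"""Clonotype table I/O and the canonical in-memory repertoire representation.

A repertoire is a table of clonotypes — independently recombined clonal
lineages — each carrying V/J gene calls and CDR3 amino acid sequences for
one or both chains, an optional epitope label (absent for background
sequences), and a clone count.  Coincidence statistics are computed over
distinct clones; clone counts are metadata unless count-weighting is
explicitly requested downstream.

Two tabular dialects are supported: the AIRR Rearrangement TSV (single
chain, standard column names) and a paired-chain TSV with columns
``cdr3_alpha, v_alpha, j_alpha, cdr3_beta, v_beta, j_beta, epitope,
clone_count``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "TcrRecord",
    "RepertoireTable",
    "read_airr",
    "read_paired_tsv",
    "write_paired_tsv",
    "write_scores",
    "read_scores",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

CANONICAL_COLUMNS = [
    "clone_id",
    "v_alpha",
    "j_alpha",
    "cdr3_alpha",
    "v_beta",
    "j_beta",
    "cdr3_beta",
    "epitope",
    "clone_count",
]

_ALLELE_RE = re.compile(r"\*\d+$")


class FormatError(ValueError):
    """A required column is missing or a file cannot be parsed."""


@dataclass(frozen=True)
class TcrRecord:
    """One clonotype: gene calls, CDR3s, epitope label, clone count."""

    clone_id: str
    v_alpha: str | None = None
    j_alpha: str | None = None
    cdr3_alpha: str | None = None
    v_beta: str | None = None
    j_beta: str | None = None
    cdr3_beta: str | None = None
    epitope: str | None = None
    clone_count: int = 1

    @property
    def is_paired(self) -> bool:
        return self.cdr3_alpha is not None and self.cdr3_beta is not None


def strip_allele(call: str | None) -> str | None:
    """Normalize a gene call to gene level by stripping the ``*NN`` allele."""
    if call is None or (isinstance(call, float) and pd.isna(call)) or call == "":
        return None
    return _ALLELE_RE.sub("", str(call).strip())


def is_canonical_cdr3(seq) -> bool:
    if not isinstance(seq, str) or len(seq) == 0:
        return False
    return set(seq) <= _AA_SET


@dataclass
class RepertoireTable:
    """An ordered collection of clonotypes with provenance.

    ``df`` holds one row per clone with the canonical columns; missing
    fields are ``None``.  Epitope labels partition the specific records;
    background records carry no epitope label.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in CANONICAL_COLUMNS:
            if col not in self.df.columns:
                self.df[col] = 1 if col == "clone_count" else None
        self.df = self.df[CANONICAL_COLUMNS].reset_index(drop=True)
        self.df["clone_count"] = self.df["clone_count"].fillna(1).astype(int)
        obj_cols = [c for c in CANONICAL_COLUMNS if c not in ("clone_count",)]
        self.df[obj_cols] = self.df[obj_cols].astype(object).where(
            self.df[obj_cols].notna(), None
        )

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records: Iterable[TcrRecord | dict], **prov) -> "RepertoireTable":
        rows = [r.__dict__ if isinstance(r, TcrRecord) else dict(r) for r in records]
        df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
        if len(df) and df["clone_id"].isna().any():
            df["clone_id"] = [
                cid if pd.notna(cid) else f"clone_{i}"
                for i, cid in enumerate(df["clone_id"])
            ]
        return cls(df, provenance=prov)

    @property
    def records(self) -> Iterator[TcrRecord]:
        for row in self.df.itertuples(index=False):
            yield TcrRecord(**row._asdict())

    @property
    def epitopes(self) -> list:
        labels = [e for e in self.df["epitope"].unique() if e is not None]
        return sorted(labels, key=str)

    def epitope_groups(self) -> dict[str, "RepertoireTable"]:
        """Subtables of the epitope-labeled (specific) records, by label."""
        return {
            e: RepertoireTable(
                self.df[self.df["epitope"] == e].copy(), dict(self.provenance)
            )
            for e in self.epitopes
        }

    def background(self) -> "RepertoireTable":
        """Subtable of records without an epitope label."""
        mask = self.df["epitope"].isna() | self.df["epitope"].isin([None, ""])
        return RepertoireTable(self.df[mask].copy(), dict(self.provenance))

    def subset(self, mask) -> "RepertoireTable":
        return RepertoireTable(self.df[mask].copy(), dict(self.provenance))


def _finalize(
    df: pd.DataFrame, n_input: int, n_dropped: int, source, fmt: str
) -> RepertoireTable:
    prov = {
        "source": str(source),
        "format": fmt,
        "n_input_rows": n_input,
        "n_dropped": n_dropped,
        "n_retained": len(df),
    }
    return RepertoireTable(df, provenance=prov)


def read_airr(path, chain_locus: str) -> RepertoireTable:
    """Read an AIRR Rearrangement TSV as a single-chain repertoire.

    Parameters
    ----------
    path
        Tab-separated file with AIRR header names (``junction_aa``,
        ``v_call``, ``j_call``; optional ``sequence_id``,
        ``duplicate_count``).
    chain_locus
        ``"alpha"`` or ``"beta"`` — which chain the rows describe.

    Rows whose ``junction_aa`` is empty or contains non-canonical letters
    are dropped and counted in the provenance.
    """
    if chain_locus not in ("alpha", "beta"):
        raise ValueError("chain_locus must be 'alpha' or 'beta'")
    raw = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("junction_aa", "v_call", "j_call"):
        if col not in raw.columns:
            raise FormatError(f"missing mandatory AIRR column: {col}")
    keep = raw["junction_aa"].map(is_canonical_cdr3).astype(bool)
    n_dropped = int((~keep).sum())
    kept = raw[keep]
    suffix = chain_locus
    df = pd.DataFrame(
        {
            "clone_id": (
                kept["sequence_id"]
                if "sequence_id" in kept.columns
                else [f"row_{i}" for i in kept.index]
            ),
            f"v_{suffix}": kept["v_call"].map(strip_allele),
            f"j_{suffix}": kept["j_call"].map(strip_allele),
            f"cdr3_{suffix}": kept["junction_aa"],
            "epitope": kept["epitope"] if "epitope" in kept.columns else None,
            "clone_count": (
                pd.to_numeric(kept["duplicate_count"], errors="coerce")
                if "duplicate_count" in kept.columns
                else 1
            ),
        }
    )
    return _finalize(df, len(raw), n_dropped, path, "airr")


_PAIRED_COLUMNS = ["cdr3_alpha", "v_alpha", "j_alpha", "cdr3_beta", "v_beta", "j_beta"]


def read_paired_tsv(path) -> RepertoireTable:
    """Read the paired-chain TSV dialect.

    Expected columns: ``cdr3_alpha, v_alpha, j_alpha, cdr3_beta, v_beta,
    j_beta, epitope, clone_count`` (``clone_count`` defaults to 1,
    ``epitope`` may be empty for background rows, ``clone_id`` optional).
    Rows sharing a ``clone_id`` are merged with counts summed; rows where a
    present CDR3 contains non-canonical letters are dropped and counted.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _PAIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"missing paired-TSV column(s): {', '.join(missing)}")
    n_input = len(raw)

    def cdr3_ok(v):
        if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
            return True  # missing chain is allowed
        return is_canonical_cdr3(v)

    keep = (raw["cdr3_alpha"].map(cdr3_ok) & raw["cdr3_beta"].map(cdr3_ok)).astype(bool)
    kept = raw[keep].copy()
    n_dropped = n_input - len(kept)
    for col in ("v_alpha", "j_alpha", "v_beta", "j_beta"):
        kept[col] = kept[col].map(strip_allele)
    kept["clone_count"] = (
        pd.to_numeric(kept["clone_count"], errors="coerce").fillna(1).astype(int)
        if "clone_count" in kept.columns
        else 1
    )
    if "epitope" not in kept.columns:
        kept["epitope"] = None
    kept["epitope"] = kept["epitope"].where(
        kept["epitope"].notna() & (kept["epitope"] != ""), None
    )
    if "clone_id" in kept.columns:
        agg = {c: "first" for c in kept.columns if c not in ("clone_id", "clone_count")}
        agg["clone_count"] = "sum"
        kept = kept.groupby("clone_id", as_index=False, sort=False).agg(agg)
    else:
        kept.insert(0, "clone_id", [f"clone_{i}" for i in range(len(kept))])
    return _finalize(kept, n_input, n_dropped, path, "paired_tsv")


def write_paired_tsv(table: RepertoireTable, path) -> None:
    """Write a repertoire in the paired-chain TSV dialect."""
    table.df.to_csv(path, sep="\t", index=False)


def _score_row(score) -> dict:
    feat = getattr(score, "feature", None)
    cond = getattr(score, "conditioning", None)
    return {
        "feature": getattr(feat, "name", feat),
        "conditioning": getattr(cond, "name", cond),
        "scope": getattr(score, "scope", "global"),
        "bits": getattr(score, "bits", None),
        "unit": "bits",
        "ci_low": getattr(score, "ci_low", None),
        "ci_high": getattr(score, "ci_high", None),
        "n_specific": getattr(score, "n_specific", None),
        "n_background": getattr(score, "n_background", None),
    }


def write_scores(scores: Iterable, path, format: str = "tsv") -> None:
    """Write information scores as TSV or JSON with an explicit bits unit."""
    rows = [_score_row(s) for s in scores]
    cols = [
        "feature",
        "conditioning",
        "scope",
        "bits",
        "unit",
        "ci_low",
        "ci_high",
        "n_specific",
        "n_background",
    ]
    df = pd.DataFrame(rows, columns=cols)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        Path(path).write_text(json.dumps(rows, indent=2, default=float) + "\n")
    else:
        raise ValueError(f"unknown score format {format!r}")


def read_scores(path, format: str = "tsv") -> pd.DataFrame:
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        return pd.DataFrame(json.loads(Path(path).read_text()))
    raise ValueError(f"unknown score format {format!r}")
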