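"""Compound ADME filtering and target-set construction.

The screening funnel implemented here mirrors standard network-pharmacology
practice for herbal formulas: candidate compounds are filtered on two ADME
axes — oral bioavailability (OB, percent of an oral dose reaching systemic
circulation) and drug-likeness (DL, similarity to known drugs) — with the
conventional inclusive thresholds OB >= 30 % and DL >= 0.18.  Putative drug
targets collected from several databases are unioned after gene-symbol
normalisation; disease targets carrying a relevance score are kept when they
score at or above the median; the common (drug AND disease) targets feed the
protein–protein-interaction analysis downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundRecord",
    "TargetSet",
    "DiseaseTargetRecord",
    "normalize_symbol",
    "filter_adme",
    "union_targets",
    "screen_disease_targets",
    "intersect_targets",
    "venn_partition",
    "read_compounds_tsv",
    "write_compounds_tsv",
    "read_target_list",
    "write_target_list",
    "read_disease_targets_tsv",
]

DEFAULT_OB_MIN = 30.0
DEFAULT_DL_MIN = 0.18


@dataclass(frozen=True)
class CompoundRecord:
    """One candidate compound with its ADME screening properties."""

    compound_id: str
    name: str
    ob: float  # oral bioavailability, percent in [0, 100]
    dl: float  # drug-likeness score in [0, 1]
    herb: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.ob <= 100.0:
            raise ValueError(f"OB must be in [0, 100], got {self.ob!r}")
        if not 0.0 <= self.dl <= 1.0:
            raise ValueError(f"DL must be in [0, 1], got {self.dl!r}")


def normalize_symbol(symbol: str) -> str:
    """Normalise a gene symbol: strip whitespace, uppercase.

    Full UniProt remapping is intentionally out of scope; an alias table can
    be supplied to :func:`union_targets` for local remapping instead.
    """
    return symbol.strip().upper()


@dataclass
class TargetSet:
    """A named, de-duplicated set of normalised gene symbols."""

    label: str
    symbols: set[str] = field(default_factory=set)
    sources: set[str] = field(default_factory=set)

    @classmethod
    def from_symbols(
        cls,
        label: str,
        symbols: Iterable[str],
        sources: Iterable[str] | None = None,
        alias_table: Mapping[str, str] | None = None,
    ) -> "TargetSet":
        alias = {normalize_symbol(k): normalize_symbol(v) for k, v in (alias_table or {}).items()}
        norm = set()
        for s in symbols:
            n = normalize_symbol(s)
            if n:
                norm.add(alias.get(n, n))
        return cls(label=label, symbols=norm, sources=set(sources) if sources else {label})

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class DiseaseTargetRecord:
    """A disease-associated gene with a nonnegative relevance score."""

    symbol: str
    relevance: float

    def __post_init__(self) -> None:
        if self.relevance < 0:
            raise ValueError(f"relevance must be >= 0, got {self.relevance!r}")


def filter_adme(
    compounds: Sequence[CompoundRecord],
    ob_min: float = DEFAULT_OB_MIN,
    dl_min: float = DEFAULT_DL_MIN,
) -> list[CompoundRecord]:
    """Keep compounds with ob >= ob_min and dl >= dl_min (inclusive), in input order."""
    if not (np.isfinite(ob_min) and np.isfinite(dl_min)):
        raise ValueError("ADME thresholds must be finite")
    return [c for c in compounds if c.ob >= ob_min and c.dl >= dl_min]


def union_targets(
    per_source: Sequence[TargetSet],
    label: str = "union",
    alias_table: Mapping[str, str] | None = None,
) -> TargetSet:
    """Union of target sets after normalisation, eliminating duplicates."""
    alias = {normalize_symbol(k): normalize_symbol(v) for k, v in (alias_table or {}).items()}
    symbols: set[str] = set()
    sources: set[str] = set()
    for ts in per_source:
        for s in ts.symbols:
            n = normalize_symbol(s)
            symbols.add(alias.get(n, n))
        sources |= ts.sources
    return TargetSet(label=label, symbols=symbols, sources=sources)


def screen_disease_targets(
    records: Sequence[DiseaseTargetRecord], label: str = "disease"
) -> TargetSet:
    """Keep disease targets whose relevance score is >= the median score.

    The median over an even count is the mean of the two central order
    statistics.  Symbols are de-duplicated before the median is taken (each
    distinct symbol contributes its maximum relevance once).
    """
    if not records:
        raise ValueError("screen_disease_targets requires at least one record")
    best: dict[str, float] = {}
    for r in records:
        n = normalize_symbol(r.symbol)
        if n not in best or r.relevance > best[n]:
            best[n] = r.relevance
    scores = np.array(list(best.values()), dtype=float)
    med = float(np.median(scores))
    kept = {s for s, v in best.items() if v >= med}
    return TargetSet(label=label, symbols=kept, sources={label})


def intersect_targets(a: TargetSet, b: TargetSet, label: str = "common") -> TargetSet:
    """Common targets of two sets (symbol intersection)."""
    return TargetSet(label=label, symbols=a.symbols & b.symbols, sources=a.sources | b.sources)


def venn_partition(a: TargetSet, b: TargetSet) -> dict[str, int]:
    """Two-set Venn partition counts {only_a, only_b, both}."""
    both = a.symbols & b.symbols
    return {
        "only_a": len(a.symbols - both),
        "only_b": len(b.symbols - both),
        "both": len(both),
    }


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_COMPOUND_COLS = ["compound_id", "name", "ob", "dl", "herb"]


def write_compounds_tsv(compounds: Sequence[CompoundRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(c.compound_id, c.name, c.ob, c.dl, c.herb) for c in compounds],
        columns=_COMPOUND_COLS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_compounds_tsv(path: str | Path) -> list[CompoundRecord]:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"compound_id": str, "name": str, "herb": str},
        float_precision="round_trip",
    )
    missing = set(_COMPOUND_COLS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"compound table missing columns: {sorted(missing)}")
    if "herb" not in df.columns:
        df["herb"] = ""
    return [
        CompoundRecord(
            compound_id=str(r.compound_id),
            name=str(r.name),
            ob=float(r.ob),
            dl=float(r.dl),
            herb="" if pd.isna(r.herb) else str(r.herb),
        )
        for r in df.itertuples()
    ]


def write_target_list(targets: TargetSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(targets.symbols)) + "\n")


def read_target_list(path: str | Path, label: str | None = None) -> TargetSet:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return TargetSet.from_symbols(label or Path(path).stem, [ln for ln in lines if ln])


def read_disease_targets_tsv(path: str | Path) -> list[DiseaseTargetRecord]:
    df = pd.read_csv(path, sep="\t")
    if not {"symbol", "relevance"} <= set(df.columns):
        raise ValueError("disease-target table needs columns: symbol, relevance")
    return [
        DiseaseTargetRecord(symbol=str(r.symbol), relevance=float(r.relevance))
        for r in df.itertuples()
    ]
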