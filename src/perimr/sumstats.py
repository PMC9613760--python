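"""GWAS summary-statistics tables and companion inputs.

The pipeline consumes per-variant association records (alleles, effect-allele
frequency, beta, SE, p-value) for one exposure GWAS and one outcome GWAS,
plus an optional pairwise-LD table and an optional variant exclusion list.
This module reads, validates and writes those inputs.

Conventions: positions are 1-based base pairs; alleles are single upper-case
bases (biallelic SNPs only — indels and multi-allelic records are rejected at
read time); betas are log-odds for binary traits and trait units for
continuous traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, InputError

log = logging.getLogger(__name__)

#: Canonical column order of a summary-statistics table.
CANONICAL_COLUMNS = (
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
)

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class StudyMetadata:
    """Trait-level metadata for one GWAS.

    Parameters
    ----------
    trait_name : str
        Human-readable trait label (e.g. ``"birth_weight"``).
    trait_type : {"continuous", "binary"}
        Scale of the phenotype; betas are log-odds for binary traits.
    n_total : int
        GWAS sample size.
    n_cases, n_controls : int, optional
        Case/control counts; required for binary traits and must sum to
        ``n_total``.
    """

    trait_name: str
    trait_type: str
    n_total: int
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigurationError(
                f"trait_type must be 'continuous' or 'binary', got {self.trait_type!r}"
            )
        if self.n_total < 0:
            raise ConfigurationError("n_total must be non-negative")
        if self.trait_type == "binary":
            if self.n_cases is None or self.n_controls is None:
                raise ConfigurationError("binary traits require n_cases and n_controls")
            if self.n_cases + self.n_controls != self.n_total:
                raise ConfigurationError(
                    f"n_cases + n_controls = {self.n_cases + self.n_controls} "
                    f"!= n_total = {self.n_total}"
                )

    @property
    def case_fraction(self) -> float | None:
        if self.trait_type != "binary":
            return None
        return self.n_cases / self.n_total


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's association record in one GWAS."""

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float  # NaN when missing
    beta: float
    se: float
    pvalue: float

    @classmethod
    def from_series(cls, row: pd.Series) -> "VariantAssociation":
        return cls(
            variant_id=str(row["variant_id"]),
            chromosome=str(row["chromosome"]),
            position=int(row["position"]),
            effect_allele=str(row["effect_allele"]),
            other_allele=str(row["other_allele"]),
            eaf=float(row["eaf"]),
            beta=float(row["beta"]),
            se=float(row["se"]),
            pvalue=float(row["pvalue"]),
        )


@dataclass
class SummaryStatsTable:
    """A validated GWAS summary-statistics table.

    ``df`` holds one row per variant with the canonical columns; variant IDs
    are unique. ``metadata`` may be ``None`` when only per-variant statistics
    are needed (e.g. ad-hoc CLI invocations).
    """

    metadata: StudyMetadata | None
    df: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.df["variant_id"].duplicated()
        if dup.any():
            first = self.df.loc[dup, "variant_id"].iloc[0]
            raise InputError(f"duplicated variant_id {first!r} in summary-statistics table")

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in set(self.df["variant_id"])

    @property
    def variant_ids(self) -> list[str]:
        return list(self.df["variant_id"])

    def get(self, variant_id: str) -> VariantAssociation:
        sub = self.df[self.df["variant_id"] == variant_id]
        if sub.empty:
            raise KeyError(variant_id)
        return VariantAssociation.from_series(sub.iloc[0])

    def indexed(self) -> dict[str, VariantAssociation]:
        """All records keyed by variant ID (materialized once for loops)."""
        return {
            str(row.variant_id): VariantAssociation(
                variant_id=str(row.variant_id),
                chromosome=str(row.chromosome),
                position=int(row.position),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
                eaf=float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                pvalue=float(row.pvalue),
            )
            for row in self.df.itertuples(index=False)
        }


def _validation_reasons(df: pd.DataFrame) -> pd.Series:
    """Per-row drop reason, or '' where the row is valid.

    Reasons are assigned in a fixed precedence so the audit trail is
    deterministic regardless of how many invariants a row violates.
    """
    reason = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, why: str) -> None:
        mask = mask & (reason == "")
        reason[mask] = why

    ea = df["effect_allele"].astype(str)
    oa = df["other_allele"].astype(str)
    valid_allele = ea.isin(_VALID_BASES) & oa.isin(_VALID_BASES)
    flag(~valid_allele, "non-SNP or invalid alleles")
    flag(ea == oa, "identical alleles")
    flag(~(df["se"] > 0), "nonpositive SE")
    flag(df["beta"].isna(), "missing beta")
    eaf_bad = df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1))
    flag(eaf_bad, "EAF outside [0,1]")
    flag(~((df["pvalue"] > 0) & (df["pvalue"] <= 1)), "p-value outside (0,1]")
    return reason


def read_sumstats(
    path: str | Path,
    metadata: StudyMetadata | None = None,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> SummaryStatsTable:
    """Read and validate a summary-statistics table.

    Parameters
    ----------
    path : path
        Tab- or comma-separated file with a header row.
    metadata : StudyMetadata, optional
        Trait metadata attached to the returned table.
    column_map : mapping, optional
        Maps canonical field names to the file's column names, absorbing
        source-specific header dialects (public GWAS releases rarely agree
        on column naming). The ``eaf`` column may be omitted entirely.
    sep : str, optional
        Field separator; inferred from the header line when not given.

    Rows violating a record invariant are dropped and logged with a reason;
    a duplicated variant ID or an empty table after validation is an error.
    Recorded p-values are cross-checked against ``2*Phi(-|beta/se|)`` and a
    mismatch beyond a factor of two is logged as a warning only — public
    summary statistics often store truncated p-values.
    """
    path = Path(path)
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype={"variant_id": str})

    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        missing_src = [s for s in rename if s not in df.columns]
        if missing_src:
            raise ConfigurationError(
                f"column_map refers to columns absent from {path.name}: {missing_src}"
            )
        df = df.rename(columns=rename)

    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns and c != "eaf"]
    if missing:
        raise ConfigurationError(f"{path.name}: missing mandatory columns {missing}")
    if "eaf" not in df.columns:
        df["eaf"] = np.nan

    df = df[list(CANONICAL_COLUMNS)].copy()
    df["variant_id"] = df["variant_id"].astype(str)
    df["chromosome"] = df["chromosome"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "pvalue"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    reason = _validation_reasons(df)
    bad = reason != ""
    for vid, why in zip(df.loc[bad, "variant_id"], reason[bad]):
        log.info("dropped %s: %s", vid, why)
    df = df[~bad].reset_index(drop=True)
    if df.empty:
        raise InputError(f"{path.name}: no valid records after validation")
    df["position"] = df["position"].astype(np.int64)

    # p-value vs z-score consistency check (warn only).
    z = np.abs(df["beta"] / df["se"])
    p_recomputed = 2.0 * stats.norm.sf(z)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = df["pvalue"].to_numpy() / p_recomputed
    inconsistent = np.isfinite(ratio) & ((ratio > 2.0) | (ratio < 0.5))
    if inconsistent.any():
        n_bad = int(inconsistent.sum())
        log.warning(
            "%s: %d record(s) with p-value off the two-sided-normal "
            "recomputation by more than a factor of 2 (kept)",
            path.name,
            n_bad,
        )

    return SummaryStatsTable(metadata=metadata, df=df)


def write_sumstats(table: SummaryStatsTable, path: str | Path) -> None:
    """Write a table as canonical tab-separated text (full float precision)."""
    table.df.to_csv(path, sep="\t", index=False)


def read_exclusion_list(path: str | Path) -> set[str]:
    """Read a variant exclusion list: one ID per line, '#' comments allowed."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise InputError(f"cannot read exclusion list {path}: {exc}") from exc
    ids: set[str] = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.add(line)
    return ids


class LDTable:
    """Pairwise LD (r-squared) lookups, symmetric, defaulting to 0.

    ``lookup(v, v)`` is 1 by definition; any pair absent from the table is
    treated as unlinked (r-squared 0), which makes the clumping stage usable
    with sparse LD extracts.
    """

    def __init__(self) -> None:
        self._r2: dict[tuple[str, str], float] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise InputError(f"r2 must be in [0,1], got {r2} for ({a}, {b})")
        self._r2[self._key(a, b)] = float(r2)

    def lookup(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    def entries(self) -> list[tuple[str, str, float]]:
        return [(a, b, r2) for (a, b), r2 in sorted(self._r2.items())]


def read_ld_table(path: str | Path) -> LDTable:
    """Read a three-column (id_a, id_b, r2) whitespace- or tab-separated file.

    A first line whose third field is not numeric is treated as a header.
    """
    path = Path(path)
    table = LDTable()
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise InputError(f"cannot read LD table {path}: {exc}") from exc
    first_data_line = True
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.replace(",", "\t").split()
        if len(fields) != 3:
            raise InputError(f"{path.name}:{lineno}: expected 3 fields, got {len(fields)}")
        a, b, r2_str = fields
        try:
            r2 = float(r2_str)
        except ValueError:
            if first_data_line:
                first_data_line = False
                continue  # header row
            raise InputError(f"{path.name}:{lineno}: r2 {r2_str!r} is not numeric") from None
        first_data_line = False
        if not 0.0 <= r2 <= 1.0:
            raise InputError(f"{path.name}:{lineno}: r2 {r2} outside [0,1]")
        table.add(a, b, r2)
    return table


def write_ld_table(table: LDTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tr2\n")
        for a, b, r2 in table.entries():
            fh.write(f"{a}\t{b}\t{r2}\n")
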