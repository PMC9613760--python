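"""Instrumental-variable selection from an exposure GWAS.

Selection proceeds in three stages, each returning a full audit of every
candidate variant: a strict genome-wide significance filter (p < 1e-6 by
default), greedy LD clumping (drop any candidate within 10 Mb of a more
significant retained SNP when their r-squared is >= 0.001), and a
user-supplied exclusion list for variants with suspected direct outcome
associations. Per-instrument strength is summarized by the F-statistic,
computed as the squared z-score (beta/se)^2 — per-SNP R-squared is not part
of the summary-statistics schema, so the (n-2) R^2 / (1 - R^2) form is not
available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .exceptions import AnalysisError
from .sumstats import LDTable, SummaryStatsTable

log = logging.getLogger(__name__)

RETAINED = "retained"
DROPPED_PVALUE = "dropped_pvalue"
DROPPED_EXCLUDED = "dropped_excluded"


def dropped_clump(index_snp: str) -> str:
    """Audit label for a variant clumped away by ``index_snp``."""
    return f"dropped_clump({index_snp})"


@dataclass
class InstrumentSet:
    """Ordered selection of instruments plus a complete audit trail.

    ``audit`` maps every candidate ever considered to its status
    (``retained``, ``dropped_pvalue``, ``dropped_clump(<index>)``,
    ``dropped_excluded``); ``selected`` lists retained variants in
    selection order; ``f_statistics`` covers the retained variants.
    """

    selected: list[str] = field(default_factory=list)
    f_statistics: dict[str, float] = field(default_factory=dict)
    audit: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.selected)

    def dropped(self) -> dict[str, str]:
        return {v: s for v, s in self.audit.items() if s != RETAINED}


def f_statistics(selected: list[str], table: SummaryStatsTable) -> dict[str, float]:
    """Per-instrument F-statistic, F_j = (beta_j / se_j)^2."""
    records = table.indexed()
    return {vid: (records[vid].beta / records[vid].se) ** 2 for vid in selected}


def filter_by_pvalue(table: SummaryStatsTable, threshold: float = 1e-6) -> InstrumentSet:
    """Retain variants with p-value strictly below ``threshold``.

    The boundary is exclusive: a record with p exactly equal to the
    threshold is dropped.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    selected: list[str] = []
    audit: dict[str, str] = {}
    for row in table.df.itertuples(index=False):
        vid = str(row.variant_id)
        if row.pvalue < threshold:
            selected.append(vid)
            audit[vid] = RETAINED
        else:
            audit[vid] = DROPPED_PVALUE
    return InstrumentSet(
        selected=selected,
        f_statistics=f_statistics(selected, table),
        audit=audit,
    )


def clump(
    candidates: InstrumentSet,
    table: SummaryStatsTable,
    ld: LDTable | None = None,
    r2_threshold: float = 0.001,
    window_kb: int = 10000,
) -> InstrumentSet:
    """Greedy LD clumping of the retained candidates.

    Candidates are processed in ascending p-value order (ties broken by
    chromosome, position, then variant ID, so the result is independent of
    input row order). Each index SNP removes every remaining candidate on
    the same chromosome within ``window_kb`` whose r-squared with it is at
    or above ``r2_threshold``. Pairs absent from the LD table count as
    unlinked.
    """
    ld = ld if ld is not None else LDTable()
    records = table.indexed()
    order = sorted(
        candidates.selected,
        key=lambda v: (
            records[v].pvalue,
            records[v].chromosome,
            records[v].position,
            v,
        ),
    )
    audit = dict(candidates.audit)
    retained: list[str] = []
    remaining = list(order)
    while remaining:
        index = remaining.pop(0)
        retained.append(index)
        irec = records[index]
        kept = []
        for vid in remaining:
            rec = records[vid]
            in_window = (
                rec.chromosome == irec.chromosome
                and abs(rec.position - irec.position) <= window_kb * 1000
            )
            if in_window and ld.lookup(index, vid) >= r2_threshold:
                audit[vid] = dropped_clump(index)
                log.info("clumped %s against index %s", vid, index)
            else:
                kept.append(vid)
        remaining = kept
    return InstrumentSet(
        selected=retained,
        f_statistics=f_statistics(retained, table),
        audit=audit,
    )


def apply_exclusions(candidates: InstrumentSet, exclusions: set[str]) -> InstrumentSet:
    """Remove listed variants (suspected direct outcome associations).

    Listing an ID not among the candidates is a warning, not an error. Pass
    an empty set to reproduce the no-exclusion sensitivity run.
    """
    audit = dict(candidates.audit)
    selected = []
    for vid in candidates.selected:
        if vid in exclusions:
            audit[vid] = DROPPED_EXCLUDED
            log.info("excluded %s (user exclusion list)", vid)
        else:
            selected.append(vid)
    for vid in exclusions - set(candidates.audit):
        log.warning("exclusion ID %s not among candidates; ignored", vid)
    return InstrumentSet(
        selected=selected,
        f_statistics={v: f for v, f in candidates.f_statistics.items() if v in selected},
        audit=audit,
    )


def select_instruments(
    table: SummaryStatsTable,
    ld: LDTable | None = None,
    exclusions: set[str] | None = None,
    pval_threshold: float = 1e-6,
    r2_threshold: float = 0.001,
    window_kb: int = 10000,
) -> InstrumentSet:
    """Full selection: significance filter, LD clumping, exclusion list."""
    candidates = filter_by_pvalue(table, pval_threshold)
    clumped = clump(candidates, table, ld, r2_threshold, window_kb)
    result = apply_exclusions(clumped, exclusions or set())
    if not result.selected:
        raise AnalysisError("no instruments survive selection")
    return result
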