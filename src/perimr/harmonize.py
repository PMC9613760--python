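"""Allele harmonization of outcome records against the exposure.

Two GWAS may report the same SNP with the roles of the two alleles swapped,
on opposite DNA strands, or both. Harmonization rewrites each outcome
record so its effect refers to the exposure's effect allele:

* swapped alleles  -> negate the outcome beta and complement its EAF;
* strand flip      -> relabel alleles via A<->T / C<->G (effect unchanged);
* both             -> apply both transformations.

Palindromic SNPs (A/T or C/G pairs) are strand-ambiguous from alleles
alone: orientation is inferred from allele-frequency concordance, and SNPs
whose frequency is too close to 0.5 to be informative (inside the
"intermediate" band, default [0.42, 0.58]) are dropped. A missing EAF on a
palindromic SNP also forces a drop — without a frequency the orientation is
unknowable. A strict mode drops every palindromic SNP regardless of
frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import AnalysisError
from .instruments import InstrumentSet
from .sumstats import SummaryStatsTable, VariantAssociation

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Drop reasons
MISSING_IN_OUTCOME = "missing_in_outcome"
ALLELE_MISMATCH = "allele_mismatch"
PALINDROMIC_INTERMEDIATE = "palindromic_intermediate"

#: Actions
ACTION_NONE = "none"
ACTION_SWAPPED = "swapped"
ACTION_FLIPPED = "strand_flipped"
ACTION_SWAPPED_FLIPPED = "swapped_and_flipped"

DEFAULT_INTERMEDIATE_BAND = (0.42, 0.58)


@dataclass(frozen=True)
class HarmonizedVariant:
    """Exposure/outcome effect pair aligned to a common effect allele."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf_x: float
    eaf_y: float
    action: str
    palindromic: bool


@dataclass
class HarmonizedDataset:
    """Surviving pairs plus the per-variant drop reasons."""

    pairs: list[HarmonizedVariant] = field(default_factory=list)
    dropped: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "variant_id",
            "effect_allele",
            "other_allele",
            "beta_x",
            "se_x",
            "beta_y",
            "se_y",
            "eaf_x",
            "eaf_y",
            "action",
            "palindromic",
        ]
        return pd.DataFrame([[getattr(p, c) for c in cols] for p in self.pairs], columns=cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HarmonizedDataset":
        pairs = [
            HarmonizedVariant(
                variant_id=str(r.variant_id),
                effect_allele=str(r.effect_allele),
                other_allele=str(r.other_allele),
                beta_x=float(r.beta_x),
                se_x=float(r.se_x),
                beta_y=float(r.beta_y),
                se_y=float(r.se_y),
                eaf_x=float(r.eaf_x),
                eaf_y=float(r.eaf_y),
                action=str(r.action),
                palindromic=bool(r.palindromic),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(pairs=pairs, dropped={})


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G} (strand-ambiguous)."""
    return _COMPLEMENT.get(effect_allele) == other_allele


def _is_intermediate(eaf: float, band: tuple[float, float]) -> bool:
    return pd.isna(eaf) or band[0] <= eaf <= band[1]


def harmonize_pair(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    intermediate_band: tuple[float, float] = DEFAULT_INTERMEDIATE_BAND,
    strict_palindromic: bool = False,
) -> HarmonizedVariant | str:
    """Align one outcome record to the exposure's effect allele.

    Returns the harmonized pair, or a drop-reason string
    (``palindromic_intermediate`` / ``allele_mismatch``). Resolution order:
    identical alleles, swapped alleles, strand complements (plain then
    swapped), palindromic frequency inference, irreconcilable.
    """
    if exposure.variant_id != outcome.variant_id:
        raise ValueError(
            f"variant_id mismatch: {exposure.variant_id} vs {outcome.variant_id}"
        )
    ea, oa = exposure.effect_allele, exposure.other_allele
    out_ea, out_oa = outcome.effect_allele, outcome.other_allele
    palindromic = is_palindromic(ea, oa)

    beta_y, eaf_y = outcome.beta, outcome.eaf
    if (out_ea, out_oa) == (ea, oa):
        action = ACTION_NONE
    elif (out_ea, out_oa) == (oa, ea):
        action = ACTION_SWAPPED
        beta_y = -beta_y
        eaf_y = 1.0 - eaf_y if pd.notna(eaf_y) else eaf_y
    elif not palindromic and (out_ea, out_oa) == (_COMPLEMENT[ea], _COMPLEMENT[oa]):
        action = ACTION_FLIPPED
    elif not palindromic and (out_ea, out_oa) == (_COMPLEMENT[oa], _COMPLEMENT[ea]):
        action = ACTION_SWAPPED_FLIPPED
        beta_y = -beta_y
        eaf_y = 1.0 - eaf_y if pd.notna(eaf_y) else eaf_y
    else:
        return ALLELE_MISMATCH

    if palindromic:
        if strict_palindromic:
            return PALINDROMIC_INTERMEDIATE
        if _is_intermediate(exposure.eaf, intermediate_band) or _is_intermediate(
            eaf_y, intermediate_band
        ):
            return PALINDROMIC_INTERMEDIATE
        # Orientation from frequency concordance: discordant sides of 0.5
        # mean the outcome record sits on the opposite strand.
        if (exposure.eaf < 0.5) != (eaf_y < 0.5):
            beta_y = -beta_y
            eaf_y = 1.0 - eaf_y
            action = ACTION_FLIPPED if action == ACTION_NONE else ACTION_SWAPPED_FLIPPED

    return HarmonizedVariant(
        variant_id=exposure.variant_id,
        effect_allele=ea,
        other_allele=oa,
        beta_x=exposure.beta,
        se_x=exposure.se,
        beta_y=beta_y,
        se_y=outcome.se,
        eaf_x=exposure.eaf,
        eaf_y=eaf_y,
        action=action,
        palindromic=palindromic,
    )


def harmonize_tables(
    instruments: InstrumentSet,
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    intermediate_band: tuple[float, float] = DEFAULT_INTERMEDIATE_BAND,
    strict_palindromic: bool = False,
) -> HarmonizedDataset:
    """Harmonize every selected instrument against the outcome table.

    Instruments absent from the outcome GWAS are recorded as
    ``missing_in_outcome``. Raises if nothing survives.
    """
    exp_records = exposure.indexed()
    out_records = outcome.indexed()
    result = HarmonizedDataset()
    for vid in instruments.selected:
        if vid not in out_records:
            result.dropped[vid] = MISSING_IN_OUTCOME
            log.info("dropped %s: %s", vid, MISSING_IN_OUTCOME)
            continue
        harmonized = harmonize_pair(
            exp_records[vid],
            out_records[vid],
            intermediate_band=intermediate_band,
            strict_palindromic=strict_palindromic,
        )
        if isinstance(harmonized, str):
            result.dropped[vid] = harmonized
            log.info("dropped %s: %s", vid, harmonized)
        else:
            result.pairs.append(harmonized)
            log.debug("harmonized %s: %s", vid, harmonized.action)
    if not result.pairs:
        raise AnalysisError("no harmonizable instruments")
    return result
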