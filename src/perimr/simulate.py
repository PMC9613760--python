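"""Synthetic paired GWAS summary statistics with known ground truth.

Generates an exposure table, an outcome table, an LD table and a truth
record so every pipeline stage (selection, harmonization, estimation,
diagnostics) can be exercised end-to-end without external downloads.

The statistical model generates summary statistics directly, without
individual-level genotypes. For SNP j with minor-allele frequency p_j:

* true instrument effect on the exposure  b_j ~ N(0, tau^2) (0 for null SNPs)
* exposure SE     se_Xj = 1 / sqrt(2 p_j (1-p_j) N_exposure)      (standardized
  continuous trait, large-sample approximation)
* observed        beta_Xj ~ N(b_j, se_Xj^2)
* outcome SE      se_Yj = 1 / sqrt(2 p_j (1-p_j) N_outcome K (1-K)), with K
  the outcome case fraction (logistic score-test approximation)
* direct (pleiotropic) effect a_j: 0, N(0, sd^2), or |N(0, sd^2)| depending
  on the pleiotropy mode
* observed        beta_Yj ~ N(theta * b_j + a_j, se_Yj^2)

where theta is the true causal log-odds per exposure unit. Default
parameters mirror the birth-weight-on-amblyopia setting: 18 instruments,
exposure GWAS of 262,966, binary outcome GWAS of 862 cases / 416,168
controls, theta = -0.73.

To exercise harmonization, every even-indexed outcome record is stored with
its alleles swapped (beta negated, EAF complemented), and a configurable
fraction of SNPs receive palindromic (A/T or C/G) allele pairs. LD blocks
are groups of co-located SNPs (within 1 Mb) assigned a constant pairwise
r-squared; all other pairs are unlinked.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .sumstats import LDTable, StudyMetadata, SummaryStatsTable, write_ld_table, write_sumstats

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_NONPALINDROMIC_PAIRS = [
    (x, y)
    for x in "ACGT"
    for y in "ACGT"
    if x != y and _COMPLEMENT[x] != y
]  # 8 ordered pairs

_TINY_P = 5e-324  # smallest positive float; keeps p-values inside (0, 1]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic summary-statistics generator.

    Defaults reproduce the scale of the birth-weight analysis: 18 true
    instruments plus a background of null SNPs, a strong protective causal
    effect, and a heavily imbalanced binary outcome.
    """

    n_instruments: int = 18
    n_null_snps: int = 100
    theta: float = -0.73
    tau: float = 0.02
    n_exposure: int = 262966
    n_cases: int = 862
    n_controls: int = 416168
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_ld_blocks: int = 0
    ld_block_size: int = 3
    ld_r2: float = 0.3
    palindromic_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instruments < 1:
            raise ConfigurationError("n_instruments must be >= 1")
        if self.n_null_snps < 0:
            raise ConfigurationError("n_null_snps must be >= 0")
        if not self.tau > 0:
            raise ConfigurationError("tau must be > 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigurationError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_mode != "none" and not self.pleiotropy_sd > 0:
            raise ConfigurationError("pleiotropy_sd must be > 0 for balanced/directional modes")
        if not 0.0 <= self.palindromic_fraction <= 1.0:
            raise ConfigurationError("palindromic_fraction must be in [0,1]")
        if self.n_ld_blocks < 0 or not 0.0 <= self.ld_r2 <= 1.0:
            raise ConfigurationError("invalid LD block settings")
        if self.n_ld_blocks * self.ld_block_size > self.n_snps:
            raise ConfigurationError("LD blocks require more SNPs than configured")
        if min(self.n_exposure, self.n_cases, self.n_controls) < 1:
            raise ConfigurationError("sample sizes must be positive")

    @property
    def n_snps(self) -> int:
        return self.n_instruments + self.n_null_snps


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset, for recovery tests."""

    theta: float
    beta_exposure: list[float]  # true per-SNP instrument effects b_j
    pleiotropy: list[float]  # direct effects a_j
    is_instrument: list[bool]
    outcome_swapped: list[bool]  # allele swap applied to the outcome record
    variant_ids: list[str]
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        return cls(**json.loads(Path(path).read_text()))


def _positions(config: SimulationConfig) -> tuple[list[str], list[int], list[int]]:
    """Assign (chromosome, position) and block labels.

    Independent SNPs are spread 25 Mb apart cycling chromosomes 1-22 so no
    pair falls inside a clumping window. LD-block members (the last
    ``n_ld_blocks * ld_block_size`` SNPs) are co-located within 1 Mb at a
    distant coordinate on their block's chromosome.
    """
    n = config.n_snps
    chrom = [""] * n
    pos = [0] * n
    block_id = [-1] * n
    n_block_snps = config.n_ld_blocks * config.ld_block_size
    n_free = n - n_block_snps
    for i in range(n_free):
        chrom[i] = str(i % 22 + 1)
        pos[i] = 1_000_000 + 25_000_000 * (i // 22)
    for j in range(n_block_snps):
        b = j // config.ld_block_size
        within = j % config.ld_block_size
        i = n_free + j
        chrom[i] = str(b % 22 + 1)
        pos[i] = 600_000_000 + 50_000_000 * (b // 22) + 100_000 * within
        block_id[i] = b
    return chrom, pos, block_id


def simulate_summary_stats(
    config: SimulationConfig,
) -> tuple[SummaryStatsTable, SummaryStatsTable, LDTable, SimulationTruth]:
    """Generate paired exposure/outcome tables, an LD table and the truth.

    Identical configurations (including seed) produce identical output. The
    instrument SNPs occupy the first ``n_instruments`` rows of both tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_snps

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=n)
    is_instr = np.arange(n) < config.n_instruments
    # Draw latent effects for every SNP so the stream layout does not depend
    # on the instrument/null split.
    b = rng.normal(0.0, config.tau, size=n) * is_instr

    se_x = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exposure)
    beta_x = b + rng.normal(size=n) * se_x

    n_outcome = config.n_cases + config.n_controls
    k = config.n_cases / n_outcome
    se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_outcome * k * (1.0 - k))
    raw_pleio = rng.normal(0.0, config.pleiotropy_sd or 1.0, size=n)
    if config.pleiotropy_mode == "none":
        a = np.zeros(n)
    elif config.pleiotropy_mode == "balanced":
        a = raw_pleio
    else:  # directional
        a = np.abs(raw_pleio)
    beta_y = config.theta * b + a + rng.normal(size=n) * se_y

    p_x = np.maximum(2.0 * stats.norm.sf(np.abs(beta_x / se_x)), _TINY_P)
    p_y = np.maximum(2.0 * stats.norm.sf(np.abs(beta_y / se_y)), _TINY_P)

    # Allele pairs: a random subset is palindromic (A/T or C/G).
    n_pal = int(round(config.palindromic_fraction * n))
    pal_idx = set(rng.choice(n, size=n_pal, replace=False).tolist())
    effect = [""] * n
    other = [""] * n
    for i in range(n):
        pool = _PALINDROMIC_PAIRS if i in pal_idx else _NONPALINDROMIC_PAIRS
        effect[i], other[i] = pool[int(rng.integers(len(pool)))]

    chrom, pos, block_id = _positions(config)
    variant_ids = [f"rs{i + 1}" for i in range(n)]

    exposure_df = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chromosome": chrom,
            "position": pos,
            "effect_allele": effect,
            "other_allele": other,
            "eaf": maf,
            "beta": beta_x,
            "se": se_x,
            "pvalue": p_x,
        }
    )

    # Outcome records: every even-indexed SNP is stored with swapped alleles
    # (beta negated, EAF complemented) to exercise harmonization.
    swapped = (np.arange(n) % 2) == 0
    out_effect = [other[i] if swapped[i] else effect[i] for i in range(n)]
    out_other = [effect[i] if swapped[i] else other[i] for i in range(n)]
    outcome_df = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chromosome": chrom,
            "position": pos,
            "effect_allele": out_effect,
            "other_allele": out_other,
            "eaf": np.where(swapped, 1.0 - maf, maf),
            "beta": np.where(swapped, -beta_y, beta_y),
            "se": se_y,
            "pvalue": p_y,
        }
    )

    ld = LDTable()
    for bidx in range(config.n_ld_blocks):
        members = [i for i in range(n) if block_id[i] == bidx]
        for ii in range(len(members)):
            for jj in range(ii + 1, len(members)):
                ld.add(variant_ids[members[ii]], variant_ids[members[jj]], config.ld_r2)

    exposure = SummaryStatsTable(
        metadata=StudyMetadata("exposure", "continuous", config.n_exposure),
        df=exposure_df,
    )
    outcome = SummaryStatsTable(
        metadata=StudyMetadata(
            "outcome", "binary", n_outcome, n_cases=config.n_cases, n_controls=config.n_controls
        ),
        df=outcome_df,
    )
    truth = SimulationTruth(
        theta=config.theta,
        beta_exposure=b.tolist(),
        pleiotropy=a.tolist(),
        is_instrument=is_instr.tolist(),
        outcome_swapped=swapped.tolist(),
        variant_ids=variant_ids,
        seed=config.seed,
    )
    return exposure, outcome, ld, truth


def write_simulation(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[Path, Path, Path, Path]:
    """Run the generator and write exposure.tsv, outcome.tsv, ld.tsv, truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    exposure, outcome, ld, truth = simulate_summary_stats(config)
    paths = (
        out_dir / "exposure.tsv",
        out_dir / "outcome.tsv",
        out_dir / "ld.tsv",
        out_dir / "truth.json",
    )
    write_sumstats(exposure, paths[0])
    write_sumstats(outcome, paths[1])
    write_ld_table(ld, paths[2])
    truth.to_json(paths[3])
    return paths
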