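"""End-to-end orchestration: simulate/load -> select -> harmonize -> mr -> power.

A single run configuration (YAML or dict) drives the whole analysis and
every stage writes a machine-readable artifact:

* instruments.tsv   variant_id, F, status, index_snp
* harmonized.tsv    one row per harmonized pair (including the action taken)
* dropped.tsv       variants removed at harmonization, with reasons
* results.tsv       Exposure / Method / Number of SNP / Beta / SE / p value
* scatter-export.tsv  per-SNP (beta_x, se_x, beta_y, se_y) for scatter plots
* report.json       full-precision estimates, diagnostics, power, audit,
                    stage counts, config echo, seed, package version

The global seed feeds each randomized stage through an independent derived
stream keyed by the stage name, so adding or re-running one stage never
perturbs another stage's randomness. Identical config + seed gives a
byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .estimators import MREstimate, DiagnosticResult, run_all_methods, wald_ratios
from .exceptions import AnalysisError, ConfigurationError
from .harmonize import DEFAULT_INTERMEDIATE_BAND, HarmonizedDataset, harmonize_tables
from .instruments import InstrumentSet, select_instruments
from .power import PowerInput, PowerResult, binary_outcome_power
from .simulate import SimulationConfig, simulate_summary_stats
from .sumstats import (
    LDTable,
    StudyMetadata,
    SummaryStatsTable,
    read_exclusion_list,
    read_ld_table,
    read_sumstats,
    write_sumstats,
)

log = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Derive an independent per-stage seed from the global seed.

    Uses a CRC32 of the stage name so streams are stable across runs and
    insensitive to stage ordering.
    """
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class IOConfig:
    """Paths and metadata for real (non-simulated) inputs."""

    exposure: str
    outcome: str
    ld: str | None = None
    exclusions: str | None = None
    exposure_metadata: dict[str, Any] = field(default_factory=dict)
    outcome_metadata: dict[str, Any] = field(default_factory=dict)
    column_map: dict[str, str] | None = None


@dataclass
class SelectionConfig:
    pval_threshold: float = 1e-6
    r2: float = 0.001
    window_kb: int = 10000
    no_exclude: bool = False
    exclude_ids: list[str] = field(default_factory=list)


@dataclass
class HarmonizationConfig:
    intermediate_band: tuple[float, float] = DEFAULT_INTERMEDIATE_BAND
    strict_palindromic: bool = False


@dataclass
class MRConfig:
    n_boot: int = 1000
    floor_dispersion: bool = False
    level: float = 0.95


@dataclass
class PowerConfig:
    r_squared: float = 0.053
    alpha: float = 0.05
    odds_ratio: float | None = None  # default: exp(IVW random-effects beta)


@dataclass
class RunConfig:
    """Full pipeline configuration. Exactly one of ``io`` / ``simulate``."""

    out_dir: str
    seed: int = 0
    io: IOConfig | None = None
    simulate: SimulationConfig | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    harmonization: HarmonizationConfig = field(default_factory=HarmonizationConfig)
    mr: MRConfig = field(default_factory=MRConfig)
    power: PowerConfig = field(default_factory=PowerConfig)

    def __post_init__(self) -> None:
        if (self.io is None) == (self.simulate is None):
            raise ConfigurationError(
                "config must contain exactly one of an 'io' section or a 'simulate' section"
            )

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        io = d.pop("io", None)
        sim = d.pop("simulate", None)
        kwargs: dict[str, Any] = {
            "out_dir": d.pop("out_dir"),
            "seed": int(d.pop("seed", 0)),
        }
        if io is not None:
            kwargs["io"] = IOConfig(**io)
        if sim is not None:
            sim = dict(sim)
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            kwargs["simulate"] = SimulationConfig(**sim)
        for name, klass in (
            ("selection", SelectionConfig),
            ("harmonization", HarmonizationConfig),
            ("mr", MRConfig),
            ("power", PowerConfig),
        ):
            if name in d:
                section = dict(d.pop(name))
                if name == "harmonization" and "intermediate_band" in section:
                    section["intermediate_band"] = tuple(section["intermediate_band"])
                kwargs[name] = klass(**section)
        if d:
            raise ConfigurationError(f"unknown config sections: {sorted(d)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunReport:
    """Everything one run computed, plus the audit needed to reproduce it."""

    version: str
    seed: int
    config: dict[str, Any]
    counts: dict[str, int]
    instrument_audit: dict[str, str]
    f_statistics: dict[str, float]
    estimates: list[dict[str, Any]]
    diagnostics: dict[str, Any]
    power: dict[str, Any] | None
    harmonization_dropped: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _serialize_config(config: RunConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)

    def clean(obj: Any) -> Any:
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        return obj

    return clean(d)


def _load_inputs(
    config: RunConfig,
) -> tuple[SummaryStatsTable, SummaryStatsTable, LDTable, set[str]]:
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=stage_seed(config.seed, "simulate"))
        exposure, outcome, ld, _truth = simulate_summary_stats(sim)
        exclusions = set(config.selection.exclude_ids)
        return exposure, outcome, ld, exclusions
    io = config.io
    assert io is not None
    exp_meta = StudyMetadata(**io.exposure_metadata) if io.exposure_metadata else None
    out_meta = StudyMetadata(**io.outcome_metadata) if io.outcome_metadata else None
    exposure = read_sumstats(io.exposure, exp_meta, column_map=io.column_map)
    outcome = read_sumstats(io.outcome, out_meta, column_map=io.column_map)
    ld = read_ld_table(io.ld) if io.ld else LDTable()
    exclusions = set(config.selection.exclude_ids)
    if io.exclusions:
        exclusions |= read_exclusion_list(io.exclusions)
    return exposure, outcome, ld, exclusions


def write_instruments_tsv(instruments: InstrumentSet, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\tF\tstatus\tindex_snp\n")
        for vid in sorted(instruments.audit):
            status = instruments.audit[vid]
            index_snp = ""
            if status.startswith("dropped_clump("):
                index_snp = status[len("dropped_clump(") : -1]
                status = "dropped_clump"
            f_val = instruments.f_statistics.get(vid, "")
            fh.write(f"{vid}\t{f_val}\t{status}\t{index_snp}\n")


def write_results_tsv(exposure_name: str, estimates: list[MREstimate], path: Path) -> None:
    """Write pooled estimates shaped like a summary results table."""
    pretty = {
        "ivw_random": "IVW (random effect)",
        "ivw_fixed": "IVW (fixed effect)",
        "simple_median": "Simple median",
        "weighted_median": "Weighted median",
        "egger_slope": "MR-Egger",
    }
    with open(path, "w") as fh:
        fh.write("Exposure\tMethod\tNumber of SNP\tBeta\tSE\tp value\n")
        for est in estimates:
            fh.write(
                f"{exposure_name}\t{pretty.get(est.method, est.method)}\t{est.n_snp}\t"
                f"{est.beta}\t{est.se}\t{est.pvalue}\n"
            )


def write_scatter_tsv(data: HarmonizedDataset, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\tbeta_x\tse_x\tbeta_y\tse_y\n")
        for p in data.pairs:
            fh.write(f"{p.variant_id}\t{p.beta_x}\t{p.se_x}\t{p.beta_y}\t{p.se_y}\n")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages; write artifacts into ``config.out_dir``.

    Any stage failure aborts with the stage name and cause, and removes
    partial outputs from the output directory.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load"
    try:
        exposure, outcome, ld, exclusions = _load_inputs(config)
        n_input = len(exposure)

        stage = "select"
        sel = config.selection
        instruments = select_instruments(
            exposure,
            ld=ld,
            exclusions=set() if sel.no_exclude else exclusions,
            pval_threshold=sel.pval_threshold,
            r2_threshold=sel.r2,
            window_kb=sel.window_kb,
        )
        path = out_dir / "instruments.tsv"
        write_instruments_tsv(instruments, path)
        written.append(path)

        stage = "harmonize"
        harmonized = harmonize_tables(
            instruments,
            exposure,
            outcome,
            intermediate_band=config.harmonization.intermediate_band,
            strict_palindromic=config.harmonization.strict_palindromic,
        )
        path = out_dir / "harmonized.tsv"
        harmonized.to_frame().to_csv(path, sep="\t", index=False)
        written.append(path)
        path = out_dir / "dropped.tsv"
        with open(path, "w") as fh:
            fh.write("variant_id\treason\n")
            for vid in sorted(harmonized.dropped):
                fh.write(f"{vid}\t{harmonized.dropped[vid]}\n")
        written.append(path)

        stage = "mr"
        estimates, diagnostics = run_all_methods(
            harmonized,
            n_boot=config.mr.n_boot,
            seed=stage_seed(config.seed, "mr"),
            level=config.mr.level,
            floor_dispersion=config.mr.floor_dispersion,
        )
        exposure_name = exposure.metadata.trait_name if exposure.metadata else "exposure"
        path = out_dir / "results.tsv"
        write_results_tsv(exposure_name, estimates, path)
        written.append(path)
        path = out_dir / "scatter-export.tsv"
        write_scatter_tsv(harmonized, path)
        written.append(path)

        stage = "power"
        power_result = None
        meta = outcome.metadata
        if meta is not None and meta.trait_type == "binary":
            or_ = config.power.odds_ratio
            if or_ is None:
                ivw_random = next(e for e in estimates if e.method == "ivw_random")
                or_ = float(np.exp(ivw_random.beta))
            power_result = binary_outcome_power(
                PowerInput(
                    n_total=meta.n_total,
                    case_fraction=meta.case_fraction,
                    odds_ratio=or_,
                    r_squared=config.power.r_squared,
                    alpha=config.power.alpha,
                )
            )

        stage = "report"
        n_ratios = len(wald_ratios(harmonized))
        counts = {
            "input_variants": n_input,
            "selected_instruments": len(instruments),
            "dropped_selection": len(instruments.dropped()),
            "harmonized_pairs": len(harmonized),
            "dropped_harmonization": len(harmonized.dropped),
            "ratio_estimates": n_ratios,
        }
        report = RunReport(
            version=__version__,
            seed=config.seed,
            config=_serialize_config(config),
            counts=counts,
            instrument_audit=dict(sorted(instruments.audit.items())),
            f_statistics={k: instruments.f_statistics[k] for k in sorted(instruments.f_statistics)},
            estimates=[dataclasses.asdict(e) for e in estimates],
            diagnostics=dataclasses.asdict(diagnostics),
            power=dataclasses.asdict(power_result) if power_result else None,
            harmonization_dropped=dict(sorted(harmonized.dropped.items())),
        )
        path = out_dir / "report.json"
        path.write_text(report.to_json())
        written.append(path)
        return report
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise AnalysisError(f"pipeline stage '{stage}' failed: {exc}") from exc
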