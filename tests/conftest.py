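import pandas as pd
import pytest

from perimr import (
    InstrumentSet,
    SimulationConfig,
    StudyMetadata,
    SummaryStatsTable,
    harmonize_tables,
    simulate_summary_stats,
)
from perimr.sumstats import CANONICAL_COLUMNS


def make_table(rows, metadata=None):
    """Build a SummaryStatsTable from a list of row dicts (canonical columns)."""
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    return SummaryStatsTable(metadata=metadata, df=df)


def make_row(variant_id, chromosome="1", position=1_000_000, effect_allele="A",
             other_allele="G", eaf=0.3, beta=0.1, se=0.02, pvalue=None):
    if pvalue is None:
        from scipy import stats
        pvalue = float(2 * stats.norm.sf(abs(beta / se)))
    return dict(variant_id=variant_id, chromosome=chromosome, position=position,
                effect_allele=effect_allele, other_allele=other_allele,
                eaf=eaf, beta=beta, se=se, pvalue=pvalue)


def all_instruments(table):
    """An InstrumentSet treating every table row as retained."""
    ids = table.variant_ids
    return InstrumentSet(selected=ids, audit={v: "retained" for v in ids})


def harmonized_sim(seed=1, **overrides):
    """Simulate, harmonize all instruments, return (dataset, truth)."""
    params = dict(n_instruments=18, n_null_snps=0, seed=seed)
    params.update(overrides)
    config = SimulationConfig(**params)
    exposure, outcome, ld, truth = simulate_summary_stats(config)
    data = harmonize_tables(all_instruments(exposure), exposure, outcome)
    return data, truth


@pytest.fixture
def small_sim():
    """A paper-scale simulated dataset (18 instruments, no null SNPs)."""
    config = SimulationConfig(n_instruments=18, n_null_snps=0, seed=7)
    return simulate_summary_stats(config)


@pytest.fixture
def binary_metadata():
    return StudyMetadata("amblyopia", "binary", 417030, n_cases=862, n_controls=416168)
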