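"""Shared fixtures: synthetic datasets at two scales.

The small dataset exercises the full pipeline quickly; the large null and
planted datasets back the calibration and signal-recovery checks.
"""

from __future__ import annotations

import pytest

from faerskit import cohort, ingest
from faerskit.synth import (
    DrugSpec,
    PlantedSignal,
    PtSpec,
    SyntheticConfig,
    emit_quarterly_files,
    generate_reports,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_reports=2000, seed=1)


@pytest.fixture(scope="session")
def small_dataset(small_config, tmp_path_factory):
    """Generated + emitted + re-ingested small dataset with ground truth."""
    reports, truth = generate_reports(small_config)
    directory = tmp_path_factory.mktemp("small_quarter")
    emit_quarterly_files(reports, directory)
    records, tallies = ingest.read_reports(directory)
    return {
        "config": small_config,
        "generated": reports,
        "truth": truth,
        "directory": directory,
        "records": records,
        "tallies": tallies,
    }


@pytest.fixture(scope="session")
def etoposide_query() -> cohort.DrugQuery:
    return cohort.DrugQuery.from_names(
        ["ETOPOSIDE", "VP-16", "LASTET", "TOPOSAR", "VEPESID", "CELLTOP"]
    )


@pytest.fixture(scope="session")
def null_dataset():
    """20k reports with no planted associations (lambda = 1 everywhere)."""
    cfg = SyntheticConfig(
        n_reports=20000,
        planted_signals=[],
        p_duplicate_case=0.0,
        p_missing_event_date=0.0,
        p_invalid_date=0.0,
        p_indication_as_reaction=0.0,
        seed=11,
    )
    reports, truth = generate_reports(cfg)
    return {"config": cfg, "reports": reports, "truth": truth}


@pytest.fixture(scope="session")
def planted_dataset():
    """20k reports with one rare drug carrying a lambda = 10 signal.

    The target drug is kept rare (3% of reports) so the planted relative
    reporting ratio is only mildly diluted by the drug's own share of the
    database, making lambda recoverable from the observed/expected ratio.
    """
    cfg = SyntheticConfig(
        n_reports=20000,
        drug_catalog=[
            DrugSpec("TARGETDRUG", 0.03),
            DrugSpec("COMPARATOR_A", 0.40),
            DrugSpec("COMPARATOR_B", 0.40),
            DrugSpec("COMPARATOR_C", 0.30),
        ],
        pt_catalog=[
            PtSpec("Planted event", "SOC one", 0.010),
            PtSpec("Background event 1", "SOC one", 0.100),
            PtSpec("Background event 2", "SOC one", 0.200),
            PtSpec("Background event 3", "SOC two", 0.300),
            PtSpec("Background event 4", "SOC two", 0.150),
        ],
        planted_signals=[PlantedSignal("TARGETDRUG", "Planted event", 10.0)],
        p_duplicate_case=0.0,
        p_indication_as_reaction=0.0,
        seed=5,
    )
    reports, truth = generate_reports(cfg)
    return {"config": cfg, "reports": reports, "truth": truth}
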