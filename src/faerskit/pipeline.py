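"""End-to-end pipeline: ingest -> cohort -> signals -> TTO -> strata.

All deliverables are flat CSV/JSON files.  Estimator tables are written at
full precision plus a rendered copy rounded to the conventional precision
(2 decimals for estimators, 1 for percentages).  A run manifest records
input hashes, the configuration, package versions and every exclusion
tally so the report flow reconciles from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cohort, disprop, ingest, strata, tto

log = logging.getLogger(__name__)

DEFAULT_DRUG_NAMES = ("ETOPOSIDE", "VP-16", "LASTET", "TOPOSAR", "VEPESID", "CELLTOP")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    data_dir: str
    out_dir: str
    drug_names: tuple[str, ...] = DEFAULT_DRUG_NAMES
    roles: tuple[str, ...] = ("PS",)
    pt_soc_map: str | None = None
    label_pts: str | None = None
    indication_list: str = "auto"  # "auto" or a path to one-PT-per-line file
    min_cases: int = 3
    rank_min_a: int = 30
    stratifications: tuple[str, ...] = ("age", "weight", "sex", "reporter")
    years: tuple[int, int] = (2004, 2022)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("drug_names", "roles", "stratifications", "years"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def _rendered(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(2)
    return out


def run_pipeline(config: PipelineConfig, stages: set[str] | None = None) -> dict:
    """Execute the pipeline and write all deliverable tables.

    ``stages`` optionally restricts output production to a subset of
    {"report", "signals", "tto", "strata"}; ingestion and cohort
    identification always run.  Any stage failure raises
    :class:`PipelineError` naming the stage, and partially written outputs
    are removed.
    """
    stages = stages or {"report", "signals", "tto", "strata"}
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "versions": {
            "faerskit": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "inputs": {},
        "tallies": {},
    }

    def emit(df: pd.DataFrame, name: str, rendered: bool = False) -> None:
        path = out_dir / name
        _write_csv(df, path)
        written.append(path)
        if rendered:
            rpath = out_dir / name.replace(".csv", "_rendered.csv")
            _write_csv(_rendered(df), rpath)
            written.append(rpath)

    current_stage = "ingest"
    try:
        data_dir = Path(config.data_dir)
        for name in ingest.TABLE_COLUMNS:
            path = data_dir / f"{name}.txt"
            if path.exists():
                manifest["inputs"][path.name] = _sha256(path)
        reports, tallies = ingest.read_reports(config.data_dir)
        manifest["tallies"].update(tallies)
        manifest["tallies"]["reports_deduplicated"] = len(reports)

        current_stage = "cohort"
        query = cohort.DrugQuery.from_names(config.drug_names, roles=config.roles)
        targets = cohort.identify_drug_reports(reports, query)
        manifest["tallies"]["target_reports"] = len(targets)

        if config.pt_soc_map is None:
            raise FileNotFoundError("pt_soc_map is required (path to PT,SOC csv)")
        soc_map = cohort.PtSocMap.from_csv(config.pt_soc_map)

        pairs = cohort.build_pair_database(reports, query)
        if config.indication_list == "auto":
            indication_set = cohort.derive_indication_set(targets)
        else:
            with open(config.indication_list, encoding="utf-8") as fh:
                indication_set = {line.strip() for line in fh if line.strip()}
        pairs, n_excluded = cohort.exclude_indications(pairs, indication_set)
        pairs = soc_map.annotate(pairs)
        manifest["tallies"]["pairs_total"] = len(pairs)
        manifest["tallies"]["pairs_target"] = int(pairs["target"].sum())
        manifest["tallies"]["indication_pairs_excluded"] = n_excluded

        if "report" in stages:
            current_stage = "report"
            emit(cohort.demographics_summary(targets), "demographics.csv")
            annual = cohort.annual_counts(targets, *config.years)
            emit(annual.reset_index(), "annual_counts.csv")

        if "signals" in stages:
            current_stage = "signals"
            pt_table = disprop.pt_signal_table(pairs, min_cases=config.min_cases)
            significant = disprop.screen_signals(pt_table)
            if config.label_pts:
                label = disprop.load_label_pts(config.label_pts)
                significant = disprop.flag_unexpected(significant, label)
            ranked = disprop.rank_and_filter(significant, min_a=config.rank_min_a)
            soc_table = disprop.soc_level_signals(pairs, min_cases=config.min_cases)
            emit(pt_table, "signals_pt_full.csv", rendered=True)
            emit(significant, "signals_pt_significant.csv", rendered=True)
            emit(ranked, "signals_pt_ranked.csv", rendered=True)
            emit(soc_table, "signals_soc.csv", rendered=True)
            manifest["tallies"]["pts_tested"] = len(pt_table)
            manifest["tallies"]["pts_significant"] = len(significant)

        if "tto" in stages:
            current_stage = "tto"
            sample = tto.compute_tto(targets, query)
            manifest["tallies"]["tto_retained"] = sample.n
            manifest["tallies"]["tto_excluded_missing"] = sample.n_excluded_missing
            manifest["tallies"]["tto_excluded_invalid"] = sample.n_excluded_invalid
            manifest["tallies"]["tto_excluded_negative"] = sample.n_excluded_negative
            emit(pd.DataFrame({"delay_days": sample.values}), "tto_delays.csv")
            bins = tto.bin_tto(sample)
            emit(bins, "tto_bins.csv")
            summary = tto.summarize_tto(sample)
            tto_out: dict = {"summary": dataclasses.asdict(summary)}
            if sample.n >= 30 and len(np.unique(sample.values)) > 1:
                fit = tto.fit_weibull(sample)
                tto_out["weibull"] = dataclasses.asdict(fit)
                tto_out["failure_type"] = tto.classify_failure(fit)
            path = out_dir / "tto_summary.json"
            path.write_text(json.dumps(tto_out, indent=2) + "\n")
            written.append(path)

        if "strata" in stages:
            current_stage = "strata"
            for var in config.stratifications:
                spec = strata.StratumSpec(var)
                per_level = strata.subgroup_signals(
                    reports, query, spec, min_cases=config.min_cases
                )
                for lvl, tables in per_level.items():
                    safe = lvl.replace("<", "lt").replace(">", "gt").replace(" ", "_")
                    emit(tables["top"], f"subgroup_{var}_{safe}.csv")
            gender = strata.gender_disproportionality(targets, min_cases=config.min_cases)
            volcano = strata.volcano_coordinates(gender)
            emit(gender, "gender_signals.csv", rendered=True)
            emit(volcano, "gender_volcano.csv")
            manifest["tallies"]["gender_pts_tested"] = len(gender)

        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(manifest_path)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage {current_stage!r} failed: {exc}") from exc

    return {"manifest": manifest, "outputs": [str(p) for p in written]}
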