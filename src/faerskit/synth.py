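"""Synthetic FAERS-like data with planted ground truth.

The generator emulates the structure of spontaneous-report extracts: one
demographic row per report version, multiple drug rows with role codes and
free-text name variants, multiple reaction PTs per report, therapy start
dates, indication PTs and outcome codes.  Drug-event associations are
planted as relative reporting ratios (lambda): in a report containing the
planted drug, the event's occurrence probability is lambda times its
baseline (capped at 1).  Event onset lags after therapy start follow a
Weibull distribution.  Duplicate case versions, missing event dates and
partial (truncated) dates are injected at configurable rates, and the
intended deduplication survivor of every case is recorded as ground truth
so the ingest stage can be checked exactly.
"""

from __future__ import annotations

import copy
import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .records import DrugEntry, ReportRecord, TherapyEntry

log = logging.getLogger(__name__)

_EPOCH = datetime.date(1970, 1, 1)


def _date_str(ordinal: int) -> str:
    return datetime.date.fromordinal(ordinal).strftime("%Y%m%d")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class DrugSpec:
    """A catalog drug with its per-report inclusion probability."""

    name: str
    p_include: float


@dataclass
class PtSpec:
    """A catalog event term: PT name, its SOC, baseline per-report
    occurrence probability, and whether the term appears on the (synthetic)
    product label -- used downstream for novelty flagging."""

    pt: str
    soc: str
    p_base: float
    labeled: bool = False


@dataclass
class PlantedSignal:
    """A planted drug-event association.

    ``lam`` multiplies the event's baseline probability in reports
    containing the drug.  ``stratum`` optionally restricts the effect to one
    subgroup level (e.g. ``("age", "<18")``); ``female_multiplier`` further
    scales the probability in female patients, for sex-difference analyses.
    """

    drug: str
    pt: str
    lam: float
    stratum: tuple[str, str] | None = None
    female_multiplier: float = 1.0


def _default_drug_catalog() -> list[DrugSpec]:
    return [
        DrugSpec("ETOPOSIDE", 0.10),
        DrugSpec("CISPLATIN", 0.20),
        DrugSpec("CARBOPLATIN", 0.15),
        DrugSpec("CYCLOPHOSPHAMIDE", 0.15),
        DrugSpec("DOXORUBICIN", 0.15),
        DrugSpec("PACLITAXEL", 0.20),
        DrugSpec("FILGRASTIM", 0.15),
        DrugSpec("ONDANSETRON", 0.25),
        DrugSpec("DEXAMETHASONE", 0.25),
        DrugSpec("ASPIRIN", 0.10),
    ]


_SOC_BLOOD = "Blood and lymphatic system disorders"
_SOC_INF = "Infections and infestations"
_SOC_GI = "Gastrointestinal disorders"
_SOC_GEN = "General disorders and administration site conditions"
_SOC_RESP = "Respiratory, thoracic and mediastinal disorders"
_SOC_NERV = "Nervous system disorders"
_SOC_REPRO = "Reproductive system and breast disorders"
_SOC_META = "Metabolism and nutrition disorders"


def _default_pt_catalog() -> list[PtSpec]:
    # Baselines sum to ~3 so reports carry ~3 reactions on average, the
    # density seen in large spontaneous-report databases.
    return [
        PtSpec("Febrile neutropenia", _SOC_BLOOD, 0.005, labeled=True),
        PtSpec("Pancytopenia", _SOC_BLOOD, 0.004, labeled=True),
        PtSpec("Thrombocytopenia", _SOC_BLOOD, 0.010, labeled=True),
        PtSpec("Neutropenia", _SOC_BLOOD, 0.012, labeled=True),
        PtSpec("Leukopenia", _SOC_BLOOD, 0.008, labeled=True),
        PtSpec("Anaemia", _SOC_BLOOD, 0.030, labeled=True),
        PtSpec("Myelosuppression", _SOC_BLOOD, 0.003, labeled=True),
        PtSpec("Thrombotic microangiopathy", _SOC_BLOOD, 0.0008),
        PtSpec("Sepsis", _SOC_INF, 0.015),
        PtSpec("Septic shock", _SOC_INF, 0.006),
        PtSpec("Pneumonia", _SOC_INF, 0.060, labeled=True),
        PtSpec("Neutropenic sepsis", _SOC_INF, 0.002),
        PtSpec("Aspergillus infection", _SOC_INF, 0.001),
        PtSpec("Urinary tract infection", _SOC_INF, 0.030),
        PtSpec("Nausea", _SOC_GI, 0.200, labeled=True),
        PtSpec("Vomiting", _SOC_GI, 0.150, labeled=True),
        PtSpec("Diarrhoea", _SOC_GI, 0.120, labeled=True),
        PtSpec("Stomatitis", _SOC_GI, 0.015, labeled=True),
        PtSpec("Oesophagitis", _SOC_GI, 0.003, labeled=True),
        PtSpec("Fatigue", _SOC_GEN, 0.250, labeled=True),
        PtSpec("Pyrexia", _SOC_GEN, 0.120, labeled=True),
        PtSpec("Mucosal inflammation", _SOC_GEN, 0.006, labeled=True),
        PtSpec("Multiple organ dysfunction syndrome", _SOC_GEN, 0.003),
        PtSpec("Drug resistance", _SOC_GEN, 0.004),
        PtSpec("Death", _SOC_GEN, 0.100),
        PtSpec("Pneumonitis", _SOC_RESP, 0.008, labeled=True),
        PtSpec("Dyspnoea", _SOC_RESP, 0.120, labeled=True),
        PtSpec("Cough", _SOC_RESP, 0.080),
        PtSpec("Respiratory failure", _SOC_RESP, 0.010),
        PtSpec("Hypoxia", _SOC_RESP, 0.006),
        PtSpec("Headache", _SOC_NERV, 0.150),
        PtSpec("Neurotoxicity", _SOC_NERV, 0.002, labeled=True),
        PtSpec("Encephalopathy", _SOC_NERV, 0.004),
        PtSpec("Peripheral sensory neuropathy", _SOC_NERV, 0.006, labeled=True),
        PtSpec("Ovarian failure", _SOC_REPRO, 0.0008),
        PtSpec("Primary hypogonadism", _SOC_REPRO, 0.0005),
        PtSpec("Tumour lysis syndrome", _SOC_META, 0.0015),
        PtSpec("Hyponatraemia", _SOC_META, 0.012),
        PtSpec("Decreased appetite", _SOC_META, 0.090, labeled=True),
        PtSpec("Dehydration", _SOC_META, 0.050),
    ]


def _default_planted_signals() -> list[PlantedSignal]:
    # Association strengths shaped like a cytotoxic agent's profile:
    # strong haematological signals plus a very strong rare one.
    return [
        PlantedSignal("ETOPOSIDE", "Febrile neutropenia", 30.0),
        PlantedSignal("ETOPOSIDE", "Pancytopenia", 15.0),
        PlantedSignal("ETOPOSIDE", "Thrombocytopenia", 8.0),
        PlantedSignal("ETOPOSIDE", "Myelosuppression", 6.0),
        PlantedSignal("ETOPOSIDE", "Tumour lysis syndrome", 37.0),
        PlantedSignal("ETOPOSIDE", "Ovarian failure", 50.0),
        PlantedSignal("CISPLATIN", "Hyponatraemia", 6.0),
        PlantedSignal("PACLITAXEL", "Peripheral sensory neuropathy", 8.0),
    ]


def _default_demographics() -> dict[str, dict[str, float]]:
    # Category weights follow the demographic mix of oncology safety
    # reporting: male excess, heavy weight-missingness, mostly
    # health-professional reporters.
    return {
        "sex": {"F": 0.343, "M": 0.496, "unknown": 0.161},
        "age_bin": {"<18": 0.225, "18-64": 0.394, ">64": 0.141, "unknown": 0.240},
        "weight_bin": {"<80": 0.157, "80-100": 0.045, ">100": 0.013, "unknown": 0.785},
        "country": {"US": 0.272, "FR": 0.111, "JP": 0.092, "CA": 0.087,
                    "IT": 0.050, "OTHER": 0.388},
        "reporter": {"MD": 0.60, "PH": 0.20, "OT": 0.087, "CN": 0.062, "": 0.051},
        "outcome": {"DE": 0.155, "LT": 0.083, "HO": 0.246, "DS": 0.011, "OT": 0.505},
    }


def _default_indications() -> dict[str, float]:
    return {
        "Product used for unknown indication": 0.30,
        "Acute myeloid leukaemia": 0.20,
        "Small cell lung cancer": 0.17,
        "Hodgkin's disease": 0.17,
        "Acute lymphocytic leukaemia": 0.16,
    }


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults define the emulated conditions."""

    n_reports: int = 5000
    drug_catalog: list[DrugSpec] = field(default_factory=_default_drug_catalog)
    pt_catalog: list[PtSpec] = field(default_factory=_default_pt_catalog)
    planted_signals: list[PlantedSignal] = field(default_factory=_default_planted_signals)
    onset_scale_days: float = 38.56
    onset_shape: float = 0.55
    p_missing_event_date: float = 0.55
    p_invalid_date: float = 0.05
    p_duplicate_case: float = 0.10
    p_indication_as_reaction: float = 0.03
    demographics: dict[str, dict[str, float]] = field(default_factory=_default_demographics)
    indication_catalog: dict[str, float] = field(default_factory=_default_indications)
    date_range: tuple[str, str] = ("20040101", "20221231")
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if not self.drug_catalog or not self.pt_catalog:
            raise ValueError("drug and PT catalogs must be non-empty")
        for p in (self.p_missing_event_date, self.p_invalid_date,
                  self.p_duplicate_case, self.p_indication_as_reaction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.onset_scale_days <= 0 or self.onset_shape <= 0:
            raise ValueError("Weibull onset parameters must be positive")
        drugs = {d.name for d in self.drug_catalog}
        pts = {p.pt for p in self.pt_catalog}
        for d in self.drug_catalog:
            if not 0.0 <= d.p_include <= 1.0:
                raise ValueError(f"inclusion probability of {d.name} outside [0, 1]")
        for p in self.pt_catalog:
            if not 0.0 <= p.p_base <= 1.0:
                raise ValueError(f"baseline probability of {p.pt} outside [0, 1]")
        for sig in self.planted_signals:
            if sig.lam < 0:
                raise ValueError("planted lambda must be >= 0")
            if sig.drug not in drugs:
                raise ValueError(f"planted drug {sig.drug!r} not in catalog")
            if sig.pt not in pts:
                raise ValueError(f"planted PT {sig.pt!r} not in catalog")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["drug_catalog"] = [DrugSpec(**d) for d in raw.get("drug_catalog", [])] or _default_drug_catalog()
        raw["pt_catalog"] = [PtSpec(**p) for p in raw.get("pt_catalog", [])] or _default_pt_catalog()
        raw["planted_signals"] = [
            PlantedSignal(**{**s, "stratum": tuple(s["stratum"]) if s.get("stratum") else None})
            for s in raw.get("planted_signals", [])
        ] or _default_planted_signals()
        if "date_range" in raw:
            raw["date_range"] = tuple(raw["date_range"])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Per-case truth the generator knows and downstream stages must recover."""

    ps_drug: dict[int, str] = field(default_factory=dict)
    contains_drug: dict[int, set[str]] = field(default_factory=dict)
    tto_days: dict[int, int] = field(default_factory=dict)  # true PS-drug onset lag
    indication: dict[int, str] = field(default_factory=dict)
    survivor: dict[int, int] = field(default_factory=dict)  # caseid -> surviving primaryid
    n_duplicates: int = 0


# ---------------------------------------------------------------------------
# generation


def _sample_categorical(rng: np.random.Generator, dist: dict[str, float], n: int) -> np.ndarray:
    keys = list(dist)
    p = np.asarray([dist[k] for k in keys], dtype=float)
    p = p / p.sum()
    return rng.choice(np.asarray(keys, dtype=object), size=n, p=p)


_NAME_VARIANTS = (
    lambda s: s,
    lambda s: s.title(),
    lambda s: s.lower(),
    lambda s: f" {s} ",
    lambda s: f"{s}. INJECTION",
)


def _stratum_matches(stratum: tuple[str, str], sex: str, age_bin: str, weight_bin: str, reporter: str) -> bool:
    var, level = stratum
    if var == "sex":
        return sex == level
    if var == "age":
        return age_bin == level
    if var == "weight":
        return weight_bin == level
    if var == "reporter":
        cat = "consumer" if reporter == "CN" else ("unknown" if reporter == "" else "health professional")
        return cat == level
    raise ValueError(f"unknown stratum variable {var!r}")


def generate_reports(config: SyntheticConfig) -> tuple[list[ReportRecord], GroundTruth]:
    """Generate ``n_reports`` unique cases, then inject duplicate versions.

    Fully reproducible from ``config.seed``.  Probabilities that exceed 1
    after lambda-scaling are capped with a logged warning.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    truth = GroundTruth()

    drug_names = [d.name for d in config.drug_catalog]
    p_drug = np.asarray([d.p_include for d in config.drug_catalog])
    pts = [p.pt for p in config.pt_catalog]
    p_base = np.asarray([p.p_base for p in config.pt_catalog])
    pt_index = {p: i for i, p in enumerate(pts)}
    drug_signals: dict[str, list[PlantedSignal]] = {}
    for sig in config.planted_signals:
        drug_signals.setdefault(sig.drug, []).append(sig)

    lo = date_to_ord(config.date_range[0])
    hi = date_to_ord(config.date_range[1])

    sexes = _sample_categorical(rng, config.demographics["sex"], n)
    age_bins = _sample_categorical(rng, config.demographics["age_bin"], n)
    weight_bins = _sample_categorical(rng, config.demographics["weight_bin"], n)
    countries = _sample_categorical(rng, config.demographics["country"], n)
    reporters = _sample_categorical(rng, config.demographics["reporter"], n)
    outcomes = _sample_categorical(rng, config.demographics["outcome"], n)
    indi_names = _sample_categorical(rng, config.indication_catalog, n)
    fda_ords = rng.integers(lo, hi + 1, size=n)
    include = rng.random((n, len(drug_names))) < p_drug[None, :]
    capped_warned: set[tuple[str, str]] = set()

    reports: list[ReportRecord] = []
    for i in range(n):
        caseid = i + 1
        primaryid = caseid * 10 + 5
        sex, age_bin, weight_bin = sexes[i], age_bins[i], weight_bins[i]

        # demographics ------------------------------------------------------
        age_value: float | None
        age_unit: str | None
        if age_bin == "<18":
            age_value = float(rng.integers(0, 18))
            age_unit = "YR"
            if age_value < 2 and rng.random() < 0.5:
                age_value, age_unit = float(rng.integers(1, 24)), "MON"
        elif age_bin == "18-64":
            age_value, age_unit = float(rng.integers(18, 65)), "YR"
        elif age_bin == ">64":
            age_value, age_unit = float(rng.integers(65, 95)), "YR"
        else:
            age_value, age_unit = None, None
        if weight_bin == "<80":
            weight_value, weight_unit = float(rng.integers(10, 80)), "KG"
        elif weight_bin == "80-100":
            weight_value, weight_unit = float(rng.integers(80, 101)), "KG"
        elif weight_bin == ">100":
            weight_value, weight_unit = float(rng.integers(101, 160)), "KG"
        else:
            weight_value, weight_unit = None, None

        # drugs -------------------------------------------------------------
        included = [drug_names[j] for j in np.flatnonzero(include[i])]
        if not included:
            # every report names at least one drug; pick one in proportion
            # to inclusion probability so marginal prevalences stay close
            # to the configured ones
            j = int(rng.choice(len(drug_names), p=p_drug / p_drug.sum()))
            included = [drug_names[j]]
        ps_idx = int(rng.integers(len(included)))
        drugs: list[DrugEntry] = []
        for seq, name in enumerate(included, start=1):
            role = "PS" if seq - 1 == ps_idx else str(rng.choice(["SS", "C", "I"]))
            variant = _NAME_VARIANTS[int(rng.integers(len(_NAME_VARIANTS)))](name)
            drugs.append(DrugEntry(seq=seq, role=role, drugname=variant, prod_ai=name))
        ps_drug = included[ps_idx]
        truth.ps_drug[caseid] = ps_drug
        truth.contains_drug[caseid] = set(included)

        # reactions ---------------------------------------------------------
        p_event = p_base.copy()
        for name in included:
            for sig in drug_signals.get(name, []):
                if sig.stratum is not None and not _stratum_matches(
                    sig.stratum, sex, age_bin, weight_bin, reporters[i]
                ):
                    continue
                j = pt_index[sig.pt]
                scale = sig.lam
                if sex == "F":
                    scale *= sig.female_multiplier
                p_new = p_base[j] * scale
                if p_new > 1.0 and (name, sig.pt) not in capped_warned:
                    log.warning(
                        "planted probability for (%s, %s) capped at 1", name, sig.pt
                    )
                    capped_warned.add((name, sig.pt))
                p_event[j] = min(p_new, 1.0)
        reactions = [pts[j] for j in np.flatnonzero(rng.random(len(pts)) < p_event)]

        # indication (sometimes contaminates the reaction list) -------------
        indication = str(indi_names[i])
        truth.indication[caseid] = indication
        if rng.random() < config.p_indication_as_reaction:
            reactions.append(indication)

        # dates and therapies ----------------------------------------------
        fda_ord = int(fda_ords[i])
        lag = int(rng.weibull(config.onset_shape) * config.onset_scale_days)
        truth.tto_days[caseid] = lag
        event_ord = fda_ord - int(rng.integers(0, 30))
        ps_start_ord = event_ord - lag
        event_dt: str | None = _date_str(event_ord)
        therapies: list[TherapyEntry] = []
        for d in drugs:
            if d.prod_ai == ps_drug:
                start_ord = ps_start_ord
            else:
                other_lag = int(rng.weibull(config.onset_shape) * config.onset_scale_days)
                start_ord = event_ord - other_lag
            start_dt: str | None = _date_str(start_ord)
            end_dt: str | None = _date_str(start_ord + int(rng.integers(1, 120)))
            if rng.random() < config.p_invalid_date:
                start_dt = start_dt[:6]  # partial date, FAERS dialect
            if rng.random() < 0.3:
                end_dt = None
            therapies.append(TherapyEntry(drug_seq=d.seq, start_dt=start_dt, end_dt=end_dt))
        if rng.random() < config.p_missing_event_date:
            event_dt = None
        elif rng.random() < config.p_invalid_date:
            event_dt = event_dt[: (6 if rng.random() < 0.5 else 4)]

        reports.append(
            ReportRecord(
                primaryid=primaryid,
                caseid=caseid,
                fda_dt=_date_str(fda_ord),
                event_dt=event_dt,
                sex=str(sex),
                age_value=age_value,
                age_unit=age_unit,
                weight_value=weight_value,
                weight_unit=weight_unit,
                country=str(countries[i]),
                reporter=str(reporters[i]),
                outcomes=[str(outcomes[i])],
                drugs=drugs,
                reactions=reactions,
                therapies=therapies,
                indications=[indication],
            )
        )

    dup_seed = int(rng.integers(2**31))
    reports, truth = inject_duplicates(reports, config.p_duplicate_case, dup_seed, truth)
    return reports, truth


def date_to_ord(yyyymmdd: str) -> int:
    return datetime.date(
        int(yyyymmdd[:4]), int(yyyymmdd[4:6]), int(yyyymmdd[6:8])
    ).toordinal()


def inject_duplicates(
    reports: list[ReportRecord],
    rate: float,
    seed: int,
    truth: GroundTruth | None = None,
) -> tuple[list[ReportRecord], GroundTruth]:
    """Append duplicate versions of a Bernoulli(rate) subset of cases.

    Each duplicate copies the case with a new PRIMARYID and an FDA_DT at or
    after the original's.  Three flavours are produced so both steps of the
    dedup rule are exercised: later FDA_DT with a higher or lower new id
    (duplicate survives either way), and equal FDA_DT with a higher id
    (duplicate survives) or lower id (original survives).  The intended
    survivor of every case is recorded in the returned ground truth.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("duplicate rate must be in [0, 1]")
    truth = truth if truth is not None else GroundTruth()
    rng = np.random.default_rng(seed)
    out = list(reports)
    for rec in reports:
        truth.survivor.setdefault(rec.caseid, rec.primaryid)
    for rec in reports:
        if rng.random() >= rate:
            continue
        dup = copy.deepcopy(rec)
        flavour = int(rng.integers(4))
        if flavour in (0, 1):  # later FDA_DT wins regardless of id
            later = date_to_ord(rec.fda_dt) + int(rng.integers(1, 200))
            dup.fda_dt = _date_str(later)
            dup.primaryid = rec.primaryid + (2 if flavour == 0 else -3)
            truth.survivor[rec.caseid] = dup.primaryid
        elif flavour == 2:  # same FDA_DT, higher id wins
            dup.primaryid = rec.primaryid + 2
            truth.survivor[rec.caseid] = dup.primaryid
        else:  # same FDA_DT, lower id: original survives
            dup.primaryid = rec.primaryid - 3
            truth.survivor[rec.caseid] = rec.primaryid
        truth.n_duplicates += 1
        out.append(dup)
    return out, truth


# ---------------------------------------------------------------------------
# file emission


def _fmt_num(x: float | None) -> str:
    if x is None:
        return ""
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def _fmt(s: str | None) -> str:
    return "" if s is None else s


def emit_quarterly_files(reports: list[ReportRecord], directory: str | Path) -> dict[str, Path]:
    """Write DEMO/DRUG/REAC/THER/INDI/OUTC dollar-delimited files.

    The files round-trip exactly through :func:`faerskit.ingest.read_quarter`
    and :func:`faerskit.ingest.assemble_reports`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    from .ingest import TABLE_COLUMNS  # single source of column names

    rows: dict[str, list[list[str]]] = {name: [] for name in TABLE_COLUMNS}
    for r in reports:
        pid = str(r.primaryid)
        rows["DEMO"].append([
            pid, str(r.caseid), r.fda_dt, _fmt(r.event_dt),
            "" if r.sex == "unknown" else r.sex,
            _fmt_num(r.age_value), _fmt(r.age_unit),
            _fmt_num(r.weight_value), _fmt(r.weight_unit),
            r.reporter, r.country,
        ])
        for d in r.drugs:
            rows["DRUG"].append([pid, str(d.seq), d.role, d.drugname, d.prod_ai])
        for pt in r.reactions:
            rows["REAC"].append([pid, pt])
        for t in r.therapies:
            rows["THER"].append([pid, str(t.drug_seq), _fmt(t.start_dt), _fmt(t.end_dt)])
        for ind in r.indications:
            rows["INDI"].append([pid, ind])
        for oc in r.outcomes:
            rows["OUTC"].append([pid, oc])

    paths: dict[str, Path] = {}
    for name, columns in TABLE_COLUMNS.items():
        path = directory / f"{name}.txt"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("$".join(columns) + "\n")
            for row in rows[name]:
                fh.write("$".join(row) + "\n")
        paths[name] = path
    return paths


def write_pt_soc_map(config: SyntheticConfig, path: str | Path) -> Path:
    """Write the generator's PT -> SOC map as a two-column CSV."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("PT,SOC\n")
        for spec in config.pt_catalog:
            fh.write(f'"{spec.pt}","{spec.soc}"\n')
    return path


def write_label_list(config: SyntheticConfig, path: str | Path) -> Path:
    """Write the synthetic product-label PT list (one PT per line)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for spec in config.pt_catalog:
            if spec.labeled:
                fh.write(spec.pt + "\n")
    return path
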