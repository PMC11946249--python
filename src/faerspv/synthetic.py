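"""Synthetic spontaneous-reporting-system generator.

Emits the six linked FAERS-format tables (DEMO, DRUG, REAC, OUTC, INDI,
THER) for a configurable population of safety reports with known
ground-truth drug-event associations, so every downstream stage of the
pipeline is testable without downloading FAERS.

Generative model, per report:

* one primary-suspect (PS) drug, drawn from the configured marginals
  (the remaining mass is a pool of background drugs outside the study
  dictionary);
* a number of distinct reaction PTs ~ 1 + Poisson(pts_per_report - 1),
  sampled without replacement with drug-conditional probabilities
  q_d(pt) proportional to background(pt) * rrr(d, pt), renormalized — an
  injected signal is exactly a reporting-rate ratio rrr > 1;
* demographics (age with FAERS unit codes, sex, country, reporter
  occupation), outcome codes, therapy start/end dates and an event date
  offset from therapy start by an exponential onset (mean 30 days);
* with probability ``duplicate_rate`` the case is re-submitted under a
  new, higher PRIMARYID with a strictly later FDA_DT and all child rows
  copied verbatim, so deduplication is decidable from keys alone.

``expected_table`` returns the exact expected 2x2 cell counts under this
model (one-PT-per-report configurations only), used as the oracle for
counting code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .contingency import ContingencyTable

__all__ = [
    "SignalSpec", "SimulationConfig", "FaersTables", "ConfigError",
    "generate", "expected_table", "write_tables", "default_study_config",
]

_BACKGROUND_DRUGS = [
    "OXALIPLATIN", "PARACETAMOL", "METFORMIN", "LISINOPRIL", "ATORVASTATIN",
    "OMEPRAZOLE", "ADALIMUMAB", "METHOTREXATE", "PEMBROLIZUMAB", "WARFARIN",
]

_BACKGROUND_INDICATIONS = [
    "hypertension", "diabetes mellitus", "rheumatoid arthritis",
    "depression", "product used for unknown indication",
]


class ConfigError(ValueError):
    """A SimulationConfig invariant is violated (message names it)."""


@dataclass(frozen=True)
class SignalSpec:
    """An injected association: the PT's background probability is
    multiplied by ``reporting_rate_ratio`` conditional on the drug."""

    drug: str
    pt: str
    reporting_rate_ratio: float


@dataclass
class SimulationConfig:
    n_reports: int
    #: (canonical drug id, marginal probability, verbatim spellings)
    drug_vocab: list[tuple[str, float, list[str]]]
    #: (PT name, background probability, SOC name)
    event_vocab: list[tuple[str, float, str]]
    signals: list[SignalSpec] = field(default_factory=list)
    duplicate_rate: float = 0.0
    missing_age_rate: float = 0.0
    missing_date_rate: float = 0.0
    pts_per_report: float = 1.0
    concomitant_rate: float = 0.0
    start_date: str = "20110101"
    end_date: str = "20231231"
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ConfigError("n_reports must be positive")
        if not self.drug_vocab:
            raise ConfigError("drug_vocab must be nonempty")
        if not self.event_vocab:
            raise ConfigError("event_vocab must be nonempty")
        drug_mass = sum(p for _, p, _ in self.drug_vocab)
        if any(p < 0 for _, p, _ in self.drug_vocab) or drug_mass > 1 + 1e-9:
            raise ConfigError(
                "drug marginal probabilities must be nonnegative and sum to <= 1"
            )
        event_mass = sum(p for _, p, _ in self.event_vocab)
        if any(p < 0 for _, p, _ in self.event_vocab) or abs(event_mass - 1) > 1e-9:
            raise ConfigError("event background probabilities must sum to 1")
        for name, rate in [
            ("duplicate_rate", self.duplicate_rate),
            ("missing_age_rate", self.missing_age_rate),
            ("missing_date_rate", self.missing_date_rate),
        ]:
            if not 0 <= rate <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.pts_per_report < 1:
            raise ConfigError("pts_per_report must be >= 1")
        drugs = {d for d, _, _ in self.drug_vocab}
        pts = {p for p, _, _ in self.event_vocab}
        for s in self.signals:
            if s.reporting_rate_ratio <= 0:
                raise ConfigError("signal reporting_rate_ratio must be > 0")
            if s.drug not in drugs:
                raise ConfigError(f"signal references unknown drug {s.drug!r}")
            if s.pt not in pts:
                raise ConfigError(f"signal references unknown pt {s.pt!r}")


@dataclass
class FaersTables:
    """The six generated string-typed DataFrames plus the ground truth."""

    frames: dict[str, pd.DataFrame]
    manifest: dict


def _conditional_pt_probs(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-drug renormalized PT probabilities.

    Row k < n_drugs is drug k of the vocabulary; the last row is the
    background ("other drug") group with every rrr = 1.
    """
    background = np.array([p for _, p, _ in config.event_vocab], float)
    pt_index = {pt: i for i, (pt, _, _) in enumerate(config.event_vocab)}
    n_drugs = len(config.drug_vocab)
    q = np.tile(background, (n_drugs + 1, 1))
    for s in config.signals:
        k = next(i for i, (d, _, _) in enumerate(config.drug_vocab) if d == s.drug)
        q[k, pt_index[s.pt]] *= s.reporting_rate_ratio
    q /= q.sum(axis=1, keepdims=True)
    marginals = np.array([p for _, p, _ in config.drug_vocab], float)
    probs = np.append(marginals, max(0.0, 1.0 - marginals.sum()))
    probs /= probs.sum()
    return probs, q


def generate(config: SimulationConfig) -> FaersTables:
    """Draw a full synthetic dataset; deterministic given config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    n_pts = len(config.event_vocab)
    pt_names = [pt for pt, _, _ in config.event_vocab]
    drug_probs, q = _conditional_pt_probs(config)
    n_drugs = len(config.drug_vocab)

    caseids = np.array([str(10_000_000 + i) for i in range(n)])
    primaryids = np.char.add(caseids, "1")

    # --- drug assignment (index n_drugs == background pool) ---------------
    drug_idx = rng.choice(n_drugs + 1, size=n, p=drug_probs)
    verbatim = np.empty(n, dtype=object)
    for k, (_, _, spellings) in enumerate(config.drug_vocab):
        mask = drug_idx == k
        cnt = int(mask.sum())
        if cnt:
            verbatim[mask] = np.array(spellings, object)[
                rng.integers(0, len(spellings), cnt)
            ]
    mask = drug_idx == n_drugs
    cnt = int(mask.sum())
    if cnt:
        verbatim[mask] = np.array(_BACKGROUND_DRUGS, object)[
            rng.integers(0, len(_BACKGROUND_DRUGS), cnt)
        ]

    # --- reaction PTs ------------------------------------------------------
    m = 1 + rng.poisson(config.pts_per_report - 1.0, size=n)
    m = np.minimum(m, n_pts)
    case_pts: list[list[str]] = [None] * n  # type: ignore[list-item]
    for k in range(n_drugs + 1):
        sel = np.flatnonzero(drug_idx == k)
        if sel.size == 0:
            continue
        single = sel[m[sel] == 1]
        if single.size:
            draws = rng.choice(n_pts, size=single.size, p=q[k])
            for i, j in zip(single, draws):
                case_pts[i] = [pt_names[j]]
        for i in sel[m[sel] > 1]:
            draws = rng.choice(n_pts, size=m[i], replace=False, p=q[k])
            case_pts[i] = [pt_names[j] for j in draws]

    # --- demographics ------------------------------------------------------
    age_years = np.clip(rng.normal(61.0, 14.0, n), 18.0, 95.0)
    unit_idx = rng.choice(3, size=n, p=[0.92, 0.04, 0.04])
    age_cod = np.array(["YR", "DEC", "MON"], object)[unit_idx]
    age_val = np.where(
        unit_idx == 0, np.round(age_years, 1),
        np.where(unit_idx == 1, np.round(age_years / 10.0, 2),
                 np.round(age_years * 12.0, 1)),
    )
    age_missing = rng.random(n) < config.missing_age_rate
    sex = rng.choice(np.array(["F", "M", ""], object), size=n, p=[0.54, 0.38, 0.08])
    country = rng.choice(
        np.array(["US", "JP", "CN", "FR", "DE", "GB", "IT", "CA"], object),
        size=n, p=[0.45, 0.12, 0.04, 0.07, 0.07, 0.08, 0.07, 0.10],
    )
    occp = rng.choice(
        np.array(["MD", "CN", "PH", "OT", "HP", ""], object),
        size=n, p=[0.38, 0.33, 0.08, 0.12, 0.05, 0.04],
    )

    # --- dates -------------------------------------------------------------
    d0 = np.datetime64(f"{config.start_date[:4]}-{config.start_date[4:6]}-"
                       f"{config.start_date[6:]}")
    d1 = np.datetime64(f"{config.end_date[:4]}-{config.end_date[4:6]}-"
                       f"{config.end_date[6:]}")
    span = int((d1 - d0) / np.timedelta64(1, "D"))
    ther_start = d0 + rng.integers(0, max(1, span - 90), n).astype("timedelta64[D]")
    onset = np.ceil(rng.exponential(30.0, n)).astype(int)
    event_dt = ther_start + onset.astype("timedelta64[D]")
    ther_end = ther_start + rng.integers(10, 400, n).astype("timedelta64[D]")
    fda_dt = event_dt + rng.integers(7, 180, n).astype("timedelta64[D]")
    ther_missing = rng.random(n) < config.missing_date_rate
    event_missing = rng.random(n) < config.missing_date_rate

    # --- outcomes -----------------------------------------------------------
    outc_choice = rng.choice(
        np.array(["", "DE", "HO", "LT", "DS", "OT", "CA", "RI"], object),
        size=n, p=[0.25, 0.15, 0.25, 0.02, 0.01, 0.22, 0.05, 0.05],
    )
    second = rng.random(n) < 0.10
    second_code = rng.choice(
        np.array(["DE", "HO", "LT", "OT"], object), size=n, p=[0.1, 0.5, 0.1, 0.3]
    )

    # --- duplicates ---------------------------------------------------------
    dup_mask = rng.random(n) < config.duplicate_rate
    dup_lag = rng.integers(30, 400, n)

    def ymd(arr: np.ndarray) -> np.ndarray:
        return np.char.replace(np.datetime_as_string(arr, unit="D"), "-", "")

    fda_str = ymd(fda_dt)
    dup_fda_str = ymd(fda_dt + dup_lag.astype("timedelta64[D]"))
    event_str = np.where(event_missing, "", ymd(event_dt))
    ther_start_str = ymd(ther_start)
    ther_end_str = ymd(ther_end)

    demo_rows = {
        "primaryid": list(primaryids),
        "caseid": list(caseids),
        "fda_dt": list(fda_str),
        "event_dt": list(event_str),
        "age": ["" if miss else repr(float(v))
                for miss, v in zip(age_missing, age_val)],
        "age_cod": ["" if miss else c for miss, c in zip(age_missing, age_cod)],
        "sex": list(sex),
        "reporter_country": list(country),
        "occp_cod": list(occp),
    }
    drug_rows = {
        "primaryid": list(primaryids),
        "drugname": list(verbatim),
        "role_cod": ["PS"] * n,
    }
    # optional concomitant medication rows
    if config.concomitant_rate > 0:
        n_con = rng.poisson(config.concomitant_rate, n)
        con_ids, con_names = [], []
        for i in np.flatnonzero(n_con):
            for _ in range(n_con[i]):
                con_ids.append(primaryids[i])
                con_names.append(
                    _BACKGROUND_DRUGS[rng.integers(0, len(_BACKGROUND_DRUGS))]
                )
        drug_rows["primaryid"] += con_ids
        drug_rows["drugname"] += con_names
        drug_rows["role_cod"] += ["C"] * len(con_ids)

    reac_ids, reac_pts = [], []
    for pid, pts in zip(primaryids, case_pts):
        for pt in pts:
            reac_ids.append(pid)
            reac_pts.append(pt)

    outc_ids, outc_codes = [], []
    for i in range(n):
        if outc_choice[i]:
            outc_ids.append(primaryids[i])
            outc_codes.append(outc_choice[i])
            if second[i] and second_code[i] != outc_choice[i]:
                outc_ids.append(primaryids[i])
                outc_codes.append(second_code[i])

    indi_ids = list(primaryids)
    indi_pts = [
        "non-small cell lung cancer" if drug_idx[i] < n_drugs
        else _BACKGROUND_INDICATIONS[i % len(_BACKGROUND_INDICATIONS)]
        for i in range(n)
    ]

    ther_ids, ther_s, ther_e = [], [], []
    for i in range(n):
        if not ther_missing[i]:
            ther_ids.append(primaryids[i])
            ther_s.append(ther_start_str[i])
            ther_e.append(ther_end_str[i])

    # duplicate re-submissions: same caseid, higher primaryid, later fda_dt,
    # all child rows copied verbatim under the new primaryid
    dup_index = np.flatnonzero(dup_mask)
    dup_pid = {int(i): caseids[i] + "2" for i in dup_index}
    for i in dup_index:
        pid = dup_pid[int(i)]
        demo_rows["primaryid"].append(pid)
        demo_rows["caseid"].append(caseids[i])
        demo_rows["fda_dt"].append(dup_fda_str[i])
        demo_rows["event_dt"].append(event_str[i])
        demo_rows["age"].append("" if age_missing[i] else repr(float(age_val[i])))
        demo_rows["age_cod"].append("" if age_missing[i] else age_cod[i])
        demo_rows["sex"].append(sex[i])
        demo_rows["reporter_country"].append(country[i])
        demo_rows["occp_cod"].append(occp[i])
    pid_to_rows: dict[str, list[int]] = {}
    for j, pid in enumerate(drug_rows["primaryid"]):
        pid_to_rows.setdefault(pid, []).append(j)
    for i in dup_index:
        for j in pid_to_rows.get(primaryids[i], []):
            drug_rows["primaryid"].append(dup_pid[int(i)])
            drug_rows["drugname"].append(drug_rows["drugname"][j])
            drug_rows["role_cod"].append(drug_rows["role_cod"][j])
    for i in dup_index:
        pid = dup_pid[int(i)]
        for pt in case_pts[i]:
            reac_ids.append(pid)
            reac_pts.append(pt)
        if outc_choice[i]:
            outc_ids.append(pid)
            outc_codes.append(outc_choice[i])
            if second[i] and second_code[i] != outc_choice[i]:
                outc_ids.append(pid)
                outc_codes.append(second_code[i])
        indi_ids.append(pid)
        indi_pts.append(indi_pts[i])
        if not ther_missing[i]:
            ther_ids.append(pid)
            ther_s.append(ther_start_str[i])
            ther_e.append(ther_end_str[i])

    frames = {
        "DEMO": pd.DataFrame(demo_rows, dtype=str),
        "DRUG": pd.DataFrame(drug_rows, dtype=str),
        "REAC": pd.DataFrame({"primaryid": reac_ids, "pt": reac_pts}, dtype=str),
        "OUTC": pd.DataFrame(
            {"primaryid": outc_ids, "outc_cod": outc_codes}, dtype=str),
        "INDI": pd.DataFrame(
            {"primaryid": indi_ids, "indi_pt": indi_pts}, dtype=str),
        "THER": pd.DataFrame(
            {"primaryid": ther_ids, "start_dt": ther_s, "end_dt": ther_e},
            dtype=str),
    }

    drug_names = [d for d, _, _ in config.drug_vocab]
    ps_counts = {drug_names[k]: int((drug_idx == k).sum()) for k in range(n_drugs)}
    manifest = {
        "n_reports": n,
        "n_distinct_cases": n,
        "n_primaryids": n + int(dup_mask.sum()),
        "n_duplicates": int(dup_mask.sum()),
        "seed": config.seed,
        "ps_report_counts": ps_counts,
        "signals": [
            {"drug": s.drug, "pt": s.pt, "rrr": s.reporting_rate_ratio}
            for s in config.signals
        ],
    }
    return FaersTables(frames, manifest)


def expected_table(config: SimulationConfig, drug: str, pt: str) -> ContingencyTable:
    """Exact expected (a, b, c, d) under the generative model, no sampling.

    Only defined for one-PT-per-report configurations (pts_per_report == 1),
    where each report's single PT is a clean multinomial draw; multi-PT
    without-replacement sampling has no tractable closed form.
    """
    config.validate()
    if config.pts_per_report != 1:
        raise ValueError("expected_table requires pts_per_report == 1")
    drug_names = [d for d, _, _ in config.drug_vocab]
    pt_names = [p for p, _, _ in config.event_vocab]
    if drug not in drug_names:
        raise KeyError(f"unknown drug {drug!r}")
    if pt not in pt_names:
        raise KeyError(f"unknown pt {pt!r}")
    probs, q = _conditional_pt_probs(config)
    k = drug_names.index(drug)
    j = pt_names.index(pt)
    n = config.n_reports
    a = n * probs[k] * q[k, j]
    drug_margin = n * probs[k]
    event_margin = n * float(np.dot(probs, q[:, j]))
    b = drug_margin - a
    c = event_margin - a
    d = n - a - b - c
    return ContingencyTable(a, b, c, d)


def write_tables(tables: FaersTables, outdir) -> dict[str, Path]:
    """Write the six "$"-delimited ASCII files plus a ground-truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for kind, df in tables.frames.items():
        path = outdir / f"{kind}.txt"
        df.to_csv(path, sep="$", index=False, lineterminator="\n")
        paths[kind] = path
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(
        json.dumps(tables.manifest, indent=2, sort_keys=True) + "\n", "utf-8"
    )
    paths["manifest"] = manifest_path
    return paths


def default_study_config(
    n_reports: int = 100_000, seed: int = 0, **overrides
) -> SimulationConfig:
    """The package's reference study conditions.

    Five ALK-TKIs with report-share marginals echoing their relative PS
    report volumes, a ~60-PT background vocabulary, liver-injury signals
    graded across the drugs (strongest for ceritinib, weakest for
    lorlatinib) and a few distinctive non-liver signals (ocular terms for
    crizotinib, lipid terms for lorlatinib, CPK for brigatinib).
    """
    drug_vocab = [
        ("crizotinib", 0.035, ["crizotinib", "XALKORI", "Xalkori"]),
        ("ceritinib", 0.016, ["ceritinib", "ZYKADIA"]),
        ("alectinib", 0.021, ["alectinib", "ALECENSA"]),
        ("brigatinib", 0.013, ["brigatinib", "ALUNBRIG"]),
        ("lorlatinib", 0.015, ["lorlatinib", "LORBRENA", "LORVIQUA"]),
    ]
    raw_events = [
        # (pt, weight, soc) -- weights normalized below
        ("nausea", 50), ("vomiting", 40), ("diarrhea", 45), ("constipation", 20),
        ("abdominal pain", 20), ("fatigue", 50), ("pyrexia", 30),
        ("oedema peripheral", 20), ("oedema", 10), ("headache", 40),
        ("dizziness", 30), ("dyspnea", 40), ("cough", 30), ("rash", 30),
        ("pruritus", 20), ("arthralgia", 20), ("myalgia", 15), ("back pain", 15),
        ("anemia", 20), ("neutropenia", 15), ("thrombocytopenia", 10),
        ("hemolytic anemia", 2), ("pneumonia", 20), ("urinary tract infection", 10),
        ("covid-19", 10), ("death", 20), ("disease progression", 20),
        ("malignant neoplasm progression", 10),
        ("metastases to central nervous system", 4),
        ("decreased appetite", 20), ("weight decreased", 20),
        ("weight increased", 10), ("insomnia", 20), ("anxiety", 15),
        ("depression", 15), ("hallucination", 4), ("renal impairment", 10),
        ("acute kidney injury", 10), ("blood creatinine increased", 10),
        ("electrocardiogram qt prolonged", 5), ("cardiac failure", 8),
        ("bradycardia", 5), ("pericardial effusion", 4), ("pleural effusion", 8),
        ("interstitial lung disease", 5), ("pneumonitis", 5), ("hemoptysis", 4),
        ("photopsia", 1), ("visual impairment", 5), ("vitreous floaters", 1),
        ("diplopia", 2), ("hypercholesterolemia", 2), ("hyperglycemia", 8),
        ("hypokalemia", 8), ("photosensitivity reaction", 3),
        ("blood creatine phosphokinase increased", 3),
        ("alanine aminotransferase increased", 0.9),
        ("aspartate aminotransferase increased", 0.75),
        ("hepatic enzyme increased", 0.55), ("blood bilirubin increased", 0.37),
        ("hepatic function abnormal", 0.37), ("hepatotoxicity", 0.22),
        ("liver disorder", 0.22), ("hyperbilirubinemia", 0.22),
        ("jaundice", 0.22), ("hepatic failure", 0.15), ("hepatitis", 0.22),
        ("cholestasis", 0.15),
    ]
    total = float(sum(w for _, w in raw_events))
    # SOC names live in the bundled hierarchy; the vocabulary stores the
    # PT and probability, with the SOC left to the mapping stage.
    event_vocab = [(pt, w / total, "") for pt, w in raw_events]

    # the DILI multiplier acts uniformly on every liver term, so the
    # consolidated DILI event inherits the drug's intended association
    liver_pts = [
        "alanine aminotransferase increased",
        "aspartate aminotransferase increased",
        "hepatic enzyme increased", "blood bilirubin increased",
        "hepatic function abnormal", "hepatotoxicity", "liver disorder",
        "hyperbilirubinemia", "jaundice", "hepatic failure", "hepatitis",
        "cholestasis",
    ]
    # graded liver-injury associations, specified as the drug-level
    # observed-to-expected reporting ratio the cohort should exhibit
    dili_target_rr = {
        "crizotinib": 3.45, "ceritinib": 5.03, "alectinib": 4.34,
        "brigatinib": 2.37, "lorlatinib": 1.48,
    }
    distinctive = {
        "crizotinib": [("photopsia", 50.0), ("visual impairment", 7.0),
                       ("vitreous floaters", 20.0)],
        "ceritinib": [("diarrhea", 4.0),
                      ("metastases to central nervous system", 40.0)],
        "alectinib": [("constipation", 6.0), ("hemolytic anemia", 30.0)],
        "brigatinib": [("blood creatine phosphokinase increased", 40.0)],
        "lorlatinib": [("hypercholesterolemia", 60.0), ("hallucination", 12.0)],
    }
    distinct_signals = [
        SignalSpec(drug, pt, m)
        for drug, specs in distinctive.items()
        for pt, m in specs
    ]
    drug_names = [d for d, _, _ in drug_vocab]
    liver_idx = [i for i, (pt, _, _) in enumerate(event_vocab) if pt in liver_pts]
    rs = dict(dili_target_rr)

    def _realized(rs_now: dict[str, float]) -> dict[str, float]:
        # drug-level liver share over the comparator's share, computed
        # exactly from the renormalized multinomial model (two effects a
        # raw multiplier alone misses: competing signals renormalize the
        # drug's own shares, and the other study cohorts sit in the
        # comparator with elevated liver rates)
        cfg_now = SimulationConfig(
            n_reports=1, drug_vocab=drug_vocab, event_vocab=event_vocab,
            signals=distinct_signals + [
                SignalSpec(d, pt, rs_now[d]) for d in drug_names
                for pt in liver_pts
            ],
        )
        probs, q = _conditional_pt_probs(cfg_now)
        share = q[:, liver_idx].sum(axis=1)
        out = {}
        for k, d in enumerate(drug_names):
            comparator = (float(np.dot(probs, share)) - probs[k] * share[k]) \
                / (1.0 - probs[k])
            out[d] = share[k] / comparator
        return out

    # fixed-point calibration of the raw multipliers to the target ratios
    for _ in range(25):
        realized = _realized(rs)
        rs = {d: rs[d] * dili_target_rr[d] / realized[d] for d in drug_names}
    signals = [SignalSpec(d, pt, rs[d]) for d in drug_names for pt in liver_pts]
    signals += distinct_signals
    base = dict(
        n_reports=n_reports,
        drug_vocab=drug_vocab,
        event_vocab=event_vocab,
        signals=signals,
        duplicate_rate=0.08,
        missing_age_rate=0.10,
        missing_date_rate=0.55,
        pts_per_report=2.0,
        concomitant_rate=0.4,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)
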