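"""End-to-end orchestration: raw tables to signal and profile outputs.

Stage order mirrors how a spontaneous-reporting-system study is run:

ingest -> assemble -> deduplicate -> DILI consolidation -> drug
canonicalisation -> 2x2 contingency (PT and SOC level) -> four-algorithm
statistics -> threshold flags -> top-k ranking -> cross-drug overlap ->
cohort profiles -> combined DILI assessment.

DILI consolidation runs before any drug counting, so a report with
several liver PTs contributes exactly one DILI event everywhere.  The
run is deterministic given (input, config, seed) and the run log keeps
the report-count accounting: ingested = kept + dedup-removed +
no-reaction-dropped.
"""

from __future__ import annotations

import json
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import contingency, dedup, faers_io, profiles, signal_stats, synthetic, vocab
from .faers_io import fmt2, percentage
from .signal_stats import SignalResult, SignalThresholds

__all__ = ["RunConfig", "PipelineResult", "PipelineError", "run"]

_UNMAPPED_SOC = "unmapped"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    #: directory of FAERS-format ASCII tables, or None to simulate
    input_dir: Optional[Path] = None
    #: generator settings used when input_dir is None
    sim_config: Optional[synthetic.SimulationConfig] = None
    drug_dictionary_path: Optional[Path] = None   # None -> bundled default
    hierarchy_path: Optional[Path] = None
    lexicon_path: Optional[Path] = None
    exclusions_path: Optional[Path] = None
    output_dir: Optional[Path] = None
    bcpnn_mode: str = "paper_compat"
    thresholds: SignalThresholds = field(default_factory=SignalThresholds)
    top_k: int = 30
    require_all_flags: bool = True
    ps_only: bool = True
    mgps_prior: str = "fit"       # "fit" or "default"
    seed: int = 0

    def validate(self) -> None:
        if self.input_dir is None and self.sim_config is None:
            raise ValueError("either input_dir or sim_config is required")
        for name in ("drug_dictionary_path", "hierarchy_path",
                     "lexicon_path", "exclusions_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise FileNotFoundError(f"input_dir: {self.input_dir} does not exist")
        if self.bcpnn_mode not in ("paper_compat", "credible_interval"):
            raise ValueError(f"unknown bcpnn_mode {self.bcpnn_mode!r}")
        if self.mgps_prior not in ("fit", "default"):
            raise ValueError(f"unknown mgps_prior {self.mgps_prior!r}")


@dataclass
class PipelineResult:
    cases: list                       # deduplicated, consolidated CaseReports
    pt_results: dict[str, list[SignalResult]]
    soc_results: dict[str, list[SignalResult]]
    top_signals: dict[str, list[SignalResult]]
    overlap: dict[tuple[str, ...], int]
    profiles: dict[str, profiles.ProfileTable]
    dili_profiles: dict[str, profiles.ProfileTable]
    dili_results: dict[str, Optional[SignalResult]]
    dili_assessment: dict[str, bool]
    prior: signal_stats.MgpsPrior
    run_log: dict
    output_paths: dict[str, Path] = field(default_factory=dict)


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


class _SafeHierarchy:
    """Hierarchy adapter mapping unknown PTs to a sentinel SOC while
    collecting the offending terms for the run log."""

    def __init__(self, hierarchy: vocab.MedDRAHierarchy):
        self._h = hierarchy
        self.unknown: set[str] = set()

    def soc_of(self, pt: str) -> str:
        try:
            return self._h.soc_of(pt)
        except vocab.UnknownPTError:
            self.unknown.add(pt)
            return _UNMAPPED_SOC


def run(config: RunConfig) -> PipelineResult:
    """Execute the full analysis; see the module docstring for stages."""
    with _stage("config"):
        config.validate()
        dictionary = vocab.DrugDictionary.from_yaml(config.drug_dictionary_path)
        hierarchy = vocab.MedDRAHierarchy.from_yaml(config.hierarchy_path)
        lexicon = vocab.PTLexicon.from_yaml(config.lexicon_path)
        if config.exclusions_path is None:
            exclusions = vocab.default_exclusions()
        else:
            import yaml as _yaml
            exclusions = _yaml.safe_load(
                Path(config.exclusions_path).read_text("utf-8"))

    run_log: dict = {"seed": config.seed, "bcpnn_mode": config.bcpnn_mode,
                     "rejects": {}, "notes": []}

    with _stage("ingest"):
        if config.input_dir is not None:
            records = {}
            for kind in faers_io.TABLE_KINDS:
                path = Path(config.input_dir) / f"{kind}.txt"
                parsed = faers_io.read_ascii_table(path, kind)
                records[kind] = parsed.records
                run_log["rejects"][kind] = parsed.rejects
        else:
            sim = config.sim_config
            tables = synthetic.generate(sim)
            records = faers_io.frames_to_records(tables.frames)
            run_log["manifest"] = tables.manifest
        run_log["ingested_reports"] = len(records["DEMO"])

    with _stage("assemble"):
        assembly = faers_io.assemble_cases(records)
        run_log["dropped_no_reac"] = assembly.dropped_no_reac
        run_log["orphan_child_rows"] = assembly.orphans

    with _stage("dedup"):
        dd = dedup.deduplicate(assembly.cases)
        cases = dd.kept
        run_log["dedup_removed"] = dd.removed_count
        run_log["dedup_rule_tally"] = dd.rule_tally
        run_log["kept_reports"] = len(cases)

    with _stage("consolidate_dili"):
        cases = [vocab.consolidate_dili(c, lexicon) for c in cases]

    with _stage("canonicalize_drugs"):
        unmatched: set[str] = set()
        for case in cases:
            new_drugs = []
            for name, role in case.drugs:
                canon = dictionary.canonicalize(name)
                if canon is None:
                    unmatched.add(name)
                    new_drugs.append((name, role))
                else:
                    new_drugs.append((canon, role))
            case.drugs = new_drugs
        run_log["n_unmatched_drug_names"] = len(unmatched)

    safe_hierarchy = _SafeHierarchy(hierarchy)
    drugs = dictionary.drugs
    with _stage("contingency"):
        pt_tables = {
            d: contingency.all_tables(cases, d, "PT", ps_only=config.ps_only)
            for d in drugs
        }
        soc_tables = {
            d: [
                (ev, t) for ev, t in contingency.all_tables(
                    cases, d, "SOC", hierarchy=safe_hierarchy,
                    ps_only=config.ps_only)
                if ev != _UNMAPPED_SOC
            ]
            for d in drugs
        }
        run_log["unmapped_pts"] = sorted(safe_hierarchy.unknown)

    with _stage("mgps_prior"):
        pooled = [t for d in drugs for _, t in pt_tables[d]]
        if config.mgps_prior == "fit":
            try:
                prior = signal_stats.fit_mgps_prior(pooled)
            except signal_stats.FittingError as exc:
                prior = signal_stats.MgpsPrior(*signal_stats.DEFAULT_PRIOR_START)
                run_log["notes"].append(f"prior fit fell back to default: {exc}")
        else:
            prior = signal_stats.MgpsPrior(*signal_stats.DEFAULT_PRIOR_START)
        run_log["mgps_prior"] = {
            "alpha1": prior.alpha1, "beta1": prior.beta1,
            "alpha2": prior.alpha2, "beta2": prior.beta2, "p": prior.p,
        }

    def _score(drug: str, event: str, level: str,
               t: contingency.ContingencyTable) -> SignalResult:
        r = signal_stats.ror(t)
        p = signal_stats.prr(t)
        m = signal_stats.ebgm(t, prior)
        i = signal_stats.ic(t, prior, config.bcpnn_mode)
        f = signal_stats.flags(r, p, i, m, t.a, config.thresholds)
        return SignalResult(drug, event, level, t, r, p, i, m, f)

    with _stage("statistics"):
        pt_results = {
            d: [_score(d, ev, "PT", t) for ev, t in pt_tables[d]] for d in drugs
        }
        soc_results = {
            d: [_score(d, ev, "SOC", t) for ev, t in soc_tables[d]] for d in drugs
        }

    with _stage("ranking"):
        top_signals = {
            d: signal_stats.top_k_signals(
                # the consolidated DILI event is an aggregate, not a PT rank row
                [r for r in pt_results[d] if r.event != lexicon.name],
                exclusions, config.top_k, config.require_all_flags)
            for d in drugs
        }

    with _stage("overlap"):
        signal_sets = {
            d: {r.event for r in pt_results[d] if r.flags.combined}
            for d in drugs
        }
        overlap = signal_stats.signal_overlap(signal_sets)

    with _stage("profiles"):
        profile_tables = {}
        dili_profile_tables = {}
        for d in drugs:
            try:
                profile_tables[d] = profiles.demographic_summary(
                    cases, d, config.ps_only)
            except ValueError:
                run_log["notes"].append(f"no reports for drug {d}")
                continue
            dili_profile_tables[d] = profiles.dili_profile(cases, d, config.ps_only)

    with _stage("dili_assessment"):
        dili_results: dict[str, Optional[SignalResult]] = {}
        per_drug_flags = {}
        for d in drugs:
            hit = next(
                (r for r in pt_results[d] if r.event == lexicon.name), None)
            dili_results[d] = hit
            if hit is not None:
                per_drug_flags[d] = hit.flags
        dili_assessment = signal_stats.combined_dili_assessment(per_drug_flags)

    result = PipelineResult(
        cases=cases, pt_results=pt_results, soc_results=soc_results,
        top_signals=top_signals, overlap=overlap, profiles=profile_tables,
        dili_profiles=dili_profile_tables, dili_results=dili_results,
        dili_assessment=dili_assessment, prior=prior, run_log=run_log,
    )

    if config.output_dir is not None:
        with _stage("write_outputs"):
            result.output_paths = _write_outputs(result, config, drugs)
    return result


def _dili_table_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for drug, res in sorted(result.dili_results.items()):
        prof = result.profiles.get(drug)
        total = prof.total if prof else 0
        if res is None:
            rows.append([drug, total, 0, fmt2(0.0)] + [""] * 8 + [0])
            continue
        a = int(res.a)
        rows.append([
            drug, total, a, fmt2(percentage(a, total)) if total else "",
            fmt2(res.ror.ror if res.ror.defined else None),
            fmt2(res.ror.ci_low if res.ror.defined else None),
            fmt2(res.ror.ci_high if res.ror.defined else None),
            fmt2(res.prr.prr if res.prr.defined else None),
            fmt2(res.prr.chi2 if res.prr.defined else None),
            fmt2(res.ic.ic), fmt2(res.ic.ic025),
            fmt2(res.mgps.ebgm), fmt2(res.mgps.ebgm05),
            int(result.dili_assessment.get(drug, False)),
        ])
    return pd.DataFrame(rows, columns=[
        "drug", "N", "dili_reports", "dili_proportion_pct",
        "ROR", "ROR_CI_low", "ROR_CI_high", "PRR", "chi2",
        "IC", "IC025", "EBGM", "EBGM05", "dili_associated",
    ])


def _write_outputs(result: PipelineResult, config: RunConfig,
                   drugs: list[str]) -> dict[str, Path]:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        flat_pt = [r for d in drugs for r in result.pt_results[d]]
        flat_soc = [r for d in drugs for r in result.soc_results[d]]
        paths = {
            "signals_pt": outdir / "signals_pt.csv",
            "signals_soc": outdir / "signals_soc.csv",
            "top_signals": outdir / "top_signals.csv",
            "overlap": outdir / "overlap.csv",
            "profiles": outdir / "profiles.csv",
            "dili_profiles": outdir / "dili_profiles.csv",
            "dili_table": outdir / "dili_table.csv",
            "run_log": outdir / "run_log.json",
        }
        faers_io.write_signal_table(flat_pt, paths["signals_pt"])
        written["signals_pt"] = paths["signals_pt"]
        if flat_soc:
            faers_io.write_signal_table(flat_soc, paths["signals_soc"])
            written["signals_soc"] = paths["signals_soc"]
        flat_top = [r for d in drugs for r in result.top_signals[d]]
        if flat_top:
            faers_io.write_signal_table(flat_top, paths["top_signals"])
            written["top_signals"] = paths["top_signals"]
        overlap_df = pd.DataFrame(
            [("|".join(k), v) for k, v in sorted(result.overlap.items())],
            columns=["drug_subset", "pt_count"],
        )
        overlap_df.to_csv(paths["overlap"], index=False)
        written["overlap"] = paths["overlap"]
        prof_frames = []
        for d in sorted(result.profiles):
            f = result.profiles[d].to_frame()
            f.insert(0, "drug", d)
            prof_frames.append(f)
        pd.concat(prof_frames).to_csv(paths["profiles"], index=False)
        written["profiles"] = paths["profiles"]
        dili_frames = []
        for d in sorted(result.dili_profiles):
            f = result.dili_profiles[d].to_frame()
            f.insert(0, "drug", d)
            dili_frames.append(f)
        if dili_frames:
            pd.concat(dili_frames).to_csv(paths["dili_profiles"], index=False)
            written["dili_profiles"] = paths["dili_profiles"]
        _dili_table_frame(result).to_csv(paths["dili_table"], index=False)
        written["dili_table"] = paths["dili_table"]
        paths["run_log"].write_text(
            json.dumps(result.run_log, indent=2, sort_keys=True) + "\n", "utf-8")
        written["run_log"] = paths["run_log"]
        return written
    except Exception:
        for p in written.values():
            p.unlink(missing_ok=True)
        raise
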