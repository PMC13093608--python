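"""End-to-end orchestration: ingest -> dedup -> cohort -> statistics ->
subgroups -> time-to-onset, with cached interim tables and a run manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from faersvig import cohort as _cohort
from faersvig import disproportionality as _dis
from faersvig import faers_io as _io
from faersvig import synthetic_faers as _syn
from faersvig import tto_weibull as _tto

logger = logging.getLogger(__name__)

INTERIM = "interim"


class ConfigError(ValueError):
    """Raised for an invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Validated run configuration (YAML-friendly; unknown keys rejected)."""

    out_dir: str
    seed: int = 0
    simulate: bool = False
    sim_overrides: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)      # demo/drug/reac/ther paths
    ptsoc_path: str | None = None
    target_variants: list[str] = field(default_factory=lambda: ["TEMAZEPAM"])
    target_role: str = "PS"
    substring_match: bool = True
    levels: list[str] = field(default_factory=lambda: ["PT", "SOC"])
    margin: str = "pairs"
    top_n: int = 50
    known_labels: list[str] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)
    subgroup_stratifiers: list[str] = field(default_factory=lambda: ["sex", "age"])
    tto_bootstrap: bool = False

    def __post_init__(self):
        if not self.simulate:
            missing = [k for k in ("demo", "drug", "reac", "ther") if k not in self.inputs]
            if missing:
                raise ConfigError(
                    f"inputs missing table path(s) {missing} (or set simulate: true)")
            if self.ptsoc_path is None:
                raise ConfigError("ptsoc_path is required for file-based runs")
        if not self.target_variants:
            raise ConfigError("target_variants must not be empty")
        bad = set(self.levels) - {"PT", "SOC"}
        if bad:
            raise ConfigError(f"unknown level(s) {sorted(bad)}")
        bad = set(self.subgroup_stratifiers) - {"sex", "age"}
        if bad:
            raise ConfigError(f"unknown stratifier(s) {sorted(bad)}")
        if self.margin not in {"pairs", "reports"}:
            raise ConfigError(f"margin must be 'pairs' or 'reports', got {self.margin!r}")
        known = {f.name for f in dataclasses.fields(_dis.Thresholds)}
        bad = set(self.thresholds) - known
        if bad:
            raise ConfigError(f"unknown threshold key(s) {sorted(bad)}")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown config key(s) {sorted(bad)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def resolved_thresholds(self) -> _dis.Thresholds:
        return _dis.Thresholds(**self.thresholds)


# ---------------------------------------------------------------------------
# Interim caching


def _interim_dir(out_dir: Path) -> Path:
    p = out_dir / INTERIM
    p.mkdir(parents=True, exist_ok=True)
    return p


def _save_reports(reports, path: Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in reports]).to_csv(path, index=False)


def _load_reports(path: Path) -> list[_io.ReportRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(_io.ReportRecord(
            primary_id=d["primary_id"], case_id=d["case_id"],
            fda_dt=d["fda_dt"] or None, event_dt=d["event_dt"] or None,
            age_value=float(d["age_value"]) if d["age_value"] else None,
            age_unit=d["age_unit"] or None, sex=d["sex"] or None,
            country=d["country"] or None, reporter=d["reporter"] or None,
        ))
    return out


def _require(path: Path, stage: str, prerequisite: str) -> Path:
    if not path.exists():
        raise ConfigError(
            f"stage '{stage}' needs {path.name}; run the '{prerequisite}' stage first")
    return path


# ---------------------------------------------------------------------------
# Stages


def stage_ingest(cfg: RunConfig) -> dict:
    """Read (or simulate) the quarterly tables, deduplicate, and cache the
    interim records.  Returns the stage counts for the manifest."""
    out_dir = Path(cfg.out_dir)
    interim = _interim_dir(out_dir)
    if cfg.simulate:
        sim_cfg = _syn.SimConfig(seed=cfg.seed, **cfg.sim_overrides)
        paths, _truth = _syn.generate(sim_cfg, out_dir / "simulated")
        ptsoc_path = paths["ptsoc"]
    else:
        paths = {k.upper(): Path(v) for k, v in cfg.inputs.items()}
        ptsoc_path = Path(cfg.ptsoc_path)  # type: ignore[arg-type]
    reports = _io.read_table(paths["DEMO"], "DEMO")
    drugs = _io.read_table(paths["DRUG"], "DRUG")
    reactions = _io.read_table(paths["REAC"], "REAC")
    thers = _io.read_table(paths["THER"], "THER")
    n_raw = len(reports)
    reports = _io.deduplicate(reports)

    _save_reports(reports, interim / "reports.csv")
    pd.DataFrame([dataclasses.asdict(d) for d in drugs]).to_csv(
        interim / "drugs.csv", index=False)
    pd.DataFrame([dataclasses.asdict(r) for r in reactions]).to_csv(
        interim / "reactions.csv", index=False)
    pd.DataFrame([dataclasses.asdict(t) for t in thers]).to_csv(
        interim / "thers.csv", index=False)
    _cohort.PtSocMap.from_file(ptsoc_path)  # validate early
    (interim / "ptsoc_path.json").write_text(json.dumps(str(ptsoc_path)))
    counts = {"raw_reports": n_raw, "deduplicated_reports": len(reports),
              "drug_rows": len(drugs), "reaction_rows": len(reactions),
              "therapy_rows": len(thers)}
    logger.info("ingest: %s", counts)
    return counts


def _load_interim(out_dir: Path, stage: str):
    interim = out_dir / INTERIM
    reports = _load_reports(_require(interim / "reports.csv", stage, "ingest"))
    drugs_df = pd.read_csv(_require(interim / "drugs.csv", stage, "ingest"),
                           dtype=str, keep_default_na=False)
    drugs = [
        _io.DrugRecord(primary_id=r.primary_id, drug_name=r.drug_name,
                       role_code=r.role_code,
                       therapy_start_dt=r.therapy_start_dt or None)
        for r in drugs_df.itertuples(index=False)
    ]
    reac_df = pd.read_csv(_require(interim / "reactions.csv", stage, "ingest"),
                          dtype=str, keep_default_na=False)
    reactions = [_io.ReactionRecord(r.primary_id, r.pt)
                 for r in reac_df.itertuples(index=False)]
    ther_df = pd.read_csv(_require(interim / "thers.csv", stage, "ingest"),
                          dtype=str, keep_default_na=False)
    thers = [_io.TherapyRecord(r.primary_id, r.start_dt or None)
             for r in ther_df.itertuples(index=False)]
    ptsoc_path = json.loads(
        _require(interim / "ptsoc_path.json", stage, "ingest").read_text())
    ptsoc = _cohort.PtSocMap.from_file(ptsoc_path)
    return reports, drugs, reactions, thers, ptsoc


def stage_signal(cfg: RunConfig) -> dict:
    """Cohort extraction, demographics, prior fit, and the ranked PT/SOC
    signal tables."""
    out_dir = Path(cfg.out_dir)
    reports, drugs, reactions, thers, ptsoc = _load_interim(out_dir, "signal")
    thresholds = cfg.resolved_thresholds()

    cohort_ids = _cohort.select_cohort(
        reports, drugs, cfg.target_variants, role=cfg.target_role,
        substring=cfg.substring_match)
    cohort_reports = [r for r in reports if r.primary_id in cohort_ids]
    demo = _cohort.summarize_demographics(cohort_reports)
    demo.to_frame().to_csv(out_dir / "demographics.csv", index=False)

    pairs = _cohort.unique_pairs(reactions)
    universe = {r.primary_id for r in reports}
    pairs = pairs[pairs["primary_id"].isin(universe)]
    pt_counts, n_pairs = _cohort.count_events(cohort_ids, reactions)

    # PS-drug assignment for the database-wide prior fit.
    ps_drug = {d.primary_id: _cohort.normalize_term(d.drug_name)
               for d in drugs if d.role_code == cfg.target_role}
    pc = _dis.pair_counts(pairs, ps_drug)
    prior = _dis.fit_mgps_prior(pc["a"], pc["expected"])
    (out_dir / "prior.json").write_text(json.dumps(dataclasses.asdict(prior), indent=1))

    tables: dict[str, pd.DataFrame] = {}
    for level in cfg.levels:
        if level == "PT":
            events = sorted(pt_counts)
        else:
            socs = {ptsoc.soc_of(pt) for pt in pt_counts}
            events = sorted(socs)
        results = []
        for ev in events:
            t = _cohort.build_contingency(ev, level, cohort_ids, pairs,
                                          ptsoc=ptsoc, margin=cfg.margin)
            if t.a == 0:
                continue
            results.append(_dis.evaluate_signal(t, prior, thresholds))
        top_n = cfg.top_n if level == "PT" else None
        table = _dis.rank_and_report(results, top_n=top_n,
                                     known_labels=cfg.known_labels or None)
        table.to_csv(out_dir / f"signals_{level.lower()}.csv", index=False)
        tables[level] = table

    (out_dir / INTERIM / "cohort_ids.json").write_text(
        json.dumps(sorted(cohort_ids)))
    counts = {
        "cohort_reports": len(cohort_ids),
        "cohort_event_pairs": n_pairs,
        "events_pt": int(len(pt_counts)),
        "positive_pt": int(tables["PT"]["positive"].sum()) if "PT" in tables else 0,
    }
    logger.info("signal: %s", counts)
    return counts


def stage_subgroup(cfg: RunConfig) -> dict:
    """Sex and age-band subgroup tables over the top-N PT events."""
    out_dir = Path(cfg.out_dir)
    reports, drugs, reactions, _thers, ptsoc = _load_interim(out_dir, "subgroup")
    sig_path = _require(out_dir / "signals_pt.csv", "subgroup", "signal")
    cohort_ids = set(json.loads(
        _require(out_dir / INTERIM / "cohort_ids.json", "subgroup", "signal").read_text()))
    top_events = pd.read_csv(sig_path)["event"].head(cfg.top_n).tolist()
    ps_drug = {d.primary_id: _cohort.normalize_term(d.drug_name)
               for d in drugs if d.role_code == cfg.target_role}
    counts = {}
    for strat in cfg.subgroup_stratifiers:
        tables = _dis.subgroup_analysis(
            strat, reports, reactions, cohort_ids, top_events,
            ptsoc=ptsoc, drug_of_report=ps_drug,
            thresholds=cfg.resolved_thresholds(), margin=cfg.margin)
        for stratum, table in tables.items():
            safe = stratum.replace("<", "lt").replace(">", "gt").replace("-", "_")
            table.to_csv(out_dir / f"subgroup_{strat}_{safe}.csv", index=False)
            counts[f"{strat}:{stratum}"] = int(len(table))
    logger.info("subgroup: %s", counts)
    return counts


def stage_tto(cfg: RunConfig) -> dict:
    """Time-to-onset summary, Weibull fit and cumulative incidence for the
    cohort."""
    out_dir = Path(cfg.out_dir)
    reports, _drugs, _reactions, thers, _ptsoc = _load_interim(out_dir, "tto")
    cohort_ids = set(json.loads(
        _require(out_dir / INTERIM / "cohort_ids.json", "tto", "signal").read_text()))
    starts: dict[str, list] = {}
    for t in thers:
        if t.primary_id in cohort_ids:
            starts.setdefault(t.primary_id, []).append(t.start_date)
    events = {r.primary_id: r.event_date for r in reports if r.primary_id in cohort_ids}
    samples = _tto.compute_tto(starts, events)
    summary = _tto.bin_tto(samples)
    df = summary.to_frame()
    df.to_csv(out_dir / "tto_bins.csv", index=False)
    _tto.cumulative_incidence(samples).to_csv(
        out_dir / "cumulative_incidence.csv", index=False)

    counts: dict = {"tto_valid": summary.n_valid,
                    "tto_median": summary.median, "tto_iqr": summary.iqr}
    days = _tto.valid_days(samples)
    try:
        fit = _tto.fit_weibull(
            days, ci_method="bootstrap" if cfg.tto_bootstrap else "wald",
            seed=cfg.seed)
    except ValueError as exc:
        logger.warning("Weibull fit skipped: %s", exc)
        fit = None
    rows = [] if fit is None else [{
        "n": fit.n, "median_days": summary.median, "iqr_days": summary.iqr,
        "scale": fit.scale, "scale_low": fit.scale_ci[0], "scale_high": fit.scale_ci[1],
        "shape": fit.shape, "shape_low": fit.shape_ci[0], "shape_high": fit.shape_ci[1],
        "failure_type": fit.failure_type,
    }]
    pd.DataFrame(rows).to_csv(out_dir / "weibull.csv", index=False)
    if fit is not None:
        counts.update({"weibull_scale": fit.scale, "weibull_shape": fit.shape,
                       "failure_type": fit.failure_type})
    logger.info("tto: %s", counts)
    return counts


def render_report(out_dir: str | Path, top: int = 50) -> pd.DataFrame:
    """Re-render the top-N PT table from cached signal output without
    recomputation."""
    out_dir = Path(out_dir)
    path = _require(out_dir / "signals_pt.csv", "report", "signal")
    return pd.read_csv(path).head(top)


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage and write the JSON run manifest.

    The manifest mirrors the analysis flow: raw report count, post-dedup
    count, cohort size, event count, subgroup sizes, onset-time summary.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yml").write_text(yaml.safe_dump(dataclasses.asdict(cfg)))
    manifest: dict = {"seed": cfg.seed, "stages": {}}
    for name, stage in (("ingest", stage_ingest), ("signal", stage_signal),
                        ("subgroup", stage_subgroup), ("tto", stage_tto)):
        try:
            manifest["stages"][name] = stage(cfg)
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
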