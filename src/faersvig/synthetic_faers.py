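"""Synthetic FAERS-format data with implanted ground truth.

The generator emits the four quarterly ASCII tables (DEMO, DRUG, REAC,
THER) in the exact dollar-delimited dialect consumed by
:mod:`faersvig.faers_io`, together with a flat PT->SOC map and a JSON-able
ground-truth object.  It emulates the structural features of a spontaneous
reporting database that the pipeline must cope with:

* many drugs x many preferred terms with a Zipf (power-law) rank-frequency
  profile of PT marginals;
* a target drug whose reports draw PTs with chosen relative reporting rates
  multiplied in (the implanted signals);
* demographics drawn from category tables whose defaults mirror the
  published cohort (sex 27.9/58.7/13.4 M/F/missing, 82.8% US, reporter
  37.8/58.3/3.9 HCP/other/missing, the 2006-2025 report-year profile);
* onset times drawn from a Weibull law (default scale 38.05 d, shape 0.41 —
  the early-failure regime) written as START_DT/EVENT_DT pairs;
* injected duplicate reports (same case id, distinct primary id, staggered
  FDA_DT) and per-field missingness.

Every draw derives from one seed through named sub-streams, so the file set
is byte-identical across runs and adding a field to one table never
perturbs another table's draws.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from faersvig.cohort import normalize_term

_DAY = np.timedelta64(1, "D")

N_SOCS = 27

# Table-style default category tables (probabilities per category; None keys
# mean the field is emitted blank).
_SEX_TABLE = {"F": 0.587, "M": 0.279, None: 0.134}
# Published age-band shares sum to 0.998 from rounding; the missing share
# absorbs the remainder so the table is a proper distribution.
_AGE_TABLE = {"<18": 0.005, "18-65": 0.364, "65-85": 0.248, ">85": 0.041, None: 0.342}
_COUNTRY_TABLE = {"US": 0.828, "GB": 0.081, "DE": 0.016, "NL": 0.015, "AU": 0.015,
                  "FR": 0.045}
_REPORTER_TABLE = {"MD": 0.378, "CN": 0.583, None: 0.039}
_YEAR_TABLE = {
    2006: 0.010, 2007: 0.011, 2008: 0.019, 2009: 0.028, 2010: 0.047,
    2011: 0.033, 2012: 0.084, 2013: 0.029, 2014: 0.052, 2015: 0.063,
    2016: 0.076, 2017: 0.081, 2018: 0.091, 2019: 0.090, 2020: 0.076,
    2021: 0.062, 2022: 0.043, 2023: 0.036, 2024: 0.043, 2025: 0.026,
}

_AGE_RANGES = {"<18": (1, 17), "18-65": (18, 64), "65-85": (65, 84), ">85": (85, 99)}


def _check_table(name: str, table: Mapping) -> None:
    total = sum(table.values())
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError(f"{name} probabilities sum to {total}, expected 1")
    if any(v < 0 for v in table.values()):
        raise ValueError(f"{name} contains a negative probability")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic database.

    ``implanted_signals`` are (PT name, relative reporting rate >= 1) pairs;
    each named PT replaces the vocabulary entry at a mid-frequency Zipf rank
    (15, 25, 35, ... by default, override via ``implanted_ranks``) and its
    draw probability for target-drug reports is multiplied by the rate
    before renormalisation.
    """

    seed: int
    n_background_reports: int = 8000
    n_drugs: int = 40
    n_pts: int = 150
    pt_marginal: float = 1.0            # Zipf exponent of the PT profile
    target_drug: str = "TEMAZEPAM"
    n_target_reports: int = 500
    implanted_signals: tuple[tuple[str, float], ...] = (
        ("EYE IRRITATION", 10.0),
        ("EYE PAIN", 8.0),
        ("SOMNAMBULISM", 5.0),
    )
    implanted_ranks: tuple[int, ...] | None = None
    mean_extra_pts: float = 3.3         # K = 1 + min(Poisson(mean), 7) PT draws
    sex_table: Mapping = field(default_factory=lambda: dict(_SEX_TABLE))
    age_table: Mapping = field(default_factory=lambda: dict(_AGE_TABLE))
    country_table: Mapping = field(default_factory=lambda: dict(_COUNTRY_TABLE))
    reporter_table: Mapping = field(default_factory=lambda: dict(_REPORTER_TABLE))
    year_table: Mapping = field(default_factory=lambda: dict(_YEAR_TABLE))
    tto_law: tuple[float, float] = (38.05, 0.41)   # Weibull (scale days, shape)
    duplicate_rate: float = 0.05
    missing_rates: Mapping = field(
        default_factory=lambda: {"event_dt": 0.55, "start_dt": 0.30}
    )

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.duplicate_rate <= 0.5:
            raise ValueError("duplicate_rate must lie in [0, 0.5]")
        if any(rate < 1.0 for _, rate in self.implanted_signals):
            raise ValueError("implanted relative rates must be >= 1")
        for name in ("sex_table", "age_table", "country_table", "reporter_table",
                     "year_table"):
            _check_table(name, getattr(self, name))
        if self.tto_law[0] <= 0 or self.tto_law[1] <= 0:
            raise ValueError("Weibull scale and shape must be positive")
        ranks = self.signal_ranks()
        if len(set(ranks)) != len(ranks) or (ranks and max(ranks) > self.n_pts):
            raise ValueError("implanted ranks must be distinct and <= n_pts")
        for rate in self.missing_rates.values():
            if not 0.0 <= rate <= 1.0:
                raise ValueError("missing rates must lie in [0, 1]")

    def signal_ranks(self) -> tuple[int, ...]:
        if self.implanted_ranks is not None:
            return tuple(self.implanted_ranks)
        return tuple(15 + 10 * i for i in range(len(self.implanted_signals)))

    # -- analytic expectations (used by tests and to size implanted signals)

    def pt_vocabulary(self) -> list[str]:
        vocab = [f"PT_{i + 1:04d}" for i in range(self.n_pts)]
        for (name, _), rank in zip(self.implanted_signals, self.signal_ranks()):
            vocab[rank - 1] = normalize_term(name)
        return vocab

    def background_pt_probs(self) -> np.ndarray:
        ranks = np.arange(1, self.n_pts + 1, dtype=float)
        w = ranks ** -self.pt_marginal
        return w / w.sum()

    def target_pt_probs(self) -> np.ndarray:
        w = self.background_pt_probs().copy()
        for (_, rate), rank in zip(self.implanted_signals, self.signal_ranks()):
            w[rank - 1] *= rate
        return w / w.sum()

    def _k_pmf(self) -> np.ndarray:
        """PMF of the per-report PT draw count K = 1 + min(Poisson(mu), 7)."""
        from scipy import stats as _stats

        mu = self.mean_extra_pts
        pmf = _stats.poisson.pmf(np.arange(8), mu)
        pmf[-1] += _stats.poisson.sf(7, mu)
        return pmf

    def expected_event_count(self, pt: str) -> float:
        """Expected number of target-drug reports mentioning the PT
        (draws are with replacement, so a report mentions the PT with
        probability 1 - E[(1-p)^K])."""
        vocab = self.pt_vocabulary()
        p = self.target_pt_probs()[vocab.index(normalize_term(pt))]
        pmf = self._k_pmf()
        k = np.arange(1, 9)
        return self.n_target_reports * float(np.sum(pmf * (1 - (1 - p) ** k)))

    def expected_relative_rate(self, pt: str) -> float:
        """Implanted observed-over-expected ratio at the per-draw level for
        the PT (the signal size the generator aims to realise)."""
        vocab = self.pt_vocabulary()
        i = vocab.index(normalize_term(pt))
        return float(self.target_pt_probs()[i] / self.background_pt_probs()[i])


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    target_drug: str
    target_ids: list[str]
    drug_of_report: dict[str, str]
    pts_of_report: dict[str, list[str]]
    lineage: dict[str, str]             # duplicate pid -> canonical pid
    expected_survivors: list[str]
    true_tto_days: dict[str, int]
    implanted: list[tuple[str, float]]

    def to_json(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["implanted"] = [[pt, rate] for pt, rate in self.implanted]
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        data["implanted"] = [(pt, float(rate)) for pt, rate in data["implanted"]]
        return cls(**data)


def _sample_table(rng: np.random.Generator, table: Mapping, size: int) -> list:
    cats = list(table.keys())
    probs = np.array([table[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(cats), size=size, p=probs)
    return [cats[i] for i in idx]


def _fmt_date(d: np.datetime64 | None) -> str:
    if d is None:
        return ""
    return pd.Timestamp(d).strftime("%Y%m%d")


def generate(config: SimConfig, out_dir: str | Path) -> tuple[dict[str, Path], GroundTruth]:
    """Write the synthetic file set and return its paths and ground truth.

    Emits ``DEMO.txt``, ``DRUG.txt``, ``REAC.txt``, ``THER.txt``, a flat
    ``pt_soc.csv`` map (27 SOCs) and ``ground_truth.json``.  Fully
    reproducible from ``config.seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(ss)
        for name, ss in zip(
            ("assign", "demo", "drug", "reac", "ther", "dup"), root.spawn(6)
        )
    }

    n_bg = config.n_background_reports
    n_tg = config.n_target_reports
    n = n_bg + n_tg
    pids = [str(100000001 + i) for i in range(n)]
    case_ids = [f"C{200000001 + i}" for i in range(n)]

    # Which reports carry the target drug (random positions, fixed count).
    rng = streams["assign"]
    target_pos = set(rng.choice(n, size=n_tg, replace=False).tolist())
    drug_names = [f"DRUG_{i + 1:03d}" for i in range(config.n_drugs)]
    drug_w = np.arange(1, config.n_drugs + 1, dtype=float) ** -0.7
    drug_w /= drug_w.sum()
    bg_drug_idx = rng.choice(config.n_drugs, size=n, p=drug_w)
    drug_of_report = {
        pid: (normalize_term(config.target_drug) if i in target_pos
              else drug_names[bg_drug_idx[i]])
        for i, pid in enumerate(pids)
    }

    # PT draws: with replacement from the report's profile, then collapsed to
    # the unique set (the ground-truth event list for the report).
    rng = streams["reac"]
    vocab = config.pt_vocabulary()
    bg_p = config.background_pt_probs()
    tg_p = config.target_pt_probs()
    k = 1 + np.minimum(rng.poisson(config.mean_extra_pts, size=n), 7)
    pts_of_report: dict[str, list[str]] = {}
    for i, pid in enumerate(pids):
        p = tg_p if i in target_pos else bg_p
        draw = rng.choice(config.n_pts, size=k[i], p=p)
        pts_of_report[pid] = sorted({vocab[j] for j in draw})

    # Demographics.
    rng = streams["demo"]
    sexes = _sample_table(rng, config.sex_table, n)
    bands = _sample_table(rng, config.age_table, n)
    ages = [
        None if b is None else int(rng.integers(_AGE_RANGES[b][0], _AGE_RANGES[b][1] + 1))
        for b in bands
    ]
    countries = _sample_table(rng, config.country_table, n)
    reporters = _sample_table(rng, config.reporter_table, n)
    years = _sample_table(rng, config.year_table, n)

    # Dates: FDA receipt inside the drawn report year; the event precedes it
    # by a short reporting lag, therapy start precedes the event by the
    # Weibull-drawn onset interval.
    rng = streams["ther"]
    scale, shape = config.tto_law
    tto = np.rint(scale * rng.weibull(shape, size=n)).astype(int)
    day_in_year = rng.integers(0, 365, size=n)
    lag = rng.integers(5, 91, size=n)
    fda_dates = np.array([np.datetime64(f"{y}-01-01") for y in years]) + day_in_year * _DAY
    event_dates = fda_dates - lag * _DAY
    start_dates = event_dates - tto * _DAY
    miss_event = rng.random(n) < config.missing_rates.get("event_dt", 0.0)
    miss_start = rng.random(n) < config.missing_rates.get("start_dt", 0.0)

    true_tto_days = {pid: int(tto[i]) for i, pid in enumerate(pids)}

    # Duplicate injection: an earlier FDA_DT version of the same case under a
    # fresh (higher) primary id, so the retention rule must pick by date, not
    # by id order.
    rng = streams["dup"]
    n_dup = int(round(config.duplicate_rate * n))
    dup_src = sorted(rng.choice(n, size=n_dup, replace=False).tolist())
    lineage: dict[str, str] = {}
    dup_rows = []
    for j, i in enumerate(dup_src):
        dup_pid = str(100000001 + n + j)
        lineage[dup_pid] = pids[i]
        back = int(rng.integers(30, 201))
        dup_rows.append((dup_pid, i, fda_dates[i] - back * _DAY))

    # ---- write the four tables ------------------------------------------
    demo_path = out_dir / "DEMO.txt"
    drug_path = out_dir / "DRUG.txt"
    reac_path = out_dir / "REAC.txt"
    ther_path = out_dir / "THER.txt"

    def demo_line(pid, cid, fda, event, age, sex, country, occp):
        return "$".join([
            pid, cid, _fmt_date(fda),
            "" if event is None else _fmt_date(event),
            "" if age is None else str(age),
            "" if age is None else "YR",
            sex or "", country or "", occp or "",
        ])

    with open(demo_path, "w", encoding="utf-8") as fh:
        fh.write("PRIMARYID$CASEID$FDA_DT$EVENT_DT$AGE$AGE_COD$SEX$OCCR_COUNTRY$OCCP_COD\n")
        for i, pid in enumerate(pids):
            fh.write(demo_line(
                pid, case_ids[i], fda_dates[i],
                None if miss_event[i] else event_dates[i],
                ages[i], sexes[i], countries[i], reporters[i]) + "\n")
        for dup_pid, i, dup_fda in dup_rows:
            fh.write(demo_line(
                dup_pid, case_ids[i], dup_fda,
                None if miss_event[i] else event_dates[i],
                ages[i], sexes[i], countries[i], reporters[i]) + "\n")

    rng = streams["drug"]
    conc = rng.random(n) < 0.3
    conc_idx = rng.choice(config.n_drugs, size=n)
    with open(drug_path, "w", encoding="utf-8") as fh:
        fh.write("PRIMARYID$DRUG_SEQ$ROLE_COD$DRUGNAME\n")
        for i, pid in enumerate(pids):
            fh.write(f"{pid}$1$PS${drug_of_report[pid]}\n")
            if conc[i]:
                fh.write(f"{pid}$2$C${drug_names[conc_idx[i]]}\n")
        for dup_pid, i, _ in dup_rows:
            fh.write(f"{dup_pid}$1$PS${drug_of_report[pids[i]]}\n")

    with open(reac_path, "w", encoding="utf-8") as fh:
        fh.write("PRIMARYID$PT\n")
        for pid in pids:
            for pt in pts_of_report[pid]:
                fh.write(f"{pid}${pt}\n")
        for dup_pid, i, _ in dup_rows:
            for pt in pts_of_report[pids[i]]:
                fh.write(f"{dup_pid}${pt}\n")

    with open(ther_path, "w", encoding="utf-8") as fh:
        fh.write("PRIMARYID$DSG_DRUG_SEQ$START_DT\n")
        for i, pid in enumerate(pids):
            start = "" if miss_start[i] else _fmt_date(start_dates[i])
            fh.write(f"{pid}$1${start}\n")
        for dup_pid, i, _ in dup_rows:
            start = "" if miss_start[i] else _fmt_date(start_dates[i])
            fh.write(f"{dup_pid}$1${start}\n")

    ptsoc_path = out_dir / "pt_soc.csv"
    with open(ptsoc_path, "w", encoding="utf-8") as fh:
        for i, pt in enumerate(vocab):
            fh.write(f"{pt},SOC_{i % N_SOCS + 1:02d}\n")

    truth = GroundTruth(
        target_drug=normalize_term(config.target_drug),
        target_ids=sorted((pids[i] for i in target_pos), key=int),
        drug_of_report=drug_of_report,
        pts_of_report=pts_of_report,
        lineage=lineage,
        expected_survivors=sorted(pids, key=int),
        true_tto_days=true_tto_days,
        implanted=[(normalize_term(pt), rate) for pt, rate in config.implanted_signals],
    )
    truth.to_json(out_dir / "ground_truth.json")
    paths = {
        "DEMO": demo_path, "DRUG": drug_path, "REAC": reac_path, "THER": ther_path,
        "ptsoc": ptsoc_path, "truth": out_dir / "ground_truth.json",
    }
    return paths, truth


def truth_check(
    survivors: Sequence[str],
    signal_table: pd.DataFrame,
    truth: GroundTruth,
    tto_samples=None,
    weibull_fit=None,
    tto_law: tuple[float, float] | None = None,
) -> dict:
    """Score a pipeline run against the generator's ground truth.

    Returns deduplication accuracy (1 minus the normalised symmetric
    difference of survivor sets), sensitivity on the implanted signal list,
    specificity over the evaluated non-implanted events, and — when time-to-
    onset output is supplied — the interval recovery error and the Weibull
    parameter errors against the generating law.
    """
    expected = set(truth.expected_survivors)
    got = set(survivors)
    sym = len(expected ^ got)
    report: dict = {
        "dedup_accuracy": max(0.0, 1.0 - sym / max(len(expected), 1)),
        "n_survivors": len(got),
        "n_expected_survivors": len(expected),
    }

    implanted = {pt for pt, _ in truth.implanted}
    events = dict(zip(signal_table["event"], signal_table["positive"]))
    found = sum(bool(events.get(pt, False)) for pt in implanted)
    report["signal_sensitivity"] = found / len(implanted) if implanted else float("nan")
    negatives = [e for e in events if e not in implanted]
    false_pos = sum(bool(events[e]) for e in negatives)
    report["signal_specificity"] = (
        1.0 - false_pos / len(negatives) if negatives else float("nan")
    )
    report["n_events_evaluated"] = len(events)
    report["n_false_positive"] = false_pos

    if tto_samples is not None:
        errs = [
            abs(s.tto_days - truth.true_tto_days[s.primary_id])
            for s in tto_samples
            if s.status == "valid" and s.primary_id in truth.true_tto_days
        ]
        report["tto_n_valid"] = len(errs)
        report["tto_mean_abs_error_days"] = float(np.mean(errs)) if errs else float("nan")
    if weibull_fit is not None and tto_law is not None:
        report["weibull_scale_error"] = abs(weibull_fit.scale - tto_law[0])
        report["weibull_shape_error"] = abs(weibull_fit.shape - tto_law[1])
    return report
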