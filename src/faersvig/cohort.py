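"""Target-drug cohort extraction, contingency tables and demographic summary.

Disproportionality analysis compares how often an adverse event is reported
with the drug of interest against the background of all other drugs, via a
2x2 contingency table per event.  This module extracts the primary-suspect
cohort for a drug, counts events at the MedDRA preferred-term (PT) level,
resolves PTs to system organ classes (SOCs) through a user-supplied mapping,
and assembles both the 2x2 tables and the cohort's demographic summary.

Counting unit
-------------
Published FAERS signal tables commonly use report-event pairs as the margin
(a report contributing three PTs contributes three pairs), which is why
SOC-level case totals may exceed the number of cohort reports.  The default
here follows that convention: the cell ``a`` is the number of unique cohort
reports carrying the event, while the margins ``a+b`` and ``c+d`` are pair
totals.  ``margin="reports"`` switches both margins to unique reports.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from faersvig.faers_io import DrugRecord, ReactionRecord, ReportRecord

logger = logging.getLogger(__name__)

UNMAPPED_SOC = "UNMAPPED"

AGE_BANDS = ("<18", "18-65", "65-85", ">85")
MISSING_LABEL = "Miss"


def normalize_term(term: str) -> str:
    """Normalise a PT/SOC/drug string for matching: trim, collapse internal
    whitespace, upper-case."""
    return " ".join(term.split()).upper()


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts for one drug-event pair against the database background.

    ``a``: target-drug reports with the event; ``b``: target-drug margin
    remainder; ``c``: background reports with the event; ``d``: background
    margin remainder.
    """

    a: int
    b: int
    c: int
    d: int
    event: str = ""
    level: str = "PT"

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in contingency table {self!r}")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of ``a`` under row/column independence."""
        if self.n_total == 0:
            return 0.0
        return (self.a + self.b) * (self.a + self.c) / self.n_total


class PtSocMap:
    """Preferred-term to (primary) system-organ-class mapping."""

    def __init__(self, entries: Mapping[str, str]):
        self._map = {normalize_term(pt): normalize_term(soc) for pt, soc in entries.items()}

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, pt: str) -> bool:
        return normalize_term(pt) in self._map

    def soc_of(self, pt: str) -> str:
        """SOC for a PT; unmapped PTs fall into the ``UNMAPPED`` bucket."""
        soc = self._map.get(normalize_term(pt))
        if soc is None:
            logger.debug("PT %r not in PT->SOC map; bucketed as %s", pt, UNMAPPED_SOC)
            return UNMAPPED_SOC
        return soc

    def socs(self) -> list[str]:
        return sorted(set(self._map.values()))

    @classmethod
    def from_file(cls, path: str | Path) -> "PtSocMap":
        """Read a two-column (PT, SOC) text file, tab- or comma-separated."""
        df = pd.read_csv(path, sep=None, engine="python", header=None,
                         names=["pt", "soc"], comment="#", skipinitialspace=True)
        first = str(df.iloc[0, 0]).strip().upper() if len(df) else ""
        if first in {"PT", "PREFERRED TERM", "PREFERRED_TERM"}:
            df = df.iloc[1:]
        return cls(dict(zip(df["pt"].astype(str), df["soc"].astype(str))))


def select_cohort(
    reports: Sequence[ReportRecord],
    drugs: Sequence[DrugRecord],
    name_variants: Iterable[str],
    role: str = "PS",
    substring: bool = True,
) -> set[str]:
    """Primary ids of reports naming the target drug in the given role.

    Matching is case-insensitive after whitespace normalisation; with
    ``substring=True`` (default) a variant matches anywhere inside the
    recorded free-text drug name, which absorbs trailing punctuation and
    salt suffixes.  Only ids present in ``reports`` (the deduplicated
    universe) are returned.
    """
    variants = [normalize_term(v) for v in name_variants if v and v.strip()]
    if not variants:
        raise ValueError("name_variants must contain at least one non-empty string")
    role = role.upper()
    universe = {r.primary_id for r in reports}
    hits: set[str] = set()
    for d in drugs:
        if d.role_code != role or d.primary_id not in universe:
            continue
        name = normalize_term(d.drug_name)
        if any((v in name) if substring else (v == name) for v in variants):
            hits.add(d.primary_id)
    return hits


def unique_pairs(reactions: Sequence[ReactionRecord]) -> pd.DataFrame:
    """Unique (primary_id, PT) pairs with normalised PT strings."""
    if not reactions:
        return pd.DataFrame(columns=["primary_id", "pt"])
    df = pd.DataFrame(
        {"primary_id": [r.primary_id for r in reactions],
         "pt": [normalize_term(r.pt) for r in reactions]}
    )
    return df.drop_duplicates(ignore_index=True)


def count_events(
    cohort_ids: set[str], reactions: Sequence[ReactionRecord]
) -> tuple[dict[str, int], int]:
    """Per-PT unique-report counts within the cohort, plus the total number
    of report-event pairs.  Duplicate identical PTs within one report count
    once."""
    pairs = unique_pairs(reactions)
    pairs = pairs[pairs["primary_id"].isin(cohort_ids)]
    counts = pairs.groupby("pt")["primary_id"].nunique().to_dict()
    return dict(sorted(counts.items())), int(len(pairs))


def build_contingency(
    event: str,
    level: str,
    cohort_ids: set[str],
    reactions: Sequence[ReactionRecord] | pd.DataFrame,
    ptsoc: PtSocMap | None = None,
    margin: str = "pairs",
    universe_ids: set[str] | None = None,
) -> ContingencyTable:
    """Assemble the 2x2 table for one event at PT or SOC level.

    ``a`` is always the number of unique cohort reports with at least one PT
    in the event class (multi-PT reports never double count).  With
    ``margin="pairs"`` (default) the totals ``a+b`` and ``c+d`` are
    report-event pair counts; with ``margin="reports"`` they are unique
    report counts.  ``universe_ids`` restricts the report universe (used by
    subgroup analysis); by default every report appearing in ``reactions``
    belongs to the background.
    """
    level = level.upper()
    if level not in {"PT", "SOC"}:
        raise ValueError(f"level must be PT or SOC, got {level!r}")
    if margin not in {"pairs", "reports"}:
        raise ValueError(f"margin must be 'pairs' or 'reports', got {margin!r}")
    pairs = reactions if isinstance(reactions, pd.DataFrame) else unique_pairs(reactions)
    if universe_ids is not None:
        pairs = pairs[pairs["primary_id"].isin(universe_ids)]
    event_n = normalize_term(event)
    if level == "SOC":
        if ptsoc is None:
            raise ValueError("SOC-level tables require a PT->SOC map")
        in_class = pairs["pt"].map(ptsoc.soc_of) == event_n
    else:
        in_class = pairs["pt"] == event_n
    is_cohort = pairs["primary_id"].isin(cohort_ids)

    a = int(pairs.loc[in_class & is_cohort, "primary_id"].nunique())
    c = int(pairs.loc[in_class & ~is_cohort, "primary_id"].nunique())
    if margin == "pairs":
        cohort_margin = int(is_cohort.sum())
        bg_margin = int((~is_cohort).sum())
    else:
        cohort_margin = int(pairs.loc[is_cohort, "primary_id"].nunique())
        bg_margin = int(pairs.loc[~is_cohort, "primary_id"].nunique())
    return ContingencyTable(a=a, b=cohort_margin - a, c=c, d=bg_margin - c,
                            event=event_n, level=level)


def _pct(count: int, n: int) -> float:
    """Percentage at one decimal, rounded half-up as printed tables are."""
    if n == 0:
        return 0.0
    exact = Decimal(100 * count) / Decimal(n)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def age_band(age_years: float | None) -> str:
    """Assign an age in years to the summary bands.

    Bands are half-open — [0,18), [18,65), [65,85), [85,inf) — so the
    partition is well defined at the published band edges 65 and 85.
    """
    if age_years is None:
        return MISSING_LABEL
    if age_years < 18:
        return "<18"
    if age_years < 65:
        return "18-65"
    if age_years < 85:
        return "65-85"
    return ">85"


@dataclass
class DemographicSummary:
    """Counts and percentages per characteristic for a report cohort."""

    n: int
    sections: dict[str, list[tuple[str, int, float]]] = field(default_factory=dict)

    def section(self, name: str) -> dict[str, tuple[int, float]]:
        return {cat: (cnt, pct) for cat, cnt, pct in self.sections[name]}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"characteristic": sec, "category": cat, "count": cnt, "percent": pct}
            for sec, entries in self.sections.items()
            for cat, cnt, pct in entries
        ]
        return pd.DataFrame(rows, columns=["characteristic", "category", "count", "percent"])


def summarize_demographics(
    reports: Sequence[ReportRecord], top_k_countries: int = 5
) -> DemographicSummary:
    """Table-1-style cohort summary: sex, age band, top-k countries,
    reporter type, report year.  Percentages use the cohort size as the
    denominator for every characteristic and are rounded to one decimal."""
    n = len(reports)
    summary = DemographicSummary(n=n)

    sex_counts = Counter(
        r.sex.upper() if r.sex and r.sex.upper() in {"M", "F"} else MISSING_LABEL
        for r in reports
    )
    summary.sections["sex"] = [
        (cat, sex_counts.get(cat, 0), _pct(sex_counts.get(cat, 0), n))
        for cat in ("M", "F", MISSING_LABEL)
    ]

    band_counts = Counter(age_band(r.age_years) for r in reports)
    summary.sections["age"] = [
        (cat, band_counts.get(cat, 0), _pct(band_counts.get(cat, 0), n))
        for cat in AGE_BANDS + (MISSING_LABEL,)
    ]

    country_counts = Counter(r.country for r in reports if r.country)
    top = country_counts.most_common(top_k_countries)
    summary.sections["country"] = [(c, k, _pct(k, n)) for c, k in top]

    rep_counts = Counter(r.reporter if r.reporter else MISSING_LABEL for r in reports)
    summary.sections["reporter"] = [
        (cat, rep_counts.get(cat, 0), _pct(rep_counts.get(cat, 0), n))
        for cat in ("HCP", "non-HCP", MISSING_LABEL)
    ]

    year_counts = Counter(r.report_year for r in reports if r.report_year is not None)
    summary.sections["report_year"] = [
        (str(y), year_counts[y], _pct(year_counts[y], n)) for y in sorted(year_counts)
    ]
    return summary
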