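"""The four detectors, the empirical-Bayes machinery and the conjunction."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from faersvig.cohort import ContingencyTable
from faersvig.disproportionality import (
    CLASSIC_PRIOR,
    MgpsHyperparams,
    Thresholds,
    bcpnn_ic,
    ebgm_from_counts,
    evaluate_signal,
    fit_mgps_prior,
    mgps_ebgm,
    pair_counts,
    prr_stat,
    rank_and_report,
    ror_stat,
    subgroup_analysis,
)
from faersvig.faers_io import ReactionRecord

from conftest import make_report


def table(a, b, c, d, event="E"):
    return ContingencyTable(a, b, c, d, event=event)


def random_tables(n, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        yield table(int(rng.integers(0, 200)), int(rng.integers(1, 5000)),
                    int(rng.integers(1, 5000)), int(rng.integers(1, 200000)))


# ---------------------------------------------------------------------------
# Closed-form oracles written independently of the implementation


def oracle_ror(t):
    ror = t.a * t.d / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return ror, ror * math.exp(-1.959963984540054 * se)


def oracle_prr(t):
    return (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))


def oracle_chi2(t):
    n = t.n_total
    total = 0.0
    for obs, row, col in (
        (t.a, t.a + t.b, t.a + t.c), (t.b, t.a + t.b, t.b + t.d),
        (t.c, t.c + t.d, t.a + t.c), (t.d, t.c + t.d, t.b + t.d),
    ):
        exp = row * col / n
        total += (obs - exp) ** 2 / exp
    return total


def oracle_ic(t):
    e = (t.a + t.b) * (t.a + t.c) / t.n_total
    return math.log2((t.a + 0.5) / (e + 0.5))


def oracle_ebgm(a, e, prior=CLASSIC_PRIOR):
    """Numerical integration over the explicit posterior density on a dense
    log-lambda grid (independent of the digamma closed form and the gamma
    CDF used by the implementation)."""
    # wide range: with a=0 the small-shape posterior component keeps
    # non-negligible log-lambda mass down to ~1e-40
    u = np.linspace(math.log(1e-40), math.log(1e6), 800_001)
    lam = np.exp(u)
    prior_pdf = (prior.p * stats.gamma.pdf(lam, prior.alpha1, scale=1 / prior.beta1)
                 + (1 - prior.p) * stats.gamma.pdf(lam, prior.alpha2,
                                                   scale=1 / prior.beta2))
    # density in u-space: f(lam) * lam
    dens = stats.poisson.pmf(a, lam * e) * prior_pdf * lam
    z = np.trapezoid(dens, u)
    mean_log = np.trapezoid(u * dens, u) / z
    ebgm = math.exp(mean_log)
    cdf = integrate.cumulative_trapezoid(dens, u, initial=0.0) / z
    eb05 = float(np.interp(0.05, cdf, lam))
    return ebgm, eb05


# ---------------------------------------------------------------------------


class TestFrequentist:
    def test_symmetric_table_is_null(self):
        t = table(10, 10, 10, 10)
        ror, low, high = ror_stat(t)
        prr, chi2 = prr_stat(t)
        assert ror == pytest.approx(1.0)
        assert low < 1.0 < high
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_textbook_table(self):
        t = table(10, 90, 100, 9900)
        assert ror_stat(t)[0] == pytest.approx(11.0)
        prr, chi2 = prr_stat(t)
        assert prr == pytest.approx(10.0)
        assert chi2 == pytest.approx(oracle_chi2(t), rel=1e-12)

    def test_zero_cells_non_computable(self):
        assert math.isnan(ror_stat(table(5, 0, 3, 10))[0])
        assert math.isnan(ror_stat(table(5, 3, 0, 10))[0])
        assert math.isnan(prr_stat(table(5, 5, 0, 10))[0])
        ror, low, high = ror_stat(table(0, 5, 3, 10))
        assert ror == 0.0 and math.isnan(low)

    def test_yates_correction_reduces_chi2(self):
        t = table(10, 90, 100, 9900)
        assert prr_stat(t, yates=True)[1] < prr_stat(t)[1]

    def test_closed_forms_match_oracles_on_random_tables(self):
        for t in random_tables(1000, seed=7):
            if min(t.a, t.b, t.c, t.d) == 0:
                continue
            ror, low, _ = ror_stat(t)
            o_ror, o_low = oracle_ror(t)
            assert ror == pytest.approx(o_ror, rel=1e-12)
            assert low == pytest.approx(o_low, rel=1e-12)
            prr, chi2 = prr_stat(t)
            assert prr == pytest.approx(oracle_prr(t), rel=1e-12)
            assert chi2 == pytest.approx(oracle_chi2(t), rel=1e-9)
            ic, _ = bcpnn_ic(t)
            assert ic == pytest.approx(oracle_ic(t), rel=1e-12)

    def test_ror_exceeds_prr_iff_above_one(self):
        """Algebraic identity of the 2x2: ROR > PRR exactly when ROR > 1
        (the pattern visible in every positive row of published tables)."""
        for t in random_tables(500, seed=11):
            if min(t.a, t.b, t.c, t.d) == 0:
                continue
            ror = ror_stat(t)[0]
            prr = prr_stat(t)[0]
            if ror > 1:
                assert ror > prr
            elif ror < 1:
                assert ror < prr


class TestBcpnn:
    def test_null_case_ic_near_zero(self):
        t = table(1000, 9000, 10000, 90000)  # observed equals expected
        ic, _ = bcpnn_ic(t)
        assert ic == pytest.approx(0.0, abs=0.01)

    def test_worked_example(self):
        t = table(10, 90, 100, 9900)
        e = t.expected
        assert e == pytest.approx(1.0891, abs=1e-4)
        ic, ic025 = bcpnn_ic(t)
        assert ic == pytest.approx(math.log2(10.5 / (e + 0.5)), rel=1e-12)
        assert ic025 == pytest.approx(ic - 3.3 / math.sqrt(10.5) - 2 / 10.5 ** 1.5,
                                      rel=1e-12)

    def test_zero_count_is_finite(self):
        ic, ic025 = bcpnn_ic(table(0, 100, 50, 10000))
        assert math.isfinite(ic) and math.isfinite(ic025)
        assert ic025 < ic < 0

    def test_bate_variant_close_to_shrinkage_for_large_counts(self):
        t = table(500, 1500, 5000, 93000)
        ic_s, _ = bcpnn_ic(t, method="shrinkage")
        ic_b, _ = bcpnn_ic(t, method="bate")
        assert ic_b == pytest.approx(ic_s, abs=0.05)


class TestMgps:
    def test_ebgm_matches_quadrature_oracle_on_grid(self):
        """EBGM/EB05 equal an independent numerical-integration oracle to
        4 significant figures over a 20-point (a, E) grid."""
        grid = [(a, e) for a in (0, 1, 3, 10, 50)
                for e in (0.2, 1.089, 5.0, 20.0)]
        assert len(grid) == 20
        for a, e in grid:
            ebgm, eb05 = ebgm_from_counts(a, e)
            o_ebgm, o_eb05 = oracle_ebgm(a, e)
            assert ebgm == pytest.approx(o_ebgm, rel=5e-4)
            assert eb05 == pytest.approx(o_eb05, rel=5e-4)

    def test_worked_example_brackets(self):
        # a=10, E=1.089 under the classic prior: shrinkage pulls the
        # estimate below the raw O/E but keeps it above 1.
        ebgm, eb05 = ebgm_from_counts(10, 1.089)
        assert 1.0 < ebgm < 10 / 1.089
        assert eb05 < ebgm

    def test_shrinkage_vanishes_for_large_counts(self):
        r = 3.0
        a = 100_000
        ebgm, _ = ebgm_from_counts(a, a / r)
        assert ebgm == pytest.approx(r, rel=0.01)

    def test_shrinkage_monotone_in_count(self):
        r = 4.0
        gaps = []
        for a in (3, 10, 30, 100, 300, 1000):
            ebgm, _ = ebgm_from_counts(a, a / r)
            gaps.append(abs(ebgm - r))
        assert all(g1 >= g2 - 1e-9 for g1, g2 in zip(gaps, gaps[1:]))

    def test_eb05_below_ebgm_everywhere(self):
        for a, e in [(0, 0.5), (2, 0.1), (5, 5), (40, 3), (200, 250)]:
            ebgm, eb05 = ebgm_from_counts(a, e)
            assert eb05 < ebgm

    def test_zero_expected_non_computable(self):
        ebgm, eb05 = ebgm_from_counts(3, 0.0)
        assert math.isnan(ebgm) and math.isnan(eb05)

    def test_ic_converges_to_log2_ebgm_for_large_counts(self):
        """The empirical near-identity IC = log2(EBGM) in large-count rows
        of published tables, asserted at a >= 1000 within 0.02 bits."""
        for a, r in [(1000, 2.0), (2000, 8.0), (5000, 1.2)]:
            # margins chosen so the table's expected count is exactly a/r:
            # (a+b)(a+c)/n = (10a)(6a)/(60ra) = a/r
            b, c = 9 * a, 5 * a
            n = round(10 * r * (a + c))
            t = table(a, b, c, n - a - b - c)
            assert t.expected == pytest.approx(a / r, rel=1e-9)
            ic, _ = bcpnn_ic(t)
            ebgm, _ = ebgm_from_counts(t.a, t.expected)
            assert ic - math.log2(ebgm) == pytest.approx(0.0, abs=0.02)

    def test_small_pair_sets_fall_back_to_classic_prior(self):
        prior = fit_mgps_prior([1, 2, 3], [1.0, 1.0, 1.0])
        assert prior == CLASSIC_PRIOR

    def test_null_simulation_prior_mean_near_one(self):
        rng = np.random.default_rng(123)
        e = 10 ** rng.uniform(-1, 2, size=5000)
        a = rng.poisson(e)
        prior = fit_mgps_prior(a, e)
        assert prior != CLASSIC_PRIOR
        assert 0.8 <= prior.mean <= 1.2

    def test_two_cluster_simulation_recovers_minority_weight(self):
        rng = np.random.default_rng(456)
        n = 5000
        lam = np.where(rng.random(n) < 0.1, 8.0, 1.0)
        e = 10 ** rng.uniform(-0.5, 1.5, size=n)
        a = rng.poisson(lam * e)
        prior = fit_mgps_prior(a, e)
        mean1 = prior.alpha1 / prior.beta1
        mean2 = prior.alpha2 / prior.beta2
        minority = prior.p if mean1 > mean2 else 1 - prior.p
        assert minority == pytest.approx(0.1, abs=0.1)

    def test_invalid_hyperparams_rejected(self):
        with pytest.raises(ValueError):
            MgpsHyperparams(-1, 1, 1, 1, 0.5)
        with pytest.raises(ValueError):
            MgpsHyperparams(1, 1, 1, 1, 1.5)


class TestConjunction:
    def test_minimum_count_gate(self):
        t = table(2, 1, 1, 100000)  # huge ROR but a < 3
        res = evaluate_signal(t)
        assert not res.positive
        assert not res.flag_ror and not res.flag_prr

    def test_null_table_all_flags_false(self):
        res = evaluate_signal(table(100, 900, 1000, 9000))
        assert not any([res.flag_ror, res.flag_prr, res.flag_bcpnn, res.flag_mgps])

    def test_strong_signal_positive(self):
        res = evaluate_signal(table(100, 400, 100, 9500))
        assert res.positive

    def test_non_computable_statistic_fails_its_flag(self):
        res = evaluate_signal(table(5, 5, 0, 100))
        assert not res.flag_ror and not res.flag_prr
        assert not res.positive

    def test_interval_orderings(self):
        res = evaluate_signal(table(40, 160, 200, 19600))
        assert res.ror_low <= res.ror <= res.ror_high
        assert res.ic025 <= res.ic
        assert res.ebgm05 <= res.ebgm

    def test_tightening_any_threshold_shrinks_positive_set(self):
        tables = [t for t in random_tables(200, seed=3)]
        base = Thresholds()
        for tighter in (
            Thresholds(min_count=5), Thresholds(ror_low=1.5),
            Thresholds(prr_min=3.0), Thresholds(chi2_min=8.0),
            Thresholds(ic025_min=0.5), Thresholds(ebgm05_min=3.0),
        ):
            pos_base = {i for i, t in enumerate(tables)
                        if evaluate_signal(t, thresholds=base).positive}
            pos_tight = {i for i, t in enumerate(tables)
                         if evaluate_signal(t, thresholds=tighter).positive}
            assert pos_tight <= pos_base


class TestRankAndReport:
    def results(self, specs):
        out = []
        for event, a in specs:
            out.append(evaluate_signal(table(a, 100, 50, 10000, event=event)))
        return out

    def test_descending_count_order(self):
        df = rank_and_report(self.results([("X", 5), ("Y", 9), ("Z", 7)]))
        assert df["count"].tolist() == [9, 7, 5]

    def test_alphabetical_tie_break(self):
        df = rank_and_report(self.results([("B", 7), ("A", 7)]))
        assert df["event"].tolist() == ["A", "B"]

    def test_truncation(self):
        df = rank_and_report(self.results([(f"E{i:03d}", i + 3) for i in range(60)]),
                             top_n=50)
        assert len(df) == 50

    def test_label_status_stars_unlabeled_events(self):
        df = rank_and_report(self.results([("KNOWN", 5), ("NOVEL", 9)]),
                             known_labels=["known"])
        stars = dict(zip(df["event"], df["unlabeled"]))
        assert stars == {"NOVEL": "*", "KNOWN": ""}


class TestSubgroup:
    def build_db(self):
        """Hand-built database with a male-only implanted signal: per sex,
        50 cohort reports against 950 background reports; 40 male cohort
        reports and 5 background reports per sex carry the event."""
        reports, reactions, cohort_ids = [], [], set()
        pid = 0
        for sex in ("M", "F"):
            for i in range(1000):
                pid += 1
                spid = str(pid)
                reports.append(make_report(pid, fda="20200101", sex=sex))
                reactions.append(ReactionRecord(spid, "BACKGROUND PAIN"))
                if i < 50:
                    cohort_ids.add(spid)
                    if sex == "M" and i < 40:
                        reactions.append(ReactionRecord(spid, "AGGRESSION"))
                elif i < 55:
                    reactions.append(ReactionRecord(spid, "AGGRESSION"))
        return reports, reactions, cohort_ids

    def test_male_only_signal_found_in_male_stratum(self):
        reports, reactions, cohort_ids = self.build_db()
        tables = subgroup_analysis("sex", reports, reactions, cohort_ids,
                                   ["AGGRESSION", "BACKGROUND PAIN"])
        male = tables["M"].set_index("event")
        assert bool(male.loc["AGGRESSION", "positive"])
        female = tables["F"]
        assert ("AGGRESSION" not in set(female["event"])
                or not bool(female.set_index("event").loc["AGGRESSION", "positive"]))

    def test_zero_count_events_absent_from_stratum_table(self):
        reports, reactions, cohort_ids = self.build_db()
        tables = subgroup_analysis("sex", reports, reactions, cohort_ids,
                                   ["AGGRESSION"])
        assert "AGGRESSION" not in set(tables["F"]["event"])

    def test_stratum_counts_partition_pooled_counts(self, default_db_loaded):
        config, paths, truth, reports, drugs, reactions, thers = default_db_loaded
        from faersvig.cohort import build_contingency, unique_pairs

        cohort_ids = set(truth.target_ids)
        tables = subgroup_analysis("sex", reports, reactions, cohort_ids,
                                   ["EYE IRRITATION", "PT_0001"])
        pairs = unique_pairs(reactions)
        sex_of = {r.primary_id: r.sex for r in reports}
        for event in ("EYE IRRITATION", "PT_0001"):
            stratum_sum = sum(
                int(tab.set_index("event").loc[event, "count"])
                for tab in tables.values() if event in set(tab["event"])
            )
            known_sex_ids = {p for p, s in sex_of.items() if s in ("M", "F")}
            pooled = build_contingency(event, "PT", cohort_ids & known_sex_ids,
                                       pairs, universe_ids=known_sex_ids)
            assert stratum_sum == pooled.a

    def test_unknown_stratifier_rejected(self):
        with pytest.raises(ValueError):
            subgroup_analysis("country", [], [], set(), [])
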