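import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from faersvig import cohort as cohort_mod
from faersvig import disproportionality as dis
from faersvig import faers_io
from faersvig.synthetic_faers import SimConfig, generate

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_report(pid, case=None, fda=None, **kw):
    return faers_io.ReportRecord(
        primary_id=str(pid), case_id=str(case if case is not None else pid),
        fda_dt=fda, **kw)


@pytest.fixture(scope="session")
def default_db(tmp_path_factory):
    """One default-condition synthetic database, generated once and shared
    (read-only) by tests that need a realistic file set."""
    out = tmp_path_factory.mktemp("synthdb")
    config = SimConfig(seed=20260920)
    paths, truth = generate(config, out)
    return config, paths, truth


@pytest.fixture(scope="session")
def default_db_loaded(default_db):
    """Parsed and deduplicated records for the shared database."""
    config, paths, truth = default_db
    reports = faers_io.deduplicate(faers_io.read_table(paths["DEMO"], "DEMO"))
    drugs = faers_io.read_table(paths["DRUG"], "DRUG")
    reactions = faers_io.read_table(paths["REAC"], "REAC")
    thers = faers_io.read_table(paths["THER"], "THER")
    return config, paths, truth, reports, drugs, reactions, thers


def signal_scan(config, paths, thresholds=dis.Thresholds()):
    """Minimal ingest -> cohort -> prior -> per-PT conjunction scan used by
    the operating-characteristic tests; returns the ranked PT table."""
    reports = faers_io.deduplicate(faers_io.read_table(paths["DEMO"], "DEMO"))
    drugs = faers_io.read_table(paths["DRUG"], "DRUG")
    reactions = faers_io.read_table(paths["REAC"], "REAC")
    cohort_ids = cohort_mod.select_cohort(reports, drugs, [config.target_drug])
    pairs = cohort_mod.unique_pairs(reactions)
    ps_drug = {d.primary_id: cohort_mod.normalize_term(d.drug_name)
               for d in drugs if d.role_code == "PS"}
    pc = dis.pair_counts(pairs, ps_drug)
    prior = dis.fit_mgps_prior(pc["a"], pc["expected"])
    counts, _ = cohort_mod.count_events(cohort_ids, reactions)
    results = []
    for pt in counts:
        t = cohort_mod.build_contingency(pt, "PT", cohort_ids, pairs)
        results.append(dis.evaluate_signal(t, prior, thresholds))
    return dis.rank_and_report(results)
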