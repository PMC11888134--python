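import datetime

import numpy as np
import pytest

from pvsignal import (
    ConfounderSpec,
    DrugEntry,
    DrugSpec,
    ICSRReport,
    ReactionEntry,
    SyntheticConfig,
    Vocabulary,
)


def make_report(
    report_id,
    terms=(),
    drugs=(),
    age_group="45-64",
    sex="female",
    serious="unknown",
    criteria=(),
):
    """Compact ICSR builder: ``drugs`` is a list of (code, role) or
    (code, role, extra-kwargs) tuples."""
    drug_entries = []
    for d in drugs:
        code, role, extra = (d[0], d[1], d[2] if len(d) > 2 else {})
        drug_entries.append(DrugEntry(report_id=report_id, drug_code=code, role=role, **extra))
    reactions = []
    for t in terms:
        if isinstance(t, tuple):
            term, onset = t
            reactions.append(ReactionEntry(report_id=report_id, term=term, onset_date=onset))
        else:
            reactions.append(ReactionEntry(report_id=report_id, term=t))
    return ICSRReport(
        report_id=report_id,
        age_group=age_group,
        sex=sex,
        serious=serious,
        seriousness_criteria=frozenset(criteria),
        drugs=drug_entries,
        reactions=reactions,
    )


@pytest.fixture
def vocab():
    return Vocabulary(
        smq_terms=frozenset({"Hypertension", "Blood pressure increased"}),
        target_drugs={
            "fluoxetine": frozenset({"N06AB03"}),
            "sertraline": frozenset({"N06AB06"}),
        },
        antihypertensive_codes=frozenset({"C02"}),
        hypertensive_inducer_codes=frozenset({"H02AB"}),
        comparator_population_codes=frozenset({"N06A"}),
        stroke_terms=frozenset({"Cerebrovascular accident"}),
        mi_terms=frozenset({"Myocardial infarction"}),
    )


@pytest.fixture
def ten_report_db():
    """10 adult reports: 3 cases, 4 sertraline-exposed, overlap 2.

    Hand enumeration for the sertraline 2x2: a=2, b=2, c=1, d=5.
    """
    S = ("N06AB06", "suspect")
    other = ("A02BC01", "suspect")
    return [
        make_report("R1", terms=["Hypertension"], drugs=[S]),
        make_report("R2", terms=["Blood pressure increased"], drugs=[S]),
        make_report("R3", terms=["Hypertension"], drugs=[other]),
        make_report("R4", terms=["Nausea"], drugs=[S]),
        make_report("R5", terms=["Rash"], drugs=[S]),
        make_report("R6", terms=["Nausea"], drugs=[other]),
        make_report("R7", terms=["Headache"], drugs=[other]),
        make_report("R8", terms=["Rash"], drugs=[other]),
        make_report("R9", terms=["Fatigue"], drugs=[other]),
        make_report("R10", terms=["Dizziness"], drugs=[other]),
    ]


def null_config(n_reports=50_000, n_drugs=3, prevalence=0.1, log_or=0.0, seed=0, **kwargs):
    """Flat synthetic config: no covariate effects, no confounding."""
    base_logit = float(np.log(0.022 / 0.978))
    specs = [
        DrugSpec(
            drug_code=f"N06AB{i:02d}",
            label=f"drug{i}",
            exposure_prevalence=prevalence,
            log_or=log_or,
        )
        for i in range(1, n_drugs + 1)
    ]
    defaults = dict(p_other_antidepressant=0.0, p_stroke_term=0.0, p_mi_term=0.0)
    defaults.update(kwargs)
    base_logit = defaults.pop("baseline_event_logit", base_logit)
    confounders = defaults.pop("confounders", ConfounderSpec())
    return SyntheticConfig(
        n_reports=n_reports,
        baseline_event_logit=base_logit,
        drug_specs=specs,
        confounders=confounders,
        seed=seed,
        **defaults,
    )


@pytest.fixture
def start(request):
    return datetime.date(2020, 1, 1)
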