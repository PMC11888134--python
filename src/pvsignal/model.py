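"""Model/Results interface over the case/non-case machinery.

``CaseNonCaseStudy`` is built from a report database plus a vocabulary and
holds the analytic dataset; ``fit()`` returns a
:class:`DisproportionalityResults` carrying per-drug crude and adjusted
reporting odds ratios, their confidence intervals, the signal flags and a
``summary()`` table.  Dose-effect and descriptive analyses hang off the
results object.

Example
-------
>>> from pvsignal import CaseNonCaseStudy, make_paper_like_config
>>> study = CaseNonCaseStudy.from_synthetic(make_paper_like_config(scale=0.02, seed=7))
>>> res = study.fit()
>>> print(res.summary())                        # doctest: +SKIP
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .dataset import CLASS_LABEL, AnalyticDataset, build_analytic_dataset
from .descriptives import CohortSummary, TTOSummary, challenge_counts, summarize_cohort, time_to_onset
from .disproportionality import signal_results
from .dose import DoseEffectResult, stratified_analysis
from .io import ICSRFrames, frames_to_reports, load_default_vocabulary, load_vocabulary, read_frames
from .simulate import SyntheticConfig, generate_frames
from .types import ICSRReport, SignalResult, Vocabulary


class CaseNonCaseStudy:
    """Case/non-case disproportionality study of one report database.

    Parameters
    ----------
    reports : list of ICSRReport or ICSRFrames
        The report database.
    vocabulary : Vocabulary, optional
        Event terms and drug code sets; defaults to the shipped fixture.
    role_policy : {"any_role", "suspect_only"}
        Whether exposure counts drugs in any role or suspect entries only.
    population_filter : {"whole_database", "antidepressant_only"}
        Optional restriction to the antidepressant-treated population.
    """

    def __init__(
        self,
        reports: Iterable[ICSRReport] | ICSRFrames,
        vocabulary: Optional[Vocabulary] = None,
        role_policy: str = "any_role",
        population_filter: str = "whole_database",
    ) -> None:
        self.vocabulary = vocabulary if vocabulary is not None else load_default_vocabulary()
        self.role_policy = role_policy
        self.population_filter = population_filter
        self._frames = reports if isinstance(reports, ICSRFrames) else None
        self._reports = None if self._frames is not None else list(reports)
        self.dataset: AnalyticDataset = build_analytic_dataset(
            self._frames if self._frames is not None else self._reports,
            self.vocabulary,
            role_policy=role_policy,
            population_filter=population_filter,
        )

    # Constructors ---------------------------------------------------------

    @classmethod
    def from_csv(
        cls,
        reports_path: str | Path,
        drugs_path: str | Path,
        reactions_path: str | Path,
        vocabulary_path: Optional[str | Path] = None,
        **kwargs,
    ) -> "CaseNonCaseStudy":
        vocab = load_vocabulary(vocabulary_path) if vocabulary_path else None
        frames = read_frames(reports_path, drugs_path, reactions_path)
        return cls(frames, vocabulary=vocab, **kwargs)

    @classmethod
    def from_synthetic(
        cls, config: SyntheticConfig, vocabulary: Optional[Vocabulary] = None, **kwargs
    ) -> "CaseNonCaseStudy":
        return cls(generate_frames(config), vocabulary=vocabulary, **kwargs)

    # Data access ----------------------------------------------------------

    @property
    def n_records(self) -> int:
        return self.dataset.n

    def case_reports(self) -> list[ICSRReport]:
        """Joined report objects for the analytic cases (descriptives input)."""
        frames = self._frames
        if frames is None:
            from .io import reports_to_frames

            frames = reports_to_frames(self._reports)
        case_ids = set(self.dataset.df.loc[self.dataset.df["is_case"], "report_id"])
        sub = ICSRFrames(
            reports=frames.reports[frames.reports["report_id"].isin(case_ids)],
            drugs=frames.drugs[frames.drugs["report_id"].isin(case_ids)],
            reactions=frames.reactions[frames.reactions["report_id"].isin(case_ids)],
        )
        return frames_to_reports(sub)

    # Fitting --------------------------------------------------------------

    def fit(self, adjusted: bool = True) -> "DisproportionalityResults":
        """Estimate crude (and optionally adjusted) RORs for every drug and
        the pooled class."""
        results = signal_results(self.dataset, adjusted=adjusted)
        return DisproportionalityResults(self, results, adjusted=adjusted)


class DisproportionalityResults:
    """Fitted per-drug disproportionality estimates."""

    def __init__(
        self, model: CaseNonCaseStudy, results: list[SignalResult], adjusted: bool
    ) -> None:
        self.model = model
        self.results = results
        self.adjusted = adjusted

    def __getitem__(self, drug: str) -> SignalResult:
        for r in self.results:
            if r.drug == drug:
                return r
        raise KeyError(drug)

    @property
    def class_result(self) -> SignalResult:
        return self[CLASS_LABEL]

    @property
    def n_signals(self) -> int:
        return sum(1 for r in self.results if r.signal)

    def as_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "drug": r.drug,
                "cases": r.a,
                "non_cases": r.b,
                "ror": r.ror,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "aror": r.aror,
                "aci_low": r.aci_low,
                "aci_high": r.aci_high,
                "signal": r.signal,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Text summary table (drug, cells, ROR, aROR, signal)."""

        def fmt(v, nd=2):
            return "NA" if v is None else f"{v:.{nd}f}"

        lines = [
            "Case/non-case disproportionality analysis",
            f"records: {self.model.n_records:,}   role policy: {self.model.role_policy}   "
            f"population: {self.model.population_filter}",
            "",
            f"{'drug':<16}{'cases':>8}{'non-cases':>11}{'ROR':>8}{'95% CI':>16}"
            f"{'aROR':>8}{'95% CI':>16}{'signal':>8}",
        ]
        for r in self.results:
            ci = "NA" if r.ror is None else f"({fmt(r.ci_low)}-{fmt(r.ci_high)})"
            aci = "NA" if r.aror is None else f"({fmt(r.aci_low)}-{fmt(r.aci_high)})"
            sig = "NA" if r.signal is None else ("yes" if r.signal else "no")
            lines.append(
                f"{r.drug:<16}{r.a:>8,}{r.b:>11,}{fmt(r.ror):>8}{ci:>16}"
                f"{fmt(r.aror):>8}{aci:>16}{sig:>8}"
            )
        return "\n".join(lines)

    # Downstream analyses --------------------------------------------------

    def dose_effect(self, drug: Optional[str] = None, adjusted: bool = True):
        """Median-split dose analysis for one drug, or all drugs when
        ``drug`` is None."""
        if drug is not None:
            return stratified_analysis(self.model.dataset, drug, adjusted=adjusted)
        return [
            stratified_analysis(self.model.dataset, d, adjusted=adjusted)
            for d in self.model.dataset.drug_labels
        ]

    def descriptives(self, n_total_reports: Optional[int] = None) -> CohortSummary:
        return summarize_cohort(
            self.model.case_reports(), self.model.vocabulary, n_total_reports=n_total_reports
        )

    def time_to_onset(self, drug: str) -> TTOSummary:
        return time_to_onset(self.model.case_reports(), drug, self.model.vocabulary)

    def challenge_counts(self, drug: str) -> tuple[int, int]:
        return challenge_counts(self.model.case_reports(), drug, self.model.vocabulary)
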