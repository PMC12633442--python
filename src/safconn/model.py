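"""Model/Results presentation layer over the concordance and reliability analyses.

Mirrors the fit/Results idiom of statistical modelling packages: an analysis
object is built from data, ``fit()`` performs the computation, and the
returned results object carries estimates, per-group breakdowns and a
``summary()`` table.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .atlas import (
    PARTITIONS,
    ConnectionKey,
    HistologyReference,
    OutcomeTable,
    load_histology_reference,
)
from .concordance import (
    ClassificationConfig,
    ConfusionSummary,
    ConnectionOutcome,
    SubjectObservation,
    classify_connection,
    outcomes_from_table,
    summarize,
    summarize_partition,
)
from .reliability import ReliabilityReport, between_subject, within_subject
from .streamlines import DensityMap

__all__ = [
    "ConcordanceAnalysis",
    "ConcordanceResults",
    "ReliabilityAnalysis",
    "ReliabilityResults",
]


class ConcordanceAnalysis:
    """Histology-concordance classification of tractography observations.

    Parameters
    ----------
    observations
        Mapping connection -> per-subject observations (one per subject).
    reference
        Histology reference; defaults to the packaged table.
    config
        Classification thresholds.
    """

    def __init__(
        self,
        observations: Mapping[ConnectionKey, Sequence[SubjectObservation]],
        reference: HistologyReference | None = None,
        config: ClassificationConfig = ClassificationConfig(),
    ) -> None:
        self.observations = dict(observations)
        self.reference = reference if reference is not None else load_histology_reference()
        self.config = config

    @classmethod
    def from_outcome_table(
        cls, table: OutcomeTable, reference: HistologyReference | None = None
    ) -> "ConcordanceResults":
        """Results directly from a packaged per-connection outcome table."""
        reference = reference if reference is not None else load_histology_reference()
        outcomes = outcomes_from_table(table, reference)
        return ConcordanceResults(outcomes=outcomes)

    def fit(self) -> "ConcordanceResults":
        outcomes = [
            classify_connection(obs, self.reference[key], self.config)
            for key, obs in self.observations.items()
        ]
        return ConcordanceResults(outcomes=outcomes)


@dataclass
class ConcordanceResults:
    """Per-connection outcomes with overall and per-partition confusion statistics."""

    outcomes: list[ConnectionOutcome]
    _overall: ConfusionSummary | None = field(default=None, repr=False)

    @property
    def overall(self) -> ConfusionSummary:
        if self._overall is None:
            self._overall = summarize(self.outcomes)
        return self._overall

    def partition(self, name: str) -> ConfusionSummary:
        return summarize_partition(self.outcomes, name)

    def outcomes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "area_a": [o.connection.area_a for o in self.outcomes],
                "area_b": [o.connection.area_b for o in self.outcomes],
                "label": [o.label for o in self.outcomes],
                "population_fraction": [o.population_fraction for o in self.outcomes],
                "population_plausible": [o.population_plausible for o in self.outcomes],
                "histology": [o.histology for o in self.outcomes],
            }
        )

    def summary(self) -> pd.DataFrame:
        """One row per scope (overall + each partition) with counts and statistics."""
        rows = []
        for name, s in [("overall", self.overall)] + [
            (p, self.partition(p)) for p in PARTITIONS
        ]:
            rows.append(
                {
                    "scope": name,
                    "n": s.total,
                    "tp": s.tp,
                    "rtp": s.rtp,
                    "tn": s.tn,
                    "fp": s.fp,
                    "fn": s.fn,
                    "accuracy_pct": s.accuracy,
                    "sensitivity_pct": s.sensitivity,
                    "specificity_pct": s.specificity,
                    "precision_pct": s.precision,
                }
            )
        return pd.DataFrame(rows).set_index("scope")


class ReliabilityAnalysis:
    """Within- and between-subject reproducibility of bundle density maps.

    Parameters
    ----------
    maps
        Mapping subject -> {"test": DensityMap | None, "retest": ...}; the
        retest entry may be missing for single-session designs.
    """

    def __init__(
        self,
        maps: Mapping[str, Mapping[str, DensityMap | None]],
        label: str = "",
    ) -> None:
        self.maps = {s: dict(m) for s, m in maps.items()}
        self.label = label

    def fit(self, max_between_pairs: int | None = None, seed: int = 0) -> "ReliabilityResults":
        has_retest = any("retest" in m for m in self.maps.values())
        within = (
            within_subject(self.maps, label=self.label) if has_retest else None
        )
        between = between_subject(
            {s: m.get("test") for s, m in self.maps.items()},
            label=self.label,
            max_pairs=max_between_pairs,
            seed=seed,
        )
        return ReliabilityResults(within=within, between=between, label=self.label)


@dataclass
class ReliabilityResults:
    """Pooled wDice and bundle-adjacency reports per comparison design."""

    within: dict[str, ReliabilityReport] | None
    between: dict[str, ReliabilityReport]
    label: str = ""

    def summary(self) -> pd.DataFrame:
        rows = []
        designs = [("between_subject", self.between)]
        if self.within is not None:
            designs.insert(0, ("within_subject", self.within))
        for design, reports in designs:
            for metric, r in reports.items():
                rows.append(
                    {
                        "comparison": design,
                        "metric": metric,
                        "mean": r.mean,
                        "sd": r.sd,
                        "n_pairs": r.n_pairs,
                        "n_excluded": r.n_excluded,
                    }
                )
        return pd.DataFrame(rows).set_index(["comparison", "metric"])
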