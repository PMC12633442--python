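"""Presence calls, histology-concordance classification, and confusion statistics.

Each subject contributes a cleaned bundle per connection; the bundle counts as
*present* for that subject when it retains at least a minimum number of
streamlines after outlier rejection.  At the population level a connection is
present when reconstructed in more than 50% of subjects, and a present,
histology-supported, anatomically plausible connection is a true positive —
*robust* (RTP) when reconstructed in more than 80% of subjects.  A present
connection that is consistently implausible counts as a false positive even
when histology supports it (a trajectory false positive).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .atlas import (
    PARTITIONS,
    AtlasError,
    ConnectionKey,
    HistologyReference,
    OutcomeTable,
)
from .streamlines import Bundle, TractSpec, streamline_length

__all__ = [
    "SubjectObservation",
    "ClassificationConfig",
    "ConnectionOutcome",
    "ConfusionSummary",
    "round_half_away",
    "observe_subject",
    "plausibility_heuristic",
    "classify_connection",
    "outcomes_from_table",
    "summarize",
    "summarize_partition",
]


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds of the population classification.

    All fraction thresholds are strict (``>``).  ``min_streamlines_present``
    separates "no or few streamlines" from a reconstructed bundle;
    ``plausibility_fraction`` is the fraction of *present* subjects that must
    carry a plausible bundle for the population bundle to count as plausible.
    """

    presence_fraction: float = 0.5
    rtp_fraction: float = 0.8
    min_streamlines_present: int = 5
    plausibility_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.presence_fraction < self.rtp_fraction <= 1.0:
            raise ValueError("need 0 < presence_fraction < rtp_fraction <= 1")
        if self.min_streamlines_present < 1:
            raise ValueError("min_streamlines_present must be >= 1")


@dataclass(frozen=True)
class SubjectObservation:
    """Per-subject, per-connection presence/plausibility record."""

    subject_id: str
    connection: ConnectionKey
    n_streamlines_clean: int
    plausible: bool
    present: bool


@dataclass(frozen=True)
class ConnectionOutcome:
    """Population-level classification of one connection against histology."""

    connection: ConnectionKey
    population_present: bool
    population_fraction: float
    population_plausible: bool
    histology: str  # {"present", "absent"}
    label: str  # {"RTP", "TP", "TN", "FP", "FN"}


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion counts and derived statistics.

    ``tp`` includes the robust subset ``rtp``.  Percentages are exposed both
    unrounded and rounded (half away from zero); a statistic whose denominator
    is zero is ``None``, never 0 or 100.
    """

    tp: int
    rtp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @staticmethod
    def _pct(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    @property
    def accuracy(self) -> float | None:
        return self._pct(self.tp + self.tn, self.total)

    @property
    def sensitivity(self) -> float | None:
        return self._pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._pct(self.tn, self.tn + self.fp)

    @property
    def precision(self) -> float | None:
        return self._pct(self.tp, self.tp + self.fp)

    def rounded(self) -> dict[str, int | None]:
        return {
            name: (None if val is None else round_half_away(val))
            for name, val in (
                ("accuracy", self.accuracy),
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("precision", self.precision),
            )
        }


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (72.5 -> 73)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def observe_subject(
    bundle: Bundle,
    config: ClassificationConfig = ClassificationConfig(),
    plausible: bool | None = None,
) -> SubjectObservation:
    """Build the per-subject record from a cleaned bundle.

    ``plausible`` is the recorded visual-QA flag; when omitted the geometric
    heuristic (:func:`plausibility_heuristic`) is applied.  Empty or
    under-threshold bundles are marked absent (plausibility then moot).
    """
    n = len(bundle)
    present = n >= config.min_streamlines_present
    if plausible is None:
        plausible = plausibility_heuristic(bundle) if n > 0 else True
    return SubjectObservation(
        subject_id=bundle.subject_id,
        connection=bundle.connection,
        n_streamlines_clean=n,
        plausible=bool(plausible),
        present=present,
    )


def plausibility_heuristic(
    bundle: Bundle,
    loop_ratio: float = 0.25,
    max_turning_rad: float = 3.0 * math.pi,
    irregular_fraction: float = 0.5,
) -> bool:
    """Geometric surrogate for visual QA of a bundle.

    A streamline is *irregular* when it loops (end-to-end distance below
    ``loop_ratio`` times its arc length) or exceeds a total-curvature budget
    (summed absolute turning angle above ``max_turning_rad``).  The bundle is
    implausible when more than ``irregular_fraction`` of its streamlines are
    irregular.  Not applicable to empty bundles (raises ValueError).
    """
    if len(bundle) == 0:
        raise ValueError("plausibility heuristic not applicable to an empty bundle")
    n_irregular = 0
    for s in bundle.streamlines:
        arr = np.asarray(s, dtype=np.float64)
        length = streamline_length(arr)
        end_to_end = float(np.linalg.norm(arr[-1] - arr[0]))
        if length > 0 and end_to_end / length < loop_ratio:
            n_irregular += 1
            continue
        seg = np.diff(arr, axis=0)
        norms = np.linalg.norm(seg, axis=1)
        ok = norms > 1e-12
        seg = seg[ok] / norms[ok, None]
        if len(seg) >= 2:
            cosang = np.clip(np.einsum("ij,ij->i", seg[:-1], seg[1:]), -1.0, 1.0)
            if float(np.arccos(cosang).sum()) > max_turning_rad:
                n_irregular += 1
    return n_irregular / len(bundle) <= irregular_fraction


def classify_connection(
    observations: Sequence[SubjectObservation],
    histology_status: str,
    config: ClassificationConfig = ClassificationConfig(),
) -> ConnectionOutcome:
    """Classify one connection from its per-subject observations.

    Decision table (fractions strict):

    ====================  ==================  ==========  =====
    histology             population present  plausible   label
    ====================  ==================  ==========  =====
    present               yes                 yes         TP (RTP if fraction > rtp threshold)
    present               yes                 no          FP (trajectory false positive)
    present               no                  --          FN
    absent                yes                 --          FP
    absent                no                  --          TN
    ====================  ==================  ==========  =====
    """
    if not observations:
        raise ValueError("need at least one observation")
    connection = observations[0].connection
    if any(o.connection != connection for o in observations):
        raise ValueError("observations mix different connections")
    if histology_status not in ("present", "absent"):
        raise ValueError(f"bad histology status {histology_status!r}")

    n_total = len(observations)
    present_obs = [o for o in observations if o.present]
    fraction = len(present_obs) / n_total
    population_present = fraction > config.presence_fraction
    if present_obs:
        plaus_frac = sum(o.plausible for o in present_obs) / len(present_obs)
        population_plausible = plaus_frac > config.plausibility_fraction
    else:
        population_plausible = True

    if histology_status == "present":
        if population_present:
            if population_plausible:
                label = "RTP" if fraction > config.rtp_fraction else "TP"
            else:
                label = "FP"
        else:
            label = "FN"
    else:
        label = "FP" if population_present else "TN"

    return ConnectionOutcome(
        connection=connection,
        population_present=population_present,
        population_fraction=fraction,
        population_plausible=population_plausible,
        histology=histology_status,
        label=label,
    )


def outcomes_from_table(
    table: OutcomeTable, reference: HistologyReference
) -> list[ConnectionOutcome]:
    """Wrap a packaged outcome table as ConnectionOutcome records.

    Population fractions are not recorded in the table; nominal values
    consistent with each label are filled in (irrelevant to the statistics).
    """
    outcomes = []
    for key, label in table.outcome.items():
        present = label in ("RTP", "TP", "FP")
        fraction = {"RTP": 0.9, "TP": 0.7, "FP": 0.7, "FN": 0.2, "TN": 0.1}[label]
        hist = reference[key]
        plausible = not (label == "FP" and hist == "present")
        outcomes.append(
            ConnectionOutcome(
                connection=key,
                population_present=present,
                population_fraction=fraction,
                population_plausible=plausible,
                histology=hist,
                label=label,
            )
        )
    return outcomes


def _tally(outcomes: Iterable[ConnectionOutcome]) -> ConfusionSummary:
    counts = {"RTP": 0, "TP": 0, "TN": 0, "FP": 0, "FN": 0}
    n = 0
    for o in outcomes:
        counts[o.label] += 1
        n += 1
    if n == 0:
        raise ValueError("no outcomes to summarize")
    return ConfusionSummary(
        tp=counts["TP"] + counts["RTP"],
        rtp=counts["RTP"],
        tn=counts["TN"],
        fp=counts["FP"],
        fn=counts["FN"],
    )


def summarize(outcomes: Sequence[ConnectionOutcome]) -> ConfusionSummary:
    """Confusion counts and statistics over all given outcomes."""
    return _tally(outcomes)


def summarize_partition(
    outcomes: Sequence[ConnectionOutcome], partition: str
) -> ConfusionSummary:
    """Summary over connections with at least one endpoint in *partition*."""
    if partition not in PARTITIONS:
        raise AtlasError(f"unknown partition {partition!r}")
    subset = [o for o in outcomes if partition in o.connection.partitions]
    return _tally(subset)
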