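"""Prefrontal atlas areas, the 91-connection pairing scheme, and packaged reference tables.

The analysis covers 14 Brodmann-style prefrontal areas grouped into the five
canonical partitions of the prefrontal cortex (dorsolateral, ventrolateral,
frontal pole, orbitofrontal, anterior cingulate).  Every unordered pair of
areas is a candidate short-range connection, giving C(14, 2) = 91 connections
per subject.  Two plain-text tables ship with the package:

* a histology reference marking each connection *present* or *absent* in the
  primate tract-tracing literature (72 present, 19 absent), and
* a per-connection tractography outcome table with labels in
  {RTP, TP, TN, FP, FN} for the population analysis this package reproduces.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from typing import Iterable, Mapping

__all__ = [
    "AREA_ORDER",
    "PARTITIONS",
    "AtlasArea",
    "ConnectionKey",
    "HistologyReference",
    "OutcomeTable",
    "ConfusionCounts",
    "AtlasError",
    "ReferenceIntegrityError",
    "build_atlas",
    "build_connection_keys",
    "load_histology_reference",
    "load_outcome_table",
    "partition_tally",
]

#: Canonical area ordering; ConnectionKey endpoints are stored in this order.
AREA_ORDER = ("8", "9", "46", "9/46", "44", "45", "47", "10", "11", "13", "14", "24", "25", "32")

#: The five canonical prefrontal partitions and their member areas.
PARTITIONS: dict[str, tuple[str, ...]] = {
    "dlPFC": ("8", "9", "9/46", "46"),
    "vlPFC": ("44", "45", "47"),
    "FrontalPole": ("10",),
    "OFC": ("11", "13", "14"),
    "ACC": ("24", "25", "32"),
}

_AREA_RANK = {a: i for i, a in enumerate(AREA_ORDER)}
_AREA_PARTITION = {a: p for p, areas in PARTITIONS.items() for a in areas}

#: Parcellation subregions absorbed by each area (from the multimodal surface
#: atlas the source parcellation is based on); free-text, informational only.
_SUBREGIONS = {
    "8": ["8Av", "8Ad", "8BL", "8BM", "8C"],
    "9": ["9p", "9a", "9m"],
    "46": ["a9-46v", "46"],
    "9/46": ["9-46d", "p9-46v", "IFSa", "IFSp"],
    "44": ["44"],
    "45": ["45", "47s"],
    "47": ["47l", "a47r", "p47r", "47m"],
    "10": ["10d", "10pp", "10r", "a10p", "p10p", "10v"],
    "11": ["11l", "OFC"],
    "13": ["13l", "pOFC"],
    "14": ["s32", "25-14", "OFC-14"],
    "24": ["p24", "a24", "a24pr", "p24pr", "24dd", "24dv"],
    "25": ["25"],
    "32": ["p32", "s32pr", "a32pr", "d32", "p32pr"],
}


class AtlasError(ValueError):
    """Invalid atlas definition (duplicate or unknown areas, bad partition)."""


class ReferenceIntegrityError(ValueError):
    """A packaged reference asset fails its structural invariants."""


@dataclass(frozen=True)
class AtlasArea:
    """One prefrontal area with its partition assignment."""

    area_id: str
    partition: str
    subregion_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.area_id not in _AREA_RANK:
            raise AtlasError(f"unknown area id {self.area_id!r}")
        if self.partition != _AREA_PARTITION[self.area_id]:
            raise AtlasError(
                f"area {self.area_id!r} belongs to partition "
                f"{_AREA_PARTITION[self.area_id]!r}, not {self.partition!r}"
            )


@dataclass(frozen=True, order=True)
class ConnectionKey:
    """Unordered area pair, canonicalized by the fixed area ordering.

    ``ConnectionKey(a, b) == ConnectionKey(b, a)`` for any two distinct areas.
    """

    area_a: str
    area_b: str

    def __init__(self, area_a: str, area_b: str) -> None:
        for a in (area_a, area_b):
            if a not in _AREA_RANK:
                raise AtlasError(f"unknown area id {a!r}")
        if area_a == area_b:
            raise AtlasError(f"connection endpoints must differ, got {area_a!r} twice")
        if _AREA_RANK[area_a] > _AREA_RANK[area_b]:
            area_a, area_b = area_b, area_a
        object.__setattr__(self, "area_a", area_a)
        object.__setattr__(self, "area_b", area_b)

    @property
    def partitions(self) -> tuple[str, ...]:
        """Partitions touched by this connection (one if intra-partition, else two)."""
        pa, pb = _AREA_PARTITION[self.area_a], _AREA_PARTITION[self.area_b]
        return (pa,) if pa == pb else (pa, pb)

    @property
    def is_intra_partition(self) -> bool:
        return len(self.partitions) == 1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.area_a}-{self.area_b}"


@dataclass(frozen=True)
class HistologyReference:
    """Present/absent status per connection, from the tract-tracing literature."""

    status: Mapping[ConnectionKey, str]
    provenance: Mapping[ConnectionKey, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require_full_coverage(self.status, "histology reference")
        n_present = sum(v == "present" for v in self.status.values())
        n_absent = sum(v == "absent" for v in self.status.values())
        if (n_present, n_absent) != (72, 19):
            raise ReferenceIntegrityError(
                f"histology reference must contain 72 present / 19 absent entries, "
                f"got {n_present}/{n_absent}"
            )

    def __getitem__(self, key: ConnectionKey) -> str:
        return self.status[key]


@dataclass(frozen=True)
class OutcomeTable:
    """Per-connection population outcome label in {RTP, TP, TN, FP, FN}."""

    outcome: Mapping[ConnectionKey, str]
    provenance: Mapping[ConnectionKey, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require_full_coverage(self.outcome, "outcome table")
        bad = {v for v in self.outcome.values()} - {"RTP", "TP", "TN", "FP", "FN"}
        if bad:
            raise ReferenceIntegrityError(f"unknown outcome labels: {sorted(bad)}")

    def __getitem__(self, key: ConnectionKey) -> str:
        return self.outcome[key]


@dataclass(frozen=True)
class ConfusionCounts:
    """Raw confusion counts; ``tp`` includes the robust (RTP) subset."""

    tp: int
    rtp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _require_full_coverage(mapping: Mapping[ConnectionKey, str], what: str) -> None:
    expected = set(build_connection_keys(build_atlas()))
    got = set(mapping)
    if got != expected:
        missing = expected - got
        extra = got - expected
        raise ReferenceIntegrityError(
            f"{what} must cover all 91 connections exactly "
            f"(missing {len(missing)}, unexpected {len(extra)})"
        )


def build_atlas() -> list[AtlasArea]:
    """Return the 14 prefrontal areas in canonical order with partition labels."""
    return [
        AtlasArea(a, _AREA_PARTITION[a], tuple(_SUBREGIONS[a]))
        for a in AREA_ORDER
    ]


def build_connection_keys(atlas: Iterable[AtlasArea]) -> list[ConnectionKey]:
    """All unordered area pairs of *atlas* in deterministic canonical order.

    For the full 14-area atlas this yields exactly 91 keys.
    """
    ids = [a.area_id for a in atlas]
    if len(set(ids)) != len(ids):
        raise AtlasError("atlas contains duplicate area ids")
    ordered = sorted(ids, key=_AREA_RANK.__getitem__)
    return [ConnectionKey(a, b) for a, b in combinations(ordered, 2)]


def _read_asset(name: str, value_column: str) -> tuple[dict, dict]:
    status: dict[ConnectionKey, str] = {}
    prov: dict[ConnectionKey, str] = {}
    with resources.files("safconn.data").joinpath(name).open("r", encoding="utf-8") as f:
        for row in csv.DictReader(f):
            key = ConnectionKey(row["area_a"], row["area_b"])
            if key in status:
                raise ReferenceIntegrityError(f"duplicate entry for {key} in {name}")
            status[key] = row[value_column]
            prov[key] = row.get("provenance", "")
    return status, prov


def load_histology_reference() -> HistologyReference:
    """Load the packaged histology reference (72 present / 19 absent)."""
    status, prov = _read_asset("histology_reference.csv", "histology_status")
    return HistologyReference(status, prov)


def load_outcome_table() -> OutcomeTable:
    """Load the packaged per-connection outcome table and check its tallies."""
    outcome, prov = _read_asset("outcome_table.csv", "outcome_label")
    table = OutcomeTable(outcome, prov)
    # Integrity: overall tallies must match the published population analysis.
    t = partition_tally(table, None)
    if (t.tp, t.rtp, t.tn, t.fp, t.fn) != (49, 41, 17, 13, 12):
        raise ReferenceIntegrityError(
            f"overall outcome tallies {t} disagree with the reference analysis"
        )
    return table


def partition_tally(table: OutcomeTable, partition: str | None) -> ConfusionCounts:
    """Confusion counts over all connections touching *partition*.

    A connection contributes to the tally of every partition containing one of
    its endpoints, so inter-partition connections appear in two partition
    summaries and intra-partition connections in exactly one.  ``partition=None``
    tallies all 91 connections once each.  RTP is counted within TP.
    """
    if partition is not None and partition not in PARTITIONS:
        raise AtlasError(
            f"unknown partition {partition!r}; expected one of {sorted(PARTITIONS)}"
        )
    if not table.outcome:
        raise ReferenceIntegrityError("outcome table is empty")
    counts = {"RTP": 0, "TP": 0, "TN": 0, "FP": 0, "FN": 0}
    for key, label in table.outcome.items():
        if partition is None or partition in key.partitions:
            counts[label] += 1
    return ConfusionCounts(
        tp=counts["TP"] + counts["RTP"],
        rtp=counts["RTP"],
        tn=counts["TN"],
        fp=counts["FP"],
        fn=counts["FN"],
    )
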