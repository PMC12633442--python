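"""Within-subject (test-retest) and between-subject bundle reproducibility.

Within-subject reliability compares each subject's test and retest density
maps; between-subject variability compares the same connection across subject
pairs in a common space.  Both designs report mean +/- sd of weighted Dice
and bundle adjacency over the eligible pairs, pooling all compared pairs
globally.  Pairs where either bundle is absent are excluded from the means
and reported as an exclusion count (the metrics are undefined on empty
supports).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .metrics import bundle_adjacency, weighted_dice
from .streamlines import DensityMap

__all__ = ["ReliabilityReport", "within_subject", "between_subject"]


@dataclass(frozen=True)
class ReliabilityReport:
    """Pooled mean +/- sd of one metric for one comparison design."""

    comparison: str  # {"within_subject", "between_subject"}
    metric: str  # {"wdice", "adjacency_mm"}
    mean: float
    sd: float
    n_pairs: int
    n_excluded: int = 0
    label: str = ""  # connection or partition tag, free text

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("a reliability report needs at least one compared pair")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def _is_present(dmap: DensityMap | None) -> bool:
    return dmap is not None and dmap.n_support > 0


def _reports(
    values_wdice: list[float],
    values_ba: list[float],
    comparison: str,
    n_excluded: int,
    label: str,
) -> dict[str, ReliabilityReport]:
    if not values_wdice:
        raise ValueError(f"no eligible pairs for {comparison} comparison")
    out = {}
    for metric, vals in (("wdice", values_wdice), ("adjacency_mm", values_ba)):
        arr = np.asarray(vals, dtype=np.float64)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        out[metric] = ReliabilityReport(
            comparison=comparison,
            metric=metric,
            mean=float(arr.mean()),
            sd=sd,
            n_pairs=len(arr),
            n_excluded=n_excluded,
            label=label,
        )
    return out


def within_subject(
    sessions: Mapping[str, Mapping[str, DensityMap | None]],
    label: str = "",
) -> dict[str, ReliabilityReport]:
    """Test-retest reliability across subjects.

    *sessions* maps subject id -> {"test": map, "retest": map}; a subject whose
    bundle is absent (or missing) in either session is excluded and counted.
    Returns {"wdice": report, "adjacency_mm": report}.
    """
    wd, ba = [], []
    n_excluded = 0
    for subject, pair in sessions.items():
        test = pair.get("test")
        retest = pair.get("retest")
        if not (_is_present(test) and _is_present(retest)):
            n_excluded += 1
            continue
        wd.append(weighted_dice(test, retest))
        ba.append(bundle_adjacency(test, retest))
    if not wd:
        raise ValueError("no subject has a present bundle in both sessions")
    return _reports(wd, ba, "within_subject", n_excluded, label)


def between_subject(
    maps: Mapping[str, DensityMap | None],
    label: str = "",
    max_pairs: int | None = None,
    seed: int = 0,
) -> dict[str, ReliabilityReport]:
    """Between-subject variability over all unordered subject pairs.

    All maps must share one grid (generated or normalized into a common
    space).  Pairs with an absent bundle on either side are excluded and
    counted.  ``max_pairs`` optionally subsamples the pair list with a fixed
    seed for large cohorts.
    """
    subjects = list(maps)
    if len(subjects) < 2:
        raise ValueError("between-subject comparison needs at least 2 subjects")
    pairs = list(combinations(subjects, 2))
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    wd, ba = [], []
    n_excluded = 0
    for sa, sb in pairs:
        a, b = maps[sa], maps[sb]
        if not (_is_present(a) and _is_present(b)):
            n_excluded += 1
            continue
        wd.append(weighted_dice(a, b))
        ba.append(bundle_adjacency(a, b))
    if not wd:
        raise ValueError("no subject pair has present bundles on both sides")
    return _reports(wd, ba, "between_subject", n_excluded, label)
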