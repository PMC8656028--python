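"""Missing-transcript intersection analysis of a transdifferentiation time course.

A transcript × timepoint abundance table is binarized to presence/absence;
transcripts are then grouped by their exact missingness pattern (the set of
timepoints at which they are undetectable), in the manner of an UpSet
intersection plot.  Three biologically meaningful endpoint classes dissect
the time course:

* cluster-I  — lost: present at the pre-induction baseline, absent at the
  final timepoint (e.g. smooth-muscle transcripts depleted during TD);
* cluster-II — retained: present at every timepoint (the pericytic core
  re-used by the emerging neural program);
* cluster-III — de novo: absent at baseline, present at the final
  timepoint (neuronal transcripts gained during TD);
* other — transient patterns matching none of the above.

With ``n`` patterned timepoints there are ``2**n - 2`` non-trivial
missingness signatures (excluding none-missing and all-missing); the five
post-induction timepoints of a TD time course give 30.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from tdprogram.errors import DataError

CLUSTER_LOST = "cluster-I"
CLUSTER_RETAINED = "cluster-II"
CLUSTER_DENOVO = "cluster-III"
CLUSTER_OTHER = "other"


@dataclass
class PresenceMatrix:
    """Boolean transcripts × ordered-timepoints table (True = present)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise DataError(f"duplicate transcript ids: {list(dupes)[:5]}")
        if self.values.shape[1] < 2:
            raise DataError("a presence matrix needs at least 2 timepoints")
        self.values = self.values.astype(bool)

    @property
    def transcripts(self) -> list:
        return list(self.values.index)

    @property
    def timepoints(self) -> list:
        return list(self.values.columns)


@dataclass(frozen=True)
class MissingnessSignature:
    """One observed pattern of missing timepoints (True = missing)."""

    pattern: tuple[bool, ...]
    count: int


def call_presence(abundance: pd.DataFrame, threshold: float = 0.0) -> PresenceMatrix:
    """Binarize abundances: present iff abundance strictly exceeds threshold."""
    if threshold < 0:
        raise DataError("presence threshold must be non-negative")
    values = abundance.to_numpy(dtype=float)
    if np.any(values < 0):
        raise DataError("abundances must be non-negative")
    return PresenceMatrix(pd.DataFrame(
        values > threshold, index=abundance.index, columns=abundance.columns
    ))


def enumerate_signatures(
    matrix: PresenceMatrix, baseline: Hashable | None = None
) -> list[MissingnessSignature]:
    """Group transcripts by exact missingness pattern.

    When ``baseline`` names a column, patterns span only the remaining
    (post-baseline) timepoints, matching the framing of loss relative to a
    pre-induction control.  Signatures are sorted by count (desc) then
    pattern (lexicographic); counts sum to the number of transcripts.
    """
    df = matrix.values
    if baseline is not None:
        if baseline not in df.columns:
            raise DataError(f"baseline column {baseline!r} not in timepoints")
        df = df.drop(columns=[baseline])
    missing = ~df.to_numpy(dtype=bool)
    counts: dict[tuple[bool, ...], int] = {}
    for row in missing:
        key = tuple(bool(x) for x in row)
        counts[key] = counts.get(key, 0) + 1
    sigs = [MissingnessSignature(p, c) for p, c in counts.items()]
    sigs.sort(key=lambda s: (-s.count, s.pattern))
    return sigs


def max_signatures(n_timepoints: int) -> int:
    """Number of non-trivial missingness patterns over ``n`` timepoints.

    Excludes the none-missing and all-missing patterns: 2**n - 2 (30 for
    the five post-induction timepoints of the TD time course).
    """
    if n_timepoints < 1:
        raise DataError("need at least one timepoint")
    return 2**n_timepoints - 2


def extract_clusters(matrix: PresenceMatrix) -> pd.Series:
    """Label each transcript cluster-I/II/III or other from its endpoints.

    The first timepoint is taken as the pre-induction baseline.  Every
    transcript receives exactly one label.
    """
    vals = matrix.values.to_numpy(dtype=bool)
    first, last, every = vals[:, 0], vals[:, -1], vals.all(axis=1)
    labels = np.where(
        every,
        CLUSTER_RETAINED,
        np.where(
            first & ~last,
            CLUSTER_LOST,
            np.where(~first & last, CLUSTER_DENOVO, CLUSTER_OTHER),
        ),
    )
    return pd.Series(labels, index=matrix.values.index, name="cluster")


def complexity_curve(matrix: PresenceMatrix) -> pd.Series:
    """Present-transcript count at each timepoint (transcriptomic complexity)."""
    return matrix.values.sum(axis=0)


def summary(matrix: PresenceMatrix, baseline: Hashable | None = None) -> dict:
    """JSON-ready report: signatures, cluster sizes, complexity curve."""
    labels = extract_clusters(matrix)
    sigs = enumerate_signatures(matrix, baseline=baseline)
    n_patterned = len(matrix.timepoints) - (1 if baseline is not None else 0)
    return {
        "n_transcripts": len(matrix.transcripts),
        "timepoints": [str(t) for t in matrix.timepoints],
        "baseline": None if baseline is None else str(baseline),
        "max_signatures": max_signatures(n_patterned),
        "signatures": [
            {"missing": list(s.pattern), "count": s.count} for s in sigs
        ],
        "clusters": labels.value_counts().to_dict(),
        "complexity": {str(k): int(v) for k, v in complexity_curve(matrix).items()},
    }
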