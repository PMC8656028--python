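"""qPCR quantification: Pfaffl relative expression and supercoiling zones.

Two explicit formulas drive this module.

The Pfaffl ratio corrects relative expression for amplification efficiency::

    ratio = Eff_tar ** dCt_tar(control - test) / Eff_ref ** dCt_ref(control - test)

The zone-topology normalization distributes a locus of interest (LoI) over
four electrophoretic-mobility zones.  Zone I holds hyper-negatively
supercoiled (sc-) DNA with low mobility; zone IV holds positively
supercoiled (sc+) DNA with high mobility.  Each zone is gel-purified and
the locus quantified by qPCR, giving one Ct per zone.  The normalized
fraction of the locus in zone *i* is::

    LoI_Zi = 2 ** dCt(Z_i - Z_1) / sum_j 2 ** dCt(Z_j - Z_1)

Two sign conventions are supported and never silently chosen.  The
"printed" convention takes dCt(Z_i - Z_1) = Ct_i - Ct_1, which weights
zones with HIGHER Ct (less template) more.  The "abundance" convention,
standard qPCR semantics, takes Ct_1 - Ct_i so that lower Ct (more
template) gets more weight.  Both are exposed because the study's written
formula and conventional qPCR arithmetic disagree; the choice is a
required, documented flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.stats import gmean

from tdprogram.errors import DataError

ZONES: tuple[str, str, str, str] = ("I", "II", "III", "IV")

#: qPCR cycle cap (38-cycle runs, rounded up); a Ct at or beyond this value
#: means "not detected" and contributes zero weight to a zone distribution.
SENTINEL_CT: float = 40.0

Convention = Literal["printed", "abundance"]


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement.

    ``zone`` is one of ``I``–``IV`` for topology assays and ``None`` for
    plain expression assays.  ``efficiency`` is the per-cycle amplification
    factor (2.0 for perfect doubling).
    """

    locus: str
    zone: str | None
    timepoint: float
    replicate: int
    ct: float
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if self.ct < 0:
            raise DataError(f"Ct must be non-negative, got {self.ct}")
        if self.zone is not None and self.zone not in ZONES:
            raise DataError(f"zone must be one of {ZONES} or None, got {self.zone!r}")
        if self.efficiency <= 0:
            raise DataError(f"efficiency must be positive, got {self.efficiency}")


@dataclass
class ZoneDistribution:
    """Normalized per-locus fractions across topology zones I–IV (sum to 1)."""

    locus: str
    timepoint: float
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (4,):
            raise DataError("a ZoneDistribution needs exactly four fractions")
        if np.any(self.fractions < -1e-12) or np.any(self.fractions > 1 + 1e-12):
            raise DataError("zone fractions must lie in [0, 1]")
        if abs(float(self.fractions.sum()) - 1.0) > 1e-9:
            raise DataError("zone fractions must sum to 1 within 1e-9")


def pfaffl_ratio(
    eff_tar: float, dct_tar: float, eff_ref: float, dct_ref: float
) -> float:
    """Efficiency-corrected relative expression of a target vs a reference.

    ``dct_*`` are Ct differences taken control − test, so a positive
    ``dct_tar`` means the target amplifies earlier (is more abundant) in the
    test sample.
    """
    if eff_tar <= 0 or eff_ref <= 0:
        raise DataError("amplification efficiencies must be positive")
    return eff_tar**dct_tar / eff_ref**dct_ref


def _is_sentinel(ct: float, sentinel_ct: float) -> bool:
    return ct >= sentinel_ct - 1e-9


def zone_distribution(
    ct_by_zone: Sequence[float],
    convention: Convention = "printed",
    sentinel_ct: float = SENTINEL_CT,
    locus: str = "",
    timepoint: float = 0.0,
) -> ZoneDistribution:
    """Normalize four zone Ct values into locus fractions LoI_Z1..LoI_Z4.

    Replicates must be pre-aggregated (by mean Ct).  A sentinel Ct (>= the
    qPCR cycle cap) marks a zone where the locus was not detected and maps
    to weight 0 before normalization.  The result is invariant under adding
    a constant to all four Ct values, so the reference zone used internally
    is the first detected zone.
    """
    ct = [float(c) for c in ct_by_zone]
    if len(ct) != 4:
        raise DataError("exactly four zone Ct values are required")
    if convention not in ("printed", "abundance"):
        raise DataError(f"unknown convention {convention!r}")
    detected = [i for i, c in enumerate(ct) if not _is_sentinel(c, sentinel_ct)]
    if not detected:
        raise DataError(f"locus {locus or '<unnamed>'} undetected in all four zones")
    ref = ct[detected[0]]
    sign = 1.0 if convention == "printed" else -1.0
    weights = np.array(
        [
            0.0 if _is_sentinel(c, sentinel_ct) else 2.0 ** (sign * (c - ref))
            for c in ct
        ]
    )
    fractions = weights / weights.sum()
    return ZoneDistribution(locus=locus, timepoint=timepoint, fractions=fractions)


def aggregate_ct(records: Iterable[CtRecord]) -> dict[tuple[str, float], list[float]]:
    """Mean Ct per (locus, timepoint) across replicates, ordered by zone I–IV.

    Missing zones are filled with the sentinel Ct so that downstream
    normalization treats them as not detected.
    """
    sums: dict[tuple[str, float, str], list[float]] = {}
    for rec in records:
        if rec.zone is None:
            raise DataError(f"record for locus {rec.locus} carries no zone label")
        sums.setdefault((rec.locus, rec.timepoint, rec.zone), []).append(rec.ct)
    out: dict[tuple[str, float], list[float]] = {}
    keys = {(locus, tp) for (locus, tp, _zone) in sums}
    for locus, tp in sorted(keys):
        out[(locus, tp)] = [
            float(np.mean(sums[(locus, tp, z)])) if (locus, tp, z) in sums else SENTINEL_CT
            for z in ZONES
        ]
    return out


def zone_distributions(
    records: Iterable[CtRecord],
    convention: Convention = "printed",
    sentinel_ct: float = SENTINEL_CT,
) -> list[ZoneDistribution]:
    """Aggregate replicate Ct records and normalize every locus/timepoint."""
    return [
        zone_distribution(ct, convention, sentinel_ct, locus=locus, timepoint=tp)
        for (locus, tp), ct in aggregate_ct(records).items()
    ]


def topology_shift(dist_a: ZoneDistribution, dist_b: ZoneDistribution) -> float:
    """Signed center-of-mass shift over zone indices 1–4, from ``a`` to ``b``.

    Positive values mean a shift toward the sc+ pole (zone IV), negative
    toward sc- (zone I); e.g. "expansion of zone IV" is a positive shift.
    """
    if dist_a.locus and dist_b.locus and dist_a.locus != dist_b.locus:
        raise DataError(
            f"topology_shift compares one locus to itself, got "
            f"{dist_a.locus!r} vs {dist_b.locus!r}"
        )
    idx = np.arange(1, 5, dtype=float)
    return float(idx @ dist_b.fractions - idx @ dist_a.fractions)


def td_tendency(
    proneural_ratios: Sequence[float], promyogenic_ratio: float
) -> float:
    """TD-tendency proxy: pro-neural over pro-myogenic relative expression.

    The pro-neural factors (ATOH1, MASH1) are combined by geometric mean and
    divided by the pro-myogenic factor (MYOD1).  The geometric mean keeps the
    score symmetric under rescaling of either pro-neural ratio.
    """
    ratios = np.asarray(proneural_ratios, dtype=float)
    if ratios.size == 0:
        raise DataError("at least one pro-neural ratio is required")
    if np.any(ratios <= 0) or promyogenic_ratio <= 0:
        raise DataError("expression ratios must be positive")
    return float(gmean(ratios) / promyogenic_ratio)
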