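"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one experimental readout of the transdifferentiation
study at its stated conditions and returns the planted truth alongside the
data, so every downstream analysis is testable as an exact (noise-free) or
statistical (noisy) round trip:

* :func:`gen_genes_with_seed` — gene sets carrying a planted shared seed
  followed by an NGG PAM in designated carrier genes;
* :func:`gen_ct_table` — qPCR Ct tables realizing known supercoiling-zone
  fractions, with independent Gaussian replicate noise on Ct;
* :func:`gen_td_chase` — TD-chase cohorts where each unconverted cell
  converts per cycle with the Poisson zero-class complement 1 - e^(-m);
* :func:`gen_presence_matrix` — presence/absence tables with planted
  lost / retained / de-novo transcript clusters.

All generators are deterministic given ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tdprogram.errors import DataError
from tdprogram.missingness import (
    CLUSTER_DENOVO,
    CLUSTER_LOST,
    CLUSTER_RETAINED,
    PresenceMatrix,
)
from tdprogram.qpcr import SENTINEL_CT, ZONES, Convention, CtRecord
from tdprogram.seedguide import revcomp

#: Retry cap for rejection sampling of seed-free / single-occurrence
#: backgrounds; exhaustion signals pathological parameters (e.g. a seed so
#: short it lands in every random sequence).
MAX_RETRIES = 100


@dataclass
class PlantedGeneSet:
    """Synthetic genes with a seed + NGG PAM planted in carrier genes.

    ``planted`` maps each carrier id to the 0-based (seed_start, pam_start)
    of its planted occurrence on the forward strand.  Carriers contain the
    seed exactly once (forward strand, nowhere on the reverse); non-carriers
    contain no occurrence on either strand.
    """

    genes: dict[str, str]
    truth_seed: str
    carriers: frozenset[str]
    planted: dict[str, tuple[int, int]]
    pam_side: str = "3prime"
    rng_seed: int = 0


@dataclass
class SimulatedCohort:
    """A simulated TD-chase: per-cycle conversion counts out of ``n_cells``."""

    n_cells: int
    m: float
    n_cycles: int
    precondition_multiplier: float
    converted_per_cycle: list[int]
    rng_seed: int = 0

    @property
    def cumulative(self) -> list[int]:
        out, total = [], 0
        for c in self.converted_per_cycle:
            total += c
            out.append(total)
        return out

    @property
    def converted_fraction(self) -> float:
        return self.cumulative[-1] / self.n_cells if self.converted_per_cycle else 0.0


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def _count_occurrences(haystack: str, needle: str) -> int:
    """Overlapping occurrence count of ``needle`` on the forward strand."""
    count, start = 0, 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def gen_genes_with_seed(
    n_genes: int,
    gene_len: int,
    seed_len: int,
    n_carriers: int,
    rng_seed: int,
    gc: float = 0.5,
) -> PlantedGeneSet:
    """Generate ``n_genes`` random genes with a shared seed in ``n_carriers``.

    The seed is a random ``seed_len``-mer planted (with a random NGG PAM
    immediately 3′) at a random position of each carrier.  Rejection
    sampling (cap ``MAX_RETRIES``) guarantees carriers hold exactly the one
    planted occurrence and non-carriers none, on either strand.
    """
    if seed_len < 1:
        raise DataError("seed_len must be >= 1")
    if n_carriers > n_genes:
        raise DataError("n_carriers cannot exceed n_genes")
    if n_carriers < 0 or n_genes < 1:
        raise DataError("counts must be non-negative and n_genes >= 1")
    if seed_len + 3 > gene_len:
        raise DataError(
            f"seed ({seed_len} bp) plus PAM (3 bp) cannot fit in a "
            f"{gene_len} bp gene"
        )
    rng = np.random.default_rng(rng_seed)
    seed = _random_seq(rng, seed_len)  # seed drawn uniform regardless of gc
    width = len(str(n_genes))
    ids = [f"gene{str(i + 1).zfill(width)}" for i in range(n_genes)]
    carrier_ids = frozenset(
        str(g) for g in rng.choice(ids, size=n_carriers, replace=False)
    )

    def seed_free(seq: str) -> bool:
        return seed not in seq and seed not in revcomp(seq)

    genes: dict[str, str] = {}
    planted: dict[str, tuple[int, int]] = {}
    for gene_id in ids:
        for _ in range(MAX_RETRIES):
            if gene_id in carrier_ids:
                background = _random_seq(rng, gene_len, gc)
                pos = int(rng.integers(0, gene_len - seed_len - 3 + 1))
                pam = rng.choice(list("ACGT")) + "GG"
                seq = (
                    background[:pos]
                    + seed
                    + pam
                    + background[pos + seed_len + 3 :]
                )
                ok = (
                    _count_occurrences(seq, seed) == 1
                    and seed not in revcomp(seq)
                )
                if ok:
                    genes[gene_id] = seq
                    planted[gene_id] = (pos, pos + seed_len)
                    break
            else:
                seq = _random_seq(rng, gene_len, gc)
                if seed_free(seq):
                    genes[gene_id] = seq
                    break
        else:
            raise DataError(
                f"could not build a valid sequence for {gene_id} in "
                f"{MAX_RETRIES} tries; parameters are pathological "
                f"(seed_len={seed_len}, gene_len={gene_len})"
            )
    return PlantedGeneSet(
        genes=genes,
        truth_seed=seed,
        carriers=carrier_ids,
        planted=planted,
        rng_seed=rng_seed,
    )


def gen_ct_table(
    zone_fractions: Mapping[tuple[str, float], Sequence[float]],
    base_ct: float = 20.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    rng_seed: int = 0,
    efficiency: float = 2.0,
    sentinel_ct: float = SENTINEL_CT,
    convention: Convention = "printed",
) -> list[CtRecord]:
    """Ct records realizing known zone fractions under a stated convention.

    ``zone_fractions`` maps (locus, timepoint) to a non-negative 4-vector
    summing to 1.  Ct values are chosen so the matching zone-normalization
    convention recovers the fractions in expectation: under "printed",
    Ct_i = base_ct + log2(f_i / f_ref); under "abundance" the offset sign
    flips.  A zero fraction maps to the "not detected" sentinel Ct (no
    noise added there).  Gaussian noise of sd ``noise_sd`` cycles is added
    independently per replicate.
    """
    if noise_sd < 0:
        raise DataError("noise_sd must be non-negative")
    if n_replicates < 1:
        raise DataError("need at least one replicate")
    if convention not in ("printed", "abundance"):
        raise DataError(f"unknown convention {convention!r}")
    rng = np.random.default_rng(rng_seed)
    sign = 1.0 if convention == "printed" else -1.0
    records: list[CtRecord] = []
    for (locus, timepoint), fractions in zone_fractions.items():
        f = np.asarray(fractions, dtype=float)
        if f.shape != (4,):
            raise DataError(f"{locus}: zone fractions must be a 4-vector")
        if np.any(f < 0):
            raise DataError(f"{locus}: zone fractions must be non-negative")
        if abs(f.sum() - 1.0) > 1e-6:
            raise DataError(f"{locus}: zone fractions must sum to 1")
        nonzero = np.flatnonzero(f)
        if nonzero.size == 0:
            raise DataError(f"{locus}: at least one zone fraction must be positive")
        ref = f[nonzero[0]]
        for i, zone in enumerate(ZONES):
            if f[i] == 0:
                ct_true = sentinel_ct
            else:
                ct_true = base_ct + sign * math.log2(f[i] / ref)
            for rep in range(1, n_replicates + 1):
                ct = ct_true
                if ct_true < sentinel_ct and noise_sd > 0:
                    ct += float(rng.normal(0.0, noise_sd))
                records.append(
                    CtRecord(
                        locus=locus,
                        zone=zone,
                        timepoint=timepoint,
                        replicate=rep,
                        ct=max(ct, 0.0),
                        efficiency=efficiency,
                    )
                )
    return records


def gen_td_chase(
    n_cells: int,
    m: float,
    n_cycles: int,
    precondition_multiplier: float = 1.0,
    rng_seed: int = 0,
) -> SimulatedCohort:
    """Simulate a TD-chase cohort under the Poisson conversion model.

    Each still-unconverted cell converts in a cycle with probability
    1 - e^(-m * multiplier) (the Poisson zero-class complement), so the
    cumulative converted fraction after c cycles converges to
    1 - e^(-c * m * multiplier).
    """
    if n_cells <= 0:
        raise DataError("n_cells must be positive")
    if m < 0:
        raise DataError("rate m must be non-negative")
    if precondition_multiplier <= 0:
        raise DataError("precondition_multiplier must be positive")
    if n_cycles < 0:
        raise DataError("n_cycles must be non-negative")
    rng = np.random.default_rng(rng_seed)
    p = 1.0 - math.exp(-m * precondition_multiplier)
    unconverted = n_cells
    per_cycle: list[int] = []
    for _ in range(n_cycles):
        new = int(rng.binomial(unconverted, p))
        per_cycle.append(new)
        unconverted -= new
    return SimulatedCohort(
        n_cells=n_cells,
        m=m,
        n_cycles=n_cycles,
        precondition_multiplier=precondition_multiplier,
        converted_per_cycle=per_cycle,
        rng_seed=rng_seed,
    )


def gen_presence_matrix(
    n_lost: int,
    n_retained: int,
    n_denovo: int,
    timepoints: Sequence,
    rng_seed: int = 0,
) -> tuple[PresenceMatrix, pd.Series]:
    """Presence/absence matrix with planted lost/retained/de-novo clusters.

    Lost transcripts are present at the first timepoint and switch off at a
    random later timepoint (staying off); de-novo transcripts mirror that
    (off at baseline, switching on); retained transcripts are always
    present.  Returns the matrix and the truth labels (cluster-I/II/III).
    """
    if min(n_lost, n_retained, n_denovo) < 0:
        raise DataError("cluster sizes must be non-negative")
    if len(timepoints) < 2:
        raise DataError("need at least 2 timepoints")
    rng = np.random.default_rng(rng_seed)
    n_tp = len(timepoints)
    rows: list[np.ndarray] = []
    labels: list[str] = []
    for _ in range(n_lost):
        drop = int(rng.integers(1, n_tp))
        rows.append(np.arange(n_tp) < drop)
        labels.append(CLUSTER_LOST)
    for _ in range(n_retained):
        rows.append(np.ones(n_tp, dtype=bool))
        labels.append(CLUSTER_RETAINED)
    for _ in range(n_denovo):
        gain = int(rng.integers(1, n_tp))
        rows.append(np.arange(n_tp) >= gain)
        labels.append(CLUSTER_DENOVO)
    n = len(rows)
    order = rng.permutation(n)
    ids = [f"tx{str(i + 1).zfill(len(str(max(n, 1))))}" for i in range(n)]
    values = pd.DataFrame(
        np.array([rows[j] for j in order]).reshape(n, n_tp),
        index=ids,
        columns=list(timepoints),
    )
    truth = pd.Series([labels[j] for j in order], index=ids, name="cluster")
    if n == 0:
        values = pd.DataFrame(
            np.empty((0, n_tp), dtype=bool), columns=list(timepoints)
        )
        truth = pd.Series([], dtype=object, name="cluster")
    return PresenceMatrix(values), truth
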