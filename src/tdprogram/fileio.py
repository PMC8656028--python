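"""Readers and writers for the package's on-disk formats.

All tabular files are UTF-8, tab-separated TSV with a required header row
and ``.`` for missing values.  Sequence sets travel as FASTA, intervals as
BED6 (0-based half-open), reports and truth sidecars as JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tdprogram.errors import DataError
from tdprogram.missingness import PresenceMatrix
from tdprogram.qpcr import CtRecord
from tdprogram.seedguide import CutSite
from tdprogram.synthetic import SimulatedCohort

_VALID_BASES = set("ACGTNU")

CT_COLUMNS = ["locus", "zone", "timepoint_min", "replicate", "ct", "efficiency"]
COHORT_COLUMNS = ["condition", "cycle", "total", "converted"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> uppercase-sequence mapping.

    Duplicate ids and bases outside {A, C, G, T, N, U} are rejected; the
    alphabet error reports the offending line number.
    """
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise DataError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise DataError(f"{path}: no FASTA records found")
    for seq_id, seq in records.items():
        if set(seq) - _VALID_BASES:
            _raise_alphabet_error(path, seq_id)
    return records


def _raise_alphabet_error(path: Path, seq_id: str) -> None:
    """Locate the first bad base of ``seq_id`` for an error with a line number."""
    current = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                current = line[1:].split()[0] if len(line) > 1 else ""
                continue
            if current == seq_id:
                bad = set(line.strip().upper()) - _VALID_BASES
                if bad:
                    raise DataError(
                        f"{path}:{lineno}: invalid bases {sorted(bad)} in "
                        f"sequence {seq_id!r}"
                    )
    raise DataError(f"{path}: invalid bases in sequence {seq_id!r}")


def write_fasta(genes: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene_id, description="") for gene_id, seq in genes.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_bed(records: Iterable, path: str | Path) -> None:
    """Write BED6 (chrom, start, end, name, score, strand), sorted.

    Accepts :class:`~tdprogram.seedguide.CutSite` records (name = seed,
    score = 0) or plain 6-tuples.  Intervals must be 0-based half-open with
    start < end.
    """
    rows = []
    for rec in records:
        if isinstance(rec, CutSite):
            rows.append((rec.gene_id, rec.start, rec.end, rec.seed_seq, 0, rec.strand))
        else:
            rows.append(tuple(rec))
    for chrom, start, end, *_rest in rows:
        if start >= end:
            raise DataError(f"inverted/empty interval {chrom}:{start}-{end}")
        if start < 0:
            raise DataError(f"negative coordinate {chrom}:{start}")
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str | Path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")
            out.append((chrom, int(start), int(end), name, int(score), strand))
    return out


def write_ct_table(records: Iterable[CtRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.locus, r.zone if r.zone is not None else ".", r.timepoint,
             r.replicate, r.ct, r.efficiency)
            for r in records
        ],
        columns=CT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path) -> list[CtRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"zone": str})
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing Ct-table columns {sorted(missing)}")
    return [
        CtRecord(
            locus=str(row.locus),
            zone=None if (pd.isna(row.zone) or row.zone == ".") else str(row.zone),
            timepoint=float(row.timepoint_min),
            replicate=int(row.replicate),
            ct=float(row.ct),
            efficiency=float(row.efficiency),
        )
        for row in df.itertuples()
    ]


def write_cohort(
    cohort: SimulatedCohort, path: str | Path, condition: str = "control"
) -> None:
    df = pd.DataFrame(
        {
            "condition": condition,
            "cycle": range(1, cohort.n_cycles + 1),
            "total": cohort.n_cells,
            "converted": cohort.cumulative,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing cohort columns {sorted(missing)}")
    return df


def write_presence(matrix: PresenceMatrix, path: str | Path) -> None:
    df = matrix.values.astype(int)
    df.index.name = "transcript"
    df.to_csv(path, sep="\t")


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Abundance (or 0/1 presence) TSV: transcript id column + timepoints."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise DataError(f"{path}: need at least two timepoint columns")
    return df


def write_json(obj, path: str | Path, rng_seed: int | None = None) -> None:
    """Write a JSON report; the run's RNG seed is recorded when given."""
    payload = dict(obj)
    if rng_seed is not None:
        payload.setdefault("rng_seed", rng_seed)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if hasattr(x, "item"):
        return x.item()
    if isinstance(x, (set, frozenset)):
        return sorted(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
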