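"""Multi-target sgRNA seed discovery and guide design ("TDi-RNA" style).

Cas9 cleavage tolerates spacer/target mismatches outside a PAM-proximal
seed of roughly 8–13 nt, so a single guide whose seed matches a region
shared by many genes — each occurrence flanked 3′ by an NGG PAM — can cut
many loci at once.  This module finds such shared seed regions by exact
match on either strand, scores how surprising each seed is under an i.i.d.
background, and assembles a 20-nt spacer plus canonical tracr scaffold.

Coordinates are 0-based half-open on each gene's forward strand.  The PAM
always occupies the 3 bases immediately 3′ of the protospacer on the
targeted strand, so every reported seed occurrence is anchored at a PAM:
on the forward strand the PAM sits at ``[end, end+3)``; on the reverse
strand at forward interval ``[start-3, start)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from tdprogram.errors import DataError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC nucleotide codes over the unambiguous DNA alphabet.  A sequence
#: base of N matches nothing (unknown bases never license a PAM or a seed).
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Canonical S. pyogenes tracr scaffold (RNA), as appended 3′ of the spacer.
CANONICAL_SCAFFOLD = (
    "GUUUUAGAGCUAGAAAUAGCAAGUUAAAAUAAGGCUAGUCCGUUAUCAACUU"
    "GAAAAAGAGGCACCGGUCGGUGCUUUU"
)

#: Prefix used to split spacer from scaffold in a full sgRNA sequence.
SCAFFOLD_PREFIX = "GUUUUAGAGCUAGA"

#: The study's published multi-target guide in vendor notation
#: (m = 2'-O-methyl, r = ribo, * = phosphorothioate linkage).
PUBLISHED_TDI_RNA = (
    "mA*mC*mU*GUGAGUGUGGAGACCUUGUUUUAGAGCUAGAAAUAGCAAGUUAAAAUAAGG"
    "CUAGUCCGUUAUCAACUUGAAAAAGAGGCACCGGUCGGUGCmU*mU*mU*rU"
)


def revcomp(seq: str) -> str:
    """Reverse complement over {A, C, G, T, N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedParameters:
    """Knobs of the seed search.

    ``min_seed_len`` is the shortest shared region reported (13 bp by
    default: the longest seed still short enough to recur, yet long enough
    that sharing is non-random).  ``pam`` is an IUPAC pattern of length 3.
    """

    min_seed_len: int = 13
    pam: str = "NGG"
    spacer_len: int = 20
    min_carriers: int = 2

    def __post_init__(self) -> None:
        if self.min_seed_len < 8:
            raise DataError("min_seed_len must be >= 8")
        if len(self.pam) != 3 or any(c not in IUPAC for c in self.pam):
            raise DataError(f"PAM must be a 3-letter IUPAC pattern, got {self.pam!r}")
        if self.spacer_len < 1:
            raise DataError("spacer_len must be positive")
        if self.min_carriers < 1:
            raise DataError("min_carriers must be >= 1")


@dataclass(frozen=True)
class SeedMatch:
    """One PAM-flanked occurrence of a seed in one gene.

    ``start``/``end`` are forward-strand coordinates of the seed itself;
    ``pam_start`` is the forward-strand start of the 3-base PAM;
    ``seed_seq`` is the seed as read on the targeted strand.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    seed_seq: str
    pam_start: int

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.seed_seq):
            raise DataError("SeedMatch interval length must equal seed length")
        if self.strand not in "+-":
            raise DataError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class SeedCluster:
    """A shared seed with its carrier genes and PAM-validated occurrences.

    ``expected_random`` is the expected number of PAM-agnostic exact
    occurrences of this seed in an i.i.d. uniform background of the same
    total length (both strands) — a small value flags a non-random cluster.
    """

    seed_seq: str
    carriers: frozenset[str]
    matches: list[SeedMatch]
    expected_random: float

    def __post_init__(self) -> None:
        if self.carriers != frozenset(m.gene_id for m in self.matches):
            raise DataError("carriers must equal the distinct gene ids of matches")


@dataclass
class GuideDesign:
    """A spacer + scaffold sgRNA against a seed cluster.

    ``n_padded`` counts 5′ spacer positions taken from the representative
    carrier rather than from the shared seed (non-shared positions).
    ``warning`` is set when padding was impossible and the spacer was
    emitted seed-only.
    """

    spacer: str
    scaffold: str
    full_sgrna: str
    targets: SeedCluster
    n_padded: int = 0
    warning: bool = False


class ParsedSgRNA(NamedTuple):
    plain_rna: str
    spacer: str
    scaffold: str
    scaffold_found: bool


@dataclass(frozen=True)
class CutSite:
    """Predicted blunt Cas9 cut, 3 bp 5′ of the PAM, as a 1-base interval."""

    gene_id: str
    start: int
    end: int
    strand: str
    seed_seq: str


def matches_pam(trinucleotide: str, pam: str) -> bool:
    """Does a 3-base sequence match an IUPAC PAM pattern?  N never matches."""
    if len(trinucleotide) != 3:
        return False
    return all(
        base in IUPAC[code] for base, code in zip(trinucleotide, pam)
    )


def _validate_genes(genes: Mapping[str, str]) -> dict[str, str]:
    if not genes:
        raise DataError("empty gene set")
    clean: dict[str, str] = {}
    for gene_id, seq in genes.items():
        seq = seq.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise DataError(f"gene {gene_id!r} has invalid bases {sorted(bad)}")
        clean[gene_id] = seq
    return clean


def _pam_sites(seq: str, pam: str) -> list[int]:
    """Start positions of PAM matches in ``seq`` (oriented coordinates)."""
    return [
        p for p in range(len(seq) - 2) if matches_pam(seq[p : p + 3], pam)
    ]


def find_shared_seeds(
    genes: Mapping[str, str], params: SeedParameters = SeedParameters()
) -> list[SeedCluster]:
    """Find maximal seeds shared by >= ``min_carriers`` genes, PAM-flanked.

    A seed qualifies when the exact sequence occurs, on either strand, in at
    least ``min_carriers`` distinct genes with a valid PAM immediately 3′ of
    every counted occurrence.  Seeds whose every occurrence extends 5′ to a
    longer seed with the identical carrier set are suppressed as redundant
    (the longer seed subsumes them); when a 5′ extension splits the carriers,
    both the shorter shared seed and any still-shared extensions are
    reported.

    Returned clusters are sorted by carrier count (desc), seed length
    (desc), expected random occurrence count (asc), then seed sequence.
    """
    clean = _validate_genes(genes)
    total_len = sum(len(s) for s in clean.values())

    # Every counted occurrence is anchored at a PAM, so candidate seeds are
    # the k-mers ending immediately 5' of a PAM site; longer candidates are
    # 5' extensions of shorter ones.  Sites are (gene, strand, pam position)
    # in oriented coordinates, with the oriented sequence kept alongside.
    oriented: dict[tuple[str, str], str] = {}
    sites: list[tuple[str, str, int]] = []
    for gene_id, seq in clean.items():
        for strand, oseq in (("+", seq), ("-", revcomp(seq))):
            oriented[(gene_id, strand)] = oseq
            sites.extend((gene_id, strand, p) for p in _pam_sites(oseq, params.pam))

    k0 = params.min_seed_len
    level: dict[str, list[tuple[str, str, int]]] = {}
    for gene_id, strand, p in sites:
        if p < k0:
            continue
        kmer = oriented[(gene_id, strand)][p - k0 : p]
        if "N" in kmer:
            continue
        level.setdefault(kmer, []).append((gene_id, strand, p))

    def n_genes(group: list[tuple[str, str, int]]) -> int:
        return len({g for g, _s, _p in group})

    level = {s: grp for s, grp in level.items() if n_genes(grp) >= params.min_carriers}

    clusters: list[SeedCluster] = []
    k = k0
    while level:
        next_level: dict[str, list[tuple[str, str, int]]] = {}
        for seed, group in level.items():
            carriers = frozenset(g for g, _s, _p in group)
            exts: dict[str, list[tuple[str, str, int]]] = {}
            for gene_id, strand, p in group:
                if p - k - 1 < 0:
                    continue
                base = oriented[(gene_id, strand)][p - k - 1]
                if base == "N":
                    continue
                exts.setdefault(base + seed, []).append((gene_id, strand, p))
            subsumed = False
            for ext_seed, ext_group in exts.items():
                ext_carriers = frozenset(g for g, _s, _p in ext_group)
                if len(ext_carriers) >= params.min_carriers:
                    next_level[ext_seed] = ext_group
                if ext_carriers == carriers:
                    subsumed = True
            if not subsumed:
                clusters.append(_build_cluster(seed, group, oriented, clean, total_len))
        level = next_level
        k += 1

    clusters.sort(
        key=lambda c: (
            -len(c.carriers),
            -len(c.seed_seq),
            c.expected_random,
            c.seed_seq,
        )
    )
    return clusters


def _build_cluster(
    seed: str,
    group: list[tuple[str, str, int]],
    oriented: Mapping[tuple[str, str], str],
    genes: Mapping[str, str],
    total_len: int,
) -> SeedCluster:
    k = len(seed)
    matches = []
    for gene_id, strand, p in group:
        n = len(genes[gene_id])
        if strand == "+":
            start, end, pam_start = p - k, p, p
        else:
            # oriented seed [p-k, p) and PAM [p, p+3) on the reverse strand
            # reflect to forward coordinates.
            start, end, pam_start = n - p, n - p + k, n - p - 3
        matches.append(
            SeedMatch(
                gene_id=gene_id,
                start=start,
                end=end,
                strand=strand,
                seed_seq=seed,
                pam_start=pam_start,
            )
        )
    matches.sort(key=lambda m: (m.gene_id, m.start, m.strand))
    return SeedCluster(
        seed_seq=seed,
        carriers=frozenset(m.gene_id for m in matches),
        matches=matches,
        expected_random=expected_random_hits(k, total_len),
    )


def expected_random_hits(
    seed_len: int, genome_len: int, gc: float = 0.5, seed: str | None = None
) -> float:
    """Expected exact occurrences of a seed in an i.i.d. background, both strands.

    With a concrete ``seed``, the per-position match probability is the
    product of its base probabilities under the GC-split background
    (p(G) = p(C) = gc/2, p(A) = p(T) = (1-gc)/2).  Without one, the
    composition-averaged match probability (gc^2 + (1-gc)^2)/2 per base is
    used, which reduces to 2 * genome_len / 4**seed_len at gc = 0.5.
    """
    if genome_len <= 0:
        raise DataError("genome_len must be positive")
    if not 0 < gc < 1:
        raise DataError("gc must lie strictly between 0 and 1")
    if seed_len < 1:
        raise DataError("seed_len must be >= 1")
    p = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2}
    if seed is not None:
        if len(seed) != seed_len:
            raise DataError("seed length disagrees with seed_len")
        per_site = math.prod(p[b] for b in seed.upper())
    else:
        per_site = ((gc**2 + (1 - gc) ** 2) / 2) ** seed_len
    return 2.0 * genome_len * per_site


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def design_guide(
    cluster: SeedCluster,
    params: SeedParameters = SeedParameters(),
    scaffold: str = CANONICAL_SCAFFOLD,
    genes: Mapping[str, str] | None = None,
) -> GuideDesign:
    """Assemble a spacer of ``spacer_len`` nt ending at the PAM-proximal seed.

    When the shared seed is shorter than the spacer, the 5′ remainder is
    padded from the designated representative carrier (the first match in
    (gene, start, strand) order); those positions are reported as non-shared
    via ``n_padded``.  If no flank is available to pad from (no gene
    sequences supplied, or the seed abuts the representative's 5′ end), the
    seed-only spacer is emitted with ``warning`` set.
    """
    if not cluster.matches:
        raise DataError("cannot design a guide for an empty cluster")
    seed = cluster.seed_seq
    if len(seed) >= params.spacer_len:
        spacer_dna = seed[-params.spacer_len :]
        n_padded, warning = 0, False
    else:
        pad_len = params.spacer_len - len(seed)
        rep = cluster.matches[0]
        pad = _five_prime_flank(rep, pad_len, genes)
        if pad is None:
            spacer_dna, n_padded, warning = seed, 0, True
        else:
            spacer_dna, n_padded, warning = pad + seed, pad_len, False
    return GuideDesign(
        spacer=dna_to_rna(spacer_dna),
        scaffold=scaffold,
        full_sgrna=dna_to_rna(spacer_dna) + scaffold,
        targets=cluster,
        n_padded=n_padded,
        warning=warning,
    )


def _five_prime_flank(
    match: SeedMatch, pad_len: int, genes: Mapping[str, str] | None
) -> str | None:
    """``pad_len`` bases immediately 5′ of a match on its targeted strand."""
    if genes is None or match.gene_id not in genes:
        return None
    seq = genes[match.gene_id].upper()
    if match.strand == "+":
        if match.start < pad_len:
            return None
        flank = seq[match.start - pad_len : match.start]
    else:
        if match.end + pad_len > len(seq):
            return None
        flank = revcomp(seq[match.end : match.end + pad_len])
    return None if "N" in flank else flank


def parse_modified_sgrna(text: str) -> ParsedSgRNA:
    """Strip vendor chemical-modification notation to plain RNA and split it.

    Recognized tokens: plain ribonucleotides A/C/G/U, the prefixes ``m``
    (2′-O-methyl) and ``r`` (explicit ribo) each followed by a base, and the
    ``*`` phosphorothioate-linkage separator.  The plain sequence is split
    into spacer and scaffold at the first occurrence of the canonical
    scaffold prefix; if that prefix is absent the whole sequence is returned
    as spacer with ``scaffold_found=False``.
    """
    plain: list[str] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c in "ACGU":
            plain.append(c)
            i += 1
        elif c in "mr":
            if i + 1 >= len(text) or text[i + 1] not in "ACGU":
                raise DataError(
                    f"modification prefix {c!r} at position {i} is not followed "
                    "by a base"
                )
            plain.append(text[i + 1])
            i += 2
        elif c == "*":
            i += 1
        else:
            raise DataError(f"unrecognized notation character {c!r} at position {i}")
    rna = "".join(plain)
    cut = rna.find(SCAFFOLD_PREFIX)
    if cut < 0:
        return ParsedSgRNA(rna, rna, "", False)
    return ParsedSgRNA(rna, rna[:cut], rna[cut:], True)


def cut_sites(cluster: SeedCluster) -> list[CutSite]:
    """Blunt Cas9 cut positions, 3 bp 5′ of the PAM, per match.

    On the forward strand the cut base is ``pam_start - 3``; on the reverse
    strand the PAM-proximal side lies 3′ of the PAM in forward coordinates,
    so the cut base is ``pam_start + 5``.
    """
    out = []
    for m in cluster.matches:
        pos = m.pam_start - 3 if m.strand == "+" else m.pam_start + 5
        out.append(
            CutSite(
                gene_id=m.gene_id,
                start=pos,
                end=pos + 1,
                strand=m.strand,
                seed_seq=m.seed_seq,
            )
        )
    return out
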