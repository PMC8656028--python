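"""Shared fixtures: hypothesis profile and an independent seed-search oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

_RC = str.maketrans("ACGTN", "TGCAN")
_PAM_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "N": "ACGT", "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
}


def _rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def brute_force_shared_seeds(genes, min_seed_len=13, pam="NGG", min_carriers=2):
    """Exhaustive shared-seed oracle, independent of the package search.

    Enumerates, for every gene and strand, every substring of length >=
    ``min_seed_len`` whose 3' flank matches the PAM.  Because a counted
    occurrence must carry the PAM immediately 3' of the seed, every
    qualifying substring ends at a PAM, so enumerating suffixes of the
    PAM-anchored context covers all substrings; a substring not ending at a
    PAM has no valid occurrence anywhere by definition.  Maximality then
    removes any seed that is a suffix of a one-base-longer seed with the
    identical carrier set (equality with any longer extension reduces to
    the one-base case by nesting of occurrence sets).

    Returns a set of (seed, frozenset-of-carriers) pairs.
    """
    occ: dict[str, set] = {}
    for gid, seq in genes.items():
        for strand in "+-":
            oseq = seq if strand == "+" else _rc(seq)
            for p in range(len(oseq) - 2):
                tri = oseq[p : p + 3]
                if any(b not in _PAM_SETS.get(c, "") for b, c in zip(tri, pam)):
                    continue
                for k in range(min_seed_len, p + 1):
                    s = oseq[p - k : p]
                    if "N" in s:
                        break
                    occ.setdefault(s, set()).add((gid, strand, p))
    carriers = {
        s: frozenset(g for g, _s, _p in sites) for s, sites in occ.items()
    }
    shared = {s for s, c in carriers.items() if len(c) >= min_carriers}
    result = set()
    for s in shared:
        subsumed = any(
            t in shared and carriers[t] == carriers[s]
            for t in (b + s for b in "ACGT")
        )
        if not subsumed:
            result.add((s, carriers[s]))
    return result


@pytest.fixture
def seed_oracle():
    return brute_force_shared_seeds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
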