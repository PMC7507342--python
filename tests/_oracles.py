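"""Independent oracles, deliberately coded apart from the package internals."""

from __future__ import annotations

from functools import lru_cache

from pyteomics import mass as _pmass


def residue_sum_mass(sequence: str) -> float:
    """Peptide monoisotopic mass via pyteomics' independent residue table."""
    return _pmass.fast_mass(sequence, ion_type="M", charge=0)


def naive_motif_scan(sequence: str, motif: str) -> list[int]:
    """O(n*m) window scan; 'x' in the motif matches any character."""
    seq = sequence.upper()
    hits = []
    for start in range(len(seq) - len(motif) + 1):
        if all(p == "x" or seq[start + i] == p for i, p in enumerate(motif)):
            hits.append(start + 1)
    return hits


def lcs_length(a: str, b: str) -> int:
    """Longest common subsequence length, recursive with memoization."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0 or j == 0:
            return 0
        if a[i - 1] == b[j - 1]:
            return rec(i - 1, j - 1) + 1
        return max(rec(i - 1, j), rec(i, j - 1))

    return rec(len(a), len(b))


def ordered_match_identity(a: str, b: str) -> float:
    """Reference value for the mining module's alignment identity."""
    if not a or not b:
        return 0.0
    matches = lcs_length(a.upper(), b.upper())
    return matches / (len(a) + len(b) - matches)
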