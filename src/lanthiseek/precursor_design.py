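"""Design of expressible hybrid precursors and mutant libraries.

Mined precursors are turned into constructs for heterologous modification
by the nisin machinery: the putative core peptide is extracted (the
conserved motif starts at residue 3 of the nisin core, so the core is taken
from two residues before the motif), its N-terminus is adjusted to an
IT/VT protease recognition site so the nisin leader protease (NisP) can
release the mature peptide, and the core is fused to the nisin leader
peptide. The module also builds position-restricted saturation-mutagenesis
libraries of the nisin Z core.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .constants import AMINO_ACIDS, NISIN_LEADER, SATURATION_POSITIONS

if TYPE_CHECKING:  # avoid a runtime cycle with mining
    from .mining import ContextEvidence, NoveltyVerdict


@dataclass(frozen=True)
class PrecursorCandidate:
    """A mined precursor with its extracted and protease-adjusted core."""

    record_id: str
    contig: str
    gene_index: int
    motif_position: int
    raw_core: str
    adjusted_core: str
    context: "ContextEvidence"
    novelty: "NoveltyVerdict"


@dataclass(frozen=True)
class HybridPrecursor:
    leader: str
    core: str

    @property
    def full_sequence(self) -> str:
        return self.leader + self.core


def extract_core(sequence: str, motif_position: int, offset: int = 2) -> str:
    """Core peptide: suffix starting ``offset`` residues before the motif.

    The start is clamped at residue 1. The default offset of 2 aligns with
    nisin, whose core motif match begins at core residue 3.
    """
    if not 1 <= motif_position <= len(sequence):
        raise ValueError(
            f"motif position {motif_position} outside sequence of length {len(sequence)}"
        )
    start = max(1, motif_position - offset)
    return sequence[start - 1 :]


def adjust_nisp_site(raw_core: str) -> str:
    """Ensure the core starts with an IT/VT NisP cleavage context.

    Cores already starting IT or VT are returned unchanged; a core starting
    with T gets a single prepended I (the minimal insertion yielding IT-);
    anything else gets a prepended IT.
    """
    if not raw_core:
        raise ValueError("raw core must be non-empty")
    head = raw_core[:2].upper()
    if head in ("IT", "VT"):
        return raw_core
    if raw_core[0].upper() == "T":
        return "I" + raw_core
    return "IT" + raw_core


def fuse_leader(core: str, leader: str = NISIN_LEADER) -> HybridPrecursor:
    """Fuse a core peptide to a leader peptide (default: nisin leader)."""
    if not core:
        raise ValueError("core must be non-empty")
    if not leader:
        raise ValueError("leader must be non-empty")
    return HybridPrecursor(leader=leader, core=core)


# ---------------------------------------------------------------------------
# saturation-mutagenesis library

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def apply_mutations(core: str, mutations: str) -> str:
    """Apply a comma-separated mutation string such as "I4R,K12W"."""
    seq = list(core)
    if not mutations:
        return core
    for token in mutations.split(","):
        m = _MUTATION_RE.match(token.strip())
        if not m:
            raise ValueError(f"malformed mutation {token!r}")
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if not 1 <= pos <= len(seq):
            raise ValueError(f"mutation position {pos} outside core of length {len(seq)}")
        if seq[pos - 1] != ref:
            raise ValueError(f"mutation {token}: core has {seq[pos - 1]} at position {pos}")
        seq[pos - 1] = alt
    return "".join(seq)


def mutation_string(base: str, variant: str, positions: tuple[int, ...]) -> str:
    """Comma-separated mutation notation for differences at given positions."""
    parts = [
        f"{base[p - 1]}{p}{variant[p - 1]}"
        for p in sorted(positions)
        if variant[p - 1] != base[p - 1]
    ]
    return ",".join(parts)


@dataclass
class LibrarySpec:
    """Specification of a position-restricted saturation library."""

    base_core: str
    positions: tuple[int, ...] = SATURATION_POSITIONS
    n_samples: int = 3000
    seed: int = 0
    alphabet: str = AMINO_ACIDS

    def __post_init__(self):
        if not self.base_core:
            raise ValueError("base core must be non-empty")
        if any(not 1 <= p <= len(self.base_core) for p in self.positions):
            raise ValueError("all positions must lie within the core")
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("positions must be distinct")

    @property
    def space_size(self) -> int:
        return len(self.alphabet) ** len(self.positions)


@dataclass(frozen=True)
class LibraryMember:
    sequence: str
    mutations: str


def build_saturation_library(spec: LibrarySpec) -> list[LibraryMember]:
    """Sample distinct mutant cores, uniformly over the saturation space.

    Each listed position is independently assigned one of the 20 residues
    (wild type included, i.e. true saturation); sampling is without
    replacement over distinct variants, the unmutated base core is excluded
    from the output, and the draw is deterministic under the seed. The
    feasible output size is therefore ``space_size - 1``.
    """
    positions = tuple(sorted(spec.positions))
    max_distinct = spec.space_size - 1  # base core itself is excluded
    if spec.n_samples > max_distinct:
        raise ValueError(
            f"n_samples={spec.n_samples} exceeds the {max_distinct} distinct "
            f"non-wild-type variants of a {len(positions)}-position library"
        )
    rng = np.random.default_rng(spec.seed)
    alphabet = np.array(list(spec.alphabet))
    base_tuple = tuple(spec.base_core[p - 1] for p in positions)

    seen: set[tuple[str, ...]] = set()
    members: list[LibraryMember] = []
    while len(members) < spec.n_samples:
        combo = tuple(alphabet[rng.integers(0, len(alphabet), size=len(positions))])
        if combo == base_tuple or combo in seen:
            continue
        seen.add(combo)
        seq = list(spec.base_core)
        for p, aa in zip(positions, combo):
            seq[p - 1] = aa
        variant = "".join(seq)
        members.append(
            LibraryMember(sequence=variant, mutations=mutation_string(spec.base_core, variant, positions))
        )
    return members
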