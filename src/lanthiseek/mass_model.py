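"""Mass and m/z modeling of lanthipeptide species.

A mature lanthipeptide is observed as a family of species: the core peptide
with ``n`` dehydrations (each Ser/Thr dehydration removes one water,
18.010565 Da; thioether ring closure itself is mass-neutral) and, after
N-ethylmaleimide (NEM) treatment, ``m`` adducts of +125.047679 Da marking
free (non-ring) cysteines. This module enumerates those species, computes
monoisotopic masses and charge-state m/z, matches observed peak lists
within a ppm tolerance, summarizes observed dehydration ranges in the
conventional "a-b (k)" notation (observed range, Ser+Thr capacity in
parentheses), and converts NEM adduct counts into ring counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .constants import (
    MONOISOTOPIC_RESIDUE_MASSES,
    NEM_ADDUCT_MONO,
    PROTON_MASS,
    WATER_MONO,
)


def monoisotopic_mass(sequence: str) -> float:
    """Monoisotopic mass of an unmodified peptide (residue sum + water)."""
    if not sequence:
        raise ValueError("empty sequence has no defined peptide mass")
    total = WATER_MONO
    for i, aa in enumerate(sequence.upper(), start=1):
        try:
            total += MONOISOTOPIC_RESIDUE_MASSES[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} at position {i}") from None
    return total


def count_dehydratable(sequence: str) -> int:
    """Number of Ser + Thr residues (the dehydration capacity)."""
    s = sequence.upper()
    return s.count("S") + s.count("T")


def count_cysteines(sequence: str) -> int:
    return sequence.upper().count("C")


def species_mass(sequence: str, n_dehyd: int = 0, n_nem: int = 0) -> float:
    """Monoisotopic mass of a dehydrated / NEM-alkylated species.

    ``n_dehyd`` must not exceed the Ser+Thr count and ``n_nem`` must not
    exceed the Cys count.
    """
    if n_dehyd < 0 or n_nem < 0:
        raise ValueError("modification counts must be non-negative")
    cap = count_dehydratable(sequence)
    if n_dehyd > cap:
        raise ValueError(f"n_dehyd={n_dehyd} exceeds Ser+Thr count {cap}")
    n_cys = count_cysteines(sequence)
    if n_nem > n_cys:
        raise ValueError(f"n_nem={n_nem} exceeds Cys count {n_cys}")
    return monoisotopic_mass(sequence) - n_dehyd * WATER_MONO + n_nem * NEM_ADDUCT_MONO


def mz(mass: float, charge: int) -> float:
    """m/z of the [M+zH]z+ ion."""
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    return (mass + charge * PROTON_MASS) / charge


@dataclass(frozen=True)
class PeptideSpecies:
    """One (sequence, dehydration count, NEM count, charge) species."""

    sequence: str
    n_dehyd: int = 0
    n_nem: int = 0
    charge: int = 1
    mono_mass: float = field(init=False)
    mz: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "mono_mass", species_mass(self.sequence, self.n_dehyd, self.n_nem))
        object.__setattr__(self, "mz", mz(self.mono_mass, self.charge))


def dehydration_series(
    sequence: str,
    charges: Sequence[int],
    nem_range: Sequence[int] = (0,),
) -> list[PeptideSpecies]:
    """All species with 0..capacity dehydrations at each charge/NEM count."""
    if not charges:
        raise ValueError("charges must be non-empty")
    cap = count_dehydratable(sequence)
    return [
        PeptideSpecies(sequence, n, m, z)
        for m in nem_range
        for n in range(cap + 1)
        for z in charges
    ]


@dataclass(frozen=True)
class PeakAssignment:
    observed_mz: float
    intensity: float
    species: PeptideSpecies
    ppm_error: float
    ambiguous: bool = False


@dataclass
class AssignmentResult:
    assignments: list[PeakAssignment]
    unassigned: list[tuple[float, float]]
    observed_dehydrations: set[int]
    report: str


def format_modification(observed: Iterable[int], capacity: int) -> str:
    """Render observed dehydration counts as "6-8 (8)" / "6,7 (9)" / "(9)".

    Contiguous runs are hyphenated; isolated values are comma-separated; the
    Ser+Thr capacity always follows in parentheses.
    """
    values = sorted(set(observed))
    if not values:
        return f"({capacity})"
    runs: list[str] = []
    start = prev = values[0]
    for v in values[1:] + [None]:  # type: ignore[list-item]
        if v is not None and v == prev + 1:
            prev = v
            continue
        runs.append(str(start) if start == prev else f"{start}-{prev}")
        if v is not None:
            start = prev = v
    return f"{','.join(runs)} ({capacity})"


def assign_peaks(
    peaks: Sequence[tuple[float, float]],
    species: Sequence[PeptideSpecies],
    tol_ppm: float = 10.0,
) -> AssignmentResult:
    """Match observed peaks to the nearest predicted species within ppm.

    Each peak is assigned to the species with the smallest absolute ppm
    error if that error is within ``tol_ppm``; ties are broken by lowest
    dehydration count. A peak with two species within tolerance at an
    indistinguishable (< 1e-6 ppm) separation is flagged ambiguous. The
    report string summarizes the distinct observed dehydration counts in
    the "a-b (k)" convention and requires all species to share one
    sequence.
    """
    if not species:
        raise ValueError("species list must be non-empty")
    sequences = {sp.sequence for sp in species}
    if len(sequences) != 1:
        raise ValueError("assign_peaks expects species of a single peptide")
    capacity = count_dehydratable(next(iter(sequences)))

    assignments: list[PeakAssignment] = []
    unassigned: list[tuple[float, float]] = []
    for observed_mz, intensity in peaks:
        scored = sorted(
            (
                (abs((observed_mz - sp.mz) / sp.mz * 1e6), sp.n_dehyd, sp)
                for sp in species
            ),
            key=lambda t: (t[0], t[1]),
        )
        best_abs, _, best = scored[0]
        if best_abs > tol_ppm:
            unassigned.append((observed_mz, intensity))
            continue
        ambiguous = len(scored) > 1 and scored[1][0] - best_abs < 1e-6 and scored[1][0] <= tol_ppm
        signed_ppm = (observed_mz - best.mz) / best.mz * 1e6
        assignments.append(PeakAssignment(observed_mz, intensity, best, signed_ppm, ambiguous))

    observed = {a.species.n_dehyd for a in assignments}
    return AssignmentResult(
        assignments=assignments,
        unassigned=unassigned,
        observed_dehydrations=observed,
        report=format_modification(observed, capacity),
    )


@dataclass(frozen=True)
class RingTopology:
    """Thioether ring count inferred from the NEM alkylation assay.

    Every cysteine engaged in a (methyl)lanthionine ring is protected from
    alkylation, so the observed adduct count equals the number of free
    cysteines and rings = total Cys - adducts.
    """

    n_cys: int
    n_free_cys: int

    @property
    def n_rings(self) -> int:
        return self.n_cys - self.n_free_cys


def ring_topology(core: str, observed_nem_adducts: int) -> RingTopology:
    n_cys = count_cysteines(core)
    if not 0 <= observed_nem_adducts <= n_cys:
        raise ValueError(
            f"observed adduct count {observed_nem_adducts} outside 0..{n_cys} (Cys count)"
        )
    return RingTopology(n_cys=n_cys, n_free_cys=observed_nem_adducts)
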