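"""Seeded generators for proteomes, peak lists and screening plates.

Every generator returns its ground truth alongside the data, so each
downstream stage (mining, peak assignment, screening) can be scored
exactly. All randomness flows from the single seed in the spec; a fixed
spec yields byte-identical outputs.

The proteome generator emulates the population mined in the real study: a
handful of planted nisin-analog precursors (40-80 aa, core motif, Lan-like
enzymes within ten genes) buried among decoys of four classes - plain
random protein, motif-without-context, context-without-motif, and a known
core replanted with full context (which must fall at the novelty stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import AMINO_ACIDS, CORE_MOTIF, NISIN_Z_CORE
from .mass_model import PeptideSpecies
from .mining import ProteinRecord, find_motif
from .screening import WELLS_96, Plate

_AA = np.array(list(AMINO_ACIDS))

#: Default planted cores: three published nisin-analog core peptides.
DEFAULT_PLANT_CORES = (
    "ITSVSLCTPGCKTGALMGCNMKTASCGCHVHVSK",  # RL6
    "VTSKSLCTPGCKTGILQTCAIKSATCGCSIHIGK",  # RL8
    "VTSISLCTPGCKTGILMTCAIKTATCGCHF",      # bagelicin
)

_NEIGHBOR_PRODUCTS = {
    "LanB-like": "lanthionine biosynthesis dehydratase (LanB-like)",
    "LanC-like": "lanthionine biosynthesis cyclase (LanC-like)",
    "LanM-like": "class II lanthipeptide synthetase (LanM-like)",
}


@dataclass(frozen=True)
class PlantSpec:
    """One planted precursor: core, total length, and Lan-gene neighborhood."""

    core_sequence: str
    precursor_length: int = 60
    neighbor_offsets: tuple[int, ...] = (3,)
    neighbor_kind: str = "LanB-like"

    def __post_init__(self):
        if not 40 <= self.precursor_length <= 80:
            raise ValueError("precursor_length must lie in [40, 80]")
        if len(self.core_sequence) >= self.precursor_length:
            raise ValueError("core must be shorter than the precursor")
        if self.neighbor_kind not in _NEIGHBOR_PRODUCTS:
            raise ValueError(f"unknown neighbor kind {self.neighbor_kind!r}")
        if any(o == 0 or abs(o) > 10 for o in self.neighbor_offsets):
            raise ValueError("neighbor offsets must be non-zero and within +/-10")


def default_plants() -> tuple[PlantSpec, ...]:
    kinds = ("LanB-like", "LanC-like", "LanM-like")
    return tuple(
        PlantSpec(core, precursor_length=50 + 8 * i, neighbor_offsets=(3, -2), neighbor_kind=kinds[i])
        for i, core in enumerate(DEFAULT_PLANT_CORES)
    )


@dataclass
class GenomeSpec:
    n_decoy_genes: int = 200
    planted: tuple[PlantSpec, ...] = field(default_factory=default_plants)
    decoy_classes: dict[str, float] = field(
        default_factory=lambda: {
            "random": 0.5,
            "motif_no_context": 0.2,
            "context_no_motif": 0.2,
            "known_duplicate": 0.1,
        }
    )
    length_range_decoy: tuple[int, int] = (30, 120)
    motif: str = CORE_MOTIF
    seed: int = 42

    def __post_init__(self):
        if abs(sum(self.decoy_classes.values()) - 1.0) > 1e-9:
            raise ValueError("decoy class proportions must sum to 1")
        unknown = set(self.decoy_classes) - {
            "random",
            "motif_no_context",
            "context_no_motif",
            "known_duplicate",
        }
        if unknown:
            raise ValueError(f"unknown decoy classes {sorted(unknown)}")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA[rng.integers(0, len(_AA), size=length)])


def _random_seq_without_motif(rng: np.random.Generator, length: int, motif: str) -> str:
    while True:
        seq = _random_seq(rng, length)
        if not find_motif(seq, motif):
            return seq


def _motif_instance(rng: np.random.Generator, motif: str) -> str:
    return "".join(_AA[rng.integers(0, len(_AA))] if c == "x" else c for c in motif)


def _plant_precursor(rng: np.random.Generator, plant: PlantSpec, motif: str) -> tuple[str, int]:
    """Random leader + core, with the core's motif as the leftmost hit."""
    core_hits = find_motif(plant.core_sequence, motif)
    if not core_hits:
        raise ValueError(
            f"planted core {plant.core_sequence!r} does not contain the motif {motif!r}"
        )
    leader_len = plant.precursor_length - len(plant.core_sequence)
    while True:
        leader = _random_seq(rng, leader_len)
        seq = leader + plant.core_sequence
        hits = find_motif(seq, motif)
        if hits[0] == leader_len + core_hits[0]:
            return seq, hits[0]


def _decoy_counts(spec: GenomeSpec) -> dict[str, int]:
    counts = {
        cls: int(np.floor(frac * spec.n_decoy_genes))
        for cls, frac in spec.decoy_classes.items()
    }
    counts["random"] = counts.get("random", 0) + spec.n_decoy_genes - sum(counts.values())
    return counts


def generate_proteome(
    spec: GenomeSpec,
) -> tuple[list[ProteinRecord], pd.DataFrame, pd.DataFrame]:
    """Synthesize (records, annotation table, truth table).

    The truth table has one row per record with columns ``record_id`` and
    ``category`` (``planted``, one of the four decoy classes,
    ``lan_neighbor`` or ``filler``).
    """
    from .reference import load_lan_references

    rng = np.random.default_rng(spec.seed)
    references = load_lan_references()
    records: list[ProteinRecord] = []
    truth_rows: list[tuple[str, str]] = []

    def add(rec: ProteinRecord, category: str) -> None:
        records.append(rec)
        truth_rows.append((rec.id, category))

    # planted precursors: one contig each, precursor at gene index 10 with
    # Lan neighbors at the specified offsets and random fillers elsewhere
    for i, plant in enumerate(spec.planted):
        contig = f"ctg_plant{i:02d}"
        seq, _ = _plant_precursor(rng, plant, spec.motif)
        occupied = {10 + off for off in plant.neighbor_offsets}
        for idx in range(21):
            pid = f"{contig}_g{idx:02d}"
            if idx == 10:
                add(ProteinRecord(pid, seq, contig, idx, "hypothetical protein"), "planted")
            elif idx in occupied:
                ref_name, ref_seq = references[i % len(references)]
                start = int(rng.integers(0, max(1, len(ref_seq) - 150)))
                add(
                    ProteinRecord(
                        pid,
                        ref_seq[start : start + 150],
                        contig,
                        idx,
                        _NEIGHBOR_PRODUCTS[plant.neighbor_kind],
                    ),
                    "lan_neighbor",
                )
            else:
                filler = _random_seq_without_motif(
                    rng, int(rng.integers(90, 240)), spec.motif
                )
                add(ProteinRecord(pid, filler, contig, idx, "hypothetical protein"), "filler")

    counts = _decoy_counts(spec)
    lo, hi = spec.length_range_decoy

    # random + motif_no_context decoys share Lan-free contigs
    decoy_idx = 0
    for _ in range(counts.get("random", 0)):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq_without_motif(rng, length, spec.motif)
        contig = f"ctg_decoys{decoy_idx // 50:02d}"
        add(
            ProteinRecord(f"decoy_r{decoy_idx:04d}", seq, contig, decoy_idx % 50, "hypothetical protein"),
            "random",
        )
        decoy_idx += 1
    for _ in range(counts.get("motif_no_context", 0)):
        length = int(rng.integers(40, 81))
        seq = list(_random_seq_without_motif(rng, length, spec.motif))
        pos = int(rng.integers(0, length - len(spec.motif) + 1))
        seq[pos : pos + len(spec.motif)] = _motif_instance(rng, spec.motif)
        contig = f"ctg_decoys{decoy_idx // 50:02d}"
        add(
            ProteinRecord(
                f"decoy_m{decoy_idx:04d}", "".join(seq), contig, decoy_idx % 50, "hypothetical protein"
            ),
            "motif_no_context",
        )
        decoy_idx += 1

    # context_no_motif and known_duplicate decoys each get their own contig
    # with a keyword-annotated Lan neighbor two genes downstream
    def add_with_context(n: int, prefix: str, category: str, make_seq) -> None:
        for j in range(n):
            contig = f"ctg_{prefix}{j:03d}"
            add(ProteinRecord(f"{prefix}_{j:04d}", make_seq(), contig, 0, "hypothetical protein"), category)
            ref_name, ref_seq = references[j % len(references)]
            add(
                ProteinRecord(
                    f"{prefix}_{j:04d}_nbr",
                    ref_seq[:150],
                    contig,
                    2,
                    _NEIGHBOR_PRODUCTS["LanB-like"],
                ),
                "lan_neighbor",
            )

    add_with_context(
        counts.get("context_no_motif", 0),
        "cnm",
        "context_no_motif",
        lambda: _random_seq_without_motif(rng, int(rng.integers(40, 81)), spec.motif),
    )

    def known_dup_seq() -> str:
        # leader sized so the full precursor stays within 40-80 aa
        leader_len = int(rng.integers(6, 81 - len(NISIN_Z_CORE)))
        leader = _random_seq_without_motif(rng, leader_len, spec.motif)
        return leader + NISIN_Z_CORE

    add_with_context(counts.get("known_duplicate", 0), "kdup", "known_duplicate", known_dup_seq)

    annotations = pd.DataFrame(
        [(r.contig, r.gene_index, r.id, r.product) for r in records],
        columns=["contig", "gene_index", "protein_id", "product"],
    )
    truth = pd.DataFrame(truth_rows, columns=["record_id", "category"])
    return records, annotations, truth


# ---------------------------------------------------------------------------
# peak lists


@dataclass
class PeakListSpec:
    species: tuple[PeptideSpecies, ...]
    ppm_noise_sd: float = 2.0
    n_noise_peaks: int = 0
    intensity_model: str = "uniform"
    seed: int = 0

    def __post_init__(self):
        if not self.species:
            raise ValueError("species must be non-empty")
        if self.ppm_noise_sd < 0:
            raise ValueError("ppm noise standard deviation must be >= 0")
        if self.n_noise_peaks < 0:
            raise ValueError("noise peak count must be >= 0")


def generate_peaklist(spec: PeakListSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One peak per species (ppm-perturbed) plus uniform decoy peaks.

    Returns (peaks, truth); peaks has columns ``mz`` and ``intensity``,
    truth maps each signal peak to its (n_dehyd, n_nem, charge).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    truth_rows = []
    for sp in spec.species:
        ppm = rng.normal(0.0, spec.ppm_noise_sd) if spec.ppm_noise_sd > 0 else 0.0
        observed = sp.mz * (1.0 + ppm * 1e-6)
        intensity = float(1e6 * rng.uniform(0.1, 1.0))
        rows.append((observed, intensity))
        truth_rows.append((observed, sp.n_dehyd, sp.n_nem, sp.charge))
    mzs = [sp.mz for sp in spec.species]
    lo, hi = 0.9 * min(mzs), 1.1 * max(mzs)
    for _ in range(spec.n_noise_peaks):
        rows.append((float(rng.uniform(lo, hi)), float(1e5 * rng.uniform(0.1, 1.0))))
    peaks = pd.DataFrame(rows, columns=["mz", "intensity"])
    truth = pd.DataFrame(truth_rows, columns=["mz", "n_dehyd", "n_nem", "charge"])
    return peaks, truth


# ---------------------------------------------------------------------------
# screening plates


@dataclass
class PlateSpec:
    n_plates: int = 32
    control_wells: tuple[str, ...] = ("A1", "A2", "A3")
    baseline_od: float = 0.6
    od_noise_sd: float = 0.02
    planted_inhibitors: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_plates < 1:
            raise ValueError("need at least one plate")
        if not self.control_wells:
            raise ValueError("need at least one control well per plate")
        if self.od_noise_sd < 0:
            raise ValueError("OD noise standard deviation must be >= 0")
        unknown = set(self.control_wells) - set(WELLS_96)
        if unknown:
            raise ValueError(f"unknown control wells {sorted(unknown)}")
        for plate_id, effects in self.planted_inhibitors.items():
            for well, effect in effects.items():
                if well in self.control_wells:
                    raise ValueError(
                        f"planted inhibitor {plate_id}/{well} collides with a control well"
                    )
                if well not in WELLS_96:
                    raise ValueError(f"unknown well {well!r}")
                if effect < 0:
                    raise ValueError("effect sizes must be >= 0")

    def plate_ids(self) -> list[str]:
        return [f"plate{i + 1:02d}" for i in range(self.n_plates)]


def generate_plates(spec: PlateSpec) -> tuple[list[Plate], pd.DataFrame]:
    """Plates of OD600 readings with planted growth-inhibiting wells.

    Control and test wells draw from Normal(baseline, sd); an inhibitor
    well's expectation is baseline - effect. All ODs are truncated at 0.
    Returns (plates, truth) with truth rows (plate_id, well, effect).
    """
    rng = np.random.default_rng(spec.seed)
    plates: list[Plate] = []
    truth_rows = []
    for plate_id in spec.plate_ids():
        effects = spec.planted_inhibitors.get(plate_id, {})
        wells = {}
        for well in WELLS_96:
            mean = spec.baseline_od - effects.get(well, 0.0)
            noise = rng.normal(0.0, spec.od_noise_sd) if spec.od_noise_sd > 0 else 0.0
            wells[well] = max(0.0, mean + noise)
        plates.append(Plate(plate_id, wells, frozenset(spec.control_wells)))
        truth_rows.extend((plate_id, w, e) for w, e in sorted(effects.items()))
    truth = pd.DataFrame(truth_rows, columns=["plate_id", "well", "effect"])
    return plates, truth
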