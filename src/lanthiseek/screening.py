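"""Two-round 96-well growth-inhibition screening analytics and MIC calling.

Round 1 picks, per plate, the k test wells with the lowest raw OD600 (the
most growth-inhibited cultures). Round 2 recomputes each candidate against
the in-plate nisin controls: dOD600 = OD(well) - mean OD(control wells of
the same plate); wells with strictly negative dOD600 (inhibiting growth
more than nisin itself) are hits, ranked ascending. MIC is the lowest
concentration in a dilution series whose OD600 is at or below a no-growth
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

ROWS = "ABCDEFGH"
COLUMNS = range(1, 13)
WELLS_96 = tuple(f"{r}{c}" for r in ROWS for c in COLUMNS)
_WELL_ORDER = {w: i for i, w in enumerate(WELLS_96)}


def well_sort_key(well: str) -> int:
    """Row-major order A1..A12, B1..H12 (used for deterministic tie-breaks)."""
    try:
        return _WELL_ORDER[well]
    except KeyError:
        raise ValueError(f"unknown well id {well!r}") from None


@dataclass
class Plate:
    plate_id: str
    wells: dict[str, float]  # well -> OD600
    control_wells: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        self.control_wells = frozenset(self.control_wells)
        missing = self.control_wells - self.wells.keys()
        if missing:
            raise ValueError(f"control wells {sorted(missing)} not present on {self.plate_id}")
        if any(od < 0 for od in self.wells.values()):
            raise ValueError("OD600 values must be non-negative")

    @property
    def test_wells(self) -> list[str]:
        return sorted(self.wells.keys() - self.control_wells, key=well_sort_key)


@dataclass(frozen=True)
class WellResult:
    plate_id: str
    well: str
    od600: float
    delta_od600: float
    round1_selected: bool = False
    round2_hit: bool = False


def delta_od(plate: Plate) -> dict[str, float]:
    """Per-well dOD600 against the mean of the plate's own control wells."""
    if not plate.control_wells:
        raise ValueError(f"plate {plate.plate_id} has no control wells")
    control_mean = sum(plate.wells[w] for w in plate.control_wells) / len(plate.control_wells)
    return {w: od - control_mean for w, od in plate.wells.items()}


def select_round1(plates: Sequence[Plate], k: int = 5) -> list[WellResult]:
    """Per plate, the k non-control wells with lowest raw OD600.

    Ties are broken by row-major well order. If a plate has fewer than k
    test wells, all are taken with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    selected: list[WellResult] = []
    for plate in plates:
        deltas = delta_od(plate)
        test = plate.test_wells
        if k > len(test):
            warnings.warn(
                f"plate {plate.plate_id}: k={k} exceeds {len(test)} test wells; taking all",
                stacklevel=2,
            )
        ranked = sorted(test, key=lambda w: (plate.wells[w], well_sort_key(w)))[:k]
        selected.extend(
            WellResult(plate.plate_id, w, plate.wells[w], deltas[w], round1_selected=True)
            for w in ranked
        )
    return selected


def select_round2(well_results: Sequence[WellResult]) -> list[WellResult]:
    """Wells with strictly negative dOD600, ranked most inhibitory first."""
    hits = [r for r in well_results if r.delta_od600 < 0]
    hits.sort(key=lambda r: (r.delta_od600, r.plate_id, well_sort_key(r.well)))
    return [
        WellResult(r.plate_id, r.well, r.od600, r.delta_od600, r.round1_selected, True)
        for r in hits
    ]


def screen(plates: Sequence[Plate], k: int = 5) -> list[WellResult]:
    """Round-1 selection followed by round-2 dOD600 hit calling."""
    return select_round2(select_round1(plates, k=k))


@dataclass
class MicInput:
    concentrations: Sequence[float]  # strictly increasing
    od600_by_conc: Mapping[float, float]
    no_growth_threshold: float = 0.05

    def __post_init__(self):
        if not self.concentrations:
            raise ValueError("empty concentration series")
        if any(b <= a for a, b in zip(self.concentrations, self.concentrations[1:])):
            raise ValueError("concentrations must be strictly increasing")
        missing = [c for c in self.concentrations if c not in self.od600_by_conc]
        if missing:
            raise ValueError(f"missing OD600 readings for concentrations {missing}")


def mic_call(mic_input: MicInput) -> float | None:
    """Lowest concentration with OD600 at or below the no-growth threshold.

    The rule is applied literally; a non-monotone series (regrowth above a
    qualifying concentration) triggers a warning but still returns the
    lowest qualifying concentration.
    """
    qualifying = [
        c
        for c in mic_input.concentrations
        if mic_input.od600_by_conc[c] <= mic_input.no_growth_threshold
    ]
    if not qualifying:
        return None
    mic = qualifying[0]
    above = [c for c in mic_input.concentrations if c > mic]
    if any(mic_input.od600_by_conc[c] > mic_input.no_growth_threshold for c in above):
        warnings.warn(
            f"growth observed above the putative MIC {mic}; series is non-monotone",
            stacklevel=2,
        )
    return mic


def delta_heatmap(plates: Sequence[Plate], path: str) -> None:
    """Write a per-plate dOD600 heat map (8x12 grid per plate) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    n = len(plates)
    fig, axes = plt.subplots(n, 1, figsize=(6, 2.2 * n), squeeze=False)
    for ax, plate in zip(axes.ravel(), plates):
        deltas = delta_od(plate)
        grid = np.full((8, 12), np.nan)
        for w, d in deltas.items():
            grid[ROWS.index(w[0]), int(w[1:]) - 1] = d
        im = ax.imshow(grid, cmap="RdYlBu", aspect="auto")
        ax.set_title(f"{plate.plate_id} dOD600")
        ax.set_yticks(range(8), list(ROWS))
        fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
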