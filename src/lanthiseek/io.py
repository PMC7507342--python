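"""Readers and writers for the package's plain-text artifact formats.

Formats: protein FASTA, gene-annotation TSV (contig, gene_index,
protein_id, product), peak-list CSV (mz, intensity), plate CSV (plate_id,
well, od600, is_control) and generic truth/candidate TSVs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mining import ProteinRecord
from .screening import Plate


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_proteome(
    records: Sequence[ProteinRecord],
    annotations: pd.DataFrame,
    outdir: str | Path,
    truth: pd.DataFrame | None = None,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([(r.id, r.sequence) for r in records], outdir / "proteome.faa")
    annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    if truth is not None:
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def read_proteome(fasta_path: str | Path, annotation_path: str | Path) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Join a protein FASTA with its annotation table into ProteinRecords."""
    annotations = pd.read_csv(annotation_path, sep="\t", dtype={"gene_index": int})
    by_id = {row["protein_id"]: row for _, row in annotations.iterrows()}
    records = []
    for name, seq in read_fasta(fasta_path):
        if name not in by_id:
            raise KeyError(f"protein {name!r} missing from the annotation table")
        row = by_id[name]
        records.append(
            ProteinRecord(name, seq, str(row["contig"]), int(row["gene_index"]), str(row["product"]))
        )
    return records, annotations


def write_peaks(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks.to_csv(path, index=False)


def read_peaks(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    if not {"mz", "intensity"} <= set(df.columns):
        raise ValueError("peak list must have 'mz' and 'intensity' columns")
    return list(df[["mz", "intensity"]].itertuples(index=False, name=None))


def write_plates(plates: Sequence[Plate], path: str | Path) -> None:
    rows = [
        (p.plate_id, well, od, well in p.control_wells)
        for p in plates
        for well, od in sorted(p.wells.items())
    ]
    pd.DataFrame(rows, columns=["plate_id", "well", "od600", "is_control"]).to_csv(
        path, index=False
    )


def read_plates(path: str | Path) -> list[Plate]:
    df = pd.read_csv(path)
    plates = []
    for plate_id, group in df.groupby("plate_id", sort=True):
        wells = dict(zip(group["well"], group["od600"]))
        controls = frozenset(group.loc[group["is_control"], "well"])
        plates.append(Plate(str(plate_id), wells, controls))
    return plates
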