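"""Loaders for the small reference datasets shipped with the package.

These cover: the published table of mined nisin-analog core peptides (used
as test fixtures and report templates), a minimal known-core database for
the novelty filter, synthetic Lan-enzyme reference sequences for the
similarity route of the gene-context filter, and the table of nisin Z
point-mutant cores from the screening campaign.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
from Bio import SeqIO


def _data_path(name: str):
    return resources.files("lanthiseek.data").joinpath(name)


def load_table1_cores() -> pd.DataFrame:
    """Published nisin-analog candidates (RL1-RL18 and bagelicin).

    Columns: ``sample``, ``core_peptide``, ``modification`` (observed
    dehydration range with Ser+Thr capacity in parentheses),
    ``anti_m_luteus``, ``source``, and ``nisp_adjusted`` ('yes' where the
    listed core carries a prepended I/IT protease site).
    """
    with resources.as_file(_data_path("table1_cores.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def load_known_cores() -> list[tuple[str, str]]:
    """(name, core sequence) pairs of known lanthipeptide core peptides.

    Minimal database standing in for an external known-lanthipeptide
    resource; callers may extend it with their own FASTA.
    """
    with resources.as_file(_data_path("known_cores.fasta")) as p:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(p), "fasta")]


def load_lan_references() -> list[tuple[str, str]]:
    """Synthetic Lan-enzyme reference sequences (clearly labelled as such).

    Used only by the sequence-similarity route of the gene-neighborhood
    filter; substitute real NisB/NisC/LanM sequences for production mining.
    """
    with resources.as_file(_data_path("lan_references_synthetic.fasta")) as p:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(p), "fasta")]


def load_nisin_variants() -> pd.DataFrame:
    """Nisin Z core and the screened point mutants (S29A, M4, M5).

    Columns: ``name``, ``mutations`` (comma-separated, e.g. ``I4R,K12W``),
    ``core_peptide``.
    """
    with resources.as_file(_data_path("nisin_variants.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    df["mutations"] = df["mutations"].fillna("")
    return df
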