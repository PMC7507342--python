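"""Four-filter genome mining for nisin-analog precursor peptides.

The scheme screens a proteome for candidate class I lanthipeptide
precursors with four independent predicates:

1. length: precursors of 40-80 amino acids (inclusive);
2. motif: the conserved core-peptide motif ``SxSLCTPGCxTG`` ('x' = any
   residue) somewhere in the sequence;
3. gene context: a LanB/LanC-like or LanM-like biosynthetic enzyme encoded
   within ten genes up- or downstream on the same contig, recognized either
   by product-description keywords or by sequence similarity to packaged
   reference enzymes;
4. novelty: global-alignment identity below a threshold against a database
   of known lanthipeptide cores.

``mine`` composes the filters, extracts and protease-site-adjusts the core
peptide of each survivor, and reports per-stage survivor counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align

from .constants import CORE_MOTIF


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence anchored at (contig, gene index)."""

    id: str
    sequence: str
    contig: str
    gene_index: int
    product: str = ""


@dataclass(frozen=True)
class GeneAnnotation:
    contig: str
    gene_index: int
    protein_id: str
    product: str


@dataclass(frozen=True)
class MotifHit:
    record_id: str
    position: int  # 1-based start of the motif match


@dataclass(frozen=True)
class ContextEvidence:
    """Neighboring genes supporting Lan-enzyme context; empty => excluded."""

    supporting_gene_ids: tuple[str, ...] = ()
    offsets: tuple[int, ...] = ()
    kinds: tuple[str, ...] = ()  # "keyword" or "similarity" per supporter

    def __bool__(self) -> bool:
        return bool(self.supporting_gene_ids)


@dataclass(frozen=True)
class NoveltyVerdict:
    is_known: bool
    best_match_name: str | None
    best_identity: float


@dataclass(frozen=True)
class KnownCoreDB:
    """Known lanthipeptide core peptides used by the novelty filter."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self):
        names = [n for n, _ in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("known-core database names must be unique")
        if any(not s for _, s in self.entries):
            raise ValueError("known-core database sequences must be non-empty")


_DEFAULT_LAN_KEYWORDS = (
    "lanthionine",
    "dehydratase",
    "cyclase",
    "lantibiotic",
    "lanb",
    "lanc",
    "lanm",
    "nisb",
    "nisc",
)


@dataclass
class MiningParams:
    min_len: int = 40
    max_len: int = 80
    motif: str = CORE_MOTIF
    context_window: int = 10
    novelty_identity_threshold: float = 0.90
    lan_keywords: tuple[str, ...] = _DEFAULT_LAN_KEYWORDS
    lan_reference_seqs: tuple[tuple[str, str], ...] | None = None
    lan_similarity_min_identity: float = 0.30
    lan_similarity_min_coverage: float = 0.50
    core_start_offset: int = 2  # core starts this many residues before the motif

    def __post_init__(self):
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("require 0 < min_len <= max_len")
        if not re.fullmatch(r"[A-Zx]+", self.motif):
            raise ValueError("motif may contain only uppercase residues and 'x'")

    def references(self) -> tuple[tuple[str, str], ...]:
        if self.lan_reference_seqs is None:
            from .reference import load_lan_references

            self.lan_reference_seqs = tuple(load_lan_references())
        return self.lan_reference_seqs


# ---------------------------------------------------------------------------
# filters


def length_filter(records: Iterable[ProteinRecord], params: MiningParams) -> list[ProteinRecord]:
    """Keep records with min_len <= length <= max_len (both inclusive)."""
    return [r for r in records if params.min_len <= len(r.sequence) <= params.max_len]


def _motif_regex(motif: str) -> re.Pattern[str]:
    if not re.fullmatch(r"[A-Zx]+", motif):
        raise ValueError(f"invalid motif pattern {motif!r}")
    # 'x' matches any residue letter; fixed positions match exactly, so an
    # 'X' (unknown residue) in the data can never satisfy a fixed position.
    body = "".join("[A-Z]" if c == "x" else re.escape(c) for c in motif)
    return re.compile(f"(?=({body}))")


def find_motif(sequence: str, motif: str = CORE_MOTIF) -> list[int]:
    """1-based start positions of every (possibly overlapping) motif match."""
    pattern = _motif_regex(motif)
    return [m.start() + 1 for m in pattern.finditer(sequence.upper())]


# Ordered-match identity: the maximum number of residue matches achievable in
# a global alignment with free gaps (equivalently the longest common
# subsequence), normalized by the induced alignment length la + lb - matches.
# Parameter-free and 1.0 exactly for identical sequences.
_LCS_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=0,
    open_gap_score=0,
    extend_gap_score=0,
)


def alignment_identity(a: str, b: str) -> float:
    """Global ordered-match identity between two sequences, in [0, 1]."""
    if not a or not b:
        return 0.0
    matches = _LCS_ALIGNER.score(a.upper(), b.upper())
    return matches / (len(a) + len(b) - matches)


def novelty_filter(core: str, known_db: KnownCoreDB, params: MiningParams) -> NoveltyVerdict:
    """Best identity against the known-core database; known iff >= threshold."""
    if not core:
        raise ValueError("core must be non-empty")
    best_name, best_identity = None, 0.0
    for name, seq in known_db.entries:
        ident = alignment_identity(core, seq)
        if ident > best_identity:
            best_name, best_identity = name, ident
    return NoveltyVerdict(
        is_known=best_identity >= params.novelty_identity_threshold,
        best_match_name=best_name,
        best_identity=best_identity,
    )


_LOCAL_ALIGNER = Align.PairwiseAligner(
    mode="local",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-0.5,
)


def _similar_to_reference(seq: str, ref: str, min_identity: float, min_coverage: float) -> bool:
    """Local-alignment test: identity over aligned columns and reference coverage."""
    if not seq:
        return False
    alignments = _LOCAL_ALIGNER.align(ref.upper(), seq.upper())
    if len(alignments) == 0:
        return False
    aln = alignments[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return False
    ref_aligned = sum(end - start for start, end in aln.aligned[0])
    identity = counts.identities / columns
    coverage = ref_aligned / len(ref)
    return identity >= min_identity and coverage >= min_coverage


def has_lan_context(
    record: ProteinRecord,
    annotations: pd.DataFrame,
    params: MiningParams,
    sequences_by_id: dict[str, str] | None = None,
) -> ContextEvidence:
    """Evidence of a Lan-enzyme gene within the context window.

    A neighbor supports the candidate iff it lies within ``context_window``
    genes on the same contig (offset 0, the candidate itself, never counts)
    and either its product description contains a Lan keyword
    (case-insensitive) or its sequence (when available through
    ``sequences_by_id``) aligns to a packaged Lan reference at the
    configured identity/coverage.
    """
    mine_rows = annotations[annotations["protein_id"] == record.id]
    if mine_rows.empty:
        raise KeyError(f"record {record.id!r} absent from the annotation table")

    neighbors = annotations[
        (annotations["contig"] == record.contig)
        & (annotations["protein_id"] != record.id)
        & ((annotations["gene_index"] - record.gene_index).abs() <= params.context_window)
    ]
    keywords = tuple(k.lower() for k in params.lan_keywords)

    ids: list[str] = []
    offsets: list[int] = []
    kinds: list[str] = []
    for _, row in neighbors.iterrows():
        product = str(row.get("product", "") or "").lower()
        kind = None
        if any(k in product for k in keywords):
            kind = "keyword"
        elif sequences_by_id is not None:
            seq = sequences_by_id.get(row["protein_id"], "")
            if seq and any(
                _similar_to_reference(
                    seq, ref, params.lan_similarity_min_identity, params.lan_similarity_min_coverage
                )
                for _, ref in params.references()
            ):
                kind = "similarity"
        if kind is not None:
            ids.append(str(row["protein_id"]))
            offsets.append(int(row["gene_index"]) - record.gene_index)
            kinds.append(kind)
    return ContextEvidence(tuple(ids), tuple(offsets), tuple(kinds))


# ---------------------------------------------------------------------------
# composition


@dataclass
class MiningResult:
    candidates: list  # list[PrecursorCandidate]
    stage_counts: dict[str, int] = field(default_factory=dict)


def mine(
    records: Sequence[ProteinRecord],
    annotations: pd.DataFrame,
    known_db: KnownCoreDB,
    params: MiningParams | None = None,
) -> MiningResult:
    """Run the full filter chain and return surviving candidates.

    Output is sorted by (contig, gene_index); ``stage_counts`` gives the
    number of records surviving each successive stage.
    """
    from .precursor_design import PrecursorCandidate, adjust_nisp_site, extract_core

    params = params or MiningParams()
    counts = {"input": len(records)}

    kept = length_filter(records, params)
    counts["length"] = len(kept)

    with_motif = [(r, find_motif(r.sequence, params.motif)) for r in kept]
    with_motif = [(r, hits) for r, hits in with_motif if hits]
    counts["motif"] = len(with_motif)

    sequences_by_id = {r.id: r.sequence for r in records}
    with_context = []
    for r, hits in with_motif:
        evidence = has_lan_context(r, annotations, params, sequences_by_id)
        if evidence:
            with_context.append((r, hits, evidence))
    counts["context"] = len(with_context)

    candidates = []
    for r, hits, evidence in with_context:
        motif_pos = hits[0]  # leftmost hit anchors the core
        raw_core = extract_core(r.sequence, motif_pos, offset=params.core_start_offset)
        verdict = novelty_filter(raw_core, known_db, params)
        if verdict.is_known:
            continue
        candidates.append(
            PrecursorCandidate(
                record_id=r.id,
                contig=r.contig,
                gene_index=r.gene_index,
                motif_position=motif_pos,
                raw_core=raw_core,
                adjusted_core=adjust_nisp_site(raw_core),
                context=evidence,
                novelty=verdict,
            )
        )
    counts["novel"] = len(candidates)

    candidates.sort(key=lambda c: (c.contig, c.gene_index))
    return MiningResult(candidates=candidates, stage_counts=counts)
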