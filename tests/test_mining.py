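import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lanthiseek.constants import AMINO_ACIDS, NISIN_Z_CORE
from lanthiseek.mining import (
    ContextEvidence,
    KnownCoreDB,
    MiningParams,
    ProteinRecord,
    alignment_identity,
    find_motif,
    has_lan_context,
    length_filter,
    mine,
    novelty_filter,
)
from lanthiseek.reference import load_lan_references

from ._oracles import naive_motif_scan, ordered_match_identity
from .conftest import RL6_CORE

sequences = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=60)


def _record(seq, idx=0, contig="c", pid=None, product="hypothetical protein"):
    return ProteinRecord(pid or f"g{idx}", seq, contig, idx, product)


def _annotations(records):
    return pd.DataFrame(
        [(r.contig, r.gene_index, r.id, r.product) for r in records],
        columns=["contig", "gene_index", "protein_id", "product"],
    )


class TestLengthFilter:
    @pytest.mark.parametrize("length,kept", [(39, False), (40, True), (80, True), (81, False)])
    def test_inclusive_bounds(self, length, kept):
        records = [_record("A" * length)]
        assert bool(length_filter(records, MiningParams())) is kept

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            MiningParams(min_len=50, max_len=40)


class TestFindMotif:
    def test_nisin_z_core_single_hit_at_three(self):
        assert find_motif(NISIN_Z_CORE) == [3]

    def test_poly_alanine_has_no_hit(self):
        assert find_motif("A" * 60) == []

    def test_wildcard_positions_accept_any_residue(self):
        assert find_motif("AASISLCTPGCKTGAA") == [3]
        assert find_motif("AASVSLCTPGCQTGAA") == [3]

    def test_unknown_residue_never_matches_fixed_position(self):
        # X at the fixed L position breaks the match
        assert find_motif("AASISXCTPGCKTGAA") == []

    def test_malformed_pattern_rejected(self):
        with pytest.raises(ValueError):
            find_motif("AAAA", motif="Sx$LC")

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(sequences)
    def test_agrees_with_naive_scan(self, seq):
        motif = "SxSLCTPGCxTG"
        assert find_motif(seq, motif) == naive_motif_scan(seq, motif)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(sequences, st.integers(min_value=0, max_value=40))
    def test_planted_motif_is_found(self, seq, offset):
        instance = "SASLCTPGCATG"
        pos = min(offset, len(seq))
        planted = seq[:pos] + instance + seq[pos:]
        assert pos + 1 in find_motif(planted, "SxSLCTPGCxTG")


class TestAlignmentIdentity:
    def test_identical_sequences_score_one(self):
        assert alignment_identity(RL6_CORE, RL6_CORE) == 1.0

    def test_empty_sequence_scores_zero(self):
        assert alignment_identity("", RL6_CORE) == 0.0

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        st.text(alphabet="ACDG", min_size=1, max_size=12),
        st.text(alphabet="ACDG", min_size=1, max_size=12),
    )
    def test_agrees_with_lcs_oracle(self, a, b):
        assert alignment_identity(a, b) == pytest.approx(ordered_match_identity(a, b))


class TestNoveltyFilter:
    def test_exact_database_entry_is_known(self, known_db):
        verdict = novelty_filter(NISIN_Z_CORE, known_db, MiningParams())
        assert verdict.is_known
        assert verdict.best_identity == 1.0
        assert verdict.best_match_name == "nisin_Z"

    def test_rl6_is_novel_against_nisin_cores(self, known_db):
        verdict = novelty_filter(RL6_CORE, known_db, MiningParams())
        assert not verdict.is_known
        assert verdict.best_identity < 0.90
        # independent oracle confirms the sub-threshold identity
        oracle_best = max(
            ordered_match_identity(RL6_CORE, seq) for _, seq in known_db.entries
        )
        assert oracle_best == pytest.approx(verdict.best_identity)
        assert oracle_best < 0.90

    def test_empty_database_keeps_everything(self):
        verdict = novelty_filter(RL6_CORE, KnownCoreDB(()), MiningParams())
        assert not verdict.is_known
        assert verdict.best_identity == 0.0

    def test_empty_core_rejected(self, known_db):
        with pytest.raises(ValueError):
            novelty_filter("", known_db, MiningParams())


class TestLanContext:
    def _records_with_neighbor(self, offset, product="nisin dehydratase NisB"):
        candidate = _record("A" * 50, idx=20, pid="cand")
        neighbor = _record("G" * 100, idx=20 + offset, pid="nbr", product=product)
        return candidate, [candidate, neighbor]

    def test_keyword_neighbor_within_window_supports(self):
        cand, records = self._records_with_neighbor(3)
        evidence = has_lan_context(cand, _annotations(records), MiningParams())
        assert evidence
        assert evidence.offsets == (3,)
        assert evidence.kinds == ("keyword",)

    @pytest.mark.parametrize("offset", [-10, 10])
    def test_window_boundary_inclusive(self, offset):
        cand, records = self._records_with_neighbor(offset)
        assert has_lan_context(cand, _annotations(records), MiningParams())

    @pytest.mark.parametrize("offset", [-11, 11])
    def test_outside_window_excluded(self, offset):
        cand, records = self._records_with_neighbor(offset)
        assert not has_lan_context(cand, _annotations(records), MiningParams())

    def test_other_contig_never_supports(self):
        cand = _record("A" * 50, idx=20, pid="cand")
        nbr = ProteinRecord("nbr", "G" * 100, "other", 21, "nisin dehydratase NisB")
        assert not has_lan_context(cand, _annotations([cand, nbr]), MiningParams())

    def test_no_lan_gene_excluded(self):
        cand, records = self._records_with_neighbor(3, product="hypothetical protein")
        assert not has_lan_context(cand, _annotations(records), MiningParams())

    def test_similarity_route_without_keyword(self):
        ref_seq = load_lan_references()[0][1]
        cand = _record("A" * 50, idx=20, pid="cand")
        nbr = _record(ref_seq[:200], idx=23, pid="nbr", product="hypothetical protein")
        evidence = has_lan_context(
            cand, _annotations([cand, nbr]), MiningParams(), {"nbr": nbr.sequence}
        )
        assert evidence.kinds == ("similarity",)

    def test_missing_record_raises_with_id(self):
        cand = _record("A" * 50, pid="ghost")
        with pytest.raises(KeyError, match="ghost"):
            has_lan_context(cand, _annotations([]), MiningParams())


class TestMine:
    def test_recovers_exactly_the_planted_precursors(self, mined_default):
        result, truth = mined_default
        planted = set(truth.loc[truth["category"] == "planted", "record_id"])
        assert {c.record_id for c in result.candidates} == planted

    def test_stage_counts_monotone_nonincreasing(self, mined_default):
        result, _ = mined_default
        counts = [result.stage_counts[k] for k in ("input", "length", "motif", "context", "novel")]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_known_duplicates_fall_at_novelty_stage(self, mined_default):
        result, truth = mined_default
        n_dup = (truth["category"] == "known_duplicate").sum()
        assert n_dup > 0
        # duplicates survive length+motif+context, then are removed
        assert result.stage_counts["context"] - result.stage_counts["novel"] >= n_dup

    def test_agrees_with_bruteforce_recheck(self, default_proteome, known_db):
        """Every record's final verdict matches an independent re-application
        of the four predicates, in a different order (novelty before context).
        """
        _, records, annotations, _ = default_proteome
        from lanthiseek.precursor_design import extract_core

        params = MiningParams()
        expected = set()
        for r in records:
            if not 40 <= len(r.sequence) <= 80:
                continue
            hits = naive_motif_scan(r.sequence, params.motif)
            if not hits:
                continue
            core = extract_core(r.sequence, hits[0])
            if novelty_filter(core, known_db, params).is_known:
                continue
            if not has_lan_context(r, annotations, params):
                continue
            expected.add(r.id)
        result = mine(records, annotations, known_db, params)
        assert {c.record_id for c in result.candidates} == expected

    def test_empty_input_yields_empty_output(self, known_db):
        result = mine([], _annotations([]), known_db)
        assert result.candidates == []
        assert result.stage_counts == {"input": 0, "length": 0, "motif": 0, "context": 0, "novel": 0}

    def test_candidates_sorted_by_locus(self, mined_default):
        result, _ = mined_default
        keys = [(c.contig, c.gene_index) for c in result.candidates]
        assert keys == sorted(keys)
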