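"""Catalog I/O, curation filters, and reference-based numbering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import archhist as ah
from archhist.catalog import CatalogError, RemovalRecord

from conftest import identity_alignment, make_seq


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_parses_id_species_headers(self, tmp_path):
        p = _write(tmp_path, "a.fasta", ">h1|spA\nACDE\n>h2|spB\nWMYG\n")
        catalog = ah.read_fasta(p)
        assert [r.id for r in catalog] == ["h1", "h2"]
        assert [r.species_id for r in catalog] == ["spA", "spB"]

    def test_header_without_pipe_is_both_id_and_species(self, tmp_path):
        p = _write(tmp_path, "a.fasta", ">lone\nACDE\n")
        (rec,) = ah.read_fasta(p)
        assert rec.id == rec.species_id == "lone"

    def test_lowercase_is_uppercased(self, tmp_path):
        p = _write(tmp_path, "a.fasta", ">h1|s\nacde\n")
        (rec,) = ah.read_fasta(p)
        assert rec.sequence == "ACDE"

    def test_empty_file_gives_empty_catalog(self, tmp_path, caplog):
        p = _write(tmp_path, "a.fasta", "")
        with caplog.at_level("WARNING"):
            catalog = ah.read_fasta(p)
        assert len(catalog) == 0
        assert any("empty" in m for m in caplog.messages)

    def test_malformed_fasta_names_line(self, tmp_path):
        p = _write(tmp_path, "a.fasta", "ACDE\n>h1|s\nACDE\n")
        with pytest.raises(CatalogError, match="line 1"):
            ah.read_fasta(p)

    def test_duplicate_id_rejected(self, tmp_path):
        p = _write(tmp_path, "a.fasta", ">h1|s\nACDE\n>h1|s\nACDF\n")
        with pytest.raises(CatalogError, match="duplicate"):
            ah.read_fasta(p)

    def test_roundtrip_write_read(self, tmp_path):
        catalog = ah.HistoneCatalog((
            ah.HistoneRecord("h1", "spA", make_seq()),
            ah.HistoneRecord("h2", "spB", make_seq({10: "R"})),
        ))
        path = tmp_path / "out.fasta"
        ah.write_fasta(catalog, path)
        back = ah.read_fasta(path)
        assert [(r.id, r.species_id, r.sequence) for r in back] == [
            (r.id, r.species_id, r.sequence) for r in catalog
        ]


class TestLengthFilter:
    @pytest.mark.parametrize("length,kept", [
        (59, False), (60, True), (69, True), (80, True), (81, False),
    ])
    def test_inclusive_bounds(self, length, kept):
        catalog = ah.HistoneCatalog(
            (ah.HistoneRecord("h", "s", "A" * length),)
        )
        out, removed = ah.filter_by_length(catalog)
        assert (len(out) == 1) is kept
        if not kept:
            assert removed[0].id == "h"

    def test_bad_bounds_rejected(self):
        catalog = ah.HistoneCatalog(())
        with pytest.raises(CatalogError):
            ah.filter_by_length(catalog, min_len=80, max_len=60)

    def test_removal_log_has_reasons(self):
        catalog = ah.HistoneCatalog((
            ah.HistoneRecord("short", "s", "A" * 10),
            ah.HistoneRecord("long", "s", "A" * 100),
        ))
        _, removed = ah.filter_by_length(catalog)
        reasons = {r.id: r.reason for r in removed}
        assert "too_short" in reasons["short"] and "too_long" in reasons["long"]


class TestDedupe:
    def test_unique_sequences_untouched(self):
        catalog = ah.HistoneCatalog((
            ah.HistoneRecord("a", "s", make_seq({1: "A"})),
            ah.HistoneRecord("b", "s", make_seq({1: "C"})),
        ))
        out, removed = ah.dedupe_identical(catalog, seed=0)
        assert out.ids == catalog.ids and not removed

    def test_identical_class_keeps_exactly_one(self):
        seq = make_seq()
        catalog = ah.HistoneCatalog(tuple(
            ah.HistoneRecord(f"h{i}", "s", seq) for i in range(3)
        ))
        out, removed = ah.dedupe_identical(catalog, seed=11)
        assert len(out) == 1 and len(removed) == 2

    def test_deterministic_given_seed(self):
        seq = make_seq()
        catalog = ah.HistoneCatalog(tuple(
            ah.HistoneRecord(f"h{i}", "s", seq) for i in range(5)
        ))
        out1, _ = ah.dedupe_identical(catalog, seed=3)
        out2, _ = ah.dedupe_identical(catalog, seed=3)
        assert out1.ids == out2.ids

    def test_survivor_set_independent_of_input_order(self):
        seq1, seq2 = make_seq({1: "A"}), make_seq({1: "C"})
        records = [
            ah.HistoneRecord("a", "s", seq1),
            ah.HistoneRecord("b", "s", seq1),
            ah.HistoneRecord("c", "s", seq2),
            ah.HistoneRecord("d", "s", seq2),
        ]
        fwd, _ = ah.dedupe_identical(ah.HistoneCatalog(tuple(records)), seed=5)
        rev, _ = ah.dedupe_identical(
            ah.HistoneCatalog(tuple(reversed(records))), seed=5
        )
        assert set(fwd.ids) == set(rev.ids)


class TestGapColumns:
    def _aligned(self, columns):
        """Build an alignment from per-column lists of characters."""
        n_rows = len(columns[0])
        rows = tuple(
            "".join(col[i] for col in columns) for i in range(n_rows)
        )
        ids = tuple(f"r{i}" for i in range(n_rows))
        return ah.AlignedCatalog(
            ids, rows, {i: i for i in ids},
            np.ones(len(columns), dtype=bool),
        )

    def test_five_percent_rule_is_strict(self):
        col_6gaps = ["-"] * 6 + ["A"] * 94
        col_5gaps = ["-"] * 5 + ["A"] * 95
        col_clean = ["A"] * 100
        col_allgap = ["-"] * 100
        aligned = self._aligned([col_6gaps, col_5gaps, col_clean, col_allgap])
        out = ah.remove_gappy_columns(aligned)
        assert out.column_kept_mask.tolist() == [False, True, True, False]

    def test_idempotent(self):
        aligned = self._aligned([["-", "A", "A"], ["A", "A", "A"]])
        once = ah.remove_gappy_columns(aligned, 0.05)
        twice = ah.remove_gappy_columns(once, 0.05)
        assert once.column_kept_mask.tolist() == twice.column_kept_mask.tolist()

    def test_empty_alignment_rejected(self):
        empty = ah.AlignedCatalog((), (), {}, np.ones(0, dtype=bool))
        with pytest.raises(CatalogError):
            ah.remove_gappy_columns(empty)


class TestPositionMap:
    def test_reference_gaps_are_unmapped(self):
        aligned = ah.AlignedCatalog(
            ("ref",), ("AC-DE",), {"ref": "ref"}, np.ones(5, dtype=bool)
        )
        posmap = ah.build_position_map(aligned, "ref")
        assert dict(posmap.column_to_position) == {0: 1, 1: 2, 3: 3, 4: 4}

    def test_ungapped_69_residue_reference_maps_69_columns(self):
        aligned, posmap = identity_alignment({"ref": make_seq()}, "ref")
        assert posmap.positions == tuple(range(1, 70))

    def test_positional_orthology_offsets_raw_index(self):
        # reference starts one column late, so another row's raw residue 50
        # sits in the column numbered 49 by orthology to the reference
        ref = "-" + make_seq()
        other = "M" + make_seq({49: "E"})
        aligned = ah.AlignedCatalog(
            ("ref", "other"), (ref, other),
            {"ref": "ref", "other": "other"}, np.ones(70, dtype=bool),
        )
        posmap = ah.build_position_map(aligned, "ref")
        assert posmap.residue_at(other, 49) == "E"
        assert other[49] == "E"  # raw 1-based index 50

    def test_missing_reference_rejected(self):
        aligned, _ = identity_alignment({"ref": make_seq()}, "ref")
        with pytest.raises(KeyError):
            ah.build_position_map(aligned, "nope")

    def test_degap_roundtrip_is_identity_on_reference(self):
        ref = "AC-DE-FG"
        aligned = ah.AlignedCatalog(
            ("ref",), (ref,), {"ref": "ref"}, np.ones(8, dtype=bool)
        )
        posmap = ah.build_position_map(aligned, "ref")
        degapped = ref.replace("-", "")
        for k, ch in enumerate(degapped, start=1):
            assert posmap.residue_at(ref, k) == ch


class TestCoreFoldComplete:
    def test_ungapped_row_is_complete(self):
        aligned, posmap = identity_alignment({"ref": make_seq()}, "ref")
        assert ah.core_fold_complete(make_seq(), posmap)

    def test_gap_inside_core_fold_fails(self):
        aligned, posmap = identity_alignment({"ref": make_seq()}, "ref")
        assert not ah.core_fold_complete(make_seq({30: "-"}), posmap)

    def test_gaps_outside_core_fold_are_tolerated(self):
        aligned, posmap = identity_alignment({"ref": make_seq()}, "ref")
        row = make_seq({1: "-", 66: "-", 67: "-", 68: "-", 69: "-"})
        assert ah.core_fold_complete(row, posmap)


@given(st.lists(
    st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=60, max_size=80),
    min_size=1, max_size=8, unique=True,
))
def test_fasta_roundtrip_property(tmp_path_factory, seqs):
    catalog = ah.HistoneCatalog(tuple(
        ah.HistoneRecord(f"h{i}", f"sp{i % 3}", s) for i, s in enumerate(seqs)
    ))
    path = tmp_path_factory.mktemp("rt") / "c.fasta"
    ah.write_fasta(catalog, path)
    back = ah.read_fasta(path)
    assert [(r.id, r.species_id, r.sequence) for r in back] == [
        (r.id, r.species_id, r.sequence) for r in catalog
    ]
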