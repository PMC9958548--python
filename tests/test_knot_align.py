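"""Loop extraction, barcode protection, alignment, assembly, back-translation."""

import numpy as np
import pytest

import ickkit as ik
from ickkit.frameworks import TOKEN_LOOP
from ickkit.knot_align import BARCODE, center_star_align


def make_family_loop_sets(seed=31, n_families=3):
    """Loop sets (and precursors) for the ICKs of a generated dataset."""
    ds = ik.generate_dataset(
        ik.GeneratorConfig(seed=seed, n_families=n_families, n_decoys=0)
    )
    precursors = {p.sequence_id: p for p in ds.precursors}
    loop_sets = [
        ik.extract_loops(
            p.mature,
            ds.truth[sid].framework_id,
            sequence_id=sid,
            mature_offset=p.signal_end,
        )
        for sid, p in precursors.items()
    ]
    return ds, precursors, loop_sets


class TestExtractLoops:
    def test_c6_loop3_between_c4_and_c5(self, schema):
        #         C1  C2   C3C4 C5  C6
        mature = "ACwwwCxxxCCyyyCzzzCn"
        ls = ik.extract_loops(mature.upper(), "6.0", schema)
        assert ls.loops[2] == "YYY"
        assert ls.loops == ("WWW", "XXX", "YYY", "ZZZ")

    def test_c10_1_loop3_retains_inner_c5(self, schema):
        prec, _ = ik.make_precursor("10.1", [3, 3, 4, 4, 3], seed=2)
        ls = ik.extract_loops(prec.mature, "10.1", schema)
        assert ls.loops[2].count("C") == 1  # C5 retained inside loop 3

    def test_c8_loop4_retains_inner_pair(self, schema):
        prec, _ = ik.make_precursor("8.0", [3, 3, 3, 3], seed=2)
        ls = ik.extract_loops(prec.mature, "8.0", schema)
        assert ls.loops[3].count("C") == 2  # C6 and C7 inside loop 4

    def test_reconstruction_oracle(self, schema, catalog):
        """Loops + anchors reconstruct the two spanned mature regions."""
        rng = np.random.default_rng(44)
        idents = list(schema.classes)
        for _ in range(200):
            ident = idents[int(rng.integers(len(idents)))]
            n_gaps = sum(1 for t in catalog.get(ident).tokens if t == TOKEN_LOOP)
            lengths = [int(rng.integers(2, 9)) for _ in range(n_gaps)]
            prec, _ = ik.make_precursor(ident, lengths, int(rng.integers(2**31)))
            ls = ik.extract_loops(prec.mature, ident, schema)
            left, right = ls.reconstructed_spans()
            p = ls.anchor_positions
            assert ls.mature[p[0] - 1 : p[2]] == left
            assert ls.mature[p[3] - 1 : p[5]] == right

    def test_missing_schema_row(self, schema):
        with pytest.raises(KeyError):
            ik.extract_loops("C" * 12, "5.5", schema)


class TestBarcode:
    def test_wrap_example(self):
        assert ik.barcode_wrap("GAK") == "WWYHWYYHMMGAKWWYHWYYHMM"

    def test_empty_loop(self):
        wrapped = ik.barcode_wrap("")
        assert wrapped == BARCODE * 2
        assert ik.barcode_unwrap(wrapped) == ""

    def test_round_trip_random_loops(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            loop = "".join(
                rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=rng.integers(0, 15))
            )
            assert ik.barcode_unwrap(ik.barcode_wrap(loop)) == loop

    def test_unwrap_rejects_corrupted_flanks(self):
        with pytest.raises(ValueError):
            ik.barcode_unwrap("A" * 25)


class TestAlignLoops:
    def test_identical_loops_no_gaps(self):
        _, _, loop_sets = make_family_loop_sets(seed=13, n_families=1)
        aligned = ik.align_loops(loop_sets)
        for loop_aln in aligned:
            for row in loop_aln.values():
                assert "-" not in row  # same family, no indels simulated

    def test_width_lower_bound(self):
        a = ik.LoopSet("a", ("GAK", "WD", "RT", "PL"), (1, 5, 8, 11, 14, 17),
                       "C" * 20, 0)
        b = ik.LoopSet("b", ("GAKDE", "WD", "RT", "PL"), (1, 7, 10, 13, 16, 19),
                       "C" * 22, 0)
        aligned = ik.align_loops([a, b])
        assert len(aligned[0]["a"]) >= 5

    def test_ungapped_families_recover_truth_columns(self):
        """No indels are simulated, so within a family every aligned loop
        equals the raw loop string."""
        _, _, loop_sets = make_family_loop_sets(seed=21, n_families=2)
        aligned = ik.align_loops(loop_sets)
        by_id = {ls.sequence_id: ls for ls in loop_sets}
        fams = {}
        for sid in by_id:
            fams.setdefault(sid.split("_")[0], []).append(sid)
        for k in range(4):
            for fam_ids in fams.values():
                lengths = {len(by_id[s].loops[k]) for s in fam_ids}
                assert len(lengths) == 1
                for s in fam_ids:
                    assert aligned[k][s].replace("-", "") == by_id[s].loops[k]

    def test_center_star_matches_pairwise_for_two(self):
        rows = center_star_align({"a": "WWYHWYYHMMGAKWWYHWYYHMM",
                                  "b": "WWYHWYYHMMGDAKWWYHWYYHMM"})
        assert rows["a"].replace("-", "") == "WWYHWYYHMMGAKWWYHWYYHMM"
        assert len(rows["a"]) == len(rows["b"])


class TestCompositionFilter:
    def test_no_failures_passthrough(self):
        _, _, loop_sets = make_family_loop_sets(seed=3, n_families=2)
        results, survivors, aligned = ik.composition_filter(loop_sets, alpha=1e-12)
        assert [ls.sequence_id for ls in survivors] == [
            ls.sequence_id for ls in loop_sets
        ]

    def test_poly_tryptophan_outlier_removed(self):
        _, _, loop_sets = make_family_loop_sets(seed=3, n_families=2)
        outlier = ik.LoopSet(
            "outlier", ("W" * 8, "W" * 8, "W" * 8, "W" * 8),
            (1, 10, 19, 28, 37, 46), "C" + "W" * 50, 0,
        )
        results, survivors, _ = ik.composition_filter(
            loop_sets + [outlier], alpha=0.05
        )
        ids = {ls.sequence_id for ls in survivors}
        assert "outlier" not in ids
        # the bulk of typical sequences survive the removal rounds
        assert len(ids) >= len(loop_sets) - 2

    def test_bad_alpha(self):
        with pytest.raises(ValueError):
            ik.composition_filter([], alpha=0.0)


class TestAssembly:
    def test_width_is_loops_plus_six_anchors(self):
        _, _, loop_sets = make_family_loop_sets(seed=7, n_families=2)
        aligned = ik.align_loops(loop_sets)
        knot = ik.assemble_alignment(aligned, loop_sets)
        widths = [len(next(iter(la.values()))) for la in aligned]
        assert knot.width == sum(widths) + 6
        labels = knot.column_labels
        assert sum(lab.startswith("anchor") for lab in labels) == 6

    def test_anchor_columns_all_cysteine(self):
        _, _, loop_sets = make_family_loop_sets(seed=7, n_families=3)
        aligned = ik.align_loops(loop_sets)
        knot = ik.assemble_alignment(aligned, loop_sets)
        knot.validate()
        for col in knot.anchor_columns():
            assert {row[col] for row in knot.rows.values()} == {"C"}

    def test_single_sequence_row_verbatim(self, schema):
        prec, _ = ik.make_precursor("6.0", [3, 3, 3, 3], seed=10, sequence_id="s")
        ls = ik.extract_loops(prec.mature, "6.0", schema, sequence_id="s")
        aligned = [{"s": loop} for loop in ls.loops]
        knot = ik.assemble_alignment(aligned, [ls])
        left, right = ls.reconstructed_spans()
        assert knot.rows["s"] == left + right

    def test_mismatched_sequence_sets_rejected(self):
        _, _, loop_sets = make_family_loop_sets(seed=7, n_families=1)
        aligned = ik.align_loops(loop_sets)
        broken = [dict(a) for a in aligned]
        broken[2].pop(loop_sets[0].sequence_id)
        with pytest.raises(ValueError):
            ik.assemble_alignment(broken, loop_sets)


class TestBackTranslation:
    def test_codon_width_and_consistency(self, tmp_path):
        from Bio import SeqIO
        from Bio.Seq import Seq

        ds, precursors, loop_sets = make_family_loop_sets(seed=19, n_families=2)
        aligned = ik.align_loops(loop_sets)
        knot = ik.assemble_alignment(aligned, loop_sets)
        codon = ik.back_translate(knot, {s: p.cds for s, p in precursors.items()})
        assert codon.width == 3 * knot.width
        codon.to_fasta(tmp_path / "codon.fasta")
        parsed = {r.id: str(r.seq) for r in SeqIO.parse(tmp_path / "codon.fasta", "fasta")}
        assert parsed == codon.rows
        for sid, row in codon.rows.items():
            protein_row = knot.rows[sid]
            for i in range(knot.width):
                c = row[3 * i : 3 * i + 3]
                if protein_row[i] == "-":
                    assert c == "---"
                else:
                    assert str(Seq(c).translate()) == protein_row[i]

    def test_codons_trace_back_to_cds(self):
        ds, precursors, loop_sets = make_family_loop_sets(seed=19, n_families=1)
        aligned = ik.align_loops(loop_sets)
        knot = ik.assemble_alignment(aligned, loop_sets)
        cds_map = {s: p.cds for s, p in precursors.items()}
        codon = ik.back_translate(knot, cds_map)
        for sid, row in codon.rows.items():
            degapped = row.replace("---", "")
            # every consecutive 3-mer chunk occurs in the source CDS in order
            pos = -1
            for i in range(0, len(degapped), 3):
                nxt = cds_map[sid].find(degapped[i : i + 3], pos + 1)
                assert nxt > pos
                pos = nxt

    def test_corrupted_cds_detected(self):
        _, precursors, loop_sets = make_family_loop_sets(seed=19, n_families=1)
        aligned = ik.align_loops(loop_sets)
        knot = ik.assemble_alignment(aligned, loop_sets)
        cds_map = {s: "A" * len(p.cds) for s, p in precursors.items()}
        with pytest.raises(ValueError):
            ik.back_translate(knot, cds_map)
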