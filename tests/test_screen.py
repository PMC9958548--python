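"""Filter cascade, signal heuristic, CDS completeness, expression summary."""

import numpy as np
import pandas as pd
import pytest

import ickkit as ik
from ickkit.screen import RULE_ORDER, builtin_homology_search

from conftest import dataset_hits


class TestCompleteCds:
    @pytest.mark.parametrize(
        "cds,ok",
        [
            ("ATGTGCTGA", True),  # start + one codon + stop
            ("ATGTGCTGC", False),  # no stop
            ("ATGTAATGCTGA", False),  # internal stop
            ("TGCTGCTGA", False),  # no start
            ("ATGTGCTG", False),  # not a codon multiple
        ],
    )
    def test_examples(self, cds, ok):
        assert ik.check_complete_cds(cds) is ok

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            ik.check_complete_cds("ATGXYZTGA")


class TestSignalHeuristic:
    def test_detects_generated_signal(self):
        prec, _ = ik.make_precursor("6.0", [2, 2, 2, 2], seed=3)
        call = ik.call_signal_heuristic(prec.protein)
        assert call.has_signal and call.cleavage == 22

    def test_mature_only_peptide(self):
        assert not ik.call_signal_heuristic("CIAKGCCSDRCDCQWKCG").has_signal

    def test_poly_lysine_n_terminus(self):
        assert not ik.call_signal_heuristic("M" + "K" * 30 + "CCCCCC").has_signal

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ik.call_signal_heuristic("")


class TestScreenCascade:
    def test_generated_batch_kept_exactly(self, small_dataset):
        ds = small_dataset
        report = ik.screen_candidates(
            ds.proteins, ds.cds_map, hits=dataset_hits(ds)
        )
        expected_kept = {
            sid for sid, rec in ds.truth.items() if not rec.violations
        }
        assert set(report.kept) == expected_kept
        for sid, reasons in report.rejected.items():
            assert tuple(reasons) == ds.truth[sid].violations

    def test_weak_evalue_rejected_as_homology(self):
        prec, _ = ik.make_precursor("8.0", [3, 3, 3, 3], seed=1, sequence_id="q")
        report = ik.screen_candidates(
            {"q": prec.protein},
            {"q": prec.cds},
            hits=[ik.HomologyHit("q", "ref", 1e-2)],
        )
        assert report.rejected["q"] == ["homology"]

    def test_all_criteria_disabled_keeps_everything(self, small_dataset):
        ds = small_dataset
        criteria = ik.ScreenCriteria(
            max_length=10**6,
            min_cysteines=0,
            require_signal=False,
            require_complete_cds=False,
            require_homology=False,
        )
        report = ik.screen_candidates(ds.proteins, criteria=criteria)
        assert set(report.kept) == set(ds.proteins)

    def test_order_independence(self, small_dataset):
        ds = small_dataset
        hits = dataset_hits(ds)
        fwd = ik.screen_candidates(ds.proteins, ds.cds_map, hits=hits)
        shuffled = dict(reversed(list(ds.proteins.items())))
        rev = ik.screen_candidates(shuffled, ds.cds_map, hits=hits)
        assert set(fwd.kept) == set(rev.kept)
        assert fwd.rejected == rev.rejected

    @pytest.mark.parametrize(
        "relaxed",
        [
            dict(max_length=400),
            dict(min_cysteines=0),
            dict(require_signal=False),
            dict(require_complete_cds=False),
            dict(require_homology=False),
            dict(evalue_cutoff=1.0),
        ],
    )
    def test_relaxing_never_shrinks_kept_set(self, small_dataset, relaxed):
        ds = small_dataset
        hits = dataset_hits(ds)
        base = ik.screen_candidates(ds.proteins, ds.cds_map, hits=hits)
        loose = ik.screen_candidates(
            ds.proteins, ds.cds_map, hits=hits, criteria=ik.ScreenCriteria(**relaxed)
        )
        assert set(base.kept) <= set(loose.kept)

    def test_audit_completeness(self, small_dataset):
        ds = small_dataset
        report = ik.screen_candidates(ds.proteins, ds.cds_map, hits=dataset_hits(ds))
        assert set(report.kept) | set(report.rejected) == set(ds.proteins)
        for reasons in report.rejected.values():
            assert reasons and all(r in RULE_ORDER for r in reasons)

    def test_missing_cds_errors(self):
        with pytest.raises(ValueError):
            ik.screen_candidates({"a": "MKC"}, cds_map={})


class TestBuiltinHomology:
    def test_reference_self_hits_are_significant(self):
        from ickkit.screen import _load_reference

        ref = _load_reference()
        some = dict(list(ref.items())[:3])
        hits = builtin_homology_search(some, reference=ref)
        by_query = {h.query_id: h for h in hits}
        assert all(by_query[q].evalue <= 1e-3 for q in some)

    def test_descendant_scores_better_than_shuffled(self):
        rng = np.random.default_rng(0)
        prec, _ = ik.make_precursor("8.0", [4, 4, 4, 4], seed=9, sequence_id="root")
        ref = {"root": prec.mature}
        tips, prots = ik.evolve_family(
            prec.cds,
            "(t1:0.05,t2:0.05);",
            [1.0] * (len(prec.cds) // 3 - 1),
            seed=4,
        )
        descendant = prots["t1"][prec.signal_end :]
        shuffled = "".join(rng.permutation(list(descendant)))
        hits = builtin_homology_search(
            {"desc": descendant, "shuf": shuffled}, reference=ref
        )
        evalues = {h.query_id: h.evalue for h in hits}
        assert evalues["desc"] < evalues.get("shuf", np.inf)


class TestExpressionSummary:
    def test_printed_row_arithmetic(self):
        """113 peptides with 5 ICKs; TPM shares reproduce the printed row."""
        ids = [f"p{i}" for i in range(113)]
        icks = {i: (idx < 5) for idx, i in enumerate(ids)}
        tpm = np.full(113, (18214.3 - 9670.5) / 108)
        tpm[:5] = 9670.5 / 5
        table = pd.DataFrame({"m242": tpm}, index=ids)
        out = ik.summarize_expression({"m242": ids}, icks, table)
        row = out.loc["m242"]
        assert row["peptides"] == 113 and row["icks"] == 5
        assert round(row["pct_ick"], 2) == 4.42
        assert round(row["pct_tpm"], 1) == 53.1

    def test_zero_icks(self):
        table = pd.DataFrame({"s": [1.0, 2.0]}, index=["a", "b"])
        out = ik.summarize_expression({"s": ["a", "b"]}, {}, table)
        assert out.loc["s", "ick_tpm"] == 0 and out.loc["s", "pct_tpm"] == 0

    def test_negative_tpm_rejected(self):
        table = pd.DataFrame({"s": [-1.0]}, index=["a"])
        with pytest.raises(ValueError):
            ik.summarize_expression({"s": ["a"]}, {"a": True}, table)
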