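"""Counting dN/dS estimator, importers, classification and loop reports."""

import json

import numpy as np
import pytest

import ickkit as ik
from ickkit.selection import ClassificationThresholds, ng_pair_counts


class TestNgPairCounts:
    def test_identical_codons(self):
        sd, nd, S, N = ng_pair_counts("GGT", "GGT")
        assert sd == nd == 0
        assert S + N == pytest.approx(3.0)

    def test_hand_counted_synonymous_pair(self):
        # CTA vs CTG (both Leu): one synonymous difference; synonymous sites
        # per codon = 4/3 (third position fully synonymous, one of three
        # first-position changes synonymous)
        sd, nd, S, N = ng_pair_counts("CTA", "CTG")
        assert (sd, nd) == (1.0, 0.0)
        assert S == pytest.approx(4 / 3)

    def test_hand_counted_two_step_pathways(self):
        # TTT (Phe) vs GTA (Val): differs at positions 1 and 3; both
        # orderings pass through sense codons, each path has 0 or 1
        # synonymous step: TTT->GTT(V)->GTA(V) gives sd=1, TTT->TTA(L)->GTA
        # gives sd=0; average 0.5
        sd, nd, S, N = ng_pair_counts("TTT", "GTA")
        assert sd == pytest.approx(0.5)
        assert nd == pytest.approx(1.5)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng_pair_counts("TAA", "GGG")


class TestNgSiteRates:
    def test_identical_sequences_zero_everywhere(self):
        rows = {"a": "ATGTGCGGT", "b": "ATGTGCGGT"}
        for rec in ik.ng_site_rates(rows):
            assert rec.dN == 0 and rec.dS == 0

    def test_single_synonymous_difference(self):
        rows = {"a": "ATGCTAGGT", "b": "ATGCTGGGT"}
        recs = ik.ng_site_rates(rows)
        assert recs[0].dN == recs[0].dS == 0
        assert recs[1].dS > 0 and recs[1].dN == 0
        assert recs[2].dN == recs[2].dS == 0

    def test_single_nonsynonymous_difference(self):
        rows = {"a": "ATGTGTGGT", "b": "ATGAGTGGT"}  # Cys -> Ser
        recs = ik.ng_site_rates(rows)
        assert recs[1].dN > 0 and recs[1].dS == 0

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(2)
        ds = ik.generate_dataset(ik.GeneratorConfig(seed=15, n_families=1,
                                                    n_decoys=0))
        rows = {p.sequence_id: p.cds[:-3] for p in ds.precursors}
        fwd = ik.ng_site_rates(rows)
        shuffled = dict(reversed(list(rows.items())))
        rev = ik.ng_site_rates(shuffled)
        for a, b in zip(fwd, rev):
            assert a.dN == pytest.approx(b.dN, nan_ok=True)
            assert a.dS == pytest.approx(b.dS, nan_ok=True)

    def test_neutral_simulation_calibration(self):
        """Under omega = 1, mean(dN - dS) across sites is zero within
        Monte-Carlo error of the replicate means."""
        rng = np.random.default_rng(8)
        diffs = []
        for _ in range(30):
            prec, _ = ik.make_precursor(
                "6.0", [4, 4, 4, 4], seed=int(rng.integers(2**31))
            )
            n_codons = len(prec.cds) // 3 - 1
            tips, _ = ik.evolve_family(
                prec.cds,
                "((t1:0.1,t2:0.1):0.05,(t3:0.1,t4:0.1):0.05);",
                [1.0] * n_codons,
                seed=int(rng.integers(2**31)),
                forbid_aas=frozenset(),
            )
            rows = {t: c[:-3] for t, c in tips.items()}
            recs = ik.ng_site_rates(rows)
            site_diffs = [
                r.dN - r.dS
                for r in recs
                if np.isfinite(r.dN) and np.isfinite(r.dS)
            ]
            diffs.append(np.mean(site_diffs))
        mean = np.mean(diffs)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(mean) <= 3 * se + 0.02

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            ik.ng_site_rates({"a": "ATGTAA", "b": "ATGTGC"})


class TestImporters:
    def test_fubar_site_table_round_trip(self, tmp_path):
        labels = ["loop1"] * 4
        payload = {
            "sites": [
                {"site": i + 1, "alpha": 0.3, "beta": 0.1,
                 "prob_negative": 0.95, "prob_positive": 0.01}
                for i in range(4)
            ]
        }
        f = tmp_path / "fubar.json"
        f.write_text(json.dumps(payload))
        recs = ik.import_selection_results([f], "fubar", loop_labels=labels)
        assert len(recs) == 4
        assert recs[0].dS == 0.3 and recs[0].posterior_negative == 0.95
        assert all(r.loop == "loop1" for r in recs)

    def test_meme_holm_correction(self, tmp_path):
        payload = {"sites": [{"site": 1, "pvalue": 0.01},
                             {"site": 2, "pvalue": 0.04}]}
        f = tmp_path / "meme.json"
        f.write_text(json.dumps(payload))
        recs = ik.import_selection_results([f], "meme")
        assert recs[0].pvalue == pytest.approx(0.02)  # 0.01 * 2
        assert recs[1].pvalue == pytest.approx(0.04)  # 0.04 * 1

    def test_site_count_mismatch(self, tmp_path):
        f = tmp_path / "fubar.json"
        f.write_text(json.dumps({"sites": [{"site": 1, "alpha": 1, "beta": 1}]}))
        with pytest.raises(ValueError):
            ik.import_selection_results([f], "fubar", loop_labels=["loop1"] * 3)

    def test_empty_results(self, tmp_path):
        f = tmp_path / "empty.json"
        f.write_text(json.dumps({"sites": []}))
        assert ik.import_selection_results([f], "meme") == []

    def test_bgm_pairs(self, tmp_path):
        f = tmp_path / "bgm.json"
        f.write_text(json.dumps(
            {"pairs": [{"site_i": 5, "site_j": 9, "posterior": 0.97}]}
        ))
        (pair,) = ik.import_selection_results([f], "bgm")
        assert pair.distance == 4 and pair.posterior == 0.97

    def test_absrel_branches(self, tmp_path):
        f = tmp_path / "absrel.json"
        f.write_text(json.dumps(
            {"branches": [{"name": "b1", "pvalue": 0.001},
                          {"name": "b2", "pvalue": 0.9}]}
        ))
        recs = ik.import_selection_results([f], "absrel")
        assert recs[0].selected and not recs[1].selected


class TestClassification:
    def test_negative_posterior(self):
        rec = ik.SiteSelectionRecord(site=1, posterior_negative=0.95)
        (out,) = ik.classify_sites([rec])
        assert out.classification == "negative"

    def test_episodic_boundary(self):
        rec = ik.SiteSelectionRecord(site=1, pvalue=0.049)
        (out,) = ik.classify_sites([rec])
        assert out.classification == "positive-episodic"

    def test_all_neutral(self):
        recs = [ik.SiteSelectionRecord(site=i) for i in range(1, 6)]
        out = ik.classify_sites(recs)
        assert {r.classification for r in out} == {"neutral"}

    def test_stricter_alpha_fewer_positives(self):
        recs = [ik.SiteSelectionRecord(site=i, pvalue=p)
                for i, p in enumerate([0.001, 0.02, 0.04, 0.2], start=1)]
        loose = ik.classify_sites(recs, ClassificationThresholds(alpha=0.05))
        strict = ik.classify_sites(recs, ClassificationThresholds(alpha=0.01))
        n = lambda rs: sum(r.classification == "positive-episodic" for r in rs)
        assert n(strict) <= n(loose)


class TestLoopReport:
    def _records(self):
        rng = np.random.default_rng(4)
        recs = []
        for i in range(1, 21):
            loop = f"loop{1 + (i - 1) % 4}"
            cls = "positive-episodic" if (loop == "loop1" and i <= 4) else "neutral"
            recs.append(
                ik.SiteSelectionRecord(
                    site=i, dS=float(rng.random()), dN=float(rng.random()),
                    classification=cls, loop=loop,
                )
            )
        return recs

    def test_per_loop_counts_match_tally(self):
        recs = self._records()
        summary, table, _ = ik.loop_report(recs)
        tally = {}
        for r in recs:
            tally[(r.loop, r.classification)] = tally.get(
                (r.loop, r.classification), 0
            ) + 1
        for (loop, cls), count in tally.items():
            assert summary.loc[loop, cls] == count
        for loop in ("loop2", "loop3", "loop4"):
            assert (
                "positive-episodic" not in summary.columns
                or summary.loc[loop].get("positive-episodic", 0) == 0
            )

    def test_exact_linear_fit(self):
        recs = [
            ik.SiteSelectionRecord(site=i, dS=float(i), dN=0.5 * i, loop="loop1")
            for i in range(1, 11)
        ]
        _, _, fit = ik.loop_report(recs)
        assert fit["slope"] == pytest.approx(0.5)
        assert fit["r_squared"] == pytest.approx(1.0)

    def test_unlabeled_site_rejected(self):
        with pytest.raises(ValueError):
            ik.loop_report([ik.SiteSelectionRecord(site=1)])
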