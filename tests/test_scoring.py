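"""Pileup exactness, score definition, background pooling, the filter
chain of site calling, and replicate aggregation."""

import numpy as np
import pandas as pd
import pytest

import glorimap as gm
from glorimap.scoring import extract_context, fisher_stage_pvalues


def make_readset(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "start", "seq", "sample_id"])
    df["molecule_id"] = [f"m{i}" for i in range(len(df))]
    return gm.ReadSet(df)


TR = gm.TranscriptModel(gene_id="g", sequence="ACGUACGUAC")


class TestPileup:
    def test_exact_base_tallies(self):
        rs = make_readset([("g", 0, "ACG", "s1")] * 3)
        counts = gm.pileup_counts(rs, [TR], min_reads_per_transcript=1)
        nc = counts["s1"]["g"]
        assert nc.counts[0].tolist() == [3, 0, 0, 0]
        assert nc.counts[1].tolist() == [0, 3, 0, 0]
        assert nc.counts[2].tolist() == [0, 0, 3, 0]
        assert nc.counts[3:].sum() == 0

    def test_transcript_below_min_reads_dropped(self):
        rs = make_readset([("g", 0, "ACGU", "s1")] * 9)
        counts = gm.pileup_counts(rs, [TR], min_reads_per_transcript=10)
        assert counts == {}

    def test_empty_readset_empty_output(self):
        rs = make_readset([])
        assert gm.pileup_counts(rs, [TR]) == {}

    def test_long_read_spans_dropped(self):
        long_tr = gm.TranscriptModel(gene_id="L", sequence="A" * 800)
        rows = [("L", 0, "A" * 800, "s1")] + [("L", 0, "AAAA", "s1")] * 5
        counts = gm.pileup_counts(
            rs := make_readset(rows), [long_tr],
            min_reads_per_transcript=1, max_read_span=700,
        )
        assert counts["s1"]["L"].counts[0, 0] == 5  # 800-nt read excluded

    def test_out_of_bounds_read_skipped(self, caplog):
        rs = make_readset([("g", 8, "ACGU", "s1")] + [("g", 0, "AC", "s1")] * 3)
        with caplog.at_level("WARNING"):
            counts = gm.pileup_counts(rs, [TR], min_reads_per_transcript=1)
        assert counts["s1"]["g"].counts[0, 0] == 3
        assert "outside bounds" in caplog.text


class TestGloriScore:
    def test_direct_ratio(self):
        nc = gm.NucleotideCounts("g", "s", np.zeros((5, 4), dtype=int))
        nc.counts[2] = [9, 0, 1, 0]
        assert gm.glori_score(nc, None, 2) == pytest.approx(0.9)

    def test_zero_when_fully_converted(self):
        nc = gm.NucleotideCounts("g", "s", np.zeros((5, 4), dtype=int))
        nc.counts[2] = [0, 0, 20, 0]
        assert gm.glori_score(nc, None, 2) == 0.0

    def test_low_combined_count_filtered(self):
        nc = gm.NucleotideCounts("g", "s", np.zeros((5, 4), dtype=int))
        nc.counts[2] = [5, 0, 4, 0]  # A+G = 9 < 10
        assert gm.glori_score(nc, None, 2) is None

    def test_non_a_reference_rejected(self):
        nc = gm.NucleotideCounts("g", "s", np.zeros((10, 4), dtype=int))
        nc.counts[1] = [10, 0, 10, 0]
        with pytest.raises(ValueError, match="not A"):
            gm.glori_score(nc, None, 1, reference=TR.sequence)


class TestBackground:
    def test_pooled_fraction_boundaries(self):
        tr = gm.TranscriptModel(gene_id="g", sequence="AAAA")
        nc = gm.NucleotideCounts("g", "s", np.zeros((4, 4), dtype=int))
        nc.counts[:, 2] = 50  # all converted
        assert gm.estimate_background({"g": nc}, [tr]) == 0.0
        nc.counts[:, 2] = 0
        nc.counts[:, 0] = 50  # all protected
        assert gm.estimate_background({"g": nc}, [tr]) == 1.0

    def test_pooling_weighs_counts_not_ratios(self):
        tr = gm.TranscriptModel(gene_id="g", sequence="AA")
        nc = gm.NucleotideCounts("g", "s", np.zeros((2, 4), dtype=int))
        nc.counts[0] = [1, 0, 1, 0]      # ratio 0.5, tiny coverage
        nc.counts[1] = [0, 0, 998, 0]    # ratio 0, deep coverage
        assert gm.estimate_background({"g": nc}, [tr]) == pytest.approx(1 / 1000)

    def test_no_counts_is_error(self):
        tr = gm.TranscriptModel(gene_id="g", sequence="CCCC")
        nc = gm.NucleotideCounts("g", "s", np.zeros((4, 4), dtype=int))
        with pytest.raises(ValueError):
            gm.estimate_background({"g": nc}, [tr])

    def test_matches_conversion_efficiency(self, small_dataset):
        # no-methylation background ~ 1 - efficiency, diluted by true sites
        for bg in small_dataset["backgrounds"].values():
            assert 0.005 < bg < 0.08


class TestCallSites:
    def _one_sample(self, a, g, length=400, cov=100):
        """Single transcript where position 1 has (a, g) counts and the
        background is set by the remaining reference-A positions."""
        seq = "GA" * (length // 2)
        tr = gm.TranscriptModel(gene_id="g", sequence=seq)
        counts = np.zeros((length, 4), dtype=int)
        a_pos = np.arange(1, length, 2)
        counts[a_pos, 2] = cov - 1
        counts[a_pos, 0] = 1  # background ~1%
        counts[1] = 0
        counts[1, 0] = a
        counts[1, 2] = g
        nc = gm.NucleotideCounts("g", "s1", counts)
        bg = gm.estimate_background({"g": nc}, [tr])
        calls = gm.call_sites({"s1": {"g": nc}}, [tr], {"s1": bg})
        return calls

    def test_enriched_position_retained(self):
        calls = self._one_sample(a=50, g=50)
        assert [c.position for c in calls] == [1]
        assert calls[0].scores["s1"] == pytest.approx(0.5)
        assert calls[0].fisher_p < 1e-10

    def test_score_at_most_threshold_filtered(self):
        assert self._one_sample(a=2, g=28) == []  # score 0.067 <= 0.1

    def test_missing_background_is_error(self, small_dataset):
        with pytest.raises(ValueError, match="background"):
            gm.call_sites(
                small_dataset["counts"], small_dataset["transcripts"], {}
            )

    def test_threshold_monotonicity(self, small_dataset):
        d = small_dataset
        base = len(
            gm.call_sites(d["counts"], d["transcripts"], d["backgrounds"])
        )
        stricter_score = len(
            gm.call_sites(
                d["counts"], d["transcripts"], d["backgrounds"], min_score=0.3
            )
        )
        stricter_cov = len(
            gm.call_sites(
                d["counts"], d["transcripts"], d["backgrounds"], min_count=30
            )
        )
        stricter_support = len(
            gm.call_sites(
                d["counts"], d["transcripts"], d["backgrounds"],
                replicate_support=3,
            )
        )
        assert stricter_score <= base
        assert stricter_cov <= base
        assert stricter_support <= base

    def test_ag_coverage_matches_pileup(self, small_dataset):
        d = small_dataset
        for c in d["calls"][:50]:
            for sample, cov in c.ag_coverage.items():
                a, g = d["counts"][sample][c.gene_id].ag(c.position)
                assert cov == a + g

    def test_context13_centered_on_a(self, small_dataset):
        for c in small_dataset["calls"]:
            assert len(c.context13) == 13
            assert c.context13[6] == "A"

    def test_most_called_sites_are_planted(self, small_dataset):
        """High-score calls should coincide with planted truth."""
        d = small_dataset
        truth = {(s.gene_id, s.position) for s in d["true_sites"]}
        strong = d["site_df"][d["site_df"]["median_control"] > 0.3]
        hits = sum(
            (g, p) in truth
            for g, p in zip(strong["gene_id"], strong["position"])
        )
        assert hits / len(strong) > 0.95


class TestFisherStage:
    def test_null_pvalues_conservative(self):
        from glorimap.calibration import null_calling_experiment

        res = null_calling_experiment(3, n_transcripts=40, coverage=80)
        assert res["fisher_rejection_rate"] <= 0.05
        assert res["n_full_chain_calls"] == 0


class TestAggregate:
    def _call(self, scores):
        return gm.SiteCall(
            gene_id="g", position=5,
            scores={f"control_rep{i+1}": s for i, s in enumerate(scores)},
            ag_coverage={f"control_rep{i+1}": 100 for i in range(len(scores))},
            pvalues={}, fisher_p=0.01, context13="N" * 6 + "A" + "N" * 6,
            replicate_support=len(scores),
        )

    def test_median_over_replicates(self):
        cmap = {f"control_rep{i}": "control" for i in (1, 2, 3)}
        df = gm.aggregate_conditions([self._call([0.8, 0.9, 1.0])], cmap)
        assert df["median_control"].iloc[0] == pytest.approx(0.9)

    def test_single_replicate_median_is_score(self):
        df = gm.aggregate_conditions([self._call([0.73])], {"control_rep1": "control"})
        assert df["median_control"].iloc[0] == pytest.approx(0.73)

    def test_cutoff_counts(self):
        cmap = {f"control_rep{i}": "control" for i in (1, 2)}
        calls = [self._call([0.95, 0.93]), self._call([0.3, 0.4]), self._call([0.05, 0.06])]
        df = gm.aggregate_conditions(calls, cmap)
        assert df.attrs["cutoff_counts"]["control"] == {0.1: 2, 0.5: 1, 0.9: 1}

    def test_condition_median_recovers_stoichiometry(self):
        """Three replicates at depth 500 for a 0.6-stoichiometry site."""
        tr = gm.TranscriptModel(gene_id="g", sequence="CCGAUCCGUU" * 6)
        site = gm.TrueSite(gene_id="g", position=3, stoichiometry=0.6, rule_class="plus1C")
        params = gm.SimParams(
            n_genes=1, length_range=(60, 60), read_length=60, depth_mean=500,
            conversion_efficiency=1.0, n_replicates=3, seed=21,
        )
        treated, _ = gm.simulate_glori_reads([tr], [site], params, with_untreated=False)
        counts = gm.pileup_counts(treated, [tr])
        bgs = {s: gm.estimate_background(pg, [tr]) for s, pg in counts.items()}
        calls = gm.call_sites(counts, [tr], bgs)
        cmap = {s: "control" for s in counts}
        df = gm.aggregate_conditions(calls, cmap)
        row = df[df["position"] == 3].iloc[0]
        assert abs(row["median_control"] - 0.6) < 0.05


def test_extract_context_padding():
    seq = "GGGGGGACUUUUU"
    assert extract_context(6, seq) == "GGGGGGACUUUUU"
    # position 2: four left pads, then GG, centre G, six downstream bases
    assert extract_context(2, seq) == "NNNNGGGGGGACU"
    assert len(extract_context(12, seq)) == 13
    assert extract_context(12, seq).endswith("NNNNNN")
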