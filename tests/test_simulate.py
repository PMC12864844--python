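"""Generator properties: GC content, sequence rules, EIJ exclusion,
conversion bookkeeping, stoichiometry recovery, determinism."""

import numpy as np
import pandas as pd
import pytest

import glorimap as gm
from glorimap.simulate import _eligible_positions


def gc_fraction(seq: str) -> float:
    return sum(b in "GC" for b in seq) / len(seq)


class TestTranscriptome:
    def test_gc_content_near_target(self):
        params = gm.SimParams(n_genes=200, length_range=(1000, 2000), seed=1)
        trs = gm.simulate_transcriptome(params)
        assert len(trs) == 200
        mean_gc = np.mean([gc_fraction(t.sequence) for t in trs])
        assert 0.29 <= mean_gc <= 0.35

    def test_single_exon_range_gives_no_junctions(self):
        params = gm.SimParams(n_genes=20, exon_count_range=(1, 1), seed=2)
        assert all(t.eij_positions == [] for t in gm.simulate_transcriptome(params))

    def test_eij_positions_strictly_interior_and_sorted(self):
        params = gm.SimParams(n_genes=30, exon_count_range=(2, 8), seed=3)
        for t in gm.simulate_transcriptome(params):
            assert t.eij_positions == sorted(t.eij_positions)
            assert all(0 < j < t.length for j in t.eij_positions)

    def test_same_seed_identical_output(self):
        params = gm.SimParams(n_genes=15, seed=9)
        a = gm.simulate_transcriptome(params)
        b = gm.simulate_transcriptome(params)
        assert [t.sequence for t in a] == [t.sequence for t in b]
        assert [t.eij_positions for t in a] == [t.eij_positions for t in b]

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            gm.SimParams(length_range=(500, 100))
        with pytest.raises(ValueError):
            gm.SimParams(gc_content=1.5)
        with pytest.raises(ValueError):
            gm.SimParams(exon_count_range=(0, 3))


class TestPlantSites:
    def test_sites_obey_sequence_rules(self, small_dataset):
        seqs = {t.gene_id: t.sequence for t in small_dataset["transcripts"]}
        for s in small_dataset["true_sites"]:
            seq = seqs[s.gene_id]
            assert seq[s.position] == "A"
            nxt = seq[s.position + 1]
            if s.rule_class == "plus1C":
                assert nxt == "C"
            else:
                assert nxt == "U" and seq[s.position + 4] == "U"
            assert 0.0 <= s.stoichiometry <= 1.0

    def test_no_site_without_eligible_adenosine(self):
        # A always followed by G: no +1 C, no +1 U
        tr = gm.TranscriptModel(gene_id="x", sequence="AG" * 300)
        params = gm.SimParams(n_genes=1, site_rate=1.0, seed=4)
        assert gm.plant_m6a_sites([tr], params) == []

    def test_eij_exclusion_zone_respected(self):
        params = gm.SimParams(
            n_genes=60, exon_count_range=(2, 6), site_rate=0.5,
            eij_exclusion_nt=100, seed=5,
        )
        trs = gm.simulate_transcriptome(params)
        eij = {t.gene_id: t.eij_positions for t in trs}
        for s in gm.plant_m6a_sites(trs, params):
            if eij[s.gene_id]:
                assert min(abs(s.position - j) for j in eij[s.gene_id]) >= 100

    def test_plus1c_stoichiometry_matches_beta_mean(self):
        # Beta(20,2) has mean 20/22; sample mean within 3 s.e.
        params = gm.SimParams(
            n_genes=150, exon_count_range=(1, 1), site_rate=0.8,
            three_prime_bias=0.0, stoich_high=(20.0, 2.0), seed=6,
        )
        trs = gm.simulate_transcriptome(params)
        stoich = [
            s.stoichiometry
            for s in gm.plant_m6a_sites(trs, params)
            if s.rule_class == "plus1C"
        ]
        mean = 20 / 22
        sd = np.sqrt(mean * (1 - mean) / 23)  # Beta sd = sqrt(m(1-m)/(a+b+1))
        assert abs(np.mean(stoich) - mean) < 3 * sd / np.sqrt(len(stoich))

    def test_three_prime_bias_shifts_sites_downstream(self):
        base = dict(n_genes=120, exon_count_range=(1, 1), site_rate=0.2, seed=7)
        flat = gm.SimParams(three_prime_bias=0.0, **base)
        biased = gm.SimParams(three_prime_bias=4.0, **base)
        trs = gm.simulate_transcriptome(flat)
        lengths = {t.gene_id: t.length for t in trs}

        def mean_rel(sites):
            return np.mean([s.position / lengths[s.gene_id] for s in sites])

        assert mean_rel(gm.plant_m6a_sites(trs, biased)) > mean_rel(
            gm.plant_m6a_sites(trs, flat)
        ) + 0.05

    def test_eligibility_scan_matches_definition(self, rng):
        seq = "".join(rng.choice(list("ACGU"), size=400))
        pos, is_high = _eligible_positions(seq)
        expected = []
        for i in range(len(seq) - 1):
            if seq[i] != "A":
                continue
            if seq[i + 1] == "C":
                expected.append((i, True))
            elif seq[i + 1] == "U" and i + 4 < len(seq) and seq[i + 4] == "U":
                expected.append((i, False))
        assert list(zip(pos.tolist(), is_high.tolist())) == expected


class TestGloriReads:
    def test_full_conversion_full_methylation(self):
        seq = "GGAACAGCAAUC"
        tr = gm.TranscriptModel(gene_id="g", sequence=seq, expression_weight=1.0)
        site = gm.TrueSite(gene_id="g", position=3, stoichiometry=1.0, rule_class="plus1C")
        params = gm.SimParams(
            n_genes=1, length_range=(12, 12), read_length=12, depth_mean=50,
            conversion_efficiency=1.0, n_replicates=1, seed=8,
        )
        treated, untreated = gm.simulate_glori_reads([tr], [site], params)
        for read in treated.records["seq"]:
            assert read[3] == "A"  # protected
            for i, b in enumerate(seq):
                if b == "A" and i != 3:
                    assert read[i] == "G"
        # untreated reads are verbatim reference
        assert set(untreated.records["seq"]) == {seq}

    def test_conversion_bookkeeping_only_a_to_g(self, small_dataset):
        seqs = {t.gene_id: t.sequence for t in small_dataset["transcripts"]}
        sample = small_dataset["treated"].records.head(500)
        for row in sample.itertuples(index=False):
            ref = seqs[row.gene_id][row.start : row.start + len(row.seq)]
            for r, q in zip(ref, row.seq):
                if r != q:
                    assert (r, q) == ("A", "G")

    def test_unmethylated_score_equals_one_minus_efficiency(self):
        tr = gm.TranscriptModel(gene_id="g", sequence="CAGU" * 25)
        params = gm.SimParams(
            n_genes=1, length_range=(100, 100), read_length=100, depth_mean=400,
            conversion_efficiency=0.9, n_replicates=1, seed=10,
        )
        treated, _ = gm.simulate_glori_reads([tr], [], params, with_untreated=False)
        counts = gm.pileup_counts(treated, [tr])
        sample_counts = next(iter(counts.values()))
        # pooled unconverted fraction at reference-A positions = 1 - efficiency
        bg = gm.estimate_background(sample_counts, [tr])
        n = int(sample_counts["g"].counts[:, [0, 2]].sum() / 2)  # ~A+G at ref A
        assert abs(bg - 0.1) < 3 * np.sqrt(0.1 * 0.9 / n)

    def test_site_score_recovers_stoichiometry(self):
        tr = gm.TranscriptModel(gene_id="g", sequence="CCGAUCCGUU" * 6)
        site = gm.TrueSite(gene_id="g", position=3, stoichiometry=0.6, rule_class="plus1C")
        params = gm.SimParams(
            n_genes=1, length_range=(60, 60), read_length=60, depth_mean=500,
            conversion_efficiency=1.0, n_replicates=1, seed=12,
        )
        treated, _ = gm.simulate_glori_reads([tr], [site], params, with_untreated=False)
        counts = gm.pileup_counts(treated, [tr])
        nc = next(iter(counts.values()))["g"]
        a, g = nc.ag(3)
        score = a / (a + g)
        assert abs(score - 0.6) < 3 * np.sqrt(0.6 * 0.4 / (a + g))

    def test_site_on_non_a_reference_rejected(self):
        tr = gm.TranscriptModel(gene_id="g", sequence="CCCC")
        bad = gm.TrueSite(gene_id="g", position=1, stoichiometry=0.5, rule_class="plus1C")
        with pytest.raises(ValueError, match="not A"):
            gm.simulate_glori_reads([tr], [bad], gm.SimParams(n_genes=1, seed=1))

    def test_determinism(self, small_params, small_dataset):
        treated2, _ = gm.simulate_glori_reads(
            small_dataset["transcripts"], small_dataset["true_sites"], small_params
        )
        pd.testing.assert_frame_equal(small_dataset["treated"].records, treated2.records)


class TestHomologs:
    def test_zero_rates_identity(self, small_dataset):
        trs = small_dataset["transcripts"]
        hom = gm.simulate_homologs(trs, 0.0, 0.0, seed=1)
        assert all(hom[t.gene_id] == t.sequence for t in trs)

    def test_class_specific_rates_realized(self):
        params = gm.SimParams(n_genes=60, length_range=(2000, 2000), seed=13)
        trs = gm.simulate_transcriptome(params)
        hom = gm.simulate_homologs(trs, 0.05, 0.15, seed=2)
        n_at = n_at_sub = n_cg = n_cg_sub = 0
        for t in trs:
            for a, b in zip(t.sequence, hom[t.gene_id]):
                if a in "CG":
                    n_cg += 1
                    n_cg_sub += a != b
                else:
                    n_at += 1
                    n_at_sub += a != b
        for rate, subs, n in ((0.05, n_at_sub, n_at), (0.15, n_cg_sub, n_cg)):
            assert abs(subs / n - rate) < 3 * np.sqrt(rate * (1 - rate) / n)

    def test_same_seed_identical(self, small_dataset):
        trs = small_dataset["transcripts"]
        assert gm.simulate_homologs(trs, 0.1, 0.2, seed=5) == gm.simulate_homologs(
            trs, 0.1, 0.2, seed=5
        )

    def test_invalid_rate_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            gm.simulate_homologs(small_dataset["transcripts"], 1.0, 0.1, seed=1)


class TestDETable:
    def test_effect_recovered_within_expression_strata(self):
        df = gm.simulate_de_table(30000, 0.3, 0.2, seed=3)
        df["is_de"] = df["padj"].fillna(1.0) < 0.05
        df["bin"] = pd.qcut(np.log10(df["baseMean"]), 10, labels=False)
        diffs, weights = [], []
        for _, grp in df.groupby("bin"):
            g1, g0 = grp[grp.has_m6a], grp[~grp.has_m6a]
            if len(g1) > 30 and len(g0) > 30:
                diffs.append(g1.is_de.mean() - g0.is_de.mean())
                weights.append(len(grp))
        pooled = np.average(diffs, weights=weights)
        assert abs(pooled - 0.2) < 0.03

    def test_null_effect_conditionally_independent(self):
        df = gm.simulate_de_table(30000, 0.3, 0.0, seed=4)
        df["is_de"] = df["padj"].fillna(1.0) < 0.05
        df["bin"] = pd.qcut(np.log10(df["baseMean"]), 10, labels=False)
        diffs = [
            grp[grp.has_m6a].is_de.mean() - grp[~grp.has_m6a].is_de.mean()
            for _, grp in df.groupby("bin")
            if grp.has_m6a.sum() > 30 and (~grp.has_m6a).sum() > 30
        ]
        assert abs(np.mean(diffs)) < 0.02

    def test_m6a_confounded_with_expression(self):
        df = gm.simulate_de_table(20000, 0.3, 0.0, seed=5)
        hi = df[df.baseMean > df.baseMean.median()]
        lo = df[df.baseMean <= df.baseMean.median()]
        assert hi.has_m6a.mean() > lo.has_m6a.mean() + 0.1

    def test_deterministic(self):
        a = gm.simulate_de_table(500, 0.3, 0.1, seed=6)
        b = gm.simulate_de_table(500, 0.3, 0.1, seed=6)
        pd.testing.assert_frame_equal(a, b)


class TestCoexpressionSets:
    @pytest.mark.parametrize(
        "sizes,overlap,expected_j",
        [((10, 10), 10, 1.0), ((10, 20), 5, 0.2), ((10, 10), 0, 0.0)],
    )
    def test_exact_overlap_and_jaccard(self, sizes, overlap, expected_j):
        _, a, b = gm.simulate_coexpression_sets(100, sizes, overlap, seed=7)
        assert len(a) == sizes[0] and len(b) == sizes[1]
        assert len(a & b) == overlap
        assert gm.jaccard(a, b) == pytest.approx(expected_j)

    def test_infeasible_overlap_rejected(self):
        with pytest.raises(ValueError):
            gm.simulate_coexpression_sets(100, (10, 10), 11, seed=1)
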