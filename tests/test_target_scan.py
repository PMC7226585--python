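import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribomech.target_scan import (
    STRATA_SCHEMES,
    ScoringCoefficients,
    SeedSite,
    aggregate_and_filter,
    assign_strata,
    find_seed_sites,
    read_targetscan_sites,
    score_site,
    seed_patterns,
)

from oracles import naive_seed_sites, straight_line_score

MIRNA = "UAAGGCACGCGG"  # seed nt 2-8 = AAGGCAC, core revcomp = GUGCCUU


class TestFindSeedSites:
    def test_no_match(self):
        assert find_seed_sites("ACGUACGUACGU", MIRNA) == []

    def test_forced_8mer_single_site(self):
        target = "CCC" + "GUGCCUUA" + "CCC"
        sites = find_seed_sites(target, MIRNA)
        assert len(sites) == 1
        assert sites[0].site_type == "8mer"
        assert sites[0].start == 3

    def test_7mer_m8_without_1a(self):
        target = "CCC" + "GUGCCUU" + "CCC"
        (site,) = find_seed_sites(target, MIRNA)
        assert site.site_type == "7mer-m8"
        assert site.start == 3

    def test_7mer_1a_without_m8(self):
        # preceding base C != G (the m8 match), following A present
        target = "CCC" + "UGCCUUA" + "CCC"
        (site,) = find_seed_sites(target, MIRNA)
        assert site.site_type == "7mer-1a"
        assert site.start == 3

    def test_6mer(self):
        target = "CCC" + "UGCCUU" + "CCC"
        (site,) = find_seed_sites(target, MIRNA)
        assert site.site_type == "6mer"
        assert site.start == 3

    def test_match_string_invariant(self):
        patterns = seed_patterns(MIRNA)
        target = "AAGUGCCUUAGGGUGCCUUCCUGCCUUAGG"
        for site in find_seed_sites(target, MIRNA):
            assert target[site.start : site.end] == patterns[site.site_type]

    def test_t_mapped_to_u(self):
        assert find_seed_sites("CCCGTGCCTTACCC", MIRNA)[0].site_type == "8mer"

    def test_alphabet_violation_reports_position(self):
        with pytest.raises(ValueError, match="position 4"):
            find_seed_sites("ACGUNACGU", MIRNA)

    def test_sites_sorted_by_start(self, rng):
        target = "".join(rng.choice(list("ACGU"), 2000))
        starts = [s.start for s in find_seed_sites(target, MIRNA)]
        assert starts == sorted(starts)

    def test_against_oracle_random(self, rng):
        for _ in range(300):
            target = "".join(rng.choice(list("ACGU"), 200))
            got = sorted((s.start, s.site_type) for s in find_seed_sites(target, MIRNA))
            assert got == naive_seed_sites(target, MIRNA)

    @given(st.text(alphabet="ACGU", min_size=8, max_size=120))
    @settings(max_examples=200, deadline=None)
    def test_against_oracle_property(self, target):
        got = sorted((s.start, s.site_type) for s in find_seed_sites(target, MIRNA))
        assert got == naive_seed_sites(target, MIRNA)


class TestScoreSite:
    def test_type_ordering_at_equal_context(self):
        seq = "C" * 40 + "GUGCCUUA" + "C" * 40
        scores = {}
        for stype in ("8mer", "7mer-m8", "7mer-1a"):
            site = SeedSite("t", "utr3", 40, stype)
            scores[stype] = score_site(site, seq)
        assert scores["8mer"] < scores["7mer-m8"] < scores["7mer-1a"]

    def test_au_flanks_shift_by_exactly_w_au(self):
        coeffs = ScoringCoefficients()
        site_seq = "GUGCCUUA"
        gc = "C" * 40 + site_seq + "C" * 40
        au = "A" * 40 + site_seq + "A" * 40
        s_gc = score_site(SeedSite("t", "utr3", 40, "8mer"), gc, coeffs=coeffs)
        s_au = score_site(SeedSite("t", "utr3", 40, "8mer"), au, coeffs=coeffs)
        assert s_au < s_gc
        assert s_au - s_gc == pytest.approx(coeffs.w_au, abs=1e-12)

    def test_batch_equals_straight_line_oracle(self, rng):
        coeffs = ScoringCoefficients()
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGU"), 300))
            for site in find_seed_sites(seq, MIRNA):
                expected = straight_line_score(
                    site.site_type, site.start, seq, coeffs.base, coeffs.w_au, coeffs.w_pos
                )
                assert score_site(site, seq, coeffs=coeffs) == pytest.approx(expected)


def _sites_df(rows):
    return pd.DataFrame(rows, columns=["gene_id", "region", "start", "site_type", "context_score"])


class TestAggregateAndFilter:
    def test_threshold_boundary(self):
        sites = _sites_df([("g1", "utr3", 5, "8mer", -0.25), ("g2", "utr3", 5, "8mer", -0.10)])
        ann = aggregate_and_filter(sites, threshold=-0.2)
        assert bool(ann.loc["g1", "utr3_target"])
        assert not bool(ann.loc["g2", "utr3_target"])

    def test_gene_without_sites_absent(self):
        ann = aggregate_and_filter(_sites_df([("g1", "utr3", 5, "8mer", -0.3)]))
        assert "g2" not in ann.index

    def test_region_exclusivity(self):
        sites = _sites_df(
            [("g1", "utr3", 5, "8mer", -0.3), ("g1", "cds", 9, "8mer", -0.3)]
        )
        ann = aggregate_and_filter(sites)
        assert not bool(ann.loc["g1", "utr3_target"])
        assert not bool(ann.loc["g1", "cds_target"])

    def test_sums_equal_oracle(self, rng):
        rows = []
        for g in range(500):
            for _ in range(rng.integers(0, 4)):
                rows.append(
                    (
                        f"g{g}",
                        rng.choice(["utr3", "cds"]),
                        int(rng.integers(0, 100)),
                        rng.choice(["8mer", "7mer-m8", "7mer-1a"]),
                        float(rng.uniform(-0.5, 0.0)),
                    )
                )
        sites = _sites_df(rows)
        ann = aggregate_and_filter(sites, threshold=-0.2)
        for gene, grp in sites.groupby("gene_id"):
            cwcs = grp.loc[grp["region"] == "utr3", "context_score"].sum()
            tcs = grp.loc[grp["region"] == "cds", "context_score"].sum()
            assert ann.loc[gene, "cwcs"] == pytest.approx(cwcs)
            assert ann.loc[gene, "tcs"] == pytest.approx(tcs)
            expect_t = cwcs < -0.2 and (grp["region"] == "cds").sum() == 0
            assert bool(ann.loc[gene, "utr3_target"]) == expect_t


class TestAssignStrata:
    def _ann(self):
        sites = _sites_df(
            [
                ("g_high", "utr3", 5, "8mer", -0.4),
                ("g_low", "utr3", 5, "8mer", -0.4),
                ("g_non", "utr3", 5, "8mer", -0.4),
                ("g_multi", "utr3", 5, "8mer", -0.3),
                ("g_multi", "utr3", 50, "7mer-1a", -0.15),
                ("g_cds", "cds", 9, "8mer", -0.4),
            ]
        )
        pct = {"g_high": 0.7, "g_low": 0.5, "g_non": 0.0, "g_multi": 0.0, "g_cds": 0.0}
        return sites, aggregate_and_filter(sites, pct=pct)

    def test_pct_thresholds(self):
        sites, ann = self._ann()
        expressed = list(ann.index) + ["g_none"]
        labels = assign_strata(ann, "pct_group", expressed)
        assert labels["g_high"] == "high"
        assert labels["g_low"] == "low"
        assert labels["g_non"] == "nonconserved"
        assert labels["g_none"] == "no_site"
        assert labels["g_cds"] == "excluded"

    def test_multi_site(self):
        sites, ann = self._ann()
        labels = assign_strata(ann, "seed_type", list(ann.index), sites=sites)
        assert labels["g_multi"] == "multi_site"
        assert labels["g_high"] == "8mer"

    def test_region_class(self):
        sites, ann = self._ann()
        labels = assign_strata(ann, "region_class", list(ann.index) + ["g_none"])
        assert labels["g_cds"] == "cds_only"
        assert labels["g_high"] == "utr3_only"
        assert labels["g_none"] == "no_site"

    def test_partition_property(self, small_sim):
        config, transcripts, truth = small_sim
        ann = aggregate_and_filter(truth.sites, pct=truth.effects["pct"])
        expressed = truth.effects.index
        for scheme in STRATA_SCHEMES:
            labels = assign_strata(ann, scheme, expressed, sites=truth.sites)
            assert len(labels) == len(expressed)
            assert labels.notna().all()

    def test_quartiles_monotone_and_tie_rule(self):
        cwcs = np.array([-1.0, -0.8, -0.6, -0.5, -0.45, -0.4, -0.3, -0.25])
        sites = _sites_df(
            [(f"g{i}", "utr3", 5, "8mer", c) for i, c in enumerate(cwcs)]
        )
        ann = aggregate_and_filter(sites, threshold=-0.2)
        labels = assign_strata(ann, "cwcs_quartile", [f"g{i}" for i in range(8)])
        q = np.quantile(cwcs, [0.25, 0.5, 0.75])
        for i, c in enumerate(cwcs):
            expected = "Q1" if c <= q[0] else "Q2" if c <= q[1] else "Q3" if c <= q[2] else "Q4"
            assert labels[f"g{i}"] == expected

    def test_unknown_scheme_raises(self):
        _, ann = self._ann()
        with pytest.raises(ValueError, match="unknown stratification scheme"):
            assign_strata(ann, "bogus", list(ann.index))


def test_targetscan_reader(tmp_path):
    path = tmp_path / "predicted_targets.tsv"
    pd.DataFrame(
        {
            "Gene Symbol": ["GENE1", "GENE2", "GENE3"],
            "Transcript ID": ["T1", "T2", "T3"],
            "Site Type": ["8mer-1a", "7mer-m8", "7mer-a1"],
            "UTR start": [10, 20, 30],
            "context++ score": [-0.41, -0.2, -0.05],
            "PCT": [0.8, 0.1, ""],
        }
    ).to_csv(path, sep="\t", index=False)
    sites = read_targetscan_sites(path)
    assert list(sites["site_type"]) == ["8mer", "7mer-m8", "7mer-1a"]
    assert list(sites["gene_id"]) == ["GENE1", "GENE2", "GENE3"]
    assert sites["context_score"].tolist() == pytest.approx([-0.41, -0.2, -0.05])
    assert sites["pct"].tolist() == pytest.approx([0.8, 0.1, 0.0])
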