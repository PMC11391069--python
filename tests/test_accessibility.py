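"""ATAC QC, normalization, NB Wald DARs, clustering, Lin DARs, motifs."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import binom
from sklearn.metrics import adjusted_rand_score

from hscfate import accessibility as atac
from hscfate import simulate as sim


class TestFripFilter:
    def test_boundary(self):
        meta = pd.DataFrame({"sample_id": ["a", "b"], "frip": [0.099, 0.10]})
        out = atac.frip_filter(meta)
        assert out["sample_id"].tolist() == ["b"]

    def test_all_excluded_is_error(self):
        meta = pd.DataFrame({"sample_id": ["a"], "frip": [0.01]})
        with pytest.raises(ValueError):
            atac.frip_filter(meta)


class TestTn5Shift:
    def _frags(self):
        return pd.DataFrame({
            "chrom": ["chr1", "chr1"],
            "start": [100, 100],
            "end": [148, 148],
            "strand": ["+", "-"],
        })

    def test_shift_arithmetic(self):
        out = atac.tn5_shift(self._frags())
        assert out.loc[0, ["start", "end"]].tolist() == [104, 148]
        assert out.loc[1, ["start", "end"]].tolist() == [100, 143]

    def test_double_application_refused(self):
        out = atac.tn5_shift(self._frags())
        with pytest.raises(ValueError, match="already"):
            atac.tn5_shift(out)

    def test_collapsed_records_dropped(self):
        frags = pd.DataFrame({"chrom": ["chr1"], "start": [100],
                              "end": [103], "strand": ["+"]})
        with pytest.warns(UserWarning, match="dropped"):
            out = atac.tn5_shift(frags)
        assert out.empty and out.attrs["n_dropped"] == 1


class TestNormalization:
    def test_reads_in_peaks_scaling(self):
        counts = pd.DataFrame({"s1": [50]}, index=["r1"])
        rip = pd.Series({"s1": 5_000_000})
        assert atac.normalize_counts(counts, rip).iloc[0, 0] == pytest.approx(10.0)

    def test_equal_depth_constant_scaling(self):
        counts = pd.DataFrame(np.arange(6).reshape(3, 2),
                              columns=["a", "b"], index=list("xyz"))
        rip = pd.Series({"a": 2e6, "b": 2e6})
        out = atac.normalize_counts(counts, rip)
        np.testing.assert_allclose(out.to_numpy(), counts.to_numpy() / 2)

    def test_zero_denominator_error(self):
        counts = pd.DataFrame({"s1": [1]})
        with pytest.raises(ValueError):
            atac.normalize_counts(counts, pd.Series({"s1": 0}))

    def test_fpkm_arithmetic(self):
        counts = pd.DataFrame({"s1": [10, 0]}, index=["r1", "r2"])
        lengths = pd.Series({"r1": 500, "r2": 500})
        rip = pd.Series({"s1": 1_000_000})
        vals = atac.fpkm(counts, lengths, rip)
        assert vals.loc["r1", "s1"] == pytest.approx(20.0)
        assert vals.loc["r2", "s1"] == 0.0

    def test_fpkm_halves_when_length_doubles(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["r1", "r2"])
        lengths = pd.Series({"r1": 500, "r2": 1000})
        rip = pd.Series({"s1": 1_000_000})
        vals = atac.fpkm(counts, lengths, rip)
        assert vals.loc["r2", "s1"] == pytest.approx(vals.loc["r1", "s1"] / 2)


class TestPresenceFilter:
    def _inputs(self, fpkms, n_samples):
        """Build counts that land exactly on the requested FPKM values
        (length 1000 bp, depth 1e6 -> FPKM == count)."""
        samples = [f"s{i}" for i in range(n_samples)]
        counts = pd.DataFrame([fpkms], index=["r1"], columns=samples)
        meta = pd.DataFrame({
            "sample_id": samples, "population": ["P"] * n_samples,
            "reads_in_peaks": [1_000_000] * n_samples,
        })
        lengths = pd.Series({"r1": 1000})
        return counts, lengths, meta

    def test_two_of_three_passing_found(self):
        counts, lengths, meta = self._inputs([6, 6, 4], 3)
        found, retained = atac.presence_filter(counts, lengths, meta)
        assert bool(found.loc["r1", "P"]) and "r1" in retained

    def test_exactly_five_fpkm_not_found(self):
        counts, lengths, meta = self._inputs([5, 5, 5], 3)
        found, retained = atac.presence_filter(counts, lengths, meta)
        assert not found.loc["r1", "P"] and len(retained) == 0

    def test_one_of_five_insufficient(self):
        # ceil(5/3) = 2 passing samples required
        counts, lengths, meta = self._inputs([5.1, 0, 0, 0, 0], 5)
        found, _ = atac.presence_filter(counts, lengths, meta)
        assert not found.loc["r1", "P"]
        counts.iloc[0, 1] = 6
        found, _ = atac.presence_filter(counts, lengths, meta)
        assert found.loc["r1", "P"]


class TestLogQuantileNormalize:
    def test_sorted_columns_identical(self, rng):
        # tie-free input: the postcondition is exact
        mat = pd.DataFrame(rng.random(size=(40, 6)) * 500)
        out = atac.log_quantile_normalize(mat)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out.iloc[:, j]), ref, atol=1e-12)

    def test_idempotent(self, rng):
        mat = pd.DataFrame(rng.random(size=(30, 4)) * 500)
        once = atac.log_quantile_normalize(mat)
        # applying quantile normalization to the already-normalized values
        # (pseudocount 0 on the 10^x scale) reproduces them
        twice = atac.log_quantile_normalize(10.0**once, pseudocount=0.0)
        np.testing.assert_allclose(twice.to_numpy(), once.to_numpy(), atol=1e-9)

    def test_rank_preservation(self, rng):
        mat = pd.DataFrame(rng.integers(0, 500, size=(25, 3)).astype(float))
        out = atac.log_quantile_normalize(mat)
        for j in range(3):
            a = mat.iloc[:, j].rank(method="average")
            b = out.iloc[:, j].rank(method="average")
            np.testing.assert_allclose(a, b)

    def test_tied_counts_map_to_equal_values(self):
        mat = pd.DataFrame({"a": [0.0, 0.0, 10.0], "b": [0.0, 5.0, 10.0]})
        out = atac.log_quantile_normalize(mat)
        assert out.loc[0, "a"] == out.loc[1, "a"]


class TestNbWald:
    def test_strong_toy_contrast(self):
        """3 vs 3 with a tenfold difference and vanishing dispersion."""
        Y = np.array([[10, 10, 10, 100, 100, 100]], dtype=float)
        res = atac.nb_wald(Y, np.array([1.0, 1, 1, 0, 0, 0]),
                          np.zeros(6), np.array([1e-8]))
        assert res["p"][0] < 1e-6
        assert res["coef"][0] / math.log(2) == pytest.approx(-math.log2(10), abs=1e-6)

    def test_symmetric_counts_zero_log2fc(self):
        Y = np.array([[7, 9, 11, 9, 7, 11]], dtype=float)
        res = atac.nb_wald(Y, np.array([1.0, 1, 1, 0, 0, 0]),
                          np.zeros(6), np.array([0.1]))
        assert res["coef"][0] == pytest.approx(0.0, abs=1e-10)

    def test_poisson_glm_oracle_low_dispersion(self, rng):
        """50-region toy: Wald z agrees with the exact Poisson GLM."""
        R, S = 50, 10
        x = np.array([1.0] * 5 + [0.0] * 5)
        off = np.log(rng.uniform(0.8, 1.2, S))
        mu = (np.exp(rng.normal(3, 1, R))[:, None] * np.exp(off)[None, :]
              * np.exp(rng.normal(0, 0.5, R))[:, None] ** x[None, :])
        Y = rng.poisson(mu)
        res = atac.nb_wald(Y, x, off, np.full(R, 1e-8))
        X = sm.add_constant(x)
        z_oracle = np.array([
            (lambda fit: fit.params[1] / fit.bse[1])(
                sm.GLM(Y[i], X, family=sm.families.Poisson(), offset=off).fit()
            )
            for i in range(R)
        ])
        assert np.max(np.abs(res["z"] - z_oracle)) < 0.05


class TestDarTest:
    def test_planted_effects_recovered(self, planted_atac):
        b = planted_atac
        dar = atac.dar_test(b["counts"], b["sample_meta"],
                            {"age_group": "O"}, {"age_group": "J"})
        truth = b["truth"].set_index("region_id")
        gain = truth.index[truth["planted_set"] == "gain"]
        loss = truth.index[truth["planted_set"] == "loss"]
        assert (dar.loc[gain, "p_adj"] < 1e-4).mean() >= 0.8
        assert (dar.loc[loss, "p_adj"] < 1e-4).mean() >= 0.8
        assert dar.loc[gain, "log2FC"].mean() == pytest.approx(2.0, abs=0.3)
        assert (dar.loc[gain, "direction"] == "up").all()

    def test_power_monotone_in_effect_size(self):
        """Detection power does not decrease with planted log2FC."""
        powers = []
        for lfc in (0.5, 1.0, 2.0):
            cfg = sim.AtacSimConfig(
                n_regions=600, groups=(("X", "J"), ("X", "O")),
                planted_sets=(sim.PlantedSet("e", 60, {"X:O": lfc}),), seed=31)
            b = sim.simulate_atac(cfg)
            dar = atac.dar_test(b["counts"], b["sample_meta"],
                                {"age_group": "O"}, {"age_group": "J"})
            planted = b["truth"].set_index("region_id")
            idx = planted.index[planted["planted_set"] == "e"]
            powers.append((dar.loc[idx, "p_adj"] < 0.05).mean())
        assert powers[0] <= powers[1] <= powers[2]

    def test_presence_exclusion_before_testing(self, null_atac):
        b = null_atac
        found = pd.DataFrame(
            {"X": [True] * 100 + [False] * 400}, index=b["counts"].index)
        dar = atac.dar_test(b["counts"], b["sample_meta"],
                            {"age_group": "O"}, {"age_group": "J"},
                            found_in=found)
        assert len(dar) == 100

    def test_minimum_group_size_enforced(self, null_atac):
        b = null_atac
        meta = b["sample_meta"].iloc[:6]
        with pytest.raises(ValueError):
            atac.dar_test(b["counts"], meta, {"age_group": "O"},
                          {"age_group": "J"})


class TestSizeFactors:
    def test_median_of_ratios_undoes_depth(self, rng):
        base = rng.poisson(100, size=(200, 1)).astype(float)
        scale = np.array([0.5, 1.0, 2.0, 4.0])
        counts = pd.DataFrame(base * scale, columns=list("abcd"))
        sf = atac.size_factors(counts)
        ratios = sf.to_numpy() / scale
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-6)

    def test_fallback_to_reads_in_peaks(self):
        counts = pd.DataFrame(np.zeros((10, 2)), columns=["a", "b"])
        rip = pd.Series({"a": 1e6, "b": 4e6})
        sf = atac.size_factors(counts, reads_in_peaks=rip)
        assert sf["b"] / sf["a"] == pytest.approx(4.0)


class TestClusterDars:
    def test_two_archetypes_perfect_rand_index(self, rng):
        """Planted up/down profiles separate with Rand index 1.0."""
        up = np.tile([0.0, 0, 0, 5, 5, 5], (40, 1)) + rng.normal(0, 0.2, (40, 6))
        down = np.tile([5.0, 5, 5, 0, 0, 0], (40, 1)) + rng.normal(0, 0.2, (40, 6))
        mat = pd.DataFrame(np.vstack([up, down]),
                           index=[f"r{i}" for i in range(80)])
        labels, _ = atac.cluster_dars(mat, k=2)
        truth = [0] * 40 + [1] * 40
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_singletons_at_k_equals_n(self, rng):
        mat = pd.DataFrame(rng.normal(size=(5, 6)))
        labels, _ = atac.cluster_dars(mat, k=5)
        assert labels.nunique() == 5

    def test_invariant_to_within_group_column_permutation(self, rng):
        up = np.tile([0.0, 0, 0, 5, 5, 5], (20, 1)) + rng.normal(0, 0.1, (20, 6))
        down = np.tile([5.0, 5, 5, 0, 0, 0], (20, 1)) + rng.normal(0, 0.1, (20, 6))
        mat = pd.DataFrame(np.vstack([up, down]), columns=list("abcdef"))
        labels, _ = atac.cluster_dars(mat, k=2)
        permuted = mat[["b", "c", "a", "f", "d", "e"]]
        labels_p, _ = atac.cluster_dars(permuted, k=2)
        assert (labels == labels_p).all()

    def test_constant_row_assigned_by_nearest_centroid(self, rng):
        up = np.tile([0.0, 0, 5, 5], (10, 1)) + rng.normal(0, 0.1, (10, 4))
        down = np.tile([5.0, 5, 0, 0], (10, 1)) + rng.normal(0, 0.1, (10, 4))
        flat = np.full((1, 4), 2.5)
        mat = pd.DataFrame(np.vstack([up, down, flat]))
        labels, _ = atac.cluster_dars(mat, k=2)
        assert labels.iloc[-1] in (1, 2)

    def test_median_profiles_reported(self, rng):
        mat = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        groups = pd.Series({"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
        _, medians = atac.cluster_dars(mat, k=2, sample_groups=groups)
        assert set(medians.columns) == {"g1", "g2"}


class TestOpenFraction:
    def test_percentages(self):
        labels = pd.Series([1] * 10, index=[f"r{i}" for i in range(10)])
        found = pd.DataFrame({"old_CD49b-": [True] * 7 + [False] * 3},
                             index=labels.index)
        out = atac.open_fraction(labels, found)
        assert out.loc[1, "old_CD49b-"] == pytest.approx(70.0)

    def test_de_novo_gain_construction(self):
        """Regions absent in juvenile but found in old: 0% vs 100%."""
        labels = pd.Series([1] * 5, index=[f"r{i}" for i in range(5)])
        found = pd.DataFrame({"J": [False] * 5, "O": [True] * 5},
                             index=labels.index)
        out = atac.open_fraction(labels, found)
        assert out.loc[1, "J"] == 0.0 and out.loc[1, "O"] == 100.0

    def test_bounds(self, rng):
        labels = pd.Series(rng.integers(1, 4, 30), index=range(30))
        found = pd.DataFrame({"p": rng.random(30) > 0.5}, index=range(30))
        out = atac.open_fraction(labels, found)
        assert ((out >= 0) & (out <= 100)).all().all()


def _fake_dar(sig_ids, universe, direction="up"):
    df = pd.DataFrame({
        "p_adj": [1e-6 if r in sig_ids else 0.5 for r in universe],
        "direction": direction if isinstance(direction, list)
        else [direction] * len(universe),
    }, index=pd.Index(universe, name="region_id"))
    return df


class TestOverlapAndLinDars:
    def test_venn_counts(self):
        universe = ["r1", "r2", "r3", "r4", "r5"]
        a = _fake_dar({"r1", "r2", "r3"}, universe)
        b = _fake_dar({"r2", "r3", "r4"}, universe)
        out = atac.aging_overlap(a, b)
        assert (out["n_shared"], out["n_only_a"], out["n_only_b"]) == (2, 1, 1)
        assert out["shared_concordant"] == ["r2", "r3"]

    def test_disjoint_sets(self):
        universe = ["r1", "r2", "r3", "r4"]
        out = atac.aging_overlap(_fake_dar({"r1"}, universe),
                                 _fake_dar({"r4"}, universe))
        assert out["n_shared"] == 0

    def test_random_sets_match_naive_oracle(self, rng):
        universe = [f"r{i}" for i in range(300)]
        for _ in range(10):
            sa = set(rng.choice(universe, size=60, replace=False))
            sb = set(rng.choice(universe, size=80, replace=False))
            out = atac.aging_overlap(_fake_dar(sa, universe),
                                     _fake_dar(sb, universe))
            assert out["n_shared"] == len(sa & sb)
            assert out["n_only_a"] == len(sa - sb)
            assert out["n_only_b"] == len(sb - sa)

    def test_direction_discordance(self):
        universe = ["r1", "r2"]
        a = _fake_dar({"r1", "r2"}, universe, direction=["up", "down"])
        b = _fake_dar({"r1", "r2"}, universe, direction=["up", "up"])
        out = atac.aging_overlap(a, b)
        assert out["shared_concordant"] == ["r1"]
        assert out["shared_discordant"] == ["r2"]

    def test_lin_dar_set_difference(self):
        universe = ["r1", "r2", "r3", "r4"]
        lineage = _fake_dar({"r1", "r2", "r3"}, universe)
        aging = _fake_dar({"r2"}, universe)
        out = atac.lin_dars(lineage, [aging], lineage_p_adj=0.05)
        assert out.tolist() == ["r1", "r3"]

    def test_aging_superset_empties_result(self):
        universe = ["r1", "r2"]
        lineage = _fake_dar({"r1", "r2"}, universe)
        aging = _fake_dar({"r1", "r2"}, universe)
        assert len(atac.lin_dars(lineage, [aging], lineage_p_adj=0.05)) == 0

    def test_union_order_invariance_and_naive_oracle(self, rng):
        universe = [f"r{i}" for i in range(500)]
        lin_set = set(rng.choice(universe, size=120, replace=False))
        a1 = set(rng.choice(universe, size=70, replace=False))
        a2 = set(rng.choice(universe, size=70, replace=False))
        lineage = _fake_dar(lin_set, universe)
        d1, d2 = _fake_dar(a1, universe), _fake_dar(a2, universe)
        fwd = atac.lin_dars(lineage, [d1, d2], lineage_p_adj=0.05)
        rev = atac.lin_dars(lineage, [d2, d1], lineage_p_adj=0.05)
        assert fwd.tolist() == rev.tolist()
        naive = [r for r in universe if r in lin_set - (a1 | a2)]
        assert fwd.tolist() == naive

    def test_intersection_mode(self):
        universe = ["r1", "r2", "r3"]
        lineage = _fake_dar({"r1", "r2", "r3"}, universe)
        d1 = _fake_dar({"r1", "r2"}, universe)
        d2 = _fake_dar({"r2", "r3"}, universe)
        out = atac.lin_dars(lineage, [d1, d2], lineage_p_adj=0.05,
                            mode="intersection")
        assert out.tolist() == ["r1", "r3"]


class TestMotifScan:
    consensus = "AGATAAGA"
    pfm = sim.consensus_to_pfm("AGATAAGA")

    def test_planted_consensus_hit(self, rng):
        bases = "ACGT"
        seq = "".join(rng.choice(list(bases), 60)) + self.consensus
        hits = atac.motif_scan({"r": seq}, self.pfm)
        assert hits["r"]

    def test_reverse_complement_hit(self):
        rc = self.consensus[::-1].translate(str.maketrans("ACGT", "TGCA"))
        seq = "C" * 30 + rc + "C" * 30
        assert atac.motif_scan({"r": seq}, self.pfm)["r"]

    def test_short_sequence_never_hits(self):
        assert not atac.motif_scan({"r": "AGAT"}, self.pfm)["r"]

    def test_exhaustive_window_oracle(self, rng):
        """Strict-threshold scan agrees with brute-force window scoring on
        length-20 toys."""
        lo = atac.pwm_log_odds(self.pfm)
        L = lo.shape[1]
        comp = str.maketrans("ACGT", "TGCA")
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}

        def brute(seq):
            best = -np.inf
            for s in (seq, seq.translate(comp)[::-1]):
                for w in range(len(s) - L + 1):
                    best = max(best,
                               sum(lo[idx[b], i] for i, b in enumerate(s[w:w + L])))
            return best >= 1.0 * lo.max(axis=0).sum()

        seqs = {f"t{i}": "".join(rng.choice(list("ACGT"), 20)) for i in range(200)}
        seqs["planted"] = "ACGT" + self.consensus + "ACGTACGT"
        hits = atac.motif_scan(seqs, self.pfm, score_fraction=1.0)
        for name, seq in seqs.items():
            assert hits[name] == brute(seq), name


class TestMotifEnrichment:
    def test_exact_tail_sum_oracle(self):
        t = pd.Series([True] * 40 + [False] * 10)
        b = pd.Series([True] * 100 + [False] * 900)
        out = atac.motif_enrichment(t, b, "m")
        oracle = sum(binom.pmf(k, 50, 0.1) for k in range(40, 51))
        assert out.p_binomial == pytest.approx(oracle, rel=1e-12)
        assert out.neg_ln_p == pytest.approx(-math.log(oracle), rel=1e-9)

    def test_null_rate_not_enriched(self):
        t = pd.Series([True] * 5 + [False] * 45)
        b = pd.Series([True] * 100 + [False] * 900)
        out = atac.motif_enrichment(t, b, "m")
        assert 0.2 < out.p_binomial < 0.8

    def test_no_target_hits_p_one(self):
        t = pd.Series([False] * 50)
        b = pd.Series([True] * 10 + [False] * 90)
        assert atac.motif_enrichment(t, b, "m").p_binomial == 1.0

    def test_zero_background_flagged(self):
        t = pd.Series([True] * 10 + [False] * 10)
        b = pd.Series([False] * 100)
        out = atac.motif_enrichment(t, b, "m")
        assert out.flag == "pseudo-background" and out.p_binomial < 1e-6

    def test_planted_motif_enriched_in_simulation(self, planted_atac):
        b = planted_atac
        truth = b["truth"].set_index("region_id")
        gain = truth.index[truth["planted_set"] == "gain"]
        none = truth.index[truth["planted_set"] == "none"]
        table = atac.motif_enrichment_table(
            {r: b["sequences"][r] for r in gain},
            {r: b["sequences"][r] for r in none},
            sim.default_motif_pfms(),
        )
        table = table.set_index("motif_id")
        assert table.loc["MOTIF_GATA", "neg_ln_p"] > 50
        assert (table.drop("MOTIF_GATA")["neg_ln_p"] < 10).all()


class TestNearestGene:
    regions = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [900, 2000, 100],
        "end": [1100, 2100, 200],
        "region_id": ["rA", "rB", "rC"],
    })

    def test_nearest_by_midpoint(self):
        tss = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "pos": [700, 1200],
            "strand": ["+", "-"], "gene": ["far", "near"],
        })
        out = atac.nearest_gene(self.regions.iloc[:1], tss).iloc[0]
        assert out["gene"] == "near" and out["distance"] == 200.0

    def test_tss_inside_region_distance_zero(self):
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [2050],
                            "strand": ["+"], "gene": ["inside"]})
        out = atac.nearest_gene(self.regions.iloc[1:2], tss).iloc[0]
        assert out["gene"] == "inside" and out["distance"] == 0.0

    def test_equidistant_lexicographic_tie(self):
        tss = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "pos": [800, 1200],
            "strand": ["+", "+"], "gene": ["zeta", "alpha"],
        })
        out = atac.nearest_gene(self.regions.iloc[:1], tss).iloc[0]
        assert out["gene"] == "alpha"

    def test_missing_chromosome_flagged(self):
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [1000],
                            "strand": ["+"], "gene": ["g"]})
        out = atac.nearest_gene(self.regions, tss)
        assert out.loc[out["region_id"] == "rC", "flag"].iloc[0] == \
            "no-TSS-on-chromosome"
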