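"""Synthetic genome and CTSS generator: determinism, conservation, structure."""

import numpy as np
import pandas as pd
import pytest

from promarch.normalization import fit_power_law
from promarch.synthetic import (
    PromoterSpec,
    default_specs,
    generate_genome,
    plant_promoters,
    sample_power_law_counts,
    simulate_ctss,
    simulate_study,
)


class TestGenerateGenome:
    def test_length_forced(self):
        g = generate_genome(1, 10_000, 0.5, seed=1)
        assert set(g) == {"chr1"} and len(g["chr1"]) == 10_000

    def test_gc_content_within_binomial_error(self):
        g = generate_genome(1, 100_000, 0.4, seed=7)
        gc = sum(g["chr1"].count(b) for b in "GC") / 100_000
        assert 0.39 <= gc <= 0.41

    def test_deterministic(self):
        assert generate_genome(2, 5_000, 0.45, seed=3) == generate_genome(2, 5_000, 0.45, seed=3)

    @pytest.mark.parametrize("kwargs", [dict(chrom_length=500), dict(gc_content=0.0), dict(gc_content=1.0)])
    def test_invalid_parameters(self, kwargs):
        args = dict(n_chroms=1, chrom_length=10_000, gc_content=0.5, seed=0)
        args.update(kwargs)
        with pytest.raises(ValueError):
            generate_genome(**args)


class TestPlantPromoters:
    def test_wbox_written_as_at_only(self):
        genome = generate_genome(1, 150_000, 0.5, seed=2)
        truth = plant_promoters(genome, [PromoterSpec("sharp_wbox", 100)], seed=2)
        assert len(truth) == 100
        for _, row in truth.iterrows():
            motif = genome[row["chrom"]][int(row["wbox_start"]) - 1 : int(row["wbox_end"])]
            assert len(motif) == 8 and set(motif) <= {"A", "T"}

    def test_zero_promoters(self):
        genome = generate_genome(1, 10_000, 0.5, seed=0)
        truth = plant_promoters(genome, [PromoterSpec("broad", 0)], seed=0)
        assert len(truth) == 0

    def test_shifting_dominants_offset_strand_oriented(self):
        genome = generate_genome(1, 200_000, 0.5, seed=4)
        truth = plant_promoters(genome, [PromoterSpec("shifting", 50, shift_offset=50)], seed=4)
        sign = np.where(truth["strand"] == "+", 1, -1)
        np.testing.assert_array_equal(
            truth["dominant_tss_mutant"] - truth["dominant_tss_wt"], sign * 50
        )

    def test_capacity_error(self):
        genome = generate_genome(1, 1_000, 0.5, seed=0)
        with pytest.raises(ValueError, match="insufficient genome space"):
            plant_promoters(genome, [PromoterSpec("broad", 500)], min_spacing=1000, seed=0)

    def test_genome_mutated_only_inside_motifs(self):
        genome = generate_genome(1, 150_000, 0.5, seed=5)
        pristine = dict(genome)
        truth = plant_promoters(genome, [PromoterSpec("sharp_wbox", 50)], seed=5)
        diff = [i for i, (a, b) in enumerate(zip(pristine["chr1"], genome["chr1"]), start=1) if a != b]
        planted = set()
        for _, row in truth.iterrows():
            planted.update(range(int(row["wbox_start"]), int(row["wbox_end"]) + 1))
        assert set(diff) <= planted

    def test_nonshifting_shift_is_zero(self):
        genome = generate_genome(1, 150_000, 0.5, seed=6)
        truth = plant_promoters(genome, default_specs(20, 20, 5), seed=6)
        non = truth[truth["promoter_class"] != "shifting"]
        assert (non["true_shift_offset"] == 0).all()


@pytest.fixture(scope="module")
def planted():
    genome = generate_genome(2, 300_000, 0.45, seed=8)
    truth = plant_promoters(genome, default_specs(100, 100, 20), seed=8)
    return genome, truth


class TestSimulateCtss:

    def test_tag_conservation(self, planted):
        _, truth = planted
        ds = simulate_ctss(truth, "wt", 10_000, seed=1)
        assert ds.total_raw == 10_000
        assert (ds.df["count"] >= 1).all()

    def test_unknown_condition(self, planted):
        _, truth = planted
        with pytest.raises(KeyError):
            simulate_ctss(truth, "het", 1000, seed=1)

    def test_deterministic(self, planted):
        _, truth = planted
        assert simulate_ctss(truth, "wt", 5000, seed=9) == simulate_ctss(truth, "wt", 5000, seed=9)

    def test_sharp_promoter_mass_concentrated(self, planted):
        # sd=1 Gaussian puts >95% of mass within +-2 bases
        _, truth = planted
        ds = simulate_ctss(truth, "wt", 500_000, seed=2)
        sharp = truth[truth["promoter_class"] == "sharp_wbox"].iloc[0]
        near = ds.df[(ds.df["chrom"] == sharp["chrom"]) & (ds.df["strand"] == sharp["strand"])
                     & (ds.df["pos"] >= sharp["dominant_tss_wt"] - 400)
                     & (ds.df["pos"] <= sharp["dominant_tss_wt"] + 400)]
        assert near["count"].sum() >= 400  # enough tags to judge
        within2 = near[(near["pos"] - sharp["dominant_tss_wt"]).abs() <= 2]["count"].sum()
        assert within2 / near["count"].sum() >= 0.90

    def test_class_spread_separation(self, planted):
        # true sharp promoters have narrower empirical spread than broad ones
        _, truth = planted
        ds = simulate_ctss(truth, "mutant", 500_000, seed=3)
        spreads = {}
        for cls in ("broad",):
            sds = []
            for _, row in truth[truth["promoter_class"] == cls].head(30).iterrows():
                sub = ds.df[(ds.df["chrom"] == row["chrom"]) & (ds.df["strand"] == row["strand"])
                            & ((ds.df["pos"] - row["dominant_tss_mutant"]).abs() <= 400)]
                if sub["count"].sum() >= 50:
                    sds.append(np.sqrt(np.cov(sub["pos"], fweights=sub["count"])))
            spreads[cls] = np.median(sds)
        ds_wt = simulate_ctss(truth, "wt", 500_000, seed=3)
        sds = []
        for _, row in truth[truth["promoter_class"] == "sharp_wbox"].head(30).iterrows():
            sub = ds_wt.df[(ds_wt.df["chrom"] == row["chrom"]) & (ds_wt.df["strand"] == row["strand"])
                           & ((ds_wt.df["pos"] - row["dominant_tss_wt"]).abs() <= 400)]
            if sub["count"].sum() >= 50:
                sds.append(np.sqrt(np.cov(sub["pos"], fweights=sub["count"])))
        assert np.median(sds) < spreads["broad"]


class TestPowerLawSampling:
    def test_ccdf_is_power_law(self):
        counts = sample_power_law_counts(200_000, alpha=1.9, seed=11, count_cap=10**9)
        # P(X >= x) = x^-alpha exactly: check at a few x
        n = counts.size
        for x in (2, 5, 10):
            frac = (counts >= x).sum() / n
            assert frac == pytest.approx(x ** -1.9, rel=0.1)

    def test_study_scale_slope_recovered(self):
        counts = sample_power_law_counts(500_000, alpha=1.9, seed=12)
        fit = fit_power_law(counts)
        assert 1.75 <= fit.alpha_sample <= 2.05

    def test_promoter_level_zipf_slope(self):
        # per-position counts of a simulated broad-promoter sample inherit
        # the Zipf exponent once the library is deep enough that the
        # weakest promoter's peak sits below the fit range
        genome = generate_genome(4, 400_000, 0.45, seed=13)
        truth = plant_promoters(
            genome,
            [PromoterSpec("broad", 1000, expression_zipf_alpha=1.9,
                          condition_weights=(1.0, 1.0))],
            min_spacing=1500, seed=13)
        ds = simulate_ctss(truth, "wt", 2_000_000, seed=13)
        fit = fit_power_law(ds)
        assert 1.75 <= fit.alpha_sample <= 2.05


class TestSimulateStudy:
    def test_reproducible_from_one_seed(self):
        g1, t1, d1 = simulate_study(seed=21, specs=default_specs(30, 30, 5),
                                    n_chroms=1, chrom_length=120_000, total_tags=50_000)
        g2, t2, d2 = simulate_study(seed=21, specs=default_specs(30, 30, 5),
                                    n_chroms=1, chrom_length=120_000, total_tags=50_000)
        assert g1 == g2
        assert t1.equals(t2)
        assert d1["wt"] == d2["wt"] and d1["mutant"] == d2["mutant"]
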