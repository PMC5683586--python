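import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from popload.io_core import GenotypeMatrix, Window, attach_scores, make_windows, polarize
from popload.load import (
    correct_gerp,
    empirical_p,
    fixed_segregating,
    gene_density,
    geneset_burden,
    individual_burden,
    load_vs_introgression,
    merge_intervals,
    null_distribution,
    pi_ratio_test,
    population_load,
    severity_class,
    window_deleterious_counts,
)
from tests.conftest import random_annotation, random_matrix


def annotated_fixture(seed=0, n_samples=8, n_sites=300):
    rng = np.random.default_rng(seed)
    gm = random_matrix(rng, n_samples=n_samples, n_sites=n_sites)
    ann = random_annotation(rng, gm)
    freqs = {
        (gm.chrom[j], int(gm.pos[j])): float(rng.random()) for j in range(gm.n_sites)
    }
    return gm, ann, freqs


class TestSeverityClass:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (3.0, "moderately"),
            (0.0, "nearly_neutral"),
            (4.01, "strongly"),
            (-1.0, "nearly_neutral"),
            (0.5, "slightly"),
            (2.0, "slightly"),
            (4.0, "moderately"),
            (-2.0, None),
            (-5.0, None),
        ],
    )
    def test_partition_boundaries(self, score, expected):
        assert severity_class(score) == expected

    def test_nan_excluded(self):
        assert severity_class(float("nan")) is None


class TestCorrectGerp:
    def test_reference_ancestral_identity(self):
        gm, ann, freqs = annotated_fixture(1)
        fixed = correct_gerp(ann, gm, freqs)
        keep = ann.derived_is_alt & ~ann.excluded & ~np.isnan(ann.gerp_raw)
        np.testing.assert_allclose(fixed.gerp_corrected[keep], ann.gerp_raw[keep])

    def test_bin_mean_by_construction(self):
        # two reference-ancestral sites with scores {2, 3} in one bin; a
        # reference-derived site in the same bin gets their mean
        gm = random_matrix(np.random.default_rng(2), n_samples=2, n_sites=3)
        out = {
            (gm.chrom[0], int(gm.pos[0])): gm.ref[0],  # derived = alt (ref ancestral)
            (gm.chrom[1], int(gm.pos[1])): gm.ref[1],
            (gm.chrom[2], int(gm.pos[2])): gm.alt[2],  # derived = ref (ref derived)
        }
        ann = polarize(gm, out)
        ann = attach_scores(
            ann,
            gm,
            {
                (gm.chrom[0], int(gm.pos[0])): 2.0,
                (gm.chrom[1], int(gm.pos[1])): 3.0,
                (gm.chrom[2], int(gm.pos[2])): 5.0,
            },
        )
        freqs = {(gm.chrom[j], int(gm.pos[j])): 0.105 for j in range(3)}
        fixed = correct_gerp(ann, gm, freqs)
        assert fixed.gerp_corrected[2] == pytest.approx(2.5)

    def test_brute_force_bin_means(self):
        gm, ann, freqs = annotated_fixture(3, n_sites=400)
        fixed = correct_gerp(ann, gm, freqs)
        scored = ~np.isnan(ann.gerp_raw) & ~ann.excluded
        bins = {}
        for j in np.flatnonzero(scored & ann.derived_is_alt):
            b = min(int(freqs[(gm.chrom[j], int(gm.pos[j]))] * 100), 99)
            bins.setdefault(b, []).append(ann.gerp_raw[j])
        means = {b: np.mean(v) for b, v in bins.items()}
        filled = sorted(means)
        for j in np.flatnonzero(scored & ~ann.derived_is_alt):
            b = min(int(freqs[(gm.chrom[j], int(gm.pos[j]))] * 100), 99)
            if b not in means:
                b = min(filled, key=lambda x: abs(x - b))
            assert fixed.gerp_corrected[j] == pytest.approx(means[b])

    def test_corrected_mean_within_bin_mean_range(self):
        gm, ann, freqs = annotated_fixture(4, n_sites=400)
        fixed = correct_gerp(ann, gm, freqs)
        scored = ~np.isnan(ann.gerp_raw) & ~ann.excluded
        derived_ref = scored & ~ann.derived_is_alt
        anc_ref = scored & ann.derived_is_alt
        if derived_ref.any():
            assert fixed.gerp_corrected[derived_ref].mean() >= ann.gerp_raw[anc_ref].min()
            assert fixed.gerp_corrected[derived_ref].mean() <= ann.gerp_raw[anc_ref].max()

    def test_restores_signal_after_injected_reference_bias(self):
        # wiping scores at reference-derived sites then correcting yields
        # higher scores at truly-deleterious reference-derived sites than
        # the biased input had
        from popload.synthetic_data.scores import apply_reference_bias, assign_scores

        rng = np.random.default_rng(5)
        s = np.where(rng.random(500) < 0.4, 0.02, 0.0)
        scores = assign_scores(s, noise_sd=0.3, rng=rng)
        ref_derived = rng.random(500) < 0.3
        biased = apply_reference_bias(scores, ref_derived, rng)
        target = ref_derived & (s > 0)
        assert biased[target].mean() < scores[target].mean()


class TestIndividualBurden:
    def _one_site(self, dosage_value, gerp):
        gm = random_matrix(np.random.default_rng(6), n_samples=1, n_sites=2)
        d = np.array([[dosage_value, 0]], dtype=np.int8)
        gm = dataclasses.replace(gm, dosage=d)
        out = {(gm.chrom[j], int(gm.pos[j])): gm.ref[j] for j in range(2)}
        ann = polarize(gm, out)
        ann = attach_scores(
            ann, gm, {(gm.chrom[j], int(gm.pos[j])): gerp for j in range(2)}
        )
        return gm, ann

    def test_het_site(self):
        gm, ann = self._one_site(1, 2.0)
        assert individual_burden(gm, ann, "s0", "additive").burden == pytest.approx(1.0)
        assert individual_burden(gm, ann, "s0", "recessive").burden == pytest.approx(0.0)

    def test_hom_site(self):
        gm, ann = self._one_site(2, 2.0)
        assert individual_burden(gm, ann, "s0", "additive").burden == pytest.approx(2.0)
        assert individual_burden(gm, ann, "s0", "recessive").burden == pytest.approx(2.0)

    def test_brute_force_site_loop(self):
        gm, ann, _ = annotated_fixture(7)
        for sample in gm.samples[:3]:
            i = gm.sample_index(sample)
            dd = ann.derived_dosage(gm)[i]
            exp_add = exp_rec = 0.0
            for j in range(gm.n_sites):
                g = ann.gerp_corrected[j]
                if ann.excluded[j] or np.isnan(g) or g <= 0 or dd[j] < 0:
                    continue
                if dd[j] == 1:
                    exp_add += 0.5 * g
                elif dd[j] == 2:
                    exp_add += g
                    exp_rec += g
            assert individual_burden(gm, ann, sample, "additive").burden == pytest.approx(exp_add)
            assert individual_burden(gm, ann, sample, "recessive").burden == pytest.approx(exp_rec)

    def test_recessive_at_most_additive(self):
        gm, ann, _ = annotated_fixture(8)
        for sample in gm.samples:
            add = individual_burden(gm, ann, sample, "additive").burden
            rec = individual_burden(gm, ann, sample, "recessive").burden
            assert rec <= add + 1e-12

    def test_partition_restricts_sites(self):
        gm, ann, _ = annotated_fixture(9)
        total = sum(
            individual_burden(gm, ann, "s0", "additive", partition=p).burden
            for p in ("slightly", "moderately", "strongly")
        )
        assert total == pytest.approx(individual_burden(gm, ann, "s0", "additive").burden)


class TestPopulationLoad:
    def test_single_site_hwe(self):
        # q = 0.5, gerp = 2 -> additive load 1.0
        gm = random_matrix(np.random.default_rng(10), n_samples=4, n_sites=1)
        gm = dataclasses.replace(gm, dosage=np.array([[0], [1], [1], [2]], dtype=np.int8))
        out = {(gm.chrom[0], int(gm.pos[0])): gm.ref[0]}
        ann = polarize(gm, out)
        ann = attach_scores(ann, gm, {(gm.chrom[0], int(gm.pos[0])): 2.0})
        pop = gm.populations[gm.samples[0]]
        gm.populations.update({s: pop for s in gm.samples})
        assert population_load(gm, ann, pop, "additive") == pytest.approx(1.0)

    def test_no_derived_zero(self):
        gm = random_matrix(np.random.default_rng(11), n_samples=4, n_sites=10)
        gm = dataclasses.replace(gm, dosage=np.zeros((4, 10), dtype=np.int8))
        out = {(gm.chrom[j], int(gm.pos[j])): gm.ref[j] for j in range(10)}
        ann = polarize(gm, out)
        ann = attach_scores(ann, gm, {(gm.chrom[j], int(gm.pos[j])): 2.0 for j in range(10)})
        pop = gm.populations[gm.samples[0]]
        assert population_load(gm, ann, pop, "additive") == 0.0

    def test_additive_equals_mean_individual_burden(self):
        # algebraic identity with complete data
        gm, ann, _ = annotated_fixture(12)
        gm = dataclasses.replace(gm, dosage=np.abs(gm.dosage))  # no missing
        pop = "A"
        samples = [s for s in gm.samples if gm.populations[s] == pop]
        mean_burden = np.mean(
            [individual_burden(gm, ann, s, "additive").burden for s in samples]
        )
        assert population_load(gm, ann, pop, "additive") == pytest.approx(mean_burden)


class TestFixedSegregating:
    def _pop_matrix(self, dosage):
        dosage = np.asarray(dosage, dtype=np.int8)
        n, s = dosage.shape
        gm = GenotypeMatrix(
            samples=[f"i{k}" for k in range(n)],
            populations={f"i{k}": "p" for k in range(n)},
            chrom=np.asarray(["c"] * s, dtype=object),
            pos=np.arange(10, 10 * (s + 1), 10),
            ref=np.asarray(["A"] * s, dtype=object),
            alt=np.asarray(["G"] * s, dtype=object),
            dosage=dosage,
        )
        out = {(gm.chrom[j], int(gm.pos[j])): gm.ref[j] for j in range(s)}
        ann = polarize(gm, out)
        ann = attach_scores(ann, gm, {(gm.chrom[j], int(gm.pos[j])): 2.0 for j in range(s)})
        return gm, ann

    def test_monomorphic_derived(self):
        gm, ann = self._pop_matrix(np.full((6, 5), 2))
        counts = fixed_segregating(gm, ann, "p", 4)
        assert len(counts) == math.comb(6, 4)
        assert all(c.fixed == 5 and c.segregating == 0 for c in counts)

    def test_private_het_counted_only_in_draws_including_carrier(self):
        dosage = np.full((5, 1), 0, dtype=np.int8)
        dosage[0, 0] = 1  # private het in i0
        gm, ann = self._pop_matrix(dosage)
        counts = fixed_segregating(gm, ann, "p", 3)
        combos = list(itertools.combinations(range(5), 3))
        for combo, c in zip(combos, counts):
            assert c.segregating == (1 if 0 in combo else 0)

    def test_conservation(self):
        gm, ann, _ = annotated_fixture(13)
        n_del = int(((ann.gerp_corrected > 0) & ~ann.excluded).sum())
        for c in fixed_segregating(gm, ann, "A", 3):
            assert c.fixed + c.segregating <= n_del

    def test_seeded_subsampling_deterministic(self):
        gm, ann, _ = annotated_fixture(14, n_samples=12)
        a = fixed_segregating(gm, ann, "A", 3, max_replicates=5, seed=9)
        b = fixed_segregating(gm, ann, "A", 3, max_replicates=5, seed=9)
        assert [(c.fixed, c.segregating) for c in a] == [
            (c.fixed, c.segregating) for c in b
        ]
        assert len(a) == 5


class TestMergeIntervals:
    def test_overlap_merged(self):
        out = merge_intervals([("c", 0, 100), ("c", 50, 150), ("c", 200, 300)])
        assert out == [("c", 0, 150), ("c", 200, 300)]

    def test_union_length_matches_bp_scan(self):
        rng = np.random.default_rng(15)
        iv = [("c", int(s), int(s) + int(rng.integers(1, 50))) for s in rng.integers(0, 500, 40)]
        merged = merge_intervals(iv)
        covered = np.zeros(600, dtype=bool)
        for _, s, e in iv:
            covered[s:e] = True
        assert sum(e - s for _, s, e in merged) == int(covered.sum())


class TestGenesetBurden:
    def test_observed_vs_null_rank(self):
        gm, ann, _ = annotated_fixture(16)
        genes = [("chr1", int(p) - 50, int(p) + 50) for p in gm.pos[:40:4]]
        null = np.array([1.0, 2.0, 3.0])
        assert empirical_p(0.5, null, sided="less") == pytest.approx(1 / 4)
        assert empirical_p(0.5, null, sided="greater") == pytest.approx(1.0)

    def test_burden_counts_only_deleterious_present(self):
        gm, ann, _ = annotated_fixture(17)
        genes = [(gm.chrom[0], 0, int(gm.pos.max()) + 1)]
        val = geneset_burden(gm, ann, genes, flank_bp=0)
        sel = (~ann.excluded) & (ann.gerp_corrected > 0)
        dd = ann.derived_dosage(gm)
        present = np.where(dd >= 0, dd, 0).sum(axis=0) > 0
        on_chrom = gm.chrom == gm.chrom[0]
        expected = (sel & present & on_chrom).sum() / (int(gm.pos.max()) + 1)
        assert val == pytest.approx(expected)

    def test_null_distribution_seeded(self):
        gm, ann, _ = annotated_fixture(18)
        genes = [("chr1", int(p), int(p) + 100) for p in gm.pos[:30:3]]
        a = null_distribution(gm, ann, genes, 4, 20, seed=3)
        b = null_distribution(gm, ann, genes, 4, 20, seed=3)
        np.testing.assert_array_equal(a, b)


class TestPiRatio:
    def test_identical_populations_ratio_one(self):
        gm, ann, _ = annotated_fixture(19)
        genes = [("chr1", 0, int(gm.pos.max()) + 1)]
        ratio, p = pi_ratio_test(gm, gm, genes, genes, n_reps=5, seed=1)
        assert ratio == pytest.approx(1.0)

    def test_order_invariance(self):
        gm, ann, _ = annotated_fixture(20)
        genes = [("chr1", int(p), int(p) + 200) for p in gm.pos[:20:2]]
        r1, _ = pi_ratio_test(gm, gm, genes, genes, n_reps=3, seed=1)
        r2, _ = pi_ratio_test(gm, gm, genes[::-1], genes, n_reps=3, seed=1)
        assert r1 == pytest.approx(r2)

    def test_sweep_scenario_candidate_depletion(self):
        from popload.synthetic_data import SimScenario, simulate
        from popload.synthetic_data.scenario import Split, Sweep

        sc = SimScenario(
            chrom_lengths={"chr1": 300_000, "chr2": 300_000},
            mu=1e-6,
            cm_per_mb=5.0,
            root="wild",
            epochs={"wild": [(10**9, 80)], "crop": [(150, 80)]},
            burn_in=600,
            splits=[Split(150, "wild", "crop", 30)],
            sweeps=[Sweep(145, "crop", "chr1", 150_000, 0.6, 0.2)],
            n_sample=8,
            pop_steps={"wild": 0, "crop": 0},
        )
        ds = simulate(sc, seed=99)
        wild_idx = ds.gm.sample_indices("wild")
        crop_idx = ds.gm.sample_indices("crop")
        import dataclasses as dc

        gm_crop = dc.replace(ds.gm, dosage=ds.gm.dosage[crop_idx],
                             samples=[ds.gm.samples[i] for i in crop_idx])
        gm_wild = dc.replace(ds.gm, dosage=ds.gm.dosage[wild_idx],
                             samples=[ds.gm.samples[i] for i in wild_idx])
        # candidate genes sit inside the sweep: crop diversity depleted there
        ratio, p = pi_ratio_test(
            gm_crop, gm_wild, ds.candidate_genes, ds.genes, n_reps=60, seed=5
        )
        genome_ratio, _ = pi_ratio_test(
            gm_crop, gm_wild, ds.genes, ds.genes, n_reps=2, seed=5
        )
        assert ratio < genome_ratio
        assert p < 0.5


class TestLoadRegression:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(21)
        n = 50
        fd = rng.random(n)
        dens = rng.random(n) * 10
        count = 5 - 2.0 * fd + 0.3 * dens
        fit = load_vs_introgression(pd.DataFrame({"fd": fd, "count": count, "gene_density": dens}))
        assert fit.fd_coef == pytest.approx(-2.0, abs=1e-8)
        assert fit.density_coef == pytest.approx(0.3, abs=1e-8)
        assert fit.intercept == pytest.approx(5.0, abs=1e-8)

    def test_nan_fd_rows_dropped(self):
        df = pd.DataFrame(
            {
                "fd": [0.1, np.nan, 0.3, 0.5],
                "count": [1.0, 2.0, 3.0, 4.0],
                "gene_density": [1.0, 1.0, 2.0, 3.0],
            }
        )
        fit = load_vs_introgression(df)
        assert fit.n_windows == 3

    def test_permuted_fd_p_uniform(self):
        rng = np.random.default_rng(22)
        n = 60
        dens = rng.random(n)
        count = rng.poisson(10, n).astype(float)
        pvals = []
        for _ in range(150):
            fd = rng.permutation(rng.random(n))
            fit = load_vs_introgression(
                pd.DataFrame({"fd": fd, "count": count, "gene_density": dens})
            )
            pvals.append(fit.fd_p)
        from scipy import stats as sp_stats

        assert sp_stats.kstest(pvals, "uniform").pvalue > 1e-3

    def test_too_few_windows(self):
        with pytest.raises(ValueError):
            load_vs_introgression(
                pd.DataFrame({"fd": [0.1], "count": [1.0], "gene_density": [1.0]})
            )


class TestWindowCounts:
    def test_modes_ordering(self):
        gm, ann, _ = annotated_fixture(23)
        windows = make_windows({"chr1": int(gm.pos.max()) + 1, "chr2": int(gm.pos.max()) + 1}, 10**9)
        sites = window_deleterious_counts(gm, ann, windows, mode="sites")
        alleles = window_deleterious_counts(gm, ann, windows, mode="alleles")
        hom = window_deleterious_counts(gm, ann, windows, mode="hom")
        assert (alleles >= sites).all()
        assert (alleles >= hom).all()

    def test_gene_density_exonic_bp_per_cm(self):
        from popload.io_core import GeneticMap

        gmap = GeneticMap.uniform({"c": 100_000}, 1.0)
        windows = [Window("c", 0, 10_000)]
        exons = [("c", 2000, 3000), ("c", 2500, 4000)]
        dens = gene_density(windows, exons, gmap)
        # union 2000..4000 = 2000 bp over 0.01 cM
        assert dens[0] == pytest.approx(2000 / 0.01)
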