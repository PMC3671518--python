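"""Synthetic study generator: determinism, composition, planted structure."""

import numpy as np
import pytest

from anagen.simulate import (
    GroundTruth,
    SimulationConfig,
    assign_categories,
    generate_contigs,
    generate_count_matrix,
    generate_qpcr,
    plant_ssrs,
    simulate_study,
)


class TestConfig:
    def test_invalid_values_rejected(self):
        for kw in (
            {"n_contigs": -1},
            {"gc_fraction": 1.2},
            {"de_fraction": -0.1},
            {"de_fold": 0.5},
            {"dispersion": -1.0},
            {"library_depths": (1e6,), "library_names": ("only",)},
            {"n_categories": 1},
        ):
            with pytest.raises(ValueError):
                SimulationConfig(**kw)


class TestContigs:
    def test_empty_case(self):
        assert generate_contigs(SimulationConfig(n_contigs=0)) == []

    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(n_contigs=50, seed=1)
        a = generate_contigs(cfg)
        b = generate_contigs(cfg)
        assert [(c.id, c.sequence) for c in a] == [(c.id, c.sequence) for c in b]

    def test_lengths_respect_floor(self):
        contigs = generate_contigs(SimulationConfig(n_contigs=200, seed=2))
        assert min(c.length for c in contigs) >= 301

    def test_pooled_gc_within_three_standard_errors(self):
        cfg = SimulationConfig(n_contigs=10_000, gc_fraction=0.5, seed=3)
        contigs = generate_contigs(cfg)
        pooled = "".join(c.sequence for c in contigs)
        n = len(pooled)
        gc = (pooled.count("G") + pooled.count("C")) / n
        se = np.sqrt(0.5 * 0.5 / n)
        assert abs(gc - 0.5) <= 3 * se


class TestPlantSsrs:
    def test_planted_substring_and_unchanged_length(self):
        cfg = SimulationConfig(n_contigs=5, seed=4)
        contigs = generate_contigs(cfg)
        planted, spans = plant_ssrs(contigs, (("AC", 9, 0),), seed=4)
        cid, start, end, motif, copies = spans[0]
        assert cid == contigs[0].id
        assert planted[0].sequence[start - 1 : end] == "AC" * 9
        assert end - start + 1 == 18
        assert planted[0].length == contigs[0].length
        assert planted[1:] == contigs[1:]

    def test_empty_plant_list_identity(self):
        cfg = SimulationConfig(n_contigs=3, seed=5)
        contigs = generate_contigs(cfg)
        planted, spans = plant_ssrs(contigs, (), seed=5)
        assert planted == contigs and spans == []

    def test_oversized_plant_rejected(self):
        cfg = SimulationConfig(n_contigs=2, seed=6)
        contigs = generate_contigs(cfg)
        too_many = contigs[0].length  # 2 bp motif -> twice the contig length
        with pytest.raises(ValueError):
            plant_ssrs(contigs, (("AC", too_many, 0),), seed=6)


class TestCountMatrix:
    def test_totals_are_column_sums(self):
        cfg = SimulationConfig(n_contigs=300, seed=7)
        contigs = generate_contigs(cfg)
        table, _ = generate_count_matrix(contigs, cfg)
        assert (table.totals == table.counts.sum(axis=0)).all()

    def test_determinism(self):
        cfg = SimulationConfig(n_contigs=100, seed=8)
        contigs = generate_contigs(cfg)
        a, _ = generate_count_matrix(contigs, cfg)
        b, _ = generate_count_matrix(contigs, cfg)
        assert a.counts.equals(b.counts)

    def test_null_symmetry_between_equal_depth_libraries(self):
        cfg = SimulationConfig(
            n_contigs=4000,
            de_fraction=0.0,
            library_names=("A", "B"),
            library_depths=(2e6, 2e6),
            seed=9,
        )
        contigs = generate_contigs(cfg)
        table, truth = generate_count_matrix(contigs, cfg)
        assert truth.up_ids == frozenset() and truth.down_ids == frozenset()
        diff = (table.counts["B"] - table.counts["A"]).to_numpy()
        # mean difference across contigs ~ 0 within 3 standard errors
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) <= 3 * se

    def test_planted_fold_recovered_over_replicates(self):
        """Counts for an up-planted contig average ~de_fold times the
        reference library across 1,000 replicate count draws of the same
        planted structure."""
        cfg = SimulationConfig(
            n_contigs=50, de_fraction=0.2, de_fold=4.0,
            library_names=("A", "B"), library_depths=(5e5, 5e5), seed=20,
        )
        contigs = generate_contigs(cfg)
        _, truth = generate_count_matrix(contigs, cfg)
        target = sorted(truth.up_ids)[0]
        ratios = []
        for rep in range(1000):
            table, _ = generate_count_matrix(contigs, cfg, counts_seed=rep)
            a = table.counts.loc[target, "A"]
            if a > 0:
                ratios.append(table.counts.loc[target, "B"] / a)
        ratios = np.array(ratios)
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 4.0) <= 3 * se

    def test_dispersion_inflates_count_noise(self):
        """Gamma mixing raises the per-contig Fano factor well above the
        Poisson value of ~1."""

        def mean_fano(dispersion):
            cfg = SimulationConfig(
                n_contigs=200, de_fraction=0.0, dispersion=dispersion, seed=21
            )
            contigs = generate_contigs(cfg)
            draws = np.stack(
                [
                    generate_count_matrix(contigs, cfg, counts_seed=rep)[0]
                    .counts["BL"]
                    .to_numpy()
                    for rep in range(30)
                ]
            )
            means = draws.mean(axis=0)
            keep = means > 10
            return float((draws.var(axis=0, ddof=1)[keep] / means[keep]).mean())

        assert mean_fano(0.0) == pytest.approx(1.0, rel=0.25)
        assert mean_fano(0.5) > 5.0


class TestCategoriesAndQpcr:
    def test_every_annotated_contig_has_a_category(self):
        b = simulate_study(SimulationConfig(n_contigs=500, seed=11))
        assert all(len(cats) >= 1 for cats in b.categories.values())
        frac = len(b.categories) / len(b.contigs)
        assert 0.2 < frac < 0.5  # around the configured annotated fraction

    def test_noise_free_ct_differences_are_exact(self):
        cfg = SimulationConfig(n_contigs=50, seed=12, qpcr_noise_sd=0.0, de_fold=4.0)
        contigs = generate_contigs(cfg)
        _, truth = generate_count_matrix(contigs, cfg)
        table = generate_qpcr(truth, cfg)
        gene = sorted(truth.true_folds)[0]
        ref = table[table["gene"] == "reference"].groupby("sample")["ct"].mean()
        tgt = table[table["gene"] == gene].groupby("sample")["ct"].mean()
        ddct = (tgt["BK"] - ref["BK"]) - (tgt["BL"] - ref["BL"])
        assert ddct == pytest.approx(-np.log2(truth.true_folds[gene]))

    def test_qpcr_requires_fold_changes(self):
        with pytest.raises(ValueError):
            generate_qpcr(GroundTruth(), SimulationConfig())


class TestBundleDeterminism:
    def test_same_seed_same_bundle(self):
        a = simulate_study(SimulationConfig(n_contigs=120, seed=13, ssr_plants=(("AT", 10, 0),)))
        b = simulate_study(SimulationConfig(n_contigs=120, seed=13, ssr_plants=(("AT", 10, 0),)))
        assert [c.sequence for c in a.contigs] == [c.sequence for c in b.contigs]
        assert a.counts.counts.equals(b.counts.counts)
        assert a.categories == b.categories
        assert a.qpcr.equals(b.qpcr)
        assert a.truth.ssr_spans == b.truth.ssr_spans
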