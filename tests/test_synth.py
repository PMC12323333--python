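import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhizonet.synth import (PHYSIOLOGY_DEFAULTS, SynthError, SyntheticSpec,
                            generate_counts, generate_metabolites,
                            generate_physiology, generate_study,
                            trend_multiplier, write_study)
from rhizonet.community import relative_abundance


class TestSpecValidation:
    def test_self_pair_rejected(self):
        with pytest.raises(SynthError, match="self-pair"):
            SyntheticSpec(planted_edges=[(3, 3, 0.5, 1)])

    def test_duplicate_edge_rejected(self):
        with pytest.raises(SynthError, match="duplicate"):
            SyntheticSpec(planted_edges=[(1, 2, 0.5, 1), (2, 1, 0.4, 1)])

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(SynthError, match="rho"):
            SyntheticSpec(planted_edges=[(1, 2, 1.0, 1)])

    def test_too_few_replicates_rejected(self):
        with pytest.raises(SynthError, match="n_replicates"):
            SyntheticSpec(n_replicates=2)

    def test_too_many_differentials_rejected(self):
        with pytest.raises(SynthError):
            SyntheticSpec(n_metabolites=10, n_diff_metabolites=11)

    def test_unrepairable_planted_star_raises(self):
        # a star of 0.9 correlations around one taxon has no positive
        # definite completion close to the requested values
        star = [(0, j, 0.9, 1) for j in range(1, 9)]
        spec = SyntheticSpec(planted_edges=star, hub_taxa={})
        with pytest.raises(SynthError, match="positive"):
            generate_counts(spec)


class TestTrendArchetypes:
    @pytest.mark.parametrize("arch", ["flat", "increasing", "decreasing",
                                      "hump", "crash", "spike"])
    def test_multiplier_positive(self, arch):
        vals = [trend_multiplier(arch, t, 6, 4.0, peak=2) for t in range(6)]
        assert all(v > 0 for v in vals)

    def test_increasing_zero_noise_strictly_increasing(self):
        spec = SyntheticSpec(seed=0, physiology_cv=0.0)
        design = generate_study(SyntheticSpec(seed=0)).design
        traits = generate_physiology(spec, design)
        means = traits.table.groupby(
            design.table["treatment"])["MDA"].mean()
        ordered = means.loc[list(design.treatments)]
        assert (np.diff(ordered.to_numpy()) > 0).all()

    def test_hump_zero_noise_peaks_at_configured_stage(self):
        spec = SyntheticSpec(seed=0, physiology_cv=0.0)
        design = generate_study(SyntheticSpec(seed=0)).design
        traits = generate_physiology(spec, design)
        means = traits.table.groupby(design.table["treatment"])["AsA"].mean()
        ordered = means.loc[list(design.treatments)]
        assert int(np.argmax(ordered.to_numpy())) == 3
        # peak amplitude matches the configured relative increase
        rel = ordered.max() / ordered.iloc[0] - 1
        assert rel == pytest.approx(PHYSIOLOGY_DEFAULTS["AsA"]["amplitude"],
                                    abs=1e-9)

    def test_mda_trend_recovered_under_noise(self):
        hits = 0
        for seed in range(25):
            study = generate_study(SyntheticSpec(seed=seed))
            t_idx = study.design.treatment_index()
            means = study.physiology.table["MDA"].groupby(t_idx).mean()
            rho = stats.spearmanr(means.index, means.to_numpy()).statistic
            hits += rho > 0
        assert hits == 25


class TestGenerateCounts:
    def test_determinism(self):
        a, _, _ = generate_counts(SyntheticSpec(seed=11))
        b, _, _ = generate_counts(SyntheticSpec(seed=11))
        pd.testing.assert_frame_equal(a.counts, b.counts)
        assert a.lineages.equals(b.lineages)

    def test_counts_are_nonnegative_ints_with_exact_depths(self):
        spec = SyntheticSpec(seed=3)
        table, design, truth = generate_counts(spec)
        vals = table.counts.to_numpy()
        assert np.issubdtype(vals.dtype, np.integer) and (vals >= 0).all()
        lo, hi = spec.library_size_range
        sums = vals.sum(axis=0)
        assert (sums >= lo).all() and (sums <= hi).all()
        assert sums.tolist() == [truth["library_sizes"][s]
                                 for s in table.samples]

    def test_null_case_has_no_planted_correlation(self):
        all_vals = []
        for seed in (5, 6, 7):
            spec = SyntheticSpec(seed=seed, planted_edges=[], hub_taxa={},
                                 trend_assignments={})
            table, design, _ = generate_counts(spec)
            props = relative_abundance(table)
            # prevalent taxa only: rare rows are tie-dominated
            keep = (table.counts > 0).mean(axis=1) > 0.8
            sub = props.loc[keep]
            rho = np.corrcoef(
                np.apply_along_axis(stats.rankdata, 1, sub.to_numpy()))
            iu = np.triu_indices(len(sub), k=1)
            all_vals.append(rho[iu])
        vals = np.concatenate(all_vals)
        assert abs(np.mean(vals)) < 0.1
        assert np.mean(np.abs(vals) > 0.6) < 0.01

    def test_single_planted_edge_recovered_at_large_n(self):
        hits = 0
        for seed in range(15):
            spec = SyntheticSpec(seed=seed, n_replicates=50,
                                 planted_edges=[(10, 11, 0.9, 1)],
                                 hub_taxa={}, trend_assignments={}, n_taxa=40)
            table, design, _ = generate_counts(spec)
            props = relative_abundance(table)
            ids = spec.taxon_ids()
            r = stats.spearmanr(props.loc[ids[10]], props.loc[ids[11]]).statistic
            hits += r > 0.6
        assert hits >= 14

    def test_truth_reports_pd_distortion(self):
        _, _, truth = generate_counts(SyntheticSpec(seed=0))
        assert truth["max_pd_distortion"] <= 0.05


class TestMetabolites:
    def test_determinism(self, default_study):
        spec = SyntheticSpec(seed=7)
        again = generate_study(spec)
        pd.testing.assert_frame_equal(again.metabolites.table,
                                      default_study.metabolites.table)

    def test_truth_references_existing_features(self, default_study):
        feats = set(default_study.metabolites.traits)
        taxa = set(default_study.counts.taxa)
        for rec in default_study.truth["differential_metabolites"]:
            assert rec["metabolite"] in feats
        for rec in default_study.truth["linked_metabolites"]:
            assert rec["metabolite"] in feats and rec["taxon"] in taxa

    def test_linked_metabolite_correlates_with_taxon(self, default_study):
        props = relative_abundance(default_study.counts)
        for rec in default_study.truth["linked_metabolites"]:
            y = default_study.metabolites.table[rec["metabolite"]]
            x = props.loc[rec["taxon"], y.index]
            res = stats.spearmanr(x, y)
            assert res.pvalue < 0.05 and res.statistic > 0


class TestEdgeRecoveryMonotonicity:
    def test_recovery_non_decreasing_in_replicates(self):
        from rhizonet.network import EdgeRule, networks_per_scope
        mean_rec = []
        for n_rep in (6, 12, 36):
            recs = []
            for seed in range(4):
                spec = SyntheticSpec(seed=seed, n_replicates=n_rep)
                table, design, truth = generate_counts(spec)
                g = networks_per_scope(table, design,
                                       EdgeRule(scope="global"))["global"]
                recs.append(sum(g.has_edge(a, b) for (a, b, _r, _s)
                                in truth["planted_edges"]))
            mean_rec.append(np.mean(recs))
        assert mean_rec[0] <= mean_rec[1] + 1e-9 <= mean_rec[2] + 2e-9


def test_write_study_emits_all_files(tmp_path, default_study):
    paths = write_study(default_study, tmp_path)
    for key in ("counts", "design", "physiology", "metabolites", "truth"):
        assert (tmp_path / f"{key}.{'json' if key == 'truth' else 'tsv'}").exists(), key
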