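"""Generators: planted effects are measurable and outputs reproducible."""

import numpy as np
import pytest
from scipy import stats

from netmark.synth import (
    ConfigError,
    SynthConfig,
    make_coexpr_data,
    make_expression,
    make_network,
    make_qpcr,
    make_survival,
)


class TestExpression:
    def test_planted_shift_measurable(self):
        cfg = SynthConfig(
            n_genes=5, n_case=50, n_ctrl=50, deg_fraction=0.2,
            planted_logfc=2.0, noise_sd=0.01, seed=3,
        )
        m, truth = make_expression(cfg)
        assert len(truth.deg_genes) == 1
        gene, sign = next(iter(truth.deg_genes.items()))
        case = m.values.loc[gene, m.samples_in_group("case")]
        ctrl = m.values.loc[gene, m.samples_in_group("control")]
        assert case.mean() - ctrl.mean() == pytest.approx(2.0 * sign, abs=0.02)

    def test_zero_fraction_plants_nothing(self):
        m, truth = make_expression(SynthConfig(n_genes=20, deg_fraction=0.0, seed=0))
        assert truth.deg_genes == {}

    def test_seeded_determinism(self):
        cfg = SynthConfig(n_genes=30, seed=11)
        a, ta = make_expression(cfg)
        b, tb = make_expression(cfg)
        assert a.values.equals(b.values) and ta.deg_genes == tb.deg_genes

    def test_truth_genes_exist_in_matrix(self):
        m, truth = make_expression(SynthConfig(n_genes=100, deg_fraction=0.1, seed=5))
        assert set(truth.deg_genes) <= set(m.genes)

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="noise_sd"):
            make_expression(SynthConfig(noise_sd=-1.0))
        with pytest.raises(ConfigError, match="deg_fraction"):
            make_expression(SynthConfig(deg_fraction=1.5))


class TestNetwork:
    def test_tree_edge_count_with_single_attachment(self):
        net, _ = make_network(SynthConfig(n_genes=5, hub_count=1, seed=0), m=1)
        assert net.number_of_edges() == 4
        assert net.number_of_nodes() == 5

    def test_hub_truth_contains_max_degree_node(self):
        net, truth = make_network(SynthConfig(n_genes=100, hub_count=6, seed=2))
        max_deg = max(dict(net.degree()).values())
        assert any(net.degree(h) == max_deg for h in truth.hub_genes)

    def test_degree_sequence_heavy_tailed(self):
        net, _ = make_network(SynthConfig(n_genes=2000, hub_count=6, seed=1))
        degrees = np.array([d for _, d in net.degree()], dtype=float)
        assert stats.skew(degrees) > 0

    def test_simple_graph(self):
        net, _ = make_network(SynthConfig(n_genes=300, hub_count=5, seed=4))
        assert all(a != b for a, b in net.edges())

    def test_hub_count_exceeding_genes_rejected(self):
        with pytest.raises(ConfigError, match="hub_count"):
            make_network(SynthConfig(n_genes=3, hub_count=5))


class TestCoexpr:
    def test_tight_module_highly_correlated(self):
        cfg = SynthConfig(
            n_genes=20, module_size=5, module_loading=1.0, noise_sd=0.01, seed=7
        )
        m, truth = make_coexpr_data(cfg, "G0001", n_samples=200)
        members = sorted(truth.module_genes)
        sub = m.values.loc[members].T.corr()
        off_diag = sub.to_numpy()[~np.eye(len(members), dtype=bool)]
        assert off_diag.min() > 0.95

    def test_non_module_pairs_uncorrelated(self):
        cfg = SynthConfig(n_genes=20, module_size=5, seed=8)
        m, truth = make_coexpr_data(cfg, "G0001", n_samples=200)
        non = [g for g in m.genes if g not in truth.module_genes][:5]
        corr = m.values.loc[non].T.corr().to_numpy()
        assert np.abs(corr[~np.eye(len(non), dtype=bool)]).max() < 0.2

    def test_determinism_and_seed_in_module(self):
        cfg = SynthConfig(n_genes=15, module_size=4, seed=9)
        a, ta = make_coexpr_data(cfg, "G0003", n_samples=50)
        b, tb = make_coexpr_data(cfg, "G0003", n_samples=50)
        assert a.values.equals(b.values)
        assert "G0003" in ta.module_genes and ta.module_genes == tb.module_genes


class TestSurvival:
    def test_null_hazard_gives_equal_group_means(self):
        cfg = SynthConfig(hazard_beta=0.0, censor_rate=0.0, seed=10)
        t = make_survival(cfg, n_subjects=2000)
        high = t[t.expression > t.expression.median()]
        low = t[t.expression <= t.expression.median()]
        assert abs(high.time.mean() / low.time.mean() - 1) < 0.10

    def test_no_censoring_all_events(self):
        t = make_survival(SynthConfig(censor_rate=0.0, seed=1), n_subjects=100)
        assert (t.event == 1).all()

    def test_hazard_ratio_two_doubles_event_rate(self):
        cfg = SynthConfig(hazard_beta=np.log(2), censor_rate=0.0, seed=12)
        t = make_survival(cfg, n_subjects=2000)
        high = t.expression > t.expression.median()
        rate_high = 1.0 / t.time[high].mean()
        rate_low = 1.0 / t.time[~high].mean()
        assert rate_high / rate_low == pytest.approx(2.0, rel=0.15)

    def test_bad_censor_rate_rejected(self):
        with pytest.raises(ConfigError, match="censor_rate"):
            make_survival(SynthConfig(censor_rate=1.0))


class TestQpcr:
    def test_planted_one_cycle_shift_doubles_fold(self):
        from netmark.qpcr import delta_delta_ct, group_fold_summary

        cfg = SynthConfig(seed=13)
        t = make_qpcr(cfg, {"ref": 0.0, "case": -1.0}, n_per_group=10, ct_sd=0.01)
        folds = group_fold_summary(delta_delta_ct(t, "ref"))
        case_fold = folds.loc[folds.group == "case", "mean_fold"].item()
        assert case_fold == pytest.approx(2.0, rel=0.02)

    def test_equal_shifts_give_unit_folds(self):
        from netmark.qpcr import delta_delta_ct, group_fold_summary

        t = make_qpcr(SynthConfig(seed=14), {"a": 0.5, "b": 0.5}, ct_sd=0.01)
        folds = group_fold_summary(delta_delta_ct(t, "a"))
        assert np.allclose(folds.mean_fold, 1.0, atol=0.05)

    def test_determinism_and_group_validation(self):
        cfg = SynthConfig(seed=15)
        a = make_qpcr(cfg, {"x": 0.0, "y": 1.0})
        b = make_qpcr(cfg, {"x": 0.0, "y": 1.0})
        assert a.equals(b)
        with pytest.raises(ConfigError, match="2 groups"):
            make_qpcr(cfg, {"only": 0.0})
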