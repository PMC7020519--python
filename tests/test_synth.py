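import dataclasses
import math

import numpy as np
import pytest
from scipy import stats as sps

import cyclegrn as cg
from cyclegrn.classify import NO_PHASE, PHASES
from cyclegrn.dynamics import SinusoidForcing
from cyclegrn.synth import phase_offset


def base_config(**kw):
    defaults = dict(
        seed=4, n_tfs=20, n_genes=200, out_degree_mean=10, n_datasets=2,
        pairwise_overlap_target=0.2, planted_ffl_count=5,
        phase_sizes={"G1": 12, "S": 6, "S-G2": 6, "G2-M": 8, "M-G1": 6},
        n_phase_tfs=10, tf_phase_effect=0.5, noise_sd=0.05,
    )
    defaults.update(kw)
    return cg.SynthConfig(**defaults)


class TestGRNCollection:
    def test_single_dataset_degenerate(self):
        grns, _ = cg.generate_grn_collection(base_config(n_datasets=1))
        assert len(grns) == 1

    def test_full_overlap_target_gives_identical_datasets(self):
        cfg = base_config(pairwise_overlap_target=1.0, planted_ffl_count=0,
                          n_datasets=3)
        grns, _ = cg.generate_grn_collection(cfg)
        assert grns[0].interactions == grns[1].interactions == grns[2].interactions
        assert cg.pairwise_overlap(grns[0], grns[1])[1] == 1.0

    def test_mean_realized_overlap_matches_target(self):
        # Monte-Carlo calibration of the shared-core construction
        target = 0.3
        vals = []
        for rep in range(300):
            cfg = cg.SynthConfig(seed=rep, n_tfs=50, n_genes=500,
                                 out_degree_mean=20, n_datasets=2,
                                 pairwise_overlap_target=target,
                                 planted_ffl_count=0)
            grns, _ = cg.generate_grn_collection(cfg)
            vals.append(cg.pairwise_overlap(grns[0], grns[1])[1])
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean() - target) < 3 * se

    def test_unattainable_target_errors(self):
        # chance overlap of dense networks exceeds a near-zero target
        cfg = base_config(n_genes=30, n_tfs=10, out_degree_mean=20,
                          pairwise_overlap_target=0.0, planted_ffl_count=0,
                          phase_sizes={"G1": 5})
        with pytest.raises(ValueError, match="chance overlap"):
            cg.generate_grn_collection(cfg)

    def test_deterministic_under_seed(self, tmp_path):
        cfg = base_config()
        a = cg.generate_collection(cfg)
        b = cg.generate_collection(dataclasses.replace(cfg))
        cg.write_collection(a, tmp_path / "a")
        cg.write_collection(b, tmp_path / "b")
        for fa in sorted((tmp_path / "a").iterdir()):
            fb = tmp_path / "b" / fa.name
            assert fa.read_bytes() == fb.read_bytes()


class TestPhaseLabels:
    def test_all_zero_sizes(self):
        labels = cg.generate_phase_labels(base_config(
            phase_sizes={p: 0 for p in PHASES}))
        assert set(labels.assignment.values()) == {NO_PHASE}

    def test_exact_sizes_at_printed_range_endpoints(self):
        cfg = base_config(n_genes=500,
                          phase_sizes={"G1": 300, "M-G1": 71})
        labels = cg.generate_phase_labels(cfg)
        assert len(labels.genes_of("G1")) == 300
        assert len(labels.genes_of("M-G1")) == 71

    def test_phases_disjoint(self):
        labels = cg.generate_phase_labels(base_config())
        sets = [labels.genes_of(p) for p in PHASES]
        union = set().union(*sets)
        assert len(union) == sum(len(s) for s in sets)

    def test_oversized_request_errors(self):
        with pytest.raises(ValueError):
            base_config(n_genes=10, phase_sizes={"G1": 20})


class TestExpression:
    def test_noise_free_peak_at_phase_offset(self):
        cfg = base_config(noise_sd=0.0)
        labels = cg.generate_phase_labels(cfg)
        expr = cg.generate_expression(labels, cfg)
        times = np.array(expr.columns, dtype=float)
        gene = sorted(labels.genes_of("G2-M"))[0]
        first_period = times <= cfg.period_minutes
        tr = expr.loc[gene].to_numpy()[first_period]
        peak_t = times[first_period][np.argmax(tr)]
        assert peak_t == pytest.approx(
            phase_offset("G2-M", cfg.period_minutes), abs=np.diff(times)[0])

    def test_traces_normalized_to_unit_interval(self, small_collection):
        expr = small_collection.expression
        assert np.allclose(expr.min(axis=1), 0.0)
        assert np.allclose(expr.max(axis=1), 1.0)

    def test_phase_order_recoverable_from_peak_times(self):
        cfg = base_config(n_genes=500, noise_sd=0.05, seed=8,
                          phase_sizes={p: 40 for p in PHASES})
        labels = cg.generate_phase_labels(cfg)
        expr = cg.generate_expression(labels, cfg)
        times = np.array(expr.columns, dtype=float)
        period = cfg.period_minutes
        first = times <= period
        idx, peaks = [], []
        for phase in PHASES:
            for g in labels.genes_of(phase):
                idx.append(PHASES.index(phase))
                peak = times[first][np.argmax(expr.loc[g].to_numpy()[first])]
                # peak time is circular: recentre so the earliest phase's
                # peak (t≈0 ≡ t≈period) maps to a single cluster
                peaks.append((peak + period / 10) % period - period / 10)
        rho = sps.spearmanr(idx, peaks).statistic
        assert rho > 0.95

    def test_too_few_timepoints_error(self):
        cfg = base_config(n_timepoints=3)
        labels = cg.generate_phase_labels(cfg)
        with pytest.raises(ValueError):
            cg.generate_expression(labels, cfg)


class TestPlantedSignal:
    def test_zero_effect_leaves_grns_unchanged(self):
        cfg = base_config(tf_phase_effect=0.0, planted_ffl_count=0)
        grns, truth = cg.generate_grn_collection(cfg)
        labels = cg.generate_phase_labels(cfg)
        planted, _ = cg.plant_tf_phase_signal(grns, labels, cfg)
        for g0, g1 in zip(grns, planted):
            assert g0.interactions == g1.interactions

    def test_full_effect_zero_background_deterministic_limit(self):
        cfg = base_config(tf_phase_effect=1.0)
        labels = cg.generate_phase_labels(cfg)
        empty = [cg.GRN("bg0", frozenset())]
        planted, truth = cg.plant_tf_phase_signal(empty, labels, cfg)
        for tf, phase in truth.tf_phase_map.items():
            assert planted[0].targets_of(tf) == labels.genes_of(phase)
        linked = set(truth.tf_phase_map)
        assert {e[0] for e in planted[0].interactions} <= linked

    def test_in_phase_targeting_exceeds_background(self):
        cfg = base_config(tf_phase_effect=0.4, n_phase_tfs=10,
                          planted_ffl_count=0)
        grns, truth = cg.generate_grn_collection(cfg)
        labels = cg.generate_phase_labels(cfg)
        planted, truth = cg.plant_tf_phase_signal(grns, labels, cfg, truth)
        in_frac, out_frac = [], []
        for tf, phase in truth.tf_phase_map.items():
            targets = planted[0].targets_of(tf)
            inset = labels.genes_of(phase)
            outset = set().union(*(labels.genes_of(p) for p in PHASES
                                   if p != phase))
            in_frac.append(len(targets & inset) / len(inset))
            out_frac.append(len(targets & outset) / len(outset))
        assert np.mean(in_frac) > np.mean(out_frac)


class TestFFLTimecourses:
    def test_pure_decay_closed_form(self):
        t = np.linspace(0, 5, 30)
        forcing = SinusoidForcing(0.0, 10.0, 0.0, 0.0)
        model = cg.ODEFFLModel(alpha_S=-1.0, alpha_T=-0.5, beta_ST=0.0,
                               beta_PS=0.0, beta_PT=0.0, S0=1.0, T0=0.0)
        _, S, T = cg.simulate_ffl_timecourses(model, forcing, t, 0.0, 0)
        assert np.allclose(S, np.exp(-t))
        assert np.allclose(T, 0.0)

    def test_noise_free_matches_solver(self):
        t = np.linspace(0, 250, 40)
        forcing = SinusoidForcing(0.5, 125.0, 0.2, 0.6)
        params = dict(alpha_S=-0.05, alpha_T=-0.08, beta_ST=0.04,
                      beta_PS=0.06, beta_PT=0.03)
        _, S, T = cg.simulate_ffl_timecourses(params, forcing, t, 0.0, 0)
        model = cg.ODEFFLModel(**params, forcing=forcing, S0=0.0, T0=0.0)
        S2, T2 = cg.solve(model, t)
        assert np.array_equal(S, S2) and np.array_equal(T, T2)

    def test_seeded_reruns_identical(self):
        t = np.linspace(0, 100, 20)
        forcing = SinusoidForcing(1.0, 50.0)
        params = dict(alpha_S=-0.1, alpha_T=-0.1, beta_ST=0.05,
                      beta_PS=0.05, beta_PT=0.05)
        a = cg.simulate_ffl_timecourses(params, forcing, t, 0.1, 42)
        b = cg.simulate_ffl_timecourses(params, forcing, t, 0.1, 42)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_non_increasing_times_error(self):
        with pytest.raises(ValueError):
            cg.simulate_ffl_timecourses(
                dict(alpha_S=-1, alpha_T=-1, beta_ST=0, beta_PS=0, beta_PT=0),
                SinusoidForcing(1.0, 10.0), np.array([0.0, 1.0, 1.0]), 0.0, 0)
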