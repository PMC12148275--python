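"""Synthetic cohort generator: determinism, point-process behavior, truth."""
import math

import numpy as np
import pandas as pd
import pytest

from spatialtil import (
    ConfigurationError,
    ContingencyTable2x2,
    SimulationConfig,
    nearest_neighbor_distances,
    odds_ratio_2x2,
    simulate_cohort,
    simulate_core,
    simulate_labels,
    simulate_survival,
    substream,
)


def _core_config(**kw):
    base = dict(n_participants=1, cores_per_participant=1, tumor_intensity=300,
                lymphocyte_intensity=60, stroma_intensity=50, seed=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateCore:
    def test_same_seed_identical_rows(self):
        cfg = _core_config(seed=9)
        a = simulate_core(cfg, "p", "c", substream(9, 0, 0, 0))
        b = simulate_core(cfg, "p", "c", substream(9, 0, 0, 0))
        pd.testing.assert_frame_equal(a, b)

    def test_zero_lymphocyte_intensity(self):
        cfg = _core_config(lymphocyte_intensity=0)
        core = simulate_core(cfg, "p", "c", substream(0, 0, 0, 0))
        assert set(core["true_class"]) <= {"tumor", "unclassified"}

    def test_all_coordinates_inside_disc(self):
        cfg = _core_config(infiltration_mode="hotspot")
        core = simulate_core(cfg, "p", "c", substream(3, 0, 0, 0))
        r = np.hypot(core["x_um"], core["y_um"])
        assert (r <= cfg.core_radius + 1e-9).all()

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ConfigurationError):
            _core_config(tumor_intensity=0)
        with pytest.raises(ConfigurationError):
            _core_config(lymphocyte_intensity=-1)

    def test_diffuse_proximity_exceeds_hotspot(self):
        """Clustered infiltration leaves distant tumor cells; homogeneous
        infiltration covers the core, so mean proximity is higher.
        Monte-Carlo over 100 seeded replicates per mode."""
        def mean_prox(mode):
            vals = []
            for seed in range(100):
                cfg = _core_config(infiltration_mode=mode, seed=seed)
                core = simulate_core(cfg, "p", "c", substream(seed, 0, 0, 0))
                tum = core.loc[core.true_class == "tumor", ["x_um", "y_um"]].to_numpy()
                cd8 = core.loc[core.true_class == "cd8", ["x_um", "y_um"]].to_numpy()
                d = nearest_neighbor_distances(tum, cd8)
                vals.append(3 - np.log10(d).mean())
            return np.mean(vals)

        assert mean_prox("diffuse") > mean_prox("hotspot")

    def test_peripheral_mode_pushes_lymphocytes_outward(self):
        radii = {}
        for mode in ("diffuse", "peripheral"):
            rs = []
            for seed in range(30):
                cfg = _core_config(infiltration_mode=mode, lymphocyte_intensity=150, seed=seed)
                core = simulate_core(cfg, "p", "c", substream(seed, 0, 0, 0))
                lym = core[core.true_class.isin(["cd8", "treg", "foxp3_only"])]
                rs.append(np.hypot(lym.x_um, lym.y_um).mean())
            radii[mode] = np.mean(rs)
        assert radii["peripheral"] > radii["diffuse"]


class TestSimulateSurvival:
    def test_determinism_and_positive_times(self):
        binary = pd.DataFrame({"proximity": ["high", "low"] * 50},
                              index=pd.Index([f"p{i}" for i in range(100)], name="participant_id"))
        cfg = SimulationConfig(n_participants=100, seed=4)
        a = simulate_survival(binary, cfg)
        b = simulate_survival(binary, cfg)
        pd.testing.assert_frame_equal(a, b)
        assert (a["time"] > 0).all()

    def test_low_group_has_higher_event_rate(self, rng):
        n = 4000
        binary = pd.DataFrame({"proximity": np.where(rng.random(n) < 0.5, "low", "high")},
                              index=pd.Index([f"p{i}" for i in range(n)], name="participant_id"))
        cfg = SimulationConfig(n_participants=n, survival_betas={"proximity": math.log(3)}, seed=0)
        surv = simulate_survival(binary, cfg, rng=rng).set_index("participant_id")
        low_rate = surv.loc[binary.proximity == "low", "event"].mean()
        high_rate = surv.loc[binary.proximity == "high", "event"].mean()
        assert low_rate > high_rate

    def test_infinite_censor_rate_censors_everything(self, rng):
        binary = pd.DataFrame({"proximity": ["high"] * 50},
                              index=pd.Index([f"p{i}" for i in range(50)], name="participant_id"))
        cfg = SimulationConfig(n_participants=50, censor_rate=1e9, seed=0)
        surv = simulate_survival(binary, cfg, rng=rng)
        assert surv["event"].sum() == 0


class TestSimulateLabels:
    @staticmethod
    def _table(binary, labels, cfg):
        merged = binary.join(labels.set_index("participant_id"))
        c1 = merged[cfg.label_name] == cfg.label_classes[0]
        hi = merged["proximity"] == "high"
        return ContingencyTable2x2(int((c1 & hi).sum()), int((c1 & ~hi).sum()),
                                   int((~c1 & hi).sum()), int((~c1 & ~hi).sum()))

    def _binary(self, rng, n):
        return pd.DataFrame({"proximity": np.where(rng.random(n) < 0.5, "high", "low")},
                            index=pd.Index([f"p{i}" for i in range(n)], name="participant_id"))

    def test_null_log_odds_or_near_one(self, rng):
        binary = self._binary(rng, 1000)
        cfg = SimulationConfig(n_participants=1000, label_log_odds={"proximity": 0.0}, seed=0)
        res = odds_ratio_2x2(self._table(binary, simulate_labels(binary, cfg, rng=rng), cfg))
        assert res.ci_lower <= 1.0 <= res.ci_upper

    def test_recovers_designed_odds_ratio(self, rng):
        binary = self._binary(rng, 5000)
        cfg = SimulationConfig(n_participants=5000,
                               label_log_odds={"proximity": math.log(4.9)}, seed=0)
        res = odds_ratio_2x2(self._table(binary, simulate_labels(binary, cfg, rng=rng), cfg))
        assert 4.0 <= res.odds_ratio <= 6.0

    def test_deterministic_labels_flagged_degenerate(self, rng):
        binary = self._binary(rng, 200)
        cfg = SimulationConfig(n_participants=200,
                               label_log_odds={"proximity": 1e9}, seed=0)
        tab = self._table(binary, simulate_labels(binary, cfg, rng=rng), cfg)
        res = odds_ratio_2x2(tab, method="conditional_mle")
        assert res.degenerate and not np.isfinite(res.odds_ratio)


class TestCohort:
    def test_identical_seed_identical_cohort(self, small_cohort):
        again = simulate_cohort(small_cohort.config, qc_min_tumor=50, qc_min_total=100)
        pd.testing.assert_frame_equal(again.cells, small_cohort.cells)
        pd.testing.assert_frame_equal(again.survival, small_cohort.survival)
        pd.testing.assert_frame_equal(again.labels, small_cohort.labels)
        pd.testing.assert_frame_equal(again.truth, small_cohort.truth)

    def test_every_participant_has_cells_and_records(self, small_cohort):
        pids = set(small_cohort.cells["participant_id"])
        assert set(small_cohort.survival["participant_id"]) <= pids
        assert set(small_cohort.labels["participant_id"]) <= pids

    def test_truth_matches_independent_recomputation(self, small_cohort):
        """Brute-force per-core NND on the true classes reproduces the
        truth table's proximity/consistency."""
        from scipy.spatial.distance import cdist

        cells = small_cohort.cells
        row = small_cohort.truth.iloc[0]
        pid = row["participant_id"]
        dists = []
        for _, core in cells[cells.participant_id == pid].groupby("core_id"):
            tum = core.loc[core.true_class == "tumor", ["x_um", "y_um"]].to_numpy()
            cd8 = core.loc[core.true_class == "cd8", ["x_um", "y_um"]].to_numpy()
            if len(cd8) == 0:
                dists.extend([1000.0] * len(tum))
            else:
                dists.extend(np.minimum(cdist(tum, cd8).min(axis=1), 1000.0))
        logs = np.log10(dists)
        assert row["proximity"] == pytest.approx(3 - logs.mean(), abs=1e-9)
        assert row["consistency"] == pytest.approx(1 - logs.var(ddof=1), abs=1e-9)

    @pytest.mark.parametrize("mode,lymph", [("diffuse", 60), ("hotspot", 60),
                                            ("peripheral", 60), ("diffuse", 0)])
    def test_spatial_pipeline_closure(self, mode, lymph):
        """Classify -> QC -> metrics raises nothing for any infiltration
        mode, including zero lymphocytes (all NNDs at the cap)."""
        from spatialtil import classify_cells, cohort_metrics, qc_filter_cores, summarize_cores

        cfg = SimulationConfig(n_participants=4, cores_per_participant=2,
                               tumor_intensity=200, lymphocyte_intensity=lymph,
                               stroma_intensity=50, infiltration_mode=mode, seed=7)
        cohort = simulate_cohort(cfg, qc_min_tumor=50, qc_min_total=100)
        classified = classify_cells(cohort.cells, cfg.matched_thresholds)
        summ = qc_filter_cores(summarize_cores(classified), min_tumor=50, min_total=100)
        metrics, _ = cohort_metrics(classified, summ)
        assert len(metrics) == 4
        if lymph == 0:
            # true classes: every NND sits at the cap, so proximity is 0
            assert (cohort.truth["proximity"].abs() <= 1e-9).all()
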