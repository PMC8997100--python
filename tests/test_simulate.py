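"""The synthetic cohort generator and its designed ground truth."""

import numpy as np
import pandas as pd
import pytest

from maaspenn.metadata import encode_pair, encode_pairs, encodings_to_frame
from maaspenn.reproducibility import (
    intersect_reproducible,
    pairwise_reproducibility,
    scenario_reproducibility,
)
from maaspenn.combat import harmonize_pair
from maaspenn.simulate import (
    GeneratorConfig,
    generate_metadata,
    ground_truth,
    simulate_dataset,
    simulate_experiment,
    simulate_feature_table,
)

QUIET = GeneratorConfig(  # all acquisition effects off
    effect_sizes=tuple((p, 0.0) for p, _ in GeneratorConfig().effect_sizes),
    noise_sd=0.0,
    n_scans=6,
)


class TestMetadataGeneration:
    def test_n_scans_and_determinism(self):
        cfg = GeneratorConfig(n_scans=25, seed=3)
        scans1 = generate_metadata(cfg)
        scans2 = generate_metadata(cfg)
        assert len(scans1) == 25
        assert scans1 == scans2
        assert len({s.scan_id for s in scans1}) == 25

    def test_values_drawn_from_pools(self):
        cfg = GeneratorConfig(n_scans=30, seed=4)
        kernels = {k for k, _ in cfg.kernels}
        for s in generate_metadata(cfg):
            assert s.vendor in cfg.vendors
            assert s.kernel in kernels
            assert s.slice_thickness in cfg.slice_thicknesses
            assert (s.vendor, s.model) in cfg.models

    def test_single_level_pools_encode_to_all_ones(self):
        cfg = GeneratorConfig(
            n_scans=4, seed=5,
            vendors=("GE",), models=(("GE", "LightSpeed16"),),
            kernels=(("STANDARD", 2.0),),
            tube_currents=(200.0,), exposures=(160.0,), exposure_times=(750.0,),
            slice_thicknesses=(2.5,), pixel_spacings=(0.68,),
        )
        scans = generate_metadata(cfg)
        encs = encode_pairs(scans, cfg.kernel_schema())
        for enc in encs:
            assert all(v == 1.0 for v in enc.values.values())

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            GeneratorConfig(noise_sd=-0.1)


class TestFeatureTables:
    def test_shape_and_determinism(self):
        cfg = GeneratorConfig(n_scans=3, seed=6)
        (meta,) = generate_metadata(cfg)[:1]
        t1, truth = simulate_feature_table(meta, cfg)
        t2, _ = simulate_feature_table(meta, cfg)
        assert t1.frame.shape == (160, 91)
        pd.testing.assert_frame_equal(t1.frame, t2.frame)
        assert set(truth.insensitive_features) <= set(t1.frame.columns)

    def test_insensitive_features_carry_zero_beta(self):
        truth = ground_truth(GeneratorConfig(seed=7))
        assert len(truth.insensitive_features) == 4
        assert (truth.beta.loc[list(truth.insensitive_features)] == 0).all().all()
        sensitive = truth.beta.drop(index=list(truth.insensitive_features))
        assert (sensitive.sum(axis=1) > 0).all()

    def test_all_effects_off_gives_perfect_concordance(self):
        ds = simulate_dataset(QUIET)
        out = pairwise_reproducibility(list(ds.tables.values()))
        assert (out["pct_reproducible"] == 100.0).all()


class TestDesignedStructure:
    def test_kernel_difference_drives_reproducibility(self):
        # only the kernel distorts; same-kernel pairs must beat different-kernel ones
        cfg = GeneratorConfig(seed=8, n_scans=20).with_effects(
            slice_thickness=0.0, pixel_spacing=0.0,
            tube_current=0.0, exposure=0.0, exposure_time=0.0,
        )
        frame, _ = simulate_experiment(cfg)
        same = frame[frame["kernel"] == 1.0]["pct_reproducible"]
        worst = frame[frame["kernel"] == frame["kernel"].min()]["pct_reproducible"]
        assert same.mean() > worst.mean() + 20

    def test_raising_an_effect_lowers_reproducibility(self):
        for seed in (1, 2):
            weak, _ = simulate_experiment(
                GeneratorConfig(seed=seed, n_scans=15).with_effects(slice_thickness=0.1)
            )
            strong, _ = simulate_experiment(
                GeneratorConfig(seed=seed, n_scans=15).with_effects(slice_thickness=1.2)
            )
            differing = weak["slice_thickness"] < 1.0
            assert (
                strong.loc[differing, "pct_reproducible"].mean()
                < weak.loc[differing, "pct_reproducible"].mean()
            )

    def test_extreme_cohort_isolates_designed_insensitive_features(self):
        # a cohort covering the extremes of every resolution parameter, with
        # distortions strong enough that every sensitive feature fails somewhere
        cfg = GeneratorConfig(seed=9, noise_sd=0.01).with_effects(
            kernel=1.5, slice_thickness=1.2, pixel_spacing=1.0,
            tube_current=0.0, exposure=0.0, exposure_time=0.0,
        )
        base = generate_metadata(GeneratorConfig(seed=9, n_scans=1))[0]
        variants = []
        for i, overrides in enumerate([
            {},
            {"kernel": "SOFT"},
            {"kernel": "B70f"},
            {"slice_thickness": 0.625},
            {"slice_thickness": 5.0},
            {"pixel_spacing": 0.39},
            {"pixel_spacing": 0.98},
        ]):
            d = {**base.__dict__, **overrides, "scan_id": f"scan{i:03d}"}
            from maaspenn.metadata import ScanMetadata
            variants.append(ScanMetadata(**d))
        tables = [
            simulate_feature_table(m, cfg, scan_index=i)[0]
            for i, m in enumerate(variants)
        ]
        results = [
            scenario_reproducibility(tables[i], tables[j])
            for i in range(len(tables))
            for j in range(i + 1, len(tables))
        ]
        truth = ground_truth(cfg)
        assert intersect_reproducible(results) == set(truth.insensitive_features)

    def test_combat_gains_in_favorable_regime(self):
        cfg = GeneratorConfig(seed=10, n_scans=8)
        ds = simulate_dataset(cfg)
        ids = [s.scan_id for s in ds.scans]
        gains = []
        for a, b in [(0, 1), (2, 3), (4, 5), (6, 7)]:
            ta, tb = ds.tables[ids[a]], ds.tables[ids[b]]
            before = scenario_reproducibility(ta, tb).n_reproducible
            ha, hb = harmonize_pair(ta, tb)
            after = scenario_reproducibility(ha, hb).n_reproducible
            # location/scale-only distortions: ComBat can only help
            assert after >= before
            gains.append(after - before)
        assert sum(gains) > 0

    def test_adverse_regime_resists_combat(self):
        favorable = GeneratorConfig(seed=11, n_scans=6)
        adverse = GeneratorConfig(seed=11, n_scans=6, combat_adverse=True,
                                  adverse_strength=2.0)
        def mean_gain(cfg):
            ds = simulate_dataset(cfg)
            ids = [s.scan_id for s in ds.scans]
            gain = []
            for a, b in [(0, 1), (2, 3), (4, 5)]:
                ta, tb = ds.tables[ids[a]], ds.tables[ids[b]]
                before = scenario_reproducibility(ta, tb).n_reproducible
                ha, hb = harmonize_pair(ta, tb)
                gain.append(scenario_reproducibility(ha, hb).n_reproducible - before)
            return np.mean(gain)
        assert mean_gain(adverse) < mean_gain(favorable)


class TestExperimentFrame:
    def test_columns_and_pair_count(self):
        frame, ds = simulate_experiment(GeneratorConfig(n_scans=10, seed=12))
        assert len(frame) == 45
        for col in ("kernel", "slice_thickness", "pixel_spacing",
                    "pct_reproducible", "n_reproducible"):
            assert col in frame.columns
        assert frame["pct_reproducible"].between(0, 100).all()
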