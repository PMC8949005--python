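"""Generators: planted correlation blocks, exact odds ratios, SIP shifts."""

import numpy as np
import pandas as pd
import pytest

from pomnet.exceptions import InvalidConfigError
from pomnet.synthetic import (SyntheticConfig, default_lifestyle_effects,
                              generate_lifestyle_pairs,
                              generate_modular_table, generate_sip_profiles,
                              read_truth, write_truth)


class TestModularTable:
    def test_seeded_runs_bit_identical(self):
        cfg = SyntheticConfig(seed=42, n_otus=30, n_samples_per_group=8)
        t1, _ = generate_modular_table(cfg)
        t2, _ = generate_modular_table(cfg)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)

    def test_column_sums_equal_sequencing_depth(self):
        cfg = SyntheticConfig(seed=0, n_otus=40, n_samples_per_group=6,
                              sequencing_depth=5000)
        t, _ = generate_modular_table(cfg)
        assert (t.sample_sums() == 5000).all()

    def test_single_module_truth(self):
        cfg = SyntheticConfig(seed=1, n_otus=20, n_modules=1,
                              within_module_correlation=0.5,
                              n_samples_per_group=5)
        _, truth = generate_modular_table(cfg)
        assert set(truth.module_of.values()) == {0}

    def test_within_module_correlation_exceeds_between(self):
        """Planted |r| structure verified on the realized count table."""
        cfg = SyntheticConfig(seed=3, n_otus=80, n_modules=4,
                              within_module_correlation=0.9,
                              between_module_correlation=0.0,
                              n_samples_per_group=30)
        t, truth = generate_modular_table(cfg)
        rel = (t.counts / t.counts.sum(axis=0)).to_numpy()
        r = np.corrcoef(rel)
        mods = np.array([truth.module_of[o] for o in t.otu_ids])
        same = mods[:, None] == mods[None, :]
        off = ~np.eye(len(mods), dtype=bool)
        assert (np.abs(r[same & off]).mean()
                > np.abs(r[~same]).mean() + 0.2)

    def test_too_many_modules_rejected(self):
        with pytest.raises(InvalidConfigError, match="n_modules"):
            generate_modular_table(SyntheticConfig(n_otus=5, n_modules=6))

    def test_truth_covers_every_otu(self):
        cfg = SyntheticConfig(seed=2, n_otus=25, n_samples_per_group=4)
        t, truth = generate_modular_table(cfg)
        assert set(truth.module_of) == set(t.otu_ids)
        assert truth.hub_otus <= set(t.otu_ids)
        assert truth.incorporators <= set(t.otu_ids)


class TestLifestylePairs:
    @staticmethod
    def _estimated_or(table, otu):
        meta = table.sample_meta
        rel = table.counts / table.counts.sum(axis=0)
        pa = rel[meta.index[meta["fraction"] == "PA"]].mean(axis=1)[otu]
        fl = rel[meta.index[meta["fraction"] == "FL"]].mean(axis=1)[otu]
        return np.log10(pa / fl)

    def test_null_effect_estimates_near_zero(self):
        effects = {"OTU01": 1.0, "OTU02": -1.0}  # rest default to 0
        cfg = SyntheticConfig(seed=5, n_otus=20, n_samples_per_group=100,
                              lifestyle_effects=effects)
        t, _ = generate_lifestyle_pairs(cfg)
        assert abs(self._estimated_or(t, "OTU10")) < 0.05

    def test_unit_effect_recovered_within_tenth(self):
        """Configured +1 recovered to ±0.1 over 100 replicate pairs."""
        effects = {"OTU01": 1.0, "OTU02": -1.0}
        cfg = SyntheticConfig(seed=6, n_otus=20, n_samples_per_group=100,
                              sequencing_depth=50000,
                              lifestyle_effects=effects)
        t, _ = generate_lifestyle_pairs(cfg)
        assert self._estimated_or(t, "OTU01") == pytest.approx(1.0, abs=0.1)
        assert self._estimated_or(t, "OTU02") == pytest.approx(-1.0, abs=0.1)

    def test_exclusive_fl_never_appears_in_pa_samples(self):
        effects = {"OTU01": -np.inf, "OTU02": np.inf}
        cfg = SyntheticConfig(seed=7, n_otus=10, n_samples_per_group=20,
                              lifestyle_effects=effects)
        t, truth = generate_lifestyle_pairs(cfg)
        meta = t.sample_meta
        pa_cols = meta.index[meta["fraction"] == "PA"]
        fl_cols = meta.index[meta["fraction"] == "FL"]
        assert (t.counts.loc["OTU01", pa_cols] == 0).all()
        assert (t.counts.loc["OTU02", fl_cols] == 0).all()
        assert truth.lifestyle_of["OTU01"] == "exclusive-FL"

    def test_unbalanced_effects_rejected(self):
        cfg = SyntheticConfig(n_otus=30, lifestyle_effects={
            "OTU01": 1.0, "OTU02": 2.0, "OTU03": 0.5})
        with pytest.raises(InvalidConfigError, match="balanced"):
            generate_lifestyle_pairs(cfg)

    def test_missing_effects_rejected(self):
        with pytest.raises(InvalidConfigError, match="lifestyle_effects"):
            generate_lifestyle_pairs(SyntheticConfig())

    def test_default_effects_are_balanced(self):
        cfg = SyntheticConfig(n_otus=50)
        eff = default_lifestyle_effects(cfg)
        vals = np.array(list(eff.values()))
        assert vals.sum() == pytest.approx(0.0)
        assert (vals > 0).sum() == (vals < 0).sum() > 0


class TestSipProfiles:
    @pytest.fixture
    def table_and_cfg(self):
        cfg = SyntheticConfig(seed=9, n_otus=30, n_samples_per_group=10)
        t, truth = generate_modular_table(cfg)
        return cfg, t, truth

    def test_every_fraction_normalized(self, table_and_cfg):
        cfg, t, _ = table_and_cfg
        for prof in generate_sip_profiles(cfg, t):
            for f in prof.fractions:
                assert f.abundances.sum() == pytest.approx(1.0, abs=1e-9)

    def test_center_shift_is_product_of_shift_and_atom_fraction(
            self, table_and_cfg):
        """¹³C − ¹²C peak density = 0.02 × 0.717 for incorporators."""
        cfg, t, truth = table_and_cfg
        profiles = generate_sip_profiles(cfg, t)
        by = {p.label: p for p in profiles}
        inc = sorted(truth.incorporators)[0]
        non = next(o for o in t.otu_ids if o not in truth.incorporators)

        def slope(profile, otu, ref):
            # log abundance ratio vs density is linear with slope
            # (c_otu − c_ref)/σ²; the within-fraction denominator cancels
            dens = profile.densities
            y = np.log([f.abundances[otu] / f.abundances[ref]
                        for f in profile.fractions])
            return np.polyfit(dens, y, 1)[0]

        sigma2 = cfg.profile_sigma ** 2
        shift = sigma2 * (slope(by["13C"], inc, non)
                          - slope(by["12C"], inc, non))
        expected = cfg.heavy_density_shift * cfg.label_atom_fraction_13C
        assert shift == pytest.approx(expected, rel=0.1)
        # a non-incorporator pair shows no shift between incubations
        non2 = [o for o in t.otu_ids
                if o not in truth.incorporators and o != non][0]
        null_shift = sigma2 * (slope(by["13C"], non2, non)
                               - slope(by["12C"], non2, non))
        assert abs(null_shift) < 0.1 * expected

    def test_densities_strictly_decreasing_and_in_range(self, table_and_cfg):
        cfg, t, _ = table_and_cfg
        for prof in generate_sip_profiles(cfg, t):
            d = prof.densities
            assert (np.diff(d) < 0).all()
            assert d.max() <= 1.80 and d.min() >= 1.60

    def test_grid_outside_cscl_range_rejected(self, table_and_cfg):
        cfg, t, _ = table_and_cfg
        import dataclasses
        bad = dataclasses.replace(cfg, density_bottom=1.85)
        with pytest.raises(InvalidConfigError, match="1.8"):
            generate_sip_profiles(bad, t)


def test_truth_round_trips_through_text(tmp_path):
    cfg = SyntheticConfig(seed=4, n_otus=15, n_samples_per_group=4)
    _, truth = generate_modular_table(cfg)
    write_truth(truth, tmp_path / "truth.tsv")
    back = read_truth(tmp_path / "truth.tsv")
    assert back.module_of == truth.module_of
    assert back.hub_otus == truth.hub_otus
    assert back.incorporators == truth.incorporators
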