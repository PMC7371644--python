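import numpy as np
import pytest

from gliaflow.flow_io import transform_intensities
from gliaflow.panels import panel_markers
from gliaflow.synthetic import (
    EffectModel,
    GroundTruthManifest,
    PopulationSpec,
    default_cohort,
    default_effects,
    default_populations,
    equicorrelation,
    generate_cohort,
    generate_sample,
    null_cohort,
)


def microglia_values(table, manifest, channel, cofactor=150.0):
    t = transform_intensities(table, cofactor=cofactor)
    return t.column(channel)[manifest.labels == "microglia"]


class TestValidation:
    def test_fractions_must_sum_to_one(self, m1_effects):
        pops = default_populations("M1")
        bad = [PopulationSpec(p.name, p.base_fraction * 0.5, p.channel_locations,
                              p.channel_scales, p.is_viable, p.is_singlet)
               for p in pops]
        with pytest.raises(ValueError, match="sum to 1"):
            generate_sample(bad, m1_effects[("sham", "ipsilateral")], 1000, seed=0)

    def test_non_psd_correlation_rejected(self):
        m = equicorrelation(["a", "b", "c"], 0.9)
        m.iloc[0, 1] = m.iloc[1, 0] = -0.9
        with pytest.raises(ValueError, match="positive semi-definite"):
            EffectModel(("CCI", "ipsilateral"), correlation_matrix=m)

    def test_sham_must_be_null(self):
        with pytest.raises(ValueError, match="sham"):
            EffectModel(("sham", "ipsilateral"), channel_shifts={"CD32": 0.5})

    def test_manifest_counts_must_match_labels(self, m1_effects):
        labels = np.array(["microglia"] * 3 + ["debris"])
        with pytest.raises(ValueError, match="count"):
            GroundTruthManifest(labels, {"microglia": 2, "debris": 2},
                                m1_effects[("sham", "ipsilateral")], 0)

    def test_minimum_events(self, m1_populations, m1_effects):
        with pytest.raises(ValueError, match="at least 100"):
            generate_sample(m1_populations, m1_effects[("sham", "ipsilateral")],
                            50, seed=0)


class TestGenerateSample:
    def test_determinism_under_fixed_seed(self, m1_populations, m1_effects):
        eff = m1_effects[("sham", "ipsilateral")]
        t1, m1 = generate_sample(m1_populations, eff, 1000, seed=7)
        t2, m2 = generate_sample(m1_populations, eff, 1000, seed=7)
        np.testing.assert_array_equal(t1.values, t2.values)
        np.testing.assert_array_equal(m1.labels, m2.labels)
        t3, _ = generate_sample(m1_populations, eff, 1000, seed=8)
        assert not np.array_equal(t1.values, t3.values)

    def test_realized_fraction_binomial_bound(self, m1_effects):
        # base microglia fraction 0.2, multiplier 1, n = 10,000:
        # realized count within 3*sqrt(n p (1-p)) of 2,000
        pops = default_populations("M1")
        adj = []
        for p in pops:
            if p.name == "microglia":
                adj.append(PopulationSpec(p.name, 0.2, p.channel_locations,
                                          p.channel_scales))
            elif p.name == "bead":
                adj.append(p)
            else:
                f = p.base_fraction * (1 - 0.2) / (1 - 0.05)
                adj.append(PopulationSpec(p.name, f, p.channel_locations,
                                          p.channel_scales, p.is_viable,
                                          p.is_singlet))
        _, manifest = generate_sample(adj, m1_effects[("sham", "ipsilateral")],
                                      10_000, seed=3)
        n, p = 10_000, 0.2
        bound = 3 * np.sqrt(n * p * (1 - p))
        assert abs(manifest.counts["microglia"] - 2000) < bound

    def test_location_shift_recovered_in_medians(self, m1_populations):
        # +0.8 arcsinh shift on CD32 moves the microglia median by 0.8 +/- 0.05
        markers = panel_markers("M1")
        sham = EffectModel(("sham", "ipsilateral"),
                           correlation_matrix=equicorrelation(markers, 0.1))
        cci = EffectModel(("CCI", "ipsilateral"), 1.0, {"CD32": 0.8},
                          equicorrelation(markers, 0.1))
        big = [PopulationSpec(p.name, 0.525 if p.name == "microglia"
                              else p.base_fraction / 2 if p.name != "bead" else 0.0,
                              p.channel_locations, p.channel_scales,
                              p.is_viable, p.is_singlet)
               for p in m1_populations]
        t_sham, m_sham = generate_sample(big, sham, 10_000, seed=11)
        t_cci, m_cci = generate_sample(big, cci, 10_000, seed=12)
        d = (np.median(microglia_values(t_cci, m_cci, "CD32"))
             - np.median(microglia_values(t_sham, m_sham, "CD32")))
        assert d == pytest.approx(0.8, abs=0.05)

    def test_copula_correlation_recovered(self, m1_populations):
        # injected rho = 0.6 between CD45 and CD32 recovered within 0.05
        markers = panel_markers("M1")
        eff = EffectModel(("CCI", "ipsilateral"), 1.0, {},
                          equicorrelation(markers, 0.6))
        big = [PopulationSpec(p.name, 0.525 if p.name == "microglia"
                              else p.base_fraction / 2 if p.name != "bead" else 0.0,
                              p.channel_locations, p.channel_scales,
                              p.is_viable, p.is_singlet)
               for p in m1_populations]
        table, manifest = generate_sample(big, eff, 10_000, seed=5)
        x = microglia_values(table, manifest, "CD45")
        y = microglia_values(table, manifest, "CD32")
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.6, abs=0.05)

    def test_bead_events_appended(self, sham_sample):
        table, manifest = sham_sample
        assert manifest.counts["bead"] == 1000
        assert table.n_events == 10_000 + 1000

    def test_doublets_double_area_not_height(self, sham_sample):
        table, manifest = sham_sample
        doublet = manifest.labels == "doublet"
        singlet = np.isin(manifest.labels, ["microglia", "infiltrate", "dead"])
        ratio_d = table.column("FSC-H")[doublet] / table.column("FSC-A")[doublet]
        ratio_s = table.column("FSC-H")[singlet] / table.column("FSC-A")[singlet]
        assert np.median(ratio_d) < 0.6 < 0.75 < np.median(ratio_s)


class TestGenerateCohort:
    def test_default_study_design_yields_24_samples(self, small_cohort):
        assert len(small_cohort) == 24
        keys = {(m.group, m.hemisphere, m.panel, m.animal_id)
                for _, m, _ in small_cohort}
        assert len(keys) == 24  # 2 groups x 2 hemispheres x 2 panels x 3 animals

    def test_cohort_reproducible_end_to_end(self):
        c1 = default_cohort(seed=77, n_events=500)
        c2 = default_cohort(seed=77, n_events=500)
        for (t1, m1, g1), (t2, m2, g2) in zip(c1, c2):
            np.testing.assert_array_equal(t1.values, t2.values)
            assert m1 == m2
            np.testing.assert_array_equal(g1.labels, g2.labels)

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            generate_cohort(design={})

    def test_partial_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            generate_cohort(design={("sham", "ipsilateral"): (3, 1000)})

    def test_injury_multiplier_enriches_microglia(self, small_cohort):
        counts = {}
        for _, meta, manifest in small_cohort:
            if meta.panel == "M1":
                counts.setdefault((meta.group, meta.hemisphere), []).append(
                    manifest.counts.get("microglia", 0))
        cci = np.mean(counts[("CCI", "ipsilateral")])
        sham = np.mean([np.mean(v) for k, v in counts.items()
                        if k != ("CCI", "ipsilateral")])
        assert cci / sham == pytest.approx(16.0, rel=0.2)

    def test_null_cohort_has_no_condition_structure(self):
        cohort = null_cohort(seed=5, n_events=500, panels=("M1",))
        for _, meta, manifest in cohort:
            assert manifest.effect.microglia_fraction_multiplier == 1.0
            assert not manifest.effect.channel_shifts
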