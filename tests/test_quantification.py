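"""Spike-in calibration, mass/cell conversion, and the CmuQuantifier."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.constants import Avogadro
from sklearn.base import clone

import cmuquant as cq
from cmuquant.errors import (
    CalibrationError,
    ConfigurationError,
    DegenerateDesignError,
    InvalidCalibrationError,
)

SPIKES = cq.SPIKE_IN_TAXA


def profile_with_spikes(spike_abundances, extra=None, sample_id="s1"):
    abund = dict(zip(SPIKES, spike_abundances))
    abund.update(extra or {})
    return cq.AbundanceProfile(sample_id, abund)


class TestCalibration:
    def test_through_origin_slope_and_r_squared(self, spike_spec):
        # (r, d) = (0.01, 0.1), (0.02, 0.2), (0.04, 0.4): exact line d = 10 r
        profile = profile_with_spikes([0.01, 0.02, 0.04])
        model = cq.fit_spike_calibration(profile, spike_spec, through_origin=True)
        assert model.slope == pytest.approx(10.0)
        assert model.intercept == 0.0
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)
        assert model.n_points == 3

    def test_free_intercept_recovers_affine_line(self, spike_spec):
        # d = 5 r + 0.05 exactly at the three spike points
        d = dict(spike_spec.masses)
        r = {t: (m - 0.05) / 5.0 for t, m in d.items()}
        profile = cq.AbundanceProfile("s1", r)
        model = cq.fit_spike_calibration(profile, spike_spec, through_origin=False)
        assert model.slope == pytest.approx(5.0)
        assert model.intercept == pytest.approx(0.05)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_single_point_identity_line(self):
        spec = cq.SpikeInSpec({"a": 0.5})
        profile = cq.AbundanceProfile("s1", {"a": 0.5})
        model = cq.fit_spike_calibration(profile, spec, through_origin=True)
        assert model.slope == pytest.approx(1.0)
        with pytest.raises(CalibrationError):
            cq.fit_spike_calibration(profile, spec, through_origin=False)

    def test_missing_spike_taxon_raises_naming_it(self, spike_spec):
        profile = cq.AbundanceProfile(
            "s1", {SPIKES[0]: 0.01, SPIKES[1]: 0.02}
        )
        with pytest.raises(CalibrationError, match=SPIKES[2]):
            cq.fit_spike_calibration(profile, spike_spec)

    def test_equal_abundances_degenerate_with_free_intercept(self, spike_spec):
        profile = profile_with_spikes([0.02, 0.02, 0.02])
        with pytest.raises(DegenerateDesignError):
            cq.fit_spike_calibration(profile, spike_spec, through_origin=False)

    def test_negative_slope_rejected(self):
        spec = cq.SpikeInSpec({"a": 0.1, "b": 0.4})
        # abundance anti-correlated with input mass -> negative slope
        profile = cq.AbundanceProfile("s1", {"a": 0.4, "b": 0.1})
        with pytest.raises(InvalidCalibrationError):
            cq.fit_spike_calibration(profile, spec, through_origin=False)


class TestMassAndCells:
    def test_estimate_dna_mass(self, spike_spec):
        model = cq.CalibrationModel("s", slope=10, intercept=0, r_squared=1, n_points=3)
        assert cq.estimate_dna_mass(model, 0.1) == pytest.approx(1.0)
        assert cq.estimate_dna_mass(model, 0.0) == 0.0

    def test_negative_intercept_floors_at_zero(self):
        model = cq.CalibrationModel("s", slope=10, intercept=-0.5, r_squared=1, n_points=3)
        assert cq.estimate_dna_mass(model, 0.01) == 0.0

    def test_negative_abundance_rejected(self):
        model = cq.CalibrationModel("s", slope=10, intercept=0, r_squared=1, n_points=3)
        with pytest.raises(ValueError):
            cq.estimate_dna_mass(model, -0.1)

    @pytest.mark.parametrize(
        "length,per_bp,expected",
        [(1_000_000, 660.0, 6.6e8), (1, 660.0, 660.0), (2_000_000, 330.0, 6.6e8)],
    )
    def test_genome_molecular_weight(self, length, per_bp, expected):
        assert cq.genome_molecular_weight(length, per_bp) == pytest.approx(expected)

    def test_nonpositive_genome_length_rejected(self):
        with pytest.raises(ValueError):
            cq.genome_molecular_weight(0)

    def test_dna_to_cells_value(self):
        # 1 ng over a 1 Mbp genome: (1e-9 / 6.6e8) * N_A cells
        expected = 1e-9 / 6.6e8 * Avogadro
        cells = cq.dna_to_cells(1.0, 6.6e8)
        assert cells == pytest.approx(expected)
        assert cells == pytest.approx(912445.57, rel=1e-6)
        assert math.log10(cells) == pytest.approx(5.960207, abs=1e-6)

    def test_dna_to_cells_zero_and_linearity(self):
        assert cq.dna_to_cells(0.0, 6.6e8) == 0.0
        assert cq.dna_to_cells(2.0, 6.6e8) == pytest.approx(2 * cq.dna_to_cells(1.0, 6.6e8))

    def test_genome_copies_divide_cell_count(self):
        assert cq.dna_to_cells(1.0, 6.6e8, copies_per_cell=2.0) == pytest.approx(
            cq.dna_to_cells(1.0, 6.6e8) / 2
        )

    def test_log10_cmu(self):
        assert cq.log10_cmu(1e6) == pytest.approx(6.0)
        assert cq.log10_cmu(0.0) == 0.0
        assert cq.log10_cmu(912445.6) == pytest.approx(5.960207, abs=1e-6)
        assert cq.log10_cmu(0.0, floor=0.1) == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            cq.log10_cmu(10.0, floor=0.0)

    def test_log10_cmu_monotone(self):
        values = [0, 0.5, 1, 10, 1e6]
        logs = [cq.log10_cmu(v) for v in values]
        assert logs == sorted(logs)


class TestQuantifySample:
    def test_composed_example(self, spike_spec):
        profile = profile_with_spikes([0.01, 0.02, 0.04], {"X": 0.1})
        catalog = {"X": cq.GenomeRecord("X", 1_000_000)}
        result = cq.quantify_sample(profile, spike_spec, catalog)
        assert result.cmus["X"] == pytest.approx(912445.57, rel=1e-6)

    def test_spikes_excluded_and_only_spikes_empty(self, spike_spec):
        profile = profile_with_spikes([0.01, 0.02, 0.04])
        result = cq.quantify_sample(
            profile, spike_spec, {"X": cq.GenomeRecord("X", 1_000_000)}
        )
        assert result.cmus == {}
        assert not set(SPIKES) & set(result.cmus)

    def test_missing_genome_reported_as_skipped(self, spike_spec):
        profile = profile_with_spikes([0.01, 0.02, 0.04], {"X": 0.1, "Y": 0.2})
        result = cq.quantify_sample(
            profile, spike_spec, {"X": cq.GenomeRecord("X", 1_000_000)}
        )
        assert "Y" in result.skipped and "Y" not in result.cmus
        assert "X" in result.cmus

    def test_empty_catalog_is_configuration_error(self, spike_spec):
        profile = profile_with_spikes([0.01, 0.02, 0.04], {"X": 0.1})
        with pytest.raises(ConfigurationError):
            cq.quantify_sample(profile, spike_spec, {})

    @pytest.mark.parametrize("factor", [0.5, 2.0, 10.0])
    def test_spike_mass_scale_invariance(self, spike_spec, factor):
        """Scaling all spike input masses by c scales every CMU by c."""
        profile = profile_with_spikes([0.01, 0.02, 0.04], {"X": 0.1, "Y": 0.05})
        catalog = {
            "X": cq.GenomeRecord("X", 1_000_000),
            "Y": cq.GenomeRecord("Y", 4_000_000),
        }
        base = cq.quantify_sample(profile, spike_spec, catalog)
        scaled = cq.quantify_sample(profile, spike_spec.scaled(factor), catalog)
        for taxon in base.cmus:
            assert scaled.cmus[taxon] == pytest.approx(factor * base.cmus[taxon])


class TestCmuQuantifier:
    def make_table(self):
        return pd.DataFrame(
            {
                SPIKES[0]: [0.01, 0.02],
                SPIKES[1]: [0.02, 0.04],
                SPIKES[2]: [0.04, 0.08],
                "X": [0.1, 0.05],
            },
            index=["s1", "s2"],
        )

    def test_fit_transform_matches_functional_path(self, spike_spec):
        table = self.make_table()
        genomes = {"X": 1_000_000}
        quantifier = cq.CmuQuantifier(spikes=spike_spec, genomes=genomes)
        cmus = quantifier.fit_transform(table)
        for sample in table.index:
            profile = cq.AbundanceProfile(sample, table.loc[sample].to_dict())
            expected = cq.quantify_sample(
                profile, spike_spec, {"X": cq.GenomeRecord("X", 1_000_000)}
            )
            assert cmus.loc[sample, "X"] == pytest.approx(expected.cmus["X"])
        assert list(cmus.columns) == ["X"]
        assert quantifier.calibrations_["s1"].slope == pytest.approx(10.0)
        assert quantifier.calibrations_["s2"].slope == pytest.approx(5.0)

    def test_sklearn_protocol(self, spike_spec):
        quantifier = cq.CmuQuantifier(spikes=spike_spec, genomes={"X": 1e6})
        params = quantifier.get_params()
        assert params["through_origin"] is True
        cloned = clone(quantifier)
        assert cloned.get_params()["per_bp_mass"] == 660.0
        cloned.set_params(per_bp_mass=650.0)
        assert cloned.per_bp_mass == 650.0

    def test_transform_rejects_unseen_samples(self, spike_spec):
        table = self.make_table()
        quantifier = cq.CmuQuantifier(spikes=spike_spec, genomes={"X": 1e6}).fit(table)
        other = table.rename(index={"s1": "s3"})
        with pytest.raises(ValueError, match="s3"):
            quantifier.transform(other)

    def test_requires_dataframe_and_valid_rows(self, spike_spec):
        quantifier = cq.CmuQuantifier(spikes=spike_spec, genomes={"X": 1e6})
        with pytest.raises(TypeError):
            quantifier.fit(np.zeros((2, 4)))
        bad = self.make_table()
        bad.loc["s1", "X"] = 1.5  # row sums above 1
        with pytest.raises(ValueError):
            quantifier.fit(bad)

    def test_missing_config_raises(self):
        with pytest.raises(ConfigurationError):
            cq.CmuQuantifier().fit(self.make_table())
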