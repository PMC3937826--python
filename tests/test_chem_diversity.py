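import math

import numpy as np
import pandas as pd
import pytest

from oxymet.chem_diversity import (
    evaluation_value,
    integral_network,
    quantile,
    species_metabolite_partition,
    wmw_effect_size,
)
from oxymet.data_model_io import OxygenClassification, SpeciesNetwork
from oxymet.errors import ValidationError

from _oracles import enumerate_wmw


class TestWmwEffectSize:
    def test_separated_small_sample_exact(self):
        rec = wmw_effect_size([4, 5, 6], [1, 2, 3])
        assert rec.p_one_tailed == pytest.approx(0.05, abs=1e-12)
        assert rec.z == pytest.approx(1.64485, abs=1e-5)
        assert rec.es == pytest.approx(0.6715, abs=1e-4)
        assert rec.es == pytest.approx(rec.z / math.sqrt(6), abs=1e-12)

    def test_fully_tied_input_degenerates_to_zero(self):
        rec = wmw_effect_size([2.0, 2.0], [2.0, 2.0, 2.0])
        assert rec.p_one_tailed == 0.5
        assert rec.z == 0.0 and rec.es == 0.0

    def test_swap_flips_sign_in_asymptotic_regime(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.6, 1.0, 40)
        b = rng.normal(0.0, 1.0, 55)
        fwd = wmw_effect_size(a, b)
        rev = wmw_effect_size(b, a)
        assert fwd.es > 0 > rev.es
        # antisymmetry holds up to the continuity correction (~1/sigma_U)
        assert rev.es == pytest.approx(-fwd.es, abs=2e-3)

    def test_empty_side_rejected(self):
        with pytest.raises(ValidationError):
            wmw_effect_size([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(n1, n - n1) for n in range(2, 11) for n1 in range(1, n)])
    def test_matches_exact_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(1000 * n1 + n2)
        vals = rng.permutation(np.arange(1, n1 + n2 + 1) * 1.37)
        a, b = vals[:n1], vals[n1:]
        p_one, p_two = enumerate_wmw(a, b)
        rec = wmw_effect_size(a, b)
        assert rec.p_one_tailed == pytest.approx(p_one, abs=1e-12)
        assert rec.p_two_tailed == pytest.approx(p_two, abs=1e-12)

    def test_no_nan_or_inf_even_at_extreme_separation(self):
        a = np.arange(200, 400.0)
        b = np.arange(0, 200.0)
        rec = wmw_effect_size(a, b)
        assert math.isfinite(rec.z) and math.isfinite(rec.es)
        assert abs(rec.es) < 2.0  # |z| bounded by isf(p_floor) ~ 37


class TestQuantile:
    def test_median_of_odd_list(self):
        assert quantile([1, 2, 3, 4, 5], 0.5) == 3

    def test_interpolated_lower_quartile(self):
        # h = (4-1)*0.25 + 1 = 1.75 => 10 + 0.75*10
        assert quantile([10, 20, 30, 40], 0.25) == pytest.approx(17.5)

    def test_interpolated_upper_tail(self):
        # h = 4.9 => 0.4 + 0.9*0.1
        assert quantile([0.1, 0.2, 0.3, 0.4, 0.5], 0.975) == pytest.approx(0.49)

    def test_out_of_range_level_rejected(self):
        with pytest.raises(ValidationError):
            quantile([1, 2, 3], 1.5)


class TestEvaluationValue:
    ES_LIST = [0.1, 0.2, 0.3, 0.4, 0.5]

    def test_at_median_ev_is_zero(self):
        out = evaluation_value(0.3, self.ES_LIST)
        assert out["ev"] == 0.0 and out["verdict"] == "consistent"

    def test_at_upper_quantile_ev_is_one(self):
        out = evaluation_value(0.49, self.ES_LIST)
        assert out["ev"] == pytest.approx(1.0, abs=1e-12)
        assert out["verdict"] == "consistent"  # strict inequality defines the verdict

    def test_hand_computed_overestimation(self):
        out = evaluation_value(0.68, self.ES_LIST)
        assert out["ev"] == pytest.approx(2.0, abs=1e-12)
        assert out["verdict"] == "over_or_under_estimated"

    def test_lower_side_uses_low_quantile(self):
        out = evaluation_value(0.0, self.ES_LIST)
        assert out["q_c"] == pytest.approx(quantile(self.ES_LIST, 0.025))
        assert out["verdict"] == "over_or_under_estimated"

    def test_ev_above_one_means_over_or_under_estimated(self):
        # mirrors the interpretation of EV = 1.56 with es_int above the median
        out = evaluation_value(0.37, [0.12, 0.18, 0.21, 0.24, 0.27, 0.30])
        assert out["ev"] > 1
        assert out["verdict"] == "over_or_under_estimated"

    def test_degenerate_zero_width_tail(self):
        out = evaluation_value(0.9, [0.5] * 5)
        assert math.isinf(out["ev"])
        assert out["verdict"] == "over_or_under_estimated"

    def test_short_list_rejected(self):
        with pytest.raises(ValidationError):
            evaluation_value(0.1, [0.1, 0.2])

    @pytest.mark.parametrize("a,b", [(2.0, 0.0), (0.5, -1.0), (3.0, 10.0)])
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(99)
        es_list = rng.normal(0.2, 0.1, 50)
        es_int = 0.35
        base = evaluation_value(es_int, es_list)
        moved = evaluation_value(a * es_int + b, a * es_list + b)
        assert moved["ev"] == pytest.approx(base["ev"], rel=1e-9)
        assert moved["verdict"] == base["verdict"]


class TestPartition:
    PROPS = pd.DataFrame(
        {
            "AlogP98": [1.0, 2.0, np.nan],
            "RotBonds": [3.0, 1.0, 5.0],
        },
        index=pd.Index(["C00001", "C00002", "C00003"], name="compound_id"),
    )

    CLS = OxygenClassification(
        oxic_metabolites=frozenset({"C00001"}),
        anoxic_metabolites=frozenset({"C00002", "C00003"}),
    )

    @staticmethod
    def _net(metabolites):
        return SpeciesNetwork("org", frozenset(), frozenset({"R00001"}), frozenset(metabolites))

    def test_sides_split_by_classification(self):
        parts = species_metabolite_partition(
            self._net(["C00001", "C00002", "C00003"]), self.CLS, self.PROPS
        )
        a, b = parts["RotBonds"]
        assert (len(a), len(b)) == (1, 2)

    def test_missing_descriptor_skips_that_descriptor_only(self):
        parts = species_metabolite_partition(
            self._net(["C00001", "C00002", "C00003"]), self.CLS, self.PROPS
        )
        _, anoxic_alogp = parts["AlogP98"]
        assert len(anoxic_alogp) == 1  # C00003 lacks AlogP98 but keeps RotBonds

    def test_empty_side_excludes_pair(self):
        parts = species_metabolite_partition(self._net(["C00002", "C00003"]), self.CLS, self.PROPS)
        assert parts == {}

    def test_overlapping_classification_rejected(self):
        cls = OxygenClassification(
            oxic_metabolites=frozenset({"C00001", "C00002"}),
            anoxic_metabolites=frozenset({"C00002"}),
        )
        with pytest.raises(ValidationError):
            species_metabolite_partition(self._net(["C00001"]), cls, self.PROPS)


def test_integral_network_is_union(small_networks):
    integral = integral_network(small_networks.values())
    for net in small_networks.values():
        assert net.reactions <= integral.reactions
        assert net.metabolites <= integral.metabolites
    assert integral.organism_id == "integral"
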