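"""Dose conversion chain: heating -> D_T -> DCC -> effective dose."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from voxdose.dosimetry import (
    TissueWeights,
    effective_dose,
    effective_dose_table,
    heating_to_dose,
    icrp103_weights,
    normalize_to_fluence,
    phantom_masses_kg,
)
from voxdose.transport import (
    FluenceTally,
    HeatingTally,
    ap_source,
    deposit_kerma,
    mc_transport,
)


def tally(heating, sem=None):
    return HeatingTally(heating, sem or {k: 0.0 for k in heating}, 1)


class TestHeatingToDose:
    def test_unit_conversion_constants(self):
        dose, _ = heating_to_dose(tally({1: 1.0}), {1: 1.0})
        assert dose[1] == pytest.approx(1.602176634e-7, rel=1e-12)

    def test_zero_heating_zero_dose(self):
        dose, _ = heating_to_dose(tally({1: 0.0}), {1: 2.0})
        assert dose[1] == 0.0

    def test_doubling_mass_halves_dose(self):
        d1, _ = heating_to_dose(tally({1: 5.0}), {1: 1.0})
        d2, _ = heating_to_dose(tally({1: 5.0}), {1: 2.0})
        assert d2[1] == pytest.approx(d1[1] / 2)

    def test_missing_mass_names_organ(self):
        with pytest.raises(KeyError, match="7"):
            heating_to_dose(tally({7: 1.0}), {1: 1.0})


class TestFluenceNormalisation:
    def test_simple_ratio(self):
        assert normalize_to_fluence(2.0, FluenceTally(2.0)) == 1.0

    def test_zero_fluence_rejected(self):
        with pytest.raises(ValueError):
            FluenceTally(0.0)

    def test_dcc_independent_of_source_area(self, tissue_slab):
        # deterministic beam fully covering the phantom: enlarging the
        # source plane changes per-particle quantities but not the DCC
        masses = phantom_masses_kg(tissue_slab)
        dccs = []
        for margin in (1.0, 7.0):
            src = ap_source(tissue_slab, 0.1, margin=margin)
            t, fl = deposit_kerma(tissue_slab, src)
            d, _ = heating_to_dose(t, masses)
            dccs.append(normalize_to_fluence(d, fl)[24])
        assert dccs[0] == pytest.approx(dccs[1], rel=1e-9)

    def test_dcc_invariant_under_particle_count(self, tissue_slab):
        # MC: doubling the history count leaves the DCC unchanged within
        # statistics
        masses = phantom_masses_kg(tissue_slab)
        out = {}
        for n in (20_000, 40_000):
            src = ap_source(tissue_slab, 0.1)
            t, fl = mc_transport(tissue_slab, src, n=n, seed=11)
            d, u = heating_to_dose(t, masses)
            out[n] = (normalize_to_fluence(d, fl)[24],
                      normalize_to_fluence(u, fl)[24])
        diff = abs(out[20_000][0] - out[40_000][0])
        err = np.hypot(out[20_000][1], out[40_000][1])
        assert diff < 4 * err


class TestTissueWeights:
    def test_default_weights_sum_to_exactly_one(self):
        w = icrp103_weights()
        assert sum(w.weights.values()) + w.remainder_weight == 1.0
        assert len(w.weights) == 14
        assert len(w.remainder_organs) == 13

    def test_bad_sum_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            TissueWeights({"a": 0.5}, 0.4, ("b",))


def full_dose_dict(value, remainder_value=None):
    """Doses for every default weighted + remainder organ name."""
    w = icrp103_weights()
    doses = {}
    for name in w.weights:
        for member in w.organ_groups.get(name, (name,)):
            doses[member] = value
    for name in w.remainder_organs:
        doses[name] = value if remainder_value is None else remainder_value
    return doses


class TestEffectiveDose:
    def test_uniform_doses_give_ed_equal_dose(self):
        ed, _ = effective_dose(full_dose_dict(3.7), icrp103_weights())
        assert ed == pytest.approx(3.7, rel=1e-12)

    def test_remainder_only_gives_012_dose(self):
        w = icrp103_weights()
        doses = full_dose_dict(0.0, remainder_value=5.0)
        ed, _ = effective_dose(doses, w)
        assert ed == pytest.approx(0.12 * 5.0, rel=1e-12)

    def test_three_organ_hand_computed(self):
        w = TissueWeights({"a": 0.5, "b": 0.3}, 0.2, ("c", "d"))
        doses = {"a": 2.0, "b": 4.0, "c": 1.0, "d": 3.0}
        # by hand: 0.5*2 + 0.3*4 + 0.2*mean(1,3) = 1 + 1.2 + 0.4
        ed, _ = effective_dose(doses, w)
        assert ed == pytest.approx(2.6, rel=1e-12)

    def test_missing_weighted_organ_listed(self):
        doses = full_dose_dict(1.0)
        del doses["thyroid"]
        with pytest.raises(KeyError, match="thyroid"):
            effective_dose(doses, icrp103_weights())

    def test_colon_group_mass_weighted(self):
        doses = full_dose_dict(1.0)
        doses["colon_upper"], doses["colon_lower"] = 2.0, 4.0
        masses = {"colon_upper": 3.0, "colon_lower": 1.0}
        ed, _ = effective_dose(doses, icrp103_weights(), masses=masses)
        ed_plain, _ = effective_dose(full_dose_dict(1.0), icrp103_weights())
        # colon dose = (3*2 + 1*4)/4 = 2.5; contributes w=0.12
        assert ed - ed_plain == pytest.approx(0.12 * (2.5 - 1.0), rel=1e-9)

    def test_remainder_permutation_invariant(self, rng):
        w = icrp103_weights()
        doses = full_dose_dict(1.0)
        vals = rng.uniform(0.5, 2.0, len(w.remainder_organs))
        for n, v in zip(w.remainder_organs, vals):
            doses[n] = v
        ed1, _ = effective_dose(doses, w)
        for n, v in zip(w.remainder_organs, np.roll(vals, 3)):
            doses[n] = v
        ed2, _ = effective_dose(doses, w)
        assert ed1 == pytest.approx(ed2, rel=1e-12)

    @given(st.integers(0, 10_000))
    def test_ed_bounded_by_organ_dose_range(self, seed):
        rng = np.random.default_rng(seed)
        doses = {k: float(v) for k, v in
                 zip(full_dose_dict(0.0), rng.uniform(0.1, 9.0, 30))}
        ed, _ = effective_dose(doses, icrp103_weights())
        assert min(doses.values()) <= ed <= max(doses.values())

    def test_linearity_in_dose_table(self):
        doses = {k: float(i + 1) for i, k in enumerate(full_dose_dict(0.0))}
        ed1, _ = effective_dose(doses, icrp103_weights())
        ed3, _ = effective_dose({k: 3 * v for k, v in doses.items()},
                                icrp103_weights())
        assert ed3 == pytest.approx(3 * ed1, rel=1e-12)

    def test_uncertainty_propagates_in_quadrature(self):
        w = TissueWeights({"a": 0.88}, 0.12, ("b",))
        ed, u = effective_dose({"a": 1.0, "b": 1.0}, w,
                               uncertainties={"a": 0.1, "b": 0.2})
        assert u == pytest.approx(np.hypot(0.88 * 0.1, 0.12 * 0.2), rel=1e-12)


def test_effective_dose_monotone_with_energy_on_body(body):
    """AP effective dose per unit fluence rises with photon energy from
    0.05 to 1 MeV: deeper penetration plus larger kerma per photon."""
    from voxdose.dosimetry import compute_organ_dose_table
    from voxdose.materials import DEFAULT_ENERGIES_MEV

    energies = [e for e in DEFAULT_ENERGIES_MEV if e >= 0.05]
    dose_df, unc_df = compute_organ_dose_table(body, energies, engine="kerma")
    masses = {o.name: body.organ_mass(o.id) for o in body.registry}
    ed = effective_dose_table(dose_df, unc_df, masses=masses)
    v = ed["effective_dose"].to_numpy()
    assert np.all(np.diff(v) > 0)
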