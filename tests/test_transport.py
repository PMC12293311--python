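"""Transport engines: traversal, attenuation, radiography, kerma, MC."""

import numpy as np
import pytest

from voxdose.materials import kn_total, kn_transfer, mixture_mu, mixture_muen
from voxdose.phantom import populate_lattice
from voxdose.synthetic import generate_slab_phantom
from voxdose.transport import (
    MeshTallySpec,
    PlanarSource,
    ap_source,
    deposit_kerma,
    mc_transport,
    michelson_contrast,
    primary_transmission,
    project_radiograph,
    sample_klein_nishina,
    siddon_traverse,
)


def vacuum_phantom(dims=(4, 4, 4), pitch=1.0):
    n = dims[0] * dims[1] * dims[2]
    return populate_lattice(np.full(n, 255), dims, pitch)


class TestSiddon:
    def test_axis_aligned_ray(self):
        ph = vacuum_phantom((5, 3, 3), pitch=0.7)
        out = siddon_traverse(ph, (-10, 0, 0), (1, 0, 0))
        assert len(out) == 5
        assert all(c == pytest.approx(0.7) for _, c in out)
        assert [v[0][2] for v in out] == [0, 1, 2, 3, 4]

    def test_body_diagonal_of_single_voxel(self):
        ph = vacuum_phantom((1, 1, 1), pitch=2.0)
        out = siddon_traverse(ph, (-2, -2, -2), (1, 1, 1))
        assert len(out) == 1
        assert out[0][1] == pytest.approx(2.0 * np.sqrt(3))

    def test_miss_returns_empty(self):
        ph = vacuum_phantom()
        assert siddon_traverse(ph, (0, 50, 0), (1, 0, 0)) == []
        with pytest.raises(ValueError):
            siddon_traverse(ph, (0, 0, 0), (0, 0, 0))

    def test_chord_sum_equals_box_intersection(self, rng):
        # geometric oracle: independent slab-clipping computation
        ph = vacuum_phantom((6, 4, 5), pitch=0.9)
        lo, hi = ph.lower_left, ph.upper_right
        checked = 0
        for _ in range(1000):
            origin = rng.uniform(-15, 15, 3)
            direction = rng.uniform(lo, hi) - origin  # aim into the box
            direction /= np.linalg.norm(direction)
            t0, t1 = -np.inf, np.inf
            for ax in range(3):
                if direction[ax] == 0:
                    if not (lo[ax] <= origin[ax] <= hi[ax]):
                        t0, t1 = 1, 0
                    continue
                ta = (lo[ax] - origin[ax]) / direction[ax]
                tb = (hi[ax] - origin[ax]) / direction[ax]
                t0, t1 = max(t0, min(ta, tb)), min(t1, max(ta, tb))
            expected = max(0.0, t1 - max(t0, 0.0))
            total = sum(c for _, c in siddon_traverse(ph, origin, direction))
            assert total == pytest.approx(expected, abs=1e-9)
            checked += expected > 0
        assert checked > 900  # the oracle actually exercised hits


class TestTransmission:
    def test_vacuum_is_unity(self):
        ph = vacuum_phantom()
        assert primary_transmission(ph, (-10, 0, 0), (1, 0, 0), 0.1) == 1.0

    @pytest.mark.parametrize("energy", [0.02, 0.1, 0.5])
    def test_homogeneous_slab_closed_form(self, registry, energy):
        muscle = registry.by_id(24)
        for L in (2.0, 6.0, 10.0):
            ph = generate_slab_phantom([(24, L)], registry, pitch=0.5)
            mu = muscle.density * mixture_mu(muscle.composition, energy)
            t = primary_transmission(ph, (-20, 0, 0), (1, 0, 0), energy)
            assert t == pytest.approx(np.exp(-mu * L), abs=1e-12)

    def test_monotone_in_thickness(self, registry):
        ts = [
            primary_transmission(
                generate_slab_phantom([(24, L)], registry, pitch=0.5),
                (-20, 0, 0), (1, 0, 0), 0.1)
            for L in (1.0, 3.0, 5.0, 9.0)
        ]
        assert all(a > b for a, b in zip(ts, ts[1:]))


class TestRadiograph:
    def mesh_behind(self, ph, n=(1, 20, 20)):
        lo, hi = ph.lower_left, ph.upper_right
        return MeshTallySpec(n, (float(hi[0]), float(lo[1]), float(lo[2])),
                             (float(hi[0]) + 1, float(hi[1]), float(hi[2])))

    def test_empty_lattice_uniform_image(self):
        ph = vacuum_phantom((8, 8, 8))
        src = ap_source(ph, 0.1, margin=5.0)
        img = project_radiograph(ph, src, self.mesh_behind(ph))
        assert np.allclose(img, 1.0)

    def test_bone_shadow_darker_than_background(self, registry):
        # bone cylinder embedded in a water-equivalent box
        from voxdose.synthetic import PhantomRecipe, Primitive, generate_phantom

        recipe = PhantomRecipe(
            dims=(20, 20, 20), pitch=0.5, jitter_cm=0.0,
            primitives=(
                Primitive(24, "box", (0, 0, 0), (5, 5, 5), 1),
                Primitive(23, "cylinder", (0, 0, 0), (1.5, 1.5, 5), 2),
            ),
        )
        ph = generate_phantom(recipe, registry)
        src = ap_source(ph, 0.08)
        img = project_radiograph(ph, src, self.mesh_behind(ph, (1, 40, 40)))
        center = img[18:22, 18:22].mean()
        edge = img[18:22, 2:6].mean()
        assert center < edge

    def test_mesh_in_front_of_source_rejected(self):
        ph = vacuum_phantom()
        src = PlanarSource(10.0, (-5, 5), (-5, 5), 0.1)
        with pytest.raises(ValueError, match="front"):
            project_radiograph(ph, src, self.mesh_behind(ph))

    def test_contrast_decreases_with_energy(self, body):
        # bone vs soft tissue contrast strictly higher at 70 than 120 keV
        lo, hi = body.lower_left, body.upper_right
        mesh = MeshTallySpec((1, 128, 160),
                             (float(hi[0]), float(lo[1]), float(lo[2])),
                             (float(hi[0]) + 1, float(hi[1]), float(hi[2])))
        contrasts = {}
        for e in (0.07, 0.12):
            img = project_radiograph(body, ap_source(body, e), mesh)
            yc = np.linspace(lo[1], hi[1], 128, endpoint=False) + (hi[1] - lo[1]) / 256
            zc = np.linspace(lo[2], hi[2], 160, endpoint=False) + (hi[2] - lo[2]) / 320
            zm = (zc > -15) & (zc < 0)            # trunk, spine region
            spine = np.abs(yc) < 1.2
            soft = np.abs(yc - 4.0) < 1.2
            i_bone = img[np.ix_(zm, spine)].mean()
            i_soft = img[np.ix_(zm, soft)].mean()
            contrasts[e] = michelson_contrast(i_soft, i_bone)
        assert contrasts[0.07] > contrasts[0.12] > 0


class TestKerma:
    def test_vacuum_deposits_nothing(self):
        ph = vacuum_phantom()
        tally, _ = deposit_kerma(ph, ap_source(ph, 0.1))
        assert tally.total() == 0.0

    def test_thin_target_limit(self, registry):
        # dose/fluence -> E * muen/rho for an optically thin layer
        muscle = registry.by_id(24)
        ph = generate_slab_phantom([(24, 0.01)], registry, pitch=0.01)
        src = ap_source(ph, 0.1)
        tally, fl = deposit_kerma(ph, src)
        muen = muscle.density * mixture_muen(muscle.composition, 0.1)
        expected = 0.1e6 * muen * 0.01 * ph.pitch**2 / src.area
        assert tally.heating_ev[24] == pytest.approx(expected, rel=5e-3)

    def test_energy_balance_closes(self, tissue_slab):
        src = ap_source(tissue_slab, 0.08)
        _, _, bal = deposit_kerma(tissue_slab, src, return_balance=True)
        lhs = bal["deposited"] + bal["scattered_escape"] + bal["transmitted"]
        assert lhs == pytest.approx(bal["incident"], rel=1e-9)
        assert bal["deposited"] > 0 and bal["transmitted"] > 0


class TestMonteCarlo:
    def test_fixed_seed_reproducible(self, tissue_slab):
        src = ap_source(tissue_slab, 0.1)
        a, _ = mc_transport(tissue_slab, src, n=5000, seed=9)
        b, _ = mc_transport(tissue_slab, src, n=5000, seed=9)
        assert a.heating_ev == b.heating_ev and a.sem_ev == b.sem_ev

    def test_invalid_particle_count(self, tissue_slab):
        with pytest.raises(ValueError):
            mc_transport(tissue_slab, ap_source(tissue_slab, 0.1), n=0)

    def test_scatter_off_matches_deterministic_kerma(self, tissue_slab):
        # the MC estimator with scattering disabled is unbiased for the
        # collision-kerma engine: agreement within 3 standard errors
        src = ap_source(tissue_slab, 0.1)
        det, _ = deposit_kerma(tissue_slab, src)
        mc, _ = mc_transport(tissue_slab, src, n=100_000, seed=42,
                             scatter=False)
        for oid in (23, 24):
            z = abs(mc.heating_ev[oid] - det.heating_ev[oid]) / mc.sem_ev[oid]
            assert z < 3.0

    def test_uncertainty_scales_as_inverse_sqrt_n(self, tissue_slab):
        src = ap_source(tissue_slab, 0.1)
        r1, _ = mc_transport(tissue_slab, src, n=20_000, seed=7)
        r4, _ = mc_transport(tissue_slab, src, n=80_000, seed=7)
        rel1 = np.mean([r1.sem_ev[k] / r1.heating_ev[k]
                        for k in (23, 24)])
        rel4 = np.mean([r4.sem_ev[k] / r4.heating_ev[k]
                        for k in (23, 24)])
        assert rel4 / rel1 == pytest.approx(0.5, rel=0.2)

    def test_scatter_on_deposits_more_than_primary_only(self, tissue_slab):
        src = ap_source(tissue_slab, 0.1)
        off, _ = mc_transport(tissue_slab, src, n=30_000, seed=5, scatter=False)
        on, _ = mc_transport(tissue_slab, src, n=30_000, seed=5, scatter=True)
        assert on.total() > off.total()

    @pytest.mark.parametrize("energy", [0.05, 0.2, 1.0])
    def test_klein_nishina_sampler_mean_transfer(self, energy, rng):
        e_sc, cos_t = sample_klein_nishina(np.full(100_000, energy), rng)
        assert np.all(e_sc <= energy + 1e-12) and np.all(np.abs(cos_t) <= 1)
        sampled = 1 - e_sc.mean() / energy
        exact = kn_transfer(energy) / kn_total(energy)
        assert sampled == pytest.approx(exact, rel=0.02)
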