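"""Temperature ladders, the toy replica-exchange sampler, mixture planting."""

import numpy as np
import pytest
from scipy.integrate import quad

from remdkit import (
    LadderSpec,
    StateMixtureSpec,
    StateSpec,
    ToyModelSpec,
    geometric_ladder,
    mixture_topology,
    run_toy_remd,
    sample_mixture_ensemble,
    swap_acceptance,
    synthetic_topology,
)
from remdkit.constants import KB
from remdkit.landscape import block_standard_error
from remdkit.synth import _ToyEnergy


class TestLadder:
    def test_endpoints_exact(self):
        t = geometric_ladder(LadderSpec(276.0, 592.3, 64))
        assert t[0] == 276.0
        assert t[-1] == 592.3
        assert len(t) == 64

    def test_known_five_replica_ladder(self):
        t = geometric_ladder(LadderSpec(300.0, 600.0, 5))
        assert np.allclose(t, 300.0 * 2 ** (np.arange(5) / 4))

    def test_constant_ratio(self):
        t = geometric_ladder(LadderSpec(280.0, 500.0, 12))
        ratios = t[1:] / t[:-1]
        assert np.allclose(ratios, ratios[0], rtol=1e-12)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            LadderSpec(300.0, 200.0, 4)
        with pytest.raises(ValueError):
            LadderSpec(300.0, 400.0, 1)


class TestSwapAcceptance:
    def test_equal_energies_always_accepted(self):
        assert swap_acceptance(300.0, 400.0, -55.0, -55.0) == 1.0

    def test_known_value(self):
        # Δβ = 0.05411 (kcal/mol)⁻¹, ΔE = −10 → exp(−0.5411) = 0.582
        p = swap_acceptance(300.0, 310.0, -100.0, -90.0)
        assert p == pytest.approx(0.582, abs=0.001)

    def test_pair_relabelling_invariance(self):
        p1 = swap_acceptance(300.0, 310.0, -100.0, -90.0)
        p2 = swap_acceptance(310.0, 300.0, -90.0, -100.0)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_nonfinite_energy_rejected(self):
        with pytest.raises(ValueError):
            swap_acceptance(300.0, 310.0, np.inf, -90.0)


class TestToyREMD:
    def test_same_seed_identical_trajectories(self):
        model = ToyModelSpec(n_beads=4)
        ladder = LadderSpec(300.0, 400.0, 2)
        e1 = run_toy_remd(model, ladder, 200, 20, seed=9)
        e2 = run_toy_remd(model, ladder, 200, 20, seed=9)
        assert np.array_equal(e1.coords, e2.coords)
        assert np.array_equal(e1.replicas, e2.replicas)

    def test_frames_carry_metadata(self):
        model = ToyModelSpec(n_beads=4)
        ens = run_toy_remd(model, LadderSpec(300.0, 400.0, 3), 100, 25, seed=1)
        assert set(ens.replicas.tolist()) == {0, 1, 2}
        assert np.isfinite(ens.temperatures).all()
        assert (ens.times > 0).all()

    def test_harmonic_equipartition(self):
        # stiff springs: mean bond energy per spring ≈ k_B T / 2 within 3 SE
        model = ToyModelSpec(n_beads=5, spring_k=1000.0, step_size=0.02)
        ladder = LadderSpec(300.0, 420.0, 2)
        ens = run_toy_remd(model, ladder, 15000, 50, seed=3, sample_interval=15)
        energy = _ToyEnergy(model)
        mask = ens.temperatures == 300.0
        e = np.array([energy.total(x) for x in ens.coords[mask]])
        e = e[len(e) // 5:] / (model.n_beads - 1)  # drop burn-in
        se = block_standard_error(e, 4)
        assert abs(e.mean() - KB * 300.0 / 2) <= 3 * se

    def test_well_occupancy_matches_boltzmann_quadrature(self):
        # two beads, one square well on the bond: radial occupancy has the
        # closed form ∫ r² exp(−βU(r)) dr over the well vs outside it
        depth, r_well, k, b0 = 1.5, 0.38, 100.0, 0.38
        model = ToyModelSpec(
            n_beads=2, bond_length=b0, spring_k=k, step_size=0.05,
            contact_wells=((0, 1, depth, r_well),),
        )
        ladder = LadderSpec(300.0, 500.0, 2)
        ens = run_toy_remd(model, ladder, 40000, 100, seed=11, sample_interval=10)
        for temp in (300.0, 500.0):
            beta = 1.0 / (KB * temp)

            def boltz(r):
                u = 0.5 * k * (r - b0) ** 2 - (depth if r < r_well else 0.0)
                return r * r * np.exp(-beta * u)

            z_in = quad(boltz, 0.0, r_well, limit=200)[0]
            z_out = quad(boltz, r_well, 5.0, limit=200)[0]
            expected = z_in / (z_in + z_out)
            mask = ens.temperatures == temp
            d = np.linalg.norm(
                ens.coords[mask, 1] - ens.coords[mask, 0], axis=1
            )
            occ = (d < r_well).astype(float)
            occ = occ[len(occ) // 5:]
            se = block_standard_error(occ, 4)
            assert abs(occ.mean() - expected) <= 3 * max(se, 0.01)

    def test_low_temperature_occupies_well_more(self):
        model = ToyModelSpec(
            n_beads=2, step_size=0.05,
            contact_wells=((0, 1, 2.0, 0.38),),
        )
        ens = run_toy_remd(model, LadderSpec(280.0, 560.0, 3), 20000, 100,
                           seed=4, sample_interval=10)
        occs = []
        for temp in sorted(set(ens.temperatures.tolist())):
            mask = ens.temperatures == temp
            d = np.linalg.norm(ens.coords[mask, 1] - ens.coords[mask, 0], axis=1)
            occs.append((d < 0.38).mean())
        assert occs[0] > occs[-1]

    def test_invalid_arguments(self):
        model = ToyModelSpec(n_beads=3)
        with pytest.raises(ValueError):
            run_toy_remd(model, LadderSpec(300, 400, 2), 0, 10)
        with pytest.raises(ValueError):
            run_toy_remd(model, LadderSpec(300, 400, 2), 10, 0)


class TestMixtureGenerator:
    def test_pure_hairpin_state_scores_high_nbeta(self, ab42_topology):
        from remdkit import assign_ss_ensemble, rc_series

        spec = StateMixtureSpec(
            states=(StateSpec("hp", 1.0, motif="hairpin3",
                              region_strand={"CHC": 1.0, "CTR": 1.0},
                              contact_prob=1.0),),
            n_frames=20, seed=5,
        )
        ens, truth = sample_mixture_ensemble(spec, ab42_topology)
        labels = assign_ss_ensemble(ens)
        rc = rc_series(ens, labels)
        assert np.all(rc.nbeta >= 0.5)
        assert np.all(rc.ncontact > 0.05)

    def test_planted_fractions_within_binomial_bound(self, ab42_topology):
        p = 0.47
        spec = StateMixtureSpec(
            states=(
                StateSpec("a", p, motif="hairpin3"),
                StateSpec("b", 1 - p, motif="coil"),
            ),
            n_frames=4000, seed=12,
        )
        _, truth = sample_mixture_ensemble(spec, ab42_topology)
        frac = truth.state_fractions()["a"]
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / 4000)

    def test_truth_labels_match_assignment(self, ab42_topology):
        from remdkit import assign_ss_ensemble

        spec = StateMixtureSpec(
            states=(StateSpec("mix", 1.0, motif="ctr_hairpin"),),
            n_frames=30, seed=2,
        )
        ens, truth = sample_mixture_ensemble(spec, ab42_topology)
        labels = assign_ss_ensemble(ens)
        assert (labels == truth.ss_labels).mean() > 0.99

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            StateMixtureSpec(
                states=(StateSpec("a", 0.6), StateSpec("b", 0.6)), n_frames=10
            )

    def test_zero_frames_rejected(self):
        with pytest.raises(ValueError):
            StateMixtureSpec(states=(StateSpec("a", 1.0),), n_frames=0)

    def test_seed_determinism(self, ab42_topology):
        spec = StateMixtureSpec(
            states=(StateSpec("a", 0.5, motif="coil"),
                    StateSpec("b", 0.5, motif="helix",
                              region_helix={"NTR": 1.0})),
            n_frames=12, seed=77,
        )
        e1, t1 = sample_mixture_ensemble(spec, ab42_topology)
        e2, t2 = sample_mixture_ensemble(spec, ab42_topology)
        assert np.array_equal(e1.coords, e2.coords)
        assert np.array_equal(t1.state_labels, t2.state_labels)

    def test_hexapeptide_bound_topology_places_second_chain(self):
        top = mixture_topology(hexapeptide="A2T")
        spec = StateMixtureSpec(
            states=(StateSpec("c", 1.0, motif="coil"),), n_frames=4, seed=1
        )
        ens, _ = sample_mixture_ensemble(spec, top)
        b_atoms = top.atom_indices(chain_id="B", heavy_only=True)
        a_atoms = top.atom_indices(chain_id="A", heavy_only=True)
        d = np.linalg.norm(
            ens.coords[0, b_atoms][:, None] - ens.coords[0, a_atoms][None],
            axis=-1,
        )
        assert d.min() < 0.45  # bound pose: interface contacts exist
        assert d.min() > 0.25  # but no steric interpenetration


class TestSyntheticTopology:
    def test_neutral_chain(self):
        top, table = synthetic_topology(6)
        assert top.charges.sum() == 0.0
        assert len(table) == top.n_atoms

    def test_dipolar_pattern(self):
        top, _ = synthetic_topology(6, "dipolar")
        assert top.charges.sum() == pytest.approx(0.0)
        assert set(np.unique(top.charges)) == {-0.5, 0.5}

    def test_seed_determinism(self):
        a, _ = synthetic_topology(5, seed=3)
        b, _ = synthetic_topology(5, seed=3)
        assert np.array_equal(a.sigmas, b.sigmas)
        assert np.array_equal(a.born_radii, b.born_radii)

    def test_impossible_pattern_rejected(self):
        with pytest.raises(ValueError):
            synthetic_topology(5, "dipolar")  # odd count cannot balance
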