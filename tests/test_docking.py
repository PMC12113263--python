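import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist
from scipy.stats import chisquare, kstest

from alphared import (
    GLOBAL_SCHEDULE,
    MoveSchedule,
    Pose,
    ReplicaLadder,
    ReplicaState,
    attempt_swap,
    cluster_decoys,
    default_score,
    funnel_score_factory,
    interface_score,
    make_decoy,
    metropolis_accept,
    perturb_backbone,
    perturb_rigid,
    pose_ligand_rmsd,
    randomize_orientation,
    run_replica_exchange,
    select_mobile_residues,
)
from alphared.docking import uniform_quaternion
from alphared.fixtures import ConfidenceSpec, make_confidence


@pytest.fixture(scope="module")
def native(toy):
    return toy[1]


def brute_force_score(pose, k_rep=5.0, eps=1.0):
    e = 0.0
    for r in pose.receptor_cb():
        for l in pose.ligand_cb():
            d = np.linalg.norm(r - l)
            if d < 4.0:
                e += k_rep * (4.0 - d) ** 2
            elif d < 8.0:
                e -= eps
    return e


class TestDefaultScore:
    def test_far_apart_is_zero(self, native):
        far = native.with_transform(native.transform.translated([200.0, 0, 0]))
        assert default_score(far) == 0.0

    def test_matches_brute_force(self, native, rng):
        for lrms in (0.0, 3.0, 10.0):
            pose = native if lrms == 0 else make_decoy(native, lrms, rng)
            assert default_score(pose) == pytest.approx(brute_force_score(pose), abs=1e-9)

    def test_invariant_under_global_rigid_transform(self, native, rng):
        """Moving the whole complex rigidly (receptor and ligand together)
        leaves the score unchanged."""
        from scipy.spatial.transform import Rotation
        from dataclasses import replace

        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(scale=20.0, size=3)
        moved = replace(
            native,
            receptor_coords=native.receptor_coords @ R.T + t,
            ligand_local=native.ligand_coords() @ R.T + t,
            transform=native.transform.identity(),
            _realized=None,
        )
        assert default_score(moved) == pytest.approx(default_score(native), abs=1e-9)


class TestInterfaceScore:
    def test_isolated_partners_zero(self, native):
        far = native.with_transform(native.transform.translated([300.0, 0, 0]))
        assert interface_score(far) == pytest.approx(0.0)

    def test_clash_free_pose_counts_contacts(self, native):
        """For the clash-free native toy pose the interface score equals
        minus the number of cross-partner Cβ pairs within the contact shell."""
        d = cdist(native.receptor_cb(), native.ligand_cb())
        n_pairs = int(((d >= 4.0) & (d < 8.0)).sum())
        assert (d < 4.0).sum() == 0
        assert interface_score(native) == pytest.approx(-n_pairs)

    def test_finite_for_random_decoys(self, native, rng):
        for lrms in (2.0, 15.0, 40.0):
            assert math.isfinite(interface_score(make_decoy(native, lrms, rng)))


class TestRandomizeOrientation:
    def test_contact_contract(self, native, rng):
        """Every randomized pose ends with at least one cross-partner atom
        pair within the slide stop distance plus one step."""
        for _ in range(25):
            pose = randomize_orientation(native, rng)
            dmin = cdist(pose.receptor_coords, pose.ligand_coords()).min()
            assert dmin <= 5.5

    def test_deterministic_per_seed(self, native):
        a = randomize_orientation(native, np.random.default_rng(42))
        b = randomize_orientation(native, np.random.default_rng(42))
        np.testing.assert_array_equal(a.ligand_coords(), b.ligand_coords())

    def test_rotation_angles_uniform(self):
        """Rotation angle of uniform quaternions follows the Haar measure
        CDF (θ - sin θ)/π on [0, π]."""
        rng = np.random.default_rng(7)
        angles = np.array(
            [2 * math.acos(min(abs(uniform_quaternion(rng)[3]), 1.0)) for _ in range(10_000)]
        )
        stat = kstest(angles, lambda x: (x - np.sin(x)) / np.pi)
        assert stat.pvalue > 0.01


class TestPerturbRigid:
    def test_zero_magnitude_is_identity(self, native, rng):
        sched = MoveSchedule(trans_mag=0.0, rot_mag=0.0)
        moved = perturb_rigid(native, sched, rng)
        np.testing.assert_allclose(
            moved.ligand_coords(), native.ligand_coords(), atol=1e-12
        )

    def test_mean_translation_magnitude(self, rng):
        """Expected |translation| matches the schedule's trans_mag within 5%."""
        sigma = 4.0 * math.sqrt(math.pi / 8.0)
        draws = rng.normal(0.0, sigma, size=(10_000, 3))
        assert np.mean(np.linalg.norm(draws, axis=1)) == pytest.approx(4.0, rel=0.05)

    def test_rotation_stays_orthonormal(self, native, rng):
        pose = native
        for _ in range(200):
            pose = perturb_rigid(pose, GLOBAL_SCHEDULE, rng)
        R = pose.transform.matrix
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm(pose.transform.quat) == pytest.approx(1.0, abs=1e-9)


class TestPerturbBackbone:
    def _mobile(self, pose, start, end):
        structure = pose.ligand.structure
        prof_vals = [
            60.0 if start <= i <= end else 95.0 for i in range(len(structure))
        ]
        from alphared.structure_io import ConfidenceProfile

        prof = ConfidenceProfile(structure.residue_ids, prof_vals)
        return select_mobile_residues(prof, threshold=80.0, min_run=3)

    def test_empty_selection_is_noop(self, native, rng):
        from alphared import MobileSelection

        sched = MoveSchedule(1.0, 3.0, backbone_weight=3.0, torsion_mag=3.0)
        out = perturb_backbone(native, MobileSelection(), sched, rng)
        assert out is native

    def test_zero_torsion_mag_leaves_coordinates(self, native, rng):
        mobile = self._mobile(native, 5, 10)
        sched = MoveSchedule(1.0, 3.0, backbone_weight=3.0, torsion_mag=0.0)
        out = perturb_backbone(native, mobile, sched, rng)
        np.testing.assert_allclose(out.ligand_local, native.ligand_local, atol=1e-9)

    def test_only_segment_and_downstream_atoms_move(self, native, rng):
        """A torsion move on ligand residues [5, 10] leaves every atom before
        the segment untouched."""
        mobile = self._mobile(native, 5, 10)
        sched = MoveSchedule(1.0, 3.0, backbone_weight=3.0, torsion_mag=5.0)
        out = perturb_backbone(native, mobile, sched, rng)
        top = native.ligand
        first_seg_row = min(top.res_rows[5])
        np.testing.assert_array_equal(
            out.ligand_local[:first_seg_row], native.ligand_local[:first_seg_row]
        )
        assert not np.allclose(out.ligand_local, native.ligand_local)
        # receptor untouched
        np.testing.assert_array_equal(out.receptor_coords, native.receptor_coords)


class TestAcceptanceRules:
    def test_downhill_and_flat_always_accept(self, rng):
        assert metropolis_accept(-1.0, 1.5, rng)
        assert metropolis_accept(0.0, 1.5, rng)

    def test_uphill_frequency(self):
        """Acceptance at ΔE = kT approaches exp(-1)."""
        rng = np.random.default_rng(3)
        n = 20_000
        hits = sum(metropolis_accept(1.5, 1.5, rng) for _ in range(n))
        assert hits / n == pytest.approx(math.exp(-1), abs=0.01)

    def test_swap_equal_energies_always_accepts(self, rng):
        si = ReplicaState(0, 1.5, -10.0)
        sj = ReplicaState(1, 3.0, -10.0)
        assert attempt_swap(si, sj, rng)

    def test_swap_symmetric_under_relabeling(self):
        """The swap probability is identical whichever member of the pair is
        passed first."""
        for e_i, e_j in [(-5.0, -2.0), (-2.0, -5.0)]:
            si = ReplicaState(0, 1.5, e_i)
            sj = ReplicaState(1, 3.0, e_j)
            n = 5000
            a = sum(attempt_swap(si, sj, np.random.default_rng(k)) for k in range(n))
            b = sum(attempt_swap(sj, si, np.random.default_rng(k)) for k in range(n))
            assert a == b

    def test_non_adjacent_rungs_rejected(self, rng):
        with pytest.raises(ValueError, match="adjacent"):
            attempt_swap(ReplicaState(0, 1.5, 0.0), ReplicaState(2, 5.0, 0.0), rng)


class TestReplicaExchangeSampling:
    def test_two_rung_harmonic_marginals(self):
        """With swaps every 10 steps, each rung of a two-temperature harmonic
        oscillator keeps its own Boltzmann distribution (χ² on binned x)."""
        rng = np.random.default_rng(11)
        kts = (1.0, 4.0)
        x = [0.0, 0.0]
        samples = ([], [])
        for step in range(60_000):
            for k in (0, 1):
                prop = x[k] + rng.normal(0.0, 1.0)
                if metropolis_accept(0.5 * prop**2 - 0.5 * x[k] ** 2, kts[k], rng):
                    x[k] = prop
            if step % 10 == 0:
                si = ReplicaState(0, kts[0], 0.5 * x[0] ** 2)
                sj = ReplicaState(1, kts[1], 0.5 * x[1] ** 2)
                if attempt_swap(si, sj, rng):
                    x[0], x[1] = x[1], x[0]
            if step % 20 == 0 and step > 5000:
                samples[0].append(x[0])
                samples[1].append(x[1])
        from scipy.stats import norm

        for k in (0, 1):
            sigma = math.sqrt(kts[k])
            edges = norm.ppf(np.linspace(0.05, 0.95, 10), scale=sigma)
            counts, _ = np.histogram(samples[k], bins=np.r_[-np.inf, edges, np.inf])
            expected = np.full(len(counts), len(samples[k]) / len(counts))
            expected[0] = expected[-1] = len(samples[k]) * 0.05
            probs = np.diff(np.r_[0, np.linspace(0.05, 0.95, 10), 1])
            expected = probs * len(samples[k])
            p = chisquare(counts, expected).pvalue
            assert p > 0.01, f"rung {k} marginal off Boltzmann (p={p:.4f})"


class TestRunReplicaExchange:
    def test_deterministic_rerun(self, native):
        score = funnel_score_factory(native)
        kw = dict(
            schedule=GLOBAL_SCHEDULE, score=score, n_steps=200, mode="global",
            seed=5, randomize_start=True,
            ladder=ReplicaLadder(n_trajectories=2),
        )
        r1 = run_replica_exchange(native, **kw)
        r2 = run_replica_exchange(native, **kw)
        assert len(r1.decoys) == len(r2.decoys)
        for a, b in zip(r1.decoys, r2.decoys):
            assert a.energy == b.energy
            np.testing.assert_array_equal(a.pose.ligand_coords(), b.pose.ligand_coords())

    def test_flat_score_accepts_everything(self, native):
        res = run_replica_exchange(
            native, schedule=GLOBAL_SCHEDULE, score=lambda p: 0.0, n_steps=100,
            mode="global", seed=1, ladder=ReplicaLadder(n_trajectories=1),
        )
        assert res.acceptance_rates[0] == 1.0

    def test_recorded_energy_matches_rescoring(self, native):
        """No drift between sampling and reporting: stored decoy energies
        equal re-scored snapshot energies."""
        score = funnel_score_factory(native)
        res = run_replica_exchange(
            native, schedule=GLOBAL_SCHEDULE, score=score, n_steps=200,
            mode="global", seed=2, randomize_start=True,
            ladder=ReplicaLadder(n_trajectories=2),
        )
        for d in res.decoys[::7]:
            assert score(d.pose) == pytest.approx(d.energy, abs=1e-9)

    def test_rigid_moves_preserve_internal_geometry(self, native):
        """Across a trajectory, no intra-partner distance changes by more
        than 1e-9 Å in global (rigid) mode."""
        score = funnel_score_factory(native)
        res = run_replica_exchange(
            native, schedule=GLOBAL_SCHEDULE, score=score, n_steps=300,
            mode="global", seed=3, randomize_start=True,
            ladder=ReplicaLadder(n_trajectories=1),
        )
        ref_lig = pdist(native.ligand.coords0)
        ref_rec = pdist(native.receptor.coords0)
        for d in res.decoys[::5]:
            assert np.max(np.abs(pdist(d.pose.ligand_coords()) - ref_lig)) < 1e-9
            assert np.max(np.abs(pdist(d.pose.receptor_coords) - ref_rec)) < 1e-9

    def test_provenance_complete(self, native):
        res = run_replica_exchange(
            native, score=lambda p: 0.0, n_steps=50, snapshot_every=10,
            mode="global", seed=9, ladder=ReplicaLadder(n_trajectories=2),
        )
        assert {d.trajectory for d in res.decoys} == {0, 1}
        assert all(d.step % 10 == 0 and d.replica == 0 and d.seed == 9 for d in res.decoys)


class TestClusterDecoys:
    def _decoy(self, pose, energy):
        from alphared.docking import Decoy

        return Decoy(pose=pose, energy=energy, interface_score=energy,
                     trajectory=0, replica=0, step=0, seed=0)

    def test_single_decoy(self, native):
        d = self._decoy(native, -1.0)
        assert cluster_decoys([d]) == [d]

    def test_two_separated_groups_give_two_representatives(self, native, rng):
        group1 = [self._decoy(make_decoy(native, 0.5, rng), -10.0 + i) for i in range(5)]
        far = native.with_transform(native.transform.translated([20.0, 0, 0]))
        group2 = [self._decoy(make_decoy(far, 0.5, rng), -9.5 + i) for i in range(5)]
        reps = cluster_decoys(group1 + group2, energy_keep_fraction=1.0,
                              rmsd_threshold=5.0, n_clusters=5)
        assert len(reps) == 2
        assert pose_ligand_rmsd(reps[0].pose, reps[1].pose) > 5.0

    def test_identical_poses_collapse_to_one(self, native):
        decoys = [self._decoy(native, -5.0 + i) for i in range(10)]
        reps = cluster_decoys(decoys, energy_keep_fraction=1.0)
        assert len(reps) == 1
        assert reps[0].energy == -5.0

    def test_representatives_sorted_by_energy(self, native, rng):
        decoys = [
            self._decoy(make_decoy(native, lrms, rng), e)
            for lrms, e in [(0.5, -8.0), (10.0, -6.0), (20.0, -7.0), (30.0, -2.0)]
        ]
        reps = cluster_decoys(decoys, energy_keep_fraction=1.0, n_clusters=5)
        energies = [r.energy for r in reps]
        assert energies == sorted(energies)
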