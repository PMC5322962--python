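"""Motion-resolved accumulation: equivalences, conservation, convergence."""

import numpy as np
import pytest

import vmat4d as v
from vmat4d.grid import translate_trilinear


def gaussian_blob_grid(center, sigma=6.0, shape=(29, 29, 29), spacing=4.0):
    """Compactly supported synthetic dose blob whose support stays inside
    the grid even under the largest test displacements."""
    n = np.array(shape)
    origin = -spacing * (n - 1) / 2.0
    ax = [origin[a] + spacing * np.arange(n[a]) for a in range(3)]
    SI, AP, LR = np.meshgrid(*ax, indexing="ij")
    r2 = ((SI - center[0]) ** 2 + (AP - center[1]) ** 2 + (LR - center[2]) ** 2)
    vals = np.exp(-r2 / (2 * sigma**2))
    vals[vals < 1e-10] = 0.0
    return v.DoseGrid(vals, spacing, tuple(origin))


@pytest.fixture(scope="module")
def blob_setup(arc):
    """Two-segment schedule with synthetic blob doses (mass fully in-grid)."""
    sch = v.discretize_arc(arc, 75.0)
    d1 = gaussian_blob_grid((-6.0, 0.0, 4.0))
    d2 = gaussian_blob_grid((6.0, 2.0, -4.0))
    doses = v.SegmentDoseSet((d1, d2), sch)
    return sch, doses


def constant_trajectory(shift, duration=60.0, dt=0.04):
    n = int(duration / dt) + 1
    samples = np.tile(np.asarray(shift, float), (n, 1))
    return v.Trajectory(dt=dt, samples=samples, label="const")


class TestAccumulate4D:
    def test_zero_motion_reduces_to_static_sum(self, blob_setup):
        sch, doses = blob_setup
        traj = constant_trajectory((0, 0, 0))
        dyn = v.accumulate_4d(doses, sch, traj, dt=0.5)
        assert np.array_equal(dyn.values, doses.summed().values)

    @pytest.mark.parametrize("shift,exact", [
        ((4.0, -8.0, 4.0), True),      # grid multiples: exact
        ((3.0, 1.5, -2.2), False),     # off-grid: within interpolation error
    ])
    def test_constant_shift_equals_shifted_static(self, blob_setup, shift, exact):
        """Shift-then-sum equals sum-then-shift for rigid constant motion."""
        sch, doses = blob_setup
        dyn = v.accumulate_4d(doses, sch, constant_trajectory(shift), dt=0.5)
        static = doses.summed()
        expected = translate_trilinear(static.values,
                                       np.asarray(shift) / np.array(static.spacing))
        tol = 1e-12 if exact else 0.01 * static.values.max()
        assert np.abs(dyn.values - expected).max() <= tol

    def test_two_segment_brute_force_oracle(self, blob_setup):
        """Motion only during segment 2: result equals D1 + shifted D2,
        composed by hand."""
        sch, doses = blob_setup
        T = sch.arc.beam_on_time
        s = np.array([8.0, 0.0, -4.0])
        dt = 0.04
        n = int(60.0 / dt) + 1
        t = np.arange(n) * dt
        samples = np.where((t >= T / 2)[:, None], s[None, :], 0.0)
        traj = v.Trajectory(dt=dt, samples=samples)
        dyn = v.accumulate_4d(doses, sch, traj, dt=0.5)
        spacing = np.array(doses.doses[0].spacing)
        expected = doses.doses[0].values + translate_trilinear(
            doses.doses[1].values, s / spacing)
        assert np.allclose(dyn.values, expected, atol=1e-12)

    def test_integral_dose_conserved_in_grid(self, blob_setup, traj_1b):
        """With all displaced mass staying inside the grid, the integral dose
        is conserved exactly (leakage ~ 0)."""
        sch, doses = blob_setup
        stats = v.AccumulationStats()
        dyn = v.accumulate_4d(doses, sch, traj_1b, dt=0.1, stats=stats)
        assert stats.leakage_fraction < 1e-9
        assert dyn.integral() == pytest.approx(doses.summed().integral(), rel=1e-9)

    def test_linearity_in_dose_scaling(self, blob_setup, traj_1b):
        sch, doses = blob_setup
        scaled = v.SegmentDoseSet(tuple(2.5 * d for d in doses.doses), sch)
        a = v.accumulate_4d(doses, sch, traj_1b, dt=0.5)
        b = v.accumulate_4d(scaled, sch, traj_1b, dt=0.5)
        assert np.allclose(b.values, 2.5 * a.values, rtol=1e-12)

    def test_trajectory_too_short_rejected(self, blob_setup):
        sch, doses = blob_setup
        short = constant_trajectory((0, 0, 0), duration=10.0)
        with pytest.raises(ValueError, match="delivery takes"):
            v.accumulate_4d(doses, sch, short, dt=0.5)

    def test_dt_halving_insensitive(self, doses30, schedule30, traj_1b):
        """Halving the sub-step changes the result by < 0.5% of max dose for
        the case-1b sinusoid (trajectory resolution effects negligible)."""
        a = v.accumulate_4d(doses30, schedule30, traj_1b, dt=0.08)
        b = v.accumulate_4d(doses30, schedule30, traj_1b, dt=0.04)
        assert np.abs(a.values - b.values).max() < 0.005 * b.values.max()

    def test_delta_alpha_refinement_cauchy(self, phantom, beam, density, arc,
                                           traj_1b):
        """Refinement convergence on case 1b: the 10-vs-5 degree difference
        dominates the 5-vs-2.5 degree difference."""
        results = {}
        for level in (10.0, 5.0, 2.5):
            sch = v.discretize_arc(arc, level)
            ds = v.compute_segment_doses(phantom, sch, beam, density=density)
            results[level] = v.accumulate_4d(ds, sch, traj_1b, dt=0.04).values
        d_coarse = np.sqrt(np.mean((results[10.0] - results[5.0]) ** 2))
        d_fine = np.sqrt(np.mean((results[5.0] - results[2.5]) ** 2))
        assert d_fine <= d_coarse


class TestCourse:
    def test_single_fraction_zero_offset_matches_accumulate(self, blob_setup,
                                                            traj_1b):
        sch, doses = blob_setup
        plan = v.CoursePlan(arcs=((sch, doses),), n_fx=1, phase_offsets=(0.0,))
        total = v.accumulate_course(plan, traj_1b, dt=0.5)
        single = v.accumulate_4d(doses, sch, traj_1b, dt=0.5)
        assert np.array_equal(total.values, single.values)

    def test_two_equal_arcs_double_the_dose(self, blob_setup, traj_1b):
        sch, doses = blob_setup
        plan = v.CoursePlan(arcs=((sch, doses), (sch, doses)), n_fx=1,
                            phase_offsets=(0.0,))
        total = v.accumulate_course(plan, traj_1b, dt=0.5)
        single = v.accumulate_4d(doses, sch, traj_1b, dt=0.5)
        assert np.allclose(total.values, 2.0 * single.values, rtol=1e-12)

    def test_seeded_phase_policy_reproducible(self, blob_setup, traj_1b):
        sch, doses = blob_setup
        p = v.CoursePlan(arcs=((sch, doses),), n_fx=3, seed=11, phase_window=4.5)
        a = v.accumulate_course(p, traj_1b, dt=0.5)
        b = v.accumulate_course(p, traj_1b, dt=0.5)
        assert np.array_equal(a.values, b.values)

    def test_unresolved_phase_policy_rejected(self, blob_setup):
        sch, doses = blob_setup
        with pytest.raises(ValueError, match="phase policy"):
            v.CoursePlan(arcs=((sch, doses),), n_fx=2)

    def test_fraction_averaging_converges_to_blurred_static(self, blob_setup,
                                                            traj_1b):
        """Many random starting phases average interplay out: the mean
        fraction dose approaches the occupancy-histogram-blurred static dose,
        with RMS deviation decreasing in the number of fractions."""
        sch, doses = blob_setup
        target = v.occupancy_blurred_static(doses, traj_1b, t_max=4.5, dt=0.04)
        rms = {}
        for n_fx in (1, 4, 64):
            plan = v.CoursePlan(arcs=((sch, doses),), n_fx=n_fx, seed=5,
                                phase_window=4.5)
            mean = v.accumulate_course(plan, traj_1b, dt=0.1) * (1.0 / n_fx)
            rms[n_fx] = float(np.sqrt(np.mean((mean.values - target.values) ** 2)))
        assert rms[64] < rms[4] < rms[1]
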