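import numpy as np
import pytest

import cvrnnseg as cv
from cvrnnseg import core, lattice
from cvrnnseg.core import IllConditionedEigenbasis, NumericRangeError

from conftest import make_random_system, wrapped_phase_diff


# -- input encoding ------------------------------------------------------------


def test_encode_input_linearity_and_position_independence():
    pixels = np.zeros((4, 4))
    pixels[0, 0] = 1.0
    pixels[3, 2] = 1.0
    pixels[1, 1] = 0.5
    drive = core.encode_input(pixels, omega_offset=0.3, omega_gain=2.0)
    omega = drive.omega.reshape(4, 4)
    # p=0 vs p=1 differ by exactly the gain
    assert omega[0, 0] - omega[2, 2] == pytest.approx(2.0)
    # equal intensities map to equal frequencies regardless of position
    assert omega[0, 0] == omega[3, 2]
    assert omega[1, 1] == pytest.approx(0.3 + 1.0)
    uniform = core.encode_input(np.full((3, 3), 0.7), 0.1, 0.5)
    assert np.all(uniform.omega == uniform.omega[0])
    with pytest.raises(ValueError):
        core.encode_input(np.array([[np.nan, 0], [0, 0]]), 0, 1)


def test_compose_system_structure():
    spec = lattice.build_lattice(3)
    conn = lattice.gaussian_adjacency(spec, lattice.KernelParams(0.4, 0.5))
    omega = np.linspace(-1, 1, 9)
    system = core.compose_system(conn, core.InputDrive(omega), epsilon=0.7)
    B = system.matrix
    np.testing.assert_allclose(np.diag(B).imag, omega)
    np.testing.assert_allclose(np.diag(B).real, 0.7 * np.diag(conn.weights))
    off = B - np.diag(np.diag(B))
    assert np.all(off.imag == 0)
    np.testing.assert_allclose(
        off.real, 0.7 * (conn.weights - np.diag(np.diag(conn.weights)))
    )
    with pytest.raises(ValueError):
        core.compose_system(conn, core.InputDrive(np.zeros(4)))


def test_null_system_is_zero_matrix():
    conn = lattice.ConnectivityMatrix(
        weights=np.zeros((4, 4)), params=lattice.KernelParams(1, 1)
    )
    system = core.compose_system(conn, core.InputDrive(np.zeros(4)))
    assert np.all(system.matrix == 0)


# -- random initial conditions -------------------------------------------------


def test_random_init_distribution_and_determinism():
    x = core.random_init(20000, seed=4)
    amp, phase = np.abs(x), np.angle(x)
    assert np.all((amp >= 0) & (amp <= 1))
    assert np.all((phase >= -np.pi) & (phase <= np.pi))
    # circular-uniform phases: mean resultant length is O(1/sqrt(n))
    assert np.abs(np.mean(np.exp(1j * phase))) < 4 / np.sqrt(20000)
    # amplitude moments of U[0,1]
    assert amp.mean() == pytest.approx(0.5, abs=0.02)
    np.testing.assert_array_equal(x, core.random_init(20000, seed=4))
    assert not np.array_equal(x, core.random_init(20000, seed=5))


# -- iteration -----------------------------------------------------------------


def test_single_decoupled_node_rotates_quarter_turn_per_step():
    """With A = 0 and scalar omega > 0, each step multiplies by i*omega."""
    conn = lattice.ConnectivityMatrix(
        weights=np.zeros((1, 1)), params=lattice.KernelParams(1, 1)
    )
    system = core.compose_system(conn, core.InputDrive([0.8]))
    traj = core.iterate(system, np.array([1.0 + 0j]), steps=8, stabilize=False)
    expected = np.angle(np.exp(1j * (np.pi / 2) * np.arange(9)))
    np.testing.assert_allclose(
        wrapped_phase_diff(traj.phases[:, 0], expected), 0, atol=1e-12
    )


def test_one_step_equals_matrix_vector_product():
    rng = np.random.default_rng(1)
    system = make_random_system(rng, n_side=4)
    x0 = core.random_init(16, seed=2)
    traj = core.iterate(system, x0, steps=1, stabilize=False)
    np.testing.assert_allclose(traj.states[1], system.matrix @ x0, rtol=1e-12)


def test_stabilization_preserves_phases_and_records_scale():
    rng = np.random.default_rng(3)
    system = make_random_system(rng, n_side=5)
    x0 = core.random_init(25, seed=6)
    on = core.iterate(system, x0, steps=30, stabilize=True)
    off = core.iterate(system, x0, steps=30, stabilize=False)
    assert wrapped_phase_diff(on.phases, off.phases).max() < 1e-10
    # undoing the recorded log-scale recovers the raw amplitudes
    restored = on.amplitudes[-1] * np.exp(on.log_scale[-1])
    np.testing.assert_allclose(
        restored, off.amplitudes[-1], rtol=1e-10, atol=1e-12
    )


def test_unstabilized_overflow_raises():
    conn = lattice.ConnectivityMatrix(
        weights=np.full((2, 2), 1e30), params=lattice.KernelParams(1, 1)
    )
    system = core.compose_system(conn, core.InputDrive(np.zeros(2)))
    with pytest.raises(NumericRangeError, match="stabilize"):
        core.iterate(system, np.ones(2, dtype=complex), steps=20, stabilize=False)
    # the recommended path succeeds
    core.iterate(system, np.ones(2, dtype=complex), steps=20, stabilize=True)


# -- exact spectral solution ---------------------------------------------------


@pytest.mark.parametrize("trial", range(5))
def test_spectral_solution_matches_iteration(trial):
    rng = np.random.default_rng(100 + trial)
    system = make_random_system(rng)
    x0 = core.random_init(system.n_nodes, seed=trial)
    for k in (1, 5, 20, 60):
        exact = core.spectral_solve(system, x0, k)
        traj = core.iterate(system, x0, k, stabilize=True)
        assert (
            wrapped_phase_diff(np.angle(exact), np.angle(traj.states[-1])).max()
            < 1e-8
        )


def test_spectral_solve_at_k0_reconstructs_x0():
    rng = np.random.default_rng(7)
    system = make_random_system(rng, n_side=4)
    x0 = core.random_init(16, seed=8)
    np.testing.assert_allclose(
        core.spectral_solve(system, x0, 0), x0, atol=1e-10
    )


def test_diagonal_system_has_trivial_eigenstructure():
    conn = lattice.ConnectivityMatrix(
        weights=np.zeros((4, 4)), params=lattice.KernelParams(1, 1)
    )
    omega = np.array([3.0, -2.0, 1.0, 0.5])
    system = core.compose_system(conn, core.InputDrive(omega))
    dec = core.spectral_decomposition(system)
    np.testing.assert_allclose(
        sorted(dec.lambdas.imag), sorted(omega), atol=1e-12
    )
    assert np.all(np.abs(dec.lambdas.real) < 1e-12)
    # eigenvectors are (up to phase/order) the canonical basis
    assert np.allclose(np.abs(dec.modes), np.eye(4), atol=1e-12)
    # sorted by decreasing absolute value
    assert np.all(np.diff(np.abs(dec.lambdas)) <= 1e-12)


def test_near_defective_matrix_warns_and_falls_back():
    # a Jordan-block-like coupling matrix has no usable eigenbasis
    conn = lattice.ConnectivityMatrix(
        weights=np.array([[1.0, 1.0], [0.0, 1.0]]),
        params=lattice.KernelParams(1, 1),
    )
    system = core.compose_system(conn, core.InputDrive(np.zeros(2)))
    x0 = np.array([1.0 + 0.5j, 0.3 - 0.2j])
    with pytest.warns(IllConditionedEigenbasis):
        result = core.spectral_solve(system, x0, 5)
    brute = np.linalg.matrix_power(system.matrix, 5) @ x0
    np.testing.assert_allclose(result, brute, rtol=1e-8)


def test_truncated_solve_limits():
    rng = np.random.default_rng(9)
    system = make_random_system(rng, n_side=4)
    x0 = core.random_init(16, seed=10)
    dec = core.spectral_decomposition(system)
    full = core.truncated_solve(system, x0, 12, rank=16, decomposition=dec)
    exact = core.spectral_solve(system, x0, 12, decomposition=dec)
    np.testing.assert_allclose(full, exact, atol=1e-10)
    # rank 1 at large k: phase field parallel to Arg(v1) up to global rotation
    one = core.truncated_solve(system, x0, 40, rank=1, decomposition=dec)
    rel = np.angle(one[np.abs(one) > 0] / dec.modes[:, 0][np.abs(one) > 0])
    assert wrapped_phase_diff(rel, rel[0]).max() < 1e-8
    for bad in (0, 17):
        with pytest.raises(ValueError):
            core.truncated_solve(system, x0, 5, rank=bad, decomposition=dec)
    with pytest.raises(ValueError):
        core.truncated_solve(system, x0, 5, rank=2, decomposition=dec, order="?")


def test_mode_coefficients_definition():
    rng = np.random.default_rng(11)
    system = make_random_system(rng, n_side=3)
    x0 = core.random_init(9, seed=12)
    dec = core.spectral_decomposition(system)
    mu0 = dec.coefficients(x0, 0)
    np.testing.assert_allclose(mu0, dec.left @ x0, rtol=1e-12)
    mu3 = dec.coefficients(x0, 3)
    np.testing.assert_allclose(mu3, dec.lambdas**3 * mu0, rtol=1e-12)
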