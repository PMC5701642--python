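"""Independent oracles used by the test suite.

These implement brute-force or closed-form alternatives to the package's
computation paths and are kept free of any beamcascade internals beyond
plain array inputs.
"""
import numpy as np

MU0_OVER_4PI = 1e-7


def homogeneous_sphere_potential(R_mm, sigma, node_mm, elec_mm, q):
    """Closed-form surface potential of a dipole in an insulated homogeneous
    sphere (generating-function summation of the classical series).

    Positions in mm, conductivity in S/m, unit dipole moment q; returns V/(A·m).
    """
    R = R_mm * 1e-3
    r0 = np.asarray(node_mm, float) * 1e-3
    r = np.asarray(elec_mm, float) * 1e-3
    b = np.linalg.norm(r0)
    uh = r0 / b if b > 0 else np.array([0.0, 0.0, 1.0])
    rh = r / np.linalg.norm(r)
    mu = rh @ uh
    f = b / R
    D = np.sqrt(1.0 - 2.0 * f * mu + f * f)
    g = 1.0 / D
    Sa = 2.0 * (mu - f) * g ** 3 + ((g - 1.0) / f if f > 0 else mu)
    Sb = 2.0 * g ** 3 + (D + 1.0) / (D * (1.0 - f * mu + D))
    q = np.asarray(q, float)
    return (q @ uh * Sa + (q @ (rh - mu * uh)) * Sb) / (4.0 * np.pi * sigma * R * R)


def geselowitz_sphere_field(sensor_mm, node_mm, q, R_mm, sigma,
                            n_quad: int = 60000):
    """MEG field of a dipole in a homogeneous conducting sphere by dense
    surface quadrature of the volume-current (secondary-source) integral.

    B(r) = B_primary(r) - (mu0 sigma / 4 pi) * ∮ V(r') n' x (r-r')/|r-r'|^3 dS'
    with V the closed-form surface potential above.  Returns Tesla per (A·m).
    """
    r = np.asarray(sensor_mm, float) * 1e-3
    r0 = np.asarray(node_mm, float) * 1e-3
    q = np.asarray(q, float)
    R = R_mm * 1e-3

    d = r - r0
    B = MU0_OVER_4PI * np.cross(q, d) / np.linalg.norm(d) ** 3

    # Fibonacci quadrature points on the sphere surface
    i = np.arange(n_quad, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n_quad
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    rho = np.sqrt(1.0 - z * z)
    nhat = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    pts = nhat * R
    dS = 4.0 * np.pi * R * R / n_quad

    V = np.array([homogeneous_sphere_potential(R_mm, sigma, node_mm,
                                               p * 1e3, q) for p in pts])
    diff = r[None, :] - pts
    dist3 = np.linalg.norm(diff, axis=1) ** 3
    integrand = np.cross(nhat, diff / dist3[:, None])
    B -= MU0_OVER_4PI * sigma * dS * (V[:, None] * integrand).sum(axis=0)
    return B


def covariance_double_loop(B):
    """Entrywise (1/T) sum_t B(t) B(t)^T by explicit loops."""
    B = np.asarray(B, float)
    n, t = B.shape
    C = np.zeros((n, n))
    for k in range(t):
        for i in range(n):
            for j in range(n):
                C[i, j] += B[i, k] * B[j, k]
    return C / t


def grid_directions(n: int = 10000) -> np.ndarray:
    """Quasi-uniform unit directions (Fibonacci sphere)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    rho = np.sqrt(1.0 - z * z)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def orientation_objective(gain, Cinv, constraint, dirs):
    """Constrained output variance as a function of direction, vectorized.

    unit gain: 1/(u^T A u);  unit array gain: (u^T G u)/(u^T A u);
    unit noise gain: (u^T A u)/(u^T A2 u), with A = L^T C^-1 L,
    G = L^T L, A2 = L^T C^-2 L.
    """
    CiL = Cinv @ gain
    A = gain.T @ CiL
    G = gain.T @ gain
    A2 = CiL.T @ CiL
    qa = np.einsum("ni,ij,nj->n", dirs, A, dirs)
    if constraint == "unit_gain":
        return 1.0 / qa
    if constraint == "unit_array_gain":
        return np.einsum("ni,ij,nj->n", dirs, G, dirs) / qa
    return qa / np.einsum("ni,ij,nj->n", dirs, A2, dirs)


def excess_kurtosis_direct(x):
    """Direct transcription of the moment-ratio definition."""
    x = np.asarray(x, float)
    t = x.size
    xbar = x.sum() / t
    m2 = ((x - xbar) ** 2).sum() / t
    m4 = ((x - xbar) ** 4).sum() / t
    return m4 / m2 ** 2 - 3.0
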