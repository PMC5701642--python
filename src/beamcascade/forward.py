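"""Synthetic forward models: sensor arrays, source spaces and leadfields.

Analytic spherical volume conductors stand in for subject-specific head
models.  EEG potentials come from a multi-shell concentric-sphere series
solution; MEG fields from the closed-form solution for a spherically
symmetric conductor (Sarvas).  A controlled, spatially smooth leadfield
perturbation emulates a cascade of progressively simplified head models
whose forward solutions diverge from a reference model by a prescribed
relative amount.

Conventions: right-handed coordinates, millimeters, conductor center at the
origin.  Leadfield units are SI — V/(A·m) for EEG, T/(A·m) for MEG.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from ._utils import fibonacci_sphere, fix_sign, random_rotation, unit
from .errors import ConfigurationError, ConstructionError, DegenerateInputError, DomainError

MU0_OVER_4PI = 1e-7  # T·m/A

# Compartment conductivities (S/m): brain 0.33, CSF 1.79, skin 0.43,
# homogenized skull 0.01, skull compacta 0.0081, skull spongiosa 0.025.
SIGMA = {
    "brain": 0.33,
    "csf": 1.79,
    "skin": 0.43,
    "skull": 0.01,
    "compacta": 0.0081,
    "spongiosa": 0.025,
}


@dataclass(frozen=True)
class ShellModel:
    """Concentric-shell volume conductor.

    radii are the *outer* radii of the shells in mm, strictly increasing from
    the innermost (brain) outward; conductivities are per-shell in S/m.
    """

    radii: tuple
    conductivities: tuple
    label: str = ""

    def __post_init__(self):
        r = np.asarray(self.radii, float)
        s = np.asarray(self.conductivities, float)
        if r.size < 1 or r.size != s.size:
            raise ConfigurationError("need matching, non-empty radii and conductivities")
        if np.any(np.diff(r) <= 0):
            raise ConfigurationError("shell radii must be strictly increasing")
        if np.any(s <= 0):
            raise ConfigurationError("conductivities must be positive")

    @property
    def inner_radius(self) -> float:
        return float(self.radii[0])

    @property
    def outer_radius(self) -> float:
        return float(self.radii[-1])


# Default sphere geometry (mm): brain 80, CSF 85, skull 90, skin 92; sources
# live on a 70 mm "cortex" sphere.  The cascade adds conductive detail
# monotonically: 3C has no CSF shell (brain extends to 85 mm), 4C separates
# the CSF, 6C splits the skull into compacta/spongiosa/compacta.
_R4 = (80.0, 85.0, 90.0, 92.0)
_R6 = (80.0, 85.0, 86.5, 88.5, 90.0, 92.0)

_CASCADE = {
    "3C": ShellModel((85.0, 90.0, 92.0), (SIGMA["brain"], SIGMA["skull"], SIGMA["skin"]), "3C"),
    "4C": ShellModel(_R4, (SIGMA["brain"], SIGMA["csf"], SIGMA["skull"], SIGMA["skin"]), "4C"),
    "6C": ShellModel(
        _R6,
        (SIGMA["brain"], SIGMA["csf"], SIGMA["compacta"], SIGMA["spongiosa"],
         SIGMA["compacta"], SIGMA["skin"]),
        "6C",
    ),
}
_CASCADE["reference"] = ShellModel(_R6, _CASCADE["6C"].conductivities, "reference")

CASCADE_LEVELS = tuple(_CASCADE.keys())


def make_shell_model(cascade_level: str) -> ShellModel:
    """Return the registered shell model for a cascade level.

    Levels "3C" -> "4C" -> "6C" -> "reference" add conductive detail
    monotonically: 3C merges CSF into brain, 4C separates CSF (sigma = 1.79
    S/m), 6C additionally splits the skull into compacta and spongiosa, and
    "reference" is the most detailed registered profile.
    """
    try:
        return _CASCADE[cascade_level]
    except KeyError:
        raise ConfigurationError(
            f"unknown cascade level {cascade_level!r}; registered: {sorted(_CASCADE)}"
        ) from None


@dataclass
class SensorArray:
    """EEG electrode or MEG gradiometer array.

    positions are in mm.  For MEG, ``orientations`` holds the (unit) coil
    normals of axial gradiometers and ``gradiometer_baseline`` the distance to
    the second coil along the normal.  EEG arrays carry a common-average
    reference by default.
    """

    positions: np.ndarray
    modality: str
    orientations: Optional[np.ndarray] = None
    gradiometer_baseline: Optional[float] = None
    reference: str = "none"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        if self.modality not in ("eeg", "meg"):
            raise ConfigurationError("modality must be 'eeg' or 'meg'")
        if self.orientations is not None:
            self.orientations = np.asarray(self.orientations, float)
            n = np.linalg.norm(self.orientations, axis=1)
            if not np.allclose(n, 1.0, atol=1e-9):
                raise ConfigurationError("sensor orientations must be unit-norm")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]


def make_eeg_sensors(n: int = 80, shell: Optional[ShellModel] = None,
                     zmin: float = -0.35) -> SensorArray:
    """Quasi-uniform electrode cap on the outer shell surface.

    80 channels emulate a dense 10/10-style montage; the cap covers the zone
    z/R > zmin, leaving the face/neck region free.  Common average reference.
    """
    shell = shell or make_shell_model("reference")
    dirs = fibonacci_sphere(n, zmin=zmin, zmax=1.0)
    return SensorArray(positions=dirs * shell.outer_radius, modality="eeg",
                       reference="common_average")


def make_meg_sensors(n: int = 273, helmet_radius: float = 110.0,
                     baseline: float = 50.0, zmin: float = -0.25) -> SensorArray:
    """Helmet-like cap of axial gradiometers with radial coil normals.

    273 channels and a 50 mm baseline emulate a whole-head axial-gradiometer
    system; the second coil of each gradiometer sits at
    position + baseline * orientation (radially outward).
    """
    dirs = fibonacci_sphere(n, zmin=zmin, zmax=1.0)
    return SensorArray(positions=dirs * helmet_radius, modality="meg",
                       orientations=dirs.copy(), gradiometer_baseline=baseline)


@dataclass
class SourceSpace:
    """Candidate source positions for the inverse scan (mm).

    Nodes lie on a "cortex" sphere strictly inside the innermost shell.  The
    nearest node to every reference source has been displaced into the
    (0.5, 0.6) mm band so that the best achievable localization error is
    bounded but never zero (no inverse crime).
    """

    node_positions: np.ndarray
    cortex_radius: float
    displaced_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def node_count(self) -> int:
        return self.node_positions.shape[0]

    @property
    def grid_spacing_stats(self) -> dict:
        tree = cKDTree(self.node_positions)
        d, _ = tree.query(self.node_positions, k=2)
        nn = d[:, 1]
        return {"min_nn_mm": float(nn.min()), "median_nn_mm": float(np.median(nn))}


# Offset band for the anti-inverse-crime rule: every reference source must be
# more than 0.5 mm and less than 0.6 mm from its nearest grid node.
OFFSET_BAND = (0.5, 0.6)
_OFFSET_TARGET = 0.55


def make_reference_sources(n: int = 60, cortex_radius: float = 70.0,
                           seed: int = 0) -> np.ndarray:
    """Quasi-uniform reference (simulated) source positions on the cortex sphere."""
    rng = np.random.default_rng(seed)
    dirs = fibonacci_sphere(n) @ random_rotation(rng).T
    return dirs * cortex_radius


def build_source_space(n_nodes: int, shells: ShellModel,
                       reference_sources: np.ndarray, seed: int,
                       cortex_radius: Optional[float] = None) -> SourceSpace:
    """Quasi-uniform inverse source space with the reference-source offset rule.

    Nodes are placed quasi-uniformly on the cortex sphere (randomly rotated by
    ``seed``); then, for each reference source in index order, its nearest node
    is displaced along the node-minus-source direction to exactly 0.55 mm, the
    midpoint of the (0.5, 0.6) mm band.  Construction fails if the displaced
    node is no longer the nearest node of its reference source.
    """
    if n_nodes < 2:
        raise ConstructionError("need at least 2 source-space nodes")
    refs = np.atleast_2d(np.asarray(reference_sources, float))
    if cortex_radius is None:
        cortex_radius = 0.875 * shells.inner_radius
    if cortex_radius + OFFSET_BAND[1] >= shells.inner_radius:
        raise ConstructionError("cortex sphere too close to the innermost shell")
    if np.any(np.linalg.norm(refs, axis=1) >= shells.inner_radius):
        raise DomainError("reference sources must lie strictly inside the innermost shell")

    rng = np.random.default_rng(seed)
    nodes = (fibonacci_sphere(n_nodes) @ random_rotation(rng).T) * cortex_radius

    taken: dict[int, int] = {}
    for i, ref in enumerate(refs):
        d = np.linalg.norm(nodes - ref, axis=1)
        j = int(np.argmin(d))  # ties -> lowest index
        if j in taken:
            raise ConstructionError(
                f"reference sources {taken[j]} and {i} share nearest node {j}; "
                "increase the node density")
        direction = nodes[j] - ref
        nd = np.linalg.norm(direction)
        direction = ref / np.linalg.norm(ref) if nd == 0 else direction / nd
        nodes[j] = ref + _OFFSET_TARGET * direction
        taken[j] = i

    # verify the offset rule holds for every reference source
    tree = cKDTree(nodes)
    dmin, _ = tree.query(refs)
    for i in range(refs.shape[0]):
        if not (OFFSET_BAND[0] < dmin[i] < OFFSET_BAND[1]):
            raise ConstructionError(
                f"offset rule violated for reference source {i}: nearest node at "
                f"{dmin[i]:.3f} mm (required in ({OFFSET_BAND[0]}, {OFFSET_BAND[1]}))")
    if np.any(np.linalg.norm(nodes, axis=1) >= shells.inner_radius):
        raise ConstructionError("a node left the innermost shell")
    return SourceSpace(node_positions=nodes, cortex_radius=float(cortex_radius),
                       displaced_nodes=np.array(sorted(taken), int))


@dataclass
class Leadfield:
    """Forward gain for one or many source positions.

    ``gain`` has shape (n_sensors, 3) for a single position or
    (n_sensors, n_nodes, 3) for a stacked source space; columns are the gains
    of unit dipoles along x, y, z.
    """

    gain: np.ndarray
    units: str
    model_label: str = ""
    modality: str = ""
    referenced: bool = False
    node_positions: Optional[np.ndarray] = None

    def __post_init__(self):
        self.gain = np.asarray(self.gain, float)
        if not np.all(np.isfinite(self.gain)):
            raise DegenerateInputError("leadfield gain contains non-finite entries")

    def node_gain(self, j: int) -> np.ndarray:
        if self.gain.ndim == 2:
            return self.gain
        return self.gain[:, j, :]


def _legendre_terms(mu: np.ndarray, n_terms: int):
    """Yield (n, P_n(mu), P'_n(mu)) for n = 1..n_terms via stable recurrences."""
    p_prev = np.ones_like(mu)   # P_0
    p = mu.copy()               # P_1
    dp = np.ones_like(mu)       # P_1'
    yield 1, p, dp
    for n in range(2, n_terms + 1):
        p_next = ((2 * n - 1) * mu * p - (n - 1) * p_prev) / n
        # derivative recurrence: (1-mu^2) P_n' = n (P_{n-1} - mu P_n); at the
        # poles use P_n'(+-1) = (+-1)^{n+1} n (n+1) / 2
        one_minus = 1.0 - mu * mu
        with np.errstate(divide="ignore", invalid="ignore"):
            dp_next = n * (p - mu * p_next) / one_minus
        pole = one_minus < 1e-14
        if np.any(pole):
            sgn = np.where(mu[pole] > 0, 1.0, (-1.0) ** (n + 1))
            dp_next[pole] = sgn * n * (n + 1) / 2.0
        p_prev, p = p, p_next
        dp = dp_next
        yield n, p, dp


def _shell_surface_coeffs(shells: ShellModel, n_terms: int) -> np.ndarray:
    """Per-order surface transfer coefficients v_n for the multi-shell sphere.

    For each harmonic order n the radial profile in shell k is
    a_k s^n + b_k s^-(n+1) (s = r/R normalized radius), with the primary
    dipole term carrying coefficient 1 on s^-(n+1) in the innermost shell.
    Continuity of potential and of radial current at each interface plus the
    insulating outer boundary give a small linear system; v_n = a_M + b_M is
    the surface value multiplying the homogeneous-medium source expansion.
    For a single shell v_n = (2n+1)/n.
    """
    rho = np.asarray(shells.radii, float) / shells.outer_radius
    sig = np.asarray(shells.conductivities, float)
    m = rho.size
    out = np.empty(n_terms)
    for n in range(1, n_terms + 1):
        # unknowns: a_1, (a_k, b_k) for k=2..m  -> 2m-1
        k_unk = 2 * m - 1
        A = np.zeros((k_unk, k_unk))
        rhs = np.zeros(k_unk)

        def col_a(k):  # index of a_k
            return 0 if k == 1 else 2 * k - 3

        def col_b(k):  # index of b_k (k >= 2)
            return 2 * k - 2

        row = 0
        for k in range(1, m):
            r = rho[k - 1]
            rn, rminus = r ** n, r ** (-(n + 1))
            # potential continuity
            A[row, col_a(k)] += rn
            if k >= 2:
                A[row, col_b(k)] += rminus
            A[row, col_a(k + 1)] -= rn
            A[row, col_b(k + 1)] -= rminus
            if k == 1:
                rhs[row] = -rminus  # primary b_1 = 1 moved to RHS
            row += 1
            # radial current continuity
            drn, drminus = n * r ** (n - 1), -(n + 1) * r ** (-(n + 2))
            A[row, col_a(k)] += sig[k - 1] * drn
            if k >= 2:
                A[row, col_b(k)] += sig[k - 1] * drminus
            A[row, col_a(k + 1)] -= sig[k] * drn
            A[row, col_b(k + 1)] -= sig[k] * drminus
            if k == 1:
                rhs[row] = -sig[0] * drminus
            row += 1
        # insulating outer boundary at s=1: n a_M - (n+1) b_M = 0
        if m == 1:
            A[row, col_a(1)] = n
            rhs[row] = (n + 1) * 1.0
        else:
            A[row, col_a(m)] = n
            A[row, col_b(m)] = -(n + 1)
        sol = np.linalg.solve(A, rhs)
        if m == 1:
            out[n - 1] = 1.0 + sol[col_a(1)]
        else:
            out[n - 1] = sol[col_a(m)] + sol[col_b(m)]
    return out


def eeg_sphere_leadfield(shells: ShellModel, electrodes: SensorArray,
                         node: np.ndarray, n_terms: int = 60,
                         tail_tol: float = 1e-6) -> np.ndarray:
    """EEG potential gain (V/(A·m)) of unit dipoles at ``node``.

    Truncated spherical-harmonic series for a dipole inside the innermost
    shell of a concentric multi-shell conductor, evaluated at electrodes on
    the outer surface and re-referenced to the common average.  A warning is
    emitted when the estimated series tail exceeds ``tail_tol`` relative to
    the accumulated sum.
    """
    node = np.asarray(node, float)
    b_mm = np.linalg.norm(node)
    if b_mm >= shells.inner_radius:
        raise DomainError("dipole must lie strictly inside the innermost shell")
    if electrodes.modality != "eeg":
        raise ConfigurationError("electrode array must have modality 'eeg'")
    pos = electrodes.positions
    radii = np.linalg.norm(pos, axis=1)
    R_mm = shells.outer_radius
    if not np.allclose(radii, R_mm, rtol=1e-6):
        raise DomainError("electrodes must lie on the outer shell surface")

    # work in meters
    R = R_mm * 1e-3
    b = b_mm * 1e-3
    x = b_mm / R_mm
    u_hat = node / b_mm if b_mm > 0 else np.array([0.0, 0.0, 1.0])
    r_hat = pos / radii[:, None]
    mu = r_hat @ u_hat

    v = _shell_surface_coeffs(shells, n_terms)
    c0 = 1.0 / (4.0 * np.pi * shells.conductivities[0] * R * R)

    gain = np.zeros((pos.shape[0], 3))
    last_term = 0.0
    for n, p, dp in _legendre_terms(mu, n_terms):
        radial = x ** (n - 1) * v[n - 1]
        # unit dipole along axis i: q·u_hat = u_hat[i], q·(r_hat - mu u_hat)
        term = radial * (n * p[:, None] * u_hat[None, :]
                         + dp[:, None] * (r_hat - mu[:, None] * u_hat[None, :]))
        gain += term
        last_term = float(np.max(np.abs(term)))
    scale = float(np.max(np.abs(gain))) or 1.0
    if last_term / scale > tail_tol:
        warnings.warn(
            f"EEG sphere series not converged at n_terms={n_terms} "
            f"(last-term ratio {last_term / scale:.2e}); increase n_terms",
            RuntimeWarning, stacklevel=2)
    gain *= c0
    if electrodes.reference == "common_average":
        gain -= gain.mean(axis=0, keepdims=True)
    return gain


def meg_sphere_leadfield(sensors: SensorArray, node: np.ndarray,
                         center: np.ndarray = None) -> np.ndarray:
    """MEG gain (T/(A·m)) of unit dipoles at ``node`` in a spherical conductor.

    Closed-form field of a current dipole in a spherically symmetric
    conductor; the result depends only on the conductor center, not on shell
    radii or conductivities.  For axial gradiometers the gain is the field at
    the first coil minus the field at the second coil, both projected on the
    coil normal.
    """
    node = np.asarray(node, float)
    center = np.zeros(3) if center is None else np.asarray(center, float)
    if np.allclose(node, center):
        raise DomainError("dipole at the conductor center has no MEG signal model")
    if sensors.modality != "meg":
        raise ConfigurationError("sensor array must have modality 'meg'")

    r0 = (node - center) * 1e-3  # meters, conductor frame
    coils = [(sensors.positions - center[None, :]) * 1e-3]
    if sensors.gradiometer_baseline:
        coils.append(((sensors.positions
                       + sensors.gradiometer_baseline * sensors.orientations)
                      - center[None, :]) * 1e-3)

    normals = sensors.orientations
    if normals is None:
        normals = unit(sensors.positions - center[None, :])

    gain = np.zeros((sensors.n_channels, 3))
    sign = 1.0
    for cpos in coils:
        B = _sarvas_field(cpos, r0)          # (n, 3 dipole dirs, 3 field comps)
        gain += sign * np.einsum("nij,nj->ni", B.transpose(0, 2, 1), normals)
        sign = -1.0
    return gain


def _sarvas_field(r: np.ndarray, r0: np.ndarray) -> np.ndarray:
    """Field of unit dipoles along x,y,z at r0 (m), sensors r (n,3) in meters.

    Returns array (n, 3 field components, 3 dipole directions).
    """
    a = r - r0[None, :]
    na = np.linalg.norm(a, axis=1)
    nr = np.linalg.norm(r, axis=1)
    if np.any(na == 0):
        raise DomainError("sensor coincides with the dipole position")
    F = na * (nr * na + nr * nr - r @ r0)
    adotr = np.einsum("ni,ni->n", a, r)
    gradF = ((na * na / nr + adotr / na + 2 * na + 2 * nr)[:, None] * r
             - (na + 2 * nr + adotr / na)[:, None] * r0[None, :])
    out = np.empty((r.shape[0], 3, 3))
    for i, q in enumerate(np.eye(3)):
        qxr0 = np.cross(q, r0)
        qxr0_dot_r = r @ qxr0
        B = MU0_OVER_4PI * (F[:, None] * qxr0[None, :]
                            - qxr0_dot_r[:, None] * gradF) / (F * F)[:, None]
        out[:, :, i] = B
    return out


def compute_leadfields(model, sensors: SensorArray, positions: np.ndarray,
                       n_terms: int = 60) -> Leadfield:
    """Stacked leadfield tensor (sensors x nodes x 3) for many positions.

    ``model`` is a ShellModel (EEG) or ignored up to the conductor center
    (MEG, where only spherical symmetry matters).
    """
    positions = np.atleast_2d(np.asarray(positions, float))
    n = positions.shape[0]
    gain = np.empty((sensors.n_channels, n, 3))
    if sensors.modality == "eeg":
        for j in range(n):
            gain[:, j, :] = eeg_sphere_leadfield(model, sensors, positions[j],
                                                 n_terms=n_terms)
        units, ref = "V/(A·m)", sensors.reference == "common_average"
        label = getattr(model, "label", "")
    else:
        for j in range(n):
            gain[:, j, :] = meg_sphere_leadfield(sensors, positions[j])
        units, ref = "T/(A·m)", False
        label = "sphere"
    return Leadfield(gain=gain, units=units, model_label=label,
                     modality=sensors.modality, referenced=ref,
                     node_positions=positions)


def reference_orientations(gain: np.ndarray):
    """Quasi-radial and quasi-tangential source directions from a gain matrix.

    Unit eigenvectors of the 3x3 Gram matrix gain^T gain for the smallest
    (quasi-radial, weakest coupling) and largest (quasi-tangential, strongest
    coupling) eigenvalue.  The pair is orthogonal.
    """
    gain = np.asarray(gain, float)
    if not np.any(gain):
        raise DegenerateInputError("all-zero gain has no preferred orientations")
    gram = gain.T @ gain
    w, v = np.linalg.eigh(gram)
    return fix_sign(v[:, 0]), fix_sign(v[:, -1])


def perturb_leadfield(lead: Leadfield, level: float, seed: int,
                      length_scale: float = 10.0, n_centers: int = 512) -> Leadfield:
    """Add a smooth, spatially correlated perturbation of prescribed size.

    The perturbation is a random linear combination of Gaussian bumps
    (width ``length_scale`` mm) centered on a random subset of nodes, scaled
    so that ||dL||_F / ||L||_F equals ``level`` exactly; it is deterministic
    given ``seed``.  EEG perturbations are re-referenced to the common
    average before scaling, so the output stays average-referenced.
    """
    if level < 0:
        raise ValueError("perturbation level must be >= 0")
    gain = lead.gain if lead.gain.ndim == 3 else lead.gain[:, None, :]
    if level == 0:
        out = lead.gain.copy()
        return Leadfield(gain=out, units=lead.units,
                         model_label=f"{lead.model_label}+perturb0.0",
                         modality=lead.modality, referenced=lead.referenced,
                         node_positions=lead.node_positions)
    if lead.node_positions is None:
        raise ValueError("perturbation requires node_positions on the leadfield")
    pos = np.atleast_2d(lead.node_positions)
    rng = np.random.default_rng(seed)
    m = min(n_centers, pos.shape[0])
    centers = pos[rng.choice(pos.shape[0], size=m, replace=False)]
    d2 = ((pos[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    phi = np.exp(-0.5 * d2 / length_scale ** 2)          # (nodes, m)
    coeff = rng.standard_normal((gain.shape[0], 3, m))   # (sensors, 3, m)
    delta = np.einsum("scm,jm->sjc", coeff, phi)
    if lead.referenced:
        delta -= delta.mean(axis=0, keepdims=True)
    nd = np.linalg.norm(delta)
    if nd == 0:
        raise ConstructionError("degenerate perturbation field")
    delta *= level * np.linalg.norm(gain) / nd
    new = gain + delta
    if lead.gain.ndim == 2:
        new = new[:, 0, :]
    return Leadfield(gain=new, units=lead.units,
                     model_label=f"{lead.model_label}+perturb{level:g}",
                     modality=lead.modality, referenced=lead.referenced,
                     node_positions=lead.node_positions)
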