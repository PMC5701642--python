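"""Scalar LCMV beamformer filters, orientations and outputs.

Three normalizations of the linearly constrained minimum-variance filter
are provided, distinguished by their gain constraint on the target
leadfield L = **L** D (with **L** the N x 3 gain and D the unit source
orientation):

* unit gain:        WᵀL = 1,      W = C⁻¹L / (LᵀC⁻¹L)
* unit array gain:  WᵀL = ‖L‖,   W = ‖L‖ C⁻¹L / (LᵀC⁻¹L)
* unit noise gain:  WᵀW = 1 and WᵀL > 0,  W = C⁻¹L / sqrt(LᵀC⁻²L)

so the array-gain and noise-gain filters are scaled versions of the
unit-gain filter (W_uag = ‖L‖ W_ug, W_ung = W_ug/‖W_ug‖).  The source
orientation is data-driven: the unit vector maximizing the constrained
output variance, obtained from a 3x3 (generalized) eigenvalue problem per
constraint.  Localization maps use either the output variance Var(WᵀB) or
the excess sample kurtosis g2(WᵀB) of the filtered waveform.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import scipy.linalg

from ._utils import fix_sign
from .errors import DegenerateInputError, InversionError

CONSTRAINTS = ("unit_gain", "unit_array_gain", "unit_noise_gain")


@dataclass
class Covariance:
    """Sample covariance C = (1/T) sum_t B(t)B(t)ᵀ with cached factorizations.

    ``loading`` is an optional relative diagonal-loading factor: inversions
    use C + loading * trace(C)/N * I.  Loading regularizes a rank-deficient
    covariance and acts like adding perfectly white sensor noise; it is off
    by default.
    """

    matrix: np.ndarray
    n_samples: int
    loading: float = 0.0
    _solve_cache: Optional[tuple] = field(default=None, repr=False, compare=False)

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def loaded_matrix(self) -> np.ndarray:
        if self.loading == 0.0:
            return self.matrix
        lam = self.loading * np.trace(self.matrix) / self.n_channels
        return self.matrix + lam * np.eye(self.n_channels)

    def _factor(self):
        if self._solve_cache is None:
            w, v = np.linalg.eigh(self.loaded_matrix)
            if w[-1] <= 0:
                raise InversionError("sample covariance has no positive eigenvalue")
            keep = w > 1e-10 * w[-1]
            # a common-average-referenced measurement is structurally rank
            # N-1; tolerate that, but reject a covariance that is deficient
            # beyond it (e.g. near-noiseless data) unless loading is on
            if keep.sum() < self.n_channels - 2:
                raise InversionError(
                    "sample covariance is numerically singular; enable diagonal "
                    "loading (Covariance.loading > 0) or add sensor noise")
            self._solve_cache = (w[keep], v[:, keep])
        return self._solve_cache

    def solve(self, x: np.ndarray) -> np.ndarray:
        """C⁻¹ x via the cached eigendecomposition (loading applied).

        Eigenvalues below 1e-10 of the largest are truncated, so a
        common-average-referenced covariance is inverted on its zero-mean
        subspace (where the referenced leadfields also live).
        """
        w, v = self._factor()
        return v @ ((v.T @ x).T / w).T


def sample_covariance(B, loading: float = 0.0) -> Covariance:
    """The 1/T (not 1/(T-1)) outer-product average of a demeaned measurement."""
    data = B.data if hasattr(B, "data") else np.asarray(B, float)
    data = np.atleast_2d(data)
    t = data.shape[1]
    if t < 2:
        raise ValueError("need at least 2 samples for a covariance")
    c = data @ data.T / t
    c = 0.5 * (c + c.T)
    return Covariance(matrix=c, n_samples=t, loading=loading)


def frobenius_normalize(gain: np.ndarray) -> np.ndarray:
    """gain / ||gain||_F — the depth-bias correction of the unit-gain variant.

    Applied to the three-dimensional leadfield before building the unit-gain
    filter only; it does not enter the orientation computation.
    """
    gain = np.asarray(gain, float)
    nf = np.linalg.norm(gain)
    if nf == 0:
        raise DegenerateInputError("cannot normalize an all-zero gain")
    return gain / nf


def excess_kurtosis(x) -> float:
    """Biased sample excess kurtosis g2 = m4/m2² - 3 (1/T moments).

    Positive for heavy-tailed (spike-containing) waveforms, 0 for Gaussian
    data, and never below -2.  Raises on zero sample variance rather than
    returning a conventional value.
    """
    x = np.asarray(x, float).ravel()
    if x.size < 4:
        raise ValueError("need at least 4 samples for kurtosis")
    d = x - x.mean()
    m2 = np.mean(d * d)
    if m2 <= 1e-14 * np.mean(x * x):
        raise DegenerateInputError("zero sample variance: kurtosis undefined")
    return float(np.mean(d ** 4) / m2 ** 2 - 3.0)


def _excess_kurtosis_rows(y: np.ndarray) -> np.ndarray:
    d = y - y.mean(axis=1, keepdims=True)
    m2 = np.mean(d * d, axis=1)
    m4 = np.mean(d ** 4, axis=1)
    out = np.full(y.shape[0], np.nan)
    ok = m2 > 1e-14 * np.mean(y * y, axis=1)
    out[ok] = m4[ok] / m2[ok] ** 2 - 3.0
    return out


# Right-singular directions of the gain with sigma below this (relative to
# sigma_max) are excluded from the orientation search: they carry no signal
# (e.g. the exactly silent radial direction of spherical MEG).
_GAIN_RANK_TOL = 1e-8
_TIE_TOL = 1e-9


def optimal_orientation(gain: np.ndarray, C: Covariance, constraint: str) -> np.ndarray:
    """Variance-optimal unit source orientation for the given constraint.

    Solves the 3x3 (generalized) eigenvalue problem of the constraint's
    output-variance Rayleigh quotient: unit gain takes the minimal
    eigenvector of A = **L**ᵀC⁻¹**L**; unit array gain the maximal
    generalized eigenvector of (**L**ᵀ**L**, A); unit noise gain the maximal
    generalized eigenvector of (A, **L**ᵀC⁻²**L**).  If the gain is
    numerically rank-deficient the problem is restricted to its
    right-singular subspace.  When every candidate direction is equivalent
    (e.g. C proportional to the identity for the noise-gain pencil) the
    documented tie-break returns the largest right singular vector of the
    gain.  The returned vector is unit-norm with a deterministic sign
    (largest-magnitude component positive).
    """
    if constraint not in CONSTRAINTS:
        raise ValueError(f"unknown constraint {constraint!r}")
    gain = np.asarray(gain, float)
    if not np.any(gain):
        raise DegenerateInputError("all-zero gain has no orientation")
    u_svd, s, vt = np.linalg.svd(gain, full_matrices=False)
    keep = s > _GAIN_RANK_TOL * s[0]
    V = vt[keep].T                      # 3 x k subspace basis
    G = gain @ V                        # N x k reduced gain
    CiG = C.solve(G)
    A = G.T @ CiG
    A = 0.5 * (A + A.T)
    if constraint == "unit_gain":
        w, vec = np.linalg.eigh(A)
        ties = (w[-1] - w[0]) <= _TIE_TOL * max(abs(w[-1]), 1e-300)
        u = V @ vec[:, 0]
    else:
        if constraint == "unit_array_gain":
            num = G.T @ G
        else:  # unit_noise_gain
            num, A = A, CiG.T @ CiG
            A = 0.5 * (A + A.T)
        num = 0.5 * (num + num.T)
        try:
            w, vec = scipy.linalg.eigh(num, A)
        except scipy.linalg.LinAlgError as e:
            raise DegenerateInputError(f"singular orientation pencil: {e}") from e
        ties = (w[-1] - w[0]) <= _TIE_TOL * max(abs(w[-1]), 1e-300)
        u = V @ vec[:, -1]
    if ties:
        u = vt[0]
    return fix_sign(u / np.linalg.norm(u))


@dataclass
class BeamformerFilter:
    """LCMV weight vector with its orientation and constraint."""

    weights: np.ndarray
    orientation: np.ndarray
    constraint: str
    node: Optional[int] = None


def filter_weights(L: np.ndarray, C: Covariance, constraint: str) -> np.ndarray:
    """Closed-form LCMV weights for a fixed 1-D leadfield L."""
    if constraint not in CONSTRAINTS:
        raise ValueError(f"unknown constraint {constraint!r}")
    L = np.asarray(L, float)
    if not np.any(L):
        raise DegenerateInputError("zero leadfield")
    CiL = C.solve(L)
    denom = float(L @ CiL)
    if denom <= 0:
        raise InversionError("LᵀC⁻¹L not positive; covariance inversion failed")
    if constraint == "unit_gain":
        return CiL / denom
    if constraint == "unit_array_gain":
        return np.linalg.norm(L) * CiL / denom
    return CiL / np.linalg.norm(CiL)  # unit noise gain


def make_filter(gain: np.ndarray, C: Covariance, constraint: str,
                node: Optional[int] = None) -> BeamformerFilter:
    """Orientation + weights for a 3-column gain under the given constraint.

    The orientation is estimated from the unnormalized gain; for the
    unit-gain variant the filter itself is then built from the
    Frobenius-normalized leadfield (the depth-bias correction), which leaves
    the orientation computation untouched.
    """
    u = optimal_orientation(gain, C, constraint)
    g = frobenius_normalize(gain) if constraint == "unit_gain" else np.asarray(gain, float)
    w = filter_weights(g @ u, C, constraint)
    return BeamformerFilter(weights=w, orientation=u, constraint=constraint, node=node)


def variance_output(weights, B_or_cov) -> float:
    """Beamformer output variance Var(WᵀB) = WᵀCW (>= 0)."""
    w = weights.weights if isinstance(weights, BeamformerFilter) else np.asarray(weights, float)
    cov = B_or_cov if isinstance(B_or_cov, Covariance) else sample_covariance(B_or_cov)
    return float(w @ cov.matrix @ w)


@dataclass
class ScanOutput:
    """Per-node beamformer outputs over the inverse source space."""

    node: int
    position: np.ndarray
    variance_output: float
    kurtosis_output: float
    orientation: np.ndarray
    constraint: str
    ok: bool = True
    note: str = ""


def scan(source_space, leadfields, B, constraint: str,
         loading: float = 0.0) -> List[ScanOutput]:
    """Variance and excess-kurtosis beamformer maps over the source space.

    For every node: the variance-optimal orientation for ``constraint``, the
    corresponding filter, the output variance WᵀCW, and the excess kurtosis
    of the same filtered waveform WᵀB.  Degenerate nodes are reported with
    ok=False and NaN outputs (with a warning), never silently zeroed; the
    returned list always has one entry per node.
    """
    nodes = source_space.node_positions
    n_nodes = nodes.shape[0]
    data = B.data if hasattr(B, "data") else np.asarray(B, float)
    C = sample_covariance(data, loading=loading)

    W = np.zeros((n_nodes, data.shape[0]))
    outputs: List[ScanOutput] = []
    bad = []
    for j in range(n_nodes):
        g = leadfields.node_gain(j)
        try:
            f = make_filter(g, C, constraint, node=j)
        except (DegenerateInputError, InversionError) as e:
            bad.append((j, str(e)))
            outputs.append(ScanOutput(node=j, position=nodes[j], variance_output=np.nan,
                                      kurtosis_output=np.nan, orientation=np.full(3, np.nan),
                                      constraint=constraint, ok=False, note=str(e)))
            continue
        W[j] = f.weights
        outputs.append(ScanOutput(node=j, position=nodes[j], variance_output=0.0,
                                  kurtosis_output=0.0, orientation=f.orientation,
                                  constraint=constraint))
    if bad:
        warnings.warn(f"{len(bad)} degenerate node(s) skipped in scan "
                      f"(first: node {bad[0][0]}: {bad[0][1]})", RuntimeWarning,
                      stacklevel=2)
    var = np.einsum("mn,nk,mk->m", W, C.matrix, W)
    Y = W @ data
    g2 = _excess_kurtosis_rows(Y)
    for out in outputs:
        if out.ok:
            out.variance_output = float(var[out.node])
            out.kurtosis_output = float(g2[out.node])
            if not np.isfinite(out.kurtosis_output):
                out.ok = False
                out.note = "zero-variance filtered waveform"
    return outputs
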