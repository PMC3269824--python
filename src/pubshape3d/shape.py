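"""Gaussian molecular shape: volumes, superposition, moments, canonical axes.

The shape Tanimoto between conformers A and B is

    ST = V_AB / (V_AA + V_BB - V_AB)

with V_AA, V_BB the Gaussian self-overlap volumes and V_AB the overlap at a
given relative pose.  ``optimize_overlap`` maximizes V_AB over rigid motions
of B (6 degrees of freedom, derivative-free refinement from the four
principal-axes sign-flip starting poses) and reports the color Tanimoto as a
single-point evaluation at the optimized pose.

Two distinct volume notions coexist and are both exposed:

* ``self_volume`` — the analytic (union) volume from the inclusion-exclusion
  expansion; a single atom's value is its hard-sphere volume 4/3*pi*R^3.
* ``self_overlap_volume`` — the product-Gaussian self overlap V_AA entering
  the Tanimoto denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .core import Conformer
from . import gaussians

__all__ = [
    "ShapeParams",
    "RigidTransform",
    "OverlapResult",
    "StericMoments",
    "SimilarityResult",
    "self_volume",
    "self_overlap_volume",
    "overlap_volume",
    "shape_tanimoto",
    "combo_tanimoto",
    "optimize_overlap",
    "steric_moments",
    "canonicalize_principal_axes",
]

#: van der Waals radii (Å) for the supported elements (Bondi-style values).
DEFAULT_RADIUS_TABLE = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Si": 2.10,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}


@dataclass
class ShapeParams:
    """Parameters of the Gaussian shape description.

    ``gaussian_height`` is the Grant-Pickup amplitude p; exponents are set
    per atom so an isolated atom integrates to its hard-sphere volume.
    ``carbon_radius_mode`` treats every heavy atom as carbon (radius 1.70 Å),
    removing element dependence from pure-shape comparisons.
    """

    gaussian_height: float = 2.7
    radius_table: dict = field(default_factory=lambda: dict(DEFAULT_RADIUS_TABLE))
    inclusion_exclusion_order: int = 2
    carbon_radius_mode: bool = False
    color_radius: float = 1.0
    opt_maxiter: int = 300
    opt_xatol: float = 1e-3
    opt_fatol: float = 1e-5

    def __post_init__(self) -> None:
        if self.gaussian_height <= 1:
            raise ValueError("gaussian_height must exceed 1")
        if self.inclusion_exclusion_order < 2:
            raise ValueError("inclusion_exclusion_order must be >= 2")
        if any(r <= 0 for r in self.radius_table.values()):
            raise ValueError("radii must be positive")


DEFAULT_PARAMS = ShapeParams()


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation applied first)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det=+1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


@dataclass
class OverlapResult:
    v_ab: float
    transform: RigidTransform


@dataclass
class StericMoments:
    """Moments of the Gaussian shape density in the principal steric frame.

    ``volume`` is the monopole (analytic volume, Å^3); ``qx >= qy >= qz`` are
    the second moments (Å^5, qx describes length); ``octopoles`` maps the ten
    third-moment labels (xxx, yyy, zzz, xxy, xxz, yyx, yyz, zzx, zzy, xyz)
    to Å^6 values.
    """

    volume: float
    qx: float
    qy: float
    qz: float
    octopoles: dict

    def __post_init__(self) -> None:
        if not (self.qx >= self.qy - 1e-9 and self.qy >= self.qz - 1e-9):
            raise ValueError("quadrupoles must be ordered qx >= qy >= qz")


@dataclass
class SimilarityResult:
    """Shape/color similarity at an optimized pose.

    ``transform`` maps conformer B's input coordinates onto conformer A's
    input frame; ``combo = st + ct`` exactly.
    """

    st: float
    ct: float
    transform: RigidTransform
    v_ab: float = 0.0

    @property
    def combo(self) -> float:
        return self.st + self.ct


def combo_tanimoto(st: float, ct: float) -> float:
    """ComboT = ST + CT (range [0, 2])."""
    if not (0.0 <= st <= 1.0 and 0.0 <= ct <= 1.0):
        raise ValueError("ST and CT must lie in [0, 1]")
    return st + ct


# ---------------------------------------------------------------------------
# radii / gaussian helpers


def _heavy_radii(conformer: Conformer, params: ShapeParams) -> np.ndarray:
    if params.carbon_radius_mode or conformer.elements is None:
        r = params.radius_table["C"]
        return np.full(len(conformer.heavy_indices), r)
    table = params.radius_table
    return np.array(
        [table.get(e, table["C"]) for e in conformer.heavy_elements()]
    )


def _heavy_gaussians(conformer: Conformer, params: ShapeParams):
    coords = conformer.heavy_coords
    if len(coords) == 0:
        raise ValueError("conformer has no heavy atoms")
    radii = _heavy_radii(conformer, params)
    return coords, gaussians.alphas_for_radii(radii, params.gaussian_height)


# ---------------------------------------------------------------------------
# volumes


def self_volume(
    conformer: Conformer, params: ShapeParams | None = None
) -> float:
    """Analytic Gaussian (union) volume over heavy atoms, Å^3."""
    params = params or DEFAULT_PARAMS
    coords, alphas = _heavy_gaussians(conformer, params)
    ws, als, _cs = gaussians.union_terms(
        coords, alphas, params.gaussian_height, params.inclusion_exclusion_order
    )
    return gaussians.terms_volume(ws, als)


def self_overlap_volume(
    conformer: Conformer, params: ShapeParams | None = None
) -> float:
    """Product-Gaussian self overlap V_AA (Tanimoto denominator), Å^3."""
    params = params or DEFAULT_PARAMS
    coords, alphas = _heavy_gaussians(conformer, params)
    return gaussians.cross_overlap(
        coords, alphas, coords, alphas, params.gaussian_height
    )


def overlap_volume(
    a: Conformer,
    b: Conformer,
    params: ShapeParams | None = None,
    transform: RigidTransform | None = None,
) -> float:
    """Overlap volume V_AB at the given pose (identity by default), Å^3.

    Symmetric at mirrored poses; evaluated on a conformer against itself it
    returns the self-overlap volume.
    """
    params = params or DEFAULT_PARAMS
    ca, aa = _heavy_gaussians(a, params)
    cb, ab = _heavy_gaussians(b, params)
    if transform is not None:
        cb = transform.apply(cb)
    return gaussians.cross_overlap(ca, aa, cb, ab, params.gaussian_height)


def shape_tanimoto(
    a: Conformer,
    b: Conformer,
    transform: RigidTransform | None = None,
    params: ShapeParams | None = None,
) -> float:
    """ST = V_AB / (V_AA + V_BB - V_AB) at the given pose."""
    params = params or DEFAULT_PARAMS
    v_aa = self_overlap_volume(a, params)
    v_bb = self_overlap_volume(b, params)
    v_ab = overlap_volume(a, b, params, transform)
    denom = v_aa + v_bb - v_ab
    assert denom > 0, "Tanimoto denominator must be positive"
    return min(1.0, max(0.0, v_ab / denom))


# ---------------------------------------------------------------------------
# principal steric axes


def _axis_sign(proj: np.ndarray) -> float:
    """Sign convention: third moment of the projections non-negative;
    symmetric distributions fall back to a lexicographic rule."""
    m3 = float(np.sum(proj ** 3))
    scale = max(1.0, float(np.max(np.abs(proj)) ** 3)) * len(proj)
    if abs(m3) > 1e-9 * scale:
        return 1.0 if m3 > 0 else -1.0
    fwd = tuple(np.round(np.sort(proj)[::-1], 9))
    rev = tuple(np.round(np.sort(-proj)[::-1], 9))
    return 1.0 if fwd >= rev else -1.0


def principal_axes_transform(conformer: Conformer) -> RigidTransform:
    """Rigid motion taking the conformer to its principal steric frame.

    Unit-weight (non-mass-weighted) second-moment tensor of the heavy atoms;
    x is the longest extent; axis signs follow the third-moment convention.
    """
    heavy = conformer.heavy_coords
    centroid = heavy.mean(axis=0)
    x = heavy - centroid
    s = x.T @ x
    evals, evecs = np.linalg.eigh(s)
    order = np.argsort(evals)[::-1]  # descending: x = longest extent
    axes = evecs[:, order]
    v1 = axes[:, 0] * _axis_sign(x @ axes[:, 0])
    v2 = axes[:, 1] * _axis_sign(x @ axes[:, 1])
    v3 = np.cross(v1, v2)  # right-handed frame
    rot = np.vstack([v1, v2, v3])
    return RigidTransform(rot, -rot @ centroid)


def canonicalize_principal_axes(conformer: Conformer) -> Conformer:
    """Return the conformer rotated/translated to its principal steric axes.

    Idempotent: a canonical conformer is returned unchanged up to 1e-9.
    Degenerate second-moment spectra (spherical tops) keep the solver's
    stable eigenbasis; the sign rule still applies.
    """
    t = principal_axes_transform(conformer)
    return conformer.with_coords(t.apply(conformer.coords))


# ---------------------------------------------------------------------------
# steric moments

_OCTO_LABELS = {
    "xxx": (3, 0, 0),
    "yyy": (0, 3, 0),
    "zzz": (0, 0, 3),
    "xxy": (2, 1, 0),
    "xxz": (2, 0, 1),
    "yyx": (1, 2, 0),
    "yyz": (0, 2, 1),
    "zzx": (1, 0, 2),
    "zzy": (0, 1, 2),
    "xyz": (1, 1, 1),
}


def steric_moments(
    conformer: Conformer, params: ShapeParams | None = None
) -> StericMoments:
    """Monopole, quadrupole and octopole moments of the shape density.

    Computed in the principal steric frame (the conformer is recanonicalized
    if needed); the quadrupole ordering qx >= qy >= qz is enforced by
    permuting axes on near-degenerate spectra.
    """
    params = params or DEFAULT_PARAMS
    conformer = canonicalize_principal_axes(conformer)
    coords, alphas = _heavy_gaussians(conformer, params)

    def moments_for(cs_xyz: np.ndarray):
        ws, als, cs = gaussians.union_terms(
            cs_xyz, alphas, params.gaussian_height,
            params.inclusion_exclusion_order,
        )
        vol = gaussians.terms_volume(ws, als)
        q = [
            gaussians.terms_moment(ws, als, cs, (2, 0, 0)),
            gaussians.terms_moment(ws, als, cs, (0, 2, 0)),
            gaussians.terms_moment(ws, als, cs, (0, 0, 2)),
        ]
        return vol, q, (ws, als, cs)

    vol, q, expansion = moments_for(coords)
    perm = np.argsort(q)[::-1]
    if not np.array_equal(perm, [0, 1, 2]):
        # re-order axes so the density second moments are descending
        coords = coords[:, perm]
        vol, q, expansion = moments_for(coords)
    ws, als, cs = expansion
    octo = {
        label: gaussians.terms_moment(ws, als, cs, powers)
        for label, powers in _OCTO_LABELS.items()
    }
    return StericMoments(volume=vol, qx=q[0], qy=q[1], qz=q[2], octopoles=octo)


# ---------------------------------------------------------------------------
# superposition optimization

_FLIP_STARTS = [
    np.diag([1.0, 1.0, 1.0]),
    np.diag([1.0, -1.0, -1.0]),
    np.diag([-1.0, 1.0, -1.0]),
    np.diag([-1.0, -1.0, 1.0]),
]


def _color_cross(fa_by_type, fb_by_type, alpha: float, p: float) -> float:
    total = 0.0
    for ftype, pa in fa_by_type.items():
        pb = fb_by_type.get(ftype)
        if pb is None or len(pa) == 0 or len(pb) == 0:
            continue
        aa = np.full(len(pa), alpha)
        ab = np.full(len(pb), alpha)
        total += gaussians.cross_overlap(pa, aa, pb, ab, p)
    return total


def optimize_overlap(
    a: Conformer,
    b: Conformer,
    mode: str = "shape",
    params: ShapeParams | None = None,
    features_a=None,
    features_b=None,
) -> SimilarityResult:
    """Maximize the overlap of B onto A over rigid motions.

    Both conformers are first canonicalized to their principal steric axes;
    derivative-free refinement (rotation vector + translation) is run from
    the four proper sign-flip poses of the canonical frames and the best
    pose kept.  In ``shape`` mode the objective is the shape overlap V_AB;
    in ``feature`` mode it is the total same-type color overlap (both
    feature sets required).  The returned CT is always a single-point
    evaluation at the final pose (0 when either feature set is missing or
    both are empty).
    """
    if mode not in ("shape", "feature"):
        raise ValueError("mode must be 'shape' or 'feature'")
    if mode == "feature" and (features_a is None or features_b is None):
        raise ValueError("feature mode requires both feature sets")
    params = params or DEFAULT_PARAMS
    p = params.gaussian_height

    t_a = principal_axes_transform(a)
    t_b = principal_axes_transform(b)
    ca, aa = _heavy_gaussians(a, params)
    cb, ab = _heavy_gaussians(b, params)
    ca = t_a.apply(ca)
    cb0 = t_b.apply(cb)

    color_alpha = float(
        gaussians.alphas_for_radii(np.array([params.color_radius]), p)[0]
    )
    fa_by_type = fb0_by_type = None
    if features_a is not None and features_b is not None:
        fa_by_type = {
            t: t_a.apply(pos) for t, pos in features_a.positions_by_type().items()
        }
        fb0_by_type = {
            t: t_b.apply(pos) for t, pos in features_b.positions_by_type().items()
        }

    def objective(x: np.ndarray, flip: np.ndarray) -> float:
        rot = Rotation.from_rotvec(x[:3]).as_matrix() @ flip
        posed = cb0 @ rot.T + x[3:]
        if mode == "shape":
            return -gaussians.cross_overlap(ca, aa, posed, ab, p)
        fb = {t: pos @ rot.T + x[3:] for t, pos in fb0_by_type.items()}
        return -_color_cross(fa_by_type, fb, color_alpha, p)

    best = None
    for flip in _FLIP_STARTS:
        res = minimize(
            objective,
            np.zeros(6),
            args=(flip,),
            method="Nelder-Mead",
            options={
                "maxiter": params.opt_maxiter,
                "xatol": params.opt_xatol,
                "fatol": params.opt_fatol,
            },
        )
        start_val = objective(np.zeros(6), flip)
        val = min(res.fun, start_val)  # never worse than the starting pose
        x = res.x if res.fun <= start_val else np.zeros(6)
        if best is None or val < best[0]:
            best = (val, x, flip)

    _, x, flip = best
    rot = Rotation.from_rotvec(x[:3]).as_matrix() @ flip
    # compose: b input frame -> b canonical -> optimized pose -> a input frame
    t_opt = RigidTransform(rot, x[3:])
    t_total = t_a.inverse().compose(t_opt).compose(t_b)

    posed = cb0 @ rot.T + x[3:]
    v_ab = gaussians.cross_overlap(ca, aa, posed, ab, p)
    v_aa = gaussians.cross_overlap(ca, aa, ca, aa, p)
    v_bb = gaussians.cross_overlap(cb0, ab, cb0, ab, p)
    st = min(1.0, max(0.0, v_ab / (v_aa + v_bb - v_ab)))

    ct = 0.0
    if fa_by_type is not None:
        fb = {t: pos @ rot.T + x[3:] for t, pos in fb0_by_type.items()}
        ct = _color_tanimoto_positions(fa_by_type, fb, color_alpha, p)
    return SimilarityResult(st=st, ct=ct, transform=t_total, v_ab=v_ab)


def _color_tanimoto_positions(fa_by_type, fb_by_type, alpha, p) -> float:
    """CT over per-type position dicts already in a common frame."""
    v_ab = _color_cross(fa_by_type, fb_by_type, alpha, p)
    v_aa = _color_cross(fa_by_type, fa_by_type, alpha, p)
    v_bb = _color_cross(fb_by_type, fb_by_type, alpha, p)
    denom = v_aa + v_bb - v_ab
    if denom <= 0:
        return 0.0  # both feature sets empty
    return min(1.0, max(0.0, v_ab / denom))
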