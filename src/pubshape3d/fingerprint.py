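"""Shape fingerprints: reference shapes, bits with packed transforms,
alignment recycling.

A reference shape set is a greedy leader clustering of canonicalized
conformers such that no two references exceed the construction ST threshold
to each other.  A conformer's fingerprint sets one "bit" per reference it
resembles beyond the query threshold; each bit carries the optimizing rigid
transform packed into a 64-bit integer, so that two conformers sharing a
reference can "replay" their alignments through it (compose the two stored
transforms) instead of re-optimizing, and pairs sharing no reference can be
skipped outright.

Packed-transform codec (64 bits, documented layout):

    bits 62-63  index of the largest-magnitude quaternion component
    bits 48-61  quantized quaternion component c (14 bits)
    bits 34-47  quantized quaternion component b (14 bits)
    bits 20-33  quantized quaternion component a (14 bits)
    bits 18-19  unused
    bits 12-17  translation x (6 bits, 0.1 Å grid over [-3.2, 3.1])
    bits  6-11  translation y
    bits  0-5   translation z

The three smallest quaternion components are stored on a uniform grid over
[-1/sqrt(2), 1/sqrt(2)]; the largest is reconstructed from normalization
(sign fixed positive).  Canonicalized conformers have near-zero centroids,
so the coarse translation grid loses little.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Conformer
from .shape import (
    RigidTransform,
    ShapeParams,
    canonicalize_principal_axes,
    optimize_overlap,
    self_overlap_volume,
    shape_tanimoto,
)

__all__ = [
    "pack_transform",
    "unpack_transform",
    "ShapeFingerprint",
    "ReferenceShapeSet",
    "build_reference_set",
    "fingerprint_conformer",
    "recycle_alignment",
    "SKIP",
]

_QBITS = 14
_QMAX = (1 << _QBITS) - 1
_QSCALE = 1.0 / math.sqrt(2.0)
_TSTEP = 0.1
_TMIN = -3.2
_TMAX = _TMIN + 63 * _TSTEP


def pack_transform(t: RigidTransform) -> int:
    """Pack a rigid transform into 64 bits (quantized; lossy)."""
    q = Rotation.from_matrix(t.rotation).as_quat()  # (x, y, z, w)
    big = int(np.argmax(np.abs(q)))
    if q[big] < 0:
        q = -q
    small = [q[i] for i in range(4) if i != big]
    codes = []
    for v in small:
        v = min(_QSCALE, max(-_QSCALE, v))
        codes.append(int(round((v + _QSCALE) / (2 * _QSCALE) * _QMAX)))
    tcodes = []
    for v in t.translation:
        v = min(_TMAX, max(_TMIN, float(v)))
        tcodes.append(int(round((v - _TMIN) / _TSTEP)))
    packed = (
        (big << 62)
        | (codes[2] << 48)
        | (codes[1] << 34)
        | (codes[0] << 20)
        | (tcodes[0] << 12)
        | (tcodes[1] << 6)
        | tcodes[2]
    )
    return packed


def unpack_transform(packed: int) -> RigidTransform:
    """Inverse of :func:`pack_transform` up to quantization error."""
    big = (packed >> 62) & 0x3
    codes = [
        (packed >> 20) & _QMAX,
        (packed >> 34) & _QMAX,
        (packed >> 48) & _QMAX,
    ]
    small = [c / _QMAX * 2 * _QSCALE - _QSCALE for c in codes]
    rest = 1.0 - sum(v * v for v in small)
    bigval = math.sqrt(max(0.0, rest))
    q = np.empty(4)
    k = 0
    for i in range(4):
        if i == big:
            q[i] = bigval
        else:
            q[i] = small[k]
            k += 1
    q /= np.linalg.norm(q)
    trans = np.array(
        [
            ((packed >> 12) & 0x3F) * _TSTEP + _TMIN,
            ((packed >> 6) & 0x3F) * _TSTEP + _TMIN,
            (packed & 0x3F) * _TSTEP + _TMIN,
        ]
    )
    return RigidTransform(Rotation.from_quat(q).as_matrix(), trans)


class SkipSignal:
    """Returned when two fingerprints share no reference bit."""

    def __repr__(self) -> str:  # pragma: no cover
        return "SKIP"


SKIP = SkipSignal()


@dataclass
class ShapeFingerprint:
    """Bits: reference id -> packed 64-bit transform (conformer -> reference
    frame); at most one bit per reference."""

    bits: dict[int, int] = field(default_factory=dict)
    threshold: float = 0.8
    reference_set_id: int = 0

    def common_bits(self, other: "ShapeFingerprint") -> list[int]:
        if self.reference_set_id != other.reference_set_id:
            raise ValueError("fingerprints built against different reference sets")
        return sorted(set(self.bits) & set(other.bits))


def _volume_bound_st(v_a: float, v_b: float) -> float:
    """Rigorous upper bound on ST from self-overlap volumes alone:
    V_AB <= min(V_AA, V_BB), so ST <= min/max."""
    lo, hi = min(v_a, v_b), max(v_a, v_b)
    return lo / hi


@dataclass
class ReferenceShapeSet:
    """Canonicalized reference conformers; no pair exceeds the construction
    ST threshold.  ``volume_bin`` labels group references by analytic-volume
    range (bin width in Å^3) for bookkeeping and serialization."""

    conformers: list[Conformer]
    ids: list[int]
    st_threshold: float
    params: ShapeParams = field(default_factory=ShapeParams)
    volume_bin_width: float = 50.0
    set_id: int = 0
    self_overlaps: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.conformers) != len(self.ids):
            raise ValueError("ids/conformers length mismatch")
        if not self.self_overlaps:
            self.self_overlaps = [
                self_overlap_volume(c, self.params) for c in self.conformers
            ]

    def volume_bin(self, index: int) -> int:
        return int(self.self_overlaps[index] // self.volume_bin_width)


def build_reference_set(
    conformers: list[Conformer],
    st_threshold: float = 0.8,
    params: ShapeParams | None = None,
    set_id: int = 0,
) -> ReferenceShapeSet:
    """Greedy leader clustering into a shape-diverse reference set.

    A conformer becomes a reference iff no existing reference exceeds the
    threshold to it (ST-optimized).  The volume-ratio bound prunes pairs
    that cannot exceed the threshold without running the optimizer.
    """
    if not conformers:
        raise ValueError("empty input")
    params = params or ShapeParams()
    refs: list[Conformer] = []
    ids: list[int] = []
    overlaps: list[float] = []
    for i, conf in enumerate(conformers):
        cand = canonicalize_principal_axes(conf)
        v_cand = self_overlap_volume(cand, params)
        similar = False
        for ref, v_ref in zip(refs, overlaps):
            if _volume_bound_st(v_cand, v_ref) <= st_threshold:
                continue
            res = optimize_overlap(ref, cand, mode="shape", params=params)
            if res.st > st_threshold:
                similar = True
                break
        if not similar:
            cand.local_id = len(refs)
            refs.append(cand)
            ids.append(i)
            overlaps.append(v_cand)
    return ReferenceShapeSet(
        conformers=refs,
        ids=ids,
        st_threshold=st_threshold,
        params=params,
        set_id=set_id,
        self_overlaps=overlaps,
    )


def fingerprint_conformer(
    c: Conformer,
    refs: ReferenceShapeSet,
    st_threshold: float = 0.8,
) -> ShapeFingerprint:
    """Fingerprint a conformer against a reference set.

    One bit per reference with ST-optimized similarity above the threshold;
    the bit value is the packed transform taking the conformer into the
    reference frame.
    """
    cand = canonicalize_principal_axes(c)
    v_cand = self_overlap_volume(cand, refs.params)
    bits: dict[int, int] = {}
    for k, (ref, v_ref) in enumerate(zip(refs.conformers, refs.self_overlaps)):
        if _volume_bound_st(v_cand, v_ref) <= st_threshold:
            continue
        res = optimize_overlap(ref, cand, mode="shape", params=refs.params)
        if res.st > st_threshold:
            bits[k] = pack_transform(res.transform)
    return ShapeFingerprint(
        bits=bits, threshold=st_threshold, reference_set_id=refs.set_id
    )


def recycle_alignment(
    a: Conformer,
    fp_a: ShapeFingerprint,
    b: Conformer,
    fp_b: ShapeFingerprint,
    params: ShapeParams | None = None,
):
    """Replay stored reference alignments instead of re-optimizing.

    Returns :data:`SKIP` when the fingerprints share no bit (the pair is
    declared shape-dissimilar).  Otherwise, for every common reference the
    two stored conformer-to-reference transforms are composed into a pose of
    b onto a and evaluated single-point; the best pose is returned as a
    ``(st, transform)`` pair.
    """
    from .shape import DEFAULT_PARAMS

    params = params or DEFAULT_PARAMS
    common = fp_a.common_bits(fp_b)
    if not common:
        return SKIP
    ca = canonicalize_principal_axes(a)
    cb = canonicalize_principal_axes(b)
    best = None
    for ref_id in common:
        t_ar = unpack_transform(fp_a.bits[ref_id])  # a -> ref frame
        t_br = unpack_transform(fp_b.bits[ref_id])  # b -> ref frame
        t = t_ar.inverse().compose(t_br)  # b -> a frame
        st = shape_tanimoto(ca, cb, transform=t, params=params)
        if best is None or st > best[0]:
            best = (st, t)
    return best
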