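"""Homogeneous 3D affine transforms and their DOF-vector parameterization.

World coordinates are in mm.  A transform is a 4x4 homogeneous matrix
with bottom row (0, 0, 0, 1).  The parameterized family used by the
registration search composes, about a configurable centre ``c``:

    A(p) = T(t) . C(c) . Rz(rz) Ry(ry) Rx(rx) . S(s) . H(h) . C(c)^-1

i.e. rotation/scale/shear pivot about ``c`` (typically the volume
centre), followed by a world translation.  Angles are exposed in degrees
throughout and converted internally.

DOF tiers: 3 = translations; 4 = + global scale; 6 = rigid; 7 = rigid +
global scale; 9 = rigid + per-axis scales; 12 = + shears.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

_DOF_LEVELS = (3, 4, 6, 7, 9, 12)


@dataclass(frozen=True)
class AffineTransform:
    """A 4x4 homogeneous world-coordinate (mm) affine map."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (4, 4):
            raise ValueError(f"matrix must be 4x4, got {m.shape}")
        if not np.array_equal(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("bottom row must be (0, 0, 0, 1)")
        object.__setattr__(self, "matrix", m)

    def __matmul__(self, other: "AffineTransform") -> "AffineTransform":
        return AffineTransform(self.matrix @ other.matrix)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        """Apply to points of shape (..., 3)."""
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    # -- plain-text 4x4 exchange format (4 whitespace-separated rows) --

    def save(self, path) -> None:
        np.savetxt(path, self.matrix, fmt="%.12g")

    @classmethod
    def load(cls, path) -> "AffineTransform":
        return cls(np.loadtxt(path).reshape(4, 4))


def identity() -> AffineTransform:
    return AffineTransform(np.eye(4))


def translation_matrix(t) -> AffineTransform:
    """Translation by ``(tx, ty, tz)`` mm."""
    t = np.asarray(t, dtype=float)
    if t.shape != (3,) or not np.all(np.isfinite(t)):
        raise ValueError("translation must be 3 finite values")
    m = np.eye(4)
    m[:3, 3] = t
    return AffineTransform(m)


def scaling_matrix(s) -> AffineTransform:
    """Anisotropic scaling by positive factors ``(sx, sy, sz)``."""
    s = np.asarray(s, dtype=float)
    if s.shape != (3,) or np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise ValueError("scales must be 3 positive finite values")
    return AffineTransform(np.diag([s[0], s[1], s[2], 1.0]))


def rotation_matrix(axis: str, theta_deg: float) -> AffineTransform:
    """Proper rotation about the named world axis through the origin."""
    if axis not in ("x", "y", "z"):
        raise ValueError(f"axis must be x, y or z, got {axis!r}")
    th = math.radians(float(theta_deg))
    c, s = math.cos(th), math.sin(th)
    m = np.eye(4)
    if axis == "x":
        m[1, 1], m[1, 2], m[2, 1], m[2, 2] = c, -s, s, c
    elif axis == "y":
        m[0, 0], m[0, 2], m[2, 0], m[2, 2] = c, s, -s, c
    else:
        m[0, 0], m[0, 1], m[1, 0], m[1, 1] = c, -s, s, c
    return AffineTransform(m)


def shear_matrix(h) -> AffineTransform:
    """Upper-triangular unit-diagonal shear with entries (hxy, hxz, hyz)."""
    h = np.asarray(h, dtype=float)
    if h.shape != (3,) or not np.all(np.isfinite(h)):
        raise ValueError("shears must be 3 finite values")
    m = np.eye(4)
    m[0, 1], m[0, 2], m[1, 2] = h
    return AffineTransform(m)


@dataclass(frozen=True)
class DOFParams:
    """A transform parameter vector restricted to a DOF tier.

    Translations in mm, rotations in degrees, scales dimensionless (> 0),
    shears dimensionless.  Fields beyond the declared ``dof`` must sit at
    their neutral values (0 for translation/rotation/shear, 1 for scale).
    """

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0
    sx: float = 1.0
    sy: float = 1.0
    sz: float = 1.0
    hxy: float = 0.0
    hxz: float = 0.0
    hyz: float = 0.0
    dof: int = 12

    def __post_init__(self) -> None:
        if self.dof not in _DOF_LEVELS:
            raise ValueError(f"dof must be one of {_DOF_LEVELS}, got {self.dof}")
        if min(self.sx, self.sy, self.sz) <= 0:
            raise ValueError("scales must be positive")
        if self.dof < 6 and any(v != 0.0 for v in (self.rx, self.ry, self.rz)):
            raise ValueError(f"rotations must be neutral at dof={self.dof}")
        if self.dof in (3, 6) and any(v != 1.0 for v in (self.sx, self.sy, self.sz)):
            raise ValueError(f"scales must be neutral at dof={self.dof}")
        if self.dof in (4, 7) and not (self.sx == self.sy == self.sz):
            raise ValueError(f"dof={self.dof} allows a single global scale only")
        if self.dof < 12 and any(v != 0.0 for v in (self.hxy, self.hxz, self.hyz)):
            raise ValueError(f"shears must be neutral at dof={self.dof}")

    @property
    def translation(self) -> tuple[float, float, float]:
        return (self.tx, self.ty, self.tz)

    @property
    def rotation(self) -> tuple[float, float, float]:
        return (self.rx, self.ry, self.rz)

    @property
    def scales(self) -> tuple[float, float, float]:
        return (self.sx, self.sy, self.sz)

    @property
    def shears(self) -> tuple[float, float, float]:
        return (self.hxy, self.hxz, self.hyz)

    def promote(self, dof: int) -> "DOFParams":
        """Re-declare at a higher DOF tier, keeping current values."""
        if dof < self.dof:
            raise ValueError("cannot demote a parameter vector")
        return replace(self, dof=dof)

    def to_json(self, path) -> None:
        import dataclasses
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "DOFParams":
        import json
        from pathlib import Path

        return cls(**json.loads(Path(path).read_text()))


def params_to_matrix(p: DOFParams, center=(0.0, 0.0, 0.0)) -> AffineTransform:
    """Build the affine ``T . C . Rz Ry Rx . S . H . C^-1`` from ``p``."""
    c = translation_matrix(center)
    rot = (
        rotation_matrix("z", p.rz)
        @ rotation_matrix("y", p.ry)
        @ rotation_matrix("x", p.rx)
    )
    lin = rot @ scaling_matrix(p.scales) @ shear_matrix(p.shears)
    return translation_matrix(p.translation) @ c @ lin @ c.inverse()


def matrix_to_params(a: AffineTransform, center=(0.0, 0.0, 0.0), dof: int = 12) -> DOFParams:
    """Decompose an affine built by :func:`params_to_matrix` back into params.

    Uses a QR factorization of the linear block into rotation x
    (scale . shear); valid whenever scales are positive and rotations keep
    ``|ry| < 90`` degrees (always true near neutral).
    """
    B = a.matrix[:3, :3]
    q, r = np.linalg.qr(B)
    # fix signs so the triangular factor has a positive diagonal
    d = np.sign(np.diag(r))
    d[d == 0] = 1.0
    q = q * d
    r = (r.T * d).T
    if np.linalg.det(q) < 0:
        raise ValueError("linear block contains a reflection; not in the DOF family")
    sx, sy, sz = np.diag(r)
    hxy, hxz, hyz = r[0, 1] / sx, r[0, 2] / sx, r[1, 2] / sy
    ry = math.degrees(math.asin(max(-1.0, min(1.0, -q[2, 0]))))
    rx = math.degrees(math.atan2(q[2, 1], q[2, 2]))
    rz = math.degrees(math.atan2(q[1, 0], q[0, 0]))
    c = np.asarray(center, dtype=float)
    t = a.matrix[:3, 3] - c + B @ c
    return DOFParams(
        tx=t[0], ty=t[1], tz=t[2], rx=rx, ry=ry, rz=rz,
        sx=float(sx), sy=float(sy), sz=float(sz),
        hxy=float(hxy), hxz=float(hxz), hyz=float(hyz), dof=dof,
    )
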