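"""Canonical coordinate frames for ligand fragments.

A fragment is an atom triple (Main-atom, Atom1, Atom2). Its canonical model
frame places the Main-atom at the origin, Atom1 on the negative z-axis (so the
main direction, Atom1 -> Main-atom, is +z) and Atom2 in the half-plane
{y = 0, x < 0}. All contact statistics are accumulated in this frame, so the
density of contact positions becomes comparable across fragment instances.

Conventions (fixed here, used everywhere else in the package):

* spherical coordinates: ``r >= 0``; polar angle ``theta in [0, pi]`` measured
  from +z (the main direction); azimuth ``phi in [0, 2*pi)`` measured from +x,
  counterclockwise about +z.  Atom2 therefore sits at ``phi = pi``.
* pole convention: ``phi := 0`` when ``theta in {0, pi}``; the origin maps to
  all-zero spherical coordinates.
* display frame: a cyclic axis permutation ``(x, y, z)_display =
  (z, x, y)_model`` used only for plotting, where the fragment lies in the
  (-x)(-y) plane and the main direction is +x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "FragmentFrame",
    "build_frame",
    "to_spherical",
    "from_spherical",
    "model_to_display",
    "display_to_model",
]

#: sine of the Atom1-Main-Atom2 angle below which the triple is collinear
COLLINEARITY_TOL = 1e-6

# display = _DISPLAY_ROT @ model : (x, y, z)_display = (z, x, y)_model
_DISPLAY_ROT = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


class DegenerateGeometryError(ValueError):
    """Raised when the fragment atom triple is coincident or collinear."""


@dataclass(frozen=True)
class FragmentFrame:
    """Rigid transform taking world coordinates into the canonical model frame.

    ``apply(p) = rotation @ (p + translation)`` with ``translation = -main``.
    """

    translation: np.ndarray  # (3,) in angstrom, applied before rotation
    rotation: np.ndarray  # (3, 3) orthonormal, det +1

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map world-frame point(s), shape (3,) or (n, 3), into the model frame."""
        p = np.asarray(points, dtype=float)
        return (p + self.translation) @ self.rotation.T

    def invert(self, points: np.ndarray) -> np.ndarray:
        """Map model-frame point(s) back to the world frame."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation - self.translation


def build_frame(main, atom1, atom2) -> FragmentFrame:
    """Solve the translation-rotation that superimposes a fragment onto the
    canonical pose.

    The rotation is built by Gram-Schmidt: +z is the unit main direction
    (Atom1 -> Main-atom); +x is the negated, z-orthogonalized Main->Atom2
    direction (so Atom2 lands at x < 0, y = 0); +y completes the right-handed
    triad via the cross product.

    Raises
    ------
    DegenerateGeometryError
        if the three atoms are pairwise coincident or collinear (sine of the
        Atom1-Main-Atom2 angle below ``COLLINEARITY_TOL``).
    """
    main = np.asarray(main, dtype=float)
    atom1 = np.asarray(atom1, dtype=float)
    atom2 = np.asarray(atom2, dtype=float)

    d1 = main - atom1
    n1 = np.linalg.norm(d1)
    if n1 < COLLINEARITY_TOL:
        raise DegenerateGeometryError("Main-atom and Atom1 coincide")
    z_axis = d1 / n1

    v = atom2 - main
    nv = np.linalg.norm(v)
    if nv < COLLINEARITY_TOL:
        raise DegenerateGeometryError("Main-atom and Atom2 coincide")
    w = v - np.dot(v, z_axis) * z_axis
    nw = np.linalg.norm(w)
    if nw / nv < COLLINEARITY_TOL:
        raise DegenerateGeometryError("fragment atoms are collinear")
    x_axis = -w / nw
    y_axis = np.cross(z_axis, x_axis)

    rotation = np.vstack([x_axis, y_axis, z_axis])
    return FragmentFrame(translation=-main, rotation=rotation)


def to_spherical(p) -> np.ndarray:
    """Cartesian model-frame point -> (r, theta, phi).

    theta is measured from +z (the main direction), phi from +x about +z.
    At the poles (theta 0 or pi) and at the origin phi is defined as 0.
    """
    x, y, z = np.asarray(p, dtype=float)
    r = float(np.sqrt(x * x + y * y + z * z))
    if r == 0.0:
        return np.array([0.0, 0.0, 0.0])
    theta = float(np.arccos(np.clip(z / r, -1.0, 1.0)))
    if theta == 0.0 or theta == np.pi or (x == 0.0 and y == 0.0):
        phi = 0.0
    else:
        phi = float(np.arctan2(y, x)) % (2.0 * np.pi)
    return np.array([r, theta, phi])


def from_spherical(p) -> np.ndarray:
    """(r, theta, phi) -> Cartesian model-frame point."""
    r, theta, phi = np.asarray(p, dtype=float)
    st = np.sin(theta)
    return np.array([r * st * np.cos(phi), r * st * np.sin(phi), r * np.cos(theta)])


def model_to_display(p) -> np.ndarray:
    """Model-frame Cartesian point -> display frame: (x,y,z)_d = (z,x,y)_m.

    The main direction (+z model) maps to +x display and the fragment plane
    (the model x-z plane) maps to the display x-y plane; the permutation is a
    proper rotation (determinant +1).
    """
    return _DISPLAY_ROT @ np.asarray(p, dtype=float)


def display_to_model(p) -> np.ndarray:
    """Inverse of :func:`model_to_display`."""
    return _DISPLAY_ROT.T @ np.asarray(p, dtype=float)
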