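"""Affine registration of the two spectral channels.

A dual-view single-molecule microscope images the two spectral channels
onto separate halves of the camera; chromatic and geometric offsets
between them are calibrated with multicolor fiducial beads visible in
both channels. A 2D affine transform (6 parameters) fitted to the
matched bead positions by linear least squares maps channel B into
channel A's coordinate frame with sub-pixel precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import LocalizationTable

__all__ = ["AffineTransform2D", "fit_affine", "apply_transform",
           "RegistrationError"]


class RegistrationError(ValueError):
    """Degenerate bead configuration or singular transform."""


@dataclass
class AffineTransform2D:
    """2D affine map ``x -> M @ x + t`` (coordinates in nm).

    Attributes
    ----------
    matrix : ndarray, shape (2, 2)
    offset : ndarray, shape (2,)
    residual_rms_nm : float
        Per-coordinate root-mean-square residual of the fit that
        produced the transform (0 for analytically constructed
        transforms); comparable to the per-axis localization noise SD.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))
    residual_rms_nm: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise RegistrationError("linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls()

    @classmethod
    def from_params(cls, rotation_deg: float = 0.0, scale=1.0,
                    shear: float = 0.0, offset=(0.0, 0.0)) -> "AffineTransform2D":
        """Build a transform from rotation (degrees), scale, shear and offset."""
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        sc = np.diag(np.broadcast_to(np.asarray(scale, dtype=float), (2,)))
        sh = np.array([[1.0, shear], [0.0, 1.0]])
        return cls(rot @ sc @ sh, np.asarray(offset, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.matrix.T + self.offset

    def inverse(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform2D(inv, -inv @ self.offset,
                                 self.residual_rms_nm)

    @property
    def rotation_deg(self) -> float:
        """Rotation angle implied by the linear part (degrees)."""
        return float(np.rad2deg(np.arctan2(self.matrix[1, 0],
                                           self.matrix[0, 0])))

    def save(self, path) -> None:
        """Serialize as six numbers + residual RMS in a small text format."""
        m, t = self.matrix, self.offset
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# affine transform: a11 a12 a21 a22 tx ty rms_nm\n")
            fh.write(" ".join(f"{v:.12g}" for v in
                              [m[0, 0], m[0, 1], m[1, 0], m[1, 1],
                               t[0], t[1], self.residual_rms_nm]) + "\n")

    @classmethod
    def load(cls, path) -> "AffineTransform2D":
        vals = [float(v) for line in Path(path).read_text().splitlines()
                if line.strip() and not line.startswith("#")
                for v in line.split()]
        if len(vals) != 7:
            raise RegistrationError("transform file must hold 7 numbers")
        a11, a12, a21, a22, tx, ty, rms = vals
        return cls(np.array([[a11, a12], [a21, a22]]), np.array([tx, ty]), rms)


def fit_affine(beads_a: np.ndarray, beads_b: np.ndarray) -> AffineTransform2D:
    """Least-squares affine transform mapping channel B onto channel A.

    Minimizes ``sum || M @ b_i + t - a_i ||^2`` over the six affine
    parameters; exact (machine precision) on noiseless affine-related
    point sets.

    Parameters
    ----------
    beads_a, beads_b : ndarray, shape (n, 2)
        Matched bead localizations in channels A and B.

    Raises
    ------
    RegistrationError
        Fewer than 3 pairs, or a collinear bead configuration.
    """
    a = np.asarray(beads_a, dtype=float)
    b = np.asarray(beads_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 2:
        raise RegistrationError("bead arrays must both have shape (n, 2)")
    n = a.shape[0]
    if n < 3:
        raise RegistrationError("at least 3 bead pairs required")
    design = np.column_stack([b, np.ones(n)])           # (n, 3)
    if np.linalg.matrix_rank(design, tol=1e-9 * max(1.0, np.abs(b).max())) < 3:
        raise RegistrationError("bead configuration is collinear")
    sol, *_ = np.linalg.lstsq(design, a, rcond=None)    # (3, 2)
    matrix = sol[:2].T
    offset = sol[2]
    resid = design @ sol - a
    # per-coordinate RMS: converges to the per-axis localization noise SD
    rms = float(np.sqrt(np.mean(resid**2)))
    return AffineTransform2D(matrix, offset, rms)


def apply_transform(table: LocalizationTable,
                    transform: AffineTransform2D) -> LocalizationTable:
    """Map a localization table's coordinates through an affine transform.

    Only ``x_nm``/``y_nm`` change; the returned table is flagged as
    registered.
    """
    xy = transform.apply(table.df[["x_nm", "y_nm"]].to_numpy())
    df = table.df.copy()
    df["x_nm"] = xy[:, 0]
    df["y_nm"] = xy[:, 1]
    return LocalizationTable(df, channel=table.channel, registered=True)
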