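"""Tissue conductivity tensors (S/m), including the tilted optic-nerve tensor.

All tissues are electrically isotropic except the optic nerve, whose myelin
sheath-dominated microstructure makes it ~6x more conductive along the fiber
axis (0.5 S/m) than across it (0.08 S/m).  The nerve tensor is expressed in
its local frame diag(0.08, 0.08, 0.5) and rotated so the 0.5-eigenvector
follows the (nasally tilted) nerve axis.  Values are low-frequency (100 Hz)
conductivities applied frequency-independently under the quasi-static
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .geometry import LABEL_OF, NAME_OF, TISSUES

#: isotropic conductivities, S/m
TABLE_CONDUCTIVITIES: Dict[str, float] = {
    "cornea": 0.422,
    "atria": 1.5,
    "lens": 0.322,
    "vitreous": 1.5,
    "retina": 0.5028,
    "muscle": 0.267,
    "fat": 0.028,
    "choroid": 0.2779,
    "sclera": 0.5028,
    "csf": 2.0,
    "sheath": 0.006,
}

#: optic nerve principal conductivities: axial, transverse (S/m)
NERVE_AXIAL = 0.5
NERVE_TRANSVERSE = 0.08

#: platinum electrode conductivity (S/m); kept for completeness -- electrodes
#: are modeled as nodal current injections, not conducting volumes
PLATINUM_CONDUCTIVITY = 8.9e6


def _rotation_z_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z onto the given unit vector."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(z @ axis)
    if np.linalg.norm(v) < 1e-15:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def tensor_for(label: str, nerve_axis: Optional[np.ndarray] = None) -> np.ndarray:
    """3x3 conductivity tensor for a tissue label.

    Isotropic tissues return sigma * I exactly.  The optic nerve returns
    R diag(0.08, 0.08, 0.5) R^T with R rotating +z onto ``nerve_axis``.
    """
    if label == "optic_nerve":
        if nerve_axis is None:
            nerve_axis = np.array([0.0, 0.0, 1.0])
        R = _rotation_z_to(nerve_axis)
        D = np.diag([NERVE_TRANSVERSE, NERVE_TRANSVERSE, NERVE_AXIAL])
        return R @ D @ R.T
    try:
        sigma = TABLE_CONDUCTIVITIES[label]
    except KeyError:
        raise KeyError(f"unknown tissue label {label!r}")
    return sigma * np.eye(3)


@dataclass
class TissueTensorMap:
    """Per-label symmetric conductivity tensors plus the nerve axis."""

    nerve_axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    entries: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.nerve_axis = np.asarray(self.nerve_axis, dtype=float)
        self.nerve_axis = self.nerve_axis / np.linalg.norm(self.nerve_axis)
        if not self.entries:
            self.entries = {name: tensor_for(name, self.nerve_axis)
                            for name in TISSUES}
        for name, T in self.entries.items():
            if not np.allclose(T, T.T):
                raise ValueError(f"tensor for {name!r} not symmetric")
            np.linalg.cholesky(T)     # raises if not positive definite

    def tensor_array(self, labels: np.ndarray) -> np.ndarray:
        """Stack of (M, 3, 3) tensors for integer label codes."""
        lut = np.stack([self.entries[NAME_OF[i]] for i in range(len(TISSUES))])
        return lut[labels]

    def to_table(self) -> Dict[str, list]:
        """{label: [xx, yy, zz, xy, xz, yz]} for provenance logging."""
        out = {}
        for name, T in self.entries.items():
            out[name] = [float(T[0, 0]), float(T[1, 1]), float(T[2, 2]),
                         float(T[0, 1]), float(T[0, 2]), float(T[1, 2])]
        return out
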