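"""Shared voxel-grid rotation helpers (nearest-neighbour, index space)."""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation


def euler_matrix_xyz(angles_deg) -> np.ndarray:
    """Rotation matrix for extrinsic x-y-z Euler angles, acting on (x, y, z)."""
    return Rotation.from_euler("xyz", angles_deg, degrees=True).as_matrix()


def to_index_space(r_xyz: np.ndarray) -> np.ndarray:
    """Re-express a rotation on physical (x, y, z) for arrays indexed (z, y, x)."""
    return r_xyz[::-1, ::-1]


def rotate_volume(
    vol: np.ndarray,
    r_idx: np.ndarray,
    order: int = 0,
    cval: float = 0,
    output_shape: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Rotate a 3D array about its centre by the index-space matrix ``r_idx``.

    The output grid is enlarged to the rotated bounding box unless
    ``output_shape`` is given, so no foreground is clipped.  Nearest-neighbour
    by default: binary and 8-bit volumes stay binary / 8-bit.
    """
    r_idx = np.asarray(r_idx, dtype=float)
    shape = np.array(vol.shape, dtype=float)
    if output_shape is None:
        corners = np.array(
            [[i, j, k] for i in (0, shape[0]) for j in (0, shape[1]) for k in (0, shape[2])]
        )
        centre_in = (shape - 1) / 2.0
        rot = (corners - centre_in) @ r_idx.T
        extent = rot.max(axis=0) - rot.min(axis=0)
        output_shape = tuple(int(np.ceil(e)) + 1 for e in extent)
    centre_in = (shape - 1) / 2.0
    centre_out = (np.array(output_shape, dtype=float) - 1) / 2.0
    # output coord o maps to input coord R^-1 (o - c_out) + c_in
    r_inv = np.linalg.inv(r_idx)
    offset = centre_in - r_inv @ centre_out
    return ndimage.affine_transform(
        vol, r_inv, offset=offset, output_shape=output_shape, order=order,
        cval=cval, mode="constant", prefilter=False,
    )


def rotation_about_z(angle_deg: float) -> np.ndarray:
    """Index-space matrix for an in-plane rotation about the long (z) axis."""
    return to_index_space(euler_matrix_xyz([0.0, 0.0, angle_deg]))
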