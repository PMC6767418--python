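"""Tikhonov-regularised channel-to-voxel image reconstruction.

The measurement model stacks OD-domain channel betas at both wavelengths,
Y = L·X, with L the block Jacobian built from extinction coefficients and
channel sensitivity volumes, and X the voxel-wise ΔHbO/ΔHbR concentration
changes. X is recovered as the minimiser of ‖Y − LX‖² + λ‖X‖², computed via
SVD (numerically equivalent to (LᵀL + λI)⁻¹LᵀY).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fnirs_preprocess import ExtinctionTable, LN10
from .forward_model import MaskVolume, ProbeGeometry, SensitivityProfile
from .glm import ChannelBetas

__all__ = [
    "MeasurementVector",
    "JacobianL",
    "VoxelBetaMap",
    "channel_betas_to_od",
    "assemble_L",
    "tikhonov_solve",
    "auto_lambda",
]


@dataclass
class MeasurementVector:
    """Stacked per-channel OD-domain betas: λ1 block then λ2 block, per condition."""

    Y: np.ndarray  # (2·n_channels,) or (2·n_channels, n_conditions)
    conditions: tuple
    n_channels: int

    def __post_init__(self):
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float).T).T
        if self.Y.shape[0] != 2 * self.n_channels:
            raise ValueError("Y length must be 2 × n_channels")


@dataclass
class JacobianL:
    """(2·n_channels) × (2·n_masked_voxels) operator; HbO columns then HbR."""

    L: np.ndarray
    mask: MaskVolume
    n_channels: int

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=float)
        nv = self.mask.n_true
        if self.L.shape != (2 * self.n_channels, 2 * nv):
            raise ValueError("L has wrong block shape")


@dataclass
class VoxelBetaMap:
    """Reconstructed ΔHbO/ΔHbR volumes (masked voxels only), per condition."""

    hbo: np.ndarray  # (n_conditions, n_masked_voxels)
    hbr: np.ndarray
    conditions: tuple
    mask: MaskVolume
    lambda_reg: float

    def volume(self, chromophore: str, condition: str) -> np.ndarray:
        """Full-grid volume with zeros outside the mask."""
        k = self.conditions.index(condition)
        flat = np.zeros(self.mask.grid.n_voxels)
        vals = {"HbO": self.hbo, "HbR": self.hbr}[chromophore][k]
        flat[self.mask.indices()] = vals
        return flat.reshape(self.mask.grid.dims)


def channel_betas_to_od(
    betas: ChannelBetas,
    ext: ExtinctionTable,
    geometry: ProbeGeometry,
    include_dpf: bool = True,
) -> MeasurementVector:
    """Forward-project channel concentration betas to OD-domain betas.

    β_dOD(λ) = d · [dpf(λ)] · ln10 · (ε_HbO(λ)·β_HbO + ε_HbR(λ)·β_HbR) per
    channel, stacked as the λ1 block followed by the λ2 block.
    ``include_dpf=False`` reproduces the literal forward relation without a
    pathlength factor.
    """
    d = geometry.distances_cm
    if len(d) != len(betas.channel_ids):
        raise ValueError("missing source-detector distances for channels")
    eps = ext.eps_ln  # (chromophore, λ)
    dpf = np.asarray(ext.dpf) if include_dpf else np.ones(2)
    hbo = betas.beta[:, :, betas.chromophores.index("HbO")]  # (cond, ch)
    hbr = betas.beta[:, :, betas.chromophores.index("HbR")]
    blocks = []
    for wi in range(2):
        blocks.append(
            d[None, :] * dpf[wi] * (eps[0, wi] * hbo + eps[1, wi] * hbr)
        )
    Y = np.concatenate(blocks, axis=1).T  # (2·n_ch, n_cond)
    return MeasurementVector(Y=Y, conditions=betas.conditions,
                             n_channels=len(betas.channel_ids))


def assemble_L(
    profiles: SensitivityProfile,
    ext: ExtinctionTable,
    mask: MaskVolume,
    include_dpf: bool = True,
    distances_cm: np.ndarray | None = None,
) -> JacobianL:
    """Assemble the block Jacobian over masked voxels.

    Block structure (HbO columns then HbR columns):
    [ε_HbO^λ1·F^λ1 | ε_HbR^λ1·F^λ1 ; ε_HbO^λ2·F^λ2 | ε_HbR^λ2·F^λ2].
    With ``include_dpf`` the rows additionally carry d·dpf(λ) so the operator
    is consistent with :func:`channel_betas_to_od`.
    """
    if profiles.grid.dims != mask.grid.dims:
        raise ValueError("profile and mask grids differ")
    idx = mask.indices()
    Ff = profiles.flat()[:, :, idx]  # (ch, λ, vox)
    eps = ext.eps_ln
    n_ch = Ff.shape[0]
    d = profiles.geometry.distances_cm if distances_cm is None else distances_cm
    dpf = np.asarray(ext.dpf) if include_dpf else np.ones(2)
    rows = []
    for wi in range(2):
        scale = (d * dpf[wi])[:, None] if include_dpf else 1.0
        hbo_block = eps[0, wi] * Ff[:, wi, :]
        hbr_block = eps[1, wi] * Ff[:, wi, :]
        if include_dpf:
            hbo_block = scale * hbo_block
            hbr_block = scale * hbr_block
        rows.append(np.concatenate([hbo_block, hbr_block], axis=1))
    L = np.concatenate(rows, axis=0)
    return JacobianL(L=L, mask=mask, n_channels=n_ch)


def auto_lambda(L: JacobianL, frac: float = 0.01) -> float:
    """Scale-invariant default: ``frac`` × max diagonal entry of LᵀL."""
    col_norms2 = (L.L**2).sum(axis=0)
    return float(frac * col_norms2.max())


def tikhonov_solve(
    L: JacobianL,
    Y: MeasurementVector,
    lambda_reg: float | str = "auto",
) -> VoxelBetaMap:
    """Ridge-regularised solve X = argmin ‖Y − LX‖² + λ‖X‖² via SVD."""
    A = L.L
    if lambda_reg == "auto":
        lam = auto_lambda(L)
    else:
        lam = float(lambda_reg)
    if lam < 0:
        raise ValueError("lambda_reg must be nonnegative")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    if lam == 0 and (
        A.shape[1] > A.shape[0]
        or s.size == 0
        or s.min() <= 1e-12 * max(s.max(), 1e-300)
    ):
        raise ValueError("LᵀL is singular; use lambda_reg > 0")
    filt = s / (s**2 + lam)
    X = Vt.T @ (filt[:, None] * (U.T @ Y.Y))  # (2·n_vox, n_cond)
    nv = L.mask.n_true
    return VoxelBetaMap(
        hbo=X[:nv].T,
        hbr=X[nv:].T,
        conditions=Y.conditions,
        mask=L.mask,
        lambda_reg=lam,
    )
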