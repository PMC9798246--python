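"""Minimal in-memory representations of protein structures.

A protein is reduced to an ordered set of labelled points: one alpha carbon
per residue for graph construction (:class:`CaStructure`), or all heavy
atoms with per-atom scattering weights for density simulation
(:class:`AtomCloud`).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class EmptyStructureError(ValueError):
    """Raised when a structure source contains no usable atoms."""


@dataclass
class CaStructure:
    """Ordered alpha-carbon trace of a protein or complex.

    Parameters
    ----------
    chain_ids : sequence of str
        Chain identifier of each residue, in file/build order.
    residue_indices : sequence of int
        Residue number of each alpha carbon. ``(chain_id, residue_index)``
        pairs must be unique.
    coords : (n, 3) array of float
        Cartesian coordinates in angstroms.
    name : str
        Human-readable name.
    source_id : str
        Identifier of the source (e.g. a PDB id or fixture spec).
    """

    chain_ids: list[str]
    residue_indices: np.ndarray
    coords: np.ndarray
    name: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.chain_ids = list(self.chain_ids)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        n = len(self.coords)
        if n == 0:
            raise EmptyStructureError("structure has no atoms")
        if len(self.chain_ids) != n or len(self.residue_indices) != n:
            raise ValueError("chain_ids, residue_indices and coords must have equal length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        keys = list(zip(self.chain_ids, self.residue_indices.tolist()))
        if len(set(keys)) != n:
            raise ValueError("(chain_id, residue_index) pairs must be unique")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_residues(self) -> int:
        return len(self.coords)

    def labels(self) -> list[str]:
        """Per-residue labels like ``'A:42'``, in order."""
        return [f"{c}:{i}" for c, i in zip(self.chain_ids, self.residue_indices)]

    def as_atom_cloud(self) -> "AtomCloud":
        """Alpha carbons as a unit-weight point cloud (backbone-only mode)."""
        return AtomCloud(positions=self.coords.copy())


@dataclass
class AtomCloud:
    """Unlabelled weighted point cloud in angstroms, input to rasterization."""

    positions: np.ndarray
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if len(self.positions) == 0:
            raise EmptyStructureError("atom cloud is empty")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.weights is None:
            self.weights = np.ones(len(self.positions))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.positions),):
            raise ValueError("weights must be one scalar per atom")
        if not np.all(self.weights > 0):
            raise ValueError("weights must be positive")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)
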