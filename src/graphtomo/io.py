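"""File I/O: PDB structures in, MRC volumes and GEXF graphs in/out.

PDB parsing goes through gemmi; density maps are written as mode-2
(float32) MRC/CCP4 maps with the voxel size recorded in the cell header;
graphs round-trip through GEXF via networkx.
"""
from __future__ import annotations

import json
from pathlib import Path

import gemmi
import networkx as nx
import numpy as np
import pandas as pd

from .structures import AtomCloud, CaStructure, EmptyStructureError
from .contact import ProteinGraph


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed."""


def _read_pdb(path) -> gemmi.Structure:
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path} contains no models")
    return st


def _is_amino_acid(residue: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(residue.name)
    return info is not None and info.is_amino_acid()


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc identifier order
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def read_ca_structure(
    path,
    model_policy: str = "first_model",
    altloc_policy: str = "highest_occupancy",
) -> CaStructure:
    """Read one alpha carbon per amino-acid residue, in file order.

    Waters, ligands, nucleotides and hydrogens are excluded. Multi-model
    (e.g. NMR) files contribute only their first model; alternate locations
    are resolved to the highest-occupancy conformer. Residues that share a
    (chain, number) pair through insertion codes are renumbered by their
    ordinal position in the chain so labels stay unique.
    """
    if model_policy != "first_model":
        raise ValueError(f"unsupported model_policy {model_policy!r}")
    if altloc_policy != "highest_occupancy":
        raise ValueError(f"unsupported altloc_policy {altloc_policy!r}")
    st = _read_pdb(path)
    model = st[0]

    chains: list[str] = []
    numbers: list[int] = []
    coords: list[list[float]] = []
    for chain in model:
        seen_in_chain: set[int] = set()
        has_collision = False
        chain_rows: list[tuple[int, list[float]]] = []
        for ordinal, residue in enumerate(chain, start=1):
            if not _is_amino_acid(residue):
                continue
            cas = [a for a in residue if a.name == "CA" and a.element.name == "C"]
            if not cas:
                continue
            atom = _pick_altloc(cas)
            num = residue.seqid.num
            if num in seen_in_chain:
                has_collision = True
            seen_in_chain.add(num)
            chain_rows.append((num, [atom.pos.x, atom.pos.y, atom.pos.z]))
        for ordinal, (num, xyz) in enumerate(chain_rows, start=1):
            chains.append(chain.name)
            numbers.append(ordinal if has_collision else num)
            coords.append(xyz)

    if not coords:
        raise EmptyStructureError(f"{path} contains no alpha carbons")
    stem = Path(str(path)).stem
    return CaStructure(
        chain_ids=chains,
        residue_indices=np.array(numbers),
        coords=np.array(coords),
        name=stem,
        source_id=stem.upper(),
    )


def read_all_atoms(path) -> AtomCloud:
    """All heavy atoms of polymer (amino-acid) residues, uniform weight 1.

    Hydrogens and deuteriums are dropped; alternate locations are resolved
    per atom name to the highest-occupancy copy.
    """
    st = _read_pdb(path)
    model = st[0]
    positions: list[list[float]] = []
    for chain in model:
        for residue in chain:
            if not _is_amino_acid(residue):
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in residue:
                if atom.element.name in ("H", "D"):
                    continue
                by_name.setdefault(atom.name, []).append(atom)
            for name in by_name:
                atom = _pick_altloc(by_name[name])
                positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not positions:
        raise EmptyStructureError(f"{path} contains no heavy polymer atoms")
    return AtomCloud(positions=np.array(positions))


# ---------------------------------------------------------------------------
# MRC volumes

def write_volume_mrc(volume, path) -> None:
    """Write a cubic density volume as a mode-2 (float32) MRC map."""
    grid = np.asarray(volume.grid, dtype=np.float32)
    if grid.ndim != 3 or len(set(grid.shape)) != 1:
        raise ValueError("only cubic volumes are supported")
    n = grid.shape[0]
    fg = gemmi.FloatGrid(n, n, n)
    np.asarray(fg.array)[:] = grid
    edge = n * volume.voxel_size
    fg.unit_cell = gemmi.UnitCell(edge, edge, edge, 90.0, 90.0, 90.0)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = fg
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def read_volume_mrc(path):
    """Read a cubic MRC map back into a DensityVolume."""
    from .tomosim import DensityVolume

    ccp4 = gemmi.read_ccp4_map(str(path))
    arr = np.array(ccp4.grid.array, dtype=np.float32)
    if arr.ndim != 3 or len(set(arr.shape)) != 1:
        raise ValueError(f"{path} is not a cubic volume: shape {arr.shape}")
    voxel = ccp4.grid.unit_cell.a / arr.shape[0]
    return DensityVolume(grid=arr, voxel_size=float(voxel))


def write_tilt_series_mrcs(series, path) -> None:
    """Store a tilt series as a z-stacked MRC file plus a JSON angle sidecar."""
    images = np.asarray(series.images, dtype=np.float32)
    n_img, nx_, ny_ = images.shape
    fg = gemmi.FloatGrid(nx_, ny_, n_img)
    np.asarray(fg.array)[:] = np.moveaxis(images, 0, 2)
    fg.unit_cell = gemmi.UnitCell(nx_, ny_, n_img, 90.0, 90.0, 90.0)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = fg
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))
    sidecar = Path(str(path)).with_suffix(".angles.json")
    sidecar.write_text(json.dumps({"angles_deg": list(map(float, series.angles)),
                                   "tilt_axis": series.tilt_axis}))


# ---------------------------------------------------------------------------
# GEXF graphs

def write_graph_gexf(pgraph: ProteinGraph, path) -> None:
    # the GEXF writer keeps only the graph's name among graph-level
    # attributes, so provenance is serialized through it
    g = pgraph.graph.copy()
    g.graph["name"] = json.dumps({"role": pgraph.role, "cutoff": pgraph.cutoff,
                                  "source_id": pgraph.source_id})
    nx.write_gexf(g, str(path))


def read_graph_gexf(path) -> ProteinGraph:
    g = nx.read_gexf(str(path), node_type=int)
    meta = {}
    try:
        meta = json.loads(g.graph.get("name", ""))
    except (ValueError, TypeError):
        pass
    return ProteinGraph(
        graph=nx.Graph(g),
        role=meta.get("role", "control"),
        cutoff=float(meta.get("cutoff", 0.0)),
        source_id=meta.get("source_id", ""),
    )


def write_feature_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=True, index_label="graph_id")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="graph_id")
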