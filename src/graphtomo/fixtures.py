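"""Synthetic alpha-carbon structures with known topology.

Parametric generators for protein-like point chains — helices, zigzag
sheets, rings/barrels, random coils, and symmetric homo-multimers — so
that every pipeline stage can be exercised without downloading real
structures. All fixtures keep the consecutive Ca-Ca spacing at the
standard trans-peptide 3.8 A, which keeps contact-graph degree statistics
protein-like, and are bit-reproducible from their parameters.
"""
from __future__ import annotations

import string

import numpy as np

from .structures import CaStructure

CA_SPACING = 3.8  # A between consecutive alpha carbons


def _structure(coords: np.ndarray, name: str, chain_ids=None) -> CaStructure:
    n = len(coords)
    if chain_ids is None:
        chain_ids = ["A"] * n
    # residues numbered 1.. within each chain
    numbers, counts = [], {}
    for c in chain_ids:
        counts[c] = counts.get(c, 0) + 1
        numbers.append(counts[c])
    return CaStructure(chain_ids=chain_ids, residue_indices=np.array(numbers),
                       coords=coords, name=name, source_id=name)


def make_helix(n: int, rise: float = 1.5, twist: float = 100.0,
               name: str = "helix") -> CaStructure:
    """Ideal alpha-helix-like spiral.

    The radius is solved so consecutive points are exactly ``CA_SPACING``
    apart given the per-residue rise (A) and twist (degrees); the defaults
    (1.5 A, 100 deg) match an ideal alpha helix.
    """
    if n < 2:
        raise ValueError("need at least 2 residues")
    dtheta = np.deg2rad(twist)
    radius = np.sqrt((CA_SPACING**2 - rise**2) / (2.0 * (1.0 - np.cos(dtheta))))
    k = np.arange(n)
    coords = np.column_stack([radius * np.cos(k * dtheta),
                              radius * np.sin(k * dtheta),
                              k * rise])
    return _structure(coords, name)


def make_helix_bundle(n_helices: int = 3, n_per_helix: int = 30,
                      separation: float = 10.0,
                      name: str = "bundle") -> CaStructure:
    """Antiparallel helices packed side by side around a polygon.

    Helix axes sit on the vertices of a regular polygon with edge length
    ``separation`` (two helices degenerate to a hairpin pair); direction
    alternates up/down as in natural helix bundles.
    """
    if n_helices < 2:
        raise ValueError("need at least 2 helices")
    if n_helices == 2:
        centers = np.array([[0.0, 0.0], [separation, 0.0]])
    else:
        circum = separation / (2.0 * np.sin(np.pi / n_helices))
        a = 2.0 * np.pi * np.arange(n_helices) / n_helices
        centers = circum * np.column_stack([np.cos(a), np.sin(a)])
    up = make_helix(n_per_helix).coords
    parts = []
    for k, (cx, cy) in enumerate(centers):
        h = up[::-1].copy() if k % 2 else up.copy()
        h[:, 0] += cx
        h[:, 1] += cy
        parts.append(h)
    return _structure(np.vstack(parts), name)


def make_helix_hairpin(n_per_helix: int = 30, separation: float = 10.0,
                       name: str = "hairpin") -> CaStructure:
    """Two antiparallel helices side by side (helix-turn-helix motif)."""
    out = make_helix_bundle(2, n_per_helix, separation, name=name)
    return out


def make_zigzag_sheet(n_strands: int = 4, strand_len: int = 16,
                      strand_spacing: float = 4.8,
                      name: str = "sheet") -> CaStructure:
    """Antiparallel zigzag strands stacked into a flat sheet."""
    if n_strands < 1 or strand_len < 2:
        raise ValueError("need >= 1 strand of >= 2 residues")
    amp = 0.5
    dx = np.sqrt(CA_SPACING**2 - (2 * amp) ** 2)
    i = np.arange(strand_len)
    rows = []
    for s in range(n_strands):
        x = i * dx
        if s % 2:  # antiparallel
            x = x[::-1]
        rows.append(np.column_stack([x, amp * (-1.0) ** i, np.full(strand_len, s * strand_spacing)]))
    return _structure(np.vstack(rows), name)


def make_ring(n: int = 24, pucker: float = 1.25, stack: int = 1,
              stack_spacing: float = 5.0, name: str = "ring") -> CaStructure:
    """Closed circular chain(s) with an alternating axial pucker.

    Consecutive residues alternate ``+pucker``/``-pucker`` along z (a
    "crown"), and the radius is solved so the chord spacing stays exactly
    ``CA_SPACING``. The pucker gives the ring axial thickness, as real
    ring-shaped assemblies have; a perfectly planar circle is a degenerate
    special case (``pucker=0``) whose density smears into a continuous
    band under single-axis tomography. ``stack`` > 1 stacks identical
    rings along z at ``stack_spacing`` A.
    """
    if n < 3:
        raise ValueError("need at least 3 residues per ring")
    if n % 2 or not 0.0 <= 2.0 * pucker < CA_SPACING:
        raise ValueError("need even n and 0 <= 2*pucker < CA spacing")
    chord = np.sqrt(CA_SPACING**2 - (2.0 * pucker) ** 2)
    radius = chord / (2.0 * np.sin(np.pi / n))
    t = 2.0 * np.pi * np.arange(n) / n
    ring = np.column_stack([radius * np.cos(t), radius * np.sin(t),
                            pucker * (-1.0) ** np.arange(n)])
    coords = np.vstack([ring + [0.0, 0.0, k * stack_spacing] for k in range(stack)])
    return _structure(coords, name)


def make_barrel(n_strands: int = 8, strand_len: int = 12, radius: float = 8.0,
                name: str = "barrel") -> CaStructure:
    """Straight antiparallel strands on a cylinder (beta-barrel-like)."""
    z = np.arange(strand_len) * CA_SPACING
    rows = []
    for s in range(n_strands):
        a = 2.0 * np.pi * s / n_strands
        zz = z[::-1] if s % 2 else z
        rows.append(np.column_stack([np.full(strand_len, radius * np.cos(a)),
                                     np.full(strand_len, radius * np.sin(a)), zz]))
    return _structure(np.vstack(rows), name)


def make_random_coil(n: int = 60, seed: int = 0, confine_radius: float = 18.0,
                     min_separation: float = 3.2, name: str = "coil") -> CaStructure:
    """Seeded self-avoiding random walk confined to a sphere."""
    rng = np.random.default_rng(seed)
    pts = [np.zeros(3)]
    while len(pts) < n:
        for _ in range(200):
            v = rng.normal(size=3)
            cand = pts[-1] + CA_SPACING * v / np.linalg.norm(v)
            if np.linalg.norm(cand) > confine_radius:
                continue
            if len(pts) > 1 and np.min(
                    np.linalg.norm(np.array(pts[:-1]) - cand, axis=1)) < min_separation:
                continue
            pts.append(cand)
            break
        else:
            raise RuntimeError("random coil generation stuck; relax constraints")
    return _structure(np.array(pts), name)


def make_multimer(monomer: CaStructure, copies: int, symmetry: str = "cyclic",
                  radius: float | None = None, contact_gap: float = 4.0,
                  name: str | None = None) -> CaStructure:
    """Arrange symmetric copies of a monomer around the z axis.

    ``cyclic`` places ``copies`` rotated images on a ring; ``dihedral``
    stacks two such rings of ``copies/2`` with the lower ring flipped. When
    ``radius`` is not given it is solved by bisection so the smallest
    inter-copy atom distance equals ``contact_gap`` (A), producing touching
    but non-clashing interfaces. Each copy gets its own chain id.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    if symmetry not in ("cyclic", "dihedral"):
        raise ValueError(f"unknown symmetry {symmetry!r}")
    if name is None:
        name = f"{monomer.name}_{symmetry[0]}{copies}"
    if copies == 1:
        out = _structure(monomer.coords.copy(), name)
        return out
    if symmetry == "dihedral" and copies % 2:
        raise ValueError("dihedral symmetry needs an even copy count")

    base = monomer.coords - monomer.coords.mean(axis=0)
    n_ring = copies if symmetry == "cyclic" else copies // 2

    def ring_coords(r: float) -> list[np.ndarray]:
        placed = []
        for k in range(n_ring):
            a = 2.0 * np.pi * k / n_ring
            c, s = np.cos(a), np.sin(a)
            rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
            placed.append((base + np.array([r, 0.0, 0.0])) @ rot.T)
        return placed

    def ring_gap(r: float) -> float:
        placed = ring_coords(r)
        if n_ring == 1:
            return np.inf
        d = placed[0][:, None] - placed[1][None, :]
        return float(np.sqrt((d**2).sum(-1)).min())

    if radius is None:
        if n_ring == 1:
            radius = 0.0
        else:
            lo, hi = 0.0, 1.0
            while ring_gap(hi) < contact_gap:
                hi *= 2.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                lo, hi = (mid, hi) if ring_gap(mid) < contact_gap else (lo, mid)
            radius = hi

    ring = ring_coords(radius)
    if symmetry == "cyclic":
        copies_xyz = ring
    else:
        flip = np.diag([1.0, -1.0, -1.0])  # 2-fold about x
        lower = [c @ flip.T for c in ring]

        def stack_gap(dz: float) -> float:
            up = ring[0] + np.array([0, 0, dz / 2.0])
            dn = lower[0] - np.array([0, 0, dz / 2.0])
            d = up[:, None] - dn[None, :]
            return float(np.sqrt((d**2).sum(-1)).min())

        lo, hi = 0.0, 1.0
        while stack_gap(hi) < contact_gap:
            hi *= 2.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            lo, hi = (mid, hi) if stack_gap(mid) < contact_gap else (lo, mid)
        dz = hi
        copies_xyz = [c + np.array([0, 0, dz / 2.0]) for c in ring] + \
                     [c - np.array([0, 0, dz / 2.0]) for c in lower]

    letters = string.ascii_uppercase + string.ascii_lowercase + string.digits
    chain_ids = []
    for k, c in enumerate(copies_xyz):
        chain_ids += [letters[k % len(letters)]] * len(c)
    return _structure(np.vstack(copies_xyz), name, chain_ids=chain_ids)


def fixture_battery(seed: int = 0) -> list[tuple[str, CaStructure]]:
    """Ten topologically distinct synthetic structures, monomers and
    multimers, ~40-240 residues, reproducible for a fixed seed."""
    battery = [
        ("helix40", make_helix(40, name="helix40")),
        ("ring48", make_ring(24, stack=2, name="ring48")),
        ("dimer60", make_multimer(make_helix(30, name="h30"), 2, name="dimer60")),
        ("sheet64", make_zigzag_sheet(4, 16, name="sheet64")),
        ("coil75", make_random_coil(75, seed=seed + 11, confine_radius=20.0,
                                    name="coil75")),
        ("tetramer80", make_multimer(make_helix(20, name="h20"), 4, name="tetramer80")),
        ("bundle90", make_helix_bundle(3, 30, name="bundle90")),
        ("barrel112", make_barrel(8, 14, radius=8.0, name="barrel112")),
        ("hexamer144", make_multimer(make_helix(24, name="h24"), 6, name="hexamer144")),
        ("octamer240", make_multimer(make_helix(30, name="h30"), 8,
                                     symmetry="dihedral", name="octamer240")),
    ]
    return battery


def write_pdb(structure: CaStructure, path) -> None:
    """Write a minimal Ca-only PDB file (glycine backbone trace)."""
    lines = []
    for serial, (chain, num, (x, y, z)) in enumerate(
            zip(structure.chain_ids, structure.residue_indices, structure.coords),
            start=1):
        lines.append(
            f"ATOM  {serial:5d}  CA  GLY {str(chain)[0]}{int(num):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
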