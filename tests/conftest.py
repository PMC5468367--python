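"""Shared fixtures: hand-written PDB texts and small synthetic ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from gorgedyn import synthio
from gorgedyn.structio import StructureModel


def pdb_line(serial: int, name: str, resname: str, chain: str, resid: int,
             xyz, occ: float = 1.0, altloc: str = " ", element: str = "") -> str:
    """One fixed-format ATOM record."""
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    if not element:
        element = name[0]
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d} {name_field}{altloc}{resname:<3s} {chain}{resid:4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2s}"
    )


@pytest.fixture
def three_atom_pdb(tmp_path):
    lines = [
        pdb_line(1, "N", "ALA", "A", 1, (11.104, 6.134, -6.504)),
        pdb_line(2, "CA", "ALA", "A", 1, (11.639, 6.071, -5.147)),
        pdb_line(3, "C", "ALA", "A", 1, (10.699, 6.639, -4.098)),
        "END",
    ]
    p = tmp_path / "three.pdb"
    p.write_text("\n".join(lines) + "\n")
    return str(p)


@pytest.fixture
def altloc_pdb(tmp_path):
    lines = [
        pdb_line(1, "CA", "ALA", "A", 1, (0.0, 0.0, 0.0), occ=0.40, altloc="A"),
        pdb_line(2, "CA", "ALA", "A", 1, (1.0, 0.0, 0.0), occ=0.60, altloc="B"),
        "END",
    ]
    p = tmp_path / "altloc.pdb"
    p.write_text("\n".join(lines) + "\n")
    return str(p)


@pytest.fixture
def multimodel_pdb(tmp_path):
    frames = []
    for m in range(3):
        frames.append(f"MODEL     {m + 1}")
        frames.append(pdb_line(1, "CA", "GLY", "A", 1, (float(m), 0.0, 0.0)))
        frames.append(pdb_line(2, "CA", "GLY", "A", 2, (float(m), 3.8, 0.0)))
        frames.append("ENDMDL")
    frames.append("END")
    p = tmp_path / "traj.pdb"
    p.write_text("\n".join(frames) + "\n")
    return str(p)


def make_model(coords, vdw=1.5, resids=None, chains=None, names=None,
               resnames=None, masses=None) -> StructureModel:
    """Bare-bones StructureModel around an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if resids is None:
        resids = np.arange(1, n + 1)
    return StructureModel(
        names=np.array(names if names is not None else ["C"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        resids=np.asarray(resids, dtype=int),
        resnames=np.array(resnames if resnames is not None else ["UNK"] * n,
                          dtype=object),
        chains=np.array(chains if chains is not None else ["A"] * n, dtype=object),
        coords=coords,
        masses=np.asarray(masses if masses is not None else [12.011] * n,
                          dtype=float),
        vdw=np.full(n, vdw) if np.isscalar(vdw) else np.asarray(vdw, dtype=float),
    )


def ring_model(radius: float = 4.0, n_atoms: int = 24, vdw: float = 1.5,
               z: float = 0.0) -> StructureModel:
    ang = 2 * np.pi * np.arange(n_atoms) / n_atoms
    coords = np.stack([radius * np.cos(ang), radius * np.sin(ang),
                       np.full(n_atoms, z)], axis=1)
    return make_model(coords, vdw=vdw)


@pytest.fixture
def small_breathing():
    spec = synthio.BreathingSpec(amplitude=1.0, n_frames=20, n_residues=6,
                                 noise_sd=0.1, seed=42)
    traj, true_r, c_map = synthio.make_breathing_ensemble(spec)
    return spec, traj, true_r, c_map
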