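"""Structure and trajectory I/O.

Wraps MDAnalysis for the heavy lifting (PDB/XTC/DCD parsing, multi-model
PDB trajectories) and exposes two plain in-memory containers used by every
downstream stage: :class:`StructureModel` (atoms, masses, vdW radii,
residue/chain metadata) and :class:`TrajectoryEnsemble` (frames +
timestamps). Geometry downstream uses heavy atoms only; hydrogens present
in a file are kept in the model but carry their own (small) vdW radii.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import MDAnalysis as mda

from . import _tables
from .errors import FormatError, InputError, SelectionError, TopologyError

__all__ = [
    "StructureModel",
    "TrajectoryEnsemble",
    "load_structure",
    "load_trajectory",
    "select",
    "write_pdb",
]

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "MSE",
}
_TWO_LETTER = {"CL", "BR", "ZN", "FE", "MG", "NA", "SE", "MN", "CU", "NI"}


def _guess_element(name: str, resname: str) -> str:
    """Element symbol from a PDB atom name, biased to protein conventions."""
    stripped = "".join(ch for ch in name if ch.isalpha()).upper()
    if not stripped:
        return ""
    if resname.upper() in _AMINO_ACIDS:
        return stripped[0]
    if stripped[:2] in _TWO_LETTER and len(name.strip()) <= 2:
        return stripped[:2]
    return stripped[0]


@dataclass
class StructureModel:
    """A static structure: per-atom identity, coordinates (Å), mass (Da), vdW radius (Å)."""

    names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    coords: np.ndarray
    masses: np.ndarray
    vdw: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.names)
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)
        self.masses = np.asarray(self.masses, dtype=float)
        self.vdw = np.asarray(self.vdw, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise InputError("non-finite coordinates in structure")
        if n and (np.any(self.masses <= 0) or np.any(self.vdw <= 0)):
            raise InputError("masses and vdW radii must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (chain, resid) pairs in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for ch, ri in zip(self.chains, self.resids):
            seen.setdefault((str(ch), int(ri)), None)
        return list(seen)

    def atoms_of_residue(self, chain: str, resid: int) -> np.ndarray:
        return np.flatnonzero((self.chains == chain) & (self.resids == resid))

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        return replace(self, coords=np.array(coords, dtype=float))

    def subset(self, idx: np.ndarray) -> "StructureModel":
        idx = np.asarray(idx, dtype=int)
        return StructureModel(
            names=self.names[idx], elements=self.elements[idx],
            resids=self.resids[idx], resnames=self.resnames[idx],
            chains=self.chains[idx], coords=self.coords[idx],
            masses=self.masses[idx], vdw=self.vdw[idx],
        )


@dataclass
class TrajectoryEnsemble:
    """Ordered coordinate frames over a reference :class:`StructureModel`."""

    model: StructureModel
    coords: np.ndarray            # (n_frames, n_atoms, 3) Å
    times_ns: np.ndarray          # strictly increasing
    stride_ns: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.model.n_atoms:
            raise TopologyError(
                f"frame atom count {self.coords.shape} does not match topology "
                f"({self.model.n_atoms} atoms)"
            )
        if len(self.times_ns) != len(self.coords):
            raise InputError("timestamps and frames differ in length")
        if len(self.times_ns) > 1 and np.any(np.diff(self.times_ns) <= 0):
            raise InputError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    def frame(self, i: int) -> StructureModel:
        return self.model.with_coords(self.coords[i])

    def subsample(self, stride: int) -> "TrajectoryEnsemble":
        if stride < 1:
            raise InputError("stride must be >= 1")
        return TrajectoryEnsemble(
            self.model, self.coords[::stride], self.times_ns[::stride],
            stride_ns=(self.stride_ns or 0.0) * stride or None,
        )


def _model_from_universe(u: mda.Universe) -> StructureModel:
    atoms = u.atoms
    names = atoms.names.astype(str)
    resnames = atoms.resnames.astype(str)
    try:
        elements = np.array([e.upper() for e in atoms.elements], dtype=object)
        blank = np.array([not e for e in elements])
        if blank.any():
            raise mda.exceptions.NoDataError("blank elements")
    except Exception:
        elements = np.array(
            [_guess_element(n, r) for n, r in zip(names, resnames)], dtype=object
        )
    unknown = sorted({e for e in elements if e.upper() not in _tables.VDW_RADII})
    if unknown:
        warnings.warn(
            f"unknown element(s) {unknown}: using default vdW radius "
            f"{_tables.DEFAULT_VDW} Å and carbon mass",
            stacklevel=3,
        )
    try:
        chains = atoms.chainIDs.astype(str)
    except mda.exceptions.NoDataError:
        chains = atoms.segids.astype(str)
    chains = np.array([c if c.strip() else "A" for c in chains], dtype=object)
    return StructureModel(
        names=np.array(names, dtype=object),
        elements=elements,
        resids=atoms.resids.astype(int),
        resnames=np.array(resnames, dtype=object),
        chains=chains,
        coords=atoms.positions.astype(float),
        masses=np.array([_tables.atomic_mass(e) for e in elements]),
        vdw=np.array([_tables.vdw_radius(e) for e in elements]),
    )


def _resolve_altlocs(u: mda.Universe) -> mda.AtomGroup:
    """Keep a single location per atom: the highest-occupancy altloc."""
    atoms = u.atoms
    try:
        altlocs = atoms.altLocs
    except mda.exceptions.NoDataError:
        return atoms
    if all(a in ("", " ") for a in altlocs):
        return atoms
    try:
        occupancies = atoms.occupancies
    except mda.exceptions.NoDataError:
        occupancies = np.ones(len(atoms))
    best: dict[tuple, int] = {}
    for i, at in enumerate(atoms):
        key = (at.segid, at.chainID if hasattr(at, "chainID") else "",
               at.resid, at.resname, at.name)
        j = best.get(key)
        if j is None or occupancies[i] > occupancies[j]:
            best[key] = i
    keep = np.array(sorted(best.values()), dtype=int)
    return atoms[keep]


def load_structure(path: str) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Alternate locations are resolved to the highest-occupancy copy; element
    symbols missing from the file are guessed from atom names. Unknown
    elements get a default radius with a warning.
    """
    try:
        u = mda.Universe(path)
    except Exception as exc:
        raise FormatError(f"cannot parse structure file {path!r}: {exc}") from exc
    group = _resolve_altlocs(u)
    if len(group) == 0:
        raise FormatError(f"no atoms in {path!r}")
    sub = mda.Merge(group)
    # Merge drops chainIDs in some paths; restore from the selected group
    try:
        sub.atoms.chainIDs = group.chainIDs
    except (mda.exceptions.NoDataError, AttributeError):
        pass
    return _model_from_universe(sub)


def load_trajectory(
    topology: StructureModel,
    path: str,
    stride_ns: float | None = None,
    frame_dt_ns: float | None = None,
) -> TrajectoryEnsemble:
    """Read an XTC/DCD/multi-model-PDB trajectory over ``topology``.

    ``frame_dt_ns`` sets the file's own frame spacing when the format does
    not record times (multi-model PDB, most DCDs); default 1 ns per frame.
    ``stride_ns`` subsamples to roughly that interval.
    """
    try:
        u = mda.Universe.empty(topology.n_atoms, trajectory=True)
        u.load_new(path)
    except Exception as exc:
        raise FormatError(f"cannot read trajectory {path!r}: {exc}") from exc
    if u.trajectory.n_atoms != topology.n_atoms:
        raise TopologyError(
            f"trajectory has {u.trajectory.n_atoms} atoms, "
            f"topology has {topology.n_atoms}"
        )
    frames, times = [], []
    for ts in u.trajectory:
        frames.append(ts.positions.copy().astype(float))
        times.append(ts.time / 1000.0)  # MDAnalysis time in ps
    if not frames:
        raise InputError(f"empty trajectory {path!r}")
    times = np.asarray(times)
    if frame_dt_ns is not None:
        times = np.arange(len(frames)) * frame_dt_ns
    elif len(times) > 1 and np.any(np.diff(times) <= 0):
        times = np.arange(len(frames), dtype=float)  # format carried no times
    traj = TrajectoryEnsemble(topology, np.stack(frames), times)
    if stride_ns is not None:
        dt = times[1] - times[0] if len(times) > 1 else stride_ns
        stride = max(1, round(stride_ns / dt))
        traj = traj.subsample(stride)
        traj.stride_ns = stride_ns
    return traj


# ---------------------------------------------------------------------------
# selection mini-language:  expr := or_expr ; or := and ('or' and)* ;
# and := unary ('and' unary)* ; unary := ['not'] (clause | '(' expr ')') ;
# clause := key value+  with keys resid/resname/name/chain/element,
# resid values may be ranges a-b or a:b.

_KEYS = ("resid", "resname", "name", "chain", "element")


def _tokenize(query: str) -> list[str]:
    out: list[str] = []
    for raw in query.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _Parser:
    def __init__(self, model: StructureModel, tokens: list[str]):
        self.m = model
        self.toks = tokens
        self.i = 0

    def peek(self) -> str | None:
        return self.toks[self.i] if self.i < len(self.toks) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection")
        self.i += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing token {self.peek()!r}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.take()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() == "and":
            self.take()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        if self.peek() == "not":
            self.take()
            return ~self.unary()
        if self.peek() == "(":
            self.take()
            mask = self.or_expr()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.clause()

    def clause(self) -> np.ndarray:
        key = self.take()
        if key not in _KEYS:
            raise SelectionError(f"unknown selection keyword {key!r}")
        values: list[str] = []
        while self.peek() is not None and self.peek() not in (
            "and", "or", "not", "(", ")", *_KEYS
        ):
            values.append(self.take())
        if not values:
            raise SelectionError(f"keyword {key!r} takes at least one value")
        mask = np.zeros(self.m.n_atoms, dtype=bool)
        for v in values:
            mask |= self._match(key, v)
        return mask

    def _match(self, key: str, value: str) -> np.ndarray:
        if key == "resid":
            for sep in ("-", ":"):
                if sep in value and not value.startswith("-"):
                    lo_s, hi_s = value.split(sep, 1)
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except ValueError as exc:
                        raise SelectionError(f"bad resid range {value!r}") from exc
                    return (self.m.resids >= lo) & (self.m.resids <= hi)
            try:
                rid = int(value)
            except ValueError as exc:
                raise SelectionError(f"bad resid {value!r}") from exc
            return self.m.resids == rid
        field = {
            "resname": self.m.resnames, "name": self.m.names,
            "chain": self.m.chains, "element": self.m.elements,
        }[key]
        return np.array([str(x).upper() == value.upper() for x in field])


def select(model: StructureModel, query: str) -> np.ndarray:
    """Atom indices matching a simple selection expression.

    Supports ``resid`` (values and ``a-b``/``a:b`` ranges), ``resname``,
    ``name``, ``chain`` and ``element`` clauses combined with
    ``and``/``or``/``not`` and parentheses, e.g.
    ``"resid 330 and name CE2"``. Returns a possibly empty index array.
    """
    tokens = _tokenize(query)
    if not tokens:
        raise SelectionError("empty selection")
    mask = _Parser(model, tokens).parse()
    return np.flatnonzero(mask)


def to_universe(model: StructureModel, coords: np.ndarray | None = None) -> mda.Universe:
    """Build an MDAnalysis Universe mirroring the model (for writing/dihedrals)."""
    n_res_keys = model.residue_keys()
    res_index = {k: i for i, k in enumerate(n_res_keys)}
    atom_resindex = np.array(
        [res_index[(str(c), int(r))] for c, r in zip(model.chains, model.resids)]
    )
    seg_keys = list(dict.fromkeys(str(c) for c in model.chains))
    seg_index = {s: i for i, s in enumerate(seg_keys)}
    residue_seg = np.array([seg_index[k[0]] for k in n_res_keys])
    u = mda.Universe.empty(
        model.n_atoms, n_residues=len(n_res_keys), n_segments=len(seg_keys),
        atom_resindex=atom_resindex, residue_segindex=residue_seg,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(x) for x in model.names])
    u.add_TopologyAttr("elements", [str(x) for x in model.elements])
    u.add_TopologyAttr("resids", [k[1] for k in n_res_keys])
    first_atom = [model.atoms_of_residue(k[0], k[1])[0] for k in n_res_keys]
    u.add_TopologyAttr("resnames", [str(model.resnames[i]) for i in first_atom])
    u.add_TopologyAttr("segids", seg_keys)
    u.add_TopologyAttr("chainIDs", [str(x) for x in model.chains])
    u.add_TopologyAttr("occupancies", np.ones(model.n_atoms))
    u.add_TopologyAttr("tempfactors", np.zeros(model.n_atoms))
    u.atoms.positions = model.coords if coords is None else coords
    return u


def write_pdb(model: StructureModel, path: str,
              frames: np.ndarray | None = None) -> None:
    """Write the model (or a stack of frames as MODEL records) to PDB."""
    u = to_universe(model)
    if frames is None:
        with mda.Writer(path, n_atoms=model.n_atoms) as w:
            w.write(u.atoms)
        return
    frames = np.asarray(frames, dtype=float)
    with mda.Writer(path, n_atoms=model.n_atoms, multiframe=True) as w:
        for f in frames:
            u.atoms.positions = f
            w.write(u.atoms)
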