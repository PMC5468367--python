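"""Correlation between residue motion and the gorge radius.

For a superposed trajectory and a bottleneck-radius series R(t), each
atom i gets a correlation 3-vector

    rho_i = < (r_i(t) - <r_i>) (R(t) - <R>) >
            / sqrt( <|r_i(t) - <r_i>|^2> <(R(t) - <R>)^2> )

(time averages, population moments), and each residue n a mass-weighted
average

    d_n = sum_{i in n} m_i rho_i / sum_{i in n} m_i .

|d_n| measures how much a residue's motion tracks the gorge radius, as
distinct from an RMSF, which measures motion per se. Cauchy-Schwarz bounds
|rho_i| by 1, and |d_n| by the largest |rho_i| of its atoms (convexity of
the norm under the mass-weighted mean).

The module also classifies gorge residues (any heavy atom within a cutoff
of the bound ligand's heavy atoms), carries the five gorge subdomains of
TcAChE, and computes per-subdomain Cα RMSD series.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import InputError, SelectionError
from .radstats import RadiusSeries
from .structio import StructureModel, TrajectoryEnsemble, select

__all__ = [
    "CorrelationField",
    "SubdomainMap",
    "TCACHE_SUBDOMAINS",
    "GORGE_RESIDUES_TCACHE",
    "expand_residue_list",
    "superpose",
    "rho_vectors",
    "residue_d",
    "gorge_residues",
    "subdomain_rmsd",
]

# The published gorge-residue enumeration for TcAChE: residues with a heavy
# atom within 10 Å of bound E2020 (one-letter code + resid, ranges inclusive).
GORGE_RESIDUES_TCACHE = (
    "Q69-F75, F78-P86, W114-S124, L127, V129, Y130, Y148, V150, "
    "G198-G203, Q225-G227, W233, R244, I275-S291, N324, D326-A336, "
    "L358, P361, V395, N399, V400, W432, M436, I439-E445"
)

# Five subdomains surrounding the active-site gorge (inclusive resid ranges).
TCACHE_SUBDOMAINS: dict[str, tuple[int, int]] = {
    "omega_loop": (67, 94),
    "S1": (114, 150),
    "S2": (225, 296),
    "S3": (324, 400),
    "S4": (428, 450),
}

_TOKEN = re.compile(r"^[A-Z]?(\d+)(?:-[A-Z]?(\d+))?$")


def expand_residue_list(text: str) -> list[int]:
    """Expand a printed residue enumeration ("Q69-F75, L127, ...") to resids.

    Ranges are inclusive; duplicates collapse; output is sorted.
    """
    resids: set[int] = set()
    for raw in text.split(","):
        tok = raw.strip()
        if not tok:
            continue
        m = _TOKEN.match(tok)
        if not m:
            raise InputError(f"cannot parse residue token {tok!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        if hi < lo:
            raise InputError(f"descending range in token {tok!r}")
        resids.update(range(lo, hi + 1))
    return sorted(resids)


@dataclass
class SubdomainMap:
    """Named residue ranges (inclusive) per chain."""

    ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(TCACHE_SUBDOMAINS)
    )

    def __post_init__(self) -> None:
        items = sorted(self.ranges.items(), key=lambda kv: kv[1][0])
        for (_, (lo1, hi1)), (_, (lo2, _)) in zip(items, items[1:]):
            if lo2 <= hi1:
                raise InputError("subdomain ranges overlap")

    def of(self, resid: int) -> str | None:
        for name, (lo, hi) in self.ranges.items():
            if lo <= resid <= hi:
                return name
        return None


@dataclass
class CorrelationField:
    """Per-atom rho vectors and per-residue d vectors for one chain's R series."""

    rho: np.ndarray                       # (n_atoms, 3)
    d: dict[tuple[str, int], np.ndarray]  # (chain, resid) -> 3-vector
    d_mag: dict[tuple[str, int], float]
    zero_variance_atoms: np.ndarray       # indices with flagged rho = 0


def _kabsch(mobile: np.ndarray, ref: np.ndarray,
            idx: np.ndarray) -> np.ndarray:
    """Least-squares rigid-body fit of ``mobile`` onto ``ref`` over atoms idx."""
    mc = mobile[idx].mean(axis=0)
    rc = ref[idx].mean(axis=0)
    h = (mobile[idx] - mc).T @ (ref[idx] - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return (mobile - mc) @ rot.T + rc


def superpose(
    traj: TrajectoryEnsemble,
    reference: int = 0,
    fit_query: str = "name CA",
) -> TrajectoryEnsemble:
    """Rigid-body fit every frame to the reference frame on the fit set.

    Defaults to all Cα; a non-protein model may pass any selection. Needs
    at least 3 fit atoms for a determined rotation.
    """
    idx = select(traj.model, fit_query)
    if len(idx) < 3:
        raise SelectionError(
            f"superposition needs >= 3 fit atoms, selection matched {len(idx)}"
        )
    ref = traj.coords[reference]
    fitted = np.stack([_kabsch(f, ref, idx) for f in traj.coords])
    return TrajectoryEnsemble(traj.model, fitted, traj.times_ns.copy(),
                              stride_ns=traj.stride_ns)


def rho_vectors(
    traj: TrajectoryEnsemble, series: RadiusSeries,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom correlation 3-vectors with R(t); returns (rho, flagged atoms).

    Frames whose R is missing are dropped pairwise. Atoms with zero
    positional variance get rho = 0 and are flagged; zero variance of R is
    a global error.
    """
    if traj.n_frames != len(series.values):
        raise InputError(
            f"frame count {traj.n_frames} != series length {len(series.values)}"
        )
    mask = ~np.isnan(series.values)
    if mask.sum() < 2:
        raise InputError("need at least two frames with a present radius")
    x = traj.coords[mask]                     # (T, N, 3)
    r = series.values[mask]
    r_dev = r - r.mean()
    var_r = float(np.mean(r_dev**2))
    if var_r == 0:
        raise InputError("radius series has zero variance")
    dev = x - x.mean(axis=0)                  # (T, N, 3)
    num = np.einsum("tnd,t->nd", dev, r_dev) / len(r)
    pos_var = np.mean(np.sum(dev**2, axis=2), axis=0)   # (N,)
    flagged = np.flatnonzero(pos_var == 0)
    denom = np.sqrt(np.where(pos_var == 0, 1.0, pos_var) * var_r)
    rho = num / denom[:, None]
    rho[flagged] = 0.0
    return rho, flagged


def residue_d(
    rho: np.ndarray, model: StructureModel,
) -> tuple[dict[tuple[str, int], np.ndarray], dict[tuple[str, int], float]]:
    """Mass-weighted per-residue average of rho; returns (d, |d|)."""
    d: dict[tuple[str, int], np.ndarray] = {}
    mag: dict[tuple[str, int], float] = {}
    for key in model.residue_keys():
        idx = model.atoms_of_residue(*key)
        m = model.masses[idx]
        vec = (m[:, None] * rho[idx]).sum(axis=0) / m.sum()
        d[key] = vec
        mag[key] = float(np.linalg.norm(vec))
    return d, mag


def correlation_field(
    traj: TrajectoryEnsemble, series: RadiusSeries,
) -> CorrelationField:
    """Convenience wrapper: rho then d on an already superposed trajectory."""
    rho, flagged = rho_vectors(traj, series)
    d, mag = residue_d(rho, traj.model)
    return CorrelationField(rho=rho, d=d, d_mag=mag, zero_variance_atoms=flagged)


def gorge_residues(
    model: StructureModel,
    ligand_query: str = "resname E20",
    cutoff: float = 10.0,
) -> set[tuple[str, int]]:
    """Residues with any heavy atom within ``cutoff`` of a ligand heavy atom."""
    lig = select(model, ligand_query)
    if len(lig) == 0:
        raise SelectionError(
            f"no ligand atoms matched {ligand_query!r}; pass an explicit "
            "residue list instead"
        )
    heavy = model.elements != "H"
    lig_mask = np.zeros(model.n_atoms, dtype=bool)
    lig_mask[lig] = True
    prot = np.flatnonzero(heavy & ~lig_mask)
    lig_heavy = np.array([i for i in lig if heavy[i]])
    if cutoff <= 0 or len(lig_heavy) == 0 or len(prot) == 0:
        return set()
    tree = cKDTree(model.coords[lig_heavy])
    dist, _ = tree.query(model.coords[prot], k=1)
    near = prot[dist <= cutoff]
    return {(str(model.chains[i]), int(model.resids[i])) for i in near}


def subdomain_rmsd(
    traj: TrajectoryEnsemble,
    submap: SubdomainMap | None = None,
    reference: int = 0,
    fit_query: str = "name CA",
    chain: str | None = None,
) -> dict[str, np.ndarray]:
    """Per-frame Cα RMSD to the reference for each subdomain, after a global fit."""
    submap = submap or SubdomainMap()
    fitted = superpose(traj, reference=reference, fit_query=fit_query)
    out: dict[str, np.ndarray] = {}
    for name, (lo, hi) in submap.ranges.items():
        q = f"resid {lo}-{hi} and name CA"
        if chain is not None:
            q += f" and chain {chain}"
        idx = select(traj.model, q)
        if len(idx) == 0:
            raise SelectionError(f"subdomain {name!r} selects no Cα atoms")
        ref = fitted.coords[reference][idx]
        diff = fitted.coords[:, idx, :] - ref
        out[name] = np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))
    return out
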