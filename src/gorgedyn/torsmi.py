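"""Residue-residue correlated dynamics as torsion-angle mutual information.

Each residue's conformation is reduced to its backbone φ/ψ and side-chain
χ torsions (χ1 only for proline); bond lengths, bond angles and ω are
ignored. For two torsion series the mutual information is the plug-in
histogram estimate

    I = S(1) + S(2) − S(1, 2)

in nats over equal-width angular bins. The trajectory is split into
blocks; within each block a circular-shift shuffle null is subtracted from
every torsion-pair I (plug-in MI is positively biased), the residue-pair
value is the maximum over the pair's torsion combinations, and the final
I is the block mean clamped at zero. Interpreting entropies in units of k
makes one nat equal one kT, which is the coupling threshold used by the
pathway search. Pairs farther apart than a Cα-Cα cutoff on the mean
structure are masked as ineligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from MDAnalysis.lib.distances import calc_dihedrals

from . import _tables
from .errors import InputError
from .structio import StructureModel, TrajectoryEnsemble
from .synthio import wrap_degrees

__all__ = [
    "TorsionSet",
    "MIMatrix",
    "extract_torsions",
    "entropy",
    "mi_pair",
    "mi_matrix",
]

DEFAULT_BINS = 24       # 15° angular bins
DEFAULT_BLOCKS = 5
DEFAULT_CUTOFF = 14.0   # Å, Cα-Cα eligibility cutoff
N_SHUFFLES = 5


@dataclass
class TorsionSet:
    """Per-residue torsion time series in degrees, wrapped to (−180, 180].

    ``torsions[(chain, resid)]`` maps torsion name ("phi", "psi", "chi1",
    "chi2") to a series; ``ca`` holds each residue's mean-structure Cα
    position for the distance filter. Residues with a broken backbone are
    recorded in ``excluded``.
    """

    torsions: dict[tuple[str, int], dict[str, np.ndarray]]
    ca: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    excluded: tuple[tuple[str, int], ...] = ()

    def residues(self) -> list[tuple[str, int]]:
        return list(self.torsions)


def _atom_index(model: StructureModel, chain: str, resid: int,
                name: str) -> int | None:
    idx = model.atoms_of_residue(chain, resid)
    hit = idx[model.names[idx] == name]
    return int(hit[0]) if len(hit) else None


def extract_torsions(traj: TrajectoryEnsemble) -> TorsionSet:
    """Backbone φ/ψ and side-chain χ1/χ2 series for every intact residue.

    Chain termini lack φ or ψ as appropriate; glycine has no χ; proline
    keeps only χ1. A residue missing any of N/CA/C is excluded and flagged.
    """
    model = traj.model
    keys = model.residue_keys()
    quads: list[tuple[tuple[str, int], str, tuple[int, int, int, int]]] = []
    excluded: list[tuple[str, int]] = []
    backbone: dict[tuple[str, int], dict[str, int | None]] = {}
    for key in keys:
        backbone[key] = {n: _atom_index(model, *key, n) for n in ("N", "CA", "C")}
    for pos, key in enumerate(keys):
        chain, resid = key
        bb = backbone[key]
        if any(v is None for v in bb.values()):
            excluded.append(key)
            continue
        prev_key = (chain, resid - 1)
        next_key = (chain, resid + 1)
        if prev_key in backbone and backbone[prev_key]["C"] is not None:
            quads.append((key, "phi",
                          (backbone[prev_key]["C"], bb["N"], bb["CA"], bb["C"])))
        if next_key in backbone and backbone[next_key]["N"] is not None:
            quads.append((key, "psi",
                          (bb["N"], bb["CA"], bb["C"], backbone[next_key]["N"])))
        resname = str(model.resnames[model.atoms_of_residue(chain, resid)[0]]).upper()
        chi_tables = [("chi1", _tables.CHI1_ATOMS), ("chi2", _tables.CHI2_ATOMS)]
        if resname == "PRO":
            chi_tables = [("chi1", _tables.CHI1_ATOMS)]
        for chi_name, table in chi_tables:
            if resname not in table:
                continue
            atoms = [_atom_index(model, chain, resid, n) for n in table[resname]]
            if any(a is None for a in atoms):
                continue    # missing side-chain atoms: that chi is absent
            quads.append((key, chi_name, tuple(atoms)))

    torsions: dict[tuple[str, int], dict[str, np.ndarray]] = {
        k: {} for k in keys if k not in excluded
    }
    if quads:
        ia = np.array([q[2][0] for q in quads])
        ib = np.array([q[2][1] for q in quads])
        ic = np.array([q[2][2] for q in quads])
        idd = np.array([q[2][3] for q in quads])
        series = np.empty((len(quads), traj.n_frames))
        for t in range(traj.n_frames):
            f = traj.coords[t]
            series[:, t] = calc_dihedrals(f[ia], f[ib], f[ic], f[idd])
        series = wrap_degrees(np.degrees(series))
        for (key, name, _), s in zip(quads, series):
            torsions[key][name] = s

    ca = {}
    for key in torsions:
        i = _atom_index(model, *key, "CA")
        if i is not None:
            ca[key] = traj.coords[:, i, :].mean(axis=0)
    return TorsionSet(torsions=torsions, ca=ca, excluded=tuple(excluded))


def _hist_entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log(p)))


def entropy(angles: np.ndarray, bins: int = DEFAULT_BINS) -> float:
    """Plug-in entropy in nats over equal-width bins spanning (−180, 180].

    A 1-D series gives the marginal entropy; a (2, n) array gives the
    joint entropy over a bins × bins grid.
    """
    if bins < 2:
        raise InputError("need at least 2 bins")
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise InputError("empty angle series")
    edges = np.linspace(-180.0, 180.0, bins + 1)
    if a.ndim == 1:
        counts, _ = np.histogram(np.clip(a, -180.0, 180.0), bins=edges)
        return _hist_entropy(counts)
    if a.ndim == 2 and a.shape[0] == 2:
        counts, _, _ = np.histogram2d(
            np.clip(a[0], -180.0, 180.0), np.clip(a[1], -180.0, 180.0),
            bins=[edges, edges],
        )
        return _hist_entropy(counts)
    raise InputError("angles must be 1-D or of shape (2, n)")


def _mi_plugin(a: np.ndarray, b: np.ndarray, bins: int) -> float:
    return entropy(a, bins) + entropy(b, bins) - entropy(np.stack([a, b]), bins)


def _null_mi(a: np.ndarray, b: np.ndarray, bins: int,
             n_shuffles: int = N_SHUFFLES) -> float:
    """Mean MI under deterministic circular shifts of one series."""
    n = len(a)
    shifts = [max(1, round((k + 1) * n / (n_shuffles + 1)))
              for k in range(n_shuffles)]
    return float(np.mean([_mi_plugin(a, np.roll(b, s), bins) for s in shifts]))


def mi_pair(
    res_a: dict[str, np.ndarray],
    res_b: dict[str, np.ndarray],
    blocks: int = DEFAULT_BLOCKS,
    bins: int = DEFAULT_BINS,
    aggregate: str = "max",
    correct: bool = True,
) -> float:
    """Block-mean, null-corrected residue-pair mutual information in nats.

    Within each block the shuffle null is subtracted from every
    torsion-torsion I; the residue-pair value per block aggregates those
    (``max`` by default, ``sum`` available); the result is the mean over
    blocks clamped at zero.
    """
    if not res_a or not res_b:
        raise InputError("residue without torsions: I is undefined")
    lengths = {len(s) for s in (*res_a.values(), *res_b.values())}
    if len(lengths) != 1:
        raise InputError("torsion series lengths differ")
    n = lengths.pop()
    block_len = n // blocks
    if block_len < 2:
        raise InputError(f"{n} frames cannot fill {blocks} blocks")
    agg = {"max": max, "sum": sum}.get(aggregate)
    if agg is None:
        raise InputError(f"unknown aggregation {aggregate!r}")
    block_vals = []
    for b in range(blocks):
        sl = slice(b * block_len, (b + 1) * block_len)
        vals = []
        for sa in res_a.values():
            for sb in res_b.values():
                i = _mi_plugin(sa[sl], sb[sl], bins)
                if correct:
                    i -= _null_mi(sa[sl], sb[sl], bins)
                vals.append(i)
        block_vals.append(agg(vals))
    return max(0.0, float(np.mean(block_vals)))


@dataclass
class MIMatrix:
    """Symmetric residue-pair MI with eligibility mask; diagonal = self-entropy."""

    residues: list[tuple[str, int]]
    mi: np.ndarray          # (n, n), NaN where ineligible
    eligible: np.ndarray    # (n, n) bool
    bins: int = DEFAULT_BINS

    def pair(self, a: tuple[str, int], b: tuple[str, int]) -> float:
        i, j = self.residues.index(a), self.residues.index(b)
        return float(self.mi[i, j])


def mi_matrix(
    torsions: TorsionSet,
    cutoff: float = DEFAULT_CUTOFF,
    blocks: int = DEFAULT_BLOCKS,
    bins: int = DEFAULT_BINS,
    aggregate: str = "max",
) -> MIMatrix:
    """Residue-pair MI for every pair within the Cα-Cα cutoff on the mean structure.

    The diagonal stores each residue's self-entropy (the aggregation over
    its marginal torsion entropies). Residues lacking torsions or a Cα are
    masked throughout.
    """
    keys = [k for k in torsions.residues() if torsions.torsions[k]]
    n = len(keys)
    mi = np.full((n, n), np.nan)
    eligible = np.zeros((n, n), dtype=bool)
    agg = max if aggregate == "max" else sum
    for i, k in enumerate(keys):
        mi[i, i] = agg(entropy(s, bins) for s in torsions.torsions[k].values())
    for i in range(n):
        for j in range(i + 1, n):
            ka, kb = keys[i], keys[j]
            if np.isfinite(cutoff):
                if ka not in torsions.ca or kb not in torsions.ca:
                    continue
                if np.linalg.norm(torsions.ca[ka] - torsions.ca[kb]) >= cutoff:
                    continue
            eligible[i, j] = eligible[j, i] = True
            val = mi_pair(torsions.torsions[ka], torsions.torsions[kb],
                          blocks=blocks, bins=bins, aggregate=aggregate)
            mi[i, j] = mi[j, i] = val
    return MIMatrix(residues=keys, mi=mi, eligible=eligible, bins=bins)
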