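"""Synthetic ensembles with known ground truth.

Three generators feed the downstream stages:

* :func:`make_breathing_ensemble` — a pseudo-protein built from stacked
  rings of atoms forming a channel along z whose bottleneck clearance
  fluctuates via a latent autoregressive "breathing" coordinate B(t), plus
  decorated single-atom residues whose displacement is coupled to B(t)
  with known coefficients c_n. Emulates the gorge of a channel enzyme
  without any pretence of real protein geometry.
* :func:`make_torsion_pairs` — pairs of torsion-angle series with known
  statistical coupling; the closed-form Gaussian mutual information
  −½·ln(1−ρ²) is attached per pair.
* :func:`make_radius_samples` — scalar draws from a stated normal
  distribution, for distribution-fit recovery tests.

All randomness flows from the seed carried in each spec; nothing touches
global random state.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import SpecError
from .structio import StructureModel, TrajectoryEnsemble, write_pdb

__all__ = [
    "BreathingSpec",
    "TorsionPairSpec",
    "make_breathing_ensemble",
    "make_torsion_pairs",
    "make_radius_samples",
    "write_ensemble",
]


@dataclass
class BreathingSpec:
    """Parameters of the breathing-pocket pseudo-protein.

    The pseudo-protein is a dead-end pocket, like an enzyme gorge: a solid
    floor of atoms, a wide cylindrical chamber above it, and a single
    constriction ring at the mouth whose radius breathes as
    base + amplitude·B(t). Every path from the pocket interior to bulk
    solvent must cross the constriction, so the analytic bottleneck
    clearance is base + amplitude·B(t) − ring_vdw (2.5 Å for the defaults
    with zero amplitude). ``flare`` sets the chamber radius as a multiple
    of the base radius; the chamber must stay wider than the fully open
    constriction. Couplings c_n ∈ [−1, 1] tie each decorated residue's
    displacement to the latent breathing coordinate.
    """

    n_rings: int = 9
    atoms_per_ring: int = 12
    base_radius: float = 4.0
    amplitude: float = 1.0
    n_residues: int = 10
    couplings: tuple[float, ...] | None = None
    n_frames: int = 200
    noise_sd: float = 0.0
    seed: int = 0
    ring_spacing: float = 1.5
    ring_vdw: float = 1.5
    flare: float = 1.4
    ar_coeff: float = 0.9

    def __post_init__(self) -> None:
        if self.amplitude >= self.base_radius:
            raise SpecError("amplitude must be smaller than the base radius "
                            "(the channel would close)")
        if self.n_frames < 2:
            raise SpecError("need at least 2 frames")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise SpecError("amplitude and noise sd must be non-negative")
        if self.n_rings < 3:
            raise SpecError("need at least 3 wall rings (chamber + mouth)")
        if self.base_radius + self.amplitude >= self.chamber_radius:
            raise SpecError(
                "fully open constriction would exceed the chamber radius; "
                "increase flare or reduce the amplitude"
            )
        if self.couplings is None:
            self.couplings = tuple(
                np.round(np.linspace(0.1, 1.0, self.n_residues), 6)
            )
        if len(self.couplings) != self.n_residues:
            raise SpecError("one coupling per decorated residue required")
        if np.any(np.abs(self.couplings) > 1):
            raise SpecError("|c_n| must be <= 1")

    @property
    def chamber_radius(self) -> float:
        return self.base_radius * self.flare

    @property
    def chamber_hint(self) -> np.ndarray:
        """A start-point hint at the chamber center, for the tunnel search."""
        return np.array([0.0, 0.0, self.ring_spacing * (self.n_rings // 2)])


@dataclass
class TorsionPairSpec:
    """Coupled torsion-angle pairs: bivariate Gaussian in angle space."""

    n_pairs: int = 1
    rho: tuple[float, ...] | float = 0.9
    angular_sd: float = 30.0     # degrees
    n_frames: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if np.isscalar(self.rho):
            self.rho = tuple([float(self.rho)] * self.n_pairs)
        if len(self.rho) != self.n_pairs:
            raise SpecError("one rho per pair required")
        if np.any(np.abs(self.rho) >= 1):
            raise SpecError("|rho| must be < 1")
        if self.n_frames < 2:
            raise SpecError("need at least 2 frames")
        if not 0 < self.angular_sd <= 30:
            raise SpecError("angular sd must be in (0, 30] degrees so the "
                            "wrapped Gaussian is effectively Gaussian")


def _latent_breathing(n: int, ar: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series clipped to [-1, 1]."""
    b = np.empty(n)
    b[0] = rng.normal(0.0, 1.0)
    innov = rng.normal(0.0, np.sqrt(1 - ar**2), size=n - 1)
    for t in range(1, n):
        b[t] = ar * b[t - 1] + innov[t - 1]
    return np.clip(b, -1.0, 1.0)


def make_breathing_ensemble(
    spec: BreathingSpec,
) -> tuple[TrajectoryEnsemble, np.ndarray, dict[tuple[str, int], float]]:
    """Build the breathing pocket; returns (trajectory, true R(t), true c_n).

    The mouth constriction ring radius at time t is
    base + amplitude·B(t) + noise, so the true bottleneck clearance is that
    minus the ring-atom vdW radius. Decorated residues sit well outside the
    pocket and translate along a fixed radial direction by
    c_n·amplitude·B(t) + noise.
    """
    rng = np.random.default_rng(spec.seed)
    nr, na = spec.n_rings, spec.atoms_per_ring
    # wall rings: chamber below, the breathing constriction as the top ring
    profile = np.full(nr, spec.chamber_radius)
    mouth = nr - 1
    profile[mouth] = spec.base_radius

    angles = 2 * np.pi * np.arange(na) / na
    zs = (1 + np.arange(nr)) * spec.ring_spacing

    # solid floor at z = 0: concentric rings tight enough to be impassable
    floor_pts = [np.zeros(3)]
    rho = 1.2
    while rho <= spec.chamber_radius + 0.6:
        n_k = max(6, int(np.ceil(2 * np.pi * rho / 1.2)))
        ang = 2 * np.pi * np.arange(n_k) / n_k
        floor_pts.extend(
            np.stack([rho * np.cos(ang), rho * np.sin(ang), np.zeros(n_k)], axis=1)
        )
        rho += 1.2
    floor = np.array(floor_pts)
    n_floor = len(floor)

    deco_r = spec.chamber_radius + 6.0
    deco_angles = 2 * np.pi * np.arange(spec.n_residues) / max(spec.n_residues, 1)
    deco_z = np.linspace(zs[0], zs[-1], spec.n_residues) if spec.n_residues else np.array([])
    deco_dirs = np.stack(
        [np.cos(deco_angles), np.sin(deco_angles), np.zeros_like(deco_angles)], axis=1
    ) if spec.n_residues else np.zeros((0, 3))
    deco_base = deco_dirs * deco_r
    if spec.n_residues:
        deco_base[:, 2] = deco_z

    n_ring_atoms = nr * na
    n_atoms = n_floor + n_ring_atoms + spec.n_residues
    names = np.array(["C"] * n_atoms, dtype=object)
    elements = np.array(["C"] * n_atoms, dtype=object)
    resids = np.concatenate([
        np.ones(n_floor),
        np.repeat(np.arange(2, nr + 2), na),
        np.arange(101, 101 + spec.n_residues),
    ]).astype(int)
    resnames = np.array(
        ["FLR"] * n_floor + ["RNG"] * n_ring_atoms + ["DEC"] * spec.n_residues,
        dtype=object,
    )
    chains = np.array(["A"] * n_atoms, dtype=object)
    masses = np.full(n_atoms, 12.011)
    vdw = np.full(n_atoms, spec.ring_vdw)

    b = _latent_breathing(spec.n_frames, spec.ar_coeff, rng)
    clearance_noise = rng.normal(0.0, spec.noise_sd, size=spec.n_frames) \
        if spec.noise_sd > 0 else np.zeros(spec.n_frames)
    deco_noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_frames, spec.n_residues)) \
        if spec.noise_sd > 0 else np.zeros((spec.n_frames, spec.n_residues))

    frames = np.empty((spec.n_frames, n_atoms, 3))
    for t in range(spec.n_frames):
        radii_t = profile + spec.amplitude * b[t] + clearance_noise[t]
        ring_xyz = np.empty((nr, na, 3))
        ring_xyz[..., 0] = radii_t[:, None] * np.cos(angles)[None, :]
        ring_xyz[..., 1] = radii_t[:, None] * np.sin(angles)[None, :]
        ring_xyz[..., 2] = zs[:, None]
        frames[t, :n_floor] = floor
        frames[t, n_floor:n_floor + n_ring_atoms] = ring_xyz.reshape(-1, 3)
        if spec.n_residues:
            disp = (np.asarray(spec.couplings) * spec.amplitude * b[t]
                    + deco_noise[t])
            frames[t, n_floor + n_ring_atoms:] = (
                deco_base + deco_dirs * disp[:, None]
            )

    model = StructureModel(
        names=names, elements=elements, resids=resids, resnames=resnames,
        chains=chains, coords=frames[0], masses=masses, vdw=vdw,
    )
    traj = TrajectoryEnsemble(model, frames, np.arange(spec.n_frames, dtype=float))
    true_r = spec.base_radius + spec.amplitude * b + clearance_noise - spec.ring_vdw
    c_map = {("A", 101 + i): float(c) for i, c in enumerate(spec.couplings)}
    traj.latent = b  # exposed for calibration tests
    return traj, true_r, c_map


def make_torsion_pairs(
    spec: TorsionPairSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated torsion pairs; returns (angles, true MI per pair).

    ``angles`` has shape (n_pairs, 2, n_frames) in degrees wrapped to
    (−180, 180]. True mutual information is the bivariate-Gaussian closed
    form −½·ln(1−ρ²) in nats; with the enforced sd bound the wrap has a
    negligible effect on it.
    """
    rng = np.random.default_rng(spec.seed)
    out = np.empty((spec.n_pairs, 2, spec.n_frames))
    true_mi = np.empty(spec.n_pairs)
    for k, rho in enumerate(spec.rho):
        cov = spec.angular_sd**2 * np.array([[1.0, rho], [rho, 1.0]])
        xy = rng.multivariate_normal([0.0, 0.0], cov, size=spec.n_frames)
        out[k] = wrap_degrees(xy.T)
        true_mi[k] = -0.5 * np.log1p(-rho**2)
    return out, true_mi


def wrap_degrees(a: np.ndarray) -> np.ndarray:
    """Wrap angles in degrees to (−180, 180]."""
    return -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)


def make_radius_samples(mean: float, sd: float, n: int, seed: int) -> np.ndarray:
    """n reproducible draws from Normal(mean, sd²); radii in Å."""
    if sd <= 0:
        raise SpecError("sd must be positive")
    if n < 10:
        raise SpecError("need at least 10 samples")
    return np.random.default_rng(seed).normal(mean, sd, size=n)


def write_ensemble(traj: TrajectoryEnsemble, true_r: np.ndarray,
                   c_map: dict[tuple[str, int], float], outdir: str) -> None:
    """Persist a breathing ensemble as multi-model PDB + ground-truth JSON."""
    os.makedirs(outdir, exist_ok=True)
    write_pdb(traj.model, os.path.join(outdir, "ensemble.pdb"), frames=traj.coords)
    truth = {
        "true_radius": [float(x) for x in true_r],
        "couplings": {f"{ch}:{ri}": c for (ch, ri), c in c_map.items()},
        "times_ns": [float(t) for t in traj.times_ns],
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
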