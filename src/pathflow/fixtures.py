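"""Synthetic multi-pose trajectories with known ground-truth motion.

Real inputs to the pipeline are MD snapshots or morph-server output; these
generators produce small multi-pose structures with analytically known motion
so every downstream stage can be checked against closed-form answers:

* a hinge motion — a stationary segment plus an arm that sweeps rigidly about
  a hinge axis (the classic lid-domain/clamshell conformational change);
* two ideal alpha helices completing a half-turn rotation about their own
  vertical axes, with a protruding pseudo-gamma carbon per residue so that
  side-chain (CA+CG) selections can be exercised;
* thermal jitter — independent Gaussian displacement of every atom in every
  pose, emulating Brownian wander around an equilibrium structure.

All generators emit valid PDB atom names and residues (GLY CA chains, LYS with
a pseudo-CG) so the default alpha-carbon selection behaves exactly as on real
data, and each call owns a fresh RNG stream fully determined by its seed.
"""

from __future__ import annotations

import numpy as np

from .pdb_io import AtomRecord, MultiPoseStructure

__all__ = [
    "generate_hinge_motion",
    "generate_helix_rotation",
    "generate_thermal_jitter",
]

#: ideal alpha-helix geometry: rise per residue (A), twist per residue (deg),
#: CA radius from the helix axis (A)
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
HELIX_CA_RADIUS = 2.3
#: pseudo-gamma carbon radius — protrudes beyond the CA ring
HELIX_CG_RADIUS = 4.6

_CA_SPACING = 3.8  # consecutive alpha-carbon distance in a trace, A


def _rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    k = np.asarray(axis, dtype=float)
    k = k / np.linalg.norm(k)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def _ca_record(i: int, xyz: np.ndarray, resname: str = "GLY",
               name: str = "CA", chain: str = "A") -> AtomRecord:
    return AtomRecord(
        serial=i + 1,
        name=name,
        resname=resname,
        chain=chain,
        resseq=i + 1,
        coords=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
        element="C",
    )


def generate_hinge_motion(
    n_fixed: int = 3,
    n_arm: int = 3,
    n_poses: int = 10,
    total_angle: float = 90.0,
    seed: int = 0,
) -> MultiPoseStructure:
    """Rigid hinge: a fixed segment and an arm rotating about a hinge axis.

    The fixed atoms lie along +x at alpha-carbon spacing and never move; the
    arm continues the chain and rotates rigidly about the z-axis through the
    last fixed atom, by ``total_angle * m / (n_poses - 1)`` degrees at pose m.
    An arm atom at distance d from the axis therefore traces an arc of
    analytic length d * total_angle (radians); with total_angle = 180 its
    end-to-end displacement is the chord 2d.

    ``seed`` is accepted for interface symmetry with the stochastic
    generators; the hinge itself is deterministic.
    """
    del seed
    if n_fixed < 1 or n_arm < 1:
        raise ValueError("atom counts must be >= 1")
    if n_poses < 2:
        raise ValueError("n_poses must be >= 2")
    n = n_fixed + n_arm
    base = np.zeros((n, 3))
    base[:, 0] = np.arange(n) * _CA_SPACING
    pivot = base[n_fixed - 1].copy()
    axis = np.array([0.0, 0.0, 1.0])
    poses = []
    for m in range(n_poses):
        angle = np.deg2rad(total_angle) * m / (n_poses - 1)
        R = _rotation_about_axis(axis, angle)
        coords = base.copy()
        coords[n_fixed:] = (base[n_fixed:] - pivot) @ R.T + pivot
        poses.append([_ca_record(i, coords[i]) for i in range(n)])
    return MultiPoseStructure(poses=poses, source_label="hinge-fixture")


def generate_helix_rotation(
    n_res: int = 6,
    n_poses: int = 10,
    seed: int = 0,
) -> MultiPoseStructure:
    """Two ideal helices each completing a half-turn about its own axis.

    Helix axes are vertical (z), 15 A apart along x.  Each residue carries a
    backbone CA at 2.3 A from the axis and a protruding pseudo-gamma carbon
    (named CG, residue LYS) at twice that radius, so selecting {"CA", "CG"}
    exercises the side-chain rendering path and every CG pathline is strictly
    longer than its CA pathline (arc length scales with radius).

    Across the poses the whole assembly rotates by 180 * m / (n_poses - 1)
    degrees, so the final pose equals the initial pose rotated 180 degrees
    about each helix axis.
    """
    del seed
    if n_res < 2:
        raise ValueError("n_res must be >= 2")
    if n_poses < 2:
        raise ValueError("n_poses must be >= 2")
    twist = np.deg2rad(HELIX_TWIST_DEG)
    helix_origins = [np.zeros(3), np.array([15.0, 0.0, 0.0])]
    base_atoms = []  # (helix, base xyz relative to its axis, name, resseq offset)
    for h, origin in enumerate(helix_origins):
        for i in range(n_res):
            phase = i * twist
            z = i * HELIX_RISE
            ca = np.array([HELIX_CA_RADIUS * np.cos(phase),
                           HELIX_CA_RADIUS * np.sin(phase), z])
            cg = np.array([HELIX_CG_RADIUS * np.cos(phase),
                           HELIX_CG_RADIUS * np.sin(phase), z])
            base_atoms.append((h, origin, ca, "CA", i))
            base_atoms.append((h, origin, cg, "CG", i))
    axis = np.array([0.0, 0.0, 1.0])
    chains = "AB"
    poses = []
    for m in range(n_poses):
        angle = np.pi * m / (n_poses - 1)
        R = _rotation_about_axis(axis, angle)
        pose = []
        for serial, (h, origin, rel, name, i) in enumerate(base_atoms):
            xyz = origin + R @ rel
            pose.append(
                AtomRecord(
                    serial=serial + 1,
                    name=name,
                    resname="LYS",
                    chain=chains[h],
                    resseq=i + 1,
                    coords=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
                    element="C",
                )
            )
        poses.append(pose)
    return MultiPoseStructure(poses=poses, source_label="helix-halfturn-fixture")


def generate_thermal_jitter(
    base: MultiPoseStructure,
    sigma: float,
    seed: int = 0,
) -> MultiPoseStructure:
    """Add independent zero-mean Gaussian displacement to every atom and pose.

    ``sigma`` is the per-axis standard deviation in Angstrom, so the expected
    per-atom RMS displacement is sigma * sqrt(3).  The same seed always yields
    the same structure; sigma = 0 returns an identical copy.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    poses = []
    for pose in base.poses:
        noisy = []
        for atom in pose:
            d = rng.normal(0.0, sigma, size=3) if sigma > 0 else np.zeros(3)
            noisy.append(
                AtomRecord(
                    serial=atom.serial,
                    name=atom.name,
                    resname=atom.resname,
                    chain=atom.chain,
                    resseq=atom.resseq,
                    coords=(atom.coords[0] + d[0], atom.coords[1] + d[1],
                            atom.coords[2] + d[2]),
                    icode=atom.icode,
                    element=atom.element,
                    hetero=atom.hetero,
                )
            )
        poses.append(noisy)
    return MultiPoseStructure(
        poses=poses, source_label=f"{base.source_label}+jitter"
    )
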