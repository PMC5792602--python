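"""Coarse-grained constant-velocity pulling of bead-per-residue models.

A structure-based (Go-type) force field is built on a Calpha bead model:
harmonic backbone bonds, 12-10 native-contact wells between residues
within a cutoff, short-range repulsion between all other pairs, optional
disulfide constraints, and an optional copper coordination sphere — an
explicit Cu bead tied to its five ligand residues by harmonic springs
with equal spring constants (equilibrium distances from the input
structure).  In the "no_axial" variant only the three equatorial bonds
(His46, Cys112, His117) are constrained.

Pulling mimics the constant-velocity protocol: one terminal bead is held
fixed, a dummy anchor moves at constant speed along the initial
end-to-end axis and drags the other terminal bead through a spring
(default 7 kcal/mol/A^2) whose elongation reports the force.  Dynamics
are Langevin (BAOAB splitting); with zero friction and thermostat the
integrator reduces to velocity Verlet and conserves energy.

Internal units: angstrom, kcal/mol, bead mass 1; the time unit is the
derived sqrt(m A^2 / kcal mol^-1).  Forces are reported in pN and
extensions in nm.  The pulling speed is deliberately far above the
0.0001 A/fs scale of all-atom work so that a full unravelling completes
in minutes on one core; the simulator targets the qualitative rupture
sequence, not quantitative force magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .constants import ANGSTROM_IN_NM, KCAL_PER_MOL_ANGSTROM_IN_PN
from .model import BeadModel, MetalSphere
from .trace import FXTrace

__all__ = [
    "PullingProtocol",
    "Trajectory",
    "build_model",
    "run_pull",
    "sweep_metal_k",
]

#: Boltzmann constant, kcal/mol/K.
KB_KCAL = 0.0019872

#: Force-field defaults (kcal/mol and angstrom).
BOND_K = 50.0
CONTACT_EPS = 5.0
CONTACT_CUTOFF = 8.0
REPULSION_SIGMA = 4.0
REPULSION_EPS = 1.0
METAL_K_GRID = (1.0, 5.0, 25.0, 100.0)


def build_model(
    structure: BeadModel,
    contact_cutoff: float = CONTACT_CUTOFF,
    metal_mode: str = "none",
    metal_k: float = 25.0,
    contact_eps: float = CONTACT_EPS,
    bond_k: float = BOND_K,
) -> BeadModel:
    """Attach a structure-based force field to a Calpha bead model.

    Contacts are Calpha pairs within ``contact_cutoff`` that are at
    least 3 residues apart; equilibrium distances are the native ones.
    ``metal_mode`` selects no copper sphere, the full 5-bond sphere, or
    the equatorial-only ("no_axial") variant; ``metal_k`` is the shared
    coordination spring constant in kcal/mol/A^2.
    """
    if metal_mode not in ("none", "full", "no_axial"):
        raise ValueError(f"metal_mode must be 'none', 'full' or 'no_axial', got {metal_mode!r}")
    coords = structure.coords
    n = len(coords)
    bonds = []
    for i in range(n - 1):
        r0 = float(np.linalg.norm(coords[i + 1] - coords[i]))
        bonds.append((i, i + 1, r0, bond_k))
    contacts = []
    for i in range(n):
        for j in range(i + 3, n):
            r0 = float(np.linalg.norm(coords[j] - coords[i]))
            if r0 <= contact_cutoff:
                contacts.append((i, j, r0, contact_eps))
    metal = None
    if metal_mode != "none":
        if structure.metal is None:
            raise ValueError(
                f"metal_mode={metal_mode!r} requires a structure with the 5 copper-ligand "
                "residues annotated (structure.metal is None)"
            )
        if metal_k <= 0:
            raise ValueError(f"metal spring constant must be > 0 kcal/mol/A^2, got {metal_k}")
        metal = replace(structure.metal.with_spring_constant(metal_k), mode=metal_mode)
    return BeadModel(
        coords=coords.copy(),
        residue_ids=structure.residue_ids.copy(),
        strand_annotations=dict(structure.strand_annotations),
        contacts=np.asarray(contacts, dtype=float).reshape(-1, 4),
        bonds=np.asarray(bonds, dtype=float).reshape(-1, 4),
        disulfides=list(structure.disulfides),
        metal=metal,
    )


@dataclass(frozen=True)
class PullingProtocol:
    """Constant-velocity pulling parameters (reduced units unless noted)."""

    velocity: float = 0.05  #: A per time unit
    dummy_k: float = 7.0  #: kcal/mol/A^2, pulling-spring stiffness
    fixed_terminus: str = "N"  #: "N" or "C"; the other terminus is pulled
    max_extension: float = 10.0  #: nm
    rupture_extension: float | None = None  #: nm; metal constraints removed here
    damping: float = 1.0  #: 1/time unit, Langevin friction
    temperature: float = 150.0  #: K; low enough that rupture order is sharp
    dt: float = 0.005  #: time units; set by stability sweep against BOND_K
    stride: int = 500  #: steps between recorded frames
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fixed_terminus not in ("N", "C"):
            raise ValueError(f"fixed_terminus must be 'N' or 'C', got {self.fixed_terminus!r}")
        if self.max_extension <= 0:
            raise ValueError(f"max_extension must be > 0 nm, got {self.max_extension}")
        if self.dummy_k <= 0 or self.dt <= 0 or self.stride < 1:
            raise ValueError("dummy_k, dt must be > 0 and stride >= 1")
        if self.damping < 0 or self.temperature < 0 or self.velocity < 0:
            raise ValueError("damping, temperature and velocity must be >= 0")

    @property
    def pulled_terminus(self) -> str:
        return "C" if self.fixed_terminus == "N" else "N"


@dataclass
class Trajectory:
    """Recorded frames of one pull (angstrom), with energies."""

    frames: np.ndarray  #: (n_frames, n_beads, 3) A
    extensions: np.ndarray  #: nm, end-to-end gain along the pulling axis
    forces: np.ndarray  #: pN, dummy-spring force
    times: np.ndarray  #: reduced time units
    potential: np.ndarray  #: kcal/mol
    kinetic: np.ndarray  #: kcal/mol
    has_copper: bool = False

    @property
    def total_energy(self) -> np.ndarray:
        return self.potential + self.kinetic

    @property
    def residue_frames(self) -> np.ndarray:
        """Frames without the copper bead (residue beads only)."""
        return self.frames[:, :-1] if self.has_copper else self.frames

    def write_xyz(self, path, stride: int = 1) -> None:
        """Write the frames as a multi-frame XYZ file (angstrom).

        Residue beads are written as pseudo-atoms ``CA``; the copper
        bead, if present, as ``CU``.
        """
        from pathlib import Path

        n = self.frames.shape[1]
        names = ["CA"] * (n - 1) + ["CU"] if self.has_copper else ["CA"] * n
        lines = []
        for k in range(0, self.frames.shape[0], stride):
            lines.append(str(n))
            lines.append(f"frame {k} extension_nm {self.extensions[k]:.4f}")
            for name, (x, y, z) in zip(names, self.frames[k]):
                lines.append(f"{name} {x:.4f} {y:.4f} {z:.4f}")
        Path(path).write_text("\n".join(lines) + "\n")


@njit(cache=True, fastmath=True)
def _eval_forces(
    x, f,
    bi, bj, br0, bk,
    ci, cj, cr0, ceps,
    ri, rj, sigma, eps_rep,
    mi, mj, mr0, mk, metal_on,
    fixed_idx, pulled_idx, axis, anchor, dummy_k,
):
    n = x.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    epot = 0.0
    for b in range(bi.shape[0]):
        i = bi[b]; j = bj[b]
        d0 = x[j, 0] - x[i, 0]; d1 = x[j, 1] - x[i, 1]; d2 = x[j, 2] - x[i, 2]
        r = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2) + 1e-12
        dr = r - br0[b]
        epot += bk[b] * dr * dr
        fmag = -2.0 * bk[b] * dr / r
        f[j, 0] += fmag * d0; f[j, 1] += fmag * d1; f[j, 2] += fmag * d2
        f[i, 0] -= fmag * d0; f[i, 1] -= fmag * d1; f[i, 2] -= fmag * d2
    for b in range(ci.shape[0]):
        i = ci[b]; j = cj[b]
        d0 = x[j, 0] - x[i, 0]; d1 = x[j, 1] - x[i, 1]; d2 = x[j, 2] - x[i, 2]
        r2 = d0 * d0 + d1 * d1 + d2 * d2 + 1e-12
        r = np.sqrt(r2)
        s = cr0[b] / r
        s2 = s * s
        s10 = s2 * s2 * s2 * s2 * s2
        s12 = s10 * s2
        epot += ceps[b] * (5.0 * s12 - 6.0 * s10)
        # dV/dr = 60 eps (s10 - s12) / r
        fmag = -ceps[b] * 60.0 * (s10 - s12) / r2
        f[j, 0] += fmag * d0; f[j, 1] += fmag * d1; f[j, 2] += fmag * d2
        f[i, 0] -= fmag * d0; f[i, 1] -= fmag * d1; f[i, 2] -= fmag * d2
    sig2 = sigma * sigma
    for b in range(ri.shape[0]):
        i = ri[b]; j = rj[b]
        d0 = x[j, 0] - x[i, 0]; d1 = x[j, 1] - x[i, 1]; d2 = x[j, 2] - x[i, 2]
        r2 = d0 * d0 + d1 * d1 + d2 * d2
        if r2 < sig2:
            r2 += 1e-12
            s2 = sig2 / r2
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            epot += eps_rep * (s12 - 1.0)
            fmag = eps_rep * 12.0 * s12 / r2
            f[j, 0] += fmag * d0; f[j, 1] += fmag * d1; f[j, 2] += fmag * d2
            f[i, 0] -= fmag * d0; f[i, 1] -= fmag * d1; f[i, 2] -= fmag * d2
    if metal_on:
        for b in range(mi.shape[0]):
            i = mi[b]; j = mj[b]
            d0 = x[j, 0] - x[i, 0]; d1 = x[j, 1] - x[i, 1]; d2 = x[j, 2] - x[i, 2]
            r = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2) + 1e-12
            dr = r - mr0[b]
            epot += mk[b] * dr * dr
            fmag = -2.0 * mk[b] * dr / r
            f[j, 0] += fmag * d0; f[j, 1] += fmag * d1; f[j, 2] += fmag * d2
            f[i, 0] -= fmag * d0; f[i, 1] -= fmag * d1; f[i, 2] -= fmag * d2
    # dummy spring along the pulling axis
    s = 0.0
    for c in range(3):
        s += (x[pulled_idx, c] - x[fixed_idx, c]) * axis[c]
    pull_force = dummy_k * (anchor - s)
    epot += 0.5 * dummy_k * (anchor - s) ** 2
    for c in range(3):
        f[pulled_idx, c] += pull_force * axis[c]
        f[fixed_idx, c] = 0.0
    return epot, pull_force, s


@njit(cache=True, fastmath=True)
def _integrate(
    x0,
    bi, bj, br0, bk,
    ci, cj, cr0, ceps,
    ri, rj, sigma, eps_rep,
    mi, mj, mr0, mk,
    fixed_idx, pulled_idx, axis, anchor0, dummy_k, velocity,
    dt, n_steps, stride, gamma, kT, seed, n_pad, rupture_ext_a,
):
    n = x0.shape[0]
    x = x0.copy()
    v = np.zeros((n, 3))
    f = np.zeros((n, 3))
    np.random.seed(seed)
    if kT > 0.0:
        for i in range(n):
            for c in range(3):
                v[i, c] = np.sqrt(kT) * np.random.standard_normal()
        for c in range(3):
            v[fixed_idx, c] = 0.0

    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1)) if gamma > 0.0 else 0.0

    n_frames = n_steps // stride + 2
    frames = np.zeros((n_frames, n, 3))
    exts = np.zeros(n_frames)
    forces = np.zeros(n_frames)
    times = np.zeros(n_frames)
    epots = np.zeros(n_frames)
    ekins = np.zeros(n_frames)

    metal_on = mi.shape[0] > 0
    s0 = 0.0
    for c in range(3):
        s0 += (x[pulled_idx, c] - x[fixed_idx, c]) * axis[c]

    epot, pf, s = _eval_forces(x, f, bi, bj, br0, bk, ci, cj, cr0, ceps,
                               ri, rj, sigma, eps_rep, mi, mj, mr0, mk, metal_on,
                               fixed_idx, pulled_idx, axis, anchor0, dummy_k)
    frame = 0
    ok = 1
    half_dt = 0.5 * dt
    pf_acc = 0.0
    pf_n = 0
    for step in range(n_steps + 1):
        pf_acc += pf
        pf_n += 1
        if step % stride == 0 or step == n_steps:
            ekin = 0.0
            for i in range(n):
                for c in range(3):
                    ekin += 0.5 * v[i, c] * v[i, c]
            frames[frame] = x
            exts[frame] = s - s0
            # stride-averaged force: the instantaneous dummy-spring
            # reading carries large thermal fluctuations
            forces[frame] = pf_acc / pf_n
            times[frame] = step * dt
            epots[frame] = epot
            ekins[frame] = ekin
            pf_acc = 0.0
            pf_n = 0
            frame += 1
        # controlled rupture: delete every active metal constraint at the
        # first step whose extension exceeds the prescribed value
        if metal_on and rupture_ext_a >= 0.0 and (s - s0) >= rupture_ext_a:
            metal_on = False
        anchor = anchor0 + velocity * (step + 1) * dt
        # BAOAB: B half-kick, A half-drift, O thermostat, A half-drift, B half-kick
        for i in range(n):
            for c in range(3):
                v[i, c] += half_dt * f[i, c]
                x[i, c] += half_dt * v[i, c]
        if gamma > 0.0:
            # the noise block always spans n_pad rows so that models with
            # and without the copper bead share the per-residue stream
            for i in range(n_pad):
                if i < n and i != fixed_idx:
                    for c in range(3):
                        v[i, c] = c1 * v[i, c] + c2 * np.random.standard_normal()
                else:
                    for c in range(3):
                        np.random.standard_normal()
        for i in range(n):
            for c in range(3):
                x[i, c] += half_dt * v[i, c]
        for c in range(3):
            x[fixed_idx, c] = x0[fixed_idx, c]
            v[fixed_idx, c] = 0.0
        epot, pf, s = _eval_forces(x, f, bi, bj, br0, bk, ci, cj, cr0, ceps,
                                   ri, rj, sigma, eps_rep, mi, mj, mr0, mk, metal_on,
                                   fixed_idx, pulled_idx, axis, anchor, dummy_k)
        for i in range(n):
            for c in range(3):
                v[i, c] += half_dt * f[i, c]
        for c in range(3):
            v[fixed_idx, c] = 0.0
        if not np.isfinite(x[pulled_idx, 0] + epot):
            ok = 0
            break
    return frames[:frame], exts[:frame], forces[:frame], times[:frame], epots[:frame], ekins[:frame], ok


def _repulsion_pairs(n_res: int, bonds: np.ndarray, contacts: np.ndarray) -> np.ndarray:
    """All residue pairs with |i-j| >= 2 that are neither bonded nor in contact."""
    excluded = {(int(r[0]), int(r[1])) for r in bonds} | {(int(r[0]), int(r[1])) for r in contacts}
    pairs = [
        (i, j)
        for i in range(n_res)
        for j in range(i + 2, n_res)
        if (i, j) not in excluded
    ]
    return np.asarray(pairs, dtype=float).reshape(-1, 2)


def run_pull(model: BeadModel, protocol: PullingProtocol) -> tuple[Trajectory, FXTrace]:
    """Run one constant-velocity pull and return the trajectory and FX trace.

    The protocol's seed fixes the thermal noise; identical model,
    protocol and seed give identical trajectories.  Raises on integrator
    blow-up with a hint to reduce the timestep.
    """
    if model.bonds.shape[0] == 0:
        raise ValueError("model has no force field; call build_model first")
    n_res = model.n_residues
    coords = model.coords
    metal_pairs = np.zeros((0, 2))
    metal_r0 = np.zeros(0)
    metal_k = np.zeros(0)
    if model.metal is not None:
        coords = np.vstack([coords, model.metal.cu_position[None, :]])
        cu = n_res
        active = model.metal.active_bonds
        metal_pairs = np.asarray([[b.residue_index, cu] for b in active], dtype=float)
        metal_r0 = np.asarray([b.r0 for b in active], dtype=float)
        metal_k = np.asarray([b.k if b.k is not None else 25.0 for b in active], dtype=float)

    fixed_idx = 0 if protocol.fixed_terminus == "N" else n_res - 1
    pulled_idx = n_res - 1 if protocol.fixed_terminus == "N" else 0
    axis = coords[pulled_idx] - coords[fixed_idx]
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ValueError("termini coincide; cannot define a pulling axis")
    axis = axis / norm
    anchor0 = float(np.dot(coords[pulled_idx] - coords[fixed_idx], axis))

    max_ext_a = protocol.max_extension / ANGSTROM_IN_NM
    n_steps = int(np.ceil(max_ext_a / (protocol.velocity * protocol.dt))) if protocol.velocity > 0 else 0
    if protocol.velocity == 0:
        n_steps = int(1e5)
    rupture_a = -1.0 if protocol.rupture_extension is None else protocol.rupture_extension / ANGSTROM_IN_NM

    rep = _repulsion_pairs(n_res, model.bonds, model.contacts)
    dis = np.asarray(
        [[i, j, float(np.linalg.norm(model.coords[i] - model.coords[j])), BOND_K]
         for i, j in model.disulfides],
        dtype=float,
    ).reshape(-1, 4)
    bonds = np.vstack([model.bonds, dis]) if dis.size else model.bonds

    def _diverged() -> FloatingPointError:
        return FloatingPointError(
            "integrator diverged (non-finite coordinates); reduce PullingProtocol.dt "
            f"(currently {protocol.dt}) or the pulling velocity"
        )

    kT = KB_KCAL * protocol.temperature
    contacts = model.contacts
    try:
        out = _integrate(
            coords.astype(float),
            bonds[:, 0].astype(np.int64), bonds[:, 1].astype(np.int64),
            bonds[:, 2].astype(float), bonds[:, 3].astype(float),
            contacts[:, 0].astype(np.int64), contacts[:, 1].astype(np.int64),
            contacts[:, 2].astype(float), contacts[:, 3].astype(float),
            rep[:, 0].astype(np.int64), rep[:, 1].astype(np.int64),
            REPULSION_SIGMA, REPULSION_EPS,
            metal_pairs[:, 0].astype(np.int64) if metal_pairs.size else np.zeros(0, dtype=np.int64),
            metal_pairs[:, 1].astype(np.int64) if metal_pairs.size else np.zeros(0, dtype=np.int64),
            metal_r0, metal_k,
            fixed_idx, pulled_idx, axis.astype(float), anchor0,
            protocol.dummy_k, protocol.velocity,
            protocol.dt, n_steps, protocol.stride,
            protocol.damping, kT, protocol.seed % (2**31), n_res + 1, rupture_a,
        )
    except ZeroDivisionError:
        # overflowing coordinates surface as a zero denominator inside
        # the jitted kernel before the non-finite guard can trip
        raise _diverged() from None
    frames, exts, forces, times, epots, ekins, ok = out
    if not ok:
        raise _diverged()
    traj = Trajectory(
        frames=frames,
        extensions=exts * ANGSTROM_IN_NM,
        forces=forces * KCAL_PER_MOL_ANGSTROM_IN_PN,
        times=times,
        potential=epots,
        kinetic=ekins,
        has_copper=model.metal is not None,
    )
    fx = FXTrace(
        extension=np.clip(traj.extensions, 0.0, None),
        force=traj.forces,
        metadata={
            "source": "cg_pulling",
            "velocity_a_per_tau": protocol.velocity,
            "metal_mode": model.metal.mode if model.metal is not None else "none",
            "seed": protocol.seed,
        },
    )
    return traj, fx


def sweep_metal_k(
    structure: BeadModel,
    protocol: PullingProtocol,
    k_values,
    metal_mode: str = "full",
    contact_cutoff: float = CONTACT_CUTOFF,
) -> dict[float, FXTrace]:
    """One pull per coordination spring constant, sharing the seed."""
    k_values = list(k_values)
    if not k_values:
        raise ValueError("k_values must be non-empty")
    out = {}
    for k in k_values:
        model = build_model(structure, contact_cutoff=contact_cutoff,
                            metal_mode=metal_mode, metal_k=float(k))
        _, fx = run_pull(model, protocol)
        out[float(k)] = fx
    return out
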