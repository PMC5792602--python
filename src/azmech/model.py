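"""Bead-per-residue structural models and PDB I/O.

A :class:`BeadModel` is a Calpha-resolution representation of a protein:
coordinates in angstrom, named beta-strand residue ranges, and — once a
force field has been built on top of it — backbone bonds, native
contacts, disulfide constraints and an optional copper coordination
sphere (:class:`MetalSphere`).

The copper site follows the type-I centre of azurin: a central Cu with
three equatorial ligands (His46:N, Cys112:S, His117:N) and two weaker
axial ligands (Gly45:O, Met121:S).  At one-bead resolution each ligand
atom is represented by its residue's Calpha bead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "EQUATORIAL_LIGANDS",
    "AXIAL_LIGANDS",
    "LIGAND_LABELS",
    "MetalBond",
    "MetalSphere",
    "BeadModel",
    "write_pdb",
    "read_pdb",
]

#: Canonical ligand-atom labels of the type-I copper centre.
EQUATORIAL_LIGANDS = ("His46:N", "Cys112:S", "His117:N")
AXIAL_LIGANDS = ("Gly45:O", "Met121:S")
LIGAND_LABELS = EQUATORIAL_LIGANDS + AXIAL_LIGANDS


@dataclass(frozen=True)
class MetalBond:
    """One harmonic copper-ligand coordination bond."""

    residue_index: int  #: bead index of the ligand residue
    label: str  #: ligand atom label, e.g. "Cys112:S"
    r0: float  #: angstrom, equilibrium Cu-ligand distance
    k: float | None = None  #: kcal/mol/A^2 spring constant
    axial: bool = False


@dataclass(frozen=True)
class MetalSphere:
    """Five-ligand harmonic model of the copper coordination sphere."""

    cu_position: np.ndarray  #: (3,) angstrom
    bonds: tuple[MetalBond, ...]
    mode: str = "full"  #: "full" or "no_axial"

    def __post_init__(self) -> None:
        if len(self.bonds) != 5:
            raise ValueError(f"a copper sphere has exactly 5 ligand bonds, got {len(self.bonds)}")
        labels = {b.label for b in self.bonds}
        if labels != set(LIGAND_LABELS):
            raise ValueError(f"ligand labels must be {set(LIGAND_LABELS)}, got {labels}")
        axial = {b.label for b in self.bonds if b.axial}
        if axial != set(AXIAL_LIGANDS):
            raise ValueError(f"axial ligand set must be {set(AXIAL_LIGANDS)}, got {axial}")
        if self.mode not in ("full", "no_axial"):
            raise ValueError(f"mode must be 'full' or 'no_axial', got {self.mode!r}")
        object.__setattr__(self, "cu_position", np.asarray(self.cu_position, dtype=float))

    @property
    def active_bonds(self) -> tuple[MetalBond, ...]:
        """Bonds carrying a harmonic constraint under the current mode."""
        if self.mode == "no_axial":
            return tuple(b for b in self.bonds if not b.axial)
        return self.bonds

    def with_spring_constant(self, k: float) -> "MetalSphere":
        if k <= 0:
            raise ValueError(f"metal spring constant must be > 0 kcal/mol/A^2, got {k}")
        return replace(self, bonds=tuple(replace(b, k=k) for b in self.bonds))


@dataclass
class BeadModel:
    """Calpha-resolution structure plus (optional) structure-based force field.

    ``contacts`` rows are ``(i, j, r0_A, epsilon_kcal)``; ``bonds`` rows are
    ``(i, j, r0_A, k_kcal_A2)``.  Both are empty until a force field is
    built (see :func:`azmech.pulling.build_model`).
    """

    coords: np.ndarray  #: (N, 3) angstrom, residue beads only
    residue_ids: np.ndarray = None  # type: ignore[assignment]
    strand_annotations: dict[str, tuple[int, int]] = field(default_factory=dict)
    contacts: np.ndarray = None  # type: ignore[assignment]
    bonds: np.ndarray = None  # type: ignore[assignment]
    disulfides: list[tuple[int, int]] = field(default_factory=list)
    metal: MetalSphere | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {self.coords.shape}")
        if self.residue_ids is None:
            self.residue_ids = np.arange(1, len(self.coords) + 1)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if self.contacts is None:
            self.contacts = np.empty((0, 4))
        if self.bonds is None:
            self.bonds = np.empty((0, 4))
        for name, (lo, hi) in self.strand_annotations.items():
            if not (0 <= lo <= hi < len(self.coords)):
                raise ValueError(f"strand {name!r} range ({lo}, {hi}) outside 0..{len(self.coords) - 1}")

    @property
    def n_residues(self) -> int:
        return len(self.coords)

    def strand_indices(self, name: str) -> np.ndarray:
        """Bead indices of a named strand."""
        if name not in self.strand_annotations:
            raise KeyError(f"unknown strand {name!r}; known: {sorted(self.strand_annotations)}")
        lo, hi = self.strand_annotations[name]
        return np.arange(lo, hi + 1)


def write_pdb(model: BeadModel, path: str | Path) -> None:
    """Write the beads as Calpha-only ATOM records, one chain; Cu as HETATM."""
    lines = []
    serial = 0
    for i, (x, y, z) in enumerate(model.coords):
        serial += 1
        resid = int(model.residue_ids[i])
        lines.append(
            f"ATOM  {serial:5d}  CA  GLY A{resid:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    if model.metal is not None:
        serial += 1
        x, y, z = model.metal.cu_position
        lines.append(
            f"HETATM{serial:5d} CU    CU A{len(model.coords) + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          CU"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path: str | Path) -> BeadModel:
    """Read Calpha coordinates (first chain, first model) from a PDB file.

    Strand annotations and any metal-site definition are not recoverable
    from bare ATOM records; they must be supplied separately.
    """
    import gemmi

    structure = gemmi.read_pdb(str(path))
    structure.setup_entities()
    chain = structure[0][0]
    coords, resids = [], []
    for residue in chain:
        for atom in residue:
            if atom.name == "CA":
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                resids.append(residue.seqid.num)
                break
    if not coords:
        raise ValueError(f"no CA atoms found in {path}")
    return BeadModel(coords=np.asarray(coords), residue_ids=np.asarray(resids))
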