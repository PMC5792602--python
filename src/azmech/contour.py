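"""Structure-based contour-length accounting.

The expected total contour-length gain when a folded domain unravels is

    dLc = (n_residues - sequestered) * l_aa - d_fold

where ``l_aa`` is the per-residue contour (0.36 nm/aa), ``sequestered``
counts residues locked away from the stretchable chain (e.g. behind the
Cys3-Cys26 disulfide, which sequesters 23 residues), and ``d_fold`` is
the folded end-to-end distance between the pulled residues.  For azurin:
(128 - 23) aa x 0.36 nm/aa - 1.4 nm = 36.4 nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import ANGSTROM_IN_NM
from .model import BeadModel

__all__ = [
    "PER_RESIDUE_CONTOUR_NM",
    "ChainAccounting",
    "expected_total_delta_lc",
    "disulfide_sequestered",
    "folded_end_to_end",
    "metal_sequestration_shift",
]

#: Contour length per amino acid, nm.
PER_RESIDUE_CONTOUR_NM = 0.36


@dataclass(frozen=True)
class ChainAccounting:
    """Bookkeeping for one domain's stretchable polypeptide."""

    n_residues: int
    per_residue: float = PER_RESIDUE_CONTOUR_NM  #: nm/aa
    folded_end_to_end: float = 0.0  #: nm
    sequestered: int = 0  #: residues removed from the stretchable chain

    def __post_init__(self) -> None:
        if self.n_residues <= 0:
            raise ValueError(f"n_residues must be > 0, got {self.n_residues}")
        if self.per_residue <= 0:
            raise ValueError(f"per_residue must be > 0 nm/aa, got {self.per_residue}")
        if not 0 <= self.sequestered < self.n_residues:
            raise ValueError(
                f"sequestered must lie in [0, n_residues), got {self.sequestered} "
                f"with n_residues={self.n_residues}"
            )
        if self.folded_end_to_end < 0:
            raise ValueError(f"folded_end_to_end must be >= 0 nm, got {self.folded_end_to_end}")


def expected_total_delta_lc(acc: ChainAccounting) -> float:
    """Expected total contour gain (nm) for complete unravelling."""
    dlc = (acc.n_residues - acc.sequestered) * acc.per_residue - acc.folded_end_to_end
    if dlc < 0:
        raise ValueError(
            f"folded end-to-end length ({acc.folded_end_to_end} nm) exceeds the stretchable "
            f"contour ({(acc.n_residues - acc.sequestered) * acc.per_residue:.2f} nm)"
        )
    return dlc


def disulfide_sequestered(res_i: int, res_j: int) -> int:
    """Residues sequestered by a disulfide bond, as the index difference.

    Follows the plain-difference convention (Cys3-Cys26 -> 23 residues);
    order-invariant.
    """
    return abs(int(res_j) - int(res_i))


def folded_end_to_end(structure: BeadModel, res_a: int, res_b: int) -> float:
    """Calpha-Calpha distance (nm) between two residues of a folded structure.

    ``res_a``/``res_b`` are residue ids as carried by the model.
    """
    ids = list(structure.residue_ids)
    try:
        ia, ib = ids.index(res_a), ids.index(res_b)
    except ValueError as err:
        raise KeyError(f"residue id not in structure: {err}") from None
    return float(np.linalg.norm(structure.coords[ia] - structure.coords[ib])) * ANGSTROM_IN_NM


def metal_sequestration_shift(
    apo_series: np.ndarray,
    constrained_series: np.ndarray,
    tail_fraction: float = 0.1,
) -> float:
    """Contour shortening attributable to the metal coordination sphere (nm).

    Compares the anchor-pair separation of an unconstrained (apo) pull
    with the metal-constrained one along a common extension series and
    returns the difference of their final plateaus (median over the last
    ``tail_fraction`` of points).  Positive values mean the constraint
    curtails chain release.
    """
    apo = np.asarray(apo_series, dtype=float)
    con = np.asarray(constrained_series, dtype=float)
    if apo.shape != con.shape:
        raise ValueError(f"series must have equal length, got {apo.shape} vs {con.shape}")
    if apo.size == 0:
        raise ValueError("series must be non-empty")
    k = max(1, int(round(apo.size * tail_fraction)))
    return float(np.median(apo[-k:]) - np.median(con[-k:]))
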