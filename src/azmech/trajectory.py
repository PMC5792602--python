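"""Unfolding order from pulling trajectories.

Strand-pair separation is tracked through the geometric centres (GCs) of
the beta-strands — unweighted means of their Calpha positions — as a
function of molecular extension.  A strand pair is considered ruptured
once its GC-GC distance has grown by more than a threshold over its
native value; the extension at which that happens orders the rupture
events along the unfolding pathway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import ANGSTROM_IN_NM
from .model import BeadModel
from .trace import FXTrace
from .wlc import detect_peaks

__all__ = [
    "StrandPair",
    "GCDistanceSeries",
    "strand_gc",
    "gc_distance_change",
    "rupture_order",
    "residue_pair_distance",
    "curtailment_extension",
    "fx_peaks",
]

#: Default GC-GC distance change (nm) above which a strand pair counts as
#: ruptured; separates the ~1.5 nm excursions of broken pairs from the
#: <1.0 nm breathing of intact ones.
RUPTURE_THRESHOLD_NM = 0.5


@dataclass(frozen=True)
class StrandPair:
    """A named pair of beta-strands, e.g. b4-b7."""

    name: str
    strand_a: tuple[int, int]  #: inclusive residue-index range
    strand_b: tuple[int, int]

    def __post_init__(self) -> None:
        a, b = sorted([self.strand_a, self.strand_b])
        if a[1] >= b[0]:
            raise ValueError(f"strand ranges of pair {self.name!r} overlap: {self.strand_a}, {self.strand_b}")


def pairs_from_model(model: BeadModel, names: list[tuple[str, str]]) -> list[StrandPair]:
    """Build StrandPairs from a model's strand annotations.

    ``names`` holds (strand_a, strand_b) annotation names, e.g.
    ``[("b4", "b7"), ("b1", "b3")]``.
    """
    out = []
    for a, b in names:
        ra = model.strand_annotations.get(a)
        rb = model.strand_annotations.get(b)
        if ra is None or rb is None:
            missing = a if ra is None else b
            raise KeyError(f"unknown strand {missing!r}; known: {sorted(model.strand_annotations)}")
        out.append(StrandPair(name=f"{a}-{b}", strand_a=ra, strand_b=rb))
    return out


@dataclass
class GCDistanceSeries:
    """Per-pair GC-GC distance change (nm) vs molecular extension (nm)."""

    extension: np.ndarray
    distance_change: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.extension = np.asarray(self.extension, dtype=float)
        for name, series in self.distance_change.items():
            series = np.asarray(series, dtype=float)
            if series.shape != self.extension.shape:
                raise ValueError(f"series {name!r} length mismatch")
            self.distance_change[name] = series


def strand_gc(frame: np.ndarray, strand: tuple[int, int]) -> np.ndarray:
    """Geometric centre of a strand: unweighted mean of its Calpha positions.

    ``frame`` is an (N, 3) coordinate array (angstrom); ``strand`` is an
    inclusive residue-index range.
    """
    frame = np.asarray(frame, dtype=float)
    lo, hi = strand
    if not (0 <= lo <= hi < frame.shape[0]):
        raise IndexError(f"strand range ({lo}, {hi}) outside 0..{frame.shape[0] - 1}")
    return frame[lo:hi + 1].mean(axis=0)


def gc_distance_change(
    frames: np.ndarray,
    extensions: np.ndarray,
    pairs: list[StrandPair],
) -> GCDistanceSeries:
    """GC-GC distance change per strand pair, relative to the first frame.

    ``frames`` is (n_frames, N, 3) in angstrom; ``extensions`` (nm) index
    the frames.  Distances are reported in nm; the first frame defines
    the zero of each series.
    """
    frames = np.asarray(frames, dtype=float)
    extensions = np.asarray(extensions, dtype=float)
    if frames.ndim != 3 or frames.shape[0] != extensions.size:
        raise ValueError("frames must be (n_frames, N, 3) matching extensions")
    if not pairs:
        raise ValueError("need at least one strand pair")
    change: dict[str, np.ndarray] = {}
    for pair in pairs:
        ga = frames[:, pair.strand_a[0]:pair.strand_a[1] + 1].mean(axis=1)
        gb = frames[:, pair.strand_b[0]:pair.strand_b[1] + 1].mean(axis=1)
        d = np.linalg.norm(ga - gb, axis=1) * ANGSTROM_IN_NM
        change[pair.name] = d - d[0]
    return GCDistanceSeries(extension=extensions, distance_change=change)


def rupture_order(
    series: GCDistanceSeries, threshold: float = RUPTURE_THRESHOLD_NM
) -> tuple[list[tuple[str, float]], list[str]]:
    """Order strand pairs by the extension at which they rupture.

    Returns ``(ruptured, intact)``: ruptured pairs as (name, extension at
    first threshold crossing) sorted by extension (ties broken by name),
    and the names of pairs that never cross the threshold.
    """
    ruptured: list[tuple[str, float]] = []
    intact: list[str] = []
    for name in sorted(series.distance_change):
        above = np.nonzero(series.distance_change[name] > threshold)[0]
        if above.size:
            ruptured.append((name, float(series.extension[above[0]])))
        else:
            intact.append(name)
    ruptured.sort(key=lambda item: (item[1], item[0]))
    return ruptured, intact


def residue_pair_distance(
    frames: np.ndarray, pairs: dict[str, tuple[int, int]]
) -> dict[str, np.ndarray]:
    """Per-frame Calpha-Calpha distances (nm) for named residue pairs."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be (n_frames, N, 3)")
    out = {}
    for name, (i, j) in pairs.items():
        out[name] = np.linalg.norm(frames[:, i] - frames[:, j], axis=1) * ANGSTROM_IN_NM
    return out


def curtailment_extension(
    fx: FXTrace,
    f_ref: float = 2000.0,
    smooth_window: int = 31,
) -> float:
    """Extension (nm) at which the pull runs into its final resistance.

    Reports the first extension where the median-smoothed force exceeds
    ``f_ref``; if it never does, the largest extension reached.  On a
    metal-constrained pull this is the position of the coordination-
    sphere wall — the fixture-level analogue of the second transition
    state peak, whose position shifts to shorter extensions when the
    copper sequesters chain (and shifts further the stiffer and more
    complete the coordination sphere).  ``f_ref`` should sit well above
    any force the unconstrained construct reaches before full extension.
    """
    from scipy.signal import medfilt

    if len(fx) == 0:
        raise ValueError("empty force-extension trace")
    win = smooth_window if smooth_window % 2 == 1 else smooth_window + 1
    sm = medfilt(fx.force, min(win, len(fx) - (1 - len(fx) % 2)))
    above = np.nonzero(sm >= f_ref)[0]
    if above.size:
        return float(fx.extension[above[0]])
    return float(fx.extension.max())


def fx_peaks(
    fx: FXTrace,
    smooth_window: int = 21,
    min_force: float = 50.0,
    min_drop: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Peak extensions and successive inter-peak separations of a simulated trace.

    Simulated force curves carry thermal noise but no instrument
    signature, so peaks are detected from the smoothed force alone
    (no extension-jump validation).  Returns (peak extensions nm,
    separations nm).
    """
    peaks = detect_peaks(fx, min_force=min_force, min_drop=min_drop,
                         smooth_window=smooth_window, min_ext_jump=0.0)
    ext = fx.extension[peaks]
    return ext, np.diff(ext)
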