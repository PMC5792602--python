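"""Force-extension trace container and plain-text I/O.

An :class:`FXTrace` is a sampled force-versus-extension curve from a
constant-velocity pulling experiment (or simulation), in nm / pN.
Synthetic traces additionally carry ground-truth rupture records so that
downstream analysis can be validated against the generating process.

Traces are stored on disk as two-column text tables
(``extension_nm  force_pN``) with ``#``-prefixed metadata header lines of
the form ``# key = value``; one trace per file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "GeneratorConfig",
    "RuptureRecord",
    "FXTrace",
    "write_trace",
    "read_trace",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions for synthetic polyprotein pulling.

    Defaults mirror a typical AFM polyprotein experiment: a heptamer
    pulled at 400 nm/s with a ~40 pN/nm cantilever sampled at 5 kHz.
    """

    n_domains: int = 7
    pulling_speed: float = 400.0  #: nm/s
    cantilever_k: float = 40.0  #: pN/nm
    sampling_rate: float = 5000.0  #: Hz
    noise_sd: float = 5.0  #: pN, Gaussian force noise
    temperature: float = 298.0  #: K
    persistence_length: float = 0.4  #: nm
    initial_contour: float = 20.0  #: nm, handles plus folded polyprotein
    domain_disorder_sd: float = 9.0  #: pN, static per-domain strength offset
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "pulling_speed",
            "cantilever_k",
            "sampling_rate",
            "temperature",
            "persistence_length",
            "initial_contour",
        ):
            value = getattr(self, name)
            if value <= 0:
                raise ValueError(f"GeneratorConfig.{name} must be > 0, got {value}")
        if self.n_domains < 1:
            raise ValueError(f"GeneratorConfig.n_domains must be >= 1, got {self.n_domains}")
        if self.noise_sd < 0:
            raise ValueError(f"GeneratorConfig.noise_sd must be >= 0, got {self.noise_sd}")
        if self.domain_disorder_sd < 0:
            raise ValueError(
                f"GeneratorConfig.domain_disorder_sd must be >= 0, got {self.domain_disorder_sd}"
            )


@dataclass(frozen=True)
class RuptureRecord:
    """One ground-truth rupture event in a synthetic trace.

    ``domain`` is -1 for the final tip-detachment event, which releases
    no further contour.
    """

    domain: int
    state_index: int
    n_states: int
    force: float  #: pN at rupture (noise-free)
    extension: float  #: nm molecular extension at rupture
    lc_before: float  #: nm total contour length before the rupture
    delta_lc: float  #: nm contour released by the rupture


@dataclass
class FXTrace:
    """A force-versus-extension curve plus metadata and optional truth."""

    extension: np.ndarray  #: nm, monotone non-decreasing
    force: np.ndarray  #: pN
    metadata: dict = field(default_factory=dict)
    truth: list[RuptureRecord] | None = None

    def __post_init__(self) -> None:
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.extension.shape != self.force.shape:
            raise ValueError(
                f"extension and force must have equal length, got "
                f"{self.extension.shape} vs {self.force.shape}"
            )
        if self.extension.size and self.extension[0] < 0:
            raise ValueError("extension must start at >= 0 nm")

    def __len__(self) -> int:
        return self.extension.size

    @property
    def pathway_labels(self) -> list[int] | None:
        """Per-domain number of states from the truth records, if present."""
        if self.truth is None:
            return None
        by_domain: dict[int, int] = {}
        for rec in self.truth:
            if rec.domain >= 0:
                by_domain[rec.domain] = rec.n_states
        return [by_domain[d] for d in sorted(by_domain)]


def write_trace(trace: FXTrace, path: str | Path) -> None:
    """Write one trace as a two-column text table with '#' metadata header."""
    path = Path(path)
    lines = [f"# {key} = {value}" for key, value in sorted(trace.metadata.items())]
    lines.append("# columns = extension_nm force_pN")
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, np.column_stack([trace.extension, trace.force]), fmt="%.6g")


def _parse_value(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def read_trace(path: str | Path) -> FXTrace:
    """Read a trace written by :func:`write_trace`."""
    path = Path(path)
    metadata: dict = {}
    rows: list[tuple[float, float]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                if key.strip() != "columns":
                    metadata[key.strip()] = _parse_value(value.strip())
            continue
        x, f = line.split()[:2]
        rows.append((float(x), float(f)))
    arr = np.asarray(rows, dtype=float).reshape(-1, 2)
    return FXTrace(extension=arr[:, 0], force=arr[:, 1], metadata=metadata)
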