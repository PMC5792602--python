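"""Synthetic data generators for every stage of the analysis.

Three generators emulate the statistical structure of the real data:

* sawtooth force-extension traces of a polyprotein (default heptamer)
  whose domains unfold through a stochastic mixture of 2-, 3- and
  4-state pathways.  Stretching follows the worm-like chain in series
  with the cantilever spring; rupture kinetics follow the Bell-Evans
  rate law k(F) = k0 exp(F dx / kBT), sampled per time step (kinetic
  Monte Carlo).  Each rupture releases its state's contour increment;
  the trace ends with a tip-detachment rupture that releases none.

* multi-exponential fluorescence decays convolved with an instrument
  response function, with Poisson counting noise.

* bead-per-residue antiparallel beta-barrel structures, optionally with
  a 5-ligand copper coordination site, standing in for the azurin fold.

Every generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .constants import kbt
from .model import AXIAL_LIGANDS, BeadModel, MetalBond, MetalSphere
from .tcspc import IRF, DecayCurve, convolve_model
from .trace import FXTrace, GeneratorConfig, RuptureRecord
from .wlc import wlc_force

__all__ = [
    "StateSpec",
    "PathwaySpec",
    "apo_pathways",
    "holo_pathways",
    "generate_fx_trace",
    "generate_dataset",
    "generate_decay",
    "gaussian_irf",
    "delta_irf",
    "generate_toy_barrel",
]


@dataclass(frozen=True)
class StateSpec:
    """One rupturable state: contour release and Bell-Evans kinetics."""

    delta_lc: float  #: nm released when this state ruptures
    k0: float  #: 1/s, intrinsic (zero-force) rupture rate
    dx: float  #: nm, distance to the transition state

    def validate(self) -> None:
        if self.delta_lc <= 0:
            raise ValueError(f"StateSpec.delta_lc must be > 0 nm, got {self.delta_lc}")
        if self.k0 <= 0:
            raise ValueError(f"StateSpec.k0 must be > 0 /s, got {self.k0}")
        if self.dx <= 0:
            raise ValueError(f"StateSpec.dx must be > 0 nm, got {self.dx}")


@dataclass(frozen=True)
class PathwaySpec:
    """An ordered rupture cascade and its probability in the mixture.

    A 2-state pathway has 1 rupture, 3-state has 2, 4-state has 3.
    """

    states: tuple[StateSpec, ...]
    weight: float

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("PathwaySpec needs at least one rupturable state")
        for s in self.states:
            s.validate()
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"PathwaySpec.weight must be in [0, 1], got {self.weight}")

    @property
    def n_states(self) -> int:
        return len(self.states) + 1

    @property
    def total_delta_lc(self) -> float:
        return float(sum(s.delta_lc for s in self.states))


#: Distance to the transition state shared by the default pathways, nm.
#: Most of the ~10 pN width of the rupture-force histograms comes from
#: the static per-domain disorder; the Bell width kBT/dx is kept narrow
#: so that an intermediate reloads measurably before it ruptures.
DX_DEFAULT = 2.0

#: Detachment barrier (final peak, releases no contour).
DETACH_STATE = StateSpec(delta_lc=1e-9, k0=2.5e-10, dx=DX_DEFAULT)


def apo_pathways(
    three_state_weight: float = 0.56,
    dlc_total: float = 37.2,
    dlc_intermediate: float = 7.5,
) -> list[PathwaySpec]:
    """Default apo mixture: 44% 2-state, 56% 3-state with a 7.5 nm intermediate.

    Bell parameters are set so that at 400 nm/s native peaks centre near
    56 pN and intermediate peaks near 46 pN.
    """
    native = dict(k0=2.5e-10, dx=DX_DEFAULT)
    interm = dict(k0=1e-8, dx=DX_DEFAULT)
    return [
        PathwaySpec(states=(StateSpec(dlc_total, **native),), weight=1.0 - three_state_weight),
        PathwaySpec(
            states=(
                StateSpec(dlc_intermediate, **native),
                StateSpec(dlc_total - dlc_intermediate, **interm),
            ),
            weight=three_state_weight,
        ),
    ]


def holo_pathways(
    intermediate_weight: float = 0.77,
    four_state_weight: float = 0.16,
    dlc_total: float = 37.0,
    dlc_intermediate: float = 6.7,
    dlc_second_intermediate: float = 5.3,
) -> list[PathwaySpec]:
    """Default copper-bound mixture: 23% 2-state, 61% 3-state, 16% 4-state.

    The first intermediate sits ~1 nm closer to the native state than in
    the apo form (copper sequestration); native peaks centre near 63 pN,
    intermediates near 54 and 51 pN.
    """
    native = dict(k0=8.3e-12, dx=DX_DEFAULT)
    interm = dict(k0=4.2e-10, dx=DX_DEFAULT)
    interm2 = dict(k0=1.8e-9, dx=DX_DEFAULT)
    three_state_weight = intermediate_weight - four_state_weight
    if three_state_weight < 0:
        raise ValueError("four_state_weight cannot exceed intermediate_weight")
    rest = dlc_total - dlc_intermediate
    rest2 = dlc_total - dlc_intermediate - dlc_second_intermediate
    return [
        PathwaySpec(states=(StateSpec(dlc_total, **native),), weight=1.0 - intermediate_weight),
        PathwaySpec(
            states=(StateSpec(dlc_intermediate, **native), StateSpec(rest, **interm)),
            weight=three_state_weight,
        ),
        PathwaySpec(
            states=(
                StateSpec(dlc_intermediate, **native),
                StateSpec(dlc_second_intermediate, **interm),
                StateSpec(rest2, **interm2),
            ),
            weight=four_state_weight,
        ),
    ]


def _solve_extension(z: float, lc: float, p: float, kc: float, T: float, x_prev: float) -> float:
    """Molecular extension where the WLC force balances the cantilever load line.

    Solves (kBT/p)[1/4 (1-x/Lc)^-2 - 1/4 + x/Lc] = kc (z - x) by Newton
    iteration warm-started from the previous sample, with a bisection
    fallback for robustness.
    """
    if z <= 0:
        return 0.0
    hi = lc * (1.0 - 1e-10)
    c = kbt(T) / p

    def g_and_dg(x: float) -> tuple[float, float]:
        r = x / lc
        om = 1.0 - r
        g = c * (0.25 * om**-2 - 0.25 + r) - kc * (z - x)
        dg = c * (0.5 * om**-3 + 1.0) / lc + kc
        return g, dg

    x = min(max(x_prev, 0.0), hi)
    if g_and_dg(hi)[0] < 0:  # z beyond what the WLC can reach before diverging
        return hi
    for _ in range(50):
        g, dg = g_and_dg(x)
        step = g / dg
        x_new = x - step
        if x_new <= 0.0 or x_new >= hi:
            break
        if abs(step) < 1e-11:
            return x_new
        x = x_new
    else:
        return x

    def g(x: float) -> float:
        return wlc_force(x, lc, p, T) - kc * (z - x)

    return optimize.brentq(g, 0.0, hi, xtol=1e-10)


def generate_fx_trace(config: GeneratorConfig, pathways: list[PathwaySpec]) -> FXTrace:
    """Simulate one constant-velocity polyprotein pulling trace.

    Each domain draws its pathway from the mixture; all currently folded
    states feel the common force and compete for rupture (kinetic Monte
    Carlo with Bell-Evans rates).  Ground truth is recorded per rupture.
    """
    config.validate()
    if not pathways:
        raise ValueError("need at least one pathway")
    weights = np.asarray([p.weight for p in pathways], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("pathway weights must be non-negative with a positive sum")
    if abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError(f"pathway weights must sum to 1, got {weights.sum():.6f}")

    rng = np.random.default_rng(config.seed)
    choice = rng.choice(len(pathways), size=config.n_domains, p=weights)

    # per-domain queue of pending states, consumed front-first
    queues: list[list[StateSpec]] = [list(pathways[c].states) for c in choice]
    n_states_by_domain = [pathways[c].n_states for c in choice]
    state_counter = [0] * config.n_domains

    # static disorder: each domain carries one strength offset (pN) that
    # shifts the rupture forces of all of its states together — the
    # native and intermediate forces of one molecule are correlated
    disorder = rng.normal(0.0, config.domain_disorder_sd, size=config.n_domains)

    dt = 1.0 / config.sampling_rate
    v = config.pulling_speed
    kc = config.cantilever_k
    p = config.persistence_length
    T = config.temperature
    kT = kbt(T)

    lc = config.initial_contour
    lc_final = lc + sum(sum(s.delta_lc for s in q) for q in queues)
    z = 0.0
    x = 0.0
    detached = False
    detach_pending = True

    ext: list[float] = []
    frc: list[float] = []
    truth: list[RuptureRecord] = []

    max_steps = int((lc_final + 40.0) / (v * dt)) + 1
    for _ in range(max_steps):
        z += v * dt
        x = _solve_extension(z, lc, p, kc, T, x)
        force = kc * (z - x)
        if force < 0:
            force = 0.0
        ext.append(x)
        frc.append(force)

        # detachment becomes eligible only one sample after the last
        # domain rupture: the force recorded this step predates the
        # contour release, so testing the detachment barrier against it
        # would fire at the (high) pre-drop force within the same sample
        detach_armed = detach_pending and not any(queues)

        # rupture attempts for every active barrier at this force
        for d in range(config.n_domains):
            if queues[d]:
                st = queues[d][0]
                rate = st.k0 * np.exp((force - disorder[d]) * st.dx / kT)
                if rng.random() < -np.expm1(-rate * dt):
                    queues[d].pop(0)
                    truth.append(
                        RuptureRecord(
                            domain=d,
                            state_index=state_counter[d],
                            n_states=n_states_by_domain[d],
                            force=force,
                            extension=x,
                            lc_before=lc,
                            delta_lc=st.delta_lc,
                        )
                    )
                    state_counter[d] += 1
                    lc += st.delta_lc
        if detach_armed:
            st = DETACH_STATE
            rate = st.k0 * np.exp(force * st.dx / kT)
            if rng.random() < -np.expm1(-rate * dt):
                truth.append(
                    RuptureRecord(
                        domain=-1, state_index=0, n_states=2,
                        force=force, extension=x, lc_before=lc, delta_lc=0.0,
                    )
                )
                detached = True
                detach_pending = False
        if detached:
            break

    # short zero-force tail after detachment so the final peak is interior
    n_tail = 25
    for _ in range(n_tail):
        z += v * dt
        ext.append(z)
        frc.append(0.0)

    force_arr = np.asarray(frc)
    if config.noise_sd > 0:
        force_arr = force_arr + rng.normal(0.0, config.noise_sd, size=force_arr.size)

    metadata = {
        "pulling_speed_nm_s": config.pulling_speed,
        "cantilever_k_pn_nm": config.cantilever_k,
        "sampling_rate_hz": config.sampling_rate,
        "noise_sd_pn": config.noise_sd,
        "temperature_k": config.temperature,
        "persistence_length_nm": config.persistence_length,
        "n_domains": config.n_domains,
        "seed": config.seed,
    }
    return FXTrace(extension=np.asarray(ext), force=force_arr, metadata=metadata, truth=truth)


def generate_dataset(
    config: GeneratorConfig, pathways: list[PathwaySpec], n_traces: int, seed: int | None = None
) -> list[FXTrace]:
    """Generate an ensemble of traces with per-trace seeds derived from one seed."""
    from dataclasses import replace

    base = config.seed if seed is None else seed
    seeds = np.random.SeedSequence(base).generate_state(n_traces) % (2**31)
    return [generate_fx_trace(replace(config, seed=int(s)), pathways) for s in seeds]


# ---------------------------------------------------------------------------
# fluorescence decays
# ---------------------------------------------------------------------------

def gaussian_irf(
    n_channels: int = 1024,
    channel_width: float = 48.9,
    fwhm: float = 80.0,
    t0: float = 1000.0,
    area: float = 1e6,
) -> IRF:
    """Gaussian instrument response (widths and centre in ps)."""
    t = np.arange(n_channels) * channel_width
    sigma = fwhm / 2.3548200450309493
    counts = np.exp(-0.5 * ((t - t0) / sigma) ** 2)
    counts *= area / counts.sum()
    return IRF(channel=np.arange(n_channels), counts=counts, channel_width=channel_width)


def delta_irf(n_channels: int = 1024, channel_width: float = 48.9, position: int = 0) -> IRF:
    """Single-channel (delta-function) response, for identity-convolution checks."""
    counts = np.zeros(n_channels)
    counts[position] = 1.0
    return IRF(channel=np.arange(n_channels), counts=counts, channel_width=channel_width)


def generate_decay(
    amplitudes,
    lifetimes,
    irf: IRF,
    shift: float = 0.0,
    peak_count: float = 10000.0,
    seed: int | None = None,
    add_noise: bool = True,
) -> DecayCurve:
    """Synthetic TCSPC decay: IRF (x) multi-exponential, Poisson noise per channel.

    Amplitude fractions are normalised to sum to 1; the noiseless
    expectation is scaled so its maximum equals ``peak_count``.
    """
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    lifetimes = np.atleast_1d(np.asarray(lifetimes, dtype=float))
    if np.any(amplitudes < 0):
        raise ValueError(f"amplitudes must be >= 0, got {amplitudes}")
    if np.any(lifetimes <= 0):
        raise ValueError(f"lifetimes must be > 0 ns, got {lifetimes}")
    if amplitudes.sum() <= 0:
        raise ValueError("amplitudes must have a positive sum")
    if peak_count <= 0:
        raise ValueError(f"peak_count must be > 0, got {peak_count}")
    alphas = amplitudes / amplitudes.sum()
    expected = convolve_model(irf, alphas, lifetimes, shift=shift)
    expected = expected * (peak_count / expected.max())
    if add_noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    return DecayCurve(channel=irf.channel.copy(), counts=counts, channel_width=irf.channel_width)


# ---------------------------------------------------------------------------
# toy beta-barrel structures
# ---------------------------------------------------------------------------

#: Fixture ligand layout mapping the five copper ligands onto barrel
#: strands: Gly45/His46 sit at the top of strand 4, Cys112 at the top of
#: strand 7, His117/Met121 on strand 8 — preserving which strands the
#: copper ties together in azurin.
_LIGAND_STRAND_SLOT = {
    "Gly45:O": (3, 0),
    "His46:N": (3, 1),
    "Cys112:S": (6, 0),
    "His117:N": (7, 0),
    "Met121:S": (7, 2),
}


def generate_toy_barrel(
    n_strands: int = 8,
    residues_per_strand: int = 6,
    with_metal_site: bool = False,
    seed: int = 0,
    strand_spacing: float = 4.8,
    rise: float = 3.4,
    jitter: float = 0.05,
) -> BeadModel:
    """Antiparallel up-down beta-barrel at one bead per residue (angstrom).

    Strands run alternately up and down on a cylinder whose radius gives
    the requested inter-strand spacing; a small seeded jitter breaks the
    exact symmetry.  With ``with_metal_site`` a 5-ligand copper sphere is
    attached with equilibrium distances read from the built geometry.
    """
    if n_strands < 3:
        raise ValueError(f"a barrel needs n_strands >= 3, got {n_strands}")
    if residues_per_strand < 3:
        raise ValueError(f"need residues_per_strand >= 3, got {residues_per_strand}")
    if with_metal_site and (n_strands < 8 or residues_per_strand < 3):
        raise ValueError("the 5-ligand metal site needs an 8-strand barrel (ligands on strands 4, 7 and 8)")

    rng = np.random.default_rng(seed)
    radius = n_strands * strand_spacing / (2.0 * np.pi)
    coords = []
    annotations: dict[str, tuple[int, int]] = {}
    idx = 0
    for s in range(n_strands):
        angle = 2.0 * np.pi * s / n_strands
        cx, cy = radius * np.cos(angle), radius * np.sin(angle)
        heights = np.arange(residues_per_strand) * rise
        if s % 2 == 1:  # antiparallel: odd strands run top to bottom
            heights = heights[::-1]
        start = idx
        for h in heights:
            coords.append([cx, cy, h])
            idx += 1
        annotations[f"b{s + 1}"] = (start, idx - 1)
    coords = np.asarray(coords) + rng.normal(0.0, jitter, size=(idx, 3))

    metal = None
    if with_metal_site:
        bonds = []
        ligand_positions = []
        ligand_index = {}
        for label, (strand, slot) in _LIGAND_STRAND_SLOT.items():
            lo, hi = annotations[f"b{strand + 1}"]
            strand_idx = np.arange(lo, hi + 1)
            # slot counts from the "top" (highest-z) end, where the copper sits
            order = np.argsort(coords[strand_idx, 2])[::-1]
            bead = int(strand_idx[order[slot]])
            ligand_index[label] = bead
            ligand_positions.append(coords[bead])
        cu = np.mean(ligand_positions, axis=0)
        for label, bead in ligand_index.items():
            bonds.append(
                MetalBond(
                    residue_index=bead,
                    label=label,
                    r0=float(np.linalg.norm(coords[bead] - cu)),
                    axial=label in AXIAL_LIGANDS,
                )
            )
        metal = MetalSphere(cu_position=cu, bonds=tuple(bonds))

    return BeadModel(coords=coords, strand_annotations=annotations, metal=metal)
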