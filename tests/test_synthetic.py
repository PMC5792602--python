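"""Generators: FX traces, fluorescence decays, toy barrel structures."""

import numpy as np
import pytest

from azmech.model import AXIAL_LIGANDS, EQUATORIAL_LIGANDS
from azmech.synthetic import (
    PathwaySpec,
    StateSpec,
    apo_pathways,
    delta_irf,
    gaussian_irf,
    generate_decay,
    generate_dataset,
    generate_fx_trace,
    generate_toy_barrel,
    holo_pathways,
)
from azmech.trace import GeneratorConfig


class TestFxTraceGenerator:
    def test_single_domain_single_rupture_then_detachment(self):
        cfg = GeneratorConfig(seed=0, noise_sd=0.0, n_domains=1)
        pathway = PathwaySpec(states=(StateSpec(37.2, 2.5e-10, 2.0),), weight=1.0)
        trace = generate_fx_trace(cfg, [pathway])
        domains = [r for r in trace.truth if r.domain >= 0]
        assert len(domains) == 1
        assert domains[0].delta_lc == pytest.approx(37.2)
        assert trace.truth[-1].domain == -1  # detachment closes the trace
        assert trace.force[-1] == 0.0

    def test_same_seed_bit_identical(self):
        cfg = GeneratorConfig(seed=42, noise_sd=5.0)
        a = generate_fx_trace(cfg, apo_pathways())
        b = generate_fx_trace(cfg, apo_pathways())
        assert np.array_equal(a.extension, b.extension)
        assert np.array_equal(a.force, b.force)

    def test_extension_monotone_and_nonnegative(self):
        trace = generate_fx_trace(GeneratorConfig(seed=5), apo_pathways())
        assert trace.extension[0] >= 0
        assert np.all(np.diff(trace.extension) >= 0)

    def test_mixture_proportions_recovered_in_truth(self):
        """3-state truth fraction over 500 traces within 3 binomial SD."""
        cfg = GeneratorConfig(seed=0, noise_sd=0.0, n_domains=1,
                              sampling_rate=2000.0)
        traces = generate_dataset(cfg, apo_pathways(), 500, seed=11)
        labels = np.asarray([t.pathway_labels[0] for t in traces])
        frac = np.mean(labels == 3)
        sd = np.sqrt(0.56 * 0.44 / labels.size)
        assert abs(frac - 0.56) < 3 * sd

    def test_rupture_force_increases_with_pulling_speed(self):
        means = []
        for speed in (40.0, 400.0, 2000.0):
            cfg = GeneratorConfig(seed=2, noise_sd=0.0, pulling_speed=speed)
            traces = generate_dataset(cfg, apo_pathways(), 15, seed=7)
            forces = [r.force for t in traces for r in t.truth
                      if r.domain >= 0 and r.state_index == 0]
            means.append(np.mean(forces))
        assert means[0] < means[1] < means[2]

    def test_rupture_forces_in_experimental_band(self):
        """Default kinetics put mean peak forces in the 45-65 pN window."""
        cfg = GeneratorConfig(seed=1, noise_sd=0.0)
        for pathways in (apo_pathways(), holo_pathways()):
            traces = generate_dataset(cfg, pathways, 30, seed=9)
            forces = [r.force for t in traces for r in t.truth if r.domain >= 0]
            assert 45.0 < np.mean(forces) < 65.0

    def test_invalid_inputs_name_the_field(self):
        cfg = GeneratorConfig(seed=0)
        with pytest.raises(ValueError, match="dx"):
            generate_fx_trace(cfg, [PathwaySpec(states=(StateSpec(37.0, 1e-9, -1.0),), weight=1.0)])
        with pytest.raises(ValueError, match="pulling_speed"):
            generate_fx_trace(GeneratorConfig(seed=0, pulling_speed=-1.0), apo_pathways())
        with pytest.raises(ValueError, match="sum to 1"):
            generate_fx_trace(cfg, [PathwaySpec(states=(StateSpec(37.0, 1e-9, 2.0),), weight=0.5)])


class TestDecayGenerator:
    def test_delta_irf_gives_pure_exponential(self):
        irf = delta_irf(512, 48.9)
        decay = generate_decay([1.0], [2.0], irf, peak_count=1e4, add_noise=False)
        t = decay.times_ns
        expected = 1e4 * np.exp(-t / 2.0)
        assert np.allclose(decay.counts, expected, rtol=1e-9)

    def test_mean_lifetime_matches_area_oracle(self):
        """For a normalised decay, area / peak equals tau_m numerically."""
        irf = delta_irf(4096, 48.9)
        decay = generate_decay([0.5, 0.5], [1.0, 5.0], irf, add_noise=False)
        area_tau = np.sum(decay.counts) * 48.9e-3 / decay.counts.max()
        assert area_tau == pytest.approx(3.0, abs=0.05)

    def test_peak_count_honoured(self, irf80):
        decay = generate_decay([0.6, 0.4], [0.5, 4.0], irf80, peak_count=6000, seed=0)
        assert decay.counts.max() >= 5000

    def test_poisson_noise_reproducible(self, irf80):
        a = generate_decay([1.0], [3.0], irf80, seed=5)
        b = generate_decay([1.0], [3.0], irf80, seed=5)
        assert np.array_equal(a.counts, b.counts)

    def test_negative_parameters_rejected(self, irf80):
        with pytest.raises(ValueError, match="lifetimes"):
            generate_decay([1.0], [-2.0], irf80)
        with pytest.raises(ValueError, match="amplitudes"):
            generate_decay([-1.0], [2.0], irf80)


class TestToyBarrel:
    def test_barrel_topology(self, barrel):
        assert barrel.n_residues == 48
        assert len(barrel.strand_annotations) == 8
        # adjacent strands sit closer than next-nearest (barrel adjacency)
        from azmech.trajectory import strand_gc

        gcs = [strand_gc(barrel.coords, barrel.strand_annotations[f"b{i}"]) for i in range(1, 9)]
        d_adj = np.linalg.norm(gcs[0] - gcs[1])
        d_far = np.linalg.norm(gcs[0] - gcs[4])
        assert d_adj < d_far

    def test_metal_site_has_five_bonds_at_built_distances(self, barrel):
        metal = barrel.metal
        assert len(metal.bonds) == 5
        assert {b.label for b in metal.bonds if b.axial} == set(AXIAL_LIGANDS)
        assert {b.label for b in metal.bonds if not b.axial} == set(EQUATORIAL_LIGANDS)
        for bond in metal.bonds:
            d = np.linalg.norm(barrel.coords[bond.residue_index] - metal.cu_position)
            assert bond.r0 == pytest.approx(d, abs=1e-9)

    def test_same_seed_identical_coordinates(self):
        a = generate_toy_barrel(8, 6, with_metal_site=True, seed=3)
        b = generate_toy_barrel(8, 6, with_metal_site=True, seed=3)
        assert np.array_equal(a.coords, b.coords)

    def test_too_few_strands_rejected(self):
        with pytest.raises(ValueError, match="n_strands"):
            generate_toy_barrel(2, 6)
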