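import numpy as np
import pytest

from endstate.constants import KB
from endstate.synth import (
    ComplexSpec,
    ContactSpec,
    SeriesSpec,
    gen_energy_series,
    gen_fep_samples,
    gen_toy_complex,
)


class TestGenEnergySeries:
    def test_zero_sigma_is_constant(self):
        series = gen_energy_series(SeriesSpec(n_points=100, mean=-60.0, sigma=0.0))
        assert np.all(series.values == -60.0)

    def test_law_of_large_numbers(self):
        series = gen_energy_series(
            SeriesSpec(n_points=10**6, mean=-60.0, sigma=2.0, seed=5)
        )
        assert abs(series.values.mean() - (-60.0)) < 0.01
        assert abs(series.values.std() - 2.0) < 0.01

    def test_seed_reproducibility(self):
        spec = SeriesSpec(n_points=1000, mean=-60.0, sigma=2.0, seed=9,
                          outlier_fraction=0.01)
        a = gen_energy_series(spec)
        b = gen_energy_series(spec)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.times, b.times)

    def test_regime_sds_order_as_specified(self):
        spec = SeriesSpec(
            n_points=30_000,
            mean=-60.0,
            sigma=1.0,
            regime_changes=((10_000, -60.0, 5.0), (20_000, -60.0, 2.0)),
            seed=2,
        )
        v = gen_energy_series(spec).values
        sds = [v[:10_000].std(), v[10_000:20_000].std(), v[20_000:].std()]
        assert np.argsort(sds).tolist() == [0, 2, 1]

    def test_outliers_at_least_scale_sigma_from_mean(self):
        spec = SeriesSpec(
            n_points=10_000, mean=-60.0, sigma=1.0,
            outlier_fraction=0.01, outlier_scale=8.0, seed=4,
        )
        v = gen_energy_series(spec).values
        n_far = int((np.abs(v - (-60.0)) >= 8.0).sum())
        assert n_far == 100  # exactly round(fraction * n), Gaussian never reaches 8 sigma

    def test_ar1_autocorrelation(self):
        tau, dt = 5.0, 1.0
        v = gen_energy_series(
            SeriesSpec(n_points=200_000, sigma=1.0, autocorrelation_time=tau,
                       dt=dt, seed=6)
        ).values
        lag1 = np.corrcoef(v[:-1], v[1:])[0, 1]
        assert lag1 == pytest.approx(np.exp(-dt / tau), abs=0.02)

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            SeriesSpec(n_points=100, sigma=-1.0)
        with pytest.raises(ValueError):
            SeriesSpec(n_points=100, outlier_fraction=0.6)


class TestGenToyComplex:
    def test_hbond_always_on_hits_target(self):
        spec = ComplexSpec(
            n_protein_chains=2, residues_per_chain=1, n_rna_nucleotides=1,
            contact_pairs=(ContactSpec("hbond", "A:1:OH", "R:1:OP2", 2.7, 1.0),),
            n_frames=8, jitter_sigma=0.03, seed=1,
        )
        system = gen_toy_complex(spec)
        donor = np.nonzero(system.names == "OH")[0][0]
        acceptor = np.nonzero(system.names == "OP2")[0][-1]
        d = np.linalg.norm(
            system.coords[:, donor] - system.coords[:, acceptor], axis=1
        )
        assert np.all(np.abs(d - 2.7) <= 0.1)

    def test_exact_on_fraction_count(self):
        spec = ComplexSpec(
            n_protein_chains=2, residues_per_chain=1, n_rna_nucleotides=1,
            contact_pairs=(ContactSpec("hbond", "A:1:OH", "R:1:OP2", 2.7, 0.621),),
            n_frames=1000, jitter_sigma=0.02, seed=3,
        )
        system = gen_toy_complex(spec)
        donor = np.nonzero(system.names == "OH")[0][0]
        acceptor = np.nonzero(system.names == "OP2")[0][-1]
        d = np.linalg.norm(
            system.coords[:, donor] - system.coords[:, acceptor], axis=1
        )
        assert int((d < 4.0).sum()) == 621

    def test_disjoint_contacts_independent(self):
        spec = ComplexSpec(
            n_protein_chains=2, residues_per_chain=2, n_rna_nucleotides=2,
            contact_pairs=(
                ContactSpec("hbond", "A:1:OH", "R:1:OP2", 2.7, 0.5),
                ContactSpec("ch_pi", "B:1:alkyl", "R:2:ring", 5.0, 0.5),
            ),
            n_frames=2000, jitter_sigma=0.0, seed=8,
        )
        system = gen_toy_complex(spec)
        donor = np.nonzero(system.names == "OH")[0][0]
        acceptor = np.nonzero(
            (system.names == "OP2") & (system.chain_ids == "R") & (system.residue_ids == 1)
        )[0][0]
        on_a = (
            np.linalg.norm(system.coords[:, donor] - system.coords[:, acceptor], axis=1)
            < 4.0
        )
        alkyl = np.nonzero(np.isin(system.names, ("CB", "CG")) & (system.chain_ids == "B") & (system.residue_ids == 1))[0]
        ring = np.nonzero(np.isin(system.names, ("N9", "C8", "N7", "C5", "C4")) & (system.residue_ids == 2) & (system.chain_ids == "R"))[0]
        cd = np.linalg.norm(
            system.coords[:, alkyl].mean(axis=1) - system.coords[:, ring].mean(axis=1),
            axis=1,
        )
        on_b = cd < 7.0
        assert int(on_a.sum()) == 1000
        assert int(on_b.sum()) == 1000
        joint = float((on_a & on_b).mean())
        assert joint == pytest.approx(0.25, abs=0.05)

    def test_salt_bridge_min_pair_exact(self, salt_bridge_complex):
        system = salt_bridge_complex
        nz = np.nonzero(
            (system.names == "NZ") & (system.chain_ids == "B") & (system.residue_ids == 1)
        )[0]
        phos = np.nonzero(
            np.isin(system.names, ("P", "OP1", "OP2")) & (system.chain_ids == "R")
        )[0]
        for f in range(system.n_frames):
            dmin = np.linalg.norm(
                system.coords[f, nz][:, None, :] - system.coords[f, phos][None, :, :],
                axis=-1,
            ).min()
            assert dmin == pytest.approx(3.7, abs=1e-6)

    def test_determinism(self):
        spec = ComplexSpec(n_protein_chains=2, residues_per_chain=1,
                           n_rna_nucleotides=1, n_frames=5, seed=12)
        a = gen_toy_complex(spec)
        b = gen_toy_complex(spec)
        assert np.array_equal(a.coords, b.coords)

    def test_infeasible_geometry_rejected(self):
        spec = ComplexSpec(
            n_protein_chains=2, residues_per_chain=1, n_rna_nucleotides=1,
            contact_pairs=(ContactSpec("hbond", "A:1:OH", "R:1:OP2", 0.1, 1.0),),
            n_frames=2, jitter_sigma=0.0, seed=1,
        )
        with pytest.raises(ValueError, match="infeasible"):
            gen_toy_complex(spec)

    def test_contacts_must_use_distinct_ligand_residues(self):
        spec = ComplexSpec(
            n_protein_chains=2, residues_per_chain=1, n_rna_nucleotides=1,
            contact_pairs=(
                ContactSpec("hbond", "A:1:OH", "R:1:OP2", 2.7, 1.0),
                ContactSpec("ch_pi", "B:1:alkyl", "R:1:ring", 5.0, 1.0),
            ),
            n_frames=2, seed=1,
        )
        with pytest.raises(ValueError, match="distinct ligand residues"):
            gen_toy_complex(spec)


class TestGenFepSamples:
    def test_identical_force_constants_zero_perturbation(self):
        ds = gen_fep_samples(2.0, 2.0, n_per_window=100, seed=1)
        for v, v_next in ds.windows:
            assert np.all(v_next - v == 0.0)

    def test_sample_variance_matches_gaussian(self):
        k_wt, k_mut, temperature = 1.0, 2.0, 300.0
        ds = gen_fep_samples(k_wt, k_mut, n_per_window=100_000,
                             temperature=temperature, seed=2)
        kt = KB * temperature
        for i, (v, _) in enumerate(ds.windows):
            lam = ds.lambdas[i]
            k_lam = (1 - lam) * k_wt + lam * k_mut
            # V = k x^2 / 2 so <V> = kT/2; var(x) = 2<V>/k
            var_x = 2.0 * v.mean() / k_lam
            assert var_x == pytest.approx(kt / k_lam, rel=0.02)

    def test_determinism(self):
        a = gen_fep_samples(1.0, 2.0, n_per_window=50, seed=3)
        b = gen_fep_samples(1.0, 2.0, n_per_window=50, seed=3)
        for (va, na), (vb, nb) in zip(a.windows, b.windows):
            assert np.array_equal(va, vb) and np.array_equal(na, nb)

    def test_invalid_force_constant(self):
        with pytest.raises(ValueError):
            gen_fep_samples(0.0, 1.0)
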