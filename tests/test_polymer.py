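"""Coarse-grained chains, restraint sampling and Metropolis simulation."""

import numpy as np
import pytest
from scipy import stats

from gcckit import core, polymer
from gcckit.core import GenomeAssembly, InteractionNetwork
from gcckit.polymer import (Ensemble, ModelSpec, RestraintSet, Structure,
                            Tether, build_chains, default_tethers, energy,
                            generate_ensemble, run_mc,
                            sample_interaction_subset, _hard_violation)


@pytest.fixture(scope="module")
def small_spec(genome):
    return ModelSpec.for_genome(genome, "G1", bp_per_granule=10_000,
                                sweeps=500)


@pytest.fixture(scope="module")
def small_granules(genome, small_spec):
    return build_chains(genome, small_spec)


@pytest.fixture(scope="module")
def small_restraints(filtered_g1, fragments, small_granules, small_spec):
    return sample_interaction_subset(filtered_g1, fragments, small_granules,
                                     0.10, seed=2, spec=small_spec)


@pytest.fixture(scope="module")
def constrained_mini(small_spec, small_granules):
    return generate_ensemble(small_spec, "constrained", small_granules,
                             n_structures=6, seed=10)


class TestBuildChains:
    def test_even_division(self):
        g = GenomeAssembly([("c", 100_000)])
        gm = build_chains(g, ModelSpec(bp_per_granule=10_000))
        assert len(gm) == 10

    def test_ceiling_with_remainder(self):
        g = GenomeAssembly([("c", 101_000)])
        gm = build_chains(g, ModelSpec(bp_per_granule=10_000))
        assert len(gm) == 11
        assert gm.end[-1] - gm.start[-1] == 1000

    def test_every_position_maps_once(self, small_granules, genome):
        rng = np.random.default_rng(0)
        for _ in range(200):
            chrom = genome.names[rng.integers(0, 3)]
            pos = int(rng.integers(0, genome.lengths[chrom]))
            g = small_granules.granule_of(chrom, pos)
            assert small_granules.chrom[g] == chrom
            assert small_granules.start[g] <= pos < small_granules.end[g]

    def test_locus_overlap_matches_brute_force(self, small_granules, genome):
        rng = np.random.default_rng(1)
        for _ in range(50):
            chrom = genome.names[rng.integers(0, 3)]
            start = int(rng.integers(0, genome.lengths[chrom] - 5000))
            end = start + int(rng.integers(1, 5000))
            got = set(small_granules.granules_overlapping(chrom, start, end))
            brute = {i for i in range(len(small_granules))
                     if small_granules.chrom[i] == chrom
                     and small_granules.start[i] < end
                     and start < small_granules.end[i]}
            assert got == brute


class TestSampleInteractionSubset:
    def test_full_fraction_selects_all(self, filtered_g1, fragments,
                                       small_granules, small_spec):
        rs = sample_interaction_subset(filtered_g1, fragments, small_granules,
                                       1.0, seed=0, spec=small_spec)
        assert len(rs) + rs.n_dropped_same_granule == len(filtered_g1)

    def test_same_granule_pairs_dropped(self, small_spec):
        frags = core.FragmentMap([
            core.RestrictionFragment(0, "chrI", 0, 2000),
            core.RestrictionFragment(1, "chrI", 2000, 4000),
            core.RestrictionFragment(2, "chrI", 4000, 500_000)])
        g = GenomeAssembly([("chrI", 500_000)])
        gm = build_chains(g, ModelSpec(bp_per_granule=10_000))
        net = InteractionNetwork("G1", {(0, 1): 5})  # both in granule 0
        rs = sample_interaction_subset(net, frags, gm, 1.0, seed=0,
                                       spec=small_spec)
        assert len(rs) == 0 and rs.n_dropped_same_granule == 1

    def test_frequency_weighted_draw_order(self, small_spec, small_granules,
                                           fragments):
        # two interactions 9:1 -- the high-frequency one is drawn first in
        # about 90% of seeds
        ids = [fragments.fragments[0].id, fragments.fragments[50].id,
               fragments.fragments[100].id, fragments.fragments[200].id]
        net = InteractionNetwork("G1", {(ids[0], ids[1]): 9,
                                        (ids[2], ids[3]): 1})
        rng = np.random.default_rng(42)
        first_high = 0
        n = 4000
        for _ in range(n):
            rs = sample_interaction_subset(net, fragments, small_granules,
                                           0.5, seed=rng, spec=small_spec)
            first_high += rs.i[0] == small_granules.granule_of(
                fragments.by_id[ids[0]].chrom,
                (fragments.by_id[ids[0]].start
                 + fragments.by_id[ids[0]].end) // 2)
        frac = first_high / n
        assert abs(frac - 0.9) < 3 * np.sqrt(0.9 * 0.1 / n)

    def test_invalid_fraction(self, filtered_g1, fragments, small_granules,
                              small_spec):
        with pytest.raises(ValueError):
            sample_interaction_subset(filtered_g1, fragments, small_granules,
                                      1.5, spec=small_spec)


class TestEnergy:
    @staticmethod
    def _straight_chain(spec, n=5):
        g = GenomeAssembly([("c", n * spec.bp_per_granule)])
        gm = build_chains(g, spec)
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n) * spec.d0 - n * spec.d0 / 2
        return Structure(coords, gm), gm

    def test_rest_length_chain_zero_bond_energy(self):
        spec = ModelSpec(nuclear_radius=1000.0)
        st, _ = self._straight_chain(spec)
        assert energy(st, spec, "confined") == 0.0

    def test_granule_outside_nucleus_infinite(self):
        spec = ModelSpec(nuclear_radius=200.0)
        st, _ = self._straight_chain(spec)
        st.coords[0] = [0, 0, 500.0]
        assert energy(st, spec, "confined") == np.inf

    def test_granule_inside_nucleolus_infinite(self):
        spec = ModelSpec(nuclear_radius=500.0)
        st, _ = self._straight_chain(spec)
        st.coords[2] = spec.nucleolus_center - [0, 0, spec.nucleolus_r / 2]
        assert energy(st, spec, "confined") == np.inf

    def test_restraint_closed_form(self):
        spec = ModelSpec(nuclear_radius=1000.0)
        st, _ = self._straight_chain(spec)
        i, j = 0, 4
        d = np.linalg.norm(st.coords[i] - st.coords[j])
        rs = RestraintSet(np.array([i]), np.array([j]),
                          np.array([d - 10.0]), np.array([spec.k_interaction]))
        e = energy(st, spec, "interactions", restraints=rs, tethers=[])
        assert e == pytest.approx(spec.k_interaction * 10.0 ** 2)

    def test_tether_flat_bottom(self):
        spec = ModelSpec(nuclear_radius=1000.0)
        st, _ = self._straight_chain(spec)
        anchor = st.coords[0] + [0, 0, 50.0]
        t = Tether(0, anchor, tolerance=60.0, k=1.0)
        assert energy(st, spec, "constrained", tethers=[t]) == 0.0
        t2 = Tether(0, anchor, tolerance=30.0, k=1.0)
        assert energy(st, spec, "constrained", tethers=[t2]) == \
               pytest.approx(20.0 ** 2)

    def test_unknown_model_type(self):
        spec = ModelSpec(nuclear_radius=1000.0)
        st, _ = self._straight_chain(spec)
        with pytest.raises(ValueError):
            energy(st, spec, "unrestrained")


class TestRunMc:
    def test_zero_sweeps_returns_valid_initial(self, genome):
        spec = ModelSpec.for_genome(genome, "G1", bp_per_granule=10_000,
                                    sweeps=0)
        gm = build_chains(genome, spec)
        st = run_mc(spec, "constrained", gm, seed=1)
        assert not _hard_violation(st.coords, gm, spec)

    def test_acceptance_fraction_reasonable(self, small_spec, small_granules):
        _, frac = run_mc(small_spec, "confined", small_granules, seed=2,
                         return_acceptance=True)
        assert 0.0 < frac < 1.0

    def test_interactions_requires_restraints(self, small_spec,
                                              small_granules):
        with pytest.raises(ValueError):
            run_mc(small_spec, "interactions", small_granules)

    def test_deterministic_ensembles(self, small_spec, small_granules):
        e1 = generate_ensemble(small_spec, "constrained", small_granules,
                               n_structures=2, seed=7)
        e2 = generate_ensemble(small_spec, "constrained", small_granules,
                               n_structures=2, seed=7)
        for s1, s2 in zip(e1.structures, e2.structures):
            assert np.array_equal(s1.coords, s2.coords)


class TestEnsembleContracts:
    def test_hard_constraints_every_structure(self, constrained_mini,
                                              small_spec, small_granules):
        for st in constrained_mini.structures:
            assert not _hard_violation(st.coords, small_granules, small_spec)

    def test_rabl_centromeres_near_spb(self, constrained_mini, small_spec,
                                       small_granules):
        tethers = default_tethers(small_granules, small_spec)
        cen = [t.granule for t in tethers
               if np.allclose(t.anchor, small_spec.spb)]
        for st in constrained_mini.structures:
            d_cen = np.linalg.norm(st.coords[cen] - small_spec.spb,
                                   axis=1).mean()
            d_all = np.linalg.norm(st.coords - small_spec.spb, axis=1).mean()
            assert d_cen < d_all

    def test_tethered_ends_near_anchors(self, constrained_mini, small_spec,
                                        small_granules):
        # tethered granules sit within tolerance plus a thermal margin
        tethers = default_tethers(small_granules, small_spec)
        margin = 3.0 / np.sqrt(small_spec.k_tether)  # ~e^-9 thermal tail
        for st in constrained_mini.structures:
            for t in tethers:
                d = np.linalg.norm(st.coords[t.granule] - t.anchor)
                assert d < t.tolerance + margin

    def test_confined_telomeres_not_anchored(self, small_spec,
                                             small_granules):
        ens = generate_ensemble(small_spec, "confined", small_granules,
                                n_structures=4, seed=3)
        tethers = default_tethers(small_granules, small_spec)
        tel = [t for t in tethers if not np.allclose(t.anchor,
                                                     small_spec.spb)]
        far = 0
        for st in ens.structures:
            for t in tel:
                if np.linalg.norm(st.coords[t.granule] - t.anchor) > \
                        2 * t.tolerance:
                    far += 1
        assert far > 0  # no envelope enrichment without tethers

    def test_restraints_pull_pairs_closer(self, small_spec, small_granules,
                                          small_restraints):
        ens_c = generate_ensemble(small_spec, "constrained", small_granules,
                                  n_structures=6, seed=20)
        ens_i = generate_ensemble(small_spec, "interactions", small_granules,
                                  restraints=small_restraints,
                                  n_structures=6, seed=21)
        dc = polymer.pair_distances(ens_c, small_restraints.i,
                                    small_restraints.j)
        di = polymer.pair_distances(ens_i, small_restraints.i,
                                    small_restraints.j)
        t, p = stats.ttest_ind(di, dc)
        assert di.mean() < dc.mean()
        assert p / 2 < 0.05  # one-sided


class TestStructureIO:
    def test_structure_tsv_round_trip_geometry(self, constrained_mini,
                                               tmp_path):
        st = constrained_mini.structures[0]
        path = tmp_path / "structure.tsv"
        polymer.write_structure_tsv(st, path)
        import pandas as pd
        frame = pd.read_csv(path, sep="\t")
        assert len(frame) == len(st.coords)
        assert np.allclose(frame[["x", "y", "z"]].to_numpy(), st.coords,
                           atol=1e-3)
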