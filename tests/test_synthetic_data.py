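import numpy as np
import pytest

from nichenull import (
    SyntheticCommunitySpec,
    cscore_summary,
    generate_community,
    generate_from_table1,
    load_paper_fixture,
    overlap_summary,
    to_presence,
)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_species": 1},
            {"structure": "clustered"},
            {"strength": 1.5},
            {"occupancy": 0.0},
            {"abundance_mean": -1},
            {"n_sectors": 0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticCommunitySpec(**kwargs)


class TestGenerateCommunity:
    def test_deterministic_given_spec_and_seed(self):
        spec = SyntheticCommunitySpec(structure="aggregated", strength=0.6, seed=11)
        a = generate_community(spec)
        b = generate_community(spec)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.species_ids == b.species_ids

    def test_dimensions_and_nonnegativity(self):
        m = generate_community(SyntheticCommunitySpec(n_species=7, n_sites=12, seed=3))
        assert m.shape == (7, 12)
        assert (m.values >= 0).all()
        assert (m.values.sum(axis=1) > 0).all()  # no empty species

    def test_sector_labels_partition_sites(self):
        m = generate_community(SyntheticCommunitySpec(n_sectors=3, seed=1))
        sectors = [m.sector_of_site[s] for s in m.site_ids]
        assert sorted(set(sectors)) == ["sector_1", "sector_2", "sector_3"]

    @pytest.mark.parametrize("structure", ["aggregated", "segregated"])
    def test_zero_strength_equals_random_mode(self, structure):
        base = generate_community(SyntheticCommunitySpec(structure="random", seed=42))
        other = generate_community(
            SyntheticCommunitySpec(structure=structure, strength=0.0, seed=42)
        )
        np.testing.assert_array_equal(base.values, other.values)

    def test_full_segregation_two_species_occupy_disjoint_blocks(self):
        m = generate_community(
            SyntheticCommunitySpec(
                n_species=2, n_sites=4, structure="segregated", strength=1.0, seed=7
            )
        )
        b = to_presence(m).values
        assert not b[0, 2:].any() and not b[1, :2].any()  # confined to own block
        r = cscore_summary(to_presence(m))
        R = to_presence(m).R
        assert r.values[0] == R[0] * R[1]

    def test_aggregation_raises_mean_overlap(self):
        means = {"random": [], "aggregated": []}
        for rep in range(50):
            for structure in means:
                m = generate_community(
                    SyntheticCommunitySpec(
                        structure=structure, strength=1.0, seed=6000 + rep
                    )
                )
                means[structure].append(overlap_summary(m).mean_overlap)
        assert np.mean(means["aggregated"]) > np.mean(means["random"])

    def test_structure_strength_is_monotone(self):
        """Stronger segregation raises the expected C-score; stronger
        aggregation raises expected mean overlap (30 replicates/point)."""
        grid = [0.0, 0.5, 1.0]
        cs, ov = [], []
        for w in grid:
            c_vals, o_vals = [], []
            for rep in range(30):
                seg = generate_community(
                    SyntheticCommunitySpec(structure="segregated", strength=w, seed=7000 + rep)
                )
                agg = generate_community(
                    SyntheticCommunitySpec(structure="aggregated", strength=w, seed=7000 + rep)
                )
                c_vals.append(cscore_summary(to_presence(seg)).mean_cscore)
                o_vals.append(overlap_summary(agg).mean_overlap)
            cs.append(np.mean(c_vals))
            ov.append(np.mean(o_vals))
        # weakly increasing (small Monte-Carlo slack), strictly over the range
        assert cs[0] <= cs[1] + 0.5 and cs[1] <= cs[2] + 0.5 and cs[2] > cs[0]
        assert ov[0] <= ov[1] + 0.01 and ov[1] <= ov[2] + 0.01 and ov[2] > ov[0]

    def test_extreme_occupancy_raises(self):
        with pytest.raises(RuntimeError, match="occupancy"):
            generate_community(
                SyntheticCommunitySpec(n_species=2, n_sites=2, occupancy=0.99, seed=0)
            )


class TestGenerateFromTable1:
    def test_marginals_match_summary_for_all_sectors(self):
        fx, design = load_paper_fixture()
        for sector in fx.sectors:
            m = generate_from_table1(sector, seed=5)
            sub = fx.sector_table(sector)
            incidence = (m.values > 0).sum(axis=1)
            np.testing.assert_array_equal(incidence, sub["n_sites"].to_numpy())
            np.testing.assert_array_equal(
                m.values.sum(axis=1), sub["n_individuals"].to_numpy()
            )
            assert m.n_sites == design.sites_in(sector)

    def test_named_species_counts(self):
        m = generate_from_table1("desert", seed=1)
        row = dict(zip(m.species_ids, m.values))
        g = row["Carabus glyptoterus Fischer Von Waldheim, 1827"]
        assert (g > 0).sum() == 15 and g.sum() == 252
        c = row["Cymindis binotata Fischer Von Waldheim, 1820"]
        assert (c > 0).sum() == 7 and c.sum() == 19

    def test_deterministic_and_seed_sensitive(self):
        a = generate_from_table1("typical_1", seed=8)
        b = generate_from_table1("typical_1", seed=8)
        c = generate_from_table1("typical_1", seed=9)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_unknown_sector_rejected(self):
        with pytest.raises(KeyError):
            generate_from_table1("alpine", seed=0)
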