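"""Synthetic cohort generator: node spaces, cohorts, masks, re-organization."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import linear_sum_assignment

import lesionconn as lc
from lesionconn.errors import ParameterError
from lesionconn.lesioning import lesioned_nodes_from_voxel_mask
from lesionconn.pipeline import cohort_hub_template, group_average_matrix
from lesionconn.synth import ReorgParams, plant_hub_nodes


def label_agreement(true_labels, est_labels):
    """Fraction of nodes whose module matches under the best relabeling."""
    M = max(true_labels.max(), est_labels.max())
    C = np.zeros((M, M))
    for a, b in zip(true_labels, est_labels):
        C[a - 1, b - 1] += 1
    r, c = linear_sum_assignment(-C)
    return C[r, c].sum() / len(true_labels)


class TestNodeSpace:
    @pytest.mark.parametrize(
        "n_nodes,n_modules",
        [(20, 2), (4, 2), (60, 6)],
    )
    def test_bilateral_balanced(self, n_nodes, n_modules):
        t = lc.generate_node_space(n_nodes, n_modules, seed=1)
        assert (t["hemisphere"] == "L").sum() == n_nodes // 2
        assert (t["hemisphere"] == "R").sum() == n_nodes // 2
        for _, sub in t.groupby("module"):
            assert set(sub["hemisphere"]) == {"L", "R"}
        assert set(t["module"]) == set(range(1, n_modules + 1))
        # no midline nodes, hemisphere consistent with x
        assert (t["x"] != 0).all()
        assert ((t["x"] < 0) == (t["hemisphere"] == "L")).all()

    def test_mirrored_coordinates(self):
        t = lc.generate_node_space(20, 2, seed=3).sort_values("node_id")
        left, right = t.iloc[:10], t.iloc[10:]
        assert np.allclose(left["x"].to_numpy(), -right["x"].to_numpy())
        assert np.allclose(left[["y", "z"]].to_numpy(), right[["y", "z"]].to_numpy())
        assert np.array_equal(left["module"].to_numpy(), right["module"].to_numpy())

    @pytest.mark.parametrize("bad", [(5, 2), (3, 2), (8, 5)])
    def test_invalid_sizes_rejected(self, bad):
        with pytest.raises(ParameterError):
            lc.generate_node_space(*bad, seed=1)

    def test_deterministic(self):
        a = lc.generate_node_space(30, 3, seed=9)
        b = lc.generate_node_space(30, 3, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestCohortGenerator:
    def test_zero_noise_gives_identical_subjects(self, small_table):
        params = lc.CohortParams(n_subjects=10, noise_sd=0.0, seed=2)
        cohort = lc.generate_connectome_cohort(small_table, params)
        assert len(cohort) == 10
        for c in cohort:
            np.testing.assert_array_equal(c.z, cohort[0].z)

    def test_symmetry_and_zero_diagonal(self, small_table):
        cohort = lc.generate_connectome_cohort(small_table, lc.CohortParams(seed=5))
        for c in cohort:
            np.testing.assert_array_equal(c.z, c.z.T)
            assert np.all(np.diag(c.z) == 0)

    def test_block_means_hit_targets(self):
        # hub-free cohort: block means are Monte-Carlo estimates of the
        # arctanh targets
        t = lc.generate_node_space(60, 6, seed=3)
        params = lc.CohortParams(
            r_within=0.6, r_between=0.1, n_global_hubs=0, n_local_hubs=0,
            n_subjects=20, seed=3,
        )
        cohort = lc.generate_connectome_cohort(t, params)
        avg = group_average_matrix(cohort)
        labels = t.sort_values("node_id")["module"].to_numpy()
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(60, dtype=bool)
        assert abs(avg[same & off].mean() - np.arctanh(0.6)) < 0.05
        assert abs(avg[~same].mean() - np.arctanh(0.1)) < 0.05

    def test_hub_rows_elevated(self, small_table):
        cohort = lc.generate_connectome_cohort(
            small_table, lc.CohortParams(seed=4, n_global_hubs=2, n_local_hubs=2)
        )
        labels = small_table.sort_values("node_id")["module"].to_numpy()
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(20, dtype=bool)
        base = cohort.base_z
        g = next(iter(cohort.planted_global_hubs))
        l = next(iter(cohort.planted_local_hubs))
        nonhub = [
            i for i in range(20)
            if i not in cohort.planted_global_hubs | cohort.planted_local_hubs
        ]
        nonhub_between = np.mean([base[i, ~same[i]].mean() for i in nonhub])
        nonhub_within = np.mean([base[i, same[i] & off[i]].mean() for i in nonhub])
        assert base[g, ~same[g]].mean() > nonhub_between + 0.1
        assert base[l, same[l] & off[l]].mean() > nonhub_within + 0.2

    def test_zero_boost_nullifies_planting(self):
        # over many seeds, rows selected as "hubs" are indistinguishable
        # from the rest when the boost is zero
        hub_means, other_means = [], []
        for seed in range(50):
            t = lc.generate_node_space(20, 2, seed=seed)
            params = lc.CohortParams(
                hub_boost=0.0, hub_boost_local=0.0, n_global_hubs=5,
                n_local_hubs=0, n_subjects=2, seed=seed,
            )
            cohort = lc.generate_connectome_cohort(t, params)
            off = ~np.eye(20, dtype=bool)
            row_means = np.array([cohort.base_z[i, off[i]].mean() for i in range(20)])
            hubs = sorted(cohort.planted_global_hubs)
            others = [i for i in range(20) if i not in cohort.planted_global_hubs]
            hub_means.append(row_means[hubs].mean())
            other_means.append(row_means[others].mean())
        p = stats.ttest_ind(hub_means, other_means).pvalue
        assert p > 0.01

    def test_deterministic_per_seed(self, small_table):
        a = lc.generate_connectome_cohort(small_table, lc.CohortParams(seed=11))
        b = lc.generate_connectome_cohort(small_table, lc.CohortParams(seed=11))
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.z, cb.z)

    def test_shared_base_with_independent_noise(self, small_table):
        p1 = lc.CohortParams(seed=11)
        p2 = dataclasses.replace(p1, noise_seed=999)
        a = lc.generate_connectome_cohort(small_table, p1)
        b = lc.generate_connectome_cohort(small_table, p2)
        np.testing.assert_array_equal(a.base_z, b.base_z)
        assert a.planted_global_hubs == b.planted_global_hubs
        assert not np.array_equal(a[0].z, b[0].z)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            lc.CohortParams(r_within=0.1, r_between=0.5).validate()
        with pytest.raises(ParameterError):
            lc.CohortParams(noise_sd=-1).validate()
        with pytest.raises(ParameterError):
            lc.CohortParams(n_nodes=10, n_global_hubs=8, n_local_hubs=8).validate()

    def test_hub_pairs_balanced_across_hemispheres(self, small_table):
        rng = np.random.default_rng(0)
        g, l = plant_hub_nodes(small_table, lc.CohortParams(n_global_hubs=4, n_local_hubs=4), rng)
        hemi = small_table.set_index("node_id")["hemisphere"]
        assert (hemi.loc[g] == "L").sum() == 2 and (hemi.loc[l] == "L").sum() == 2


class TestLesionMasks:
    def test_masks_are_left_and_sized(self, small_table):
        masks = lc.generate_lesion_masks(small_table, n_masks=25, size_min=3,
                                         size_max=8, seed=0)
        hemi = small_table.set_index("node_id")["hemisphere"]
        assert len(masks) == 25
        for m in masks:
            assert 3 <= len(m.node_set) <= 8
            assert all(hemi.loc[n] == "L" for n in m.node_set)

    def test_masks_connected_under_knn(self, small_table):
        from lesionconn.synth import _knn_adjacency

        left = small_table[small_table["hemisphere"] == "L"].sort_values("node_id")
        neigh = _knn_adjacency(left[["x", "y", "z"]].to_numpy(), 6)
        ids = left["node_id"].to_numpy()
        pos = {nid: i for i, nid in enumerate(ids)}
        for m in lc.generate_lesion_masks(small_table, 10, 2, 6, seed=3):
            nodes = {pos[n] for n in m.node_set}
            seen = {next(iter(nodes))}
            frontier = [next(iter(nodes))]
            while frontier:
                cur = frontier.pop()
                for nb in neigh[cur]:
                    if nb in nodes and nb not in seen:
                        seen.add(int(nb))
                        frontier.append(int(nb))
            assert seen == nodes, f"mask {m.mask_id} not connected"

    def test_singleton_masks(self, small_table):
        masks = lc.generate_lesion_masks(small_table, 5, 1, 1, seed=0)
        assert all(len(m.node_set) == 1 for m in masks)

    def test_infeasible_sizes_rejected(self, small_table):
        with pytest.raises(ParameterError):
            lc.generate_lesion_masks(small_table, 5, 3, 11, seed=0)  # only 10 L nodes

    def test_damage_scores_vary_across_masks(self, default_world):
        pc = [d.pc_damage for d in default_world.damage]
        wd = [d.wd_damage for d in default_world.damage]
        assert np.std(pc) > 0 and np.std(wd) > 0


class TestVoxelMasks:
    def test_full_cover_roundtrip(self, small_table):
        mask = lc.generate_voxel_mask(small_table, {0, 3, 7}, covered_fraction=1.0, seed=0)
        assert lesioned_nodes_from_voxel_mask(mask, small_table) == {0, 3, 7}

    def test_zero_cover_empty(self, small_table):
        mask = lc.generate_voxel_mask(small_table, {0, 3, 7}, covered_fraction=0.0, seed=0)
        assert lesioned_nodes_from_voxel_mask(mask, small_table) == set()

    def test_half_cover_recovered_at_quarter_threshold(self, small_table):
        mask = lc.generate_voxel_mask(small_table, {2, 5}, covered_fraction=0.5, seed=1)
        got = lesioned_nodes_from_voxel_mask(mask, small_table, frac_threshold=0.25)
        assert got == {2, 5}

    def test_invalid_fraction_rejected(self, small_table):
        with pytest.raises(ParameterError):
            lc.generate_voxel_mask(small_table, {0}, covered_fraction=1.5)


class TestReorganization:
    def test_identity_when_all_params_zero(self, default_world):
        conn = default_world.pseudo[0]
        dmg = default_world.damage[0]
        out = lc.apply_reorganization(conn, dmg, ReorgParams(), default_world.node_table)
        np.testing.assert_array_equal(out.z, conn.z)
        assert out.group == "REAL"

    def test_symmetry_preserved(self, default_world):
        conn = default_world.pseudo[3]
        params = ReorgParams(pc_coupling=-1.0, wd_coupling=-0.2, new_hub_count=6,
                             rh_bias=0.7, seed=5)
        out = lc.apply_reorganization(conn, default_world.damage[0], params,
                                      default_world.node_table)
        np.testing.assert_array_equal(out.z, out.z.T)
        assert np.all(np.diag(out.z) == 0)

    def test_full_rh_bias_promotes_only_right(self, default_world):
        conn = default_world.pseudo[0]
        params = ReorgParams(new_hub_count=6, rh_bias=1.0, promotion_boost=0.5, seed=3)
        out = lc.apply_reorganization(conn, default_world.damage[0], params,
                                      default_world.node_table)
        changed = np.flatnonzero(np.abs(out.z - conn.z).sum(axis=1) > 1e-12)
        changed_ids = conn.nodes[changed]
        hemi = default_world.node_table.set_index("node_id")["hemisphere"]
        promoted = [n for n in changed_ids
                    if np.abs(out.z - conn.z)[conn.index_of([n])[0]].max() >= 0.5 - 1e-12]
        assert len(promoted) >= 6
        rows_fully_boosted = [
            n for n in promoted
            if (np.count_nonzero(np.abs(out.z - conn.z)[conn.index_of([n])[0]]) > 5)
        ]
        assert all(hemi.loc[n] == "R" for n in rows_fully_boosted)

    def test_promotions_consistent_across_cohort(self, default_world):
        params = ReorgParams(new_hub_count=4, rh_bias=1.0, promotion_boost=0.5, seed=3)

        def promoted_rows(conn):
            out = lc.apply_reorganization(conn, default_world.damage[0], params,
                                          default_world.node_table)
            delta = np.abs(out.z - conn.z)
            return {int(n) for n, d in zip(conn.nodes, delta)
                    if np.count_nonzero(d) > 5}

        sets = [promoted_rows(default_world.pseudo[i]) for i in range(3)]
        assert sets[0] == sets[1] == sets[2]


class TestPlantedStructureRecovery:
    def test_partition_recovery_low_noise(self):
        """Ward clustering recovers planted modules in low-noise cohorts."""
        accs = []
        for seed in range(20):
            t = lc.generate_node_space(60, 6, seed=seed)
            params = lc.CohortParams(seed=seed, noise_sd=0.02, pair_sd=0.1)
            cohort = lc.generate_connectome_cohort(t, params)
            part = lc.reference_partition(group_average_matrix(cohort), 6)
            accs.append(label_agreement(
                t.sort_values("node_id")["module"].to_numpy(),
                part.labels_for(np.arange(60)),
            ))
        assert np.mean(accs) >= 0.95

    def test_hub_recovery(self):
        """Template hub identification recovers planted hubs at default boost."""
        grec, lrec = [], []
        for seed in range(20):
            t = lc.generate_node_space(60, 6, seed=seed)
            cohort = lc.generate_connectome_cohort(t, lc.CohortParams(seed=seed))
            part = lc.reference_partition(group_average_matrix(cohort), 6)
            tpl = cohort_hub_template(cohort, part)
            grec.append(len(tpl.global_hubs & cohort.planted_global_hubs)
                        / len(cohort.planted_global_hubs))
            lrec.append(len(tpl.local_hubs & cohort.planted_local_hubs)
                        / len(cohort.planted_local_hubs))
        assert np.mean(grec) >= 0.8
        assert np.mean(lrec) >= 0.8
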