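"""Spatial-cluster filtering of predicted binding residues."""

import numpy as np
import pytest

from bindstack.evaluation import confusion_from_arrays, metrics
from bindstack.postprocess import (
    PredictedSite,
    filter_by_spatial_clusters,
    sites_from_structure,
)
from bindstack.synthetic import ComplexSpec, build_toy_complex


def union_find_components(coords, link_distance):
    """Brute-force oracle over the all-pairs distance graph."""
    n = len(coords)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(coords[i] - coords[j]) <= link_distance:
                parent[find(i)] = find(j)
    roots = [find(i) for i in range(n)]
    return {r: {i for i in range(n) if find(i) == r} for r in set(roots)}


def make_sites(coords):
    return [
        PredictedSite(residue_id=("A", i + 1, ""), ca=c) for i, c in enumerate(coords)
    ]


def test_min_cluster_size_one_is_identity():
    rng = np.random.default_rng(0)
    sites = make_sites(rng.uniform(0, 50, (30, 3)))
    retained, _ = filter_by_spatial_clusters(sites, 8.0, min_cluster_size=1)
    assert retained == sites


def test_isolated_site_removed_from_chain_plus_outlier():
    chain = [np.array([5.0 * i, 0.0, 0.0]) for i in range(5)]
    outlier = [np.array([50.0, 50.0, 50.0])]
    sites = make_sites(chain + outlier)
    retained, report = filter_by_spatial_clusters(sites, link_distance=8.0, min_cluster_size=2)
    assert len(retained) == 5 and sites[-1] not in retained
    assert sorted(report["size"]) == [1, 5]
    assert list(report["retained"]) == [True, False]


def test_components_match_union_find_oracle():
    rng = np.random.default_rng(4)
    coords = rng.uniform(0, 60, (100, 3))
    sites = make_sites(coords)
    _, report = filter_by_spatial_clusters(sites, link_distance=10.0, min_cluster_size=3)
    oracle = union_find_components(coords, 10.0)
    ours = {
        frozenset(int(m.split("/")[1]) - 1 for m in members.split(";"))
        for members in report["members"]
    }
    assert ours == {frozenset(c) for c in oracle.values()}


def test_filtering_only_trades_sensitivity_for_specificity():
    rng = np.random.default_rng(8)
    coords = rng.uniform(0, 40, (80, 3))
    truth = rng.integers(0, 2, 80)
    predicted = rng.integers(0, 2, 80)
    sites = make_sites(coords[predicted == 1])
    for link, min_size in [(5.0, 2), (10.0, 3), (20.0, 5)]:
        retained, _ = filter_by_spatial_clusters(sites, link, min_size)
        kept = {s.residue_id for s in retained}
        filtered = np.array(
            [
                1 if p and ("A", i + 1, "") in kept else 0
                for i, p in enumerate(predicted)
            ]
        )
        before = metrics(confusion_from_arrays(predicted, truth))
        after = metrics(confusion_from_arrays(filtered, truth))
        assert after.specificity >= before.specificity
        assert after.sensitivity <= before.sensitivity


def test_invariant_to_ordering_and_rigid_motion():
    rng = np.random.default_rng(2)
    coords = rng.uniform(0, 30, (40, 3))
    sites = make_sites(coords)
    retained, _ = filter_by_spatial_clusters(sites, 7.0, 2)
    kept = {s.residue_id for s in retained}

    perm = rng.permutation(40)
    shuffled, _ = filter_by_spatial_clusters([sites[i] for i in perm], 7.0, 2)
    assert {s.residue_id for s in shuffled} == kept

    A = np.linalg.qr(rng.standard_normal((3, 3)))[0]
    moved = [
        PredictedSite(residue_id=s.residue_id, ca=A @ s.ca + 100.0) for s in sites
    ]
    moved_kept, _ = filter_by_spatial_clusters(moved, 7.0, 2)
    assert {s.residue_id for s in moved_kept} == kept


def test_filter_is_idempotent():
    rng = np.random.default_rng(6)
    sites = make_sites(rng.uniform(0, 40, (60, 3)))
    once, _ = filter_by_spatial_clusters(sites, 9.0, 3)
    twice, _ = filter_by_spatial_clusters(once, 9.0, 3)
    assert twice == once


def test_coincident_cas_link_at_distance_zero():
    sites = make_sites([np.zeros(3), np.zeros(3), np.array([100.0, 0, 0])])
    retained, _ = filter_by_spatial_clusters(sites, 1.0, 2)
    assert {s.residue_id for s in retained} == {("A", 1, ""), ("A", 2, "")}


def test_sites_from_structure_requires_ca():
    structure, _ = build_toy_complex(ComplexSpec(residue_distances=(3.0, 5.0)))
    sites = sites_from_structure(structure, [("A", 1, ""), ("A", 2, "")])
    assert len(sites) == 2 and np.isfinite(sites[0].ca).all()
    structure.protein_residues()[0].atoms[0].name = "CX"  # knock out the CA
    with pytest.raises(ValueError, match=r"\('A', 1, ''\)"):
        sites_from_structure(structure, [("A", 1, "")])
    with pytest.raises(KeyError):
        sites_from_structure(structure, [("A", 99, "")])


def test_parameter_validation_and_empty_input():
    assert filter_by_spatial_clusters([], 8.0, 3)[0] == []
    with pytest.raises(ValueError):
        filter_by_spatial_clusters([], 0.0, 3)
    with pytest.raises(ValueError):
        filter_by_spatial_clusters([], 8.0, 0)
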