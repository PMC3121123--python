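"""Gold-standard binding annotation: distance and buried-surface criteria."""

import numpy as np
import pytest

from bindstack.annotate import (
    annotate_by_delta_asa,
    annotate_by_distance,
    dataset_label_summary,
    read_label_tracks,
    residue_delta_asa,
    write_label_tracks,
)
from bindstack.structure import ComplexStructure
from bindstack.synthetic import ComplexSpec, build_toy_complex


def brute_force_distance_labels(structure, cutoff):
    """All-pairs oracle: strict '<' over every (protein atom, DNA atom)."""
    dna = np.concatenate(
        [
            r.coords()
            for c in structure.chains
            for r in c.residues
            if r.polymer_class == "dna"
        ]
    )
    labels = []
    for res in structure.protein_residues():
        dmin = min(
            float(np.linalg.norm(a - d)) for a in res.coords() for d in dna
        )
        labels.append(1 if dmin < cutoff else 0)
    return tuple(labels)


def rotated(structure, seed=0):
    rng = np.random.default_rng(seed)
    A = np.linalg.qr(rng.standard_normal((3, 3)))[0]
    if np.linalg.det(A) < 0:
        A[:, 0] *= -1
    shift = rng.uniform(-30, 30, 3)
    import copy

    moved = copy.deepcopy(structure)
    for chain in moved.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.coord = A @ atom.coord + shift
    return moved


def test_boundary_residues_use_strict_less_than(toy_complex):
    structure, _ = toy_complex  # distances 3.0, 3.4, 3.6, 7.0
    (track,) = annotate_by_distance(structure, cutoff=3.5)
    assert track.labels == (1, 1, 0, 0)
    assert track.criterion == "distance" and track.threshold == 3.5


@pytest.mark.parametrize("cutoff", [3.5, 4.5, 5.5, 6.0])
def test_scripted_complex_matches_brute_force(scripted_complex, cutoff):
    structure, _ = scripted_complex
    (track,) = annotate_by_distance(structure, cutoff=cutoff)
    assert track.labels == brute_force_distance_labels(structure, cutoff)


def test_binding_sets_are_nested_in_cutoff(scripted_complex):
    structure, _ = scripted_complex
    sets = [
        annotate_by_distance(structure, cutoff=c)[0].binding_set()
        for c in (3.5, 4.5, 5.5, 6.0)
    ]
    for smaller, larger in zip(sets, sets[1:]):
        assert smaller <= larger


def test_distance_labels_invariant_under_rigid_motion(scripted_complex):
    structure, _ = scripted_complex
    moved = rotated(structure, seed=3)
    assert (
        annotate_by_distance(structure, 4.5)[0].labels
        == annotate_by_distance(moved, 4.5)[0].labels
    )


def test_annotation_requires_dna_and_sane_cutoff(toy_complex):
    structure, _ = toy_complex
    protein_only = ComplexStructure(
        structure_id="p", chains=[structure.chains[0]]
    )
    with pytest.raises(ValueError, match="no DNA"):
        annotate_by_distance(protein_only, 3.5)
    with pytest.raises(ValueError, match="sane"):
        annotate_by_distance(structure, 12.0)


def test_distant_dna_buries_no_surface():
    structure, _ = build_toy_complex(
        ComplexSpec(residue_distances=(25.0, 30.0), dna_length=5)
    )
    areas = residue_delta_asa(structure)
    assert all(free == pytest.approx(bound) for free, bound in areas.values())
    (track,) = annotate_by_delta_asa(structure)
    assert track.labels == (0, 0)


def test_close_dna_buries_over_one_square_angstrom(toy_complex):
    structure, _ = toy_complex
    areas = residue_delta_asa(structure)
    deltas = {rid: free - bound for rid, (free, bound) in areas.items()}
    assert deltas[("A", 1, "")] > 1.0  # residue at 3.0 A
    assert all(d >= 0 for d in deltas.values())  # occlusion only
    (track,) = annotate_by_delta_asa(structure)
    assert track.labels[0] == 1 and track.labels[-1] == 0


def test_delta_asa_is_reproducible_and_has_relative_mode(toy_complex):
    structure, _ = toy_complex
    a = annotate_by_delta_asa(structure)
    b = annotate_by_delta_asa(structure)
    assert a[0].labels == b[0].labels  # deterministic point lattice
    rel = annotate_by_delta_asa(structure, threshold=0.01, mode="relative")
    assert rel[0].criterion == "delta_asa_relative"
    with pytest.raises(ValueError, match="mode"):
        annotate_by_delta_asa(structure, mode="fraction")


def test_label_summary_arithmetic_and_errors(scripted_complex):
    structure, _ = scripted_complex
    t1 = annotate_by_distance(structure, 3.5)[0]
    t2 = annotate_by_distance(structure, 6.0)[0]
    summary = dataset_label_summary([t1, t2])
    pos = t1.n_binding + t2.n_binding
    assert summary["positives"] == pos
    assert summary["negatives"] == 2 * len(t1) - pos
    assert summary["ratio"] == pytest.approx(pos / (2 * len(t1) - pos))
    with pytest.raises(ValueError):
        dataset_label_summary([])


def test_label_track_tsv_roundtrip(tmp_path, scripted_complex):
    structure, _ = scripted_complex
    tracks = annotate_by_distance(structure, 4.5)
    path = tmp_path / "labels.tsv"
    write_label_tracks(tracks, path)
    (back,) = read_label_tracks(path)
    assert back.labels == tracks[0].labels
    assert back.residue_ids == tracks[0].residue_ids
    assert back.criterion == "distance" and back.threshold == 4.5
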