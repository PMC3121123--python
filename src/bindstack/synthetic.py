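"""Synthetic complexes and simulated base-predictor tracks.

Real evaluation of the meta-predictor needs six third-party web servers and
a curated structure benchmark; neither is reproducible offline.  This module
generates (i) toy protein-DNA complexes whose residues sit at scripted
minimum distances from an idealized DNA helix, giving exact ground truth for
the annotation code, and (ii) per-residue predictor score tracks with
controlled class separation and inter-predictor correlation at the benchmark's
~1:12.6 positive:negative imbalance, giving an honest testbed for stacking.

The score model is class-conditional Gaussian with a single shared latent
factor: for residue ``i`` with label ``y_i`` and predictor ``p``,

    s_pi = mu_p(y_i) + sigma_p * (sqrt(rho_p) * z_i + sqrt(1 - rho_p) * e_pi)

with z_i and e_pi standard normal; ``rho_p`` is the between-predictor score
correlation (the realistic obstacle to stacking gains).  With the binary
threshold at the class midpoint, sensitivity = specificity =
Phi(delta_p / (2 sigma_p)) where delta_p = mu_p(1) - mu_p(0), which is the
profile's analytic strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .features import BasePredictionTrack, FeatureMatrix, encode_tracks
from .structure import AtomRecord, Chain, ComplexStructure, ResidueRecord

__all__ = [
    "ComplexSpec",
    "PredictorProfile",
    "build_toy_complex",
    "default_profiles",
    "simulate_labels",
    "simulate_tracks",
    "simulate_dataset",
    "random_protein_sequence",
    "BENCHMARK_POSITIVE_FRACTION",
]

#: Positive-class fraction matching the structure-derived benchmark
#: (5342 binding / 67396 non-binding residues, ~1:12.6).
BENCHMARK_POSITIVE_FRACTION = 5342 / (5342 + 67396)

_HELIX_RADIUS = 9.0  # Angstrom, backbone radius of the pseudo-helix
_HELIX_RISE = 3.4  # Angstrom per step
_HELIX_TWIST = np.deg2rad(36.0)
_AA_CYCLE = ("ALA", "SER", "LEU", "THR", "GLY", "VAL", "ASP", "LYS", "PHE", "ARG")


@dataclass(frozen=True)
class ComplexSpec:
    """Recipe for a toy complex: one scripted minimum protein-DNA distance
    per protein residue."""

    residue_distances: tuple
    dna_length: int = 20
    structure_id: str = "toy"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.residue_distances:
            raise ValueError("at least one residue distance required")
        if any(d <= 0 for d in self.residue_distances):
            raise ValueError("unsatisfiable geometry: distances must be > 0")
        if self.dna_length < 1:
            raise ValueError("dna_length must be >= 1")


def _helix_coords(n: int) -> np.ndarray:
    k = np.arange(n)
    return np.column_stack(
        (
            _HELIX_RADIUS * np.cos(k * _HELIX_TWIST),
            _HELIX_RADIUS * np.sin(k * _HELIX_TWIST),
            _HELIX_RISE * k,
        )
    )


def build_toy_complex(spec: ComplexSpec) -> tuple[ComplexStructure, pd.DataFrame]:
    """Deterministic toy complex plus its ground-truth distance table.

    DNA is a single pseudo-atom helical trace (rise 3.4 Angstrom, twist 36
    degrees); each protein residue is a CA plus a side-chain pseudo-atom (CB)
    placed on the outward radial ray of one helix atom so that the residue's
    minimum distance to any DNA atom equals the scripted value.
    """
    helix = _helix_coords(spec.dna_length)
    dna_chain = Chain(chain_id="D")
    for k, coord in enumerate(helix):
        dna_chain.residues.append(
            ResidueRecord(
                chain_id="D",
                seq_number=k + 1,
                insertion_code="",
                res_name="DA" if k % 2 == 0 else "DT",
                atoms=[AtomRecord(serial=0, name="P", element="P", coord=coord)],
                polymer_class="dna",
            )
        )

    protein_chain = Chain(chain_id="A")
    truth_rows = []
    for i, d in enumerate(spec.residue_distances):
        k = i % spec.dna_length
        u = np.array([np.cos(k * _HELIX_TWIST), np.sin(k * _HELIX_TWIST), 0.0])
        cb = helix[k] + d * u
        ca = helix[k] + (d + 1.53) * u
        res_name = _AA_CYCLE[i % len(_AA_CYCLE)]
        protein_chain.residues.append(
            ResidueRecord(
                chain_id="A",
                seq_number=i + 1,
                insertion_code="",
                res_name=res_name,
                atoms=[
                    AtomRecord(serial=0, name="CA", element="C", coord=ca),
                    AtomRecord(serial=0, name="CB", element="C", coord=cb),
                ],
                polymer_class="protein",
            )
        )
        achieved = float(
            np.min(np.linalg.norm(helix - cb, axis=1).min(initial=np.inf))
        )
        achieved = min(
            achieved, float(np.linalg.norm(helix - ca, axis=1).min())
        )
        truth_rows.append(
            {
                "chain_id": "A",
                "seq_number": i + 1,
                "index": i,
                "requested_distance": float(d),
                "achieved_distance": achieved,
            }
        )

    structure = ComplexStructure(
        structure_id=spec.structure_id, chains=[protein_chain, dna_chain]
    )
    truth = pd.DataFrame(truth_rows)
    bad = truth[np.abs(truth.achieved_distance - truth.requested_distance) > 0.05]
    if not bad.empty:
        raise RuntimeError(
            f"geometry fidelity violated for residues {bad.seq_number.tolist()}"
        )
    return structure, truth


@dataclass(frozen=True)
class PredictorProfile:
    """Class-conditional Gaussian score model for one simulated predictor."""

    predictor_id: str
    kind: str  # "scoring" | "binary"
    mu_pos: float
    mu_neg: float
    sigma: float = 1.0
    rho: float = 0.4  # shared latent-factor loading in [0, 1)
    threshold: float | None = None  # binary kind; default = class midpoint

    def __post_init__(self) -> None:
        if self.mu_pos < self.mu_neg:
            raise ValueError(f"{self.predictor_id}: informative direction requires mu_pos >= mu_neg")
        if self.sigma <= 0:
            raise ValueError(f"{self.predictor_id}: sigma must be > 0")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"{self.predictor_id}: rho must be in [0, 1)")

    @property
    def effective_threshold(self) -> float:
        return (self.mu_pos + self.mu_neg) / 2 if self.threshold is None else self.threshold

    @property
    def analytic_strength(self) -> float:
        """Strength at the class-midpoint threshold: Phi(delta / (2 sigma))."""
        return float(norm.cdf((self.mu_pos - self.mu_neg) / (2 * self.sigma)))


def _delta_for_strength(strength: float) -> float:
    return 2.0 * float(norm.ppf(strength))


def default_profiles(rho: float = 0.4) -> tuple[PredictorProfile, ...]:
    """Six profiles emulating the published single-predictor strength band
    (0.59-0.75): four scoring predictors and two binary-call predictors,
    moderately correlated through the shared latent factor."""
    targets = {
        "disis": ("scoring", 0.59),
        "dnabindr": ("scoring", 0.70),
        "bindn": ("scoring", 0.67),
        "bindn_rf": ("scoring", 0.75),
        "dpbind": ("binary", 0.74),
        "dbs_pred": ("binary", 0.65),
    }
    return tuple(
        PredictorProfile(
            predictor_id=pid,
            kind=kind,
            mu_pos=_delta_for_strength(s),
            mu_neg=0.0,
            sigma=1.0,
            rho=rho,
        )
        for pid, (kind, s) in targets.items()
    )


def simulate_labels(n: int, positive_fraction: float = BENCHMARK_POSITIVE_FRACTION,
                    seed: int = 0) -> np.ndarray:
    """Independent Bernoulli binding labels (1/0), deterministic per seed."""
    if not 0.0 < positive_fraction < 1.0:
        raise ValueError(f"positive_fraction must be in (0, 1), got {positive_fraction}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return (rng.random(n) < positive_fraction).astype(int)


def simulate_tracks(labels, profiles=None, seed: int = 0) -> list[BasePredictionTrack]:
    """Simulated per-residue predictor outputs for the given binding labels."""
    labels = np.asarray(labels).astype(int)
    profiles = default_profiles() if profiles is None else tuple(profiles)
    if not profiles:
        raise ValueError("at least one predictor profile required")
    ss = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(c) for c in ss.spawn(len(profiles) + 1)]
    z = streams[0].standard_normal(len(labels))

    tracks = []
    for profile, rng in zip(profiles, streams[1:]):
        eps = rng.standard_normal(len(labels))
        mu = np.where(labels == 1, profile.mu_pos, profile.mu_neg)
        scores = mu + profile.sigma * (
            np.sqrt(profile.rho) * z + np.sqrt(1.0 - profile.rho) * eps
        )
        if profile.kind == "binary":
            values = (scores > profile.effective_threshold).astype(float)
        else:
            values = scores
        tracks.append(
            BasePredictionTrack(predictor_id=profile.predictor_id, kind=profile.kind,
                                values=values)
        )
    return tracks


def simulate_dataset(
    n: int,
    positive_fraction: float = BENCHMARK_POSITIVE_FRACTION,
    profiles=None,
    seed: int = 0,
) -> tuple[FeatureMatrix, np.ndarray, list[BasePredictionTrack], np.ndarray]:
    """Labels + tracks + encoded features in one call.

    Returns ``(features, y, tracks, labels01)`` with ``y`` in +1/-1 as the
    stacker expects.
    """
    ss = np.random.SeedSequence(seed)
    seed_labels, seed_tracks = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    labels01 = simulate_labels(n, positive_fraction, seed_labels)
    tracks = simulate_tracks(labels01, profiles, seed_tracks)
    features = encode_tracks(tracks, seq_length=n)
    y = np.where(labels01 == 1, 1, -1)
    return features, y, tracks, labels01


def random_protein_sequence(n: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
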