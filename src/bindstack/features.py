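"""Alignment and encoding of base-predictor outputs into feature vectors.

Six sequence-based DNA-binding-site predictors feed the meta-classifier:
four return a continuous per-residue score (disis, dnabindr, bindn,
bindn_rf) and two return only a binary call (dpbind, dbs_pred), encoded as
+1 for a predicted binding site and 0 otherwise.  Each residue therefore
becomes a six-component vector, one column per registered predictor in a
fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "PREDICTOR_REGISTRY",
    "PREDICTOR_ORDER",
    "BasePredictionTrack",
    "FeatureMatrix",
    "encode_tracks",
    "read_track_tsv",
    "write_track_tsv",
    "read_fasta_sequence",
]

#: Registered predictors and their output kind, in fixed column order.
PREDICTOR_REGISTRY: dict[str, str] = {
    "disis": "scoring",
    "dnabindr": "scoring",
    "bindn": "scoring",
    "bindn_rf": "scoring",
    "dpbind": "binary",
    "dbs_pred": "binary",
}
PREDICTOR_ORDER: tuple[str, ...] = tuple(PREDICTOR_REGISTRY)


@dataclass
class BasePredictionTrack:
    """One predictor's per-residue output aligned to a target sequence."""

    predictor_id: str
    kind: str  # "scoring" | "binary"
    values: np.ndarray | None = None
    available: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("scoring", "binary"):
            raise ValueError(f"{self.predictor_id}: unknown kind {self.kind!r}")
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)
            if self.kind == "binary" and not np.isin(self.values, (0.0, 1.0)).all():
                raise ValueError(f"{self.predictor_id}: binary track values must be 0/1")
        if self.available and self.values is None:
            raise ValueError(f"{self.predictor_id}: available track has no values")


@dataclass
class FeatureMatrix:
    """Residues x predictors feature matrix with an availability mask."""

    values: np.ndarray  # (n_residues, n_columns), no missing cells
    columns: tuple[str, ...]
    mask: np.ndarray  # True where the cell came from a real track

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column names do not match matrix width")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite cells")

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.columns))

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        values = df.to_numpy(dtype=float)
        return cls(values=values, columns=tuple(df.columns), mask=np.ones_like(values, bool))


def _minmax(column: np.ndarray) -> np.ndarray:
    lo, hi = column.min(), column.max()
    if hi == lo:
        return np.full_like(column, 0.5)  # degenerate range: neutral constant
    return (column - lo) / (hi - lo)


def encode_tracks(
    tracks: Iterable[BasePredictionTrack],
    seq_length: int,
    normalization: str = "minmax",
    impute_value: float = 0.0,
    columns: Sequence[str] = PREDICTOR_ORDER,
) -> FeatureMatrix:
    """Assemble per-residue feature vectors from the predictor tracks.

    Scoring tracks go through per-track min-max normalization to [0, 1] by
    default (``normalization="raw"`` passes scores through untouched); binary
    tracks contribute +1/0 as-is.  A predictor with no available track is
    imputed with ``impute_value`` and masked.  At least one track must be
    available; any available track must have exactly ``seq_length`` values.
    """
    if normalization not in ("minmax", "raw"):
        raise ValueError(f"unknown normalization {normalization!r}")
    by_id: dict[str, BasePredictionTrack] = {}
    for t in tracks:
        if t.predictor_id in by_id:
            raise ValueError(f"duplicate track for predictor {t.predictor_id!r}")
        by_id[t.predictor_id] = t
    unknown = set(by_id) - set(columns)
    if unknown:
        raise ValueError(f"unregistered predictor(s): {sorted(unknown)}")

    n_avail = 0
    values = np.full((seq_length, len(columns)), float(impute_value))
    mask = np.zeros((seq_length, len(columns)), dtype=bool)
    for j, pid in enumerate(columns):
        t = by_id.get(pid)
        if t is None or not t.available:
            continue
        if len(t.values) != seq_length:
            raise ValueError(
                f"predictor {pid!r}: track length {len(t.values)} != sequence length {seq_length}"
            )
        col = t.values.astype(float)
        if t.kind == "scoring" and normalization == "minmax":
            col = _minmax(col)
        values[:, j] = col
        mask[:, j] = True
        n_avail += 1
    if n_avail == 0:
        raise ValueError("no available predictor tracks; cannot encode features")
    return FeatureMatrix(values=values, columns=tuple(columns), mask=mask)


def write_track_tsv(track: BasePredictionTrack, sequence: str, path: str | Path) -> None:
    """Per-predictor track TSV: 0-based index, residue letter, value."""
    if track.values is None or len(track.values) != len(sequence):
        raise ValueError(f"{track.predictor_id}: track does not match the sequence")
    pd.DataFrame(
        {"index": np.arange(len(sequence)), "residue": list(sequence), "value": track.values}
    ).to_csv(path, sep="\t", index=False)


def read_track_tsv(path: str | Path, predictor_id: str, kind: str | None = None) -> BasePredictionTrack:
    df = pd.read_csv(path, sep="\t").sort_values("index")
    if kind is None:
        kind = PREDICTOR_REGISTRY.get(predictor_id, "scoring")
    return BasePredictionTrack(
        predictor_id=predictor_id, kind=kind, values=df["value"].to_numpy()
    )


def read_fasta_sequence(path: str | Path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return str(records[0].seq)
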