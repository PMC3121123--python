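"""Fixed-width per-residue text report of base and meta predictions.

Each 60-residue block shows the sequence with a 1-based position ruler and
one symbol line per method: "+" marks a base predictor's positive call, "*"
the meta-predictor's, and "-" a negative call.  The layout is deterministic
and loss-lessly parseable back into call tracks.
"""

from __future__ import annotations

import numpy as np

__all__ = ["render_report", "parse_report", "META_TRACK"]

META_TRACK = "meta"
_WIDTH = 60


def render_report(sequence: str, call_tracks: dict, meta_id: str = META_TRACK) -> str:
    """Format call tracks under the sequence in 60-column blocks.

    ``call_tracks`` maps method name -> per-residue binary calls (1/0), all
    the same length as ``sequence``; the ``meta_id`` track renders "*" for
    positives, every other track "+".
    """
    tracks = {}
    for name, calls in call_tracks.items():
        arr = np.asarray(calls).astype(int)
        if arr.shape != (len(sequence),):
            raise ValueError(
                f"track {name!r} has {arr.size} calls for a {len(sequence)}-residue sequence"
            )
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"track {name!r}: calls must be 1/0")
        tracks[name] = arr
    label_w = max(8, *(len(n) for n in tracks)) if tracks else 8

    blocks = []
    for start in range(0, len(sequence), _WIDTH):
        chunk = sequence[start : start + _WIDTH]
        lines = [f"{'sequence':>{label_w}} {start + 1:>6} {chunk}"]
        for name, arr in tracks.items():
            positive = "*" if name == meta_id else "+"
            symbols = "".join(
                positive if c else "-" for c in arr[start : start + _WIDTH]
            )
            lines.append(f"{name:>{label_w}} {'':6} {symbols}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def parse_report(text: str) -> tuple[str, dict]:
    """Invert :func:`render_report`: recover the sequence and call tracks."""
    sequence_parts: list[str] = []
    tracks: dict[str, list[int]] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        tokens = line.split()
        if tokens[0] == "sequence":
            sequence_parts.append(tokens[2])
            continue
        name, symbols = tokens[0], tokens[1]
        bad = set(symbols) - set("+*-")
        if bad:
            raise ValueError(f"track {name!r}: unexpected symbols {sorted(bad)}")
        tracks.setdefault(name, []).extend(0 if s == "-" else 1 for s in symbols)
    return "".join(sequence_parts), {k: np.array(v) for k, v in tracks.items()}
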