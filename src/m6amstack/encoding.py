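"""Numeric encodings of sequence windows.

Three per-position channel sets are supported and freely concatenable:

* one-hot — A=(1,0,0,0), C=(0,1,0,0), G=(0,0,1,0), U=(0,0,0,1);
* NCP (nucleotide chemical properties) — three binary channels: ring
  structure (purine A/G = 1), functional group (amino A/C = 1) and
  hydrogen-bond strength (strong A/U = 1);
* ND (nucleotide density) — the running frequency d_i = n/i of the base at
  position i within the prefix 1..i.

The pad symbol 'N' (lenient alphabet policy) encodes as an all-zero row in
every channel set and is excluded from ND prefix counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_io import LabeledDataset, SiteWindow

__all__ = [
    "EncodingMatrix", "EncodingError",
    "one_hot_encode", "ncp_encode", "nd_encode", "combined_ncp_nd",
    "concat_encodings", "flatten", "encode_windows", "encode_dataset",
    "ENCODERS",
]

_ONE_HOT = {
    "A": (1.0, 0.0, 0.0, 0.0),
    "C": (0.0, 1.0, 0.0, 0.0),
    "G": (0.0, 0.0, 1.0, 0.0),
    "U": (0.0, 0.0, 0.0, 1.0),
    "N": (0.0, 0.0, 0.0, 0.0),
}

# (ring, amino, hydrogen-bond) class membership per base
_NCP = {
    "A": (1.0, 1.0, 1.0),
    "C": (0.0, 1.0, 0.0),
    "G": (1.0, 0.0, 0.0),
    "U": (0.0, 0.0, 1.0),
    "N": (0.0, 0.0, 0.0),
}


class EncodingError(ValueError):
    pass


@dataclass(frozen=True)
class EncodingMatrix:
    values: np.ndarray            # (L, C) float64
    channel_names: tuple[str, ...]

    def __post_init__(self):
        if self.values.ndim != 2:
            raise EncodingError("EncodingMatrix must be 2-D")
        if self.values.shape[1] != len(self.channel_names):
            raise EncodingError("channel_names length must match columns")

    @property
    def window_length(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def _sequence_of(window: SiteWindow | str) -> str:
    return window.window if isinstance(window, SiteWindow) else window


def _rows(seq: str, table: dict) -> np.ndarray:
    try:
        return np.array([table[b] for b in seq], dtype=float)
    except KeyError as exc:
        raise EncodingError(f"cannot encode symbol {exc.args[0]!r}") from None


def one_hot_encode(window: SiteWindow | str) -> EncodingMatrix:
    seq = _sequence_of(window)
    return EncodingMatrix(_rows(seq, _ONE_HOT), ("A", "C", "G", "U"))


def ncp_encode(window: SiteWindow | str) -> EncodingMatrix:
    seq = _sequence_of(window)
    return EncodingMatrix(_rows(seq, _NCP), ("ring", "amino", "hbond"))


def nd_encode(window: SiteWindow | str) -> EncodingMatrix:
    """Cumulative density of the base at each position within its prefix.

    Densities are computed over the literal symbols of the input, so 'T'
    (tolerated here, unlike the other encoders) is counted separately from
    'U' — this is how the published worked example treats it.  Pipeline
    windows are T->U normalized before they reach any encoder.
    """
    seq = _sequence_of(window)
    if set(seq) - set(_ONE_HOT) - {"T"}:
        raise EncodingError(
            f"cannot encode symbols {set(seq) - set(_ONE_HOT) - {'T'}}")
    counts: dict[str, int] = {}
    values = np.zeros((len(seq), 1), dtype=float)
    for i, base in enumerate(seq, start=1):
        if base == "N":
            continue  # pad positions stay 0 and do not count
        counts[base] = counts.get(base, 0) + 1
        values[i - 1, 0] = counts[base] / i
    return EncodingMatrix(values, ("density",))


def combined_ncp_nd(window: SiteWindow | str) -> EncodingMatrix:
    return concat_encodings([ncp_encode(window), nd_encode(window)])


def concat_encodings(matrices: list[EncodingMatrix]) -> EncodingMatrix:
    lengths = {m.window_length for m in matrices}
    if len(lengths) > 1:
        raise EncodingError(f"mismatched window lengths: {sorted(lengths)}")
    return EncodingMatrix(
        np.concatenate([m.values for m in matrices], axis=1),
        tuple(name for m in matrices for name in m.channel_names))


def flatten(matrix: EncodingMatrix) -> np.ndarray:
    """Row-major flattening; ``values.reshape(L, C)`` inverts it."""
    return matrix.values.reshape(-1)


def _onehot_ncp_nd(window):
    return concat_encodings([one_hot_encode(window), combined_ncp_nd(window)])


ENCODERS = {
    "onehot": one_hot_encode,
    "ncp_nd": combined_ncp_nd,
    "onehot_ncp_nd": _onehot_ncp_nd,
}


def encode_windows(windows, scheme: str = "onehot") -> np.ndarray:
    """Stack encodings of many windows into an (n, L, C) array."""
    try:
        encoder = ENCODERS[scheme]
    except KeyError:
        raise EncodingError(
            f"unknown encoding {scheme!r}; choose from {sorted(ENCODERS)}")
    mats = [encoder(w).values for w in windows]
    return np.stack(mats).astype(np.float32)


def encode_dataset(dataset: LabeledDataset, scheme: str = "onehot"
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Encode all windows and return (X, y) with y in {0, 1}."""
    X = encode_windows(dataset.sequences(), scheme)
    y = np.asarray(dataset.labels(), dtype=np.int64)
    return X, y
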