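"""Feature encodings for DNA windows: k-mer composition, EIIP, multifeature.

Two complementary encodings drive the predictor:

* **Kmer** — overlapping k-nucleotide frequencies.  For k-mer X in a window
  of length L, the feature value is f(X) = F(X) / (L - k + 1), F(X) the
  overlapping occurrence count.  Each k-block therefore sums to 1.  Run over
  k = 1..5 this yields sum_k 4^k = 1364 compositional features.
* **EIIP** — electron-ion interaction pseudopotential, a fixed scalar per
  nucleotide (A 0.1260, C 0.1340, G 0.0806, T 0.1335) substituted position
  by position, giving L positional features (41 for the standard window).

The **multifeature** concatenates [Kmer k=1..5 | EIIP] for 1364 + L = 1405
features on a 41-nt window.  Column order within each k-block is
lexicographic over A < C < G < T and is written to a column manifest so that
fitted models are portable.  No scaling is applied by the encoders.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Optional, Protocol, Sequence

import numpy as np

from .sequence_io import SequenceWindow, WindowSet

#: per-nucleotide electron-ion interaction pseudopotential values
EIIP_VALUES = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "T": 0.1335}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


@dataclass(frozen=True)
class FeatureVector:
    """Dense numeric vector tagged with its scheme name and column order."""

    values: np.ndarray
    scheme: str
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("FeatureVector values must be 1-D")
        if len(self.columns) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.columns)} column names for {self.values.shape[0]} values"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature value")

    @property
    def dim(self) -> int:
        return int(self.values.shape[0])


def kmer_columns(k: int) -> tuple[str, ...]:
    """All 4^k k-mers in lexicographic order over A < C < G < T."""
    return tuple("".join(p) for p in product(_BASES, repeat=k))


def _seq_to_codes(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGT symbol {exc.args[0]!r} in sequence") from None


def encode_kmer(w: SequenceWindow, k: int) -> FeatureVector:
    """Overlapping k-mer frequency vector of length 4^k.

    Entries are F(X)/(L-k+1) in lexicographic k-mer order and sum to 1.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    L = len(w.seq)
    if k > L:
        raise ValueError(f"k={k} exceeds sequence length {L}")
    codes = _seq_to_codes(w.seq)
    # rolling base-4 index of each overlapping k-mer
    idx = np.zeros(L - k + 1, dtype=np.int64)
    for j in range(k):
        idx = idx * 4 + codes[j: L - k + 1 + j]
    counts = np.bincount(idx, minlength=4 ** k).astype(float)
    return FeatureVector(counts / (L - k + 1), f"kmer{k}", kmer_columns(k))


def encode_kmer_multi(
    w: SequenceWindow, ks: Sequence[int] = (1, 2, 3, 4, 5)
) -> FeatureVector:
    """Concatenated k-mer blocks in ascending k (1364-dim for k = 1..5)."""
    if len(ks) == 0:
        raise ValueError("ks must be non-empty")
    ks = sorted(ks)
    parts = [encode_kmer(w, k) for k in ks]
    values = np.concatenate([p.values for p in parts])
    columns = tuple(c for p in parts for c in p.columns)
    return FeatureVector(values, "kmer_multi", columns)


def encode_eiip(w: SequenceWindow) -> FeatureVector:
    """Per-position EIIP lookup: position i carries the scalar of nucleotide i."""
    try:
        values = np.array([EIIP_VALUES[b] for b in w.seq], dtype=float)
    except KeyError as exc:
        raise ValueError(f"non-ACGT symbol {exc.args[0]!r} in sequence") from None
    columns = tuple(f"eiip_{i + 1}" for i in range(len(w.seq)))
    return FeatureVector(values, "eiip", columns)


def encode_multifeature(w: SequenceWindow) -> FeatureVector:
    """[Kmer k=1..5 | EIIP] concatenation; 1405-dim on a 41-nt window."""
    km = encode_kmer_multi(w)
    ei = encode_eiip(w)
    return FeatureVector(
        np.concatenate([km.values, ei.values]),
        "multifeature",
        km.columns + ei.columns,
    )


class EncodingScheme(Protocol):
    """Contract every encoder plug-in satisfies: deterministic, fixed column order."""

    name: str

    def dim(self, L: int) -> int: ...

    def encode(self, w: SequenceWindow) -> FeatureVector: ...


@dataclass(frozen=True)
class KmerScheme:
    k: int = 2
    name: str = "kmer"

    def dim(self, L: int) -> int:
        return 4 ** self.k

    def encode(self, w: SequenceWindow) -> FeatureVector:
        return encode_kmer(w, self.k)


@dataclass(frozen=True)
class KmerMultiScheme:
    ks: tuple[int, ...] = (1, 2, 3, 4, 5)
    name: str = "kmer_multi"

    def dim(self, L: int) -> int:
        return sum(4 ** k for k in self.ks)

    def encode(self, w: SequenceWindow) -> FeatureVector:
        return encode_kmer_multi(w, self.ks)


@dataclass(frozen=True)
class EIIPScheme:
    name: str = "eiip"

    def dim(self, L: int) -> int:
        return L

    def encode(self, w: SequenceWindow) -> FeatureVector:
        return encode_eiip(w)


@dataclass(frozen=True)
class MultiFeatureScheme:
    name: str = "multifeature"

    def dim(self, L: int) -> int:
        return 1364 + L

    def encode(self, w: SequenceWindow) -> FeatureVector:
        return encode_multifeature(w)


_SCHEMES = {
    "kmer": KmerScheme,
    "kmer_multi": KmerMultiScheme,
    "eiip": EIIPScheme,
    "multifeature": MultiFeatureScheme,
}


def get_scheme(name: str, **params) -> EncodingScheme:
    """Look up an encoding scheme by name (extension point for plug-ins)."""
    if name not in _SCHEMES:
        raise KeyError(
            f"unknown encoding scheme {name!r}; known: {sorted(_SCHEMES)}"
        )
    return _SCHEMES[name](**params)


def register_scheme(name: str, factory) -> None:
    """Register a third-party EncodingScheme factory under ``name``."""
    _SCHEMES[name] = factory


def encode_set(
    ws: WindowSet, scheme: EncodingScheme
) -> tuple[np.ndarray, Optional[np.ndarray], tuple[str, ...]]:
    """Encode a WindowSet into an (n, dim) matrix plus aligned labels.

    Returns ``(X, y, columns)`` where ``y`` is ``None`` for unlabelled sets.
    Rows follow WindowSet order; the column manifest names every feature.
    """
    if len(ws) == 0:
        raise ValueError("cannot encode an empty WindowSet")
    first = scheme.encode(ws[0])
    X = np.empty((len(ws), first.dim), dtype=float)
    X[0] = first.values
    for i, w in enumerate(ws.windows[1:], start=1):
        fv = scheme.encode(w)
        if fv.dim != first.dim:
            raise ValueError(
                f"window {w.id!r} encodes to dim {fv.dim}, expected {first.dim} "
                "(mixed window lengths?)"
            )
        X[i] = fv.values
    labels = ws.labels
    y = np.asarray(labels, dtype=int) if labels is not None else None
    return X, y, first.columns


def write_feature_matrix(
    path: str | Path,
    X: np.ndarray,
    columns: Sequence[str],
    ids: Optional[Sequence[str]] = None,
) -> None:
    """Export a feature matrix as TSV with the column manifest as header."""
    import pandas as pd

    df = pd.DataFrame(np.asarray(X, dtype=float), columns=list(columns))
    if ids is not None:
        df.insert(0, "id", list(ids))
    # repr-based float formatting keeps the round-trip bit-exact
    df.to_csv(path, sep="\t", index=False, float_format=lambda v: repr(float(v)))


def read_feature_matrix(
    path: str | Path,
) -> tuple[np.ndarray, tuple[str, ...], Optional[list[str]]]:
    """Read a TSV feature matrix; returns (X, columns, ids-or-None)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    ids = None
    if df.columns[0] == "id":
        ids = df["id"].astype(str).tolist()
        df = df.drop(columns="id")
    return df.to_numpy(dtype=float), tuple(df.columns), ids
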