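"""Reading, writing and validating fixed-length DNA windows.

The predictor operates on fixed-length windows (default 41 nt) centred on a
candidate cytosine.  Windows arrive as FASTA, either one file per class
(positives = 4mC, negatives = non-4mC) or with a two-column ``id<TAB>label``
sidecar.  All coordinates in messages and ids are 1-based, inclusive; the
middle of a 41-mer is position 21.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGT")

#: default flank size either side of the candidate cytosine (window = 2*20+1)
DEFAULT_FLANK = 20
DEFAULT_WINDOW_LENGTH = 2 * DEFAULT_FLANK + 1


class WindowValidationError(ValueError):
    """A sequence record violates the window convention or alphabet."""


@dataclass(frozen=True)
class SequenceWindow:
    """One fixed-length DNA window with an optional binary label.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header word).
    seq : str
        Upper-case sequence over ``{A, C, G, T}``.
    label : int, optional
        1 for a methylated (4mC) window, 0 for an unmethylated one,
        ``None`` when unknown.
    """

    id: str
    seq: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if self.label is not None and self.label not in (0, 1):
            raise WindowValidationError(
                f"record {self.id!r}: label must be 0 or 1, got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def centre(self) -> str:
        """Nucleotide at the central (1-based position (L+1)/2) site."""
        return self.seq[len(self.seq) // 2]

    def validate(self, check_convention: bool = True,
                 length: int = DEFAULT_WINDOW_LENGTH) -> None:
        """Raise :class:`WindowValidationError` on alphabet or convention violations."""
        bad = set(self.seq) - ALPHABET
        if bad:
            raise WindowValidationError(
                f"record {self.id!r}: non-ACGT symbol(s) {sorted(bad)}"
            )
        if check_convention:
            if len(self.seq) != length:
                raise WindowValidationError(
                    f"record {self.id!r}: length {len(self.seq)} != {length}"
                )
            if self.centre != "C":
                raise WindowValidationError(
                    f"record {self.id!r}: centre position "
                    f"{len(self.seq) // 2 + 1} is {self.centre!r}, expected 'C'"
                )


@dataclass
class WindowSet:
    """Ordered collection of equal-length windows (file order preserved)."""

    windows: list[SequenceWindow] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(w) for w in self.windows}
        if len(lengths) > 1:
            raise WindowValidationError(
                f"mixed window lengths {sorted(lengths)} in one set"
            )

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[SequenceWindow]:
        return iter(self.windows)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return WindowSet(self.windows[i])
        return self.windows[i]

    @property
    def length(self) -> int:
        """Common window length L (0 for an empty set)."""
        return len(self.windows[0]) if self.windows else 0

    @property
    def ids(self) -> list[str]:
        return [w.id for w in self.windows]

    @property
    def labels(self) -> Optional[list[int]]:
        """Label vector in set order, or None if any window is unlabelled."""
        if any(w.label is None for w in self.windows):
            return None
        return [w.label for w in self.windows]

    def is_labelled(self) -> bool:
        return bool(self.windows) and all(w.label is not None for w in self.windows)

    @classmethod
    def concatenate(cls, sets: Iterable["WindowSet"]) -> "WindowSet":
        out: list[SequenceWindow] = []
        for s in sets:
            out.extend(s.windows)
        return cls(out)


def _read_sidecar(path: Path) -> dict[str, int]:
    mapping: dict[str, int] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise WindowValidationError(
                f"{path}:{lineno}: expected 'id<TAB>label', got {line!r}"
            )
        rec_id, lab = parts[0].strip(), parts[1].strip()
        if lab not in ("0", "1"):
            raise WindowValidationError(
                f"{path}:{lineno}: label must be 0 or 1, got {lab!r}"
            )
        mapping[rec_id] = int(lab)
    return mapping


def read_windows(
    fasta_path: str | Path,
    label: Optional[int] = None,
    sidecar: Optional[str | Path] = None,
    policy: str = "strict",
    check_convention: bool = True,
    length: int = DEFAULT_WINDOW_LENGTH,
) -> WindowSet:
    """Read a FASTA file into a :class:`WindowSet`.

    Parameters
    ----------
    fasta_path
        Multi-record FASTA (wrapped or unwrapped lines).
    label
        Per-file label applied to every record (how the benchmark ships:
        one file of positives, one of negatives).  Mutually exclusive with
        ``sidecar``.
    sidecar
        Path to an ``id<TAB>label`` TSV; every FASTA record id must appear.
    policy
        ``"strict"`` — any invalid record aborts the read;
        ``"drop"`` — invalid records are excluded and logged.
    check_convention
        Enforce length ``length`` with a central ``C``.  Turn off to use
        the encoders on other window geometries.
    """
    fasta_path = Path(fasta_path)
    if policy not in ("strict", "drop"):
        raise ValueError(f"policy must be 'strict' or 'drop', got {policy!r}")
    if label is not None and sidecar is not None:
        raise ValueError("give either a per-file label or a sidecar, not both")

    sidecar_map = _read_sidecar(Path(sidecar)) if sidecar is not None else None

    accepted: list[SequenceWindow] = []
    rejected = 0
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        rec_label = label
        if sidecar_map is not None:
            if record.id not in sidecar_map:
                raise WindowValidationError(
                    f"record {record.id!r} missing from sidecar {sidecar}"
                )
            rec_label = sidecar_map[record.id]
        window = SequenceWindow(id=record.id, seq=str(record.seq), label=rec_label)
        try:
            window.validate(check_convention=check_convention, length=length)
        except WindowValidationError as exc:
            if policy == "strict":
                raise
            rejected += 1
            logger.warning("dropped %s", exc)
            continue
        accepted.append(window)
    logger.info(
        "%s: accepted %d record(s), rejected %d", fasta_path.name, len(accepted), rejected
    )
    if not accepted and rejected == 0:
        raise WindowValidationError(f"{fasta_path}: no FASTA records parsed")
    return WindowSet(accepted)


def write_windows(ws: WindowSet, fasta_path: str | Path) -> None:
    """Write a WindowSet as FASTA; round-trips ids, sequences and order exactly."""
    if len(ws) == 0:
        raise ValueError("refusing to write an empty WindowSet")
    records = [
        SeqRecord(Seq(w.seq), id=w.id, description="") for w in ws
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


def write_sidecar(ws: WindowSet, tsv_path: str | Path) -> None:
    """Write the ``id<TAB>label`` sidecar for a labelled WindowSet."""
    if not ws.is_labelled():
        raise ValueError("WindowSet is not fully labelled")
    with open(tsv_path, "w") as fh:
        for w in ws:
            fh.write(f"{w.id}\t{w.label}\n")


def extract_candidate_windows(
    seq: str, flank: int = DEFAULT_FLANK, source_id: str = "seq"
) -> WindowSet:
    """Extract every candidate window from a longer sequence.

    One unlabelled window per ``C`` at an interior position (1-based
    positions ``flank+1 .. len(seq)-flank``), each of length ``2*flank+1``
    centred on that cytosine.  Ids encode the 1-based source position as
    ``<source_id>:c<pos>``.
    """
    seq = seq.upper()
    if len(seq) < 2 * flank + 1:
        raise ValueError(
            f"sequence length {len(seq)} < window length {2 * flank + 1}"
        )
    out = []
    for i in range(flank, len(seq) - flank):  # 0-based centre candidates
        if seq[i] == "C":
            out.append(
                SequenceWindow(
                    id=f"{source_id}:c{i + 1}",
                    seq=seq[i - flank: i + flank + 1],
                )
            )
    return WindowSet(out)
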