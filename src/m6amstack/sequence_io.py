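"""Sequence I/O: FASTA reading/writing, alphabet normalization and
extraction of labeled fixed-length windows centered on candidate adenosines.

Coordinates are 1-based throughout; a window with half-width ``delta`` spans
the fully closed interval [center - delta, center + delta] and therefore has
length 2*delta + 1.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlphabetPolicy", "PadPolicy", "RnaRecord", "SiteWindow", "LabeledDataset",
    "ParseError", "ValidationError",
    "normalize_sequence", "read_fasta", "write_fasta", "extract_window",
    "find_candidate_centers", "load_labeled_dataset", "write_labeled_dataset",
]

RNA_ALPHABET = frozenset("ACGU")
PAD_SYMBOL = "N"  # encodes as all-zero rows under the lenient policy


class ParseError(ValueError):
    pass


class ValidationError(ValueError):
    pass


class AlphabetPolicy(str, enum.Enum):
    STRICT = "strict"      # reject anything outside {A,C,G,U} after T->U
    LENIENT = "lenient"    # replace unknown symbols with the pad symbol


class PadPolicy(str, enum.Enum):
    REJECT = "reject"      # windows running off the sequence raise
    PAD = "pad"            # out-of-range positions filled with PAD_SYMBOL


class Label(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNLABELED = "unlabeled"


def normalize_sequence(seq: str,
                       policy: AlphabetPolicy = AlphabetPolicy.STRICT,
                       context: str = "sequence") -> str:
    """Uppercase, map T->U, and apply the alphabet policy."""
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET - {PAD_SYMBOL}
    if bad:
        if policy == AlphabetPolicy.STRICT:
            raise ValidationError(
                f"{context}: disallowed characters {sorted(bad)} under strict policy")
        table = str.maketrans({c: PAD_SYMBOL for c in bad})
        seq = seq.translate(table)
    return seq


@dataclass(frozen=True)
class RnaRecord:
    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteWindow:
    source_id: str
    center_position: int        # 1-based position of the center in the source
    delta: int
    window: str
    label: Label = Label.UNLABELED

    def __post_init__(self):
        if len(self.window) != 2 * self.delta + 1:
            raise ValidationError(
                f"window length {len(self.window)} != 2*{self.delta}+1")

    @property
    def center_base(self) -> str:
        return self.window[self.delta]


@dataclass
class LabeledDataset:
    windows: list[SiteWindow] = field(default_factory=list)

    def __post_init__(self):
        deltas = {w.delta for w in self.windows}
        if len(deltas) > 1:
            raise ValidationError(f"mixed deltas in dataset: {sorted(deltas)}")

    @property
    def delta(self) -> int:
        return self.windows[0].delta if self.windows else 0

    @property
    def n_pos(self) -> int:
        return sum(w.label == Label.POSITIVE for w in self.windows)

    @property
    def n_neg(self) -> int:
        return sum(w.label == Label.NEGATIVE for w in self.windows)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset([self.windows[i] for i in indices])

    def labels(self) -> list[int]:
        return [1 if w.label == Label.POSITIVE else 0 for w in self.windows]

    def sequences(self) -> list[str]:
        return [w.window for w in self.windows]


# ---------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------

def read_fasta(path: str | Path,
               alphabet_policy: AlphabetPolicy = AlphabetPolicy.STRICT
               ) -> list[RnaRecord]:
    """Read a FASTA file into normalized RNA records, preserving file order."""
    path = Path(path)
    records: list[RnaRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        seq = normalize_sequence(str(rec.seq), alphabet_policy,
                                 context=f"{path}:{rec.id}")
        records.append(RnaRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[RnaRecord], path: str | Path) -> None:
    bio = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(Path(path)), "fasta")


# ---------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------

def extract_window(record: RnaRecord, center: int, delta: int,
                   pad_policy: PadPolicy = PadPolicy.REJECT,
                   require_center_a: bool = True,
                   label: Label = Label.UNLABELED) -> SiteWindow:
    """Cut the closed window [center-delta, center+delta] around `center`."""
    if not 1 <= center <= record.length:
        raise IndexError(
            f"center {center} out of range 1..{record.length} for {record.id}")
    if require_center_a and record.sequence[center - 1] != "A":
        raise ValidationError(
            f"{record.id}: position {center} is "
            f"{record.sequence[center - 1]!r}, not 'A'")
    lo = center - delta - 1  # 0-based inclusive
    hi = center + delta      # 0-based exclusive
    if lo < 0 or hi > record.length:
        if pad_policy == PadPolicy.REJECT:
            raise IndexError(
                f"{record.id}: window [{center - delta}, {center + delta}] "
                f"exceeds sequence of length {record.length}")
        left_pad = max(0, -lo)
        right_pad = max(0, hi - record.length)
        core = record.sequence[max(lo, 0):min(hi, record.length)]
        window = PAD_SYMBOL * left_pad + core + PAD_SYMBOL * right_pad
    else:
        window = record.sequence[lo:hi]
    return SiteWindow(source_id=record.id, center_position=center,
                      delta=delta, window=window, label=label)


def find_candidate_centers(record: RnaRecord,
                           require_motif: bool = False) -> list[int]:
    """1-based positions of candidate adenosines.

    With ``require_motif`` the A must close a B-C-A context (B in {C,G,U})
    on the two positions immediately upstream.  The exact motif geometry is
    not standardized, so this filter is optional and off by default.
    """
    centers = []
    seq = record.sequence
    for i, base in enumerate(seq, start=1):
        if base != "A":
            continue
        if require_motif:
            if i < 3:
                continue
            b, c = seq[i - 3], seq[i - 2]
            if b not in "CGU" or c != "C":
                continue
        centers.append(i)
    return centers


# ---------------------------------------------------------------------
# labeled-dataset loading (FASTA with pos/neg header tokens, or a
# delimited sequence,label table)
# ---------------------------------------------------------------------

_POS_TOKENS = {"pos", "positive", "1"}
_NEG_TOKENS = {"neg", "negative", "0"}


def _label_from_token(token: str) -> Label:
    t = token.strip().lower()
    if t in _POS_TOKENS:
        return Label.POSITIVE
    if t in _NEG_TOKENS:
        return Label.NEGATIVE
    raise ParseError(f"cannot interpret label token {token!r}")


def _window_from_seq(seq: str, label: Label, idx: int, source_id: str,
                     policy: AlphabetPolicy) -> SiteWindow:
    seq = normalize_sequence(seq, policy, context=source_id)
    if len(seq) % 2 == 0:
        raise ParseError(
            f"{source_id}: window length {len(seq)} is even; expected 2*delta+1")
    delta = (len(seq) - 1) // 2
    return SiteWindow(source_id=source_id, center_position=delta + 1,
                      delta=delta, window=seq, label=label)


def load_labeled_dataset(path: str | Path,
                         alphabet_policy: AlphabetPolicy = AlphabetPolicy.STRICT
                         ) -> LabeledDataset:
    """Load labeled windows, sniffing the dialect.

    Accepted dialects: FASTA whose headers carry a pos/neg token separated
    by ``|``, ``_`` or whitespace; or a delimited (TSV/CSV) table with
    columns ``sequence`` and ``label`` (header row required).
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    if head.startswith(">"):
        windows = []
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            header = rec.id.replace("|", " ").replace("_", " ")
            tokens = header.split() + rec.description.split()
            label = None
            for tok in tokens:
                try:
                    label = _label_from_token(tok)
                    break
                except ParseError:
                    continue
            if label is None:
                raise ParseError(
                    f"{path}: header {rec.id!r} carries no pos/neg token")
            windows.append(_window_from_seq(str(rec.seq), label, i, rec.id,
                                            alphabet_policy))
        return LabeledDataset(windows)

    delimiter = "\t" if "\t" in head else ","
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty table")
        cols = {c.strip().lower(): c for c in reader.fieldnames}
        if "sequence" not in cols or "label" not in cols:
            raise ParseError(
                f"{path}: expected 'sequence' and 'label' columns, "
                f"got {reader.fieldnames}")
        windows = []
        for i, row in enumerate(reader):
            label = _label_from_token(row[cols["label"]])
            windows.append(_window_from_seq(row[cols["sequence"]], label,
                                            i, f"{path.name}:{i + 2}",
                                            alphabet_policy))
    return LabeledDataset(windows)


def write_labeled_dataset(dataset: LabeledDataset, path: str | Path) -> None:
    """Write windows as a TSV table (sequence, label)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["sequence", "label"])
        for w in dataset.windows:
            tok = {Label.POSITIVE: "pos", Label.NEGATIVE: "neg",
                   Label.UNLABELED: "unlabeled"}[w.label]
            writer.writerow([w.window, tok])
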