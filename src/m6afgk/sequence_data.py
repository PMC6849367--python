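"""Fixed-length RNA site windows: I/O, validation, and synthetic corpora.

The unit of data is a *site window*: a fixed-length RNA sequence (51 nt by
default) centered on an adenosine, labelled 1 if the central A carries the
m6A modification and 0 otherwise.  DNA input is accepted and converted to
RNA (T -> U).  The synthetic generator emulates the published yeast
benchmark layout — balanced classes, fixed odd window length, central A in
every window — and plants a gapped consensus motif (GAC-containing by
default) in positives so the downstream miner and classifier have a known
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    CentralSiteError,
    ConfigurationError,
    InvalidAlphabetError,
    LengthError,
)

RNA_ALPHABET = ("A", "C", "G", "U")
DEFAULT_WINDOW_LENGTH = 51

_NORMALIZE = str.maketrans("acgutT", "ACGUUU")
_VALID = frozenset("ACGU")


def normalize_sequence(raw: str) -> str:
    """Uppercase, map T->U, and reject anything outside {A,C,G,U,T}.

    Raises :class:`InvalidAlphabetError` naming the 0-based position of the
    first offending character (ambiguity codes such as N are not allowed in
    input windows; the wildcard N exists only in patterns).
    """
    if not raw:
        raise InvalidAlphabetError("empty sequence")
    seq = raw.translate(_NORMALIZE)
    for i, ch in enumerate(seq):
        if ch not in _VALID:
            raise InvalidAlphabetError(
                f"invalid character {raw[i]!r} at position {i}"
            )
    return seq


@dataclass(frozen=True)
class SampleRecord:
    """One labelled site window."""

    id: str
    sequence: str
    label: int

    def validate(self, window_length: int, enforce_central_a: bool = True) -> None:
        if len(self.sequence) != window_length:
            raise LengthError(
                f"record {self.id!r}: length {len(self.sequence)} != "
                f"window length {window_length}"
            )
        if enforce_central_a:
            center = (window_length - 1) // 2
            if self.sequence[center] != "A":
                raise CentralSiteError(
                    f"record {self.id!r}: central base "
                    f"{self.sequence[center]!r} is not A"
                )


def read_fasta(path: str | Path, label: int, window_length: int = DEFAULT_WINDOW_LENGTH,
               enforce_central_a: bool = True) -> list[SampleRecord]:
    """Read one FASTA file of site windows, all given the same label."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        sample = SampleRecord(rec.id, normalize_sequence(str(rec.seq)), label)
        sample.validate(window_length, enforce_central_a)
        records.append(sample)
    return records


def read_labeled_fasta(pos_path: str | Path, neg_path: str | Path,
                       window_length: int = DEFAULT_WINDOW_LENGTH,
                       enforce_central_a: bool = True) -> list[SampleRecord]:
    """Read a positive and a negative FASTA file into one labelled corpus.

    Order is preserved: positives (label 1) first, then negatives (label 0).
    """
    return (read_fasta(pos_path, 1, window_length, enforce_central_a)
            + read_fasta(neg_path, 0, window_length, enforce_central_a))


def write_fasta(records: Iterable[SampleRecord], path: str | Path) -> None:
    """Write records as single-line FASTA."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta-2line")


def write_manifest(records: Iterable[SampleRecord], path: str | Path) -> None:
    """Write the corpus manifest as TSV: id, label, sequence."""
    with open(path, "w") as fh:
        fh.write("id\tlabel\tsequence\n")
        for r in records:
            fh.write(f"{r.id}\t{r.label}\t{r.sequence}\n")


def read_manifest(path: str | Path,
                  window_length: int | None = None,
                  enforce_central_a: bool = True) -> list[SampleRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["id", "label", "sequence"]:
            raise ConfigurationError(f"unrecognized manifest header: {header}")
        for line in fh:
            rid, label, seq = line.rstrip("\n").split("\t")
            rec = SampleRecord(rid, normalize_sequence(seq), int(label))
            if window_length is not None:
                rec.validate(window_length, enforce_central_a)
            records.append(rec)
    return records


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the motif-planting corpus generator.

    ``motif`` is a gapped-pattern string over {A,C,G,U,N}; at plant time each
    N is filled with a base drawn from ``background_composition``, so the
    planted instances share the matched positions but vary in the gaps.
    ``plant_rate`` is the per-positive probability of receiving one planted
    instance; negatives never receive one.
    """

    n_pos: int
    n_neg: int
    window_length: int = DEFAULT_WINDOW_LENGTH
    motif: str = "GGACU"
    plant_rate: float = 0.9
    background_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ConfigurationError("sample counts must be non-negative")
        if self.window_length < 1 or self.window_length % 2 == 0:
            raise ConfigurationError("window_length must be odd and positive")
        if not 0.0 <= self.plant_rate <= 1.0:
            raise ConfigurationError("plant_rate must be in [0, 1]")
        comp = self.background_composition
        if len(comp) != 4 or any(p < 0 for p in comp):
            raise ConfigurationError("background_composition needs 4 non-negative entries")
        if abs(sum(comp) - 1.0) > 1e-9:
            raise ConfigurationError("background_composition must sum to 1")
        if len(self.motif) > self.window_length:
            raise ConfigurationError("motif span exceeds window length")
        bad = set(self.motif) - set("ACGUN")
        if bad or not self.motif or self.motif[0] == "N" or self.motif[-1] == "N":
            raise ConfigurationError(f"motif must be a gapped pattern over ACGUN: {self.motif!r}")


def _valid_offsets(motif: str, window_length: int) -> list[int]:
    # an offset is valid unless it would overwrite the central A with a
    # non-A pattern character (N does not count: it is filled randomly)
    center = (window_length - 1) // 2
    offsets = []
    for t in range(window_length - len(motif) + 1):
        rel = center - t
        if 0 <= rel < len(motif) and motif[rel] != "A":
            continue
        offsets.append(t)
    return offsets


def generate_corpus(config: SyntheticConfig) -> list[SampleRecord]:
    """Generate a balanced-by-construction labelled synthetic corpus.

    Every window is i.i.d. background with the central base forced to A;
    each positive additionally receives, with probability ``plant_rate``,
    one motif instantiation at a uniformly chosen valid offset.  Identical
    configs (including seed) give byte-identical corpora.
    """
    rng = np.random.default_rng(config.seed)
    center = (config.window_length - 1) // 2
    comp = np.asarray(config.background_composition, dtype=float)
    comp = comp / comp.sum()
    offsets = _valid_offsets(config.motif, config.window_length)
    if not offsets and config.n_pos > 0 and config.plant_rate > 0:
        raise ConfigurationError(
            "motif admits no placement compatible with the central A"
        )
    bases = np.array(list(RNA_ALPHABET))

    def draw_window() -> list[str]:
        idx = rng.choice(4, size=config.window_length, p=comp)
        w = [bases[i] for i in idx]
        w[center] = "A"
        return w

    records: list[SampleRecord] = []
    width = max(4, len(str(max(config.n_pos, config.n_neg))))
    for i in range(config.n_pos):
        w = draw_window()
        if rng.random() < config.plant_rate:
            t = offsets[rng.integers(len(offsets))]
            for j, ch in enumerate(config.motif):
                w[t + j] = bases[rng.choice(4, p=comp)] if ch == "N" else ch
            w[center] = "A"
        records.append(SampleRecord(f"pos_{i:0{width}d}", "".join(w), 1))
    for i in range(config.n_neg):
        records.append(SampleRecord(f"neg_{i:0{width}d}", "".join(draw_window()), 0))
    return records


def sequences(records: Sequence[SampleRecord]) -> list[str]:
    return [r.sequence for r in records]


def labels(records: Sequence[SampleRecord]) -> np.ndarray:
    return np.array([r.label for r in records], dtype=int)
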