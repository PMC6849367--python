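"""Frequent gapped k-mer pattern (FGKP) discovery.

A gapped k-mer is a pattern over {A,C,G,U} plus the wildcard N with exactly
``k`` matched (non-N) positions; wildcards may appear only strictly inside
the pattern, and the total span is bounded by ``max_span``.  The *support*
of a pattern in a corpus is the fraction of sequences containing at least
one occurrence (multiple occurrences in one sequence count once — the same
0/1 presence semantics the encoder uses).  Mining returns exactly the
patterns whose support reaches the threshold gamma.

Two equivalent routes are provided:

* :func:`enumerate_candidates` + :func:`support` — brute force over the
  full syntactic candidate space, used as the oracle at small k;
* :func:`mine_frequent` — a single pass that extracts, from every corpus
  sequence, the set of gapped k-mers it instantiates and tallies
  per-sequence presence.  A pattern absent from every sequence has support
  0 and can never be frequent, so the two routes agree exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigurationError, EmptyCorpusError

WILDCARD = "N"
# canonical character order: A < C < G < U < N
_ORDER = {c: i for i, c in enumerate("ACGUN")}


def canonical_key(pattern_text: str) -> tuple[int, ...]:
    """Sort key implementing lexicographic order with A<C<G<U<N."""
    return tuple(_ORDER[c] for c in pattern_text)


@dataclass(frozen=True, order=False)
class GappedKmerPattern:
    """A gapped k-mer; its canonical text is its identity."""

    text: str

    def __post_init__(self) -> None:
        t = self.text
        if not t or any(c not in _ORDER for c in t):
            raise ConfigurationError(f"invalid pattern text: {t!r}")
        if t[0] == WILDCARD or t[-1] == WILDCARD:
            raise ConfigurationError(
                f"pattern {t!r}: leading/trailing wildcard is meaningless"
            )

    @property
    def k(self) -> int:
        """Number of matched (non-wildcard) positions."""
        return len(self.text) - self.text.count(WILDCARD)

    @property
    def span(self) -> int:
        return len(self.text)

    def matches(self, sequence: str) -> bool:
        """True iff the pattern occurs at >=1 offset, N matching any base."""
        return matches(self, sequence)

    def __str__(self) -> str:  # pragma: no cover
        return self.text


def matches(pattern: GappedKmerPattern, sequence: str) -> bool:
    t = pattern.text
    span = len(t)
    if span > len(sequence):
        return False
    fixed = [(i, c) for i, c in enumerate(t) if c != WILDCARD]
    for off in range(len(sequence) - span + 1):
        if all(sequence[off + i] == c for i, c in fixed):
            return True
    return False


def support(pattern: GappedKmerPattern, corpus: Sequence[str]) -> float:
    """Presence fraction: sequences matched / corpus size."""
    if len(corpus) == 0:
        raise EmptyCorpusError("support undefined on an empty corpus")
    return sum(matches(pattern, s) for s in corpus) / len(corpus)


@lru_cache(maxsize=None)
def gap_layouts(k: int, max_span: int) -> tuple[tuple[int, ...], ...]:
    """All placements of k matched positions with first/last matched.

    A layout is the tuple of matched-position indices within the span; for
    span s there are C(s-2, k-2) layouts (one layout, (0,), when k == 1).
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if k > max_span:
        raise ConfigurationError(f"k={k} exceeds max_span={max_span}")
    if k == 1:
        return ((0,),)
    layouts = []
    for span in range(k, max_span + 1):
        for interior in itertools.combinations(range(1, span - 1), k - 2):
            layouts.append((0, *interior, span - 1))
    return tuple(layouts)


def _layout_text(layout: tuple[int, ...], chars: str) -> str:
    span = layout[-1] + 1
    out = [WILDCARD] * span
    for pos, ch in zip(layout, chars):
        out[pos] = ch
    return "".join(out)


def enumerate_candidates(k: int, max_span: int,
                         alphabet: Sequence[str] = "ACGU") -> list[GappedKmerPattern]:
    """Every syntactically valid pattern, canonically sorted, no duplicates."""
    patterns = []
    for layout in gap_layouts(k, max_span):
        for combo in itertools.product(alphabet, repeat=k):
            patterns.append(_layout_text(layout, "".join(combo)))
    patterns.sort(key=canonical_key)
    return [GappedKmerPattern(t) for t in patterns]


@dataclass(frozen=True)
class MiningConfig:
    """Mining parameters; the published best setting is k=4, gamma=0.025."""

    k: int = 4
    gamma: float = 0.025
    max_span: int | None = None  # defaults to 2k
    corpus_scope: str = "both"  # "both" classes or "positives" only

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ConfigurationError("gamma must be in (0, 1]")
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.max_span is not None and self.k > self.max_span:
            raise ConfigurationError("k exceeds max_span")
        if self.corpus_scope not in ("both", "positives"):
            raise ConfigurationError(f"unknown corpus_scope: {self.corpus_scope}")

    @property
    def effective_max_span(self) -> int:
        return 2 * self.k if self.max_span is None else self.max_span

    @staticmethod
    def from_absolute_count(k: int, min_count: int, corpus_size: int,
                            max_span: int | None = None) -> "MiningConfig":
        """Convert an absolute support count into a relative gamma."""
        if corpus_size <= 0 or min_count < 1:
            raise ConfigurationError("need corpus_size >= 1 and min_count >= 1")
        return MiningConfig(k=k, gamma=min_count / corpus_size, max_span=max_span)


@dataclass(frozen=True)
class FeatureSet:
    """The ordered frequent-pattern list defining the encoding dimensions."""

    patterns: tuple[GappedKmerPattern, ...]
    supports: tuple[float, ...] = ()
    config: MiningConfig | None = None
    corpus_fingerprint: str = ""

    def __post_init__(self) -> None:
        texts = [p.text for p in self.patterns]
        if len(set(texts)) != len(texts):
            raise ConfigurationError("duplicate patterns in feature set")

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)

    @property
    def fingerprint(self) -> str:
        """Order-sensitive identity of the pattern list."""
        import hashlib

        h = hashlib.sha256("\n".join(p.text for p in self.patterns).encode())
        return h.hexdigest()[:16]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("pattern\tk\tspan\tsupport\n")
            sup = self.supports or [float("nan")] * len(self.patterns)
            for p, s in zip(self.patterns, sup):
                fh.write(f"{p.text}\t{p.k}\t{p.span}\t{s!r}\n")

    @staticmethod
    def from_tsv(path: str | Path) -> "FeatureSet":
        pats, sups = [], []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:1] != ["pattern"]:
                raise ConfigurationError(f"unrecognized pattern table header: {header}")
            for line in fh:
                cells = line.rstrip("\n").split("\t")
                pats.append(GappedKmerPattern(cells[0]))
                sups.append(float(cells[3]))
        return FeatureSet(tuple(pats), tuple(sups))


def corpus_fingerprint(corpus: Sequence[str]) -> str:
    import hashlib

    h = hashlib.sha256()
    for s in corpus:
        h.update(s.encode())
        h.update(b"\n")
    return h.hexdigest()[:16]


def present_pattern_keys(sequence: str,
                         layouts: Iterable[tuple[int, ...]]) -> set[tuple[tuple[int, ...], str]]:
    """All (layout, matched-chars) pairs instantiated anywhere in a sequence."""
    out: set[tuple[tuple[int, ...], str]] = set()
    n = len(sequence)
    for layout in layouts:
        span = layout[-1] + 1
        for off in range(n - span + 1):
            out.add((layout, "".join(sequence[off + i] for i in layout)))
    return out


def mine_frequent(corpus: Sequence[str], config: MiningConfig) -> FeatureSet:
    """Return exactly the patterns with support >= gamma, canonically ordered.

    Counting is corpus-driven (only patterns actually instantiated are
    tallied), which is exactly equivalent to enumerate-then-filter because
    non-occurring patterns have support 0 < gamma.
    """
    if len(corpus) == 0:
        raise EmptyCorpusError("cannot mine an empty corpus")
    layouts = gap_layouts(config.k, config.effective_max_span)
    counts: dict[tuple[tuple[int, ...], str], int] = {}
    for seq in corpus:
        for key in present_pattern_keys(seq, layouts):
            counts[key] = counts.get(key, 0) + 1
    n = len(corpus)
    frequent = [
        (_layout_text(layout, chars), c / n)
        for (layout, chars), c in counts.items()
        if c / n >= config.gamma
    ]
    frequent.sort(key=lambda item: canonical_key(item[0]))
    return FeatureSet(
        patterns=tuple(GappedKmerPattern(t) for t, _ in frequent),
        supports=tuple(s for _, s in frequent),
        config=config,
        corpus_fingerprint=corpus_fingerprint(corpus),
    )
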