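"""Expanding a small set of column names into a labeled training corpus.

Column headers alone are far too few for a learned classifier, so the
list is grown in two stages: a five-step heuristic expansion (case
transforms, space/underscore substitution, and random token
re-concatenation) followed by a character-level generative name model.
Generated strings that look like plausible column titles are labeled
positive; incoherent character soup is labeled negative.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

_SPLIT_RE = re.compile(r"[ _]+")

Origin = str  # {"original", "heuristic", "generated"}


@dataclass(frozen=True)
class CorpusEntry:
    name: str
    label: int
    origin: Origin


@dataclass
class NameCorpus:
    """Labeled set of column-name strings (positive = plausible title)."""

    entries: list[CorpusEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for e in self.entries:
            key = (e.name, e.label)
            if key in seen:
                raise ValueError(f"duplicate (name, label) pair: {key!r}")
            seen.add(key)
            if e.origin == "original" and e.label != 1:
                raise ValueError("original entries must carry label 1")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def labels(self) -> list[int]:
        return [e.label for e in self.entries]

    def add(self, entry: CorpusEntry) -> bool:
        """Add an entry unless its (name, label) pair already exists."""
        if any(e.name == entry.name and e.label == entry.label for e in self.entries):
            return False
        self.entries.append(entry)
        return True

    def extend(self, entries: Iterable[CorpusEntry]) -> None:
        for e in entries:
            self.add(e)

    def token_vocabulary(self) -> set[str]:
        """Lowercased tokens of every entry, split on space/underscore."""
        vocab: set[str] = set()
        for e in self.entries:
            vocab.update(t.lower() for t in _SPLIT_RE.split(e.name) if t)
        return vocab

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("name\tlabel\torigin\n")
            for e in self.entries:
                fh.write(f"{e.name}\t{e.label}\t{e.origin}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NameCorpus":
        entries = []
        with open(path, encoding="utf-8") as fh:
            next(fh)  # header
            for line in fh:
                name, label, origin = line.rstrip("\n").split("\t")
                entries.append(CorpusEntry(name, int(label), origin))
        return cls(entries)


@dataclass
class GeneratorConfig:
    """Sampling configuration for the generative name model."""

    seed: int = 0
    n_samples: int = 0
    max_length: int = 40
    temperature: float = 1.0
    order: int = 3  # context length of the character model

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        if self.max_length < 1:
            raise ValueError("max_length must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


def _tokens(name: str) -> list[str]:
    return [t for t in _SPLIT_RE.split(name) if t]


def heuristic_expand(
    names: Sequence[str],
    seed: int = 0,
    n_recombinations: int = 900,
    k_tokens: int = 2,
) -> NameCorpus:
    """Five-step heuristic expansion of a seed list of column names.

    For every input name the output contains its lowercase form, its
    uppercase form, its space-to-underscore form and its
    underscore-to-space form, plus ``n_recombinations`` strings built by
    splitting all names on space/underscore and concatenating
    ``k_tokens`` randomly chosen tokens with no separator (so the titles
    "gene family" and "prev symbols" can yield "symbolgene"). The result
    is deduplicated; all entries are labeled 1 (plausible titles by
    construction).
    """
    if not names:
        raise ValueError("names must be non-empty")
    corpus = NameCorpus()
    for name in names:
        corpus.add(CorpusEntry(name, 1, "original"))
    transforms = (
        str.lower,
        str.upper,
        lambda s: s.replace(" ", "_"),
        lambda s: s.replace("_", " "),
    )
    for name in names:
        # closure under the four transforms, so re-expansion adds nothing
        variants = {name}
        frontier = {name}
        while frontier:
            frontier = {t(v) for v in frontier for t in transforms} - variants
            variants |= frontier
        for variant in sorted(variants - {name}):
            if variant:
                corpus.add(CorpusEntry(variant, 1, "heuristic"))
    token_pool = sorted({t for n in names for t in _tokens(n)})
    if token_pool and n_recombinations > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_recombinations):
            picks = rng.choice(len(token_pool), size=k_tokens, replace=True)
            corpus.add(CorpusEntry("".join(token_pool[i] for i in picks), 1, "heuristic"))
    return corpus


class NameGenerator:
    """Seeded character-level generative model over corpus names.

    An order-k character model with temperature sampling: transition
    counts over k-character contexts (with back-off to shorter contexts)
    are turned into a categorical distribution at each step. Sampling
    with a fixed seed is byte-reproducible.
    """

    BOS = "\x02"
    EOS = "\x03"

    def __init__(self, config: GeneratorConfig):
        self.config = config
        self._counts: dict[str, dict[str, int]] = {}
        self._trained = False

    def fit(self, names: Sequence[str]) -> "NameGenerator":
        if len(names) < 2:
            raise ValueError("need at least 2 names to train the generator")
        k = self.config.order
        for name in names:
            padded = self.BOS * k + name + self.EOS
            for i in range(k, len(padded)):
                for ctx_len in range(1, k + 1):
                    ctx = padded[i - ctx_len : i]
                    self._counts.setdefault(ctx, {}).setdefault(padded[i], 0)
                    self._counts[ctx][padded[i]] += 1
        self._trained = True
        return self

    def _next_char(self, context: str, rng: np.random.Generator) -> str:
        k = self.config.order
        for ctx_len in range(k, 0, -1):
            ctx = context[-ctx_len:]
            if ctx in self._counts:
                chars = sorted(self._counts[ctx])
                counts = np.array([self._counts[ctx][c] for c in chars], dtype=float)
                logits = np.log(counts) / self.config.temperature
                logits -= logits.max()
                probs = np.exp(logits)
                probs /= probs.sum()
                return chars[rng.choice(len(chars), p=probs)]
        return self.EOS

    def sample(self, n: int | None = None, seed: int | None = None) -> list[str]:
        """Draw n strings; identical (n, seed) pairs give identical output."""
        if not self._trained:
            raise RuntimeError("generator is not trained")
        n = self.config.n_samples if n is None else n
        seed = self.config.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            context = self.BOS * self.config.order
            chars: list[str] = []
            while len(chars) < self.config.max_length:
                c = self._next_char(context, rng)
                if c == self.EOS:
                    break
                chars.append(c)
                context = (context + c)[-self.config.order :]
            out.append("".join(chars))
        return out


def train_name_generator(corpus: NameCorpus, config: GeneratorConfig) -> NameGenerator:
    """Fit the character-level name generator on a corpus's names."""
    if not corpus.entries:
        raise ValueError("corpus is empty")
    return NameGenerator(config).fit(corpus.names)


LabelRule = Callable[[str], int]


def vocabulary_rule(vocabulary: set[str]) -> LabelRule:
    """Default automatic labeling: positive iff every token is known.

    A generated string is a plausible column title when every
    space/underscore-separated token (lowercased) appears in the original
    token vocabulary; anything else — notably random character runs —
    is labeled negative.
    """
    vocab = {v.lower() for v in vocabulary}

    def rule(name: str) -> int:
        toks = _tokens(name)
        if not toks:
            return 0
        return int(all(t.lower() in vocab for t in toks))

    return rule


def label_generated(
    names: Sequence[str],
    rules: LabelRule,
    curator: Callable[[str], int | None] | None = None,
) -> list[CorpusEntry]:
    """Label generated strings; a curator verdict always overrides the rule.

    Empty (whitespace-only) strings are dropped, not labeled.
    """
    entries: list[CorpusEntry] = []
    for name in names:
        if not name.strip():
            continue
        label: int | None = None
        if curator is not None:
            label = curator(name)
        if label is None:
            label = rules(name)
        entries.append(CorpusEntry(name, int(label), "generated"))
    return entries
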