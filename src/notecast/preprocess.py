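"""Clinical-note text normalisation.

Raw free-text notes are turned into controlled lowercase token streams in
three stages:

1. :func:`clean_text` — whitespace/punctuation removal, lowercasing, and
   spelling out every digit run as cardinal words;
2. :func:`remove_unwanted` — corpus-aware filtering of stopwords, section
   headings, medico-legal boilerplate phrases, proper nouns and rare terms;
3. :func:`apply_lexicon` — many-to-one mapping of surface terms onto
   controlled vocabulary tokens (CLEVER-style, e.g. "brother" -> "FAM",
   "cancer"/"lesion"/"oncology" -> "CA").

Corpus statistics needed downstream (term counts, per-note document
frequencies) live in :class:`VocabularyStats`.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RawNote",
    "CleanNote",
    "TermLexicon",
    "VocabularyStats",
    "number_to_words",
    "clean_text",
    "detect_proper_nouns",
    "remove_unwanted",
    "apply_lexicon",
    "build_vocabulary",
    "preprocess_note",
]


@dataclass(frozen=True)
class RawNote:
    """One clinical note as ingested: free text keyed by patient and date."""

    patient_id: str
    note_id: str
    timestamp: date
    text: str


@dataclass(frozen=True)
class CleanNote:
    """A note after preprocessing: an ordered stream of controlled tokens."""

    patient_id: str
    note_id: str
    timestamp: date
    tokens: tuple[str, ...]


class TermLexicon:
    """Many-to-one surface-term -> controlled-token map with total lookup.

    Terms absent from the map pass through unchanged, so ``lookup`` never
    fails and mapped streams keep their length.
    """

    def __init__(self, entries: Mapping[str, str] | None = None):
        self.entries: dict[str, str] = dict(entries or {})

    def lookup(self, term: str) -> str:
        return self.entries.get(term, term)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path) -> "TermLexicon":
        entries = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                surface, _, controlled = line.partition("\t")
                if controlled:
                    entries[surface.strip()] = controlled.strip()
        return cls(entries)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for surface, controlled in sorted(self.entries.items()):
                fh.write(f"{surface}\t{controlled}\n")


@dataclass
class VocabularyStats:
    """Corpus counts backing rare-term filtering and idf weighting.

    ``term_count`` is total occurrences per token; ``doc_freq`` counts each
    note at most once per token; ``n_notes`` is the corpus size N of the
    tf-idf formula.
    """

    term_count: Counter = field(default_factory=Counter)
    doc_freq: Counter = field(default_factory=Counter)
    n_notes: int = 0


# ---------------------------------------------------------------------------
# number spelling

_ONES = (
    "zero one two three four five six seven eight nine ten eleven twelve "
    "thirteen fourteen fifteen sixteen seventeen eighteen nineteen"
).split()
_TENS = ("", "", "twenty", "thirty", "forty", "fifty", "sixty", "seventy", "eighty", "ninety")
_SCALES = ("", "thousand", "million", "billion", "trillion")


def _below_thousand(n: int) -> list[str]:
    words: list[str] = []
    if n >= 100:
        words += [_ONES[n // 100], "hundred"]
        n %= 100
    if n >= 20:
        words.append(_TENS[n // 10])
        n %= 10
    if 0 < n < 20:
        words.append(_ONES[n])
    return words


def number_to_words(n: int) -> str:
    """Spell a nonnegative integer as space-separated cardinal words."""
    if n < 0:
        raise ValueError("only nonnegative integers are spelled out")
    if n == 0:
        return "zero"
    groups: list[str] = []
    scale = 0
    while n > 0:
        n, rem = divmod(n, 1000)
        if rem:
            part = _below_thousand(rem)
            if scale:
                part.append(_SCALES[scale])
            groups = part + groups
        scale += 1
        if scale >= len(_SCALES) and n > 0:
            # beyond supported magnitude: spell remaining digits one by one
            groups = [_ONES[int(d)] for d in str(n)] + groups
            break
    return " ".join(groups)


_NUMBER_RE = re.compile(r"\d+(?:\.\d+)?")
_NON_ALPHA_RE = re.compile(r"[^a-z\s]+")


def _spell_match(m: re.Match) -> str:
    token = m.group(0)
    if "." in token:
        whole, frac = token.split(".", 1)
        frac_words = " ".join(_ONES[int(d)] for d in frac)
        return f" {number_to_words(int(whole))} point {frac_words} "
    return f" {number_to_words(int(token))} "


def clean_text(text: str) -> list[str]:
    """Normalise free text to lowercase alphabetic tokens.

    Every maximal digit run is spelled out as cardinal words (decimals split
    on the point: "2.5" -> "two point five"), the text is lowercased,
    punctuation collapses to whitespace, and tokenisation is whitespace
    splitting. Idempotent on its own output.
    """
    text = _NUMBER_RE.sub(_spell_match, text)
    text = text.lower()
    text = _NON_ALPHA_RE.sub(" ", text)
    return text.split()


_WORD_RE = re.compile(r"[A-Za-z][A-Za-z']*")
_SENT_SPLIT_RE = re.compile(r"[.!?;:\n]+")


def detect_proper_nouns(text: str, name_list: Iterable[str] = ()) -> set[str]:
    """Find proper-noun candidates on the *raw* text, before lowercasing.

    A token is flagged when it is capitalised (not all-caps) in a
    non-sentence-initial position, or its lowercase form is in ``name_list``.
    Working on raw text preserves the capitalisation evidence that
    lowercasing destroys.
    """
    names = {n.strip().lower() for n in name_list if n.strip()}
    flagged: set[str] = set()
    for sentence in _SENT_SPLIT_RE.split(text):
        words = _WORD_RE.findall(sentence)
        for i, w in enumerate(words):
            lower = w.lower()
            if lower in names:
                flagged.add(lower)
            elif i > 0 and w[0].isupper() and not w.isupper() and len(w) > 1:
                flagged.add(lower)
    return flagged


def _remove_phrases(tokens: list[str], phrases: Iterable[Sequence[str]]) -> list[str]:
    """Drop every occurrence of each phrase (token n-gram) from the stream."""
    phrase_list = [tuple(p) for p in phrases if p]
    if not phrase_list:
        return tokens
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = False
        for ph in phrase_list:
            k = len(ph)
            if tuple(tokens[i : i + k]) == ph:
                i += k
                matched = True
                break
        if not matched:
            out.append(tokens[i])
            i += 1
    return out


def remove_unwanted(
    tokens: Sequence[str],
    vocab: VocabularyStats | None,
    stopwords: Iterable[str] = (),
    headings: Iterable[str] = (),
    legal_phrases: Iterable[str] = (),
    proper_nouns: Iterable[str] = (),
    min_count: int = 50,
) -> list[str]:
    """Filter noise tokens: stopwords, section headings, boilerplate
    phrases, proper nouns, and corpus-rare terms (fewer than ``min_count``
    occurrences). Order is preserved.

    ``vocab`` must cover the full training corpus; without it the rare-term
    rule cannot be applied and a ``ValueError`` is raised (pass
    ``min_count=0`` to filter without corpus statistics).
    """
    if vocab is None and min_count > 0:
        raise ValueError(
            "corpus VocabularyStats required for rare-term filtering; "
            "pass min_count=0 to skip it"
        )
    stop = {s.strip().lower() for s in stopwords if s.strip()}
    head = {h.strip().lower() for h in headings if h.strip()}
    nouns = {p.strip().lower() for p in proper_nouns if p.strip()}
    phrase_grams = [tuple(clean_text(p)) for p in legal_phrases]

    toks = _remove_phrases(list(tokens), phrase_grams)
    out = []
    for t in toks:
        if t in stop or t in head or t in nouns:
            continue
        if min_count > 0 and vocab is not None and vocab.term_count.get(t, 0) < min_count:
            continue
        out.append(t)
    return out


def apply_lexicon(tokens: Sequence[str], lexicon: TermLexicon) -> list[str]:
    """Map each token to its controlled term; unmapped tokens pass through."""
    return [lexicon.lookup(t) for t in tokens]


def build_vocabulary(corpus: Iterable[Sequence[str]]) -> VocabularyStats:
    """Exact term and document-frequency counts over a token-sequence corpus."""
    stats = VocabularyStats()
    n = 0
    for note_tokens in corpus:
        n += 1
        stats.term_count.update(note_tokens)
        stats.doc_freq.update(set(note_tokens))
    if n == 0:
        raise ValueError("empty corpus")
    stats.n_notes = n
    return stats


def preprocess_note(
    note: RawNote,
    *,
    vocab: VocabularyStats | None,
    lexicon: TermLexicon,
    stopwords: Iterable[str] = (),
    headings: Iterable[str] = (),
    legal_phrases: Iterable[str] = (),
    name_list: Iterable[str] = (),
    min_count: int = 50,
) -> CleanNote:
    """Full cleaning pipeline for one note: clean -> remove -> map.

    Proper nouns are detected on the raw text (capitalisation evidence)
    before lowercasing; the rare-term threshold is applied before lexicon
    mapping, so controlled tokens introduced by the lexicon are always
    retained.
    """
    nouns = detect_proper_nouns(note.text, name_list)
    toks = clean_text(note.text)
    toks = remove_unwanted(
        toks,
        vocab,
        stopwords=stopwords,
        headings=headings,
        legal_phrases=legal_phrases,
        proper_nouns=nouns,
        min_count=min_count,
    )
    toks = apply_lexicon(toks, lexicon)
    return CleanNote(note.patient_id, note.note_id, note.timestamp, tuple(toks))
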