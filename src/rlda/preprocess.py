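"""Text pre-processing: segmentation, lemmatization, POS tagging, content-word
filtering and stop-word removal.

The pipeline turns raw title+abstract text into content-word token sequences:
punctuation-delimited lowercase segmentation, rule-based English
lemmatization (plural nouns to singular, inflected verbs to base form),
rule-based POS tagging over a fixed 25-tag inventory, retention of nouns and
adjectives only (NN*/JJ* tag families), and stop-word removal.  Nouns and
adjectives carry most topical content in abstracts; function words, verbs and
numbers mostly add noise to a bag-of-words topic model.

The tagger and lemmatizer are deliberately small deterministic rule systems:
the downstream contract (content-word retention, idempotent lemmas) is what
matters, not agreement with any particular treebank model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "TAGSET",
    "TaggedToken",
    "TokenizedCorpus",
    "segment",
    "lemmatize",
    "lemmatize_token",
    "pos_tag",
    "filter_content_words",
    "remove_stopwords",
    "tokenize_document",
    "tokenize_collection",
]

#: POS tag inventory used by the tagger.
TAGSET = frozenset(
    {
        "CC", "CD", "DT", "EX", "FW", "IN", "JJ", "LS", "MD", "NN", "NNP",
        "PDT", "POS", "PRP", "PRP$", "RB", "RP", "SYM", "TO", "UH", "VB",
        "WDT", "WP", "WP$", "WRB",
    }
)


@dataclass(frozen=True)
class TaggedToken:
    surface: str
    lemma: str
    tag: str

    def __post_init__(self) -> None:
        if self.tag not in TAGSET:
            raise ValueError(f"unknown POS tag {self.tag!r}")
        if self.surface and not self.lemma:
            raise ValueError("empty lemma for non-empty surface")


_TOKEN_RE = re.compile(r"[a-z0-9]+")


def segment(text: str) -> list[str]:
    """Split text into lowercase tokens; punctuation delimits and is dropped."""
    return _TOKEN_RE.findall(text.lower())


# Irregular forms map straight to their prototype.
_IRREGULAR = {
    "men": "man", "women": "woman", "children": "child", "feet": "foot",
    "teeth": "tooth", "mice": "mouse", "geese": "goose", "people": "person",
    "is": "be", "are": "be", "was": "be", "were": "be", "been": "be",
    "being": "be", "am": "be", "has": "have", "had": "have", "having": "have",
    "does": "do", "did": "do", "done": "do", "goes": "go", "went": "go",
    "gone": "go", "made": "make", "took": "take", "taken": "take",
    "found": "find", "gave": "give", "given": "give", "shown": "show",
    "data": "data", "analyses": "analysis", "diagnoses": "diagnosis",
    "hypotheses": "hypothesis", "criteria": "criterion", "phenomena": "phenomenon",
    "bacteria": "bacterium", "fungi": "fungus", "nuclei": "nucleus",
    "stimuli": "stimulus", "foci": "focus", "indices": "index",
    "matrices": "matrix", "vertebrae": "vertebra", "mellitus": "mellitus",
    "diabetes": "diabetes", "tuberculosis": "tuberculosis",
    "hepatitis": "hepatitis", "arthritis": "arthritis", "asthma": "asthma",
    "pancreas": "pancreas", "series": "series", "species": "species",
    "caries": "caries", "herpes": "herpes", "rabies": "rabies",
    "news": "news", "lens": "lens", "aegis": "aegis",
}

_VOWELS = set("aeiou")


def _has_vowel(s: str) -> bool:
    return any(c in _VOWELS for c in s)


def lemmatize_token(token: str) -> str:
    """Reduce one lowercase token to its prototype form.

    Handles irregular plurals/verbs via a lookup table and regular
    inflection by suffix stripping (-ies/-es/-s, -ied/-ed, -ing with
    consonant-doubling repair), iterated to a fixed point so the map is
    idempotent (stripping a plural may expose a verb suffix).
    """
    out = _lemmatize_once(token)
    for _ in range(3):
        again = _lemmatize_once(out)
        if again == out:
            break
        out = again
    return out


def _lemmatize_once(token: str) -> str:
    if not token or not token.isalpha():
        return token
    if token in _IRREGULAR:
        return _IRREGULAR[token]

    w = token
    # -ing / -ed verb inflections (walked -> walk, walking -> walk,
    # running -> run, studied -> study)
    for suf, repl in (("ing", ""), ("ied", "y"), ("ed", "")):
        if w.endswith(suf) and len(w) - len(suf) + len(repl) >= 3:
            stem = w[: -len(suf)] + repl
            if not _has_vowel(stem):
                continue
            # undo consonant doubling: running -> runn -> run
            if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS | {"s", "l"}:
                stem = stem[:-1]
            return stem
    # plural nouns / 3rd-person verbs
    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith(("sses", "xes", "zes", "ches", "shes")) and len(w) > 4:
        return w[:-2]
    if w.endswith("s") and not w.endswith(("ss", "us", "is")) and len(w) > 3:
        return w[:-1]
    return w


def lemmatize(tokens: list[str]) -> list[str]:
    """Lemmatize a token sequence (tokens already lowercase)."""
    return [lemmatize_token(t) for t in tokens]


# Closed-class word lists for the tagger.
_CLOSED_CLASS: dict[str, str] = {}
for _tag, _words in {
    "CC": "and or but nor yet plus versus",
    "DT": "a an the this these those each every either neither another",
    "EX": "there",
    "IN": "of in by with on at from for into during against between among"
          " within without about above below under over after before through"
          " toward towards upon per via than since until although because if"
          " while whereas despite except",
    "MD": "can could may might must shall should will would",
    "PDT": "all both half",
    "PRP": "i you he she it we they me him her us them itself himself herself"
           " themselves myself yourself ourselves",
    "PRP$": "my your his its our their her hers ours yours theirs mine",
    "RB": "not never quickly always often sometimes very too also however"
          " moreover furthermore respectively significantly approximately",
    "RP": "up off out down away back",
    "TO": "to",
    "UH": "ah oh oops alas",
    "WDT": "which whichever",
    "WP": "what who whom whoever",
    "WP$": "whose",
    "WRB": "how where when why wherever whenever",
}.items():
    for _w in _words.split():
        _CLOSED_CLASS[_w] = _tag

_NUMBER_WORDS = set(
    "one two three four five six seven eight nine ten eleven twelve twenty"
    " thirty forty fifty hundred thousand million billion first second third".split()
)

# Common base verbs frequent in abstracts; everything else defaults to NN.
_BASE_VERBS = set(
    "be have do go make take find give show look eat walk use see get say"
    " report suggest indicate observe measure compare include perform conduct"
    " increase decrease reduce improve associate correlate treat study analyze"
    " assess evaluate examine investigate determine identify demonstrate"
    " reveal confirm develop occur remain become provide require obtain".split()
)

_ADJ_SUFFIXES = (
    "ous", "ful", "ive", "ible", "able", "al", "ic", "ical", "less", "ish",
    "ary", "ory", "ant", "ent",
)

_ADJ_WORDS = set(
    "good long high low new old large small great big main major minor"
    " common rare severe mild acute chronic clinical normal abnormal obese"
    " diabetic healthy unhealthy early late young elderly overweight similar"
    " different significant important effective positive negative".split()
)


def _tag_one(token: str) -> str:
    if token.isdigit() or token in _NUMBER_WORDS:
        return "CD"
    if token in _CLOSED_CLASS:
        return _CLOSED_CLASS[token]
    if token in _ADJ_WORDS:
        return "JJ"
    if token in _BASE_VERBS:
        return "VB"
    if token.endswith("ly") and len(token) > 3:
        return "RB"
    if token.endswith(_ADJ_SUFFIXES) and len(token) > 4:
        return "JJ"
    if not token.isascii():
        return "FW"
    return "NN"


def pos_tag(tokens: list[str]) -> list[TaggedToken]:
    """Assign each token exactly one tag from the inventory.

    Closed-class words and numbers are recognized on the surface form
    (so inflection rules never mangle them); open-class words are tagged on
    their lemma and default to NN, the safe choice for a noun-keeping pipeline.
    """
    out = []
    for tok in tokens:
        if tok.isdigit() or tok in _NUMBER_WORDS:
            out.append(TaggedToken(surface=tok, lemma=tok, tag="CD"))
            continue
        if tok in _CLOSED_CLASS:
            out.append(TaggedToken(surface=tok, lemma=tok, tag=_CLOSED_CLASS[tok]))
            continue
        lemma = lemmatize_token(tok)
        out.append(TaggedToken(surface=tok, lemma=lemma, tag=_tag_one(lemma)))
    return out


def filter_content_words(tagged: list[TaggedToken]) -> list[str]:
    """Keep only nouns and adjectives (NN*/JJ* tag families), in order."""
    return [t.lemma for t in tagged if t.tag.startswith(("NN", "JJ"))]


def remove_stopwords(tokens: list[str], stoplist: list[str] | set[str]) -> list[str]:
    """Drop tokens present in the (lowercase) stop-word list, preserving order."""
    stop = set(stoplist)
    return [t for t in tokens if t not in stop]


def tokenize_document(text: str, stoplist: list[str] | set[str]) -> list[str]:
    """Full pipeline: segment -> lemmatize -> tag -> content filter -> stop removal.

    Additionally drops single-character tokens and pure digits, which carry
    no topical content (digits are already excluded by the noun/adjective
    filter via the CD tag).
    """
    tagged = pos_tag(segment(text))
    content = filter_content_words(tagged)
    content = [t for t in content if len(t) > 1 and not t.isdigit()]
    return remove_stopwords(content, stoplist)


class TokenizedCorpus:
    """Bag-of-words corpus: token-id sequences over an ordered vocabulary.

    ``docs[m]`` is the id sequence of document m, ``vocabulary[i]`` the
    surface form of token id i, ``N`` the per-document lengths.
    """

    def __init__(self, docs: list[list[int]], vocabulary: list[str]):
        if len(set(vocabulary)) != len(vocabulary):
            raise ValueError("vocabulary contains duplicates")
        V = len(vocabulary)
        for seq in docs:
            if any(t < 0 or t >= V for t in seq):
                raise ValueError("token id out of vocabulary range")
        self.docs = docs
        self.vocabulary = vocabulary
        self.word_index = {w: i for i, w in enumerate(vocabulary)}

    @classmethod
    def from_token_lists(cls, token_lists: list[list[str]]) -> "TokenizedCorpus":
        """Build id sequences and vocabulary (first-occurrence order)."""
        vocab: dict[str, int] = {}
        docs = []
        for toks in token_lists:
            seq = []
            for t in toks:
                if t not in vocab:
                    vocab[t] = len(vocab)
                seq.append(vocab[t])
            docs.append(seq)
        return cls(docs, list(vocab))

    @property
    def M(self) -> int:
        return len(self.docs)

    @property
    def V(self) -> int:
        return len(self.vocabulary)

    @property
    def N(self) -> list[int]:
        return [len(d) for d in self.docs]

    def tokens(self, m: int) -> list[str]:
        return [self.vocabulary[i] for i in self.docs[m]]


def tokenize_collection(collection, stoplist=None) -> TokenizedCorpus:
    """Tokenize every document of a collection through the full pipeline."""
    from .corpus_io import default_stopwords

    if stoplist is None:
        stoplist = default_stopwords()
    return TokenizedCorpus.from_token_lists(
        [tokenize_document(doc.text, stoplist) for doc in collection]
    )
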