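"""Text preprocessing and the in-network "idea space" representation.

Participant responses are short free-text phrases ("use it to build a
wall"). Direction scoring needs them as a bag of in-network word tokens:
responses are lower-cased, stripped of punctuation, split on whitespace,
and filtered against a stop-word list; the surviving tokens that exist in
the semantic network form the idea space. Words outside the network have
undefined path length and are kept only for audit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .network import SemanticNetwork, shortest_path_length

__all__ = [
    "IdeaSpace",
    "preprocess_response",
    "build_idea_space",
    "adherence",
]

# Strip everything outside [a-z0-9]; internal hyphens/apostrophes are
# removed rather than split, so "don't" -> "dont", "mad-hat" -> "madhat".
_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def normalize_bag_token(raw: str) -> str:
    """Apply the bag-of-words token normalization to one raw token."""
    return _NON_ALNUM.sub("", raw.lower())


def preprocess_response(text: str, stoplist: set[str]) -> list[str]:
    """Turn a free-text response into an ordered list of content tokens.

    Lower-case, strip punctuation, collapse whitespace, split, drop
    stop-words. Token order is preserved; the operation is idempotent
    (re-processing its own joined output changes nothing).
    """
    if not stoplist:
        raise ValueError("stoplist must be nonempty")
    tokens = []
    for raw in text.split():
        tok = normalize_bag_token(raw)
        if tok and tok not in stoplist:
            tokens.append(tok)
    return tokens


@dataclass
class IdeaSpace:
    """The in-network token set distilled from a participant's responses.

    ``tokens`` is the set actually used for direction scoring (guaranteed
    to be network nodes); ``raw_tokens`` keeps every post-stoplist token,
    including out-of-network ones, in response order for auditing.
    """

    tokens: set[str] = field(default_factory=set)
    raw_tokens: list[str] = field(default_factory=list)
    source_response_ids: list[int] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not self.tokens

    def members(self, mode: str = "set") -> list[str]:
        """In-network tokens under ``set`` or ``multiset`` semantics.

        Multiset semantics repeat a token once per occurrence across
        responses, weighting the direction score toward repeated words.
        """
        if mode == "set":
            return sorted(self.tokens)
        if mode == "multiset":
            return [t for t in self.raw_tokens if t in self.tokens]
        raise ValueError(f"unknown idea_space mode: {mode!r}")


def build_idea_space(
    responses: Sequence[str],
    net: SemanticNetwork,
    stoplist: set[str],
    response_ids: Iterable[int] | None = None,
) -> IdeaSpace:
    """Extract the idea space from a list of response texts.

    An empty result (all tokens out-of-network, or no responses) is legal;
    the recommender falls back to a seeded random pick in that case.
    """
    ids = list(response_ids) if response_ids is not None else list(range(len(responses)))
    space = IdeaSpace()
    for rid, text in zip(ids, responses):
        toks = preprocess_response(text, stoplist)
        if toks:
            space.source_response_ids.append(rid)
        space.raw_tokens.extend(toks)
        space.tokens.update(t for t in toks if t in net)
    return space


def adherence(
    net: SemanticNetwork,
    recommendation_word: str,
    response_text: str,
    stoplist: set[str],
) -> float | None:
    """Mean path length from a recommendation to a response's tokens.

    Measures how semantically close the response stayed to the shown
    recommendation: 0 means the response used the recommended word itself.
    Returns ``None`` when the response has no in-network tokens (the
    distance is undefined).
    """
    net.require(recommendation_word)
    tokens = {
        t for t in preprocess_response(response_text, stoplist) if t in net
    }
    if not tokens:
        return None
    return sum(
        shortest_path_length(net, recommendation_word, t) for t in tokens
    ) / len(tokens)


def read_stoplist(path) -> set[str]:
    """Read a stop-word file: one token per line, ``#`` comments allowed.

    Tokens are normalized with the same punctuation rules as responses so
    that entries like "don't" match the processed token "dont".
    """
    stops: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            tok = normalize_bag_token(line)
            if tok:
                stops.add(tok)
    if not stops:
        raise ValueError(f"stoplist file {path} contains no tokens")
    return stops


def default_stoplist() -> set[str]:
    """The bundled English stop-word snapshot."""
    from importlib.resources import files

    path = files("ideaspark.data").joinpath("stopwords_en.txt")
    stops = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            tok = normalize_bag_token(line)
            if tok:
                stops.add(tok)
    return stops
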