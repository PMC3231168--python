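"""Compression-based next-event baselines: LZ78, LZW and Active LeZi.

These treat the event stream as a plain symbol string (timing discarded) and
grow a frequency-annotated phrase trie.  Prediction walks the deepest suffix
of the recent context present in the trie and normalizes the child counts
into a posterior over the next symbol, backing off to shorter suffixes and
finally to root frequencies.  A confidence threshold on the top posterior
turns the posterior into a claimed prediction or an abstention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "TrieNode",
    "PhraseTrie",
    "lz78_train",
    "lzw_train",
    "alz_train",
    "predict_next",
    "confident_prediction",
]


@dataclass
class TrieNode:
    symbol: Optional[str] = None
    count: int = 0
    children: dict = field(default_factory=dict)

    def child(self, symbol: str) -> "TrieNode":
        node = self.children.get(symbol)
        if node is None:
            node = TrieNode(symbol)
            self.children[symbol] = node
        return node


@dataclass
class PhraseTrie:
    """Frequency-annotated phrase tree; paths from the root are phrases."""

    variant: str
    root: TrieNode = field(default_factory=TrieNode)

    @property
    def longest_phrase_len(self) -> int:
        def depth(node: TrieNode) -> int:
            if not node.children:
                return 0
            return 1 + max(depth(c) for c in node.children.values())

        return depth(self.root)

    def phrases(self) -> set[tuple[str, ...]]:
        out: set[tuple[str, ...]] = set()

        def walk(node: TrieNode, prefix: tuple[str, ...]) -> None:
            for sym, child in node.children.items():
                out.add(prefix + (sym,))
                walk(child, prefix + (sym,))

        walk(self.root, ())
        return out

    def _add_phrase(self, phrase: Sequence[str]) -> None:
        node = self.root
        for sym in phrase:
            node = node.child(sym)
            node.count += 1

    def walk(self, phrase: Sequence[str]) -> Optional[TrieNode]:
        node = self.root
        for sym in phrase:
            node = node.children.get(sym)
            if node is None:
                return None
        return node


def lz78_train(symbols: Sequence[str], trie: PhraseTrie | None = None) -> PhraseTrie:
    """LZ78: parse into the shortest phrases not yet in the dictionary.

    Each parsed phrase increments the counts along its path; the pending
    (unterminated) final phrase is counted too.
    """
    trie = trie or PhraseTrie("lz78")
    w: list[str] = []
    known = trie.phrases()
    for s in symbols:
        w.append(s)
        if tuple(w) not in known:
            known.add(tuple(w))
            trie._add_phrase(w)
            w = []
    if w:
        trie._add_phrase(w)
    return trie


def lzw_train(
    symbols: Sequence[str], alphabet: set[str], trie: PhraseTrie | None = None
) -> PhraseTrie:
    """LZW: like LZ78 but with the single-symbol alphabet pre-seeded.

    Pre-seeding avoids ill-detected phrases at the start of the stream; an
    out-of-alphabet symbol is an error.
    """
    trie = trie or PhraseTrie("lzw")
    for s in sorted(alphabet):
        trie.root.child(s)  # seeded at count 0
    known = trie.phrases()
    w: list[str] = []
    for s in symbols:
        if s not in alphabet:
            raise ValueError(f"symbol {s!r} not in the LZW alphabet")
        cand = w + [s]
        if tuple(cand) in known:
            w = cand
        else:
            known.add(tuple(cand))
            trie._add_phrase(cand)
            w = [s]  # the unmatched symbol starts the next phrase
    if w:
        trie._add_phrase(w)
    return trie


def alz_train(symbols: Sequence[str], trie: PhraseTrie | None = None) -> PhraseTrie:
    """Active LeZi: per-position sliding-window suffix insertion.

    The LZ78 parse is maintained only to track l, the current longest-phrase
    length; at every position all window suffixes of length <= l ending there
    are inserted, restoring the prediction continuity LZ78 loses at phrase
    boundaries.
    """
    trie = trie or PhraseTrie("alz")
    known: set[tuple[str, ...]] = set()
    w: list[str] = []
    l = 0
    window: list[str] = []
    for s in symbols:
        w.append(s)
        if tuple(w) not in known:
            known.add(tuple(w))
            l = max(l, len(w))
            w = []
        window.append(s)
        if len(window) > l:
            window = window[-l:]
        for start in range(len(window)):
            trie._add_phrase(window[start:])
    return trie


def predict_next(trie: PhraseTrie, context: Sequence[str]) -> dict[str, float]:
    """Posterior over the next symbol from the deepest matching context suffix.

    Backs off to shorter suffixes when the matched node has no children and
    finally to root frequencies; an empty trie abstains (empty posterior).
    """
    context = list(context)
    for k in range(len(context), -1, -1):
        node = trie.walk(context[len(context) - k:])
        if node is not None and node.children:
            total = sum(c.count for c in node.children.values())
            if total > 0:
                return {sym: c.count / total for sym, c in node.children.items()}
    return {}


def confident_prediction(posterior: dict[str, float], threshold: float) -> Optional[str]:
    """Argmax symbol if its posterior reaches the threshold, else abstain.

    Ties are broken lexicographically.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if not posterior:
        return None
    best = min(posterior.items(), key=lambda kv: (-kv[1], kv[0]))
    return best[0] if best[1] >= threshold else None
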