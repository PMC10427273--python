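"""Porter suffix-stripping stemmer.

A self-contained implementation of the classic Porter (1980) algorithm,
with one optional dialect extension (enabled by default): in step 2 a
trailing ``li`` is deleted whenever the remaining stem has positive
measure and contains a vowel.  This maps adverbs such as ``happily``
(``happili`` after step 1c) onto the same stem as ``happy`` and
``happiness`` (``happi``), which is the convention this package's corpus
processing standardises on.
"""

from __future__ import annotations

__all__ = ["PorterStemmer", "stem_word"]

_VOWELS = "aeiou"


def _is_consonant(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of vowel->consonant transitions: the Porter *m* value."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        cons = _is_consonant(stem, i)
        if cons and prev_vowel:
            m += 1
        prev_vowel = not cons
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


# (suffix, replacement) rule tables; first matching suffix wins, the
# replacement is applied only when the measure condition holds.
_STEP2_RULES = [
    ("ational", "ate"),
    ("tional", "tion"),
    ("enci", "ence"),
    ("anci", "ance"),
    ("izer", "ize"),
    ("abli", "able"),
    ("alli", "al"),
    ("entli", "ent"),
    ("eli", "e"),
    ("ousli", "ous"),
    ("ization", "ize"),
    ("ation", "ate"),
    ("ator", "ate"),
    ("alism", "al"),
    ("iveness", "ive"),
    ("fulness", "ful"),
    ("ousness", "ous"),
    ("aliti", "al"),
    ("iviti", "ive"),
    ("biliti", "ble"),
]

_STEP3_RULES = [
    ("icate", "ic"),
    ("ative", ""),
    ("alize", "al"),
    ("iciti", "ic"),
    ("ical", "ic"),
    ("ful", ""),
    ("ness", ""),
]

_STEP4_SUFFIXES = [
    "ement",
    "ance",
    "ence",
    "able",
    "ible",
    "ment",
    "ant",
    "ent",
    "ion",
    "ism",
    "ate",
    "iti",
    "ous",
    "ive",
    "ize",
    "al",
    "er",
    "ic",
    "ou",
]


class PorterStemmer:
    """Callable Porter stemmer.

    Parameters
    ----------
    adverbial_li : bool
        Enable the step-2 ``li``-deletion extension (see module docstring).
    """

    def __init__(self, adverbial_li: bool = True):
        self.adverbial_li = adverbial_li

    def __call__(self, word: str) -> str:
        return self.stem(word)

    def stem(self, word: str) -> str:
        word = word.lower()
        if len(word) <= 2:
            return word
        word = self._step1a(word)
        word = self._step1b(word)
        word = self._step1c(word)
        word = self._step2(word)
        word = self._step3(word)
        word = self._step4(word)
        word = self._step5(word)
        return word

    @staticmethod
    def _step1a(w: str) -> str:
        if w.endswith("sses"):
            return w[:-2]
        if w.endswith("ies"):
            return w[:-2]
        if w.endswith("ss"):
            return w
        if w.endswith("s"):
            return w[:-1]
        return w

    @staticmethod
    def _step1b(w: str) -> str:
        if w.endswith("eed"):
            if _measure(w[:-3]) > 0:
                return w[:-1]
            return w
        stripped = None
        if w.endswith("ed") and _contains_vowel(w[:-2]):
            stripped = w[:-2]
        elif w.endswith("ing") and _contains_vowel(w[:-3]):
            stripped = w[:-3]
        if stripped is None:
            return w
        if stripped.endswith(("at", "bl", "iz")):
            return stripped + "e"
        if _ends_double_consonant(stripped) and stripped[-1] not in "lsz":
            return stripped[:-1]
        if _measure(stripped) == 1 and _ends_cvc(stripped):
            return stripped + "e"
        return stripped

    @staticmethod
    def _step1c(w: str) -> str:
        if w.endswith("y") and _contains_vowel(w[:-1]):
            return w[:-1] + "i"
        return w

    def _step2(self, w: str) -> str:
        rules = sorted(_STEP2_RULES, key=lambda r: -len(r[0]))
        for suffix, repl in rules:
            if w.endswith(suffix):
                stem = w[: -len(suffix)]
                if _measure(stem) > 0:
                    return stem + repl
                return w
        if self.adverbial_li and w.endswith("li"):
            stem = w[:-2]
            if _measure(stem) > 0 and _contains_vowel(stem):
                return stem
        return w

    @staticmethod
    def _step3(w: str) -> str:
        for suffix, repl in sorted(_STEP3_RULES, key=lambda r: -len(r[0])):
            if w.endswith(suffix):
                stem = w[: -len(suffix)]
                if _measure(stem) > 0:
                    return stem + repl
                return w
        return w

    @staticmethod
    def _step4(w: str) -> str:
        for suffix in sorted(_STEP4_SUFFIXES, key=len, reverse=True):
            if w.endswith(suffix):
                stem = w[: -len(suffix)]
                if suffix == "ion" and not stem.endswith(("s", "t")):
                    return w
                if _measure(stem) > 1:
                    return stem
                return w
        return w

    @staticmethod
    def _step5(w: str) -> str:
        if w.endswith("e"):
            stem = w[:-1]
            m = _measure(stem)
            if m > 1 or (m == 1 and not _ends_cvc(stem)):
                w = stem
        if w.endswith("ll") and _measure(w[:-1]) > 1:
            w = w[:-1]
        return w


_DEFAULT = PorterStemmer()


def stem_word(word: str) -> str:
    """Stem a single word with the default (``adverbial_li``) dialect."""
    return _DEFAULT.stem(word)
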