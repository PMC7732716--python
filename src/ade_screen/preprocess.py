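"""Text cleaning and Japanese-rule sentence segmentation.

Sentences are split after the Japanese full stop and after an ASCII
period only when the period immediately follows a Japanese letter
(hiragana, katakana, or a CJK ideograph).  A period after a digit —
"3.5" — therefore never opens a new sentence.  Delimiters stay attached
to the preceding sentence so that joining the output reproduces the
input exactly.
"""

from __future__ import annotations

DEFAULT_STRIP_SET = frozenset({"$", "^"})

JAPANESE_FULL_STOP = "。"  # 。


def is_japanese_letter(ch: str) -> bool:
    """True for hiragana (U+3040–309F), katakana (U+30A0–30FF) or CJK
    unified ideographs (U+4E00–9FFF)."""
    cp = ord(ch)
    return 0x3040 <= cp <= 0x30FF or 0x4E00 <= cp <= 0x9FFF


def clean_text(raw: str, strip_set: frozenset[str] | set[str] = DEFAULT_STRIP_SET) -> str:
    """Remove every character in ``strip_set``; preserve all others in order."""
    if not strip_set:
        return raw
    return "".join(ch for ch in raw if ch not in strip_set)


def split_sentences(text: str) -> list[str]:
    """Segment cleaned text into sentences.

    Splits after every "。", and after "." only when the preceding
    character is a Japanese letter.  Newlines are ordinary characters,
    not boundaries.  Empty segments are dropped; the concatenation of
    the output equals the input.
    """
    sentences: list[str] = []
    buf: list[str] = []
    prev = ""
    for ch in text:
        buf.append(ch)
        if ch == JAPANESE_FULL_STOP or (ch == "." and prev and is_japanese_letter(prev)):
            sentences.append("".join(buf))
            buf = []
        prev = ch
    if buf:
        sentences.append("".join(buf))
    return sentences
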