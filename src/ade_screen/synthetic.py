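"""Seeded synthetic corpora and toy term dictionaries.

The generator emulates the statistical structure of an annotated corpus
of Japanese medical case reports screened for adverse drug events
(ADEs), so that every other module is testable without any external
data:

* ~58.9% of articles are ADE containing;
* each positive article holds one contiguous run of ADE-suggesting
  sentences with length ~ Normal(3.9, 2.7) truncated to >= 1 and
  rounded, among background sentences counted ~ Normal(48.2, 72.1)
  truncated to >= 1;
* ADE-suggesting sentences follow a criterion-A template (a drug
  mention, then a cue phrase and an adverse-event mention) with a
  criterion-B template (an explicit ADE statement) mixed at the
  observed 3.5 : 0.4 rate;
* entity mentions are drawn from toy dictionaries with surface-form
  variants and optional per-character noise; background sentences carry
  entity mentions at the same rate in both classes, so with
  cue_strength = 0 the classes are textually indistinguishable;
* "general statement" distractor sentences (a disease described without
  a patient case) are mixed into the background at a configurable rate.

Text is a whitespace-tokenizable pseudo-language over a closed syllable
inventory; sentences end with the Japanese full stop so the segmentation
path is exercised.  An optional katakana mode transliterates tokens into
Japanese script.  Identical config + seed yields a byte-identical corpus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Article, Dictionary, EntitySpan, Sentence, validate_article
from .normalize import similarity

SYLLABLES = (
    "ka ki ku ke ko sa shi su se so ta chi tsu te to na ni nu ne no "
    "ha hi fu he ho ma mi mu me mo ya yu yo ra ri ru re ro wa "
    "ga gi gu ge go za ji zu ze zo da de do ba bi bu be bo pa pi pu pe po"
).split()

_KANA = {
    "ka": "カ", "ki": "キ", "ku": "ク", "ke": "ケ", "ko": "コ",
    "sa": "サ", "shi": "シ", "su": "ス", "se": "セ", "so": "ソ",
    "ta": "タ", "chi": "チ", "tsu": "ツ", "te": "テ", "to": "ト",
    "na": "ナ", "ni": "ニ", "nu": "ヌ", "ne": "ネ", "no": "ノ",
    "ha": "ハ", "hi": "ヒ", "fu": "フ", "he": "ヘ", "ho": "ホ",
    "ma": "マ", "mi": "ミ", "mu": "ム", "me": "メ", "mo": "モ",
    "ya": "ヤ", "yu": "ユ", "yo": "ヨ",
    "ra": "ラ", "ri": "リ", "ru": "ル", "re": "レ", "ro": "ロ", "wa": "ワ",
    "ga": "ガ", "gi": "ギ", "gu": "グ", "ge": "ゲ", "go": "ゴ",
    "za": "ザ", "ji": "ジ", "zu": "ズ", "ze": "ゼ", "zo": "ゾ",
    "da": "ダ", "de": "デ", "do": "ド",
    "ba": "バ", "bi": "ビ", "bu": "ブ", "be": "ベ", "bo": "ボ",
    "pa": "パ", "pi": "ピ", "pu": "プ", "pe": "ペ", "po": "ポ",
}

DISEASE_SUFFIXES = ("itis", "osis", "emia", "pathy")
DRUG_SUFFIXES = ("mab", "nib", "pril", "statin", "olol")

# closed cue vocabularies, disjoint from entity and filler tokens by
# construction (fillers/entities are syllable strings; cues carry "q").
# Cue phrases are multi-word expressions ("we stopped the drug"-style), so
# one cue fires several word-token features at once, sharing tokens across
# phrases the way real cue expressions share words.
CUE_PHRASES_A = (
    ("weq", "stoppedq", "theq", "drugq"),
    ("causedq", "byq", "theq", "drugq"),
    ("afterq", "dosingq", "onsetq"),
    ("adverseq", "eventq", "afterq", "administrationq"),
    ("drugq", "wasq", "discontinuedq"),
    ("onsetq", "afterq", "prescriptionq"),
)
CUE_PHRASES_B = (
    ("suspectedq", "adverseq", "reactionq"),
    ("drugq", "inducedq", "eventq"),
    ("sideq", "effectq", "observedq"),
)
GENERAL_MARKERS = ("isqcharacterized", "inqgeneral", "reportedqoverall",
                   "literatureqreview")

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass
class GeneratorConfig:
    """Study conditions of the emulated corpus.

    The defaults are the observed corpus statistics: positive-document
    rate 0.589; ADE-suggesting run length mean 3.9 (SD 2.7); background
    sentence count mean 48.2 (SD 72.1), both truncated to >= 1;
    criterion-B share 0.4/3.9 of ADE-suggesting sentences.
    """

    n_docs: int = 100
    positive_rate: float = 0.589
    ade_run_mean: float = 3.9
    ade_run_sd: float = 2.7
    nonade_sent_mean: float = 48.2
    nonade_sent_sd: float = 72.1
    criterion_b_rate: float = 0.4 / 3.9
    n_diseases: int = 30
    n_drugs: int = 30
    variant_noise: float = 0.05     # per-character perturbation prob. of mentions
    cue_strength: float = 0.9       # prob. a positive sentence uses an ADE template
    bg_entity_rate: float = 0.3     # prob. a background sentence mentions an entity
    distractor_rate: float = 0.1    # prob. a background sentence is a general statement
    filler_vocab_size: int = 200
    kana: bool = False              # transliterate tokens into katakana
    seed: int = 0

    def __post_init__(self):
        for name in ("positive_rate", "variant_noise", "cue_strength",
                     "bg_entity_rate", "distractor_rate", "criterion_b_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("ade_run_mean", "nonade_sent_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _syllable_word(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    idx = rng.integers(0, len(SYLLABLES), size=n)
    return "".join(SYLLABLES[i] for i in idx)


def _perturb_once(name: str, rng: np.random.Generator) -> str:
    """One random character edit (substitute, delete, or insert)."""
    i = int(rng.integers(0, len(name)))
    op = int(rng.integers(0, 3))
    ch = _LETTERS[int(rng.integers(0, len(_LETTERS)))]
    if op == 0:
        return name[:i] + ch + name[i + 1:]
    if op == 1 and len(name) > 2:
        return name[:i] + name[i + 1:]
    return name[:i] + ch + name[i:]


def generate_dictionaries(config: GeneratorConfig) -> tuple[Dictionary, Dictionary]:
    """Toy disease and drug dictionaries: canonical names from a closed
    syllable inventory, each with 1-3 surface variants mapping to the
    same standard name; the two surface sets are disjoint, and every
    variant keeps similarity > 0.3 to its canonical form."""
    if config.n_diseases < 1 or config.n_drugs < 1:
        raise ValueError("n_diseases and n_drugs must be >= 1")
    rng = np.random.default_rng((config.seed, 0xD1C7))
    used: set[str] = set()

    def build(n: int, suffixes: tuple[str, ...]) -> dict[str, str]:
        entries: dict[str, str] = {}
        for _ in range(n):
            while True:
                canonical = _syllable_word(rng, 2, 4) + suffixes[int(rng.integers(0, len(suffixes)))]
                if canonical not in used:
                    break
            used.add(canonical)
            entries[canonical] = canonical
            for _ in range(int(rng.integers(0, 3))):
                for _attempt in range(20):
                    variant = _perturb_once(canonical, rng)
                    if variant not in used and variant != canonical \
                            and similarity(variant, canonical) > 0.3:
                        used.add(variant)
                        entries[variant] = canonical
                        break
        return entries

    disease = Dictionary(etype="disease", entries=build(config.n_diseases, DISEASE_SUFFIXES))
    drug = Dictionary(etype="drug", entries=build(config.n_drugs, DRUG_SUFFIXES))
    return disease, drug


# ---------------------------------------------------------------------------
# corpus generation

def _kana_token(token: str) -> str:
    """Transliterate a syllable token into katakana (non-syllable tokens,
    e.g. cue phrases, are left as is)."""
    out = []
    i = 0
    while i < len(token):
        for l in (3, 2):
            if token[i:i + l] in _KANA:
                out.append(_KANA[token[i:i + l]])
                i += l
                break
        else:
            return token  # not pure-syllable; leave unchanged
    return "".join(out)


class _Maker:
    def __init__(self, config: GeneratorConfig, disease: Dictionary,
                 drug: Dictionary, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.surfaces = {"disease": sorted(disease.entries),
                         "drug": sorted(drug.entries)}
        reserved = set(disease.entries) | set(drug.entries)
        fillers = []
        while len(fillers) < config.filler_vocab_size:
            w = _syllable_word(rng, 2, 3)
            if w not in reserved:
                fillers.append(w)
                reserved.add(w)
        self.fillers = fillers

    def _mention(self, etype: str) -> str:
        pool = self.surfaces[etype]
        surf = pool[int(self.rng.integers(0, len(pool)))]
        if self.cfg.variant_noise > 0:
            chars = list(surf)
            for i in range(len(chars)):
                if self.rng.random() < self.cfg.variant_noise:
                    chars[i] = _LETTERS[int(self.rng.integers(0, len(_LETTERS)))]
            surf = "".join(chars)
        return surf

    def _fillers(self, lo: int, hi: int) -> list[str]:
        n = int(self.rng.integers(lo, hi + 1))
        idx = self.rng.integers(0, len(self.fillers), size=n)
        return [self.fillers[i] for i in idx]

    def _assemble(self, sent_id: int, parts: list[tuple[str, str | None]],
                  sent_label: int, criterion: str) -> Sentence:
        """parts: (token, etype-or-None); builds text + spans with offsets."""
        if self.cfg.kana:
            parts = [(tok if et is not None else _kana_token(tok), et)
                     for tok, et in parts]
        tokens = [tok for tok, _ in parts]
        text = " ".join(tokens) + "。"
        spans = []
        pos = 0
        for tok, etype in parts:
            if etype is not None:
                spans.append(EntitySpan(pos, pos + len(tok), etype, tok))
            pos += len(tok) + 1
        return Sentence(sent_id, text, sent_label, criterion, tuple(spans))

    def background(self, sent_id: int) -> Sentence:
        r = self.rng.random()
        if r < self.cfg.distractor_rate:
            # general statement: a disease discussed without a patient case
            marker = GENERAL_MARKERS[int(self.rng.integers(0, len(GENERAL_MARKERS)))]
            parts = [(t, None) for t in self._fillers(1, 3)]
            parts += [(self._mention("disease"), "disease"), (marker, None)]
            parts += [(t, None) for t in self._fillers(2, 5)]
            return self._assemble(sent_id, parts, 0, "none")
        parts: list[tuple[str, str | None]] = [(t, None) for t in self._fillers(5, 12)]
        if self.rng.random() < self.cfg.bg_entity_rate:
            etype = "disease" if self.rng.random() < 0.5 else "drug"
            k = int(self.rng.integers(0, len(parts) + 1))
            parts.insert(k, (self._mention(etype), etype))
        return self._assemble(sent_id, parts, 0, "none")

    def ade_sentence(self, sent_id: int) -> Sentence:
        if self.rng.random() >= self.cfg.cue_strength:
            # textual signal absent: sentence looks like background, but the
            # annotation (known from context) still marks it ADE suggesting
            bg = self.background(sent_id)
            return Sentence(sent_id, bg.text, 1, "A", bg.spans)
        if self.rng.random() < self.cfg.criterion_b_rate:
            cue = CUE_PHRASES_B[int(self.rng.integers(0, len(CUE_PHRASES_B)))]
            parts = [(t, None) for t in cue]
            parts += [(self._mention("disease"), "disease")]
            parts += [(t, None) for t in self._fillers(1, 4)]
            return self._assemble(sent_id, parts, 1, "B")
        cue = CUE_PHRASES_A[int(self.rng.integers(0, len(CUE_PHRASES_A)))]
        parts = [(t, None) for t in self._fillers(1, 3)]
        parts += [(self._mention("drug"), "drug")]
        parts += [(t, None) for t in self._fillers(1, 2)]
        parts += [(t, None) for t in cue]
        parts += [(self._mention("disease"), "disease")]
        parts += [(t, None) for t in self._fillers(0, 2)]
        return self._assemble(sent_id, parts, 1, "A")


def _trunc_round_normal(rng: np.random.Generator, mean: float, sd: float) -> int:
    return max(1, round(float(rng.normal(mean, sd))))


def generate_corpus(config: GeneratorConfig,
                    dictionaries: tuple[Dictionary, Dictionary] | None = None
                    ) -> list[Article]:
    """Generate a labeled corpus under the configured study conditions."""
    if dictionaries is None:
        dictionaries = generate_dictionaries(config)
    disease, drug = dictionaries
    rng = np.random.default_rng((config.seed, 0xC0))
    maker = _Maker(config, disease, drug, rng)
    articles: list[Article] = []
    for d in range(config.n_docs):
        positive = rng.random() < config.positive_rate
        n_bg = _trunc_round_normal(rng, config.nonade_sent_mean, config.nonade_sent_sd)
        kinds = ["bg"] * n_bg
        if positive:
            run_len = _trunc_round_normal(rng, config.ade_run_mean, config.ade_run_sd)
            at = int(rng.integers(0, n_bg + 1))
            kinds[at:at] = ["ade"] * run_len
        sentences = []
        for sid, kind in enumerate(kinds):
            sentences.append(maker.ade_sentence(sid) if kind == "ade"
                             else maker.background(sid))
        raw_text = "".join(s.text for s in sentences)
        article = Article(doc_id=f"doc{d:05d}", raw_text=raw_text,
                          sentences=tuple(sentences),
                          doc_label=1 if positive else 0)
        validate_article(article)
        articles.append(article)
    return articles


# ---------------------------------------------------------------------------
# OCR-noise robustness

def perturb_ocr(article: Article, char_error_rate: float, seed: int = 0) -> Article:
    """Simulate OCR noise: characters independently substituted or deleted
    at ``char_error_rate``; gold span offsets are remapped, and a span all
    of whose characters were deleted is dropped.  Labels are unchanged."""
    if not 0.0 <= char_error_rate < 1.0:
        raise ValueError("char_error_rate must lie in [0, 1)")
    rng = np.random.default_rng((seed, 0x0C2))
    new_sentences = []
    for sent in article.sentences:
        out_chars: list[str] = []
        new_index: list[int | None] = []   # old position -> new position
        for ch in sent.text:
            if rng.random() < char_error_rate:
                if rng.random() < 0.5:
                    new_index.append(None)          # deletion
                    continue
                ch = _LETTERS[int(rng.integers(0, len(_LETTERS)))]  # substitution
            new_index.append(len(out_chars))
            out_chars.append(ch)
        new_text = "".join(out_chars)
        if not new_text:
            new_text = " "       # keep the sentence non-empty (fully erased line)
        spans = []
        prev_end = 0
        for sp in sent.spans:
            surviving = [new_index[i] for i in range(sp.start, sp.end)
                         if new_index[i] is not None]
            if not surviving:
                continue
            s, e = surviving[0], surviving[-1] + 1
            if s < prev_end:
                continue
            prev_end = e
            spans.append(EntitySpan(s, e, sp.etype, new_text[s:e], sp.standard))
        new_sentences.append(Sentence(sent.sent_id, new_text, sent.sent_label,
                                      sent.criterion, tuple(spans)))
    raw_text = "".join(s.text for s in new_sentences)
    return Article(article.doc_id, raw_text, tuple(new_sentences), article.doc_label)
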