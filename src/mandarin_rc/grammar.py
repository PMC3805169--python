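"""Probabilistic finite-state grammar over a 28-unit localist vocabulary.

The grammar generates simple Mandarin-like sentences and sentences with a
single, non-recursive relative clause (RC) at the matrix subject and/or
object position.  Production probabilities encode corpus-derived bigram
transitional statistics: the overt-subject/pro-drop split, the
transitive/intransitive VP split, per-position RC rates, RC-type splits,
and animacy-conditioned embedded-noun and head-noun choices.

The module serves three roles:

* **generator** — :func:`sample_sentence` / :func:`generate_corpus` draw
  training and test sentences (words uniform within category);
* **analytic oracle** — :func:`enumerate_templates` lists every
  category-level sentence pattern with its exact joint probability, from
  which prefix masses and exact next-category conditional distributions
  (the target activations for prediction-error scoring) are derived;
* **file formats** — a plain-text corpus format and a YAML grammar config.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Category",
    "CATEGORY_UNITS",
    "UNIT_CATEGORY",
    "VOCABULARY",
    "NOUN_CATEGORY",
    "GrammarSpec",
    "RCAnnotation",
    "SentenceTemplate",
    "TemplateSet",
    "Sentence",
    "Corpus",
    "UngrammaticalPrefixError",
    "enumerate_templates",
    "sample_category_sequence",
    "sample_sentence",
    "generate_corpus",
]


class Category(str, enum.Enum):
    """The six grammatical categories of the 28-unit vocabulary."""

    ANI_N = "aniN"   # animate nouns
    INA_N = "inaN"   # inanimate nouns
    VT = "VT"        # transitive verbs
    VI = "VI"        # intransitive verbs
    DE = "DE"        # relativizer particle, ends the RC, precedes the head
    EOS = "EOS"      # end-of-sentence marker

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# Fixed unit layout: 0-6 aniN, 7-13 inaN, 14-19 VT, 20-25 VI, 26 DE, 27 EOS.
CATEGORY_UNITS: dict[Category, tuple[int, ...]] = {
    Category.ANI_N: tuple(range(0, 7)),
    Category.INA_N: tuple(range(7, 14)),
    Category.VT: tuple(range(14, 20)),
    Category.VI: tuple(range(20, 26)),
    Category.DE: (26,),
    Category.EOS: (27,),
}

N_UNITS = 28

UNIT_CATEGORY: tuple[Category, ...] = tuple(
    cat for cat in Category for _ in CATEGORY_UNITS[cat]
)

VOCABULARY: tuple[str, ...] = tuple(
    f"{cat.value}{i + 1}" if len(CATEGORY_UNITS[cat]) > 1 else cat.value
    for cat in Category
    for i in range(len(CATEGORY_UNITS[cat]))
)

_WORD_INDEX: dict[str, int] = {w: i for i, w in enumerate(VOCABULARY)}

# Animacy labels used throughout ("ani"/"ina") and the noun category they map to.
NOUN_CATEGORY: dict[str, Category] = {"ani": Category.ANI_N, "ina": Category.INA_N}

_PROB_TOL = 1e-9


class UngrammaticalPrefixError(ValueError):
    """Raised when a category prefix has zero probability under the grammar."""

    def __init__(self, prefix: Sequence[Category], first_bad: int):
        self.prefix = tuple(prefix)
        #: index into ``prefix`` of the first symbol at which the mass drops to 0
        self.first_bad = first_bad
        super().__init__(
            f"prefix {[c.value for c in prefix]} has zero probability "
            f"(first ungrammatical symbol at index {first_bad})"
        )


def _check_split(name: str, split: Mapping[str, float]) -> None:
    total = sum(split.values())
    if abs(total - 1.0) > _PROB_TOL:
        raise ValueError(f"{name} must sum to 1, got {total!r}")
    for key, p in split.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}[{key}] = {p!r} outside [0, 1]")


@dataclass(frozen=True)
class GrammarSpec:
    """All production probabilities of the sentence grammar.

    Defaults are the corpus-derived transitional probabilities used to build
    the 10,000-sentence training corpus.  Splits keyed by ``"subject"`` /
    ``"object"`` refer to the matrix position the RC modifies; animacy keys
    are ``"ani"`` / ``"ina"``.
    """

    p_subject: dict[str, float] = field(
        default_factory=lambda: {"overt": 0.7, "prodrop": 0.3}
    )
    p_vp: dict[str, float] = field(default_factory=lambda: {"vi": 0.21, "vt": 0.79})
    subject_np: dict[str, float] = field(
        default_factory=lambda: {"ani": 0.5, "ina": 0.34, "rc": 0.16}
    )
    object_np: dict[str, float] = field(
        default_factory=lambda: {"ani": 0.18, "ina": 0.73, "rc": 0.09}
    )
    rc_type: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "subject": {"SRC_VI": 0.11, "SRC": 0.58, "ORC": 0.31},
            "object": {"SRC_VI": 0.26, "SRC": 0.47, "ORC": 0.27},
        }
    )
    # intransitive SRC:  VI + DE + head
    src_vi_head: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "subject": {"ani": 0.2, "ina": 0.8},
            "object": {"ani": 0.31, "ina": 0.69},
        }
    )
    # transitive SRC:  VT + embedded noun + DE + head
    src_embedded: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "subject": {"ani": 0.35, "ina": 0.65},
            "object": {"ani": 0.29, "ina": 0.71},
        }
    )
    src_head: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=lambda: {
            "subject": {
                "ani": {"ani": 0.47, "ina": 0.53},
                "ina": {"ani": 0.87, "ina": 0.13},
            },
            "object": {
                "ani": {"ani": 0.53, "ina": 0.47},
                "ina": {"ani": 0.45, "ina": 0.55},
            },
        }
    )
    # ORC:  embedded noun + VT + DE + head
    orc_embedded: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "subject": {"ani": 0.88, "ina": 0.12},
            "object": {"ani": 0.80, "ina": 0.20},
        }
    )
    orc_head: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=lambda: {
            "subject": {
                "ani": {"ani": 0.06, "ina": 0.94},
                "ina": {"ani": 0.0, "ina": 1.0},
            },
            "object": {
                "ani": {"ani": 0.11, "ina": 0.89},
                "ina": {"ani": 0.0, "ina": 1.0},
            },
        }
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_split("p_subject", self.p_subject)
        _check_split("p_vp", self.p_vp)
        _check_split("subject_np", self.subject_np)
        _check_split("object_np", self.object_np)
        for pos in ("subject", "object"):
            _check_split(f"rc_type[{pos}]", self.rc_type[pos])
            _check_split(f"src_vi_head[{pos}]", self.src_vi_head[pos])
            _check_split(f"src_embedded[{pos}]", self.src_embedded[pos])
            _check_split(f"orc_embedded[{pos}]", self.orc_embedded[pos])
            for emb in ("ani", "ina"):
                _check_split(f"src_head[{pos}][{emb}]", self.src_head[pos][emb])
                _check_split(f"orc_head[{pos}][{emb}]", self.orc_head[pos][emb])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "GrammarSpec":
        return cls(**{k: data[k] for k in cls.__dataclass_fields__ if k in data})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GrammarSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Short content hash identifying the grammar in file headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def structural_variant(self, delta: float = 1e-9) -> "GrammarSpec":
        """Copy of the grammar with zero-probability head-animacy cells set to
        ``delta``.

        Conditional next-category distributions computed from the variant
        converge, as ``delta`` goes to 0, to the limiting "structural"
        distributions for prefixes that are category-grammatical but carry an
        animacy configuration of probability zero (an ORC with an inanimate
        embedded noun and an animate head).  Used to score such test items.
        """
        data = self.to_dict()
        for pos in ("subject", "object"):
            smoothed = {}
            for emb, split in data["orc_head"][pos].items():
                if any(p == 0.0 for p in split.values()):
                    raised = {k: (delta if p == 0.0 else p) for k, p in split.items()}
                    norm = sum(raised.values())
                    split = {k: v / norm for k, v in raised.items()}
                smoothed[emb] = split
            data["orc_head"][pos] = smoothed
        return GrammarSpec.from_dict(data)


@dataclass(frozen=True)
class RCAnnotation:
    """Location and description of one relative clause inside a template."""

    rc_type: str            # "SRC_VI" | "SRC" | "ORC"
    position: str           # "subject" | "object" (matrix position modified)
    embedded_animacy: str | None  # None for SRC_VI (no embedded noun)
    head_animacy: str       # "ani" | "ina"
    start: int              # index of the first RC-internal word
    de_index: int
    head_index: int         # head noun; always de_index + 1


@dataclass(frozen=True)
class SentenceTemplate:
    """One category-level sentence pattern with its exact joint probability."""

    categories: tuple[Category, ...]
    probability: float
    subject_kind: str               # "ani" | "ina" | "rc" | "prodrop"
    vp_kind: str                    # "vi" | "vt"
    object_kind: str | None         # "ani" | "ina" | "rc" | None (intransitive)
    subject_rc: RCAnnotation | None
    object_rc: RCAnnotation | None

    def __post_init__(self) -> None:
        if self.probability <= 0.0:
            raise ValueError("template probability must be positive")
        if self.categories[-1] is not Category.EOS:
            raise ValueError("template must end in EOS")


def _rc_variants(grammar: GrammarSpec, position: str):
    """Expand the RC production at one matrix position.

    Yields ``(categories, rc_type, embedded_animacy, head_animacy, prob)``
    where ``categories`` covers the RC-internal words, DE and the head noun,
    and ``prob`` is the product of the RC-internal splits (RC-type, embedded
    animacy where applicable, head animacy).  Zero-probability animacy cells
    are skipped.
    """
    types = grammar.rc_type[position]
    for head, p_head in grammar.src_vi_head[position].items():
        p = types["SRC_VI"] * p_head
        if p > 0.0:
            cats = (Category.VI, Category.DE, NOUN_CATEGORY[head])
            yield cats, "SRC_VI", None, head, p
    for emb, p_emb in grammar.src_embedded[position].items():
        for head, p_head in grammar.src_head[position][emb].items():
            p = types["SRC"] * p_emb * p_head
            if p > 0.0:
                cats = (Category.VT, NOUN_CATEGORY[emb], Category.DE,
                        NOUN_CATEGORY[head])
                yield cats, "SRC", emb, head, p
    for emb, p_emb in grammar.orc_embedded[position].items():
        for head, p_head in grammar.orc_head[position][emb].items():
            p = types["ORC"] * p_emb * p_head
            if p > 0.0:
                cats = (NOUN_CATEGORY[emb], Category.VT, Category.DE,
                        NOUN_CATEGORY[head])
                yield cats, "ORC", emb, head, p


class TemplateSet:
    """The complete enumeration of positive-probability sentence patterns.

    Supports exact prefix masses, conditional next-category distributions
    and probability mass of annotated template families.
    """

    def __init__(self, templates: Sequence[SentenceTemplate], grammar: GrammarSpec):
        self.templates: tuple[SentenceTemplate, ...] = tuple(templates)
        self.grammar = grammar
        self._by_categories = {t.categories: t for t in self.templates}
        if len(self._by_categories) != len(self.templates):
            raise ValueError("duplicate category-level sentence patterns")
        total = sum(t.probability for t in self.templates)
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(f"template probabilities sum to {total!r}, not 1")
        self._mass_cache: dict[tuple[Category, ...], float] = {}

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates)

    def lookup(self, categories: Sequence[Category]) -> SentenceTemplate:
        """Template whose category string equals ``categories`` exactly."""
        return self._by_categories[tuple(categories)]

    def prefix_mass(self, prefix: Sequence[Category]) -> float:
        """Summed probability of all templates starting with ``prefix``.

        Returns 0 for prefixes matching no template; callers must treat 0 as
        an ungrammatical context.
        """
        key = tuple(prefix)
        cached = self._mass_cache.get(key)
        if cached is not None:
            return cached
        n = len(key)
        mass = sum(
            t.probability for t in self.templates if t.categories[:n] == key
        )
        self._mass_cache[key] = mass
        return mass

    def next_category_distribution(
        self, prefix: Sequence[Category] = ()
    ) -> dict[Category, float]:
        """Exact conditional distribution of the next category given ``prefix``.

        The empty prefix gives the sentence-initial distribution.  For each
        category ``c`` the value is ``prefix_mass(prefix + [c]) /
        prefix_mass(prefix)``; zero-probability continuations are included
        with value 0.  Raises :class:`UngrammaticalPrefixError` when the
        prefix itself has zero mass.
        """
        prefix = tuple(prefix)
        mass = self.prefix_mass(prefix)
        if mass <= 0.0:
            # locate the first symbol at which the mass vanished
            for i in range(1, len(prefix) + 1):
                if self.prefix_mass(prefix[:i]) <= 0.0:
                    raise UngrammaticalPrefixError(prefix, i - 1)
            raise UngrammaticalPrefixError(prefix, len(prefix) - 1)
        dist = {
            c: self.prefix_mass(prefix + (c,)) / mass for c in Category
        }
        return dist

    def mass(self, where: Callable[[SentenceTemplate], bool]) -> float:
        """Summed probability of templates satisfying the predicate.

        Used to evaluate joint probabilities of annotated families, e.g. the
        mass of all sentences whose matrix subject is a bare animate noun.
        """
        return sum(t.probability for t in self.templates if where(t))


def enumerate_templates(grammar: GrammarSpec) -> TemplateSet:
    """Enumerate every positive-probability category-level sentence pattern.

    Subject and VP expansions are independent, so the enumeration is the
    cross product of subject options (bare animate/inanimate noun, each RC
    variant's head, or pro-drop) and VP options (intransitive, or transitive
    with a bare-noun or RC-modified object), each pattern terminated by EOS.
    """
    p_overt = grammar.p_subject["overt"]
    p_drop = grammar.p_subject["prodrop"]

    # (categories, subject_kind, rc_annotation, probability)
    subject_options: list[tuple[tuple[Category, ...], str, RCAnnotation | None, float]] = [
        ((Category.ANI_N,), "ani", None, p_overt * grammar.subject_np["ani"]),
        ((Category.INA_N,), "ina", None, p_overt * grammar.subject_np["ina"]),
    ]
    for cats, rc_type, emb, head, p in _rc_variants(grammar, "subject"):
        ann = RCAnnotation(
            rc_type=rc_type, position="subject", embedded_animacy=emb,
            head_animacy=head, start=0, de_index=len(cats) - 2,
            head_index=len(cats) - 1,
        )
        subject_options.append(
            (cats, "rc", ann, p_overt * grammar.subject_np["rc"] * p)
        )
    subject_options.append(((), "prodrop", None, p_drop))

    # (categories, vp_kind, object_kind, rc_annotation_relative, probability)
    vp_options: list[
        tuple[tuple[Category, ...], str, str | None, RCAnnotation | None, float]
    ] = [((Category.VI,), "vi", None, None, grammar.p_vp["vi"])]
    p_vt = grammar.p_vp["vt"]
    vp_options.append(
        ((Category.VT, Category.ANI_N), "vt", "ani", None,
         p_vt * grammar.object_np["ani"])
    )
    vp_options.append(
        ((Category.VT, Category.INA_N), "vt", "ina", None,
         p_vt * grammar.object_np["ina"])
    )
    for cats, rc_type, emb, head, p in _rc_variants(grammar, "object"):
        ann = RCAnnotation(
            rc_type=rc_type, position="object", embedded_animacy=emb,
            head_animacy=head, start=1, de_index=len(cats) - 1,
            head_index=len(cats),
        )
        vp_options.append(
            ((Category.VT,) + cats, "vt", "rc", ann,
             p_vt * grammar.object_np["rc"] * p)
        )

    templates = []
    for s_cats, s_kind, s_rc, s_p in subject_options:
        offset = len(s_cats)
        for v_cats, v_kind, o_kind, o_rc, v_p in vp_options:
            if o_rc is not None:
                o_rc_shifted = RCAnnotation(
                    rc_type=o_rc.rc_type, position="object",
                    embedded_animacy=o_rc.embedded_animacy,
                    head_animacy=o_rc.head_animacy,
                    start=offset + o_rc.start,
                    de_index=offset + o_rc.de_index,
                    head_index=offset + o_rc.head_index,
                )
            else:
                o_rc_shifted = None
            templates.append(
                SentenceTemplate(
                    categories=s_cats + v_cats + (Category.EOS,),
                    probability=s_p * v_p,
                    subject_kind=s_kind,
                    vp_kind=v_kind,
                    object_kind=o_kind,
                    subject_rc=s_rc,
                    object_rc=o_rc_shifted,
                )
            )
    return TemplateSet(templates, grammar)


@dataclass(frozen=True)
class Sentence:
    """A concrete token sequence with parallel categories.

    ``template`` is the category-level pattern the sentence instantiates
    (``None`` for sentences read back from disk without a template set).
    """

    tokens: tuple[int, ...]
    template: SentenceTemplate | None = None

    @property
    def categories(self) -> tuple[Category, ...]:
        return tuple(UNIT_CATEGORY[t] for t in self.tokens)

    @property
    def words(self) -> tuple[str, ...]:
        return tuple(VOCABULARY[t] for t in self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


def _draw(rng: np.random.Generator, split: Mapping[str, float]) -> str:
    """Draw a key from a categorical split (fixed insertion order)."""
    u = rng.random()
    acc = 0.0
    keys = list(split)
    for k in keys:
        acc += split[k]
        if u < acc:
            return k
    return keys[-1]


def sample_category_sequence(
    grammar: GrammarSpec, rng: np.random.Generator
) -> tuple[Category, ...]:
    """Sample one category-level sentence by walking the generative process.

    Independent of :func:`enumerate_templates`; used as a brute-force check
    of the enumeration.
    """
    cats: list[Category] = []

    def emit_rc(position: str) -> None:
        rc_type = _draw(rng, grammar.rc_type[position])
        if rc_type == "SRC_VI":
            head = _draw(rng, grammar.src_vi_head[position])
            cats.extend((Category.VI, Category.DE, NOUN_CATEGORY[head]))
        elif rc_type == "SRC":
            emb = _draw(rng, grammar.src_embedded[position])
            head = _draw(rng, grammar.src_head[position][emb])
            cats.extend((Category.VT, NOUN_CATEGORY[emb], Category.DE,
                         NOUN_CATEGORY[head]))
        else:
            emb = _draw(rng, grammar.orc_embedded[position])
            head = _draw(rng, grammar.orc_head[position][emb])
            cats.extend((NOUN_CATEGORY[emb], Category.VT, Category.DE,
                         NOUN_CATEGORY[head]))

    if _draw(rng, grammar.p_subject) == "overt":
        kind = _draw(rng, grammar.subject_np)
        if kind == "rc":
            emit_rc("subject")
        else:
            cats.append(NOUN_CATEGORY[kind])
    if _draw(rng, grammar.p_vp) == "vi":
        cats.append(Category.VI)
    else:
        cats.append(Category.VT)
        kind = _draw(rng, grammar.object_np)
        if kind == "rc":
            emit_rc("object")
        else:
            cats.append(NOUN_CATEGORY[kind])
    cats.append(Category.EOS)
    return tuple(cats)


def sample_words(
    categories: Sequence[Category], rng: np.random.Generator
) -> tuple[int, ...]:
    """Choose a word index for each category, uniform within category."""
    return tuple(
        CATEGORY_UNITS[c][rng.integers(len(CATEGORY_UNITS[c]))]
        for c in categories
    )


def sample_sentence(
    grammar: GrammarSpec,
    rng: np.random.Generator,
    templates: TemplateSet | None = None,
) -> Sentence:
    """Draw one sentence: a category pattern from the grammar, then words
    uniform within each category.

    Passing ``templates`` attaches the matching annotated template to the
    sentence (it never influences the draw).
    """
    cats = sample_category_sequence(grammar, rng)
    tokens = sample_words(cats, rng)
    template = templates.lookup(cats) if templates is not None else None
    return Sentence(tokens=tokens, template=template)


@dataclass
class Corpus:
    """A list of sentences plus the provenance recorded in corpus files."""

    sentences: list[Sentence]
    grammar_hash: str = ""
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)

    def token_sequences(self) -> set[tuple[int, ...]]:
        """Distinct token sequences, for novelty checks against test items."""
        return {s.tokens for s in self.sentences}

    def write(self, path: str | Path) -> None:
        """One sentence per line, space-separated vocabulary words; a header
        comment records the grammar hash, size and seed."""
        lines = [f"# grammar={self.grammar_hash} n={len(self.sentences)} "
                 f"seed={self.seed}"]
        lines += [" ".join(s.words) for s in self.sentences]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | Path, templates: TemplateSet | None = None) -> "Corpus":
        text = Path(path).read_text().strip().splitlines()
        grammar_hash, seed = "", None
        body = text
        if text and text[0].startswith("#"):
            header = dict(
                kv.split("=", 1) for kv in text[0].lstrip("# ").split() if "=" in kv
            )
            grammar_hash = header.get("grammar", "")
            seed = None if header.get("seed") in (None, "None") else int(header["seed"])
            body = text[1:]
        sentences = []
        for line in body:
            tokens = tuple(_WORD_INDEX[w] for w in line.split())
            template = None
            if templates is not None:
                cats = tuple(UNIT_CATEGORY[t] for t in tokens)
                template = templates._by_categories.get(cats)
            sentences.append(Sentence(tokens=tokens, template=template))
        return cls(sentences=sentences, grammar_hash=grammar_hash, seed=seed)


def generate_corpus(
    grammar: GrammarSpec,
    n: int,
    seed: int,
    templates: TemplateSet | None = None,
) -> Corpus:
    """Generate ``n`` independent sentences, reproducibly from ``seed``."""
    if n < 1:
        raise ValueError(f"corpus size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    sentences = [sample_sentence(grammar, rng, templates) for _ in range(n)]
    return Corpus(sentences=sentences, grammar_hash=grammar.hash(), seed=seed)
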