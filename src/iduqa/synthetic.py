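"""Synthetic clinical-note corpora with planted, gold-annotated IDU facts.

Real VA clinical notes are not shareable, so every other module is exercised
on generated notes: boilerplate sections (chief complaint, demographics,
family history, exam, plan) with IDU snippets planted into a social-history
section. Snippet templates are seeded from published exemplar sentences (the
query-group sample answers and the free-text forms quoted in the source
material) with slot-filled drug names and durations, so each planted fact's
reduced answer is known by construction. Negative notes are verified
keyword-free against the lexicon.

Formatting noise (newlines after commas, mid-sentence line breaks, repeated
punctuation) is injected at configurable rates and is constrained to be
exactly invertible by the four cleaning rules: ``clean(corrupt(x)) == x`` for
every generated note.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .lexicon import KeywordLexicon, QueryGroup, load_lexicon
from .notes import ClinicalNote, match_keywords

__all__ = [
    "NoiseSpec",
    "NoteRecipe",
    "PlantedFact",
    "SnippetTemplate",
    "TEMPLATES",
    "generate_corpus",
    "corrupt_formatting",
    "emit_null_cohort",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Rates of the three invertible formatting corruptions."""

    newline_after_comma_rate: float = 0.30
    newline_midword_rate: float = 0.08
    punct_run_rate: float = 0.10

    def validate(self) -> None:
        for name, rate in self.__dict__.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"noise rate {name} must be in [0, 1], got {rate}")


#: Default query-group weights: active/historical use dominates, existence of
#: IDU and drug names follow, skin popping and harm reduction are rarest.
_DEFAULT_MIX: dict[str, float] = {
    "active_historical": 0.28,
    "existence": 0.20,
    "drug_names": 0.16,
    "last_use": 0.09,
    "frequency": 0.08,
    "risky_needle": 0.07,
    "visible_signs": 0.06,
    "skin_popping": 0.03,
    "harm_reduction": 0.03,
}


@dataclass
class NoteRecipe:
    """Study conditions for one synthetic corpus."""

    n_patients: int = 50
    notes_per_patient: dict[int, float] = field(
        default_factory=lambda: {1: 0.50, 2: 0.35, 3: 0.15}
    )
    positive_rate: float = 0.80
    facts_per_note: dict[int, float] = field(
        default_factory=lambda: {1: 0.65, 2: 0.25, 3: 0.10}
    )
    group_mix: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MIX))
    negation_rate: float = 0.35
    temporal_rate: float = 0.35
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def validate(self) -> None:
        for name in ("positive_rate", "negation_rate", "temporal_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.group_mix or all(w == 0 for w in self.group_mix.values()):
            raise ValueError("group_mix must have a nonzero weight")
        if any(w < 0 for w in self.group_mix.values()):
            raise ValueError("group_mix weights must be nonnegative")
        for g in self.group_mix:
            QueryGroup(g)
            if self.group_mix[g] > 0 and not any(
                t.group.value == g for t in TEMPLATES
            ):
                raise ValueError(f"group {g!r} has weight but no snippet templates")
        self.noise.validate()


@dataclass(frozen=True)
class PlantedFact:
    """Ground truth for one planted snippet: gold span offsets into the CLEAN note."""

    note_id: str
    group: QueryGroup
    gold_text: str
    gold_start: int
    gold_end: int


@dataclass(frozen=True)
class SnippetTemplate:
    """A plantable sentence plus the answer substring the parsing rules recover.

    ``family`` tags which rule family reduces the sentence (negation,
    temporal, or plain for track-marks/fallback reductions). ``sentence`` and
    ``answer`` may contain ``{drug}`` and ``{n}`` slots.
    """

    group: QueryGroup
    family: str  # negation | temporal | plain
    sentence: str
    answer: str


_G = QueryGroup
TEMPLATES: list[SnippetTemplate] = [
    # drug names
    SnippetTemplate(_G.drug_names, "plain",
                    "hx of iv heroin abuse, cocaine, and bnz",
                    "hx of iv heroin abuse, cocaine, and bnz"),
    SnippetTemplate(_G.drug_names, "plain",
                    "reports using iv {drug}", "reports using iv {drug}"),
    SnippetTemplate(_G.drug_names, "plain",
                    "ivdu (cocaine/methamphetamine)", "ivdu (cocaine/methamphetamine)"),
    SnippetTemplate(_G.drug_names, "plain",
                    "iv cocaine mixed with heroin use", "iv cocaine mixed with heroin use"),
    # visible signs
    SnippetTemplate(_G.visible_signs, "plain",
                    "track marks noted over bilateral upper extremities",
                    "track marks noted over bilateral upper extremities"),
    SnippetTemplate(_G.visible_signs, "plain",
                    "on exam, fresh track marks on his forearms",
                    "fresh track marks on his forearms"),
    # risky needle use
    SnippetTemplate(_G.risky_needle, "plain",
                    "hx of ivdu, has shared needles in the past few weeks",
                    "hx of ivdu, has shared needles in the past few weeks"),
    SnippetTemplate(_G.risky_needle, "negation",
                    "denies sharing needles", "denies sharing needles"),
    # active / historical use
    SnippetTemplate(_G.active_historical, "plain",
                    "h/o active iv drug use", "h/o active iv drug use"),
    SnippetTemplate(_G.active_historical, "temporal",
                    "recent ivdu with meth and heroin",
                    "recent ivdu with meth and heroin"),
    # frequency
    SnippetTemplate(_G.frequency, "plain",
                    "history of ivdu (reports daily use of {drug})",
                    "history of ivdu (reports daily use of {drug})"),
    # last use
    SnippetTemplate(_G.last_use, "temporal",
                    "daily use of iv {drug} with last use {n} days prior to admission",
                    "daily use of iv {drug} with last use {n} days prior to admission"),
    SnippetTemplate(_G.last_use, "temporal",
                    "last used iv {drug} {n} years ago",
                    "last used iv {drug} {n} years ago"),
    # skin popping
    SnippetTemplate(_G.skin_popping, "plain",
                    "diffuse scarring from skin popping on lower extremities",
                    "diffuse scarring from skin popping on lower extremities"),
    # harm reduction
    SnippetTemplate(_G.harm_reduction, "plain",
                    "discussed the importance of using clean needles with patient "
                    "should he continue to inject drugs",
                    "discussed the importance of using clean needles with patient "
                    "should he continue to inject drugs"),
    SnippetTemplate(_G.harm_reduction, "plain",
                    "counseled on safer injection techniques during visit",
                    "counseled on safer injection techniques during visit"),
    # existence of IDU
    SnippetTemplate(_G.existence, "negation",
                    "no ivdu or h/o sharing needles", "no ivdu or h/o sharing needles"),
    SnippetTemplate(_G.existence, "negation",
                    "pt lives with family, denies any tobacco, etoh or ivdu",
                    "denies any tobacco, etoh or ivdu"),
    SnippetTemplate(_G.existence, "negation",
                    "no history of idu", "no history of idu"),
    SnippetTemplate(_G.existence, "negation",
                    "never injected drugs", "never injected drugs"),
    SnippetTemplate(_G.existence, "plain", "has h/o ivdu", "has h/o ivdu"),
    SnippetTemplate(_G.existence, "temporal",
                    "hx ivdu, last use {n} yrs ago", "hx ivdu, last use {n} yrs ago"),
]

_DRUGS = ("heroin", "meth", "cocaine", "crack")

# keyword-free boilerplate; "individual" is a deliberate boundary distractor
_HEADERS = (
    "chief complaint: follow up visit",
    "chief complaint: medication refill",
    "chief complaint: routine annual exam",
)
_DEMOGRAPHICS = (
    "pt is a {age} yo male seen in clinic today",
    "pt is a {age} yo female presenting for evaluation",
)
_FILLERS = (
    "family hx: father with htn, mother with dm",
    "medications: lisinopril, metformin, atorvastatin",
    "physical exam: lungs clear, heart regular rate and rhythm",
    "the individual reported intermittent knee pain",
    "denies fever, chills, or night sweats",
    "social ethanol user, quit smoking 10 years ago",
    "labs reviewed, renal function stable",
)
_SOCIAL_FILLERS = (
    "lives with family in town",
    "works part time at a warehouse",
    "retired, lives alone",
)
_PLANS = (
    "plan: continue current medications, follow up in 3 months",
    "plan: labs today, return visit in 6 weeks",
)
_NOTE_TYPES = ("internal medicine note", "primary care note", "addendum", "nursing note")


def _pick(rng: random.Random, dist: dict[int, float]) -> int:
    vals = sorted(dist)
    weights = [dist[v] for v in vals]
    return rng.choices(vals, weights=weights, k=1)[0]


def _fill(template: str, rng: random.Random) -> str:
    return template.format(drug=rng.choice(_DRUGS), n=rng.randint(2, 9),
                           age=rng.randint(35, 79))


def _choose_template(rng: random.Random, recipe: NoteRecipe, group: QueryGroup
                     ) -> SnippetTemplate:
    pool = [t for t in TEMPLATES if t.group is group]
    negated = [t for t in pool if t.family == "negation"]
    temporal = [t for t in pool if t.family == "temporal"]
    if negated and rng.random() < recipe.negation_rate:
        return rng.choice(negated)
    if temporal and rng.random() < recipe.temporal_rate:
        return rng.choice(temporal)
    rest = [t for t in pool if t.family == "plain"] or pool
    return rng.choice(rest)


def _assemble_note(
    rng: random.Random, note_id: str, facts: list[tuple[QueryGroup, str, str]]
) -> tuple[str, list[PlantedFact]]:
    """Build the CLEAN note text; returns it with gold offsets for each fact."""
    lines = [
        rng.choice(_HEADERS),
        _fill(rng.choice(_DEMOGRAPHICS), rng),
        rng.choice(_FILLERS),
        rng.choice(_FILLERS),
    ]
    text_parts: list[str] = []
    pos = 0
    for line in lines:
        text_parts.append(line + ".\n")
        pos += len(line) + 2
    social = "social history: " + rng.choice(_SOCIAL_FILLERS) + "."
    text_parts.append(social)
    pos += len(social)
    planted: list[PlantedFact] = []
    for group, sentence, answer in facts:
        rel = sentence.find(answer)
        assert rel != -1, f"answer not found in template sentence: {sentence!r}"
        start = pos + 1 + rel  # +1 for the separating space
        planted.append(PlantedFact(note_id, group, answer, start, start + len(answer)))
        text_parts.append(" " + sentence + ".")
        pos += 1 + len(sentence) + 1
    text_parts.append("\n" + rng.choice(_PLANS) + ".")
    clean = "".join(text_parts)
    for f in planted:
        assert clean[f.gold_start : f.gold_end] == f.gold_text
    return clean, planted


def corrupt_formatting(clean_note: str, noise: NoiseSpec, seed: int) -> str:
    """Inject formatting noise that the cleaning rules invert exactly.

    Newlines are inserted after ``", "`` (undone by rule i), single spaces
    between word characters become newlines (rule iii), and sentence-ending
    periods are replicated (rule iv): ``clean(corrupt(x)) == x`` whenever
    ``x`` is itself clean.
    """
    noise.validate()
    rng = random.Random(seed)
    out: list[str] = []
    n = len(clean_note)
    i = 0
    while i < n:
        ch = clean_note[i]
        prev = clean_note[i - 1] if i > 0 else ""
        nxt = clean_note[i + 1] if i + 1 < n else ""
        if (
            ch == " "
            and (prev.isalnum() or prev == "_")
            and (nxt.isalnum() or nxt == "_")
            and rng.random() < noise.newline_midword_rate
        ):
            out.append("\n")
        elif ch == "," and nxt == " " and rng.random() < noise.newline_after_comma_rate:
            out.append(",\n")
        elif (
            ch == "."
            and (nxt in (" ", "\n") or i + 1 == n)
            and rng.random() < noise.punct_run_rate
        ):
            out.append("." * rng.randint(2, 6))
        else:
            out.append(ch)
        i += 1
    return "".join(out)


def generate_corpus(
    recipe: NoteRecipe, lexicon: KeywordLexicon | None = None
) -> tuple[list[ClinicalNote], list[PlantedFact]]:
    """Generate a raw-note corpus plus the planted gold facts.

    Notes are deterministic for a fixed recipe seed. ``raw_text`` carries the
    injected formatting noise; gold offsets refer to the clean rendering,
    which the cleaning rules recover exactly. Negative notes are verified to
    contain no lexicon keyword.
    """
    recipe.validate()
    lex = lexicon if lexicon is not None else load_lexicon()
    rng = random.Random(recipe.seed)
    groups = [g for g, w in sorted(recipe.group_mix.items()) if w > 0]
    weights = [recipe.group_mix[g] for g in groups]
    notes: list[ClinicalNote] = []
    gold: list[PlantedFact] = []
    note_seq = 0
    for p in range(recipe.n_patients):
        patient_id = f"P{p:05d}"
        for _ in range(_pick(rng, recipe.notes_per_patient)):
            note_id = f"N{note_seq:06d}"
            note_seq += 1
            facts: list[tuple[QueryGroup, str, str]] = []
            if rng.random() < recipe.positive_rate:
                for _ in range(_pick(rng, recipe.facts_per_note)):
                    group = QueryGroup(rng.choices(groups, weights=weights, k=1)[0])
                    tpl = _choose_template(rng, recipe, group)
                    drug = rng.choice(_DRUGS)
                    num = rng.randint(2, 9)
                    sentence = tpl.sentence.format(drug=drug, n=num)
                    answer = tpl.answer.format(drug=drug, n=num)
                    facts.append((group, sentence, answer))
            clean, planted = _assemble_note(rng, note_id, facts)
            if not facts and match_keywords(clean, lex):
                raise AssertionError(
                    f"negative note {note_id} unexpectedly matches the lexicon"
                )
            raw = corrupt_formatting(clean, recipe.noise, seed=rng.randrange(2**31))
            notes.append(
                ClinicalNote(
                    note_id=note_id,
                    patient_id=patient_id,
                    date=f"2022-01-{rng.randint(1, 28):02d}",
                    note_type=rng.choice(_NOTE_TYPES),
                    raw_text=raw,
                )
            )
            gold.extend(planted)
    return notes, gold


def emit_null_cohort(
    n_notes: int, seed: int, lexicon: KeywordLexicon | None = None
) -> list[ClinicalNote]:
    """Notes guaranteed free of lexicon keywords (verified by the matcher)."""
    lex = lexicon if lexicon is not None else load_lexicon()
    recipe = NoteRecipe(n_patients=n_notes, notes_per_patient={1: 1.0},
                        positive_rate=0.0, seed=seed)
    notes, _ = generate_corpus(recipe, lex)
    return notes[:n_notes]
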