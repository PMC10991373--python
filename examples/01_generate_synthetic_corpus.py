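"""Generate a small synthetic note corpus with planted IDU facts.

Builds 20 patients' worth of notes at the default study conditions, shows one
raw (noisy) note next to its cleaned form, and lists the planted gold spans.
"""

from iduqa import NoteRecipe, clean_text, generate_corpus

recipe = NoteRecipe(n_patients=20, seed=42)
notes, gold = generate_corpus(recipe)
print(f"{len(notes)} notes, {len(gold)} planted facts\n")

note = next(n for n in notes if any(f.note_id == n.note_id for f in gold))
print("--- raw note (formatting noise visible) ---")
print(note.raw_text)
clean, _ = clean_text(note.raw_text)
print("\n--- cleaned ---")
print(clean)

print("\n--- planted gold spans in this note ---")
for f in gold:
    if f.note_id == note.note_id:
        # offsets index the CLEAN text; the span is verbatim by construction
        assert clean[f.gold_start : f.gold_end] == f.gold_text
        print(f"[{f.group.value}] {f.gold_text!r} @ {f.gold_start}:{f.gold_end}")
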