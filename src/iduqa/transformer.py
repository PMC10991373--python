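"""Optional transformer back-end behind the extractor contract.

Adapts a Hugging Face span-QA checkpoint (BERT, BioBERT, BlueBERT,
ClinicalBERT, ...) to the :class:`~iduqa.engine.Extractor` contract: each
chunk is encoded as ``[CLS] question [SEP] window [SEP]`` and the model's
start/end logits yield scored span candidates plus a null candidate from the
CLS position. Requires the ``transformer`` extra (``transformers`` and
``torch``); the rule-based reference extractor covers all desk-scale use.

Fine-tuning at the published scale (batch size 32, learning rate 3e-5,
5 epochs on GPU) is out of scope here; this adapter is inference-only.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Callable

from .engine import Candidate, Chunk

if TYPE_CHECKING:  # pragma: no cover
    pass

__all__ = ["transformer_extractor"]


def transformer_extractor(
    model_name_or_path: str,
    top_k: int = 5,
    device: str = "cpu",
) -> Callable[[Chunk], list[Candidate]]:
    """Build an extractor from a span-QA checkpoint (requires ``transformers``)."""
    try:
        import torch
        from transformers import AutoModelForQuestionAnswering, AutoTokenizer
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError(
            "the transformer back-end needs the 'transformer' extra: "
            "pip install iduqa[transformer]"
        ) from err

    tokenizer = AutoTokenizer.from_pretrained(model_name_or_path)
    model = AutoModelForQuestionAnswering.from_pretrained(model_name_or_path)
    model.to(device).eval()

    def extractor(chunk: Chunk) -> list[Candidate]:  # pragma: no cover - needs weights
        window_words = [t.text for t in chunk.window_tokens]
        enc = tokenizer(
            " ".join(chunk.question_tokens),
            window_words,
            is_split_into_words=True,
            return_tensors="pt",
            truncation=True,
        ).to(device)
        with torch.no_grad():
            out = model(**enc)
        start_logits = out.start_logits[0]
        end_logits = out.end_logits[0]
        word_ids = enc.word_ids(0)
        candidates = [Candidate(None, None, float(start_logits[0] + end_logits[0]))]
        starts = torch.topk(start_logits, min(top_k, len(start_logits))).indices
        ends = torch.topk(end_logits, min(top_k, len(end_logits))).indices
        for si in starts:
            for ei in ends:
                ws, we = word_ids[int(si)], word_ids[int(ei)]
                if ws is None or we is None or we < ws:
                    continue
                candidates.append(
                    Candidate(ws, we, float(start_logits[si] + end_logits[ei]))
                )
        return candidates

    return extractor
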