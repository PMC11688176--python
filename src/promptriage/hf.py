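"""Pretrained masked-LM adapter (optional; requires the ``adapter`` extra).

Adapts a Hugging Face ``AutoModelForMaskedLM`` checkpoint (e.g. a Chinese
BERT for the triage setting) to the :class:`~promptriage.mlm.MLMBackend`
contract.  Soft template slots are realized as trainable prompt embeddings
spliced into the input embedding sequence; the ``tune`` switch selects
whether a gradient step updates only those embeddings (``"prompt"``) or all
model weights (``"full"``, the default, consistent with a 3e-5 fine-tuning
learning rate).

Label words that the checkpoint's tokenizer splits into several subword
pieces cannot be scored at a single mask slot and are dropped with a
warning by the classifier; the stub backend has no such words.

This module is import-guarded: the rest of the package never imports it, so
the deterministic stub pipeline works without torch/transformers installed.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np

from .mlm import BackendError, BackendVocabulary, MaskDistribution, MLMBackend
from .templating import PromptedInstance

logger = logging.getLogger(__name__)

__all__ = ["PretrainedMLMBackend"]


def _require_torch():
    try:
        import torch
        from transformers import AutoModelForMaskedLM, AutoTokenizer
    except ImportError as exc:  # pragma: no cover - exercised only with the extra
        raise ImportError(
            "PretrainedMLMBackend needs torch and transformers; "
            "install promptriage[adapter]"
        ) from exc
    return torch, AutoModelForMaskedLM, AutoTokenizer


class PretrainedMLMBackend(MLMBackend):  # pragma: no cover - needs the adapter extra
    """Masked-LM backend backed by a pretrained transformer checkpoint."""

    def __init__(self, model_name: str, n_soft_slots: int = 3, tune: str = "full",
                 dropout: float = 0.5):
        torch, AutoModelForMaskedLM, AutoTokenizer = _require_torch()
        if tune not in ("full", "prompt"):
            raise BackendError(f"tune must be 'full' or 'prompt', got {tune!r}")
        self._torch = torch
        self.model_name = model_name
        self.tune = tune
        self.tokenizer = AutoTokenizer.from_pretrained(model_name)
        self.model = AutoModelForMaskedLM.from_pretrained(
            model_name, hidden_dropout_prob=dropout)
        self.model.eval()
        hidden = self.model.get_input_embeddings().embedding_dim
        self.soft_embeddings = torch.nn.Parameter(
            torch.zeros(n_soft_slots, hidden), requires_grad=True)
        vocab = self.tokenizer.get_vocab()
        ordered = [w for w, _ in sorted(vocab.items(), key=lambda kv: kv[1])]
        specials = set(self.tokenizer.all_special_tokens)
        self.vocabulary = BackendVocabulary(
            words=tuple(w for w in ordered if w not in specials),
            bos_token=self.tokenizer.cls_token,
            mask_token=self.tokenizer.mask_token,
        )
        self._row = np.array([vocab[w] for w in self.vocabulary.words])

    def _embed(self, instance: PromptedInstance):
        torch = self._torch
        embed = self.model.get_input_embeddings()
        rows = []
        soft_ordinal = 0
        for i, tok in enumerate(instance.tokens):
            if i in instance.soft_indices:
                rows.append(self.soft_embeddings[soft_ordinal])
                soft_ordinal += 1
            else:
                tok_id = self.tokenizer.convert_tokens_to_ids(tok)
                rows.append(embed.weight[tok_id])
        return torch.stack(rows).unsqueeze(0)

    def mask_fill_distribution(self, instance: PromptedInstance) -> MaskDistribution:
        torch = self._torch
        n_masks = sum(1 for t in instance.tokens if t == self.vocabulary.mask_token)
        if n_masks != 1:
            raise BackendError(f"instance must contain exactly one mask slot, found {n_masks}")
        with torch.no_grad():
            logits = self.model(inputs_embeds=self._embed(instance)).logits
        mask_pos = instance.tokens.index(self.vocabulary.mask_token)
        logp = torch.log_softmax(logits[0, mask_pos], dim=-1).cpu().numpy()
        p = np.exp(logp[self._row])
        p = p / p.sum()  # renormalize over the non-special vocabulary
        return MaskDistribution(probabilities=p, vocabulary=self.vocabulary)

    def trainable_parameters(self) -> dict[str, np.ndarray]:
        params = {"soft_embeddings": self.soft_embeddings.detach().cpu().numpy().copy()}
        if self.tune == "full":
            for name, p in self.model.named_parameters():
                params[name] = p.detach().cpu().numpy().copy()
        return params

    def apply_gradient_step(self, gradients: Mapping[str, np.ndarray],
                            learning_rate: float) -> None:
        torch = self._torch
        declared = self.trainable_parameters()
        with torch.no_grad():
            for name, grad in gradients.items():
                if name not in declared:
                    raise BackendError(f"unknown trainable parameter {name!r}")
                grad = np.asarray(grad, dtype=float)
                if grad.shape != declared[name].shape:
                    raise BackendError(f"gradient shape mismatch for {name!r}")
                target = (self.soft_embeddings if name == "soft_embeddings"
                          else dict(self.model.named_parameters())[name])
                target -= learning_rate * torch.as_tensor(grad, dtype=target.dtype)

    def backprop_mask(self, instance: PromptedInstance,
                      dloss_dp: np.ndarray) -> dict[str, np.ndarray]:
        raise NotImplementedError(
            "adapter training uses autograd end-to-end; use torch-side losses"
        )

    def copy(self) -> "PretrainedMLMBackend":
        import copy as _copy

        return _copy.deepcopy(self)
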