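"""Cloze templates: wrap a document into a prompted instance.

A template is an ordered sequence of literal tokens, one input slot ``{X}``,
exactly one mask slot ``{MASK}`` and, for soft templates, ``{SOFT}`` slots —
trainable placeholders with no fixed surface form.  Wrapping substitutes the
document's tokens at the input slot and prepends a begin-of-sequence marker,
producing the token sequence the masked LM scores.

Four hand-crafted templates ship as built-ins with ids ``"0"``–``"3"``,
alongside the three-slot soft template ``"soft"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Sequence

from .corpus_io import Document
from .mlm import BOS_TOKEN, MASK_TOKEN, SOFT_TOKEN

__all__ = [
    "TemplateError",
    "Segment",
    "Template",
    "PromptedInstance",
    "parse_template",
    "get_template",
    "wrap",
    "BUILTIN_TEMPLATES",
]


class TemplateError(ValueError):
    """Ill-formed template spec or impossible wrap."""


# literal runs are tokenized as words or single punctuation marks, so
# "department: X" renders the colon as its own token
_LITERAL_TOKEN_RE = re.compile(r"\w+|[^\w\s]")
_PLACEHOLDER_RE = re.compile(r"(\{X\}|\{MASK\}|\{SOFT\})")


@dataclass(frozen=True)
class Segment:
    """One template element: a literal token or an x/mask/soft slot."""

    kind: str  # "lit" | "x" | "mask" | "soft"
    token: str = ""


@dataclass(frozen=True)
class Template:
    kind: str  # "hard" | "soft"
    segments: tuple[Segment, ...]

    @property
    def soft_count(self) -> int:
        return sum(1 for s in self.segments if s.kind == "soft")

    @property
    def fixed_length(self) -> int:
        """Token count excluding the input slot, including the BOS marker."""
        return 1 + sum(1 for s in self.segments if s.kind != "x")

    def render(self) -> str:
        """Spec string whose re-parse reproduces this template's segments."""
        parts = []
        for seg in self.segments:
            if seg.kind == "lit":
                parts.append(seg.token)
            else:
                parts.append({"x": "{X}", "mask": "{MASK}", "soft": "{SOFT}"}[seg.kind])
        return " ".join(parts)


@dataclass(frozen=True)
class PromptedInstance:
    """A resolved token sequence with one mask slot and optional soft slots."""

    tokens: tuple[str, ...]
    mask_index: int | None
    soft_indices: tuple[int, ...]
    doc_id: str
    label: str | None = None

    def __post_init__(self) -> None:
        if self.mask_index is not None:
            if not 0 <= self.mask_index < len(self.tokens):
                raise TemplateError("mask index out of range")
            if self.mask_index in self.soft_indices:
                raise TemplateError("mask index collides with a soft slot")

    def with_mask_at(self, position: int) -> "PromptedInstance":
        """Copy with the token at ``position`` replaced by the mask marker."""
        tokens = list(self.tokens)
        tokens[position] = MASK_TOKEN
        return replace(self, tokens=tuple(tokens), mask_index=position)

    def substitute_mask(self, word: str) -> "PromptedInstance":
        """Copy with the mask slot filled by ``word`` (no mask slot remains)."""
        if self.mask_index is None:
            raise TemplateError("instance has no mask slot to substitute")
        tokens = list(self.tokens)
        tokens[self.mask_index] = word
        return replace(self, tokens=tuple(tokens), mask_index=None)


def parse_template(spec: str) -> Template:
    """Parse a template spec with ``{X}``, ``{MASK}`` and ``{SOFT}`` placeholders."""
    segments: list[Segment] = []
    for part in _PLACEHOLDER_RE.split(spec):
        if part == "{X}":
            segments.append(Segment("x"))
        elif part == "{MASK}":
            segments.append(Segment("mask"))
        elif part == "{SOFT}":
            segments.append(Segment("soft"))
        else:
            segments.extend(Segment("lit", tok) for tok in _LITERAL_TOKEN_RE.findall(part))
    n_x = sum(1 for s in segments if s.kind == "x")
    n_mask = sum(1 for s in segments if s.kind == "mask")
    if n_x != 1:
        raise TemplateError(f"template must contain exactly one {{X}} (found {n_x}): {spec!r}")
    if n_mask != 1:
        raise TemplateError(
            f"template must contain exactly one {{MASK}} (found {n_mask}): {spec!r}"
        )
    kind = "soft" if any(s.kind == "soft" for s in segments) else "hard"
    return Template(kind=kind, segments=tuple(segments))


BUILTIN_TEMPLATES: dict[str, str] = {
    "0": "{MASK} department: {X}",
    "1": "{X}, The text is about {MASK}",
    "2": "{X}, This text belongs to the {MASK}",
    "3": "This text belongs to the {MASK}, {X}",
    "soft": "{X}, {SOFT}{SOFT}{SOFT}{MASK}",
}


def get_template(id_or_spec: str) -> Template:
    """Resolve a built-in template id (``0``–``3``, ``soft``) or parse a spec string."""
    key = str(id_or_spec)
    return parse_template(BUILTIN_TEMPLATES.get(key, key))


def wrap(doc: Document, template: Template, max_length: int = 128) -> PromptedInstance:
    """Wrap a document into a prompted instance.

    The begin-of-sequence marker is prepended and the document's tokens are
    substituted at the input slot.  If the instance would exceed
    ``max_length`` tokens, document tokens are truncated from their right end;
    template literals, soft slots and the mask slot are never truncated.
    """
    doc_tokens = list(doc.tokens)
    if not doc_tokens:
        raise TemplateError(f"document {doc.id!r} has no tokens")
    budget = max_length - template.fixed_length
    if budget < 1:
        raise TemplateError(
            f"max_length={max_length} leaves no room for document tokens "
            f"(template needs {template.fixed_length})"
        )
    doc_tokens = doc_tokens[:budget]

    tokens: list[str] = [BOS_TOKEN]
    mask_index = -1
    soft_indices: list[int] = []
    for seg in template.segments:
        if seg.kind == "lit":
            tokens.append(seg.token)
        elif seg.kind == "x":
            tokens.extend(doc_tokens)
        elif seg.kind == "mask":
            mask_index = len(tokens)
            tokens.append(MASK_TOKEN)
        else:
            soft_indices.append(len(tokens))
            tokens.append(SOFT_TOKEN)
    return PromptedInstance(
        tokens=tuple(tokens),
        mask_index=mask_index,
        soft_indices=tuple(soft_indices),
        doc_id=doc.id,
        label=doc.label,
    )
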