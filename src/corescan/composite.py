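"""Dependency-aware composite element calling.

Downstream core promoter elements such as the DPE function only at a precise
spacing from an initiator's A+1 base. Given the raw hit list and the
library's composite rules, this module pairs each dependent-element hit with
the best qualifying initiator hit on the same sequence and strand. Spacing
is measured on the anchor-A+1 axis: the A+1 base is +1, there is no 0, and
on the minus strand "downstream" runs toward lower plus-strand coordinates.

Dependent hits with no qualifying anchor are kept and flagged as orphans
(never deleted), so positional QC can still display their raw distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .element_library import CompositeRule
from .scanner import MotifHit

__all__ = ["CompositeCall", "AnnotatedHit", "call_composites"]


@dataclass(frozen=True)
class CompositeCall:
    """A dependent hit paired with its initiator anchor."""

    seq_id: str
    rule: CompositeRule
    anchor: MotifHit
    dependent: MotifHit
    spacing: int
    combined_score: float


@dataclass(frozen=True)
class AnnotatedHit:
    """A raw hit plus its composite annotation (if any).

    ``orphan`` is True for a hit of a dependent element that found no
    qualifying anchor; independent elements and anchors are never orphans.
    """

    hit: MotifHit
    rule: CompositeRule | None = None
    anchor_id: str | None = None
    spacing: int | None = None
    orphan: bool = False


def _linear(rel: int) -> int:
    """Zero-free axis label -> signed base offset from the reference base."""
    return rel - 1 if rel > 0 else rel


def _skip_zero(d: int) -> int:
    """Signed base offset -> zero-free axis label (+1 = the reference base)."""
    return d + 1 if d >= 0 else d


def spacing_between(anchor: MotifHit, dependent: MotifHit) -> int:
    """Position of the dependent start on the anchor's A+1 axis.

    Both hits must be on the same strand of the same sequence. A dependent
    start 27 bases downstream of the A+1 is at spacing +28 (the A+1 itself
    is +1).
    """
    d = _linear(dependent.start_tss_rel) - _linear(anchor.anchor_tss_rel)
    if anchor.strand == "-":
        d = -d
    return _skip_zero(d)


def call_composites(
    hits: Iterable[MotifHit | AnnotatedHit],
    rules: Sequence[CompositeRule],
) -> tuple[list[CompositeCall], list[AnnotatedHit]]:
    """Pair dependent hits with anchors; annotate the full hit list.

    For each dependent hit and each rule, at most one call is made: among
    anchor hits on the same sequence and strand whose spacing falls inside
    the rule's window, the highest-scoring anchor wins; ties break toward
    the spacing closest to the window midpoint, then the smallest spacing.
    Re-running on annotated output is a no-op (idempotent).
    """
    raw: list[MotifHit] = [h.hit if isinstance(h, AnnotatedHit) else h for h in hits]
    rules = list(rules)
    by_key: dict[tuple[str, str, str], list[MotifHit]] = {}
    for h in raw:
        by_key.setdefault((h.seq_id, h.strand, h.element), []).append(h)

    calls: list[CompositeCall] = []
    annotation: dict[int, AnnotatedHit] = {}
    dependent_names = {r.dependent for r in rules}

    for rule in rules:
        lo, hi = rule.spacing_window
        for (seq_id, strand, element), dep_hits in by_key.items():
            if element != rule.dependent:
                continue
            anchors = by_key.get((seq_id, strand, rule.anchor), [])
            for dep in dep_hits:
                best = None
                for anc in anchors:
                    if anc is dep:
                        continue
                    s = spacing_between(anc, dep)
                    if not lo <= s <= hi:
                        continue
                    key = (-anc.score, abs(s - rule.midpoint), s)
                    if best is None or key < best[0]:
                        best = (key, anc, s)
                if best is not None:
                    _, anc, s = best
                    calls.append(
                        CompositeCall(
                            seq_id=seq_id,
                            rule=rule,
                            anchor=anc,
                            dependent=dep,
                            spacing=s,
                            combined_score=anc.score + dep.score,
                        )
                    )
                    annotation[id(dep)] = AnnotatedHit(
                        hit=dep,
                        rule=rule,
                        anchor_id=f"{anc.element}@{anc.anchor_tss_rel}",
                        spacing=s,
                        orphan=False,
                    )

    annotated: list[AnnotatedHit] = []
    for h in raw:
        if id(h) in annotation:
            annotated.append(annotation[id(h)])
        else:
            annotated.append(AnnotatedHit(hit=h, orphan=h.element in dependent_names))
    return calls, annotated
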