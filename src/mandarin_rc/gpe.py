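"""Grammatical Prediction Error (GPE).

GPE scores a network's output activations against the *exact* conditional
next-category distribution derived from the generating grammar:

    GPE = 1 - hits / (hits + false alarms + misses)

* **hits** — summed activation over units belonging to grammatical
  categories (those with positive target probability);
* **false alarms** — summed activation over units of ungrammatical
  categories;
* **misses** — per grammatical category, the shortfall of the summed unit
  activation below the category's target probability, clipped at zero.

0 is a perfect prediction, 1 a completely wrong one.  Targets and misses
live at the category level (unit activations are summed within a category);
hits and false alarms sum raw unit activations.  Over-activating one
grammatical category is penalised implicitly: with a roughly conserved
total output, dislocated activation produces shortfalls elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from mandarin_rc.grammar import (
    CATEGORY_UNITS,
    Category,
    N_UNITS,
    Sentence,
    TemplateSet,
    UngrammaticalPrefixError,
)
from mandarin_rc.srn import SRNState, predict_sentence

__all__ = [
    "GPEResult",
    "TargetOracle",
    "compute_gpe",
    "gpe_trace",
]

CONVENTIONS = ("predict_next", "predict_current")


@dataclass(frozen=True)
class GPEResult:
    """GPE decomposition for one scored word position."""

    position: int          # 0-based token index the score is assigned to
    hits: float
    false_alarms: float
    misses: float
    gpe: float
    convention: str = "predict_next"


def category_sums(activations: np.ndarray) -> dict[Category, float]:
    """Summed activation per grammatical category."""
    return {
        c: float(activations[list(units)].sum())
        for c, units in CATEGORY_UNITS.items()
    }


def compute_gpe(
    activations: np.ndarray,
    target: Mapping[Category, float],
    position: int = 0,
    convention: str = "predict_next",
) -> GPEResult:
    """Score one output vector against a target category distribution.

    ``target`` maps categories to target probabilities (may omit
    zero-probability categories).  A zero denominator — possible only when
    all activations are zero and no grammatical category has positive
    target, which a valid distribution excludes — yields GPE = 1.
    """
    activations = np.asarray(activations, dtype=float)
    if activations.shape != (N_UNITS,):
        raise ValueError(
            f"expected {N_UNITS} activations, got shape {activations.shape}"
        )
    sums = category_sums(activations)
    hits = 0.0
    false_alarms = 0.0
    misses = 0.0
    for c in Category:
        t_c = float(target.get(c, 0.0))
        if t_c > 0.0:
            hits += sums[c]
            misses += max(0.0, t_c - sums[c])
        else:
            false_alarms += sums[c]
    denom = hits + false_alarms + misses
    gpe = 1.0 if denom <= 0.0 else 1.0 - hits / denom
    # guard against floating-point excursions just outside [0, 1]
    gpe = min(1.0, max(0.0, gpe))
    return GPEResult(
        position=position, hits=hits, false_alarms=false_alarms,
        misses=misses, gpe=gpe, convention=convention,
    )


class TargetOracle:
    """Exact next-category targets, with an optional structural fallback.

    Wraps the template enumeration; for prefixes of zero probability (test
    items in animacy cells the grammar assigns probability zero) the oracle
    can fall back to the limiting conditional distribution computed from a
    template set built on :meth:`GrammarSpec.structural_variant`, in which
    the zero animacy cells carry an infinitesimal probability.  Residual
    probabilities of the order of the smoothing constant are truncated to
    zero so the grammatical-category support stays exact.
    """

    #: continuation probabilities below this are artefacts of smoothing
    RESIDUAL = 1e-6

    def __init__(self, templates: TemplateSet,
                 structural: TemplateSet | None = None):
        self.templates = templates
        self.structural = structural

    def distribution(self, prefix: Sequence[Category]) -> dict[Category, float]:
        try:
            return self.templates.next_category_distribution(prefix)
        except UngrammaticalPrefixError:
            if self.structural is None:
                raise
        dist = self.structural.next_category_distribution(prefix)
        dist = {c: (0.0 if p < self.RESIDUAL else p) for c, p in dist.items()}
        total = sum(dist.values())
        return {c: p / total for c, p in dist.items()}


def gpe_trace(
    state: SRNState,
    sentence: Sentence,
    templates: TemplateSet | TargetOracle,
    convention: str = "predict_next",
) -> list[GPEResult]:
    """Word-by-word GPE for one sentence.

    Under the default ``predict_next`` convention the result assigned to
    token position ``n`` scores the output produced *after token n is
    input* against the exact distribution of the continuation given the
    prefix up to and including token ``n``; the final EOS token has no
    continuation and is not scored.  Under ``predict_current`` position
    ``n`` scores the output produced after token ``n - 1`` against the
    distribution *of* position ``n``; the sentence-initial token has no
    preceding output and is not scored.

    Raises :class:`UngrammaticalPrefixError` (identifying the first bad
    position) when a needed prefix has zero probability and the oracle has
    no structural fallback.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    oracle = templates if isinstance(templates, TargetOracle) else TargetOracle(templates)
    cats = sentence.categories
    trace = predict_sentence(state, sentence)
    results = []
    for n in range(len(cats) - 1):
        target = oracle.distribution(cats[: n + 1])
        position = n if convention == "predict_next" else n + 1
        results.append(
            compute_gpe(trace.outputs[n], target, position=position,
                        convention=convention)
        )
    return results
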