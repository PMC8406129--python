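"""CIPN20 scale scoring and case classification.

The EORTC QLQ-CIPN20 has 20 items answered 1-4 (1 = not at all, 4 = very
much): items 1-9 sensory, 10-17 motor, 18-20 autonomic.  Scale scores are
the item mean linearly transformed to 0-100::

    score = (mean(present items) - 1) / 3 * 100

with the EORTC half-rule: a scale is scored only if at least half of its
items were answered.

Case labels follow the screening rule used with this instrument: a
participant is a *case* if they answered "quite a bit" (3) or "very much"
(4) on any of the first 4 items (numbness/tingling in feet and hands);
*feet case* and *hands case* restrict the rule to items 1-2 and 3-4.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean
from typing import Optional, Sequence

from .session_io import SurveyResponse

# 0-based item index maps (instrument order)
CIPN20_ITEMS = tuple(range(20))
CIPN8_ITEMS = tuple(range(8))     # first 8 sensory items
CIPN4_ITEMS = tuple(range(4))     # first 4 sensory items
CIPN2FEET_ITEMS = (0, 1)          # feet numbness, feet tingling
CIPN2HANDS_ITEMS = (2, 3)         # hands numbness, hands tingling
CIPNM_ITEMS = tuple(range(9, 17))  # the 8 motor items

SCALE_ITEM_MAP: dict[str, tuple[int, ...]] = {
    "cipn20": CIPN20_ITEMS,
    "cipn8": CIPN8_ITEMS,
    "cipn4": CIPN4_ITEMS,
    "cipn2feet": CIPN2FEET_ITEMS,
    "cipn2hands": CIPN2HANDS_ITEMS,
    "cipnm": CIPNM_ITEMS,
}


@dataclass
class ScaleScores:
    """The six 0-100 scale scores; ``None`` where the half-rule failed."""

    cipn20: Optional[float] = None
    cipn8: Optional[float] = None
    cipn4: Optional[float] = None
    cipn2feet: Optional[float] = None
    cipn2hands: Optional[float] = None
    cipnm: Optional[float] = None

    def as_dict(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in SCALE_ITEM_MAP}


@dataclass
class CaseLabels:
    """Case / feet-case / hands-case booleans; ``None`` if undeterminable."""

    is_case: Optional[bool] = None
    is_feet_case: Optional[bool] = None
    is_hands_case: Optional[bool] = None


def score_scale(
    items: Sequence[Optional[int]], item_subset: Sequence[int]
) -> Optional[float]:
    """Score one scale over ``item_subset`` (0-based indices into ``items``).

    Returns the 0-100 score, or ``None`` if fewer than half the subset's
    items are present.  Raises ``ValueError`` on an empty subset.
    """
    if len(item_subset) == 0:
        raise ValueError("empty item subset")
    present = [items[i] for i in item_subset if items[i] is not None]
    if 2 * len(present) < len(item_subset):
        return None
    return (mean(present) - 1.0) / 3.0 * 100.0


def score_all(resp: SurveyResponse) -> ScaleScores:
    """Compute all six scale scores; missingness propagates per scale."""
    items = resp.cipn20_items
    return ScaleScores(
        **{name: score_scale(items, idx) for name, idx in SCALE_ITEM_MAP.items()}
    )


def _rule(items: Sequence[Optional[int]], idx: Sequence[int]) -> Optional[bool]:
    present = [items[i] for i in idx if items[i] is not None]
    if not present:
        return None
    return max(present) >= 3


def classify(resp: SurveyResponse) -> CaseLabels:
    """Apply the case-classification rule to one survey response.

    ``is_case`` iff max of items 1-4 >= 3; feet/hands variants restrict to
    items 1-2 / 3-4.  Each label is ``None`` when all its items are absent.
    When all four items are present, ``is_case == is_feet_case or
    is_hands_case`` by construction.
    """
    items = resp.cipn20_items
    return CaseLabels(
        is_case=_rule(items, CIPN4_ITEMS),
        is_feet_case=_rule(items, CIPN2FEET_ITEMS),
        is_hands_case=_rule(items, CIPN2HANDS_ITEMS),
    )
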