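"""Instrument definitions: item lists, response ranges, subscales, cut-offs.

A :class:`ScaleSpec` describes one self-report questionnaire.  The three
instruments of the pipeline are provided as factories:

* :func:`ctq_sf` — Childhood Trauma Questionnaire, Short Form (28 items,
  1–5), five clinical subscales with published moderate-severity cut-offs;
  items 10/16/22 form the minimization/denial scale and are unscored here.
* :func:`gad7` — Generalized Anxiety Disorder scale (7 items, 0–3).
* :func:`phq9` — Patient Health Questionnaire depression module (9 items,
  0–3).

Responses are assumed to be already keyed (reverse-scored items such as the
CTQ-SF neglect items arrive in their scored direction); the ``reverse_items``
field records which items a raw-data user would need to re-key.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ScaleSpec:
    """One instrument: items, response range, subscales, screening cut-offs.

    A participant is flagged on a subscale when its summed score is greater
    than or equal to the subscale's cut-off.
    """

    name: str
    items: tuple[str, ...]
    response_range: tuple[int, int]
    subscales: dict[str, tuple[str, ...]] = field(default_factory=dict)
    cutoffs: dict[str, int] = field(default_factory=dict)
    reverse_items: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.response_range
        if lo >= hi:
            raise ValueError("response_range must be (low, high) with low < high")
        seen: set[str] = set()
        for sub, its in self.subscales.items():
            unknown = set(its) - set(self.items)
            if unknown:
                raise ValueError(f"subscale {sub!r} uses unknown items {sorted(unknown)}")
            overlap = seen & set(its)
            if overlap:
                raise ValueError(f"subscale item sets overlap on {sorted(overlap)}")
            seen |= set(its)
        for sub, cut in self.cutoffs.items():
            k = len(self.subscales[sub])
            if not (k * lo <= cut <= k * hi):
                raise ValueError(
                    f"cut-off {cut} for {sub!r} outside achievable range "
                    f"[{k * lo}, {k * hi}]"
                )

    def subscale_items(self, subscale: str) -> tuple[str, ...]:
        return self.subscales[subscale]


def _ctq(i: int) -> str:
    return f"CTQ{i:02d}"


def ctq_sf() -> ScaleSpec:
    """CTQ-SF with the standard five-subscale item map and cut-offs.

    Cut-offs flag moderate-to-severe exposure: emotional abuse >= 13,
    physical abuse >= 10, sexual abuse >= 8, emotional neglect >= 15,
    physical neglect >= 10.
    """
    subscales = {
        "emotional_abuse": tuple(_ctq(i) for i in (3, 8, 14, 18, 25)),
        "physical_abuse": tuple(_ctq(i) for i in (9, 11, 12, 15, 17)),
        "sexual_abuse": tuple(_ctq(i) for i in (20, 21, 23, 24, 27)),
        "emotional_neglect": tuple(_ctq(i) for i in (5, 7, 13, 19, 28)),
        "physical_neglect": tuple(_ctq(i) for i in (1, 2, 4, 6, 26)),
    }
    return ScaleSpec(
        name="CTQ-SF",
        items=tuple(_ctq(i) for i in range(1, 29)),
        response_range=(1, 5),
        subscales=subscales,
        cutoffs={
            "emotional_abuse": 13,
            "physical_abuse": 10,
            "sexual_abuse": 8,
            "emotional_neglect": 15,
            "physical_neglect": 10,
        },
        reverse_items=tuple(_ctq(i) for i in (2, 5, 7, 13, 19, 26, 28)),
    )


def gad7() -> ScaleSpec:
    items = tuple(f"GAD{i:02d}" for i in range(1, 8))
    return ScaleSpec(
        name="GAD-7",
        items=items,
        response_range=(0, 3),
        subscales={"anxiety": items},
        cutoffs={},
    )


def phq9() -> ScaleSpec:
    items = tuple(f"PHQ{i:02d}" for i in range(1, 10))
    return ScaleSpec(
        name="PHQ-9",
        items=items,
        response_range=(0, 3),
        subscales={"depression": items},
        cutoffs={},
    )
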