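"""Global Usability Score (GUS) scoring engine.

The GUS questionnaire assesses one inhaler at a time through five "boxes":

* box 1 — the patient's preference at glance after a standardized nurse
  demonstration;
* boxes 2–4 — nurse-measured actuation performance (critical issues noticed,
  number of attempts before a correct actuation, seconds until the patient
  handles the device autonomously);
* box 5 — ten closed acceptance/preference questions.

Each box yields a sub-score and the GUS total is the plain sum of the five
sub-scores, on a 0–50 scale (higher = more usable).  The published instrument's
item weights are not public, so the scheme is configuration-driven: a
:class:`ScoringScheme` is read from JSON and validated against the structural
constraints every valid scheme must honour (exactly five boxes, box maxima
summing to 50, non-negative item awards, measurement rules monotone
non-increasing in attempts/time).  The shipped :func:`default_scheme` is a
clearly-labelled placeholder satisfying those constraints, not the authors'
weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .devices import GROUP_DEVICES, canonical_device, canonical_stratum, sort_devices
from .errors import DesignViolationError, InvalidSchemeError, MissingAnswerError

GUS_MAX = 50

CATEGORICAL = "categorical"
COUNT_THRESHOLD = "count-threshold"
TIME_THRESHOLD = "time-threshold"
_MEASUREMENT_KINDS = (COUNT_THRESHOLD, TIME_THRESHOLD)


@dataclass(frozen=True)
class ItemRule:
    """One questionnaire item and the rule mapping its answer to points.

    ``mapping`` is either ``{option: points}`` (categorical) or a sequence of
    half-open intervals ``(lo, hi, points)`` with ``hi=None`` meaning +inf
    (measurement kinds).  Intervals must partition the item's domain.
    """

    item_id: str
    kind: str
    mapping: object  # dict for categorical, tuple of (lo, hi, points) otherwise

    @property
    def intervals(self) -> tuple[tuple[float, float | None, int], ...]:
        if self.kind == CATEGORICAL:
            raise TypeError(f"item {self.item_id!r} is categorical")
        return tuple(self.mapping)

    @property
    def max_points(self) -> int:
        if self.kind == CATEGORICAL:
            return max(self.mapping.values())
        return max(p for _, _, p in self.mapping)

    @property
    def min_points(self) -> int:
        if self.kind == CATEGORICAL:
            return min(self.mapping.values())
        return min(p for _, _, p in self.mapping)

    @property
    def point_values(self) -> frozenset[int]:
        """All point awards this item can produce."""
        if self.kind == CATEGORICAL:
            return frozenset(self.mapping.values())
        return frozenset(p for _, _, p in self.mapping)

    def best_answer(self):
        """An answer earning the item's maximum points."""
        if self.kind == CATEGORICAL:
            return max(self.mapping, key=self.mapping.__getitem__)
        lo, hi, _ = max(self.mapping, key=lambda t: t[2])
        return _representative(lo, hi, self.kind)

    def worst_answer(self):
        if self.kind == CATEGORICAL:
            return min(self.mapping, key=self.mapping.__getitem__)
        lo, hi, _ = min(self.mapping, key=lambda t: t[2])
        return _representative(lo, hi, self.kind)

    def answers_scoring(self, points: int) -> list:
        """All answer representatives that earn exactly ``points``."""
        if self.kind == CATEGORICAL:
            return [o for o, p in self.mapping.items() if p == points]
        return [
            _representative(lo, hi, self.kind)
            for lo, hi, p in self.mapping
            if p == points
        ]


def _representative(lo: float, hi: float | None, kind: str):
    """A concrete in-domain value inside the half-open interval [lo, hi)."""
    if kind == COUNT_THRESHOLD:
        return int(lo)
    # time: must be strictly positive
    if lo > 0:
        return float(lo)
    return (hi / 2.0) if hi is not None else 1.0


@dataclass(frozen=True)
class BoxScheme:
    box_id: int
    items: tuple[ItemRule, ...]
    max_points: int

    @property
    def min_points(self) -> int:
        return sum(it.min_points for it in self.items)

    def achievable_scores(self) -> frozenset[int]:
        """All sub-score values this box can produce (subset-sum over items)."""
        sums = {0}
        for it in self.items:
            sums = {s + p for s in sums for p in it.point_values}
        return frozenset(sums)


@dataclass(frozen=True)
class ScoringScheme:
    version: str
    boxes: tuple[BoxScheme, ...]

    def box(self, box_id: int) -> BoxScheme:
        for b in self.boxes:
            if b.box_id == box_id:
                return b
        raise KeyError(box_id)

    @property
    def items(self) -> tuple[ItemRule, ...]:
        return tuple(it for b in self.boxes for it in b.items)

    def achievable_totals(self) -> frozenset[int]:
        sums = {0}
        for b in self.boxes:
            sums = {s + a for s in sums for a in b.achievable_scores()}
        return frozenset(sums)

    # -- JSON round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        out = {"version": self.version, "boxes": []}
        for b in self.boxes:
            items = []
            for it in b.items:
                if it.kind == CATEGORICAL:
                    mapping = dict(it.mapping)
                else:
                    mapping = [list(iv) for iv in it.mapping]
                items.append({"id": it.item_id, "kind": it.kind, "mapping": mapping})
            out["boxes"].append(
                {"box_id": b.box_id, "max_points": b.max_points, "items": items}
            )
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScoringScheme":
        boxes = []
        for bd in data["boxes"]:
            items = []
            for it in bd["items"]:
                kind = it["kind"]
                if kind == CATEGORICAL:
                    mapping = {str(k): int(v) for k, v in it["mapping"].items()}
                else:
                    mapping = tuple(
                        (float(lo), None if hi is None else float(hi), int(p))
                        for lo, hi, p in it["mapping"]
                    )
                items.append(ItemRule(item_id=it["id"], kind=kind, mapping=mapping))
            boxes.append(
                BoxScheme(
                    box_id=int(bd["box_id"]),
                    items=tuple(items),
                    max_points=int(bd["max_points"]),
                )
            )
        return cls(version=str(data.get("version", "unversioned")), boxes=tuple(boxes))

    @classmethod
    def from_json(cls, path) -> "ScoringScheme":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class QuestionnaireResponse:
    """One respondent's raw answers for every device they tested.

    ``answers`` maps device -> {item_id -> raw answer}; answers are the option
    label for categorical items and the measured count/seconds otherwise.
    """

    respondent_id: str
    stratum: str
    group: int
    answers: Mapping[str, Mapping[str, object]]


@dataclass(frozen=True)
class GUSRecord:
    """One respondent x device observation: five box sub-scores and the total."""

    respondent_id: str
    stratum: str
    group: int
    device: str
    subscores: tuple[int, int, int, int, int]
    gus_total: int

    def __post_init__(self):
        if self.gus_total != sum(self.subscores):
            raise ValueError(
                f"gus_total {self.gus_total} != sum of sub-scores "
                f"{sum(self.subscores)} for {self.respondent_id}/{self.device}"
            )
        if not 0 <= self.gus_total <= GUS_MAX:
            raise ValueError(f"gus_total {self.gus_total} outside [0, {GUS_MAX}]")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def validate_scheme(scheme: ScoringScheme) -> ScoringScheme:
    """Check every structural invariant; return the scheme unchanged if valid.

    Raises :class:`InvalidSchemeError` naming the offending constraint.
    """
    if len(scheme.boxes) != 5:
        raise InvalidSchemeError(
            f"scheme must have exactly 5 boxes, found {len(scheme.boxes)}"
        )
    if sorted(b.box_id for b in scheme.boxes) != [1, 2, 3, 4, 5]:
        raise InvalidSchemeError("box ids must be exactly 1..5")
    total_max = sum(b.max_points for b in scheme.boxes)
    if total_max != GUS_MAX:
        raise InvalidSchemeError(
            f"box maxima must sum to {GUS_MAX}, found {total_max}"
        )
    for b in scheme.boxes:
        attainable = sum(it.max_points for it in b.items)
        if b.max_points != attainable:
            raise InvalidSchemeError(
                f"box {b.box_id}: declared max {b.max_points} != attainable {attainable}"
            )
        for it in b.items:
            if it.min_points < 0:
                raise InvalidSchemeError(
                    f"item {it.item_id}: negative point award"
                )
            if it.kind == CATEGORICAL:
                continue
            if it.kind not in _MEASUREMENT_KINDS:
                raise InvalidSchemeError(
                    f"item {it.item_id}: unknown kind {it.kind!r}"
                )
            ivs = sorted(it.mapping, key=lambda t: t[0])
            prev_hi = ivs[0][0]
            prev_pts = None
            for lo, hi, pts in ivs:
                if lo != prev_hi:
                    raise InvalidSchemeError(
                        f"item {it.item_id}: intervals do not partition the domain "
                        f"(gap/overlap at {lo})"
                    )
                if prev_pts is not None and pts > prev_pts:
                    raise InvalidSchemeError(
                        f"item {it.item_id}: points must be non-increasing in the "
                        f"measured value (interval starting at {lo})"
                    )
                prev_pts = pts
                prev_hi = hi if hi is not None else float("inf")
            if prev_hi != float("inf"):
                raise InvalidSchemeError(
                    f"item {it.item_id}: last interval must be unbounded above"
                )
    return scheme


def score_measurement(value: float, rule: ItemRule) -> int:
    """Points for a nurse-measured count/time under a threshold rule.

    Intervals are half-open ``[lo, hi)``: a value exactly on a boundary scores
    with the interval whose lower edge it is.
    """
    if rule.kind not in _MEASUREMENT_KINDS:
        raise TypeError(f"item {rule.item_id!r} is not a measurement rule")
    if value < 0:
        raise ValueError(f"item {rule.item_id}: negative measurement {value}")
    for lo, hi, pts in rule.mapping:
        if value >= lo and (hi is None or value < hi):
            return pts
    raise ValueError(f"item {rule.item_id}: value {value} outside rule domain")


def score_item(answer, rule: ItemRule) -> int:
    if rule.kind == CATEGORICAL:
        try:
            return rule.mapping[answer]
        except KeyError:
            raise ValueError(
                f"item {rule.item_id}: unknown option {answer!r}"
            ) from None
    return score_measurement(float(answer), rule)


def score_box(answers: Mapping[str, object], box: BoxScheme, *, context: str = "") -> int:
    """Sub-score for one box: the sum of its item points.

    Missing answers raise :class:`MissingAnswerError` (supervised
    administration means a blank is a data error, never something to impute).
    """
    total = 0
    for it in box.items:
        if it.item_id not in answers:
            raise MissingAnswerError(
                f"missing answer for box {box.box_id} item {it.item_id!r}"
                + (f" ({context})" if context else "")
            )
        total += score_item(answers[it.item_id], it)
    return total


def compute_gus(
    response: QuestionnaireResponse, scheme: ScoringScheme
) -> list[GUSRecord]:
    """Score a full response: one :class:`GUSRecord` per tested device.

    The GUS total is the exact sum of the five box sub-scores and always lies
    in [0, 50] for a valid scheme.
    """
    stratum = canonical_stratum(response.stratum)
    allowed = GROUP_DEVICES[response.group]
    records = []
    for device in sort_devices(canonical_device(d) for d in response.answers):
        if device not in allowed:
            raise DesignViolationError(
                f"respondent {response.respondent_id} (group {response.group}) "
                f"reports device {device} outside the group set "
                f"{sorted(allowed)}"
            )
        # answers may be keyed by the raw device name
        raw_key = next(
            k for k in response.answers if canonical_device(k) == device
        )
        answers = response.answers[raw_key]
        subs = tuple(
            score_box(
                answers,
                scheme.box(b),
                context=f"respondent {response.respondent_id}, device {device}",
            )
            for b in range(1, 6)
        )
        records.append(
            GUSRecord(
                respondent_id=response.respondent_id,
                stratum=stratum,
                group=response.group,
                device=device,
                subscores=subs,  # type: ignore[arg-type]
                gus_total=sum(subs),
            )
        )
    return records


# ---------------------------------------------------------------------------
# default (placeholder) scheme
# ---------------------------------------------------------------------------

def default_scheme() -> ScoringScheme:
    """A placeholder scheme honouring every structural constraint.

    Box maxima are (10, 10, 10, 10, 10).  Box 1 is the at-glance preference,
    boxes 2-4 are the nurse measurements (critical issues, attempts, seconds
    to autonomy) and box 5 holds ten one-point closed questions.  The point
    values are NOT the published instrument's weights (those are not public);
    any study using real data should supply its own scheme JSON.
    """
    glance = ItemRule(
        "glance_preference",
        CATEGORICAL,
        {"very favourable": 10, "favourable": 7, "neutral": 4, "unfavourable": 0},
    )
    critical = ItemRule(
        "critical_issues",
        COUNT_THRESHOLD,
        ((0.0, 1.0, 10), (1.0, 2.0, 7), (2.0, 3.0, 4), (3.0, None, 0)),
    )
    attempts = ItemRule(
        "actuation_attempts",
        COUNT_THRESHOLD,
        ((1.0, 2.0, 10), (2.0, 3.0, 7), (3.0, 5.0, 4), (5.0, None, 0)),
    )
    autonomy = ItemRule(
        "seconds_to_autonomy",
        TIME_THRESHOLD,
        ((0.0, 60.0, 10), (60.0, 120.0, 7), (120.0, 300.0, 4), (300.0, None, 0)),
    )
    closed = tuple(
        ItemRule(f"closed_q{i:02d}", CATEGORICAL, {"yes": 1, "no": 0})
        for i in range(1, 11)
    )
    return ScoringScheme(
        version="default-placeholder-1",
        boxes=(
            BoxScheme(1, (glance,), 10),
            BoxScheme(2, (critical,), 10),
            BoxScheme(3, (attempts,), 10),
            BoxScheme(4, (autonomy,), 10),
            BoxScheme(5, closed, 10),
        ),
    )


def best_answers(scheme: ScoringScheme) -> dict[str, object]:
    """Item answers earning the maximum on every item (scores GUS_MAX)."""
    return {it.item_id: it.best_answer() for it in scheme.items}


def worst_answers(scheme: ScoringScheme) -> dict[str, object]:
    return {it.item_id: it.worst_answer() for it in scheme.items}
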