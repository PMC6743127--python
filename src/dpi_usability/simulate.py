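"""Synthetic cohorts with the trial's incomplete-block design and known truth.

The real per-patient questionnaire data are not publicly deposited, so every
downstream stage (scoring, network building, model fitting, ranking) is
exercised against cohorts simulated from the same design: 103 respondents,
74 DPI-experienced and 29 DPI-naive, split into three groups that each test
a fixed subset of the seven devices (2-4 devices per respondent, every group
containing Breezhaler).

Scores are generated from the additive model the fitting stage assumes,

    y_ik = clamp(round(mu_i + e_k + eta_ik + eps_ik), 0, 50)

with respondent usability level mu_i ~ N(anchor, respondent_sd^2), device
effects e_k (reference Breezhaler at e=0, its absolute level set by the
anchor), respondent-by-device heterogeneity eta ~ N(0, heterogeneity_sd^2)
(zero for fixed-effect truth) and residual noise eps ~ N(0, residual_sd^2).
All latent draws are returned as ground truth so recovery can be measured.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .devices import DEVICES, DEVICE_INDEX, GROUP_DEVICES, REFERENCE_DEVICE, sort_devices
from .scoring import (
    BoxScheme,
    GUSRecord,
    GUS_MAX,
    ItemRule,
    QuestionnaireResponse,
    ScoringScheme,
    validate_scheme,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupArm:
    devices: frozenset[str]
    n_experienced: int
    n_naive: int


@dataclass(frozen=True)
class CohortDesign:
    groups: dict[int, GroupArm]

    @property
    def n_experienced(self) -> int:
        return sum(g.n_experienced for g in self.groups.values())

    @property
    def n_naive(self) -> int:
        return sum(g.n_naive for g in self.groups.values())

    @property
    def n_total(self) -> int:
        return self.n_experienced + self.n_naive

    def scaled(self, factor: int) -> "CohortDesign":
        """The same block structure with every arm size multiplied."""
        return CohortDesign(
            {
                gid: GroupArm(a.devices, a.n_experienced * factor, a.n_naive * factor)
                for gid, a in self.groups.items()
            }
        )


def paper_design() -> CohortDesign:
    """The published design: 103 respondents (74 experienced / 29 naive).

    Group 1 (27 experienced + 9 naive) tests Breezhaler, Spiromax, Nexthaler,
    Ellipta; Group 2 (28 + 9) tests Breezhaler, Spiromax, Diskus, Turbohaler;
    Group 3 (19 + 11) tests Breezhaler and Genuair.
    """
    return CohortDesign(
        {
            1: GroupArm(GROUP_DEVICES[1], 27, 9),
            2: GroupArm(GROUP_DEVICES[2], 28, 9),
            3: GroupArm(GROUP_DEVICES[3], 19, 11),
        }
    )


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth parameters for one simulated cohort.

    ``true_effects`` holds the seven device effects in canonical device order,
    with the reference (Breezhaler) conventionally at 0; its absolute GUS
    level is ``anchor`` (default 25, mid-scale, which keeps 0/50 truncation
    negligible for |e_k| <= 15).
    """

    true_effects: tuple[float, ...]
    respondent_sd: float = 5.0
    residual_sd: float = 5.0
    heterogeneity_sd: float = 0.0
    anchor: float = 25.0
    rounding: str = "integer"  # none | integer | half-point
    seed: int = 0

    def __post_init__(self):
        if len(self.true_effects) != len(DEVICES):
            raise ValueError(f"true_effects must have {len(DEVICES)} entries")
        for name in ("respondent_sd", "residual_sd", "heterogeneity_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rounding not in ("none", "integer", "half-point"):
            raise ValueError(f"unknown rounding mode {self.rounding!r}")


@dataclass
class GroundTruth:
    """Latent draws behind a simulated cohort."""

    params: SimulationParams
    mu: dict[str, float]                      # respondent -> latent level
    eta: dict[tuple[str, str], float]         # (respondent, device) -> heterogeneity
    truncated: int = 0
    n_scores: int = 0

    @property
    def truncation_rate(self) -> float:
        return self.truncated / self.n_scores if self.n_scores else 0.0

    def to_dict(self) -> dict:
        return {
            "true_effects": dict(zip(DEVICES, self.params.true_effects)),
            "anchor": self.params.anchor,
            "respondent_sd": self.params.respondent_sd,
            "residual_sd": self.params.residual_sd,
            "heterogeneity_sd": self.params.heterogeneity_sd,
            "rounding": self.params.rounding,
            "seed": self.params.seed,
            "mu": self.mu,
            "truncation_rate": self.truncation_rate,
        }


def _round(values: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return values
    if mode == "integer":
        return np.rint(values)
    return np.rint(values * 2.0) / 2.0  # half-point


def generate_cohort(
    design: CohortDesign, params: SimulationParams
) -> tuple[list[GUSRecord], GroundTruth]:
    """Simulate one cohort; deterministic for a fixed seed.

    Returns the GUS records (with sub-scores allocated consistently with the
    default box maxima) and the full latent ground truth.
    """
    effects = np.asarray(params.true_effects, float)
    extreme = params.anchor + effects
    if np.any(extreme < 5.0) or np.any(extreme > 45.0):
        warnings.warn(
            "true device means approach the 0/50 bounds; truncation bias likely",
            stacklevel=2,
        )
    rng = np.random.default_rng(params.seed)
    records: list[GUSRecord] = []
    truth = GroundTruth(params=params, mu={}, eta={})
    counter = 0
    for gid in sorted(design.groups):
        arm = design.groups[gid]
        devices = sort_devices(arm.devices)
        dev_idx = np.array([DEVICE_INDEX[d] for d in devices])
        for stratum, n in (("experienced", arm.n_experienced), ("naive", arm.n_naive)):
            for _ in range(n):
                counter += 1
                rid = f"R{counter:04d}"
                mu_i = params.anchor + rng.normal(0.0, params.respondent_sd)
                truth.mu[rid] = float(mu_i)
                eta = rng.normal(0.0, params.heterogeneity_sd, size=len(devices))
                eps = rng.normal(0.0, params.residual_sd, size=len(devices))
                y = mu_i + effects[dev_idx] + eta + eps
                y = _round(y, params.rounding)
                clipped = np.clip(y, 0.0, GUS_MAX)
                truth.truncated += int(np.sum(clipped != y))
                truth.n_scores += len(devices)
                for d, e, total in zip(devices, eta, clipped):
                    truth.eta[(rid, d)] = float(e)
                    total_val = int(total) if params.rounding == "integer" else float(total)
                    records.append(
                        GUSRecord(
                            respondent_id=rid,
                            stratum=stratum,
                            group=gid,
                            device=d,
                            subscores=_allocate_subscores(total_val),
                            gus_total=total_val,
                        )
                    )

    if truth.truncated:
        logger.warning(
            "simulate: %d/%d scores truncated at the 0/50 bounds (rate %.3f)",
            truth.truncated,
            truth.n_scores,
            truth.truncation_rate,
        )
    return records, truth


# ---------------------------------------------------------------------------
# sub-score allocation and questionnaire inversion
# ---------------------------------------------------------------------------

def _box_sets(scheme: ScoringScheme) -> list[tuple[int, frozenset[int]]]:
    return [(b.box_id, b.achievable_scores()) for b in scheme.boxes]


def _reachable_suffix(box_sets: list[tuple[int, frozenset[int]]]) -> list[set[int]]:
    """reachable[j] = totals attainable by boxes j..end."""
    reachable: list[set[int]] = [set() for _ in range(len(box_sets) + 1)]
    reachable[-1] = {0}
    for j in range(len(box_sets) - 1, -1, -1):
        _, scores = box_sets[j]
        reachable[j] = {s + r for s in scores for r in reachable[j + 1]}
    return reachable


def allocate_box_scores(
    total: int | float,
    scheme: ScoringScheme,
    rng: np.random.Generator | None = None,
) -> tuple[int, ...]:
    """Split an achievable total into per-box sub-scores (DP over boxes).

    With an ``rng`` the split is sampled uniformly over valid first choices at
    each box; without one the largest feasible sub-score is taken greedily.
    """
    total = int(total)
    box_sets = _box_sets(scheme)
    reachable = _reachable_suffix(box_sets)
    if total not in reachable[0]:
        raise ValueError(f"total {total} not achievable under scheme")
    out = []
    remaining = total
    for j, (_, scores) in enumerate(box_sets):
        feasible = sorted(s for s in scores if remaining - s in reachable[j + 1])
        pick = int(rng.choice(feasible)) if rng is not None else feasible[-1]
        out.append(pick)
        remaining -= pick
    return tuple(out)


_DEFAULT_ALLOC_CACHE: dict[int, tuple[int, ...]] = {}


def _allocate_subscores(total: int | float) -> tuple:
    """Deterministic sub-score split under the default scheme (cached).

    Fractional totals (rounding modes other than integer) put the fractional
    remainder on box 5 so the sub-scores still sum exactly to the total.
    """
    base = int(np.floor(total))
    if base not in _DEFAULT_ALLOC_CACHE:
        from .scoring import default_scheme

        _DEFAULT_ALLOC_CACHE[base] = allocate_box_scores(base, default_scheme())
    subs = _DEFAULT_ALLOC_CACHE[base]
    frac = total - base
    if frac:
        subs = subs[:4] + (subs[4] + frac,)
    return subs


def _invert_box(
    box: BoxScheme, target: int, rng: np.random.Generator
) -> dict[str, object]:
    """Item answers for one box whose points sum to ``target`` (DP over items)."""
    items = box.items
    reachable: list[set[int]] = [set() for _ in range(len(items) + 1)]
    reachable[-1] = {0}
    for j in range(len(items) - 1, -1, -1):
        reachable[j] = {
            p + r for p in items[j].point_values for r in reachable[j + 1]
        }
    if target not in reachable[0]:
        raise ValueError(f"box {box.box_id}: sub-score {target} not achievable")
    answers: dict[str, object] = {}
    remaining = target
    for j, it in enumerate(items):
        feasible = sorted(
            p for p in it.point_values if remaining - p in reachable[j + 1]
        )
        pts = int(rng.choice(feasible))
        candidates = it.answers_scoring(pts)
        answers[it.item_id] = candidates[int(rng.integers(len(candidates)))]
        remaining -= pts
    return answers


def inverse_questionnaire(
    records: list[GUSRecord],
    scheme: ScoringScheme,
    seed: int,
) -> list[QuestionnaireResponse]:
    """Construct raw questionnaire answers that score back to each record.

    For every record the scored total of the produced answers equals the
    record's ``gus_total`` (round-trip identity), provided the total is
    achievable under the scheme's granularity; otherwise the nearest
    achievable total is used and a warning is emitted naming both values.
    """
    validate_scheme(scheme)
    rng = np.random.default_rng(seed)
    achievable = sorted(scheme.achievable_totals())
    by_resp: dict[str, list[GUSRecord]] = {}
    for r in records:
        by_resp.setdefault(r.respondent_id, []).append(r)
    responses = []
    for rid, recs in by_resp.items():
        answers: dict[str, dict[str, object]] = {}
        for rec in recs:
            target = int(round(rec.gus_total))
            if target not in achievable or target != rec.gus_total:
                nearest = min(achievable, key=lambda a: abs(a - rec.gus_total))
                warnings.warn(
                    f"gus_total {rec.gus_total} unreachable under scheme "
                    f"{scheme.version!r}; using nearest achievable {nearest}",
                    stacklevel=2,
                )
                target = nearest
            subs = allocate_box_scores(target, scheme, rng)
            dev_answers: dict[str, object] = {}
            for box, s in zip(scheme.boxes, subs):
                dev_answers.update(_invert_box(box, s, rng))
            answers[rec.device] = dev_answers
        first = recs[0]
        responses.append(
            QuestionnaireResponse(
                respondent_id=rid,
                stratum=first.stratum,
                group=first.group,
                answers=answers,
            )
        )
    return responses
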