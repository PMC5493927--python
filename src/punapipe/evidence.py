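"""Land-use models, per-hypothesis support records, and the evidence scorecard.

Three competing models for hunter-gatherer use of a high-elevation site are
encoded as expectation rows (:class:`ModelExpectation`):

* ``logistical`` — task groups provisioned from a low-elevation base camp;
* ``seasonal``   — whole-group transhumance across the 2500 m contour;
* ``permanent``  — annual rounds situated almost entirely at high elevation.

Five independent lines of evidence are tested against each model: drinking
water delta-18O (H1), diet delta-13C (H2), travel distance to the 2500 m
contour (H3), demographic composition (H4), and non-local lithic abundance
(H5).  Support is conjunctive: a model is selected only when every evaluated
hypothesis supports it.  Because the lines are independent, the probability
that k supporting lines are all false positives decays as p**k — with an
illustrative per-line false-positive rate of 0.20, two convergent lines leave
only a 0.04 joint false-positive probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "MODEL_IDS",
    "ModelExpectation",
    "SupportRecord",
    "EvidenceScorecard",
    "expectations",
    "joint_false_positive",
    "distance_rule_eval",
    "score",
    "scorecard_markdown",
]

MODEL_IDS = ("logistical", "seasonal", "permanent")

#: canonical hypothesis labels, section numbering (distance is H3, demography H4)
HYPOTHESES = ("H1_d18O", "H2_d13C", "H3_distance", "H4_demography", "H5_provenance")


@dataclass(frozen=True)
class ModelExpectation:
    """One land-use model's acceptance windows and rules.

    ``d18O_window``/``d13C_window`` are closed per-mil intervals; a sample set
    supports the model only when every value lies inside.  ``distance_rule_km``
    is the maximum admissible round-trip distance to the 2500 m contour
    (``None`` = any distance).  ``demography_rule`` is ``"task_group"``
    (children absent, sex parity rejected) or ``"full_spectrum"`` (children and
    old adults present, parity not rejected).  ``nonlocal_rule`` names the
    expected abundance class of non-local lithic raw material.
    """

    model_id: str
    d18O_window: tuple[float, float]
    d13C_window: tuple[float, float]
    demography_rule: str
    distance_rule_km: Optional[float]
    nonlocal_rule: str

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        for w in (self.d18O_window, self.d13C_window):
            if w[0] > w[1]:
                raise ValueError(f"window {w} is not well-ordered")
        if self.demography_rule not in ("task_group", "full_spectrum"):
            raise ValueError(f"unknown demography_rule {self.demography_rule!r}")
        if self.nonlocal_rule not in ("abundant", "present", "absent"):
            raise ValueError(f"unknown nonlocal_rule {self.nonlocal_rule!r}")


# Published isotope windows come in two printed variants: the summary-table
# rows ("table2") and the narrative's per-model ranges ("text").  The two
# disagree for delta-13C, and the summary-table model-3 window (-28..-21)
# does not even contain the observed human range (-24..-20) that the source
# nonetheless scores as supporting model 3.  The "reconciled" preset resolves
# that internal inconsistency: it keeps the summary-table delta-18O windows,
# and for delta-13C uses the narrative windows for models 1 and 3 with the
# summary-table window for model 2 — the unique assignment consistent with the
# published per-cell support pattern.  See docs/methods.md.
_D18O = {
    "table2": {"logistical": (-8.0, -5.0), "seasonal": (-12.0, -5.0), "permanent": (-25.0, -8.0)},
    "text": {"logistical": (-8.0, -5.0), "seasonal": (-12.0, -5.0), "permanent": (-25.0, -8.0)},
}
_D13C = {
    "table2": {"logistical": (-29.0, -24.0), "seasonal": (-28.0, -22.0), "permanent": (-28.0, -21.0)},
    "text": {"logistical": (-27.0, -22.0), "seasonal": (-27.0, -19.0), "permanent": (-27.0, -19.0)},
}
_D18O["reconciled"] = _D18O["table2"]
_D13C["reconciled"] = {
    "logistical": _D13C["text"]["logistical"],
    "seasonal": _D13C["table2"]["seasonal"],
    "permanent": _D13C["text"]["permanent"],
}

_DEMOGRAPHY_RULE = {"logistical": "task_group", "seasonal": "full_spectrum",
                    "permanent": "full_spectrum"}
#: round-trip bounds (km): logistical forays stay under 80 km round-trip,
#: annual residential rounds under 1000 km; permanent use admits any distance.
_DISTANCE_RT_KM = {"logistical": 80.0, "seasonal": 1000.0, "permanent": None}
_NONLOCAL_RULE = {"logistical": "abundant", "seasonal": "present", "permanent": "absent"}


def expectations(preset: str = "reconciled") -> list[ModelExpectation]:
    """The three-model expectation matrix under a named isotope-window preset.

    Presets: ``"reconciled"`` (default; for observed data), ``"table2"``
    (summary-table windows as printed; also the generating windows of the
    synthetic population model), ``"text"`` (narrative windows as printed).
    """
    if preset not in _D13C:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_D13C)}")
    return [
        ModelExpectation(
            model_id=m,
            d18O_window=_D18O[preset][m],
            d13C_window=_D13C[preset][m],
            demography_rule=_DEMOGRAPHY_RULE[m],
            distance_rule_km=_DISTANCE_RT_KM[m],
            nonlocal_rule=_NONLOCAL_RULE[m],
        )
        for m in MODEL_IDS
    ]


@dataclass
class SupportRecord:
    """Outcome of one hypothesis test: per-model support flags plus detail.

    ``per_model`` maps model_id -> True/False, or ``None`` when the hypothesis
    could not be evaluated for that model (e.g. an empty demographic profile).
    """

    hypothesis: str
    per_model: dict[str, Optional[bool]]
    detail: dict = field(default_factory=dict)

    def evaluated(self) -> bool:
        return any(v is not None for v in self.per_model.values())


@dataclass
class EvidenceScorecard:
    """Aggregate of all evaluated hypotheses across the three models."""

    records: list[SupportRecord]
    support_counts: dict[str, int]
    n_evaluated: int
    selected_model: Optional[str]
    joint_fp: Optional[float]
    skipped_hypotheses: list[str] = field(default_factory=list)


def joint_false_positive(p_per_line: float, k_lines: int) -> float:
    """Probability that ``k_lines`` independent supporting lines of evidence
    are all false positives, each with per-line rate ``p_per_line``."""
    if not (0.0 <= p_per_line <= 1.0):
        raise ValueError(f"p_per_line must be in [0, 1], got {p_per_line}")
    if k_lines < 1:
        raise ValueError(f"k_lines must be >= 1, got {k_lines}")
    return p_per_line ** k_lines


def distance_rule_eval(round_trip_km: float,
                       models: Optional[Sequence[ModelExpectation]] = None,
                       encoding: str = "round_trip") -> SupportRecord:
    """Evaluate the travel-distance hypothesis for each model.

    ``encoding="round_trip"`` (default) compares the round-trip distance
    against each model's bound inclusively (supported iff distance <= bound).
    ``encoding="one_way_strict"`` is the alternative printed encoding — the
    summary table's "less than 40 km / less than 500 km" cells read as one-way
    bounds with strict inequality.  Both resolve identically except exactly at
    a bound.
    """
    if not math.isfinite(round_trip_km) or round_trip_km < 0:
        raise ValueError(f"round_trip_km must be finite and >= 0, got {round_trip_km}")
    if models is None:
        models = expectations()
    per_model: dict[str, Optional[bool]] = {}
    for m in models:
        bound = m.distance_rule_km
        if bound is None:
            per_model[m.model_id] = True
        elif encoding == "round_trip":
            per_model[m.model_id] = round_trip_km <= bound
        elif encoding == "one_way_strict":
            per_model[m.model_id] = round_trip_km / 2.0 < bound / 2.0
        else:
            raise ValueError(f"unknown encoding {encoding!r}")
    return SupportRecord(
        hypothesis="H3_distance",
        per_model=per_model,
        detail={"round_trip_km": round_trip_km, "encoding": encoding},
    )


def score(h_results: Sequence[SupportRecord], p_per_line: float = 0.20) -> EvidenceScorecard:
    """Aggregate hypothesis outcomes into a scorecard.

    A model's support count is the number of evaluated hypotheses it passes;
    ``selected_model`` is the unique model passing *every* evaluated
    hypothesis, else ``None``.  ``joint_fp`` is the probability that all lines
    supporting the selected model are false positives (``None`` when no model
    is selected).  Hypotheses with no evaluable outcome are excluded and
    listed in ``skipped_hypotheses``.  The result is invariant to the input
    order of ``h_results``.
    """
    if not h_results:
        raise ValueError("at least one hypothesis result is required")
    records = sorted(h_results, key=lambda r: r.hypothesis)
    evaluated = [r for r in records if r.evaluated()]
    skipped = [r.hypothesis for r in records if not r.evaluated()]
    if not evaluated:
        raise ValueError("no hypothesis could be evaluated")

    model_ids = list(evaluated[0].per_model)
    counts = {m: sum(1 for r in evaluated if r.per_model.get(m) is True) for m in model_ids}
    full = [m for m in model_ids
            if all(r.per_model.get(m) is True for r in evaluated)]
    selected = full[0] if len(full) == 1 else None
    joint_fp = joint_false_positive(p_per_line, counts[selected]) if selected else None
    return EvidenceScorecard(
        records=records,
        support_counts=counts,
        n_evaluated=len(evaluated),
        selected_model=selected,
        joint_fp=joint_fp,
        skipped_hypotheses=skipped,
    )


def scorecard_markdown(card: EvidenceScorecard) -> str:
    """Human-readable summary table mirroring the three-model matrix."""
    model_ids = list(card.support_counts)
    lines = ["| hypothesis | " + " | ".join(model_ids) + " |",
             "|---" * (len(model_ids) + 1) + "|"]
    sym = {True: "pass", False: "fail", None: "n/a"}
    for r in card.records:
        lines.append("| " + r.hypothesis + " | "
                     + " | ".join(sym[r.per_model.get(m)] for m in model_ids) + " |")
    lines.append("| supported / evaluated | "
                 + " | ".join(f"{card.support_counts[m]}/{card.n_evaluated}"
                              for m in model_ids) + " |")
    lines.append("")
    if card.selected_model:
        lines.append(f"selected model: **{card.selected_model}** "
                     f"(joint false-positive probability {card.joint_fp:.2g} "
                     f"at 0.20 per line)")
    else:
        lines.append("selected model: none (no model supported across the board)")
    return "\n".join(lines)
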