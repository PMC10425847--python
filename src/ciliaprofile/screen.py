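"""Phenotype-scoring rubrics for the in vivo follow-up screens.

Two model organisms probe the candidate genes: RNAi knockdown in the fly
(viability, uncoordination, wing posture, flight, male fertility,
spermiogenesis stages, chordotonal-organ scolopidia) and mutant dye-fill
assays in the worm (lipophilic dye only enters amphid/phasmid sensory
neurons through structurally intact cilia).  Every assay maps onto a 0 (no
phenotype) to 4 (strong) scale; a gene is called significant when any assay
scores above 1.

The printed dye-fill bins leave small gaps between adjacent intervals
(e.g. 10.9-11.0 amphid neurons) because means were reported to one decimal;
bins here are half-open with the gap attached to the worse (higher) score,
so every in-range value scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

#: Scores strictly above this count as a significant phenotype.
SIGNIFICANCE_THRESHOLD = 1

#: A scolopidium is called abnormal when more than this fraction of its
#: neurons are morphologically defective.
SCOLOPIDIA_ABNORMAL_FRACTION = 0.20


@dataclass
class ScreenRecord:
    """Per-gene phenotype scores from either organism's screen.

    ``scores`` maps assay name -> integer 0-4; assays not performed are
    simply absent (never imputed as 0).
    """

    gene_id: str
    organism: str  # fly | worm
    scores: dict[str, int] = field(default_factory=dict)
    novelty: str | None = None  # known | novel

    def __post_init__(self) -> None:
        if self.organism not in ("fly", "worm"):
            raise ValueError(f"unknown organism {self.organism!r}")
        for assay, score in self.scores.items():
            if score not in (0, 1, 2, 3, 4):
                raise ValueError(f"{assay}: score {score!r} not in 0-4")
        if self.novelty not in (None, "known", "novel"):
            raise ValueError(f"unknown novelty {self.novelty!r}")

    @property
    def significant(self) -> bool:
        return any(s > SIGNIFICANCE_THRESHOLD for s in self.scores.values())


# ---------------------------------------------------------------------------
# worm dye-fill scoring
# ---------------------------------------------------------------------------

def score_dyefill(amphid_mean: float, phasmid_mean: float) -> tuple[int, int, int]:
    """Bin mean dye-filled neuron counts into (amphid, phasmid, overall).

    Amphids (12 neurons): 0 = 11.5-12, 1 = 11-11.49, 2 = 10-10.9,
    3 = 6-9.9, 4 = 0-5.9.  Phasmids (4 neurons): 0 = 3.85-4, 1 = 3.75-3.84,
    2 = 3.5-3.74, 3 = 0.25-3.49, 4 = 0-0.24.  The stronger of the two is
    the overall phenotype.
    """
    if not 0 <= amphid_mean <= 12:
        raise ValueError(f"amphid mean {amphid_mean} outside [0, 12]")
    if not 0 <= phasmid_mean <= 4:
        raise ValueError(f"phasmid mean {phasmid_mean} outside [0, 4]")
    amphid = _bin_descending(amphid_mean, [(11.5, 0), (11.0, 1), (10.0, 2), (6.0, 3)])
    phasmid = _bin_descending(phasmid_mean, [(3.85, 0), (3.75, 1), (3.5, 2), (0.25, 3)])
    return amphid, phasmid, max(amphid, phasmid)


def _bin_descending(value: float, edges: list[tuple[float, int]]) -> int:
    """Half-open bins: score of the first edge the value reaches, else 4."""
    for lower, score in edges:
        if value >= lower:
            return score
    return 4


# ---------------------------------------------------------------------------
# fly rubrics
# ---------------------------------------------------------------------------

def score_fertility(pupae_count: float) -> int:
    """Male-fertility score from the pupae count of a test cross
    (control crosses average 120 pupae): >=90 -> 0, 60-89 -> 1, 30-59 -> 2,
    10-29 -> 3, <10 -> 4."""
    if pupae_count < 0:
        raise ValueError(f"negative pupae count {pupae_count}")
    return _bin_descending(pupae_count, [(90, 0), (60, 1), (30, 2), (10, 3)])


def _score_viability(dead_fraction: float) -> int:
    # 4 = complete lethality; 3 = few survivors; 2 = half died;
    # 1 = dead but less than half; 0 = no or few dead
    if not 0 <= dead_fraction <= 1:
        raise ValueError(f"dead fraction {dead_fraction} outside [0, 1]")
    if dead_fraction >= 1:
        return 4
    if dead_fraction >= 0.9:
        return 3
    if dead_fraction >= 0.5:
        return 2
    if dead_fraction >= 0.1:
        return 1
    return 0


def _score_uncoordination(category: str) -> int:
    # strong classes are categorical observations; weak classes (flight
    # test) go through the "flight" rubric
    table = {"stuck_to_food": 4, "unable_to_climb": 3, "coordinated": 0}
    try:
        return table[category]
    except KeyError:
        raise ValueError(
            f"unknown uncoordination category {category!r}; "
            f"weak phenotypes are scored with the 'flight' rubric"
        ) from None


def _score_flight(nonflier_fraction: float) -> int:
    # 2 = half or more of the flies unable to fly; 1 = less than half but a
    # clear group of non-fliers; 0 otherwise
    if not 0 <= nonflier_fraction <= 1:
        raise ValueError(f"non-flier fraction {nonflier_fraction} outside [0, 1]")
    if nonflier_fraction >= 0.5:
        return 2
    if nonflier_fraction >= 0.15:
        return 1
    return 0


def _score_wing_posture(affected_fraction: float) -> int:
    # 4 = all individuals affected, 3 = more than half, 2 = half,
    # 1 = several individuals, 0 = no or few
    if not 0 <= affected_fraction <= 1:
        raise ValueError(f"affected fraction {affected_fraction} outside [0, 1]")
    if affected_fraction >= 1:
        return 4
    if affected_fraction > 0.5:
        return 3
    if affected_fraction >= 0.5:
        return 2
    if affected_fraction >= 0.15:
        return 1
    return 0


def _score_spermiogenesis(category: str) -> int:
    # per spermiogenesis stage: 0 normal morphology .. 4 missing stage
    table = {
        "normal": 0,
        "weak_deviation": 1,
        "stronger_effect": 2,
        "majority_aberrant": 3,
        "missing_stage": 4,
    }
    try:
        return table[category]
    except KeyError:
        raise ValueError(f"unknown spermiogenesis category {category!r}") from None


def _score_scolopidia(defective_fraction: float) -> int:
    # binary call: 1 = abnormal organ (defective fraction strictly above
    # 20%), 0 = normal
    if not 0 <= defective_fraction <= 1:
        raise ValueError(f"defective fraction {defective_fraction} outside [0, 1]")
    return int(defective_fraction > SCOLOPIDIA_ABNORMAL_FRACTION)


RUBRICS: dict[str, Callable] = {
    "fertility": score_fertility,
    "viability": _score_viability,
    "uncoordination": _score_uncoordination,
    "flight": _score_flight,
    "wing_posture": _score_wing_posture,
    "spermiogenesis_stage": _score_spermiogenesis,
    "scolopidia": _score_scolopidia,
}


def score_rubric(value, rubric_name: str) -> int:
    """Apply a named scoring rubric to a raw assay value.

    Numeric rubrics take a count or fraction; categorical rubrics
    (uncoordination, spermiogenesis_stage) take a category string.  The
    scolopidia rubric returns 1 (abnormal) when more than 20% of scolopidia
    are defective, 0 otherwise — strictly greater, so exactly 20% is normal.
    """
    try:
        fn = RUBRICS[rubric_name]
    except KeyError:
        raise ValueError(
            f"unknown rubric {rubric_name!r}; known: {sorted(RUBRICS)}"
        ) from None
    return fn(value)


def scolopidia_abnormal(defective_fraction: float) -> bool:
    return bool(_score_scolopidia(defective_fraction))


# ---------------------------------------------------------------------------
# significance aggregation
# ---------------------------------------------------------------------------

def aggregate_significance(
    records: Iterable[ScreenRecord],
    annotations: Mapping[str, str] | None = None,
) -> dict[str, dict[str, float]]:
    """Summarize significant phenotypes split by known vs novel genes.

    A gene is significant when any of its assay scores exceeds 1.  Novelty
    comes from the record itself or from ``annotations`` (gene -> known |
    novel); a gene with neither is an error.  Returns, per novelty class,
    the number of genes tested, number significant, and the percentage
    (rounded to integer, as conventionally reported).
    """
    summary: dict[str, dict[str, float]] = {}
    for rec in records:
        novelty = rec.novelty or (annotations or {}).get(rec.gene_id)
        if novelty not in ("known", "novel"):
            raise ValueError(f"gene {rec.gene_id!r} has no novelty annotation")
        bucket = summary.setdefault(novelty, {"tested": 0, "significant": 0})
        bucket["tested"] += 1
        bucket["significant"] += int(rec.significant)
    for bucket in summary.values():
        bucket["percent"] = round(100 * bucket["significant"] / bucket["tested"])
    return summary
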