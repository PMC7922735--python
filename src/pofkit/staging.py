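"""Six-stage postovulatory-follicle (POF) degeneration key for European anchovy.

After each nightly ovulation the emptied follicle (theca + granulosa envelope)
degenerates over roughly a day and a half at 24-25 degC.  Its histomorphology
passes through six recognisable stages: vacuolation of the granulosa, loss of
cell-wall integrity, nuclear pycnosis, lumen collapse and the progressive
shrinkage from a large folded cordon to a small triangular amorphous remnant.
This module encodes that key three ways:

* ``classify_stage`` -- a deterministic classifier over annotated
  histomorphological features (the key's rows plus a documented precedence
  order for near-miss annotation vectors);
* ``canonical_features`` -- the canonical feature vector of each stage
  (round-trips through the classifier);
* ``StageSchedule`` / ``stage_at_elapsed`` -- the forward aging key mapping
  hours since ovulation to a stage, used as simulator ground truth.

Feature annotations arrive as categorical tokens (e.g. from a reader scoring
slides); no image processing happens here.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd


class PofStage(enum.IntEnum):
    """Ordinal resorption stage, I (fresh) through VI (almost resorbed)."""

    I = 1
    II = 2
    III = 3
    IV = 4
    V = 5
    VI = 6

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


STAGES = tuple(PofStage)


class Vacuoles(str, enum.Enum):
    ABSENT = "absent"
    NUMEROUS = "numerous"
    ENLARGED_BREAKING_WALLS = "enlarged_breaking_walls"
    NEARLY_ABSENT = "nearly_absent"
    ABSENT_AMORPHOUS = "absent_amorphous"


class GranulosaShape(str, enum.Enum):
    COLUMNAR_OR_CUBIC = "columnar_or_cubic"
    SPHERICAL_SPREAD = "spherical_spread"
    WALLS_BROKEN = "walls_broken"
    WALLS_ABSENT = "walls_absent"
    INDISTINCT = "indistinct"


class Nuclei(str, enum.Enum):
    VISIBLE_NORMAL = "visible_normal"
    ONSET_PYCNOSIS = "onset_pycnosis"
    ALL_PYCNOTIC = "all_pycnotic"
    PYCNOTIC_OR_ABSENT = "pycnotic_or_absent"
    NONE_DISTINCT = "none_distinct"


class Lumen(str, enum.Enum):
    IRREGULAR_PRESENT = "irregular_present"
    PRESENT = "present"
    SHRINKING_OR_ABSENT = "shrinking_or_absent"
    ABSENT = "absent"


class OverallShape(str, enum.Enum):
    FOLDED_CORDON = "folded_cordon"
    WRINKLED_FOLDED = "wrinkled_folded"
    FLAT_FEW_FOLDS = "flat_few_folds"
    COMPACT_FLAT = "compact_flat"
    TRIANGULAR_SHRUNKEN = "triangular_shrunken"
    TRIANGULAR_ELONGATED_AMORPHOUS = "triangular_elongated_amorphous"


class Theca(str, enum.Enum):
    DISTINCT_LAYER = "distinct_layer"
    THIN_ADHERING = "thin_adhering"
    VISIBLE_CELLS_INDISTINCT = "visible_cells_indistinct"
    INCORPORATED_IN_STROMA = "incorporated_in_stroma"
    NO_DIFFERENTIATION = "no_differentiation"


class OocyteStage(str, enum.Enum):
    """Most-advanced oocyte developmental class in the ovary section."""

    PE = "PE"      # perinucleolar
    CA = "CA"      # cortical alveoli
    VIT1 = "VIT1"  # partially vitellogenic
    VIT2 = "VIT2"  # fully vitellogenic
    NM = "NM"      # nucleus migration
    HYD = "HYD"    # hydrated


FEATURE_FIELDS = ("vacuoles", "granulosa_cell_shape", "nuclei", "lumen",
                  "overall_shape", "theca")

_FIELD_ENUMS = {
    "vacuoles": Vacuoles,
    "granulosa_cell_shape": GranulosaShape,
    "nuclei": Nuclei,
    "lumen": Lumen,
    "overall_shape": OverallShape,
    "theca": Theca,
}


@dataclass(frozen=True)
class HistoFeatures:
    """One POF's histomorphological annotation, one categorical value per trait."""

    vacuoles: Vacuoles
    granulosa_cell_shape: GranulosaShape
    nuclei: Nuclei
    lumen: Lumen
    overall_shape: OverallShape
    theca: Theca

    @classmethod
    def from_tokens(cls, **tokens: str) -> "HistoFeatures":
        """Build from lowercase string tokens (the CSV serialisation)."""
        vals = {}
        for field in FEATURE_FIELDS:
            if field not in tokens:
                raise ValueError(f"missing feature field: {field}")
            vals[field] = _FIELD_ENUMS[field](tokens[field])
        return cls(**vals)

    def to_tokens(self) -> dict:
        return {f: getattr(self, f).value for f in FEATURE_FIELDS}


class UnclassifiableFeaturesError(ValueError):
    """Raised when an annotation vector matches no row of the staging key.

    Carries the names of the conflicting fields so the offending annotation
    can be reviewed; the classifier never falls back to a silent default.
    """

    def __init__(self, message: str, conflicting_fields: tuple):
        super().__init__(message)
        self.conflicting_fields = conflicting_fields


# Canonical feature vector of each stage.  Stage I is the intact post-ovulation
# follicle (two organised cell layers, open irregular lumen, folded cordon);
# stage II adds massive granulosa vacuolation with cells turning spherical;
# stage III shows enlarged vacuoles breaking cell walls, first pycnotic nuclei,
# a flattening outline and a shrinking lumen; stage IV is compact and flat with
# every nucleus pycnotic and no lumen; stage V is a shrunken triangle with
# vacuoles and granulosa walls nearly gone and the theca merging into the
# stroma; stage VI is a small amorphous triangular remnant with no
# distinguishable cellular structure.
CANONICAL_FEATURES: dict = {
    PofStage.I: HistoFeatures(
        Vacuoles.ABSENT, GranulosaShape.COLUMNAR_OR_CUBIC, Nuclei.VISIBLE_NORMAL,
        Lumen.IRREGULAR_PRESENT, OverallShape.FOLDED_CORDON, Theca.DISTINCT_LAYER),
    PofStage.II: HistoFeatures(
        Vacuoles.NUMEROUS, GranulosaShape.SPHERICAL_SPREAD, Nuclei.VISIBLE_NORMAL,
        Lumen.PRESENT, OverallShape.WRINKLED_FOLDED, Theca.DISTINCT_LAYER),
    PofStage.III: HistoFeatures(
        Vacuoles.ENLARGED_BREAKING_WALLS, GranulosaShape.WALLS_BROKEN,
        Nuclei.ONSET_PYCNOSIS, Lumen.SHRINKING_OR_ABSENT,
        OverallShape.FLAT_FEW_FOLDS, Theca.THIN_ADHERING),
    PofStage.IV: HistoFeatures(
        Vacuoles.ENLARGED_BREAKING_WALLS, GranulosaShape.WALLS_BROKEN,
        Nuclei.ALL_PYCNOTIC, Lumen.ABSENT, OverallShape.COMPACT_FLAT,
        Theca.VISIBLE_CELLS_INDISTINCT),
    PofStage.V: HistoFeatures(
        Vacuoles.NEARLY_ABSENT, GranulosaShape.WALLS_ABSENT,
        Nuclei.PYCNOTIC_OR_ABSENT, Lumen.ABSENT, OverallShape.TRIANGULAR_SHRUNKEN,
        Theca.INCORPORATED_IN_STROMA),
    PofStage.VI: HistoFeatures(
        Vacuoles.ABSENT_AMORPHOUS, GranulosaShape.INDISTINCT, Nuclei.NONE_DISTINCT,
        Lumen.ABSENT, OverallShape.TRIANGULAR_ELONGATED_AMORPHOUS,
        Theca.NO_DIFFERENTIATION),
}

# Precedence used when an annotation does not exactly match a key row: the
# vacuolation state and overall shape are the dominant degradation indices,
# nuclear pycnosis breaks remaining ties; the other traits (granulosa detail,
# lumen, theca) only count towards overall agreement.
_PRECEDENCE_FIELDS = ("vacuoles", "overall_shape")
_TIEBREAK_FIELD = "nuclei"


def _distance(a: HistoFeatures, b: HistoFeatures) -> int:
    return sum(getattr(a, f) != getattr(b, f) for f in FEATURE_FIELDS)


def classify_stage(features: HistoFeatures) -> PofStage:
    """Classify an annotated POF into one of the six resorption stages.

    An exact match of a canonical row returns its stage.  A vector differing
    from exactly one canonical row in a single trait is attributed to that
    stage (within-stage variation; the degeneration is a continuum and single
    traits routinely lag or lead).  If several rows are equally close, the
    dominant degradation indices (vacuoles, overall shape) and then nuclear
    state decide; a vector further than one trait from every row, or still
    ambiguous after precedence, raises :class:`UnclassifiableFeaturesError`
    naming the conflicting fields -- never a silent default.
    """
    if not isinstance(features, HistoFeatures):
        raise TypeError("classify_stage expects HistoFeatures")
    dists = {s: _distance(features, canon) for s, canon in CANONICAL_FEATURES.items()}
    dmin = min(dists.values())
    nearest = [s for s in STAGES if dists[s] == dmin]
    if dmin == 0:
        return nearest[0]
    if dmin == 1 and len(nearest) == 1:
        return nearest[0]
    if dmin <= 1:
        # several equally-near rows: apply the documented precedence order
        for fields in (_PRECEDENCE_FIELDS, (_TIEBREAK_FIELD,)):
            exact = [s for s in nearest
                     if all(getattr(features, f) == getattr(CANONICAL_FEATURES[s], f)
                            for f in fields)]
            if len(exact) == 1:
                return exact[0]
            if exact:
                nearest = exact
    conflicting = tuple(
        f for f in FEATURE_FIELDS
        if any(getattr(features, f) != getattr(CANONICAL_FEATURES[s], f) for s in nearest))
    raise UnclassifiableFeaturesError(
        "feature combination matches no stage of the key "
        f"(nearest: {', '.join(s.name for s in nearest)}; "
        f"conflicting fields: {', '.join(conflicting)})",
        conflicting)


def canonical_features(stage: PofStage) -> HistoFeatures:
    """The canonical feature vector written for ``stage`` in the key."""
    return CANONICAL_FEATURES[PofStage(stage)]


def oocyte_consistency_check(stage: PofStage, most_advanced_oocyte: OocyteStage) -> str:
    """Cross-check a POF stage against the ovary's most-advanced oocyte class.

    Fresh POFs (stage I) co-occur with partial/full vitellogenesis; a stage-I
    POF in an ovary already at nucleus migration or hydration is suspicious.
    Conversely, late POFs (V-VI) in an ovary whose most advanced oocytes are
    pre-vitellogenic suggest a staging or phase-scoring slip.  Auxiliary
    signal only: returns ``"warning"`` rather than raising.
    """
    stage = PofStage(stage)
    ooc = OocyteStage(most_advanced_oocyte)
    if stage == PofStage.I and ooc in (OocyteStage.NM, OocyteStage.HYD):
        return "warning"
    if stage >= PofStage.V and ooc in (OocyteStage.PE, OocyteStage.CA):
        return "warning"
    return "consistent"


@dataclass(frozen=True)
class StageSchedule:
    """Stage durations (hours) of the aging key at some reference temperature.

    ``cumulative_breaks[k]`` is the elapsed time at which stage k+1 ends; the
    last break is the total POF persistence.  Stage windows are half-open
    ``[break[k-1], break[k])`` so every elapsed time maps to exactly one stage.
    """

    durations: tuple

    def __post_init__(self):
        d = tuple(float(x) for x in self.durations)
        if len(d) != 6:
            raise ValueError("StageSchedule needs exactly six durations")
        if any(x <= 0 for x in d):
            raise ValueError("all stage durations must be positive")
        object.__setattr__(self, "durations", d)

    @property
    def cumulative_breaks(self) -> np.ndarray:
        return np.cumsum(self.durations)

    @property
    def total_persistence(self) -> float:
        return float(sum(self.durations))

    @property
    def mid_stage_ages(self) -> np.ndarray:
        b = self.cumulative_breaks
        return b - np.asarray(self.durations) / 2.0


def stage_at_elapsed(t: float, schedule: StageSchedule) -> Optional[PofStage]:
    """Stage of a POF ``t`` hours after ovulation, or ``None`` once resorbed."""
    if t < 0:
        raise ValueError(f"elapsed time must be non-negative, got {t}")
    breaks = schedule.cumulative_breaks
    if t >= breaks[-1]:
        return None
    return PofStage(int(np.searchsorted(breaks, t, side="right")) + 1)


def stages_at_elapsed(t: np.ndarray, breaks: np.ndarray) -> np.ndarray:
    """Vectorised form over per-POF cumulative breaks (rows) -- 1..6, 7=resorbed."""
    t = np.asarray(t, float)
    return (t[:, None] >= np.concatenate(
        [np.zeros((breaks.shape[0], 1)), breaks], axis=1)).sum(axis=1)


def read_features_csv(path) -> list:
    """Read one-row-per-POF feature annotations (columns = the six trait names)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in FEATURE_FIELDS if c not in df.columns]
    if missing:
        raise ValueError(f"feature CSV missing columns: {', '.join(missing)}")
    return [HistoFeatures.from_tokens(**{f: row[f] for f in FEATURE_FIELDS})
            for _, row in df.iterrows()]


def write_features_csv(features: Iterable[HistoFeatures], path) -> None:
    pd.DataFrame([f.to_tokens() for f in features],
                 columns=list(FEATURE_FIELDS)).to_csv(path, index=False)
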