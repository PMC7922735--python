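"""CSV schemas, packaged sampling-design fixtures, run manifest and report.

All tabular artifacts are plain CSV (comma, UTF-8, mandatory header), floats
formatted to six significant digits and date-times serialized as ISO-8601
local time, so every writer is byte-stable under fixed inputs.  The analysis
pipeline can be run blind on real data in the same schema: truth columns are
segregated under a ``truth_`` prefix and are optional on read.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .simulate import OvaryRecord, PofObservation, SimulationConfig, StageSchedule
from .staging import FEATURE_FIELDS, HistoFeatures, OocyteStage, PofStage

FLOAT_FORMAT = "%.6g"

# Sampling-design fixtures: the yearly collection summary and the diel
# distribution of catches and POFs from the field study these schemas mirror.
YEARLY_SAMPLING_ROWS = [
    (2008, "August", 152, 11),
    (2009, "August", 446, 29),
    (2012, "June-July", 474, 46),
    (2013, "June", 298, 41),
    (2014, "July", 222, 44),
    (2015, "July", 516, 74),
]
YEARLY_SAMPLING_COLUMNS = ["year", "sampling_period", "n_females", "n_ovaries"]

DIEL_SAMPLING_ROWS = [
    ("00:00-01:59", 4, 37),
    ("02:00-03:59", 4, 34),
    ("04:00-05:59", 33, 369),
    ("06:00-07:59", 8, 47),
    ("08:00-09:59", 50, 471),
    ("10:00-11:59", 25, 158),
    ("12:00-13:59", 32, 208),
    ("14:00-15:59", 38, 262),
    ("16:00-17:59", 27, 197),
    ("18:00-19:59", 9, 47),
    ("20:00-21:59", 8, 54),
    ("22:00-23:59", 8, 54),
]
DIEL_SAMPLING_COLUMNS = ["time", "n_catches", "n_pofs"]


class SchemaError(ValueError):
    pass


class OrphanPofError(ValueError):
    pass


def load_fixture_table(name: str) -> pd.DataFrame:
    """Packaged fixture tables: ``"yearly_sampling"`` (yearly) or ``"diel_sampling"`` (diel)."""
    if name == "yearly_sampling":
        return pd.DataFrame(YEARLY_SAMPLING_ROWS, columns=YEARLY_SAMPLING_COLUMNS)
    if name == "diel_sampling":
        return pd.DataFrame(DIEL_SAMPLING_ROWS, columns=DIEL_SAMPLING_COLUMNS)
    raise KeyError(f"unknown fixture table {name!r}")


def write_fixture_tables(out_dir) -> tuple:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = (out_dir / "yearly_sampling.csv", out_dir / "diel_sampling.csv")
    load_fixture_table("yearly_sampling").to_csv(paths[0], index=False)
    load_fixture_table("diel_sampling").to_csv(paths[1], index=False)
    return paths


OVARY_COLUMNS = ["fish_id", "capture_time", "most_advanced_oocyte",
                 "gonad_section_area"]
POF_BASE_COLUMNS = ["pof_id", "fish_id", "area"]


def records_to_frames(records: Sequence[OvaryRecord]) -> tuple:
    """Split records into the ovary table and the POF table (foreign key fish_id)."""
    orows, prows = [], []
    for rec in records:
        orow = {
            "fish_id": rec.fish_id,
            "capture_time": rec.capture_time.isoformat(),
            "most_advanced_oocyte": rec.most_advanced_oocyte.value,
            "gonad_section_area": rec.gonad_section_area,
        }
        if rec.truth_spawn_times is not None:
            orow["truth_spawn_times"] = ";".join(
                t.isoformat() for t in rec.truth_spawn_times)
        orows.append(orow)
        for p in rec.pofs:
            prow = {"pof_id": p.pof_id, "fish_id": rec.fish_id, "area": p.area}
            if p.stage is not None:
                prow["stage"] = p.stage.name
            if p.features is not None:
                prow.update(p.features.to_tokens())
            if p.truth_age is not None:
                prow["truth_age_h"] = p.truth_age
                prow["truth_cohort_day"] = p.truth_cohort_day
                prow["truth_stage"] = p.truth_stage.name if p.truth_stage else ""
            prows.append(prow)
    ovaries = pd.DataFrame(orows)
    pofs = pd.DataFrame(prows)
    return ovaries, pofs


def write_ovary_tables(records: Sequence[OvaryRecord], ovaries_path,
                       pofs_path) -> None:
    ovaries, pofs = records_to_frames(records)
    ovaries.to_csv(ovaries_path, index=False, float_format=FLOAT_FORMAT)
    pofs.to_csv(pofs_path, index=False, float_format=FLOAT_FORMAT)


def _parse_stage(token) -> Optional[PofStage]:
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return None
    return PofStage[str(token)]


def read_ovary_tables(ovaries_path, pofs_path) -> List[OvaryRecord]:
    """Read and validate the two-table schema into linked records.

    Raises :class:`SchemaError` for missing columns or unparseable values and
    :class:`OrphanPofError` for POF rows referencing an unknown fish.
    """
    ovaries = pd.read_csv(ovaries_path)
    pofs = pd.read_csv(pofs_path)
    missing = [c for c in OVARY_COLUMNS if c not in ovaries.columns]
    if missing:
        raise SchemaError(f"{ovaries_path}: missing columns {missing}")
    missing = [c for c in POF_BASE_COLUMNS if c not in pofs.columns]
    if missing:
        raise SchemaError(f"{pofs_path}: missing columns {missing}")
    has_stage = "stage" in pofs.columns
    has_features = all(c in pofs.columns for c in FEATURE_FIELDS)
    if not (has_stage or has_features) and len(pofs):
        raise SchemaError(
            f"{pofs_path}: needs a 'stage' column or the six feature columns")

    records: Dict[int, OvaryRecord] = {}
    for _, row in ovaries.iterrows():
        try:
            ts = datetime.fromisoformat(str(row["capture_time"]))
        except ValueError as exc:
            raise SchemaError(
                f"fish {row['fish_id']}: unparseable capture_time "
                f"{row['capture_time']!r}") from exc
        gonad = float(row["gonad_section_area"])
        if gonad <= 0:
            raise SchemaError(
                f"fish {row['fish_id']}: gonad_section_area must be positive")
        truth_spawns = None
        if "truth_spawn_times" in ovaries.columns:
            cell = row.get("truth_spawn_times")
            if isinstance(cell, str):
                truth_spawns = tuple(datetime.fromisoformat(t)
                                     for t in cell.split(";")) if cell else ()
            elif pd.isna(cell):
                truth_spawns = ()  # simulated female with no spawning nights
        fid = int(row["fish_id"])
        if fid in records:
            raise SchemaError(f"duplicate fish_id {fid}")
        records[fid] = OvaryRecord(
            fish_id=fid, capture_time=ts,
            most_advanced_oocyte=OocyteStage(str(row["most_advanced_oocyte"])),
            gonad_section_area=gonad, truth_spawn_times=truth_spawns)

    for _, row in pofs.iterrows():
        fid = int(row["fish_id"])
        if fid not in records:
            raise OrphanPofError(
                f"POF {row['pof_id']} references unknown fish_id {fid}")
        stage = _parse_stage(row["stage"]) if has_stage else None
        features = None
        if has_features and all(isinstance(row[c], str) for c in FEATURE_FIELDS):
            features = HistoFeatures.from_tokens(
                **{c: row[c] for c in FEATURE_FIELDS})
        truth_age = truth_day = truth_stage = None
        if "truth_age_h" in pofs.columns and pd.notna(row.get("truth_age_h")):
            truth_age = float(row["truth_age_h"])
            truth_day = int(row["truth_cohort_day"])
            truth_stage = _parse_stage(row.get("truth_stage"))
        records[fid].pofs.append(PofObservation(
            pof_id=str(row["pof_id"]), area=float(row["area"]), stage=stage,
            features=features, truth_age=truth_age, truth_cohort_day=truth_day,
            truth_stage=truth_stage))
    return list(records.values())


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility fingerprint of one pipeline run.

    The hash covers configuration, seed, software version and input digests
    (not the wall-clock timestamp), so identical inputs give identical hashes.
    """

    config_hash: str
    seed: int
    version: str
    input_digests: tuple
    timestamp: str

    @property
    def hash(self) -> str:
        payload = json.dumps({
            "config_hash": self.config_hash, "seed": self.seed,
            "version": self.version, "inputs": list(self.input_digests),
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_json(self) -> str:
        return json.dumps({
            "config_hash": self.config_hash, "seed": self.seed,
            "version": self.version,
            "input_digests": list(self.input_digests),
            "timestamp": self.timestamp, "hash": self.hash,
        }, indent=2, sort_keys=True)


def config_to_json(config: SimulationConfig) -> str:
    d = {k: getattr(config, k) for k in config.__dataclass_fields__}
    d["schedule"] = list(config.schedule.durations)
    for k in ("area_profile", "effort_weights", "duration_sigma", "duration_trunc"):
        d[k] = list(d[k])
    return json.dumps(d, indent=2, sort_keys=True)


def config_from_json(text: str) -> SimulationConfig:
    d = json.loads(text)
    if "schedule" in d:
        d["schedule"] = StageSchedule(tuple(d["schedule"]))
    for k in ("area_profile", "effort_weights", "duration_sigma", "duration_trunc"):
        if k in d:
            d[k] = tuple(d[k])
    unknown = set(d) - set(SimulationConfig.__dataclass_fields__)
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(**d).validate()


def build_manifest(config: SimulationConfig, seed: int,
                   inputs: Optional[Dict[str, Path]] = None,
                   now: Optional[datetime] = None) -> RunManifest:
    cfg_hash = hashlib.sha256(config_to_json(config).encode()).hexdigest()
    digests = []
    for name, path in sorted((inputs or {}).items()):
        digests.append((name, hashlib.sha256(Path(path).read_bytes()).hexdigest()))
    ts = (now or datetime.now()).isoformat(timespec="seconds")
    return RunManifest(config_hash=cfg_hash, seed=int(seed), version=__version__,
                       input_digests=tuple(digests), timestamp=ts)


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "--"
    return FLOAT_FORMAT % x if isinstance(x, float) else str(x)


def render_report(stage_areas: Optional[pd.DataFrame],
                  kw: Optional["object"],
                  interval_summary: Optional[pd.DataFrame],
                  resorption: Optional[pd.DataFrame],
                  stage_ages: Optional[pd.DataFrame],
                  cohorts: Optional[pd.DataFrame],
                  manifest: Optional[RunManifest] = None) -> str:
    """Plain-text analysis report: stage-key morphometry, diel composition,
    resorption rates, the aging key with CIs, and the cohort table.

    Missing sections are listed by name; an analysis of a POF-free collection
    still renders, with explicit "no POFs" placeholders.  Deterministic given
    its inputs; every number also appears in the corresponding output CSV.
    """
    lines = ["POF aging-key analysis report", "=" * 31, ""]
    if manifest is not None:
        lines += [f"run manifest hash: {manifest.hash}", ""]

    lines.append("Per-stage POF areas (um^2)")
    lines.append("-" * 26)
    if stage_areas is None or stage_areas.empty:
        lines.append("no POFs: no area summary")
    else:
        for _, r in stage_areas.iterrows():
            lines.append(f"  {r['stage']:>3}  n={int(r['n']):5d}  "
                         f"mean={_fmt(float(r['mean_area']))}  "
                         f"rel_I={_fmt(r['relative_to_stage_I'])}")
    lines.append("")

    lines.append("Kruskal-Wallis test of equal areas across stages")
    lines.append("-" * 48)
    if kw is None:
        lines.append("no POFs: test not run")
    else:
        lines.append(f"  H({kw.df}, n = {kw.n_total}) = {kw.H:.2f}, p = {kw.p:.3g}")
        lines.append("  pairwise adjusted p-values (upper triangle):")
        lines.append("    " + kw.pairwise.to_string().replace("\n", "\n    "))
    lines.append("")

    lines.append("Standardized occurrence per two-hour interval")
    lines.append("-" * 45)
    if interval_summary is None or interval_summary.empty:
        lines.append("no records: no interval summary")
    else:
        lines.append("  " + interval_summary.to_string(index=False,
                                                       float_format=lambda v: _fmt(float(v))
                                                       ).replace("\n", "\n  "))
    lines.append("")

    lines.append("Resorption rates (relative area per hour)")
    lines.append("-" * 41)
    if resorption is None or resorption.empty:
        lines.append("no POFs: rates inestimable")
    else:
        for _, r in resorption.iterrows():
            if not r.get("estimable", True):
                lines.append(f"  {r['stage']:>3}  inestimable")
            else:
                lines.append(f"  {r['stage']:>3}  rate={_fmt(float(r['rate']))}  "
                             f"CI=[{_fmt(r['ci_low'])}, {_fmt(r['ci_high'])}]")
    lines.append("")

    lines.append("Stage ages relative to the spawning peak (h)")
    lines.append("-" * 44)
    if stage_ages is None or stage_ages.empty:
        lines.append("no POFs: no aging key")
    else:
        for _, r in stage_ages.iterrows():
            lines.append(f"  {r['stage']:>3}  Day {int(r['cohort_day'])}  "
                         f"mean={float(r['mean_age']):.2f}  "
                         f"CI=[{float(r['ci_low']):.2f}, {float(r['ci_high']):.2f}]  "
                         f"persists<={float(r['max_persistence']):.1f}")
    lines.append("")

    lines.append("Spawning-cohort labels")
    lines.append("-" * 22)
    if cohorts is None or cohorts.empty:
        lines.append("no POFs: no cohort labels")
    else:
        counts = cohorts["labels"].value_counts().sort_index()
        for label, n in counts.items():
            lines.append(f"  {label}: {n} females")
    lines.append("")
    return "\n".join(lines)
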