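"""Study file I/O: TAC/blood TSV, metadata CSV, truth ledger, pipeline.

Schemas (all plain text, schema version in a header comment):

* ``tacs.tsv``: subject_id, region, frame_start_min, frame_dur_min,
  activity_kBq_mL
* ``blood.tsv``: subject_id, time_min, whole_plasma_kBq_mL, parent_fraction
* ``metadata.csv``: subject_id, group, age, sex, scan_date_frac, fP,
  injected_dose
* ``truth.json``: injected-effect ledger (optional)

Write -> read round-trips are lossless for all numeric fields (floats are
serialized with 17 significant digits).
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .kinetic import ArterialInput, FrameSchedule, TimeActivityCurve

__all__ = [
    "SCHEMA_VERSION",
    "StudyBundle",
    "StudyValidationError",
    "write_study",
    "read_study",
    "run_pipeline",
]

SCHEMA_VERSION = "hierpet-study-v1"
_FLOAT_FMT = "%.17g"


class StudyValidationError(ValueError):
    """Raised with an itemized list of study-schema violations."""

    def __init__(self, problems: List[str]):
        self.problems = list(problems)
        super().__init__("invalid study bundle:\n- " + "\n- ".join(problems))


@dataclass
class StudyBundle:
    """In-memory study loaded from disk (or ready to be written)."""

    participants: pd.DataFrame
    tacs: dict                   # subject -> region -> TimeActivityCurve
    aifs: dict                   # subject -> ArterialInput
    schedule: FrameSchedule
    truth: Optional[dict] = None

    @property
    def subject_ids(self):
        return list(self.participants["subject_id"])

    @property
    def regions(self):
        first = self.subject_ids[0]
        return list(self.tacs[first].keys())


def _write_table(df: pd.DataFrame, path: Path, sep: str):
    with open(path, "w") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        df.to_csv(fh, sep=sep, index=False, float_format=_FLOAT_FMT)


def _read_table(path: Path, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#",
                       float_precision="round_trip")


def write_study(study, out_dir) -> List[Path]:
    """Write a study (synthetic or bundle) to a directory; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sched = study.schedule
    tac_rows = []
    for s in study.subject_ids:
        for region, tac in study.tacs[s].items():
            for f in range(sched.n_frames):
                tac_rows.append((s, region, sched.start[f], sched.duration[f],
                                 tac.activity[f]))
    tacs = pd.DataFrame(tac_rows, columns=[
        "subject_id", "region", "frame_start_min", "frame_dur_min",
        "activity_kBq_mL"])
    blood_rows = []
    for s in study.subject_ids:
        aif = study.aifs[s]
        wp = aif.wholeplasma_values
        pf = np.divide(aif.cp_parent_values, wp,
                       out=np.ones_like(wp), where=wp > 0)
        # thin the dense generator grid to a realistic sampling scheme
        keep = np.unique(np.searchsorted(
            aif.times, np.concatenate([np.arange(0, 3, 0.1),
                                       np.arange(3, 20, 1.0),
                                       np.arange(20, aif.times[-1] + 1, 5.0)])))
        keep = keep[keep < aif.times.size]
        for i in keep:
            blood_rows.append((s, aif.times[i], wp[i], np.clip(pf[i], 0, 1)))
    blood = pd.DataFrame(blood_rows, columns=[
        "subject_id", "time_min", "whole_plasma_kBq_mL", "parent_fraction"])
    paths = []
    _write_table(tacs, out / "tacs.tsv", "\t"); paths.append(out / "tacs.tsv")
    _write_table(blood, out / "blood.tsv", "\t"); paths.append(out / "blood.tsv")
    _write_table(study.participants, out / "metadata.csv", ",")
    paths.append(out / "metadata.csv")
    truth = getattr(study, "truth", None)
    if truth is not None:
        with open(out / "truth.json", "w") as fh:
            json.dump({"schema": SCHEMA_VERSION, **truth}, fh, indent=1)
        paths.append(out / "truth.json")
    return paths


def read_study(in_dir) -> StudyBundle:
    """Read and validate a study directory (see module docstring schemas)."""
    d = Path(in_dir)
    problems = []
    for fname in ("tacs.tsv", "blood.tsv", "metadata.csv"):
        if not (d / fname).exists():
            problems.append(f"missing file {fname}")
    if problems:
        raise StudyValidationError(problems)
    tacs_df = _read_table(d / "tacs.tsv", "\t")
    blood_df = _read_table(d / "blood.tsv", "\t")
    meta = _read_table(d / "metadata.csv", ",")

    meta_subjects = set(meta["subject_id"])
    tac_subjects = set(tacs_df["subject_id"])
    for s in sorted(tac_subjects - meta_subjects):
        problems.append(f"metadata missing subject {s}")
    for s in sorted(meta_subjects - tac_subjects):
        problems.append(f"no TACs for subject {s}")
    for s, grp in blood_df.groupby("subject_id"):
        t = grp["time_min"].to_numpy()
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            problems.append(
                f"blood times for subject {s} not strictly increasing "
                f"at row {int(bad[0]) + 1}")
    schedule = None
    tacs = {}
    for (s, region), grp in tacs_df.groupby(["subject_id", "region"],
                                            sort=False):
        grp = grp.sort_values("frame_start_min")
        try:
            sch = FrameSchedule(grp["frame_start_min"].to_numpy(),
                                grp["frame_dur_min"].to_numpy())
        except ValueError as e:
            problems.append(f"bad schedule for {s}/{region}: {e}")
            continue
        if schedule is None:
            schedule = sch
        elif sch.n_frames != schedule.n_frames or not np.allclose(
                sch.start, schedule.start, atol=1e-9):
            problems.append(f"inconsistent schedule for {s}/{region}")
        tacs.setdefault(s, {})[region] = TimeActivityCurve(
            s, region, sch, grp["activity_kBq_mL"].to_numpy())
    if problems:
        raise StudyValidationError(problems)

    fp_by_subject = meta.set_index("subject_id")["fP"].to_dict() \
        if "fP" in meta.columns else {}
    aifs = {}
    for s, grp in blood_df.groupby("subject_id"):
        grp = grp.sort_values("time_min")
        from .kinetic import BloodData
        bd = BloodData(grp["time_min"].to_numpy(),
                       grp["whole_plasma_kBq_mL"].to_numpy(),
                       grp["parent_fraction"].to_numpy())
        aifs[s] = ArterialInput.from_blood_data(
            bd, fP=float(fp_by_subject.get(s, 1.0)))
    truth = None
    if (d / "truth.json").exists():
        truth = json.loads((d / "truth.json").read_text())
    return StudyBundle(participants=meta, tacs=tacs, aifs=aifs,
                       schedule=schedule, truth=truth)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_pipeline(config: dict, out_dir) -> Path:
    """Simulate -> NLS -> hierarchical fit -> contrasts, with logged seed.

    ``config`` keys (all optional): ``seed``, ``cohort`` (CohortConfig
    fields), ``model`` (HierarchicalModelSpec fields), ``priors``
    (PriorSpec fields), ``settings`` (InferenceSettings fields).
    Artifacts: study files, ``nls_params.csv``, ``contrasts.csv``,
    ``draws.csv``, ``summary.json``, ``run_log.json``.
    """
    from . import __version__
    from .cohort import CohortConfig, simulate_cohort
    from .contrasts import contrasts_to_frame, group_contrasts
    from .inference import InferenceSettings, PriorSpec
    from .nls import fit_cohort_nls
    from .simba import HierarchicalModelSpec, build_simba_model, fit_simba

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    log = {"schema": SCHEMA_VERSION, "seed": seed,
           "config_hash": _config_hash(config),
           "versions": {"hierpet": __version__,
                        "python": sys.version.split()[0],
                        "numpy": np.__version__}}
    try:
        cohort_kwargs = dict(config.get("cohort", {}))
        cfg = CohortConfig(**cohort_kwargs)
        study = simulate_cohort(cfg, seed=seed)
        write_study(study, out / "study")
        model_kwargs = dict(config.get("model", {}))
        if "outcome" in config:  # shorthand used by the CLI
            model_kwargs.setdefault("outcome", config["outcome"])
        spec = HierarchicalModelSpec(**model_kwargs)
        nls = fit_cohort_nls(study, "2tcm", spec.outcome, seed=seed)
        _write_table(nls, out / "nls_params.csv", ",")
        priors = PriorSpec(**dict(config.get("priors", {})))
        model = build_simba_model(study, spec, priors)
        settings = InferenceSettings(seed=seed,
                                     **dict(config.get("settings", {})))
        fit = fit_simba(model, settings)
        contrasts = group_contrasts(fit)
        _write_table(contrasts_to_frame(contrasts),
                     out / "contrasts.csv", ",")
        fit.to_files(out)
        log["status"] = "ok"
    except Exception as e:  # preserve partial outputs, then fail
        log["status"] = "error"
        log["error"] = repr(e)
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=1)
        raise
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1)
    return out
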