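"""End-to-end analysis runs: sessions in, report tables out.

``run_analysis`` drives the full chain — (optionally) synthesize sessions,
segment trials, classify units, build waiting-modulation curves and
logistic fits per group, detect movement onsets — and writes plain-text
artifacts (trials.csv, units.csv, curves.csv, fits.json, onsets.csv) that
round-trip through pandas. Given a seed and fixed inputs the outputs are
byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import accel as accel_mod
from .classify import ClassificationConfig, classify_units
from .population import build_population, default_counts
from .session_io import Session, SessionMeta, read_session
from .synth import SynthConfig, WaitMixture, simulate_session
from .trials import TrialTable, segment_trials
from .waitmod import (
    LogisticFit,
    WaitingBinScheme,
    anticipatory_curve,
    compare_p2,
    fit_logistic,
    profile_ci_p2,
)

logger = logging.getLogger(__name__)


def linear_regression(x, y) -> tuple[float, float, float, float]:
    """OLS fit ``y = slope*x + intercept``; returns (slope, intercept, r2, p).

    ``p`` tests the slope against zero. Raises on constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("x is constant")
    res = sstats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (inputs XOR synthesis)."""

    input_dirs: tuple[str, ...] = ()
    synth: dict | None = None
    scheme: str = "paper10"
    out_dir: str = "striatim_out"
    seed: int = 0
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)

    def __post_init__(self) -> None:
        if bool(self.input_dirs) == bool(self.synth):
            raise ValueError("exactly one of input_dirs / synth must be given")


def synth_config_from_dict(d: dict, n_units: int | None = None) -> SynthConfig:
    """Build a SynthConfig from a plain dict (as parsed from YAML)."""
    meta_d = dict(d.get("meta", {}))
    meta_d.setdefault("subject_id", "synth")
    meta = SessionMeta(**meta_d)
    wait = WaitMixture(**d.get("wait_dist", {}))
    cfg = SynthConfig(
        meta=meta,
        n_trials=int(d.get("n_trials", 300)),
        wait_dist=wait,
        p_complete_seq8=float(d.get("p_complete_seq8", 0.75)),
    )
    n_units = n_units if n_units is not None else int(d.get("n_units", 20))
    wm = d.get("wait_modulation")
    specs = build_population(
        default_counts(n_units), cfg,
        wait_modulation=tuple(wm) if wm else None,
    )
    return dataclasses.replace(cfg, unit_specs=specs)


def _scheme(name: str) -> WaitingBinScheme:
    if name in ("paper10", "fixed_paper_10"):
        return WaitingBinScheme.paper10()
    if name in ("paper11", "fixed_paper_11"):
        return WaitingBinScheme.paper11()
    raise ValueError(f"unknown scheme {name!r}")


def _fit_to_dict(fit: LogisticFit) -> dict:
    return {
        "p1": round(fit.p1, 9),
        "p2": round(fit.p2, 9),
        "p3": round(fit.p3, 9),
        "sse": round(fit.sse, 12),
        "r2": round(fit.r2, 9),
        "n": fit.n,
        "ci_p2": [round(v, 9) for v in fit.ci_p2] if fit.ci_p2 else None,
    }


def run_analysis(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns a summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sessions: list[Session] = []
    if config.synth is not None:
        rng = np.random.default_rng(config.seed)
        n_sessions = int(config.synth.get("n_sessions", 1))
        for _ in range(n_sessions):
            cfg = synth_config_from_dict(config.synth)
            session, _ = simulate_session(cfg, rng)
            sessions.append(session)
    else:
        sessions = [read_session(d) for d in config.input_dirs]

    tables: list[TrialTable] = [segment_trials(s) for s in sessions]

    trial_frames = []
    for i, table in enumerate(tables):
        df = table.to_frame()
        df.insert(0, "session", i)
        trial_frames.append(df)
    trials_df = pd.concat(trial_frames, ignore_index=True)
    trials_df.to_csv(out / "trials.csv", index=False, float_format="%.6f")

    unit_rows = []
    classes_per_session = []
    for i, (session, table) in enumerate(zip(sessions, tables)):
        classes = classify_units(session, table, config.classification)
        classes_per_session.append(classes)
        for uid, uc in sorted(classes.items()):
            unit_rows.append(
                {
                    "session": i,
                    "unit_id": uid,
                    "boundary": uc.boundary,
                    "inside_port": uc.inside_port,
                    "tonic_wait": uc.tonic_wait,
                    "cue": uc.cue,
                    "lick": uc.lick,
                    "outcome": uc.outcome,
                    "di": uc.di,
                    "z_entry": uc.z_entry,
                    "z_exit": uc.z_exit,
                }
            )
    units_df = pd.DataFrame(unit_rows)
    units_df.to_csv(out / "units.csv", index=False, float_format="%.6f")

    # waiting-time modulation per age group
    scheme = _scheme(config.scheme)
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(sessions):
        groups.setdefault(s.meta.age_group, []).append(i)

    curve_rows = []
    fits: dict[str, dict] = {}
    group_fits: dict[str, LogisticFit] = {}
    curves_xy: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for group, idxs in sorted(groups.items()):
        st = [(sessions[i], tables[i]) for i in idxs]
        uids = [
            [
                uid
                for uid, uc in classes_per_session[i].items()
                if uc.boundary in ("entry_only", "both")
            ]
            for i in idxs
        ]
        if not any(uids):
            logger.warning("group %s: no entry-responsive units; skipping curve", group)
            continue
        curve = anticipatory_curve(st, uids, scheme, config.classification, group=group)
        for x, y, n in zip(curve.x, curve.y, curve.n_trials):
            curve_rows.append({"group": group, "x_s": x, "y_z": y, "n_trials": int(n)})
        if curve.x.size >= 4:
            try:
                fit = profile_ci_p2(fit_logistic(curve.x, curve.y), curve.x, curve.y)
                group_fits[group] = fit
                curves_xy[group] = (curve.x, curve.y)
                fits[group] = _fit_to_dict(fit)
            except Exception as exc:
                logger.warning("group %s: logistic fit failed: %s", group, exc)
    pd.DataFrame(curve_rows).to_csv(out / "curves.csv", index=False, float_format="%.6f")

    if len(group_fits) == 2:
        (ga, fa), (gb, fb) = sorted(group_fits.items())
        xa, ya = curves_xy[ga]
        xb, yb = curves_xy[gb]
        fstat, p = compare_p2(xa, ya, xb, yb)
        fits["p2_comparison"] = {
            "groups": [ga, gb],
            "F": round(fstat, 6),
            "p": round(p, 9),
            "df_denominator": int(xa.size + xb.size - 6),
        }
    (out / "fits.json").write_text(json.dumps(fits, indent=2, sort_keys=True) + "\n", encoding="utf-8")

    onset_rows = []
    for i, (session, table) in enumerate(zip(sessions, tables)):
        if session.accel is None:
            continue
        series = accel_mod.preprocess(session.accel)
        for t in table:
            if t.first_trial:
                continue
            onset = accel_mod.movement_onset_before_entry(series, t.entry_s, t.waiting_s)
            onset_rows.append(
                {
                    "session": i,
                    "entry_s": t.entry_s,
                    "waiting_s": t.waiting_s,
                    "onset_s": math.nan if onset is None else onset,
                    "lead_s": math.nan if onset is None else t.entry_s - onset,
                }
            )
    pd.DataFrame(onset_rows, columns=["session", "entry_s", "waiting_s", "onset_s", "lead_s"]).to_csv(
        out / "onsets.csv", index=False, float_format="%.6f"
    )

    return {
        "n_sessions": len(sessions),
        "n_trials": int(len(trials_df)),
        "n_units": int(len(units_df)),
        "fits": fits,
    }
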