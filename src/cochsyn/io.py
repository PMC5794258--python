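"""Plain-text readers and writers tying the analysis stages together.

Spike trains, PSTHs and model trajectories travel as CSV; parameter sets,
fit results and vesicle scenes as JSON.  All writers round-trip losslessly
through their readers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .model_fitting import FitResult
from .morphometry import AZGeometry, VesicleRecord
from .release_model import KineticParams, RefractoryParams, Trajectory
from .spike_stats import PSTHData, SpikeTrainSet

PathLike = Union[str, Path]

TRAJECTORY_COLUMNS = ("t_s", "n_filled", "f_avail", "f_relref", "f_absref",
                      "epsc_rate_hz", "ap_rate_hz")


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

def write_spike_trains(path: PathLike, spikes: SpikeTrainSet,
                       unit_id: str = "unit0") -> None:
    rows = []
    for trial, times in enumerate(spikes.trials):
        for t in times:
            rows.append((unit_id, trial, float(t)))
    df = pd.DataFrame(rows, columns=["unit_id", "trial", "spike_time_s"])
    df.to_csv(path, index=False)


def read_spike_trains(path: PathLike, duration: float,
                      unit_id: Optional[str] = None,
                      n_trials: Optional[int] = None) -> SpikeTrainSet:
    """Read one unit's trials; ``n_trials`` pads empty trailing trials."""
    df = pd.read_csv(path)
    if unit_id is not None:
        df = df[df["unit_id"] == unit_id]
    if df.empty and n_trials is None:
        raise ValueError("no spikes found and n_trials not given")
    nt = int(df["trial"].max()) + 1 if not df.empty else 0
    nt = max(nt, n_trials or 0)
    trials: List[np.ndarray] = [np.empty(0)] * nt
    for trial, grp in df.groupby("trial"):
        trials[int(trial)] = grp["spike_time_s"].to_numpy()
    return SpikeTrainSet(trials=trials, duration=duration)


# ---------------------------------------------------------------------------
# PSTHs and trajectories
# ---------------------------------------------------------------------------

def write_psth(path: PathLike, psth: PSTHData) -> None:
    df = pd.DataFrame({"t_ms": psth.centers * 1e3, "rate_hz": psth.rate})
    df.attrs["n_trials"] = psth.n_trials
    df.to_csv(path, index=False)


def read_psth(path: PathLike, n_trials: int = 1,
              onset: Optional[float] = None) -> PSTHData:
    df = pd.read_csv(path)
    centers = df["t_ms"].to_numpy() * 1e-3
    bw = float(centers[1] - centers[0])
    edges = np.concatenate([centers - bw / 2, [centers[-1] + bw / 2]])
    return PSTHData(bin_width=bw, edges=edges,
                    rate=df["rate_hz"].to_numpy(),
                    n_trials=n_trials, onset=onset)


def write_trajectory(path: PathLike, traj: Trajectory) -> None:
    df = pd.DataFrame(dict(zip(TRAJECTORY_COLUMNS,
                               (traj.t, traj.n_filled, traj.f_avail,
                                traj.f_relref, traj.f_absref,
                                traj.epsc_rate, traj.ap_rate))))
    df.to_csv(path, index=False)


def read_trajectory(path: PathLike) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(t=df["t_s"].to_numpy(),
                      n_filled=df["n_filled"].to_numpy(),
                      f_avail=df["f_avail"].to_numpy(),
                      f_relref=df["f_relref"].to_numpy(),
                      f_absref=df["f_absref"].to_numpy(),
                      epsc_rate=df["epsc_rate_hz"].to_numpy(),
                      ap_rate=df["ap_rate_hz"].to_numpy())


# ---------------------------------------------------------------------------
# parameters and fit results
# ---------------------------------------------------------------------------

def write_params(path: PathLike, params: KineticParams,
                 refrac: Optional[RefractoryParams] = None,
                 note: str = "") -> None:
    data = asdict(params)
    if refrac is not None:
        data.update(asdict(refrac))
    data["note"] = note
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))


def read_params(path: PathLike,
                ) -> Tuple[KineticParams, Optional[RefractoryParams], str]:
    data = json.loads(Path(path).read_text())
    note = data.pop("note", "")
    refrac = None
    if "t_abs" in data:
        refrac = RefractoryParams(t_abs=data.pop("t_abs"),
                                  tau_rel=data.pop("tau_rel"))
    return KineticParams(**data), refrac, note


def fit_result_summary(res: FitResult) -> Dict[str, float]:
    """Parameter summary shaped like the model-parameter table."""
    p = res.params
    return {"N_slots": p.n_slots,
            "k_refill_stim": p.k_refill_stim,
            "k_refill_spont": p.k_refill_spont,
            "k_fusion_stim": p.k_fus_stim,
            "k_fusion_spont": p.k_fus_spont,
            "f": p.f,
            "t_abs_s": res.refrac.t_abs,
            "tau_rel_s": res.refrac.tau_rel,
            "loss": res.loss}


def write_fit_result(path: PathLike, res: FitResult) -> None:
    data = {"summary": fit_result_summary(res),
            "success": res.success,
            "n_evals": res.n_evals,
            "message": res.message,
            "residual_rms": {k: float(np.sqrt(np.mean(v ** 2)))
                             for k, v in res.residuals.items()}}
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# vesicle scenes
# ---------------------------------------------------------------------------

def write_scene(path: PathLike, vesicles: List[VesicleRecord],
                geometry: AZGeometry) -> None:
    data = {
        "membrane": geometry.membrane.tolist(),
        "pd_segments": [p.tolist() for p in geometry.pd_segments],
        "ribbon": None if geometry.ribbon is None
        else geometry.ribbon.tolist(),
        "psd": None if geometry.psd is None else geometry.psd.tolist(),
        "vesicles": [{"center": list(v.center),
                      "diameter_h": v.diameter_h,
                      "diameter_v": v.diameter_v,
                      "tethers": v.tethers} for v in vesicles],
    }
    Path(path).write_text(json.dumps(data, indent=2))


def read_scene(path: PathLike) -> Tuple[List[VesicleRecord], AZGeometry]:
    data = json.loads(Path(path).read_text())
    geometry = AZGeometry(
        membrane=np.array(data["membrane"]),
        pd_segments=[np.array(p) for p in data["pd_segments"]],
        ribbon=None if data.get("ribbon") is None
        else np.array(data["ribbon"]),
        psd=None if data.get("psd") is None else np.array(data["psd"]))
    vesicles = [VesicleRecord(center=tuple(v["center"]),
                              diameter_h=v["diameter_h"],
                              diameter_v=v["diameter_v"],
                              tethers=v.get("tethers"))
                for v in data["vesicles"]]
    return vesicles, geometry


def config_hash(config: dict) -> str:
    """Deterministic short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
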