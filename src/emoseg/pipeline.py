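"""End-to-end study analysis: screen, score, consensus, vocabulary, reliability.

``run_pipeline`` executes the fixed stage order

    load -> completeness filter -> segmentation metrics (MLU, SA)
         -> consensus events (magnitude, bootstrap threshold, windows, CEA)
         -> vocabulary metrics (NUL, AoA, familiarity, SAS)
         -> MAD outlier screening -> reliability (omega) / validity reports

and returns a result bundle with a manifest (config hash, derived seeds,
row counts per stage). Identical config and inputs give identical outputs:
the single global seed fans out to one deterministic sub-seed per stimulus
bootstrap, so any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus as cons
from . import io as eio
from . import psychometrics as psy
from . import segmentation as seg
from . import vocabulary as voc

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending entity."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative configuration of a full analysis run.

    The defaults reproduce the canonical analysis parameters: 0.8-s Gaussian
    kernel, 1-s SA bins, 500-iteration bootstrap at critical probability
    0.95, 800-ms merge window, 0.1-s magnitude grid.
    """

    records_path: str | None = None
    stimuli_path: str | None = None
    block: str = "affective"
    kernel_sd: float = cons.KERNEL_SD
    bin_width: float = 1.0
    n_iterations: int = 500
    critical_probability: float = 0.95
    bootstrap_scheme: str = "pooled"
    merge_window: float = cons.MERGE_WINDOW
    grid_dt: float = cons.GRID_DT
    pelt_penalty: float | None = None
    custom_stopwords: tuple[str, ...] = ()
    norms_path: str | None = None
    embedding_path: str | None = None
    questionnaire_path: str | None = None
    compute_sas: bool = False
    sa_leave_one_out: bool = False
    sas_leave_one_out: bool = False
    mad_screening: bool = True
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "custom_stopwords" in raw:
            raw["custom_stopwords"] = tuple(raw["custom_stopwords"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def derive_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2**31) from the global seed."""
    return int((base_seed * 2654435761 + zlib.crc32(stage.encode())) % (2**31))


@dataclass
class PipelineResult:
    metrics: pd.DataFrame              # per-participant wide summary (screened)
    metrics_raw: pd.DataFrame          # before MAD screening
    segmentation_long: pd.DataFrame    # per participant x stimulus MLU/SA
    events: pd.DataFrame               # consensus events across stimuli
    events_by_stimulus: dict
    curves: dict                       # stimulus_id -> MagnitudeCurve
    thresholds: dict                   # stimulus_id -> bootstrap threshold
    reliability: pd.DataFrame
    validity: pd.DataFrame | None
    removed_participants: list[str]
    manifest: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        self.metrics_raw.to_csv(out / "metrics_raw.csv", index=False)
        self.segmentation_long.to_csv(out / "segmentation_long.csv", index=False)
        self.events.to_csv(out / "events.csv", index=False)
        self.reliability.to_csv(out / "reliability.csv", index=False)
        if self.validity is not None:
            self.validity.to_csv(out / "validity.csv", index=False)
        rows = []
        for sid, curve in self.curves.items():
            for t, v in zip(curve.grid, curve.values):
                rows.append({"stimulus_id": sid, "time_s": t, "magnitude": v})
        pd.DataFrame(rows).to_csv(out / "magnitude_curves.csv", index=False)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def consensus_for_dataset(
    ds: eio.Dataset, cfg: RunConfig
) -> tuple[dict, dict, dict]:
    """Consensus events, magnitude curves, and thresholds per stimulus."""
    events_by_stimulus, curves, thresholds = {}, {}, {}
    for stim in ds.stimuli_in_block(cfg.block):
        by_p = ds.pauses_by_participant(stim.stimulus_id)
        if not by_p:
            logger.warning("no pauses on stimulus %s", stim.stimulus_id)
            events_by_stimulus[stim.stimulus_id] = []
            continue
        spec = cons.BootstrapSpec(
            n_iterations=cfg.n_iterations,
            critical_probability=cfg.critical_probability,
            seed=derive_seed(cfg.seed, f"bootstrap:{stim.stimulus_id}"),
            scheme=cfg.bootstrap_scheme,
        )
        events, curve, thr = cons.consensus_events_for_stimulus(
            by_p,
            stim.duration,
            spec,
            stimulus_id=stim.stimulus_id,
            kernel_sd=cfg.kernel_sd,
            dt=cfg.grid_dt,
            merge_window=cfg.merge_window,
            penalty=cfg.pelt_penalty,
        )
        events_by_stimulus[stim.stimulus_id] = events
        curves[stim.stimulus_id] = curve
        thresholds[stim.stimulus_id] = thr
    return events_by_stimulus, curves, thresholds


def reliability_report(
    ds: eio.Dataset,
    seg_long: pd.DataFrame,
    events_by_stimulus: dict,
    nul_by_stim: pd.DataFrame | None,
    block: str,
) -> pd.DataFrame:
    """Omega-total per metric across the block's trials."""
    rows = []
    for metric in ("mlu", "sa"):
        wide = seg_long.pivot(index="participant_id", columns="stimulus_id", values=metric)
        rows.append({"metric": metric, "block": block, "omega_total": _safe_omega(wide)})
    cea_trials = cons.cea_trial_matrix(ds, events_by_stimulus, block)
    rows.append({"metric": "cea", "block": block, "omega_total": _safe_omega(cea_trials)})
    if nul_by_stim is not None:
        rows.append({"metric": "nul", "block": block, "omega_total": _safe_omega(nul_by_stim)})
    return pd.DataFrame(rows)


def _safe_omega(wide: pd.DataFrame) -> float:
    try:
        return psy.omega_total(wide.dropna(axis=1, how="all"))
    except (ValueError, np.linalg.LinAlgError) as err:
        logger.warning("omega_total failed: %s", err)
        return float("nan")


def nul_trial_matrix(ds: eio.Dataset, block: str, custom_stopwords: frozenset[str]) -> pd.DataFrame:
    per_stim = voc.labels_by_stimulus(ds, block, custom_stopwords=custom_stopwords)
    stim_ids = [s.stimulus_id for s in ds.stimuli_in_block(block)]
    return pd.DataFrame(
        {
            sid: {
                p: float(len(per_stim.get((p, sid), voc.CleanLabelSet()).unique))
                for p in ds.participants
            }
            for sid in stim_ids
        }
    )[stim_ids]


def run_pipeline(
    cfg: RunConfig,
    dataset: eio.Dataset | None = None,
    norms: voc.NormsTable | None = None,
    embedding: voc.EmbeddingSpace | None = None,
    questionnaire: pd.DataFrame | None = None,
) -> PipelineResult:
    """Execute the full analysis; inputs may be paths (in ``cfg``) or objects."""
    # --- load ---------------------------------------------------------
    if dataset is None:
        if not cfg.records_path or not cfg.stimuli_path:
            raise PipelineError("load", "records_path and stimuli_path are required")
        try:
            stimuli = eio.read_stimulus_table(cfg.stimuli_path)
            dataset = eio.read_segmentation_table(cfg.records_path, stimuli)
        except (OSError, ValueError) as err:
            raise PipelineError("load", str(err)) from err
    if norms is None and cfg.norms_path:
        norms = voc.NormsTable.read_csv(cfg.norms_path)
    if embedding is None and cfg.embedding_path:
        embedding = voc.EmbeddingSpace.read_csv(cfg.embedding_path)
    if cfg.compute_sas and embedding is None:
        raise PipelineError("vocabulary", "SAS requested but no embedding table provided")
    if questionnaire is None and cfg.questionnaire_path:
        questionnaire = pd.read_csv(cfg.questionnaire_path, index_col="participant_id")

    n_records_in = len(dataset.records)
    # --- completeness screen -----------------------------------------
    ds, removed = eio.filter_complete_participants(dataset, cfg.block)
    if not ds.records:
        raise PipelineError("screen", "no participant segmented every stimulus of the block")

    # --- segmentation metrics ----------------------------------------
    seg_long = seg.segmentation_metrics_table(
        ds, cfg.block, cfg.bin_width, self_included=not cfg.sa_leave_one_out
    )
    metrics = seg.participant_means(seg_long, ["mlu", "sa"]).set_index("participant_id")

    # --- consensus events --------------------------------------------
    events_by_stimulus, curves, thresholds = consensus_for_dataset(ds, cfg)
    metrics["cea"] = pd.Series(cons.compute_cea(ds, events_by_stimulus, cfg.block))

    # --- vocabulary ----------------------------------------------------
    custom_sw = frozenset(cfg.custom_stopwords)
    metrics["nul"] = pd.Series(voc.compute_nul(ds, cfg.block, custom_stopwords=custom_sw))
    nul_by_stim = nul_trial_matrix(ds, cfg.block, custom_sw)
    if norms is not None:
        lex = voc.lexical_complexity_table(ds, norms, cfg.block, custom_stopwords=custom_sw)
        metrics = metrics.join(lex.set_index("participant_id")[["aoa", "familiarity", "coverage"]])
    if cfg.compute_sas:
        sas = voc.compute_sas(
            ds,
            events_by_stimulus,
            embedding,
            cfg.block,
            leave_one_out=cfg.sas_leave_one_out,
            custom_stopwords=custom_sw,
        )
        metrics["sas"] = pd.Series(sas)
    metrics_raw = metrics.reset_index()

    # --- outlier screening --------------------------------------------
    if cfg.mad_screening:
        screen_cols = [c for c in metrics.columns if c != "coverage"]
        screened, _mask = eio.apply_mad_screening(metrics, columns=screen_cols)
    else:
        screened = metrics

    # --- reliability & validity ---------------------------------------
    reliability = reliability_report(ds, seg_long, events_by_stimulus, nul_by_stim, cfg.block)
    validity = None
    if questionnaire is not None:
        vcols = [c for c in screened.columns if c != "coverage"]
        validity = psy.correlation_report(screened[vcols], questionnaire)

    events_df = pd.DataFrame(
        [
            {
                "stimulus_id": sid,
                "timestamp_s": e.timestamp,
                "window_start_s": e.window_start,
                "window_end_s": e.window_end,
                "peak_magnitude": e.peak_magnitude,
            }
            for sid, evs in events_by_stimulus.items()
            for e in evs
        ]
    )

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "derived_seeds": {
            sid: derive_seed(cfg.seed, f"bootstrap:{sid}") for sid in events_by_stimulus
        },
        "n_records_in": n_records_in,
        "n_records_analyzed": len(ds.records),
        "n_participants": len(ds.participants),
        "n_removed_incomplete": len(removed),
        "n_consensus_events": int(sum(len(v) for v in events_by_stimulus.values())),
        "thresholds": thresholds,
    }
    result = PipelineResult(
        metrics=screened.reset_index(),
        metrics_raw=metrics_raw,
        segmentation_long=seg_long,
        events=events_df,
        events_by_stimulus=events_by_stimulus,
        curves=curves,
        thresholds=thresholds,
        reliability=reliability,
        validity=validity,
        removed_participants=removed,
        manifest=manifest,
    )
    if cfg.output_dir:
        result.write(cfg.output_dir)
    return result
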