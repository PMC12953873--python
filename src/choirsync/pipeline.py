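"""End-to-end orchestration: simulate -> coupling -> accuracy -> statistics.

``run_pipeline`` executes one full study: generate (or load) the raw
material, compute the coupling indices per trial, build the piece- and
recording-unit-level accuracy tables, merge coupling into the unit table,
fit the condition contrasts and the six coupling -> accuracy prediction
models (3 indices x 2 accuracy measures), and write every table plus a run
manifest.  Row counts are validated against the design before writing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accuracy as acc
from . import coupling as cpl
from . import simulate as sim
from . import stats as st
from .design import ObservationLevel, StudyDesign, default_design, observation_count, tiny_design

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "make_fixtures", "coupling_tables"]

log = logging.getLogger("choirsync")


@dataclass
class PipelineConfig:
    design: StudyDesign = field(default_factory=default_design)
    resp_cfg: sim.RespirationSimConfig | None = None
    perf_cfg: sim.PerformanceSimConfig | None = None
    wavelet: cpl.WaveletSpec = field(default_factory=cpl.WaveletSpec)
    thresholds: acc.AccuracyThresholds = field(default_factory=acc.AccuracyThresholds)
    clip_duration: float = 360.0
    condition_effects: dict | None = None
    contrast_conditions: tuple[str, str] = ("touch", "no_touch")
    indices: tuple[str, ...] = ("ACI", "PSI", "ICI")
    band: str = "all"
    seed: int = 0
    output_dir: Path | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        kwargs: dict = {}
        if "design" in raw:
            d = raw["design"]
            kwargs["design"] = (
                StudyDesign.from_json(d) if isinstance(d, str) else StudyDesign.from_dict(d)
            )
        if "respiration" in raw:
            kwargs["resp_cfg"] = sim.RespirationSimConfig(**raw["respiration"])
        if "performance" in raw:
            kwargs["perf_cfg"] = sim.PerformanceSimConfig(**raw["performance"])
        if "wavelet" in raw:
            kwargs["wavelet"] = cpl.WaveletSpec(**raw["wavelet"])
        if "thresholds" in raw:
            kwargs["thresholds"] = acc.AccuracyThresholds(**raw["thresholds"])
        for key in ("clip_duration", "seed", "band", "condition_effects"):
            if key in raw:
                kwargs[key] = raw[key]
        if "output_dir" in raw:
            kwargs["output_dir"] = Path(raw["output_dir"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, (np.ndarray, tuple, list)):
                return [enc(v) for v in o]
            if isinstance(o, Path):
                return str(o)
            if isinstance(o, dict):
                return {k: enc(v) for k, v in o.items()}
            return o

        payload = {
            "design": self.design.to_dict(),
            "resp": enc(self.resp_cfg),
            "perf": enc(self.perf_cfg),
            "wavelet": enc(self.wavelet),
            "thresholds": enc(self.thresholds),
            "clip": self.clip_duration,
            "effects": enc(self.condition_effects),
            "band": self.band,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    row_counts: dict[str, int] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    removal_report: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def coupling_tables(
    study: sim.SyntheticStudy, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial pairwise indices and voice-level band means.

    Returns (long pairwise table, voice-mean table with one row per
    (block x condition x voice) carrying ACI/PSI/ICI means for each band).
    """
    design = config.design
    pair_frames = []
    voice_rows = []
    bands = ["all"] + [
        b
        for b in cpl.BANDS
        if any(
            cpl.band_of_frequency(f) == b for f in config.wavelet.frequencies
        )
    ]
    for (block, cond), traces in sorted(study.respiration.items()):
        pw = cpl.pairwise_coupling(traces, config.wavelet, clip=config.clip_duration)
        tagged = pw.copy()
        tagged["block"] = block
        tagged["condition"] = cond
        pair_frames.append(tagged)
        for band in bands:
            aggs = {
                name: cpl.aggregate_coupling(pw, design, index_name=name, band=band)
                for name in config.indices
            }
            for voice in design.voices:
                voice_rows.append(
                    {
                        "block": block,
                        "condition": cond,
                        "unit": design.blocks[block],
                        "voice": voice,
                        "band": band,
                        **{name: aggs[name].voice_means[voice] for name in config.indices},
                    }
                )
    return pd.concat(pair_frames, ignore_index=True), pd.DataFrame(voice_rows)


def run_pipeline(config: PipelineConfig, write: bool = True) -> tuple[RunManifest, dict]:
    """Run every stage; return the manifest and a dict of result objects."""
    t0 = time.time()
    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed)
    design = config.design
    out: dict = {}

    def tic(stage: str, start: float) -> None:
        manifest.timings_s[stage] = round(time.time() - start, 3)

    s = time.time()
    study = sim.generate_study_dataset(
        design,
        resp_cfg=config.resp_cfg,
        perf_cfg=config.perf_cfg,
        condition_effects=config.condition_effects,
        seed=config.seed,
    )
    out["study"] = study
    manifest.row_counts["note_streams"] = study.n_streams
    expected_streams = observation_count(design, ObservationLevel.AUDIO_FILE)
    if study.n_streams != expected_streams:
        raise RuntimeError(
            f"simulated {study.n_streams} note streams, design expects {expected_streams}"
        )
    manifest.row_counts["respiration_trials"] = len(study.respiration)
    tic("simulate", s)

    s = time.time()
    pairwise, voice_coupling = coupling_tables(study, config)
    out["pairwise_coupling"] = pairwise
    out["voice_coupling"] = voice_coupling
    n_grid = observation_count(design, ObservationLevel.RESPIRATION_GRID)
    manifest.row_counts["respiration_grid_per_condition"] = (
        pairwise["block"].nunique() * design.n_singers * pairwise["frequency_hz"].nunique()
    )
    if manifest.row_counts["respiration_grid_per_condition"] != n_grid:
        manifest.warnings.append("respiration grid count does not match design")
    tic("coupling", s)

    s = time.time()
    piece_table, rep1 = acc.accuracy_table(
        study.notes, study.score, level="piece", thresholds=config.thresholds, design=design
    )
    unit_table, rep2 = acc.accuracy_table(
        study.notes, study.score, level="recording_unit", thresholds=config.thresholds, design=design
    )
    vc_all = voice_coupling[voice_coupling["band"] == config.band]
    unit_merged = unit_table.merge(
        vc_all.drop(columns=["band"]), on=["block", "condition", "voice", "unit"], validate="1:1"
    )
    out["piece_table"] = piece_table
    out["unit_table"] = unit_merged
    manifest.removal_report = rep1.as_dict()
    manifest.row_counts["piece_table"] = len(piece_table)
    manifest.row_counts["unit_table"] = len(unit_merged)
    if len(unit_merged) != observation_count(design, ObservationLevel.RECORDING_UNIT):
        raise RuntimeError("unit-level table row count does not match design")
    tic("accuracy", s)

    s = time.time()
    contrast_fits: dict[str, st.FitResult] = {}
    ttests = {}
    for label, response in (("timing", "LMOE"), ("intonation", "LMAPE")):
        ttests[label] = st.paired_ttest(
            piece_table, response, conditions=config.contrast_conditions
        )
        contrast_fits[label] = st.fit_contrast_model(
            piece_table, response, conditions=config.contrast_conditions
        )
    prediction_fits: dict[str, st.FitResult] = {}
    for index in config.indices:
        for label, response in (("timing", "LMOE"), ("intonation", "LMAPE")):
            prediction_fits[f"{index}_{label}"] = st.fit_prediction_model(
                unit_merged, response, index
            )
    out["ttests"] = ttests
    out["contrast_table"] = st.report_tables(contrast_fits)
    out["prediction_table"] = st.report_tables(prediction_fits)
    out["index_correlations"] = cpl.index_correlations(
        voice_coupling[voice_coupling["band"] == "all"]
    )
    tic("stats", s)

    if write and config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        piece_table.to_csv(outdir / "piece_accuracy.csv", index=False)
        unit_merged.to_csv(outdir / "unit_accuracy_coupling.csv", index=False)
        pairwise.to_csv(outdir / "pairwise_coupling.csv", index=False)
        voice_coupling.to_csv(outdir / "voice_coupling.csv", index=False)
        out["contrast_table"].to_csv(outdir / "contrast_models.csv", index=False)
        out["prediction_table"].to_csv(outdir / "prediction_models.csv", index=False)
        out["index_correlations"].to_csv(outdir / "index_correlations.csv", index=False)
        ttest_rows = [
            {"measure": k, **dataclasses.asdict(v)} for k, v in ttests.items()
        ]
        pd.DataFrame(ttest_rows).to_csv(outdir / "paired_ttests.csv", index=False)
        manifest.timings_s["total"] = round(time.time() - t0, 3)
        manifest.to_json(outdir / "manifest.json")
    else:
        manifest.timings_s["total"] = round(time.time() - t0, 3)
    return manifest, out


def make_fixtures(size: str = "tiny", outdir: str | Path = "fixtures", seed: int = 0) -> Path:
    """Write a self-contained fixture directory (CSV + JSON, text only).

    ``tiny``: 2 voices, 1 block per unit, 60-s traces — seconds-fast.
    ``full``: the full default design with 400-s traces.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if size == "tiny":
        design = tiny_design(n_voices=2)
        resp = sim.RespirationSimConfig(n_singers=design.n_singers, duration=60.0)
        events = 15
        clip = 50.0
    elif size == "full":
        design = default_design()
        resp = sim.RespirationSimConfig(n_singers=design.n_singers)
        events = None
        clip = 360.0
    else:
        raise ValueError("size must be 'tiny' or 'full'")
    design.to_json(outdir / "design.json")
    study = sim.generate_study_dataset(
        design, resp_cfg=resp, seed=seed, events_per_piece=events
    )
    sim.write_score(study.score, outdir / "score.csv")
    study.notes.to_csv(outdir / "notes.csv", index=False)
    for (block, cond), traces in study.respiration.items():
        df = pd.DataFrame({"time_s": traces[0].times})
        for t in traces:
            df[t.singer] = t.samples
        df.to_csv(outdir / f"respiration_block{block}_{cond}.csv", index=False)
    (outdir / "meta.json").write_text(
        json.dumps({"size": size, "seed": seed, "clip_duration": clip}, indent=2)
    )
    return outdir
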