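"""Reproducible stage runs: configuration, seeding, and artifact manifests.

A :class:`RunConfig` is one JSON document with per-stage sections.  Running a
stage writes its outputs plus ``manifest.json`` recording the canonical
config, its hash, the package version, and the SHA-256 of every output file,
so a rerun with the same config is verifiably bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__, io
from .curvature import render_map
from .imaging import RatioQuantifier, group_summary
from .midline import MidlineExtractor
from .scoring import NaClClassifier, ThermotaxisClassifier, fraction_summary
from .segmentation import StateSegmenter, turn_statistics
from .simulate import (
    SimulationConfig,
    rasterize,
    simulate_plate_track,
    simulate_posture_sequence,
    simulate_ratio_traces,
)

STAGES = ("simulate-video", "simulate-track", "simulate-traces",
          "analyze-video", "analyze-calcium", "score-behavior")


@dataclasses.dataclass
class RunConfig:
    """One pipeline stage plus its parameters.

    ``params`` holds the stage-specific section; ``seed`` feeds every source
    of randomness in the stage.
    """

    stage: str
    out_dir: str
    seed: int = 0
    params: dict = dataclasses.field(default_factory=dict)
    inputs: dict = dataclasses.field(default_factory=dict)
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        if self.stage == "simulate-video":
            sim = {k: v for k, v in self.params.items()
                   if k in {f.name for f in dataclasses.fields(SimulationConfig)}}
            SimulationConfig(**sim).validate()
        for path in self.inputs.values():
            if not Path(path).exists():
                raise FileNotFoundError(f"missing input: {path}")
        return self

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def canonical_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute one stage and return its artifact manifest (also written to
    ``<out_dir>/manifest.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = config.stage
    p = dict(config.params)

    if stage == "simulate-video":
        sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        sim = {k: v for k, v in p.items() if k in sim_fields}
        sim.setdefault("rng_seed", config.seed)
        posture = simulate_posture_sequence(SimulationConfig(**sim))
        stack = rasterize(
            posture,
            pixel_size_mm=p.get("pixel_size_mm", 0.02),
            image_shape=tuple(p.get("image_shape", (128, 128))),
            noise_sd=p.get("noise_sd", 0.0),
            seed=config.seed,
        )
        io.write_frame_stack(stack, out / "stack.tif")
        io.write_posture_csv(posture, out / "true_midlines.csv", out / "true_states.csv")

    elif stage == "simulate-track":
        tracks = []
        n_tracks = p.get("n_tracks", 1)
        for i in range(n_tracks):
            tr = simulate_plate_track(
                p.get("kind", "thermotaxis"),
                p.get("behavior_params", {}),
                seed=config.seed + i,
            )
            path = out / f"track_{i:03d}.csv"
            io.write_track_csv(tr, path)
            tracks.append(tr)

    elif stage == "simulate-traces":
        traces = simulate_ratio_traces(
            n_traces=p.get("n_traces", 10),
            response_percent=p.get("response_percent", 17.0),
            onset_s=p.get("onset_s", 30.0),
            kinetics=tuple(p.get("kinetics", (2.0, 15.0))),
            noise_snr=p.get("noise_snr", np.inf),
            bleach_rate=p.get("bleach_rate", 0.0),
            seed=config.seed,
        )
        for i, tr in enumerate(traces):
            io.write_trace_csv(tr.data, out / f"trace_{i:03d}.csv")
        (out / "ground_truth.json").write_text(
            json.dumps({"true_peak_pct": [tr.true_peak_pct for tr in traces]})
        )

    elif stage == "analyze-video":
        stack = io.read_frame_stack(config.inputs["stack"])
        extractor = MidlineExtractor(
            n_points=p.get("n_points", 50),
            threshold_policy=p.get("threshold_policy", "otsu"),
        ).fit(stack)
        midlines = extractor.transform(stack)
        seg = StateSegmenter(frame_rate_hz=stack.frame_rate_hz).fit(midlines)
        stats = turn_statistics(seg.states_, window_s=p.get("window_s", 1000.0))
        io.write_midlines_csv(midlines, out / "midlines.csv")
        io.write_curvature_map(seg.curvature_map_, out / "curvature.csv",
                               out / "curvature_meta.json")
        io.write_states(seg.states_, out / "states.csv", out / "intervals.csv")
        io.write_turn_statistics(stats, out / "turn_statistics.json")
        render_map(seg.curvature_map_, seg.states_, path=out / "kymograph.png")

    elif stage == "analyze-calcium":
        frames = [io.read_trace_csv(v) for k, v in sorted(config.inputs.items())]
        quant = RatioQuantifier(
            baseline_s=p.get("baseline_s", 10.0), detrend=p.get("detrend", False)
        ).fit()
        completed = quant.transform(frames)
        summary = group_summary(completed, mode=p.get("mode", "max"))
        pd.DataFrame(
            {
                "time_s": summary.time_s,
                "mean_ratio_change_pct": summary.mean_trace_pct,
                "sem_ratio_change_pct": summary.sem_trace_pct,
            }
        ).to_csv(out / "group_trace.csv", index=False)
        (out / "summary.json").write_text(
            json.dumps(
                {
                    "max_ratio_change_pct": summary.max_changes_pct.tolist(),
                    "mean_max_pct": summary.mean_max_pct,
                    "sem_max_pct": summary.sem_max_pct,
                    "n": summary.n,
                },
                indent=2,
            )
        )

    elif stage == "score-behavior":
        assay = p.get("assay", "ttx")
        tracks = [
            io.read_track_csv(
                v,
                plate_radius_mm=p.get("plate_radius_mm", 45.0),
                gradient=(assay == "ttx"),
                peak=tuple(p["peak"]) if "peak" in p else None,
            )
            for k, v in sorted(config.inputs.items())
        ]
        if assay == "ttx":
            clf = ThermotaxisClassifier(visit_frac=p.get("visit_frac", 0.10)).fit()
            cats = clf.predict(tracks)
            occ = [s.occupancies for s in clf.scores_]
        elif assay == "nacl":
            clf = NaClClassifier(
                peak=tuple(p["peak"]) if "peak" in p else None,
                min_excursion_s=p.get("min_excursion_s", 30.0),
                long_dwell_frac=p.get("long_dwell_frac", 0.5),
            ).fit()
            cats = clf.predict(tracks)
            occ = [s.details for s in clf.scores_]
        else:
            raise ValueError(f"unknown assay {assay!r}")
        pd.DataFrame({"track": np.arange(len(cats)), "category": cats}).to_csv(
            out / "scores.csv", index=False
        )
        (out / "summary.json").write_text(
            json.dumps(
                {
                    "fractions": fraction_summary([list(cats)]).to_dict(),
                    "per_track": [
                        {k: (v if np.isfinite(v) else None) if isinstance(v, float) else v
                         for k, v in o.items()}
                        for o in occ
                    ],
                },
                indent=2,
                default=float,
            )
        )

    outputs = sorted(
        str(f.relative_to(out)) for f in out.rglob("*")
        if f.is_file() and f.name != "manifest.json"
    )
    manifest = {
        "package": "wormkymo",
        "version": __version__,
        "config": json.loads(config.canonical_json()),
        "config_sha256": hashlib.sha256(config.canonical_json().encode()).hexdigest(),
        "inputs": dict(config.inputs),
        "outputs": {name: _sha256_file(out / name) for name in outputs},
    }
    manifest["manifest_sha256"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
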