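"""Config-driven orchestration of the analysis stages.

A run is described by a small YAML/JSON mapping::

    stage: motility            # motility | tem | atp
    seed: 1
    out_dir: results/
    simulate: {n_cells: 4, step_sigma_um: 0.3}   # or
    inputs: {stack: movie.ome.tif, annotations: cells.geojson}
    params: {theta_deg: 10, fraction_um: 7}

Outputs are CSV tables with JSON metadata sidecars recording every tunable
parameter, the package version and the seed, plus a plain-text run log.
Identical configs and seeds give byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (ResultsTable, ValidationError, read_annotations, read_stack,
                 read_tem_annotations, write_results, write_stack,
                 write_tem_annotations, write_annotations)
from .morphometry import tem_morphometry
from .motility import analyze_movie
from .ratiometric import analyze_ratio_movie
from .synthetic import (MicrodomainSpec, MovieConfig, simulate_movie,
                        simulate_ratio_movie, simulate_tem_annotations)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        path = Path(config)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        config = yaml.safe_load(path.read_text())
    if not isinstance(config, dict) or "stage" not in config:
        raise ValidationError("config must be a mapping with a 'stage' key")
    return config


def _movie_config(config: dict) -> MovieConfig:
    kwargs = dict(config.get("simulate") or {})
    kwargs.setdefault("seed", config.get("seed", 0))
    return MovieConfig(**kwargs)


def run_pipeline(config, out_dir: str | Path | None = None) -> dict:
    """Execute one configured stage end to end; returns output paths.

    Raises on any stage failure (the CLI converts that into a non-zero exit
    naming the stage).
    """
    config = _load_config(config)
    stage = config["stage"]
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    params = dict(config.get("params") or {})
    inputs = dict(config.get("inputs") or {})
    log_lines = [f"isletmito {__version__}", f"stage: {stage}",
                 f"seed: {seed}", f"params: {json.dumps(params, sort_keys=True)}"]
    outputs: dict = {}

    try:
        if stage == "motility":
            if inputs:
                stack = read_stack(inputs["stack"],
                                   pixel_size_override=inputs.get("pixel_size_um"))
                ann = read_annotations(inputs["annotations"],
                                       pixel_size_um=stack.pixel_size_um,
                                       image_shape=stack.frame_shape)
            else:
                stack, ann, _gt = simulate_movie(_movie_config(config))
            _results, table = analyze_movie(stack, ann, **params)
            table.metadata.update(version=__version__, seed=seed)
            outputs["results"] = str(write_results(table, out / "motility.csv"))
        elif stage == "tem":
            if inputs:
                cells = read_tem_annotations(inputs["annotations"],
                                             pixel_size_um=inputs.get("pixel_size_um"))
            else:
                sim = dict(config.get("simulate") or {})
                sim.setdefault("seed", seed)
                cells, _truth = simulate_tem_annotations(**sim)
            table = tem_morphometry(cells)
            table.metadata.update(version=__version__, seed=seed)
            outputs["results"] = str(write_results(table, out / "morphometry.csv"))
        elif stage == "atp":
            if inputs:
                stack = read_stack(inputs["stack"],
                                   pixel_size_override=inputs.get("pixel_size_um"))
                ann = read_annotations(inputs["annotations"],
                                       pixel_size_um=stack.pixel_size_um,
                                       image_shape=stack.frame_shape)
            else:
                md = config.get("microdomains")
                spec = MicrodomainSpec(**md) if md else None
                stack, ann, _gt = simulate_ratio_movie(_movie_config(config),
                                                       microdomains=spec)
            results = analyze_ratio_movie(stack, ann, **params)
            rows = []
            for r in results:
                for t, (m, v) in enumerate(zip(r.mean_ratio, r.valid_fraction)):
                    rows.append({"cell_id": r.cell_id, "frame": t,
                                 "shell_mean_ratio": m, "valid_fraction": v,
                                 "n_microdomains": len(r.microdomains[t])
                                 if r.microdomains else 0})
            table = ResultsTable(df=pd.DataFrame(rows),
                                 metadata=dict(params, operation="atp_ratio",
                                               version=__version__, seed=seed))
            outputs["results"] = str(write_results(table, out / "ratio.csv"))
        else:
            raise ValidationError(f"unknown stage {stage!r}")
    except Exception as exc:
        log_lines.append(f"FAILED in stage {stage}: {exc}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    rel = {k: Path(v).name for k, v in outputs.items()}
    log_lines.append(f"outputs: {json.dumps(rel, sort_keys=True)}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    outputs["log"] = str(out / "run.log")
    return outputs


def simulate_to_files(kind: str, out_dir: str | Path, seed: int = 0,
                      config_kwargs: dict | None = None,
                      microdomains: dict | None = None,
                      tem_kwargs: dict | None = None) -> dict:
    """Run one generator and write its movie/annotations/ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}
    if kind in ("movie", "ratio"):
        cfg = MovieConfig(**dict(config_kwargs or {}, seed=seed))
        if kind == "movie":
            stack, ann, gt = simulate_movie(cfg)
        else:
            spec = MicrodomainSpec(**microdomains) if microdomains else None
            stack, ann, gt = simulate_ratio_movie(cfg, microdomains=spec)
        outputs["stack"] = str(write_stack(stack, out / f"{kind}.ome.tif"))
        outputs["annotations"] = str(write_annotations(ann, out / f"{kind}.geojson"))
        truth = {
            "cells": [{"cell_id": c.cell_id, "class": c.cell_class,
                       "motile": c.motile.tolist(),
                       "trajectories_um": c.trajectories_um.tolist(),
                       "microdomains": [
                           {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                            for k, v in d.items() if k != "mask"}
                           for d in c.microdomains]}
                      for c in gt.cells],
            "config": dataclasses.asdict(cfg)}
        (out / f"{kind}.truth.json").write_text(json.dumps(truth))
        outputs["truth"] = str(out / f"{kind}.truth.json")
    elif kind == "tem":
        cells, truth = simulate_tem_annotations(**dict(tem_kwargs or {},
                                                       seed=seed))
        outputs["annotations"] = str(write_tem_annotations(cells,
                                                           out / "tem.geojson"))
        (out / "tem.truth.json").write_text(json.dumps(truth))
        outputs["truth"] = str(out / "tem.truth.json")
    else:
        raise ValidationError(f"unknown simulation kind {kind!r}")
    return outputs
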