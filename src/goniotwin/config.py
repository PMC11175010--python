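"""YAML configuration for instruments and samples.

A config file has up to four blocks::

    source:                # optional; default = instrument preset
      kind: instrument | pencil
    detector:
      distance_mm: 120.8
      aperture_radius_mm: 2.5
    angles:                # optional; default = 150 angles, 0-79 + 100-169
      start: 0.0
      stop: 170.0
      step: 1.0
      exclude: [[80.0, 100.0]]
    sample:
      cutout_radius_mm: 10.5
      layers:
        - {thickness_mm: 1.0, n: 1.51, mua_per_mm: 0.0, mus_per_mm: 0.0}
        - {thickness_mm: 2.0, n: 1.33, mua_per_mm: 0.1, mus_per_mm: 0.15,
           phase: {model: hg, g: 0.75}, perturbable: true}
        - {thickness_mm: 1.0, n: 1.51, mua_per_mm: 0.0, mus_per_mm: 0.0}

Phase blocks: ``{model: hg, g}``, ``{model: rm, gs, alpha}``,
``{model: double_hg, g1, g2, beta}``, ``{model: tabulated, path}``,
``{model: spline, knots_cos, knots_density}``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import yaml

from .detection import DetectorSpec, default_angle_grid
from .forward import ForwardModel, instrument_source, pencil_source
from .phasefunc import (
    DoubleHenyeyGreenstein,
    HenyeyGreenstein,
    ReynoldsMcCormick,
    SplinePhase,
    load_tabulated,
)
from .sample import Layer, Material, SampleDomain

__all__ = ["load_config", "model_from_config", "phase_from_config", "domain_from_config"]


def phase_from_config(block: dict):
    model = block.get("model", "hg").lower().replace("-", "_")
    if model == "hg":
        return HenyeyGreenstein(float(block["g"]))
    if model == "rm":
        return ReynoldsMcCormick(float(block["gs"]), float(block["alpha"]))
    if model == "double_hg":
        return DoubleHenyeyGreenstein(float(block["g1"]), float(block["g2"]),
                                      float(block["beta"]))
    if model == "tabulated":
        return load_tabulated(block["path"])
    if model == "spline":
        return SplinePhase(np.asarray(block["knots_cos"], dtype=float),
                           np.asarray(block["knots_density"], dtype=float))
    raise ValueError(f"unknown phase-function model {model!r}")


def domain_from_config(block: dict) -> SampleDomain:
    layers = []
    perturbable = None
    for i, lay in enumerate(block["layers"]):
        phase = phase_from_config(lay["phase"]) if "phase" in lay else None
        mat = Material(float(lay.get("mua_per_mm", 0.0)),
                       float(lay.get("mus_per_mm", 0.0)),
                       float(lay.get("n", 1.0)), phase)
        layers.append(Layer(float(lay["thickness_mm"]), mat))
        if lay.get("perturbable"):
            perturbable = i
    if perturbable is None:
        # default: the layer that scatters, else the thickest one
        scat = [i for i, l in enumerate(layers) if l.material.mus > 0]
        perturbable = scat[0] if scat else int(np.argmax([l.thickness_mm for l in layers]))
    return SampleDomain(tuple(layers),
                        cutout_radius_mm=float(block.get("cutout_radius_mm", 10.5)),
                        perturbable=perturbable)


def angles_from_config(block: Optional[dict]) -> np.ndarray:
    if block is None:
        return default_angle_grid()
    grid = np.arange(float(block.get("start", 0.0)),
                     float(block.get("stop", 170.0)) + 1e-9,
                     float(block.get("step", 1.0)))
    for lo, hi in block.get("exclude", [[80.0, 100.0]]):
        grid = grid[(grid < lo) | (grid >= hi)]
    return grid


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def model_from_config(cfg: dict) -> ForwardModel:
    """Build the forward model described by a parsed config dict.

    The sample block defines the *fixed* geometry; the perturbable layer's
    (mu_a, mu_s, g) act as defaults that the fitter overrides.
    """
    src_block = cfg.get("source", {}) or {}
    kind = src_block.get("kind", "instrument")
    source = pencil_source() if kind == "pencil" else instrument_source()
    det_block = cfg.get("detector", {}) or {}
    detector = DetectorSpec(0.0,
                            distance_mm=float(det_block.get("distance_mm", 120.8)),
                            aperture_radius_mm=float(det_block.get("aperture_radius_mm", 2.5)))
    angles = angles_from_config(cfg.get("angles"))
    base_domain = domain_from_config(cfg["sample"])

    def factory(mua, mus, g):
        layers = list(base_domain.layers)
        k = base_domain.perturbable
        med = layers[k].material
        phase = HenyeyGreenstein(g) if isinstance(med.phase, HenyeyGreenstein) or med.phase is None else med.phase
        layers[k] = Layer(layers[k].thickness_mm, Material(mua, mus, med.n, phase))
        return SampleDomain(tuple(layers), base_domain.cutout_radius_mm,
                            base_domain.perturbable, base_domain.n_outside)

    return ForwardModel(factory, angles_deg=angles, source=source, detector=detector)
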