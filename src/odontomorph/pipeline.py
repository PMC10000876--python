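"""End-to-end orchestration: simulate -> outline analysis -> mesh morph -> reports.

A single YAML config (or :class:`PipelineConfig`) drives a deterministic run:
all randomness flows from one seed through named per-stage substreams, every
intermediate is written to the output directory, and a manifest records the
config hash, seed and package versions so two runs with the same config are
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from odontomorph import __version__
from odontomorph.crownstats import morphotype_frequencies
from odontomorph.dataio import (
    DEFAULT_CUSP_PAIRING,
    DomainError,
    load_upper_molar_survey,
    write_mesh,
    write_outline,
)
from odontomorph.morph import (
    apply_morph,
    build_displacement_field,
    cervical_margin_vertices,
    dense_correspondence,
    transfer_morph,
)
from odontomorph.morphospace import OutlinePipelineConfig, outline_pipeline
from odontomorph.simulate import (
    CrownModelParams,
    CuspPeak,
    OutlineModelParams,
    default_mouse_crown,
    simulate_crown_mesh,
    simulate_outline_cohorts,
)

log = logging.getLogger("odontomorph.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of a full run; defaults reproduce the demo analysis."""

    seed: int = 0
    # outline simulation
    n_wt: int = 21
    n_mut: int = 33
    n_points: int = 64
    delta_theta_c1: float = 0.3
    amp_scale_c1: float = 1.0
    noise_sd: float = 0.01
    # outline analysis
    tooth_class: str = "M1_upper"
    n_harmonics: int | None = None
    variance_threshold: float = 0.95
    average_sides: bool = True
    # mesh morphing
    morph_cutoff: float = 5.0
    boundary_fraction: float = 0.15
    per_cusp: bool = False
    crown_resolution: int = 40

    def __post_init__(self) -> None:
        if not 0.0 < self.variance_threshold <= 1.0:
            raise DomainError("variance threshold must lie in (0, 1]")
        if self.n_harmonics is not None and self.n_harmonics < 2:
            raise DomainError("harmonics must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise DomainError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sha256(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _substream(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") >> 1


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full analysis; returns a summary dict (also written as
    JSON into ``outdir``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    # ---- stage 1: outline simulation -------------------------------------
    log.info("stage simulate-outlines: %d WT + %d mutant", config.n_wt, config.n_mut)
    params = OutlineModelParams(delta_theta_c1=config.delta_theta_c1,
                                amp_scale_c1=config.amp_scale_c1,
                                noise_sd=config.noise_sd)
    outlines = simulate_outline_cohorts(params, config.n_wt, config.n_mut,
                                        n_points=config.n_points,
                                        seed=_substream(config.seed, "outlines"))
    outline_dir = outdir / "outlines"
    outline_dir.mkdir(exist_ok=True)
    for outline in outlines:
        write_outline(outline, outline_dir / f"{outline.label}.csv")

    # ---- stage 2: outline analysis ---------------------------------------
    log.info("stage outline-analysis: %s", config.tooth_class)
    analysis_cfg = OutlinePipelineConfig(
        n_points=config.n_points, n_harmonics=config.n_harmonics,
        variance_threshold=config.variance_threshold,
        average_sides=config.average_sides)
    result = outline_pipeline(outlines, tooth_class=config.tooth_class,
                              config=analysis_cfg)
    result.matrix.X.to_csv(outdir / "coefficients.csv")
    pd.DataFrame(result.pca.scores,
                 index=result.matrix.X.index,
                 columns=[f"PC{i+1}" for i in range(result.pca.n_components)]
                 ).to_csv(outdir / "scores.csv")
    manova = result.manova
    summary["manova"] = {
        "wilks_lambda": manova.wilks_lambda, "F": manova.f_statistic,
        "df1": manova.df1, "df2": manova.df2, "p_value": manova.p_value,
        "n_axes_retained": result.n_axes_retained,
    }
    (outdir / "manova.json").write_text(json.dumps(summary["manova"], indent=2))
    for name, outline in zip(("extreme_neg", "extreme_pos"), result.extremes):
        write_outline(outline, outdir / f"{name}.csv")

    # ---- stage 3: morphotype frequencies (packaged survey) ---------------
    log.info("stage morphotype-frequencies")
    survey = load_upper_molar_survey()
    freqs = {}
    for trait, state in (("m1_c1c2_profile", "U"), ("m2_spur", "absent"),
                         ("m3_c1", "reduced")):
        rep = morphotype_frequencies(survey, "mutant", trait, state)
        freqs[f"mutant_{trait}_{state}"] = {
            "observed": rep.count_observed, "scored": rep.count_scored,
            "percentage": rep.percentage,
        }
    summary["morphotype_frequencies"] = freqs
    (outdir / "morphotype_frequencies.json").write_text(json.dumps(freqs, indent=2))

    # ---- stage 4: crown morphing and transfer ----------------------------
    log.info("stage crown-morph: resolution %d", config.crown_resolution)
    crown = default_mouse_crown()
    crown = CrownModelParams(a=crown.a, b=crown.b, h=crown.h, cusps=crown.cusps,
                             cusp_shift=crown.cusp_shift,
                             resolution=config.crown_resolution,
                             seed=_substream(config.seed, "crowns"))
    wt_mesh, wt_lms = simulate_crown_mesh(crown, cohort="WT")
    mut_mesh, _ = simulate_crown_mesh(crown, cohort="mutant")
    corr = dense_correspondence(wt_mesh, mut_mesh, cutoff=config.morph_cutoff)
    boundary = cervical_margin_vertices(wt_mesh, config.boundary_fraction)
    disp_field = build_displacement_field(corr, boundary=boundary)
    morphed = apply_morph(wt_mesh, disp_field)
    write_mesh(morphed, outdir / "morphed_wt.stl")
    pd.DataFrame({
        "vertex": np.arange(len(disp_field.vectors)),
        "dx": disp_field.vectors[:, 0], "dy": disp_field.vectors[:, 1],
        "dz": disp_field.vectors[:, 2], "magnitude": disp_field.magnitudes,
        "kind": corr.kind,
    }).to_csv(outdir / "field.csv", index=False)

    # homologous "human-like" third crown: same four cusps under their human
    # names, twice the linear size
    human = CrownModelParams(
        a=2 * crown.a, b=2 * crown.b, h=2 * crown.h,
        cusps={h: CuspPeak((2 * c.center[0], 2 * c.center[1]), 2 * c.height,
                           2 * c.width)
               for h, m in DEFAULT_CUSP_PAIRING.items()
               for c in [crown.cusps[m]]},
        resolution=config.crown_resolution,
        seed=_substream(config.seed, "human"))
    human_mesh, human_lms = simulate_crown_mesh(human)
    predicted = transfer_morph(disp_field, wt_lms, human_mesh, human_lms,
                               pairing=DEFAULT_CUSP_PAIRING,
                               cutoff=config.morph_cutoff,
                               mode="per_cusp" if config.per_cusp else "global")
    write_mesh(predicted, outdir / "predicted_human.stl")
    shift = np.linalg.norm(predicted.vertices - human_mesh.vertices, axis=1)
    summary["transfer"] = {"max_vertex_shift_mm": float(shift.max()),
                           "mean_vertex_shift_mm": float(shift.mean())}

    # ---- manifest --------------------------------------------------------
    manifest = {
        "config": asdict(config),
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "versions": {"odontomorph": __version__, "numpy": np.__version__},
        "outputs": sorted({p.name for p in outdir.iterdir() if p.is_file()}
                          | {"manifest.json", "summary.json"}),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
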