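"""End-to-end pipeline: stimuli -> simulated study -> fits -> report.

A run is driven by a :class:`RunConfig` (optionally loaded from YAML), executes
the requested stages in dependency order, and writes a manifest listing every
output file with a content hash.  A single global seed spawns per-stage child
seeds through ``numpy`` seed sequences keyed by stage name, so adding a stage
never perturbs earlier stages' random streams.
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
import yaml

from . import fit as fitmod
from .metrics import coherence_scan, coherence_to_csv
from .observer import PopulationSpec, ThresholdMatrix, generate_matrix, simulate_study
from .staircase import StaircaseConfig
from .stimulus import BandSpec, StimulusConfig, build_interval, write_sidecar, write_wav

__all__ = [
    "RunConfig",
    "Diagnostic",
    "STAGE_ORDER",
    "derive_seed",
    "validate_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

STAGE_ORDER = ("stimuli", "simulate", "fit", "report")


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31), stable across stage sets."""
    key = zlib.crc32(stage.encode())
    ss = np.random.SeedSequence([int(global_seed), key])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    stages: tuple[str, ...] = STAGE_ORDER
    out_dir: str = "binauralgap_run"
    seed: int = 0
    population: PopulationSpec = field(default_factory=PopulationSpec)
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    sessions: int = 3
    fast_simulation: bool = False  # distributional shortcut instead of staircases
    matrix_path: str | None = None  # pre-existing matrix CSV for fit-only runs

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("stages", "out_dir", "seed", "sessions", "fast_simulation", "matrix_path"):
            if key in raw:
                kwargs[key] = tuple(raw[key]) if key == "stages" else raw[key]
        if "population" in raw:
            kwargs["population"] = PopulationSpec(**raw["population"])
        if "staircase" in raw:
            kwargs["staircase"] = StaircaseConfig(**raw["staircase"])
        if "stimulus" in raw:
            kwargs["stimulus"] = StimulusConfig(**raw["stimulus"])
        return cls(**kwargs)


@dataclass
class Diagnostic:
    level: str  # "error" | "warning"
    message: str


def validate_config(config: RunConfig) -> list[Diagnostic]:
    """Range and consistency checks; diagnostics only, no side effects."""
    diags: list[Diagnostic] = []
    unknown = [s for s in config.stages if s not in STAGE_ORDER]
    if unknown:
        diags.append(Diagnostic("error", f"unknown stages: {unknown}"))
    if "fit" in config.stages and "simulate" not in config.stages and not config.matrix_path:
        diags.append(
            Diagnostic(
                "error",
                "the fit stage needs either the simulate stage or a matrix_path",
            )
        )
    nyq = config.stimulus.sample_rate_hz / 2.0
    for cf in config.population.condition_cfs:
        hi = cf * 2.0 ** (1.0 / 6.0)
        if hi >= nyq:
            diags.append(
                Diagnostic(
                    "error",
                    f"upper band edge {hi:.0f} Hz for CF {cf:g} Hz is at or above "
                    f"Nyquist ({nyq:.0f} Hz)",
                )
            )
    if config.stimulus.cic_duration_ms >= config.stimulus.interval_duration_ms:
        diags.append(
            Diagnostic(
                "warning",
                "the uncorrelated segment spans the entire interval, leaving no "
                "flanking correlated noise; a change in correlation is then "
                "ill-defined (shorter cic_duration_ms recommended)",
            )
        )
    if config.sessions < 1:
        diags.append(Diagnostic("error", "sessions must be >= 1"))
    return diags


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and return the manifest (also written to disk)."""
    errors = [d for d in validate_config(config) if d.level == "error"]
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(d.message for d in errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    stages = [s for s in STAGE_ORDER if s in config.stages]

    matrix: ThresholdMatrix | None = None
    if "stimuli" in stages:
        seed = derive_seed(config.seed, "stimuli")
        for contains_cic, name in ((False, "reference"), (True, "target")):
            stim = build_interval(
                config.stimulus, BandSpec.wideband(), contains_cic=contains_cic, seed=seed
            )
            wav = out / f"example_{name}.wav"
            write_wav(stim, wav)
            write_sidecar(stim, out / f"example_{name}.json")
            curve = coherence_scan(stim, max_lag_ms=10.0)
            coherence_to_csv(curve, out / f"example_{name}_coherence.csv")
            outputs += [wav, out / f"example_{name}.json", out / f"example_{name}_coherence.csv"]
        logger.info("stimuli stage complete")

    if "simulate" in stages:
        seed = derive_seed(config.seed, "simulate")
        if config.fast_simulation:
            matrix = generate_matrix(config.population, seed=seed)
        else:
            matrix = simulate_study(
                config.population,
                config.staircase,
                seed=seed,
                sessions=config.sessions,
            )
        mpath = out / "threshold_matrix.csv"
        matrix.to_csv(mpath)
        outputs.append(mpath)
        logger.info("simulate stage complete (n=%d, m=%d)", matrix.n, matrix.m)

    report: dict | None = None
    if "fit" in stages:
        if matrix is None:
            if not config.matrix_path:
                raise ValueError("fit stage: no matrix available; run simulate or give matrix_path")
            matrix = ThresholdMatrix.from_csv(config.matrix_path)
        wres = fitmod.fit_weights(matrix)
        corr = fitmod.correlate_bands(matrix)
        curve = fitmod.fit_cf_curve(matrix)
        report = {
            "omega": wres.omega.tolist(),
            "cf_labels": [float(c) for c in matrix.cf_labels],
            "r_squared_weights": wres.r_squared,
            "T_prime_ms": wres.T_prime,
            "mean_wideband_ms": float(np.mean(matrix.T_i)),
            "per_cf_r": corr.r.tolist(),
            "cf_curve": {"family": curve.family, "params": curve.params,
                         "r_squared": curve.r_squared},
        }
        rpath = out / "fit_report.json"
        rpath.write_text(json.dumps(report, indent=2))
        outputs.append(rpath)
        logger.info("fit stage complete")

    if "report" in stages:
        if matrix is not None:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(5, 4))
            fitmod.fit_cf_curve(matrix).plot(ax=ax)
            fig.tight_layout()
            fpath = out / "cf_curve.png"
            fig.savefig(fpath, dpi=120)
            plt.close(fig)
            outputs.append(fpath)
        logger.info("report stage complete")

    manifest = {
        "seed": config.seed,
        "stages": stages,
        "stage_seeds": {s: derive_seed(config.seed, s) for s in stages},
        "config": {
            "population": dataclasses.asdict(config.population),
            "staircase": dataclasses.asdict(config.staircase),
            "stimulus": dataclasses.asdict(config.stimulus),
            "sessions": config.sessions,
            "fast_simulation": config.fast_simulation,
        },
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
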