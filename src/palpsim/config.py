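"""Configuration schema, file I/O and fixture generation.

The whole apparatus is configured by one nested YAML (or JSON) document with
sections mirroring the simulation stages: phantom / control / encoder /
subject / session / analysis.  Validation is strict — unknown keys are
rejected — and every section falls back to the apparatus defaults (50 mm
neutral sphere, 0.5 N force threshold, 5 kHz neuron, 12 inclusions) when
omitted, so an empty file is a valid all-defaults configuration.

All randomness flows from the single session seed through named
sub-streams, so the phantom layout, latency jitter and subject scatter are
independently reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import control, encoder, phantom as phantom_mod, psychophysics, session, subject

__all__ = [
    "ArtifactConfig",
    "load_config",
    "save_config",
    "generate_fixtures",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MaterialCfg(_Strict):
    name: str
    stiffness: float = Field(gt=0)


class PhantomCfg(_Strict):
    size_xyz: tuple[float, float, float] = (100.0, 100.0, 15.0)
    matrix: MaterialCfg = MaterialCfg(name="DS10", stiffness=2.14)
    materials: list[MaterialCfg] = [
        MaterialCfg(name="DS20", stiffness=2.74),
        MaterialCfg(name="DS30", stiffness=2.88),
        MaterialCfg(name="PDMS", stiffness=3.68),
        MaterialCfg(name="SC", stiffness=3.69),
    ]
    replicas: int = Field(default=3, ge=0)
    radius: float = Field(default=5.0, gt=0)
    edge_margin: float = Field(default=5.0, ge=0)
    blend_width: float = Field(default=0.0, ge=0)
    max_attempts: int = Field(default=10_000, gt=0)

    def build(self, seed: int) -> phantom_mod.Phantom:
        mats = {m.name: phantom_mod.MaterialSpec(m.name, m.stiffness)
                for m in self.materials}
        return phantom_mod.generate_phantom(
            size_xyz=self.size_xyz,
            matrix=phantom_mod.MaterialSpec(self.matrix.name, self.matrix.stiffness),
            inclusion_materials=mats,
            replicas=self.replicas,
            radius=self.radius,
            edge_margin=self.edge_margin,
            blend_width=self.blend_width,
            max_attempts=self.max_attempts,
            seed=seed,
        )


class ControlCfg(_Strict):
    rho0: float = Field(default=50.0, gt=0)
    gain: float = Field(default=1.0, gt=0)
    max_speed: float = Field(default=20.0, gt=0)
    workspace: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 100.0), (0.0, 100.0))

    def build(self) -> control.ControlConfig:
        return control.ControlConfig(self.rho0, self.gain, self.max_speed,
                                     self.workspace)


class EncoderCfg(_Strict):
    izh_a: float = 0.02
    izh_b: float = 0.2
    izh_c: float = -65.0
    izh_d: float = 8.0
    v_peak: float = 30.0
    dt_ms: float = Field(default=0.2, gt=0)
    force_max: float = Field(default=0.5, gt=0)
    target_rate_top: float = Field(default=100.0, gt=0)
    input_offset: float = 0.0

    def build(self) -> tuple[encoder.IzhikevichParams, encoder.EncoderCalibration]:
        p = encoder.IzhikevichParams(self.izh_a, self.izh_b, self.izh_c,
                                     self.izh_d, self.v_peak, self.dt_ms)
        cal = encoder.calibrate_gain(
            p, force_max=self.force_max,
            target_rate_range=(0.0, self.target_rate_top),
            input_offset=self.input_offset,
        )
        return p, cal


class SubjectCfg(_Strict):
    rate_window: float = Field(default=0.25, gt=0)
    change_threshold: float = 12.0
    reaction_latency: float = Field(default=0.3, ge=0)
    refractory: float = Field(default=1.0, gt=0)
    guess_rate: float = Field(default=0.0, ge=0, lt=1)
    lapse_rate: float = Field(default=0.0, ge=0, lt=1)
    press_jitter_sd: float = Field(default=2.0, ge=0)
    baseline_windows: int = Field(default=5, gt=0)

    def build(self) -> subject.SubjectModel:
        return subject.SubjectModel(**self.model_dump())


class LatencyCfg(_Strict):
    kind: str = "fixed"
    bound_ms: float = Field(default=15.0, ge=0)

    def build(self) -> session.LatencyModel:
        return session.LatencyModel(self.kind, self.bound_ms / 1000.0)


class SessionCfg(_Strict):
    duration: float = Field(default=360.0, gt=0)
    control_rate: float = Field(default=100.0, gt=0)
    encoder_rate: float = Field(default=5000.0, gt=0)
    force_setpoint: float = Field(default=0.25, gt=0, le=session.FORCE_LIMIT_N)
    servo_tau: float = Field(default=0.4, gt=0)
    latency: LatencyCfg = LatencyCfg()
    mode: str = "ILS"
    seed: int = Field(default=0, ge=0)

    def build(self) -> session.SessionConfig:
        return session.SessionConfig(
            duration=self.duration, control_rate=self.control_rate,
            encoder_rate=self.encoder_rate, force_setpoint=self.force_setpoint,
            servo_tau=self.servo_tau, latency=self.latency.build(),
            mode=self.mode, seed=self.seed,
        )


class AnalysisCfg(_Strict):
    tolerances_mm: list[float] = [5.0, 10.0, 15.0, 20.0]
    accuracy_definition: str = "standard"
    boundary_shrink: float = Field(default=0.5, ge=0, le=1)


class ArtifactConfig(_Strict):
    """Top-level configuration: one section per simulation stage."""

    phantom: PhantomCfg = PhantomCfg()
    control: ControlCfg = ControlCfg()
    encoder: EncoderCfg = EncoderCfg()
    subject: SubjectCfg = SubjectCfg()
    session: SessionCfg = SessionCfg()
    analysis: AnalysisCfg = AnalysisCfg()

    def seeds(self) -> dict[str, int]:
        """Named per-component sub-seeds derived from the session seed."""
        ss = np.random.SeedSequence(self.session.seed)
        names = ("phantom", "latency", "subject")
        return {n: int(c.generate_state(1)[0] % 2**31)
                for n, c in zip(names, ss.spawn(len(names)))}


def load_config(path: str | Path) -> ArtifactConfig:
    """Read and validate a YAML/JSON config file; empty file = all defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    return ArtifactConfig.model_validate(data)


def save_config(cfg: ArtifactConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=True)
    )


# ---------------------------------------------------------------------------
# fixture bundles

_FIXTURES = ("default",)


def generate_fixtures(name: str, seed: int, out_dir: str | Path) -> Path:
    """Write a self-contained, seed-reproducible fixture bundle.

    The ``default`` bundle holds the standard phantom layout, one short
    raster session log and an analysis snapshot; identical (name, seed)
    always produce byte-identical bundles.
    """
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture name {name!r}; known: {_FIXTURES}")
    out = Path(out_dir) / f"{name}-{seed}"
    out.mkdir(parents=True, exist_ok=True)

    cfg = ArtifactConfig()
    cfg = cfg.model_copy(update={
        "session": cfg.session.model_copy(update={"seed": seed, "duration": 60.0}),
    })
    seeds = cfg.seeds()
    ph = cfg.phantom.build(seeds["phantom"])
    phantom_mod.save_phantom(ph, out / "phantom.json")

    ctrl = cfg.control.build()
    neuron, cal = cfg.encoder.build()
    traj = session.make_trajectory("raster", {"line_spacing": 10.0, "speed": 10.0},
                                   ctrl, cfg.session.control_rate)
    log = session.run_session(ph, cfg.subject.build(), ctrl, neuron, cal,
                              cfg.session.build(), traj)
    log.to_dir(out / "session")

    c = psychophysics.classify_responses(log.responses, ph, 10.0)
    snapshot = {
        "n_responses": len(c),
        "tp": c.tp_count,
        "fp": c.fp_count,
        "tolerance_mm": 10.0,
        "seed": seed,
    }
    (out / "analysis.json").write_text(json.dumps(snapshot, indent=2, sort_keys=True) + "\n")
    return out


def validate_fixture(bundle: str | Path) -> bool:
    """Re-check a fixture's analysis snapshot against its stored session log."""
    bundle = Path(bundle)
    ph = phantom_mod.load_phantom(bundle / "phantom.json")
    import pandas as pd

    resp = pd.read_csv(bundle / "session" / "responses.csv")
    snapshot = json.loads((bundle / "analysis.json").read_text())
    pts = resp[["x_mm", "y_mm"]].to_numpy()
    c = psychophysics.classify_responses(pts, ph, snapshot["tolerance_mm"])
    return (c.tp_count == snapshot["tp"] and c.fp_count == snapshot["fp"]
            and len(c) == snapshot["n_responses"])
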