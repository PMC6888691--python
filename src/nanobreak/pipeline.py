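"""Configuration-driven pipeline runner.

Ties the stages together into the study's two arms:

* **simulation arm** — phantom → synthetic tracks → strand-break scoring,
  run twice with common random numbers: a control pass with the
  near-particle enhancement switched off and a nanoparticle pass with the
  configured shell-material enhancement. Because both passes share the
  event seed, identical configurations give an amplification factor of
  exactly zero and the enhancement contrast is variance-reduced.
* **experimental arm** — gel lanes (from CSV files or the forward
  synthetic-gel generator) for up to four conditions (control, NP,
  control+DMSO, NP+DMSO) → Poisson inversion → dose-response fits →
  amplification factors and the hydroxyl-radical decomposition.

Every stage's parameters are validated up front, and a reproducibility
manifest (seeds, config digest, package version) accompanies each report.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from nanobreak import __version__
from nanobreak import gelquant
from nanobreak.damage import DamageConfig, amplification_factor, dsb_rate, score_damage
from nanobreak.dnageom import DuplexGeometry, build_bdna, load_pdb
from nanobreak.npgeom import Phantom, build_phantom
from nanobreak.tracks import TrackConfig, sample_events

ARM_NAMES = ("control", "np", "control_dmso", "np_dmso")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclasses.dataclass
class PipelineConfig:
    """Validated parameters for every pipeline stage.

    The phantom block defaults to the full study conditions (191
    core-shell particles in a 50 µm³ water sphere); desk-scale simulation
    runs should use :func:`desk_simulation_config`, which shrinks the
    geometry so strand-break statistics are reachable at modest event
    counts.
    """

    seed: int = 1
    output_dir: str | None = None
    phantom: dict = dataclasses.field(
        default_factory=lambda: {
            "n_particles": 191,
            "sphere_volume": 50.0,
            "core_diameter": 3.0,
            "shell_thickness": 2.0,
            "shell_material": "Pt",
        }
    )
    tracks: dict = dataclasses.field(
        default_factory=lambda: {"target_dose": 1.0, "n_repeats": 3}
    )
    duplex: dict = dataclasses.field(
        default_factory=lambda: {"kind": "procedural", "n_bp": 120}
    )
    damage: dict = dataclasses.field(default_factory=dict)
    gel: dict = dataclasses.field(
        default_factory=lambda: {
            "doses": [0.0, 100.0, 200.0, 300.0, 400.0, 500.0],
            "replicates": 3,
            "noise_sd": 0.01,
            "m_ssb_true": 2.0e-3,
            "staining_factor": gelquant.DEFAULT_STAINING_FACTOR,
            "arms": {},
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown top-level keys {sorted(unknown)}")
        base = cls()
        for key, value in raw.items():
            if isinstance(value, dict) and isinstance(getattr(base, key), dict):
                merged = dict(getattr(base, key))
                merged.update(value)
                setattr(base, key, merged)
            else:
                setattr(base, key, value)
        return base

    def validate(self) -> None:
        """Check every stage's parameters before any stage runs."""
        try:
            self._track_config(enhanced=True)
        except Exception as exc:
            raise PipelineError(f"tracks config: {exc}") from exc
        try:
            DamageConfig(**self.damage)
        except Exception as exc:
            raise PipelineError(f"damage config: {exc}") from exc
        if self.phantom.get("n_particles", 0) < 0:
            raise PipelineError("phantom config: n_particles must be >= 0")
        kind = self.duplex.get("kind", "procedural")
        if kind not in ("procedural", "pdb"):
            raise PipelineError(f"duplex config: unknown kind {kind!r}")
        if kind == "pdb" and "path" not in self.duplex:
            raise PipelineError("duplex config: pdb kind requires a path")

    def _track_config(self, enhanced: bool) -> TrackConfig:
        opts = {
            k: v
            for k, v in self.tracks.items()
            if k not in ("target_dose", "n_repeats")
        }
        cfg = TrackConfig(**opts)
        if not enhanced:
            cfg.enhancement_factor = {m: 0.0 for m in cfg.enhancement_factor}
        return cfg

    def _build_duplex(self, phantom: Phantom) -> DuplexGeometry:
        opts = dict(self.duplex)
        kind = opts.pop("kind", "procedural")
        if kind == "pdb":
            return load_pdb(opts["path"], capture_radius=opts.get("capture_radius", 0.35))
        opts.setdefault("n_bp", 120)
        # center the helix axis on the phantom center
        rise = opts.get("rise", 0.34)
        opts.setdefault("origin", (0.0, 0.0, -opts["n_bp"] * rise / 2.0))
        return build_bdna(**opts)


def desk_simulation_config(seed: int = 1) -> PipelineConfig:
    """Scaled study conditions for the simulation arm.

    A tens-of-nanometres phantom (radius ≈ 40 nm) with 12 particles around
    a 120 bp duplex at the centre, scored at a nanodosimetric local dose.
    These sizes make strand-break counts reachable with ~1e5 events while
    preserving the structure of the full-size study (same particle
    geometry, same damage rules).
    """
    cfg = PipelineConfig(seed=seed)
    cfg.phantom = {
        "n_particles": 12,
        "sphere_volume": 4.0 / 3.0 * 3.141592653589793 * 0.04**3,  # r = 40 nm, µm³
        "core_diameter": 3.0,
        "shell_thickness": 2.0,
        "shell_material": "Pt",
    }
    cfg.tracks = {
        # local nanodosimetric dose per repeat; kept low enough that breaks
        # stay sparse on the duplex (dense breaks chain into single large
        # clusters and the one-cluster-one-DSB rule saturates)
        "target_dose": 2.5e5,  # Gy
        "n_repeats": 12,
        "enhancement_factor": {"Au": 1.0, "Pt": 1.2},
        "enhancement_radius": 25.0,
    }
    cfg.duplex = {"kind": "procedural", "n_bp": 120, "capture_radius": 0.5}
    return cfg


def _manifest(cfg: PipelineConfig, extra: dict) -> dict:
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": {
            "phantom": cfg.phantom,
            "tracks": cfg.tracks,
            "duplex": {k: str(v) for k, v in cfg.duplex.items()},
            "damage": cfg.damage,
        },
    }
    manifest.update(extra)
    return manifest


def run_simulation_arm(cfg: PipelineConfig) -> dict:
    """Phantom → tracks → damage for control and NP-loaded arms.

    Returns a report with per-arm SSB/DSB counts, DSB rates
    (Gy⁻¹·Gbp⁻¹ pooled over repeats) and the amplification factor
    (``None`` when the control arm scored no DSBs).
    """
    cfg.validate()
    try:
        phantom = build_phantom(seed=cfg.seed, **cfg.phantom)
    except Exception as exc:
        raise PipelineError(f"phantom stage: {exc}") from exc
    duplex = cfg._build_duplex(phantom)
    damage_cfg = DamageConfig(**cfg.damage)
    target_dose = float(cfg.tracks.get("target_dose", 1.0))
    n_repeats = int(cfg.tracks.get("n_repeats", 1))
    arms = {"control": cfg._track_config(enhanced=False), "np": cfg._track_config(enhanced=True)}

    counts = {name: {"n_ssb": 0, "n_dsb": 0} for name in arms}
    event_seeds = [cfg.seed + 1 + i for i in range(n_repeats)]
    for name, track_cfg in arms.items():
        for event_seed in event_seeds:
            try:
                ps = sample_events(phantom, target_dose, track_cfg, seed=event_seed)
            except Exception as exc:
                raise PipelineError(f"tracks stage ({name} arm): {exc}") from exc
            record = score_damage(ps, duplex, damage_cfg)
            counts[name]["n_ssb"] += record.n_ssb
            counts[name]["n_dsb"] += record.n_dsb

    total_dose = target_dose * n_repeats
    report: dict = {"arms": {}}
    for name in arms:
        n_dsb = counts[name]["n_dsb"]
        report["arms"][name] = {
            "n_ssb": counts[name]["n_ssb"],
            "n_dsb": n_dsb,
            "dsb_rate_per_gy_per_gbp": dsb_rate(n_dsb, total_dose, duplex.n_bp)
            if n_dsb
            else 0.0,
        }
    control_dsb = counts["control"]["n_dsb"]
    np_dsb = counts["np"]["n_dsb"]
    report["af_percent"] = (
        amplification_factor(np_dsb, control_dsb) if control_dsb > 0 else None
    )
    report["manifest"] = _manifest(
        cfg,
        {
            "phantom_seed": cfg.seed,
            "event_seeds": event_seeds,
            "track_config_digest": arms["np"].digest(),
            "total_dose_gy": total_dose,
            "duplex_source": duplex.source,
            "duplex_n_bp": duplex.n_bp,
        },
    )
    _write_report(cfg, report, "simulation_report.json")
    return report


def _arm_lanes(cfg: PipelineConfig, name: str, arm_seed: int) -> list[gelquant.GelLane]:
    gel = cfg.gel
    arms = gel.get("arms", {})
    spec = arms.get(name)
    if spec is None:
        raise PipelineError(f"experimental arm {name!r} missing: provide lanes or truth")
    if isinstance(spec, dict) and "lanes" in spec:
        return gelquant.read_lanes_csv(spec["lanes"])
    truth = spec["truth"] if isinstance(spec, dict) else float(spec)
    return gelquant.synth_gel(
        doses=gel.get("doses", [0.0, 100.0, 200.0, 300.0, 400.0, 500.0]),
        m_dsb_true=float(truth),
        m_ssb_true=float(gel.get("m_ssb_true", 0.0)),
        noise_sd=float(gel.get("noise_sd", 0.0)),
        replicates=int(gel.get("replicates", 3)),
        seed=arm_seed,
        staining_factor=float(gel.get("staining_factor", gelquant.DEFAULT_STAINING_FACTOR)),
    )


def run_experimental_arm(cfg: PipelineConfig) -> tuple[gelquant.AmplificationResult, dict]:
    """Gel quantification for the four-condition scavenger experiment.

    The ``control`` and ``np`` arms are required; the two DMSO arms must
    be provided together or not at all. Each arm is either a lane CSV
    (``{"lanes": path}``) or a generating truth for the synthetic gel
    (a slope in breaks·plasmid⁻¹·Gy⁻¹).
    """
    arms_cfg = cfg.gel.get("arms", {})
    for required in ("control", "np"):
        if required not in arms_cfg:
            raise PipelineError(f"experimental arm {required!r} missing")
    with_dmso = [a for a in ("control_dmso", "np_dmso") if a in arms_cfg]
    if len(with_dmso) == 1:
        missing = ({"control_dmso", "np_dmso"} - set(with_dmso)).pop()
        raise PipelineError(f"experimental arm {missing!r} missing (DMSO arms come in pairs)")

    staining = float(cfg.gel.get("staining_factor", gelquant.DEFAULT_STAINING_FACTOR))
    fits: dict[str, gelquant.DoseResponse] = {}
    for i, name in enumerate(ARM_NAMES):
        if name not in arms_cfg:
            continue
        lanes = _arm_lanes(cfg, name, arm_seed=cfg.seed + 10 + i)
        fits[name] = gelquant.fit_dose_response(lanes, staining_factor=staining)

    result = gelquant.AmplificationResult(
        y_control=fits["control"],
        y_np=fits["np"],
        y_control_dmso=fits.get("control_dmso"),
        y_np_dmso=fits.get("np_dmso"),
    )
    result.af, result.af_se = gelquant.amplification(fits["np"], fits["control"])
    if with_dmso:
        result.af_dmso, result.af_dmso_se = gelquant.amplification(
            fits["np_dmso"], fits["control_dmso"]
        )
        result.oh_effect_control, result.oh_effect_control_se = gelquant.oh_effect(
            fits["control"], fits["control_dmso"]
        )
        result.oh_effect_np, result.oh_effect_np_se = gelquant.oh_effect(
            fits["np"], fits["np_dmso"]
        )

    report = {
        "yields_per_plasmid_per_gy": {
            name: {"slope": fit.slope, "slope_se": fit.slope_se, "intercept": fit.intercept}
            for name, fit in fits.items()
        },
        "af_percent": result.af,
        "af_se": result.af_se,
        "af_dmso_percent": result.af_dmso,
        "af_dmso_se": result.af_dmso_se,
        "oh_effect_control_percent": result.oh_effect_control,
        "oh_effect_np_percent": result.oh_effect_np,
        "manifest": _manifest(cfg, {"gel": {k: v for k, v in cfg.gel.items()}}),
    }
    _write_report(cfg, report, "experimental_report.json")
    return result, report


def _write_report(cfg: PipelineConfig, report: dict, filename: str) -> None:
    if cfg.output_dir is None:
        return
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with (out / filename).open("w") as fh:
        json.dump(report, fh, indent=2, default=str)
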