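"""One-config orchestration of the full analysis workflow.

generate/load → elastic models (+ subsystem overlap + hinges) → PRS →
trajectory statistics → residue network (+ communication pathways),
with every produced file listed in a ``manifest.json`` carrying sha256
hashes and the parameters used.  Reruns with the same config are
bit-identical, so the manifest doubles as a provenance record.

Configs are plain-text ``key = value`` files with ``[section]``
headers (INI syntax); :func:`default_config` prints every default.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import enm, hinges, prs, resnetwork, synth, traj_stats
from .structio import (
    CoarseStructure,
    ResidueSelection,
    Trajectory,
    read_pdb,
    read_selection,
    read_trajectory,
    write_pdb,
    write_reports,
    write_trajectory,
)

logger = logging.getLogger("allodyn.pipeline")

__all__ = ["RunConfig", "PipelineError", "run", "default_config"]

DEFAULTS: dict[str, dict[str, str]] = {
    "input": {"structure": "", "trajectory": "", "selections": ""},
    "synth": {
        "topology": "", "n_residues": "40", "linker": "", "interface_pairs": "3",
        "seed": "1", "sample_trajectory": "true", "n_frames": "300",
        "amplitude": "1.0", "trajectory_seed": "2",
    },
    "enm": {"anm_cutoff": "15", "gnm_cutoff": "10", "gamma": "1.0",
            "n_modes": "10"},
    "hinges": {"mode": "1", "window": "3", "floor": "0.2"},
    "network": {"cutoff": "6.5", "occupancy": "0.5", "source": "", "sink": "",
                "max_paths": "50"},
    "stages": {"enm": "true", "hinges": "true", "prs": "true", "traj": "true",
               "network": "true"},
    "output": {"dir": "allodyn_out"},
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated pipeline configuration (sections of key=value strings)."""

    sections: dict[str, dict[str, str]] = field(default_factory=dict)
    base_dir: Path = Path(".")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        parser = configparser.ConfigParser()
        with open(path) as fh:
            parser.read_file(fh)
        sections = {s: dict(DEFAULTS[s]) for s in DEFAULTS}
        for sec in parser.sections():
            if sec not in sections:
                raise ValueError(f"unknown config section [{sec}]")
            for key, val in parser[sec].items():
                if key not in sections[sec]:
                    raise ValueError(f"unknown config key {key!r} in [{sec}]")
                sections[sec][key] = val
        cfg = cls(sections, path.parent)
        cfg.validate()
        return cfg

    @classmethod
    def from_defaults(cls, **overrides: dict[str, str]) -> "RunConfig":
        sections = {s: dict(DEFAULTS[s]) for s in DEFAULTS}
        for sec, kv in overrides.items():
            sections[sec].update(kv)
        return cls(sections, Path("."))

    def get(self, sec: str, key: str) -> str:
        return self.sections[sec][key]

    def getbool(self, sec: str, key: str) -> bool:
        return self.get(sec, key).strip().lower() in ("1", "true", "yes", "on")

    def path(self, sec: str, key: str) -> Path | None:
        val = self.get(sec, key).strip()
        return (self.base_dir / val) if val else None

    def validate(self) -> None:
        has_structure = bool(self.get("input", "structure").strip())
        has_synth = bool(self.get("synth", "topology").strip())
        if has_structure == has_synth:
            raise ValueError(
                "config must provide exactly one of [input] structure "
                "or [synth] topology"
            )
        for key in ("structure", "trajectory", "selections"):
            p = self.path("input", key)
            if p is not None and not p.is_file():
                raise ValueError(f"[input] {key} file not found: {p}")
        needs_traj = self.getbool("stages", "traj") or self.getbool(
            "stages", "network"
        )
        has_traj = bool(self.get("input", "trajectory").strip()) or (
            has_synth and self.getbool("synth", "sample_trajectory")
        )
        if needs_traj and not has_traj:
            raise ValueError(
                "trajectory-based stages are enabled but no trajectory "
                "input or synthetic sampling is configured"
            )

    def to_dict(self) -> dict:
        return {s: dict(kv) for s, kv in self.sections.items()}


def default_config() -> str:
    """The full default config as INI text."""
    lines = []
    for sec, kv in DEFAULTS.items():
        lines.append(f"[{sec}]")
        lines.extend(f"{k} = {v}" for k, v in kv.items())
        lines.append("")
    return "\n".join(lines)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _synth_spec(cfg: RunConfig) -> synth.SynthSpec:
    linker = cfg.get("synth", "linker").strip()
    linker_range = None
    if linker:
        lo, hi = linker.split(":")
        linker_range = (int(lo), int(hi))
    return synth.SynthSpec(
        n_residues=int(cfg.get("synth", "n_residues")),
        topology=cfg.get("synth", "topology").strip(),
        linker_range=linker_range,
        interface_pairs=int(cfg.get("synth", "interface_pairs")),
        seed=int(cfg.get("synth", "seed")),
    )


def run(config: RunConfig) -> dict:
    """Execute all enabled stages; returns (and writes) the manifest."""
    config.validate()
    out_dir = Path(config.get("output", "dir"))
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": [], "complete": False}

    def record(stage: str, params: dict, files: list[Path]) -> None:
        manifest["stages"].append({
            "stage": stage,
            "params": {k: str(v) for k, v in sorted(params.items())},
            "outputs": [
                {"path": p.name, "sha256": _sha256(p)} for p in sorted(files)
            ],
        })

    def fail(stage: str, exc: Exception):
        _write_manifest(out_dir, manifest, incomplete=stage)
        raise PipelineError(stage, exc) from exc

    # ---- inputs -----------------------------------------------------
    stage = "input"
    try:
        traj: Trajectory | None = None
        if config.get("input", "structure").strip():
            structure = read_pdb(config.path("input", "structure"))
            tpath = config.path("input", "trajectory")
            if tpath is not None:
                traj = traj_stats.superpose(
                    read_trajectory(tpath, structure), reference="mean"
                )
            files: list[Path] = []
            params = {"structure": config.get("input", "structure")}
        else:
            spec = _synth_spec(config)
            structure = synth.make_structure(spec)
            files = [write_pdb(structure, out_dir / "structure.pdb")]
            params = {
                "topology": spec.topology, "n_residues": spec.n_residues,
                "seed": spec.seed,
            }
            if config.getbool("synth", "sample_trajectory"):
                anm_modes = enm.ANM(
                    structure, float(config.get("enm", "anm_cutoff")),
                    float(config.get("enm", "gamma")),
                ).fit()
                traj = synth.sample_enm_trajectory(
                    anm_modes,
                    int(config.get("synth", "n_frames")),
                    float(config.get("synth", "amplitude")),
                    int(config.get("synth", "trajectory_seed")),
                )
                files.append(write_trajectory(traj, out_dir / "trajectory.pdb"))
                params.update(n_frames=traj.n_frames,
                              amplitude=config.get("synth", "amplitude"))
        selections: list[ResidueSelection] = []
        spath = config.path("input", "selections")
        if spath is not None:
            selections = read_selection(spath, structure)
        record(stage, params, files)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        fail(stage, exc)

    labels = structure.labels
    by_label = {sel.label: sel for sel in selections}

    # ---- elastic models and mode comparison -------------------------
    anm_modes = gnm_modes = None
    if config.getbool("stages", "enm"):
        stage = "enm"
        try:
            gamma = float(config.get("enm", "gamma"))
            anm_modes = enm.ANM(
                structure, float(config.get("enm", "anm_cutoff")), gamma
            ).fit()
            gnm_modes = enm.GNM(
                structure, float(config.get("enm", "gnm_cutoff")), gamma
            ).fit()
            out = {
                "anm_eigenvalues": anm_modes.nonzero_eigenvalues,
                "gnm_eigenvalues": gnm_modes.nonzero_eigenvalues,
                "anm_msf": anm_modes.msf(),
                "gnm_msf": gnm_modes.msf(),
            }
            files = write_reports(
                {k: v for k, v in out.items() if "msf" in k}, out_dir, labels
            )
            for name in ("anm_eigenvalues", "gnm_eigenvalues"):
                import pandas as pd

                df = pd.DataFrame({
                    "mode": np.arange(1, len(out[name]) + 1),
                    "eigenvalue": out[name],
                })
                p = out_dir / f"{name}.csv"
                df.to_csv(p, index=False, float_format="%.10g",
                          lineterminator="\n")
                files.append(p)
            params = {
                "anm_cutoff": config.get("enm", "anm_cutoff"),
                "gnm_cutoff": config.get("enm", "gnm_cutoff"),
                "gamma": gamma,
            }
            if "subsystem" in by_label:
                k = int(config.get("enm", "n_modes"))
                sub = by_label["subsystem"]
                reduced = enm.reduce_to_subsystem(anm_modes.model, sub).fit()
                apo = enm.ANM(
                    enm.substructure(structure, sub.sorted()),
                    float(config.get("enm", "anm_cutoff")), gamma,
                ).fit()
                k = min(k, len(apo.nonzero_eigenvalues),
                        len(reduced.nonzero_eigenvalues))
                ov = enm.cumulative_overlap(apo, reduced, k=k)
                files += write_reports(
                    {"overlap_pairs": ov.pair_matrix,
                     "overlap_cumulative": ov.cumulative},
                    out_dir,
                    [str(i + 1) for i in range(k)],
                )
                params["n_modes"] = k
            record(stage, params, files)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            fail(stage, exc)

    # ---- hinge prediction -------------------------------------------
    if config.getbool("stages", "hinges"):
        stage = "hinges"
        try:
            if gnm_modes is None:
                gnm_modes = enm.GNM(
                    structure, float(config.get("enm", "gnm_cutoff")),
                    float(config.get("enm", "gamma")),
                ).fit()
            mode = int(config.get("hinges", "mode"))
            hs = hinges.find_mode_hinges(
                gnm_modes, mode,
                int(config.get("hinges", "window")),
                float(config.get("hinges", "floor")),
            )
            files = write_reports(
                {"hinges": {"mode": mode, "residues": hs.labels(structure)},
                 "hinge_profile": hs.profile},
                out_dir, labels,
            )
            record(stage, {"mode": mode,
                           "window": config.get("hinges", "window"),
                           "floor": config.get("hinges", "floor")}, files)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            fail(stage, exc)

    # ---- perturbation response scanning -----------------------------
    if config.getbool("stages", "prs"):
        stage = "prs"
        try:
            if anm_modes is None:
                anm_modes = enm.ANM(
                    structure, float(config.get("enm", "anm_cutoff")),
                    float(config.get("enm", "gamma")),
                ).fit()
            result = prs.prs_matrix(anm_modes)
            objs = {
                "prs_normalized": result.normalized,
                "prs_effectiveness": result.effectiveness,
                "prs_sensitivity": result.sensitivity,
            }
            files = write_reports(objs, out_dir, labels)
            for sel in selections:
                if sel.label == "subsystem":
                    continue
                table = prs.rank_sites(result, sel)
                p = out_dir / f"prs_ranks_{sel.label}.csv"
                table.to_csv(p, index=False, float_format="%.10g",
                             lineterminator="\n")
                files.append(p)
            record(stage, {}, files)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            fail(stage, exc)

    # ---- trajectory statistics --------------------------------------
    if config.getbool("stages", "traj"):
        stage = "traj"
        try:
            assert traj is not None
            files = write_reports({
                "rmsf": traj_stats.rmsf(traj),
                "dccm": traj_stats.dccm(traj).matrix,
            }, out_dir, labels)
            import pandas as pd

            p = out_dir / "rmsd.csv"  # per frame, not per residue
            pd.DataFrame({
                "frame": np.arange(traj.n_frames),
                "rmsd": traj_stats.rmsd_series(traj),
            }).to_csv(p, index=False, float_format="%.10g", lineterminator="\n")
            files.append(p)
            record(stage, {"n_frames": traj.n_frames}, files)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            fail(stage, exc)

    # ---- residue network --------------------------------------------
    if config.getbool("stages", "network"):
        stage = "network"
        try:
            assert traj is not None
            net = resnetwork.build_network(
                traj, structure,
                float(config.get("network", "cutoff")),
                float(config.get("network", "occupancy")),
            )
            objs: dict[str, object] = {"bc": resnetwork.betweenness(net)}
            params = {
                "cutoff": config.get("network", "cutoff"),
                "occupancy": config.get("network", "occupancy"),
            }
            source = config.get("network", "source").strip()
            sink = config.get("network", "sink").strip()
            if source and sink:
                paths = resnetwork.shortest_paths(
                    net, source, sink, int(config.get("network", "max_paths"))
                )
                objs["paths"] = [p.to_dict() for p in paths]
                params.update(source=source, sink=sink)
            files = write_reports(objs, out_dir, labels)
            record(stage, params, files)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            fail(stage, exc)

    manifest["complete"] = True
    _write_manifest(out_dir, manifest)
    return manifest


def _write_manifest(out_dir: Path, manifest: dict, incomplete: str | None = None):
    if incomplete is not None:
        manifest = dict(manifest, complete=False, failed_stage=incomplete)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
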