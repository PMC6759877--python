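"""Plain-text file formats: trajectories, manifests, silhouettes, configs.

Trajectories are tab-separated text with a header row: column 1 is the time
``t``, followed by the 20 articulatory or 12 acoustic coordinate columns, one
trajectory per file.  Values are written with 17 significant digits so a
write/read round trip is bit-exact.  A manifest is a JSON document listing
linked motor/perceptual file pairs (and optional exemplar entries), from
which a perceptual-motor map can be reconstructed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .matching import Exemplar, SalienceFn
from .phonforms import Silhouette
from .pm_map import PerceptualMotorMap
from .spaces import ARTIC_FIELDS, SOUND_FIELDS, ValidationError
from .trajectories import MotorTrajectory, PerceptualTrajectory
from .devsim import SimConfig

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_manifest",
    "write_manifest",
    "write_silhouette",
    "load_config",
    "dump_config",
]


class ParseError(ValidationError):
    """Malformed input file; message includes the offending line number."""


def write_trajectory(traj, path) -> None:
    path = Path(path)
    fields = ARTIC_FIELDS if isinstance(traj, MotorTrajectory) else SOUND_FIELDS
    with path.open("w") as fh:
        fh.write("t\t" + "\t".join(fields) + "\n")
        for t, row in zip(traj.times, traj.values):
            fh.write("\t".join(f"{x:.17g}" for x in (t, *row)) + "\n")


def read_trajectory(path, kind: str | None = None, id: str = ""):
    """Read a trajectory file; ``kind`` is 'motor', 'perceptual' or inferred."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    ncols = len(header) - 1
    if kind is None:
        kind = {20: "motor", 12: "perceptual"}.get(ncols)
        if kind is None:
            raise ParseError(
                f"{path}:1: expected 20 (motor) or 12 (perceptual) value columns, got {ncols}"
            )
    expected = 20 if kind == "motor" else 12
    if ncols != expected:
        raise ParseError(f"{path}:1: expected {expected} value columns, got {ncols}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != expected + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {expected + 1} columns, got {len(parts)}"
            )
        try:
            rows.append([float(x) for x in parts])
        except ValueError as e:
            raise ParseError(f"{path}:{lineno}: {e}") from None
    data = np.asarray(rows)
    times, values = data[:, 0], data[:, 1:]
    if np.any(np.diff(times) <= 0):
        raise ParseError(f"{path}: time column must be strictly increasing")
    cls = MotorTrajectory if kind == "motor" else PerceptualTrajectory
    try:
        return cls(times=times, values=values, id=id)
    except ValidationError as e:
        raise ParseError(f"{path}: {e}") from None


def write_manifest(pm: PerceptualMotorMap, directory, exemplars=None) -> Path:
    """Write every trajectory of a map plus a manifest.json into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for mid, pid in pm.pairs:
        mf, pf = f"{mid}.tsv", f"{pid}.tsv"
        write_trajectory(pm.motor[mid], directory / mf)
        write_trajectory(pm.perceptual[pid], directory / pf)
        entries.append(
            {
                "motor_id": mid,
                "perceptual_id": pid,
                "motor_file": mf,
                "perceptual_file": pf,
                "syllables": pm.perceptual[pid].syllables,
            }
        )
    ex_entries = []
    for ex in exemplars or []:
        f = f"{ex.trajectory.id}.tsv"
        write_trajectory(ex.trajectory, directory / f)
        t, v = ex.salience.sampled(len(ex.trajectory.times))
        ex_entries.append(
            {
                "id": ex.trajectory.id,
                "file": f,
                "concept": ex.concept,
                "salience_times": list(map(float, t)),
                "salience_values": list(map(float, v)),
            }
        )
    manifest = directory / "manifest.json"
    manifest.write_text(json.dumps({"pairs": entries, "exemplars": ex_entries}, indent=1))
    return manifest


def read_manifest(manifest_path) -> tuple[PerceptualMotorMap, list[Exemplar]]:
    """Rebuild a perceptual-motor map (and exemplars) from a manifest."""
    manifest_path = Path(manifest_path)
    doc = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    pm = PerceptualMotorMap()
    for e in doc.get("pairs", []):
        m = read_trajectory(base / e["motor_file"], "motor", id=e["motor_id"])
        p = read_trajectory(base / e["perceptual_file"], "perceptual", id=e["perceptual_id"])
        if e.get("syllables") is not None:
            p = dataclasses.replace(p, syllables=int(e["syllables"]))
        pm.motor[e["motor_id"]] = m
        pm.perceptual[e["perceptual_id"]] = p
        pm._partner[e["motor_id"]] = e["perceptual_id"]
        pm._partner[e["perceptual_id"]] = e["motor_id"]
        pm._counter += 1
    if not pm.check_bijection():
        raise ParseError(f"{manifest_path}: manifest pairs do not form a bijection")
    exemplars = []
    for e in doc.get("exemplars", []):
        p = read_trajectory(base / e["file"], "perceptual", id=e["id"])
        sal = SalienceFn.from_samples(
            np.asarray(e["salience_times"]), np.asarray(e["salience_values"])
        )
        exemplars.append(Exemplar(trajectory=p, concept=e["concept"], salience=sal))
    return pm, exemplars


def write_silhouette(sil: Silhouette, path) -> None:
    """Per-time vertex blocks in tabular text."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# concept={sil.concept} n={sil.n} domain_end={sil.domain_end:.17g}\n")
        fh.write("t\tvertex\t" + "\t".join(ARTIC_FIELDS) + "\n")
        for t, region in zip(sil.times, sil.regions):
            for vi, vert in enumerate(region):
                coords = "\t".join(f"{x:.17g}" for x in vert)
                fh.write(f"{t:.17g}\t{vi}\t{coords}\n")


def load_config(path) -> SimConfig:
    """Load and validate a run configuration from YAML (unknown keys rejected)."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    return SimConfig(**doc)


def dump_config(cfg: SimConfig, path) -> None:
    """Write the fully materialized configuration (all defaults resolved)."""
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))
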