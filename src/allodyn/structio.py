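"""Coarse-grained structure and trajectory I/O.

One node per residue: the Cα position, plus the Cβ position where the
side chain provides one (glycine has none).  Structures and trajectories
are exchanged as standard PDB ATOM records (``MODEL``/``ENDMDL`` for
multi-frame files) or, for trajectories, as plain whitespace-separated
``x y z`` frame blocks.  Internally residues are addressed by 0-based
index; every user-facing file uses ``chain:resnum`` labels so that
multi-chain complexes are addressed unambiguously.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

logger = logging.getLogger("allodyn.structio")

__all__ = [
    "ResidueKey",
    "CoarseStructure",
    "ResidueSelection",
    "Trajectory",
    "read_pdb",
    "read_trajectory",
    "read_selection",
    "write_pdb",
    "write_trajectory",
    "write_selection",
    "write_reports",
]


class ResidueKey(NamedTuple):
    """Identity of one residue: chain id, residue number, 3-letter name."""

    chain_id: str
    res_number: int
    res_name: str
    icode: str = ""

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.res_number}{self.icode}"


@dataclass
class CoarseStructure:
    """A multi-chain protein reduced to one Cα (and optional Cβ) per residue.

    Parameters
    ----------
    residues
        Ordered residue identities; ``(chain_id, res_number)`` pairs must
        be unique (insertion codes keep otherwise-duplicate numbers apart).
    ca_coords
        ``(N, 3)`` array of Cα positions in Å.
    cb_coords
        ``(N, 3)`` array of Cβ positions in Å; rows of NaN mark residues
        without a Cβ (glycine convention).
    """

    residues: list[ResidueKey]
    ca_coords: np.ndarray
    cb_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        n = len(self.residues)
        if n < 2:
            raise ValueError("a coarse structure needs at least 2 residues")
        if self.ca_coords.shape != (n, 3):
            raise ValueError(
                f"ca_coords shape {self.ca_coords.shape} does not match "
                f"{n} residues"
            )
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError("non-finite Cα coordinates")
        if self.cb_coords is None:
            self.cb_coords = np.full((n, 3), np.nan)
        else:
            self.cb_coords = np.asarray(self.cb_coords, dtype=float)
            if self.cb_coords.shape != (n, 3):
                raise ValueError("cb_coords shape does not match residue count")
        keys = [(r.chain_id, r.res_number, r.icode) for r in self.residues]
        if len(set(keys)) != n:
            raise ValueError("duplicate (chain, residue number) pairs")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.residues]

    @property
    def chain_ids(self) -> np.ndarray:
        return np.array([r.chain_id for r in self.residues])

    @property
    def has_cb(self) -> np.ndarray:
        """Boolean mask of residues carrying a Cβ."""
        return np.all(np.isfinite(self.cb_coords), axis=1)

    def node_coords(self) -> np.ndarray:
        """Cβ position per residue, falling back to Cα where absent."""
        coords = np.where(self.has_cb[:, None], self.cb_coords, self.ca_coords)
        return coords

    def index_of(self, label: str) -> int:
        """Resolve a ``chain:resnum`` label to a 0-based residue index."""
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no residue labelled {label!r}") from None

    def chain_slices(self) -> dict[str, slice]:
        """Contiguous index range of each chain, in file order."""
        out: dict[str, slice] = {}
        start = 0
        for i in range(1, self.n_residues + 1):
            if i == self.n_residues or (
                self.residues[i].chain_id != self.residues[start].chain_id
            ):
                out[self.residues[start].chain_id] = slice(start, i)
                start = i
        return out


@dataclass
class ResidueSelection:
    """A labelled set of residue indices (mutation sites, subsystem, ...)."""

    indices: frozenset[int]
    label: str = "selection"

    def __post_init__(self) -> None:
        self.indices = frozenset(int(i) for i in self.indices)
        if not self.indices:
            raise ValueError("empty residue selection")
        if min(self.indices) < 0:
            raise ValueError("negative residue index in selection")

    @classmethod
    def from_labels(
        cls, labels: Iterable[str], structure: CoarseStructure, label: str = "selection"
    ) -> "ResidueSelection":
        return cls(frozenset(structure.index_of(x) for x in labels), label)

    def sorted(self) -> list[int]:
        return sorted(self.indices)

    def validate(self, structure: CoarseStructure) -> None:
        if max(self.indices) >= structure.n_residues:
            raise ValueError("selection index out of range for structure")


@dataclass
class Trajectory:
    """Frames × residues × 3 coordinate array tied to a structure."""

    frames: np.ndarray
    structure_ref: CoarseStructure
    aligned: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, N, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if self.frames.shape[1] != self.structure_ref.n_residues:
            raise ValueError(
                f"trajectory residue count {self.frames.shape[1]} does not "
                f"match structure ({self.structure_ref.n_residues})"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite trajectory coordinates")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_residues(self) -> int:
        return self.frames.shape[1]


# ---------------------------------------------------------------------------
# readers


def _parse_models(path: Path):
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure(path.stem, str(path))
    return list(structure.get_models())


def read_pdb(path: str | Path, atom_mode: str = "CA+CB") -> CoarseStructure:
    """Read a coarse structure from PDB ATOM records.

    One entry per residue per chain, in file order.  Residues without a
    Cα are skipped with a logged warning; a missing Cβ is recorded as
    missing (the glycine convention).  ``atom_mode`` is ``"CA-only"`` or
    ``"CA+CB"``.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"cannot read PDB file: {path}")
    if atom_mode not in ("CA-only", "CA+CB"):
        raise ValueError(f"unknown atom_mode {atom_mode!r}")
    models = _parse_models(path)
    if not models:
        raise ValueError(f"no models found in {path}")
    residues: list[ResidueKey] = []
    ca: list[np.ndarray] = []
    cb: list[np.ndarray] = []
    for chain in models[0]:
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag.strip():
                continue  # hetero atoms / waters are out of scope
            if "CA" not in res:
                logger.warning(
                    "residue %s:%s%s (%s) has no CA atom; skipped",
                    chain.id, resseq, icode.strip(), res.get_resname(),
                )
                continue
            residues.append(
                ResidueKey(chain.id, int(resseq), res.get_resname(), icode.strip())
            )
            ca.append(np.asarray(res["CA"].get_coord(), dtype=float))
            if atom_mode == "CA+CB" and "CB" in res:
                cb.append(np.asarray(res["CB"].get_coord(), dtype=float))
            else:
                cb.append(np.full(3, np.nan))
    if not residues:
        raise ValueError(f"no parsable residues with CA atoms in {path}")
    return CoarseStructure(residues, np.array(ca), np.array(cb))


def _read_plain_frames(path: Path) -> np.ndarray:
    """Plain-text trajectory: ``x y z`` rows, frames split by blank lines."""
    blocks: list[list[list[float]]] = [[]]
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            if blocks[-1]:
                blocks.append([])
            continue
        blocks[-1].append([float(tok) for tok in line.split()[:3]])
    if not blocks[-1]:
        blocks.pop()
    if not blocks:
        raise ValueError(f"no coordinate frames in {path}")
    lengths = {len(b) for b in blocks}
    if len(lengths) > 1:
        bad = next(i for i, b in enumerate(blocks) if len(b) != len(blocks[0]))
        raise ValueError(
            f"frame {bad} has {len(blocks[bad])} residues, expected {len(blocks[0])}"
        )
    return np.asarray(blocks, dtype=float)


def read_trajectory(path: str | Path, structure: CoarseStructure) -> Trajectory:
    """Read a Cα trajectory (multi-model PDB or plain frame blocks).

    Frames keep file order and the result is flagged unaligned.  A frame
    whose atom count disagrees with the structure raises, naming the
    offending 0-based frame index.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"cannot read trajectory file: {path}")
    head = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                head = line
                break
    if head[:6].rstrip() in ("ATOM", "MODEL", "HEADER", "REMARK", "CRYST1", "TITLE"):
        frames = []
        for f, model in enumerate(_parse_models(path)):
            coords = [
                np.asarray(res["CA"].get_coord(), dtype=float)
                for chain in model
                for res in chain
                if not res.id[0].strip() and "CA" in res
            ]
            if len(coords) != structure.n_residues:
                raise ValueError(
                    f"frame {f} has {len(coords)} residues, expected "
                    f"{structure.n_residues}"
                )
            frames.append(coords)
        arr = np.asarray(frames, dtype=float)
    else:
        arr = _read_plain_frames(path)
        if arr.shape[1] != structure.n_residues:
            bad = 0
            raise ValueError(
                f"frame {bad} has {arr.shape[1]} residues, expected "
                f"{structure.n_residues}"
            )
    return Trajectory(arr, structure, aligned=False)


def read_selection(
    path: str | Path, structure: CoarseStructure, default_label: str = "site"
) -> list[ResidueSelection]:
    """Read residue selections: one ``chain:resnum[:label]`` per line.

    Lines sharing a label are merged into one :class:`ResidueSelection`;
    ``#`` starts a comment.  Selections are returned in first-appearance
    order of their labels.
    """
    path = Path(path)
    groups: dict[str, set[int]] = {}
    order: list[str] = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split(":")
        if len(parts) < 2:
            raise ValueError(f"malformed selection line: {raw!r}")
        label = parts[2] if len(parts) > 2 else default_label
        idx = structure.index_of(f"{parts[0]}:{parts[1]}")
        groups.setdefault(label, set()).add(idx)
        if label not in order:
            order.append(label)
    if not groups:
        raise ValueError(f"no selections in {path}")
    return [ResidueSelection(frozenset(groups[lab]), lab) for lab in order]


# ---------------------------------------------------------------------------
# writers

_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:<4s}{altloc:1s}{resname:>3s} {chain:1s}"
    "{resseq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def _atom_line(serial, name, res: ResidueKey, xyz, element) -> str:
    return _ATOM_FMT.format(
        serial=serial, name=f" {name:<3s}", altloc=" ", resname=res.res_name,
        chain=res.chain_id, resseq=res.res_number, icode=res.icode or " ",
        x=xyz[0], y=xyz[1], z=xyz[2], occ=1.00, b=0.00, element=name[0],
    )


def _frame_lines(structure: CoarseStructure, coords: np.ndarray) -> list[str]:
    lines = []
    serial = 0
    has_cb = structure.has_cb
    for i, res in enumerate(structure.residues):
        serial += 1
        lines.append(_atom_line(serial, "CA", res, coords[i], "C"))
        if has_cb[i]:
            serial += 1
            lines.append(_atom_line(serial, "CB", res, structure.cb_coords[i], "C"))
    return lines


def write_pdb(structure: CoarseStructure, path: str | Path) -> Path:
    """Write a coarse structure as fixed-width PDB ATOM records (%8.3f)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.writelines(_frame_lines(structure, structure.ca_coords))
        fh.write("END\n")
    return path


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write a trajectory as a multi-model PDB (Cα records only)."""
    path = Path(path)
    s = traj.structure_ref
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:>4d}\n")
            for i, res in enumerate(s.residues):
                fh.write(_atom_line(i + 1, "CA", res, traj.frames[f, i], "C"))
            fh.write("ENDMDL\n")
        fh.write("END\n")
    return path


def write_selection(
    selections: Sequence[ResidueSelection], structure: CoarseStructure, path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for sel in selections:
            for i in sel.sorted():
                fh.write(f"{structure.labels[i]}:{sel.label}\n")
    return path


def write_reports(
    objects: Mapping[str, object],
    out_dir: str | Path,
    labels: Sequence[str] | None = None,
) -> list[Path]:
    """Write analysis results as deterministic CSV / JSON files.

    2-D arrays become label-indexed CSV matrices, 1-D arrays two-column
    ``residue,value`` CSV profiles, DataFrames plain CSV, and anything
    else (path lists, dicts) JSON.  Identical inputs produce byte-identical
    files, so reruns can be compared by hash.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        for name, obj in objects.items():
            if isinstance(obj, pd.DataFrame):
                p = out_dir / f"{name}.csv"
                obj.to_csv(p, index=False, float_format="%.10g", lineterminator="\n")
            elif isinstance(obj, np.ndarray) and obj.ndim == 2:
                p = out_dir / f"{name}.csv"
                lab = list(labels) if labels is not None else [
                    str(i) for i in range(obj.shape[0])
                ]
                df = pd.DataFrame(obj, index=lab, columns=lab[: obj.shape[1]])
                df.to_csv(p, index_label="residue", float_format="%.10g",
                          lineterminator="\n")
            elif isinstance(obj, np.ndarray):
                p = out_dir / f"{name}.csv"
                lab = list(labels) if labels is not None else [
                    str(i) for i in range(len(obj))
                ]
                df = pd.DataFrame({"residue": lab, "value": obj})
                df.to_csv(p, index=False, float_format="%.10g", lineterminator="\n")
            else:
                p = out_dir / f"{name}.json"
                with open(p, "w") as fh:
                    json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)
                    fh.write("\n")
            written.append(p)
        return written
    except OSError as exc:
        raise IOError(f"cannot write reports under {out_dir}: {exc}") from exc


def _jsonable(obj):
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj)!r}")
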