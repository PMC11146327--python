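"""Landmark data containers and I/O in TPS (TpsDig dialect) and wide-CSV form.

A TPS record looks like::

    LM=3
    0.0 0.0
    1.0 1.0
    2.0 0.0
    IMAGE=fish001.jpg
    ID=MUPA-LH-545a
    SCALE=0.01

``SCALE`` (units per pixel), when present, is multiplied into the coordinates
on read so that in-memory coordinates are always in physical units; it is not
re-emitted on write.  Keys are matched case-insensitively; unknown keys are
ignored with a logged warning.  Landmark indices are 1-based in all
user-facing interfaces and converted to 0-based internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, StructuralError

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkConfiguration",
    "Dataset",
    "read_tps",
    "write_tps",
    "read_table",
    "write_table",
    "average_replicates",
]


@dataclass
class LandmarkConfiguration:
    """One specimen: ``p`` ordered 2D landmarks plus identifying metadata.

    Parameters
    ----------
    specimen_id : str
        Unique specimen label (TPS ``ID=``, falling back to ``IMAGE=``).
    coords : (p, 2) float array
        Landmark coordinates in consistent physical units (scale already
        applied).
    scale : float, optional
        Units-per-pixel factor that was applied on read, kept for provenance.
    species : str, optional
        Species label.
    replicate : int, optional
        Digitization-replicate number.
    """

    specimen_id: str
    coords: np.ndarray
    scale: float | None = None
    species: str | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise StructuralError(
                f"{self.specimen_id!r}: coords must be (p, 2), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 3:
            raise StructuralError(
                f"{self.specimen_id!r}: need at least 3 landmarks, got {self.coords.shape[0]}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructuralError(f"{self.specimen_id!r}: non-finite coordinates")
        if self.scale is not None and self.scale <= 0:
            raise StructuralError(f"{self.specimen_id!r}: scale must be > 0")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    def with_coords(self, coords: np.ndarray) -> "LandmarkConfiguration":
        """Copy of this configuration with new coordinates."""
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class Dataset:
    """A list of configurations sharing one landmark scheme."""

    configurations: list[LandmarkConfiguration] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.configurations:
            p = self.configurations[0].n_landmarks
            for c in self.configurations:
                if c.n_landmarks != p:
                    raise StructuralError(
                        f"landmark count mismatch: {c.specimen_id!r} has "
                        f"{c.n_landmarks}, expected {p}"
                    )

    @property
    def n_specimens(self) -> int:
        return len(self.configurations)

    @property
    def n_landmarks(self) -> int:
        if not self.configurations:
            raise StructuralError("empty dataset has no landmark count")
        return self.configurations[0].n_landmarks

    def __iter__(self):
        return iter(self.configurations)

    def __len__(self) -> int:
        return len(self.configurations)

    def __getitem__(self, i):
        return self.configurations[i]

    def coords_array(self) -> np.ndarray:
        """Stacked (n, p, 2) coordinate array."""
        return np.stack([c.coords for c in self.configurations])

    def ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def species(self) -> list[str | None]:
        return [c.species for c in self.configurations]


_KNOWN_KEYS = {"LM", "IMAGE", "ID", "SCALE"}


def _parse_records(lines: Iterable[str]):
    """Split raw TPS lines into per-record dictionaries (generator)."""
    record: dict | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        key, sep, value = line.partition("=")
        if sep and key.strip().upper() in _KNOWN_KEYS:
            key = key.strip().upper()
            value = value.strip()
            if key == "LM":
                if record is not None:
                    yield record
                try:
                    count = int(value)
                except ValueError:
                    raise ParseError(f"line {lineno}: bad LM count {value!r}") from None
                record = {"lm": count, "coords": [], "start": lineno}
            else:
                if record is None:
                    raise ParseError(f"line {lineno}: {key}= before any LM= record")
                record[key.lower()] = value
        elif sep and record is not None and not _looks_numeric(line):
            logger.warning("line %d: ignoring unknown TPS key %r", lineno, key.strip())
        else:
            if record is None:
                raise ParseError(f"line {lineno}: coordinate data before any LM= record")
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(
                    f"line {lineno}: expected 2 coordinates, got {len(parts)}"
                )
            try:
                record["coords"].append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric coordinate {line!r}") from None
    if record is not None:
        yield record


def _looks_numeric(line: str) -> bool:
    try:
        [float(tok) for tok in line.split()]
        return True
    except ValueError:
        return False


def read_tps(path: str | Path) -> Dataset:
    """Read a TPS file into a :class:`Dataset`.

    ``SCALE=`` is multiplied into coordinates; ``ID=`` is preferred over
    ``IMAGE=`` for the specimen id; landmark order is preserved exactly.

    Raises
    ------
    ParseError
        If an LM count disagrees with the number of coordinate lines, or a
        coordinate is non-numeric.
    StructuralError
        If records carry differing numbers of landmarks.
    """
    path = Path(path)
    configs: list[LandmarkConfiguration] = []
    with path.open() as fh:
        for idx, rec in enumerate(_parse_records(fh)):
            if len(rec["coords"]) != rec["lm"]:
                raise ParseError(
                    f"record {idx + 1} (line {rec['start']}): LM={rec['lm']} but "
                    f"{len(rec['coords'])} coordinate lines"
                )
            coords = np.asarray(rec["coords"], dtype=float)
            scale = None
            if "scale" in rec:
                try:
                    scale = float(rec["scale"])
                except ValueError:
                    raise ParseError(
                        f"record {idx + 1}: non-numeric SCALE {rec['scale']!r}"
                    ) from None
                coords = coords * scale
            specimen_id = rec.get("id") or rec.get("image") or f"record_{idx + 1}"
            configs.append(
                LandmarkConfiguration(specimen_id=specimen_id, coords=coords, scale=scale)
            )
    return Dataset(configs)


def write_tps(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset as TPS records readable by :func:`read_tps`.

    Coordinates are serialized with 12 significant digits; SCALE is not
    re-emitted (in-memory coordinates are already physical).
    """
    if dataset.n_specimens == 0:
        raise StructuralError("refusing to write an empty dataset")
    path = Path(path)
    with path.open("w") as fh:
        for c in dataset:
            fh.write(f"LM={c.n_landmarks}\n")
            for x, y in c.coords:
                fh.write(f"{x:.12g} {y:.12g}\n")
            fh.write(f"ID={c.specimen_id}\n")


def _coord_columns(p: int) -> list[str]:
    cols: list[str] = []
    for i in range(1, p + 1):
        cols += [f"x{i}", f"y{i}"]
    return cols


def read_table(path: str | Path) -> Dataset:
    """Read a wide CSV (columns ``id, species, x1, y1, ..., xp, yp``)."""
    df = pd.read_csv(path)
    coord_cols = [c for c in df.columns if c[0] in "xy" and c[1:].isdigit()]
    if not coord_cols:
        raise ParseError(f"{path}: no coordinate columns (x1, y1, ...)")
    if len(coord_cols) % 2:
        raise ParseError(f"{path}: odd number of coordinate columns")
    p = len(coord_cols) // 2
    expected = _coord_columns(p)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing coordinate columns {missing}")
    configs = []
    for _, row in df.iterrows():
        coords = row[expected].to_numpy(dtype=float).reshape(p, 2)
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(row["id"]),
                coords=coords,
                species=(str(row["species"]) if "species" in df.columns
                         and pd.notna(row.get("species")) else None),
            )
        )
    return Dataset(configs)


def write_table(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset as the wide CSV accepted by :func:`read_table`."""
    if dataset.n_specimens == 0:
        raise StructuralError("refusing to write an empty dataset")
    p = dataset.n_landmarks
    rows = []
    for c in dataset:
        row: dict = {"id": c.specimen_id, "species": c.species}
        for i in range(p):
            row[f"x{i + 1}"] = c.coords[i, 0]
            row[f"y{i + 1}"] = c.coords[i, 1]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def average_replicates(replicates: Sequence[Dataset]) -> Dataset:
    """Average repeated digitizations of the same specimens landmark-wise.

    Every specimen id must appear in every replicate dataset; per specimen and
    landmark the arithmetic mean of the replicate coordinates is taken.
    Metadata comes from the first replicate.
    """
    if not replicates:
        raise StructuralError("no replicate datasets given")
    first = replicates[0]
    p = first.n_landmarks
    for r in replicates[1:]:
        if r.n_landmarks != p:
            raise StructuralError(
                f"landmark count mismatch across replicates: {r.n_landmarks} vs {p}"
            )
    id_sets = [set(r.ids()) for r in replicates]
    common = set.intersection(*id_sets)
    union = set.union(*id_sets)
    if union - common:
        raise StructuralError(
            "specimen ids present in some replicates only: "
            + ", ".join(sorted(union - common))
        )
    by_id = [{c.specimen_id: c for c in r} for r in replicates]
    out = []
    for c in first:
        stack = np.stack([d[c.specimen_id].coords for d in by_id])
        out.append(replace(c, coords=stack.mean(axis=0), replicate=None))
    return Dataset(out)
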