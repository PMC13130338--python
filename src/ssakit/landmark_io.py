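"""Landmark data model and readers/writers for the tpsDig TPS dialect and CSV.

The TPS dialect honored here consists of records of the form::

    LM=<k>
    <x> <y>          (k coordinate lines)
    IMAGE=<path>     (optional)
    ID=<label>       (optional)
    SCALE=<factor>   (optional; coordinates are multiplied by it on read)

Unknown ``KEY=value`` lines are ignored with a logged warning.  Landmark
indices are 1-based in files and reports, 0-based internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkConfiguration",
    "LandmarkSample",
    "TPSParseError",
    "ValidationError",
    "read_tps",
    "write_tps",
    "read_csv_landmarks",
]


class TPSParseError(ValueError):
    """Raised when a TPS file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when landmark data violate structural invariants."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen's k x 2 landmark coordinate matrix.

    Coordinates are stored post-scale: if ``scale`` is present, ``coords``
    have already been multiplied by it.
    """

    specimen_id: str
    coords: np.ndarray
    scale: float | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: coords must be k x 2, got {coords.shape}"
            )
        if coords.shape[0] < 3:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: need at least 3 landmarks, got {coords.shape[0]}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValidationError(
                f"specimen {self.specimen_id!r}: non-finite coordinate present"
            )
        if self.scale is not None and not self.scale > 0:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: scale must be positive, got {self.scale}"
            )
        object.__setattr__(self, "coords", coords)

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class LandmarkSample:
    """An ordered, homogeneous collection of configurations (one group)."""

    group_label: str
    configurations: tuple[LandmarkConfiguration, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        configs = tuple(self.configurations)
        if not configs:
            raise ValidationError(f"sample {self.group_label!r} is empty")
        k = configs[0].k
        for c in configs:
            if c.k != k:
                raise ValidationError(
                    f"sample {self.group_label!r}: specimen {c.specimen_id!r} has "
                    f"k={c.k}, expected {k}"
                )
        ids = [c.specimen_id for c in configs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(
                f"sample {self.group_label!r}: duplicate specimen ids {dupes}"
            )
        object.__setattr__(self, "configurations", configs)

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    @property
    def k(self) -> int:
        return self.configurations[0].k

    @property
    def n(self) -> int:
        return len(self.configurations)

    def coords_array(self) -> np.ndarray:
        """All configurations stacked as an n x k x 2 array."""
        return np.stack([c.coords for c in self.configurations])

    @classmethod
    def from_array(
        cls,
        group_label: str,
        coords: np.ndarray,
        specimen_ids: Sequence[str] | None = None,
    ) -> "LandmarkSample":
        coords = np.asarray(coords, dtype=float)
        if specimen_ids is None:
            specimen_ids = [str(i) for i in range(coords.shape[0])]
        configs = [
            LandmarkConfiguration(specimen_id=sid, coords=c)
            for sid, c in zip(specimen_ids, coords)
        ]
        return cls(group_label=group_label, configurations=tuple(configs))


_KNOWN_KEYS = {"LM", "IMAGE", "ID", "SCALE"}


def read_tps(path: str | Path, group_label: str | None = None) -> LandmarkSample:
    """Read a TPS landmark file into a :class:`LandmarkSample`.

    Parameters
    ----------
    path
        Path to a TPS text file.
    group_label
        Label for the returned sample; defaults to the file stem.

    Raises
    ------
    TPSParseError
        On truncated records or non-numeric coordinates.
    ValidationError
        If records disagree on landmark count.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    record_index = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TPSParseError(
                f"{path}: line {i + 1}: expected 'LM=' record start, got {line!r}"
            )
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(f"{path}: line {i + 1}: bad landmark count {line!r}") from exc
        i += 1
        pts: list[tuple[float, float]] = []
        while len(pts) < k and i < len(lines):
            raw = lines[i].strip()
            if not raw:
                i += 1
                continue
            if "=" in raw and not _looks_numeric(raw.split()[0]):
                break  # a KEY=value line terminates the coordinate block early
            parts = raw.split()
            if len(parts) != 2:
                raise TPSParseError(
                    f"{path}: line {i + 1}: expected two coordinates, got {raw!r}"
                )
            try:
                pts.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise TPSParseError(
                    f"{path}: line {i + 1}: non-numeric coordinate in {raw!r}"
                ) from exc
            i += 1
        if len(pts) < k:
            raise TPSParseError(
                f"{path}: record {record_index}: declared LM={k} but found only "
                f"{len(pts)} coordinate lines"
            )
        specimen_id: str | None = None
        scale: float | None = None
        while i < len(lines):
            raw = lines[i].strip()
            if not raw:
                i += 1
                continue
            if raw.upper().startswith("LM="):
                break
            if "=" not in raw:
                raise TPSParseError(
                    f"{path}: line {i + 1}: unexpected content {raw!r} between records"
                )
            key, _, value = raw.partition("=")
            key_u = key.strip().upper()
            if key_u == "ID":
                specimen_id = value.strip()
            elif key_u == "SCALE":
                try:
                    scale = float(value)
                except ValueError as exc:
                    raise TPSParseError(
                        f"{path}: line {i + 1}: non-numeric SCALE {value!r}"
                    ) from exc
            elif key_u == "IMAGE":
                pass
            elif key_u not in _KNOWN_KEYS:
                logger.warning("%s: line %d: ignoring unknown key %r", path, i + 1, key)
            i += 1
        coords = np.asarray(pts, dtype=float)
        if scale is not None:
            coords = coords * scale
        configs.append(
            LandmarkConfiguration(
                specimen_id=specimen_id if specimen_id is not None else str(record_index),
                coords=coords,
                scale=scale,
            )
        )
        record_index += 1
    return LandmarkSample(
        group_label=group_label if group_label is not None else path.stem,
        configurations=tuple(configs),
    )


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_tps(sample: LandmarkSample, path: str | Path) -> None:
    """Write a sample as TPS records readable by :func:`read_tps`.

    Coordinates are written with 6 decimal places; SCALE is not emitted
    (coordinates are stored post-scale), so the round-trip is the identity
    on coordinates to within 1e-6.
    """
    path = Path(path)
    out: list[str] = []
    for config in sample:
        out.append(f"LM={config.k}")
        for x, y in config.coords:
            out.append(f"{x:.6f} {y:.6f}")
        out.append(f"ID={config.specimen_id}")
    path.write_text("\n".join(out) + "\n")


def read_csv_landmarks(path: str | Path, group_label: str | None = None) -> LandmarkSample:
    """Read long-format CSV with columns specimen_id, landmark_index, x, y.

    ``landmark_index`` is 1-based; each specimen must carry the complete,
    duplicate-free index set 1..k.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"specimen_id", "landmark_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    k = int(df["landmark_index"].max())
    configs: list[LandmarkConfiguration] = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        idx = grp["landmark_index"].to_numpy()
        counts = np.bincount(idx, minlength=k + 1)[1:]
        dup = np.nonzero(counts > 1)[0] + 1
        if dup.size:
            raise ValidationError(
                f"{path}: specimen {sid!r}: duplicate landmark index {int(dup[0])}"
            )
        absent = np.nonzero(counts == 0)[0] + 1
        if absent.size:
            raise ValidationError(
                f"{path}: specimen {sid!r}: missing landmark index {int(absent[0])}"
            )
        ordered = grp.sort_values("landmark_index")
        coords = ordered[["x", "y"]].to_numpy(dtype=float)
        configs.append(LandmarkConfiguration(specimen_id=str(sid), coords=coords))
    return LandmarkSample(
        group_label=group_label if group_label is not None else path.stem,
        configurations=tuple(configs),
    )
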