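"""Landmark data I/O and normalization.

Reads and writes landmark configurations in the tpsDig TPS dialect and in
flat tabular (CSV) form, mirrors left-side configurations onto the right,
validates the landmark scheme, and joins coordinates with specimen
metadata tables.

The default scheme is the caprine third-lower-molar protocol: 55 points in
two dimensions, of which 7 are fixed anatomical landmarks and 48 are
sliding semi-landmarks arranged in 6 curves of 8 points each.  Internally
all indices are 0-based; TPS files and slider CSV files use the field's
1-based numbering.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: size of the molar landmark scheme: 7 fixed + 48 sliding semi-landmarks
DEFAULT_SCHEME_K = 55
N_FIXED = 7
N_SEMI = 48
N_CURVES = 6
POINTS_PER_CURVE = 8


class SchemeMismatchError(ValueError):
    """A configuration does not match the expected landmark scheme."""


class TPSParseError(ValueError):
    """A TPS file could not be parsed."""


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2-D landmark set.

    Coordinates are stored in physical units (image coordinates already
    multiplied by any SCALE factor present in the source file).
    """

    specimen_id: str
    coords: np.ndarray  # (k, 2) float array
    side: str = "right"  # "left" | "right"
    scale: float = 1.0
    source_file: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(
                f"{self.specimen_id}: coords must be (k, 2), got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.specimen_id}: non-finite coordinates")
        if self.side not in ("left", "right"):
            raise ValueError(f"{self.specimen_id}: side must be left|right")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def validate_scheme(self, expected_k: int = DEFAULT_SCHEME_K) -> None:
        if self.k != expected_k:
            raise SchemeMismatchError(
                f"specimen {self.specimen_id!r}: {self.k} landmarks, "
                f"expected {expected_k}"
            )


@dataclass(frozen=True)
class SliderMap:
    """Before/slider/after neighbor triplets for sliding semi-landmarks.

    ``triplets`` holds 0-based (before, slider, after) index triples; each
    semi-landmark appears exactly once as a slider.  ``curves`` partitions
    the semi-landmark indices into ordered curves.
    """

    triplets: tuple[tuple[int, int, int], ...]
    curves: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        sliders = [t[1] for t in self.triplets]
        if len(set(sliders)) != len(sliders):
            raise ValueError("duplicate slider index in SliderMap")
        for b, s, a in self.triplets:
            if len({b, s, a}) != 3:
                raise ValueError(f"degenerate triplet ({b}, {s}, {a})")

    @property
    def slider_indices(self) -> np.ndarray:
        return np.array([t[1] for t in self.triplets], dtype=int)

    @property
    def n_sliders(self) -> int:
        return len(self.triplets)

    def validate_against(self, k: int, fixed_indices: Iterable[int]) -> None:
        fixed = set(fixed_indices)
        for b, s, a in self.triplets:
            if not (0 <= b < k and 0 <= s < k and 0 <= a < k):
                raise ValueError(f"triplet ({b}, {s}, {a}) out of range for k={k}")
            if s in fixed:
                raise ValueError(f"slider index {s} collides with a fixed landmark")


@dataclass
class MorphoDataset:
    """Configurations joined with their metadata, in a common order.

    ``metadata`` is indexed 0..n-1 in the same order as ``configurations``
    and always carries a ``specimen_id`` column.
    """

    configurations: list[LandmarkConfiguration]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.configurations) != len(self.metadata):
            raise ValueError("configurations and metadata length mismatch")

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def coords_array(self) -> np.ndarray:
        """Stack coordinates into an (n, k, 2) array (common scheme required)."""
        ks = {c.k for c in self.configurations}
        if len(ks) > 1:
            raise SchemeMismatchError(f"mixed landmark counts in dataset: {sorted(ks)}")
        return np.stack([c.coords for c in self.configurations])


# ---------------------------------------------------------------------------
# TPS I/O (tpsDig dialect)
# ---------------------------------------------------------------------------

_TPS_KEY_RE = re.compile(r"^\s*([A-Za-z_]+)\s*=\s*(.*?)\s*$")


def read_tps(path: str | Path, expected_k: int | None = None) -> list[LandmarkConfiguration]:
    """Read a TPS file, one configuration per ``LM=`` block.

    Recognized keys are ``LM=``, ``ID=``, ``IMAGE=`` and ``SCALE=``; unknown
    keys are ignored.  Coordinates are multiplied by SCALE when present.
    Specimen ids fall back from ID to the IMAGE basename to the block
    ordinal.  When ``expected_k`` is given, every block must declare exactly
    that many landmarks.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    configs: list[LandmarkConfiguration] = []
    block: dict | None = None

    def flush(block: dict) -> None:
        if len(block["points"]) != block["lm"]:
            raise TPSParseError(
                f"{path}: block {block['ordinal']} declares LM={block['lm']} "
                f"but has {len(block['points'])} points"
            )
        scale = block.get("scale", 1.0)
        coords = np.asarray(block["points"], dtype=float) * scale
        spec_id = block.get("id")
        if spec_id is None:
            image = block.get("image")
            spec_id = Path(image).stem if image else str(block["ordinal"])
        cfg = LandmarkConfiguration(
            specimen_id=spec_id,
            coords=coords,
            scale=scale,
            source_file=str(path),
        )
        if expected_k is not None:
            cfg.validate_scheme(expected_k)
        configs.append(cfg)

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        m = _TPS_KEY_RE.match(line)
        if m and not _looks_like_point(line):
            key, value = m.group(1).upper(), m.group(2)
            if key == "LM":
                if block is not None:
                    flush(block)
                try:
                    lm = int(value)
                except ValueError:
                    raise TPSParseError(f"{path}:{lineno}: bad LM count {value!r}")
                block = {"lm": lm, "points": [], "ordinal": len(configs) + 1}
            elif block is None:
                raise TPSParseError(f"{path}:{lineno}: {key}= before any LM= record")
            elif key == "ID":
                block["id"] = value
            elif key == "IMAGE":
                block["image"] = value
            elif key == "SCALE":
                try:
                    block["scale"] = float(value)
                except ValueError:
                    raise TPSParseError(f"{path}:{lineno}: bad SCALE {value!r}")
            # any other key: ignored
        else:
            if block is None:
                raise TPSParseError(f"{path}:{lineno}: coordinates before LM= record")
            parts = line.split()
            if len(parts) != 2:
                raise TPSParseError(
                    f"{path}:{lineno}: expected 'x y' pair, got {line!r}"
                )
            try:
                block["points"].append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise TPSParseError(f"{path}:{lineno}: non-numeric coordinate in {line!r}")
    if block is not None:
        flush(block)
    return configs


def _looks_like_point(line: str) -> bool:
    parts = line.split()
    if len(parts) != 2:
        return False
    try:
        float(parts[0]), float(parts[1])
        return True
    except ValueError:
        return False


def write_tps(configs: Sequence[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations to a TPS file (coordinates in image units).

    Stored coordinates are divided by each configuration's scale so that a
    round trip through :func:`read_tps` reproduces the physical coordinates.
    """
    path = Path(path)
    out_lines: list[str] = []
    for cfg in configs:
        out_lines.append(f"LM={cfg.k}")
        image_coords = cfg.coords / cfg.scale
        for x, y in image_coords:
            out_lines.append(f"{x:.17g} {y:.17g}")
        out_lines.append(f"ID={cfg.specimen_id}")
        if cfg.scale != 1.0:
            out_lines.append(f"SCALE={cfg.scale:.17g}")
    path.write_text("\n".join(out_lines) + "\n")


# ---------------------------------------------------------------------------
# Slider map I/O
# ---------------------------------------------------------------------------

def read_slider_csv(path: str | Path) -> SliderMap:
    """Read a 3-column (before, slider, after) CSV with 1-based indices."""
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: slider CSV needs 3 columns (before, slider, after)")
    arr = df.iloc[:, :3].to_numpy(dtype=int) - 1
    return SliderMap(triplets=tuple(tuple(int(v) for v in row) for row in arr))


def write_slider_csv(slider_map: SliderMap, path: str | Path) -> None:
    arr = np.array([t for t in slider_map.triplets], dtype=int) + 1
    pd.DataFrame(arr, columns=["before", "slider", "after"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Mirroring
# ---------------------------------------------------------------------------

def mirror_configuration(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Mirror a left-side configuration about its centroid's vertical axis.

    Reflection (x -> 2*cx - x) maps a left molar outline onto right-molar
    orientation without changing landmark order, centroid position or
    centroid size.  Applied to a right-side configuration this is a no-op
    with a logged warning; handedness is handled here and nowhere else
    (the superimposition itself never reflects).
    """
    if config.side == "right":
        logger.warning(
            "mirror_configuration called on right-side specimen %r: no-op",
            config.specimen_id,
        )
        return config
    cx = config.coords[:, 0].mean()
    mirrored = config.coords.copy()
    mirrored[:, 0] = 2.0 * cx - mirrored[:, 0]
    return replace(config, coords=mirrored, side="right")


def normalize_sides(
    configs: Sequence[LandmarkConfiguration],
) -> tuple[list[LandmarkConfiguration], int]:
    """Mirror every left-side configuration; return (configs, n_mirrored)."""
    out = []
    n_mirrored = 0
    for c in configs:
        if c.side == "left":
            out.append(mirror_configuration(c))
            n_mirrored += 1
        else:
            out.append(c)
    if n_mirrored:
        logger.info("mirrored %d left-side configurations", n_mirrored)
    return out, n_mirrored


# ---------------------------------------------------------------------------
# Metadata join and tabular round trip
# ---------------------------------------------------------------------------

def join_metadata(
    configs: Sequence[LandmarkConfiguration],
    meta: pd.DataFrame,
    side_column: str = "side",
) -> MorphoDataset:
    """Inner-join configurations with a metadata table on ``specimen_id``.

    Unmatched ids on either side are counted and logged.  A missing side
    column means every specimen is assumed right-side (and this is logged);
    duplicated metadata ids or an empty join are errors.
    """
    if "specimen_id" not in meta.columns:
        raise ValueError("metadata table lacks a specimen_id column")
    meta = meta.copy()
    meta["specimen_id"] = meta["specimen_id"].astype(str)
    dup = meta["specimen_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate specimen_id in metadata: {sorted(meta['specimen_id'][dup])}"
        )
    if side_column not in meta.columns:
        logger.info("no %r column in metadata: assuming all right-side", side_column)

    meta_by_id = meta.set_index("specimen_id")
    joined_cfgs: list[LandmarkConfiguration] = []
    rows = []
    orphan_configs = 0
    for cfg in configs:
        if cfg.specimen_id in meta_by_id.index:
            row = meta_by_id.loc[cfg.specimen_id]
            if side_column in meta.columns and isinstance(row[side_column], str):
                cfg = replace(cfg, side=row[side_column])
            joined_cfgs.append(cfg)
            rows.append(row)
        else:
            orphan_configs += 1
    orphan_meta = len(meta) - len(rows)
    if orphan_configs or orphan_meta:
        logger.warning(
            "join_metadata: %d configurations and %d metadata rows unmatched",
            orphan_configs,
            orphan_meta,
        )
    if not joined_cfgs:
        raise ValueError("join_metadata: zero matching specimen ids")
    out_meta = pd.DataFrame(rows)
    out_meta.index.name = "specimen_id"
    out_meta = out_meta.reset_index()
    return MorphoDataset(configurations=joined_cfgs, metadata=out_meta)


def write_dataset(dataset: MorphoDataset, path: str | Path) -> None:
    """Export a dataset as one CSV row per specimen: x1,y1..xk,yk + metadata."""
    if len(dataset) == 0:
        pd.DataFrame(columns=["specimen_id"]).to_csv(path, index=False)
        return
    coords = dataset.coords_array()
    n, k, _ = coords.shape
    cols = {}
    flat = coords.reshape(n, 2 * k)
    for j in range(k):
        cols[f"x{j + 1}"] = flat[:, 2 * j]
        cols[f"y{j + 1}"] = flat[:, 2 * j + 1]
    coord_df = pd.DataFrame(cols)
    meta = dataset.metadata.reset_index(drop=True)
    meta = meta[[c for c in meta.columns if c not in coord_df.columns]]
    out = pd.concat([meta, coord_df], axis=1)
    out.to_csv(path, index=False, float_format="%.17g")


def read_dataset(path: str | Path) -> MorphoDataset:
    """Read a dataset written by :func:`write_dataset`."""
    df = pd.read_csv(path)
    coord_cols = [c for c in df.columns if re.fullmatch(r"[xy]\d+", c)]
    k = len(coord_cols) // 2
    meta_cols = [c for c in df.columns if c not in coord_cols]
    configs = []
    for _, row in df.iterrows():
        coords = np.array(
            [[row[f"x{j + 1}"], row[f"y{j + 1}"]] for j in range(k)], dtype=float
        )
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(row.get("specimen_id", "")),
                coords=coords,
                side=str(row["side"]) if "side" in df.columns else "right",
                source_file=str(path),
            )
        )
    meta = df[meta_cols].copy()
    if "specimen_id" in meta.columns:
        meta["specimen_id"] = meta["specimen_id"].astype(str)
    return MorphoDataset(configurations=configs, metadata=meta)
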