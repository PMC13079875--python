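"""Schema-validated readers and writers for the pipeline's file formats.

All CSV files are UTF-8, comma-separated, '.' decimal, with a mandatory
header row.  Schema violations are hard errors naming the offending rows;
nothing is silently coerced.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dots import MaskSequence
from .materials import ATTRIBUTES, TrajectorySet
from .rsa import RDM


class SchemaError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


# --- trajectories -----------------------------------------------------------

def write_trajectories(videos: list[TrajectorySet], path) -> None:
    """Tidy CSV: video_id, frame, point_id, x, y."""
    frames = []
    for t in videos:
        f, p, _ = t.positions.shape
        frames.append(
            pd.DataFrame(
                {
                    "video_id": np.repeat(t.video_id, f * p),
                    "material": np.repeat(t.material, f * p),
                    "exemplar": np.repeat(t.exemplar, f * p),
                    "view": np.repeat(t.view, f * p),
                    "frame": np.repeat(np.arange(f), p),
                    "point_id": np.tile(np.arange(p), f),
                    "x": t.positions[:, :, 0].ravel(),
                    "y": t.positions[:, :, 1].ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path) -> list[TrajectorySet]:
    df = pd.read_csv(path)
    _require_columns(df, ["video_id", "frame", "point_id", "x", "y"], "trajectories")
    if df[["x", "y"]].isna().any().any():
        bad = df.index[df[["x", "y"]].isna().any(axis=1)][:5].tolist()
        raise SchemaError(f"trajectories: non-finite coordinates at rows {bad}")
    out = []
    for vid, grp in df.groupby("video_id", sort=True):
        frames = np.sort(grp["frame"].unique())
        points = np.sort(grp["point_id"].unique())
        if len(grp) != len(frames) * len(points):
            raise SchemaError(f"trajectories: ragged frame/point grid for {vid!r}")
        wide = grp.pivot(index="frame", columns="point_id", values=["x", "y"])
        pos = np.stack(
            [wide["x"].to_numpy(), wide["y"].to_numpy()], axis=-1
        )
        out.append(
            TrajectorySet(
                positions=pos,
                video_id=str(vid),
                material=str(grp["material"].iloc[0]) if "material" in grp else "",
                exemplar=str(grp["exemplar"].iloc[0]) if "exemplar" in grp else "",
                view=int(grp["view"].iloc[0]) if "view" in grp else 0,
            )
        )
    return out


# --- masks ------------------------------------------------------------------

def write_mask_stack(m: MaskSequence, path) -> None:
    """Single .npy stack of 0/1 uint8 frames."""
    np.save(path, m.masks.astype(np.uint8))


def read_mask_stack(path) -> MaskSequence:
    arr = np.load(path)
    if not np.isin(arr, (0, 1)).all():
        raise SchemaError("mask stack must contain only 0/1 values")
    return MaskSequence(arr)


def write_mask_pngs(m: MaskSequence, directory) -> None:
    """Per-frame 0/255 PNGs named frame_0000.png, ..."""
    from imageio.v3 import imwrite

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for f in range(m.n_frames):
        imwrite(
            directory / f"frame_{f:04d}.png",
            (m.masks[f].astype(np.uint8) * 255),
        )


def read_mask_pngs(directory) -> MaskSequence:
    from imageio.v3 import imread

    files = sorted(Path(directory).glob("frame_*.png"))
    if not files:
        raise SchemaError(f"no frame_*.png files in {directory}")
    frames = [np.asarray(imread(f)) > 127 for f in files]
    return MaskSequence(np.stack(frames).astype(np.uint8))


# --- ratings / triplets -----------------------------------------------------

RATING_COLUMNS = ["participant_id", "video_id", "condition", "attribute", "rating"]


def write_ratings(ratings: pd.DataFrame, path) -> None:
    validate_ratings(ratings)
    ratings[RATING_COLUMNS].to_csv(path, index=False)


def validate_ratings(ratings: pd.DataFrame) -> None:
    _require_columns(ratings, RATING_COLUMNS, "ratings")
    bad = ratings.index[
        (ratings["rating"] < 0) | (ratings["rating"] > 1) | ratings["rating"].isna()
    ]
    if len(bad):
        raise SchemaError(f"ratings: rating outside [0, 1] at rows {bad[:5].tolist()}")
    unknown = set(ratings["attribute"]) - set(ATTRIBUTES)
    if unknown:
        raise SchemaError(f"ratings: unknown attribute(s) {sorted(unknown)}")
    dup = ratings.duplicated(["participant_id", "video_id", "attribute"])
    if dup.any():
        raise SchemaError(
            f"ratings: duplicate participant/video/attribute rows at "
            f"{ratings.index[dup][:5].tolist()}"
        )


def read_ratings(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_ratings(df)
    return df


TRIPLET_COLUMNS = [
    "participant_id",
    "reference_id",
    "left_id",
    "right_id",
    "chosen_id",
    "chosen_side",
    "rt_ms",
]


def validate_triplets(triplets: pd.DataFrame) -> None:
    _require_columns(triplets, TRIPLET_COLUMNS, "triplets")
    bad = triplets.index[
        (triplets["chosen_id"] != triplets["left_id"])
        & (triplets["chosen_id"] != triplets["right_id"])
    ]
    if len(bad):
        raise SchemaError(
            f"triplets: chosen_id not among the tests at rows {bad[:5].tolist()}"
        )
    bad_rt = triplets.index[(triplets["rt_ms"] <= 0) | triplets["rt_ms"].isna()]
    if len(bad_rt):
        raise SchemaError(f"triplets: nonpositive rt_ms at rows {bad_rt[:5].tolist()}")
    bad_side = triplets.index[~triplets["chosen_side"].isin(["left", "right"])]
    if len(bad_side):
        raise SchemaError(
            f"triplets: chosen_side must be left/right at rows {bad_side[:5].tolist()}"
        )


def write_triplets(triplets: pd.DataFrame, path) -> None:
    validate_triplets(triplets)
    cols = [c for c in triplets.columns if c in TRIPLET_COLUMNS + ["trial"]]
    triplets[cols].to_csv(path, index=False)


def read_triplets(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_triplets(df)
    return df


# --- RDMs and reports -------------------------------------------------------

def write_rdm(rdm: RDM, path) -> None:
    rdm.to_frame().to_csv(path)


def read_rdm(path, tol: float = 1e-9) -> RDM:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise SchemaError("RDM: row and column labels must match")
    vals = df.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T, atol=tol, equal_nan=True):
        raise SchemaError("RDM: asymmetric entries beyond tolerance")
    if not np.allclose(np.diag(vals), 0.0, atol=tol):
        raise SchemaError("RDM: nonzero diagonal")
    vals = 0.5 * (vals + vals.T)
    np.fill_diagonal(vals, 0.0)
    return RDM([str(i) for i in df.index], vals)


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
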