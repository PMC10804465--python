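"""Trial manifests, image stacks, exclusion lists and result artifacts.

The on-disk layout is deliberately plain: a CSV manifest describes one
movement attempt (trial) per row and points at a multi-frame TIFF or HDF5
stack holding the grayscale ultrasound frames for that trial.  Matrices are
written as labeled CSV, permutation-test results as JSON, so every artifact
is diffable and round-trips at full float precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sonorsa")

#: Fixed movement vocabulary and class order used by every matrix artifact.
MOVEMENTS: tuple[str, ...] = (
    "power",
    "point",
    "pinch",
    "key",
    "wrist_flexion",
    "wrist_rotation",
)

LIMBS: tuple[str, ...] = ("affected", "unaffected")

MANIFEST_COLUMNS = ("subject_id", "limb", "movement", "trial_index", "file")


class LoadError(RuntimeError):
    """A manifest row or image stack could not be read."""


@dataclass
class TrialRecording:
    """One movement attempt: an ordered frame sequence plus its labels.

    ``frames`` is a float array of shape ``(n_frames, rows, cols)``; all
    frames share one shape and intensities are nonnegative.  A recording
    longer than the configured trial window (default 4 s) only warns — the
    protocol window is a guideline, not a hard format constraint.
    """

    subject_id: str
    limb: str
    movement: str
    trial_index: int
    frames: np.ndarray
    frame_rate_hz: float = 30.0

    trial_window_s: float = 4.0
    _window_tolerance_s: float = 0.25

    def __post_init__(self) -> None:
        if self.limb not in LIMBS:
            raise ValueError(f"unknown limb {self.limb!r}; expected one of {LIMBS}")
        if self.movement not in MOVEMENTS:
            raise ValueError(
                f"unknown movement {self.movement!r}; expected one of {MOVEMENTS}"
            )
        if self.trial_index < 1:
            raise ValueError("trial_index must be a positive integer")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        frames = np.asarray(self.frames)
        if frames.ndim != 3 or frames.shape[0] == 0:
            raise ValueError(
                f"frames must be a nonempty (n_frames, rows, cols) array, got shape {frames.shape}"
            )
        if not np.issubdtype(frames.dtype, np.floating):
            frames = frames.astype(np.float32)
        self.frames = frames
        duration = frames.shape[0] / self.frame_rate_hz
        if duration > self.trial_window_s + self._window_tolerance_s:
            warnings.warn(
                f"trial {self.subject_id}/{self.limb}/{self.movement}#{self.trial_index} "
                f"lasts {duration:.2f} s, beyond the {self.trial_window_s:.1f} s window",
                stacklevel=2,
            )

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (int(self.frames.shape[1]), int(self.frames.shape[2]))

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.subject_id, self.limb, self.movement, self.trial_index)


@dataclass
class TrialSet:
    """A collection of trial recordings plus free-form session metadata."""

    trials: list[TrialRecording] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def subset(self, *, subject_id: str | None = None, limb: str | None = None,
               movement: str | None = None) -> "TrialSet":
        """Trials matching every given label, in stored order."""
        keep = [
            t for t in self.trials
            if (subject_id is None or t.subject_id == subject_id)
            and (limb is None or t.limb == limb)
            and (movement is None or t.movement == movement)
        ]
        return TrialSet(trials=keep, metadata=dict(self.metadata))

    def movements_present(self) -> list[str]:
        present = {t.movement for t in self.trials}
        return [m for m in MOVEMENTS if m in present]


@dataclass
class ExclusionList:
    """Trials flagged for removal: (subject_id, limb, movement, trial_index)."""

    entries: list[tuple[str, str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("exclusion entries must be unique")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExclusionList":
        df = pd.read_csv(path)
        required = ("subject_id", "limb", "movement", "trial_index")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise LoadError(f"exclusion list {path} missing columns {missing}")
        entries = [
            (str(r.subject_id), str(r.limb), str(r.movement), int(r.trial_index))
            for r in df.itertuples()
        ]
        return cls(entries=entries)


@dataclass
class RunConfig:
    """Analysis configuration shared by the CLI and library entry points."""

    k_neighbors: int = 1
    end_state_frames: int = 5
    downsample_to: tuple[int, int] = (128, 128)
    static_pixel_tolerance: float = 0.0
    split_policy: str = "contiguous"
    split_seed: int = 0
    alpha: float = 0.05
    mds_dims: int = 3
    ca_threshold: float = 0.80

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be a positive integer")
        if self.end_state_frames < 1:
            raise ValueError("end_state_frames must be a positive integer")
        rows, cols = self.downsample_to
        if rows < 1 or cols < 1:
            raise ValueError("downsample_to dimensions must be positive")
        self.downsample_to = (int(rows), int(cols))
        if self.static_pixel_tolerance < 0:
            raise ValueError("static_pixel_tolerance must be nonnegative")
        if self.split_policy not in ("contiguous", "random"):
            raise ValueError("split_policy must be 'contiguous' or 'random'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.mds_dims < 1:
            raise ValueError("mds_dims must be a positive integer")
        if not 0 < self.ca_threshold <= 1:
            raise ValueError("ca_threshold must lie in (0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a YAML/JSON key-value file; unknown keys are rejected."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "downsample_to" in raw:
            raw["downsample_to"] = tuple(raw["downsample_to"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["downsample_to"] = list(self.downsample_to)
        return d


# ---------------------------------------------------------------------------
# image stacks


def read_stack(path: str | Path) -> np.ndarray:
    """Read a (frames, rows, cols) grayscale stack from TIFF or HDF5.

    HDF5 files are expected to carry the stack in a dataset named ``frames``
    (falling back to the file's sole dataset).  Intensities of any numeric
    dtype are converted to floating point.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"image stack not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    elif suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as fh:
            if "frames" in fh:
                arr = fh["frames"][:]
            else:
                keys = [k for k in fh.keys() if isinstance(fh[k], h5py.Dataset)]
                if len(keys) != 1:
                    raise LoadError(
                        f"{path}: expected a 'frames' dataset or a single dataset, found {keys}"
                    )
                arr = fh[keys[0]][:]
    else:
        raise LoadError(f"unsupported stack format {suffix!r} for {path}")
    arr = np.asarray(arr)
    if arr.ndim == 2:  # single-frame stack
        arr = arr[None]
    if arr.ndim != 3:
        raise LoadError(f"{path}: expected a (frames, rows, cols) stack, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    return arr


def write_stack(frames: np.ndarray, path: str | Path) -> Path:
    """Write a stack as multi-frame TIFF or HDF5, by file extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, np.asarray(frames), photometric="minisblack")
    elif suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("frames", data=np.asarray(frames))
    else:
        raise ValueError(f"unsupported stack format {suffix!r}")
    return path


# ---------------------------------------------------------------------------
# manifests


def load_trial_set(manifest_path: str | Path, data_root: str | Path | None = None) -> TrialSet:
    """Load every trial listed in a CSV manifest, preserving row order.

    Required columns: subject_id, limb, movement, trial_index, file.  Extra
    columns pass through into ``TrialSet.metadata['columns']``.  File paths
    are resolved relative to ``data_root`` (default: the manifest's folder).
    """
    manifest_path = Path(manifest_path)
    root = Path(data_root) if data_root is not None else manifest_path.parent
    try:
        df = pd.read_csv(manifest_path)
    except OSError as exc:
        raise LoadError(f"cannot read manifest {manifest_path}: {exc}") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"manifest {manifest_path} missing required columns {missing}")

    trials: list[TrialRecording] = []
    for i, row in enumerate(df.itertuples(index=False)):
        limb, movement = str(row.limb), str(row.movement)
        if limb not in LIMBS:
            raise LoadError(f"manifest row {i}: unknown limb token {limb!r}")
        if movement not in MOVEMENTS:
            raise LoadError(f"manifest row {i}: unknown movement token {movement!r}")
        stack_path = root / str(row.file)
        try:
            frames = read_stack(stack_path)
        except LoadError as exc:
            raise LoadError(f"manifest row {i}: {exc}") from exc
        trials.append(
            TrialRecording(
                subject_id=str(row.subject_id),
                limb=limb,
                movement=movement,
                trial_index=int(row.trial_index),
                frames=frames,
            )
        )
    extra = [c for c in df.columns if c not in MANIFEST_COLUMNS]
    metadata: dict[str, Any] = {}
    if extra:
        metadata["columns"] = df[extra].to_dict(orient="list")
    return TrialSet(trials=trials, metadata=metadata)


def save_trial_set(ts: TrialSet, out_dir: str | Path, stack_format: str = "tiff") -> Path:
    """Write one stack per trial plus a manifest.csv; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = {"tiff": ".tif", "hdf5": ".h5"}[stack_format]
    rows = []
    for t in ts.trials:
        fname = f"{t.subject_id}_{t.limb}_{t.movement}_{t.trial_index:02d}{ext}"
        write_stack(t.frames, out_dir / fname)
        rows.append(
            {
                "subject_id": t.subject_id,
                "limb": t.limb,
                "movement": t.movement,
                "trial_index": t.trial_index,
                "file": fname,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def apply_exclusions(ts: TrialSet, ex: ExclusionList) -> TrialSet:
    """Remove every trial matching an exclusion entry; unmatched entries warn."""
    keys = {t.key for t in ts.trials}
    for entry in ex.entries:
        if entry not in keys:
            logger.warning("exclusion entry %s matches no trial; ignored", entry)
    excluded = set(ex.entries)
    kept = [t for t in ts.trials if t.key not in excluded]
    return TrialSet(trials=kept, metadata=dict(ts.metadata))


# ---------------------------------------------------------------------------
# result artifacts


def _write_labeled_matrix(matrix: np.ndarray, labels: Sequence[str], path: Path) -> Path:
    pd.DataFrame(np.asarray(matrix), index=list(labels), columns=list(labels)).to_csv(
        path, float_format="%.17g"
    )
    return path


def read_labeled_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(), list(df.columns)


def write_results(obj: Any, out_dir: str | Path) -> Path:
    """Write a result object to ``out_dir``; returns the written path.

    Dispatches on type: confusion matrices and RDMs become labeled CSV,
    permutation-test results become JSON (full null distribution retained),
    MDS embeddings become a coordinates CSV.
    """
    from . import classification, geometry, rsa  # local import to avoid cycles

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, classification.ConfusionMatrix):
        return _write_labeled_matrix(obj.counts, obj.classes, out_dir / "confusion_matrix.csv")
    if isinstance(obj, rsa.SplitDataRDM):
        return _write_labeled_matrix(obj.matrix, obj.classes, out_dir / "sdrdm.csv")
    if isinstance(obj, rsa.MovementRDM):
        return _write_labeled_matrix(obj.matrix, obj.classes, out_dir / "movement_rdm.csv")
    if isinstance(obj, rsa.PermutationTestResult):
        path = out_dir / f"{obj.statistic_name}_test.json"
        null = np.asarray(obj.null_values, dtype=float)
        payload = {
            "statistic_name": obj.statistic_name,
            "observed": float(obj.observed),
            "p_value": float(obj.p_value),
            "n_permutations": int(obj.n_permutations),
            "null_summary": {
                "mean": float(null.mean()),
                "sd": float(null.std(ddof=1)),
                "min": float(null.min()),
                "max": float(null.max()),
            },
            "null_values": [float(v) for v in null],
        }
        path.write_text(json.dumps(payload, indent=2))
        return path
    if isinstance(obj, geometry.MDSEmbedding):
        path = out_dir / "mds_coordinates.csv"
        df = obj.frame_info.copy()
        for j in range(obj.coordinates.shape[1]):
            df[f"dim{j + 1}"] = obj.coordinates[:, j]
        df.to_csv(path, index=False, float_format="%.17g")
        meta = {
            "eigenvalues": [float(v) for v in obj.eigenvalues],
            "stress": float(obj.stress),
            "negative_eigenvalue_mass": (
                None if np.isnan(obj.negative_eigenvalue_mass)
                else float(obj.negative_eigenvalue_mass)
            ),
        }
        (out_dir / "mds_summary.json").write_text(json.dumps(meta, indent=2))
        return path
    raise TypeError(f"do not know how to write a {type(obj).__name__}")


def read_permutation_result(path: str | Path):
    from .rsa import PermutationTestResult

    payload = json.loads(Path(path).read_text())
    return PermutationTestResult(
        observed=payload["observed"],
        null_values=np.asarray(payload["null_values"], dtype=float),
        p_value=payload["p_value"],
        n_permutations=payload["n_permutations"],
        statistic_name=payload["statistic_name"],
    )
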