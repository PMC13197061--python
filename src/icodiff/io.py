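"""File formats, configuration and cohort persistence.

Per-vertex morphometry travels in the FreeSurfer "curv" binary dialect and
parcellations in the FreeSurfer ".annot" dialect (both via nibabel), so the
synthetic and real-data paths share one reader.  Manifests are plain CSV and
run configuration a nested YAML mapping; every run writes its seed and a
config hash into the manifest for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from nibabel.freesurfer import io as fsio

from .geometry import Parcellation
from .synthetic import SubjectRecord

__all__ = [
    "read_freesurfer_morph",
    "write_freesurfer_morph",
    "read_annot",
    "write_annot",
    "read_surface_geometry",
    "ChannelStats",
    "standardize_channels",
    "RunConfig",
    "save_cohort",
    "load_cohort",
]

CHANNEL_NAMES = ("ct", "si")


def read_freesurfer_morph(path, expected_vertices: int | None = None) -> np.ndarray:
    """Read a FreeSurfer "curv"-format per-vertex scalar file.

    Values are big-endian float32 on disk and returned as float64.  When the
    target mesh is known, the on-file vertex count is validated against it
    rather than silently truncated.
    """
    path = Path(path)
    try:
        values = fsio.read_morph_data(str(path)).astype(np.float64)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"{path}: not a valid FreeSurfer curv file ({exc})") from exc
    if expected_vertices is not None and values.shape[0] != expected_vertices:
        raise ValueError(
            f"{path}: has {values.shape[0]} vertices, expected {expected_vertices}"
        )
    return values


def write_freesurfer_morph(path, values: np.ndarray) -> None:
    fsio.write_morph_data(str(path), np.asarray(values, dtype=np.float32))


def read_annot(path) -> Parcellation:
    """Read a FreeSurfer ".annot" parcellation.

    ROI ids are remapped to ``0..n_rois-1`` in colortable order; vertices with
    no colortable entry (id -1) are assigned a reserved trailing id.
    """
    path = Path(path)
    try:
        labels, ctab, names = fsio.read_annot(str(path))
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"{path}: not a valid FreeSurfer annot file ({exc})") from exc
    names = [n.decode() if isinstance(n, bytes) else str(n) for n in names]
    labels = np.asarray(labels, dtype=np.int64)
    n_named = len(names)
    unlabeled = labels < 0
    if unlabeled.any():
        labels = labels.copy()
        labels[unlabeled] = n_named
        names = names + ["unknown"]
    return Parcellation(labels=labels, n_rois=len(names), names=names)


def write_annot(path, parcellation: Parcellation) -> None:
    """Write a parcellation as a FreeSurfer ".annot" with a synthetic colortable."""
    n = parcellation.n_rois
    rng = np.random.default_rng(0)
    # distinct colors; annot encodes labels through packed RGB so they must differ
    ctab = np.zeros((n, 5), dtype=np.int64)
    colors = rng.permutation(256**3 - 1)[:n] + 1
    ctab[:, 0] = colors % 256
    ctab[:, 1] = (colors // 256) % 256
    ctab[:, 2] = colors // 65536
    ctab[:, 3] = 0
    ctab[:, 4] = ctab[:, 0] + ctab[:, 1] * 256 + ctab[:, 2] * 65536
    names = parcellation.names or [f"roi-{i:02d}" for i in range(n)]
    fsio.write_annot(
        str(path),
        parcellation.labels.astype(np.int32),
        ctab,
        [str(x) for x in names],
        fill_ctab=False,
    )


def read_surface_geometry(path) -> tuple[np.ndarray, np.ndarray]:
    """Read FreeSurfer binary surface geometry -> (vertices, faces)."""
    coords, faces = fsio.read_geometry(str(path))
    return np.asarray(coords, dtype=np.float64), np.asarray(faces, dtype=np.int64)


@dataclass
class ChannelStats:
    """Per-channel standardization statistics computed on a training cohort."""

    mean: np.ndarray
    std: np.ndarray

    def apply(self, features: np.ndarray) -> np.ndarray:
        return (features - self.mean) / self.std

    def invert(self, features: np.ndarray) -> np.ndarray:
        return features * self.std + self.mean

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelStats":
        return cls(mean=np.asarray(d["mean"]), std=np.asarray(d["std"]))


def standardize_channels(
    feature_stack: np.ndarray, stats: ChannelStats | None = None
) -> tuple[np.ndarray, ChannelStats]:
    """Standardize each channel to mean 0 / sd 1 over all subjects and vertices.

    When ``stats`` is given (test-time), it is applied verbatim instead of
    being recomputed — test subjects are always transformed with the training
    cohort's statistics.
    """
    x = np.asarray(feature_stack, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("expected (n_subjects, n_vertices, n_channels)")
    if x.shape[0] == 0:
        raise ValueError("cohort is empty")
    if stats is None:
        mean = x.mean(axis=(0, 1))
        std = x.std(axis=(0, 1))
        if np.any(std == 0):
            raise ValueError("constant channel cannot be standardized")
        stats = ChannelStats(mean=mean, std=std)
    return stats.apply(x), stats


@dataclass
class RunConfig:
    """End-to-end run configuration (YAML-serializable)."""

    order: int = 2
    channels: tuple = ("ct", "si")
    # schedule
    T: int = 250
    s: float = 0.008
    beta_clip: float = 0.999
    t_start: int | None = None          # defaults to T // 2
    clip_x0: float = 6.0
    # denoiser
    hidden_dims: tuple = (16, 32, 48)
    n_levels: int = 3
    resblocks_per_level: int = 2
    attention_levels: tuple = (1, 2)
    time_embed_dim: int = 64
    use_mask: bool = True
    use_demographics: bool = True
    # training
    train_steps: int = 2000
    batch_size: int = 16
    learning_rate: float = 2e-3
    # normative
    n_samples: int = 10
    folds: int = 10
    n_rois: int = 34
    seed: int = 0

    def resolved_t_start(self) -> int:
        return self.T // 2 if self.t_start is None else self.t_start

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("channels", "hidden_dims", "attention_levels"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)


def save_cohort(directory, subjects: list, manifest: pd.DataFrame) -> None:
    """Write a cohort: one curv file per subject and channel, the mask as a
    curv file, and the demographic manifest as CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sub in subjects:
        for c, name in enumerate(CHANNEL_NAMES[: sub.features.shape[1]]):
            write_freesurfer_morph(directory / f"{sub.subject_id}.{name}.curv", sub.features[:, c])
        write_freesurfer_morph(directory / f"{sub.subject_id}.mask.curv", sub.mask)
    manifest.to_csv(directory / "manifest.csv", index=False)
    parc = subjects[0].parcellation
    if parc is not None:
        write_annot(directory / "parcellation.annot", parc)


def load_cohort(directory, expected_vertices: int | None = None) -> tuple[list, pd.DataFrame]:
    """Read back a cohort written by :func:`save_cohort`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    parc_path = directory / "parcellation.annot"
    parc = read_annot(parc_path) if parc_path.exists() else None
    subjects = []
    for row in manifest.itertuples():
        feats = []
        for name in CHANNEL_NAMES:
            p = directory / f"{row.subject_id}.{name}.curv"
            if p.exists():
                feats.append(read_freesurfer_morph(p, expected_vertices))
        mask = read_freesurfer_morph(
            directory / f"{row.subject_id}.mask.curv", expected_vertices
        )
        subjects.append(
            SubjectRecord(
                subject_id=row.subject_id,
                features=np.stack(feats, axis=1),
                mask=mask.astype(np.int8),
                age=float(row.age),
                sex=int(row.sex),
                group=str(row.group),
                parcellation=parc,
            )
        )
    return subjects, manifest
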