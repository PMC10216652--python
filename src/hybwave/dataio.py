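"""Dataset I/O: the cjdata MAT (HDF5) dialect, manifests, PNG/CSV helpers.

The public brain-tumor MRI collection this package targets ships one MAT
v7.3 (HDF5-based) file per slice with a ``cjdata`` group holding ``image``,
``label`` (1 = meningioma, 2 = glioma, 3 = pituitary by default), ``PID``
(patient id as uint16 character codes), and optional ``tumorMask`` /
``tumorBorder`` arrays.  ``load_cjdata_mat`` parses one such file into a
:class:`DatasetRecord`; ``dataset_manifest`` summarizes a directory tree of
them.  ``write_cjdata_mat`` emits the same dialect and exists so tests and
demos can build synthetic fixture sets without the download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "DEFAULT_LABEL_MAP",
    "DatasetRecord",
    "Manifest",
    "load_cjdata_mat",
    "write_cjdata_mat",
    "dataset_manifest",
    "read_feature_csv",
    "write_feature_csv",
]

logger = logging.getLogger(__name__)

DEFAULT_LABEL_MAP = {1: "meningioma", 2: "glioma", 3: "pituitary"}


@dataclass
class DatasetRecord:
    """One MRI slice: image, integer label (+ name), patient id, optional mask."""

    image: np.ndarray
    label: int
    label_name: str
    subject_id: str
    tumor_mask: np.ndarray | None = None
    tumor_border: np.ndarray | None = None
    plane: str | None = None

    def __post_init__(self) -> None:
        if self.tumor_mask is not None and \
                self.tumor_mask.shape != self.image.shape:
            raise ValueError("tumorMask shape must match the image")


@dataclass
class Manifest:
    """Directory-level counts: total, per class, per plane, distinct subjects."""

    total: int
    per_class: dict = field(default_factory=dict)
    per_plane: dict = field(default_factory=dict)
    n_subjects: int = 0

    def as_dict(self) -> dict:
        return {"total": self.total, "per_class": dict(self.per_class),
                "per_plane": dict(self.per_plane),
                "n_subjects": self.n_subjects}


class FormatError(ValueError):
    """A cjdata file is missing a required group or field."""


def _decode_mat_string(arr) -> str:
    """MAT v7.3 stores char arrays as uint16 code units."""
    a = np.asarray(arr)
    return "".join(chr(int(c)) for c in a.ravel())


def load_cjdata_mat(path, label_map: dict | None = None) -> DatasetRecord:
    """Parse one cjdata MAT v7.3 file into a :class:`DatasetRecord`.

    Missing optional fields (``tumorMask``, ``tumorBorder``) yield None; a
    missing ``cjdata`` group or required field raises :class:`FormatError`
    naming it.
    """
    label_map = DEFAULT_LABEL_MAP if label_map is None else label_map
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise OSError(f"cannot read {path}: {exc}") from exc
    with f:
        if "cjdata" not in f:
            raise FormatError(f"{path}: missing 'cjdata' group")
        g = f["cjdata"]
        for req in ("image", "label", "PID"):
            if req not in g:
                raise FormatError(f"{path}: missing field 'cjdata/{req}'")
        image = np.asarray(g["image"], dtype=np.float64)
        label = int(np.asarray(g["label"]).ravel()[0])
        pid = _decode_mat_string(g["PID"])
        mask = None
        if "tumorMask" in g:
            mask = np.asarray(g["tumorMask"]).astype(bool)
        border = None
        if "tumorBorder" in g:
            border = np.asarray(g["tumorBorder"], dtype=np.float64)
        plane = None
        if "plane" in g:
            plane = _decode_mat_string(g["plane"])
    if label not in label_map:
        raise FormatError(f"{path}: label {label} not in label map")
    return DatasetRecord(image=image, label=label,
                         label_name=label_map[label], subject_id=pid,
                         tumor_mask=mask, tumor_border=border, plane=plane)


def write_cjdata_mat(path, image, label: int, pid: str, tumor_mask=None,
                     tumor_border=None, plane: str | None = None) -> None:
    """Write a record in the cjdata dialect (used for fixtures and demos)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("cjdata")
        g.create_dataset("image", data=np.asarray(image, dtype=np.float64))
        g.create_dataset("label", data=np.array([[float(label)]]))
        g.create_dataset("PID",
                         data=np.array([[ord(c)] for c in pid],
                                       dtype=np.uint16))
        if tumor_mask is not None:
            g.create_dataset("tumorMask",
                             data=np.asarray(tumor_mask, dtype=np.uint8))
        if tumor_border is not None:
            g.create_dataset("tumorBorder",
                             data=np.asarray(tumor_border, dtype=np.float64))
        if plane is not None:
            g.create_dataset("plane",
                             data=np.array([[ord(c)] for c in plane],
                                           dtype=np.uint16))


def dataset_manifest(directory, label_map: dict | None = None) -> Manifest:
    """Count records per class / plane / subject across a directory tree.

    File order never matters: files are visited in sorted order and the
    counts are order-invariant.  An empty directory yields a zero manifest
    with a warning.
    """
    label_map = DEFAULT_LABEL_MAP if label_map is None else label_map
    files = sorted(Path(directory).rglob("*.mat"))
    if not files:
        logger.warning("no .mat files under %s", directory)
        return Manifest(total=0)
    per_class: dict = {}
    per_plane: dict = {}
    subjects = set()
    for path in files:
        rec = load_cjdata_mat(path, label_map=label_map)
        per_class[rec.label_name] = per_class.get(rec.label_name, 0) + 1
        plane = rec.plane if rec.plane else "unknown"
        per_plane[plane] = per_plane.get(plane, 0) + 1
        subjects.add(rec.subject_id)
    return Manifest(total=len(files), per_class=per_class,
                    per_plane=per_plane, n_subjects=len(subjects))


def write_feature_csv(path, features, labels=None, header: bool = True) -> None:
    """Delimited text: one row per sample, ``f0..f{D-1}`` columns (+ label)."""
    X = np.asarray(features, dtype=float)
    cols = [f"f{j}" for j in range(X.shape[1])]
    out = X
    if labels is not None:
        out = np.column_stack([X, np.asarray(labels, dtype=float)])
        cols.append("label")
    np.savetxt(path, out, delimiter=",",
               header=",".join(cols) if header else "", comments="")


def read_feature_csv(path):
    """Inverse of :func:`write_feature_csv`; returns ``(features, labels|None)``."""
    with open(path) as fh:
        first = fh.readline()
    has_label = first.strip().split(",")[-1] == "label"
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    data = np.atleast_2d(data)
    if has_label:
        return data[:, :-1], data[:, -1].astype(int)
    return data, None
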