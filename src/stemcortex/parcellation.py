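"""Parcellation metadata, regional time series, annotation maps, and their I/O.

A parcellation assigns every region a label, a structure class (cortex,
brainstem, or other), a hemisphere, optional laminar/cytoarchitectonic
classes, a volumetric centroid in millimetres and -- for cortical regions --
a spherical surface coordinate used by the rotation-based null models.
Regional time series are stored regions x timepoints; temporal
signal-to-noise ratio (tSNR) is the temporal mean divided by the temporal
standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParameterError, ShapeError

STRUCTURES = ("cortex", "brainstem", "other")
HEMISPHERES = ("L", "R", "midline")

#: Columns a parcellation table must provide.
REQUIRED_COLUMNS = ("label", "structure", "hemisphere", "x", "y", "z")
#: Optional columns, read when present.
OPTIONAL_COLUMNS = ("laminar_class", "cyto_class", "sx", "sy", "sz", "n_voxels")


@dataclass
class ParcellationScheme:
    """Region metadata for one parcellation.

    The backing table is indexed by a contiguous 0-based ``region_id``.
    Spherical coordinates (``sx, sy, sz``) must have unit norm for every
    cortical region that participates in spin tests.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"parcellation table missing columns: {missing}")
        if df["label"].duplicated().any():
            dups = df.loc[df["label"].duplicated(), "label"].tolist()
            raise FormatError(f"duplicate region labels: {dups}")
        bad_struct = set(df["structure"]) - set(STRUCTURES)
        if bad_struct:
            raise FormatError(f"unknown structure classes: {sorted(bad_struct)}")
        bad_hemi = set(df["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise FormatError(f"unknown hemispheres: {sorted(bad_hemi)}")
        for c in ("x", "y", "z"):
            if not np.issubdtype(df[c].dtype, np.number) or df[c].isna().any():
                raise FormatError(f"non-numeric centroid coordinate in column {c!r}")
        self.table = df.reset_index(drop=True)

    # -- basic structure --------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()

    @property
    def centroids(self) -> np.ndarray:
        """Region centroids, (n, 3), millimetres."""
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def sphere_coords(self) -> np.ndarray:
        """Spherical surface coordinates, (n, 3); NaN where undefined."""
        if not {"sx", "sy", "sz"} <= set(self.table.columns):
            return np.full((len(self), 3), np.nan)
        return self.table[["sx", "sy", "sz"]].to_numpy(dtype=float)

    def mask(self, structure: str) -> np.ndarray:
        if structure not in STRUCTURES:
            raise ParameterError(f"unknown structure {structure!r}")
        return (self.table["structure"] == structure).to_numpy()

    def indices(self, structure: str) -> np.ndarray:
        return np.flatnonzero(self.mask(structure))

    @property
    def n_cortex(self) -> int:
        return int(self.mask("cortex").sum())

    @property
    def n_brainstem(self) -> int:
        return int(self.mask("brainstem").sum())


def read_parcellation(path) -> ParcellationScheme:
    """Read a parcellation metadata TSV into a validated scheme."""
    df = pd.read_csv(path, sep="\t")
    for c in ("x", "y", "z", "sx", "sy", "sz"):
        if c in df.columns:
            coerced = pd.to_numeric(df[c], errors="coerce")
            if c in ("x", "y", "z") and coerced.isna().any() and not df[c].isna().any():
                raise FormatError(f"non-numeric values in coordinate column {c!r}")
            df[c] = coerced
    return ParcellationScheme(df)


def write_parcellation(scheme: ParcellationScheme, path) -> None:
    scheme.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass
class TimeSeriesSet:
    """Regional time series for one subject, regions x timepoints.

    ``run_boundaries`` lists the starting timepoint of each concatenated run
    (first entry 0).
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    run_boundaries: list[int] = field(default_factory=lambda: [0])

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ShapeError("time series must be a 2-D regions x timepoints array")
        if not np.isfinite(self.data).all():
            raise FormatError("non-finite entries in time series")
        if self.tr_seconds <= 0:
            raise ParameterError("tr_seconds must be positive")
        bounds = list(self.run_boundaries) + [self.data.shape[1]]
        if any(b - a < 3 for a, b in zip(bounds[:-1], bounds[1:])):
            raise ParameterError("each run must contain at least 3 timepoints")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


def read_timeseries(path, subject_id: str | None = None,
                    tr_seconds: float = 2.5) -> TimeSeriesSet:
    """Read a regions x timepoints TSV whose first column holds labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return TimeSeriesSet(subject_id or str(path), df.to_numpy(dtype=float),
                         tr_seconds)


def write_timeseries(ts: TimeSeriesSet, labels, path) -> None:
    df = pd.DataFrame(ts.data, index=list(labels))
    df.index.name = "label"
    df.to_csv(path, sep="\t", float_format="%.17g")


@dataclass
class AnnotationTable:
    """One region-indexed scalar map (receptor density, term map, ...)."""

    map_name: str
    values: np.ndarray
    scope: str = "cortex"  # cortex | brainstem | all

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.scope not in ("cortex", "brainstem", "all"):
            raise ParameterError(f"unknown scope {self.scope!r}")

    def zscored(self) -> "AnnotationTable":
        v = self.values
        sd = v.std(ddof=0)
        if sd == 0:
            raise ParameterError(f"map {self.map_name!r} is constant; cannot z-score")
        return AnnotationTable(self.map_name, (v - v.mean()) / sd, self.scope)


def read_annotation(path, map_name: str | None = None,
                    scope: str = "cortex") -> AnnotationTable:
    df = pd.read_csv(path, sep="\t")
    if "value" not in df.columns:
        raise FormatError("annotation TSV needs columns (label, value)")
    return AnnotationTable(map_name or str(path), df["value"].to_numpy(float), scope)


def write_annotation(table: AnnotationTable, labels, path) -> None:
    pd.DataFrame({"label": list(labels), "value": table.values}).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


# -- matrices --------------------------------------------------------------

def write_matrix(matrix: np.ndarray, labels, path) -> None:
    """Write a labelled square matrix.

    ``.npz`` paths use a binary container (bit-exact round trip); any other
    suffix writes TSV with labels as header and index.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ShapeError(f"matrix must be square, got {matrix.shape}")
    labels = np.asarray(list(labels), dtype=object)
    if len(labels) != matrix.shape[0]:
        raise ShapeError("label count does not match matrix size")
    if str(path).endswith(".npz"):
        np.savez(path, matrix=matrix, labels=labels.astype(str))
    else:
        df = pd.DataFrame(matrix, index=labels, columns=labels)
        df.index.name = "label"
        df.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a labelled square matrix written by :func:`write_matrix`."""
    if str(path).endswith(".npz"):
        with np.load(path, allow_pickle=False) as f:
            matrix, labels = f["matrix"], f["labels"]
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        matrix, labels = df.to_numpy(dtype=float), df.index.to_numpy()
    if matrix.shape[0] != matrix.shape[1]:
        raise ShapeError(f"matrix in {path} is not square: {matrix.shape}")
    return matrix, np.asarray(labels)


# -- volumetric extraction -------------------------------------------------

def extract_parcel_timeseries(image, atlas, threshold: float = 0.35,
                              subject_id: str = "volume",
                              tr_seconds: float = 2.5) -> tuple[TimeSeriesSet, np.ndarray]:
    """Average voxel signals within probabilistically defined parcels.

    Parameters
    ----------
    image
        4-D nibabel image (x, y, z, t) or ndarray.
    atlas
        Per-region probability volumes: a 4-D array/image (x, y, z, region)
        or a sequence of 3-D volumes, values in [0, 1].
    threshold
        Probability cutoff; voxels with probability strictly greater than
        the threshold contribute to the region mean.

    Returns
    -------
    (TimeSeriesSet, missing)
        ``missing`` flags regions whose mask is empty after thresholding;
        their rows are NaN-free zeros are *not* substituted -- the rows are
        masked as NaN and a warning is emitted.
    """
    img = np.asarray(image.get_fdata() if hasattr(image, "get_fdata") else image,
                     dtype=float)
    if img.ndim != 4:
        raise ShapeError("image must be 4-D (x, y, z, t)")
    if hasattr(atlas, "get_fdata"):
        atl = np.asarray(atlas.get_fdata(), dtype=float)
    elif isinstance(atlas, (list, tuple)):
        vols = [np.asarray(a.get_fdata() if hasattr(a, "get_fdata") else a,
                           dtype=float) for a in atlas]
        atl = np.stack(vols, axis=-1)
    else:
        atl = np.asarray(atlas, dtype=float)
    if atl.ndim != 4:
        raise ShapeError("atlas must be 4-D (x, y, z, region)")
    if atl.shape[:3] != img.shape[:3]:
        raise ShapeError(
            f"image grid {img.shape[:3]} does not match atlas grid {atl.shape[:3]}")
    if not 0 <= threshold <= 1:
        raise ParameterError("threshold must lie in [0, 1]")

    n_regions, n_t = atl.shape[3], img.shape[3]
    flat_img = img.reshape(-1, n_t)
    flat_atl = atl.reshape(-1, n_regions)
    data = np.empty((n_regions, n_t))
    missing = np.zeros(n_regions, dtype=bool)
    for r in range(n_regions):
        mask = flat_atl[:, r] > threshold
        if not mask.any():
            missing[r] = True
            data[r] = 0.0  # placeholder; masked below
        else:
            data[r] = flat_img[mask].mean(axis=0)
    ts = TimeSeriesSet(subject_id, data, tr_seconds)
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} region(s) empty after thresholding at "
            f"{threshold}; their rows are masked", stacklevel=2)
        ts.data[missing] = np.nan  # mask after finite-validation of real rows
    return ts, missing


def compute_tsnr(ts: TimeSeriesSet, scope: str = "all") -> AnnotationTable:
    """Temporal SNR per region: temporal mean / temporal sample SD.

    Zero-variance regions are reported as NaN with a warning rather than as
    an arbitrary value.
    """
    if ts.n_timepoints < 2:
        raise ParameterError("tSNR needs at least 2 timepoints")
    mean = ts.data.mean(axis=1)
    sd = ts.data.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = np.where(sd > 0, mean / sd, np.nan)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} constant region(s); tSNR undefined",
                      stacklevel=2)
    return AnnotationTable("tsnr", tsnr, scope)
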