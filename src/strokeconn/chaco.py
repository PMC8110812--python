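"""Streamline-based structural disconnection scoring.

A lesion mask is intersected with reference whole-brain tractograms: for
every grey-matter region the fraction of streamlines connected to that
region whose path touches the lesion is recorded, and fractions are averaged
across reference subjects.  Scores live in [0, 1]; 0 means no streamline of
the region runs through the lesion, 1 means complete disconnection.

Streamlines are stored as voxelized paths (integer voxel indices on the
parcellation grid); intersection is voxel-set membership.  Millimetre-space
streamlines read from TCK/TRK files are voxelized by rounding under the
reference affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LesionMask",
    "Parcellation",
    "Tractogram",
    "ReferenceSet",
    "ChaCoProfile",
    "GridMismatchError",
    "BilateralLesionError",
    "assign_endpoints",
    "lesion_hits",
    "chaco_single",
    "chaco_score",
    "restrict_to_stroke_hemisphere",
    "chaco_change",
    "read_nifti_mask",
    "read_nifti_parcellation",
    "read_tck",
    "write_profile_csv",
    "profiles_to_long_table",
]


class GridMismatchError(ValueError):
    """Raised when a lesion and a tractogram/parcellation disagree on the grid."""


class BilateralLesionError(ValueError):
    """Raised when a lesion occupies both hemispheres (excluded from analysis)."""


@dataclass(frozen=True)
class LesionMask:
    """Binary lesion mask on the parcellation grid."""

    data: np.ndarray
    voxel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("lesion mask must be binary (0/1)")
        object.__setattr__(self, "data", arr.astype(bool))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * self.voxel_size_mm**3 / 1000.0

    def voxels(self) -> np.ndarray:
        """(n, 3) integer array of lesion voxel indices."""
        return np.argwhere(self.data)


@dataclass(frozen=True)
class Parcellation:
    """Voxel label volume plus a region table.

    ``labels`` uses 0 for background and contiguous integers 1..R for
    regions.  ``regions`` is indexed by label and carries ``name``,
    ``hemisphere`` ('L'/'R') and ``lobe`` columns.
    """

    labels: np.ndarray
    regions: pd.DataFrame
    voxel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        present = np.unique(labels)
        present = present[present > 0]
        expected = np.asarray(sorted(self.regions.index))
        if len(expected) == 0:
            raise ValueError("parcellation has no regions")
        if not np.array_equal(expected, np.arange(1, len(expected) + 1)):
            raise ValueError("region labels must be contiguous from 1")
        if not np.array_equal(present, expected):
            raise ValueError("every region must be non-empty and labeled in the volume")
        object.__setattr__(self, "labels", labels.astype(np.int32))

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def region_ids(self) -> np.ndarray:
        return np.arange(1, self.n_regions + 1)

    def hemisphere_of(self, region_id: int) -> str:
        return str(self.regions.loc[region_id, "hemisphere"])

    def regions_in_hemisphere(self, hemisphere: str) -> np.ndarray:
        mask = self.regions["hemisphere"] == hemisphere
        return np.asarray(self.regions.index[mask])

    def lesion_hemisphere(self, lesion: LesionMask) -> str:
        """Hemisphere containing the lesion; bilateral lesions are rejected."""
        if lesion.data.shape != self.labels.shape:
            raise GridMismatchError("lesion grid does not match parcellation grid")
        labels_under = self.labels[lesion.data]
        labels_under = labels_under[labels_under > 0]
        if labels_under.size:
            hemis = set(self.regions.loc[lab, "hemisphere"] for lab in np.unique(labels_under))
        else:
            # Lesion entirely on background: fall back to the x-midline between
            # the two hemispheres' label extents.
            mid = self._hemisphere_midline()
            xs = lesion.voxels()[:, 0]
            hemis = set(np.where(xs < mid, "L", "R"))
        if len(hemis) != 1:
            raise BilateralLesionError("lesion occupies both hemispheres")
        return hemis.pop()

    def _hemisphere_midline(self) -> float:
        left = np.isin(self.labels, self.regions_in_hemisphere("L"))
        right = np.isin(self.labels, self.regions_in_hemisphere("R"))
        lx = np.argwhere(left)[:, 0]
        rx = np.argwhere(right)[:, 0]
        return (lx.max() + rx.min() + 1) / 2.0


@dataclass
class Tractogram:
    """One reference subject's streamlines as voxel paths.

    ``streamlines`` holds (k_i, 3) integer arrays.  ``endpoints`` (n, 2) and
    ``totals`` are filled in by :func:`assign_endpoints`; a self-connecting
    streamline counts once toward its region's total.
    """

    subject_id: str
    streamlines: list[np.ndarray]
    endpoints: np.ndarray | None = None
    totals: np.ndarray | None = None  # indexed by region id (length R + 1)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        for s in self.streamlines:
            if len(s) < 2:
                raise ValueError("streamlines need at least 2 voxels")

    @property
    def n_streamlines(self) -> int:
        return len(self.streamlines)


@dataclass
class ReferenceSet:
    """Collection of reference tractograms sharing one parcellation."""

    tractograms: list[Tractogram]

    def __post_init__(self) -> None:
        if not self.tractograms:
            raise ValueError("reference set must contain at least one tractogram")

    @property
    def n_subjects(self) -> int:
        return len(self.tractograms)


@dataclass
class ChaCoProfile:
    """Per-region disconnection scores for one lesion at one time point.

    ``scores`` maps region id -> mean proportion across reference subjects;
    NaN marks regions undefined (zero total connectivity) in every subject.
    ``per_subject`` retains the raw per-reference-subject proportions.
    """

    subject_id: str
    time: str
    scores: pd.Series
    per_subject: pd.DataFrame = field(repr=False)
    undefined_regions: tuple[int, ...] = ()

    def region_ids(self) -> np.ndarray:
        return np.asarray(self.scores.index)


def assign_endpoints(tractogram: Tractogram, parcellation: Parcellation) -> Tractogram:
    """Assign endpoint regions and per-region totals; drop unlabeled endpoints.

    Returns a new Tractogram whose streamlines all have both endpoints inside
    labeled regions; dropped streamlines are tallied in ``n_dropped``.
    """
    if tractogram.n_streamlines == 0:
        raise ValueError("empty tractogram")
    labels = parcellation.labels
    kept: list[np.ndarray] = []
    ends: list[tuple[int, int]] = []
    dropped = 0
    for path in tractogram.streamlines:
        a, b = path[0], path[-1]
        ra = int(labels[tuple(a)])
        rb = int(labels[tuple(b)])
        if ra == 0 or rb == 0:
            dropped += 1
            continue
        kept.append(path)
        ends.append((ra, rb))
    endpoints = np.asarray(ends, dtype=np.int32).reshape(len(ends), 2)
    totals = np.zeros(parcellation.n_regions + 1, dtype=np.int64)
    for ra, rb in ends:
        totals[ra] += 1
        if rb != ra:
            totals[rb] += 1
    return Tractogram(
        subject_id=tractogram.subject_id,
        streamlines=kept,
        endpoints=endpoints,
        totals=totals,
        n_dropped=dropped,
    )


def lesion_hits(tractogram: Tractogram, lesion: LesionMask) -> np.ndarray:
    """Indices of streamlines with at least one path voxel inside the lesion."""
    data = lesion.data
    hits = []
    for i, path in enumerate(tractogram.streamlines):
        if np.any(np.max(path, axis=0) >= data.shape) or np.any(path < 0):
            raise GridMismatchError("streamline voxel outside lesion grid")
        if data[path[:, 0], path[:, 1], path[:, 2]].any():
            hits.append(i)
    return np.asarray(hits, dtype=np.int64)


def chaco_single(
    tractogram: Tractogram,
    parcellation: Parcellation,
    lesion: LesionMask,
) -> pd.Series:
    """Per-region proportion of connected streamlines running through the lesion.

    Requires endpoint assignment.  Regions with zero total connectivity get
    NaN (undefined), never a silent 0.
    """
    if tractogram.endpoints is None or tractogram.totals is None:
        raise ValueError("call assign_endpoints first")
    if lesion.data.shape != parcellation.labels.shape:
        raise GridMismatchError("lesion grid does not match parcellation grid")
    hit_idx = lesion_hits(tractogram, lesion)
    hit_counts = np.zeros(parcellation.n_regions + 1, dtype=np.int64)
    for i in hit_idx:
        ra, rb = tractogram.endpoints[i]
        hit_counts[ra] += 1
        if rb != ra:
            hit_counts[rb] += 1
    totals = tractogram.totals
    out = np.full(parcellation.n_regions, np.nan)
    nz = totals[1:] > 0
    out[nz] = hit_counts[1:][nz] / totals[1:][nz]
    return pd.Series(out, index=parcellation.region_ids, name=tractogram.subject_id)


def chaco_score(
    reference_set: ReferenceSet,
    parcellation: Parcellation,
    lesion: LesionMask,
    subject_id: str = "",
    time: str = "T1",
    strict: bool = False,
) -> ChaCoProfile:
    """Mean of per-reference-subject proportions (raw values retained).

    A region undefined (zero total) in some reference subject is excluded
    from that subject's mean contribution; under ``strict`` this is an error.
    """
    cols = {}
    for tg in reference_set.tractograms:
        cols[tg.subject_id] = chaco_single(tg, parcellation, lesion)
    per_subject = pd.DataFrame(cols)
    if strict and per_subject.isna().any().any():
        bad = per_subject.index[per_subject.isna().any(axis=1)].tolist()
        raise ValueError(f"regions undefined in some reference subject: {bad}")
    scores = per_subject.mean(axis=1, skipna=True)
    undefined = tuple(int(r) for r in per_subject.index[per_subject.isna().all(axis=1)])
    return ChaCoProfile(
        subject_id=subject_id,
        time=time,
        scores=scores,
        per_subject=per_subject,
        undefined_regions=undefined,
    )


def restrict_to_stroke_hemisphere(
    profile: ChaCoProfile,
    lesion: LesionMask,
    parcellation: Parcellation,
) -> ChaCoProfile:
    """Keep only regions of the lesion's hemisphere.

    Contralateral streamlines already contributed to totals and hit counts;
    only the reported region set shrinks.  Bilateral lesions raise
    :class:`BilateralLesionError`.
    """
    hemi = parcellation.lesion_hemisphere(lesion)
    keep = parcellation.regions_in_hemisphere(hemi)
    keep = [r for r in profile.scores.index if r in set(keep)]
    return ChaCoProfile(
        subject_id=profile.subject_id,
        time=profile.time,
        scores=profile.scores.loc[keep],
        per_subject=profile.per_subject.loc[keep],
        undefined_regions=tuple(r for r in profile.undefined_regions if r in set(keep)),
    )


def chaco_change(profile_t1: ChaCoProfile, profile_t2: ChaCoProfile) -> pd.Series:
    """Per-region score difference T2 - T1 (negative allowed: lesion shrinkage)."""
    if list(profile_t1.scores.index) != list(profile_t2.scores.index):
        raise ValueError("profiles are defined on different region sets")
    if profile_t1.subject_id != profile_t2.subject_id:
        raise ValueError("profiles belong to different subjects")
    return profile_t2.scores - profile_t1.scores


# ---------------------------------------------------------------------------
# I/O


def read_nifti_mask(path, voxel_size_mm: float | None = None) -> LesionMask:
    """Read a binary NIfTI lesion mask (values are thresholded at 0.5)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj) > 0.5
    if voxel_size_mm is None:
        voxel_size_mm = float(np.abs(img.header.get_zooms()[0]))
    return LesionMask(data=data.astype(np.uint8), voxel_size_mm=voxel_size_mm)


def read_nifti_parcellation(path, region_table: pd.DataFrame | None = None) -> Parcellation:
    """Read a NIfTI label volume; synthesize a region table if none is given.

    Without metadata, hemisphere is inferred from the voxel x-midline of each
    region's centroid (documented dialect for MNI-like grids).
    """
    import nibabel as nib

    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj).astype(np.int32)
    voxel_size = float(np.abs(img.header.get_zooms()[0]))
    if region_table is None:
        ids = np.unique(labels)
        ids = ids[ids > 0]
        mid = labels.shape[0] / 2.0
        rows = []
        for rid in ids:
            cx = np.argwhere(labels == rid)[:, 0].mean()
            rows.append(
                {"name": f"region_{rid:03d}", "hemisphere": "L" if cx < mid else "R", "lobe": ""}
            )
        region_table = pd.DataFrame(rows, index=ids)
    return Parcellation(labels=labels, regions=region_table, voxel_size_mm=voxel_size)


def read_tck(path, affine: np.ndarray, subject_id: str = "") -> Tractogram:
    """Read a TCK/TRK file and voxelize streamlines under ``affine``.

    Points in mm are mapped through the inverse affine and rounded to the
    nearest voxel; consecutive duplicate voxels are collapsed.
    """
    import nibabel as nib

    tf = nib.streamlines.load(str(path))
    inv = np.linalg.inv(affine)
    voxelized = []
    for sl in tf.streamlines:
        pts = np.c_[sl, np.ones(len(sl))] @ inv.T
        vox = np.rint(pts[:, :3]).astype(np.int64)
        keep = np.ones(len(vox), dtype=bool)
        keep[1:] = np.any(vox[1:] != vox[:-1], axis=1)
        vox = vox[keep]
        if len(vox) >= 2:
            voxelized.append(vox)
    return Tractogram(subject_id=subject_id or str(path), streamlines=voxelized)


def write_profile_csv(profile: ChaCoProfile, path) -> None:
    df = pd.DataFrame(
        {
            "subject": profile.subject_id,
            "time": profile.time,
            "region": profile.scores.index,
            "score": profile.scores.values,
        }
    )
    df.to_csv(path, index=False)


def profiles_to_long_table(profiles: list[ChaCoProfile]) -> pd.DataFrame:
    """Stack profiles into a long table (subject, time, region, score)."""
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "subject": p.subject_id,
                    "time": p.time,
                    "region": p.scores.index,
                    "score": p.scores.values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
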