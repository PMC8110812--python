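import numpy as np
import pandas as pd
import pytest

from strokeconn import chaco


def make_toy_parcellation(shape=(4, 1, 1), regions=None, voxel_size_mm=1.0):
    """Tiny parcellation; by default two regions A=1 (voxels x<2), B=2 (x>=2)."""
    labels = np.zeros(shape, dtype=np.int32)
    if regions is None:
        labels[: shape[0] // 2] = 1
        labels[shape[0] // 2 :] = 2
        table = pd.DataFrame(
            {"name": ["A", "B"], "hemisphere": ["L", "R"], "lobe": ["", ""]}, index=[1, 2]
        )
    else:
        table_rows = []
        for rid, (voxels, hemi) in enumerate(regions, start=1):
            for v in voxels:
                labels[v] = rid
            table_rows.append({"name": f"R{rid}", "hemisphere": hemi, "lobe": ""})
        table = pd.DataFrame(table_rows, index=np.arange(1, len(regions) + 1))
    return chaco.Parcellation(labels=labels, regions=table, voxel_size_mm=voxel_size_mm)


def mask_from_voxels(shape, voxels, voxel_size_mm=1.0):
    data = np.zeros(shape, dtype=np.uint8)
    for v in voxels:
        data[v] = 1
    return chaco.LesionMask(data=data, voxel_size_mm=voxel_size_mm)


def brute_force_chaco(streamline_paths, endpoint_labels, lesion_voxels, n_regions):
    """Independent enumerator: per-region hit and total counts by direct loops.

    ``streamline_paths`` is a list of lists of voxel tuples, ``endpoint_labels``
    a list of (r_start, r_end) region ids (0 = unlabeled, dropped), and
    ``lesion_voxels`` a set of voxel tuples.  Returns dict region -> score or
    None for zero-total regions.
    """
    totals = {r: 0 for r in range(1, n_regions + 1)}
    hits = {r: 0 for r in range(1, n_regions + 1)}
    for path, (ra, rb) in zip(streamline_paths, endpoint_labels):
        if ra == 0 or rb == 0:
            continue
        touched = any(tuple(v) in lesion_voxels for v in path)
        for r in {ra, rb}:
            totals[r] += 1
            if touched:
                hits[r] += 1
    return {
        r: (hits[r] / totals[r] if totals[r] > 0 else None) for r in range(1, n_regions + 1)
    }


def random_toy_case(rng, max_regions=8, max_streamlines=50, shape=(6, 6, 6)):
    """Random parcellation + tractogram + lesion for oracle-equivalence tests."""
    n_regions = int(rng.integers(2, max_regions + 1))
    voxels = [tuple(v) for v in np.argwhere(np.ones(shape, dtype=bool))]
    order = rng.permutation(len(voxels))
    labels = np.zeros(shape, dtype=np.int32)
    # leave ~30% background, split the rest into n_regions non-empty chunks
    labeled = [voxels[i] for i in order[: max(n_regions, int(0.7 * len(voxels)))]]
    n_regions = min(n_regions, len(labeled))
    chunks = np.array_split(np.arange(len(labeled)), n_regions)
    for rid, chunk in enumerate(chunks, start=1):
        for i in chunk:
            labels[labeled[i]] = rid
    mid = shape[0] // 2
    table = pd.DataFrame(
        [
            {
                "name": f"R{rid}",
                "hemisphere": "L" if np.argwhere(labels == rid)[:, 0].mean() < mid else "R",
                "lobe": "",
            }
            for rid in range(1, n_regions + 1)
        ],
        index=np.arange(1, n_regions + 1),
    )
    parc = chaco.Parcellation(labels=labels, regions=table)
    n_sl = int(rng.integers(1, max_streamlines + 1))
    paths = []
    for _ in range(n_sl):
        k = int(rng.integers(2, 7))
        pts = [tuple(rng.integers(0, s, size=1)[0] for s in shape) for _ in range(k)]
        paths.append(np.asarray(pts, dtype=np.int64))
    tg = chaco.Tractogram(subject_id="toy", streamlines=paths)
    n_lesion = int(rng.integers(0, 12))
    lesion_voxels = {voxels[i] for i in rng.permutation(len(voxels))[:n_lesion]}
    lesion = mask_from_voxels(shape, lesion_voxels)
    return parc, tg, lesion, lesion_voxels


@pytest.fixture
def spec_toy():
    """The three-streamline worked example: s1 (A-B through (0,0,0),(1,0,0)),
    s2 (A-B through (2,0,0) plus endpoints), s3 (B-B)."""
    shape = (4, 1, 1)
    parc = make_toy_parcellation(shape)
    s1 = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]])  # A -> B
    s2 = np.array([[1, 0, 0], [2, 0, 0], [3, 0, 0]])  # A -> B
    s3 = np.array([[3, 0, 0], [2, 0, 0], [3, 0, 0]])  # B -> B
    tg = chaco.Tractogram(subject_id="ref1", streamlines=[s1, s2, s3])
    return shape, parc, tg
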