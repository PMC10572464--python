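import json

import numpy as np
import pytest

from tfconn import (
    ConnectivityMatrix,
    NetworkAtlas,
    StudyDesign,
    default_atlas,
)


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture(scope="session")
def small_atlas():
    """Two 4-ROI networks, 8 ROIs: enough structure for fast end-to-end runs."""
    networks = {
        "NetA": ["R1", "R2 (L)", "R2 (R)", "R3"],
        "NetB": ["R4", "R5 (L)", "R5 (R)", "R6"],
    }
    labels = tuple(f"{n}.{r}" for n, rois in networks.items() for r in rois)
    return NetworkAtlas(
        roi_labels=labels,
        network_of={f"{n}.{r}": n for n, rois in networks.items() for r in rois},
        networks=("NetA", "NetB"),
        name="small",
    )


@pytest.fixture
def small_atlas_file(small_atlas, tmp_path):
    payload = {
        "name": "small",
        "networks": {
            n: [lab.split(".", 1)[1] for lab in small_atlas.roi_labels
                if small_atlas.network_of[lab] == n]
            for n in small_atlas.networks
        },
    }
    path = tmp_path / "small_atlas.json"
    path.write_text(json.dumps(payload))
    return path


def make_z_matrices(values_per_subject, labels=("A.x", "A.y")):
    """ConnectivityMatrix list with one edge per ROI pair set from flat values
    (two-ROI case) or from full symmetric matrices."""
    mats = []
    n = len(labels)
    for k, v in enumerate(values_per_subject):
        if np.isscalar(v):
            z = np.zeros((n, n))
            z[0, 1] = z[1, 0] = float(v)
        else:
            z = np.asarray(v, dtype=float)
        m = ConnectivityMatrix(
            subject_id=f"S{k:03d}",
            r=np.tanh(z),
            roi_labels=tuple(labels),
            n_timepoints_used=100,
        )
        m.z = z
        np.fill_diagonal(m.r, 1.0)
        mats.append(m)
    return mats


def make_design(group_sizes, cdr=None):
    """StudyDesign for subjects S000, S001, ... assigned to groups in order."""
    subject_ids = []
    group_of = {}
    k = 0
    for group, size in group_sizes.items():
        for _ in range(size):
            sid = f"S{k:03d}"
            subject_ids.append(sid)
            group_of[sid] = group
            k += 1
    return StudyDesign(
        subject_ids=tuple(subject_ids),
        group_of=group_of,
        cdr=cdr or {},
        seed=0,
    )
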