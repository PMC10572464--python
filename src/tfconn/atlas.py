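"""Network atlas definitions: named ROIs grouped into large-scale brain networks.

The packaged default groups 32 ROIs into 8 resting-state networks (default
mode, sensorimotor, visual, salience, dorsal attention, frontoparietal,
language, cerebellar).  A larger bookkeeping definition additionally lists the
132 anatomical parcels (Harvard-Oxford cortical/subcortical plus AAL
cerebellum) that, together with the 32 network ROIs, make up the full
164-region parcellation these labels come from.

ROI labels follow the ``Network.ROIName (L|R)`` grammar, hemisphere optional,
e.g. ``DorsalAttention.FEF (R)`` or ``DefaultMode.PCC``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "NetworkAtlas",
    "AtlasFormatError",
    "read_atlas",
    "default_atlas",
    "full_atlas",
    "parse_roi_label",
]

_LABEL_RE = re.compile(r"^(?P<network>[^.]+)\.(?P<roi>.+?)(?:\s*\((?P<hemi>[LR])\))?$")


class AtlasFormatError(ValueError):
    """Raised when an atlas definition violates its structural invariants."""


def parse_roi_label(label: str) -> tuple[str, str, str | None]:
    """Split ``Network.ROIName (L|R)`` into (network, roi, hemisphere).

    Hemisphere is ``None`` for midline/unlateralized ROIs.
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise AtlasFormatError(f"cannot parse ROI label {label!r}")
    return m.group("network"), m.group("roi").strip(), m.group("hemi")


@dataclass(frozen=True)
class NetworkAtlas:
    """Ordered ROI labels and their assignment to named networks."""

    roi_labels: tuple[str, ...]
    network_of: dict[str, str]
    networks: tuple[str, ...]
    name: str = "atlas"
    anatomical_labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label in self.roi_labels:
            if label in seen:
                raise AtlasFormatError(f"duplicate ROI label {label!r}")
            seen.add(label)
            if label not in self.network_of:
                raise AtlasFormatError(f"ROI {label!r} is not assigned to any network")
        for label in self.anatomical_labels:
            if label in seen:
                raise AtlasFormatError(f"duplicate ROI label {label!r}")
            seen.add(label)
        for net in set(self.network_of.values()):
            if net not in self.networks:
                raise AtlasFormatError(f"network {net!r} missing from network list")
        for net in self.networks:
            if not any(v == net for v in self.network_of.values()):
                raise AtlasFormatError(f"network {net!r} has no ROIs")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    @property
    def all_labels(self) -> tuple[str, ...]:
        """Network ROIs followed by anatomical bookkeeping parcels."""
        return self.roi_labels + self.anatomical_labels

    def rois_of(self, network: str) -> list[str]:
        return [r for r in self.roi_labels if self.network_of[r] == network]

    def index_of(self, label: str) -> int:
        return self.roi_labels.index(label)

    def networks_of_edges(self, edges) -> set[str]:
        out: set[str] = set()
        for a, b in edges:
            out.add(self.network_of[a])
            out.add(self.network_of[b])
        return out


def _from_mapping(payload: dict, name: str) -> NetworkAtlas:
    try:
        networks_map = payload["networks"]
    except (KeyError, TypeError):
        raise AtlasFormatError("atlas JSON must contain a 'networks' mapping")
    roi_labels: list[str] = []
    network_of: dict[str, str] = {}
    for network, rois in networks_map.items():
        if not rois:
            raise AtlasFormatError(f"network {network!r} has no ROIs")
        for roi in rois:
            label = f"{network}.{roi}"
            if label in network_of:
                raise AtlasFormatError(f"duplicate ROI label {label!r}")
            roi_labels.append(label)
            network_of[label] = network
    anatomical = tuple(payload.get("anatomical", ()))
    if len(set(anatomical)) != len(anatomical):
        dupes = sorted({a for a in anatomical if list(anatomical).count(a) > 1})
        raise AtlasFormatError(f"duplicate anatomical label {dupes[0]!r}")
    return NetworkAtlas(
        roi_labels=tuple(roi_labels),
        network_of=network_of,
        networks=tuple(networks_map),
        name=payload.get("name", name),
        anatomical_labels=anatomical,
    )


def read_atlas(path: str | Path) -> NetworkAtlas:
    """Read a JSON atlas definition mapping network names to ROI name lists."""
    path = Path(path)
    with path.open() as f:
        payload = json.load(f)
    return _from_mapping(payload, name=path.stem)


def _packaged(filename: str) -> NetworkAtlas:
    text = resources.files("tfconn.data").joinpath(filename).read_text()
    return _from_mapping(json.loads(text), name=filename)


def default_atlas() -> NetworkAtlas:
    """The packaged 8-network, 32-ROI definition."""
    return _packaged("networks_8.json")


def full_atlas() -> NetworkAtlas:
    """The packaged full definition: 32 network ROIs + 132 anatomical parcels."""
    return _packaged("atlas_164.json")
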