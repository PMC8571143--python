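"""Marker panel: names, compartments, and positivity thresholds.

A panel describes the stains measured on each segmented cell and how each is
scored: the compartment whose median intensity is thresholded (nucleus for
FOXP3, membrane for the surface markers) and a single global intensity
threshold per marker. DAPI is the nuclear counterstain driving segmentation,
so every segmented cell is treated as DAPI-positive and no DAPI threshold is
applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ConfigError

NUCLEUS = "nucleus"
MEMBRANE = "membrane"

DEFAULT_MARKERS = ("DAPI", "CD4", "CD8", "CD68", "FOXP3", "PD-1", "CD21")
DEFAULT_PHENOTYPING_MARKERS = ("CD4", "CD8", "CD68", "FOXP3", "PD-1")
DEFAULT_COMPARTMENTS: Mapping[str, str] = {
    "DAPI": NUCLEUS,
    "CD4": MEMBRANE,
    "CD8": MEMBRANE,
    "CD68": MEMBRANE,
    "FOXP3": NUCLEUS,
    "PD-1": MEMBRANE,
    "CD21": MEMBRANE,
}


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered marker panel with per-marker compartment and threshold.

    Parameters
    ----------
    markers:
        All stains in the panel, in display order.
    phenotyping_markers:
        The ordered subset used to enumerate phenotype combination codes
        (excludes DAPI and CD21 under the default panel).
    compartment_of:
        Marker -> ``"nucleus"`` or ``"membrane"``; the compartment whose
        median intensity is compared against the threshold.
    threshold_of:
        Marker -> non-negative intensity threshold (arbitrary units).
        DAPI needs no threshold (segmentation implies DAPI positivity).
    """

    markers: tuple[str, ...] = DEFAULT_MARKERS
    phenotyping_markers: tuple[str, ...] = DEFAULT_PHENOTYPING_MARKERS
    compartment_of: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COMPARTMENTS)
    )
    threshold_of: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in self.phenotyping_markers:
            if m not in self.markers:
                raise ConfigError(f"phenotyping marker {m!r} not in panel markers")
        for m in self.scored_markers:
            if m not in self.compartment_of:
                raise ConfigError(f"marker {m!r} has no compartment assignment")
            if self.compartment_of[m] not in (NUCLEUS, MEMBRANE):
                raise ConfigError(
                    f"marker {m!r}: compartment must be 'nucleus' or 'membrane'"
                )
            if m not in self.threshold_of:
                raise ConfigError(f"marker {m!r} has no threshold")
            if not (float(self.threshold_of[m]) >= 0):
                raise ConfigError(f"marker {m!r}: threshold must be non-negative")

    @property
    def scored_markers(self) -> tuple[str, ...]:
        """Markers that receive a threshold call (everything except DAPI)."""
        return tuple(m for m in self.markers if m != "DAPI")

    def intensity_column(self, marker: str) -> str:
        """Cell-table column holding the marker's scoring-compartment intensity."""
        return f"{marker}:{self.compartment_of[marker]}"

    def required_columns(self) -> tuple[str, ...]:
        return tuple(self.intensity_column(m) for m in self.scored_markers)


def load_panel(path: str | Path) -> MarkerPanel:
    """Read a panel/threshold configuration from YAML or JSON.

    The file maps marker name -> ``{compartment: ..., threshold: ...}``;
    optional top-level keys ``markers`` and ``phenotyping_markers`` override
    the default ordering.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"panel config {path} must be a mapping")
    markers = tuple(data.pop("markers", DEFAULT_MARKERS))
    phenotyping = tuple(data.pop("phenotyping_markers", DEFAULT_PHENOTYPING_MARKERS))
    compartments: dict[str, str] = dict(DEFAULT_COMPARTMENTS)
    thresholds: dict[str, float] = {}
    for marker, entry in data.items():
        if not isinstance(entry, dict):
            raise ConfigError(f"panel entry for {marker!r} must be a mapping")
        if "compartment" in entry:
            compartments[marker] = str(entry["compartment"])
        if "threshold" in entry:
            thresholds[marker] = float(entry["threshold"])
    return MarkerPanel(
        markers=markers,
        phenotyping_markers=phenotyping,
        compartment_of=compartments,
        threshold_of=thresholds,
    )


def default_panel(thresholds: Mapping[str, float] | Sequence[float] | float) -> MarkerPanel:
    """Build the default seven-marker panel with the given thresholds.

    ``thresholds`` may be a mapping marker -> value, a sequence aligned with
    the scored markers, or a single scalar applied to every scored marker.
    """
    scored = tuple(m for m in DEFAULT_MARKERS if m != "DAPI")
    if isinstance(thresholds, Mapping):
        thr = {m: float(thresholds[m]) for m in scored}
    elif isinstance(thresholds, (int, float)):
        thr = {m: float(thresholds) for m in scored}
    else:
        vals = list(thresholds)
        if len(vals) != len(scored):
            raise ConfigError(
                f"expected {len(scored)} thresholds for {scored}, got {len(vals)}"
            )
        thr = {m: float(v) for m, v in zip(scored, vals)}
    return MarkerPanel(threshold_of=thr)
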