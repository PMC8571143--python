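"""Per-core diversity features.

Two Shannon indices (natural log, i.e. nats) summarise the immune
microenvironment of a core:

* **Phenotype entropy** — entropy of the proportions of phenotype
  combination codes among included cells,  H = −Σ_i p_i ln p_i.
  Cells positive only for DAPI or only for CD21 are excluded, since these
  may contain tumour B-cell subsets.
* **Interaction entropy** — every unordered pair of cells whose centroids
  lie within a fixed radius (default 30 μm, a 3–4 cell neighbourhood) is a
  co-occurrence; co-occurrences are typed by their unordered phenotype pair
  {i, j}, and the entropy of the pair-type proportions is
  H = −Σ_{i≤j} p_ij ln p_ij. DAPI-only cells are ignored.

Alongside the entropies, the module computes per-subset cell densities
(cells/mm² of artefact-free tissue), the total immune-infiltrate ratio
(immune cells per DAPI-only cell), and the CD21+ follicular dendritic
meshwork area fraction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.ops import unary_union

from .annotations import UM2_PER_MM2, CoreSample
from .cells import positivity_column
from .errors import GeometryError, StateError, ValidationError
from .panel import MarkerPanel
from .phenotypes import CD21_ONLY, DAPI_ONLY

log = logging.getLogger(__name__)

DEFAULT_PHENOTYPE_EXCLUSIONS = frozenset({DAPI_ONLY, CD21_ONLY})
DEFAULT_INTERACTION_EXCLUSIONS = frozenset({DAPI_ONLY})
DEFAULT_RADIUS_UM = 30.0

#: marker-positivity subsets whose densities are reported by default
DEFAULT_DENSITY_SUBSETS = (
    "CD4+CD68-",
    "CD4+FOXP3+",
    "CD8+",
    "CD68+",
    "CD4+CD68-PD-1+",
    "CD8+PD-1+",
)


@dataclass(frozen=True)
class PhenotypeDistribution:
    """Counts and proportions of phenotype labels in one core."""

    counts: Mapping[str, int]
    n_cells: int
    exclusions: frozenset[str] = DEFAULT_PHENOTYPE_EXCLUSIONS

    @property
    def proportions(self) -> dict[str, float]:
        if self.n_cells == 0:
            return {}
        return {k: v / self.n_cells for k, v in self.counts.items()}


@dataclass(frozen=True)
class InteractionCounts:
    """Unordered phenotype-pair co-occurrence counts at a fixed radius.

    Keys are sorted 2-tuples of labels; self-pairs ``(x, x)`` enumerate
    unordered pairs of distinct same-label cells. Each distinct cell pair
    within the radius contributes exactly once.
    """

    radius_um: float
    counts: Mapping[tuple[str, str], int]
    n_pairs: int
    excluded_labels: frozenset[str] = DEFAULT_INTERACTION_EXCLUSIONS

    @property
    def proportions(self) -> dict[tuple[str, str], float]:
        if self.n_pairs == 0:
            return {}
        return {k: v / self.n_pairs for k, v in self.counts.items()}


@dataclass(frozen=True)
class DiversityProfile:
    """All per-core features, one bundle per TMA core."""

    core_id: str
    patient_id: str
    phenotype_entropy: float
    interaction_entropy: float
    density: Mapping[str, float]
    immune_ratio: float
    cd21_area_fraction: float
    n_cells_included: int
    n_pairs: int

    def to_row(self) -> dict:
        row = {
            "core_id": self.core_id,
            "patient_id": self.patient_id,
            "phenotype_entropy": self.phenotype_entropy,
            "interaction_entropy": self.interaction_entropy,
            "immune_ratio": self.immune_ratio,
            "cd21_area_fraction": self.cd21_area_fraction,
            "n_cells_included": self.n_cells_included,
            "n_pairs": self.n_pairs,
        }
        for name, value in self.density.items():
            row[f"density_{name}"] = value
        return row


def _labels(core_or_cells) -> pd.Series:
    cells = core_or_cells.cells if isinstance(core_or_cells, CoreSample) else core_or_cells
    if "phenotype" not in cells.columns:
        raise StateError("cells must be phenotyped first")
    return cells["phenotype"]


def phenotype_distribution(
    core: CoreSample | pd.DataFrame,
    exclusions: Iterable[str] = DEFAULT_PHENOTYPE_EXCLUSIONS,
) -> PhenotypeDistribution:
    """Count phenotype labels, dropping the excluded reserved classes."""
    labels = _labels(core)
    exclusions = frozenset(exclusions)
    kept = labels[~labels.isin(exclusions)]
    counts = kept.value_counts().to_dict()
    return PhenotypeDistribution(
        counts=counts, n_cells=int(len(kept)), exclusions=exclusions
    )


def shannon_entropy(dist: PhenotypeDistribution | Mapping[str, float]) -> float:
    """Shannon entropy −Σ p ln p in nats, with 0·ln 0 ≡ 0.

    Degenerate inputs (0 or 1 item) return 0.
    """
    if isinstance(dist, PhenotypeDistribution):
        if dist.n_cells <= 1:
            return 0.0
        p = np.array(list(dist.proportions.values()), float)
    else:
        p = np.array(list(dist.values()), float)
        if p.size == 0:
            return 0.0
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def count_interactions(
    core: CoreSample | pd.DataFrame,
    radius_um: float = DEFAULT_RADIUS_UM,
    excluded_labels: Iterable[str] = DEFAULT_INTERACTION_EXCLUSIONS,
) -> InteractionCounts:
    """Count unordered within-radius cell pairs typed by their label pair.

    Distance is closed Euclidean (``<= radius_um``) on centroids, with no
    boundary correction. Implementation uses a k-d tree radius query but is
    exactly equivalent to enumerating all O(n²) pairs.
    """
    if not radius_um > 0:
        raise ValidationError("radius_um must be positive")
    cells = core.cells if isinstance(core, CoreSample) else core
    labels = _labels(cells)
    excluded = frozenset(excluded_labels)
    keep = ~labels.isin(excluded)
    sub = cells.loc[keep]
    xy = sub[["x_um", "y_um"]].to_numpy(float)
    labs = sub["phenotype"].to_numpy(object)
    counts: dict[tuple[str, str], int] = {}
    n_pairs = 0
    if len(sub) >= 2:
        pairs = cKDTree(xy).query_pairs(float(radius_um), output_type="ndarray")
        n_pairs = len(pairs)
        if n_pairs:
            la, lb = labs[pairs[:, 0]], labs[pairs[:, 1]]
            keys = [(a, b) if a <= b else (b, a) for a, b in zip(la, lb)]
            counts = pd.Series(keys).value_counts().to_dict()
    return InteractionCounts(
        radius_um=float(radius_um),
        counts=counts,
        n_pairs=int(n_pairs),
        excluded_labels=excluded,
    )


def interaction_entropy(counts: InteractionCounts) -> float:
    """Shannon entropy of the pair-type proportions, in nats."""
    if counts.n_pairs <= 1:
        if counts.n_pairs == 0:
            log.debug("no within-radius pairs; interaction entropy 0")
        return 0.0
    return shannon_entropy(counts.proportions)


def parse_subset(expression: str, panel: MarkerPanel) -> list[tuple[str, bool]]:
    """Parse a marker-positivity expression like ``CD4+CD68-PD-1+``."""
    names = sorted((m for m in panel.markers), key=len, reverse=True)
    pattern = re.compile("(" + "|".join(re.escape(m) for m in names) + r")([+-])")
    terms: list[tuple[str, bool]] = []
    pos = 0
    while pos < len(expression):
        m = pattern.match(expression, pos)
        if m is None:
            raise ValidationError(
                f"cannot parse subset expression {expression!r} at offset {pos}"
            )
        terms.append((m.group(1), m.group(2) == "+"))
        pos = m.end()
    if not terms:
        raise ValidationError("empty subset expression")
    return terms


def cell_density(core: CoreSample, subset: str, panel: MarkerPanel) -> float:
    """Cells matching a positivity expression per mm² of tissue.

    A term mentions a marker explicitly; unmentioned markers are
    unconstrained, so ``CD68+`` counts all CD68-positive cells regardless of
    other markers.
    """
    area = core.tissue_area_mm2
    if not area > 0:
        raise ValidationError(f"core {core.core_id}: non-positive tissue area")
    mask = np.ones(len(core.cells), bool)
    for marker, wanted in parse_subset(subset, panel):
        col = positivity_column(marker)
        if col not in core.cells.columns:
            raise StateError(f"cells not scored for marker {marker!r}")
        mask &= core.cells[col].to_numpy(bool) == wanted
    return float(mask.sum()) / area


def immune_ratio(core: CoreSample | pd.DataFrame) -> float:
    """Immune cells (any phenotyping marker positive) per DAPI-only cell.

    CD21-only cells count in neither term. Undefined (error) when the core
    has no DAPI-only cells.
    """
    labels = _labels(core)
    n_dapi_only = int((labels == DAPI_ONLY).sum())
    if n_dapi_only == 0:
        raise ValidationError("immune ratio undefined: no DAPI-only cells")
    n_immune = int((~labels.isin((DAPI_ONLY, CD21_ONLY))).sum())
    return n_immune / n_dapi_only


def cd21_area_fraction(core: CoreSample) -> float:
    """Fraction of artefact-free tissue covered by CD21+ meshwork polygons."""
    ann = core.annotations
    ann.validate()
    denom = ann.tissue_area_mm2
    if not denom > 0:
        raise ValidationError(f"core {core.core_id}: non-positive tissue area")
    if not ann.cd21_meshwork:
        return 0.0
    mesh = unary_union(ann.cd21_meshwork).intersection(ann.tissue)
    if ann.exclusions:
        mesh = mesh.difference(unary_union(ann.exclusions))
    return (mesh.area / UM2_PER_MM2) / denom


@dataclass(frozen=True)
class ProfileSettings:
    """Settings bundle for :func:`profile_core` (defaults follow the method)."""

    radius_um: float = DEFAULT_RADIUS_UM
    phenotype_exclusions: frozenset[str] = DEFAULT_PHENOTYPE_EXCLUSIONS
    interaction_exclusions: frozenset[str] = DEFAULT_INTERACTION_EXCLUSIONS
    density_subsets: tuple[str, ...] = DEFAULT_DENSITY_SUBSETS


def profile_core(
    core: CoreSample,
    panel: MarkerPanel,
    settings: ProfileSettings = ProfileSettings(),
) -> DiversityProfile:
    """Compute the full per-core feature bundle."""
    dist = phenotype_distribution(core, settings.phenotype_exclusions)
    if dist.n_cells <= 1:
        log.warning(
            "core %s: %d included cells; phenotype entropy set to 0",
            core.core_id,
            dist.n_cells,
        )
    inter = count_interactions(core, settings.radius_um, settings.interaction_exclusions)
    density = {s: cell_density(core, s, panel) for s in settings.density_subsets}
    return DiversityProfile(
        core_id=core.core_id,
        patient_id=core.patient_id,
        phenotype_entropy=shannon_entropy(dist),
        interaction_entropy=interaction_entropy(inter),
        density=density,
        immune_ratio=immune_ratio(core),
        cd21_area_fraction=cd21_area_fraction(core),
        n_cells_included=dist.n_cells,
        n_pairs=inter.n_pairs,
    )


def profiles_to_frame(profiles: Sequence[DiversityProfile]) -> pd.DataFrame:
    """Stack per-core profiles into a tidy features table (one row per core)."""
    return pd.DataFrame([p.to_row() for p in profiles])


def interactions_to_frame(
    per_core: Mapping[str, InteractionCounts]
) -> pd.DataFrame:
    """Long-format interaction table: core_id, label_i, label_j, count, proportion."""
    rows = []
    for core_id, ic in per_core.items():
        props = ic.proportions
        for (a, b), n in sorted(ic.counts.items()):
            rows.append(
                {
                    "core_id": core_id,
                    "label_i": a,
                    "label_j": b,
                    "count": n,
                    "proportion": props[(a, b)],
                }
            )
    return pd.DataFrame(
        rows, columns=["core_id", "label_i", "label_j", "count", "proportion"]
    )
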