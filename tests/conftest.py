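import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from tmediv.annotations import CoreAnnotations, CoreSample
from tmediv.cells import assign_phenotypes, positivity_column, score_cells
from tmediv.panel import DEFAULT_PHENOTYPING_MARKERS, default_panel
from tmediv.phenotypes import combination_code


@pytest.fixture
def panel():
    """Default seven-marker panel with a uniform threshold of 4.0."""
    return default_panel(4.0)


def code(*positives):
    m = DEFAULT_PHENOTYPING_MARKERS
    return combination_code([x in positives for x in m], m)


@pytest.fixture
def make_core(panel):
    """Factory: build a scored+phenotyped CoreSample from (x, y, marker-set) triples.

    Each cell spec is ``(x, y, positives)`` where ``positives`` is an
    iterable of marker names to set above threshold (may include "CD21").
    Tissue is a square of the given side (μm).
    """

    def build(cell_specs, side=1000.0, exclusions=(), cd21_polys=(), core_id="T1"):
        rows = []
        for i, (x, y, positives) in enumerate(cell_specs):
            row = {
                "cell_id": f"c{i}",
                "core_id": core_id,
                "patient_id": "PT",
                "x_um": x,
                "y_um": y,
            }
            for m in panel.scored_markers:
                designated = panel.intensity_column(m)
                other = (
                    f"{m}:membrane"
                    if designated.endswith("nucleus")
                    else f"{m}:nucleus"
                )
                row[designated] = 8.0 if m in positives else 1.0
                row[other] = 1.0
            row["DAPI:nucleus"] = 10.0
            row["DAPI:membrane"] = 1.0
            rows.append(row)
        if rows:
            cells = pd.DataFrame(rows)
        else:
            cols = ["cell_id", "core_id", "patient_id", "x_um", "y_um"]
            cols += [f"{m}:{c}" for m in panel.markers for c in ("nucleus", "membrane")]
            cells = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
            for m in panel.markers:
                cells[f"{m}:nucleus"] = cells[f"{m}:nucleus"].astype(float)
                cells[f"{m}:membrane"] = cells[f"{m}:membrane"].astype(float)
        cells = assign_phenotypes(score_cells(cells, panel), panel)
        ann = CoreAnnotations(
            core_id=core_id,
            tissue=Polygon([(0, 0), (side, 0), (side, side), (0, side)]),
            exclusions=list(exclusions),
            cd21_meshwork=list(cd21_polys),
        )
        return CoreSample(core_id=core_id, patient_id="PT", cells=cells, annotations=ann)

    return build


def naive_pair_counts(xy, labels, radius):
    """O(n²) all-pairs co-occurrence oracle (closed distance rule)."""
    from scipy.spatial.distance import cdist

    d = cdist(xy, xy)
    counts = {}
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= radius:
                key = tuple(sorted((labels[i], labels[j])))
                counts[key] = counts.get(key, 0) + 1
    return counts
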