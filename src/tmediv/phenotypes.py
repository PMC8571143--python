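"""Phenotype labels.

Every cell is assigned exactly one label. With the default five phenotyping
markers there are 2^5 = 32 positivity-combination codes, written like
``CD4+CD8-CD68-FOXP3+PD-1-``. Two reserved categories cover cells outside
the combination space:

* ``DAPI_ONLY`` — no phenotyping marker positive and CD21 negative; in this
  tissue these are predominantly tumour B cells.
* ``CD21_ONLY`` — no phenotyping marker positive but CD21 positive
  (follicular dendritic cells, possibly B-cell subsets).

A cell positive for CD21 *and* at least one phenotyping marker keeps its
combination code: CD21 does not participate in the code.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable, Mapping, Sequence

DAPI_ONLY = "DAPI_ONLY"
CD21_ONLY = "CD21_ONLY"
RESERVED_LABELS = (DAPI_ONLY, CD21_ONLY)


def combination_code(flags: Sequence[bool], markers: Sequence[str]) -> str:
    """Positivity vector -> combination code string (e.g. ``CD4+CD8-...``)."""
    if len(flags) != len(markers):
        raise ValueError("flags and markers must have equal length")
    return "".join(f"{m}{'+' if f else '-'}" for m, f in zip(markers, flags))


def all_combination_codes(markers: Sequence[str]) -> list[str]:
    """All 2^k combination codes in lexicographic (−/+ per marker) order."""
    return [
        combination_code(bits, markers)
        for bits in product((False, True), repeat=len(markers))
    ]


def label_for(
    positive: Mapping[str, bool],
    phenotyping_markers: Sequence[str],
    cd21_marker: str = "CD21",
) -> str:
    """Label a single scored cell.

    ``positive`` maps marker -> call; ``cd21_marker`` may be absent from the
    mapping (treated as negative).
    """
    flags = [bool(positive[m]) for m in phenotyping_markers]
    if any(flags):
        return combination_code(flags, phenotyping_markers)
    return CD21_ONLY if positive.get(cd21_marker, False) else DAPI_ONLY


def parse_code(code: str, markers: Sequence[str]) -> dict[str, bool]:
    """Combination code string -> marker -> bool. Reserved labels map to all-False."""
    if code in RESERVED_LABELS:
        return {m: False for m in markers}
    out: dict[str, bool] = {}
    rest = code
    for m in markers:
        if not rest.startswith(m) or len(rest) <= len(m) or rest[len(m)] not in "+-":
            raise ValueError(f"malformed phenotype code {code!r} for markers {markers}")
        out[m] = rest[len(m)] == "+"
        rest = rest[len(m) + 1 :]
    if rest:
        raise ValueError(f"trailing text {rest!r} in phenotype code {code!r}")
    return out


def positive_markers(code: str, markers: Iterable[str]) -> frozenset[str]:
    """Set of markers called positive in a combination code (empty for reserved)."""
    if code in RESERVED_LABELS:
        return frozenset()
    parsed = parse_code(code, tuple(markers))
    return frozenset(m for m, f in parsed.items() if f)
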