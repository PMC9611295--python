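"""Electrode montage: channel labels, scalp regions and edge bookkeeping.

The analysis operates on 60 scalp channels of an extended 10-20 layout
(a conventional 64-channel cap with the cerebellar and ocular channels
CB1/CB2/HEO/VEO removed).  Channel order is fixed and shared by every
downstream matrix; unordered channel pairs ("edges") are enumerated in
upper-triangle row-major order, giving n(n-1)/2 = 1770 edges for n = 60.

Scalp regions are assigned by label prefix:

    Fp/AF/F -> frontal,  FC/C -> central,  CP/P -> parietal,
    PO/O -> occipital,   FT/T/TP -> temporal

with the longest matching prefix winning (so FC is central, not frontal).
The packaged label/region table is a plain two-column CSV that users can
replace wholesale via :func:`load_montage`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

REGIONS = ("frontal", "central", "parietal", "occipital", "temporal")

# longest prefixes first so FC/CP/PO/FT/TP beat their one-letter heads
_PREFIX_REGION = [
    ("FP", "frontal"),
    ("AF", "frontal"),
    ("FC", "central"),
    ("CP", "parietal"),
    ("PO", "occipital"),
    ("FT", "temporal"),
    ("TP", "temporal"),
    ("F", "frontal"),
    ("C", "central"),
    ("P", "parietal"),
    ("O", "occipital"),
    ("T", "temporal"),
]


def region_for_label(label: str) -> str:
    """Scalp region of a 10-20 channel label, by longest-prefix rule."""
    up = label.upper()
    for prefix, region in _PREFIX_REGION:
        if up.startswith(prefix):
            return region
    raise KeyError(f"no region rule matches channel label {label!r}")


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels plus a total label -> region map."""

    labels: tuple[str, ...]
    region_of: dict[str, str] = field(compare=False)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        missing = [lb for lb in self.labels if lb not in self.region_of]
        if missing:
            raise ValueError(f"labels without a region: {missing}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        n = len(self.labels)
        return n * (n - 1) // 2

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None

    def edge_index(self, a: str | int, b: str | int) -> int:
        """Flat index of the unordered pair (a, b) in upper-triangle order."""
        i = a if isinstance(a, int) else self.index(a)
        j = b if isinstance(b, int) else self.index(b)
        if i == j:
            raise ValueError("an edge needs two distinct channels")
        if i > j:
            i, j = j, i
        n = self.n_channels
        return i * n - i * (i + 1) // 2 + (j - i - 1)

    def edge_at(self, k: int) -> tuple[int, int]:
        """Inverse of :meth:`edge_index`: (i, j) with i < j for flat index k."""
        n = self.n_channels
        if not 0 <= k < self.n_edges:
            raise IndexError(f"edge index {k} out of range [0, {self.n_edges})")
        i = 0
        row = n - 1
        while k >= row:
            k -= row
            i += 1
            row -= 1
        return i, i + 1 + k

    def edge_labels(self, k: int) -> tuple[str, str]:
        i, j = self.edge_at(k)
        return self.labels[i], self.labels[j]


def edge_region_category(edge: tuple[str, str], montage: Montage) -> str:
    """Canonical region-pair label of an edge, e.g. ``"frontal–parietal"``.

    Region order inside the label is canonical: frontal first when present,
    otherwise the fixed REGIONS order.
    """
    a, b = edge
    for name in (a, b):
        if name not in montage.region_of:
            raise KeyError(f"unknown channel label {name!r}")
    ra, rb = montage.region_of[a], montage.region_of[b]
    first, second = sorted((ra, rb), key=REGIONS.index)
    return f"{first}–{second}"


def load_montage(path: str | Path | None = None) -> Montage:
    """Load a montage from a two-column ``label,region`` CSV.

    With no argument, loads the packaged 60-channel fixture.
    """
    if path is None:
        src = resources.files("plinet.data").joinpath("montage60.csv")
        text = src.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    labels: list[str] = []
    region_of: dict[str, str] = {}
    for row in csv.reader(text.strip().splitlines()):
        if not row or row[0].startswith("#"):
            continue
        label, region = row[0].strip(), row[1].strip()
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r} for channel {label!r}")
        labels.append(label)
        region_of[label] = region
    return Montage(labels=tuple(labels), region_of=region_of)


def default_montage() -> Montage:
    """The packaged 60-channel extended 10-20 montage."""
    return load_montage(None)
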