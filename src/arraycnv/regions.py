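"""Regions of interest and the proportional overlapping-window layout.

A region (gene or explicit interval, hg38 coordinates) is expanded by a
symmetric buffer (default 250 kb) and then tiled with a proportional
window scheme controlled by two integers:

* ``split`` — the region is conceptually divided into ``split`` equal,
  non-overlapping segments; the segment length is the window length,
  ``W = floor(L / split)`` for region length ``L``.
* ``total_windows`` — ``n`` windows of length ``W`` are laid across the
  region at stride ``s = floor((L - W) / (n - 1))`` (``s = 0`` for a
  single window), so consecutive windows overlap by ``W - s`` bases.

Because window length and stride are proportional to the region, the
same (split, total_windows) pair yields equal-length feature sequences
for regions of any size, which is what lets one trained model serve
many regions.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_BUFFER_BP",
    "RegionSpec",
    "WindowScheme",
    "load_gene_table",
    "resolve_region",
    "compute_window_scheme",
    "assign_snps_to_windows",
]

DEFAULT_BUFFER_BP = 250_000


@dataclasses.dataclass(frozen=True)
class RegionSpec:
    """A genomic interval plus the symmetric buffer applied around it."""

    chromosome: str
    start: int
    stop: int
    buffer: int = DEFAULT_BUFFER_BP
    name: str | None = None

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError(f"region stop must exceed start: {self.start}..{self.stop}")
        if self.buffer < 0:
            raise ValueError("buffer must be >= 0")

    @property
    def buffered_start(self) -> int:
        return max(1, self.start - self.buffer)

    @property
    def buffered_stop(self) -> int:
        return self.stop + self.buffer

    @property
    def length(self) -> int:
        """Unbuffered length, stop − start."""
        return self.stop - self.start

    @property
    def buffered_length(self) -> int:
        return self.buffered_stop - self.buffered_start


@dataclasses.dataclass(frozen=True)
class WindowScheme:
    """Overlapping-window layout over a (possibly buffered) interval.

    ``windows`` holds half-open ``[start, end)`` intervals; the last
    window's end is raised to the interval stop so integer flooring of
    the stride never truncates coverage.
    """

    split: int
    total_windows: int
    window_length: int
    stride: int
    region_start: int
    region_stop: int
    windows: tuple[tuple[int, int], ...]

    @property
    def starts(self) -> np.ndarray:
        return np.array([w[0] for w in self.windows], dtype=np.int64)

    @property
    def ends(self) -> np.ndarray:
        return np.array([w[1] for w in self.windows], dtype=np.int64)


def load_gene_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the bundled (or a user-supplied) gene coordinate table.

    Columns: name, chromosome, start, stop, assembly (hg38).
    """
    if path is None:
        src = resources.files("arraycnv").joinpath("data/genes.tsv")
        with resources.as_file(src) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    required = {"name", "chromosome", "start", "stop"}
    if not required.issubset(table.columns):
        raise ValueError(f"gene table needs columns {sorted(required)}")
    return table


def resolve_region(
    query: str | tuple[str, int, int],
    buffer: int = DEFAULT_BUFFER_BP,
    gene_table: pd.DataFrame | None = None,
) -> RegionSpec:
    """Resolve a gene name or (chromosome, start, stop) triple to a RegionSpec."""
    if isinstance(query, str):
        table = load_gene_table() if gene_table is None else gene_table
        hits = table.loc[table["name"].str.upper() == query.upper()]
        if hits.empty:
            known = ", ".join(sorted(table["name"]))
            raise KeyError(f"unknown gene {query!r}; known genes: {known}")
        row = hits.iloc[0]
        return RegionSpec(
            chromosome=str(row["chromosome"]),
            start=int(row["start"]),
            stop=int(row["stop"]),
            buffer=buffer,
            name=str(row["name"]),
        )
    chromosome, start, stop = query
    return RegionSpec(chromosome=str(chromosome), start=int(start), stop=int(stop), buffer=buffer)


def compute_window_scheme(
    region: RegionSpec,
    split: int,
    total_windows: int,
    use_buffer: bool = True,
) -> WindowScheme:
    """Compute the proportional overlapping-window layout for a region.

    With ``use_buffer`` the layout spans the buffered interval; without
    it, the raw gene interval (useful for reasoning about the geometry
    itself).  Window length ``W = floor(L / split)`` and stride
    ``s = floor((L − W) / (n − 1))`` for ``n = total_windows > 1``.
    """
    if split < 1:
        raise ValueError("split must be >= 1")
    if total_windows < split:
        raise ValueError(f"total_windows ({total_windows}) must be >= split ({split})")
    lo = region.buffered_start if use_buffer else region.start
    hi = region.buffered_stop if use_buffer else region.stop
    length = hi - lo
    if length < total_windows:
        raise ValueError(
            f"region length {length} too small for {total_windows} distinct windows"
        )
    window_length = length // split
    # capping at the window length keeps the tiling gapless when flooring
    # leaves a remainder (only possible when total_windows == split)
    stride = (
        min(window_length, (length - window_length) // (total_windows - 1))
        if total_windows > 1
        else 0
    )
    if total_windows > 1 and stride == 0:
        raise ValueError(
            f"too few bases for {total_windows} distinct windows of length "
            f"{window_length} over {length} bp; lower total_windows or raise split"
        )
    windows = []
    for i in range(total_windows):
        w_start = lo + i * stride
        w_end = w_start + window_length
        if i == total_windows - 1:
            w_end = hi
        windows.append((w_start, w_end))
    return WindowScheme(
        split=split,
        total_windows=total_windows,
        window_length=window_length,
        stride=stride,
        region_start=lo,
        region_stop=hi,
        windows=tuple(windows),
    )


def assign_snps_to_windows(positions, scheme: WindowScheme) -> list[np.ndarray]:
    """Index SNP positions into every window containing them.

    Accepts a position array or a :class:`~arraycnv.signals.SignalPanel`
    (whose unique SNP positions are used).  Windows overlap, so one SNP
    commonly belongs to several windows; a window may be empty.  Returns
    one integer index array per window.
    """
    if hasattr(positions, "snps"):
        positions = positions.snps["position"].to_numpy()
    positions = np.asarray(positions)
    return [
        np.flatnonzero((positions >= s) & (positions < e)) for s, e in scheme.windows
    ]
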