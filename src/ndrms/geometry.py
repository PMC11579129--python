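"""Electrode grid geometry: layouts, pair distances and equidistant binning.

ECoG grids are modelled as planar point sets (coordinates in mm).  The
analyses downstream group electrode pairs by inter-electrode distance
(IED); a "bin" is the set of pairs whose centre-to-centre distance rounds
to the same value (0.1 mm resolution by default).  Bins with fewer than
``min_pairs`` pairs (default 10) are discarded before any averaging.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ElectrodeLayout",
    "PairTable",
    "IedBins",
    "make_square_layout",
    "make_hex_layout",
    "pair_distance_table",
    "bin_equidistant",
    "matched_ied_bins",
    "read_electrodes_tsv",
    "write_electrodes_tsv",
]


@dataclass(frozen=True)
class ElectrodeLayout:
    """A planar electrode grid.

    Attributes
    ----------
    electrode_id : list of str
        Channel labels, row-major from the layout's origin corner.
    positions : ndarray, shape (n, 2)
        Electrode centre coordinates in mm.
    pitch_mm : float
        Nearest-neighbour centre-to-centre distance.
    exposed_diameter_mm : float
        Diameter of the conductive contact open to tissue; sets the
        spatial averaging footprint of each electrode.
    lattice : str
        One of ``{"square", "hex", "custom"}``.
    """

    electrode_id: tuple[str, ...]
    positions: np.ndarray
    pitch_mm: float
    exposed_diameter_mm: float
    lattice: str = "custom"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array of mm coordinates")
        object.__setattr__(self, "positions", pos)
        if len(self.electrode_id) != len(pos):
            raise ValueError("electrode_id and positions length mismatch")
        if self.pitch_mm <= 0:
            raise ValueError("pitch_mm must be positive")
        if not 0 < self.exposed_diameter_mm < self.pitch_mm:
            raise ValueError("exposed_diameter_mm must lie in (0, pitch_mm)")
        if len(pos) >= 2:
            d = _pairwise_distances(pos)
            dmin = d[np.triu_indices(len(pos), k=1)].min()
            if dmin < 1e-12:
                raise ValueError("electrode positions must be unique")
            if self.lattice != "custom" and abs(dmin - self.pitch_mm) > 1e-9:
                raise ValueError(
                    f"minimum pairwise distance {dmin} does not equal pitch {self.pitch_mm}"
                )

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_id)


@dataclass
class PairTable:
    """All unordered pairs of (good) electrodes with Euclidean distances."""

    index_a: np.ndarray  # int indices into the layout
    index_b: np.ndarray
    id_a: tuple[str, ...]
    id_b: tuple[str, ...]
    distance_mm: np.ndarray
    included: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.included is None:
            self.included = np.ones(len(self.distance_mm), dtype=bool)
        if np.any(self.distance_mm <= 0):
            raise ValueError("pair distances must be positive")

    def __len__(self) -> int:
        return len(self.distance_mm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "a": list(self.id_a),
                "b": list(self.id_b),
                "distance_mm": self.distance_mm,
                "included": self.included,
            }
        )


@dataclass
class IedBins:
    """Pairs grouped by rounded IED; bins below ``min_pairs`` removed."""

    bin_distance_mm: np.ndarray  # representative (rounded) distance, ascending
    pair_count: np.ndarray
    members: list[np.ndarray]  # row indices into the PairTable per bin

    def __len__(self) -> int:
        return len(self.bin_distance_mm)


def _pairwise_distances(pos: np.ndarray) -> np.ndarray:
    diff = pos[:, None, :] - pos[None, :, :]
    return np.sqrt((diff**2).sum(-1))


def _labels(n: int) -> tuple[str, ...]:
    width = max(2, len(str(n)))
    return tuple(f"E{i + 1:0{width}d}" for i in range(n))


def make_square_layout(
    rows: int, cols: int, pitch_mm: float, exposed_diameter_mm: float
) -> ElectrodeLayout:
    """Square lattice, row-major ordering; positions in mm.

    ``(8, 12, 3.0, 1.0)`` gives the 96-contact high-density grid and
    ``(4, 8, 0.9, 0.2)`` the 32-contact ultra-high-density variant.
    """
    if rows < 1 or cols < 1 or pitch_mm <= 0:
        raise ValueError("rows, cols must be >= 1 and pitch_mm > 0")
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    pos = np.column_stack([cc.ravel() * pitch_mm, rr.ravel() * pitch_mm])
    return ElectrodeLayout(_labels(rows * cols), pos, pitch_mm, exposed_diameter_mm, "square")


def make_hex_layout(
    rows: int, cols: int, pitch_mm: float, exposed_diameter_mm: float
) -> ElectrodeLayout:
    """Triangular (hexagonal-packing) lattice.

    Alternate rows are offset by ``pitch/2`` and rows are spaced
    ``pitch * sqrt(3)/2`` apart, so the nearest-neighbour distance equals
    the pitch.  A single row degenerates to a line.
    """
    if rows < 1 or cols < 1 or pitch_mm <= 0:
        raise ValueError("rows, cols must be >= 1 and pitch_mm > 0")
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x = cc.ravel() * pitch_mm + (rr.ravel() % 2) * pitch_mm / 2.0
    y = rr.ravel() * pitch_mm * np.sqrt(3.0) / 2.0
    return ElectrodeLayout(
        _labels(rows * cols), np.column_stack([x, y]), pitch_mm, exposed_diameter_mm, "hex"
    )


def pair_distance_table(
    layout: ElectrodeLayout, good_mask: np.ndarray | None = None
) -> PairTable:
    """Enumerate all unordered pairs of good electrodes with distances.

    Bad electrodes (``good_mask`` False) are excluded entirely; at least
    two good electrodes are required.
    """
    n = layout.n_electrodes
    if good_mask is None:
        good_mask = np.ones(n, dtype=bool)
    good_mask = np.asarray(good_mask, dtype=bool)
    if good_mask.shape != (n,):
        raise ValueError("good_mask must have one entry per electrode")
    good = np.flatnonzero(good_mask)
    if len(good) < 2:
        raise ValueError("need at least 2 good electrodes to form pairs")
    ia, ib = zip(*itertools.combinations(good.tolist(), 2))
    ia = np.asarray(ia)
    ib = np.asarray(ib)
    dist = np.sqrt(((layout.positions[ia] - layout.positions[ib]) ** 2).sum(-1))
    ids = layout.electrode_id
    return PairTable(
        index_a=ia,
        index_b=ib,
        id_a=tuple(ids[i] for i in ia),
        id_b=tuple(ids[i] for i in ib),
        distance_mm=dist,
    )


def bin_equidistant(
    pairs: PairTable, round_to_mm: float = 0.1, min_pairs: int = 10
) -> IedBins:
    """Group included pairs into equidistant IED bins.

    Distances are rounded to the nearest multiple of ``round_to_mm``
    (0.1 mm by default, so a 3 mm-lattice diagonal of 4.2426 mm labels
    as 4.2).  Bins with fewer than ``min_pairs`` pairs are dropped.
    """
    if round_to_mm <= 0:
        raise ValueError("round_to_mm must be positive")
    if min_pairs < 1:
        raise ValueError("min_pairs must be >= 1")
    if len(pairs) == 0:
        raise ValueError("empty pair table")
    rows = np.flatnonzero(pairs.included)
    keys = np.round(pairs.distance_mm[rows] / round_to_mm).astype(np.int64)
    order = np.argsort(keys, kind="stable")
    rows, keys = rows[order], keys[order]
    uniq, starts, counts = np.unique(keys, return_index=True, return_counts=True)
    keep = counts >= min_pairs
    members = [rows[s : s + c] for s, c, k in zip(starts, counts, keep) if k]
    return IedBins(
        # round away float residue of key*round_to (e.g. 14*0.1 = 1.4000000000000001)
        bin_distance_mm=np.round(uniq[keep] * round_to_mm, 9),
        pair_count=counts[keep],
        members=members,
    )


def matched_ied_bins(
    bins_a: IedBins, bins_b: IedBins, tolerance_mm: float = 0.2
) -> list[tuple[int, int, float, float]]:
    """Greedily match bin distances across two grids within a tolerance.

    Returns ``(bin_index_a, bin_index_b, distance_a, distance_b)`` tuples,
    closest matches first; each bin is used at most once.  With the default
    grids this pairs 3.0 mm (HD) with 3.1 mm (UHD) and 4.2 mm with 4.1 mm.
    """
    if tolerance_mm <= 0:
        raise ValueError("tolerance_mm must be positive")
    da, db = bins_a.bin_distance_mm, bins_b.bin_distance_mm
    cand = [
        (abs(da[i] - db[j]), i, j)
        for i in range(len(da))
        for j in range(len(db))
        if abs(da[i] - db[j]) <= tolerance_mm + 1e-12
    ]
    cand.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((i, j, float(da[i]), float(db[j])))
    out.sort(key=lambda t: t[2])
    return out


def write_electrodes_tsv(layout: ElectrodeLayout, path) -> None:
    """Write a BIDS-iEEG-style ``_electrodes.tsv`` (name, x, y, z, size)."""
    df = pd.DataFrame(
        {
            "name": list(layout.electrode_id),
            "x": layout.positions[:, 0],
            "y": layout.positions[:, 1],
            "z": np.zeros(layout.n_electrodes),
            "size": np.full(layout.n_electrodes, layout.exposed_diameter_mm),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_electrodes_tsv(path) -> ElectrodeLayout:
    """Read a ``_electrodes.tsv``; pitch is inferred as the minimum pair
    distance and the lattice is marked custom.  Given electrode order is
    preserved."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "x", "y", "size"}
    if not required.issubset(df.columns):
        raise ValueError(f"electrodes.tsv must contain columns {sorted(required)}")
    pos = df[["x", "y"]].to_numpy(dtype=float)
    pitch = float(_pairwise_distances(pos)[np.triu_indices(len(pos), k=1)].min())
    size = float(df["size"].iloc[0])
    return ElectrodeLayout(
        tuple(str(n) for n in df["name"]), pos, pitch, size, "custom"
    )
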