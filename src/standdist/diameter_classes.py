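"""Diameter-class histograms and stand records.

Tree lists (one DBH per tree, cm) are binned into fixed-width diameter
classes — 2 cm by default, anchored at a lower bound of 1 cm so that the
class with midpoint k covers [k-1, k+1): a 1.0-2.9 cm tree falls in class 2,
a 3.0-4.9 cm tree in class 4, and so on.  Relative frequencies f_k = n_k / N
and cumulative frequencies F_k = sum_{j<=k} f_j are the observed cumulative
diameter distribution that the nonlinear-regression fitting matches.

Binned skewness and kurtosis are frequency-weighted central moments over the
class midpoints, scaled by s^3 and s^4; kurtosis is reported raw
(non-excess) by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StandRecord",
    "DiameterHistogram",
    "assign_class",
    "build_histogram",
    "quadratic_mean_dbh",
    "binned_skewness",
    "binned_kurtosis",
    "read_tree_lists",
    "read_stand_characteristics",
    "write_histogram",
    "CHARACTERISTIC_NAMES",
]

#: Lower bound of the first diameter class, cm (trees below this are not
#: measurable as DBH records in the class system).
FIRST_CLASS_LOWER = 1.0

#: Stand characteristics available as regressors in stand-level prediction.
CHARACTERISTIC_NAMES = (
    "age",
    "planting_density",
    "stand_density",
    "site_index",
    "mean_height",
    "dominant_height",
    "dg",
)


@dataclass
class StandRecord:
    """One stand: its tree list plus whole-stand characteristics.

    diameters are DBH in cm; age in years; densities in stems/ha; site index
    (dominant height at reference age 20) and heights in m.  ``thinned``
    marks stands that received a thinning from below.
    """

    stand_id: str
    diameters: np.ndarray
    age: float
    planting_density: float
    stand_density: float
    site_index: float
    mean_height: float
    dominant_height: float
    thinned: bool = False

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.diameters.size and np.any(self.diameters <= 0):
            raise ValueError(f"stand {self.stand_id}: all diameters must be > 0")

    @property
    def n_trees(self) -> int:
        return int(self.diameters.size)

    @property
    def dg(self) -> float:
        """Quadratic mean DBH of the tree list, cm."""
        return quadratic_mean_dbh(self.diameters)

    def characteristics(self) -> dict[str, float]:
        """Stand characteristics as a name -> value mapping (includes D_g)."""
        return {
            "age": self.age,
            "planting_density": self.planting_density,
            "stand_density": self.stand_density,
            "site_index": self.site_index,
            "mean_height": self.mean_height,
            "dominant_height": self.dominant_height,
            "dg": self.dg,
        }


@dataclass
class DiameterHistogram:
    """Diameter-class histogram of one stand.

    class_midpoints are the class midpoints in cm (even integers under the
    default 2-cm convention); empty interior classes are retained with zero
    count so the cumulative curve is evaluated on a contiguous grid.
    """

    class_midpoints: np.ndarray
    class_width: float
    counts: np.ndarray
    n_total: int
    frequencies: np.ndarray = field(init=False)
    cumulative: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.class_midpoints = np.asarray(self.class_midpoints, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.sum() != self.n_total:
            raise ValueError("counts must sum to n_total")
        self.frequencies = self.counts / self.n_total
        self.cumulative = np.cumsum(self.frequencies)

    @property
    def upper_boundaries(self) -> np.ndarray:
        return self.class_midpoints + self.class_width / 2.0

    @property
    def lower_boundaries(self) -> np.ndarray:
        return self.class_midpoints - self.class_width / 2.0

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.counts))


def assign_class(d, width: float = 2.0, lower: float = FIRST_CLASS_LOWER):
    """Midpoint of the diameter class containing d.

    Classes are half-open intervals [lower + i*width, lower + (i+1)*width);
    with the defaults, d = 1.0..2.999 -> 2, d = 3.0..4.999 -> 4.  Diameters
    below ``lower`` raise — they fall outside the class system.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < lower):
        raise ValueError(f"diameter below the first class lower bound {lower} cm")
    out = lower + width * np.floor((d - lower) / width) + width / 2.0
    return out if out.ndim else float(out)


def build_histogram(stand: StandRecord, width: float = 2.0) -> DiameterHistogram:
    """Bin a stand's tree list into a DiameterHistogram.

    Interior classes with zero trees are kept so that midpoints form an
    arithmetic grid from the first to the last occupied class.
    """
    d = stand.diameters
    if d.size == 0:
        raise ValueError(f"stand {stand.stand_id}: empty tree list")
    mids = assign_class(d, width=width)
    mids = np.atleast_1d(mids)
    lo, hi = mids.min(), mids.max()
    grid = np.arange(lo, hi + width / 2.0, width)
    idx = np.rint((mids - lo) / width).astype(int)
    counts = np.bincount(idx, minlength=grid.size)
    return DiameterHistogram(
        class_midpoints=grid, class_width=width, counts=counts, n_total=d.size
    )


def quadratic_mean_dbh(diameters) -> float:
    """Quadratic mean DBH, D_g = sqrt(sum d^2 / n) — the diameter of the tree
    of mean basal area; always >= the arithmetic mean."""
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("cannot compute D_g of an empty tree list")
    return float(np.sqrt(np.mean(d**2)))


def _weighted_moments(hist: DiameterHistogram):
    x = hist.class_midpoints
    f = hist.frequencies
    mean = float(np.sum(f * x))
    var = float(np.sum(f * (x - mean) ** 2))
    if var <= 0:
        raise ValueError("histogram has zero variance; need >= 2 occupied classes")
    return x, f, mean, np.sqrt(var)


def binned_skewness(hist: DiameterHistogram) -> float:
    """Frequency-weighted skewness of the class midpoints,
    sum f_k (x_k - xbar)^3 / s^3."""
    x, f, mean, s = _weighted_moments(hist)
    return float(np.sum(f * (x - mean) ** 3) / s**3)


def binned_kurtosis(hist: DiameterHistogram, excess: bool = False) -> float:
    """Frequency-weighted kurtosis, sum f_k (x_k - xbar)^4 / s^4.

    Raw (non-excess) by default; pass excess=True to subtract 3.
    """
    x, f, mean, s = _weighted_moments(hist)
    k = float(np.sum(f * (x - mean) ** 4) / s**4)
    return k - 3.0 if excess else k


# --------------------------------------------------------------------------
# Delimited-text I/O
# --------------------------------------------------------------------------

def read_tree_lists(path, sep: str = ",") -> dict[str, np.ndarray]:
    """Read a tree-list table (columns stand_id, dbh_cm) into arrays per stand."""
    df = pd.read_csv(path, sep=sep)
    missing = {"stand_id", "dbh_cm"} - set(df.columns)
    if missing:
        raise ValueError(f"tree list {path}: missing columns {sorted(missing)}")
    return {
        str(sid): grp["dbh_cm"].to_numpy(dtype=float)
        for sid, grp in df.groupby("stand_id", sort=False)
    }


_CHAR_COLUMNS = {
    "age_yr": "age",
    "planting_density": "planting_density",
    "stand_density": "stand_density",
    "site_index_m": "site_index",
    "mean_height_m": "mean_height",
    "dominant_height_m": "dominant_height",
}


def read_stand_characteristics(path, trees: dict[str, np.ndarray] | None = None,
                               sep: str = ",") -> list[StandRecord]:
    """Read a stand-characteristics table into StandRecords.

    Expected columns: stand_id, age_yr, planting_density, stand_density,
    site_index_m, mean_height_m, dominant_height_m, thinned.  When ``trees``
    is given, each record carries its tree list; otherwise the list is empty
    (characteristics-only records, enough for prediction methods that do not
    touch the trees — D_g must then be supplied as a dg_cm column).
    """
    df = pd.read_csv(path, sep=sep)
    if "stand_id" not in df.columns:
        raise ValueError(f"characteristics table {path}: missing column 'stand_id'")
    records = []
    for _, row in df.iterrows():
        sid = str(row["stand_id"])
        kwargs = {}
        for col, attr in _CHAR_COLUMNS.items():
            if col not in df.columns:
                raise ValueError(f"characteristics table {path}: missing column '{col}'")
            kwargs[attr] = float(row[col])
        d = trees.get(sid) if trees is not None else None
        if d is None:
            if "dg_cm" in df.columns:
                # characteristics-only record: stash D_g as a single pseudo-tree
                d = np.array([float(row["dg_cm"])])
            else:
                raise ValueError(
                    f"stand {sid}: no tree list and no dg_cm column to supply D_g"
                )
        records.append(
            StandRecord(
                stand_id=sid,
                diameters=d,
                thinned=bool(row["thinned"]) if "thinned" in df.columns else False,
                **kwargs,
            )
        )
    return records


def write_tree_lists(stands: list[StandRecord], path, sep: str = ",") -> None:
    """Write tree lists of several stands as one stand_id/dbh_cm table."""
    frames = [
        pd.DataFrame({"stand_id": s.stand_id, "dbh_cm": s.diameters})
        for s in stands
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep=sep, index=False, float_format="%.6g"
    )


def write_stand_characteristics(stands: list[StandRecord], path,
                                sep: str = ",") -> None:
    """Write the stand-characteristics table (includes derived dg_cm)."""
    rows = []
    for s in stands:
        rows.append(
            {
                "stand_id": s.stand_id,
                "age_yr": s.age,
                "planting_density": s.planting_density,
                "stand_density": s.stand_density,
                "site_index_m": s.site_index,
                "mean_height_m": s.mean_height,
                "dominant_height_m": s.dominant_height,
                "dg_cm": s.dg,
                "thinned": int(s.thinned),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.6g")


def write_histogram(hist: DiameterHistogram, path, sep: str = ",") -> None:
    """Write a histogram as a delimited table (midpoint, count, f, F)."""
    pd.DataFrame(
        {
            "class_midpoint": hist.class_midpoints,
            "count": hist.counts.astype(int),
            "frequency": hist.frequencies,
            "cumulative": hist.cumulative,
        }
    ).to_csv(path, sep=sep, index=False, float_format="%.6g")
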