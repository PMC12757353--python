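"""Tree tables: domain types, CSV I/O, sample filtering and summaries.

The atomic observation is one tree with a genotype label, a planting-density
indicator, field measurements (DBH in cm, height H and crown diameter CD in
m, all optional) and LiDAR-derived height LH and crown diameter LCD (m).
A :class:`Dataset` is an ordered collection of such trees grouped by
genotype — the grouping factor of the mixed model.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import TreeTableFormatError, ValidationError

CANONICAL_COLUMNS = ("genotype_id", "p1", "dbh", "h", "cd", "lh", "lcd")
REQUIRED_COLUMNS = ("genotype_id", "p1", "lh", "lcd")
_NUMERIC = ("p1", "dbh", "h", "cd", "lh", "lcd")


@dataclass(frozen=True)
class TreeRecord:
    """One tree: genotype, density class and its measured / LiDAR covariates.

    ``p1`` is 1 for high-density planting (2 m x 2 m spacing) and 0
    otherwise.  ``dbh``, ``h`` and ``cd`` may be absent (``None``) for rows
    used purely for prediction.
    """

    genotype_id: str
    p1: int
    lh: float
    lcd: float
    dbh: float | None = None
    h: float | None = None
    cd: float | None = None

    def __post_init__(self):
        if self.p1 not in (0, 1):
            raise ValidationError(f"p1 must be 0 or 1, got {self.p1!r}")
        if not (math.isfinite(self.lh) and self.lh >= 0):
            raise ValidationError(f"lh must be finite and non-negative, got {self.lh!r}")
        if not (math.isfinite(self.lcd) and self.lcd >= 0):
            raise ValidationError(f"lcd must be finite and non-negative, got {self.lcd!r}")
        for name in ("dbh", "h", "cd"):
            v = getattr(self, name)
            if v is not None and not (math.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be positive when present, got {v!r}")


class Dataset:
    """Ordered collection of :class:`TreeRecord` grouped by genotype.

    Internally backed by a :class:`pandas.DataFrame` with the canonical
    columns ``genotype_id, p1, dbh, h, cd, lh, lcd``; missing optional
    measurements are ``NaN``.  Row order is preserved from the source.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise TreeTableFormatError(f"missing required column(s): {', '.join(missing)}")
        df = pd.DataFrame(index=range(len(frame)))
        df["genotype_id"] = frame["genotype_id"].astype(str).to_numpy()
        for col in _NUMERIC:
            if col in frame.columns:
                vals = pd.to_numeric(frame[col], errors="coerce").to_numpy(dtype=float)
                bad = np.isnan(vals) & frame[col].notna().to_numpy() \
                    & (frame[col].astype(str).str.strip() != "").to_numpy()
                if bad.any():
                    raise TreeTableFormatError(
                        f"unparseable numeric value in column {col!r} at row "
                        f"{int(np.flatnonzero(bad)[0])}"
                    )
                df[col] = vals
            else:
                df[col] = np.nan
        p1 = df["p1"].to_numpy()
        if np.isnan(p1).any():
            raise ValidationError("p1 must be present for every record")
        if not np.isin(p1, (0.0, 1.0)).all():
            raise ValidationError("p1 must be 0 or 1 for every record")
        df["p1"] = p1.astype(int)
        for col, positive in (("lh", False), ("lcd", False)):
            v = df[col].to_numpy()
            if np.isnan(v).any():
                raise ValidationError(f"{col} must be present for every record")
            if not np.isfinite(v).all() or (v < 0).any():
                raise ValidationError(f"{col} must be finite and non-negative")
        for col in ("dbh", "h", "cd"):
            v = df[col].to_numpy()
            present = ~np.isnan(v)
            if (v[present] <= 0).any():
                raise ValidationError(f"{col} must be positive when present")
        self._frame = df[list(CANONICAL_COLUMNS)]

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[TreeRecord]) -> "Dataset":
        rows = [
            {
                "genotype_id": r.genotype_id, "p1": r.p1, "dbh": r.dbh,
                "h": r.h, "cd": r.cd, "lh": r.lh, "lcd": r.lcd,
            }
            for r in records
        ]
        frame = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
        return cls(frame)

    # -- views ------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Copy of the underlying canonical DataFrame."""
        return self._frame.copy()

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def records(self) -> list[TreeRecord]:
        out = []
        for row in self._frame.itertuples(index=False):
            out.append(
                TreeRecord(
                    genotype_id=row.genotype_id, p1=int(row.p1),
                    lh=float(row.lh), lcd=float(row.lcd),
                    dbh=None if pd.isna(row.dbh) else float(row.dbh),
                    h=None if pd.isna(row.h) else float(row.h),
                    cd=None if pd.isna(row.cd) else float(row.cd),
                )
            )
        return out

    @property
    def groups(self) -> dict[str, np.ndarray]:
        """Genotype id -> positional indices, in order of first appearance."""
        out: dict[str, list[int]] = {}
        for i, g in enumerate(self._frame["genotype_id"].to_numpy()):
            out.setdefault(g, []).append(i)
        return {g: np.asarray(ix, dtype=int) for g, ix in out.items()}

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.groups.keys())

    @property
    def n_genotypes(self) -> int:
        return self._frame["genotype_id"].nunique()

    def group_sizes(self) -> dict[str, int]:
        return {g: len(ix) for g, ix in self.groups.items()}

    def subset(self, indices: Sequence[int]) -> "Dataset":
        return Dataset(self._frame.iloc[list(indices)].reset_index(drop=True))

    def column(self, name: str) -> np.ndarray:
        return self._frame[name].to_numpy(dtype=float if name != "genotype_id" else object)

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        a, b = self._frame, other._frame
        if len(a) != len(b):
            return False
        if not (a["genotype_id"].to_numpy() == b["genotype_id"].to_numpy()).all():
            return False
        for col in _NUMERIC:
            x, y = a[col].to_numpy(), b[col].to_numpy()
            if not ((np.isnan(x) & np.isnan(y)) | np.isclose(x, y, rtol=1e-12, atol=0, equal_nan=True)).all():
                return False
        return True

    def __repr__(self) -> str:
        return f"Dataset(n_trees={len(self)}, n_genotypes={self.n_genotypes})"


# -- CSV I/O --------------------------------------------------------------

def read_tree_table(source, column_map: Mapping[str, str] | None = None) -> Dataset:
    """Read a tree table from CSV.

    Parameters
    ----------
    source : path-like or text stream
        CSV with a header row; comma separated, '.' decimal, empty = missing.
    column_map : mapping, optional
        Maps canonical names (``genotype_id``, ``p1``, ...) to the source
        file's header names for files with non-canonical headers.
    """
    frame = pd.read_csv(source, dtype=str, skipinitialspace=True)
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        missing = [s for s in rename if s not in frame.columns]
        if missing:
            raise TreeTableFormatError(f"missing required column(s): {', '.join(missing)}")
        frame = frame.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise TreeTableFormatError(f"missing required column(s): {', '.join(missing)}")
    return Dataset(frame)


def write_tree_table(data: Dataset, sink) -> None:
    """Write the canonical CSV (header ``genotype_id,p1,dbh,h,cd,lh,lcd``).

    Absent values become empty cells; floats are rendered at full precision
    so that read -> write round-trips are lossless.
    """
    df = data.to_frame()
    if isinstance(sink, (str,)) or hasattr(sink, "__fspath__"):
        df.to_csv(sink, index=False, float_format=None)
    else:
        if not hasattr(sink, "write"):
            raise OSError(f"unwritable sink: {sink!r}")
        df.to_csv(sink, index=False)


def dataset_to_csv_text(data: Dataset) -> str:
    buf = io.StringIO()
    write_tree_table(data, buf)
    return buf.getvalue()


# -- filtering ------------------------------------------------------------

@dataclass
class FilterReport:
    """Counts removed at each filtering step."""

    n_input: int
    n_removed_height: int
    n_genotypes_removed: int
    n_removed_small_groups: int
    n_output: int
    min_trees: int = 30
    height_floor: float = 1.3
    height_rule: str = "and"


def filter_dataset(
    data: Dataset,
    min_trees: int = 30,
    height_floor: float = 1.3,
    height_rule: str = "and",
) -> tuple[Dataset, FilterReport]:
    """Apply the study's sample-exclusion rules.

    Step 1 removes trees shorter than ``height_floor`` (default 1.3 m, the
    breast-height datum): under the default ``"and"`` rule a tree is removed
    only when *both* its LiDAR height and its field height are below the
    floor; ``"or"`` removes it when either is.  Step 2 then drops every
    genotype whose surviving tree count is below ``min_trees`` (default 30).
    The height filter runs first so the count threshold applies to the
    surviving trees.  Set ``height_floor=0`` to disable step 1 (e.g. for
    LiDAR-only tables without field heights).
    """
    if height_rule not in ("and", "or"):
        raise ValidationError(f"height_rule must be 'and' or 'or', got {height_rule!r}")
    frame = data.to_frame()
    n_input = len(frame)

    if height_floor > 0:
        h = frame["h"].to_numpy()
        if np.isnan(h).any():
            raise ValidationError(
                "height filtering requires h present for every record; "
                "set height_floor=0 to disable the height filter"
            )
        lh = frame["lh"].to_numpy()
        if height_rule == "and":
            drop = (lh < height_floor) & (h < height_floor)
        else:
            drop = (lh < height_floor) | (h < height_floor)
        frame = frame.loc[~drop]
    n_removed_height = n_input - len(frame)

    sizes = frame.groupby("genotype_id", sort=False)["genotype_id"].transform("size")
    keep = sizes >= min_trees
    n_genotypes_removed = frame.loc[~keep, "genotype_id"].nunique()
    frame = frame.loc[keep]
    n_removed_small = n_input - n_removed_height - len(frame)

    out = Dataset(frame.reset_index(drop=True))
    report = FilterReport(
        n_input=n_input,
        n_removed_height=n_removed_height,
        n_genotypes_removed=int(n_genotypes_removed),
        n_removed_small_groups=n_removed_small,
        n_output=len(out),
        min_trees=min_trees,
        height_floor=height_floor,
        height_rule=height_rule,
    )
    return out, report


# -- descriptive summary --------------------------------------------------

@dataclass
class DatasetSummary:
    variables: pd.DataFrame
    r_squared: dict[tuple[str, str], float] = field(default_factory=dict)


_SUMMARY_VARS = ("dbh", "h", "cd", "lh", "lcd")
_R2_PAIRS = (("lh", "h"), ("lcd", "cd"), ("dbh", "h"))


def summarize(data: Dataset) -> DatasetSummary:
    """Descriptive statistics per variable plus pairwise linear-fit R^2.

    Mean, SD (N-1 denominator), max, min over present values for DBH, H,
    CD, LH and LCD; R^2 of the ordinary linear fits LH~H, LCD~CD, DBH~H
    (computed on rows where both members are present).
    """
    if len(data) == 0:
        raise ValidationError("summarize requires a non-empty Dataset")
    frame = data.frame
    rows = {}
    for var in _SUMMARY_VARS:
        v = frame[var].dropna().to_numpy()
        if v.size == 0:
            warnings.warn(f"variable {var!r} entirely absent; omitted from summary")
            continue
        sd = float(np.std(v, ddof=1)) if v.size >= 2 else np.nan
        rows[var] = {
            "mean": float(np.mean(v)), "sd": sd,
            "max": float(np.max(v)), "min": float(np.min(v)),
            "n": int(v.size),
        }
    variables = pd.DataFrame.from_dict(rows, orient="index")

    r2 = {}
    for a, b in _R2_PAIRS:
        sub = frame[[a, b]].dropna()
        if len(sub) >= 3 and sub[a].nunique() > 1 and sub[b].nunique() > 1:
            r = np.corrcoef(sub[a], sub[b])[0, 1]
            r2[(a, b)] = float(r * r)
    return DatasetSummary(variables=variables, r_squared=r2)
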