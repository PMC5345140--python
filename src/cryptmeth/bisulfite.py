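"""Scoring of clone-by-CpG bisulfite sequencing matrices.

Each sequenced bacterial colony (clone) contributes one row of per-CpG-site
calls: methylated, unmethylated, or undetermined.  The per-region
methylation ratio is methylated / (methylated + unmethylated), with
undetermined calls excluded from both numerator and denominator; groups are
compared by an unpaired two-tailed t test on per-clone ratios (the
10-colonies-per-group design).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "METHYLATED",
    "UNMETHYLATED",
    "UNDETERMINED",
    "BisulfiteCloneMatrix",
    "methylation_ratio",
    "per_clone_ratios",
    "per_site_ratios",
    "compare_groups",
    "lollipop_export",
    "lollipop_parse",
    "read_clone_matrix",
    "write_clone_matrix",
]

METHYLATED = 1
UNMETHYLATED = 0
UNDETERMINED = -1

_CODE_TO_CHAR = {METHYLATED: "M", UNMETHYLATED: "U", UNDETERMINED: "X"}
_CHAR_TO_CODE = {v: k for k, v in _CODE_TO_CHAR.items()}

_LOLLIPOP = {METHYLATED: "●", UNMETHYLATED: "○", UNDETERMINED: "×"}
_LOLLIPOP_INV = {v: k for k, v in _LOLLIPOP.items()}


@dataclass
class BisulfiteCloneMatrix:
    """Clones x CpG-sites call matrix for one amplicon region."""

    region_id: str
    clone_ids: list[str]
    site_positions: list[int]  # bp
    calls: np.ndarray  # int8, values in {1, 0, -1}

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.clone_ids), len(self.site_positions)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.clone_ids)} clones x {len(self.site_positions)} sites"
            )
        if self.calls.size == 0:
            raise ValueError("empty clone matrix")
        bad = ~np.isin(self.calls, [METHYLATED, UNMETHYLATED, UNDETERMINED])
        if bad.any():
            raise ValueError("calls must be 1 (methylated), 0 (unmethylated) or -1")
        if (self.calls == UNDETERMINED).all(axis=1).any():
            raise ValueError("every clone needs at least one determined call")

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)


def _ratio(calls: np.ndarray) -> float:
    n_meth = int((calls == METHYLATED).sum())
    n_unmeth = int((calls == UNMETHYLATED).sum())
    if n_meth + n_unmeth == 0:
        return float("nan")
    return n_meth / (n_meth + n_unmeth)


def methylation_ratio(matrix: BisulfiteCloneMatrix) -> float:
    """Fraction of determined CpG calls that are methylated, over the region."""
    r = _ratio(matrix.calls)
    if np.isnan(r):
        raise ValueError(f"{matrix.region_id}: all calls undetermined")
    return r


def per_clone_ratios(matrix: BisulfiteCloneMatrix) -> list[float]:
    """Methylation ratio of each clone (row); same exclusion rule."""
    return [_ratio(row) for row in matrix.calls]


def per_site_ratios(matrix: BisulfiteCloneMatrix) -> list[float]:
    """Methylation ratio of each CpG site (column); NaN for all-undetermined sites."""
    return [_ratio(col) for col in matrix.calls.T]


def compare_groups(matrix_a: BisulfiteCloneMatrix, matrix_b: BisulfiteCloneMatrix,
                   per: str = "clone", equal_var: bool = True) -> dict:
    """Unpaired two-tailed t test between two groups' per-clone (or per-site) ratios.

    Student's t by default, Welch with ``equal_var=False``.

    Returns ``{"ratio_a", "ratio_b", "t_p"}``; ``t_p`` is NaN when both
    groups have zero variance (identical ratios carry no evidence scale).
    """
    if matrix_a.n_clones < 2 or matrix_b.n_clones < 2:
        raise ValueError("need >=2 clones per group for a t test")
    if per == "clone":
        xa = np.array(per_clone_ratios(matrix_a), dtype=float)
        xb = np.array(per_clone_ratios(matrix_b), dtype=float)
    elif per == "site":
        xa = np.array([r for r in per_site_ratios(matrix_a) if not np.isnan(r)])
        xb = np.array([r for r in per_site_ratios(matrix_b) if not np.isnan(r)])
    else:
        raise ValueError("per must be 'clone' or 'site'")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(xa, xb, equal_var=equal_var)
    return {
        "ratio_a": methylation_ratio(matrix_a),
        "ratio_b": methylation_ratio(matrix_b),
        "t_p": float(res.pvalue),
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_clone_matrix(path: str | os.PathLike) -> list[BisulfiteCloneMatrix]:
    """Read matrices from TSV: region_id, clone_id, then one M/U/X column per site.

    Site columns are named by CpG position (bp).  Multiple regions may share
    one file; a matrix is returned per region.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    site_cols = [c for c in frame.columns if c not in ("region_id", "clone_id")]
    out = []
    for region_id, sub in frame.groupby("region_id", sort=False):
        calls = np.array(
            [[_CHAR_TO_CODE[v] for v in row] for row in sub[site_cols].to_numpy()],
            dtype=np.int8,
        )
        out.append(
            BisulfiteCloneMatrix(
                region_id=str(region_id),
                clone_ids=[str(c) for c in sub["clone_id"]],
                site_positions=[int(c) for c in site_cols],
                calls=calls,
            )
        )
    return out


def write_clone_matrix(matrices: Sequence[BisulfiteCloneMatrix], path: str | os.PathLike) -> None:
    rows = []
    site_cols = [str(p) for p in matrices[0].site_positions]
    for m in matrices:
        if [str(p) for p in m.site_positions] != site_cols:
            raise ValueError("all matrices in one file must share site positions")
        for clone, row in zip(m.clone_ids, m.calls):
            rows.append(
                {"region_id": m.region_id, "clone_id": clone,
                 **{c: _CODE_TO_CHAR[int(v)] for c, v in zip(site_cols, row)}}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def lollipop_export(matrix: BisulfiteCloneMatrix, path: str | os.PathLike) -> None:
    """Write a text lollipop grid: filled/open circles and crosses per call."""
    with open(path, "w") as fh:
        fh.write(f"# region {matrix.region_id}\n")
        fh.write("# sites " + " ".join(str(p) for p in matrix.site_positions) + "\n")
        width = max(len(c) for c in matrix.clone_ids)
        for clone, row in zip(matrix.clone_ids, matrix.calls):
            glyphs = " ".join(_LOLLIPOP[int(v)] for v in row)
            fh.write(f"{clone:<{width}}  {glyphs}\n")


def lollipop_parse(path: str | os.PathLike) -> BisulfiteCloneMatrix:
    """Inverse of :func:`lollipop_export`."""
    region_id = ""
    sites: list[int] = []
    clones: list[str] = []
    rows: list[list[int]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# region "):
                region_id = line[len("# region "):]
            elif line.startswith("# sites "):
                sites = [int(x) for x in line[len("# sites "):].split()]
            elif line.strip():
                parts = line.split()
                clones.append(parts[0])
                rows.append([_LOLLIPOP_INV[g] for g in parts[1:]])
    return BisulfiteCloneMatrix(region_id, clones, sites, np.array(rows, dtype=np.int8))
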