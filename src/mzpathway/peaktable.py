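"""Peak tables, annotated peak lists, and ranked-feature-statistics files.

The central container is :class:`PeakTable`: an (m/z, retention time)-keyed
feature x sample intensity matrix with a two-level group factor, the object
every downstream statistic operates on. Missing intensities are NaN and are
distinct from measured zeros — the imputation step depends on that
distinction, so readers never coerce empty cells to 0.

Three text dialects are supported:

* peak table CSV — header row of sample ids, second row of group labels,
  then one row per feature keyed either by a ``mz__rt`` string or by
  separate leading ``mz``/``rt`` columns;
* annotated peak list CSV — the rule-based-annotation export layout
  (``mz, rt, <samples...>, isotopes, adduct, pcgroup``) that
  :func:`format_peak_list` filters down to monoisotopic, kept-adduct rows;
* ranked feature statistics TSV/CSV — the three-column ``m.z / p.value /
  t.score`` dialect consumed by the pathway-activity methods.

Parsing uses the stdlib csv module deliberately: the dialect contracts
(empty cell vs "0", hard rejection of short rows with row/column context)
need cell-level control.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PeakTable",
    "AnnotatedPeakList",
    "PeakTableError",
    "read_peak_table",
    "write_peak_table",
    "read_annotated_peak_list",
    "format_peak_list",
    "read_mummichog_input",
    "write_mummichog_input",
]


class PeakTableError(ValueError):
    """Raised on malformed peak-table input."""


@dataclass
class PeakTable:
    """Feature x sample intensity matrix with group labels.

    ``mz`` and ``rt`` (seconds) key the features; ``intensities`` is a
    float array of shape (n_features, n_samples) with NaN for missing.
    """

    mz: np.ndarray
    rt: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    group_labels: list[str]

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        n_feat, n_samp = self.intensities.shape
        if len(self.mz) != n_feat or len(self.rt) != n_feat:
            raise PeakTableError("mz/rt length does not match intensity rows")
        if len(self.sample_ids) != n_samp or len(self.group_labels) != n_samp:
            raise PeakTableError("sample ids/labels do not match intensity columns")
        if np.any(self.mz <= 0):
            raise PeakTableError("all m/z values must be positive")
        if np.any(self.rt < 0):
            raise PeakTableError("retention times must be non-negative")

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        seen: list[str] = []
        for g in self.group_labels:
            if g not in seen:
                seen.append(g)
        return seen

    def require_two_groups(self) -> tuple[str, str]:
        g = self.groups
        if len(g) != 2:
            raise PeakTableError(f"expected exactly 2 groups, found {len(g)}: {g}")
        return g[0], g[1]

    def group_columns(self, label: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.group_labels) if g == label])

    def copy(self) -> "PeakTable":
        return PeakTable(
            self.mz.copy(), self.rt.copy(), self.intensities.copy(),
            list(self.sample_ids), list(self.group_labels),
        )

    def select_features(self, index: np.ndarray) -> "PeakTable":
        """Subset features by integer index, preserving order."""
        index = np.asarray(index, dtype=int)
        return PeakTable(
            self.mz[index], self.rt[index], self.intensities[index],
            list(self.sample_ids), list(self.group_labels),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensities, columns=self.sample_ids)
        df.insert(0, "rt", self.rt)
        df.insert(0, "mz", self.mz)
        return df


@dataclass
class AnnotatedPeakList:
    """A peak table plus per-row isotope/adduct/co-elution-group annotations."""

    table: PeakTable
    isotopes: list[str]
    adducts: list[str]
    pcgroups: list[int]

    def __post_init__(self) -> None:
        n = self.table.n_features
        if not (len(self.isotopes) == len(self.adducts) == len(self.pcgroups) == n):
            raise PeakTableError("annotation column lengths do not match row count")


_MISSING_TOKENS = {"", "na", "nan", "n/a"}


def _parse_cell(cell: str, row: int, col: int, path: str) -> float:
    s = cell.strip()
    if s.lower() in _MISSING_TOKENS:
        return np.nan
    try:
        return float(s)
    except ValueError:
        raise PeakTableError(
            f"{path}: non-numeric intensity {cell!r} at row {row}, column {col}"
        ) from None


def _read_rows(path: str | Path) -> list[list[str]]:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        return [row for row in csv.reader(fh, delimiter=delim) if row]


def _parse_feature_key(key: str, row: int, path: str) -> tuple[float, float]:
    parts = key.split("__")
    if len(parts) != 2:
        raise PeakTableError(f"{path}: row {row}: feature key {key!r} is not 'mz__rt'")
    try:
        return float(parts[0]), float(parts[1])
    except ValueError:
        raise PeakTableError(f"{path}: row {row}: non-numeric mz/rt in key {key!r}") from None


def read_peak_table(path: str | Path) -> PeakTable:
    """Read a peak-table CSV (samples as columns, group-label second row).

    Accepts the ``mz__rt`` single-key dialect and the separate ``mz,rt``
    leading-column dialect. Empty cells become NaN (missing); "0" stays 0.
    """
    rows = _read_rows(path)
    p = str(path)
    if len(rows) < 3:
        raise PeakTableError(f"{p}: need a header, a group row and at least one feature")
    header = rows[0]
    ncol = len(header)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) < ncol:
            raise PeakTableError(f"{p}: row {i} has {len(row)} cells, header has {ncol}")
    split_key = [h.strip().lower() for h in header[:2]] == ["mz", "rt"]
    first_data_col = 2 if split_key else 1
    sample_ids = [h.strip() for h in header[first_data_col:]]
    if not sample_ids:
        raise PeakTableError(f"{p}: no sample columns")
    group_labels = [c.strip() for c in rows[1][first_data_col:]]
    if any(not g for g in group_labels):
        raise PeakTableError(f"{p}: empty group label in second row")
    mz, rt, data = [], [], []
    for i, row in enumerate(rows[2:], start=3):
        if split_key:
            try:
                mz.append(float(row[0]))
                rt.append(float(row[1]))
            except ValueError:
                raise PeakTableError(f"{p}: row {i}: non-numeric mz/rt") from None
        else:
            m, r = _parse_feature_key(row[0], i, p)
            mz.append(m)
            rt.append(r)
        data.append(
            [_parse_cell(c, i, j + first_data_col + 1, p)
             for j, c in enumerate(row[first_data_col:ncol])]
        )
    return PeakTable(np.array(mz), np.array(rt), np.array(data), sample_ids, group_labels)


def write_peak_table(pt: PeakTable, path: str | Path) -> None:
    """Write a peak table in the ``mz__rt`` dialect; NaN becomes an empty cell."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["Sample"] + pt.sample_ids)
        w.writerow(["Label"] + pt.group_labels)
        for i in range(pt.n_features):
            key = f"{pt.mz[i]:.6f}__{pt.rt[i]:.4f}"
            cells = ["" if np.isnan(v) else repr(float(v)) for v in pt.intensities[i]]
            w.writerow([key] + cells)


def read_annotated_peak_list(path: str | Path, group_labels: list[str] | None = None) -> AnnotatedPeakList:
    """Read a rule-annotation CSV: mz, rt, <samples...>, isotopes, adduct, pcgroup."""
    rows = _read_rows(path)
    p = str(path)
    if len(rows) < 2:
        raise PeakTableError(f"{p}: empty annotated peak list")
    header = [h.strip() for h in rows[0]]
    lower = [h.lower() for h in header]
    for col in ("mz", "rt", "isotopes", "adduct", "pcgroup"):
        if col not in lower:
            raise PeakTableError(f"{p}: missing required column {col!r}")
    idx = {c: lower.index(c) for c in ("mz", "rt", "isotopes", "adduct", "pcgroup")}
    annot_cols = set(idx.values())
    sample_cols = [j for j in range(len(header)) if j not in annot_cols]
    ncol = len(header)
    mz, rt, data, isotopes, adducts, pcgroups = [], [], [], [], [], []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) < ncol:
            raise PeakTableError(f"{p}: row {i} has {len(row)} cells, header has {ncol}")
        try:
            mz.append(float(row[idx["mz"]]))
            rt.append(float(row[idx["rt"]]))
        except ValueError:
            raise PeakTableError(f"{p}: row {i}: non-numeric mz/rt") from None
        data.append([_parse_cell(row[j], i, j + 1, p) for j in sample_cols])
        isotopes.append(row[idx["isotopes"]].strip())
        adducts.append(row[idx["adduct"]].strip())
        pc = row[idx["pcgroup"]].strip()
        pcgroups.append(int(pc) if pc else 0)
    sample_ids = [header[j] for j in sample_cols]
    labels = group_labels if group_labels is not None else ["unassigned"] * len(sample_ids)
    table = PeakTable(np.array(mz), np.array(rt), np.array(data), sample_ids, labels)
    return AnnotatedPeakList(table, isotopes, adducts, pcgroups)


# Isotope annotations marking a non-monoisotopic peak look like "[M+1]+",
# "[12][M+2]+" etc.; the monoisotopic peak itself is "[M]+" (kept).
def _is_heavier_isotope(annotation: str) -> bool:
    return "[M+" in annotation.replace(" ", "")


def format_peak_list(
    apl: AnnotatedPeakList,
    keep_adducts: set[str] | None = None,
    monoisotopic_only: bool = True,
) -> PeakTable:
    """Filter an annotated peak list down to a clean feature table.

    Rows with a non-empty adduct annotation not in ``keep_adducts`` are
    dropped; rows annotated as heavier isotopes (``[M+1]``, ``[M+2]`` ...)
    are dropped when ``monoisotopic_only``. Unannotated rows are retained —
    absence of an annotation is not evidence of degeneracy.
    """
    keep = keep_adducts if keep_adducts is not None else {"[M+H]+", "[M-H]-"}
    kept_idx = []
    for i in range(apl.table.n_features):
        adduct = apl.adducts[i]
        if adduct and adduct not in keep:
            continue
        if monoisotopic_only and _is_heavier_isotope(apl.isotopes[i]):
            continue
        kept_idx.append(i)
    if not kept_idx:
        logger.warning("format_peak_list: all %d rows filtered out", apl.table.n_features)
        return PeakTable(
            np.empty(0), np.empty(0),
            np.empty((0, apl.table.n_samples)),
            list(apl.table.sample_ids), list(apl.table.group_labels),
        )
    return apl.table.select_features(np.array(kept_idx))


def read_mummichog_input(path: str | Path) -> pd.DataFrame:
    """Read a ranked-feature-statistics file (m.z / p.value / t.score).

    Returns a DataFrame with columns ``mz``, ``p_value``, ``t_score`` and,
    when present in the file, ``rt``. Row order is preserved; duplicate m/z
    values are allowed (distinct features can share a mass).
    """
    rows = _read_rows(path)
    p = str(path)
    if len(rows) < 2:
        raise PeakTableError(f"{p}: no data rows")
    header = [h.strip().lower().replace("/", ".") for h in rows[0]]
    aliases = {"m.z": "mz", "mz": "mz", "p.value": "p_value", "p_value": "p_value",
               "t.score": "t_score", "t_score": "t_score", "r.t": "rt", "rt": "rt"}
    colmap: dict[str, int] = {}
    for j, h in enumerate(header):
        if h in aliases and aliases[h] not in colmap:
            colmap[aliases[h]] = j
    for required in ("mz", "p_value", "t_score"):
        if required not in colmap:
            raise PeakTableError(f"{p}: missing required column {required!r} (header {header})")
    ncol = len(header)
    out: dict[str, list[float]] = {k: [] for k in colmap}
    for i, row in enumerate(rows[1:], start=2):
        if len(row) < ncol:
            raise PeakTableError(f"{p}: row {i} has {len(row)} cells, header has {ncol}")
        for key, j in colmap.items():
            try:
                out[key].append(float(row[j]))
            except ValueError:
                raise PeakTableError(f"{p}: row {i}: non-numeric {key} {row[j]!r}") from None
    df = pd.DataFrame(out)
    bad = (df["p_value"] < 0) | (df["p_value"] > 1)
    if bad.any():
        raise PeakTableError(f"{p}: p-values outside [0, 1] at rows {list(df.index[bad] + 2)}")
    cols = ["mz"] + (["rt"] if "rt" in df else []) + ["p_value", "t_score"]
    return df[cols]


def write_mummichog_input(stats: pd.DataFrame, path: str | Path) -> None:
    """Write feature statistics in the three-column dialect (TSV).

    Extra columns (fold_change, fdr, ...) are appended after the canonical
    three so the file stays consumable by external ranked-list tools.
    """
    df = stats.copy()
    rename = {"mz": "m.z", "p_value": "p.value", "t_score": "t.score", "rt": "r.t"}
    df = df.rename(columns=rename)
    lead = ["m.z", "p.value", "t.score"]
    rest = [c for c in df.columns if c not in lead]
    df[lead + rest].to_csv(path, sep="\t", index=False, float_format="%.10g")
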