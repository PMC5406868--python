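"""Core data types and TSV readers/writers for cross-species array analysis.

The on-disk format is plain TSV (UTF-8, header row, ``.`` decimal) throughout:
a chip layout mapping perfect-match probe pairs to probe sets, a sample sheet
describing the hybridisation design, probe-level intensity matrices and
summarized probe-set expression matrices.  Mismatch probes are not modelled;
only PM probes carry information in this pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TREATMENTS = ("water_sufficient", "water_limited", "recovery")

LAYOUT_COLUMNS = ["probe_id", "probe_set_id", "pair_index"]
SHEET_COLUMNS = ["sample_id", "genotype", "treatment", "replicate", "excluded"]


class ValidationError(ValueError):
    """Raised when an input table violates a model invariant."""


# ---------------------------------------------------------------------------
# chip layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChipLayout:
    """Mapping of probe pairs to probe sets.

    ``table`` has columns ``probe_id, probe_set_id, pair_index``.  Every probe
    pair belongs to exactly one probe set and pair indices within a set run
    0..k-1 without gaps.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in LAYOUT_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"layout is missing columns {missing}")
        if t["probe_id"].duplicated().any():
            dup = t.loc[t["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValidationError(f"duplicate probe_id {dup!r} in layout")
        if len(t) == 0:
            raise ValidationError("layout has no probe pairs")
        idx = t["pair_index"].to_numpy()
        if (idx < 0).any():
            raise ValidationError("pair_index must be >= 0")
        for set_id, grp in t.groupby("probe_set_id", sort=False):
            got = np.sort(grp["pair_index"].to_numpy())
            if not np.array_equal(got, np.arange(len(grp))):
                raise ValidationError(
                    f"probe set {set_id!r} has pair indices {got.tolist()}, "
                    f"expected 0..{len(grp) - 1} without gaps"
                )

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    @property
    def probe_set_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_set_id"].unique())

    @property
    def n_sets(self) -> int:
        return self.table["probe_set_id"].nunique()

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    def set_of(self) -> pd.Series:
        """probe_id -> probe_set_id mapping."""
        return self.table.set_index("probe_id")["probe_set_id"]

    def restrict(self, probe_ids) -> "ChipLayout":
        """Sub-layout containing only the given probe pairs (indices re-packed)."""
        keep = self.table[self.table["probe_id"].isin(set(probe_ids))].copy()
        keep["pair_index"] = keep.groupby("probe_set_id").cumcount()
        return ChipLayout(keep.reset_index(drop=True))


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSheet:
    """Hybridisation design: sample_id, genotype, treatment, replicate, excluded."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in SHEET_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"sample sheet is missing columns {missing}")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        bad = set(t["treatment"]) - set(TREATMENTS)
        if bad:
            raise ValidationError(
                f"unknown treatment values {sorted(bad)}; expected one of {TREATMENTS}"
            )
        if (t["replicate"].to_numpy() < 1).any():
            raise ValidationError("replicate numbers must be >= 1")

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.table["genotype"]))

    def active(self) -> pd.DataFrame:
        """Rows for samples not flagged as excluded."""
        return self.table[~self.table["excluded"].astype(bool)]

    def samples_for(self, genotype: str, treatment: str) -> list[str]:
        """Non-excluded sample ids of one genotype x treatment group."""
        a = self.active()
        sel = (a["genotype"] == genotype) & (a["treatment"] == treatment)
        return list(a.loc[sel, "sample_id"])

    def exclude(self, sample_id: str) -> "SampleSheet":
        if sample_id not in set(self.table["sample_id"]):
            raise ValidationError(f"unknown sample_id {sample_id!r}")
        t = self.table.copy()
        t.loc[t["sample_id"] == sample_id, "excluded"] = True
        return SampleSheet(t)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeIntensityMatrix:
    """Linear-scale probe-pair intensities, one column per hybridisation."""

    values: pd.DataFrame  # index probe_id, numeric columns

    def __post_init__(self) -> None:
        v = self.values
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("intensity matrix must be numeric")
        bad = ~(np.isfinite(arr) & (arr > 0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-positive or non-finite intensity at probe "
                f"{v.index[i]!r}, column {v.columns[j]!r}: {arr[i, j]!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2-scale summarized expression, probe sets x samples."""

    values: pd.DataFrame  # index probe_set_id, numeric columns

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression matrix must be numeric")
        if not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains non-finite values")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate probe_set_id in expression matrix")

    @property
    def probe_set_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_layout(path) -> ChipLayout:
    t = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "probe_set_id": str})
    return ChipLayout(t[LAYOUT_COLUMNS].astype({"pair_index": int}))


def write_layout(layout: ChipLayout, path) -> None:
    out = layout.table.sort_values(["probe_set_id", "pair_index"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False, columns=LAYOUT_COLUMNS)


def read_sample_sheet(path) -> SampleSheet:
    t = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "genotype": str, "treatment": str},
    )
    missing = [c for c in SHEET_COLUMNS if c not in t.columns]
    if missing:
        raise ValidationError(f"sample sheet is missing columns {missing}")
    t["replicate"] = t["replicate"].astype(int)
    t["excluded"] = _parse_bool(t["excluded"])
    return SampleSheet(t[SHEET_COLUMNS])


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    out = sheet.table.copy()
    out["excluded"] = out["excluded"].astype(bool).map({True: "true", False: "false"})
    out = out.sort_values("sample_id", kind="mergesort")
    out.to_csv(path, sep="\t", index=False, columns=SHEET_COLUMNS)


def read_intensities(path, layout: ChipLayout) -> ProbeIntensityMatrix:
    """Read a probe-level intensity TSV, restricted to probes in ``layout``.

    Row order of the file is preserved.  Non-positive or non-numeric values
    and probe ids absent from the layout are rejected.
    """
    t = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    if "probe_id" not in t.columns:
        raise ValidationError("intensity TSV must have a 'probe_id' column")
    t = t.set_index("probe_id")
    for col in t.columns:
        if not np.issubdtype(t[col].dtype, np.number):
            bad = t.loc[~t[col].map(_is_number), col]
            where = bad.index[0] if len(bad) else "?"
            raise ValidationError(
                f"non-numeric intensity at probe {where!r}, column {col!r}"
            )
    unknown = t.index.difference(layout.probe_ids)
    if len(unknown):
        raise ValidationError(
            f"probe id {unknown[0]!r} not present in the chip layout"
        )
    return ProbeIntensityMatrix(t.astype(float))


def write_intensities(matrix: ProbeIntensityMatrix, path) -> None:
    out = matrix.values.sort_index(kind="mergesort")
    out.to_csv(path, sep="\t", index_label="probe_id")


def read_expression(path) -> ExpressionMatrix:
    t = pd.read_csv(path, sep="\t", dtype={"probe_set_id": str}).set_index(
        "probe_set_id"
    )
    return ExpressionMatrix(t.astype(float))


def write_expression(expr: ExpressionMatrix, path) -> None:
    out = expr.values.sort_index(kind="mergesort")
    out.to_csv(path, sep="\t", index_label="probe_set_id")


def _parse_bool(s: pd.Series) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False,
    }
    def conv(x):
        if isinstance(x, (bool, np.bool_)):
            return bool(x)
        key = str(x).strip().lower()
        if key not in mapping:
            raise ValidationError(f"cannot parse boolean value {x!r}")
        return mapping[key]
    return s.map(conv)


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False
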