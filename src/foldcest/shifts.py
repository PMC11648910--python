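"""Residue-level chemical-shift perturbation statistics.

Fitted minor-state shift differences (delta-omega, signed, minor minus
major, ppm) are condensed into a per-residue composite

    dw_RMS = sqrt( (1/N) * sum_i (dw_i / std_i)^2 )

where the sum runs over the backbone/side-chain nuclei of the residue for
which a value is available and std_i is the standard deviation of
reported chemical shifts for that nucleus type (a normalizer making the
different nuclei commensurate).  Residues with dw_RMS above a threshold
(default 0.5) are flagged as structurally perturbed in the minor state.

Glycine contributes its two HA shifts as two separate terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SUPPORTED_NUCLEI",
    "DEFAULT_STD",
    "ShiftTable",
    "StdTable",
    "delta_omega_rms",
    "classify_perturbed",
    "shift_rmsd",
    "export_peaklist",
]

logger = logging.getLogger(__name__)

SUPPORTED_NUCLEI = frozenset(
    {"15N", "1HN", "1HA", "13CA", "13CO", "13CB", "methyl-13C", "methyl-1H"})

#: Synthetic default normalizers (ppm): round-number stand-ins of typical
#: spreads of reported protein chemical shifts per nucleus type.  They are
#: configuration, not a literature table -- replace with your preferred
#: reference SDs via StdTable / the --std option for quantitative work.
DEFAULT_STD = {
    "15N": 4.5,
    "1HN": 0.7,
    "1HA": 0.45,
    "13CA": 3.0,
    "13CO": 2.0,
    "13CB": 2.5,
    "methyl-13C": 2.0,
    "methyl-1H": 0.4,
}


@dataclass
class StdTable:
    """Per-nucleus shift-spread normalizers (ppm), all strictly positive."""

    values: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STD))

    def __post_init__(self):
        for nuc, v in self.values.items():
            if v <= 0:
                raise ValueError(f"std for {nuc!r} must be > 0, got {v}")

    def __getitem__(self, nucleus: str) -> float:
        return self.values[nucleus]

    def __contains__(self, nucleus: str) -> bool:
        return nucleus in self.values

    @classmethod
    def from_tsv(cls, path) -> "StdTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(dict(zip(df["nucleus"], df["std_ppm"].astype(float))))

    def to_tsv(self, path) -> None:
        pd.DataFrame({"nucleus": list(self.values),
                      "std_ppm": list(self.values.values())}
                     ).to_csv(path, sep="\t", index=False)


@dataclass
class ShiftTable:
    """Signed shift differences for one state pair, one row per measurement.

    Columns: residue (int), resname (str), nucleus, delta_omega_ppm.
    Most (residue, nucleus) pairs occur once; glycine 1HA may occur twice
    (two alpha protons, both kept as separate terms).
    """

    data: pd.DataFrame
    condition: str = ""

    REQUIRED = ("residue", "resname", "nucleus", "delta_omega_ppm")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"shift table missing columns {missing}")
        unknown = set(self.data["nucleus"]) - SUPPORTED_NUCLEI
        if unknown:
            raise ValueError(f"unsupported nuclei {sorted(unknown)}")
        dup = self.data[self.data["nucleus"] != "1HA"].duplicated(
            subset=["residue", "nucleus"])
        if dup.any():
            raise ValueError("duplicate (residue, nucleus) records "
                             "(only 1HA may repeat, for glycine)")

    @classmethod
    def from_records(cls, records, condition: str = "") -> "ShiftTable":
        """records: iterable of (residue, resname, nucleus, delta_omega_ppm)."""
        df = pd.DataFrame(records, columns=list(cls.REQUIRED))
        return cls(df, condition=condition)

    @classmethod
    def from_tsv(cls, path, condition: str = "") -> "ShiftTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"),
                   condition=condition or Path(path).stem)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def delta_omega_rms(table: ShiftTable, std: StdTable | None = None) -> pd.Series:
    """Per-residue composite shift perturbation (dimensionless, 'ppm-normalized').

    Only nuclei present in both the table and the std table contribute;
    N is the per-residue count of usable terms.  Residues with no usable
    nucleus are omitted with a warning.
    """
    std = std or StdTable()
    df = table.data
    usable = df[df["nucleus"].map(lambda n: n in std)].copy()
    skipped = set(df["residue"]) - set(usable["residue"])
    for res in sorted(skipped):
        logger.warning("residue %s has no nucleus with a defined std; omitted", res)
    if usable.empty:
        return pd.Series(dtype=float, name="dw_rms")
    usable["normalized_sq"] = (
        usable["delta_omega_ppm"] / usable["nucleus"].map(std.values)) ** 2
    rms = usable.groupby("residue")["normalized_sq"].mean() ** 0.5
    rms.name = "dw_rms"
    return rms


def classify_perturbed(rms: pd.Series, threshold: float = 0.5) -> set:
    """Residues whose composite perturbation exceeds the threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return set(rms[rms > threshold].index)


def shift_rmsd(a: ShiftTable, b: ShiftTable, nucleus: str | None = None,
               exclude: set | None = None) -> float:
    """RMS difference (ppm) over the (residue, nucleus) records shared by a and b.

    ``nucleus`` restricts the comparison to one nucleus type; ``exclude``
    removes residue numbers (e.g. sites adjacent to a mutation).
    Symmetric in its two tables.
    """
    exclude = exclude or set()
    da, db = a.data, b.data
    if nucleus is not None:
        da = da[da["nucleus"] == nucleus]
        db = db[db["nucleus"] == nucleus]
    da = da[~da["residue"].isin(exclude)]
    db = db[~db["residue"].isin(exclude)]
    merged = da.merge(db, on=["residue", "nucleus"], suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("no shared (residue, nucleus) records to compare")
    diff = merged["delta_omega_ppm_a"] - merged["delta_omega_ppm_b"]
    return float(np.sqrt(np.mean(diff**2)))


def export_peaklist(major: ShiftTable | pd.DataFrame, table: ShiftTable,
                    path=None) -> pd.DataFrame:
    """Reconstruct minor-state absolute shifts: minor = major + delta_omega.

    ``major`` holds major-state absolute shifts in a ``delta_omega_ppm``-free
    layout: columns residue, nucleus, shift_ppm.  Records without a major
    shift are skipped with a warning.  Optionally written as TSV.
    """
    mdf = major.data if isinstance(major, ShiftTable) else major
    if "shift_ppm" not in mdf.columns:
        raise ValueError("major shift table needs a shift_ppm column")
    merged = table.data.merge(mdf[["residue", "nucleus", "shift_ppm"]],
                              on=["residue", "nucleus"], how="left")
    missing = merged["shift_ppm"].isna()
    for _, row in merged[missing].iterrows():
        logger.warning("no major shift for residue %s %s; skipped",
                       row["residue"], row["nucleus"])
    out = merged[~missing].copy()
    out["shift_ppm"] = out["shift_ppm"] + out["delta_omega_ppm"]
    out = out[["residue", "nucleus", "shift_ppm"]].reset_index(drop=True)
    if path is not None:
        out.to_csv(path, sep="\t", index=False)
    return out
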