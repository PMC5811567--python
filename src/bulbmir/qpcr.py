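"""Stem-loop qPCR relative quantification (2^-ddCt) and miRNA/target
expression-pattern comparison across tissues.

Ct values are normalised within each tissue against a reference assay
(e.g. 5.8S rRNA), then against a calibrator tissue; the relative level is
2 to the minus ddCt, so the calibrator tissue maps to exactly 1. Replicate
standard deviation of the assay Ct is propagated onto the level scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CtTable:
    """Replicate Ct measurements with a reference assay and calibrator tissue.

    rows: DataFrame with columns (assay, tissue, replicate, ct), ct > 0.
    """

    rows: pd.DataFrame
    reference_assay: str
    calibrator_tissue: str

    def __post_init__(self) -> None:
        required = {"assay", "tissue", "replicate", "ct"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"Ct table missing columns {sorted(missing)}")
        if (self.rows["ct"] <= 0).any():
            raise ValueError("all Ct values must be positive")
        tissues = set(self.rows["tissue"])
        ref_tissues = set(
            self.rows.loc[self.rows["assay"] == self.reference_assay, "tissue"]
        )
        absent = tissues - ref_tissues
        if absent:
            raise ValueError(
                f"reference assay {self.reference_assay!r} missing in "
                f"tissue(s) {sorted(absent)}"
            )
        if self.calibrator_tissue not in tissues:
            raise ValueError(
                f"calibrator tissue {self.calibrator_tissue!r} not in table"
            )

    @classmethod
    def from_tsv(cls, path, reference_assay: str,
                 calibrator_tissue: str) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"),
                   reference_assay=reference_assay,
                   calibrator_tissue=calibrator_tissue)


def relative_expression(table: CtTable) -> pd.DataFrame:
    """Mean relative level (2^-ddCt) and dispersion per (assay, tissue).

    dCt = mean Ct(assay) - mean Ct(reference) within a tissue;
    ddCt = dCt(tissue) - dCt(calibrator); level = 2^-ddCt. The dispersion
    columns give the replicate SD of the assay Ct and the level range it
    implies (level * 2^+/-sd).
    """
    df = table.rows
    means = df.groupby(["assay", "tissue"])["ct"].agg(["mean", "std", "count"])
    ref = means.xs(table.reference_assay, level="assay")["mean"]

    records = []
    for assay in sorted(set(df["assay"]) - {table.reference_assay}):
        sub = means.xs(assay, level="assay")
        dct = sub["mean"] - ref.reindex(sub.index)
        if table.calibrator_tissue not in dct.index:
            raise ValueError(
                f"assay {assay!r} not measured in calibrator tissue"
            )
        ddct = dct - dct[table.calibrator_tissue]
        for tissue in sub.index:
            sd = sub.loc[tissue, "std"]
            sd = 0.0 if pd.isna(sd) else float(sd)
            level = float(2.0 ** -ddct[tissue])
            records.append({
                "assay": assay,
                "tissue": tissue,
                "ddct": float(ddct[tissue]),
                "level": level,
                "ct_sd": sd,
                "level_low": level * 2.0 ** -sd,
                "level_high": level * 2.0 ** sd,
            })
    return pd.DataFrame(records)


def opposite_pattern(
    mirna_levels: dict[str, float],
    target_levels: dict[str, float],
) -> tuple[bool | None, float]:
    """Spearman rank correlation of miRNA vs target levels across tissues.

    Returns (opposite_flag, rho); the flag is True when rho < 0, and None
    (undefined) when either vector is constant. Requires >= 3 shared tissues.
    """
    shared = sorted(set(mirna_levels) & set(target_levels))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared tissues")
    x = np.array([mirna_levels[t] for t in shared], dtype=float)
    y = np.array([target_levels[t] for t in shared], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None, float("nan")
    rho = float(stats.spearmanr(x, y).statistic)
    return rho < 0, rho
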