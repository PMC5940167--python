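"""Reading and writing phenotype/marker tables.

Datasets are plain CSV: a phenotype file with one value per line (either a
single ``value`` column or ``id,value``), and a marker file whose rows are
lines and whose columns are numeric genotype codes in {0, 1, 2} (an
optional leading ``id`` column is aligned against the phenotype ids).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .augmented import RegressionData

__all__ = ["read_dataset", "write_dataset"]

_VALID_CODES = {0.0, 1.0, 2.0}


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return pd.read_csv(path)


def read_dataset(phenotype_path, marker_path) -> RegressionData:
    """Load and align a phenotype CSV and a marker CSV into RegressionData.

    Errors name the offending cell/row; missing values and genotype codes
    outside {0, 1, 2} are rejected.
    """
    pheno = _read_table(phenotype_path)
    geno = _read_table(marker_path)

    if "id" in pheno.columns:
        if "id" not in geno.columns:
            raise ValueError("phenotype file has ids but marker file does not")
        unmatched = set(pheno["id"]) ^ set(geno["id"])
        if unmatched:
            raise ValueError(f"ids not present in both files: {sorted(unmatched)[:10]}")
        geno = geno.set_index("id").loc[pheno["id"]].reset_index()
        geno = geno.drop(columns=["id"])
        value_cols = [c for c in pheno.columns if c != "id"]
    else:
        value_cols = list(pheno.columns)

    if len(value_cols) != 1:
        raise ValueError(
            f"phenotype file must have exactly one value column, found {value_cols}"
        )
    y = pd.to_numeric(pheno[value_cols[0]], errors="coerce").to_numpy(dtype=float)
    if np.isnan(y).any():
        bad = np.flatnonzero(np.isnan(y))
        raise ValueError(f"missing/non-numeric phenotype at rows {bad.tolist()[:10]}")

    if y.size != len(geno):
        raise ValueError(
            f"phenotype has {y.size} rows but marker file has {len(geno)}"
        )
    X = geno.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(X).any():
        i, j = np.argwhere(np.isnan(X))[0]
        raise ValueError(
            f"missing/non-numeric genotype at row {i}, column {geno.columns[j]!r}"
        )
    bad = ~np.isin(X, list(_VALID_CODES))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"genotype value {X[i, j]!r} at row {i}, column {geno.columns[j]!r} "
            "is not a valid code (expected 0, 1 or 2)"
        )
    return RegressionData(y, X)


def write_dataset(data: RegressionData, phenotype_path, marker_path,
                  ids=None) -> None:
    """Write RegressionData back to the CSV pair read by read_dataset."""
    pheno = pd.DataFrame({"value": data.y})
    geno = pd.DataFrame(
        data.X.astype(int), columns=[f"m{j+1}" for j in range(data.p)]
    )
    if ids is not None:
        pheno.insert(0, "id", ids)
        geno.insert(0, "id", ids)
    pheno.to_csv(phenotype_path, index=False)
    geno.to_csv(marker_path, index=False)
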