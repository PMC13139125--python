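"""Phenotype statistics on the accession x trait matrix.

Per-trait summaries (mean, SD, CV%), one-pass Z-score outlier removal at
|Z| >= 4, and the pairwise-complete Pearson correlation matrix — producing
the tidy CSVs a downstream GWAS (rMVP/FarmCPU) consumes.

The trait matrix is a plain :class:`pandas.DataFrame` indexed by accession id
with the 24 fixed trait columns; missing cells are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd

from .traits import TRAIT_NAMES


@dataclass(frozen=True)
class StatsConfig:
    """Z-score magnitude at or above which a cell is an outlier."""

    z_threshold: float = 4.0
    ddof: int = 0

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")


def trait_matrix(rows: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Assemble per-image trait vectors into an accession x trait matrix."""
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.reindex(columns=list(TRAIT_NAMES))
    df.index.name = "Taxa"
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate accession ids: {dupes}")
    return df


def summarize(m: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Per-trait mean, SD, CV% and non-missing count (missing cells excluded).

    CV% = 100 * sd / mean, undefined (NaN) when the mean is 0.
    """
    rows = []
    for trait in m.columns:
        vals = m[trait].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            rows.append((trait, np.nan, np.nan, np.nan, 0))
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=ddof)) if vals.size > ddof else 0.0
        cv = 100.0 * sd / mean if mean != 0 else np.nan
        rows.append((trait, mean, sd, cv, int(vals.size)))
    return pd.DataFrame(rows, columns=["trait", "mean", "sd", "cv_percent",
                                       "n_nonmissing"]).set_index("trait")


def zscore_filter(m: pd.DataFrame, config: StatsConfig = StatsConfig()
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Set outlier cells (|Z| >= threshold) to missing, trait by trait.

    Single pass: Z-scores use the mean/SD of the unfiltered non-missing
    values, and removal is not re-iterated.  A zero-SD trait never loses a
    value.  Returns the filtered matrix and a removal log with one row per
    removed cell (accession, trait, value, z).
    """
    out = m.copy()
    removals = []
    for trait in m.columns:
        col = m[trait]
        vals = col.dropna()
        if vals.empty:
            continue
        sd = float(vals.std(ddof=config.ddof)) if vals.size > config.ddof else 0.0
        if sd == 0:
            continue
        mean = float(vals.mean())
        z = (vals - mean) / sd
        for accession, zval in z[z.abs() >= config.z_threshold].items():
            removals.append((accession, trait, float(col[accession]), float(zval)))
            out.loc[accession, trait] = np.nan
    log = pd.DataFrame(removals, columns=["accession", "trait", "value", "z"])
    return out, log


def pearson_matrix(m: pd.DataFrame, min_obs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between traits.

    Cells with fewer than ``min_obs`` complete pairs, or involving a
    zero-variance trait, are missing; the diagonal is 1 for any trait with
    enough non-missing, non-constant values.
    """
    corr = m.corr(method="pearson", min_periods=min_obs)
    # pandas leaves diag 1 even for constant columns; blank those out
    for trait in m.columns:
        vals = m[trait].dropna()
        if vals.size < min_obs or float(vals.std()) == 0.0:
            corr.loc[trait, :] = np.nan
            corr.loc[:, trait] = np.nan
    # enforce exact symmetry against float asymmetries
    arr = corr.to_numpy()
    sym = (arr + arr.T) / 2.0
    return pd.DataFrame(sym, index=corr.index, columns=corr.columns)


def export_phenotypes(m: pd.DataFrame) -> str:
    """GWAS phenotype CSV: ``Taxa`` column then the 24 traits; missing as NA."""
    out = m.copy()
    out.index.name = "Taxa"
    return out.to_csv(na_rep="NA")


def read_phenotypes(text: str) -> pd.DataFrame:
    """Inverse of :func:`export_phenotypes`."""
    df = pd.read_csv(StringIO(text), index_col="Taxa", na_values=["NA"])
    df.index = df.index.astype(str)
    return df
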