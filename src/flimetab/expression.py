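"""Relative qPCR quantification and gene-expression z-scores.

Expression is quantified with the 2^-ddCt method: per sample,
dCt = Ct_gene - Ct_reference (technical replicates averaged
arithmetically first); against a calibrator condition,
ddCt = dCt_sample - dCt_calibrator and fold = 2^-ddCt.  The default
reference gene is beta-actin (ACTB).  Heatmap matrices are z-scored
within gene across samples, z = (x - mu) / sigma, using the sample
(n-1) standard deviation.  RNA purity bookkeeping checks the A260/A280
and A260/A230 ratios against the ~1.8 acceptability band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ZScoreMatrix",
    "RnaQc",
    "ExpressionError",
    "delta_delta_ct",
    "zscore_matrix",
    "rna_qc",
]


class ExpressionError(ValueError):
    """Raised for malformed Ct tables or degenerate expression inputs."""


@dataclass(frozen=True)
class RnaQc:
    """RNA purity check from NanoDrop absorbance ratios."""

    a260_a280: float
    a260_a230: float
    passed: bool
    target: float = 1.8
    tolerance: float = 0.2


@dataclass(frozen=True)
class ZScoreMatrix:
    """Genes x samples matrix of z-scores, scaled within gene."""

    values: pd.DataFrame
    degenerate_genes: tuple[str, ...]
    orientation: str = "genes_x_samples"


def delta_delta_ct(
    table: pd.DataFrame,
    ref_gene: str = "ACTB",
    calibrator: str = "Xpan",
) -> pd.DataFrame:
    """2^-ddCt fold changes from a long-format Ct table.

    ``table`` columns: condition, gene, ct (and optionally sample,
    replicate).  Replicate Ct values are averaged arithmetically per
    (condition, gene) before any differencing.  Returns one row per
    gene x condition with dct, ddct and fold; the calibrator condition's
    fold is exactly 1 for every gene.
    """
    required = {"condition", "gene", "ct"}
    if not required.issubset(table.columns):
        raise ExpressionError(f"Ct table must have columns {sorted(required)}")
    ct = np.asarray(table["ct"], dtype=float)
    if np.any(~np.isfinite(ct)) or np.any(ct <= 0):
        raise ExpressionError("Ct values must be finite and positive")
    mean_ct = (
        table.groupby(["condition", "gene"], sort=False)["ct"].mean().unstack()
    )
    if ref_gene not in mean_ct.columns:
        raise ExpressionError(f"reference gene {ref_gene!r} missing from table")
    if calibrator not in mean_ct.index:
        raise ExpressionError(f"calibrator condition {calibrator!r} missing")
    missing_ref = mean_ct[ref_gene].isna()
    if missing_ref.any():
        raise ExpressionError(
            f"no reference-gene Ct for condition(s) "
            f"{list(mean_ct.index[missing_ref])}"
        )
    dct = mean_ct.sub(mean_ct[ref_gene], axis=0)
    ddct = dct.sub(dct.loc[calibrator], axis=1)
    rows = []
    for condition in dct.index:
        for gene in dct.columns:
            if gene == ref_gene:
                continue
            rows.append({
                "condition": condition, "gene": gene,
                "dct": float(dct.loc[condition, gene]),
                "ddct": float(ddct.loc[condition, gene]),
                "fold": float(2.0 ** -ddct.loc[condition, gene]),
            })
    return pd.DataFrame(rows)


def zscore_matrix(values: pd.DataFrame | np.ndarray) -> ZScoreMatrix:
    """Z-score each gene (row) across samples (columns).

    Uses the sample (n-1) standard deviation.  Genes with zero variance
    return all-zero rows and are listed in ``degenerate_genes`` rather
    than producing NaNs.  Requires >= 2 samples.
    """
    df = pd.DataFrame(values)
    if df.shape[1] < 2:
        raise ExpressionError("z-scoring needs >= 2 samples per gene")
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    degenerate = sd == 0
    safe_sd = sd.where(~degenerate, 1.0)
    z = df.sub(mu, axis=0).div(safe_sd, axis=0)
    z.loc[degenerate] = 0.0
    return ZScoreMatrix(
        values=z,
        degenerate_genes=tuple(str(g) for g in df.index[degenerate]),
    )


def rna_qc(
    a260: float,
    a280: float,
    a230: float,
    target: float = 1.8,
    tolerance: float = 0.2,
) -> RnaQc:
    """RNA purity from absorbance ratios.

    Passes iff both A260/A280 and A260/A230 lie within ``tolerance`` of
    ``target`` (~1.8 for pure RNA); the band is configurable.
    """
    if a260 <= 0 or a280 <= 0 or a230 <= 0:
        raise ExpressionError("absorbances must be positive")
    r280 = a260 / a280
    r230 = a260 / a230
    passed = abs(r280 - target) <= tolerance and abs(r230 - target) <= tolerance
    return RnaQc(
        a260_a280=r280, a260_a230=r230, passed=passed,
        target=target, tolerance=tolerance,
    )
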