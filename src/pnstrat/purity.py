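"""Log transformation and gene-wise tumour-purity residualisation.

Bulk tumour expression mixes tumour and stromal signal; clustering on raw
values can therefore track cellular composition rather than tumour state.
The remedy used here is to regress each gene's log2 expression on the
per-sample tumour-purity estimate (ordinary least squares with intercept)
and cluster the residuals instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import DataError, ExpressionMatrix, logger


def log_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount) on a linear-scale matrix."""
    if expr.scale != "linear":
        raise DataError(f"log_transform expects a linear-scale matrix, got {expr.scale!r}")
    if pseudocount <= 0:
        raise DataError("pseudocount must be > 0")
    if (expr.data.to_numpy() < 0).any():
        raise DataError("negative expression value encountered before log transform")
    return ExpressionMatrix(np.log2(expr.data + pseudocount), scale="log2")


def adjust_for_purity(logexpr: ExpressionMatrix, purity: pd.Series) -> ExpressionMatrix:
    """Per-gene OLS residuals of log2 expression against tumour purity.

    Samples with missing purity are dropped (logged), not imputed.  If all
    retained purities are identical the fit degenerates to intercept-only
    and the output is per-gene mean-centred expression (logged warning).
    Residuals satisfy, per gene, mean 0 and zero inner product with the
    centred purity vector up to numerical tolerance.
    """
    if logexpr.scale != "log2":
        raise DataError(f"adjust_for_purity expects a log2 matrix, got {logexpr.scale!r}")
    purity = purity.reindex(logexpr.sample_ids)
    keep = purity.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d samples with missing purity", n_dropped)
    if keep.sum() < 3:
        raise DataError("need at least 3 samples with purity for residualisation")
    data = logexpr.data.loc[:, keep.to_numpy()]
    p = purity[keep].to_numpy(dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise DataError("purity values must lie in [0, 1]")

    y = data.to_numpy()
    pc = p - p.mean()
    ss = float(pc @ pc)
    if ss < 1e-24:
        logger.warning("all purity values identical; falling back to mean-centering")
        resid = y - y.mean(axis=1, keepdims=True)
    else:
        slope = (y @ pc) / ss
        resid = y - y.mean(axis=1, keepdims=True) - slope[:, None] * pc[None, :]
    out = pd.DataFrame(resid, index=data.index, columns=data.columns)
    return ExpressionMatrix(out, scale="residual", purity_used=purity[keep].copy())
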