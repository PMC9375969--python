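"""Expression-based validation of copy-number calls (GECNAV).

A gene-level CNA call is only trusted when the tumour's mRNA level moves
in the same direction relative to the gene's median expression across the
cohort.  Expression is discretised to the same five-level code used for
CNA status (-2 deep loss ... +2 high gain); a CNA whose sign is not echoed
by expression is zeroed out, one whose sign matches is replaced by the
(usually more conservative) expression status.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import DataError

STATUS_LEVELS = (-2, -1, 0, 1, 2)

# Multiples of the per-gene median bounding each expression status band.
LOW_DEEP = 0.05   # below -> -2
LOW = 0.75        # [0.05m, 0.75m) -> -1
HIGH = 1.25       # (1.25m, 1.75m] -> +1
HIGH_AMP = 1.75   # above -> +2


def expression_status(value, gene_median):
    """Five-level expression status of ``value`` against the gene median.

    Accepts scalars or numpy arrays.  Bands (half-open at the outer edges):
    ``< 0.05*m`` -> -2; ``[0.05*m, 0.75*m)`` -> -1; ``(1.25*m, 1.75*m]`` -> +1;
    ``> 1.75*m`` -> +2; otherwise 0.  With ``m == 0`` every positive value is
    +2 and zero is 0, which the general rule already yields.
    """
    v = np.asarray(value, dtype=float)
    m = np.asarray(gene_median, dtype=float)
    if (v < 0).any() or (m < 0).any():
        raise DataError("expression values and medians must be non-negative")
    status = np.select(
        [v < LOW_DEEP * m, v < LOW * m, v > HIGH_AMP * m, v > HIGH * m],
        [-2, -1, 2, 1],
        default=0,
    )
    if np.isscalar(value) or np.ndim(value) == 0:
        return int(status)
    return status


def expression_status_matrix(expression: pd.DataFrame) -> pd.DataFrame:
    """Discretise a genes x patients expression matrix.

    The reference median is computed per gene across all patients in the
    matrix (pan-cancer, post-QC population).
    """
    values = expression.to_numpy(dtype=float)
    if (values < 0).any():
        raise DataError("expression matrix contains negative values")
    medians = np.median(values, axis=1, keepdims=True)
    status = expression_status(values, medians)
    return pd.DataFrame(status, index=expression.index, columns=expression.columns, dtype=int)


def validate_cna(cna: int, expr_status) -> int:
    """Validate one CNA status against one expression status.

    ``expr_status`` of ``None`` (or NaN) means no expression was found for
    the gene: the CNA status is left unchanged.  Otherwise a nonzero CNA
    whose sign matches a nonzero expression status is replaced by the
    expression status; everything else becomes 0.
    """
    if cna not in STATUS_LEVELS:
        raise DataError(f"CNA status {cna!r} outside {{-2..2}}")
    if expr_status is None or (isinstance(expr_status, float) and np.isnan(expr_status)):
        return int(cna)
    expr_status = int(expr_status)
    if expr_status not in STATUS_LEVELS:
        raise DataError(f"expression status {expr_status!r} outside {{-2..2}}")
    if cna != 0 and expr_status != 0 and np.sign(cna) == np.sign(expr_status):
        return expr_status
    return 0


def validate_cna_matrix(cna: pd.DataFrame, expr_status: pd.DataFrame) -> pd.DataFrame:
    """Element-wise CNA validation over genes x patients matrices.

    Genes (rows) or patients (columns) absent from ``expr_status`` count as
    "expression not found": their CNA statuses pass through unchanged.
    Output has the shape and ordering of ``cna``.
    """
    values = cna.to_numpy()
    if not np.isin(values, STATUS_LEVELS).all():
        raise DataError("CNA matrix contains entries outside {-2..2}")

    expr = expr_status.reindex(index=cna.index, columns=cna.columns)
    e = expr.to_numpy(dtype=float)
    known = ~np.isnan(e)
    if not np.isin(e[known], STATUS_LEVELS).all():
        raise DataError("expression status matrix contains entries outside {-2..2}")

    same_sign = (values != 0) & (np.sign(values) == np.sign(e)) & (e != 0)
    validated = np.where(known, np.where(same_sign, e, 0), values)
    return pd.DataFrame(
        validated.astype(int), index=cna.index, columns=cna.columns
    )
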