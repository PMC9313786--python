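"""Count-to-expression transforms: CPM, RPKM, log2, row z-scores, TMM factors.

RPKM divides by raw library size (read depth as mapped), while CPM accepts
optional TMM scaling factors so the differential-expression stage can test on
effective library sizes. Row z-scores use the sample (n-1) standard
deviation; constant rows map to zeros so downstream clustering stays defined
for flat transcripts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data_model import CountMatrix, DataValidationError, ExpressionMatrix


def _check_libraries(counts: CountMatrix) -> pd.Series:
    libs = counts.library_sizes
    zero = libs[libs == 0]
    if len(zero):
        raise DataValidationError(f"all-zero sample column(s): {zero.index.tolist()}")
    return libs.astype(float)


def to_cpm(counts: CountMatrix, factors: pd.Series | None = None) -> ExpressionMatrix:
    """Counts per million: count / (library_size * factor) * 1e6."""
    libs = _check_libraries(counts)
    if factors is not None:
        factors = pd.Series(factors).reindex(libs.index)
        if factors.isna().any() or (factors <= 0).any():
            raise DataValidationError("TMM factors must be positive and cover all samples")
        libs = libs * factors
    values = counts.counts.astype(float).div(libs, axis=1) * 1e6
    return ExpressionMatrix(values=values, measure="CPM", samples=counts.samples, factors=factors)


def to_rpkm(counts: CountMatrix) -> ExpressionMatrix:
    """Reads per kilobase per million: count / (length_kb * library_millions)."""
    libs = _check_libraries(counts)
    length_kb = counts.lengths_bp.astype(float) / 1e3
    values = (
        counts.counts.astype(float)
        .div(libs / 1e6, axis=1)
        .div(length_kb, axis=0)
    )
    return ExpressionMatrix(values=values, measure="RPKM", samples=counts.samples)


def log2p(expr: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2(value + offset)."""
    if expr.measure.startswith("log2") or expr.measure == "zscore":
        raise DataValidationError(f"cannot log-transform measure {expr.measure!r}")
    shifted = expr.values + offset
    if (shifted.values <= 0).any():
        raise DataValidationError("log2p requires value + offset > 0 everywhere")
    return ExpressionMatrix(
        values=np.log2(shifted),
        measure=f"log2{expr.measure}",
        samples=expr.samples,
        factors=expr.factors,
    )


def zscore_rows(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-transcript standardization: (x - row mean) / row sd (ddof=1).

    Constant rows map to all-zeros rather than NaN.
    """
    if expr.values.shape[1] < 2:
        raise DataValidationError("z-scoring needs at least 2 samples")
    x = expr.values.values.astype(float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    z[np.repeat(sd == 0, x.shape[1], axis=1)] = 0.0
    return ExpressionMatrix(
        values=pd.DataFrame(z, index=expr.values.index, columns=expr.values.columns),
        measure="zscore",
        samples=expr.samples,
    )


def _choose_reference(props: np.ndarray) -> int:
    """Column whose 75th percentile of count proportions is closest to the mean."""
    q75 = np.quantile(props, 0.75, axis=0)
    return int(np.argmin(np.abs(q75 - q75.mean())))


def tmm_factors(
    counts: CountMatrix,
    ref_sample: str | None = None,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors (Robinson & Oshlack).

    For each non-reference sample: over transcripts nonzero in both it and
    the reference, compute M (log2 ratio of library-scaled proportions) and
    A (mean log2 abundance); drop the extreme 30% of M and 5% of A from each
    tail; the factor is 2 to the precision-weighted mean of the surviving M.
    Factors are rescaled to geometric mean 1.
    """
    libs = _check_libraries(counts).values
    if counts.counts.shape[1] < 2:
        raise DataValidationError("TMM needs at least 2 samples")
    y = counts.counts.values.astype(float)
    props = y / libs
    samples = list(counts.counts.columns)
    if ref_sample is None:
        ref = _choose_reference(props)
    else:
        ref = samples.index(ref_sample)

    log_factors = np.zeros(len(samples))
    for k in range(len(samples)):
        if k == ref:
            continue
        keep = (y[:, k] > 0) & (y[:, ref] > 0)
        if not keep.any():
            warnings.warn(f"no transcripts shared with reference for sample {samples[k]}")
            continue
        pk, pr = props[keep, k], props[keep, ref]
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        # asymptotic binomial variance of M (delta method) for weighting
        w = (libs[k] - y[keep, k]) / (libs[k] * y[keep, k]) + (
            libs[ref] - y[keep, ref]
        ) / (libs[ref] * y[keep, ref])
        n = len(m)
        lo_m = np.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * abundance_trim) + 1
        hi_a = n + 1 - lo_a
        rank_m = pd.Series(m).rank(method="first").values
        rank_a = pd.Series(a).rank(method="first").values
        surviving = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not surviving.any():
            warnings.warn(
                f"TMM trimming left no transcripts for sample {samples[k]}; factor set to 1"
            )
            continue
        log_factors[k] = np.sum(m[surviving] / w[surviving]) / np.sum(1.0 / w[surviving])

    log_factors -= log_factors.mean()  # geometric mean of 2**logf equals 1
    return pd.Series(2.0 ** log_factors, index=samples, name="tmm_factor")
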