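"""Array preprocessing: sample QC, quantile normalization, probe handling.

The contract, in fixed order: (1) drop samples whose median coefficient of
variation on replicated probes is too high, (2) quantile-normalize log2
values across the remaining arrays, (3) average replicated probes (values
and flags) and drop control probes and heavily flagged probes, (4) for the
metabolic view, average probes of the same gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "QCReport",
    "qc_filter_samples",
    "quantile_normalize",
    "collapse_replicates_and_filter",
    "average_probes_to_genes",
    "read_expression_tsv",
    "read_geo_series_matrix",
]

REASON_MISSING = "missing_values"
REASON_FLAGGED = "flag_fraction_exceeded"
REASON_CONTROL = "control_probe"
REASON_SAMPLE_CV = "median_cv_above_threshold"


@dataclass
class QCReport:
    """Per-sample CV medians and every exclusion with its single reason."""

    sample_cv_spikein: dict[str, float] = field(default_factory=dict)
    sample_cv_replicated: dict[str, float] = field(default_factory=dict)
    excluded_samples: dict[str, str] = field(default_factory=dict)
    excluded_probes: dict[str, str] = field(default_factory=dict)


def _median_replicate_cv(matrix: pd.DataFrame, probe_ids: pd.Series) -> pd.Series:
    """Per-sample median CV across probes measured by >= 2 replicate rows."""
    counts = probe_ids.value_counts()
    replicated = counts[counts >= 2].index
    sub = matrix.loc[probe_ids.isin(replicated).to_numpy()]
    ids = probe_ids[probe_ids.isin(replicated).to_numpy()]
    if sub.empty:
        return pd.Series(np.nan, index=matrix.columns)
    grouped = sub.groupby(ids.to_numpy())
    cv = grouped.std(ddof=1) / grouped.mean()
    return cv.abs().median(axis=0)


def qc_filter_samples(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    cv_threshold: float = 0.10,
    require_both_fail: bool = True,
) -> tuple[pd.DataFrame, QCReport]:
    """Remove samples whose replicate reproducibility is poor.

    For each sample the median CV is computed over spike-in/control probes
    and, separately, over non-control replicated probes (CV across the
    replicate rows of a probe within that sample). With the default
    ``require_both_fail`` a sample is retained if either probe set achieves
    a median CV below ``cv_threshold`` and excluded only when both fail;
    set it False for the disjunctive reading (exclude if either fails).

    ``annotation`` rows align with ``matrix`` rows and must carry
    ``probe_id`` and ``is_control`` columns.
    """
    report = QCReport()
    is_control = annotation["is_control"].to_numpy(dtype=bool)
    probe_ids = annotation["probe_id"].reset_index(drop=True)

    cv_spike = _median_replicate_cv(matrix.loc[is_control], probe_ids[is_control])
    cv_repl = _median_replicate_cv(matrix.loc[~is_control], probe_ids[~is_control])
    if cv_repl.isna().all():
        warnings.warn(
            "no non-control replicated probes; sample QC uses spike-ins only",
            stacklevel=2,
        )
    report.sample_cv_spikein = cv_spike.to_dict()
    report.sample_cv_replicated = cv_repl.to_dict()

    # NaN (criterion unavailable) counts as "fails" so the other set decides
    fail_spike = ~(cv_spike < cv_threshold)
    fail_repl = ~(cv_repl < cv_threshold)
    if cv_spike.isna().all() and cv_repl.isna().all():
        excluded = pd.Series(False, index=matrix.columns)
    elif require_both_fail:
        excluded = fail_spike & fail_repl
    else:
        excluded = (fail_spike & cv_spike.notna()) | (fail_repl & cv_repl.notna())
    for sample in matrix.columns[excluded.to_numpy()]:
        report.excluded_samples[sample] = REASON_SAMPLE_CV
    return matrix.loc[:, ~excluded.to_numpy()], report


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean distribution of order statistics.

    After normalization all columns share the identical sorted value vector
    (the across-column mean of order statistics) while within-column ranks
    are preserved. Ties within a column receive the mean of the target
    quantiles they span. Idempotent. A single-column matrix is returned
    unchanged with a warning.
    """
    if matrix.isna().to_numpy().any():
        raise ValueError("quantile_normalize requires a complete matrix")
    if matrix.shape[1] < 2:
        warnings.warn("single-column matrix: quantile normalization is identity",
                      stacklevel=2)
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    target = np.sort(values, axis=0).mean(axis=1)
    n = values.shape[0]
    out = np.empty_like(values)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, target)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_replicates_and_filter(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    flags: pd.DataFrame | None = None,
    flag_fraction: float = 0.66,
    report: QCReport | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None, QCReport]:
    """Average replicate probe rows, then drop controls and flagged probes.

    Replicate rows of a probe are averaged (values as means; a collapsed
    probe counts as flagged in a sample when more than half of its replicate
    rows are flagged there). Control probes are dropped, as are probes with
    missing values after collapsing and probes flagged in strictly more than
    ``flag_fraction`` of samples.
    """
    if report is None:
        report = QCReport()
    is_control = annotation["is_control"].to_numpy(dtype=bool)
    probe_ids = annotation["probe_id"].to_numpy()
    for pid in pd.unique(probe_ids[is_control]):
        report.excluded_probes[str(pid)] = REASON_CONTROL

    keep = ~is_control
    sub = matrix.loc[keep]
    ids = probe_ids[keep]
    collapsed = sub.groupby(ids, sort=True).mean()
    collapsed.index.name = "probe_id"

    if flags is not None:
        fsub = flags.loc[keep].astype(float)
        collapsed_flags = fsub.groupby(ids, sort=True).mean() > 0.5
        collapsed_flags = collapsed_flags.loc[collapsed.index, collapsed.columns]
    else:
        collapsed_flags = None

    missing = collapsed.isna().any(axis=1)
    for pid in collapsed.index[missing]:
        report.excluded_probes[str(pid)] = REASON_MISSING

    if collapsed_flags is not None:
        frac = collapsed_flags.mean(axis=1)
        over = (frac > flag_fraction) & ~missing
        for pid in collapsed.index[over]:
            report.excluded_probes[str(pid)] = REASON_FLAGGED
        drop = missing | over
    else:
        drop = missing

    out = collapsed.loc[~drop]
    out_flags = collapsed_flags.loc[~drop] if collapsed_flags is not None else None
    return out, out_flags, report


def average_probes_to_genes(
    matrix: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Gene x sample matrix: mean over each gene's probes.

    ``annotation`` must carry probe_id and gene_symbol; probes without a
    symbol are excluded from this view (they remain in the probe matrix).
    """
    ann = annotation.drop_duplicates("probe_id").set_index("probe_id")
    symbols = ann["gene_symbol"].reindex(matrix.index)
    has_symbol = symbols.notna() & (symbols.astype(str).str.strip() != "")
    sub = matrix.loc[has_symbol.to_numpy()]
    genes = symbols[has_symbol.to_numpy()].astype(str).to_numpy()
    out = sub.groupby(genes, sort=True).mean()
    out.index.name = "gene_symbol"
    return out


# ---------------------------------------------------------------------------
# readers

def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_geo_series_matrix(path) -> pd.DataFrame:
    """Read a GEO series-matrix-style export (plain-text, '!' header lines)."""
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith(("!", "#")) and ln.strip()]
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines)), sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = [str(c).strip('"') for c in df.columns]
    return df
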