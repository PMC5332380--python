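"""Normalization, differential-expression calls, and reverse-regulated genes.

The pipeline compares three conditions pairwise: disease-vs-control gives
the disease-perturbed genes, treated-vs-disease gives the drug-responsive
genes, and their opposite-sign intersection gives the drug-*regulated*
(reverse-regulated) genes whose disease shift the treatment inverts.

The differential test is pluggable: a precomputed table (e.g. from a
negative-binomial GLM package) can be ingested verbatim; the built-in
stand-in is a per-gene Welch t-test on log2(TPM + 1) with Benjamini-
Hochberg FDR, which keeps the pipeline self-contained end to end.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_FDR_MAX = 0.10
DEFAULT_ABS_LOG2FC_MIN = 0.58


class NormalizationError(ValueError):
    pass


class ContrastError(ValueError):
    pass


def normalize_tpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Rescale each sample column to sum to one million (tags per million).

    Raises :class:`NormalizationError` naming the first all-zero sample,
    since a zero column cannot be placed on the per-million scale.
    """
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise NormalizationError(f"sample {zero.index[0]!r} has an all-zero count column")
    return counts / totals * 1.0e6


def validate_count_matrix(counts: pd.DataFrame, condition_of: pd.Series) -> None:
    """Check the count-matrix contract: unique IDs, full condition map,
    nonnegative integral values, exactly three conditions."""
    if counts.index.has_duplicates:
        raise ValueError("duplicate gene identifiers in count matrix")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers in count matrix")
    missing = [s for s in counts.columns if s not in condition_of.index]
    if missing:
        raise ValueError(f"samples missing from condition map: {missing[:5]}")
    vals = counts.to_numpy()
    if (vals < 0).any():
        raise ValueError("count matrix contains negative values")
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("count matrix contains non-integral values")
    n_cond = condition_of.loc[counts.columns].nunique()
    if n_cond != 3:
        raise ValueError(f"expected exactly three conditions, found {n_cond}")


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample size factors: median ratio to the per-gene geometric mean,
    over genes expressed in every sample.  Robust to composition shifts."""
    vals = counts.to_numpy(dtype=float)
    positive = (vals > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError("no gene has positive counts in every sample")
    log_geo = np.log(vals[positive]).mean(axis=1)
    sf = np.exp(np.median(np.log(vals[positive]) - log_geo[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _trended_prior(abundance: np.ndarray, variances: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Per-gene shrinkage target: median variance within abundance-quantile bins."""
    m = len(abundance)
    n_bins = max(1, min(n_bins, m // 10 or 1))
    order = np.argsort(abundance, kind="stable")
    bins = np.array_split(order, n_bins)
    prior = np.empty(m)
    for idx in bins:
        prior[idx] = np.median(variances[idx])
    return prior


def test_differential(
    counts: pd.DataFrame,
    condition_of: pd.Series,
    contrast: tuple[str, str],
    pseudocount: float = 1.0,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Built-in differential test for ``contrast = (reference, comparison)``.

    Per gene: log2 fold change of mean TPM (with pseudocount), a two-sided
    unequal-variance t-test on log2(TPM + pseudocount), and BH FDR across
    all genes.  With only a handful of replicates a per-gene variance
    estimate is hopeless (2 df at triplicates), so each group's variance
    is shrunk toward the experiment-wide median with ``prior_df`` prior
    degrees of freedom (empirical-Bayes moderation in the limma mold) and
    the Welch-Satterthwaite df gains ``prior_df`` per group; ``prior_df=0``
    recovers the plain Welch test.  All-zero genes in both groups get
    log2fc 0, p 1.

    Returns a DataFrame indexed by gene with columns
    ``log2fc``, ``pvalue``, ``fdr`` and a ``contrast`` label.
    """
    ref, comp = contrast
    for cond in contrast:
        if cond not in set(condition_of):
            raise ContrastError(f"condition {cond!r} absent from condition map")
    ref_samples = condition_of.index[condition_of == ref]
    comp_samples = condition_of.index[condition_of == comp]
    if len(ref_samples) < 2 or len(comp_samples) < 2:
        raise ContrastError("each contrast condition needs >= 2 samples")

    # Median-of-ratios size factors: per-million scaling is not robust to
    # composition shifts when many genes move strongly in one direction,
    # which would smear an apparent fold change over every null gene.
    norm = counts / median_of_ratios_size_factors(counts)
    log_ref = np.log2(norm[ref_samples].to_numpy() + pseudocount)
    log_comp = np.log2(norm[comp_samples].to_numpy() + pseudocount)

    log2fc = np.log2(norm[comp_samples].mean(axis=1) + pseudocount) - np.log2(
        norm[ref_samples].mean(axis=1) + pseudocount
    )
    n1, n2 = log_ref.shape[1], log_comp.shape[1]
    v1 = log_ref.var(axis=1, ddof=1)
    v2 = log_comp.var(axis=1, ddof=1)
    if prior_df > 0:
        # Trended prior: counts are heteroscedastic on the log scale (the
        # Poisson term shrinks with expression), so the shrinkage target is
        # the median within-group variance of genes of similar abundance.
        abundance = np.concatenate([log_ref, log_comp], axis=1).mean(axis=1)
        s0 = _trended_prior(abundance, 0.5 * (v1 + v2))
        v1 = (prior_df * s0 + (n1 - 1) * v1) / (prior_df + n1 - 1)
        v2 = (prior_df * s0 + (n2 - 1) * v2) / (prior_df + n2 - 1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (log_comp.mean(axis=1) - log_ref.mean(axis=1)) / np.sqrt(se2)
        df = se2**2 / (
            (v1 / n1) ** 2 / (n1 - 1 + prior_df)
            + (v2 / n2) ** 2 / (n2 - 1 + prior_df)
        )
    p = 2.0 * stats.t.sf(np.abs(t), df=df)

    flat = np.logical_and(
        np.ptp(log_ref, axis=1) == 0,
        np.logical_and(np.ptp(log_comp, axis=1) == 0,
                       log_ref[:, 0] == log_comp[:, 0]),
    )
    p = np.where(np.isnan(p) | flat, 1.0, p)
    log2fc = np.where(flat, 0.0, log2fc)

    fdr = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {"log2fc": log2fc, "pvalue": p, "fdr": fdr}, index=counts.index.copy()
    )
    out.attrs["contrast"] = f"{comp}-vs-{ref}"
    return out


def read_differential_table(path: str | Path, contrast: str = "") -> pd.DataFrame:
    """Ingest a precomputed table (TSV: gene, log2fc, pvalue, fdr) verbatim."""
    tab = pd.read_csv(path, sep="\t", index_col="gene")
    required = {"log2fc", "pvalue", "fdr"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"differential table missing columns: {sorted(missing)}")
    for col in ("pvalue", "fdr"):
        if ((tab[col] < 0) | (tab[col] > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
    tab.attrs["contrast"] = contrast
    return tab


def write_differential_table(table: pd.DataFrame, path: str | Path) -> None:
    table.rename_axis("gene").to_csv(path, sep="\t")


def call_degs(
    table: pd.DataFrame,
    fdr_max: float = DEFAULT_FDR_MAX,
    abs_log2fc_min: float = DEFAULT_ABS_LOG2FC_MIN,
) -> pd.Series:
    """Differentially expressed genes at ``fdr < fdr_max`` and
    ``|log2fc| > abs_log2fc_min`` (both strict).

    Returns a Series gene -> sign (+1 up, -1 down by log2fc sign).
    """
    if not (0 < fdr_max <= 1):
        raise ValueError("fdr_max must lie in (0, 1]")
    if abs_log2fc_min < 0:
        raise ValueError("abs_log2fc_min must be >= 0")
    keep = (table["fdr"] < fdr_max) & (table["log2fc"].abs() > abs_log2fc_min)
    return np.sign(table.loc[keep, "log2fc"]).astype(int)


def reverse_regulated(
    disease_degs: pd.Series, treatment_degs: pd.Series
) -> pd.Series:
    """Opposite-sign intersection of the two DEG sets.

    A gene up in disease-vs-control and down in treated-vs-disease is
    ``inversely_down`` (the treatment pushes it down, back toward control);
    the mirror case is ``inversely_up``.  Same-sign overlaps are excluded.
    """
    common = disease_degs.index.intersection(treatment_degs.index)
    opposite = common[disease_degs.loc[common] * treatment_degs.loc[common] == -1]
    labels = np.where(
        treatment_degs.loc[opposite] > 0, "inversely_up", "inversely_down"
    )
    return pd.Series(labels, index=opposite, name="direction").sort_index()
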