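"""Label-free proteomics rollup and transcript-protein correlation.

Peptide tables are log2 abundances with missing values and a peptide ->
protein mapping.  The pipeline removes peptides with insufficient data,
estimates per-sample offsets from rank-invariant peptides, rolls peptides up
to protein profiles against a reference peptide (R-Rollup), and correlates
protein with transcript profiles per gene across the 12 samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import FactorialDEResults, adjust_bh

__all__ = [
    "filter_peptides",
    "rank_invariant_normalize",
    "rollup_proteins",
    "correlate_rna_protein",
    "coverage_fraction",
]


def filter_peptides(
    peptides: pd.DataFrame, min_fraction_observed: float = 0.5
) -> pd.DataFrame:
    """Drop peptides observed in fewer than ``min_fraction_observed`` of samples."""
    frac = peptides.notna().mean(axis=1)
    return peptides.loc[frac >= min_fraction_observed]


def rank_invariant_normalize(
    peptides: pd.DataFrame, rank_span_fraction: float = 0.1
) -> pd.DataFrame:
    """Subtract per-sample offsets estimated from rank-invariant peptides.

    Complete-case peptides whose abundance rank moves by less than
    ``rank_span_fraction`` of the complete-case peptide count across all
    samples are selected; each sample's offset is the median deviation of the
    selected peptides from their across-sample mean.  Falls back to global
    median centering (with a warning) when no peptide is rank-invariant.
    """
    complete = peptides.dropna(axis=0)
    if len(complete) < 10:
        raise ValueError(
            f"need >= 10 complete-case peptides for normalization, have {len(complete)}"
        )
    ranks = complete.rank(axis=0)
    span = ranks.max(axis=1) - ranks.min(axis=1)
    invariant = complete.loc[span < rank_span_fraction * len(complete)]
    if invariant.empty:
        warnings.warn(
            "no rank-invariant peptides found; falling back to global median centering",
            stacklevel=2,
        )
        offsets = peptides.median(axis=0) - float(np.nanmedian(peptides.to_numpy()))
    else:
        deviation = invariant.sub(invariant.mean(axis=1), axis=0)
        offsets = deviation.median(axis=0)
    return peptides.sub(offsets, axis=1)


def rollup_proteins(
    peptides: pd.DataFrame, mapping: pd.Series
) -> pd.DataFrame:
    """Reference-based rollup of peptides into protein profiles (R-Rollup).

    Per protein, the reference peptide is the most frequently observed one
    (ties break toward the higher median abundance); every other peptide is
    shifted by the median of its per-sample log2 difference to the reference,
    and the protein's abundance in a sample is the median of the shifted
    peptide values observed there.
    """
    missing = peptides.index.difference(mapping.index)
    if len(missing):
        raise ValueError(f"peptides without protein mapping: {list(missing[:5])}")
    profiles = {}
    for protein, members in peptides.groupby(mapping.loc[peptides.index]):
        n_obs = members.notna().sum(axis=1)
        med = members.median(axis=1)
        ref_id = members.index[np.lexsort((-med.to_numpy(), -n_obs.to_numpy()))[0]]
        ref = members.loc[ref_id]
        scaled = []
        for pep_id, row in members.iterrows():
            if pep_id == ref_id:
                scaled.append(row)
                continue
            diff = (row - ref).dropna()
            shift = float(diff.median()) if len(diff) else 0.0
            scaled.append(row - shift)
        profiles[protein] = pd.concat(scaled, axis=1).median(axis=1)
    return pd.DataFrame(profiles).T.reindex(columns=peptides.columns)


def coverage_fraction(n_complete: int, n_annotated: int) -> float:
    """Percentage of annotated genes with complete dual-platform coverage."""
    if n_annotated <= 0:
        raise ValueError("annotation count must be positive")
    return 100.0 * n_complete / n_annotated


def correlate_rna_protein(
    rna: pd.DataFrame,
    protein: pd.DataFrame,
    fits: FactorialDEResults | None = None,
    de_alpha: float = 0.01,
    corr_alpha: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene Pearson correlation of transcript and protein profiles.

    Only genes observed in every sample on both platforms enter the table
    (complete dual coverage).  Returns the per-gene table (r, P, DE flag,
    highly-correlated flag) and a summary dict with the pooled all-pairs r
    and median r stratified by DE status.  The ``highly_correlated`` gene
    list (correlation P < ``corr_alpha``) is what feeds hypergeometric
    enrichment downstream.
    """
    shared = rna.index.intersection(protein.index)
    rna_s = rna.loc[shared]
    prot_s = protein.loc[shared, rna.columns]
    complete = shared[rna_s.notna().all(axis=1).to_numpy() & prot_s.notna().all(axis=1).to_numpy()]
    if rna.shape[1] < 3:
        raise ValueError("need at least 3 shared samples for correlation")

    x = rna_s.loc[complete].to_numpy(float)
    y = prot_s.loc[complete].to_numpy(float)
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc * yc).sum(axis=1) / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    # two-sided P from the t transform of r with n-2 df
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    pvals = 2.0 * stats.t.sf(np.abs(tstat), n - 2)

    table = pd.DataFrame({"r": r, "pvalue": pvals}, index=complete)
    table["adj_pvalue"] = adjust_bh(table["pvalue"]) if len(table) else []
    if fits is not None:
        de_genes = set(fits.significant(alpha=de_alpha))
        table["de"] = [g in de_genes for g in complete]
    else:
        table["de"] = False
    table["highly_correlated"] = table["pvalue"] < corr_alpha

    pooled = float(np.corrcoef(x.ravel(), y.ravel())[0, 1]) if len(complete) > 1 else np.nan
    de_r = table.loc[table["de"], "r"]
    summary = {
        "n_complete": int(len(complete)),
        "pooled_r": pooled,
        "median_r_all": float(table["r"].median()) if len(table) else np.nan,
        "median_r_de": float(de_r.median()) if len(de_r) else np.nan,
        "median_r_non_de": float(table.loc[~table["de"], "r"].median())
        if (~table["de"]).any()
        else np.nan,
        "n_highly_correlated": int(table["highly_correlated"].sum()),
    }
    return table, summary
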