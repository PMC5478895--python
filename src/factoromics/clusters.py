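"""Group differentially expressed genes by the rank order of their three
factor contributions.

Each significant gene's three signed coefficients (nitrogen limitation N,
DGA1 overexpression D, and the interaction DxN, all on the log2 scale) are
ranked from highest to lowest; genes sharing the same ordering form one of
the 3! = 6 clusters.  The "contribution" is the signed coefficient value —
e.g. the pattern N > D > DxN describes genes pushed up by nitrogen
limitation and down by the interaction.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .diffexpr import FactorialDEResults

__all__ = ["FACTOR_ORDER", "cluster_labels", "rank_factor_contributions"]

#: Fixed tie-break priority: N before D before DxN.
FACTOR_ORDER = ("N", "D", "DxN")

_COEF_FOR = {"N": "Nlim", "D": "DGA", "DxN": "DGAxNlim"}


def cluster_labels() -> list[str]:
    """The 6 possible ordering labels, in a stable enumeration order."""
    return [">".join(p) for p in itertools.permutations(FACTOR_ORDER)]


def rank_factor_contributions(
    fits: FactorialDEResults, alpha: float = 0.01
) -> pd.DataFrame:
    """Assign each significant gene to one of the 6 factor-order clusters.

    A gene is eligible when the minimum of its three non-intercept adjusted
    P values is below ``alpha``.  Its label orders the three signed
    coefficients from highest to lowest; exact ties fall back to the fixed
    factor priority N > D > DxN and are flagged in the ``tied`` column.

    Returns a DataFrame indexed by gene with columns ``cluster`` and
    ``tied``; the per-cluster counts (including empty clusters with count 0)
    are attached as ``result.attrs["cluster_sizes"]``.
    """
    coefs = fits.coefficients[["Nlim", "DGA", "DGAxNlim"]]
    sig = fits.significant(alpha=alpha)
    if len(sig) == 0:
        warnings.warn(f"no genes significant at adjusted P < {alpha}", stacklevel=2)

    records = {}
    tie_priority = {f: i for i, f in enumerate(FACTOR_ORDER)}
    for gene in sig:
        values = {f: coefs.loc[gene, _COEF_FOR[f]] for f in FACTOR_ORDER}
        ordering = sorted(FACTOR_ORDER, key=lambda f: (-values[f], tie_priority[f]))
        tied = len({np.round(v, 12) for v in values.values()}) < 3
        records[gene] = {"cluster": ">".join(ordering), "tied": tied}

    assignment = pd.DataFrame.from_dict(records, orient="index")
    if assignment.empty:
        assignment = pd.DataFrame(columns=["cluster", "tied"])
    sizes = pd.Series(0, index=cluster_labels(), dtype=int, name="n_genes")
    if not assignment.empty:
        observed = assignment["cluster"].value_counts()
        sizes.loc[observed.index] = observed
    assignment.attrs["cluster_sizes"] = sizes
    return assignment
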