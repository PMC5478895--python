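"""Gene-set enrichment: hypergeometric tests and consensus gene-set analysis.

Two complementary tools:

* :func:`hypergeometric_enrichment` — classic over-representation of a gene
  list (e.g. highly correlated genes, or one factor-order cluster) against a
  gene-set collection, with BH adjustment across sets.

* :func:`consensus_gsa` — rank-based consensus over three whole-distribution
  set statistics (mean t, median t, Stouffer combination of one-sided P)
  evaluated under four directionality classes, with a gene-label permutation
  null.  A set's consensus rank score is the median of its ranks under the
  three statistics; low scores (e.g. <= 1, or <= 5 for a looser view) flag
  the consistently top-ranked sets.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh

__all__ = [
    "filter_sets",
    "hypergeometric_enrichment",
    "consensus_gsa",
    "DIRECTION_CLASSES",
    "GSA_METHODS",
]

DIRECTION_CLASSES = ("distinct_up", "distinct_down", "mixed", "non_directional")
GSA_METHODS = ("mean", "median", "stouffer")


def filter_sets(
    sets: dict[str, dict],
    universe: list[str] | set[str],
    min_size: int = 5,
    max_size: int = 500,
) -> dict[str, dict]:
    """Restrict sets to the gene universe, then drop sets with fewer than
    ``min_size`` or more than ``max_size`` members."""
    universe = set(universe)
    out: dict[str, dict] = {}
    for name, entry in sets.items():
        genes = [g for g in entry["genes"] if g in universe]
        if min_size <= len(genes) <= max_size:
            out[name] = {"description": entry.get("description", ""), "genes": genes}
    return out


def hypergeometric_enrichment(
    gene_list: list[str] | set[str],
    universe: list[str] | set[str],
    sets: dict[str, dict],
) -> pd.DataFrame:
    """One-sided (upper tail) hypergeometric over-representation test.

    For each set of size K in a universe of size N, with a query list of
    size n overlapping the set in k genes, P = P(X >= k) for X
    hypergeometric(N, K, n).  BH adjustment is applied across sets.
    """
    universe = set(universe)
    gene_list = set(gene_list)
    missing = gene_list - universe
    if missing:
        raise ValueError(f"query genes not in universe: {sorted(missing)[:10]}")
    N, n = len(universe), len(gene_list)
    rows = []
    for name, entry in sets.items():
        members = set(entry["genes"]) & universe
        K = len(members)
        k = len(members & gene_list)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, p))
    table = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "list_size", "universe_size", "pvalue"]
    ).set_index("set")
    table["adj_pvalue"] = adjust_bh(table["pvalue"]) if len(table) else []
    return table.sort_values("pvalue")


# ---------------------------------------------------------------------------
# consensus GSA
# ---------------------------------------------------------------------------


def _one_sided_up_p(t: np.ndarray, p_two: np.ndarray) -> np.ndarray:
    return np.where(t > 0, p_two / 2.0, 1.0 - p_two / 2.0)


def _set_stats(values: np.ndarray, member_idx: np.ndarray, kind: str) -> float:
    sub = values[member_idx]
    if kind == "mean":
        return float(np.mean(sub))
    if kind == "median":
        return float(np.median(sub))
    raise ValueError(kind)


def _stouffer(z: np.ndarray, member_idx: np.ndarray) -> float:
    sub = z[member_idx]
    return float(np.sum(sub) / math.sqrt(len(sub)))


def consensus_gsa(
    gene_stats: pd.DataFrame,
    sets: dict[str, dict],
    n_perm: int | None = 1000,
    seed: int = 0,
    rank_score_cutoff: float | None = None,
) -> pd.DataFrame:
    """Consensus gene-set analysis for one factor's statistics.

    Parameters
    ----------
    gene_stats :
        DataFrame indexed by gene with columns ``t`` (moderated t) and ``p``
        (two-sided P) covering the universe.
    sets :
        Gene-set collection (``filter_sets`` output); sets with no member in
        the universe are skipped with a warning.
    n_perm :
        Number of gene-label permutations (>= 100), or ``None`` for exact
        enumeration over all same-size gene subsets (only feasible for tiny
        universes; enumeration is capped at 200,000 subsets).
    seed :
        Seed for the permutation draws; fixed seed gives fixed output.
    rank_score_cutoff :
        If given, only rows whose consensus score is <= the cutoff in at
        least one direction class are returned.

    Returns
    -------
    DataFrame with one row per (set, direction class): the three method P
    values, their ranks across sets, and the consensus rank score (median of
    the three ranks).
    """
    if n_perm is not None and n_perm < 100:
        raise ValueError("n_perm must be >= 100 (or None for exact enumeration)")
    genes = list(gene_stats.index)
    pos = {g: i for i, g in enumerate(genes)}
    t = gene_stats["t"].to_numpy(float)
    p_two = np.clip(gene_stats["p"].to_numpy(float), 1e-300, 1.0)
    z_up = stats.norm.isf(np.clip(_one_sided_up_p(t, p_two), 1e-300, 1 - 1e-16))
    abs_t = np.abs(t)
    z_nd = stats.norm.isf(np.clip(p_two, 1e-300, 1 - 1e-16))

    member_idx: dict[str, np.ndarray] = {}
    for name, entry in sets.items():
        idx = np.array([pos[g] for g in entry["genes"] if g in pos], dtype=int)
        if idx.size == 0:
            warnings.warn(f"set {name!r} has no members in the universe; skipped", stacklevel=2)
            continue
        member_idx[name] = idx

    def observed(idx: np.ndarray) -> dict[str, dict[str, float]]:
        # signed statistics feed the directional classes; |t|-based feed non-directional
        return {
            "signed": {
                "mean": _set_stats(t, idx, "mean"),
                "median": _set_stats(t, idx, "median"),
                "stouffer": _stouffer(z_up, idx),
            },
            "absolute": {
                "mean": _set_stats(abs_t, idx, "mean"),
                "median": _set_stats(abs_t, idx, "median"),
                "stouffer": _stouffer(z_nd, idx),
            },
        }

    obs = {name: observed(idx) for name, idx in member_idx.items()}

    # permutation null: counts of null statistics >= / <= the observed value
    ge_signed = {name: dict.fromkeys(GSA_METHODS, 0) for name in member_idx}
    le_signed = {name: dict.fromkeys(GSA_METHODS, 0) for name in member_idx}
    ge_abs = {name: dict.fromkeys(GSA_METHODS, 0) for name in member_idx}

    def tally(name: str, idx: np.ndarray) -> None:
        for method in GSA_METHODS:
            if method == "stouffer":
                s_signed = _stouffer(z_up, idx)
                s_abs = _stouffer(z_nd, idx)
            else:
                s_signed = _set_stats(t, idx, method)
                s_abs = _set_stats(abs_t, idx, method)
            if s_signed >= obs[name]["signed"][method]:
                ge_signed[name][method] += 1
            if s_signed <= obs[name]["signed"][method]:
                le_signed[name][method] += 1
            if s_abs >= obs[name]["absolute"][method]:
                ge_abs[name][method] += 1

    if n_perm is None:
        sizes = {len(idx) for idx in member_idx.values()}
        denom_for: dict[str, int] = {}
        for k in sizes:
            n_subsets = math.comb(len(genes), k)
            if n_subsets > 200_000:
                raise ValueError(
                    f"exact enumeration infeasible: C({len(genes)},{k}) = {n_subsets}"
                )
        for name, idx in member_idx.items():
            k = len(idx)
            denom_for[name] = math.comb(len(genes), k)
            for combo in itertools.combinations(range(len(genes)), k):
                tally(name, np.asarray(combo, dtype=int))
        pvalue = lambda count, name: count / denom_for[name]  # noqa: E731
    else:
        rng = np.random.default_rng(seed)
        all_idx = np.arange(len(genes))
        for _ in range(n_perm):
            perm = rng.permutation(all_idx)
            for name, idx in member_idx.items():
                tally(name, perm[idx])
        pvalue = lambda count, name: (count + 1) / (n_perm + 1)  # noqa: E731

    rows = []
    for name, idx in member_idx.items():
        for cls in DIRECTION_CLASSES:
            rec = {"set": name, "class": cls, "n_genes": len(idx)}
            for method in GSA_METHODS:
                if cls == "distinct_up":
                    p = pvalue(ge_signed[name][method], name)
                elif cls == "distinct_down":
                    p = pvalue(le_signed[name][method], name)
                elif cls == "mixed":
                    p_up = pvalue(ge_signed[name][method], name)
                    p_dn = pvalue(le_signed[name][method], name)
                    p = min(1.0, 2.0 * min(p_up, p_dn))
                else:  # non_directional
                    p = pvalue(ge_abs[name][method], name)
                rec[f"p_{method}"] = p
            rows.append(rec)
    table = pd.DataFrame(rows)
    if table.empty:
        return table

    # per-class, per-method ranks across sets; consensus = median of ranks
    for method in GSA_METHODS:
        table[f"rank_{method}"] = (
            table.groupby("class")[f"p_{method}"].rank(method="min").astype(int)
        )
    rank_cols = [f"rank_{m}" for m in GSA_METHODS]
    table["consensus_score"] = table[rank_cols].median(axis=1)
    table = table.set_index(["set", "class"]).sort_values("consensus_score")
    if rank_score_cutoff is not None:
        keep_sets = table.index.get_level_values("set")[
            table["consensus_score"] <= rank_score_cutoff
        ].unique()
        table = table.loc[table.index.get_level_values("set").isin(keep_sets)]
    return table
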