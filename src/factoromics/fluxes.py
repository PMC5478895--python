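"""Constraint-based flux sampling and flux-expression regulation scoring.

A small stoichiometric model (JSON schema below) is constrained per
experimental condition: measured exchange fluxes and the growth rate are
bounded to one standard deviation around their means, the biomass reaction
is recomposed to the condition's measured protein/lipid coefficients, and
the non-growth-associated maintenance (NGAM) ATP drain is restricted to a
5% window below its LP maximum.  The feasible flux polytope
{v : S v = 0, lb <= v <= ub} is then explored with an artificial-centering
hit-and-run (ACHR) sampler, cross-condition changes are summarized as flux
Z-scores, and reaction-gene pairs whose flux, transcript and protein
Z-scores agree in sign receive a regulation score (the signed minimum of the
three magnitudes).

JSON model schema::

    {
      "metabolites": ["glc", "atp", ...],
      "reactions": [
        {"id": "GLYC", "metabolites": {"glc": -1, "pyr": 2, "atp": 2},
         "lower_bound": 0, "upper_bound": 1000,
         "gpr": "g0001 and g0002",           # optional
         "exchange": false,
         "direction": "uptake"}              # exchanges only: uptake|excretion
      ],
      "biomass": "BIOMASS", "ngam": "NGAM"
    }

Exchange reactions are written ``met ->`` (positive flux = excretion); an
uptake measurement of magnitude m with SD s becomes the bound
[-(m + s), -(m - s)].
"""

from __future__ import annotations

import copy
import dataclasses
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, optimize

__all__ = [
    "MetabolicModel",
    "FluxSamples",
    "apply_condition_constraints",
    "calibrate_ngam",
    "sample_fluxes",
    "flux_zscores",
    "regulation_scores",
]


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MetabolicModel:
    metabolites: list[str]
    reactions: list[dict]
    biomass: str
    ngam: str

    def __post_init__(self) -> None:
        met_set = set(self.metabolites)
        if len(met_set) != len(self.metabolites):
            raise ValueError("duplicate metabolite IDs")
        seen = set()
        for rxn in self.reactions:
            if rxn["id"] in seen:
                raise ValueError(f"duplicate reaction ID {rxn['id']!r}")
            seen.add(rxn["id"])
            unknown = set(rxn["metabolites"]) - met_set
            if unknown:
                raise ValueError(f"reaction {rxn['id']!r} uses unknown metabolites {sorted(unknown)}")
            if rxn["lower_bound"] > rxn["upper_bound"]:
                raise ValueError(f"reaction {rxn['id']!r}: lower bound exceeds upper bound")
            gpr = rxn.get("gpr", "")
            if gpr:
                for gene in gpr_genes(gpr):
                    if not re.fullmatch(r"[A-Za-z_][\w.-]*", gene):
                        raise ValueError(f"invalid gene ID {gene!r} in GPR of {rxn['id']!r}")

    @property
    def reaction_ids(self) -> list[str]:
        return [r["id"] for r in self.reactions]

    def reaction(self, rxn_id: str) -> dict:
        for rxn in self.reactions:
            if rxn["id"] == rxn_id:
                return rxn
        raise KeyError(rxn_id)

    def stoichiometric_matrix(self) -> np.ndarray:
        met_pos = {m: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coeff in rxn["metabolites"].items():
                S[met_pos[met], j] = coeff
        return S

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r["lower_bound"] for r in self.reactions], float)
        ub = np.array([r["upper_bound"] for r in self.reactions], float)
        return lb, ub

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            list(self.metabolites), copy.deepcopy(self.reactions), self.biomass, self.ngam
        )

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_json(cls, path: str | Path) -> "MetabolicModel":
        with open(path) as handle:
            obj = json.load(handle)
        return cls(obj["metabolites"], obj["reactions"], obj["biomass"], obj["ngam"])

    def to_json(self, path: str | Path) -> None:
        obj = {
            "metabolites": self.metabolites,
            "reactions": self.reactions,
            "biomass": self.biomass,
            "ngam": self.ngam,
        }
        with open(path, "w") as handle:
            json.dump(obj, handle, indent=2, sort_keys=True)
            handle.write("\n")


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------


def _tokenize_gpr(expr: str) -> list[str]:
    return re.findall(r"\(|\)|\band\b|\bor\b|[\w.-]+", expr)


def _parse_gpr(tokens: list[str], pos: int = 0):
    # expr := term ('or' term)*; term := factor ('and' factor)*; factor := gene | '(' expr ')'
    def parse_expr(i):
        node, i = parse_term(i)
        terms = [node]
        while i < len(tokens) and tokens[i] == "or":
            nxt, i = parse_term(i + 1)
            terms.append(nxt)
        return (("or", terms) if len(terms) > 1 else node), i

    def parse_term(i):
        node, i = parse_factor(i)
        factors = [node]
        while i < len(tokens) and tokens[i] == "and":
            nxt, i = parse_factor(i + 1)
            factors.append(nxt)
        return (("and", factors) if len(factors) > 1 else node), i

    def parse_factor(i):
        if tokens[i] == "(":
            node, i = parse_expr(i + 1)
            if i >= len(tokens) or tokens[i] != ")":
                raise ValueError("unbalanced parentheses in GPR")
            return node, i + 1
        return ("gene", tokens[i]), i + 1

    node, end = parse_expr(pos)
    if end != len(tokens):
        raise ValueError("trailing tokens in GPR")
    return node


def gpr_genes(expr: str) -> list[str]:
    """All gene IDs appearing in a GPR expression."""
    return [t for t in _tokenize_gpr(expr) if t not in {"(", ")", "and", "or"}]


def resolve_gpr(expr: str, abs_z: dict[str, float]) -> str | None:
    """Pick the representative gene of a GPR: AND takes the minimum-|z|
    gene of its children, OR the maximum-|z| gene.  Genes absent from
    ``abs_z`` are ignored; returns None when no gene is scored."""
    tree = _parse_gpr(_tokenize_gpr(expr))

    def walk(node) -> str | None:
        kind = node[0]
        if kind == "gene":
            return node[1] if node[1] in abs_z else None
        children = [walk(c) for c in node[1]]
        children = [c for c in children if c is not None]
        if not children:
            return None
        pick = min if kind == "and" else max
        return pick(children, key=lambda g: (abs_z[g], g))

    return walk(tree)


# ---------------------------------------------------------------------------
# condition constraints and NGAM calibration
# ---------------------------------------------------------------------------


def _solve_lp(model: MetabolicModel, c: np.ndarray):
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    return optimize.linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )


def _assert_feasible(model: MetabolicModel, context: str, touched: list[str]) -> None:
    res = _solve_lp(model, np.zeros(len(model.reactions)))
    if res.status == 0:
        return
    # diagnose: which single constraint relaxation restores feasibility
    culprits = []
    for rxn_id in touched:
        relaxed = model.copy()
        rxn = relaxed.reaction(rxn_id)
        rxn["lower_bound"], rxn["upper_bound"] = -1e6, 1e6
        if _solve_lp(relaxed, np.zeros(len(model.reactions))).status == 0:
            culprits.append(rxn_id)
    detail = f"; relaxing any of {culprits} restores feasibility" if culprits else ""
    raise ValueError(f"infeasible model after {context}{detail}")


def apply_condition_constraints(
    model: MetabolicModel,
    physiology: pd.DataFrame,
    condition: str,
    sd_multiplier: float = 1.0,
) -> MetabolicModel:
    """Bound measured exchanges and growth to mean +/- ``sd_multiplier`` SD.

    Physiology columns ``r_<x>`` / ``r_<x>_sd`` map to exchange reaction
    ``EX_<x>``; uptake exchanges get negative bounds.  Columns
    ``protein_coeff`` / ``lipid_coeff`` recompose the biomass reaction's
    ``prot`` and ``lipid`` consumption.
    """
    if condition not in physiology.index:
        raise KeyError(f"condition {condition!r} not in physiology table")
    row = physiology.loc[condition]
    out = model.copy()
    touched: list[str] = []

    for col in physiology.columns:
        if not col.startswith("r_") or col.endswith("_sd"):
            continue
        ex_id = "EX_" + col[2:]
        try:
            rxn = out.reaction(ex_id)
        except KeyError:
            continue
        mean = float(row[col])
        sd = float(row.get(col + "_sd", 0.0)) * sd_multiplier
        if rxn.get("direction") == "uptake":
            rxn["lower_bound"], rxn["upper_bound"] = -(mean + sd), -(mean - sd)
        else:
            rxn["lower_bound"], rxn["upper_bound"] = mean - sd, mean + sd
        touched.append(ex_id)

    if "mu" in physiology.columns:
        mu = float(row["mu"])
        sd = float(row.get("mu_sd", 0.0)) * sd_multiplier
        growth = out.reaction(out.biomass)
        growth["lower_bound"], growth["upper_bound"] = max(0.0, mu - sd), mu + sd
        touched.append(out.biomass)

    biomass = out.reaction(out.biomass)
    for met, col in (("prot", "protein_coeff"), ("lipid", "lipid_coeff")):
        if col in physiology.columns and met in biomass["metabolites"]:
            biomass["metabolites"][met] = -float(row[col])

    _assert_feasible(out, f"constraining to condition {condition!r}", touched)
    return out


def calibrate_ngam(model: MetabolicModel, window: float = 0.05) -> MetabolicModel:
    """Maximize the NGAM drain by LP and bound it to [(1-window)*max, max]."""
    c = np.zeros(len(model.reactions))
    c[model.reaction_ids.index(model.ngam)] = -1.0  # maximize
    res = _solve_lp(model, c)
    if res.status == 3:
        raise ValueError("NGAM maximization is unbounded; cap it via substrate limits")
    if res.status != 0:
        raise ValueError(f"NGAM calibration failed: model infeasible (status {res.status})")
    ngam_max = float(-res.fun)
    out = model.copy()
    rxn = out.reaction(out.ngam)
    rxn["lower_bound"], rxn["upper_bound"] = (1.0 - window) * ngam_max, ngam_max
    _assert_feasible(out, "NGAM calibration", [out.ngam])
    return out


# ---------------------------------------------------------------------------
# ACHR sampling
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FluxSamples:
    """Flux draws from the constrained polytope, with per-reaction summaries."""

    draws: pd.DataFrame  # reactions x draws

    @property
    def mean(self) -> pd.Series:
        return self.draws.mean(axis=1)

    @property
    def sd(self) -> pd.Series:
        return self.draws.std(axis=1, ddof=1)

    @property
    def rsd(self) -> pd.Series:
        mean = self.mean
        with np.errstate(divide="ignore", invalid="ignore"):
            return (self.sd / mean.abs()).replace([np.inf, -np.inf], np.nan)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd, "rsd": self.rsd})


def sample_fluxes(
    model: MetabolicModel,
    n_draws: int = 5000,
    seed: int = 0,
    n_warmup: int = 100,
    thinning: int = 10,
) -> FluxSamples:
    """Artificial-centering hit-and-run over {v : S v = 0, lb <= v <= ub}.

    Warm-up points are LP solutions of random +/- objectives; each chain step
    moves from the current point along the direction from the running center
    to a random warm-up point (projected onto the null space of S), by a
    uniformly drawn feasible step.  Every ``thinning``-th point is recorded.
    Deterministic for fixed (model, n_draws, seed, n_warmup, thinning).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    n_rxn = len(model.reactions)

    if S.shape[0] > 0:
        svals = linalg.svdvals(S)
        tol = max(S.shape) * np.finfo(float).eps * (svals[0] if svals.size else 1.0)
        kept = svals[svals > tol]
        if kept.size and kept[0] / kept[-1] > 1e12:
            raise ValueError(
                f"stoichiometric matrix numerically rank-deficient "
                f"(condition number {kept[0] / kept[-1]:.2e})"
            )
        nullbasis = linalg.null_space(S)
        pinv = np.linalg.pinv(S)
    else:
        nullbasis = np.eye(n_rxn)
        pinv = np.zeros((n_rxn, 0))

    def correct(x: np.ndarray) -> np.ndarray:
        if S.shape[0]:
            x = x - pinv @ (S @ x)
        return np.clip(x, lb, ub)

    # warm-up: random-objective LP vertices
    warmup = []
    for _ in range(n_warmup):
        c = rng.standard_normal(n_rxn)
        res = _solve_lp_cached(model, c, S, lb, ub)
        if res.status != 0:
            raise ValueError("model infeasible; cannot sample")
        warmup.append(correct(res.x))
    warmup = np.array(warmup)

    spread = np.ptp(warmup, axis=0).max() if n_warmup > 1 else 0.0
    if nullbasis.shape[1] == 0 or spread < 1e-10:
        # fully determined network (bounds and balances pin a unique point)
        point = correct(warmup.mean(axis=0))
        draws = np.tile(point[:, None], (1, n_draws))
        return FluxSamples(pd.DataFrame(draws, index=model.reaction_ids))

    center = warmup.mean(axis=0)
    x = center.copy()
    draws = np.empty((n_rxn, n_draws))
    recorded = 0
    step = 0
    n_visited = n_warmup
    max_steps = n_draws * thinning * 10  # safety net against degenerate directions
    while recorded < n_draws and step < max_steps:
        step += 1
        d = warmup[rng.integers(n_warmup)] - center
        d = nullbasis @ (nullbasis.T @ d)
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            continue
        d /= norm
        with np.errstate(divide="ignore", invalid="ignore"):
            moving = np.abs(d) > 1e-11
            alpha_lo = (lb[moving] - x[moving]) / d[moving]
            alpha_hi = (ub[moving] - x[moving]) / d[moving]
        lo = np.where(d[moving] > 0, alpha_lo, alpha_hi)
        hi = np.where(d[moving] > 0, alpha_hi, alpha_lo)
        a_min, a_max = lo.max(initial=-np.inf), hi.min(initial=np.inf)
        if not np.isfinite(a_min) or not np.isfinite(a_max) or a_max <= a_min:
            continue
        x = x + rng.uniform(a_min, a_max) * d
        n_visited += 1
        center = center + (x - center) / n_visited
        if step % thinning == 0:
            draws[:, recorded] = correct(x)
            recorded += 1
    if recorded < n_draws:
        raise RuntimeError("sampler failed to produce the requested draws")
    return FluxSamples(pd.DataFrame(draws, index=model.reaction_ids))


def _solve_lp_cached(model, c, S, lb, ub):
    return optimize.linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lb, ub)), method="highs"
    )


# ---------------------------------------------------------------------------
# Z-scores and regulation scores
# ---------------------------------------------------------------------------


def flux_zscores(a: FluxSamples, b: FluxSamples, sd_floor: float = 1e-12) -> pd.Series:
    """Standardized mean flux difference a - b per reaction:
    Z = (mean_a - mean_b) / sqrt(sd_a^2 + sd_b^2)."""
    if list(a.draws.index) != list(b.draws.index):
        raise ValueError("reaction sets differ between the two samples")
    diff = a.mean - b.mean
    denom = np.sqrt(a.sd**2 + b.sd**2)
    z = diff / denom.clip(lower=sd_floor)
    z[(denom < sd_floor) & (diff.abs() < sd_floor)] = 0.0
    return z.rename("flux_z")


def regulation_scores(
    flux_z: pd.Series,
    rna_z: pd.Series,
    prot_z: pd.Series,
    model: MetabolicModel,
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Score each reaction-gene pair for concordant three-level regulation.

    When the flux Z and the gene's transcript and protein z-scores share a
    sign, score = sign * min(|Z_flux|, |z_rna|, |z_prot|); otherwise 0.  A
    pair with |score| above ``threshold`` is called transcriptionally
    regulated.  The GPR-resolved representative gene (AND -> minimum-|z|
    member on transcript z, OR -> maximum) is flagged per reaction.
    """
    rows = []
    for rxn in model.reactions:
        gpr = rxn.get("gpr", "")
        if not gpr or rxn["id"] not in flux_z.index:
            continue
        abs_rna = {g: abs(rna_z[g]) for g in gpr_genes(gpr) if g in rna_z.index}
        representative = resolve_gpr(gpr, abs_rna) if abs_rna else None
        for gene in dict.fromkeys(gpr_genes(gpr)):
            if gene not in rna_z.index or gene not in prot_z.index:
                continue  # pair skipped: gene not scored on both platforms
            zf, zr, zp = float(flux_z[rxn["id"]]), float(rna_z[gene]), float(prot_z[gene])
            signs = {np.sign(zf), np.sign(zr), np.sign(zp)}
            if len(signs) == 1 and 0.0 not in signs:
                score = float(next(iter(signs)) * min(abs(zf), abs(zr), abs(zp)))
            else:
                score = 0.0
            rows.append(
                {
                    "reaction": rxn["id"],
                    "gene": gene,
                    "flux_z": zf,
                    "rna_z": zr,
                    "protein_z": zp,
                    "score": score,
                    "regulated": abs(score) > threshold,
                    "gpr_representative": gene == representative,
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values("score", key=lambda s: s.abs(), ascending=False).reset_index(
            drop=True
        )
    return table
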