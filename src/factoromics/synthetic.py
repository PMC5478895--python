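"""Synthetic 2x2 factorial chemostat study with known ground truth.

The generator emulates the data layers of a multifactorial chemostat
experiment (control vs DGA1-overexpressing strain under carbon vs nitrogen
limitation, triplicate cultures):

* RNA counts: negative binomial per gene with mean
  ``lib_size * 2^(X beta_g) / sum_g 2^(X beta_g)`` and variance
  ``mu + phi mu^2``; six planted clusters realize the 3! orderings of the
  signed factor contributions (N, D, DxN), the rest of the genes are null.
* Proteins: coupled genes follow ``translation_efficiency * RNA`` with
  lognormal noise; a decoupled subset gets RNA-independent noise.  Proteins
  shatter into 2-8 peptides with lognormal response factors and random
  missingness.
* Metabolites: lognormal intensities with configured factor effects
  (including an IPM-like intermediate suppressed by the DxN interaction).
* Promoters: uniform-background sequences with one planted motif instance
  in a configured fraction of each cluster's members; non-cluster promoters
  are redrawn until they contain no planted motif.
* Gene sets: one coherent planted set per cluster plus random background
  sets, written as GMT.
* Metabolic model and physiology: a ~14-reaction toy network (glycolysis
  and TCA surrogates, lipid branch, leucine-like branch with an IPM
  intermediate and its exchange) whose per-condition exchange measurements
  are taken from a closed-form reference flux state, so the constrained
  polytope is feasible by construction and the leucine-branch flux shift
  between conditions is known exactly.

Everything is drawn from one seeded generator: identical (config, seed)
gives bit-identical bundles, including after serialization.
"""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .fluxes import MetabolicModel
from .io import StudyDesign
from .motifs import reverse_complement

__all__ = ["SimulationConfig", "GroundTruth", "SyntheticBundle", "generate_study", "write_bundle", "read_bundle"]

_FACTORS = ("N", "D", "DxN")
_COEF_FOR = {"N": "Nlim", "D": "DGA", "DxN": "DGAxNlim"}
CONDITIONS = ("WT-C", "WT-N", "DGA1-C", "DGA1-N")


@dataclasses.dataclass
class SimulationConfig:
    """Tunable parameters of the synthetic study.

    Defaults describe a desk-scale study: hundreds of genes, triplicate
    2x2 design, library depth around 2 million reads.
    """

    n_genes: int = 600
    n_replicates: int = 3
    cluster_size: int = 20  # per factor-order group (6 groups)
    coef_values: tuple[float, float, float] = (2.0, 0.5, -1.5)  # ranked contributions
    coef_jitter: float = 0.1
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    dispersion_range: tuple[float, float] = (0.01, 0.5)
    library_size_mean: float = 2e6
    library_size_log_sd: float = 0.2
    # proteomics
    protein_fraction: float = 0.6
    decoupled_fraction: float = 0.1
    protein_noise_sd: float = 0.3  # log2
    peptides_per_protein: tuple[int, int] = (2, 8)
    peptide_noise_sd: float = 0.25  # log2
    peptide_missingness: float = 0.1
    # promoters / motifs
    promoter_length: int = 600
    motif_length: int = 8
    motif_fraction: float = 0.8
    # metabolites
    n_metabolites: int = 30
    metabolite_noise_sd: float = 0.3  # log2
    # gene sets
    n_random_sets: int = 10
    random_set_size: tuple[int, int] = (8, 30)
    planted_set_size: int = 12
    #: plant the strong concordant leucine-branch effects on the two genes
    #: behind the model's LEU reactions; disable for global-null studies
    plant_pathway: bool = True

    def validate(self) -> None:
        if self.n_genes < 100:
            raise ValueError("n_genes must be >= 100")
        if self.cluster_size < 2 or 6 * self.cluster_size > self.n_genes:
            raise ValueError("cluster_size out of range for the gene universe")
        if not (4 <= self.motif_length <= 8):
            raise ValueError("motif_length must be in [4, 8]")
        if self.peptides_per_protein[0] < 2:
            raise ValueError("need at least 2 peptides per protein")
        if not (0 < self.dispersion_range[0] <= self.dispersion_range[1]):
            raise ValueError("dispersion range must be positive and ordered")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")


@dataclasses.dataclass
class GroundTruth:
    true_coefficients: pd.DataFrame  # genes x (Intercept, Nlim, DGA, DGAxNlim), log2
    dispersion: pd.Series
    translation_efficiency: pd.Series
    decoupled_genes: list[str]
    cluster_of: pd.Series  # gene -> ordering label ("" for null genes)
    planted_motifs: dict[str, str]  # cluster label -> word
    planted_sets: dict[str, list[str]]
    true_fluxes: pd.DataFrame  # reactions x conditions, reference flux state
    true_flux_shift: pd.Series  # DGA1-N minus WT-N reference flux
    model_genes: dict[str, str]  # role -> gene id


@dataclasses.dataclass
class SyntheticBundle:
    design: StudyDesign
    counts: pd.DataFrame
    peptides: pd.DataFrame  # log2 with NaN for missing
    peptide_map: pd.Series  # peptide -> protein(gene)
    metabolites: pd.DataFrame  # linear intensities
    promoters: dict[str, str]
    gene_sets: dict[str, dict]
    model: MetabolicModel
    physiology: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# pieces
# ---------------------------------------------------------------------------


def _make_design(n_replicates: int) -> StudyDesign:
    rows = []
    for dga1, nlim in ((0, 0), (0, 1), (1, 0), (1, 1)):
        strain = "DGA1" if dga1 else "WT"
        lim = "N" if nlim else "C"
        for rep in range(1, n_replicates + 1):
            rows.append({"sample_id": f"{strain}-{lim}-{rep}", "nlim": nlim, "dga1": dga1, "replicate": rep})
    return StudyDesign(pd.DataFrame(rows))


def _cluster_labels() -> list[str]:
    return [">".join(p) for p in itertools.permutations(_FACTORS)]


#: Overridden coefficients for the two leucine-branch genes: a strong
#: negative DGA and interaction effect (contrast D + DxN = -4 log2) while
#: keeping the N > D > DxN ordering of their cluster.
_LEU_COEFS = {"Nlim": 0.5, "DGA": -1.5, "DGAxNlim": -2.5}

#: Reference flux state parameters per condition:
#: (growth rate mu, glucose uptake, protein coeff, lipid coeff, IPM excretion)
_CONDITION_PARAMS = {
    "WT-C": (0.048, 0.65, 2.0, 0.5, 0.0),
    "WT-N": (0.048, 0.68, 2.0, 0.8, 0.10),
    "DGA1-C": (0.048, 0.62, 2.0, 0.7, 0.0),
    "DGA1-N": (0.048, 0.66, 1.2, 2.2, 0.002),
}

_MEASUREMENT_SD = {"mu": 0.001, "r_glc": 0.01, "r_o2": 0.02, "r_co2": 0.02, "r_ipm": 0.005}


def _reference_fluxes(mu: float, glc: float, p: float, l: float, ipm_ex: float) -> dict[str, float]:
    """Closed-form steady-state flux vector of the toy network."""
    prot = p * mu
    leu = 2.0 * prot
    lipid = l * mu
    leu1 = leu + ipm_ex
    pyr = 2.0 * glc
    pdh = pyr - 2.0 * leu1
    tca = pdh - leu1 - 8.0 * lipid
    if tca < 0:
        raise ValueError("reference state infeasible: TCA flux negative")
    o2 = 2.0 * tca
    co2 = pdh + 2.0 * tca + leu1 + leu
    ngam = 2.0 * glc + 10.0 * tca - 7.0 * lipid - 4.0 * prot - 20.0 * mu
    if ngam < 0:
        raise ValueError("reference state infeasible: ATP balance negative")
    return {
        "EX_glc": -glc,
        "EX_o2": -o2,
        "EX_co2": co2,
        "EX_ipm": ipm_ex,
        "EX_biomass": mu,
        "GLYC": glc,
        "PDH": pdh,
        "TCA": tca,
        "LEU1": leu1,
        "LEU2": leu,
        "LIPSYN": lipid,
        "PROTSYN": prot,
        "BIOMASS": mu,
        "NGAM": ngam,
    }


def build_toy_model(model_genes: dict[str, str]) -> MetabolicModel:
    """Toy stoichiometric network with a leucine-like branch.

    ``model_genes`` maps reaction roles (glyc, pdh, tca1, tca2, leu1, leu2,
    lip1, lip2, prot) to gene IDs from the synthetic universe.
    """
    g = model_genes
    mets = ["glc", "o2", "co2", "pyr", "accoa", "atp", "ipm", "leu", "lipid", "prot", "biomass"]
    big = 1000.0

    def rxn(rid, stoich, lb=0.0, ub=big, gpr="", exchange=False, direction=None):
        out = {
            "id": rid,
            "metabolites": stoich,
            "lower_bound": lb,
            "upper_bound": ub,
            "gpr": gpr,
            "exchange": exchange,
        }
        if direction:
            out["direction"] = direction
        return out

    reactions = [
        rxn("EX_glc", {"glc": -1}, lb=-big, ub=0.0, exchange=True, direction="uptake"),
        rxn("EX_o2", {"o2": -1}, lb=-big, ub=0.0, exchange=True, direction="uptake"),
        rxn("EX_co2", {"co2": -1}, exchange=True, direction="excretion"),
        rxn("EX_ipm", {"ipm": -1}, exchange=True, direction="excretion"),
        rxn("EX_biomass", {"biomass": -1}, exchange=True, direction="excretion"),
        rxn("GLYC", {"glc": -1, "pyr": 2, "atp": 2}, gpr=g["glyc"]),
        rxn("PDH", {"pyr": -1, "accoa": 1, "co2": 1}, gpr=g["pdh"]),
        rxn("TCA", {"accoa": -1, "o2": -2, "co2": 2, "atp": 10}, gpr=f"{g['tca1']} and {g['tca2']}"),
        rxn("LEU1", {"pyr": -2, "accoa": -1, "ipm": 1, "co2": 1}, gpr=g["leu1"]),
        rxn("LEU2", {"ipm": -1, "leu": 1, "co2": 1}, gpr=g["leu2"]),
        rxn("LIPSYN", {"accoa": -8, "atp": -7, "lipid": 1}, gpr=f"{g['lip1']} or {g['lip2']}"),
        rxn("PROTSYN", {"leu": -2, "atp": -4, "prot": 1}, gpr=g["prot"]),
        rxn("BIOMASS", {"prot": -2.0, "lipid": -0.5, "atp": -20, "biomass": 1}),
        rxn("NGAM", {"atp": -1}),
    ]
    return MetabolicModel(mets, reactions, biomass="BIOMASS", ngam="NGAM")


def _make_physiology() -> pd.DataFrame:
    rows = {}
    for cond, params in _CONDITION_PARAMS.items():
        fluxes = _reference_fluxes(*params)
        rows[cond] = {
            "mu": fluxes["BIOMASS"],
            "mu_sd": _MEASUREMENT_SD["mu"],
            "r_glc": -fluxes["EX_glc"],
            "r_glc_sd": _MEASUREMENT_SD["r_glc"],
            "r_o2": -fluxes["EX_o2"],
            "r_o2_sd": _MEASUREMENT_SD["r_o2"],
            "r_co2": fluxes["EX_co2"],
            "r_co2_sd": _MEASUREMENT_SD["r_co2"],
            "r_ipm": fluxes["EX_ipm"],
            "r_ipm_sd": _MEASUREMENT_SD["r_ipm"],
            "protein_coeff": params[2],
            "lipid_coeff": params[3],
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "condition"
    return frame


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


def generate_study(config: SimulationConfig | None = None, seed: int = 0) -> SyntheticBundle:
    """Generate a complete synthetic study bundle with ground truth."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    design = _make_design(config.n_replicates)
    X = design.model_matrix().to_numpy(float)
    n_samples = design.n_samples
    genes = [f"g{i:04d}" for i in range(1, config.n_genes + 1)]

    # --- planted coefficients ------------------------------------------------
    labels = _cluster_labels()
    coefs = pd.DataFrame(0.0, index=genes, columns=["Intercept", "Nlim", "DGA", "DGAxNlim"])
    coefs["Intercept"] = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    cluster_of = pd.Series("", index=genes)
    cursor = 0
    for label in labels:
        members = genes[cursor : cursor + config.cluster_size]
        cursor += config.cluster_size
        cluster_of[members] = label
        order = label.split(">")
        for rank, factor in enumerate(order):
            col = _COEF_FOR[factor]
            jitter = rng.uniform(-config.coef_jitter, config.coef_jitter, len(members))
            coefs.loc[members, col] = config.coef_values[rank] + jitter

    # leucine-branch genes: strong concordant down through D and DxN
    leu_label = "N>D>DxN"
    leu_members = [g for g in genes if cluster_of[g] == leu_label][:2]
    if config.plant_pathway:
        for gene in leu_members:
            for col, value in _LEU_COEFS.items():
                coefs.loc[gene, col] = value + rng.uniform(-0.05, 0.05)

    # --- dispersion, libraries, counts --------------------------------------
    lo, hi = config.dispersion_range
    dispersion = pd.Series(
        np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_genes)), index=genes
    )
    dispersion[leu_members] = lo  # well-measured pathway genes
    lib_sizes = np.exp(
        rng.normal(np.log(config.library_size_mean), config.library_size_log_sd, n_samples)
    )

    log2_rel = coefs.to_numpy() @ X.T  # genes x samples
    rel = 2.0**log2_rel
    frac = rel / rel.sum(axis=0, keepdims=True)
    mu = frac * lib_sizes[None, :]
    phi = dispersion.to_numpy()[:, None]
    n_param = 1.0 / phi
    p_param = n_param / (n_param + mu)
    counts = pd.DataFrame(
        rng.negative_binomial(n_param, p_param), index=genes, columns=design.sample_ids
    )
    counts.index.name = "gene"

    # --- proteins and peptides ----------------------------------------------
    n_prot = int(round(config.protein_fraction * config.n_genes))
    measured = list(rng.choice(genes, size=n_prot, replace=False))
    for gene in leu_members:
        if gene not in measured:
            measured[measured.index(max(measured))] = gene  # force pathway coverage
    measured = sorted(set(measured))
    te = pd.Series(np.exp(rng.normal(0.0, 0.8, len(measured))), index=measured)

    n_dec = int(round(config.decoupled_fraction * len(measured)))
    decoupled = sorted(rng.choice([g for g in measured if g not in leu_members], n_dec, replace=False))

    cpm_vals = counts.loc[measured].to_numpy(float) / lib_sizes[None, :] * 1e6 + 0.5
    noise = 2.0 ** rng.normal(0.0, config.protein_noise_sd, cpm_vals.shape)
    protein = te.to_numpy()[:, None] * cpm_vals * noise
    dec_idx = [measured.index(g) for g in decoupled]
    base = np.exp(rng.normal(np.log(np.median(cpm_vals)), 1.0, len(dec_idx)))
    protein[dec_idx, :] = (
        te.to_numpy()[dec_idx, None]
        * base[:, None]
        * 2.0 ** rng.normal(0.0, config.protein_noise_sd * 2, (len(dec_idx), n_samples))
    )

    pep_rows, pep_ids, pep_prot = [], [], []
    k_lo, k_hi = config.peptides_per_protein
    for i, gene in enumerate(measured):
        k = int(rng.integers(k_lo, k_hi + 1))
        response = np.exp(rng.normal(0.0, 0.5, k))
        for j in range(k):
            values = (
                protein[i] * response[j] * 2.0 ** rng.normal(0.0, config.peptide_noise_sd, n_samples)
            )
            log2_values = np.log2(values)
            missing = rng.random(n_samples) < config.peptide_missingness
            log2_values[missing] = np.nan
            pep_rows.append(log2_values)
            pep_ids.append(f"pep{len(pep_ids) + 1:05d}")
            pep_prot.append(gene)
    peptides = pd.DataFrame(pep_rows, index=pep_ids, columns=design.sample_ids)
    peptides.index.name = "peptide"
    peptide_map = pd.Series(pep_prot, index=pep_ids, name="protein")
    peptide_map.index.name = "peptide"

    # --- metabolites ----------------------------------------------------------
    met_names = ["2-isopropylmalate", "d-mannitol"] + [
        f"met{i:03d}" for i in range(1, config.n_metabolites - 1)
    ]
    met_effects = pd.DataFrame(
        0.0, index=met_names, columns=["Intercept", "Nlim", "DGA", "DGAxNlim"]
    )
    met_effects["Intercept"] = rng.normal(10.0, 1.0, len(met_names))
    met_effects.loc["2-isopropylmalate", ["Nlim", "DGAxNlim"]] = (1.5, -2.0)
    met_effects.loc["d-mannitol", "Nlim"] = 2.0
    shifted = rng.choice(met_names[2:], size=max(1, len(met_names) // 5), replace=False)
    met_effects.loc[shifted, "Nlim"] = rng.normal(0.0, 1.0, len(shifted))
    met_log2 = met_effects.to_numpy() @ X.T + rng.normal(
        0.0, config.metabolite_noise_sd, (len(met_names), n_samples)
    )
    metabolites = pd.DataFrame(2.0**met_log2, index=met_names, columns=design.sample_ids)
    metabolites.index.name = "metabolite"

    # --- promoters with planted motifs ---------------------------------------
    bases = np.array(list("ACGT"))
    planted_motifs: dict[str, str] = {}
    for label in labels:
        while True:
            word = "".join(rng.choice(bases, config.motif_length))
            if word not in planted_motifs.values() and reverse_complement(word) != word:
                planted_motifs[label] = word
                break

    def random_promoter() -> str:
        return "".join(rng.choice(bases, config.promoter_length))

    def contains_planted(seq: str) -> bool:
        rc = reverse_complement(seq)
        return any(w in seq or w in rc for w in planted_motifs.values())

    promoters: dict[str, str] = {}
    for label in labels:
        members = [g for g in genes if cluster_of[g] == label]
        n_plant = int(np.ceil(config.motif_fraction * len(members)))
        chosen = set(rng.choice(members, n_plant, replace=False))
        word = planted_motifs[label]
        for gene in members:
            while True:
                seq = random_promoter()
                if not contains_planted(seq):
                    break
            if gene in chosen:
                pos = int(rng.integers(0, config.promoter_length - len(word) + 1))
                seq = seq[:pos] + word + seq[pos + len(word) :]
            promoters[gene] = seq
    for gene in genes:
        if gene in promoters:
            continue
        while True:
            seq = random_promoter()
            if not contains_planted(seq):
                break
        promoters[gene] = seq
    promoters = {g: promoters[g] for g in genes}

    # --- gene sets -------------------------------------------------------------
    gene_sets: dict[str, dict] = {}
    planted_sets: dict[str, list[str]] = {}
    for i, label in enumerate(labels, start=1):
        members = [g for g in genes if cluster_of[g] == label]
        chosen = sorted(rng.choice(members, min(config.planted_set_size, len(members)), replace=False))
        name = f"planted_cluster{i}"
        gene_sets[name] = {"description": f"coherent set from group {label}", "genes": chosen}
        planted_sets[name] = chosen
    for i in range(1, config.n_random_sets + 1):
        size = int(rng.integers(config.random_set_size[0], config.random_set_size[1] + 1))
        members = sorted(rng.choice(genes, size, replace=False))
        gene_sets[f"random_set{i}"] = {"description": "background set", "genes": members}

    # --- metabolic model, physiology, flux truth -------------------------------
    null_genes = [g for g in genes if cluster_of[g] == ""]
    model_genes = {
        "glyc": null_genes[0],
        "pdh": null_genes[1],
        "tca1": null_genes[2],
        "tca2": null_genes[3],
        "lip1": null_genes[4],
        "lip2": null_genes[5],
        "prot": null_genes[6],
        "leu1": leu_members[0],
        "leu2": leu_members[1],
    }
    model = build_toy_model(model_genes)
    physiology = _make_physiology()
    true_fluxes = pd.DataFrame(
        {cond: _reference_fluxes(*params) for cond, params in _CONDITION_PARAMS.items()}
    )
    flux_shift = (true_fluxes["DGA1-N"] - true_fluxes["WT-N"]).rename("flux_shift")

    truth = GroundTruth(
        true_coefficients=coefs,
        dispersion=dispersion,
        translation_efficiency=te,
        decoupled_genes=list(decoupled),
        cluster_of=cluster_of,
        planted_motifs=planted_motifs,
        planted_sets=planted_sets,
        true_fluxes=true_fluxes,
        true_flux_shift=flux_shift,
        model_genes=model_genes,
    )
    return SyntheticBundle(
        design=design,
        counts=counts,
        peptides=peptides,
        peptide_map=peptide_map,
        metabolites=metabolites,
        promoters=promoters,
        gene_sets=gene_sets,
        model=model,
        physiology=physiology,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_bundle(bundle: SyntheticBundle, directory: str | Path) -> dict[str, Path]:
    """Write the bundle's interchange files; round-trips through the io
    readers losslessly."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": directory / "counts.tsv",
            "design": directory / "design.tsv",
            "peptides": directory / "peptides.tsv",
            "metabolites": directory / "metabolites.tsv",
            "promoters": directory / "promoters.fasta",
            "sets": directory / "sets.gmt",
            "model": directory / "model.json",
            "physiology": directory / "physiology.tsv",
        }
        fio.write_counts(bundle.counts, paths["counts"])
        fio.write_design(bundle.design, paths["design"])
        peptable = bundle.peptides.copy()
        peptable.insert(0, "protein", bundle.peptide_map)
        fio.write_table(peptable, paths["peptides"])
        fio.write_table(bundle.metabolites, paths["metabolites"])
        fio.write_fasta(bundle.promoters, paths["promoters"])
        fio.write_gmt(bundle.gene_sets, paths["sets"])
        bundle.model.to_json(paths["model"])
        fio.write_physiology(bundle.physiology, paths["physiology"])
    except OSError as exc:
        raise OSError(f"failed writing bundle to {directory}: {exc}") from exc
    return paths


def read_bundle(directory: str | Path) -> dict:
    """Read back the files written by :func:`write_bundle` (no ground truth)."""
    directory = Path(directory)
    peptable = fio.read_table(directory / "peptides.tsv")
    return {
        "counts": fio.read_counts(directory / "counts.tsv"),
        "design": fio.read_design(directory / "design.tsv"),
        "peptides": peptable.drop(columns="protein"),
        "peptide_map": peptable["protein"],
        "metabolites": fio.read_table(directory / "metabolites.tsv"),
        "promoters": fio.read_fasta(directory / "promoters.fasta"),
        "gene_sets": fio.read_gmt(directory / "sets.gmt"),
        "model": MetabolicModel.from_json(directory / "model.json"),
        "physiology": fio.read_physiology(directory / "physiology.tsv"),
    }
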