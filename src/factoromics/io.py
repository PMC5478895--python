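"""Readers and writers for the interchange formats used across the pipeline.

All tabular formats are TSV with a header row and feature IDs in the first
column.  Gene sets use GMT (set name, description, then tab-separated member
genes), promoters use FASTA, the metabolic model uses a small JSON schema
(see :mod:`factoromics.fluxes`), and simulation configs use YAML.

Gene and sample identifiers are opaque strings; no organism-specific ID
validation is performed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ParseError",
    "StudyDesign",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_table",
    "write_table",
    "read_gmt",
    "write_gmt",
    "read_fasta",
    "write_fasta",
    "read_physiology",
    "write_physiology",
    "compute_yield_and_rq",
    "GLUCOSE_MOLAR_MASS",
]

#: Molar mass of glucose in g/mmol, used to convert specific uptake rates
#: (mmol gDW^-1 h^-1) into gram-based biomass yields.
GLUCOSE_MOLAR_MASS = 0.18016


class ParseError(ValueError):
    """Malformed input file; the message names the offending path and row."""


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class StudyDesign:
    """A 2x2 factorial design with replicates.

    Factors are ``nlim`` (nitrogen limitation; 0 = carbon limitation) and
    ``dga1`` (DGA1 overexpression; 0 = control strain).  The canonical study
    holds 3 replicates of each of the 4 factor combinations (12 samples).
    """

    frame: pd.DataFrame  # columns: sample_id, nlim, dga1, replicate

    def __post_init__(self) -> None:
        required = {"sample_id", "nlim", "dga1", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ParseError(f"design table lacks columns {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            dups = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"]
            raise ParseError(f"duplicate sample IDs in design: {list(dups)}")
        for col in ("nlim", "dga1"):
            bad = set(self.frame[col].unique()) - {0, 1}
            if bad:
                raise ParseError(f"factor {col!r} must be binary, found {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    def model_matrix(self) -> pd.DataFrame:
        """Design matrix with columns (Intercept, Nlim, DGA, DGAxNlim)."""
        n = self.frame["nlim"].to_numpy(float)
        d = self.frame["dga1"].to_numpy(float)
        X = pd.DataFrame(
            {
                "Intercept": np.ones(len(n)),
                "Nlim": n,
                "DGA": d,
                "DGAxNlim": n * d,
            },
            index=self.frame["sample_id"].to_numpy(),
        )
        return X

    def condition_labels(self) -> pd.Series:
        """Human-readable condition per sample, e.g. ``WT-C`` or ``DGA1-N``."""
        strain = np.where(self.frame["dga1"] == 1, "DGA1", "WT")
        lim = np.where(self.frame["nlim"] == 1, "N", "C")
        return pd.Series(
            [f"{s}-{l}" for s, l in zip(strain, lim)],
            index=self.frame["sample_id"].to_numpy(),
            name="condition",
        )


def read_design(path: str | Path) -> StudyDesign:
    frame = read_table(path)
    frame = frame.reset_index().rename(columns={frame.index.name or "index": "sample_id"})
    frame["nlim"] = frame["nlim"].astype(int)
    frame["dga1"] = frame["dga1"].astype(int)
    frame["replicate"] = frame["replicate"].astype(int)
    return StudyDesign(frame)


def write_design(design: StudyDesign, path: str | Path) -> None:
    design.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# numeric tables (counts, peptides, metabolites, ...)
# ---------------------------------------------------------------------------


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with IDs in the first column into a DataFrame.

    Raises :class:`ParseError` on duplicate IDs or ragged rows, naming the
    offending line.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path}: {exc}") from exc
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        row = int(np.flatnonzero(frame.index == dup)[-1]) + 2  # header + 1-based
        raise ParseError(f"{path}: duplicate ID {dup!r} (line {row})")
    if frame.columns.duplicated().any():
        dup = frame.columns[frame.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicate column {dup!r}")
    return frame


def write_table(frame: pd.DataFrame, path: str | Path, float_format: str | None = None) -> None:
    frame.to_csv(path, sep="\t", float_format=float_format)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample count matrix; cells must be non-negative numbers."""
    path = Path(path)
    frame = read_table(path)
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = frame.columns[[not np.issubdtype(d, np.number) for d in frame.dtypes]][0]
        raise ParseError(f"{path}: non-numeric cells in column {bad!r}")
    if (values < 0).any():
        gene = frame.index[np.argwhere(values < 0)[0][0]]
        raise ParseError(f"{path}: negative count for feature {gene!r}")
    return frame


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Read a GMT file into ``{set_name: {"description": str, "genes": [..]}}``."""
    path = Path(path)
    sets: dict[str, dict] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: GMT rows need >= 3 fields")
            name, desc, *genes = parts
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set {name!r}")
            genes = [g for g in genes if g]
            if len(genes) != len(set(genes)):
                raise ParseError(f"{path}: line {lineno}: duplicate members in {name!r}")
            sets[name] = {"description": desc, "genes": genes}
    return sets


def write_gmt(sets: dict[str, dict], path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, entry in sets.items():
            fields = [name, entry.get("description", "")] + list(entry["genes"])
            handle.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA into ``{id: sequence}``; duplicate headers are an error."""
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ParseError(f"{path}: duplicate FASTA header {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    return sequences


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# physiology
# ---------------------------------------------------------------------------


def read_physiology(path: str | Path) -> pd.DataFrame:
    """Read a per-condition physiology table.

    Rows are conditions (e.g. ``WT-C``); columns hold the growth rate ``mu``
    (h^-1) and exchange-rate measurements ``r_<id>`` (mmol gDW^-1 h^-1), each
    with an ``_sd`` companion, plus biomass composition coefficients.  All
    rates and SDs must be >= 0 (uptake rates are recorded as positive
    magnitudes; sign conventions are applied when constraining the model).
    """
    frame = read_table(path)
    rate_cols = [c for c in frame.columns if c == "mu" or c.startswith("r_")]
    for col in rate_cols:
        if (frame[col] < 0).any():
            cond = frame.index[frame[col] < 0][0]
            raise ParseError(f"{path}: negative rate {col!r} for condition {cond!r}")
    return frame


def write_physiology(physiology: pd.DataFrame, path: str | Path) -> None:
    physiology.to_csv(path, sep="\t")


def compute_yield_and_rq(physiology: pd.DataFrame) -> pd.DataFrame:
    """Derive biomass yield and respiratory quotient from a physiology table.

    Per condition::

        Y_sx = mu / (r_Gluc * 0.18016)     [gDW per g glucose]
        RQ   = r_CO2 / r_O2                [dimensionless]

    ``mu`` is the specific growth rate in h^-1 and the exchange rates are in
    mmol gDW^-1 h^-1, so the glucose rate is converted to g gDW^-1 h^-1 with
    the 180.16 g/mol molar mass.  Columns ``Y_sx_rounded``/``RQ_rounded``
    carry the 2-decimal presentation values.
    """
    required = {"mu", "r_glc", "r_o2", "r_co2"}
    missing = required - set(physiology.columns)
    if missing:
        raise ParseError(f"physiology table lacks columns {sorted(missing)}")
    if (physiology["r_glc"] <= 0).any():
        cond = physiology.index[physiology["r_glc"] <= 0][0]
        raise ValueError(f"undefined yield: zero glucose uptake for {cond!r}")
    if (physiology["mu"] <= 0).any():
        cond = physiology.index[physiology["mu"] <= 0][0]
        raise ValueError(f"undefined yield: non-positive growth rate for {cond!r}")
    y_sx = physiology["mu"] / (physiology["r_glc"] * GLUCOSE_MOLAR_MASS)
    with np.errstate(divide="ignore", invalid="ignore"):
        rq = physiology["r_co2"] / physiology["r_o2"]
    out = pd.DataFrame(
        {
            "Y_sx": y_sx,
            "RQ": rq,
            "Y_sx_rounded": y_sx.round(2),
            "RQ_rounded": rq.round(2),
        },
        index=physiology.index,
    )
    return out


# ---------------------------------------------------------------------------
# JSON / YAML helpers
# ---------------------------------------------------------------------------


def read_json(path: str | Path) -> dict:
    with open(path) as handle:
        return json.load(handle)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")
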