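"""Readers and writers for the file formats the toolkit touches.

FASTA protein databases (plain or UniProt ``sp|ACC|NAME`` headers),
delimited peptide quantification reports, sample->group design tables and
PRM-style targeted reports all come through here, so the rest of the
package only ever sees :class:`~pepsite.core.ProteinDatabase`, pandas
matrices and small dataclasses.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import ProteinDatabase, ProteinRecord

logger = logging.getLogger("pepsite")

MISSING_TOKENS = {"", "na", "nan", "n/a", "null", "none"}


# ---------------------------------------------------------------------------
# design

@dataclass
class GroupDesign:
    """Sample -> group assignment plus the ordered severity of groups.

    ``group_order`` lists groups from least to most severe (e.g.
    ``["Ctr", "TT", "TI", "TM"]``); ``reference_samples`` names pooled
    reference replicate runs, which belong to no study group.
    """

    sample_to_group: dict[str, str]
    group_order: list[str]
    reference_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        groups_present = set(self.sample_to_group.values())
        missing = groups_present - set(self.group_order)
        if missing:
            raise ValueError(f"groups absent from severity order: {sorted(missing)}")
        for g in self.group_order:
            if g in groups_present and not self.samples_in(g):
                raise ValueError(f"group {g} has no samples")

    @property
    def samples(self) -> list[str]:
        return list(self.sample_to_group)

    @property
    def groups(self) -> list[str]:
        """Groups actually present, in severity order."""
        present = set(self.sample_to_group.values())
        return [g for g in self.group_order if g in present]

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.sample_to_group.items() if g == group]


def read_design(path: str | Path) -> GroupDesign:
    """Read a design TSV/CSV with columns sample, group, optional role.

    Rows with role ``reference`` become reference replicates.  Severity
    order is the order of first appearance of each group.
    """
    df = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    if "sample" not in cols or "group" not in cols:
        raise ValueError("design table needs 'sample' and 'group' columns")
    role_col = cols.get("role")
    mapping: dict[str, str] = {}
    order: list[str] = []
    refs: list[str] = []
    for _, row in df.iterrows():
        sample = str(row[cols["sample"]])
        group = str(row[cols["group"]])
        if role_col is not None and str(row[role_col]).strip().lower() == "reference":
            refs.append(sample)
            continue
        if sample in mapping:
            raise ValueError(f"duplicate sample {sample} in design")
        mapping[sample] = group
        if group not in order:
            order.append(group)
    return GroupDesign(mapping, order, refs)


# ---------------------------------------------------------------------------
# FASTA

def _accession_from_header(header: str) -> str:
    first = header.split()[0]
    if first.count("|") >= 2:  # UniProt sp|ACC|NAME / tr|ACC|NAME
        return first.split("|")[1]
    return first


def read_fasta(path: str | Path) -> ProteinDatabase:
    """Read a multi-record FASTA into a protein database.

    Accessions are the first header token; UniProt-style headers yield the
    central accession.  Duplicate accessions and empty files are errors.
    """
    records = [
        ProteinRecord(_accession_from_header(rec.description or rec.id), str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return ProteinDatabase(records)


def write_fasta(db: ProteinDatabase, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in db:
            fh.write(f">{rec.accession}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# peptide reports

@dataclass
class PeptideReport:
    """A parsed quantification report: metadata plus the abundance matrix."""

    matrix: pd.DataFrame                 # peptides x samples, NaN = missing
    proteins: pd.Series | None = None    # optional peptide -> accession
    evidence: pd.Series | None = None    # optional fragment-evidence strings
    rejected: list[tuple[str, str]] = field(default_factory=list)


def _detect_delimiter(path: str | Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(64 * 1024)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_detect_delimiter(path), dtype=str,
                       keep_default_na=False)


def _parse_abundance(token: str) -> float:
    token = token.strip()
    if token.lower() in MISSING_TOKENS:
        return np.nan
    return float(token)


def read_peptide_report(
    path: str | Path,
    design: GroupDesign,
    zero_is_missing: bool = False,
) -> PeptideReport:
    """Parse a peptide quantification table against a design.

    Non-sample columns recognised by name (case-insensitive): ``peptide``
    (required), ``protein``, ``modifications``, ``evidence``.  Every other
    column must be a sample named in the design (reference replicates
    included).  Blank/NA cells become explicit missing values; negative
    abundances reject the row.
    """
    df = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    if "peptide" not in cols:
        raise ValueError("report lacks a 'peptide' column")
    meta_names = {"peptide", "protein", "modifications", "evidence"}
    sample_cols = [c for c in df.columns if c.lower() not in meta_names]
    known = set(design.samples) | set(design.reference_samples)
    unknown = [c for c in sample_cols if c not in known]
    if unknown:
        raise ValueError(f"sample columns not in design: {unknown}")

    rows: dict[str, np.ndarray] = {}
    proteins: dict[str, str] = {}
    evidence: dict[str, str] = {}
    rejected: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        pep = row[cols["peptide"]].strip().upper()
        if not pep:
            rejected.append(("", "empty peptide sequence"))
            continue
        try:
            values = np.array([_parse_abundance(row[c]) for c in sample_cols])
        except ValueError as exc:
            rejected.append((pep, f"unparseable abundance: {exc}"))
            continue
        if np.any(values[~np.isnan(values)] < 0):
            rejected.append((pep, "negative abundance"))
            continue
        if zero_is_missing:
            values = np.where(values == 0, np.nan, values)
        if pep in rows:  # modified forms of one sequence: summed
            prev = rows[pep]
            both = np.isnan(prev) & np.isnan(values)
            rows[pep] = np.where(both, np.nan, np.nansum([prev, values], axis=0))
            logger.warning("duplicate peptide rows for %s summed", pep)
        else:
            rows[pep] = values
        if "protein" in cols and row[cols["protein"]].strip():
            proteins[pep] = row[cols["protein"]].strip()
        if "evidence" in cols and row[cols["evidence"]].strip():
            evidence[pep] = row[cols["evidence"]].strip()

    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=sample_cols)
    matrix.index.name = "peptide"
    return PeptideReport(
        matrix=matrix,
        proteins=pd.Series(proteins, name="protein") if proteins else None,
        evidence=pd.Series(evidence, name="evidence") if evidence else None,
        rejected=rejected,
    )


# ---------------------------------------------------------------------------
# PRM reports

@dataclass
class PRMReport:
    """Precursor-level PRM quantities: one row per (peptide, charge, sample)."""

    table: pd.DataFrame          # columns: peptide, charge, sample, light, heavy
    label_free: bool = False     # no heavy-label column present


def read_prm_report(path: str | Path, q_cutoff: float = 0.01) -> PRMReport:
    """Read a PRM table, apply the q-value gate and aggregate to precursors.

    Rows with q-value above ``q_cutoff`` are discarded.  Duplicate
    (peptide, charge, sample) rows — e.g. transition-level exports — are
    summed with a warning.  A missing heavy column flags the report as
    label-free.
    """
    df = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    for req in ("peptide", "sample"):
        if req not in cols:
            raise ValueError(f"PRM report lacks a '{req}' column")
    light_col = cols.get("light") or cols.get("endogenous") or cols.get("intensity")
    if light_col is None:
        raise ValueError("PRM report lacks a light/endogenous intensity column")
    heavy_col = cols.get("heavy")
    out = pd.DataFrame(
        {
            "peptide": df[cols["peptide"]].str.strip().str.upper(),
            "charge": pd.to_numeric(df[cols["charge"]], errors="coerce").astype("Int64")
            if "charge" in cols else 1,
            "sample": df[cols["sample"]].str.strip(),
            "light": df[light_col].map(_parse_abundance),
        }
    )
    if heavy_col is not None:
        out["heavy"] = df[heavy_col].map(_parse_abundance)
    if "q_value" in cols:
        q = pd.to_numeric(df[cols["q_value"]], errors="coerce")
        out = out[(q.isna() | (q <= q_cutoff)).to_numpy()]
    keys = ["peptide", "charge", "sample"]
    if out.duplicated(keys).any():
        logger.warning("duplicate PRM precursor rows summed")
        out = out.groupby(keys, as_index=False, dropna=False).sum(min_count=1)
    return PRMReport(table=out.reset_index(drop=True), label_free=heavy_col is None)


# ---------------------------------------------------------------------------
# writers

def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.sort_index().to_csv(path, sep="\t", float_format="%.10g", na_rep="NA")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return df


def write_results(
    out_dir: str | Path,
    catalog: pd.DataFrame | None = None,
    tracks: pd.DataFrame | None = None,
    stats: pd.DataFrame | None = None,
    summary: Mapping | None = None,
) -> list[Path]:
    """Write the standard result tables with deterministic layout.

    Column order is fixed by the producing module; rows are sorted by the
    leading columns so reruns are byte-identical for identical inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in (("points", catalog), ("tracks", tracks), ("stats", stats)):
        if df is None:
            continue
        path = out / f"{name}.tsv"
        frame = df.copy()
        if len(frame):
            frame = frame.sort_values(list(frame.columns[: min(3, frame.shape[1])]))
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")
        written.append(path)
    if summary is not None:
        path = out / "summary.json"
        with open(path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(path)
    return written
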