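"""Readers and writers for the formats the pipeline touches.

Sequence I/O is delegated to :mod:`Bio.SeqIO`; tabular inputs are parsed with
pandas. The module also exposes the packaged attribute-table fixture describing
the 64 putative AGP genes of *Brassica rapa* (gene IDs, PAST%, signal-peptide
and GPI flags, dipeptide-repeat counts, length, chromosome, subgenome, ancestral
block and *A. thaliana* ortholog).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "CdsRecord",
    "AttributeRow",
    "read_fasta",
    "read_cds_fasta",
    "write_fasta",
    "load_attribute_table",
    "load_at_gene_table",
    "load_presence_matrix",
    "read_evidence_table",
    "write_newick",
    "fixture_path",
]

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWYX")
_NT_LETTERS = set("ACGTN")
_SUBGENOMES = {"LF", "MF1", "MF2", "unplaced"}


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence; the unit of composition screening."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid record id: {self.id!r}")
        if not self.residues:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.residues) - _AA_LETTERS
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-amino-acid letters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence; paired with a protein for Ka/Ks analysis."""

    id: str
    nucleotides: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid record id: {self.id!r}")
        if not self.nucleotides:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.nucleotides) - _NT_LETTERS
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-nucleotide letters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.nucleotides)


@dataclass(frozen=True)
class AttributeRow:
    """One row of the packaged attribute table (printed per-gene evidence)."""

    gene_name: str
    gene_id: str
    subfamily: str
    past_percent: int
    sp: bool
    gpi: bool
    repeat_counts: tuple[int, int, int, int]  # AP, PA, SP, TP residues
    length: int
    chromosome: str
    subgenome: str
    block: str | None
    at_gene: str | None
    at_id: str | None
    high_confidence_printed: bool

    def __post_init__(self) -> None:
        if self.subgenome not in _SUBGENOMES:
            raise ValueError(
                f"{self.gene_name}: unknown subgenome {self.subgenome!r} "
                f"(expected one of {sorted(_SUBGENOMES)})"
            )
        if not 0 <= self.past_percent <= 100:
            raise ValueError(f"{self.gene_name}: PAST% out of range")


def _records_from_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    out: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty record body for {rec.id!r} in {path}")
        out.append((rec.id, seq, rec.description))
    return out


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file, preserving record order.

    Wrapped sequence lines are concatenated and residues uppercased.
    Duplicate IDs and empty record bodies raise ``ValueError``.
    """
    return [ProteinRecord(i, s, d) for i, s, d in _records_from_fasta(path)]


def read_cds_fasta(path: str | Path) -> list[CdsRecord]:
    """Read a nucleotide FASTA file of coding sequences."""
    return [CdsRecord(i, s) for i, s, _ in _records_from_fasta(path)]


def write_fasta(records: Iterable[ProteinRecord | CdsRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.residues if isinstance(rec, ProteinRecord) else rec.nucleotides
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def fixture_path(name: str = "table2_attributes.tsv") -> Path:
    """Path of a packaged data file (attribute table, At gene list, presence matrix)."""
    return Path(str(resources.files("agpkit.data").joinpath(name)))


def _parse_flag(value: str, context: str) -> bool:
    v = str(value).strip().lower()
    if v in {"yes", "y", "1", "true"}:
        return True
    if v in {"no", "n", "0", "false"}:
        return False
    raise ValueError(f"{context}: expected yes/no, got {value!r}")


def load_attribute_table(path: str | Path | None = None) -> list[AttributeRow]:
    """Load a per-gene attribute table (the packaged fixture by default).

    Returns one :class:`AttributeRow` per gene with flags normalised to
    booleans. Unknown subgenome labels raise ``ValueError``.
    """
    if path is None:
        path = fixture_path()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"attribute table {path} contains no rows")
    required = {
        "gene_name", "gene_id", "subfamily", "past_percent", "sp", "gpi",
        "ap_repeats", "pa_repeats", "sp_repeats", "tp_repeats", "length",
        "chromosome", "subgenome", "block", "at_gene", "at_id",
        "high_confidence",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"attribute table {path} missing columns: {sorted(missing)}")
    rows = []
    for r in df.itertuples(index=False):
        rows.append(
            AttributeRow(
                gene_name=r.gene_name,
                gene_id=r.gene_id,
                subfamily=r.subfamily,
                past_percent=int(r.past_percent),
                sp=_parse_flag(r.sp, r.gene_name),
                gpi=_parse_flag(r.gpi, r.gene_name),
                repeat_counts=(
                    int(r.ap_repeats), int(r.pa_repeats),
                    int(r.sp_repeats), int(r.tp_repeats),
                ),
                length=int(r.length),
                chromosome=r.chromosome,
                subgenome=r.subgenome,
                block=r.block or None,
                at_gene=r.at_gene or None,
                at_id=r.at_id or None,
                high_confidence_printed=_parse_flag(r.high_confidence, r.gene_name),
            )
        )
    return rows


def load_at_gene_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the annotated *A. thaliana* AGP gene list.

    Columns: at_gene, at_id, subfamily, block, status where status is one of
    conserved | lost_in_brapa | lineage1_specific.
    """
    if path is None:
        path = fixture_path("at_agps.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    bad = set(df["status"]) - {"conserved", "lost_in_brapa", "lineage1_specific"}
    if bad:
        raise ValueError(f"unknown lineage status labels: {sorted(bad)}")
    return df


def load_presence_matrix(path: str | Path | None = None) -> pd.DataFrame:
    """Load a gene x species 0/1 presence matrix (index: at_id)."""
    if path is None:
        path = fixture_path("lineage_presence.tsv")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not df.isin([0, 1]).all().all():
        raise ValueError("presence matrix entries must be 0/1")
    return df


def read_evidence_table(path: str | Path, kind: str) -> dict[str, dict]:
    """Read a normalised external-predictor evidence TSV.

    Two or three tab-separated columns: gene id, yes/no call, and an optional
    position (signal-peptide cleavage site / GPI omega site) or domain name.
    ``kind`` is one of ``sp``, ``gpi`` or ``domain``; it labels what the third
    column means. Returns a map gene_id -> {"present": bool, ...}.
    """
    if kind not in {"sp", "gpi", "domain"}:
        raise ValueError(f"unknown evidence kind {kind!r}")
    out: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
            gene, call = parts[0], parts[1]
            present = _parse_flag(call, f"{path}:{lineno}")
            if gene in out and out[gene]["present"] != present:
                raise ValueError(f"{path}:{lineno}: conflicting calls for {gene!r}")
            entry: dict = {"present": present}
            if len(parts) >= 3 and parts[2]:
                if kind == "domain":
                    entry["domain"] = parts[2]
                else:
                    entry["position"] = int(parts[2])
            out[gene] = entry
    return out


def write_newick(tree, path: str | Path) -> None:
    """Write an skbio ``TreeNode`` as Newick; supports become internal labels.

    Branch lengths must be finite; a NaN length raises ``ValueError``.
    """
    for node in tree.traverse(include_self=False):
        if node.length is not None and math.isnan(node.length):
            raise ValueError("tree contains a NaN branch length")
    tree.write(str(path), format="newick")
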