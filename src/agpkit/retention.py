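"""Ortholog rescue, systematic naming and WGT-aware retention accounting.

*Brassica rapa* descends from a whole-genome triplication (WGT), so each
ancestral gene may be retained as up to three copies, one per subgenome
(LF, MF1, MF2 — least to most fractionated). The retained proportion of a
gene family is

    retained copies with an A. thaliana ortholog / (3 x ancestral genes)

for the whole genome, or, restricted to one subgenome,

    copies in that subgenome with an ortholog / ancestral genes,

expressed as an integer percentage rounded half away from zero. Ancestral
genes are the annotated *A. thaliana* family members minus lineage-I-specific
genes (which postdate the *A. thaliana* / *B. rapa* split); genes lost in
*B. rapa* remain in the denominator. Scaffold-located (unplaced) copies count
in whole-genome numerators but in no per-subgenome numerator.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import AttributeRow
from .screen import AgpCall

__all__ = [
    "OrthologRecord",
    "RetentionReport",
    "SUBGENOME_ORDER",
    "rescue_orthologs",
    "assign_names",
    "lineage_status",
    "round_half_away",
    "retained_proportion",
    "retention_by_family",
    "make_link_table",
]

logger = logging.getLogger(__name__)

SUBGENOME_ORDER = ("LF", "MF1", "MF2", "unplaced")


@dataclass(frozen=True)
class OrthologRecord:
    """One B. rapa gene with its ortholog/synteny annotation."""

    br_id: str
    at_id: str | None
    block: str | None
    chromosome: str
    subgenome: str
    assigned_name: str | None = None


@dataclass(frozen=True)
class RetentionReport:
    family: str
    subgenome: str | None  # None = whole genome
    numerator: int
    denominator: int
    percent: int


def rescue_orthologs(
    screen_calls: Sequence[AgpCall],
    ortholog_table: Mapping[str, str],
    annotated_at_agps: Mapping[str, str],
) -> list[AgpCall]:
    """Add candidate calls for genes orthologous to annotated At AGPs.

    ``ortholog_table`` maps B. rapa gene id -> A. thaliana gene id;
    ``annotated_at_agps`` maps A. thaliana gene id -> subfamily. Every B. rapa
    gene whose ortholog is an annotated AGP and which is not already a
    high-confidence call is added as a candidate with the subfamily inherited
    from the ortholog. Rescue never demotes an existing call and never
    duplicates one; orthologs outside the annotation list are logged and
    skipped.
    """
    high = {c.gene_id for c in screen_calls if c.confidence == "high"}
    existing = {c.gene_id for c in screen_calls if c.subfamily != "non_agp"}
    added: list[AgpCall] = []
    for br_id, at_id in ortholog_table.items():
        if at_id not in annotated_at_agps:
            logger.info("ortholog %s of %s is not an annotated AGP; skipped", at_id, br_id)
            continue
        if br_id in high or br_id in existing:
            continue
        added.append(
            AgpCall(
                br_id,
                annotated_at_agps[at_id],
                "candidate",
                {"ortholog_rescued": True, "at_id": at_id},
            )
        )
    return added


def _at_number(at_gene: str) -> int:
    m = re.search(r"(\d+)$", at_gene)
    if not m:
        raise ValueError(f"cannot parse gene number from {at_gene!r}")
    return int(m.group(1))


def assign_names(
    records: Sequence[OrthologRecord],
    at_gene_by_id: Mapping[str, str],
    prefix: str = "BrAGP",
) -> dict[str, str]:
    """Name B. rapa genes after their A. thaliana orthologs.

    Single-copy families get the bare name (``BrAGP6``); multi-copy families
    get ``.1``, ``.2``, ... suffixes in subgenome order LF, MF1, MF2 then
    unplaced (ties broken by gene id). Genes without an ortholog receive fresh
    sequential numbers after the largest annotated ortholog number, ordered by
    gene id. Returns a bijective map br_id -> name, stable under permutation
    of the input.
    """
    sub_rank = {s: i for i, s in enumerate(SUBGENOME_ORDER)}
    by_family: dict[str, list[OrthologRecord]] = {}
    orphans: list[OrthologRecord] = []
    for rec in records:
        if rec.at_id and rec.at_id in at_gene_by_id:
            by_family.setdefault(rec.at_id, []).append(rec)
        else:
            orphans.append(rec)
    names: dict[str, str] = {}
    for at_id, members in by_family.items():
        number = _at_number(at_gene_by_id[at_id])
        members = sorted(members, key=lambda r: (sub_rank[r.subgenome], r.br_id))
        if len(members) == 1:
            names[members[0].br_id] = f"{prefix}{number}"
        else:
            for i, rec in enumerate(members, 1):
                names[rec.br_id] = f"{prefix}{number}.{i}"
    next_number = max(
        (_at_number(g) for g in at_gene_by_id.values()), default=0
    ) + 1
    for rec in sorted(orphans, key=lambda r: r.br_id):
        names[rec.br_id] = f"{prefix}{next_number}"
        next_number += 1
    return names


def lineage_status(
    at_id: str,
    presence: pd.DataFrame,
    lineage1: Sequence[str],
    lineage2: Sequence[str],
    outgroup: str,
    target: str = "B.rapa",
) -> str:
    """Classify an A. thaliana gene absent or present across related crucifers.

    Returns ``conserved`` (present in the target species), ``lost_in_brapa``
    (absent from the target but present in Lineage II or the outgroup — the
    gene predates the split and stays in the ancestral set), or
    ``lineage1_specific`` (present only in Lineage I — the gene arose after
    the split and is excluded from the ancestral set).
    """
    if at_id not in presence.index:
        raise KeyError(f"{at_id} not in presence matrix")
    row = presence.loc[at_id]
    if row.sum() == 0:
        raise ValueError(f"{at_id} absent from every species")
    if row.get(target, 0) == 1:
        return "conserved"
    others_l2 = [s for s in lineage2 if s != target]
    if any(row.get(s, 0) == 1 for s in others_l2) or row.get(outgroup, 0) == 1:
        return "lost_in_brapa"
    if any(row.get(s, 0) == 1 for s in lineage1):
        return "lineage1_specific"
    raise ValueError(f"{at_id}: unclassifiable presence pattern")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (62.5 -> 63)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def retained_proportion(
    records: Sequence[AttributeRow | OrthologRecord],
    ancestral_set: Iterable[str],
    wgt_factor: int = 3,
    subgenome: str | None = None,
    family: str = "all",
) -> RetentionReport:
    """Retained proportion of a family, whole-genome or per-subgenome.

    The numerator counts records whose ``at_id`` is in the ancestral set
    (orphans never contribute); the denominator is ``wgt_factor`` x the
    ancestral-set size for the whole genome, or the ancestral-set size alone
    when restricted to one subgenome.
    """
    if wgt_factor < 1:
        raise ValueError("wgt_factor must be >= 1")
    ancestral = set(ancestral_set)
    if not ancestral:
        raise ValueError("ancestral set is empty")
    pool = records
    if subgenome is not None:
        pool = [r for r in records if r.subgenome == subgenome]
        denominator = len(ancestral)
    else:
        denominator = wgt_factor * len(ancestral)
    numerator = sum(1 for r in pool if r.at_id is not None and r.at_id in ancestral)
    percent = round_half_away(100.0 * numerator / denominator)
    return RetentionReport(family, subgenome, numerator, denominator, percent)


def retention_by_family(
    rows: Sequence[AttributeRow],
    at_genes: pd.DataFrame,
    wgt_factor: int = 3,
    subgenome: str | None = None,
) -> dict[str, RetentionReport]:
    """Per-subfamily (and combined) retention reports from an attribute table.

    ``at_genes`` is the annotated A. thaliana gene list with ``status``;
    lineage-I-specific genes are dropped from every ancestral set, lost genes
    are kept.
    """
    reports: dict[str, RetentionReport] = {}
    ancestral_all: set[str] = set()
    for family in ("classical", "ag_peptide", "lys_rich"):
        anc = set(
            at_genes.loc[
                (at_genes["subfamily"] == family)
                & (at_genes["status"] != "lineage1_specific"),
                "at_id",
            ]
        )
        ancestral_all |= anc
        fam_rows = [r for r in rows if r.subfamily == family]
        reports[family] = retained_proportion(
            fam_rows, anc, wgt_factor=wgt_factor, subgenome=subgenome, family=family
        )
    reports["all"] = retained_proportion(
        rows, ancestral_all, wgt_factor=wgt_factor, subgenome=subgenome, family="all"
    )
    return reports


def make_link_table(
    rows: Sequence[AttributeRow],
    at_blocks: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Synteny link rows (one per ortholog pair) for external Circos rendering.

    Orphans (no ortholog) are excluded. ``at_blocks`` optionally maps At gene
    id -> ancestral block on the A. thaliana side (defaults to the B. rapa
    block, which the fixture shares). Pairs whose blocks disagree are still
    emitted, flagged in ``block_mismatch``.
    """
    links = []
    for r in rows:
        if r.at_id is None:
            continue
        at_block = at_blocks.get(r.at_id, r.block) if at_blocks else r.block
        links.append(
            {
                "br_id": r.gene_id,
                "br_chromosome": r.chromosome,
                "br_block": r.block,
                "at_id": r.at_id,
                "at_block": at_block,
                "family": r.subfamily,
                "block_mismatch": bool(r.block and at_block and r.block != at_block),
            }
        )
    return pd.DataFrame(
        links,
        columns=[
            "br_id", "br_chromosome", "br_block", "at_id", "at_block",
            "family", "block_mismatch",
        ],
    )
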