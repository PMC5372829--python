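"""Synthetic inputs with the statistical structure each pipeline stage assumes.

Every generator is a pure function of its spec (including the seed) and
returns ground-truth sidecar tables sufficient to score the downstream stage:

* planted proteomes — PAST-rich proteins carrying built-in-detectable
  N-terminal secretion signals and C-terminal GPI signals, with lys-rich
  domains for the lys-rich class and decoys violating exactly one criterion;
* codon-pair evolution — proposal/acceptance simulation at a target omega
  (synonymous proposals always accepted, nonsynonymous with probability
  omega, stop-creating proposals rejected) run to a target synonymous
  divergence, reporting the realised substitution counts;
* synteny fixtures — ancestral genes retained independently per subgenome
  with known probabilities, plus lineage-specific genes excluded from the
  ancestral truth set;
* Ct tables — planted log2 effects per (gene, treatment, timepoint) on top
  of a baseline with Gaussian replicate noise; the water control and the
  reference gene carry no effect.

The planted terminal signals satisfy the built-in heuristics' own definitions
with safety margins, so the signal-prediction tests are constructive. Bodies
are built from Pro-anchored dipeptide motifs: with every other residue being
Pro (hydropathy -1.6), no body window can mimic a hydrophobic signal core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CdsRecord, ProteinRecord
from .kaks import CODON_TO_AA, STOP_CODONS, ng86_site_counts

__all__ = [
    "PlantedProteomeSpec",
    "EvolSimSpec",
    "SynSyntenySpec",
    "CtSimSpec",
    "generate_proteome",
    "evolve_codon_pair",
    "generate_synteny_fixture",
    "generate_ct_table",
]

# N-terminal secretion signal: hydrophobic core LLLLVV (mean KD 3.9) starting
# at residue 3, cleavage site A|x with A at -3 and -1 (position 14 <= 50).
SP_PREFIX = "MKLLLLVVLLLAVASA"
# C-terminal GPI signal: omega site S, small omega+2, hydrophilic 5-residue
# spacer, 10-residue hydrophobic tail reaching the terminus.
GPI_TAIL = "SGA" + "SNNSA" + "LLLVVLLAVL"
# charged N-terminus that cannot seed a hydrophobic core
NO_SP_PREFIX = "MDDEEKDDSE"
# hydrophilic C-terminus that cannot form a GPI tail
NO_GPI_TAIL = "SSDDEESSDD"

_PAST_MOTIFS = ("PA", "PS", "PT", "AP", "SP", "TP")
_DILUTE_MOTIF = "GN"
_LOW_PAST_MOTIFS = ("GK", "GN", "DE", "KN", "EG")

PLANT_CLASSES = (
    "classical", "ag_peptide", "lys_rich",
    "chimeric_decoy", "low_past_decoy", "sp_only_decoy", "gpi_only_decoy",
)


@dataclass(frozen=True)
class PlantedProteomeSpec:
    """Counts, length windows and PAST targets for a planted proteome."""

    counts: Mapping[str, int] = field(
        default_factory=lambda: {k: 10 for k in PLANT_CLASSES}
    )
    classical_body_range: tuple[int, int] = (80, 200)   # body residues (motifs)
    peptide_total_range: tuple[int, int] = (55, 85)     # total residues
    dilute_fraction: float = 0.10                       # non-PAST motifs in bodies
    lys_run: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(PLANT_CLASSES)
        if unknown:
            raise ValueError(f"unknown planted classes: {sorted(unknown)}")
        if self.peptide_total_range[1] > 90:
            raise ValueError("planted peptides must stay within the 50-90 window")
        if self.classical_body_range[0] < 70:
            raise ValueError("classical bodies must keep total length safely above 90")


@dataclass(frozen=True)
class EvolSimSpec:
    """Codon-pair divergence simulation at a controlled omega."""

    n_codons: int = 300
    omega: float = 0.3
    target_ds: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be non-negative")
        if not 0 <= self.target_ds < 0.7:
            raise ValueError("target dS must lie in [0, 0.7)")


@dataclass(frozen=True)
class SynSyntenySpec:
    """Per-subgenome retention with a lineage-specific fraction."""

    n_ancestral: int = 500
    retention: tuple[float, float, float] = (0.7, 0.45, 0.35)  # LF, MF1, MF2
    lineage_specific_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 <= p <= 1 for p in self.retention):
            raise ValueError("retention probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class CtSimSpec:
    """qPCR Ct tables with planted log2 effects.

    Defaults mirror the profiling design: three hormone treatments plus a
    water control, sampling at 0/4/12 hours after treatment, three
    replicates, and modest replicate noise.
    """

    genes: tuple[str, ...] = tuple(f"g{i:02d}" for i in range(1, 11))
    effects: Mapping[tuple[str, str, int], float] = field(default_factory=dict)
    reference: str = "ref"
    baseline_ct: float = 24.0
    reference_ct: float = 18.0
    noise_sd: float = 0.2
    replicates: int = 3
    treatments: tuple[str, ...] = ("ABA", "GA", "MeJA")
    control: str = "water"
    timepoints: tuple[int, ...] = (0, 4, 12)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("at least one replicate required")


def _body(rng: np.random.Generator, n_motifs: int, dilute: float) -> str:
    motifs = []
    for _ in range(n_motifs):
        if rng.random() < dilute:
            motifs.append(_DILUTE_MOTIF)
        else:
            motifs.append(_PAST_MOTIFS[rng.integers(len(_PAST_MOTIFS))])
    return "".join(motifs)


def _low_past_body(rng: np.random.Generator, n_motifs: int) -> str:
    return "".join(
        _LOW_PAST_MOTIFS[rng.integers(len(_LOW_PAST_MOTIFS))] for _ in range(n_motifs)
    )


def generate_proteome(
    spec: PlantedProteomeSpec,
) -> tuple[list[ProteinRecord], pd.DataFrame, dict[str, str]]:
    """Planted proteome with truth table and chimeric domain evidence.

    Returns ``(records, truth, domain_evidence)`` where ``truth`` records the
    intended class, subfamily and confidence of every protein and
    ``domain_evidence`` maps chimeric decoys to their extra domain name.
    Deterministic in the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    truth_rows = []
    domains: dict[str, str] = {}
    lo_b, hi_b = spec.classical_body_range

    def classical_like(gene_id: str) -> str:
        n_motifs = int(rng.integers(lo_b // 2, hi_b // 2 + 1))
        return SP_PREFIX + _body(rng, n_motifs, spec.dilute_fraction) + GPI_TAIL

    for klass in PLANT_CLASSES:
        for i in range(spec.counts.get(klass, 0)):
            gene_id = f"{klass}_{i:03d}"
            if klass == "classical":
                seq = classical_like(gene_id)
                expect = ("classical", "high")
            elif klass == "lys_rich":
                n_motifs = int(rng.integers(lo_b // 2, hi_b // 2 + 1))
                half = n_motifs // 2
                seq = (
                    SP_PREFIX
                    + _body(rng, half, 0.0)
                    + "K" * spec.lys_run
                    + _body(rng, n_motifs - half, 0.0)
                    + GPI_TAIL
                )
                expect = ("lys_rich", "high")
            elif klass == "ag_peptide":
                total = int(rng.integers(*spec.peptide_total_range))
                n_body = max(11, (total - len(SP_PREFIX) - len(GPI_TAIL) + 1) // 2)
                seq = SP_PREFIX + _body(rng, n_body, 0.0) + GPI_TAIL
                expect = ("ag_peptide", "high")
            elif klass == "chimeric_decoy":
                seq = classical_like(gene_id)
                domains[gene_id] = "fasciclin"
                expect = ("chimeric", "excluded")
            elif klass == "low_past_decoy":
                n_motifs = int(rng.integers(lo_b // 2, hi_b // 2 + 1))
                seq = SP_PREFIX + _low_past_body(rng, n_motifs) + GPI_TAIL
                expect = ("non_agp", "excluded")
            elif klass == "sp_only_decoy":
                n_motifs = int(rng.integers(lo_b // 2, hi_b // 2 + 1))
                seq = SP_PREFIX + _body(rng, n_motifs, spec.dilute_fraction) + NO_GPI_TAIL
                expect = ("classical", "candidate")
            else:  # gpi_only_decoy
                n_motifs = int(rng.integers(max(lo_b // 2, 30), hi_b // 2 + 1))
                seq = NO_SP_PREFIX + _body(rng, n_motifs, spec.dilute_fraction) + GPI_TAIL
                expect = ("classical", "candidate")
            records.append(ProteinRecord(gene_id, seq))
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "planted_class": klass,
                    "expected_subfamily": expect[0],
                    "expected_confidence": expect[1],
                    "length": len(seq),
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "planted_class", "expected_subfamily",
                 "expected_confidence", "length"],
    )
    return records, truth, domains


_SENSE_CODONS = sorted(set(CODON_TO_AA) - STOP_CODONS)
_NUCS = "ACGT"


def evolve_codon_pair(
    spec: EvolSimSpec,
) -> tuple[CdsRecord, CdsRecord, dict[str, float]]:
    """Evolve a derived CDS from a random ancestor at a controlled omega.

    Single-nucleotide changes are proposed uniformly at random; synonymous
    proposals are always accepted, nonsynonymous ones with probability
    ``omega``, stop-creating ones rejected. Evolution stops once the realised
    synonymous divergence (accepted synonymous events per ancestral
    synonymous site) reaches ``target_ds``. Realised event counts are
    returned as the per-replicate ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    codons = [
        _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))] for _ in range(spec.n_codons)
    ]
    ancestor = "".join(codons)
    s_sites = sum(ng86_site_counts(c)[0] for c in codons)
    syn_events = nonsyn_events = 0
    max_proposals = 200 * spec.n_codons  # safety valve for omega == 0 edge cases
    proposals = 0
    while s_sites > 0 and syn_events / s_sites < spec.target_ds and proposals < max_proposals:
        proposals += 1
        ci = int(rng.integers(spec.n_codons))
        pos = int(rng.integers(3))
        old = codons[ci]
        nuc = _NUCS[rng.integers(4)]
        if nuc == old[pos]:
            continue
        new = old[:pos] + nuc + old[pos + 1 :]
        if new in STOP_CODONS:
            continue
        if CODON_TO_AA[new] == CODON_TO_AA[old]:
            codons[ci] = new
            syn_events += 1
        elif rng.random() < spec.omega:
            codons[ci] = new
            nonsyn_events += 1
    derived = "".join(codons)
    realized = {
        "syn_events": float(syn_events),
        "nonsyn_events": float(nonsyn_events),
        "realized_ds": syn_events / s_sites if s_sites else 0.0,
        "ancestral_s_sites": s_sites,
    }
    return CdsRecord("ancestor", ancestor), CdsRecord("derived", derived), realized


_BLOCKS = [chr(c) for c in range(ord("A"), ord("X") + 1)]
_SUBGENOMES = ("LF", "MF1", "MF2")


def generate_synteny_fixture(
    spec: SynSyntenySpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Ortholog table with known per-subgenome retention probabilities.

    Returns ``(ortholog_table, at_gene_table, truth)``. The first
    ``lineage_specific_fraction`` of ancestral genes is marked
    lineage1-specific (no retained copies, excluded from the ancestral set);
    each remaining gene retains one copy per subgenome independently with
    that subgenome's probability. ``truth`` holds the exact realised
    proportions.
    """
    rng = np.random.default_rng(spec.seed)
    n_l1 = int(round(spec.lineage_specific_fraction * spec.n_ancestral))
    at_rows = []
    orth_rows = []
    retained = {s: 0 for s in _SUBGENOMES}
    n_ancestral_kept = 0
    for i in range(spec.n_ancestral):
        at_id = f"AtSyn{i + 1:04d}"
        block = _BLOCKS[rng.integers(len(_BLOCKS))]
        status = "lineage1_specific" if i < n_l1 else "conserved"
        at_rows.append(
            {"at_gene": f"AtSynG{i + 1}", "at_id": at_id, "subfamily": "all",
             "block": block, "status": status}
        )
        if status == "lineage1_specific":
            continue
        n_ancestral_kept += 1
        any_copy = False
        for sub, p in zip(_SUBGENOMES, spec.retention):
            if rng.random() < p:
                retained[sub] += 1
                any_copy = True
                orth_rows.append(
                    {
                        "br_id": f"BrSyn{i + 1:04d}{sub}",
                        "at_id": at_id,
                        "block": block,
                        "chromosome": f"A{rng.integers(1, 11):02d}",
                        "subgenome": sub,
                    }
                )
        if not any_copy:
            at_rows[-1]["status"] = "lost_in_brapa"
    total = sum(retained.values())
    truth = {
        "whole_genome": 100.0 * total / (3 * n_ancestral_kept) if n_ancestral_kept else 0.0,
        **{s: 100.0 * retained[s] / n_ancestral_kept if n_ancestral_kept else 0.0
           for s in _SUBGENOMES},
    }
    ortholog_table = pd.DataFrame(
        orth_rows, columns=["br_id", "at_id", "block", "chromosome", "subgenome"]
    )
    at_table = pd.DataFrame(
        at_rows, columns=["at_gene", "at_id", "subfamily", "block", "status"]
    )
    return ortholog_table, at_table, truth


def generate_ct_table(spec: CtSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct table with planted log2 effects and Gaussian replicate noise.

    ``Ct = baseline - effect + N(0, sd)`` per replicate; the reference gene
    and the water control carry no effect, and no effect applies at 0 HAT.
    Returns ``(ct_table, truth_effects)``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    all_treatments = (*spec.treatments, spec.control)
    for gene in (*spec.genes, spec.reference):
        base = spec.reference_ct if gene == spec.reference else spec.baseline_ct
        for treatment in all_treatments:
            for tp in spec.timepoints:
                effect = 0.0
                if gene != spec.reference and treatment != spec.control and tp != 0:
                    effect = float(spec.effects.get((gene, treatment, tp), 0.0))
                for rep in range(1, spec.replicates + 1):
                    noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
                    rows.append(
                        {
                            "gene": gene,
                            "treatment": treatment,
                            "timepoint": tp,
                            "replicate": rep,
                            "ct": base - effect + noise,
                        }
                    )
    truth = pd.DataFrame(
        [
            {"gene": g, "treatment": t, "timepoint": tp, "log2_effect": e}
            for (g, t, tp), e in sorted(spec.effects.items())
        ],
        columns=["gene", "treatment", "timepoint", "log2_effect"],
    )
    return pd.DataFrame(rows), truth
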