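"""Composition-bias screening and subfamily classification of AGP candidates.

Arabinogalactan proteins (AGPs) have protein backbones dominated by Pro, Ala,
Ser and Thr (the "PAST" fraction). The screen retains proteins whose PAST
fraction and length fall in subfamily-specific windows:

* classical AGPs / lys-rich AGPs: PAST >= 0.50 and length > 90 residues,
* AG peptides: PAST >= 0.35 and length in [50, 90] residues.

Candidates carrying both an N-terminal signal peptide and a C-terminal GPI
anchor signal are called *high confidence*; proteins with an additional
unrelated domain (fasciclin, early nodulin, nsLTP, ...) are chimeric AGPs and
excluded from the three subfamilies. Lys-rich AGPs are classical-pool members
carrying a short internal lysine-rich domain flanked by PAST-rich glycomodules.

Both thresholds are applied inclusively to the unrounded fraction; a protein
at exactly 50% PAST passes the classical threshold. Dipeptide-repeat counts
(AP/PA/SP/TP) follow the residue convention: each overlapping occurrence
contributes two residues, so every reported count is even.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .io import AttributeRow, ProteinRecord

__all__ = [
    "ScreenConfig",
    "CompositionProfile",
    "RepeatCounts",
    "LysRichDomain",
    "AgpCall",
    "SUBFAMILIES",
    "past_fraction",
    "count_dipeptide_repeats",
    "find_lys_rich_domain",
    "screen_candidates",
    "classify",
    "classify_proteome",
    "classify_attribute_row",
    "classify_attribute_table",
    "summarize_calls",
    "calls_to_frame",
]

SUBFAMILIES = ("classical", "ag_peptide", "lys_rich")
_PAST = set("PAST")
_MOTIFS = ("AP", "PA", "SP", "TP")


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the composition/length screen and lys-rich domain rule."""

    past_min_classical: float = 0.50
    past_min_peptide: float = 0.35
    len_min_classical: int = 91          # "length > 90"
    peptide_len_range: tuple[int, int] = (50, 90)  # inclusive
    signal_window: int = 50              # max SP cleavage position
    lys_window_range: tuple[int, int] = (10, 20)
    lys_min_k: int = 4
    lys_min_k_fraction: float = 0.25
    lys_flank_len: int = 20
    lys_flank_past_min: float = 0.50

    def __post_init__(self) -> None:
        if not (0.0 <= self.past_min_peptide <= self.past_min_classical <= 1.0):
            raise ValueError("PAST thresholds must satisfy 0 <= peptide <= classical <= 1")
        if self.peptide_len_range[1] >= self.len_min_classical:
            raise ValueError("peptide length window must end below the classical minimum")


@dataclass(frozen=True)
class CompositionProfile:
    past_fraction: float
    counts: Mapping[str, int]
    length: int


@dataclass(frozen=True)
class RepeatCounts:
    """AP/PA/SP/TP repeat content in residues (2 x overlapping occurrences)."""

    ap: int
    pa: int
    sp: int
    tp: int

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.ap, self.pa, self.sp, self.tp)


@dataclass(frozen=True)
class LysRichDomain:
    start: int  # 1-based inclusive
    end: int
    lys_fraction: float


@dataclass(frozen=True)
class AgpCall:
    gene_id: str
    subfamily: str  # classical | ag_peptide | lys_rich | chimeric | non_agp
    confidence: str  # high | candidate | excluded
    evidence: dict = field(default_factory=dict)


def past_fraction(record: ProteinRecord) -> CompositionProfile:
    """PAST fraction and residue counts over the full annotated sequence.

    Computed signal peptide included, since the composition screen precedes
    signal-peptide prediction. ``X`` counts toward length but not PAST.
    """
    counts = Counter(record.residues)
    past = sum(counts[c] for c in _PAST)
    return CompositionProfile(
        past_fraction=past / record.length,
        counts=dict(counts),
        length=record.length,
    )


def count_dipeptide_repeats(record: ProteinRecord) -> RepeatCounts:
    """Count AP/PA/SP/TP dipeptides, reported in residues.

    Overlapping occurrences of different motifs each count ("APA" holds one AP
    and one PA); each occurrence contributes 2 residues, so all counts are even.
    """
    seq = record.residues
    occ = {m: 0 for m in _MOTIFS}
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair in occ:
            occ[pair] += 1
    return RepeatCounts(*(2 * occ[m] for m in _MOTIFS))


def _window_past(seq: str, start: int, end: int) -> float:
    """PAST fraction of seq[start:end] (0-based, half-open)."""
    window = seq[start:end]
    return sum(c in _PAST for c in window) / len(window)


def find_lys_rich_domain(
    record: ProteinRecord, config: ScreenConfig = ScreenConfig()
) -> LysRichDomain | None:
    """Locate a short internal Lys-rich domain flanked by AGP glycomodules.

    A qualifying window has length within ``lys_window_range``, at least
    ``lys_min_k`` lysines at a fraction >= ``lys_min_k_fraction``, and both
    adjacent ``lys_flank_len``-residue flanks entirely inside the sequence
    with PAST fraction >= ``lys_flank_past_min``. Among qualifying windows the
    one with the highest K fraction is returned (ties: leftmost, then
    shortest). Absence is a normal result, returned as ``None``.
    """
    seq = record.residues
    n = len(seq)
    lo, hi = config.lys_window_range
    flank = config.lys_flank_len
    best: tuple[float, int, int] | None = None  # (-kfrac ordering via compare)
    best_dom: LysRichDomain | None = None
    for start in range(n):
        if start - flank < 0:
            continue
        for wlen in range(lo, hi + 1):
            end = start + wlen  # half-open
            if end + flank > n:
                break
            window = seq[start:end]
            k = window.count("K")
            if k < config.lys_min_k:
                continue
            kfrac = k / wlen
            if kfrac < config.lys_min_k_fraction:
                continue
            if _window_past(seq, start - flank, start) < config.lys_flank_past_min:
                continue
            if _window_past(seq, end, end + flank) < config.lys_flank_past_min:
                continue
            key = (-kfrac, start, wlen)
            if best is None or key < best:
                best = key
                best_dom = LysRichDomain(start=start + 1, end=end, lys_fraction=kfrac)
    return best_dom


def screen_candidates(
    proteome: Sequence[ProteinRecord], config: ScreenConfig = ScreenConfig()
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Split a proteome into the classical-length and AG-peptide pools.

    Returns ``(classical_pool, peptide_pool)``; the pools are disjoint by
    construction (the length windows do not overlap).
    """
    if not proteome:
        raise ValueError("proteome is empty")
    classical, peptide = [], []
    pmin, pmax = config.peptide_len_range
    for rec in proteome:
        frac = past_fraction(rec).past_fraction
        if frac >= config.past_min_classical and rec.length >= config.len_min_classical:
            classical.append(rec)
        elif frac >= config.past_min_peptide and pmin <= rec.length <= pmax:
            peptide.append(rec)
    return classical, peptide


def classify(
    record: ProteinRecord,
    pools: tuple[Sequence[ProteinRecord], Sequence[ProteinRecord]],
    sp_present: bool,
    gpi_present: bool,
    extra_domain: str | None = None,
    lys_domain: LysRichDomain | None = None,
    rescued: bool | str = False,
    config: ScreenConfig = ScreenConfig(),
) -> AgpCall:
    """Assign subfamily and confidence tier to one screened (or rescued) protein.

    Chimeric proteins (any annotated non-P/HRGP domain) are excluded from the
    three subfamilies. Otherwise classical-pool members with a lys-rich domain
    become lys-rich AGPs; pool membership decides classical vs AG peptide.
    High confidence requires both terminal signals on a pool member; rescued
    genes failing the pool thresholds are retained as candidates. ``rescued``
    may carry the subfamily inherited from the *A. thaliana* ortholog; a bare
    ``True`` falls back to the length window (<= 90 residues -> AG peptide).
    """
    classical_ids = {r.id for r in pools[0]}
    peptide_ids = {r.id for r in pools[1]}
    in_classical = record.id in classical_ids
    in_peptide = record.id in peptide_ids
    evidence = {
        "past_pass": in_classical or in_peptide,
        "length_class": "classical" if in_classical else ("peptide" if in_peptide else None),
        "sp": sp_present,
        "gpi": gpi_present,
        "lys_domain": lys_domain is not None,
        "extra_domain": extra_domain,
        "ortholog_rescued": rescued,
    }
    if extra_domain:
        return AgpCall(record.id, "chimeric", "excluded", evidence)
    if in_classical:
        subfamily = "lys_rich" if lys_domain is not None else "classical"
    elif in_peptide:
        subfamily = "ag_peptide"
    elif rescued:
        if isinstance(rescued, str):
            subfamily = rescued
        else:
            subfamily = "ag_peptide" if record.length <= config.peptide_len_range[1] else "classical"
        return AgpCall(record.id, subfamily, "candidate", evidence)
    else:
        return AgpCall(record.id, "non_agp", "excluded", evidence)
    confidence = "high" if (sp_present and gpi_present) else "candidate"
    return AgpCall(record.id, subfamily, confidence, evidence)


def classify_proteome(
    proteome: Sequence[ProteinRecord],
    sp_evidence: Mapping[str, bool],
    gpi_evidence: Mapping[str, bool],
    domain_evidence: Mapping[str, str] | None = None,
    rescued_ids: Iterable[str] | Mapping[str, str] = (),
    config: ScreenConfig = ScreenConfig(),
) -> list[AgpCall]:
    """Screen and classify every protein of a proteome.

    ``sp_evidence``/``gpi_evidence`` map gene id -> presence flag (missing ids
    are treated as negative); ``domain_evidence`` maps gene id -> extra domain
    name for chimeric exclusion. Deterministic and order-independent: results
    are reported in input order, but each call depends only on its own record.
    """
    pools = screen_candidates(proteome, config)
    domain_evidence = domain_evidence or {}
    if isinstance(rescued_ids, Mapping):
        rescued_map: dict[str, bool | str] = dict(rescued_ids)
    else:
        rescued_map = {i: True for i in rescued_ids}
    calls = []
    for rec in proteome:
        calls.append(
            classify(
                rec,
                pools,
                sp_present=bool(sp_evidence.get(rec.id, False)),
                gpi_present=bool(gpi_evidence.get(rec.id, False)),
                extra_domain=domain_evidence.get(rec.id),
                lys_domain=find_lys_rich_domain(rec, config),
                rescued=rescued_map.get(rec.id, False),
                config=config,
            )
        )
    return calls


def _window_matches(subfamily: str, past: float, length: int, config: ScreenConfig) -> bool:
    if subfamily in ("classical", "lys_rich"):
        return past >= config.past_min_classical and length >= config.len_min_classical
    if subfamily == "ag_peptide":
        pmin, pmax = config.peptide_len_range
        return past >= config.past_min_peptide and pmin <= length <= pmax
    return False


def classify_attribute_row(
    row: AttributeRow, config: ScreenConfig = ScreenConfig()
) -> AgpCall:
    """Apply the high-confidence rule to one printed attribute row.

    The printed PAST percentage is compared as ``percent/100`` against the
    fraction thresholds. Rows failing the rule are ortholog-rescued candidates.
    """
    past = row.past_percent / 100.0
    window_ok = _window_matches(row.subfamily, past, row.length, config)
    high = window_ok and row.sp and row.gpi
    evidence = {
        "past_pass": window_ok,
        "length_class": row.subfamily,
        "sp": row.sp,
        "gpi": row.gpi,
        "lys_domain": row.subfamily == "lys_rich",
        "extra_domain": None,
        "ortholog_rescued": not high,
    }
    return AgpCall(row.gene_id, row.subfamily, "high" if high else "candidate", evidence)


def classify_attribute_table(
    rows: Sequence[AttributeRow], config: ScreenConfig = ScreenConfig()
) -> list[AgpCall]:
    return [classify_attribute_row(r, config) for r in rows]


def summarize_calls(calls: Sequence[AgpCall]) -> dict[str, dict[str, int]]:
    """Count calls per subfamily x confidence tier, with totals.

    Returns ``{subfamily: {"high": n, "candidate": n}, "total": {...}}``;
    chimeric and non-AGP records are tallied separately and excluded from the
    total AGP count.
    """
    out: dict[str, dict[str, int]] = {
        s: {"high": 0, "candidate": 0} for s in SUBFAMILIES
    }
    out["chimeric"] = {"excluded": 0}
    out["non_agp"] = {"excluded": 0}
    for call in calls:
        if call.subfamily in SUBFAMILIES:
            out[call.subfamily][call.confidence] += 1
        else:
            out[call.subfamily]["excluded"] += 1
    total_high = sum(out[s]["high"] for s in SUBFAMILIES)
    total_cand = sum(out[s]["candidate"] for s in SUBFAMILIES)
    out["total"] = {
        "high": total_high,
        "candidate": total_cand,
        "agps": total_high + total_cand,
    }
    return out


def calls_to_frame(calls: Sequence[AgpCall]):
    """Calls as a DataFrame with documented column order."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "subfamily": c.subfamily,
                "confidence": c.confidence,
                "sp": c.evidence.get("sp"),
                "gpi": c.evidence.get("gpi"),
                "past_pass": c.evidence.get("past_pass"),
                "lys_domain": c.evidence.get("lys_domain"),
                "extra_domain": c.evidence.get("extra_domain"),
                "rescued": c.evidence.get("ortholog_rescued"),
            }
            for c in calls
        ],
        columns=[
            "gene_id", "subfamily", "confidence", "sp", "gpi",
            "past_pass", "lys_domain", "extra_domain", "rescued",
        ],
    )
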