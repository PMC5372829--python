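"""Heuristic N-terminal signal-peptide and C-terminal GPI-anchor prediction.

Real screens use dedicated external predictors (SignalP for secretion signals;
big-PI and PSORT for GPI anchors, combined with a strict both-positive
consensus). This module provides (a) documented hydropathy-based built-in
heuristics so the whole pipeline runs offline on synthetic data, and (b) the
consensus rule over normalised external evidence tables.

The built-ins use the Kyte-Doolittle hydropathy scale (embedded below as a
constant to avoid dependency drift):

* signal peptide — a hydrophobic core of >= 6 residues with mean hydropathy
  >= 1.6 starting within the first 35 residues, followed by the first
  downstream cleavage position whose -3 and -1 residues are small/neutral
  (A, G, S, C, T, V), no later than residue 50;
* GPI anchor — an omega site among the last 40 residues with small residues at
  omega and omega+2, a hydrophilic spacer of 4-12 residues, then a terminal
  hydrophobic stretch of >= 8 residues (mean hydropathy >= 1.0) reaching the
  C-terminus.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import ProteinRecord
from .screen import ScreenConfig

__all__ = [
    "KYTE_DOOLITTLE",
    "SignalPrediction",
    "GpiPrediction",
    "SignalConfig",
    "predict_signal_peptide",
    "predict_gpi",
    "combine_evidence",
]

# Kyte & Doolittle (1982) hydropathy values; X treated as neutral.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

_SP_SMALL = set("AGSCTV")          # allowed at -3/-1 of the cleavage site
_GPI_OMEGA = set("SGANDC")         # allowed at the omega site
_GPI_OMEGA2 = set("SGANDCTV")      # allowed at omega+2


@dataclass(frozen=True)
class SignalConfig:
    """Tunables of the two built-in heuristics."""

    sp_core_len: int = 6
    sp_core_min_kd: float = 1.6
    sp_core_max_start: int = 35    # 1-based latest start of the hydrophobic core
    sp_max_cleavage: int = 50      # 1-based latest cleavage position
    sp_min_length: int = 15
    gpi_search_window: int = 40    # omega site within this many C-terminal residues
    gpi_spacer_range: tuple[int, int] = (4, 12)
    gpi_spacer_max_kd: float = 0.0
    gpi_tail_min_len: int = 8
    gpi_tail_min_kd: float = 1.0
    gpi_min_length: int = 25


@dataclass(frozen=True)
class SignalPrediction:
    present: bool
    cleavage_pos: int | None = None  # 1-based last residue of the signal
    source: str = "builtin"


@dataclass(frozen=True)
class GpiPrediction:
    present: bool
    omega_pos: int | None = None  # 1-based
    sources: frozenset[str] = frozenset({"builtin"})


def _mean_kd(seq: str) -> float:
    return sum(KYTE_DOOLITTLE[c] for c in seq) / len(seq)


def predict_signal_peptide(
    record: ProteinRecord, config: SignalConfig = SignalConfig()
) -> SignalPrediction:
    """Built-in secretion-signal heuristic.

    Sequences shorter than ``sp_min_length`` are reported absent (documented
    behaviour, not an error): a cleavable signal cannot fit.
    """
    seq = record.residues
    n = len(seq)
    if n < config.sp_min_length:
        return SignalPrediction(False)
    core = config.sp_core_len
    core_start = None
    for i in range(min(config.sp_core_max_start, n - core)):
        if _mean_kd(seq[i : i + core]) >= config.sp_core_min_kd:
            core_start = i
            break
    if core_start is None:
        return SignalPrediction(False)
    # first downstream position whose -3 / -1 residues are small
    for p0 in range(core_start + core, min(config.sp_max_cleavage, n)):
        if p0 - 2 >= 0 and seq[p0] in _SP_SMALL and seq[p0 - 2] in _SP_SMALL:
            return SignalPrediction(True, cleavage_pos=p0 + 1)
    return SignalPrediction(False)


def predict_gpi(
    record: ProteinRecord, config: SignalConfig = SignalConfig()
) -> GpiPrediction:
    """Built-in GPI-anchor-signal heuristic; leftmost qualifying omega reported."""
    seq = record.residues
    n = len(seq)
    if n < config.gpi_min_length:
        return GpiPrediction(False)
    smin, smax = config.gpi_spacer_range
    for w in range(max(0, n - config.gpi_search_window), n - 2):
        if seq[w] not in _GPI_OMEGA or seq[w + 2] not in _GPI_OMEGA2:
            continue
        for spacer in range(smin, smax + 1):
            tail_start = w + 3 + spacer
            tail = seq[tail_start:]
            if len(tail) < config.gpi_tail_min_len:
                break
            if (
                _mean_kd(seq[w + 3 : tail_start]) <= config.gpi_spacer_max_kd
                and _mean_kd(tail) >= config.gpi_tail_min_kd
            ):
                return GpiPrediction(True, omega_pos=w + 1)
    return GpiPrediction(False)


def combine_evidence(
    builtin_sp: SignalPrediction,
    builtin_gpi: GpiPrediction,
    external_sp: bool | None = None,
    external_sp_pos: int | None = None,
    external_gpi_bigpi: bool | None = None,
    external_gpi_psort: bool | None = None,
) -> tuple[SignalPrediction, GpiPrediction]:
    """Consensus over built-in and external predictor evidence for one gene.

    The signal peptide follows the external call when one is provided,
    otherwise the built-in. GPI evidence is gated by a strict both-positive
    consensus over the two external predictors; supplying only one of the two
    is rejected as ambiguous. With no external GPI evidence the built-in
    passes through. Symmetric in the two GPI sources and idempotent.
    """
    if external_sp is not None:
        sp = SignalPrediction(external_sp, cleavage_pos=external_sp_pos, source="external")
    else:
        sp = builtin_sp
    has_bigpi = external_gpi_bigpi is not None
    has_psort = external_gpi_psort is not None
    if has_bigpi != has_psort:
        raise ValueError(
            "ambiguous GPI evidence: both external predictors are required "
            "when any external GPI evidence is supplied"
        )
    if has_bigpi:
        present = bool(external_gpi_bigpi) and bool(external_gpi_psort)
        gpi = GpiPrediction(present, sources=frozenset({"bigpi", "psort"}))
    else:
        gpi = builtin_gpi
    if sp.present and sp.cleavage_pos is not None and sp.cleavage_pos > 50:
        sp = SignalPrediction(False, source=sp.source)
    return sp, gpi
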