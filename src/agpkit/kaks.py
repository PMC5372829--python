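"""Pairwise Ka/Ks estimation by Nei-Gojobori (1986) pathway counting.

For each sense codon the three single-nucleotide changes per position are
enumerated under the standard genetic code; changes creating a stop codon are
excluded from both synonymous and nonsynonymous tallies, so a codon's
synonymous (s) plus nonsynonymous (n) site count is 3 minus the stop-excluded
fraction. Differences between two codons are averaged uniformly over all
minimal mutational pathways that avoid stop codons. Proportions
pS = Sd/S and pN = Nd/N are corrected with the Jukes-Cantor formula
d = -(3/4) ln(1 - 4p/3), and omega = dN/dS. Site counts S and N are averaged
over the two sequences of a pair.

The protein-guided codon alignment projects a gapped protein alignment onto
the coding sequences: each protein column maps to one codon column and
columns gapped in either row are dropped pairwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from scipy import stats

__all__ = [
    "CODON_TO_AA",
    "STOP_CODONS",
    "CodonAlignment",
    "KaKsResult",
    "RateGroupComparison",
    "project_codon_alignment",
    "ng86_site_counts",
    "ng86_differences",
    "kaks",
    "compare_groups",
]

# standard genetic code (NCBI table 1)
_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
_NUCS = "ACGT"


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-free paired codon sequences ready for Ka/Ks counting."""

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon rows differ in length")
        for row in (self.codons_a, self.codons_b):
            for i, codon in enumerate(row):
                if len(codon) != 3 or set(codon) - set(_NUCS):
                    raise ValueError(f"invalid codon {codon!r} at column {i}")
                if codon in STOP_CODONS:
                    raise ValueError(f"internal stop codon {codon} at column {i}")

    def __len__(self) -> int:
        return len(self.codons_a)


@dataclass(frozen=True)
class KaKsResult:
    s_sites: float        # S: average synonymous sites
    n_sites: float        # N
    s_diffs: float        # Sd: pathway-averaged synonymous differences
    n_diffs: float        # Nd
    ps: float
    pn: float
    ds: float | None      # dS (None when saturated)
    dn: float | None
    omega: float | None
    undefined: bool       # dS == 0
    saturated: bool       # pS or pN >= 3/4


@dataclass(frozen=True)
class RateGroupComparison:
    groups: tuple[str, ...]
    means: dict[str, float]
    f_statistic: float
    p_value: float
    letters: dict[str, str]
    alpha: float = 0.05


def _translate(cds: str) -> str:
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon at nucleotide {i + 1}")
        aas.append(CODON_TO_AA.get(codon, "X"))
    return "".join(aas)


def project_codon_alignment(
    protein_rows: tuple[str, str],
    cds_a: str,
    cds_b: str,
) -> CodonAlignment:
    """Project a pairwise gapped protein alignment onto the two CDS.

    Each CDS must translate (standard code, terminal stop allowed) to its
    ungapped protein row; a mismatch raises with the offending position.
    Columns gapped in either protein row are dropped.
    """
    out_rows: list[list[str]] = []
    prots = []
    for row, cds in zip(protein_rows, (cds_a, cds_b)):
        cds = cds.upper()
        ungapped = row.replace("-", "").upper()
        if len(cds) % 3 == 0 and len(cds) // 3 == len(ungapped) + 1:
            if cds[-3:] in STOP_CODONS:
                cds = cds[:-3]  # trim terminal stop
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"CDS length {len(cds)} does not match 3 x protein length "
                f"{len(ungapped)}"
            )
        translated = _translate(cds)
        for pos, (x, y) in enumerate(zip(translated, ungapped), 1):
            if x != y and x != "X" and y != "X":
                raise ValueError(
                    f"translation mismatch at protein position {pos}: "
                    f"CDS gives {x}, alignment row has {y}"
                )
        prots.append((row.upper(), cds))
    codon_cols_a: list[str] = []
    codon_cols_b: list[str] = []
    ia = ib = 0
    row_a, cds_a_t = prots[0]
    row_b, cds_b_t = prots[1]
    for ca, cb in zip(row_a, row_b):
        codon_a = cds_a_t[3 * ia : 3 * ia + 3] if ca != "-" else None
        codon_b = cds_b_t[3 * ib : 3 * ib + 3] if cb != "-" else None
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
        if codon_a is not None and codon_b is not None:
            codon_cols_a.append(codon_a)
            codon_cols_b.append(codon_b)
    return CodonAlignment(tuple(codon_cols_a), tuple(codon_cols_b))


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    Each of the nine single-nucleotide changes contributes 1/3 of a site to
    the synonymous or nonsynonymous total; changes to stop codons contribute
    to neither, so s + n < 3 for stop-adjacent codons.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = CODON_TO_AA[codon]
    s = n = 0.0
    for pos in range(3):
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            mutant = codon[:pos] + nuc + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            if CODON_TO_AA[mutant] == aa:
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n


@lru_cache(maxsize=None)
def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences between two sense codons.

    Averaged uniformly over all minimal mutational pathways between the
    codons that avoid stop codons; if every pathway crosses a stop (possible
    only for 2-3 differences), the average falls back to all pathways.
    The two returned values sum to the number of differing positions.
    """
    for c in (codon_a, codon_b):
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c}")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def pathway_counts(order: tuple[int, ...], allow_stops: bool):
        cur = codon_a
        s = n = 0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if CODON_TO_AA.get(cur, "*") == CODON_TO_AA.get(nxt, "*") and \
                    nxt not in STOP_CODONS and cur not in STOP_CODONS:
                s += 1
            else:
                n += 1
            cur = nxt
        return s, n

    results = [
        r for order in permutations(diff_pos)
        if (r := pathway_counts(order, allow_stops=False)) is not None
    ]
    if not results:
        results = [pathway_counts(order, allow_stops=True) for order in permutations(diff_pos)]
    s = sum(r[0] for r in results) / len(results)
    n = sum(r[1] for r in results) / len(results)
    return s, n


def kaks(alignment: CodonAlignment, min_codons: int = 10) -> KaKsResult:
    """NG86 Ka/Ks with Jukes-Cantor correction for one codon alignment.

    Site counts are summed per sequence and averaged over the pair;
    differences are pathway-averaged per codon column. ``omega`` is ``None``
    when dS = 0 (``undefined``) or when either proportion reaches the
    Jukes-Cantor ceiling of 3/4 (``saturated``).
    """
    if len(alignment) < min_codons:
        raise ValueError(
            f"alignment has {len(alignment)} codons; at least {min_codons} required"
        )
    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        sa, na = ng86_site_counts(ca)
        sb, nb = ng86_site_counts(cb)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        dsd, dnd = ng86_differences(ca, cb)
        sd += dsd
        nd += dnd
    s_sites = 0.5 * (s_a + s_b)
    n_sites = 0.5 * (n_a + n_b)
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0

    def jc(p: float) -> float | None:
        if p >= 0.75:
            return None
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    ds, dn = jc(ps), jc(pn)
    saturated = ds is None or dn is None
    undefined = (not saturated) and ds == 0.0
    omega = None
    if not saturated and not undefined:
        omega = dn / ds
    return KaKsResult(
        s_sites=s_sites, n_sites=n_sites, s_diffs=sd, n_diffs=nd,
        ps=ps, pn=pn, ds=ds, dn=dn, omega=omega,
        undefined=undefined, saturated=saturated,
    )


def _maximal_cliques(nodes: Sequence[str], edges: set[frozenset[str]]) -> list[set[str]]:
    """Maximal cliques of a small undirected graph (brute-force growth)."""
    cliques: list[set[str]] = []
    def connected(a: str, b: str) -> bool:
        return frozenset((a, b)) in edges
    for i, start in enumerate(nodes):
        clique = {start}
        for other in nodes:
            if other in clique:
                continue
            if all(connected(other, m) for m in clique):
                clique.add(other)
        if not any(clique <= c for c in cliques):
            cliques = [c for c in cliques if not (c <= clique)] + [clique]
    # cover any pair missed by the greedy pass
    for e in edges:
        if not any(e <= c for c in cliques):
            cliques.append(set(e))
    for n in nodes:
        if not any(n in c for c in cliques):
            cliques.append({n})
    return cliques


def compare_groups(
    omega_by_group: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> RateGroupComparison:
    """One-way ANOVA across groups of omega values with Tukey HSD letters.

    Groups sharing a compact-display letter are not significantly different
    at ``alpha``. Requires >= 2 groups with >= 2 finite values each.
    """
    groups = tuple(omega_by_group)
    if len(groups) < 2:
        raise ValueError("at least 2 groups required")
    data = {}
    for g in groups:
        vals = [v for v in omega_by_group[g] if v is not None and math.isfinite(v)]
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 finite omega values")
        data[g] = np.asarray(vals, dtype=float)
    f_stat, p_value = stats.f_oneway(*data.values())

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate([data[g] for g in groups])
    labels = np.concatenate([[g] * len(data[g]) for g in groups])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    # edges connect groups NOT significantly different
    res = tukey.summary().data[1:]
    ns_edges: set[frozenset[str]] = set()
    for row in res:
        g1, g2, reject = str(row[0]), str(row[1]), bool(row[-1])
        if not reject:
            ns_edges.add(frozenset((g1, g2)))
    means = {g: float(np.mean(data[g])) for g in groups}
    order = sorted(groups, key=lambda g: means[g])
    cliques = _maximal_cliques(order, ns_edges)
    cliques.sort(key=lambda c: min(means[g] for g in c))
    letters = {g: "" for g in groups}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for g in order:
            if g in clique:
                letters[g] += letter
    return RateGroupComparison(
        groups=groups, means=means, f_statistic=float(f_stat),
        p_value=float(p_value), letters=letters, alpha=alpha,
    )
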