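"""Relative qPCR quantification and hormone-response profiling.

Expression is quantified with the 2^-ddCt method: per replicate the target
gene's Ct is normalised to a reference gene (dCt), replicate dCt values are
averaged, the treated dCt is normalised to the water control at the same
timepoint (ddCt), and the fold change is 2^-ddCt. A gene is called
up-regulated under a treatment when its fold change reaches the threshold
(default 2-fold) at either sampling timepoint (4 or 12 hours after
treatment), down-regulated at the reciprocal threshold; the onset is the
earliest qualifying timepoint and a response that qualifies at 4 but not 12
hours is flagged as recovered.

Clustering mirrors the Cluster-3.0 recipe: rows are mean-centred, scaled to
unit root-mean-square ("normalize genes"), compared by centred Pearson
correlation (distance 1 - r) and agglomerated with centroid linkage. Centroid
linkage can produce inversions (a merge below an earlier merge height); the
dendrogram is reported as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CtTable",
    "RegulationCall",
    "ClusterTree",
    "ddct_fold_change",
    "call_regulation",
    "overlap_summary",
    "normalize_and_cluster",
]

TREATMENTS = ("ABA", "GA", "MeJA")
CONTROL = "water"
TIMEPOINTS = (4, 12)


@dataclass(frozen=True)
class CtTable:
    """Long-format Ct data: gene, treatment, timepoint, replicate, ct."""

    data: pd.DataFrame
    reference: str
    control: str = CONTROL

    def __post_init__(self) -> None:
        required = {"gene", "treatment", "timepoint", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        if self.reference not in set(self.data["gene"]):
            raise ValueError(f"reference gene {self.reference!r} absent from table")


@dataclass(frozen=True)
class RegulationCall:
    gene: str
    treatment: str
    direction: str          # up | down | nc
    onset: int | None       # 4 or 12 (HAT), None for nc
    recovered: bool         # qualified at 4 HAT but not at 12 HAT


@dataclass(frozen=True)
class ClusterTree:
    """Centroid-linkage dendrogram over genes (scipy-style linkage matrix)."""

    linkage: np.ndarray
    genes: tuple[str, ...]
    excluded: tuple[str, ...]

    def cut(self, k: int) -> dict[str, int]:
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.genes, (int(x) for x in labels)))


def ddct_fold_change(table: CtTable) -> pd.DataFrame:
    """Fold changes 2^-ddCt per gene x (treatment, timepoint).

    dCt is averaged over replicates (mean of per-replicate dCt, not of fold
    changes); ddCt is relative to the control treatment at the same
    timepoint. The control itself and timepoint 0 are not reported. The
    reference gene appears with fold change identically 1.
    """
    df = table.data
    ref = df[df["gene"] == table.reference].set_index(
        ["treatment", "timepoint", "replicate"]
    )["ct"]
    genes = [g for g in df["gene"].unique()]
    treatments = [t for t in df["treatment"].unique() if t != table.control]
    timepoints = sorted(t for t in df["timepoint"].unique() if t != 0)
    if table.control not in set(df["treatment"]):
        raise ValueError(f"control treatment {table.control!r} absent from table")

    def mean_dct(gene: str, treatment: str, timepoint) -> float:
        sel = df[
            (df["gene"] == gene)
            & (df["treatment"] == treatment)
            & (df["timepoint"] == timepoint)
        ]
        if sel.empty:
            raise ValueError(f"no Ct for ({gene}, {treatment}, {timepoint})")
        dcts = []
        for r in sel.itertuples(index=False):
            key = (treatment, timepoint, r.replicate)
            if key not in ref.index:
                raise ValueError(f"missing reference Ct for {key}")
            dcts.append(r.ct - float(ref.loc[key]))
        return float(np.mean(dcts))

    cols = pd.MultiIndex.from_product([treatments, timepoints], names=["treatment", "timepoint"])
    out = pd.DataFrame(index=genes, columns=cols, dtype=float)
    for gene in genes:
        for treatment in treatments:
            for tp in timepoints:
                ddct = mean_dct(gene, treatment, tp) - mean_dct(gene, table.control, tp)
                out.loc[gene, (treatment, tp)] = 2.0 ** (-ddct)
    return out


def call_regulation(
    fc: pd.DataFrame, threshold: float = 2.0
) -> list[RegulationCall]:
    """Direction, onset and recovery calls from a fold-change matrix.

    Up if FC >= threshold at either timepoint, down if FC <= 1/threshold;
    the onset is the earliest qualifying timepoint; a call that qualifies at
    the early timepoint only is flagged recovered. Monotone in FC: raising a
    gene's fold changes can never turn an up call into nc or down.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    calls = []
    treatments = fc.columns.get_level_values(0).unique()
    for gene in fc.index:
        for treatment in treatments:
            tps = sorted(fc[treatment].columns)
            values = {tp: float(fc.loc[gene, (treatment, tp)]) for tp in tps}
            up_at = [tp for tp in tps if values[tp] >= threshold]
            down_at = [tp for tp in tps if values[tp] <= 1.0 / threshold]
            if up_at and (not down_at or up_at[0] <= down_at[0]):
                direction, hits = "up", up_at
            elif down_at:
                direction, hits = "down", down_at
            else:
                calls.append(RegulationCall(gene, treatment, "nc", None, False))
                continue
            onset = hits[0]
            recovered = tps[0] in hits and tps[-1] not in hits and len(tps) > 1
            calls.append(RegulationCall(gene, treatment, direction, onset, recovered))
    return calls


def overlap_summary(
    calls: Sequence[RegulationCall],
    treatments: Sequence[str] = TREATMENTS,
) -> dict[str, dict[str, int]]:
    """Venn region counts of regulated genes across three treatments.

    Returns, per direction (up/down), the seven disjoint region counts keyed
    by '+'-joined treatment combinations. Region counts sum to each
    treatment's marginal count. All calls must share one gene universe.
    """
    if len(treatments) != 3:
        raise ValueError("overlap summary is defined for exactly 3 treatments")
    universe: dict[str, set[str]] = {}
    for c in calls:
        universe.setdefault(c.treatment, set()).add(c.gene)
    present = [t for t in treatments if t in universe]
    if len({frozenset(universe[t]) for t in present}) > 1:
        raise ValueError("treatments cover inconsistent gene universes")
    out: dict[str, dict[str, int]] = {}
    for direction in ("up", "down"):
        sets = {
            t: {c.gene for c in calls if c.treatment == t and c.direction == direction}
            for t in treatments
        }
        a, b, c3 = (sets[t] for t in treatments)
        regions = {
            treatments[0]: a - b - c3,
            treatments[1]: b - a - c3,
            treatments[2]: c3 - a - b,
            f"{treatments[0]}+{treatments[1]}": (a & b) - c3,
            f"{treatments[0]}+{treatments[2]}": (a & c3) - b,
            f"{treatments[1]}+{treatments[2]}": (b & c3) - a,
            "+".join(treatments): a & b & c3,
        }
        out[direction] = {k: len(v) for k, v in regions.items()}
    return out


def _normalize_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    centered = matrix.sub(matrix.mean(axis=1), axis=0)
    rms = np.sqrt((centered**2).mean(axis=1))
    excluded = list(matrix.index[rms == 0])
    if excluded:
        warnings.warn(
            f"excluding zero-variance rows from clustering: {excluded}",
            stacklevel=3,
        )
    keep = centered.loc[rms > 0]
    return keep.div(rms[rms > 0], axis=0), excluded


def _pearson_distance(u: np.ndarray, v: np.ndarray) -> float:
    uc = u - u.mean()
    vc = v - v.mean()
    denom = np.sqrt((uc**2).sum() * (vc**2).sum())
    if denom == 0:
        return 1.0
    return float(1.0 - (uc @ vc) / denom)


def normalize_and_cluster(log2_fc: pd.DataFrame) -> ClusterTree:
    """Cluster-3.0-style gene clustering of a log2 fold-change matrix.

    Rows are mean-centred and scaled to unit RMS, compared by centred Pearson
    correlation (distance 1 - r) and agglomerated with centroid linkage
    (cluster centroid = mean of member rows in normalised space). Merge ties
    break by input order. Zero-variance rows are excluded with a warning.
    """
    if log2_fc.shape[0] < 2 or log2_fc.shape[1] < 2:
        raise ValueError("clustering needs at least 2 genes and 2 conditions")
    norm, excluded = _normalize_rows(log2_fc)
    genes = tuple(norm.index)
    n = len(genes)
    if n < 2:
        raise ValueError("fewer than 2 usable rows after zero-variance exclusion")
    centroids: dict[int, np.ndarray] = {i: norm.iloc[i].to_numpy() for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                i, j = active[ii], active[jj]
                dist = _pearson_distance(centroids[i], centroids[j])
                key = (dist, i, j)
                if best is None or key < best:
                    best = key
        dist, i, j = best
        merged = (
            sizes[i] * centroids[i] + sizes[j] * centroids[j]
        ) / (sizes[i] + sizes[j])
        centroids[next_id] = merged
        sizes[next_id] = sizes[i] + sizes[j]
        Z[step] = [i, j, dist, sizes[next_id]]
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return ClusterTree(linkage=Z, genes=genes, excluded=tuple(excluded))
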